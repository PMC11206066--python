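"""C-score co-occurrence analysis against a binary fixed-margin null.

The C-score is the mean checkerboard value over all OTU pairs,
(R_i - S_ij)(R_j - S_ij), where R are row totals of the incidence matrix
and S_ij the number of samples shared by the pair.  Standardised effect
size SES = (obs - null mean) / null sd; negative SES indicates
aggregation, positive indicates segregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._swaps import quasiswap_binary_matrices
from .core import OTUTable, RunConfig

__all__ = ["AssemblyNullResult", "c_score", "quasiswap_binary", "ses_cscore"]


@dataclass
class AssemblyNullResult:
    """Observed C-score, null summary and standardised effect size."""

    c_score_obs: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when null_sd == 0
    n_null: int
    direction: str  # aggregated | random | segregated
    scope: str = "all"


def to_incidence(counts: np.ndarray, threshold: int = 1) -> np.ndarray:
    """Presence/absence matrix: 1 where count >= threshold."""
    return (np.asarray(counts) >= threshold).astype(np.int64)


def c_score(incidence: np.ndarray) -> float:
    """Mean checkerboard value over all distinct OTU (row) pairs."""
    a = np.asarray(incidence, dtype=np.int64)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need a 2-D incidence matrix with at least 2 OTUs")
    if not np.isin(a, (0, 1)).all():
        raise ValueError("incidence matrix must be binary")
    r = a.sum(axis=1).astype(float)
    shared = (a @ a.T).astype(float)
    cb = (r[:, None] - shared) * (r[None, :] - shared)
    iu = np.triu_indices(a.shape[0], k=1)
    return float(cb[iu].mean())


def quasiswap_binary(incidence: np.ndarray, n: int, seed: int):
    """Stream of *n* fixed-margin binary null matrices (trial-swap chain)."""
    yield from quasiswap_binary_matrices(incidence, n, seed)


def ses_cscore(
    table: OTUTable,
    config: RunConfig,
    scope: str = "all",
    presence_threshold: int = 1,
) -> AssemblyNullResult:
    """Observed C-score of *table* vs its binary fixed-margin null.

    OTUs absent from every sample in the table are dropped before the
    analysis (their pairs carry no information and they have no margin
    freedom).
    """
    inc = to_incidence(table.counts, presence_threshold)
    inc = inc[inc.sum(axis=1) > 0]
    obs = c_score(inc)
    null_scores = np.array(
        [c_score(m) for m in quasiswap_binary_matrices(inc, config.n_permutations, config.rng_seed)]
    )
    mean = float(null_scores.mean())
    sd = float(null_scores.std(ddof=1)) if len(null_scores) > 1 else 0.0
    if sd > 0:
        ses = (obs - mean) / sd
        direction = "segregated" if ses > 0 else ("aggregated" if ses < 0 else "random")
    else:
        ses = float("nan")
        direction = "random"
    return AssemblyNullResult(
        c_score_obs=obs,
        null_mean=mean,
        null_sd=sd,
        ses=float(ses),
        n_null=len(null_scores),
        direction=direction,
        scope=scope,
    )
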