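"""Levins niche breadth and generalist/neutral/specialist classification.

Breadth of OTU j is B_j = 1 / sum_i P_ij^2 where P_ij is OTU j's relative
abundance in habitat (sample) i, normalised per OTU — each OTU's counts are
divided by that OTU's total across all samples.  Classification compares
the observed breadth with empirical quantiles of its distribution under a
count-quasiswap permutation null that preserves row sums, column sums,
grand total and fill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._swaps import quasiswap_count_matrices
from .core import OTUTable, RunConfig

__all__ = ["NicheClassification", "levins_breadth", "quasiswap_counts", "classify_otus"]

CATEGORIES = ("generalist", "neutral", "specialist")


@dataclass
class NicheClassification:
    """Per-OTU breadth, permutation-null bounds and category."""

    otu_id: str
    B_obs: float
    null_low: float
    null_high: float
    category: str
    n_permutations: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.null_low > self.null_high:
            raise ValueError("null_low > null_high")


def _breadth_from_counts(counts: np.ndarray) -> np.ndarray:
    """B for each row; NaN for all-zero rows."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / totals
        b = 1.0 / np.square(p).sum(axis=1)
    b[totals[:, 0] == 0] = np.nan
    return b


def levins_breadth(table: OTUTable) -> np.ndarray:
    """Levins breadth per OTU, in [1, n_samples]; NaN (with a warning) for
    OTUs absent from every sample."""
    b = _breadth_from_counts(table.counts)
    n_zero = int(np.isnan(b).sum())
    if n_zero:
        warnings.warn(f"{n_zero} all-zero OTU(s): breadth undefined, set to NaN")
    return b


def quasiswap_counts(table: OTUTable, n: int, seed: int):
    """Stream of *n* count-quasiswap permutations of *table*.

    Each permuted table preserves the original's row sums, column sums,
    grand total and fill.
    """
    for mat in quasiswap_count_matrices(table.counts, n, seed):
        yield OTUTable(list(table.otu_ids), list(table.sample_ids), mat)


def classify_otus(table: OTUTable, config: RunConfig) -> list[NicheClassification]:
    """Classify each OTU against the quasiswap null distribution of B.

    Bounds are the empirical alpha/2 and 1 - alpha/2 quantiles of the
    permutation distribution (alpha = 1 - ci_level).  Strictly above the
    upper bound -> generalist, strictly below the lower -> specialist,
    otherwise (ties included) neutral.  All-zero OTUs are excluded.
    """
    b_obs = _breadth_from_counts(table.counts)
    keep = ~np.isnan(b_obs)
    n_perm = config.n_permutations
    null_b = np.empty((n_perm, table.n_otus))
    for i, mat in enumerate(quasiswap_count_matrices(table.counts, n_perm, config.rng_seed)):
        null_b[i] = _breadth_from_counts(mat)
    alpha = 1.0 - config.ci_level
    lo = np.full(table.n_otus, np.nan)
    hi = np.full(table.n_otus, np.nan)
    lo[keep] = np.quantile(null_b[:, keep], alpha / 2.0, axis=0)
    hi[keep] = np.quantile(null_b[:, keep], 1.0 - alpha / 2.0, axis=0)
    results = []
    for j in np.flatnonzero(keep):
        if b_obs[j] > hi[j]:
            cat = "generalist"
        elif b_obs[j] < lo[j]:
            cat = "specialist"
        else:
            cat = "neutral"
        results.append(
            NicheClassification(
                otu_id=table.otu_ids[j],
                B_obs=float(b_obs[j]),
                null_low=float(lo[j]),
                null_high=float(hi[j]),
                category=cat,
                n_permutations=n_perm,
            )
        )
    return results


def classification_frame(results: list[NicheClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "otu_id": [r.otu_id for r in results],
            "B_obs": [r.B_obs for r in results],
            "null_low": [r.null_low for r in results],
            "null_high": [r.null_high for r in results],
            "category": [r.category for r in results],
            "n_permutations": [r.n_permutations for r in results],
        }
    )
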