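"""Redundancy analysis, envfit-style permutation tests, CLR transform and
three-block variance partitioning.

RDA here is the classical linear form: PCA of the fitted values of a
multivariate least-squares regression of the (centred) community matrix on
standardised predictors.  Variance partitioning decomposes Ezekiel-adjusted
R-squared into unique and joint fractions of the topography / light / soil
blocks by inclusion-exclusion; individual fractions can be slightly
negative, which is a known property of adjusted R-squared and is reported
as computed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import OTUTable

__all__ = [
    "RDAResult",
    "VPAResult",
    "clr_transform",
    "rda",
    "envfit",
    "variance_partition",
]


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def clr_transform(table: OTUTable, pseudocount: float = 0.5) -> np.ndarray:
    """Centred log-ratio transform, zeros replaced by *pseudocount*.

    Returns a samples x OTUs matrix; each sample's CLR values sum to zero.
    The pseudocount is added to zero cells only, leaving observed counts
    untouched.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    x = table.counts.T.astype(float)  # samples x OTUs
    x[x == 0] = pseudocount
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _drop_aliased(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily drop columns that are linear combinations of earlier ones."""
    kept_idx: list[int] = []
    aliased: list[str] = []
    for j in range(x.shape[1]):
        cand = x[:, kept_idx + [j]]
        if np.linalg.matrix_rank(cand) > len(kept_idx):
            kept_idx.append(j)
        else:
            aliased.append(names[j])
    if aliased:
        warnings.warn(f"dropping aliased (collinear) predictors: {aliased}")
    return x[:, kept_idx], [names[i] for i in kept_idx], aliased


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

@dataclass
class RDAResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    proportion_constrained: float
    site_scores: np.ndarray = field(repr=False)  # samples x 2
    biplot_scores: pd.DataFrame = field(repr=False)  # predictor x 2 correlations
    predictor_names: list[str] = field(default_factory=list)
    aliased: list[str] = field(default_factory=list)
    envfit_table: pd.DataFrame | None = field(default=None, repr=False)


def rda(response: np.ndarray, predictors: np.ndarray,
        predictor_names: list[str] | None = None) -> RDAResult:
    """Redundancy analysis of *response* (samples x features) on predictors.

    The response is centred and the predictors standardised internally;
    collinear predictors are dropped with a warning and reported in the
    ``aliased`` field.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("response and predictors must have the same number of samples")
    if predictor_names is None:
        predictor_names = [f"X{j}" for j in range(x.shape[1])]
    xs = _standardize(x)
    xs, kept_names, aliased = _drop_aliased(xs, list(predictor_names))
    if n <= xs.shape[1]:
        raise ValueError("need more samples than predictors")
    yc = y - y.mean(axis=0, keepdims=True)

    beta, *_ = np.linalg.lstsq(xs, yc, rcond=None)
    fitted = xs @ beta
    resid = yc - fitted

    total_var = float(np.square(yc).sum())
    u, s, _vt = np.linalg.svd(fitted, full_matrices=False)
    eig_c = (s**2) / (n - 1)
    eig_c = eig_c[eig_c > 1e-12 * max(eig_c.max(initial=0.0), 1.0)]
    _ur, sr, _vr = np.linalg.svd(resid, full_matrices=False)
    eig_u = (sr**2) / (n - 1)
    eig_u = eig_u[eig_u > 1e-12 * max(eig_u.max(initial=0.0), 1.0)]
    prop = float(np.square(fitted).sum()) / total_var if total_var > 0 else 0.0

    n_axes = min(2, len(s))
    site = u[:, :n_axes] * s[:n_axes]
    if site.shape[1] < 2:
        site = np.column_stack([site, np.zeros(n)])
    with np.errstate(invalid="ignore", divide="ignore"):
        biplot = np.corrcoef(np.column_stack([xs, site]).T)[: xs.shape[1], xs.shape[1]:]
    biplot = np.nan_to_num(biplot)
    return RDAResult(
        constrained_eigenvalues=eig_c,
        unconstrained_eigenvalues=eig_u,
        proportion_constrained=prop,
        site_scores=site,
        biplot_scores=pd.DataFrame(biplot, index=kept_names, columns=["RDA1", "RDA2"]),
        predictor_names=kept_names,
        aliased=aliased,
    )


# ---------------------------------------------------------------------------
# envfit
# ---------------------------------------------------------------------------

def envfit(
    ordination_scores: np.ndarray,
    variable: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Squared multiple correlation of *variable* with two ordination axes
    and its permutation p-value.

    The variable (not the scores) is permuted across samples; the p-value
    is (1 + #{perm r2 >= observed}) / (n_perm + 1).
    """
    scores = np.asarray(ordination_scores, dtype=float)
    v = np.asarray(variable, dtype=float)
    n = len(v)
    if scores.shape != (n, 2):
        raise ValueError("ordination_scores must be samples x 2")
    if np.all(v == v[0]):
        return 0.0, 1.0
    q, _ = np.linalg.qr(scores - scores.mean(axis=0, keepdims=True))

    def r2_of(cols: np.ndarray) -> np.ndarray:
        vc = cols - cols.mean(axis=0, keepdims=True)
        proj = q.T @ vc
        return np.square(proj).sum(axis=0) / np.square(vc).sum(axis=0)

    obs = float(r2_of(v[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(v)
    perm_r2 = r2_of(perms)
    p = (1.0 + float((perm_r2 >= obs - 1e-12).sum())) / (n_perm + 1.0)
    return obs, p


def envfit_all(
    ordination_scores: np.ndarray,
    variables: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """envfit for every column of *variables*; independent sub-seeds."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for child, col in zip(ss.spawn(variables.shape[1]), variables.columns):
        r2, p = envfit(ordination_scores, variables[col].to_numpy(),
                       n_perm=n_perm, seed=np.random.default_rng(child))
        rows.append({"variable": col, "r2": r2, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

@dataclass
class VPAResult:
    """Adjusted-R2 fractions for three predictor blocks."""

    fractions: dict[str, float]  # keys: pure_<b>, joint_<a>_<b>, joint_all
    residual: float
    adjusted_r2_by_union: dict[tuple[str, ...], float]
    block_names: tuple[str, str, str]


def _trace_r2(yc: np.ndarray, x: np.ndarray) -> float:
    """Multivariate (trace) R2 of centred response on predictors."""
    beta, *_ = np.linalg.lstsq(x, yc, rcond=None)
    fitted = x @ beta
    return float(np.square(fitted).sum() / np.square(yc).sum())


def _ezekiel(r2: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError("not enough residual degrees of freedom for adjusted R2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def variance_partition(
    response: np.ndarray, blocks: dict[str, np.ndarray]
) -> VPAResult:
    """Partition community variation among three named predictor blocks.

    Ezekiel-adjusted trace R2 is computed for all 7 non-empty unions of
    blocks; unique and joint fractions are obtained by solving the
    inclusion-exclusion system, so every union's adjusted R2 is exactly
    reconstructed from the fractions.
    """
    if len(blocks) != 3:
        raise ValueError("exactly three predictor blocks are required")
    y = np.asarray(response, dtype=float)
    n = y.shape[0]
    names = tuple(blocks.keys())
    mats = {}
    for name, x in blocks.items():
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] == 0:
            raise ValueError(f"block {name!r} is empty")
        if x.shape[1] >= n:
            raise ValueError(f"block {name!r} has as many columns as samples")
        mats[name] = _standardize(x)
    yc = y - y.mean(axis=0, keepdims=True)
    if np.square(yc).sum() == 0:
        raise ValueError("constant response")

    unions = [tuple(c) for r in (1, 2, 3) for c in itertools.combinations(names, r)]
    adj: dict[tuple[str, ...], float] = {}
    for u in unions:
        x = np.column_stack([mats[b] for b in u])
        x, _, _ = _drop_aliased(x, [f"{b}{j}" for b in u for j in range(mats[b].shape[1])])
        adj[u] = _ezekiel(_trace_r2(yc, x), n, x.shape[1])

    # subsets S (of blocks) indexing the 7 disjoint fractions f_S; for any
    # union U, adjR2(U) = sum of f_S over S intersecting U
    subsets = unions  # same 7 non-empty combinations
    a = np.zeros((7, 7))
    for i, u in enumerate(unions):
        for j, s in enumerate(subsets):
            if set(u) & set(s):
                a[i, j] = 1.0
    f = np.linalg.solve(a, np.array([adj[u] for u in unions]))

    fractions: dict[str, float] = {}
    for j, s in enumerate(subsets):
        if len(s) == 1:
            key = f"pure_{s[0]}"
        elif len(s) == 2:
            key = f"joint_{s[0]}_{s[1]}"
        else:
            key = "joint_all"
        fractions[key] = float(f[j])
    residual = 1.0 - adj[tuple(names)]
    return VPAResult(
        fractions=fractions,
        residual=float(residual),
        adjusted_r2_by_union=adj,
        block_names=names,
    )
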