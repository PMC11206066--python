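"""Diversity indices, Kruskal-Wallis group comparisons and Venn-style
shared/unique OTU summaries across bands."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import OTUTable, relative_abundance

__all__ = ["DiversitySummary", "GroupComparison", "shannon", "kruskal_wallis", "venn_shared"]


@dataclass
class DiversitySummary:
    sample_id: str
    richness: int
    shannon: float


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    group_medians: dict[str, float]
    grouping: str


def shannon(table: OTUTable) -> list[DiversitySummary]:
    """Shannon-Wiener index (natural log) and richness per sample."""
    rel = relative_abundance(table, axis="per_sample")
    out = []
    for j, sid in enumerate(table.sample_ids):
        p = rel[:, j]
        p = p[p > 0]
        h = float(-(p * np.log(p)).sum())
        out.append(DiversitySummary(sample_id=sid, richness=int(len(p)), shannon=h))
    return out


def diversity_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in summaries],
            "richness": [s.richness for s in summaries],
            "shannon": [s.shannon for s in summaries],
        }
    )


def kruskal_wallis(values, groups, grouping: str = "group") -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) with chi-squared p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    medians = {str(g): float(np.median(s)) for g, s in zip(labels, samples)}
    if np.all(values == values[0]):
        return GroupComparison(0.0, 1.0, medians, grouping)
    h, p = sps.kruskal(*samples)
    return GroupComparison(float(h), float(p), medians, grouping)


_REGIONS = (
    ("100", (True, False, False)),
    ("010", (False, True, False)),
    ("001", (False, False, True)),
    ("110", (True, True, False)),
    ("101", (True, False, True)),
    ("011", (False, True, True)),
    ("111", (True, True, True)),
)


def venn_shared(
    table: OTUTable,
    bands: pd.Series | dict,
    categories: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Venn region counts of OTU presence across exactly three bands.

    An OTU is present in a band when its count is > 0 in at least one
    sample of that band.  If *categories* (otu_id, category) is given, the
    summary is repeated per niche category in addition to all OTUs.
    Returns one row per (category, region) plus per-category totals and
    the fraction shared by all three bands.
    """
    bands = pd.Series(bands)
    band_names = sorted(bands.unique(), key=list(bands).index)  # stable order
    if len(band_names) != 3:
        raise ValueError(f"exactly 3 bands required, got {band_names}")
    for b in band_names:
        if (bands == b).sum() == 0:
            raise ValueError(f"band {b!r} has no samples")
    sample_idx = {s: i for i, s in enumerate(table.sample_ids)}
    presence = {}
    for b in band_names:
        cols = [sample_idx[s] for s in bands.index[bands == b]]
        presence[b] = table.counts[:, cols].sum(axis=1) > 0

    groups: dict[str, np.ndarray] = {"all": np.ones(table.n_otus, dtype=bool)}
    if categories is not None:
        cat_of = dict(zip(categories["otu_id"], categories["category"]))
        cat_vec = np.array([cat_of.get(o, "unclassified") for o in table.otu_ids])
        for cat in ("generalist", "neutral", "specialist"):
            groups[cat] = cat_vec == cat

    rows = []
    for gname, mask in groups.items():
        in_any = mask & (presence[band_names[0]] | presence[band_names[1]] | presence[band_names[2]])
        total = int(in_any.sum())
        for region, pattern in _REGIONS:
            sel = mask.copy()
            for b, want in zip(band_names, pattern):
                sel &= presence[b] == want
            rows.append(
                {
                    "category": gname,
                    "region": region,
                    "bands": "&".join(b for b, w in zip(band_names, pattern) if w),
                    "count": int(sel.sum()),
                    "total_present": total,
                    "fraction": (int(sel.sum()) / total) if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def shared_fraction(venn: pd.DataFrame, category: str = "all") -> float:
    """Fraction of a category's OTUs present in all three bands."""
    row = venn[(venn["category"] == category) & (venn["region"] == "111")]
    if row.empty:
        raise ValueError(f"category {category!r} not in Venn table")
    return float(row["fraction"].iloc[0])
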