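"""Synthetic community generator with known ground truth.

The backbone is a neutral assembly process whose per-sample compositions
are Dirichlet with concentration N * m * p (p = metacommunity relative
abundances), so each taxon's local relative abundance is marginally
Beta(N*m*p_i, N*m*(1-p_i)) — exactly the law the Sloan neutral fit
assumes.  Reads are then drawn multinomially with a fixed per-sample
total.  On top of the backbone, designated specialists are restricted to
one elevation band and designated generalists are spread evenly across all
samples, giving every downstream classifier a known answer.  Environmental
covariates are linear functions of elevation plus Gaussian noise, with
elevation drawn from non-overlapping per-band ranges so the planted band
breakpoints are recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import OTUTable, SampleMetadata

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "simulate_neutral_community",
    "plant_niche_structure",
    "simulate_metadata",
    "simulate_dataset",
]

_BAND_LABELS = ("LEG", "MEG", "HEG")

# study-design proportions: 767 generalists / 6753 neutral / 5332 specialists
_DEFAULT_FRAC_GENERALIST = 767 / 12852
_DEFAULT_FRAC_SPECIALIST = 5332 / 12852


@dataclass
class SynthSpec:
    """Parameters of the synthetic study design."""

    n_samples: int = 120
    band_sizes: tuple[int, ...] = (49, 27, 44)
    n_otus: int = 2000
    reads_per_sample: int = 500
    m_true: float = 0.3
    frac_specialist: float = 0.10
    frac_generalist: float = 0.06
    metacommunity_shape: str = "lognormal"
    lognormal_sigma: float = 1.0
    light_effect: float = 1.0
    soil_effect: float = 1.0
    covariate_noise: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.band_sizes) != self.n_samples:
            raise ValueError("band_sizes must sum to n_samples")
        if not (0.0 < self.m_true <= 1.0):
            raise ValueError("m_true must be in (0, 1]")
        for name in ("frac_specialist", "frac_generalist"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_specialist + self.frac_generalist > 1.0:
            raise ValueError("category fractions sum to more than 1")
        if self.metacommunity_shape not in ("lognormal", "logseries"):
            raise ValueError(f"unknown metacommunity_shape {self.metacommunity_shape!r}")

    @property
    def band_labels(self) -> tuple[str, ...]:
        if len(self.band_sizes) == 3:
            return _BAND_LABELS
        return tuple(f"L{i + 1}" for i in range(len(self.band_sizes)))

    @classmethod
    def study_design(cls, rng_seed: int = 0) -> "SynthSpec":
        """Full-size design: 120 samples in 49/27/44 bands, ~12,852 OTUs
        with the study's generalist/neutral/specialist proportions.

        Heavy — intended for full-scale runs, not the test suite; note
        that planted categories this dense are at the edge of what a
        fill-preserving permutation null can resolve.
        """
        return cls(
            n_otus=12852,
            reads_per_sample=2000,
            frac_generalist=_DEFAULT_FRAC_GENERALIST,
            frac_specialist=_DEFAULT_FRAC_SPECIALIST,
            rng_seed=rng_seed,
        )


@dataclass
class GroundTruth:
    """Per-OTU categories, per-sample bands and planted parameters."""

    category: np.ndarray  # one of generalist/neutral/specialist per OTU
    band: list[str]  # per sample
    m_true: float
    breakpoints: list[float] = field(default_factory=list)
    specialist_band: dict[str, str] = field(default_factory=dict)
    metacommunity_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        bad = set(np.unique(self.category)) - {"generalist", "neutral", "specialist"}
        if bad:
            raise ValueError(f"unknown categories {bad}")

    def to_frame(self, otu_ids: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "otu_id": otu_ids,
                "category": self.category,
                "specialist_band": [self.specialist_band.get(o, "") for o in otu_ids],
            }
        )


def _rng(spec: SynthSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.rng_seed), stage])


def _metacommunity(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.metacommunity_shape == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=spec.lognormal_sigma, size=spec.n_otus)
    else:
        raw = rng.logseries(0.995, size=spec.n_otus).astype(float)
    return raw / raw.sum()


def simulate_neutral_community(spec: SynthSpec) -> tuple[OTUTable, GroundTruth]:
    """Neutral Dirichlet-multinomial community; all OTUs labelled neutral."""
    rng = _rng(spec, 0)
    p = _metacommunity(spec, rng)
    n_reads = spec.reads_per_sample
    alpha = n_reads * spec.m_true * p
    gammas = rng.gamma(np.broadcast_to(alpha, (spec.n_samples, spec.n_otus)))
    totals = gammas.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    comps = gammas / totals
    counts = np.empty((spec.n_otus, spec.n_samples), dtype=np.int64)
    for s in range(spec.n_samples):
        counts[:, s] = rng.multinomial(n_reads, comps[s])
    otu_ids = [f"OTU{i + 1:05d}" for i in range(spec.n_otus)]
    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    table = OTUTable(otu_ids, sample_ids, counts)
    bands = [
        label for label, size in zip(spec.band_labels, spec.band_sizes) for _ in range(size)
    ]
    truth = GroundTruth(
        category=np.array(["neutral"] * spec.n_otus, dtype=object),
        band=bands,
        m_true=spec.m_true,
        metacommunity_p=p,
    )
    return table, truth


def plant_niche_structure(
    table: OTUTable, truth: GroundTruth, spec: SynthSpec
) -> tuple[OTUTable, GroundTruth]:
    """Plant detectable generalists and specialists on a neutral backbone.

    Specialists keep their counts inside one assigned band and are zeroed
    elsewhere; generalists get their total spread as evenly as integers
    allow over all samples.  Candidate OTUs are the most abundant ones (a
    planted label on a near-singleton OTU would be undetectable in
    principle).  Neutral OTU counts are redrawn multinomially from their
    mean composition so that every sample total equals reads_per_sample
    exactly and neutral labels mean "no habitat association".
    """
    n_spec = round(spec.frac_specialist * table.n_otus)
    n_gen = round(spec.frac_generalist * table.n_otus)
    if n_spec + n_gen > table.n_otus:
        raise ValueError("category fractions exceed available OTUs")
    if n_spec == 0 and n_gen == 0:
        return table, truth
    rng = _rng(spec, 1)
    counts = table.counts.copy()
    totals = counts.sum(axis=1)
    pool = np.argsort(-totals, kind="stable")[: n_spec + n_gen]
    pool = rng.permutation(pool)
    spec_idx = pool[:n_spec]
    gen_idx = pool[n_spec : n_spec + n_gen]

    bands = np.asarray(truth.band)
    band_labels = list(spec.band_labels)
    category = truth.category.copy()
    specialist_band: dict[str, str] = {}

    for rank, i in enumerate(spec_idx):
        b = band_labels[rank % len(band_labels)]
        outside = bands != b
        counts[i, outside] = 0
        category[i] = "specialist"
        specialist_band[table.otu_ids[i]] = b

    n_samples = table.n_samples
    for i in gen_idx:
        t = int(totals[i])
        base, rem = divmod(t, n_samples)
        row = np.full(n_samples, base, dtype=np.int64)
        if rem:
            row[rng.choice(n_samples, size=rem, replace=False)] += 1
        counts[i] = row
        category[i] = "generalist"

    planted = np.zeros(table.n_otus, dtype=bool)
    planted[spec_idx] = True
    planted[gen_idx] = True
    target = spec.reads_per_sample
    planted_totals = counts[planted].sum(axis=0)
    for _ in range(50):
        deficit = planted_totals - target
        if (deficit <= 0).all():
            break
        # planted mass exceeds the per-sample budget: thin generalists
        for i in gen_idx:
            counts[i] = counts[i] * 9 // 10
        planted_totals = counts[planted].sum(axis=0)
    else:
        raise ValueError("planted structure exceeds per-sample read budget")

    # neutral rows are redrawn from their mean composition: planted-table
    # "neutral" means no habitat association, i.e. exchangeable across
    # samples, which is what the classification null tests against
    neutral_idx = np.flatnonzero(~planted)
    neutral_totals = totals[neutral_idx].astype(float)
    if neutral_totals.sum() > 0:
        probs = neutral_totals / neutral_totals.sum()
    else:
        probs = np.full(len(neutral_idx), 1.0 / len(neutral_idx))
    for s in range(n_samples):
        need = target - int(planted_totals[s])
        counts[neutral_idx, s] = rng.multinomial(need, probs)

    new_table = OTUTable(list(table.otu_ids), list(table.sample_ids), counts)
    new_truth = GroundTruth(
        category=category,
        band=list(truth.band),
        m_true=truth.m_true,
        breakpoints=list(truth.breakpoints),
        specialist_band=specialist_band,
        metacommunity_p=truth.metacommunity_p,
    )
    return new_table, new_truth


# covariate model: (intercept, slope on standardised elevation, noise sd,
# lower bound, upper bound, block)
_COVARIATE_MODEL = {
    "ALA": (40.0, 8.0, 3.0, 0.0, 90.0, "light"),
    "CC": (0.70, -0.08, 0.05, 0.0, 1.0, "light"),
    "TR": (1200.0, 150.0, 80.0, 0.0, np.inf, "light"),
    "SR": (500.0, 60.0, 40.0, 0.0, np.inf, "light"),
    "DR": (700.0, 90.0, 60.0, 0.0, np.inf, "light"),
    "LT": (0.25, 0.05, 0.04, 0.0, 1.0, "light"),
    "LAI": (3.5, -0.5, 0.3, 0.0, np.inf, "light"),
    "soil_pH": (5.5, 0.4, 0.2, 3.0, 9.0, "soil"),
    "organic_matter": (0.050, 0.010, 0.005, 0.0, 1.0, "soil"),
    "alkaline_N": (0.012, 0.002, 0.001, 0.0, 1.0, "soil"),
    "available_P": (0.008, -0.001, 0.0008, 0.0, 1.0, "soil"),
    "water_content": (0.30, 0.05, 0.03, 0.0, 1.0, "soil"),
}

_BAND_RANGE_BASE = 1000.0
_BAND_RANGE_WIDTH = 180.0
_BAND_RANGE_STEP = 240.0  # leaves a 60 m gap between consecutive bands


def simulate_metadata(spec: SynthSpec, truth: GroundTruth) -> list[SampleMetadata]:
    """Elevation-structured covariates with planted band breakpoints.

    Elevation (MEA) is uniform within non-overlapping per-band ranges; the
    planted breakpoints (midpoints of the inter-band gaps) are stored in
    ``truth.breakpoints``.  Light and soil covariates are linear in
    standardised elevation, scaled by the block effect sizes, plus noise
    scaled by ``covariate_noise``; bounded covariates are clipped.
    """
    rng = _rng(spec, 2)
    bands = truth.band
    labels = list(spec.band_labels)
    band_index = {b: i for i, b in enumerate(labels)}
    lo = np.array([_BAND_RANGE_BASE + _BAND_RANGE_STEP * band_index[b] for b in bands])
    mea = lo + rng.uniform(0.0, _BAND_RANGE_WIDTH, size=len(bands))
    truth.breakpoints = [
        _BAND_RANGE_BASE + _BAND_RANGE_STEP * i - (_BAND_RANGE_STEP - _BAND_RANGE_WIDTH) / 2.0
        for i in range(1, len(labels))
    ]
    z = (mea - mea.mean()) / mea.std()

    n = len(bands)
    cov = {"MEA": mea}
    cov["CON"] = rng.normal(0.0, 1.0, size=n)
    cov["SLO"] = rng.uniform(5.0, 40.0, size=n)
    cov["ASP"] = rng.uniform(0.0, 360.0, size=n)
    for name, (icpt, slope, noise_sd, lo_b, hi_b, block) in _COVARIATE_MODEL.items():
        effect = spec.light_effect if block == "light" else spec.soil_effect
        vals = icpt + slope * effect * z + noise_sd * spec.covariate_noise * rng.normal(size=n)
        cov[name] = np.clip(vals, lo_b, hi_b)

    records = []
    for s in range(n):
        records.append(
            SampleMetadata(
                sample_id=f"S{s + 1:03d}",
                band=bands[s],
                **{k: float(v[s]) for k, v in cov.items()},
            )
        )
    return records


def simulate_dataset(spec: SynthSpec) -> tuple[OTUTable, list[SampleMetadata], GroundTruth]:
    """Full synthetic dataset: neutral backbone, planted niche structure,
    elevation-structured metadata."""
    table, truth = simulate_neutral_community(spec)
    table, truth = plant_niche_structure(table, truth, spec)
    metadata = simulate_metadata(spec, truth)
    return table, metadata, truth
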