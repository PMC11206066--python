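"""End-to-end orchestration: simulate or load data, band the elevation
gradient with an MRT, then run niche classification, the neutral model,
C-score nulls, diversity statistics and RDA/envfit/VPA overall and per
band, writing TSV outputs and a JSON manifest."""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    COVARIATE_BLOCKS,
    OTUTable,
    RunConfig,
    metadata_frame,
    read_metadata,
    read_otu_table,
    write_manifest,
    write_metadata,
    write_otu_table,
)
from .cooccur import ses_cscore
from .mrt import assign_bands, grow_mrt, hellinger, prune_mrt
from .neutral import fit_ncm
from .niche import classification_frame, classify_otus
from .ordination import envfit_all, rda, variance_partition
from .simulate import SynthSpec, simulate_dataset
from .stats import diversity_frame, kruskal_wallis, shannon, venn_shared

logger = logging.getLogger("ecoassembly")

__all__ = ["PipelineManifest", "run_all"]


def stage_seed(base_seed: int, stage: int) -> int:
    """Deterministic independent sub-seed for a pipeline stage."""
    return int(np.random.SeedSequence([int(base_seed), stage]).generate_state(1)[0])


@dataclass
class PipelineManifest:
    seed: int
    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # filename -> sha256
    started: float = 0.0
    finished: float = 0.0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "version": self.version,
            "stages": self.stages,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: PipelineManifest) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest.outputs[path.name] = _sha256(path)


class _Stage:
    def __init__(self, manifest: PipelineManifest, name: str):
        self.manifest = manifest
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is not None:
            logger.error("stage %s: FAILED after %.1fs", self.name, dt)
            raise RuntimeError(f"pipeline stage {self.name!r} failed") from exc
        self.manifest.stages.append({"name": self.name, "seconds": round(dt, 3)})
        logger.info("stage %s: done in %.1fs", self.name, dt)
        return False


def run_all(
    config: RunConfig,
    spec: SynthSpec | None = None,
) -> PipelineManifest:
    """Run the full analysis; returns the manifest (also written to disk).

    Data come either from ``config.otu_table_path``/``metadata_path`` or
    from a synthetic *spec* (seeded from the config seed).  Output TSVs are
    pure functions of (inputs, seed, config); the manifest additionally
    records wall-clock timings.
    """
    outdir = Path(config.outdir or "ecoassembly_run")
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = PipelineManifest(
        seed=config.rng_seed, config=config.to_dict(), version=__version__,
        started=time.time(),
    )

    # -- load or simulate ------------------------------------------------
    truth = None
    with _Stage(manifest, "data"):
        if config.otu_table_path:
            table = read_otu_table(config.otu_table_path)
            metadata = (
                read_metadata(config.metadata_path, table) if config.metadata_path else []
            )
        else:
            if spec is None:
                spec = SynthSpec(rng_seed=config.rng_seed)
            table, metadata, truth = simulate_dataset(spec)
            write_otu_table(table, outdir / "otu_table.tsv")
            write_metadata(metadata, outdir / "metadata.tsv")
            truth.to_frame(table.otu_ids).to_csv(
                outdir / "ground_truth.tsv", sep="\t", index=False
            )
            for name in ("otu_table.tsv", "metadata.tsv", "ground_truth.tsv"):
                manifest.outputs[name] = _sha256(outdir / name)
    meta_df = metadata_frame(metadata) if metadata else pd.DataFrame()
    if not meta_df.empty:
        meta_df = meta_df.set_index("sample_id").loc[table.sample_ids].reset_index()

    # -- MRT banding -----------------------------------------------------
    hell = hellinger(table.counts)  # samples x OTUs
    bands = None
    with _Stage(manifest, "mrt"):
        if not meta_df.empty and meta_df["MEA"].notna().all():
            mea = meta_df["MEA"].to_numpy(dtype=float)
            model = grow_mrt(hell, mea, "MEA")
            model = prune_mrt(model, hell, mea, k_folds=10, seed=stage_seed(config.rng_seed, 1))
            bands = assign_bands(model, mea, table.sample_ids)
            _write(
                pd.DataFrame({"threshold": model.thresholds(), "variable": "MEA"}),
                outdir / "mrt_splits.tsv", manifest,
            )
            if model.cv_table is not None:
                _write(model.cv_table, outdir / "mrt_cv.tsv", manifest)
            _write(
                pd.DataFrame({"sample_id": table.sample_ids, "band": bands.to_numpy()}),
                outdir / "bands.tsv", manifest,
            )
        elif not meta_df.empty and meta_df.get("band") is not None and meta_df["band"].notna().all():
            bands = pd.Series(meta_df["band"].to_numpy(), index=table.sample_ids, name="band")
            logger.info("no MEA column: using band labels from metadata")
        else:
            logger.warning("no elevation or band information: per-band stages skipped")

    scopes: list[tuple[str, OTUTable]] = [("all", table)]
    if bands is not None:
        for b in pd.unique(bands):
            ids = [s for s in table.sample_ids if bands[s] == b]
            if len(ids) >= 5:
                scopes.append((str(b), table.subset_samples(ids)))

    # -- niche classification -------------------------------------------
    with _Stage(manifest, "niche"):
        niche_frames = []
        for k, (scope, sub) in enumerate(scopes):
            cfg = RunConfig(
                rng_seed=stage_seed(config.rng_seed, 100 + k),
                n_permutations=config.n_permutations,
                ci_level=config.ci_level,
            )
            frame = classification_frame(classify_otus(sub, cfg))
            frame.insert(0, "scope", scope)
            niche_frames.append(frame)
        niche_df = pd.concat(niche_frames, ignore_index=True)
        _write(niche_df, outdir / "niche_classification.tsv", manifest)
    niche_all = niche_df[niche_df["scope"] == "all"]

    # -- neutral model ---------------------------------------------------
    with _Stage(manifest, "ncm"):
        summaries, per_otu_frames = [], []
        for scope, sub in scopes:
            fit = fit_ncm(sub, config)
            frac = fit.partition_fractions
            summaries.append(
                {
                    "scope": scope, "m": fit.m, "N": fit.N, "Nm": fit.Nm,
                    "r_squared": fit.r_squared, "detection_limit": fit.detection_limit,
                    "frac_above": frac["above"], "frac_within": frac["within"],
                    "frac_below": frac["below"], "boundary_flag": fit.boundary_flag,
                }
            )
            po = fit.per_otu.copy()
            po.insert(0, "scope", scope)
            per_otu_frames.append(po)
        _write(pd.DataFrame(summaries), outdir / "ncm_summary.tsv", manifest)
        _write(pd.concat(per_otu_frames, ignore_index=True), outdir / "ncm_per_otu.tsv", manifest)

    # -- C-score / SES ---------------------------------------------------
    with _Stage(manifest, "cscore"):
        rows = []
        for k, (scope, sub) in enumerate(scopes):
            cfg = RunConfig(
                rng_seed=stage_seed(config.rng_seed, 200 + k),
                n_permutations=config.n_permutations,
            )
            res = ses_cscore(sub, cfg, scope=scope)
            rows.append(
                {
                    "scope": scope, "c_score_obs": res.c_score_obs,
                    "null_mean": res.null_mean, "null_sd": res.null_sd,
                    "ses": res.ses, "n_null": res.n_null, "direction": res.direction,
                }
            )
        _write(pd.DataFrame(rows), outdir / "cscore.tsv", manifest)

    # -- diversity & group stats ----------------------------------------
    with _Stage(manifest, "stats"):
        div = diversity_frame(shannon(table))
        _write(div, outdir / "diversity.tsv", manifest)
        if bands is not None:
            band_vec = bands.loc[div["sample_id"]].to_numpy()
            kw_rows = []
            for metric in ("shannon", "richness"):
                cmp = kruskal_wallis(div[metric].to_numpy(), band_vec, grouping="band")
                kw_rows.append(
                    {
                        "metric": metric, "statistic": cmp.statistic, "p_value": cmp.p_value,
                        **{f"median_{g}": v for g, v in cmp.group_medians.items()},
                    }
                )
            _write(pd.DataFrame(kw_rows), outdir / "kruskal_wallis.tsv", manifest)
            if len(pd.unique(bands)) == 3:
                venn = venn_shared(table, bands, categories=niche_all)
                _write(venn, outdir / "venn.tsv", manifest)

    # -- ordination / envfit / VPA --------------------------------------
    blocks_present = (
        not meta_df.empty
        and all(
            c in meta_df.columns and meta_df[c].notna().all()
            for cols in COVARIATE_BLOCKS.values()
            for c in cols
        )
    )
    with _Stage(manifest, "ordination"):
        if not blocks_present:
            logger.warning("metadata blocks incomplete: RDA/envfit/VPA skipped")
        else:
            env_cols = [c for cols in COVARIATE_BLOCKS.values() for c in cols]
            env = meta_df[env_cols]
            result = rda(hell, env.to_numpy(), env_cols)
            eig_rows = [
                {"component": f"RDA{i + 1}", "eigenvalue": e, "constrained": True}
                for i, e in enumerate(result.constrained_eigenvalues)
            ] + [
                {"component": f"PC{i + 1}", "eigenvalue": e, "constrained": False}
                for i, e in enumerate(result.unconstrained_eigenvalues)
            ]
            eig_df = pd.DataFrame(eig_rows)
            eig_df["proportion_constrained"] = result.proportion_constrained
            _write(eig_df, outdir / "rda_eigenvalues.tsv", manifest)
            env_table = envfit_all(
                result.site_scores, env,
                n_perm=config.envfit_permutations,
                seed=stage_seed(config.rng_seed, 300),
            )
            _write(env_table, outdir / "envfit.tsv", manifest)

            vpa_rows = []
            n_env_cols = len(env_cols)
            for scope, sub in scopes:
                if sub.n_samples <= n_env_cols + 1:
                    logger.warning(
                        "VPA skipped for scope %s: %d samples <= %d predictors",
                        scope, sub.n_samples, n_env_cols,
                    )
                    continue
                sub_meta = meta_df.set_index("sample_id").loc[sub.sample_ids]
                blocks = {
                    name: sub_meta[cols].to_numpy() for name, cols in COVARIATE_BLOCKS.items()
                }
                vres = variance_partition(hellinger(sub.counts), blocks)
                row = {"scope": scope, **vres.fractions, "residual": vres.residual}
                vpa_rows.append(row)
            _write(pd.DataFrame(vpa_rows), outdir / "vpa.tsv", manifest)

    manifest.finished = time.time()
    write_manifest(outdir / "manifest.json", manifest.to_dict())
    return manifest
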