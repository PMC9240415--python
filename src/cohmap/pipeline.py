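"""End-to-end orchestration: coherence scoring -> group statistics ->
lesion-symptom mapping, with a YAML-configurable entry point."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .behavioural_stats import (executive_only_regression, mixed_anova,
                                regression_report, staged_regressions)
from .coherence import deficit_table, score_cohort
from .io import read_lesion_stack, read_manifest, write_statmap
from .lesion_mapping import svr_lsm, vbcm
from .semantic_space import load_space
from .stoplist import DEFAULT_STOPLIST, load_stoplist, stoplist_hash

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`."""

    manifest: str
    space: str
    out_dir: str
    components: str | None = None
    images_dir: str | None = None
    covariates: str | None = None
    stoplist_path: str | None = None
    composition: str = "instance"
    alpha: float = 0.05
    lsm_mode: str = "vbcm"            # "vbcm" | "svr" | "both"
    n_perm: int = 1000
    voxel_p: float | None = None      # default depends on mode
    cluster_p: float = 0.05
    lesion_threshold: int = 4
    connectivity: int = 26
    control_volume: bool = False
    fwhm_mm: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for name in ("manifest", "space"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ValueError(f"config: {name} path does not exist: {p}")
        for name in ("components", "images_dir", "covariates", "stoplist_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config: {name} path does not exist: {p}")
        if self.lsm_mode not in ("vbcm", "svr", "both"):
            raise ValueError("lsm_mode must be vbcm, svr or both")
        if self.images_dir is not None and self.covariates is None:
            raise ValueError("lesion mapping requires a covariates CSV")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the report directory.

    Always: score the cohort (scores.csv, composite.csv, deficits.csv) and
    run the mixed ANOVA. If a components CSV is configured: staged
    regressions. If an images directory is configured: lesion mapping in the
    configured mode. A run log records the seed, stoplist hash and library
    versions. Deterministic under a fixed seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stoplist = (load_stoplist(config.stoplist_path)
                if config.stoplist_path else DEFAULT_STOPLIST)
    runlog: dict = {
        "cohmap_version": __version__,
        "seed": config.seed,
        "stoplist_sha256": stoplist_hash(frozenset(stoplist)),
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
    }

    try:
        stage = "coherence"
        records = read_manifest(config.manifest)
        space = load_space(config.space)
        scores = score_cohort(records, space, stoplist=stoplist,
                              composition=config.composition)
        composite = scores.attrs["composite"]
        scores_out = deficit_table(scores)
        scores_out.to_csv(out / "scores.csv", index=False)
        composite.to_csv(out / "composite.csv", index=False)

        stage = "anova"
        effects, contrasts = mixed_anova(scores)
        anova_rows = [{
            "effect": e.effect, "F": e.F, "df1": e.df[0], "df2": e.df[1],
            "p": e.p, "partial_eta_sq": e.partial_eta_sq, "p_gg": e.p_gg,
        } for e in effects]
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
        if contrasts is not None:
            contrasts.to_csv(out / "task_contrasts.csv", index=False)

        if config.components is not None:
            stage = "regressions"
            comps = pd.read_csv(config.components)
            patients = composite[composite["group"] == "patient"]
            merged = patients.merge(comps, on="participant_id", how="inner")
            y = merged["composite_coherence"]
            results = staged_regressions(y, merged)
            results.append(executive_only_regression(y, merged))
            regression_report(results).to_csv(out / "regressions.csv", index=False)

        if config.images_dir is not None:
            stage = "lesion_mapping"
            covs = pd.read_csv(config.covariates)
            patients = composite[composite["group"] == "patient"].reset_index(drop=True)
            merged = patients.merge(covs, on="participant_id", how="inner")
            behaviour = merged["composite_coherence"].to_numpy()
            cov_cols = [c for c in merged.columns
                        if c not in ("participant_id", "group", "composite_coherence")]
            ds = read_lesion_stack(config.images_dir, behaviour, merged[cov_cols])
            if config.lsm_mode in ("vbcm", "both"):
                vp = config.voxel_p if config.voxel_p is not None else 0.001
                smap, cset = vbcm(ds, voxel_p=vp, cluster_p=config.cluster_p,
                                  n_perm=config.n_perm,
                                  connectivity=config.connectivity,
                                  control_volume=config.control_volume,
                                  seed=config.seed)
                write_statmap(smap, cset, out, "vbcm", ds.affine, ds.voxel_size)
            if config.lsm_mode in ("svr", "both"):
                vp = config.voxel_p if config.voxel_p is not None else 0.005
                smap, cset = svr_lsm(ds, lesion_threshold=config.lesion_threshold,
                                     voxel_p=vp, cluster_p=config.cluster_p,
                                     n_perm=config.n_perm,
                                     connectivity=config.connectivity,
                                     control_volume=config.control_volume,
                                     seed=config.seed)
                write_statmap(smap, cset, out, "svr", ds.affine, ds.voxel_size)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "run_log.json").write_text(json.dumps(runlog, indent=1, default=str),
                                      encoding="utf-8")
    return out
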