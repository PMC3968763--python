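"""End-to-end orchestration: features -> clustering -> selection -> contrast -> association.

A run is fully described by a :class:`RunConfig` (loadable from YAML) and
writes a directory of CSV tables plus a run log. Reruns with the same
config and seeds are bit-identical for all deterministic stages.

Emitted tables: ``features.csv``, ``clusters.csv``, ``adaptor_sets.csv``,
``contrast.csv``, ``contrast_summary.csv``, ``spearman_table.csv`` (one row
per "c/k" cluster x property for every k in the configured range, plus the
"average evaluation" row), ``regression.csv`` (standardized betas for the
beauty and contrast responses) and ``mixed_model.csv``.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, clustering, contrast, features, ratings, synth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "artstats_run"
    seed: int = 0
    # image source: a manifest CSV or a synthetic collection
    manifest: str | None = None
    n_images: int = 150
    image_size: tuple[int, int] = (256, 256)
    # ratings source: a long CSV (baseline + adaptation phases) or simulation
    ratings_csv: str | None = None
    population: synth.PopulationSpec = field(default_factory=synth.PopulationSpec)
    # analysis options
    pixel_budget: int | None = 100_000
    k: int = 7
    k_range: tuple[int, ...] = (3, 4, 5, 6, 7)
    n_adapt: int = 15
    n_eval: int = 60
    ss_aggregate: str = "median"
    anisotropy_pooling: str = "pooled"
    circular_hue: bool = False

    def __post_init__(self) -> None:
        bad = [k for k in (*self.k_range, self.k) if not 2 <= k <= 10]
        if bad:
            raise ValueError(f"cluster counts outside [2, 10]: {bad}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pop_raw = raw.pop("population", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if pop_raw:
            for key in ("cluster_sizes", "intercepts", "inverted_clusters"):
                if key in pop_raw:
                    pop_raw[key] = tuple(pop_raw[key])
            if "weights" in pop_raw:
                pop_raw["weights"] = tuple(pop_raw["weights"])
            cfg.population = synth.PopulationSpec(**pop_raw)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_full_analysis(cfg: RunConfig) -> dict[str, object]:
    """Execute the full pipeline and write its tables under ``cfg.out_dir``.

    Any stage failure aborts with a stage-tagged error; tables written by
    earlier stages are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed: {cfg.seed}", f"python: {sys.version.split()[0]}"]
    for mod in ("numpy", "scipy", "pandas", "sklearn", "skimage", "statsmodels"):
        try:
            log_lines.append(f"{mod}: {__import__(mod).__version__}")
        except Exception:  # pragma: no cover
            pass
    results: dict[str, object] = {}

    def _stage(name: str):
        logger.info("stage: %s", name)
        log_lines.append(f"stage: {name}")

    # --- features ---------------------------------------------------------
    _stage("features")
    try:
        opts = dict(
            pixel_budget=cfg.pixel_budget,
            ss_aggregate=cfg.ss_aggregate,
            anisotropy_pooling=cfg.anisotropy_pooling,
            circular_hue=cfg.circular_hue,
        )
        if cfg.manifest:
            feats = features.compute_features_from_manifest(cfg.manifest, **opts)
        else:
            images, truth = synth.generate_image_collection(
                cfg.n_images, seed=cfg.seed, size=cfg.image_size
            )
            feats = features.compute_all_features(images, **opts)
            truth.to_csv(out / "generator_truth.csv")
        feats.to_csv(out / "features.csv")
        results["features"] = feats
    except Exception as exc:
        _write_log(out, log_lines, f"ABORT in features: {exc}")
        raise StageError("features", exc) from exc

    # --- ratings ----------------------------------------------------------
    _stage("ratings")
    try:
        if cfg.ratings_csv:
            baseline = ratings.load_ratings(cfg.ratings_csv, phase="baseline")
            true_clusters = None
        else:
            baseline, true_clusters = synth.simulate_baseline_ratings(
                feats, cfg.population, seed=cfg.seed + 1
            )
        results["baseline"] = baseline
    except Exception as exc:
        _write_log(out, log_lines, f"ABORT in ratings: {exc}")
        raise StageError("ratings", exc) from exc

    # --- clustering + selection ------------------------------------------
    _stage("clustering")
    try:
        sol = clustering.cluster_raters(baseline, k=cfg.k, seed=cfg.seed)
        cl = sol.assignment.rename("cluster").to_frame()
        if true_clusters is not None:
            cl["true_cluster"] = true_clusters
        cl.to_csv(out / "clusters.csv")
        sol.diagnostics.to_csv(out / "cluster_diagnostics.csv")
        means = clustering.cluster_mean_ratings(baseline, sol)
        sets = clustering.select_adaptor_sets(means, n_adapt=cfg.n_adapt, n_eval=cfg.n_eval)
        rows = [
            {"cluster": c, "role": role, "image_id": img}
            for c, s in sets.items()
            for role, imgs in (
                ("most_beautiful", s.most_beautiful),
                ("least_beautiful", s.least_beautiful),
                ("evaluation", s.evaluation),
            )
            for img in imgs
        ]
        pd.DataFrame(rows).to_csv(out / "adaptor_sets.csv", index=False)
        results.update(solution=sol, cluster_means=means, adaptor_sets=sets)
    except Exception as exc:
        _write_log(out, log_lines, f"ABORT in clustering: {exc}")
        raise StageError("clustering", exc) from exc

    # --- contrast ---------------------------------------------------------
    _stage("contrast")
    try:
        if cfg.ratings_csv:
            after_b = ratings.load_ratings(cfg.ratings_csv, phase="after_beautiful")
            after_l = ratings.load_ratings(cfg.ratings_csv, phase="after_least")
        else:
            after_b, after_l, _ = synth.simulate_adaptation_ratings(
                feats, cfg.population, sets, sol.assignment, seed=cfg.seed + 2,
                true_clusters=true_clusters,
            )
        table = contrast.compute_contrast(after_b, after_l, sol)
        table.to_csv(out / "contrast.csv", index=False)
        test = contrast.paired_contrast_test(table)
        summary = contrast.per_cluster_contrast_summary(table)
        summary.to_csv(out / "contrast_summary.csv", index=False)
        results.update(contrast_table=table, contrast_test=test, contrast_summary=summary)
        log_lines.append(test.summary())
    except Exception as exc:
        _write_log(out, log_lines, f"ABORT in contrast: {exc}")
        raise StageError("contrast", exc) from exc

    # --- association ------------------------------------------------------
    _stage("association")
    try:
        spearman_blocks = []
        for kk in cfg.k_range:
            sol_k = (
                sol
                if kk == cfg.k
                else clustering.cluster_raters(baseline, k=kk, seed=cfg.seed, compute_diagnostics=False)
            )
            means_k = clustering.cluster_mean_ratings(baseline, sol_k)
            spearman_blocks.append(
                association.spearman_table(
                    means_k, feats, cluster_label_suffix=str(kk), include_average=(kk == cfg.k_range[-1])
                )
            )
        spearman = pd.concat(spearman_blocks, ignore_index=True)
        spearman.to_csv(out / "spearman_table.csv", index=False)

        predictors = [p for p in association.MIXED_MODEL_PROPERTIES if p in feats.columns]
        beauty = baseline.ratings.mean(axis=0)
        reg_beauty = association.regression_standardized(
            beauty, feats, predictors, response_name="average_beauty"
        )
        pooled = table.groupby("image_id")["contrast"].mean()
        reg_contrast = association.regression_standardized(
            pooled, feats, predictors, response_name="perceptual_contrast"
        )
        reg = pd.concat(
            [
                reg_beauty.summary().assign(response="average_beauty", r_squared=reg_beauty.r_squared),
                reg_contrast.summary().assign(response="perceptual_contrast", r_squared=reg_contrast.r_squared),
            ]
        )
        reg.index.name = "property"
        reg.to_csv(out / "regression.csv")

        mm = association.mixed_model_cluster_interaction(means, feats, properties=predictors)
        mm_table = mm.interaction_tests.join(
            mm.cluster_slopes.pivot(index="property", columns="cluster", values="rc").add_prefix("rc_c")
        )
        mm_table.to_csv(out / "mixed_model.csv")
        hue = association.hue_group_analysis(feats, means)
        hue.to_csv(out / "hue_groups.csv", index=False)
        results.update(
            spearman=spearman,
            regression_beauty=reg_beauty,
            regression_contrast=reg_contrast,
            mixed_model=mm,
            hue_groups=hue,
        )
    except Exception as exc:
        _write_log(out, log_lines, f"ABORT in association: {exc}")
        raise StageError("association", exc) from exc

    _write_log(out, log_lines, "run complete")
    return results


def _write_log(out: Path, lines: list[str], final: str) -> None:
    (out / "run_log.txt").write_text("\n".join([*lines, final]) + "\n")
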