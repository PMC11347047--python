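"""Pipeline orchestration: simulate -> metrics -> cluster -> survival.

Each stage is a pure function of (inputs, config, seed); ``run_all`` writes
the feature matrix, cluster assignments and model, comparison tables,
survival results, and a reproducibility manifest into the output directory.
A stage failure removes any partial outputs from this run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .clustering import elbow_select, kmeans_fit, pca_project, standardize
from .curves import read_cohort, records_to_frame
from .metrics import ALL_FEATURE_COLUMNS, FEATURE_COLUMNS, features_table
from .simulate import CohortConfig, simulate_cohort
from .survival import (
    cluster_contrasts,
    compare_clusters,
    comparisons_frame,
    cox_fit,
    km_logrank,
)

logger = logging.getLogger("dyssync")

CONTINUOUS_COMPARISON_VARS = [
    "age_y", "bsa_m2", "qrs_ms", "edvi_ml_m2", "esvi_ml_m2", "massi_g_m2",
    "ef_pct",
]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    out_dir: str = "dyssync_out"
    seed: int = 0
    simulate: bool = True
    curves_path: Optional[str] = None
    subjects_path: Optional[str] = None
    n_patients: int = 512
    n_controls: int = 42
    k: Optional[int] = None  # fixed k; None -> elbow selection
    k_min: int = 1
    k_max: int = 10
    ccd_percentile: float = 80.0
    adjustments: Tuple[str, ...] = ("morphology", "edvi")
    bonferroni: bool = False

    def validate(self) -> None:
        if not self.simulate and not (self.curves_path and self.subjects_path):
            raise ValueError("either simulate=True or cohort file paths are required")
        if self.k is not None and self.k < 2:
            raise ValueError("fixed k must be >= 2")
        if self.k_max - self.k_min < 2:
            raise ValueError("k range must span at least 3 values")
        if not 0 < self.ccd_percentile < 100:
            raise ValueError("ccd_percentile must lie in (0, 100)")
        for adj in self.adjustments:
            if adj not in ("morphology", "edvi"):
                raise ValueError(f"unknown adjustment {adj!r}")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "adjustments" in raw:
            raw["adjustments"] = tuple(raw["adjustments"])
        return cls(**raw)


@dataclass
class RunReport:
    """Artifacts and headline results of one pipeline run."""

    out_dir: Path
    paths: Dict[str, Path]
    selected_k: int
    no_elbow_warning: bool
    labels: pd.Series
    features: pd.DataFrame
    survival_results: Dict[str, object]
    warnings: List[str] = field(default_factory=list)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts.

    Idempotent given (config, seed): rerunning writes byte-identical feature
    and cluster CSVs.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    run_warnings: List[str] = []
    timings: Dict[str, float] = {}

    def _write_csv(df: pd.DataFrame, name: str, index: bool) -> Path:
        path = out_dir / name
        df.to_csv(path, index=index)
        written.append(path)
        return path

    try:
        # ---- stage 1: cohort ------------------------------------------------
        t0 = time.perf_counter()
        if config.simulate:
            cohort = simulate_cohort(CohortConfig(
                n_patients=config.n_patients, n_controls=config.n_controls,
                seed=config.seed,
            ))
            datasets, records = cohort.datasets, cohort.records
            logger.info("simulated cohort: %d patients + %d controls",
                        config.n_patients, config.n_controls)
        else:
            datasets, records = read_cohort(config.curves_path, config.subjects_path)
            logger.info("read cohort: %d subjects", len(records))
        timings["cohort"] = time.perf_counter() - t0

        # ---- stage 2: dyssynchrony features --------------------------------
        t0 = time.perf_counter()
        features = features_table(datasets, ccd_percentile=config.ccd_percentile)
        paths = {"features": _write_csv(features, "features.csv", index=True)}
        timings["metrics"] = time.perf_counter() - t0
        logger.info("computed %d features for %d subjects",
                    features.shape[1], features.shape[0])

        # ---- stage 3: clustering -------------------------------------------
        t0 = time.perf_counter()
        Z, std_params = standardize(features[FEATURE_COLUMNS])
        elbow = elbow_select(Z, k_range=range(config.k_min, config.k_max + 1),
                             seed=config.seed)
        if elbow.no_elbow_warning:
            run_warnings.append("no elbow detected in inertia curve")
        k = config.k if config.k is not None else elbow.k
        model = kmeans_fit(Z, k=k, seed=config.seed)
        scores, explained, components = pca_project(Z)
        model.pca_coordinates = scores
        model.inertia_by_k = elbow.inertia_by_k
        clusters_df = pd.DataFrame({
            "subject_id": list(model.subject_ids),
            "cluster": model.labels,
            "pc1": scores[:, 0],
            "pc2": scores[:, 1],
        })
        paths["clusters"] = _write_csv(clusters_df, "clusters.csv", index=False)
        model_json = {
            "k": model.k,
            "seed": model.seed,
            "selected_by_elbow": config.k is None,
            "no_elbow_warning": elbow.no_elbow_warning,
            "order_feature": model.order_feature,
            "standardization": {
                "columns": list(std_params.columns),
                "mean": std_params.mean.tolist(),
                "sd": std_params.sd.tolist(),
            },
            "centroids_z": model.centroids.to_numpy().tolist(),
            "inertia": model.inertia,
            "inertia_by_k": {str(kk): v for kk, v in elbow.inertia_by_k.items()},
            "pca_explained_variance": explained.tolist(),
        }
        model_path = out_dir / "cluster_model.json"
        model_path.write_text(json.dumps(model_json, indent=2))
        written.append(model_path)
        paths["model"] = model_path
        timings["clustering"] = time.perf_counter() - t0
        logger.info("k=%d clusters (elbow%s)", k,
                    " overridden" if config.k is not None else " selected")

        # ---- stage 4: comparisons + survival -------------------------------
        t0 = time.perf_counter()
        table = records_to_frame(records).set_index("subject_id")
        table = table.join(features).join(
            clusters_df.set_index("subject_id")["cluster"]
        )
        table["male"] = (table["sex"] == "M").astype(float)
        comparisons = compare_clusters(
            table,
            continuous=CONTINUOUS_COMPARISON_VARS + ALL_FEATURE_COLUMNS,
            binary=["male"],
        )
        paths["comparisons"] = _write_csv(
            comparisons_frame(comparisons), "comparisons.csv", index=False)

        patients = table[table["group"] == "fontan"]
        contrast = km_logrank(patients, bonferroni=config.bonferroni)
        worst = int(patients["cluster"].max())
        cox_results = {}
        for adj in config.adjustments:
            cox_results[adj] = {
                "full_model": cox_fit(patients, adjustment=adj,
                                      reference_cluster=1).to_dict("records"),
                "worst_cluster_contrasts": cluster_contrasts(
                    patients, target_cluster=worst, adjustment=adj
                ).to_dict("records"),
            }
        survival_results = {
            "km": {
                g: {
                    "times": c.times.tolist(),
                    "survival": c.survival.tolist(),
                    "at_risk": c.at_risk.tolist(),
                    "n": c.n,
                    "n_events": c.n_events,
                }
                for g, c in contrast.km_curves.items()
            },
            "pairwise_logrank": contrast.pairwise_logrank.to_dict("records"),
            "cox": cox_results,
            "n_patients": int(len(patients)),
            "n_events": int(patients["event"].sum()),
        }
        survival_path = out_dir / "survival.json"
        survival_path.write_text(json.dumps(survival_results, indent=2))
        written.append(survival_path)
        paths["survival"] = survival_path
        timings["survival"] = time.perf_counter() - t0

        # ---- manifest -------------------------------------------------------
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config": asdict(config),
            "config_hash": _config_hash(config),
            "selected_k": k,
            "warnings": run_warnings,
            "stage_seconds": {s: round(v, 3) for s, v in timings.items()},
            "library_versions": _library_versions(),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        written.append(manifest_path)
        paths["manifest"] = manifest_path
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    return RunReport(
        out_dir=out_dir, paths=paths, selected_k=k,
        no_elbow_warning=elbow.no_elbow_warning,
        labels=clusters_df.set_index("subject_id")["cluster"],
        features=features, survival_results=survival_results,
        warnings=run_warnings,
    )


def _library_versions() -> Dict[str, str]:
    import lifelines
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "lifelines": lifelines.__version__,
    }
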