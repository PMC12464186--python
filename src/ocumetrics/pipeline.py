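"""End-to-end study orchestration: images -> metrics -> opacities -> statistics.

The on-disk study layout is flat and auditable::

    study_root/
      clinical.csv                  # eye_id, iop_T0..T3, cde, phaco_time, fluid
      eyes/<eye_id>/<T0..T3>/<SVP|ICP|DCP>.png   (+ .json sidecar: quality_index)
      eyes/<eye_id>/lens/scan-NN.png

:func:`simulate_study` materializes a synthetic study in that layout
with ground-truth sidecars; :func:`run_study` consumes it, quantifies
every angiogram behind the quality gate, measures lens opacity from the
radial series, assembles the longitudinal cohort table and writes the
study-style summary tables (per-visit means with RM-ANOVA, and the
change-vs-predictor Pearson screen). Reruns with identical inputs and
configuration reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_stats as cs
from . import lens as lens_mod
from . import octa
from . import synthetic as syn
from .images import read_asoct_png, read_enface_png, write_grayscale_png

PLEXUSES = syn.PLEXUSES
TIMEPOINTS = syn.TIMEPOINTS


@dataclass
class StudyConfig:
    """Paths and stage configurations for one study run."""

    study_root: Path
    output_dir: Path
    quant: octa.QuantConfig = field(default_factory=octa.QuantConfig)
    lens: lens_mod.LensConfig = field(default_factory=lens_mod.LensConfig)
    delta_from: str = "T0"
    delta_to: str = "T3"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.study_root = Path(self.study_root)
        self.output_dir = Path(self.output_dir)
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def hash(self) -> str:
        payload = {
            "quant": dataclasses.asdict(self.quant),
            "lens": dataclasses.asdict(self.lens),
            "delta": [self.delta_from, self.delta_to],
            "alpha": self.alpha,
            "seed": self.seed,
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class SimulatedStudyParams:
    """Image-level study simulation conditions.

    Cohort-level conditions come from :class:`~ocumetrics.synthetic.
    CohortSimParams`; the fields here control rendering. ``image_size``
    and counts default to a desk-scale study; the cohort's per-eye VAD
    targets drive the rendered tree density so that measured perfusion
    changes inherit the configured opacity correlation.
    """

    cohort: syn.CohortSimParams = field(default_factory=syn.CohortSimParams)
    image_size: tuple[int, int] = (160, 160)
    n_scans: int = 15
    lens_size: tuple[int, int] = (160, 192)
    tree_depth: int = 2
    speckle_sigma: float = 0.05
    quality_index: float = 35.0
    seed: int = 0


def _density_from_vad(v: float) -> int:
    # monotone map from a VAD-scale target to a tree count
    return int(np.clip(round(2 + (v - 0.10) * 40), 1, 16))


def simulate_study(out_dir: str | Path, params: SimulatedStudyParams | None = None) -> Path:
    """Materialize a synthetic study tree on disk; returns its root."""
    params = params or SimulatedStudyParams()
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    cohort = syn.generate_cohort(params.cohort)

    clinical_cols = [f"iop_{tp}" for tp in TIMEPOINTS] + [
        "cde",
        "phaco_time",
        "fluid",
        "lens_opacity",
        "nuclear_opacity",
    ]
    cohort[clinical_cols].to_csv(root / "clinical.csv")
    cohort.to_csv(root / "cohort_truth.csv")

    for eye_id, row in cohort.iterrows():
        eye_dir = root / "eyes" / str(eye_id)
        for tp in TIMEPOINTS:
            tp_dir = eye_dir / tp
            tp_dir.mkdir(parents=True, exist_ok=True)
            for plexus in PLEXUSES:
                target_vad = float(row[syn.metric_column("vad", plexus, tp)])
                tree_seed = int(rng.integers(0, 2**31 - 1))
                tree = syn.generate_vascular_tree(
                    depth=params.tree_depth,
                    n_trees=_density_from_vad(target_vad),
                    canvas_size=params.image_size,
                    seed=tree_seed,
                )
                img = syn.render_octa_image(
                    tree,
                    size=params.image_size,
                    speckle_sigma=params.speckle_sigma,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    quality_index=params.quality_index,
                    plexus_label=plexus,
                )
                path = tp_dir / f"{plexus}.png"
                write_grayscale_png(
                    path,
                    img.pixels,
                    metadata={
                        "quality_index": params.quality_index,
                        "plexus_label": plexus,
                        "mm_per_pixel": img.mm_per_pixel,
                    },
                )
                (tp_dir / f"{plexus}.truth.json").write_text(tree.to_json())
        lens_dir = eye_dir / "lens"
        lens_dir.mkdir(parents=True, exist_ok=True)
        scene = syn.make_lens_scene(
            size=params.lens_size,
            cortex_intensity=float(np.clip(row["lens_opacity"], 10.0, 200.0)),
            nucleus_intensity=float(np.clip(row["nuclear_opacity"], 10.0, 200.0)),
            speckle_sigma=params.speckle_sigma,
        )
        scans = syn.generate_lens_series(
            scene, n_scans=params.n_scans, size=params.lens_size, seed=int(rng.integers(0, 2**31 - 1))
        )
        for scan in scans:
            path = lens_dir / f"scan-{scan.scan_index:02d}.png"
            write_grayscale_png(path, scan.pixels, metadata={"scan_index": scan.scan_index})
        (lens_dir / "scene.truth.json").write_text(
            json.dumps(
                {
                    "anterior_coeffs": scene.anterior_coeffs.tolist(),
                    "posterior_coeffs": scene.posterior_coeffs.tolist(),
                    "cortex_intensity": scene.cortex_intensity,
                    "nucleus_intensity": scene.nucleus_intensity,
                    "mixture_mean": scene.mixture_mean(params.lens_size),
                }
            )
        )
    return root


def run_study(config: StudyConfig) -> dict[str, Path]:
    """Run the full analysis on a study tree; returns output file paths.

    Eyes with missing or gate-rejected images keep NaN cells and drop
    out of the affected per-metric analyses (complete-case); every
    exclusion is logged with its reason.
    """
    root = config.study_root
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    clinical = pd.read_csv(root / "clinical.csv", index_col="eye_id")
    eye_dirs = sorted((root / "eyes").iterdir()) if (root / "eyes").is_dir() else []

    metric_rows: list[dict] = []
    opacity_rows: list[dict] = []
    lens_cfg = dataclasses.replace(config.lens)

    for eye_dir in eye_dirs:
        eye_id = eye_dir.name
        for tp in TIMEPOINTS:
            for plexus in PLEXUSES:
                path = eye_dir / tp / f"{plexus}.png"
                if not path.exists():
                    log.append(
                        {"eye_id": eye_id, "stage": "octa", "timepoint": tp, "plexus": plexus,
                         "event": "missing_image"}
                    )
                    continue
                image = read_enface_png(path)
                try:
                    metrics = octa.quantify(image, config.quant)
                except octa.QualityGateError as exc:
                    log.append(
                        {"eye_id": eye_id, "stage": "octa", "timepoint": tp, "plexus": plexus,
                         "event": "quality_gate_rejected", "detail": str(exc)}
                    )
                    continue
                row = {"eye_id": eye_id, "timepoint": tp, "plexus": plexus}
                row.update(metrics.as_dict())
                row["threshold"] = metrics.threshold
                row["n_loops_excluded"] = metrics.n_loops_excluded
                metric_rows.append(row)
        lens_dir = eye_dir / "lens"
        scan_paths = sorted(lens_dir.glob("scan-*.png")) if lens_dir.is_dir() else []
        if scan_paths:
            try:
                scans = [read_asoct_png(p) for p in scan_paths]
                series_cfg = dataclasses.replace(lens_cfg, n_scans=len(scans))
                result = lens_mod.lens_opacity_from_series(scans, series_cfg)
                rec = {
                    "eye_id": eye_id,
                    "lens_opacity": result.lens_opacity,
                    "nuclear_opacity": result.nuclear_opacity,
                    "corrected_points": sum(result.corrected_points),
                }
                for i, (lv, nv) in enumerate(zip(result.per_scan_lens, result.per_scan_nucleus), 1):
                    rec[f"lens_scan{i:02d}"] = lv
                    rec[f"nucleus_scan{i:02d}"] = nv
                opacity_rows.append(rec)
            except lens_mod.SegmentationError as exc:
                log.append(
                    {"eye_id": eye_id, "stage": "lens", "event": "segmentation_failed",
                     "detail": str(exc)}
                )

    metrics_df = pd.DataFrame(metric_rows)
    opacity_df = pd.DataFrame(opacity_rows).set_index("eye_id") if opacity_rows else pd.DataFrame()

    # assemble the longitudinal cohort: measured metrics wide by tp/plexus
    cohort = clinical.copy()
    if not metrics_df.empty:
        measured: dict[str, pd.Series] = {}
        for metric in syn.METRICS:
            wide = metrics_df.pivot_table(
                index="eye_id", columns=["plexus", "timepoint"], values=metric, aggfunc="first"
            )
            for plexus in PLEXUSES:
                for tp in TIMEPOINTS:
                    if (plexus, tp) in wide.columns:
                        measured[syn.metric_column(metric, plexus, tp)] = wide[(plexus, tp)]
        cohort = pd.concat([cohort, pd.DataFrame(measured)], axis=1)
    if not opacity_df.empty:
        # measured opacity supersedes the clinical-table preoperative value
        cohort["lens_opacity"] = opacity_df["lens_opacity"]
        cohort["nuclear_opacity"] = opacity_df["nuclear_opacity"]

    table1 = cs.anova_table(cohort, alpha=config.alpha)
    table2 = cs.correlation_screen(
        cohort, from_tp=config.delta_from, to_tp=config.delta_to, alpha=config.alpha
    )

    paths = {
        "metrics": out / "metrics.csv",
        "opacity": out / "opacity.csv",
        "cohort": out / "cohort.csv",
        "anova": out / "table1_anova.csv",
        "correlations": out / "table2_correlations.csv",
        "log": out / "run_log.json",
    }
    metrics_df.to_csv(paths["metrics"], index=False)
    (opacity_df if not opacity_df.empty else pd.DataFrame()).to_csv(paths["opacity"])
    cohort.to_csv(paths["cohort"])
    table1.to_csv(paths["anova"], index=False)
    table2.to_csv(paths["correlations"], index=False)
    provenance = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_eyes": len(eye_dirs),
        "events": log,
    }
    paths["log"].write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return paths
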