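"""End-to-end recalibration pipeline with a run manifest.

Steps, in order: candidate search over the reference database -> coverage
filter -> per-candidate KDE ridge / spline / outlier rule / acceptance ->
GAM trend fit -> per-pixel common-error filter and calibration fit ->
application to all ROI pixels -> optional test-mass evaluation.  Every stage
logs its counts and parameters into a manifest so a run is auditable and
reproducible from its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .drift import DriftTrend, ReferenceDiscarded, build_drift_trend
from .evaluation import EvaluationReport, evaluate_recalibration
from .io import MSIDataset, ROIMask
from .recal import recalibrate_dataset
from .references import ReferenceDatabase, coverage_filter, search_reference

logger = logging.getLogger("msirecal")


class NoReferencesError(RuntimeError):
    """No candidate reference survived the acceptance gates."""


@dataclass
class PipelineConfig:
    analyzer: str = "orbitrap"
    window_ppm: float | None = None  # default 20 (Orbitrap) / 100 (TOF)
    coverage: float = 0.75
    dispersion_ppm: float = 10.0
    kde_grid: int = 1024
    gam_terms: int = 20
    error_band_ppm: float | None = None  # default 2.5 (Orbitrap) / 10 (TOF)
    eval_window_ppm: float = 2.5
    bootstrap_B: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.analyzer not in ("orbitrap", "tof"):
            raise ValueError(f"analyzer must be 'orbitrap' or 'tof', got {self.analyzer!r}")
        if self.window_ppm is None:
            self.window_ppm = 20.0 if self.analyzer == "orbitrap" else 100.0
        for name in ("window_ppm", "coverage", "dispersion_ppm", "eval_window_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    recalibrated: MSIDataset
    trends: list[DriftTrend]
    models: list
    diagnostics: list[dict]
    manifest: dict
    evaluation: EvaluationReport | None = None


def fit_reference_trends(
    dataset: MSIDataset,
    roi: ROIMask,
    candidate_mz: np.ndarray,
    config: PipelineConfig,
) -> tuple[list[DriftTrend], list[dict]]:
    """Search, filter and model every candidate reference; return accepted trends."""
    if roi.n_roi == 0:
        raise ValueError("ROI mask contains no sample pixels")
    tables = [search_reference(dataset, roi, float(m), config.window_ppm) for m in candidate_mz]
    covered = coverage_filter(tables, roi, config.coverage)
    logger.info("reference search: %d candidates, %d covered", len(tables), len(covered))

    trends, diags = [], []
    for table in covered:
        record = {
            "reference_mz": table.reference_mz,
            "n_matches": table.n_matches,
            "coverage": table.coverage(roi.n_roi),
            "accepted": False,
            "reason": "",
        }
        try:
            trend, diag = build_drift_trend(
                table,
                roi,
                dataset,
                G=config.kde_grid,
                min_frac=config.coverage,
                max_dispersion_ppm=config.dispersion_ppm,
                seed=config.seed,
                J=config.gam_terms,
            )
        except ReferenceDiscarded as exc:
            record["reason"] = str(exc)
            diags.append(record)
            continue
        record["accepted"] = True
        record["n_inliers"] = diag.inlier.sum().item()
        record["max_dispersion_ppm"] = (
            float(diag.dispersion.max()) if diag.dispersion.size else float("nan")
        )
        diags.append(record)
        trends.append(trend)
    return trends, diags


def run_pipeline(
    dataset: MSIDataset,
    roi: ROIMask,
    database: ReferenceDatabase | np.ndarray,
    config: PipelineConfig,
    test_masses: np.ndarray | None = None,
) -> PipelineResult:
    """Run the full recalibration workflow on an in-memory dataset.

    ``database`` is either a neutral-mass :class:`ReferenceDatabase` (expanded
    into polarity-matched adduct m/z) or an array of candidate m/z values.
    Raises :class:`NoReferencesError` if no reference is accepted.
    """
    if isinstance(database, ReferenceDatabase):
        candidates = database.candidate_mz(dataset.polarity)["mz"].to_numpy()
    else:
        candidates = np.asarray(database, dtype=float)

    manifest = {
        "config": asdict(config),
        "n_pixels": dataset.n_pixels,
        "n_roi": roi.n_roi,
        "n_candidates": int(candidates.size),
    }
    trends, diags = fit_reference_trends(dataset, roi, candidates, config)
    manifest["n_covered"] = len(diags)
    manifest["n_accepted"] = len(trends)
    if not trends:
        raise NoReferencesError(
            "no reference mass passed the coverage and dispersion gates; "
            "check polarity, search window and database"
        )
    recal, models = recalibrate_dataset(
        dataset,
        roi,
        trends,
        analyzer=config.analyzer,
        band_ppm=config.error_band_ppm,
    )
    manifest["n_pixels_recalibrated"] = len(models)
    degree_counts: dict[int, int] = {}
    for mdl in models:
        degree_counts[mdl.degree] = degree_counts.get(mdl.degree, 0) + 1
    manifest["pixels_per_degree"] = degree_counts

    evaluation = None
    if test_masses is not None and len(test_masses):
        fitted = np.array([t.reference_mz for t in trends])
        keep = np.array([np.abs(fitted - m).min() > 1e-4 for m in test_masses])
        evaluation = evaluate_recalibration(
            dataset,
            recal,
            roi,
            np.asarray(test_masses)[keep],
            match_window_ppm=config.window_ppm,
            B=config.bootstrap_B,
            seed=config.seed,
        )
        manifest["evaluation"] = evaluation.to_dict()
    return PipelineResult(recal, trends, models, diags, manifest, evaluation)


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
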