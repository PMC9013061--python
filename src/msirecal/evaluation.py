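"""Recalibration benefit on held-out test masses.

A list of test ions disjoint from the fitting references probes the mass
accuracy before and after recalibration.  Test masses whose pooled relative
error sits far from the dominant error mode are excluded (they are likely
absent or mismatched).  The headline statistic is

    Delta-tilde = median over pixels of the pixel-wise median of
                  (|error before| - |error after|)  [ppm],

positive values meaning improvement.  Its significance against H0:
Delta-tilde = 0 is assessed by bootstrapping pixels (B = 10,000) and, across
datasets, Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io import MSIDataset, ROIMask
from .recal import _kde_mode
from .references import search_reference


@dataclass
class EvaluationReport:
    delta_tilde: float  # ppm; positive = improvement
    p_value: float
    p_adjusted: float | None
    n_pixels: int
    n_test_masses: int
    median_abs_before: float
    median_abs_after: float
    per_pixel_diffs: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "delta_tilde_ppm": self.delta_tilde,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "n_pixels": self.n_pixels,
            "n_test_masses": self.n_test_masses,
            "median_abs_error_before_ppm": self.median_abs_before,
            "median_abs_error_after_ppm": self.median_abs_after,
        }


def select_test_masses(
    candidates: np.ndarray,
    candidate_errors: dict[float, np.ndarray],
    window_ppm: float = 2.5,
    reference_masses: np.ndarray | None = None,
    exclusion_tol: float = 1e-4,
) -> np.ndarray:
    """Keep test candidates consistent with the dominant relative-error mode.

    The mode of the pooled per-candidate errors (ppm) is located by a 1D
    triangular-kernel KDE argmax; a candidate survives if its median error is
    within +/- ``window_ppm`` of the mode.  Candidates within
    ``exclusion_tol`` Th of any fitting reference are excluded first (the test
    list must be disjoint from the fitting set).
    """
    cands = np.asarray(candidates, dtype=float)
    if reference_masses is not None and len(reference_masses):
        refs = np.asarray(reference_masses, dtype=float)
        disjoint = np.array([np.abs(refs - c).min() > exclusion_tol for c in cands])
        cands = cands[disjoint]
    med_err = {}
    pooled = []
    for c in cands:
        errs = candidate_errors.get(float(c))
        if errs is None or len(errs) == 0:
            continue
        med_err[float(c)] = float(np.median(errs))
        pooled.extend(np.asarray(errs, dtype=float))
    if not med_err:
        warnings.warn("no test-mass candidates with observed errors; evaluation skipped")
        return np.empty(0)
    mode = _kde_mode(np.asarray(pooled))
    kept = [c for c, me in med_err.items() if abs(me - mode) <= window_ppm]
    return np.array(sorted(kept))


def delta_statistic(per_pixel_diffs: np.ndarray) -> float:
    """Median over pixels of the pixel-wise median |before|-|after| difference."""
    d = np.asarray(per_pixel_diffs, dtype=float)
    if d.size == 0:
        raise ValueError("no per-pixel differences")
    return float(np.median(d))


def pixel_median_differences(
    before_errors: list[np.ndarray], after_errors: list[np.ndarray]
) -> np.ndarray:
    """Per pixel: median over test masses of (|err_before| - |err_after|).

    ``before_errors[i]`` and ``after_errors[i]`` hold the paired ppm errors of
    the test masses matched in pixel i.
    """
    diffs = []
    for b, a in zip(before_errors, after_errors):
        b, a = np.asarray(b, dtype=float), np.asarray(a, dtype=float)
        if b.size == 0:
            continue
        diffs.append(np.median(np.abs(b) - np.abs(a)))
    return np.asarray(diffs)


def bootstrap_test(per_pixel_diffs: np.ndarray, B: int = 10_000, seed: int = 0) -> float:
    """Two-sided bootstrap p-value for H0: Delta-tilde = 0.

    Pixels are resampled with replacement B times; the p-value is twice the
    fraction of bootstrap medians whose sign contradicts the observed
    Delta-tilde, clipped to [2/B, 1].
    """
    d = np.asarray(per_pixel_diffs, dtype=float)
    if d.size < 10:
        raise ValueError("bootstrap test requires at least 10 pixels")
    obs = np.median(d)
    if obs == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(B, d.size))
    boot_medians = np.median(d[idx], axis=1)
    frac = np.mean(boot_medians <= 0) if obs > 0 else np.mean(boot_medians >= 0)
    return float(np.clip(2.0 * frac, 2.0 / B, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def match_errors(
    dataset: MSIDataset, roi: ROIMask, test_masses: np.ndarray, window_ppm: float
) -> dict[int, dict[float, float]]:
    """Per ROI pixel, the signed ppm error of the best match of each test mass.

    When a pixel holds several matches for one test mass, the one with the
    smallest absolute error is taken.
    """
    out: dict[int, dict[float, float]] = {}
    for tm in np.asarray(test_masses, dtype=float):
        table = search_reference(dataset, roi, tm, window_ppm)
        if table.n_matches == 0:
            continue
        err = (table.masses - tm) / tm * 1e6
        for p in np.unique(table.pixels):
            sel = table.pixels == p
            best = err[sel][np.argmin(np.abs(err[sel]))]
            out.setdefault(int(p), {})[float(tm)] = float(best)
    return out


def evaluate_recalibration(
    original: MSIDataset,
    recalibrated: MSIDataset,
    roi: ROIMask,
    test_masses: np.ndarray,
    match_window_ppm: float,
    B: int = 10_000,
    seed: int = 0,
) -> EvaluationReport:
    """Before/after comparison of test-mass accuracy with a bootstrap test.

    Test masses are matched in each ROI pixel of both datasets with the same
    ppm window; only (pixel, mass) pairs matched in both contribute, keeping
    the differences paired.
    """
    before = match_errors(original, roi, test_masses, match_window_ppm)
    after = match_errors(recalibrated, roi, test_masses, match_window_ppm)
    b_list, a_list = [], []
    all_b, all_a = [], []
    for p, errs_b in before.items():
        errs_a = after.get(p, {})
        common = sorted(set(errs_b) & set(errs_a))
        if not common:
            continue
        b = np.array([errs_b[m] for m in common])
        a = np.array([errs_a[m] for m in common])
        b_list.append(b)
        a_list.append(a)
        all_b.extend(b)
        all_a.extend(a)
    diffs = pixel_median_differences(b_list, a_list)
    if diffs.size == 0:
        raise ValueError("no test masses matched in any pixel")
    delta = delta_statistic(diffs)
    p_value = bootstrap_test(diffs, B=B, seed=seed) if diffs.size >= 10 else np.nan
    return EvaluationReport(
        delta_tilde=delta,
        p_value=float(p_value),
        p_adjusted=None,
        n_pixels=int(diffs.size),
        n_test_masses=int(np.asarray(test_masses).size),
        median_abs_before=float(np.median(np.abs(all_b))),
        median_abs_after=float(np.median(np.abs(all_a))),
        per_pixel_diffs=diffs,
    )
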