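"""Per-pixel calibration refit and application.

For every ROI pixel the GAM-predicted observed masses of the accepted
references are paired with their theoretical values.  References whose
relative error falls outside a band around the dominant error mode (a 1D
triangular-kernel density argmax) are dropped — most true matches share a
similar ppm error, so a discordant reference is likely mismatched in that
pixel.  The surviving pairs parametrize the analyzer-specific calibration:

* Orbitrap: ordinary least squares  M* ~ b0 + b1 * Mhat  (near-linear
  response of orbital traps to calibration drift);
* TOF: polynomial regression in the sqrt-mass domain,
  sqrt(M*) ~ sum_d b_d * sqrt(Mhat)^d, degree D <= 5 chosen by the smallest
  BIC (time-of-flight physics makes sqrt(m/z) the natural calibration axis).

The fitted map recalibrates every observed mass in the pixel; intensities
are untouched and off-sample pixels pass through unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MSIDataset, PeakSpectrum, ROIMask
from .kde import triangular_kernel

#: default common-error band half-widths, ppm
DEFAULT_ERROR_BAND = {"orbitrap": 2.5, "tof": 10.0}


@dataclass
class PixelReferenceSet:
    """Theoretical and GAM-predicted reference masses available in one pixel."""

    pixel_index: int
    theoretical: np.ndarray  # M*_k, Th
    predicted: np.ndarray  # Mhat_k, Th
    filtered: bool = False  # True once the common-error filter has run

    @property
    def errors_ppm(self) -> np.ndarray:
        return (self.predicted - self.theoretical) / self.theoretical * 1e6

    def __len__(self) -> int:
        return int(self.theoretical.size)


@dataclass
class PixelRecalModel:
    """Fitted per-pixel calibration g_p."""

    pixel_index: int
    analyzer: str
    coefficients: np.ndarray  # beta_0..beta_D
    degree: int
    bic: dict[int, float] = field(default_factory=dict)
    sigma2: float = 0.0
    n_refs: int = 0
    mz_range: tuple[float, float] = (np.nan, np.nan)

    def predict(self, masses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map observed masses through g_p.

        Returns (recalibrated masses, corrected flag); a TOF prediction that
        lands at a negative sqrt-domain value is left uncorrected and flagged.
        """
        m = np.asarray(masses, dtype=float)
        ok = np.ones(m.shape, dtype=bool)
        if self.analyzer == "orbitrap":
            out = self.coefficients[0] + self.coefficients[1] * m
        else:
            s = np.sqrt(m)
            pred = np.polynomial.polynomial.polyval(s, self.coefficients)
            neg = pred < 0
            out = np.where(neg, m, pred**2)
            ok = ~neg
        return out, ok


def _kde_mode(errors: np.ndarray, grid_size: int = 512) -> float:
    """Dominant mode of the ppm errors via a 1D triangular-kernel KDE argmax.

    Ties take the lowest-ppm grid point (argmax returns the first index on a
    grid sorted ascending), making the choice deterministic.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 1 or np.ptp(e) == 0:
        return float(e[0])
    sigma = float(e.std())
    h = max(2.576 * sigma * e.size ** (-0.2), 1e-9)
    grid = np.linspace(e.min() - h, e.max() + h, grid_size)
    dens = triangular_kernel((grid[:, None] - e[None, :]) / h).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def filter_common_error(refs: PixelReferenceSet, band_ppm: float) -> PixelReferenceSet:
    """Retain references whose ppm error lies within +/- band of the dominant mode.

    If fewer than 2 references survive, the unfiltered set is returned with a
    warning so the pixel can still be recalibrated.
    """
    if len(refs) < 2:
        raise ValueError("common-error filter requires at least 2 references")
    e = refs.errors_ppm
    mode = _kde_mode(e)
    keep = np.abs(e - mode) <= band_ppm
    if keep.sum() < 2:
        warnings.warn(
            f"pixel {refs.pixel_index}: common-error filter left <2 references; "
            "falling back to the unfiltered set"
        )
        return PixelReferenceSet(refs.pixel_index, refs.theoretical, refs.predicted, filtered=True)
    return PixelReferenceSet(
        refs.pixel_index, refs.theoretical[keep], refs.predicted[keep], filtered=True
    )


def fit_orbitrap_model(refs: PixelReferenceSet) -> PixelRecalModel:
    """OLS of theoretical on predicted-observed mass: M* ~ b0 + b1 * Mhat."""
    if len(refs) < 2:
        raise ValueError("Orbitrap model requires at least 2 references")
    x, y = refs.predicted, refs.theoretical
    if np.ptp(x) == 0:
        raise ValueError(f"pixel {refs.pixel_index}: degenerate design (all Mhat equal)")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    n = len(refs)
    sigma2 = rss / max(n - 2, 1)
    return PixelRecalModel(
        refs.pixel_index,
        "orbitrap",
        beta,
        degree=1,
        sigma2=sigma2,
        n_refs=n,
        mz_range=(float(x.min()), float(x.max())),
    )


def _bic(n: int, rss: float, n_par: int, y_scale: float) -> float:
    # Gaussian log-likelihood form; RSS floored at machine precision so that
    # exactly-interpolating fits are ranked by the complexity penalty alone
    floor = n * (np.finfo(float).eps * max(y_scale, 1.0)) ** 2
    return n * np.log(max(rss, floor) / n) + n_par * np.log(n)


def fit_tof_model(refs: PixelReferenceSet, max_degree: int = 5) -> PixelRecalModel:
    """sqrt-domain polynomial calibration with BIC degree selection.

    For each candidate degree D (1..min(max_degree, n-2)) an OLS fit of
    sqrt(M*) on powers of sqrt(Mhat) is scored by
    BIC = n ln(RSS/n) + (D+1) ln(n); the smallest BIC wins.  Ill-conditioned
    designs at high degree are skipped.
    """
    n = len(refs)
    if n < 3:
        raise ValueError("TOF model requires at least 3 references")
    s = np.sqrt(refs.predicted)
    y = np.sqrt(refs.theoretical)
    y_scale = float(np.abs(y).mean())
    bics: dict[int, float] = {}
    fits: dict[int, tuple[np.ndarray, float]] = {}
    for D in range(1, min(max_degree, n - 2) + 1):
        X = np.vander(s, D + 1, increasing=True)
        if np.linalg.matrix_rank(X) < D + 1:
            continue
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        rss = float(resid @ resid)
        bics[D] = _bic(n, rss, D + 1, y_scale)
        fits[D] = (beta, rss)
    if not fits:
        raise ValueError(f"pixel {refs.pixel_index}: no TOF degree could be fitted")
    best = min(bics, key=bics.get)
    beta, rss = fits[best]
    sigma2 = rss / max(n - (best + 1), 1)
    return PixelRecalModel(
        refs.pixel_index,
        "tof",
        beta,
        degree=best,
        bic=bics,
        sigma2=sigma2,
        n_refs=n,
        mz_range=(float(refs.predicted.min()), float(refs.predicted.max())),
    )


def apply_model(model: PixelRecalModel, spectrum: PeakSpectrum) -> PeakSpectrum:
    """Map all observed masses in a pixel through g_p; intensities unchanged.

    Output masses are re-sorted (with intensities permuted consistently) if
    the calibration perturbed the order.
    """
    if len(spectrum) == 0:
        return PeakSpectrum(
            spectrum.pixel_index, spectrum.x, spectrum.y, spectrum.masses, spectrum.intensities
        )
    new_mz, _ok = model.predict(spectrum.masses)
    return PeakSpectrum(spectrum.pixel_index, spectrum.x, spectrum.y, new_mz, spectrum.intensities)


def build_pixel_reference_sets(trends, roi_pixels: np.ndarray) -> dict[int, PixelReferenceSet]:
    """Evaluate every accepted trend at every ROI pixel.

    Returns a map pixel_index -> PixelReferenceSet with one entry per trend.
    """
    theo = np.array([t.reference_mz for t in trends])
    pred = np.vstack([t.predict(roi_pixels) for t in trends])  # trends x pixels
    return {
        int(p): PixelReferenceSet(int(p), theo.copy(), pred[:, j].copy())
        for j, p in enumerate(roi_pixels)
    }


def recalibrate_dataset(
    dataset: MSIDataset,
    roi: ROIMask,
    trends,
    analyzer: str | None = None,
    band_ppm: float | None = None,
    max_degree: int = 5,
) -> tuple[MSIDataset, list[PixelRecalModel]]:
    """Recalibrate all ROI pixels of a dataset given accepted drift trends.

    Off-sample pixels pass through unchanged.  Returns the recalibrated
    dataset and the per-pixel fitted models.
    """
    analyzer = analyzer or dataset.analyzer
    if analyzer not in ("orbitrap", "tof"):
        raise ValueError(f"unknown analyzer {analyzer!r}")
    trends = list(trends)
    if not trends:
        raise ValueError("no accepted reference trends; cannot recalibrate")
    band = DEFAULT_ERROR_BAND[analyzer] if band_ppm is None else band_ppm
    min_refs = 2 if analyzer == "orbitrap" else 3

    roi_pixels = roi.roi_pixel_indices(dataset)
    ref_sets = build_pixel_reference_sets(trends, roi_pixels)

    new_spectra: list[PeakSpectrum] = []
    models: list[PixelRecalModel] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-pixel fallback warnings would flood
        for spec in dataset.spectra:
            refs = ref_sets.get(spec.pixel_index)
            if refs is None or len(refs) < min_refs:
                new_spectra.append(spec)
                continue
            refs = filter_common_error(refs, band)
            if len(refs) < min_refs:
                new_spectra.append(spec)
                continue
            try:
                if analyzer == "orbitrap":
                    model = fit_orbitrap_model(refs)
                else:
                    model = fit_tof_model(refs, max_degree=max_degree)
            except ValueError:
                new_spectra.append(spec)
                continue
            models.append(model)
            new_spectra.append(apply_model(model, spec))
    recal = MSIDataset(
        new_spectra, dataset.n_rows, dataset.n_cols, dataset.polarity, analyzer
    )
    return recal, models
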