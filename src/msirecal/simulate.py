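"""Synthetic DESI-MSI datasets with planted mass drift and known ground truth.

The generator emulates the features of real acquisitions that the
recalibration exploits or must survive: a smooth pixel-order-dependent mass
drift (ppm-domain for Orbitrap-like data, a sqrt-mass-domain field for
TOF-like data), Bernoulli per-pixel detection of each reference, ppm-scale
multiplicative measurement noise, decoy interferent peaks at fixed ppm
offsets with configurable spatial masks, uniform chemical-noise background
peaks, and off-sample pixels containing background only.

Every random draw flows from the mandatory seed, so a configuration is a
complete, reproducible specification of a study condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MSIDataset, PeakSpectrum, ROIMask

def _mask_fn(name: str, n_cols: int):
    """Spatial detectability mask by name; (x, y) are 1-based coordinates."""
    if name == "all":
        return lambda x, y: True
    if name == "even_rows":
        return lambda x, y: y % 2 == 0
    if name == "odd_rows":
        return lambda x, y: y % 2 == 1
    if name == "left_half":
        return lambda x, y: x <= n_cols // 2
    if name == "right_half":
        return lambda x, y: x > n_cols // 2
    raise ValueError(f"unknown spatial mask {name!r}")


@dataclass
class DecoySpec:
    """An interferent peak near a reference track.

    The decoy sits at a fixed ppm offset from ``anchor_mz`` and drifts with
    the same field as genuine ions; its spatial mask can be made
    complementary to the reference's to reproduce close-peak scenarios.
    """

    anchor_mz: float
    offset_ppm: float
    detection_prob: float = 0.5
    mask: str = "all"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic acquisition.

    Defaults describe the Orbitrap-like condition used throughout the test
    suite: a 50 x 40 grid acquired row-major (2,000 pixels, all on-sample),
    20 reference ions and 20 held-out test ions spread over 250-900 Th, one
    full sine period of 5 ppm drift amplitude over the acquisition, 0.5 ppm
    multiplicative noise, and 90% per-pixel detection probability.
    """

    n_rows: int = 50
    n_cols: int = 40
    roi_margin: int = 0  # border of off-sample pixels on every side
    analyzer: str = "orbitrap"
    reference_mz: np.ndarray | None = None
    test_mz: np.ndarray | None = None
    drift_kind: str = "ppm_sine"  # or "sqrt_quadratic"
    amplitude_ppm: float = 5.0
    period_pixels: float | None = None  # default: one period over the acquisition
    phase: float = 0.0
    noise_sigma_ppm: float = 0.5
    detection_prob: float = 0.9
    ref_masks: dict[float, str] = field(default_factory=dict)
    decoys: list[DecoySpec] = field(default_factory=list)
    n_background: int = 30
    background_range: tuple[float, float] = (200.0, 1000.0)
    intensity_logmean: float = 3.0
    intensity_logsd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.amplitude_ppm < 0:
            problems.append("amplitude_ppm must be >= 0")
        if not 0.0 <= self.detection_prob <= 1.0:
            problems.append("detection_prob must lie in [0, 1]")
        if self.noise_sigma_ppm < 0:
            problems.append("noise_sigma_ppm must be >= 0")
        if self.analyzer not in ("orbitrap", "tof"):
            problems.append("analyzer must be 'orbitrap' or 'tof'")
        if self.drift_kind not in ("ppm_sine", "sqrt_quadratic"):
            problems.append("drift_kind must be 'ppm_sine' or 'sqrt_quadratic'")
        if self.roi_margin * 2 >= min(self.n_rows, self.n_cols):
            problems.append("roi_margin leaves no ROI pixels")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))
        if self.reference_mz is None:
            self.reference_mz = np.round(np.linspace(255.23, 885.55, 20), 4)
        self.reference_mz = np.asarray(self.reference_mz, dtype=float)
        if self.test_mz is None:
            self.test_mz = np.round(np.linspace(270.19, 900.61, 20), 4)
        self.test_mz = np.asarray(self.test_mz, dtype=float)


@dataclass
class GroundTruth:
    """Per pixel, per planted ion: truth needed to score the recalibration."""

    ion_mz: np.ndarray  # theoretical m/z, references then test ions
    is_test: np.ndarray  # bool per ion
    detected: np.ndarray  # (n_pixels, n_ions) bool
    prenoise: np.ndarray  # drifted observed mass before noise
    noisy: np.ndarray  # mass actually planted in the spectrum
    drift_ppm: np.ndarray  # (prenoise - theoretical)/theoretical * 1e6
    peak_rank: np.ndarray  # index of the planted peak in the pixel's sorted spectrum; -1

    @property
    def n_pixels(self) -> int:
        return self.detected.shape[0]


def _drift_field(config: SimulationConfig, n_pixels: int):
    """Return epsilon(mass, pixel) in ppm."""
    period = config.period_pixels or n_pixels
    A, phase = config.amplitude_ppm, config.phase

    def g(p):
        return np.sin(2 * np.pi * np.asarray(p, dtype=float) / period + phase)

    if config.drift_kind == "ppm_sine":
        return lambda m, p: A * g(p) * np.ones_like(np.asarray(m, dtype=float))

    # sqrt_quadratic: ppm error linear in sqrt(m), i.e. the sqrt-domain drift
    # map sqrt(obs) vs sqrt(true) is quadratic — the TOF model class.
    # Normalized over the planted ion range so amplitude_ppm is the maximum
    # |drift| actually reached.
    ions = np.concatenate([config.reference_mz, config.test_mz])
    s_lo = np.sqrt(ions.min())
    s_hi = np.sqrt(ions.max())
    s_mid = 0.5 * (s_lo + s_hi)

    def eps(m, p):
        s = np.sqrt(np.asarray(m, dtype=float))
        q = 2.0 * (s - s_mid) / (s_hi - s_lo)
        return A * g(p) * q

    return eps


def simulate_dataset(config: SimulationConfig) -> tuple[MSIDataset, ROIMask, GroundTruth]:
    """Generate a synthetic dataset, its ROI mask and the planted ground truth.

    Pixels are acquired row-major; the ROI is the grid minus an off-sample
    border of ``roi_margin`` pixels.  Deterministic for a given config.
    """
    rng = np.random.default_rng(config.seed)
    n_rows, n_cols = config.n_rows, config.n_cols
    n_pixels = n_rows * n_cols
    grid = np.zeros((n_rows, n_cols), dtype=np.int8)
    m = config.roi_margin
    grid[m : n_rows - m or None, m : n_cols - m or None] = 1
    roi = ROIMask(grid)

    ion_mz = np.concatenate([config.reference_mz, config.test_mz])
    is_test = np.concatenate(
        [np.zeros(len(config.reference_mz), bool), np.ones(len(config.test_mz), bool)]
    )
    n_ions = ion_mz.size
    eps = _drift_field(config, n_pixels)
    mask_fns = {mz: _mask_fn(name, n_cols) for mz, name in config.ref_masks.items()}
    decoy_fns = [_mask_fn(d.mask, n_cols) for d in config.decoys]

    detected = np.zeros((n_pixels, n_ions), dtype=bool)
    prenoise = np.full((n_pixels, n_ions), np.nan)
    noisy = np.full((n_pixels, n_ions), np.nan)
    drift = np.full((n_pixels, n_ions), np.nan)
    rank = np.full((n_pixels, n_ions), -1, dtype=np.int64)

    spectra = []
    p = 0
    for row in range(1, n_rows + 1):
        for col in range(1, n_cols + 1):
            x, y = col, row
            on_roi = roi.contains(x, y)
            masses, intens, ion_of_peak = [], [], []
            if on_roi:
                d_ppm = eps(ion_mz, p)
                pre = ion_mz * (1.0 + d_ppm * 1e-6)
                nu = rng.normal(0.0, config.noise_sigma_ppm, n_ions)
                obs = pre * (1.0 + nu * 1e-6)
                det = rng.random(n_ions) < config.detection_prob
                for k in range(n_ions):
                    fn = mask_fns.get(float(ion_mz[k]))
                    if fn is not None and not fn(x, y):
                        det[k] = False
                detected[p] = det
                prenoise[p] = pre
                noisy[p] = obs
                drift[p] = d_ppm
                masses.extend(obs[det])
                intens.extend(np.exp(rng.normal(config.intensity_logmean, config.intensity_logsd, det.sum())))
                ion_of_peak.extend(np.nonzero(det)[0])
                for d_spec, fn in zip(config.decoys, decoy_fns):
                    if fn(x, y) and rng.random() < d_spec.detection_prob:
                        theo_d = d_spec.anchor_mz * (1.0 + d_spec.offset_ppm * 1e-6)
                        pre_d = theo_d * (1.0 + float(eps(theo_d, p)) * 1e-6)
                        obs_d = pre_d * (1.0 + rng.normal(0.0, config.noise_sigma_ppm) * 1e-6)
                        masses.append(obs_d)
                        intens.append(np.exp(rng.normal(config.intensity_logmean, config.intensity_logsd)))
                        ion_of_peak.append(-1)
            bg = rng.uniform(*config.background_range, config.n_background)
            masses.extend(bg)
            intens.extend(np.exp(rng.normal(config.intensity_logmean - 1.0, config.intensity_logsd, bg.size)))
            ion_of_peak.extend([-1] * bg.size)

            masses = np.asarray(masses, dtype=np.float64)
            order = np.argsort(masses, kind="stable")
            inv = np.empty_like(order)
            inv[order] = np.arange(order.size)
            for pos, ion in enumerate(ion_of_peak):
                if ion >= 0:
                    rank[p, ion] = inv[pos]
            spectra.append(
                PeakSpectrum(
                    p, x, y, masses[order], np.asarray(intens, dtype=np.float32)[order]
                )
            )
            p += 1

    dataset = MSIDataset(spectra, n_rows, n_cols, polarity="negative", analyzer=config.analyzer)
    truth = GroundTruth(ion_mz, is_test, detected, prenoise, noisy, drift, rank)
    return dataset, roi, truth


def _summary(abs_err: np.ndarray) -> dict:
    return {
        "median": float(np.median(abs_err)),
        "p95": float(np.percentile(abs_err, 95)),
        "n": int(abs_err.size),
    }


def score_recalibration(
    truth: GroundTruth,
    recal: MSIDataset,
    models=None,
    test_only: bool = True,
) -> dict:
    """Before/after |ppm error| summaries of the planted ions.

    'before' is the planted systematic drift |eps| of detected ions.  'after'
    is measured two ways: ``after_total`` reads the recalibrated peak back out
    of the spectrum (drift residue plus measurement noise), while ``after``
    evaluates each pixel's fitted calibration at the noise-free drifted mass
    when ``models`` are supplied — the systematic drift left uncorrected,
    which is the quantity the recalibration controls.
    """
    if truth.n_pixels != recal.n_pixels:
        raise ValueError("ground truth and dataset pixel sets differ")
    sel_ions = truth.is_test if test_only else np.ones_like(truth.is_test)
    model_by_pixel = {mdl.pixel_index: mdl for mdl in models} if models is not None else {}

    before, after_total, after_sys = [], [], []
    spectra = {s.pixel_index: s for s in recal.spectra}
    for p in range(truth.n_pixels):
        det = truth.detected[p] & sel_ions
        if not det.any():
            continue
        ions = np.nonzero(det)[0]
        theo = truth.ion_mz[ions]
        before.extend(np.abs(truth.drift_ppm[p, ions]))
        spec = spectra[p]
        ranks = truth.peak_rank[p, ions]
        ok = (ranks >= 0) & (ranks < len(spec))
        if ok.any():
            rec_m = spec.masses[ranks[ok]]
            after_total.extend(np.abs((rec_m - theo[ok]) / theo[ok] * 1e6))
        mdl = model_by_pixel.get(p)
        if mdl is not None:
            pred, _ = mdl.predict(truth.prenoise[p, ions])
            after_sys.extend(np.abs((pred - theo) / theo * 1e6))
        elif models is not None:
            # pixel had no fitted model (e.g. off-ROI): drift stays as-is
            after_sys.extend(np.abs(truth.drift_ppm[p, ions]))

    out = {
        "before": _summary(np.asarray(before)),
        "after_total": _summary(np.asarray(after_total)) if after_total else None,
    }
    if models is not None:
        out["after"] = _summary(np.asarray(after_sys))
    return out
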