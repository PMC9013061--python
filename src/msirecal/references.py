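"""Reference-ion database expansion and ppm-window peak matching.

A neutral-mass database (lipids, fatty acids, glycerides, cholesterols,
ceramides...) is expanded into singly charged adduct m/z values appropriate
for the acquisition polarity.  For each candidate reference m/z M, every
observed peak within the closed window [M - lambda, M + lambda],
lambda = W * M * 1e-6, across all ROI pixels is collected; candidates
detected in fewer than 75% of ROI pixels are dropped (coverage filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MSIDataset, ROIMask

#: Adduct mass deltas in Da (monoisotopic, including the electron mass).
ADDUCTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (+1.007276, "positive"),
    "[M+Na]+": (+22.989218, "positive"),
    "[M+K]+": (+38.963158, "positive"),
    "[M-H]-": (-1.007276, "negative"),
    "[M+Cl]-": (+34.969402, "negative"),
}


@dataclass(frozen=True)
class AdductSpec:
    label: str
    mass_delta: float
    polarity: str

    @classmethod
    def from_label(cls, label: str) -> "AdductSpec":
        delta, pol = ADDUCTS[label]
        return cls(label, delta, pol)


def adduct_mz(neutral_mass: float, adduct: AdductSpec, polarity: str | None = None) -> float:
    """m/z of a singly charged adduct of a neutral monoisotopic mass."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if polarity is not None and adduct.polarity != polarity:
        raise ValueError(
            f"adduct {adduct.label} is a {adduct.polarity}-mode species, dataset is {polarity}"
        )
    return neutral_mass + adduct.mass_delta


def ppm_window(M: float, W: float) -> tuple[float, float]:
    """Closed search interval [M - lambda, M + lambda], lambda = W * M * 1e-6."""
    lam = W * M * 1e-6
    return M - lam, M + lam


@dataclass
class ReferenceDatabase:
    """Neutral-mass records (name, formula, neutral_mass, class)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"name", "formula", "neutral_mass"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"database needs columns {sorted(required)}")
        if (self.records["neutral_mass"] <= 0).any():
            raise ValueError("database contains non-positive neutral masses")

    @classmethod
    def from_csv(cls, path: str) -> "ReferenceDatabase":
        return cls(pd.read_csv(path))

    @classmethod
    def builtin_fatty_acids(cls) -> "ReferenceDatabase":
        """Starter database of ubiquitous tissue fatty acids (negative mode).

        Their deprotonated forms are the reference ions most consistently
        detected in DESI-MSI of biological tissue.
        """
        from importlib.resources import files

        return cls(pd.read_csv(files("msirecal") / "data" / "fatty_acids_neg.csv"))

    def candidate_mz(self, polarity: str) -> pd.DataFrame:
        """Expand to adduct m/z for one polarity, deduplicated at 1e-4 Th.

        Near-duplicate database masses are kept as separate candidates (the
        KDE track filter disambiguates them); only exactly coincident adduct
        m/z (within 1e-4 Th rounding) are merged, recording contributors.
        """
        rows = []
        for label, (delta, pol) in ADDUCTS.items():
            if pol != polarity:
                continue
            for rec in self.records.itertuples():
                rows.append(
                    {
                        "mz": rec.neutral_mass + delta,
                        "adduct": label,
                        "name": rec.name,
                        "formula": rec.formula,
                    }
                )
        df = pd.DataFrame(rows)
        df["mz_key"] = df["mz"].round(4)
        agg = (
            df.groupby("mz_key")
            .agg(mz=("mz", "first"), contributors=("name", lambda s: ";".join(sorted(set(s)))))
            .reset_index(drop=True)
            .sort_values("mz")
            .reset_index(drop=True)
        )
        return agg


@dataclass
class ReferenceMatchTable:
    """All candidate peak matches for one reference m/z across ROI pixels."""

    reference_mz: float
    pixels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    peak_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    masses: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensities: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_matches(self) -> int:
        return int(self.pixels.size)

    @property
    def distinct_pixels(self) -> int:
        return int(np.unique(self.pixels).size)

    def coverage(self, n_roi: int) -> float:
        return self.distinct_pixels / n_roi if n_roi else 0.0


def search_reference(dataset: MSIDataset, roi: ROIMask, M: float, W: float) -> ReferenceMatchTable:
    """Find all ROI-pixel peaks inside the closed ppm window around M.

    Peak lists are sorted by m/z, so each pixel is searched with two binary
    searches (O(log n) per pixel); multiple matches per pixel are all kept.
    """
    lo, hi = ppm_window(M, W)
    pix, idx, mz, inten = [], [], [], []
    for spec in dataset.spectra:
        if len(spec) == 0 or not roi.contains(spec.x, spec.y):
            continue
        a = int(np.searchsorted(spec.masses, lo, side="left"))
        b = int(np.searchsorted(spec.masses, hi, side="right"))
        for j in range(a, b):
            pix.append(spec.pixel_index)
            idx.append(j)
            mz.append(spec.masses[j])
            inten.append(float(spec.intensities[j]))
    return ReferenceMatchTable(
        M,
        np.array(pix, dtype=np.intp),
        np.array(idx, dtype=np.intp),
        np.array(mz, dtype=np.float64),
        np.array(inten, dtype=np.float64),
    )


def coverage_filter(
    tables: list[ReferenceMatchTable], roi: ROIMask, min_frac: float = 0.75
) -> list[ReferenceMatchTable]:
    """Keep candidates detected in at least ``min_frac`` of ROI pixels.

    Coverage counts distinct pixels with at least one match; the boundary is
    inclusive (exactly 75% of pixels passes at the default).
    """
    n_roi = roi.n_roi
    if n_roi == 0:
        raise ValueError("ROI contains no sample pixels")
    return [t for t in tables if t.distinct_pixels / n_roi >= min_frac]
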