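"""imzML and ROI-mask input/output.

Only processed-mode (per-pixel m/z arrays) centroid imzML is supported: the
recalibration operates on per-pixel centroids, so continuous-mode files must
be centroided and converted first.  The spectrum storage order of the imzML
file is taken as the acquisition order; ``pixel_index`` is assigned 0..N-1
in that order and serves as the time proxy for all drift models.  An explicit
acquisition-order vector can be supplied to override this assumption.

Masses are held as 64-bit floats (accuracy critical), intensities as 32-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class PeakSpectrum:
    """One pixel's centroided peak list.

    Parameters
    ----------
    pixel_index : int
        0-based acquisition order within the dataset.
    x, y : int
        1-based grid coordinates (imzML convention).
    masses : ndarray of float64
        m/z values in Thomson, strictly increasing.
    intensities : ndarray of float32
        Non-negative abundances, same length as ``masses``.
    """

    pixel_index: int
    x: int
    y: int
    masses: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.masses.shape != self.intensities.shape or self.masses.ndim != 1:
            raise FormatError(
                f"pixel {self.pixel_index}: masses and intensities must be 1D and equal length"
            )
        if self.masses.size and np.any(self.intensities < 0):
            raise FormatError(f"pixel {self.pixel_index}: negative intensity")
        if self.masses.size > 1 and np.any(np.diff(self.masses) < 0):
            order = np.argsort(self.masses, kind="stable")
            self.masses = self.masses[order]
            self.intensities = self.intensities[order]

    def __len__(self) -> int:
        return int(self.masses.size)


@dataclass
class MSIDataset:
    """An ordered collection of per-pixel spectra on an n_rows x n_cols grid."""

    spectra: list[PeakSpectrum]
    n_rows: int
    n_cols: int
    polarity: str = "negative"
    analyzer: str = "orbitrap"

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise FormatError(f"polarity must be 'positive' or 'negative', got {self.polarity!r}")
        if self.analyzer not in ("orbitrap", "tof"):
            raise FormatError(f"analyzer must be 'orbitrap' or 'tof', got {self.analyzer!r}")
        if len(self.spectra) > self.n_rows * self.n_cols:
            raise FormatError("more spectra than grid positions")
        idx = [s.pixel_index for s in self.spectra]
        if len(set(idx)) != len(idx):
            raise FormatError("pixel_index values are not unique")
        self.spectra = sorted(self.spectra, key=lambda s: s.pixel_index)

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)

    def mass_range(self) -> tuple[float, float]:
        lo = min((s.masses[0] for s in self.spectra if len(s)), default=np.nan)
        hi = max((s.masses[-1] for s in self.spectra if len(s)), default=np.nan)
        return float(lo), float(hi)


@dataclass
class ROIMask:
    """Binary sample/off-sample map; 1 = on-tissue."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise FormatError("ROI mask must be a 2D matrix")
        if not np.isin(self.grid, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.grid, (0, 1)))[0]
            raise FormatError(f"ROI mask entry at row {bad[0]}, col {bad[1]} is not 0/1")
        self.grid = self.grid.astype(np.int8)

    @property
    def n_roi(self) -> int:
        return int(self.grid.sum())

    def contains(self, x: int, y: int) -> bool:
        """1-based pixel coordinates -> on-tissue flag."""
        return bool(self.grid[y - 1, x - 1])

    def roi_pixel_indices(self, dataset: MSIDataset) -> np.ndarray:
        """Acquisition indices of the dataset pixels inside the mask."""
        return np.array(
            [s.pixel_index for s in dataset.spectra if self.contains(s.x, s.y)], dtype=np.intp
        )


def read_imzml(path: str, acquisition_order: np.ndarray | None = None) -> MSIDataset:
    """Read a processed-mode centroid imzML file into an :class:`MSIDataset`.

    ``pixel_index`` is assigned in storage order unless ``acquisition_order``
    (a permutation of 0..N-1 giving each stored spectrum's acquisition rank)
    is provided.  Unsorted m/z arrays are sorted ascending with intensities
    permuted consistently.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    try:
        parser = ImzMLParser(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # garbled XML / missing ibd
        raise IOError(f"cannot read imzML file {path!r}: {exc}") from exc

    params = parser.metadata.file_description.param_by_name
    if params.get("continuous") and not params.get("processed"):
        raise FormatError(
            f"{path!r} is a continuous-mode imzML file; centroid the spectra and "
            "convert to processed mode before recalibration"
        )

    n = len(parser.coordinates)
    if acquisition_order is None:
        order = np.arange(n)
    else:
        order = np.asarray(acquisition_order, dtype=np.intp)
        if sorted(order.tolist()) != list(range(n)):
            raise FormatError("acquisition_order must be a permutation of 0..N-1")

    spectra = []
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=np.float64)
        ints = np.asarray(ints)
        keep = mzs > 0  # drop the m/z 0 sentinel used to store empty spectra
        spectra.append(PeakSpectrum(int(order[i]), int(x), int(y), mzs[keep], ints[keep]))

    xs = [s.x for s in spectra]
    ys = [s.y for s in spectra]
    polarity = parser.polarity if parser.polarity in ("positive", "negative") else "negative"
    return MSIDataset(spectra, n_rows=max(ys), n_cols=max(xs), polarity=polarity)


def write_imzml(dataset: MSIDataset, path: str) -> str:
    """Write a dataset as processed-mode centroid imzML (m/z float64, intensity float32).

    A peak-less pixel is stored as a single sentinel entry at m/z 0 (the
    format library cannot encode zero-length arrays); :func:`read_imzml`
    strips it back out, so the roundtrip is the identity.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    with ImzMLWriter(
        str(path),
        polarity=dataset.polarity,
        mode="processed",
        spec_type="centroid",
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
    ) as writer:
        for spec in dataset.spectra:
            if len(spec) == 0:
                writer.addSpectrum(np.zeros(1), np.zeros(1), (spec.x, spec.y, 1))
            else:
                writer.addSpectrum(spec.masses, spec.intensities, (spec.x, spec.y, 1))
    return str(path)


def read_roi_mask(path: str, n_rows: int | None = None, n_cols: int | None = None) -> ROIMask:
    """Read a dense 0/1 CSV (row-major image orientation) into an :class:`ROIMask`."""
    rows = []
    with open(path) as fh:
        for r, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            vals = []
            for c, tok in enumerate(line.split(",")):
                tok = tok.strip()
                if tok not in ("0", "1"):
                    raise FormatError(f"{path}: non-binary entry {tok!r} at row {r}, col {c}")
                vals.append(int(tok))
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: empty ROI mask file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise FormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    grid = np.array(rows, dtype=np.int8)
    if n_rows is not None and grid.shape != (n_rows, n_cols):
        raise FormatError(
            f"{path}: ROI mask is {grid.shape[0]}x{grid.shape[1]}, expected {n_rows}x{n_cols}"
        )
    return ROIMask(grid)


def write_roi_mask(mask: ROIMask, path: str) -> str:
    np.savetxt(path, mask.grid, fmt="%d", delimiter=",")
    return str(path)


def read_pixel_labels(path: str):
    """Read a pixel label CSV with columns x,y,label (label in {sample, background}).

    Returns a list of (x, y, label) tuples; used to train the ROI classifier.
    """
    import csv

    entries = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        required = {"x", "y", "label"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FormatError(f"{path}: expected header columns x,y,label")
        for row in reader:
            label = row["label"].strip().lower()
            if label not in ("sample", "background"):
                raise FormatError(f"{path}: label must be 'sample' or 'background', got {label!r}")
            entries.append((int(row["x"]), int(row["y"]), label))
    if not entries:
        raise FormatError(f"{path}: no labeled pixels")
    return entries
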