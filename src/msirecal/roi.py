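"""Sample/background pixel classification.

Pixels are featurized by uniform 1-m/z binning of their peak intensities, a
linear SVM is trained on user-labeled pixels (labels come from a CSV; the
original interactive labeling GUI is out of scope), and small 8-connected
sample components are reassigned to the background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.svm import LinearSVC

from .io import MSIDataset, ROIMask


@dataclass
class BinnedFeatures:
    """pixels x bins summed intensities on a uniform 1-m/z grid (half-open bins)."""

    bin_edges: np.ndarray
    matrix: np.ndarray
    pixel_coords: list[tuple[int, int]]  # (x, y) per row, dataset order


def bin_spectra(dataset: MSIDataset) -> BinnedFeatures:
    """Sum peak intensities into unit-width m/z bins [k, k+1) with integer edges."""
    if dataset.n_pixels == 0:
        raise ValueError("empty dataset")
    lo, hi = dataset.mass_range()
    if np.isnan(lo):  # all spectra empty
        lo, hi = 0.0, 1.0
    edges = np.arange(np.floor(lo), np.ceil(hi) + 1.0)
    if edges[-1] <= hi:  # peak exactly on the last edge belongs to [edge, edge+1)
        edges = np.append(edges, edges[-1] + 1.0)
    nbins = len(edges) - 1
    matrix = np.zeros((dataset.n_pixels, nbins))
    for row, spec in enumerate(dataset.spectra):
        if len(spec) == 0:
            continue
        idx = np.floor(spec.masses - edges[0]).astype(np.intp)
        np.add.at(matrix[row], idx, spec.intensities.astype(np.float64))
    coords = [(s.x, s.y) for s in dataset.spectra]
    return BinnedFeatures(edges, matrix, coords)


def _normalize_rows(matrix: np.ndarray) -> np.ndarray:
    totals = matrix.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return matrix / totals


def fit_roi_classifier(features: BinnedFeatures, labels, C: float = 1.0) -> LinearSVC:
    """Fit a linear SVM on TIC-normalized binned features of labeled pixels.

    ``labels`` is an iterable of (x, y, label) with label in
    {'sample', 'background'}; both classes must be present.
    """
    coord_to_row = {xy: i for i, xy in enumerate(features.pixel_coords)}
    rows, y = [], []
    for x, yy, label in labels:
        if (x, yy) not in coord_to_row:
            raise ValueError(f"labeled pixel ({x},{yy}) not present in dataset")
        rows.append(coord_to_row[(x, yy)])
        y.append(1 if label == "sample" else 0)
    if len(set(y)) < 2:
        raise ValueError("labels must include both 'sample' and 'background' pixels")
    X = _normalize_rows(features.matrix[rows])
    model = LinearSVC(C=C, random_state=0)
    model.fit(X, y)
    return model


def predict_roi(model: LinearSVC, features: BinnedFeatures, n_rows: int, n_cols: int) -> ROIMask:
    """Predict every pixel's class and return the binary ROI map."""
    pred = model.predict(_normalize_rows(features.matrix))
    grid = np.zeros((n_rows, n_cols), dtype=np.int8)
    for (x, y), p in zip(features.pixel_coords, pred):
        grid[y - 1, x - 1] = int(p)
    return ROIMask(grid)


def clean_components(mask: ROIMask, min_size: int = 50) -> ROIMask:
    """Reassign 8-connected sample components smaller than ``min_size`` to background.

    Components of size >= min_size are kept unchanged; the operation is
    idempotent.
    """
    structure = np.ones((3, 3), dtype=int)  # 8-neighborhood
    labeled, n_comp = ndimage.label(mask.grid, structure=structure)
    if n_comp == 0:
        return ROIMask(mask.grid.copy())
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n_comp + 1))
    keep = np.zeros(n_comp + 1, dtype=bool)
    keep[1:] = sizes >= min_size
    return ROIMask(keep[labeled].astype(np.int8))
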