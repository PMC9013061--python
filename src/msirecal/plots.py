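"""Optional diagnostic figures (matplotlib).

Per-reference track plots show the matched (pixel order, delta-m/z) cloud
with the ridge spline and the GAM trend overlaid, inliers and outliers
distinguished; the evaluation scatter shows each dataset's Delta-tilde
against the bootstrap significance.
"""

from __future__ import annotations

import numpy as np


def plot_reference_track(matches, spline, trend, diag, path: str) -> str:
    """Matched-point cloud with ridge spline and GAM overlays for one reference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = matches.reference_mz
    fig, ax = plt.subplots(figsize=(8, 4))
    delta = matches.masses - ref
    ax.scatter(matches.pixels[diag.inlier], delta[diag.inlier], s=3, c="0.3", label="inliers")
    ax.scatter(
        matches.pixels[~diag.inlier], delta[~diag.inlier], s=3, c="tab:red", label="outliers"
    )
    xs = np.linspace(matches.pixels.min(), matches.pixels.max(), 400)
    ax.plot(xs, spline(xs) - ref, c="tab:orange", lw=1.5, label="ridge spline")
    if trend is not None:
        ax.plot(xs, trend.predict(xs) - ref, c="tab:green", lw=1.5, label="GAM trend")
    ax.set_xlabel("pixel order")
    ax.set_ylabel(f"m/z - {ref:.4f}")
    ax.legend(markerscale=3, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_match_image(matches, diag, n_rows: int, n_cols: int, dataset, path: str) -> str:
    """Ion image of the matched intensities (smallest-residual match per pixel)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.full((n_rows, n_cols), np.nan)
    coord = {s.pixel_index: (s.x, s.y) for s in dataset.spectra}
    best = {}
    for i in range(matches.n_matches):
        p = int(matches.pixels[i])
        if p not in best or diag.residuals[i] < diag.residuals[best[p]]:
            best[p] = i
    for p, i in best.items():
        x, y = coord[p]
        img[y - 1, x - 1] = matches.intensities[i]
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(img, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="intensity")
    ax.set_title(f"matched intensity, m/z {matches.reference_mz:.4f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_delta_scatter(reports, labels, path: str) -> str:
    """Delta-tilde (ppm) versus -log10 bootstrap p across datasets."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for rep, lab in zip(reports, labels):
        ax.scatter(rep.delta_tilde, -np.log10(max(rep.p_value, 1e-10)), s=30)
        ax.annotate(lab, (rep.delta_tilde, -np.log10(max(rep.p_value, 1e-10))), fontsize=7)
    ax.axhline(-np.log10(0.05), ls="--", c="0.6")
    ax.axvline(0.0, ls=":", c="0.6")
    ax.set_xlabel(r"$\tilde{\Delta}$ (ppm)")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
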