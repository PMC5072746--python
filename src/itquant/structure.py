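"""Model-structure fingerprints from rasterized causal information planes.

A simulation run (e.g. one land model under one forcing scenario) produces a
point cloud in the entropy-complexity or Shannon-Fisher plane — one point per
grid cell.  Rasterizing each cloud on a regular 25x25 pixel grid and
normalizing the counts yields a fixed-length "fingerprint" vector per run.
Principal component analysis of these vectors separates runs by model
structure: runs of the same model under different scenarios land close
together, different models apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gridded import GriddedField, itq_map
from .ordinal import OrdinalConfig

__all__ = [
    "PlaneRaster",
    "StructureScores",
    "rasterize_plane",
    "assemble_count_matrix",
    "pca_scores",
    "windowed_runs",
]


@dataclass
class PlaneRaster:
    """Normalized 2-D histogram of plane points on [0,1] x [0,1]."""

    plane: str  # "HC" or "HF"
    npix: int
    counts: np.ndarray  # (npix, npix), axis 0 = first coordinate (H)
    normalized: bool
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.npix, self.npix):
            raise ValueError("counts must be (npix, npix)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.normalized and abs(self.counts.sum() - 1.0) > 1e-12:
            raise ValueError("normalized raster must sum to 1")

    def vector(self) -> np.ndarray:
        return self.counts.ravel()


@dataclass
class StructureScores:
    """PCA scores of run fingerprint vectors."""

    labels: list[str]
    scores: np.ndarray  # (runs, components)
    explained_variance: np.ndarray  # fractions, non-increasing
    kept_pixels: np.ndarray  # flat indices retained in the count matrix


def rasterize_plane(points, plane: str = "HC", npix: int = 25,
                    label: str = "") -> PlaneRaster:
    """Bin plane points on a regular ``npix x npix`` grid over [0,1]^2.

    Pixels are half-open ``[i/npix, (i+1)/npix)`` with the top edge closed;
    counts are normalized to sum to 1 so rasters from point clouds of
    different sizes (spatial resolutions) are comparable.
    """
    if plane not in ("HC", "HF"):
        raise ValueError("plane must be 'HC' or 'HF'")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if pts.shape[0] == 0:
        raise ValueError("no points to rasterize")
    if np.any(pts < 0.0) or np.any(pts > 1.0):
        raise ValueError("plane coordinates must lie in [0, 1]")
    ix = np.minimum((pts[:, 0] * npix).astype(int), npix - 1)
    iy = np.minimum((pts[:, 1] * npix).astype(int), npix - 1)
    counts = np.zeros((npix, npix))
    np.add.at(counts, (ix, iy), 1.0)
    counts /= counts.sum()
    return PlaneRaster(plane=plane, npix=npix, counts=counts,
                       normalized=True, label=label)


def assemble_count_matrix(rasters):
    """Stack raster vectors into a runs x kept-pixels matrix.

    Pixels (columns) that are zero across every run are dropped — in the
    H x C plane many are empty by necessity, lying above the upper
    complexity limit curve.  Returns ``(matrix, kept_pixels, labels)``; row
    sums are unchanged by the removal.
    """
    rasters = list(rasters)
    if not rasters:
        raise ValueError("no rasters")
    planes = {r.plane for r in rasters}
    if len(planes) != 1:
        raise ValueError("mixed plane types")
    if len({r.npix for r in rasters}) != 1:
        raise ValueError("rasters must share npix")
    mat = np.vstack([r.vector() for r in rasters])
    kept = np.flatnonzero(mat.any(axis=0))
    return mat[:, kept], kept, [r.label for r in rasters]


def pca_scores(matrix, n_components: int = 2, labels=None,
               kept_pixels=None) -> StructureScores:
    """PCA of fingerprint vectors: column-centered SVD, no variance scaling.

    The count vectors share a common scale (each sums to 1), so only mean
    centering is applied.  Returns per-run scores on the leading components
    and their explained-variance fractions.
    """
    from sklearn.decomposition import PCA

    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 runs")
    max_comp = min(mat.shape[0] - 1, mat.shape[1])
    if n_components > max_comp:
        raise ValueError(
            f"n_components {n_components} > min(runs-1, pixels) = {max_comp}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(mat)
    if labels is None:
        labels = [f"run{i}" for i in range(mat.shape[0])]
    if kept_pixels is None:
        kept_pixels = np.arange(mat.shape[1])
    return StructureScores(
        labels=list(labels),
        scores=scores,
        explained_variance=pca.explained_variance_ratio_,
        kept_pixels=np.asarray(kept_pixels),
    )


def windowed_runs(
    grid: GriddedField,
    window_length: int,
    stride: int,
    config: OrdinalConfig | None = None,
    plane: str = "HC",
    npix: int = 25,
    label: str = "run",
    min_valid_fraction: float = 0.9,
):
    """Slice a run into time windows and rasterize each window's point cloud.

    Windows start at 0, step ``stride``, and must fit entirely:
    ``floor((T - window_length) / stride) + 1`` windows for time length T.
    Per window, cell-wise ITQ points populate one :class:`PlaneRaster`;
    labels carry the run name and the window start index.
    """
    config = config or OrdinalConfig()
    T = grid.shape[0]
    if not 1 <= window_length <= T:
        raise ValueError("window_length must lie in [1, time length]")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    out = []
    for start in range(0, T - window_length + 1, stride):
        sub = GriddedField(
            values=grid.values[start : start + window_length],
            time=grid.time[start : start + window_length],
            lat=grid.lat,
            lon=grid.lon,
            missing_mask=grid.missing_mask[start : start + window_length],
            name=grid.name,
            step=grid.step,
            step_unit=grid.step_unit,
        )
        maps = itq_map(sub, config, min_valid_fraction=min_valid_fraction)
        pts = maps.points() if plane == "HC" else maps.points_hf()
        raster = rasterize_plane(np.clip(pts, 0.0, 1.0), plane=plane,
                                 npix=npix, label=f"{label}@{start}")
        out.append((raster.label, raster))
    return out
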