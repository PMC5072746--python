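"""Per-grid-cell quantifier maps and model-observation mismatch maps.

Each land grid cell of a space-time field (time x lat x lon) holds a time
series; applying the ITQ suite cell-wise yields maps of permutation entropy,
statistical complexity and Fisher information whose spatial gradients reflect
differences in temporal dynamics.  Two mismatch maps compare an observed and
a simulated field: the Jensen-Shannon divergence between their cell-wise
ordinal pattern distributions (sensitive to dynamics, blind to magnitude) and
the conventional RMSE (sensitive to magnitude, blind to ordinal dynamics) —
complementary, non-redundant metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .measures import jensen_shannon_divergence, itq_suite
from .ordinal import OrdinalConfig, TimeSeries, ordinal_distribution

__all__ = [
    "GriddedField",
    "ITQMaps",
    "itq_map",
    "rgb_composite",
    "jsd_map",
    "rmse_map",
    "metric_correlation",
]


@dataclass
class GriddedField:
    """A 3-D (time x lat x lon) field with coordinates and missing mask."""

    values: np.ndarray
    time: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    missing_mask: np.ndarray | None = None
    name: str = "field"
    units: str = ""
    step: float = 1.0
    step_unit: str = "month"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (time, lat, lon)")
        self.time = np.asarray(self.time)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        nt, ny, nx = self.values.shape
        if (self.time.size, self.lat.size, self.lon.size) != (nt, ny, nx):
            raise ValueError("coordinate lengths must match array dimensions")
        for name, coord in (("lat", self.lat), ("lon", self.lon)):
            d = np.diff(coord)
            if coord.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} must be strictly monotone")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape must match values")
            self.missing_mask = self.missing_mask | np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def cell_series(self, i: int, j: int) -> TimeSeries:
        """The time series of cell (lat index i, lon index j)."""
        return TimeSeries(
            self.values[:, i, j],
            step=self.step,
            step_unit=self.step_unit,
            missing_mask=self.missing_mask[:, i, j],
        )

    def same_grid(self, other: "GriddedField") -> bool:
        return (
            self.shape == other.shape
            and np.array_equal(self.lat, other.lat)
            and np.array_equal(self.lon, other.lon)
        )

    def to_dataset(self):
        """Represent as an :class:`xarray.Dataset` (CF-style dims)."""
        import xarray as xr

        arr = np.where(self.missing_mask, np.nan, self.values)
        da = xr.DataArray(
            arr,
            dims=("time", "lat", "lon"),
            coords={"time": self.time, "lat": self.lat, "lon": self.lon},
            name=self.name,
            attrs={"units": self.units} if self.units else {},
        )
        return da.to_dataset()


@dataclass
class ITQMaps:
    """Cell-wise (H, C, F) maps sharing one missing mask."""

    H: np.ndarray
    C: np.ndarray
    F: np.ndarray
    missing_mask: np.ndarray
    lat: np.ndarray
    lon: np.ndarray
    config: OrdinalConfig = field(default_factory=OrdinalConfig)

    def points(self) -> np.ndarray:
        """Valid (H, C) pairs as an (n, 2) array (for plane rasterization)."""
        ok = ~self.missing_mask
        return np.column_stack([self.H[ok], self.C[ok]])

    def points_hf(self) -> np.ndarray:
        ok = ~self.missing_mask
        return np.column_stack([self.H[ok], self.F[ok]])


def itq_map(
    grid: GriddedField,
    config: OrdinalConfig | None = None,
    min_valid_fraction: float = 0.9,
) -> ITQMaps:
    """Apply the ITQ suite to every grid cell.

    Cells whose fraction of valid (non-missing) time steps is below
    ``min_valid_fraction``, or whose series is degenerate (e.g. constant),
    are missing in all three maps.
    """
    config = config or OrdinalConfig()
    nt, ny, nx = grid.shape
    H = np.full((ny, nx), np.nan)
    C = np.full((ny, nx), np.nan)
    F = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            valid_frac = 1.0 - grid.missing_mask[:, i, j].mean()
            if valid_frac < min_valid_fraction:
                continue
            try:
                res = itq_suite(grid.cell_series(i, j), config)
            except ValueError:
                continue
            H[i, j], C[i, j], F[i, j] = res.H, res.C, res.F
    mask = np.isnan(H)
    if mask.all():
        raise ValueError("empty grid: no cell passed the validity checks")
    return ITQMaps(H=H, C=C, F=F, missing_mask=mask, lat=grid.lat,
                   lon=grid.lon, config=config)


def rgb_composite(maps: ITQMaps) -> np.ndarray:
    """RGBA composite: R = H, G = C, B = F, each scaled [0,1] -> [0,255].

    Scaling is linear over the theoretical [0, 1] range (not per-map
    min-max) so composites are comparable across datasets.  Missing cells
    are transparent (alpha 0).  Rounding is half-up.
    """
    shapes = {maps.H.shape, maps.C.shape, maps.F.shape, maps.missing_mask.shape}
    if len(shapes) != 1:
        raise ValueError("maps must share one shape")
    ny, nx = maps.H.shape
    out = np.zeros((ny, nx, 4), dtype=np.uint8)
    for k, band in enumerate((maps.H, maps.C, maps.F)):
        scaled = np.floor(np.clip(band, 0.0, 1.0) * 255.0 + 0.5)
        out[:, :, k] = np.where(maps.missing_mask, 0, scaled).astype(np.uint8)
    out[:, :, 3] = np.where(maps.missing_mask, 0, 255).astype(np.uint8)
    return out


def _check_comparable(obs: GriddedField, mod: GriddedField) -> None:
    if not obs.same_grid(mod):
        raise ValueError("grid mismatch: shapes or coordinates differ")
    if obs.shape[0] != mod.shape[0]:
        raise ValueError("grid mismatch: time axes differ")


def jsd_map(
    obs: GriddedField,
    mod: GriddedField,
    config: OrdinalConfig | None = None,
    min_valid_fraction: float = 0.9,
) -> np.ndarray:
    """Cell-wise Jensen-Shannon divergence (nats) between two fields.

    Per cell, the ordinal pattern distributions of the observed and modelled
    series are compared; invariant under strictly increasing transformations
    of either field, hence zero for pure magnitude biases.
    """
    _check_comparable(obs, mod)
    config = config or OrdinalConfig()
    nt, ny, nx = obs.shape
    out = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            vo = 1.0 - obs.missing_mask[:, i, j].mean()
            vm = 1.0 - mod.missing_mask[:, i, j].mean()
            if min(vo, vm) < min_valid_fraction:
                continue
            try:
                po = ordinal_distribution(obs.cell_series(i, j), config)
                pm = ordinal_distribution(mod.cell_series(i, j), config)
            except ValueError:
                continue
            out[i, j] = jensen_shannon_divergence(po, pm)
    return out


def rmse_map(obs: GriddedField, mod: GriddedField) -> np.ndarray:
    """Cell-wise root mean squared difference over shared valid time steps."""
    _check_comparable(obs, mod)
    both = ~(obs.missing_mask | mod.missing_mask)
    diff = np.where(both, obs.values - mod.values, np.nan)
    with np.errstate(invalid="ignore"):
        mse = np.nanmean(diff**2, axis=0)
    return np.sqrt(mse)


def metric_correlation(jsd: np.ndarray, rmse: np.ndarray) -> float:
    """Pearson correlation between two mismatch maps over shared valid cells."""
    jsd = np.asarray(jsd, dtype=float)
    rmse = np.asarray(rmse, dtype=float)
    if jsd.shape != rmse.shape:
        raise ValueError("maps must share one shape")
    ok = ~(np.isnan(jsd) | np.isnan(rmse))
    if ok.sum() < 3:
        raise ValueError("need at least 3 valid cells")
    a, b = jsd[ok], rmse[ok]
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero variance in a mismatch map; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
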