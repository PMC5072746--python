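"""Canonical synthetic processes for the causal information planes.

These generators populate the reference geography of the entropy-complexity
(H x C) and Shannon-Fisher (H x F) planes: periodic signals sit at low H /
low C / high F, white noise at the (1, 0, ~0) corner, coloured 1/f^k noise at
intermediate positions ordered by k, and chaotic maps at intermediate H with
near-maximal C.  GPP-like site series and grids emulate the seasonal/diurnal
structure of ecosystem carbon-flux data so the gridded and structural
diagnostics can be exercised without any external dataset.

All generators are seed-deterministic.
"""

from __future__ import annotations

import numpy as np

from .ordinal import TimeSeries

__all__ = [
    "white_noise",
    "k_noise",
    "logistic_map",
    "harmonic",
    "gpp_site",
    "gpp_grid",
]

#: samples per day for each supported sub-monthly resolution label
RESOLUTION_STEPS_PER_DAY = {"halfhourly": 48, "hourly": 24, "daily": 1}


def white_noise(n: int, seed: int = 0) -> TimeSeries:
    """IID standard Gaussian noise of length ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return TimeSeries(rng.standard_normal(n), step=1.0, step_unit="step")


def k_noise(n: int, k: float, seed: int = 0) -> TimeSeries:
    """Coloured noise with power spectrum proportional to 1/f^k.

    Spectral synthesis: unit amplitudes scaled by f^(-k/2), iid uniform
    phases, zero DC component, inverse FFT, then standardized to zero mean
    and unit variance.  ``k = 0`` reduces to white noise; 1 <= k <= 3 spans
    the classic coloured-noise band (pink to black).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 <= k <= 3.0:
        raise ValueError("spectral exponent k must lie in [0, 3]")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-k / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = amp[-1] * np.cos(phases[-1])  # Nyquist bin must be real
    x = np.fft.irfft(spec, n=n)
    x = (x - x.mean()) / x.std()
    return TimeSeries(x, step=1.0, step_unit="step")


def logistic_map(
    n: int, r: float = 4.0, x0: float = 0.3, warmup: int = 1000
) -> TimeSeries:
    """Orbit of the logistic map x_{t+1} = r x_t (1 - x_t).

    A ``warmup`` transient is discarded before emitting ``n`` samples.  For
    r = 4 the map is fully chaotic on [0, 1]; the degenerate orbit through
    x = 0.5 (which maps to 1 and then sticks at 0) is left to the caller.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < r <= 4.0:
        raise ValueError("map parameter r must lie in (0, 4]")
    if not 0.0 < x0 < 1.0:
        raise ValueError("initial value x0 must lie in (0, 1)")
    if warmup < 0:
        raise ValueError("warmup must be >= 0")
    x = x0
    for _ in range(warmup):
        x = r * x * (1.0 - x)
    out = np.empty(n)
    out[0] = x
    for t in range(1, n):
        x = r * x * (1.0 - x)
        out[t] = x
    return TimeSeries(out, step=1.0, step_unit="iteration")


def harmonic(
    n: int,
    period: float = 48.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeSeries:
    """Sinusoid ``amplitude * sin(2 pi t / period)`` plus Gaussian noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if period < 2:
        raise ValueError("period must be >= 2 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(n)
    x = amplitude * np.sin(2.0 * np.pi * t / period)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=n)
    return TimeSeries(x, step=1.0, step_unit="step")


def _seasonal_signal(frac_of_year: np.ndarray, regime: str, amplitude: float):
    """Noise-free seasonal GPP signal at fractional-year positions.

    ``unimodal``: single mid-summer maximum.  ``bimodal``: mid-summer
    depression carved out of the seasonal hump, producing an early-summer and
    an autumn peak (the water-limited Mediterranean pattern).  ``noise``
    returns a flat zero baseline (all structure then comes from noise).
    """
    phase = 2.0 * np.pi * (frac_of_year - 0.25)  # maximum at mid-year
    base = 0.5 * amplitude * (1.0 + np.sin(phase))
    if regime == "unimodal":
        return base
    if regime == "bimodal":
        depression = 0.7 * amplitude * np.exp(
            -0.5 * ((frac_of_year - 0.5) / 0.07) ** 2
        )
        return np.clip(base - depression, 0.0, None)
    if regime == "noise":
        return np.zeros_like(frac_of_year)
    raise ValueError(f"unknown regime {regime!r}")


def _ar1(n: int, phi: float, sd: float, rng) -> np.ndarray:
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def gpp_site(
    years: int = 10,
    resolution: str = "monthly",
    regime: str = "unimodal",
    seed: int = 0,
    amplitude: float = 10.0,
    noise_sd: float = 1.0,
    ar_phi: float = 0.6,
) -> TimeSeries:
    """GPP-like site series: seasonal cycle, optional diurnal cycle, AR(1) noise.

    Parameters mimic a mid-latitude flux-tower record: ``amplitude`` is the
    peak seasonal GPP (arbitrary flux units, default 10), ``noise_sd`` the
    standard deviation of the autocorrelated observation/weather noise
    (default 1, i.e. 10% of the seasonal peak).  Sub-daily resolutions
    modulate the signal by a daylight half-sine (zero at night).
    ``regime`` is ``"unimodal"``, ``"bimodal"`` or ``"noise"``.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    if resolution == "monthly":
        n = 12 * years
        frac = (np.arange(n) / 12.0) % 1.0  # month starts: the mid-year peak
        # falls on a single sample rather than tying two mid-months
        signal = _seasonal_signal(frac, regime, amplitude)
        step, unit = 1.0, "month"
    elif resolution in RESOLUTION_STEPS_PER_DAY:
        per_day = RESOLUTION_STEPS_PER_DAY[resolution]
        n = 365 * per_day * years
        day = np.arange(n) / per_day
        frac = (day / 365.0) % 1.0
        seasonal = _seasonal_signal(frac, regime, amplitude)
        hour = (np.arange(n) % per_day) / per_day * 24.0
        daylight = np.clip(np.sin(np.pi * (hour - 6.0) / 12.0), 0.0, None)
        signal = seasonal * (daylight if per_day > 1 else 1.0)
        step, unit = 24.0 / per_day, "hour"
    else:
        raise ValueError(
            f"unsupported resolution {resolution!r}; use one of "
            f"{sorted(RESOLUTION_STEPS_PER_DAY) + ['monthly']}"
        )
    noise = _ar1(n, ar_phi, noise_sd, rng) if noise_sd > 0 else 0.0
    return TimeSeries(signal + noise, step=step, step_unit=unit)


def gpp_grid(
    nlat: int = 8,
    nlon: int = 8,
    months: int = 360,
    regimes: tuple[str, ...] = ("unimodal", "noise"),
    seed: int = 0,
    amplitude: float = 10.0,
    noise_sd: float = 1.0,
):
    """Gridded monthly GPP-like field with latitude-banded regimes.

    The latitude axis is split into ``len(regimes)`` equal bands (first
    regime at the northernmost band) and every cell carries an independent
    noise realization of its band's :func:`gpp_site` process, creating
    spatial gradients in the information quantifiers.  Returns a
    :class:`~itquant.gridded.GriddedField` (time x lat x lon).
    """
    from .gridded import GriddedField  # local import to avoid a cycle

    if nlat < 1 or nlon < 1 or months < 1:
        raise ValueError("grid dimensions must be >= 1")
    if not regimes:
        raise ValueError("at least one regime required")
    rng = np.random.default_rng(seed)
    years = int(np.ceil(months / 12))
    values = np.empty((months, nlat, nlon))
    bands = np.array_split(np.arange(nlat), len(regimes))
    for regime, band in zip(regimes, bands):
        for i in band:
            for j in range(nlon):
                cell_seed = int(rng.integers(0, 2**31 - 1))
                ts = gpp_site(
                    years=years,
                    resolution="monthly",
                    regime=regime,
                    seed=cell_seed,
                    amplitude=amplitude,
                    noise_sd=noise_sd,
                )
                values[:, i, j] = ts.values[:months]
    lat = np.linspace(75.0, 35.0, nlat)  # north to south
    lon = np.linspace(-10.0, 30.0, nlon)
    time = np.arange(months, dtype=float)
    return GriddedField(values=values, time=time, lat=lat, lon=lon, name="gpp")
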