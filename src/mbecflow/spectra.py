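"""Two-state spectral model of methylene blue (MB) emission.

Intracellular MB emits in the far red with a primary peak at 696 nm.
Phagolysosomal oxidation shifts emission toward a 760 nm shoulder; we model an
observed emission curve as a convex mixture of two fixed basis spectra,

    S(lambda; rho) = (1 - rho) * reduced(lambda) + rho * oxidized(lambda),

where ``rho`` in [0, 1] is the oxidized fraction.  The three red-laser
detector windows of a conventional cytometer (AF647: 655-685 nm, AF700:
705-750 nm, APC-Cy7: 750-810 nm) are rendered as band-pass integrals of the
emission curve, and the red shift is summarized as the APC-Cy7 : AF647 signal
ratio, which is strictly increasing in ``rho`` by construction.

All spectra live on a common 1 nm wavelength grid and are stored
sum-normalized (each basis sums to 1 over the grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DegenerateSpectrumError",
    "EmissionSpectrum",
    "BandPassChannel",
    "SpectralModel",
    "UnmixResult",
    "default_model",
    "default_absorbance_model",
    "normalize_spectrum",
    "find_peak",
    "band_integral",
    "mix_spectrum",
    "predict_redshift_ratio",
    "unmix_oxidized_fraction",
    "resample_spectrum",
    "peroxide_oxidized_fraction",
    "mean_emission_wavelength",
    "REDUCED_PEAK_NM",
    "OXIDIZED_PEAK_NM",
    "ABSORBANCE_PEAK_NM",
]

# Emission anchors of methylene blue inside phagocytes: primary peak of the
# unoxidized dye, shoulder peak that grows with phagolysosomal oxidation, and
# the absorbance maximum that makes the red (638/640 nm class) laser optimal.
REDUCED_PEAK_NM = 696.0
OXIDIZED_PEAK_NM = 760.0
ABSORBANCE_PEAK_NM = 665.0

#: Wavelength grid: covers the merged 655-810 nm detection range with margin.
DEFAULT_GRID_NM = np.arange(650.0, 821.0, 1.0)


class DegenerateSpectrumError(ValueError):
    """Raised for spectra or models on which an operation is undefined."""


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence (or absorbance) curve on a strictly increasing nm grid."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.shape != it.shape:
            raise ValueError("wavelengths and intensities must be 1-D and equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least 2 grid points")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(it < 0) or not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite and nonnegative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)

    @property
    def total(self) -> float:
        return float(self.intensities.sum())


@dataclass(frozen=True)
class BandPassChannel:
    """A detector window [lo_nm, hi_nm] with a multiplicative gain.

    The gain models detector voltage as a pure scale factor; the absolute
    instrument voltages are metadata, not physics.
    """

    name: str
    lo_nm: float
    hi_nm: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not self.lo_nm < self.hi_nm:
            raise ValueError(f"channel {self.name}: lo_nm must be < hi_nm")
        if not self.gain > 0:
            raise ValueError(f"channel {self.name}: gain must be positive")

    @property
    def width_nm(self) -> float:
        return self.hi_nm - self.lo_nm


def _lognormal_shape(wl: np.ndarray, mode_nm: float, sigma: float, origin_nm: float) -> np.ndarray:
    x = wl - origin_nm
    if np.any(x <= 0):
        raise ValueError("grid must lie above the shape origin")
    mu = np.log(mode_nm - origin_nm) + sigma**2
    pdf = np.exp(-((np.log(x) - mu) ** 2) / (2 * sigma**2)) / x
    return pdf / pdf.sum()


def _basis(
    wl: np.ndarray,
    mode_nm: float,
    sigma: float,
    broad_weight: float = 0.30,
    broad_sd_nm: float = 120.0,
    origin_nm: float = 600.0,
) -> EmissionSpectrum:
    """Unimodal log-normal-shaped basis plus a broad component.

    The broad Gaussian (renormalized on the grid) spreads enough mass into
    every detector band (>= 5% each) that all three channels stay informative
    for both oxidation states, without moving the mode.
    """
    core = _lognormal_shape(wl, mode_nm, sigma, origin_nm)
    broad = np.exp(-((wl - mode_nm) ** 2) / (2 * broad_sd_nm**2))
    broad /= broad.sum()
    b = (1 - broad_weight) * core + broad_weight * broad
    return EmissionSpectrum(wl, b / b.sum())


@dataclass(frozen=True)
class SpectralModel:
    """Reduced/oxidized MB emission bases plus the detector band definitions."""

    reduced_basis: EmissionSpectrum
    oxidized_basis: EmissionSpectrum
    absorbance_peak_nm: float
    channels: tuple[BandPassChannel, ...]

    def __post_init__(self) -> None:
        if not np.array_equal(
            self.reduced_basis.wavelengths_nm, self.oxidized_basis.wavelengths_nm
        ):
            raise ValueError("both bases must share one wavelength grid")
        for b, nm in ((self.reduced_basis, "reduced"), (self.oxidized_basis, "oxidized")):
            if abs(b.total - 1.0) > 1e-9:
                raise ValueError(f"{nm} basis must be stored sum-normalized")
        if find_peak(self.oxidized_basis) <= find_peak(self.reduced_basis):
            raise ValueError("oxidized basis must peak at a longer wavelength than reduced")

    @property
    def grid_nm(self) -> np.ndarray:
        return self.reduced_basis.wavelengths_nm

    def channel(self, name: str) -> BandPassChannel:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"no channel named {name!r}")


def default_model(gains: dict[str, float] | None = None) -> SpectralModel:
    """The default MB model: 696/760 nm bases and the AF647/AF700/APC-Cy7 bands."""
    gains = gains or {}
    wl = DEFAULT_GRID_NM
    channels = (
        BandPassChannel("AF647", 655.0, 685.0, gains.get("AF647", 1.0)),
        BandPassChannel("AF700", 705.0, 750.0, gains.get("AF700", 1.0)),
        BandPassChannel("APC-Cy7", 750.0, 810.0, gains.get("APC-Cy7", 1.0)),
    )
    return SpectralModel(
        reduced_basis=_basis(wl, REDUCED_PEAK_NM, sigma=0.35),
        oxidized_basis=_basis(wl, OXIDIZED_PEAK_NM, sigma=0.30),
        absorbance_peak_nm=ABSORBANCE_PEAK_NM,
        channels=channels,
    )


def normalize_spectrum(s: EmissionSpectrum) -> EmissionSpectrum:
    """Divide each point by the sum of all points (curve then sums to 1).

    This is the correction that removes overall-brightness differences so
    emission curves from different conditions can be compared side by side.
    """
    total = s.total
    if total <= 0:
        raise DegenerateSpectrumError("cannot normalize an all-zero spectrum")
    return EmissionSpectrum(s.wavelengths_nm, s.intensities / total)


def find_peak(s: EmissionSpectrum) -> float:
    """Wavelength of the global intensity maximum; ties break to the shortest.

    A perfectly flat spectrum has no meaningful peak: the grid start is
    returned with a warning.
    """
    it = s.intensities
    if np.all(it == it[0]):
        warnings.warn("flat spectrum: peak tie-broken to the grid start", stacklevel=2)
    return float(s.wavelengths_nm[int(np.argmax(it))])


def band_integral(s: EmissionSpectrum, c: BandPassChannel) -> float:
    """Trapezoidal integral of the spectrum over the channel window, times gain.

    The window is clipped to the grid; endpoints inside the grid are linearly
    interpolated so the integral is additive over adjacent sub-windows.
    """
    wl, it = s.wavelengths_nm, s.intensities
    lo = max(c.lo_nm, float(wl[0]))
    hi = min(c.hi_nm, float(wl[-1]))
    if lo >= hi:
        warnings.warn(
            f"channel {c.name} [{c.lo_nm}, {c.hi_nm}] nm does not overlap the grid",
            stacklevel=2,
        )
        return 0.0
    inner = wl[(wl > lo) & (wl < hi)]
    xs = np.concatenate(([lo], inner, [hi]))
    ys = np.interp(xs, wl, it)
    return float(c.gain * np.trapezoid(ys, xs))


def mix_spectrum(m: SpectralModel, rho: float) -> EmissionSpectrum:
    """The noise-free emission curve at oxidized fraction ``rho``."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    mixed = (1.0 - rho) * m.reduced_basis.intensities + rho * m.oxidized_basis.intensities
    return EmissionSpectrum(m.grid_nm, mixed)


def predict_redshift_ratio(m: SpectralModel, rho: float) -> float:
    """Closed-form APC-Cy7 : AF647 band ratio of the mixture at ``rho``."""
    mixed = mix_spectrum(m, rho)
    num = band_integral(mixed, m.channel("APC-Cy7"))
    den = band_integral(mixed, m.channel("AF647"))
    if den <= 0:
        raise DegenerateSpectrumError("AF647 band integral is zero: degenerate model")
    return num / den


def resample_spectrum(s: EmissionSpectrum, grid_nm: np.ndarray) -> EmissionSpectrum:
    """Linear interpolation of a spectrum onto another grid (clipped at edges)."""
    grid_nm = np.asarray(grid_nm, dtype=float)
    it = np.interp(grid_nm, s.wavelengths_nm, s.intensities)
    return EmissionSpectrum(grid_nm, it)


@dataclass(frozen=True)
class UnmixResult:
    rho: float
    residual_norm: float


def unmix_oxidized_fraction(observed: EmissionSpectrum, m: SpectralModel) -> UnmixResult:
    """Estimate the oxidized fraction by constrained least squares.

    The observed curve is sum-normalized and fit as a one-parameter mixture of
    the (sum-normalized) bases; ``rho`` is the box-constrained minimizer,
    available in closed form because the model is affine in ``rho``.  When the
    observed grid differs from the model grid, the bases are resampled onto
    the observed grid and renormalized first.
    """
    grid = observed.wavelengths_nm
    if np.array_equal(grid, m.grid_nm):
        red = m.reduced_basis.intensities
        oxi = m.oxidized_basis.intensities
    else:
        red = normalize_spectrum(resample_spectrum(m.reduced_basis, grid)).intensities
        oxi = normalize_spectrum(resample_spectrum(m.oxidized_basis, grid)).intensities
    direction = oxi - red
    denom = float(direction @ direction)
    if denom < 1e-18:
        raise DegenerateSpectrumError("reduced and oxidized bases are identical: unidentifiable")
    obs = normalize_spectrum(observed).intensities
    rho = float(np.clip((obs - red) @ direction / denom, 0.0, 1.0))
    resid = obs - ((1.0 - rho) * red + rho * oxi)
    return UnmixResult(rho=rho, residual_norm=float(np.linalg.norm(resid)))


# --- absorbance side ---------------------------------------------------------
#
# In vitro, hydrogen peroxide drives the same two-state transition in the MB
# absorbance curve.  Only the direction of the effect is modeled: peroxide
# concentration maps to the oxidized fraction through a saturating Hill curve
# (coefficient 1), and the resulting spectral shift is monotone in dose.

ABSORBANCE_GRID_NM = np.arange(560.0, 781.0, 1.0)


def default_absorbance_model() -> SpectralModel:
    """Two-state absorbance mixture; the unoxidized curve peaks at 665 nm."""
    wl = ABSORBANCE_GRID_NM
    channels = (
        BandPassChannel("ABS_blue_side", 600.0, 660.0, 1.0),
        BandPassChannel("ABS_red_side", 680.0, 760.0, 1.0),
    )
    return SpectralModel(
        reduced_basis=_basis(wl, ABSORBANCE_PEAK_NM, sigma=0.30, origin_nm=520.0),
        oxidized_basis=_basis(wl, 720.0, sigma=0.28, origin_nm=520.0),
        absorbance_peak_nm=ABSORBANCE_PEAK_NM,
        channels=channels,
    )


def peroxide_oxidized_fraction(conc_mM: float, half_sat_mM: float = 5.0) -> float:
    """Saturating (Hill coefficient 1) map from H2O2 concentration to rho."""
    if conc_mM < 0:
        raise ValueError("concentration must be nonnegative")
    return conc_mM / (conc_mM + half_sat_mM)


def mean_emission_wavelength(s: EmissionSpectrum) -> float:
    """Intensity-weighted mean wavelength; a smooth red-shift summary."""
    n = normalize_spectrum(s)
    return float(n.wavelengths_nm @ n.intensities)
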