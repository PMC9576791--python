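"""Image rendering, resolution and particle-profile metrics.

Localization tables are rendered as plain 2D histograms (default 5 nm
pixels).  Image resolution is estimated by Fourier ring correlation (FRC):
the data are split at random into two halves, both are rendered, and the
normalized cross-correlation of their Fourier transforms is averaged over
rings of spatial frequency; the resolution is the inverse of the frequency
where the curve first drops below 1/7.  The module also provides the
particle statistics used for averaged nuclear-pore images: a radial
density profile normalized by annulus area, and alignment of axial
("side view") profiles by a two-Gaussian fit.  Finally,
:func:`average_wavelength` computes the intensity-weighted mean emission
wavelength of a fluorophore seen through a chain of filters and the camera
quantum efficiency — the statistic that quantifies how much chromatic
separation a channel configuration leaves between species.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .tables import LocalizationTable, Rectangle

__all__ = [
    "RenderedImage",
    "FRCResult",
    "RadialProfile",
    "Spectrum",
    "SideviewFit",
    "render_histogram",
    "frc_curve",
    "frc_resolution",
    "radial_distribution",
    "fit_sideview_profile",
    "average_wavelength",
    "DEFAULT_RENDER_PIXEL_NM",
]

#: Reconstruction pixel size for super-resolution histograms.
DEFAULT_RENDER_PIXEL_NM = 5.0

FRC_THRESHOLD = 1.0 / 7.0


@dataclass
class RenderedImage:
    """2D histogram of localization coordinates."""

    pixels: np.ndarray  # (ny, nx) counts
    pixel_size: float  # nm
    origin: Tuple[float, float]  # nm position of pixel (0, 0)'s corner

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, np.clip(self.pixels, 0, 65535).astype(np.uint16))


def render_histogram(
    table: LocalizationTable,
    pixel_size: float = DEFAULT_RENDER_PIXEL_NM,
    bounds: Optional[Rectangle] = None,
) -> RenderedImage:
    """Render a table as a 2D histogram with half-open (floor) pixel bins.

    Every localization inside ``bounds`` (default: the table's field of
    view) increments exactly one pixel, so the pixel sum equals the number
    of rendered localizations.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if bounds is None:
        bounds = table.bounds
    nx = max(int(np.ceil(bounds.width / pixel_size)), 1)
    ny = max(int(np.ceil(bounds.height / pixel_size)), 1)
    xy = table.xy
    ix = np.floor((xy[:, 0] - bounds.xmin) / pixel_size).astype(np.int64)
    iy = np.floor((xy[:, 1] - bounds.ymin) / pixel_size).astype(np.int64)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    img = np.zeros((ny, nx))
    np.add.at(img, (iy[ok], ix[ok]), 1.0)
    return RenderedImage(img, pixel_size, (bounds.xmin, bounds.ymin))


@dataclass
class FRCResult:
    """Fourier ring correlation curves and the 1/7-criterion resolution."""

    frequency: np.ndarray  # 1/nm, ring-bin centers
    curves: np.ndarray  # (n_repeats, n_freq_steps)
    resolutions: np.ndarray  # nm per repeat; NaN where 1/7 never crossed

    @property
    def mean_curve(self) -> np.ndarray:
        return self.curves.mean(axis=0)

    @property
    def resolution_mean(self) -> float:
        vals = self.resolutions[np.isfinite(self.resolutions)]
        return float(vals.mean()) if len(vals) else float("nan")

    @property
    def resolution_sd(self) -> float:
        vals = self.resolutions[np.isfinite(self.resolutions)]
        return float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    @property
    def not_reached(self) -> int:
        """Number of repeats whose curve never crossed 1/7."""
        return int(np.sum(~np.isfinite(self.resolutions)))

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "freq_per_nm": self.frequency,
                "frc_mean": self.curves.mean(axis=0),
                "frc_sd": self.curves.std(axis=0, ddof=1) if len(self.curves) > 1
                else np.zeros_like(self.frequency),
            }
        ).to_csv(path, index=False)


def _square_bounds(bounds: Rectangle, pixel: float) -> Rectangle:
    """Expand to a square so both FFT axes share the same frequency step."""
    side = max(bounds.width, bounds.height)
    side = np.ceil(side / pixel) * pixel
    return Rectangle(bounds.xmin, bounds.xmin + side, bounds.ymin, bounds.ymin + side)


def frc_curve(
    img1: np.ndarray, img2: np.ndarray, pixel_size: float, n_freq_steps: int = 90
) -> Tuple[np.ndarray, np.ndarray]:
    """Ring-averaged normalized Fourier cross-correlation of two images.

    Returns (frequency bin centers in 1/nm up to Nyquist, FRC values).
    """
    if img1.shape != img2.shape:
        raise ValueError("half-images must have the same shape")
    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    ny, nx = img1.shape
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=pixel_size))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=pixel_size))
    rho = np.hypot(*np.meshgrid(fx, fy))

    nyquist = 0.5 / pixel_size
    edges = np.linspace(0.0, nyquist, n_freq_steps + 1)
    which = np.digitize(rho.ravel(), edges) - 1
    ok = (which >= 0) & (which < n_freq_steps)

    num = np.bincount(which[ok], weights=(f1 * np.conj(f2)).real.ravel()[ok],
                      minlength=n_freq_steps)
    p1 = np.bincount(which[ok], weights=(np.abs(f1) ** 2).ravel()[ok],
                     minlength=n_freq_steps)
    p2 = np.bincount(which[ok], weights=(np.abs(f2) ** 2).ravel()[ok],
                     minlength=n_freq_steps)
    with np.errstate(divide="ignore", invalid="ignore"):
        frc = num / np.sqrt(p1 * p2)
    frc[~np.isfinite(frc)] = 0.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, frc


def _smooth(curve: np.ndarray, window: int = 3) -> np.ndarray:
    """Light moving-average smoothing, endpoint-padded."""
    if window <= 1:
        return curve
    kernel = np.ones(window) / window
    padded = np.pad(curve, window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _first_crossing(freq: np.ndarray, curve: np.ndarray,
                    threshold: float = FRC_THRESHOLD) -> float:
    """Resolution (nm) from the first sub-threshold crossing, interpolated."""
    below = np.flatnonzero(curve < threshold)
    below = below[below > 0]  # ignore the DC bin
    if len(below) == 0:
        return float("nan")
    i = below[0]
    f0, f1 = freq[i - 1], freq[i]
    c0, c1 = curve[i - 1], curve[i]
    f_cross = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0) if c0 != c1 else f1
    return float(1.0 / f_cross)


def frc_resolution(
    table: LocalizationTable,
    pixel_size: float = DEFAULT_RENDER_PIXEL_NM,
    n_freq_steps: int = 90,
    n_repeats: int = 10,
    seed: Optional[int] = None,
) -> FRCResult:
    """FRC resolution of a localization table by the 1/7 criterion.

    Each repeat splits the localizations Bernoulli(1/2), renders the halves
    on a common square grid, ring-averages their normalized Fourier
    cross-correlation over ``n_freq_steps`` uniform frequency bins up to
    Nyquist, smooths lightly, and reports the first crossing below 1/7 as a
    resolution in nm (NaN if never crossed).
    """
    if len(table) < 100:
        raise ValueError("need >= 100 localizations for a meaningful FRC")
    rng = np.random.default_rng(seed)
    bounds = _square_bounds(table.bounds, pixel_size)
    curves = []
    resolutions = []
    freq = None
    for _ in range(n_repeats):
        half = rng.random(len(table)) < 0.5
        t1 = table.with_df(table.df.loc[half])
        t2 = table.with_df(table.df.loc[~half])
        img1 = render_histogram(t1, pixel_size, bounds).pixels
        img2 = render_histogram(t2, pixel_size, bounds).pixels
        freq, frc = frc_curve(img1, img2, pixel_size, n_freq_steps)
        frc = _smooth(frc)
        curves.append(frc)
        resolutions.append(_first_crossing(freq, frc))
    return FRCResult(freq, np.array(curves), np.array(resolutions))


@dataclass
class RadialProfile:
    """Annulus-area-normalized radial density of particle localizations."""

    bin_edges: np.ndarray  # nm
    density: np.ndarray  # counts per nm^2 per bin
    counts: np.ndarray  # raw counts per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def radial_distribution(
    particles: Sequence[Tuple[np.ndarray, Tuple[float, float]]],
    bin_width: float = 5.0,
    r_max: float = 130.0,
) -> RadialProfile:
    """Pooled radial density of localizations around per-particle centers.

    ``particles`` is a sequence of ``(xy_array, (cx, cy))``.  Distances to
    each particle's own center are pooled into bins of ``bin_width`` up to
    ``r_max`` and each bin's count is divided by the area of its annulus,
    pi * (R_{k+1}^2 - R_k^2), giving a quantity proportional to the image
    profile of the averaged particle.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    radii = []
    for xy, center in particles:
        xy = np.asarray(xy, dtype=float)
        if len(xy) == 0:
            continue
        radii.append(np.linalg.norm(xy - np.asarray(center, dtype=float), axis=1))
    pooled = np.concatenate(radii) if radii else np.array([])
    counts, _ = np.histogram(pooled, bins=edges)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return RadialProfile(edges, counts / areas, counts)


@dataclass
class SideviewFit:
    """Two-Gaussian fit of an axial particle profile.

    ``center`` is the midpoint between the two Gaussian means — the origin
    to which aligned particles are shifted (shift = -center).  ``degenerate``
    flags fits whose two means collapse onto each other (effectively a
    single peak), for which the alignment is unreliable.
    """

    amplitudes: Tuple[float, float]
    means: Tuple[float, float]
    sigmas: Tuple[float, float]
    center: float
    degenerate: bool

    @property
    def separation(self) -> float:
        return abs(self.means[1] - self.means[0])

    @property
    def alignment_shift(self) -> float:
        return -self.center


def _double_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - mu2) / s2) ** 2
    )


def fit_sideview_profile(
    positions: np.ndarray, intensities: np.ndarray
) -> SideviewFit:
    """Least-squares sum-of-two-Gaussians fit of a 1D axial profile."""
    x = np.asarray(positions, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(x) < 8:
        raise ValueError("profile needs >= 8 samples")
    span = x.max() - x.min()
    mid = 0.5 * (x.max() + x.min())
    # initial guess: one peak in each half of the profile
    lo, hi = x < mid, x >= mid
    mu1 = x[lo][np.argmax(y[lo])] if lo.any() else mid - span / 4
    mu2 = x[hi][np.argmax(y[hi])] if hi.any() else mid + span / 4
    p0 = [y.max(), mu1, span / 8, y.max(), mu2, span / 8]
    try:
        popt, _ = curve_fit(
            _double_gauss, x, y, p0=p0,
            bounds=([0, x.min() - span, 1e-6, 0, x.min() - span, 1e-6],
                    [np.inf, x.max() + span, span, np.inf, x.max() + span, span]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"two-Gaussian fit did not converge (n={len(x)}, span={span:.1f} nm): {exc}"
        ) from exc
    a1, m1, s1, a2, m2, s2 = popt
    if m1 > m2:
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    # a fit is degenerate when the two components are effectively one peak:
    # overlapping means, or one amplitude vanishing
    degenerate = abs(m2 - m1) < 0.5 * max(s1, s2) or min(a1, a2) < 0.05 * max(a1, a2)
    return SideviewFit(
        amplitudes=(float(a1), float(a2)),
        means=(float(m1), float(m2)),
        sigmas=(float(s1), float(s2)),
        center=float(0.5 * (m1 + m2)),
        degenerate=bool(degenerate),
    )


@dataclass(frozen=True)
class Spectrum:
    """Sampled spectrum: strictly increasing wavelengths (nm), values >= 0."""

    wavelength: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if wl.ndim != 1 or wl.shape != v.shape:
            raise ValueError("wavelength and value must be matching 1D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("spectrum values must be >= 0")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "value", v)

    @classmethod
    def from_file(cls, path, delimiter=None) -> "Spectrum":
        data = np.loadtxt(path, delimiter=delimiter)
        return cls(data[:, 0], data[:, 1])

    def interpolate(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid``; zero outside the sampled range."""
        return np.interp(grid, self.wavelength, self.value, left=0.0, right=0.0)


def average_wavelength(
    emission: Spectrum,
    transmissions: Sequence[Spectrum] = (),
    qe: Optional[Spectrum] = None,
    wavelength_range: Tuple[float, float] = (630.0, 800.0),
    grid_step: float = 0.5,
) -> float:
    """Intensity-weighted mean wavelength of a filtered emission spectrum.

    The effective intensity is the emission spectrum multiplied by every
    transmission curve and by the camera quantum efficiency, all linearly
    interpolated onto a common ``grid_step`` nm grid; the average is the
    ratio of trapezoidal integrals of lambda * I(lambda) and I(lambda) over
    ``wavelength_range``.  The result is invariant under rescaling any of
    the input spectra.
    """
    lo, hi = wavelength_range
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    intensity = emission.interpolate(grid)
    for t in transmissions:
        intensity = intensity * t.interpolate(grid)
    if qe is not None:
        intensity = intensity * qe.interpolate(grid)
    denom = np.trapezoid(intensity, grid)
    if denom <= 0:
        raise ValueError("effective intensity is zero on the integration range")
    return float(np.trapezoid(grid * intensity, grid) / denom)
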