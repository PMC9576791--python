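"""Spectral demixing: species assignment and output-coordinate computation.

Each paired localization carries photon counts ``(I_S, I_L)`` in the two
splitter channels.  A fluorophore species is characterized by the ratio
``r = I_L / I_S`` set by its emission spectrum and the dichroic edge, so on
the bivariate histogram of ``(I_S, I_L)`` a species populates a wedge around
the line ``I_L = r * I_S``.  Assignment gates each pair by user-defined
sector regions (ratio interval plus total-intensity bounds); pairs outside
every sector — including low-intensity pairs that cannot be demixed
reliably — are rejected.

The demixed output coordinate of a pair can be computed six ways:

``brightest``     coordinates of the brighter channel (ties go to S)
``lambdaS``       S-channel coordinates
``lambdaL``       L-channel coordinates
``mean``          simple mean of the two — chromatic-error-free reference
``wmean``         photon-weighted mean (w_c = I_c / (I_S+I_L)) — the
                  shot-noise-optimal estimate using every detected photon
``wmean_chroma``  weighted mean minus a fitted residual chromatic field

The weighted mean keeps the full-photon precision sigma_0/sqrt(I_S+I_L) but
retains a ratio-dependent chromatic residual (w_L - 1/2) * delta, where
delta is the inter-channel chromatic shift.  For a species with constant r
that residual depends only on position, so it is registered against the
simple-mean position (delta_x = x_wm - x_m), fitted with a low-order 2D
polynomial per species and per axis, and subtracted.  Every output pair
keeps photons = I_S + I_L.

Cross-talk between demixed channels is estimated from a single-labeled
sample as the fraction of its assigned pairs that land in another species'
sector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .tables import LocalizationTable, Rectangle

__all__ = [
    "SectorRegion",
    "BivariateHistogram",
    "ChromaticModel",
    "ChromaticCorrector",
    "DemixResult",
    "CrosstalkResult",
    "photon_ratio",
    "bivariate_histogram",
    "assign_species",
    "demix_coordinates",
    "fit_chromatic_model",
    "estimate_crosstalk",
    "METHODS",
    "REJECTED_LABEL",
]

METHODS = ("brightest", "lambdaS", "lambdaL", "mean", "wmean", "wmean_chroma")

#: Label used for pairs falling outside every sector.
REJECTED_LABEL = ""


class SectorConfigError(ValueError):
    """Sector regions of different species overlap."""


@dataclass(frozen=True)
class SectorRegion:
    """A wedge of the bivariate photon-count histogram owning one species.

    A pair belongs to the sector iff ``r_min <= r < r_max`` and
    ``i_total_min <= I_S + I_L`` (``< i_total_max`` if set).  Ratio
    intervals are half-open so adjacent sectors partition ratio space.
    """

    species_name: str
    r_min: float
    r_max: float
    i_total_min: float = 0.0
    i_total_max: Optional[float] = None

    def __post_init__(self):
        if not (0 <= self.r_min < self.r_max):
            raise ValueError(f"need 0 <= r_min < r_max, got [{self.r_min}, {self.r_max})")
        if self.i_total_min < 0:
            raise ValueError("i_total_min must be >= 0")
        if self.i_total_max is not None and self.i_total_max <= self.i_total_min:
            raise ValueError("i_total_max must exceed i_total_min")

    def contains(self, r, i_total) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        i_total = np.asarray(i_total, dtype=float)
        m = (r >= self.r_min) & (r < self.r_max) & (i_total >= self.i_total_min)
        if self.i_total_max is not None:
            m &= i_total < self.i_total_max
        return m


def load_sectors(path) -> List[SectorRegion]:
    """Read a YAML list of {species, r_min, r_max, i_total_min[, i_total_max]}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    sectors = []
    for e in entries:
        sectors.append(
            SectorRegion(
                species_name=e["species"],
                r_min=float(e["r_min"]),
                r_max=float(e["r_max"]),
                i_total_min=float(e.get("i_total_min", 0.0)),
                i_total_max=(float(e["i_total_max"]) if "i_total_max" in e else None),
            )
        )
    return sectors


def _check_disjoint(sectors: Sequence[SectorRegion]) -> None:
    if len({s.species_name for s in sectors}) != len(sectors):
        raise SectorConfigError("duplicate species names among sectors")
    for i, a in enumerate(sectors):
        for b in sectors[i + 1:]:
            r_overlap = max(a.r_min, b.r_min) < min(a.r_max, b.r_max)
            a_hi = np.inf if a.i_total_max is None else a.i_total_max
            b_hi = np.inf if b.i_total_max is None else b.i_total_max
            i_overlap = max(a.i_total_min, b.i_total_min) < min(a_hi, b_hi)
            if r_overlap and i_overlap:
                raise SectorConfigError(
                    f"sectors {a.species_name!r} and {b.species_name!r} overlap"
                )


def photon_ratio(i_s, i_l) -> np.ndarray:
    """Channel photon-count ratio r = I_L / I_S (requires I_S > 0)."""
    i_s = np.asarray(i_s, dtype=float)
    if np.any(i_s <= 0):
        raise ValueError("I_S must be > 0")
    return np.asarray(i_l, dtype=float) / i_s


@dataclass
class BivariateHistogram:
    """2D histogram of per-pair photon counts (I_S, I_L)."""

    counts: np.ndarray
    edges_s: np.ndarray
    edges_l: np.ndarray
    scale: str  # "linear" | "log"


def bivariate_histogram(
    pairs: pd.DataFrame, bins_per_axis: int = 64, scale: str = "linear"
) -> BivariateHistogram:
    """Histogram the pairs' (I_S, I_L); in log scale both axes are log10.

    On the log-log plot a fixed-ratio species forms a band of slope 1 with
    intercept log10(r), which is what makes the sectors straight wedges.
    """
    if bins_per_axis < 2:
        raise ValueError("bins_per_axis must be >= 2")
    if scale not in ("linear", "log"):
        raise ValueError(f"scale must be 'linear' or 'log', got {scale!r}")
    i_s = pairs["i_s"].to_numpy(dtype=float)
    i_l = pairs["i_l"].to_numpy(dtype=float)
    if scale == "log":
        if np.any(i_s <= 0) or np.any(i_l <= 0):
            raise ValueError("log scale requires strictly positive intensities")
        i_s, i_l = np.log10(i_s), np.log10(i_l)
    if len(i_s) == 0:
        edges = np.linspace(0.0, 1.0, bins_per_axis + 1)
        return BivariateHistogram(
            np.zeros((bins_per_axis, bins_per_axis), dtype=np.int64), edges, edges, scale
        )
    counts, es, el = np.histogram2d(i_s, i_l, bins=bins_per_axis)
    return BivariateHistogram(counts.astype(np.int64), es, el, scale)


def assign_species(
    pairs: pd.DataFrame, sectors: Sequence[SectorRegion]
) -> Tuple[np.ndarray, float]:
    """Label each pair with its sector's species, or reject it.

    Sectors are validated pairwise-disjoint before any assignment.  Returns
    the label array (rejected pairs get :data:`REJECTED_LABEL`) and the
    rejection fraction.
    """
    _check_disjoint(sectors)
    r = pairs["r"].to_numpy(dtype=float)
    i_total = (pairs["i_s"] + pairs["i_l"]).to_numpy(dtype=float)
    labels = np.full(len(pairs), REJECTED_LABEL, dtype=object)
    for sector in sectors:
        labels[sector.contains(r, i_total)] = sector.species_name
    rejected = float(np.mean(labels == REJECTED_LABEL)) if len(labels) else 0.0
    return labels, rejected


# ---------------------------------------------------------------------------
# residual chromatic field


def _poly_terms(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix of 2D monomials x^i y^j with total degree i + j <= degree."""
    cols = [
        x**i * y**j
        for total in range(degree + 1)
        for i in range(total + 1)
        for j in [total - i]
    ]
    return np.column_stack(cols)


@dataclass
class ChromaticModel:
    """Per-axis polynomial field of the residual chromatic offset (nm).

    Coordinates are centered and scaled before evaluation for numerical
    conditioning; ``coeffs_x``/``coeffs_y`` multiply the monomial basis of
    total degree <= ``degree`` in the scaled coordinates.
    """

    degree: int
    coeffs_x: np.ndarray
    coeffs_y: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    fit_residual_rms: float

    def evaluate(self, positions: np.ndarray) -> np.ndarray:
        """Chromatic offsets (dx, dy) in nm at the given (N, 2) positions."""
        p = (np.asarray(positions, dtype=float) - self.center) / self.scale
        design = _poly_terms(p[:, 0], p[:, 1], self.degree)
        out = np.column_stack([design @ self.coeffs_x, design @ self.coeffs_y])
        if not np.all(np.isfinite(out)):
            raise ValueError("chromatic model evaluated to non-finite offsets")
        return out


class ChromaticCorrector(BaseEstimator):
    """Fit the position-dependent chromatic residual of weighted-mean output.

    For each pair the offset ``delta = x_wm - x_m`` between the weighted-mean
    and simple-mean positions mixes a zero-mean random part (localization
    noise, photon fluctuations; typically up to ~20 nm per pair) with a
    systematic chromatic part (a few nm) that varies smoothly with position.
    Fitting ``delta`` against position with a low-order polynomial, per
    axis, isolates the systematic part, which :meth:`transform` subtracts.

    Parameters
    ----------
    degree : total polynomial degree per axis (default 1: linear fields
        capture lateral chromatic aberration and unequal channel
        magnification, the two dominant effects of splitter optics).

    Attributes
    ----------
    model_ : fitted :class:`ChromaticModel`.
    """

    def __init__(self, degree: int = 1):
        self.degree = degree

    def fit(self, wmean_positions: np.ndarray, mean_positions: np.ndarray):
        wm = np.asarray(wmean_positions, dtype=float)
        m = np.asarray(mean_positions, dtype=float)
        if wm.shape != m.shape or wm.ndim != 2 or wm.shape[1] != 2:
            raise ValueError("positions must be matching (N, 2) arrays")
        n_terms = (self.degree + 1) * (self.degree + 2) // 2
        if len(wm) < 10 * (self.degree + 1) ** 2:
            raise ValueError(
                f"need >= {10 * (self.degree + 1) ** 2} pairs for degree {self.degree}"
            )
        delta = wm - m
        center = m.mean(axis=0)
        scale = np.maximum(m.std(axis=0), 1e-9)
        p = (m - center) / scale
        design = _poly_terms(p[:, 0], p[:, 1], self.degree)
        if np.linalg.matrix_rank(design) < n_terms:
            raise np.linalg.LinAlgError(
                "rank-deficient chromatic fit (points may be collinear); "
                "try a lower polynomial degree"
            )
        cx, *_ = np.linalg.lstsq(design, delta[:, 0], rcond=None)
        cy, *_ = np.linalg.lstsq(design, delta[:, 1], rcond=None)
        resid = delta - np.column_stack([design @ cx, design @ cy])
        self.model_ = ChromaticModel(
            degree=self.degree,
            coeffs_x=cx,
            coeffs_y=cy,
            center=center,
            scale=scale,
            fit_residual_rms=float(np.sqrt(np.mean(resid**2))),
        )
        return self

    def transform(self, wmean_positions: np.ndarray,
                  eval_positions: Optional[np.ndarray] = None) -> np.ndarray:
        """Subtract the fitted chromatic field from weighted-mean positions.

        The field is evaluated at ``eval_positions`` (default: the
        weighted-mean positions themselves).
        """
        wm = np.asarray(wmean_positions, dtype=float)
        at = wm if eval_positions is None else np.asarray(eval_positions, dtype=float)
        return wm - self.model_.evaluate(at)


def fit_chromatic_model(
    wmean_positions: np.ndarray, mean_positions: np.ndarray, degree: int = 1
) -> ChromaticModel:
    """Functional wrapper over :class:`ChromaticCorrector`."""
    return ChromaticCorrector(degree=degree).fit(wmean_positions, mean_positions).model_


# ---------------------------------------------------------------------------
# output coordinates


@dataclass
class DemixResult:
    """Demixed localization tables, one per species, plus the rejects."""

    tables: Dict[str, LocalizationTable]
    rejected: pd.DataFrame
    method: str
    chromatic_models: Dict[str, ChromaticModel] = field(default_factory=dict)

    @property
    def n_assigned(self) -> int:
        return sum(len(t) for t in self.tables.values())


def _method_coordinates(df: pd.DataFrame, method: str) -> np.ndarray:
    xs = df[["x_s", "y_s"]].to_numpy(dtype=float)
    xl = df[["x_l", "y_l"]].to_numpy(dtype=float)
    i_s = df["i_s"].to_numpy(dtype=float)[:, None]
    i_l = df["i_l"].to_numpy(dtype=float)[:, None]
    if method == "lambdaS":
        return xs
    if method == "lambdaL":
        return xl
    if method == "brightest":
        # ties resolve to the S channel
        return np.where(i_l > i_s, xl, xs)
    if method == "mean":
        return (xs + xl) / 2.0
    if method in ("wmean", "wmean_chroma"):
        w_l = i_l / (i_s + i_l)
        return (1.0 - w_l) * xs + w_l * xl
    raise ValueError(f"unknown demixing method {method!r}; expected one of {METHODS}")


def demix_coordinates(
    pairs: pd.DataFrame,
    labels: np.ndarray,
    method: str = "wmean",
    bounds: Optional[Rectangle] = None,
    chroma_degree: int = 1,
    per_species_chroma: bool = True,
    chromatic_models: Optional[Dict[str, ChromaticModel]] = None,
) -> DemixResult:
    """Compute demixed output tables from labeled pairs.

    Every output localization carries photons = I_S + I_L of its source
    pair, whatever the coordinate method.  For ``wmean_chroma`` the
    residual chromatic field is fitted (against the simple-mean positions)
    and subtracted — by default separately per species, because the
    weighted-mean residual scales with (w_L - 1/2) and is therefore
    species-dependent; ``per_species_chroma=False`` pools all assigned
    pairs into a single fit.  Pre-fitted models can be supplied via
    ``chromatic_models`` (keyed by species, or "*" for a pooled model).
    """
    if method not in METHODS:
        raise ValueError(f"unknown demixing method {method!r}; expected one of {METHODS}")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(pairs):
        raise ValueError("labels and pairs length mismatch")

    coords = _method_coordinates(pairs, method)
    photons = (pairs["i_s"] + pairs["i_l"]).to_numpy(dtype=float)
    frames = pairs["frame"].to_numpy()

    models: Dict[str, ChromaticModel] = dict(chromatic_models or {})
    if method == "wmean_chroma":
        mean_coords = _method_coordinates(pairs, "mean")
        assigned = labels != REJECTED_LABEL
        if not models:
            if per_species_chroma:
                for name in pd.unique(labels[assigned]):
                    sel = labels == name
                    models[name] = fit_chromatic_model(
                        coords[sel], mean_coords[sel], degree=chroma_degree
                    )
            else:
                models["*"] = fit_chromatic_model(
                    coords[assigned], mean_coords[assigned], degree=chroma_degree
                )
        corrected = coords.copy()
        for name in pd.unique(labels[assigned]):
            sel = labels == name
            model = models.get(name, models.get("*"))
            if model is None:
                raise ValueError(f"no chromatic model for species {name!r}")
            corrected[sel] = coords[sel] - model.evaluate(mean_coords[sel])
        coords = corrected

    tables: Dict[str, LocalizationTable] = {}
    for name in pd.unique(labels[labels != REJECTED_LABEL]):
        sel = labels == name
        tables[name] = LocalizationTable.from_arrays(
            frames[sel],
            coords[sel, 0],
            coords[sel, 1],
            photons[sel],
            bounds=bounds,
            source_channel=f"demixed:{name}",
        )
    rejected = pairs.loc[labels == REJECTED_LABEL].reset_index(drop=True)
    return DemixResult(tables=tables, rejected=rejected, method=method,
                       chromatic_models=models)


# ---------------------------------------------------------------------------
# cross-talk


@dataclass
class CrosstalkResult:
    """Cross-talk fractions from a single-labeled sample.

    ``matrix`` has one row (the declared species) and one column per
    sector; entries are counts assigned to that sector divided by counts
    assigned to any sector.  Rejected pairs are excluded from the
    denominator — dim spurious localizations otherwise inflate the
    apparent cross-talk — and reported as ``rejection_fraction``.
    """

    matrix: pd.DataFrame
    rejection_fraction: float


def estimate_crosstalk(
    single_label_pairs: pd.DataFrame,
    sectors: Sequence[SectorRegion],
    declared_species: str,
) -> CrosstalkResult:
    """Cross-talk of one single-labeled acquisition against sector regions."""
    if len(sectors) < 2:
        raise ValueError("need >= 2 sectors to estimate cross-talk")
    labels, rejection = assign_species(single_label_pairs, sectors)
    assigned = labels[labels != REJECTED_LABEL]
    if len(assigned) == 0:
        raise ZeroDivisionError(
            "no pairs assigned to any sector; cross-talk undefined"
        )
    fractions = {
        s.species_name: float(np.mean(assigned == s.species_name)) for s in sectors
    }
    matrix = pd.DataFrame([fractions], index=[declared_species])
    return CrosstalkResult(matrix=matrix, rejection_fraction=rejection)
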