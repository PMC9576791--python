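"""Post-processing of demixed localization tables.

Covers three steps that follow demixing in the reconstruction workflow:

1. *Grouping and refinement of re-localizations.*  A fluorophore that stays
   on for several consecutive camera frames produces a run of detections of
   the same molecule.  These are chained within a search radius (default
   50 nm) and either merged to one localization at the photon-weighted
   centroid, or — the refinement mode — every member is kept but its
   coordinates are redrawn from a normal law of standard deviation
   ``sigma_psf / sqrt(N_ph)`` about the centroid, where ``N_ph`` is the
   group's summed photon count.  Refinement encodes the improved combined
   precision without collapsing the localization density, which merging
   does at a cost in image resolution.

2. *Photon filtering* of dim localizations.

3. *Drift correction.*  Slow stage/sample motion is estimated by rendering
   time-binned 2D histograms of the summed demixed channels and locating
   the sub-pixel cross-correlation peak of each bin against the first;
   because the splitter records all species simultaneously, the drift is
   common to all channels and the sum gives the best-conditioned estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .pairing import _render, _xcorr_shift, AlignmentError
from .tables import LocalizationTable, Rectangle

__all__ = [
    "ConsecutiveGroup",
    "ConsecutiveRefiner",
    "DriftTrack",
    "DriftCorrector",
    "group_consecutive",
    "refine_groups",
    "filter_min_photons",
    "estimate_drift",
    "apply_drift",
    "DEFAULT_SEARCH_RADIUS_NM",
    "DEFAULT_SIGMA_PSF_NM",
]

logger = logging.getLogger(__name__)

#: Search radius for chaining re-localizations on consecutive frames.
DEFAULT_SEARCH_RADIUS_NM = 50.0

#: PSF standard deviation of the reference setup.
DEFAULT_SIGMA_PSF_NM = 140.0


@dataclass
class ConsecutiveGroup:
    """Detections of one molecule on strictly consecutive frames.

    ``indices`` are row indices into the source table (frame-sorted);
    ``n_ph`` is the summed photon count and ``centroid`` the
    photon-weighted mean position.
    """

    indices: np.ndarray
    n_ph: float
    centroid: np.ndarray


def group_consecutive(
    table: LocalizationTable, search_radius: float = DEFAULT_SEARCH_RADIUS_NM
) -> List[ConsecutiveGroup]:
    """Greedily chain re-localizations across consecutive frames.

    Frames are visited in order; a localization on frame f joins the group
    whose photon-weighted running centroid (among groups last extended on
    frame f-1) is nearest and within ``search_radius``.  A group accepts at
    most one member per frame, so detections sharing a frame never merge.
    Equidistant candidate groups resolve to the lower group index (logged).
    Every localization ends up in exactly one group; singletons are allowed.
    """
    if search_radius <= 0:
        raise ValueError("search_radius must be > 0")
    df = table.df
    n = len(df)
    frames = df["frame"].to_numpy()
    xy = df[["x", "y"]].to_numpy(dtype=float)
    ph = df["photons"].to_numpy(dtype=float)

    group_of = np.full(n, -1, dtype=np.int64)
    # per group running sums for the weighted centroid
    sums_xy: List[np.ndarray] = []
    sums_ph: List[float] = []
    last_frame: List[int] = []

    active: List[int] = []  # group ids extendable into the current frame
    order = np.argsort(frames, kind="stable")
    start = 0
    ties = 0
    while start < n:
        f = frames[order[start]]
        stop = start
        while stop < n and frames[order[stop]] == f:
            stop += 1
        rows = order[start:stop]

        # only groups last extended on the previous frame may be joined;
        # groups born in this frame are excluded, so same-frame detections
        # can never merge
        prev_active = [g for g in active if last_frame[g] == f - 1]
        taken: set[int] = set()
        if prev_active:
            centroids = np.array([sums_xy[g] / sums_ph[g] for g in prev_active])
            tree = cKDTree(centroids)
            dists, nearest = tree.query(xy[rows], k=min(2, len(prev_active)))
            dists = np.atleast_2d(np.asarray(dists).T).T
            nearest = np.atleast_2d(np.asarray(nearest).T).T
        new_groups: List[int] = []
        for k, row in enumerate(rows):
            gid = -1
            if prev_active:
                cand = [
                    (dists[k, c], prev_active[nearest[k, c]])
                    for c in range(dists.shape[1])
                    if dists[k, c] <= search_radius
                    and prev_active[nearest[k, c]] not in taken
                ]
                if cand:
                    best = min(cand, key=lambda t: (t[0], t[1]))
                    if len(cand) > 1 and abs(cand[0][0] - cand[1][0]) <= 1e-9:
                        ties += 1
                    gid = best[1]
            if gid < 0:
                gid = len(sums_ph)
                sums_xy.append(ph[row] * xy[row].copy())
                sums_ph.append(ph[row])
                last_frame.append(int(f))
                new_groups.append(gid)
            else:
                sums_xy[gid] = sums_xy[gid] + ph[row] * xy[row]
                sums_ph[gid] += ph[row]
                last_frame[gid] = int(f)
                taken.add(gid)
            group_of[row] = gid
        active = sorted(taken) + new_groups
        start = stop

    if ties:
        logger.info("group_consecutive: %d equidistant joins resolved to lower index", ties)

    groups = []
    order_by_group = np.argsort(group_of, kind="stable")
    boundaries = np.flatnonzero(np.diff(group_of[order_by_group])) + 1
    for chunk in np.split(order_by_group, boundaries):
        gid = group_of[chunk[0]]
        groups.append(
            ConsecutiveGroup(
                indices=np.sort(chunk),
                n_ph=sums_ph[gid],
                centroid=sums_xy[gid] / sums_ph[gid],
            )
        )
    groups.sort(key=lambda g: g.indices[0])
    return groups


class ConsecutiveRefiner(BaseEstimator):
    """Group re-localizations and refine or merge them.

    Parameters
    ----------
    search_radius : chaining radius in nm (default 50).
    sigma_psf : PSF standard deviation in nm (default 140); the refined
        per-axis draw uses sigma_psf / sqrt(N_ph).
    mode : "refine" keeps every member, redrawing coordinates from an
        isotropic normal about the group centroid; "merge" collapses each
        group to one localization (photons = N_ph, frame = first member's);
        "none" passes the table through.
    seed : RNG seed for the refinement draws.
    redraw_singletons : if False, groups of one member pass through
        unchanged in refine mode.

    Attributes
    ----------
    groups_ : list of :class:`ConsecutiveGroup` found by the last transform.
    """

    def __init__(self, search_radius: float = DEFAULT_SEARCH_RADIUS_NM,
                 sigma_psf: float = DEFAULT_SIGMA_PSF_NM, mode: str = "refine",
                 seed: Optional[int] = None, redraw_singletons: bool = True):
        self.search_radius = search_radius
        self.sigma_psf = sigma_psf
        self.mode = mode
        self.seed = seed
        self.redraw_singletons = redraw_singletons

    def fit(self, table: LocalizationTable):
        self.groups_ = group_consecutive(table, self.search_radius)
        return self

    def transform(self, table: LocalizationTable) -> LocalizationTable:
        if self.mode not in ("refine", "merge", "none"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sigma_psf <= 0:
            raise ValueError("sigma_psf must be > 0")
        if self.mode == "none":
            self.groups_ = []
            return table
        self.fit(table)
        df = table.df
        rng = np.random.default_rng(self.seed)

        if self.mode == "merge":
            rows = {
                "frame": [int(df["frame"].iloc[g.indices[0]]) for g in self.groups_],
                "x": [g.centroid[0] for g in self.groups_],
                "y": [g.centroid[1] for g in self.groups_],
                "photons": [g.n_ph for g in self.groups_],
            }
            return table.with_df(pd.DataFrame(rows)).sort()

        xy = df[["x", "y"]].to_numpy(dtype=float).copy()
        for g in self.groups_:
            if len(g.indices) == 1 and not self.redraw_singletons:
                continue
            sd = self.sigma_psf / np.sqrt(g.n_ph)
            xy[g.indices] = g.centroid + rng.normal(0.0, sd, size=(len(g.indices), 2))
        out = df.copy()
        out["x"], out["y"] = xy[:, 0], xy[:, 1]
        return table.with_df(out)


def refine_groups(
    table: LocalizationTable,
    sigma_psf: float = DEFAULT_SIGMA_PSF_NM,
    seed: Optional[int] = None,
    mode: str = "refine",
    search_radius: float = DEFAULT_SEARCH_RADIUS_NM,
    redraw_singletons: bool = True,
) -> LocalizationTable:
    """Functional wrapper over :class:`ConsecutiveRefiner`."""
    return ConsecutiveRefiner(
        search_radius=search_radius,
        sigma_psf=sigma_psf,
        mode=mode,
        seed=seed,
        redraw_singletons=redraw_singletons,
    ).transform(table)


def filter_min_photons(table: LocalizationTable, threshold: float) -> LocalizationTable:
    """Keep localizations with photons >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return table.with_df(table.df.loc[table.df["photons"] >= threshold])


# ---------------------------------------------------------------------------
# drift


@dataclass
class DriftTrack:
    """Piecewise-linear drift (nm) versus frame, zero at the first time bin."""

    bin_center_frames: np.ndarray
    displacements: np.ndarray  # (n_bins, 2), relative to bin 1

    def __post_init__(self):
        self.bin_center_frames = np.asarray(self.bin_center_frames, dtype=float)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if not np.allclose(self.displacements[0], 0.0):
            raise ValueError("displacement of the first bin must be (0, 0)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("drift displacements must be finite")

    def at(self, frames) -> np.ndarray:
        """Drift (dx, dy) at each frame: linear interpolation between bin
        centers, constant beyond the ends."""
        f = np.asarray(frames, dtype=float)
        dx = np.interp(f, self.bin_center_frames, self.displacements[:, 0])
        dy = np.interp(f, self.bin_center_frames, self.displacements[:, 1])
        return np.column_stack([dx, dy])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "bin_center_frame": self.bin_center_frames,
                "dx_nm": self.displacements[:, 0],
                "dy_nm": self.displacements[:, 1],
            }
        ).to_csv(path, index=False)


class DriftCorrector(BaseEstimator):
    """Estimate and subtract drift from time-binned image cross-correlation.

    The input tables (normally all demixed channels) are concatenated, the
    frame range is cut into ``n_time_bins`` equal bins, each bin is rendered
    as a 2D histogram at ``render_pixel`` nm, and the displacement of every
    bin relative to the first is the sub-pixel peak of their
    cross-correlation.  Bins with fewer than ``min_locs_per_bin``
    localizations are interpolated over (with a warning).

    Attributes
    ----------
    track_ : fitted :class:`DriftTrack`.
    """

    def __init__(self, n_time_bins: int = 10, render_pixel: float = 25.0,
                 min_locs_per_bin: int = 10):
        self.n_time_bins = n_time_bins
        self.render_pixel = render_pixel
        self.min_locs_per_bin = min_locs_per_bin

    def fit(self, tables: Sequence[LocalizationTable] | LocalizationTable):
        if isinstance(tables, LocalizationTable):
            tables = [tables]
        df = pd.concat([t.df for t in tables], ignore_index=True)
        if len(df) == 0:
            raise ValueError("no localizations to estimate drift from")
        frames = df["frame"].to_numpy()
        f_lo, f_hi = int(frames.min()), int(frames.max())
        if f_hi - f_lo + 1 < 2 * self.n_time_bins:
            raise ValueError("need at least 2 frames per time bin")
        edges = np.linspace(f_lo, f_hi + 1, self.n_time_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])

        xy = df[["x", "y"]].to_numpy(dtype=float)
        lo = xy.min(axis=0)
        hi = xy.max(axis=0) + self.render_pixel
        bounds = Rectangle(lo[0], hi[0], lo[1], hi[1])

        which = np.clip(
            np.digitize(frames, edges) - 1, 0, self.n_time_bins - 1
        )
        ref_img = None
        disp = np.full((self.n_time_bins, 2), np.nan)
        for b in range(self.n_time_bins):
            sel = which == b
            if sel.sum() < self.min_locs_per_bin:
                logger.warning(
                    "drift bin %d has only %d localizations; interpolating over it",
                    b, int(sel.sum()),
                )
                continue
            img = _render(xy[sel], bounds, self.render_pixel)
            if ref_img is None:
                ref_img = img
                disp[b] = 0.0
                ref_bin = b
                continue
            try:
                dx, dy = _xcorr_shift(ref_img, img, self.render_pixel)
            except AlignmentError:
                logger.warning("drift bin %d: no correlation peak; interpolating", b)
                continue
            # shift that maps the bin onto the reference = -(bin displacement)
            disp[b] = (-dx, -dy)
        if ref_img is None:
            raise ValueError("no usable time bins for drift estimation")

        good = ~np.isnan(disp[:, 0])
        for ax in range(2):
            disp[:, ax] = np.interp(centers, centers[good], disp[good, ax])
        disp -= disp[0]  # reference = first bin even if it was interpolated
        self.track_ = DriftTrack(centers, disp)
        return self

    def transform(self, table: LocalizationTable) -> LocalizationTable:
        return apply_drift(table, self.track_)


def estimate_drift(
    tables: Sequence[LocalizationTable] | LocalizationTable,
    n_time_bins: int = 10,
    render_pixel: float = 25.0,
) -> DriftTrack:
    """Functional wrapper over :class:`DriftCorrector`."""
    return DriftCorrector(n_time_bins=n_time_bins, render_pixel=render_pixel).fit(
        tables
    ).track_


def apply_drift(table: LocalizationTable, track: DriftTrack) -> LocalizationTable:
    """Subtract the interpolated drift from every localization.

    Frames beyond the track's bin centers use the constant end value.
    """
    frames = table.df["frame"].to_numpy()
    if len(frames) and (
        frames.min() < track.bin_center_frames[0]
        or frames.max() > track.bin_center_frames[-1]
    ):
        logger.info("apply_drift: frames outside track range; constant extrapolation")
    d = track.at(frames)
    df = table.df.copy()
    df["x"] = df["x"].to_numpy() - d[:, 0]
    df["y"] = df["y"].to_numpy() - d[:, 1]
    return table.with_df(df)
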