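"""Pairing localizations across the two channels of a spectral image splitter.

A dichroic splitter projects a short-wavelength (S) and a long-wavelength (L)
image of the same field side by side on one camera chip.  The same molecule
therefore appears once in each half, and its two detections must be matched
before its photon ratio can be computed.  This module splits a whole-chip
table into the two channel sub-tables, registers the L channel onto the S
frame of reference, and pairs detections frame by frame with a
mutual-nearest-neighbor rule inside a distance tolerance.  Detections seen in
only one channel are rejected as unreliable: genuine emitters produce light
in both spectral bands, whereas background noise fires independently in each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage, signal
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .tables import LocalizationTable, Rectangle

__all__ = [
    "ChannelTransform",
    "ChannelAligner",
    "split_by_roi",
    "estimate_alignment",
    "pair_within_tolerance",
    "DEFAULT_PAIRING_TOLERANCE_NM",
]

logger = logging.getLogger(__name__)

#: Upper end of the 50-100 nm window needed to absorb chromatic offsets and
#: per-channel localization error when matching the two detections.
DEFAULT_PAIRING_TOLERANCE_NM = 100.0

#: Distances closer than this are treated as exact ties when pairing.
TIE_EPS_NM = 1e-9


class AlignmentError(RuntimeError):
    """Cross-correlation peak indistinguishable from background."""


@dataclass(frozen=True)
class ChannelTransform:
    """Affine map from L-channel coordinates (nm) into the S reference frame.

    ``matrix`` is 2x3: ``[x', y']^T = A @ [x, y, 1]^T``.  A pure translation
    has an identity linear part.
    """

    kind: str  # "translation" | "affine"
    matrix: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls("translation", np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def translation(cls, dx: float, dy: float) -> "ChannelTransform":
        return cls("translation", np.array([[1.0, 0.0, dx], [0.0, 1.0, dy]]))

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "ChannelTransform":
        a = self.matrix[:, :2]
        t = self.matrix[:, 2]
        a_inv = np.linalg.inv(a)
        return ChannelTransform(
            self.kind, np.column_stack([a_inv, -a_inv @ t]), self.residual_rms
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "kind": self.kind,
                    "matrix_nm": [[float(v) for v in row] for row in self.matrix],
                    "residual_rms_nm": float(self.residual_rms),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "ChannelTransform":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["kind"], np.asarray(d["matrix_nm"]), d.get("residual_rms_nm", 0.0))


def split_by_roi(
    table: LocalizationTable, roi_S: Rectangle, roi_L: Rectangle
) -> Tuple[LocalizationTable, LocalizationTable]:
    """Split a whole-chip table into S- and L-channel sub-tables.

    The two regions of interest must be disjoint.  Localizations in neither
    region are dropped (the count is logged).
    """
    if roi_S.intersects(roi_L):
        raise ValueError("channel ROIs overlap")
    x = table.df["x"].to_numpy()
    y = table.df["y"].to_numpy()
    in_s = roi_S.contains(x, y)
    in_l = roi_L.contains(x, y)
    dropped = int((~in_s & ~in_l).sum())
    if dropped:
        logger.info("split_by_roi: dropped %d localizations outside both ROIs", dropped)
    t_s = table.with_df(table.df.loc[in_s], bounds=roi_S, source_channel="S")
    t_l = table.with_df(table.df.loc[in_l], bounds=roi_L, source_channel="L")
    return t_s, t_l


def _render(xy: np.ndarray, bounds: Rectangle, pixel: float) -> np.ndarray:
    nx = max(int(np.ceil(bounds.width / pixel)), 1)
    ny = max(int(np.ceil(bounds.height / pixel)), 1)
    ix = np.floor((xy[:, 0] - bounds.xmin) / pixel).astype(np.int64)
    iy = np.floor((xy[:, 1] - bounds.ymin) / pixel).astype(np.int64)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    img = np.zeros((ny, nx))
    np.add.at(img, (iy[ok], ix[ok]), 1.0)
    return img


def _xcorr_shift(img_ref: np.ndarray, img_mov: np.ndarray, pixel: float,
                 min_peak_sd: float = 5.0) -> Tuple[float, float]:
    """Shift (dx, dy) in nm that moves ``img_mov`` onto ``img_ref``.

    Peak of the full cross-correlation surface, refined to sub-pixel
    precision by the intensity centroid of a small window around the peak.
    """
    a = img_ref - img_ref.mean()
    b = img_mov - img_mov.mean()
    corr = signal.fftconvolve(a, b[::-1, ::-1], mode="full")
    peak = corr.max()
    if peak < corr.mean() + min_peak_sd * corr.std():
        raise AlignmentError("correlation peak indistinguishable from background")
    py, px = np.unravel_index(np.argmax(corr), corr.shape)
    # centroid of a 5x5 window around the peak, on positive values only
    half = 2
    y0, y1 = max(py - half, 0), min(py + half + 1, corr.shape[0])
    x0, x1 = max(px - half, 0), min(px + half + 1, corr.shape[1])
    win = np.clip(corr[y0:y1, x0:x1], 0.0, None)
    cy, cx = ndimage.center_of_mass(win)
    sub_y = y0 + cy - (img_mov.shape[0] - 1)
    sub_x = x0 + cx - (img_mov.shape[1] - 1)
    return float(sub_x * pixel), float(sub_y * pixel)


def _mutual_nn_pairs(xy_a: np.ndarray, xy_b: np.ndarray, tol: float):
    """Indices of mutual nearest neighbors within ``tol`` (no tie handling)."""
    tree_a = cKDTree(xy_a)
    tree_b = cKDTree(xy_b)
    d_ab, j_ab = tree_b.query(xy_a, k=1)
    d_ba, j_ba = tree_a.query(xy_b, k=1)
    idx_a = np.arange(len(xy_a))
    mutual = (d_ab <= tol) & (j_ba[j_ab] == idx_a)
    return idx_a[mutual], j_ab[mutual]


class ChannelAligner(BaseEstimator):
    """Estimate the static geometric registration of the L channel onto S.

    The two channel tables are rendered as 2D histograms and the translation
    is taken from the sub-pixel cross-correlation peak.  With
    ``model="affine"``, provisional nearest-neighbor pairs formed after the
    translation are then fit by least squares to a full 2x3 matrix, which
    also absorbs any unequal magnification produced by the splitting optics.

    Parameters
    ----------
    model : {"translation", "affine"}
    render_pixel : histogram pixel size in nm used for the correlation.

    Attributes
    ----------
    transform_ : ChannelTransform mapping L coordinates into the S frame.
    n_pairs_ : number of provisional pairs used for the affine refinement
        (0 for a pure translation).
    """

    def __init__(self, model: str = "translation", render_pixel: float = 50.0):
        self.model = model
        self.render_pixel = render_pixel

    def fit(self, table_S: LocalizationTable, table_L: LocalizationTable):
        if self.model not in ("translation", "affine"):
            raise ValueError(f"unknown alignment model {self.model!r}")
        if len(table_S) == 0 or len(table_L) == 0:
            raise ValueError("both channel tables must be non-empty")
        xy_s = table_S.xy
        xy_l = table_L.xy

        # common render bounds covering both clouds
        lo = np.minimum(xy_s.min(axis=0), xy_l.min(axis=0))
        hi = np.maximum(xy_s.max(axis=0), xy_l.max(axis=0)) + self.render_pixel
        bounds = Rectangle(lo[0], hi[0], lo[1], hi[1])
        img_s = _render(xy_s, bounds, self.render_pixel)
        img_l = _render(xy_l, bounds, self.render_pixel)
        dx, dy = _xcorr_shift(img_s, img_l, self.render_pixel)
        transform = ChannelTransform.translation(dx, dy)
        self.n_pairs_ = 0

        if self.model == "affine":
            # provisional mutual-NN pairs after the coarse translation, then
            # iterate: each refit brings outlying (e.g. magnification-shifted)
            # points back inside the pairing tolerance
            tol = max(2.0 * self.render_pixel, 1.0)
            for _ in range(3):
                moved = transform.apply(xy_l)
                ia, ib = _mutual_nn_pairs(xy_s, moved, tol)
                if len(ia) < 3:
                    raise AlignmentError(
                        f"only {len(ia)} provisional pairs; cannot fit affine model"
                    )
                src = np.column_stack([xy_l[ib], np.ones(len(ib))])
                sol, *_ = np.linalg.lstsq(src, xy_s[ia], rcond=None)
                transform = ChannelTransform("affine", sol.T)
            self.n_pairs_ = int(len(ia))

        resid = np.array([])
        if self.model == "affine":
            resid = np.linalg.norm(transform.apply(xy_l[ib]) - xy_s[ia], axis=1)
        elif len(xy_s) and len(xy_l):
            moved = transform.apply(xy_l)
            ia, ib = _mutual_nn_pairs(xy_s, moved, max(2.0 * self.render_pixel, 1.0))
            if len(ia):
                resid = np.linalg.norm(moved[ib] - xy_s[ia], axis=1)
        rms = float(np.sqrt(np.mean(resid**2))) if len(resid) else 0.0
        self.transform_ = ChannelTransform(transform.kind, transform.matrix, rms)
        return self

    def transform(self, table_L: LocalizationTable) -> LocalizationTable:
        """Map an L-channel table into the S frame of reference."""
        df = table_L.df.copy()
        xy = self.transform_.apply(df[["x", "y"]].to_numpy())
        df["x"], df["y"] = xy[:, 0], xy[:, 1]
        return table_L.with_df(df)


def estimate_alignment(
    table_S: LocalizationTable,
    table_L: LocalizationTable,
    model: str = "translation",
    render_pixel: float = 50.0,
) -> ChannelTransform:
    """Functional wrapper over :class:`ChannelAligner`."""
    return ChannelAligner(model=model, render_pixel=render_pixel).fit(
        table_S, table_L
    ).transform_


def _flag_ties(d_sorted: np.ndarray, tol: float) -> np.ndarray:
    """Rows whose two nearest candidates are in-tolerance and equidistant."""
    if d_sorted.shape[1] < 2:
        return np.zeros(len(d_sorted), dtype=bool)
    d1, d2 = d_sorted[:, 0], d_sorted[:, 1]
    return (d1 <= tol) & (d2 <= tol) & (d2 - d1 <= TIE_EPS_NM)


def pair_within_tolerance(
    table_S: LocalizationTable,
    table_L: LocalizationTable,
    transform: Optional[ChannelTransform] = None,
    tolerance: float = DEFAULT_PAIRING_TOLERANCE_NM,
) -> Tuple[pd.DataFrame, LocalizationTable, LocalizationTable]:
    """Match S and L detections of the same molecule, frame by frame.

    After mapping the L table through ``transform`` (identity if None),
    detections in the same frame are paired by mutual nearest neighbor
    within ``tolerance`` nm.  Ambiguous candidates — a detection whose two
    nearest in-tolerance partners are equidistant, or a non-reciprocated
    nearest neighbor — are left unpaired, together with everything they
    touch.  Unpaired detections are the unreliable set excluded from
    reconstruction.

    Returns
    -------
    pairs : DataFrame with columns ``frame, x_s, y_s, x_l, y_l, i_s, i_l, r``
        where ``r = i_l / i_s`` and coordinates are in the S reference frame.
    unpaired_S, unpaired_L : the rejected single-channel detections
        (L coordinates returned un-transformed, as read).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if transform is None:
        transform = ChannelTransform.identity()

    df_s = table_S.df
    df_l = table_L.df
    xy_l_moved = transform.apply(df_l[["x", "y"]].to_numpy()) if len(df_l) else np.empty((0, 2))

    pair_s_idx: list[np.ndarray] = []
    pair_l_idx: list[np.ndarray] = []

    s_groups = dict(df_s.groupby("frame").indices) if len(df_s) else {}
    l_groups = dict(df_l.groupby("frame").indices) if len(df_l) else {}

    for f, s_idx in s_groups.items():
        l_idx = l_groups.get(f)
        if l_idx is None:
            continue
        xy_s = df_s[["x", "y"]].to_numpy()[s_idx]
        xy_l = xy_l_moved[l_idx]
        tree_s = cKDTree(xy_s)
        tree_l = cKDTree(xy_l)
        k_l = min(2, len(xy_l))
        k_s = min(2, len(xy_s))
        d_sl, j_sl = tree_l.query(xy_s, k=k_l)
        d_ls, j_ls = tree_s.query(xy_l, k=k_s)
        d_sl = np.atleast_2d(d_sl.T).T if d_sl.ndim == 1 else d_sl
        j_sl = np.atleast_2d(j_sl.T).T if j_sl.ndim == 1 else j_sl
        d_ls = np.atleast_2d(d_ls.T).T if d_ls.ndim == 1 else d_ls
        j_ls = np.atleast_2d(j_ls.T).T if j_ls.ndim == 1 else j_ls

        s_tie = _flag_ties(d_sl, tolerance)
        l_tie = _flag_ties(d_ls, tolerance)
        # a tied detection poisons all of its in-tolerance candidates
        bad_l = np.zeros(len(xy_l), dtype=bool)
        bad_s = np.zeros(len(xy_s), dtype=bool)
        if s_tie.any():
            for col in range(j_sl.shape[1]):
                sel = s_tie & (d_sl[:, col] <= tolerance)
                bad_l[j_sl[sel, col]] = True
        if l_tie.any():
            for col in range(j_ls.shape[1]):
                sel = l_tie & (d_ls[:, col] <= tolerance)
                bad_s[j_ls[sel, col]] = True
        s_ok = ~(s_tie | bad_s)
        l_ok = ~(l_tie | bad_l)

        nn_of_s = j_sl[:, 0]
        nn_of_l = j_ls[:, 0]
        cand = (
            (d_sl[:, 0] <= tolerance)
            & s_ok
            & (nn_of_l[nn_of_s] == np.arange(len(xy_s)))
            & l_ok[nn_of_s]
        )
        pair_s_idx.append(s_idx[cand])
        pair_l_idx.append(l_idx[nn_of_s[cand]])

    if pair_s_idx:
        si = np.concatenate(pair_s_idx)
        li = np.concatenate(pair_l_idx)
    else:
        si = np.array([], dtype=np.int64)
        li = np.array([], dtype=np.int64)

    pairs = pd.DataFrame(
        {
            "frame": df_s["frame"].to_numpy()[si] if len(si) else np.array([], dtype=np.int64),
            "x_s": df_s["x"].to_numpy()[si],
            "y_s": df_s["y"].to_numpy()[si],
            "x_l": xy_l_moved[li, 0] if len(li) else np.array([]),
            "y_l": xy_l_moved[li, 1] if len(li) else np.array([]),
            "i_s": df_s["photons"].to_numpy()[si],
            "i_l": df_l["photons"].to_numpy()[li],
        }
    )
    pairs["r"] = pairs["i_l"] / pairs["i_s"]
    pairs = pairs.sort_values("frame", kind="stable").reset_index(drop=True)

    mask_s = np.ones(len(df_s), dtype=bool)
    mask_s[si] = False
    mask_l = np.ones(len(df_l), dtype=bool)
    mask_l[li] = False
    unpaired_S = table_S.with_df(df_s.loc[mask_s])
    unpaired_L = table_L.with_df(df_l.loc[mask_l])
    return pairs, unpaired_S, unpaired_L
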