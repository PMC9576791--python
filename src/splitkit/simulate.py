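"""Ground-truthed simulator for two-channel split-camera localization data.

The generator reproduces the statistical structure the demixing method
assumes, event by event:

* each blink event of an emitter draws a total photon count ``I`` (fixed,
  Poisson, or lognormal), which is split *exactly* between the two channels,
  ``I_L ~ Binomial(I, r / (1 + r))`` and ``I_S = I - I_L``, so that
  ``I_S + I_L = I`` holds per event and ``E[I_L] / E[I_S] = r``;
* the true L-channel position is offset from the S-channel position by a
  position-dependent chromatic field (the S channel is the reference frame);
* each channel's observed position adds isotropic Gaussian localization
  noise of per-axis standard deviation ``sigma_0 / sqrt(I_c)`` — pure shot
  noise with PSF width ``sigma_0``;
* emitters blink in geometric-length runs of consecutive frames, so the
  same molecule produces chains of re-localizations;
* each channel independently drops events below its detection threshold
  and gains uniformly scattered background localizations, creating the
  unreliable single-channel detections that coincidence filtering removes.

All randomness derives from a single seed, so identical configs give
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd

from .tables import LocalizationTable, Rectangle

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "SimulationOutput",
    "simulate_acquisition",
    "simulate_drifted_series",
    "colocated_species_scenario",
    "grouping_scenario",
    "FWHM_TO_SIGMA",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpeciesSpec:
    """One fluorophore species: channel ratio, photon budget, emitter count."""

    name: str
    ratio: float  # r = E[I_L] / E[I_S]
    mean_photons: float  # mean total photons per blink event
    n_emitters: int = 1
    positions: Optional[np.ndarray] = None  # (n_emitters, 2) nm; random if None

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")
        if self.mean_photons <= 0:
            raise ValueError("mean_photons must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of a synthetic two-channel acquisition.

    ``chromatic_field`` maps true (N, 2) positions to (N, 2) offsets in nm,
    applied to the L channel only.  ``photon_model`` is one of ``"fixed"``,
    ``"poisson"``, ``"lognormal"`` (with ``photon_sd`` as the lognormal
    standard deviation of the total).  The blink model turns an emitter on
    with probability ``blink_on_probability`` per frame and keeps it on for
    a geometric run of mean ``blink_mean_run`` consecutive frames.
    ``background_rate`` is the Poisson mean of spurious localizations per
    frame per channel, uniform over the field with lognormal photon counts.
    """

    fov: Rectangle = Rectangle(0.0, 20_000.0, 0.0, 20_000.0)
    species: Tuple[SpeciesSpec, ...] = ()
    psf_sigma: float = 300.0 * FWHM_TO_SIGMA  # nm
    chromatic_field: Optional[Callable[[np.ndarray], np.ndarray]] = None
    n_frames: int = 10_000
    blink_on_probability: float = 1e-4
    blink_mean_run: float = 2.0
    photon_model: str = "lognormal"
    photon_sd: float = 0.5  # lognormal sd of log-total, used when lognormal
    background_rate: float = 0.0
    background_mean_photons: float = 300.0
    detection_threshold_s: float = 0.0
    detection_threshold_l: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.blink_on_probability <= 1.0):
            raise ValueError("blink_on_probability must be in [0, 1]")
        if self.photon_model not in ("fixed", "poisson", "lognormal"):
            raise ValueError(f"unknown photon model {self.photon_model!r}")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")

    @classmethod
    def from_fwhm(cls, psf_fwhm: float, **kwargs) -> "SimulationConfig":
        return cls(psf_sigma=psf_fwhm * FWHM_TO_SIGMA, **kwargs)


@dataclass
class SimulationOutput:
    """Two channel tables plus the per-event ground truth."""

    table_S: LocalizationTable
    table_L: LocalizationTable
    truth: pd.DataFrame  # emitter_id, species, frame, mu_x, mu_y, i_s, i_l,
    #                      detected_s, detected_l


def _draw_totals(rng: np.random.Generator, n: int, cfg: SimulationConfig,
                 mean: float) -> np.ndarray:
    if cfg.photon_model == "fixed":
        return np.full(n, int(round(mean)), dtype=np.int64)
    if cfg.photon_model == "poisson":
        return rng.poisson(mean, size=n).astype(np.int64)
    # lognormal parameterized so the median is `mean`
    draw = rng.lognormal(np.log(mean), cfg.photon_sd, size=n)
    return np.maximum(np.round(draw).astype(np.int64), 1)


def _blink_frames(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Frames (1-based) on which one emitter is on, as geometric runs."""
    n = cfg.n_frames
    starts = np.flatnonzero(rng.random(n) < cfg.blink_on_probability) + 1
    if len(starts) == 0:
        return np.array([], dtype=np.int64)
    p = min(1.0 / max(cfg.blink_mean_run, 1.0), 1.0)
    lengths = rng.geometric(p, size=len(starts))
    frames = np.concatenate([np.arange(s, min(s + L, n + 1)) for s, L in zip(starts, lengths)])
    return np.unique(frames)


def simulate_acquisition(
    config: SimulationConfig,
    drift_nm_per_frame: Tuple[float, float] = (0.0, 0.0),
) -> SimulationOutput:
    """Generate the S- and L-channel tables and the event-level ground truth.

    ``drift_nm_per_frame`` adds ``frame * drift`` to every true position
    before localization noise (zero by default).
    """
    rng = np.random.default_rng(config.seed)
    fov = config.fov
    drift = np.asarray(drift_nm_per_frame, dtype=float)

    records = []
    emitter_id = 0
    for spec in config.species:
        if spec.positions is not None:
            positions = np.asarray(spec.positions, dtype=float)
        else:
            positions = np.column_stack(
                [
                    rng.uniform(fov.xmin, fov.xmax, spec.n_emitters),
                    rng.uniform(fov.ymin, fov.ymax, spec.n_emitters),
                ]
            )
        p_l = spec.ratio / (1.0 + spec.ratio)
        for mu in positions:
            frames = _blink_frames(rng, config)
            if len(frames) == 0:
                emitter_id += 1
                continue
            totals = _draw_totals(rng, len(frames), config, spec.mean_photons)
            i_l = rng.binomial(totals, p_l)
            i_s = totals - i_l
            mu_frame = mu[None, :] + frames[:, None] * drift[None, :]
            if config.chromatic_field is not None:
                mu_l = mu_frame + config.chromatic_field(mu_frame)
            else:
                mu_l = mu_frame
            with np.errstate(divide="ignore"):
                sd_s = np.where(i_s > 0, config.psf_sigma / np.sqrt(np.maximum(i_s, 1)), np.inf)
                sd_l = np.where(i_l > 0, config.psf_sigma / np.sqrt(np.maximum(i_l, 1)), np.inf)
            x_s = mu_frame + rng.normal(size=(len(frames), 2)) * sd_s[:, None]
            x_l = mu_l + rng.normal(size=(len(frames), 2)) * sd_l[:, None]
            det_s = (i_s > config.detection_threshold_s) & (i_s > 0)
            det_l = (i_l > config.detection_threshold_l) & (i_l > 0)
            records.append(
                pd.DataFrame(
                    {
                        "emitter_id": emitter_id,
                        "species": spec.name,
                        "frame": frames,
                        "mu_x": mu_frame[:, 0],
                        "mu_y": mu_frame[:, 1],
                        "i_s": i_s,
                        "i_l": i_l,
                        "x_s": x_s[:, 0],
                        "y_s": x_s[:, 1],
                        "x_l": x_l[:, 0],
                        "y_l": x_l[:, 1],
                        "detected_s": det_s,
                        "detected_l": det_l,
                    }
                )
            )
            emitter_id += 1

    truth = (
        pd.concat(records, ignore_index=True)
        if records
        else pd.DataFrame(
            columns=[
                "emitter_id", "species", "frame", "mu_x", "mu_y", "i_s", "i_l",
                "x_s", "y_s", "x_l", "y_l", "detected_s", "detected_l",
            ]
        )
    )
    truth = truth.sort_values(["frame", "emitter_id"], kind="stable").reset_index(drop=True)

    def channel_table(which: str) -> LocalizationTable:
        det = truth[f"detected_{which.lower()}"].to_numpy(dtype=bool) if len(truth) else np.array([], bool)
        sub = truth.loc[det]
        frames = sub["frame"].to_numpy(dtype=np.int64)
        x = sub[f"x_{which.lower()}"].to_numpy(dtype=float)
        y = sub[f"y_{which.lower()}"].to_numpy(dtype=float)
        ph = sub[f"i_{which.lower()}"].to_numpy(dtype=float)
        # channel-independent background
        rate = config.background_rate
        if rate > 0:
            n_bg = rng.poisson(rate * config.n_frames)
            if n_bg:
                frames = np.concatenate([frames, rng.integers(1, config.n_frames + 1, n_bg)])
                x = np.concatenate([x, rng.uniform(fov.xmin, fov.xmax, n_bg)])
                y = np.concatenate([y, rng.uniform(fov.ymin, fov.ymax, n_bg)])
                ph = np.concatenate(
                    [ph, np.maximum(np.round(
                        rng.lognormal(np.log(config.background_mean_photons), 0.5, n_bg)
                    ), 1.0)]
                )
        return LocalizationTable.from_arrays(
            frames, x, y, ph, bounds=None if len(x) == 0 else _padded(fov),
            source_channel=which,
        )

    return SimulationOutput(channel_table("S"), channel_table("L"), truth)


def _padded(fov: Rectangle, pad: float = 500.0) -> Rectangle:
    """Field of view padded so noisy coordinates stay in bounds."""
    return Rectangle(fov.xmin - pad, fov.xmax + pad, fov.ymin - pad, fov.ymax + pad)


def simulate_drifted_series(
    config: SimulationConfig, drift_nm_per_frame: Tuple[float, float]
) -> SimulationOutput:
    """Acquisition with linear drift ``frame * drift`` added to true positions."""
    return simulate_acquisition(config, drift_nm_per_frame=drift_nm_per_frame)


def colocated_species_scenario(
    n_detections: int = 50, seed: int = 0
) -> Tuple[SimulationConfig, pd.DataFrame]:
    """Two co-located species benchmark for the output-coordinate methods.

    Two fluorophore species sit at the same true position; channel ratios
    0.6 and 3.5; every blink event carries exactly 2000 total photons; PSF
    FWHM 300 nm; a constant chromatic shift of (24, 8) nm on the L channel;
    ``n_detections`` events per species; no background, no thresholds.

    Because the blink machinery is bypassed (one event per listed frame),
    this returns the config *and* the ready-made event table produced by
    :func:`simulate_events`.
    """
    species = (
        SpeciesSpec("red", ratio=0.6, mean_photons=2000.0, n_emitters=1,
                    positions=np.array([[5000.0, 5000.0]])),
        SpeciesSpec("blue", ratio=3.5, mean_photons=2000.0, n_emitters=1,
                    positions=np.array([[5000.0, 5000.0]])),
    )
    config = SimulationConfig(
        fov=Rectangle(0.0, 10_000.0, 0.0, 10_000.0),
        species=species,
        psf_sigma=300.0 * FWHM_TO_SIGMA,
        chromatic_field=lambda pos: np.broadcast_to(np.array([24.0, 8.0]), pos.shape),
        n_frames=n_detections,
        photon_model="fixed",
        background_rate=0.0,
        detection_threshold_s=0.0,
        detection_threshold_l=0.0,
        seed=seed,
    )
    pairs = simulate_events(config, n_events_per_species=n_detections)
    return config, pairs


def simulate_events(
    config: SimulationConfig, n_events_per_species: int
) -> pd.DataFrame:
    """Draw a fixed number of paired blink events per species.

    Bypasses the blink/per-frame machinery: event k of every species lands
    on frame k+1, and both channels always detect.  Returns a pair table
    (columns ``frame, x_s, y_s, x_l, y_l, i_s, i_l, r, species, mu_x,
    mu_y``) ready for the demixing operations — the closed system in which
    the precision and chromatic properties of the output methods are
    exactly those of the per-event model.
    """
    rng = np.random.default_rng(config.seed)
    frames = np.arange(1, n_events_per_species + 1, dtype=np.int64)
    chunks = []
    for spec in config.species:
        mu = (
            np.asarray(spec.positions, dtype=float)[0]
            if spec.positions is not None
            else np.array([
                0.5 * (config.fov.xmin + config.fov.xmax),
                0.5 * (config.fov.ymin + config.fov.ymax),
            ])
        )
        totals = _draw_totals(rng, n_events_per_species, config, spec.mean_photons)
        p_l = spec.ratio / (1.0 + spec.ratio)
        i_l = rng.binomial(totals, p_l)
        i_s = totals - i_l
        # re-draw the rare all-in-one-channel events: a pair needs both > 0
        bad = (i_s == 0) | (i_l == 0)
        while bad.any():
            i_l[bad] = rng.binomial(totals[bad], p_l)
            i_s = totals - i_l
            bad = (i_s == 0) | (i_l == 0)
        mu_tiled = np.tile(mu, (n_events_per_species, 1))
        mu_l = mu_tiled + (
            config.chromatic_field(mu_tiled) if config.chromatic_field is not None
            else 0.0
        )
        sd_s = config.psf_sigma / np.sqrt(i_s)
        sd_l = config.psf_sigma / np.sqrt(i_l)
        x_s = mu_tiled + rng.normal(size=(n_events_per_species, 2)) * sd_s[:, None]
        x_l = mu_l + rng.normal(size=(n_events_per_species, 2)) * sd_l[:, None]
        chunks.append(
            pd.DataFrame(
                {
                    "frame": frames,
                    "x_s": x_s[:, 0],
                    "y_s": x_s[:, 1],
                    "x_l": x_l[:, 0],
                    "y_l": x_l[:, 1],
                    "i_s": i_s.astype(float),
                    "i_l": i_l.astype(float),
                    "species": spec.name,
                    "mu_x": mu_tiled[:, 0],
                    "mu_y": mu_tiled[:, 1],
                }
            )
        )
    pairs = pd.concat(chunks, ignore_index=True)
    pairs["r"] = pairs["i_l"] / pairs["i_s"]
    return pairs


def grouping_scenario(
    n_emitters: int = 300,
    fov_side: float = 2000.0,
    mean_photons: float = 1000.0,
    seed: int = 0,
) -> SimulationConfig:
    """Standard blinking scenario exercising consecutive-frame grouping.

    Emitters scattered in a small field blink in runs of mean 2-3 frames,
    each event around 1000 photons, so groups carry enough photons for the
    refinement to visibly tighten the reconstruction.
    """
    rng = np.random.default_rng(seed)
    positions = rng.uniform(100.0, fov_side - 100.0, size=(n_emitters, 2))
    return SimulationConfig(
        fov=Rectangle(0.0, fov_side, 0.0, fov_side),
        species=(
            SpeciesSpec("single", ratio=1.0, mean_photons=mean_photons,
                        n_emitters=n_emitters, positions=positions),
        ),
        psf_sigma=140.0,
        n_frames=4000,
        blink_on_probability=2e-3,
        blink_mean_run=2.5,
        photon_model="lognormal",
        photon_sd=0.3,
        seed=seed,
    )
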