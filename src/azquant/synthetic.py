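"""Synthetic forward models for single-active-zone imaging experiments.

This module generates every input the analysis pipeline consumes, with known
ground truth: maps of active zones (AZs) carrying a right-skewed channel
intensity, a correlated second channel, and an intensity-coupled release
probability; rendered two-channel punctum images; stimulus-locked Bernoulli
release trials and the movies they produce; paired before/after intensity
tables under null/additive/multiplicative perturbations with a vehicle group;
ratiometric Ca2+ transient recordings; and quantal ephys recordings.

Conventions
-----------
Pixel coordinates are 0-based ``(x, y)`` with continuous AZ centers; ``x`` is
the column index and ``y`` the row index of the pixel grid. Fields are given
as ``(width, height)`` in pixels. All randomness flows through
``numpy.random.default_rng(seed)``: identical seeds and parameters yield
bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AZMap",
    "ImageFrame",
    "Movie",
    "EventStream",
    "PerturbationModel",
    "TransientRecording",
    "EphysRecording",
    "gen_az_map",
    "render_puncta_image",
    "gen_release_trials",
    "render_event_movie",
    "gen_paired_intensities",
    "gen_transient_recording",
    "gen_ephys_recording",
    "DEFAULT_FIELD",
    "DEFAULT_LEVEL_DIST",
    "DEFAULT_COUPLING",
    "PR_FLOOR",
]

#: default imaging field, (width, height) in pixels at 0.1 um/px
DEFAULT_FIELD: tuple[int, int] = (256, 256)

#: gamma parameters of the per-AZ channel-level distribution (a.u.);
#: right-skewed: most AZs low-to-moderate, a minority bright. The positive
#: offset is the fluorescence floor of a formed punctum — every AZ carries
#: a resolvable punctum, so even the dimmest sits above the camera noise.
#: The Pr coupling min-max-normalizes levels and is invariant to the offset.
DEFAULT_LEVEL_DIST: dict = {"shape": 2.0, "scale": 300.0, "loc": 250.0}

#: affine coupling from min-max-normalized level to release probability;
#: slope 0.5 with gamma(2) levels puts the median Pr near 0.11 with ~90 %
#: of AZs between 0.01 and 0.5
DEFAULT_COUPLING: dict = {"slope": 0.5, "intercept": 0.0, "noise_sd": 0.03}

#: lower clamp of release probability (an AZ never releases with exactly 0)
PR_FLOOR: float = 0.001


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AZMap:
    """Ground-truth map of active zones in one simulated NMJ field.

    Attributes
    ----------
    az_id : int array
        Stable identifiers, ``0..n-1``.
    x, y : float arrays
        Continuous AZ centers in pixels (0-based, ``x`` = column).
    true_level : float array
        Latent first-channel (Cac) intensity per AZ, a.u., > 0.
    second_level : float array
        Correlated second-channel (Brp) intensity, a.u., > 0.
    true_pr : float array
        Per-AZ single-stimulus release probability in ``[PR_FLOOR, 1]``.
    field : (width, height)
        Pixel extent of the imaging field.
    """

    az_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    true_level: np.ndarray
    second_level: np.ndarray
    true_pr: np.ndarray
    field: tuple[int, int]

    def __len__(self) -> int:
        return len(self.az_id)

    @property
    def centers(self) -> np.ndarray:
        """``(n, 2)`` array of ``(x, y)`` centers."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "az_id": self.az_id,
                "x": self.x,
                "y": self.y,
                "true_level": self.true_level,
                "second_level": self.second_level,
                "true_pr": self.true_pr,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, field: tuple[int, int]) -> "AZMap":
        return cls(
            az_id=df["az_id"].to_numpy(int),
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            true_level=df["true_level"].to_numpy(float),
            second_level=df["second_level"].to_numpy(float),
            true_pr=df["true_pr"].to_numpy(float),
            field=tuple(field),
        )


@dataclass(frozen=True)
class ImageFrame:
    """A single 2-D grayscale intensity image."""

    pixels: np.ndarray  # (height, width), nonnegative
    pixel_size: float = 0.1  # um / px
    channel: str = ""

    def __post_init__(self):
        if self.pixels.ndim != 2:
            raise ValueError("ImageFrame.pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("ImageFrame.pixels must be finite")


@dataclass(frozen=True)
class Movie:
    """An ordered stack of frames with stimulus-locked frame indices."""

    frames: np.ndarray  # (n_frames, height, width)
    frame_rate: float  # frames / s
    stim_frames: np.ndarray  # strictly increasing frame indices

    def __post_init__(self):
        if self.frames.ndim != 3:
            raise ValueError("Movie.frames must be (t, h, w)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        sf = np.asarray(self.stim_frames)
        if sf.size and (np.any(np.diff(sf) <= 0) or sf[0] < 0 or sf[-1] >= len(self.frames)):
            raise ValueError("stim_frames must be strictly increasing and in range")

    @property
    def n_stimuli(self) -> int:
        return len(self.stim_frames)


@dataclass(frozen=True)
class EventStream:
    """Stimulus-indexed postsynaptic event coordinates.

    ``events`` has columns ``stimulus_index, x, y`` (plus ``true_az_id`` when
    produced by the generator — simulation truth, absent on detected streams).
    """

    events: pd.DataFrame
    n_stimuli: int

    def __post_init__(self):
        if len(self.events):
            si = self.events["stimulus_index"]
            if si.min() < 0 or si.max() >= self.n_stimuli:
                raise ValueError("stimulus_index out of range")

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class PerturbationModel:
    """Before -> after transform applied to per-AZ intensities.

    ``mode`` is one of ``null`` (after = before), ``additive``
    (after = before + param) or ``multiplicative`` (after = param * before).
    Measurement noise is multiplicative with coefficient of variation
    ``noise_cv`` plus an optional additive floor of SD ``noise_floor_sd``
    (a.u.; intensity-independent camera/readout noise — responsible for
    apparent decreases concentrating in dim AZs). ``vehicle_drift``
    multiplies every after-value, treated and vehicle alike (rundown /
    focus drift common to the session).
    """

    mode: str = "null"
    param: float = 0.0
    noise_cv: float = 0.0
    vehicle_drift: float = 1.0
    noise_floor_sd: float = 0.0

    def __post_init__(self):
        if self.mode not in ("null", "additive", "multiplicative"):
            raise ValueError(f"invalid perturbation mode: {self.mode!r}")
        if self.mode == "multiplicative" and self.param <= 0:
            raise ValueError("multiplicative factor must be > 0")
        if self.noise_cv < 0 or self.noise_floor_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class TransientRecording:
    """Two-channel ratiometric Ca2+ indicator recording.

    ``rhod`` is the Ca2+-sensitive channel, ``af647`` the insensitive
    normalizer; the quantity of interest is their ratio R(t).
    """

    time: np.ndarray  # s, strictly increasing
    rhod: np.ndarray
    af647: np.ndarray
    stimulus_times: np.ndarray  # s, single-AP stimuli
    train: dict | None = None  # {"start", "rate", "duration"}
    truth: dict = field(default_factory=dict)  # generator ground truth

    def __post_init__(self):
        n = len(self.time)
        if len(self.rhod) != n or len(self.af647) != n:
            raise ValueError("series lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.af647 <= 0):
            raise ValueError("af647 must be > 0 everywhere")


@dataclass(frozen=True)
class EphysRecording:
    """Amplitude lists and quality metadata from one sharp-electrode NMJ recording."""

    mejp_amplitudes: np.ndarray  # mV
    ejp_amplitudes: np.ndarray  # mV
    v_rest: float  # mV
    r_in: float  # MOhm


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _place_centers(
    rng: np.random.Generator,
    n: int,
    field: tuple[int, int],
    min_spacing: float,
    margin: float,
    max_attempts_per_point: int = 2000,
) -> np.ndarray:
    """Rejection-sample ``n`` centers with pairwise spacing >= min_spacing."""
    width, height = field
    if width - 2 * margin <= 0 or height - 2 * margin <= 0:
        raise ValueError("field too small for requested margin")
    placed: list[tuple[float, float]] = []
    attempts = 0
    budget = max_attempts_per_point * n
    while len(placed) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n} AZs at spacing {min_spacing} in field "
                f"{field} after {budget} attempts"
            )
        attempts += 1
        cx = rng.uniform(margin, width - margin)
        cy = rng.uniform(margin, height - margin)
        ok = True
        for px, py in placed:
            if (cx - px) ** 2 + (cy - py) ** 2 < min_spacing**2:
                ok = False
                break
        if ok:
            placed.append((cx, cy))
    return np.asarray(placed, dtype=float)


def apply_coupling(
    levels: np.ndarray,
    coupling: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Map channel levels to release probabilities.

    Levels are min-max normalized within the sample and transformed affinely
    (``slope * z + intercept``) with optional Gaussian noise, then clamped to
    ``[PR_FLOOR, 1]``. A degenerate sample (all levels equal) normalizes to 0.5.
    """
    c = dict(DEFAULT_COUPLING)
    if coupling:
        c.update(coupling)
    levels = np.asarray(levels, dtype=float)
    lo, hi = levels.min(), levels.max()
    if hi > lo:
        z = (levels - lo) / (hi - lo)
    else:
        z = np.full_like(levels, 0.5)
    pr = c["slope"] * z + c["intercept"]
    if c["noise_sd"] > 0:
        if rng is None:
            rng = np.random.default_rng()
        pr = pr + rng.normal(0.0, c["noise_sd"], size=len(levels))
    return np.clip(pr, PR_FLOOR, 1.0)


def gen_az_map(
    n_az: int,
    field: tuple[int, int] = DEFAULT_FIELD,
    level_dist: Mapping[str, float] | None = None,
    coupling: Mapping[str, float] | None = None,
    second_channel_r: float = 0.95,
    min_spacing: float = 8.0,
    margin: float = 10.0,
    seed: int | None = None,
) -> AZMap:
    """Generate a ground-truth AZ map.

    Parameters
    ----------
    n_az : int
        Number of active zones (>= 1).
    field : (width, height)
        Field extent in pixels.
    level_dist : mapping
        ``{"shape", "scale", "loc"}`` of the gamma level distribution (a.u.).
    coupling : mapping
        ``{"slope", "intercept", "noise_sd"}`` of the level -> Pr map.
    second_channel_r : float
        Target Pearson correlation between the two channel levels.
    min_spacing : float
        Minimum pairwise center distance in pixels.
    margin : float
        Keep-out border so rendered puncta stay inside the field.
    seed : int, optional
        RNG seed; identical seed and parameters give identical maps.
    """
    if n_az < 1:
        raise ValueError("n_az must be >= 1")
    ld = dict(DEFAULT_LEVEL_DIST)
    if level_dist:
        ld.update(level_dist)
    rng = np.random.default_rng(seed)
    centers = _place_centers(rng, n_az, field, min_spacing, margin)
    levels = ld.get("loc", 0.0) + rng.gamma(ld["shape"], ld["scale"], size=n_az)
    pr = apply_coupling(levels, coupling, rng)

    # second channel: share the standardized level signal at correlation r,
    # mapped back onto the same scale and clipped positive
    r = float(second_channel_r)
    if not -1.0 <= r <= 1.0:
        raise ValueError("second_channel_r must be in [-1, 1]")
    mu, sd = levels.mean(), levels.std()
    if sd > 0 and n_az > 1:
        z = (levels - mu) / sd
        mix = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n_az)
        second = mu + sd * mix
    else:
        second = levels.copy()
    second = np.maximum(second, 1e-6 + 0.01 * max(mu, 1.0))

    return AZMap(
        az_id=np.arange(n_az),
        x=centers[:, 0],
        y=centers[:, 1],
        true_level=levels,
        second_level=second,
        true_pr=pr,
        field=tuple(field),
    )


def _add_gaussian_spots(
    canvas: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    integrals: np.ndarray,
    sigma: float,
) -> None:
    """Add unit-normalized 2-D Gaussian spots in place.

    Each spot deposits a discrete kernel normalized to sum 1 over its full
    (untruncated) support, scaled by its integrated intensity; spots clipped
    by the field border lose the clipped flux, as real puncta do.
    """
    height, width = canvas.shape
    half = int(math.ceil(5.0 * sigma))
    for cx, cy, amp in zip(xs, ys, integrals):
        x0 = int(math.floor(cx)) - half
        y0 = int(math.floor(cy)) - half
        xx = np.arange(x0, x0 + 2 * half + 1)
        yy = np.arange(y0, y0 + 2 * half + 1)
        gx = np.exp(-((xx - cx) ** 2) / (2.0 * sigma**2))
        gy = np.exp(-((yy - cy) ** 2) / (2.0 * sigma**2))
        patch = np.outer(gy, gx)
        patch *= amp / patch.sum()
        # clip patch to field
        ux0, ux1 = max(x0, 0), min(x0 + 2 * half + 1, width)
        uy0, uy1 = max(y0, 0), min(y0 + 2 * half + 1, height)
        if ux0 >= ux1 or uy0 >= uy1:
            continue
        canvas[uy0:uy1, ux0:ux1] += patch[uy0 - y0 : uy1 - y0, ux0 - x0 : ux1 - x0]


def render_puncta_image(
    az_map: AZMap,
    psf_sigma: float = 1.5,
    background: float = 20.0,
    noise: Mapping | None = None,
    channel: str = "cac",
    use_second_level: bool = False,
    pixel_size: float = 0.1,
    seed: int | None = None,
) -> ImageFrame:
    """Render an AZ map as a diffraction-limited punctum image.

    Each AZ appears as an isotropic Gaussian whose *integrated* intensity
    equals its channel level, on a constant background, with optional seeded
    noise (``{"gaussian_sd": s}`` or ``{"poisson": True}``).
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    width, height = az_map.field
    if len(az_map) and (
        az_map.x.min() < 0 or az_map.x.max() >= width or az_map.y.min() < 0 or az_map.y.max() >= height
    ):
        raise ValueError("AZ center outside field")
    canvas = np.full((height, width), float(background))
    levels = az_map.second_level if use_second_level else az_map.true_level
    if len(az_map):
        _add_gaussian_spots(canvas, az_map.x, az_map.y, levels, psf_sigma)
    if noise:
        rng = np.random.default_rng(seed)
        if noise.get("poisson"):
            canvas = rng.poisson(np.maximum(canvas, 0.0)).astype(float)
        if noise.get("gaussian_sd", 0.0) > 0:
            canvas = canvas + rng.normal(0.0, noise["gaussian_sd"], canvas.shape)
        canvas = np.maximum(canvas, 0.0)
    return ImageFrame(pixels=canvas, pixel_size=pixel_size, channel=channel)


def gen_release_trials(
    az_map: AZMap,
    n_stimuli: int = 100,
    jitter_sd: float = 1.0,
    seed: int | None = None,
) -> EventStream:
    """Simulate stimulus-locked release: independent Bernoulli(true_pr) per
    AZ per stimulus, with isotropic Gaussian localization jitter.

    The returned stream carries a ``true_az_id`` column (simulation truth,
    used only for validation — detected streams do not have it).
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(az_map)
    # (n_stimuli, n_az) Bernoulli table
    hits = rng.random((n_stimuli, n)) < az_map.true_pr[None, :]
    stim_idx, az_idx = np.nonzero(hits)
    k = len(stim_idx)
    if jitter_sd > 0:
        jit = rng.normal(0.0, jitter_sd, size=(k, 2))
    else:
        jit = np.zeros((k, 2))
    df = pd.DataFrame(
        {
            "stimulus_index": stim_idx,
            "x": az_map.x[az_idx] + jit[:, 0],
            "y": az_map.y[az_idx] + jit[:, 1],
            "true_az_id": az_map.az_id[az_idx],
        }
    )
    return EventStream(events=df, n_stimuli=n_stimuli)


def render_event_movie(
    events: EventStream,
    field: tuple[int, int],
    frame_rate: float = 15.3,
    frames_per_stim: int = 4,
    n_baseline_frames: int = 12,
    flash_amplitude: float = 500.0,
    flash_sigma: float = 2.0,
    decay_ratio: float = 0.5,
    decay_frames: int = 3,
    background: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Movie:
    """Render an event stream as a stimulus-locked movie.

    The movie starts with ``n_baseline_frames`` quiescent frames; stimulus
    ``i`` occurs at frame ``n_baseline_frames + i * frames_per_stim``. Each
    event is a Gaussian flash of peak-frame integrated intensity
    ``flash_amplitude`` that decays geometrically (ratio ``decay_ratio``)
    over ``decay_frames`` frames.
    """
    if decay_frames < 2:
        raise ValueError("decay_frames must be >= 2 (events must persist)")
    if frames_per_stim < 1:
        raise ValueError("frames_per_stim must be >= 1")
    width, height = field
    n_frames = n_baseline_frames + events.n_stimuli * frames_per_stim + decay_frames
    frames = np.full((n_frames, height, width), float(background), dtype=np.float64)
    stim_frames = n_baseline_frames + np.arange(events.n_stimuli) * frames_per_stim
    ev = events.events
    for s, x, y in zip(ev["stimulus_index"].to_numpy(), ev["x"].to_numpy(), ev["y"].to_numpy()):
        f0 = int(stim_frames[int(s)])
        for k in range(decay_frames):
            if f0 + k >= n_frames:
                break
            amp = flash_amplitude * decay_ratio**k
            _add_gaussian_spots(
                frames[f0 + k], np.array([x]), np.array([y]), np.array([amp]), flash_sigma
            )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
        frames = np.maximum(frames, 0.0)
    return Movie(frames=frames, frame_rate=frame_rate, stim_frames=stim_frames)


def gen_paired_intensities(
    az_map: AZMap,
    model: PerturbationModel,
    n_vehicle_az: int | None = None,
    vehicle_az_map: AZMap | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate raw paired before/after intensity tables.

    Returns ``(treated, vehicle)`` DataFrames with columns
    ``punctum_id, baseline, after_raw``. Treated after-values apply the
    perturbation transform; vehicle after-values do not. Both groups share
    the multiplicative ``vehicle_drift`` and the seeded noise model
    ``after = transform(before) * (1 + cv_noise) * drift + floor_noise``.

    The vehicle group comes from ``vehicle_az_map`` when given (an
    independent preparation); otherwise ``n_vehicle_az`` baselines are
    resampled with replacement from the treated map's levels.
    """
    rng = np.random.default_rng(seed)
    base = az_map.true_level.astype(float)
    if vehicle_az_map is not None:
        vbase = vehicle_az_map.true_level.astype(float)
    else:
        if n_vehicle_az is None:
            n_vehicle_az = len(az_map)
        vbase = rng.choice(base, size=n_vehicle_az, replace=True)

    if model.mode == "null":
        transformed = base
    elif model.mode == "additive":
        transformed = base + model.param
    elif model.mode == "multiplicative":
        transformed = base * model.param
    else:  # pragma: no cover - guarded by PerturbationModel
        raise ValueError(model.mode)

    def _noisy(values: np.ndarray) -> np.ndarray:
        out = values.copy()
        if model.noise_cv > 0:
            out = out * (1.0 + rng.normal(0.0, model.noise_cv, size=len(out)))
        out = out * model.vehicle_drift
        if model.noise_floor_sd > 0:
            out = out + rng.normal(0.0, model.noise_floor_sd, size=len(out))
        return out

    treated = pd.DataFrame(
        {"punctum_id": np.arange(len(base)), "baseline": base, "after_raw": _noisy(transformed)}
    )
    vehicle = pd.DataFrame(
        {"punctum_id": np.arange(len(vbase)), "baseline": vbase, "after_raw": _noisy(vbase)}
    )
    return treated, vehicle


def gen_transient_recording(
    resting_R: float = 2.7,
    delta_R: float = 4.5,
    tau: float = 0.08,
    n_sweeps: int = 10,
    train: Mapping | None = None,
    noise_sd: float = 0.0,
    sample_rate: float = 114.0,
    af647_level: float = 100.0,
    seed: int | None = None,
) -> TransientRecording:
    """Generate a ratiometric Ca2+ transient recording.

    ``n_sweeps`` single action potentials at 1 Hz, each an instantaneous-rise
    exponential-decay ratio transient ``delta_R * exp(-t/tau)``, followed by a
    stimulus train modeled as a flat plateau ``plateau_dR`` above rest for its
    duration (``train = {"rate", "duration", "plateau_dR"}``), decaying with
    ``tau`` afterwards. Noise of SD ``noise_sd`` (ratio units) enters through
    the rhod channel; af647 is constant.

    Stimulus times are snapped to the sample grid so the noiseless peak
    equals ``resting_R + delta_R`` exactly.
    """
    if n_sweeps < 0:
        raise ValueError("n_sweeps must be >= 0")
    tr = {"rate": 20.0, "duration": 1.0, "plateau_dR": 9.71}
    if train:
        tr.update(train)
    dt = 1.0 / sample_rate
    stim_times = np.array([round((1.0 + i) * sample_rate) * dt for i in range(n_sweeps)])
    train_start = round((n_sweeps + 2.0) * sample_rate) * dt
    train_end = train_start + tr["duration"]
    total = train_end + 1.5
    t = np.arange(0.0, total, dt)

    ratio = np.full_like(t, float(resting_R))
    for ts in stim_times:
        mask = t >= ts - 0.5 * dt
        ratio[mask] += delta_R * np.exp(-(t[mask] - ts) / tau)
    in_train = (t >= train_start - 0.5 * dt) & (t < train_end - 0.5 * dt)
    ratio[in_train] += tr["plateau_dR"]
    post = t >= train_end - 0.5 * dt
    ratio[post] += tr["plateau_dR"] * np.exp(-(t[post] - train_end) / tau)

    rhod = ratio * af647_level
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rhod = rhod + rng.normal(0.0, noise_sd * af647_level, size=len(t))
    af = np.full_like(t, float(af647_level))
    return TransientRecording(
        time=t,
        rhod=rhod,
        af647=af,
        stimulus_times=stim_times,
        train={"start": train_start, "rate": tr["rate"], "duration": tr["duration"]},
        truth={
            "resting_R": resting_R,
            "delta_R": delta_R,
            "tau": tau,
            "plateau_dR": tr["plateau_dR"],
        },
    )


def gen_ephys_recording(
    mejp_mean: float = 1.0,
    mejp_cv: float = 0.3,
    n_mejps: int = 120,
    quantal_content: float = 30.0,
    n_ejps: int = 25,
    v_rest: float = -70.0,
    r_in: float = 8.0,
    seed: int | None = None,
) -> EphysRecording:
    """Generate a quantal ephys recording.

    mEJP amplitudes are gamma-distributed with the stated mean and CV
    (``cv=0`` degenerates to a constant). Each EJP is the sum of
    ``k ~ Poisson(quantal_content)`` quanta drawn from the mEJP distribution
    (``k`` floored at 1 so amplitudes stay positive), so mean EJP approaches
    ``quantal_content * mejp_mean``.
    """
    if n_mejps < 1:
        raise ValueError("n_mejps must be >= 1")
    if n_ejps < 1:
        raise ValueError("n_ejps must be >= 1")
    if mejp_mean <= 0:
        raise ValueError("mejp_mean must be > 0")
    rng = np.random.default_rng(seed)

    def _quanta(size: int) -> np.ndarray:
        if mejp_cv == 0:
            return np.full(size, float(mejp_mean))
        shape = 1.0 / mejp_cv**2
        scale = mejp_mean * mejp_cv**2
        return rng.gamma(shape, scale, size=size)

    mejps = _quanta(n_mejps)
    counts = np.maximum(rng.poisson(quantal_content, size=n_ejps), 1)
    ejps = np.array([_quanta(int(k)).sum() for k in counts])
    return EphysRecording(
        mejp_amplitudes=mejps, ejp_amplitudes=ejps, v_rest=float(v_rest), r_in=float(r_in)
    )
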