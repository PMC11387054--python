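"""Reading, cleaning and aligning the raw biologging streams.

Raw inputs are delimited text, one directory per flight:
``track_<bird>.csv`` (5 Hz positions, metres east/north/up, accuracy
flag), ``accel_<bird>.csv`` (20 Hz tri-axial acceleration in g) and
``hr_<bird>.csv`` (heart rate in bpm).  Cleaning follows the study's
rules: trim the departure/landing minutes, drop low-accuracy fixes,
interpolate only gaps under 1 s, optionally exclude thermalling
(circling climbs), and align everything on the 5 Hz trajectory clock.
Birds whose acceleration stream is offset from the GNSS clock by more
than a tolerance (default 1 s) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from wakeflight import signals

__all__ = [
    "ParseError",
    "AlignmentError",
    "StreamOffsetError",
    "CleaningConfig",
    "BirdTrajectory",
    "AlignedStreams",
    "load_tracks",
    "load_accel",
    "load_hr",
    "clean_trajectory",
    "detect_thermalling",
    "estimate_stream_offset",
    "align_streams",
]


class ParseError(ValueError):
    """A raw file violates the fixture contract (columns, time order)."""


class AlignmentError(ValueError):
    """Streams share no usable time support."""


class StreamOffsetError(AlignmentError):
    """Accelerometer/GNSS clock offset exceeds the tolerance; bird excluded."""


@dataclass(frozen=True)
class CleaningConfig:
    """Trajectory cleaning rules.

    ``trim_s`` seconds are removed at both ends (the birds take a while
    to settle behind the guide aircraft after departure, default 600 s);
    masked gaps shorter than ``max_gap_interp_s`` are linearly
    interpolated, longer gaps stay masked.  Thermal exclusion flags
    windows with a full rotation while climbing.
    """

    trim_s: float = 600.0
    max_gap_interp_s: float = 1.0
    exclude_thermals: bool = False
    thermal_rotation_deg: float = 360.0
    thermal_window_s: float = 20.0
    thermal_climb_ms: float = 0.5
    max_stream_offset_s: float = 1.0

    def __post_init__(self):
        if self.trim_s < 0 or self.max_gap_interp_s < 0:
            raise ValueError("trim_s and max_gap_interp_s must be non-negative")


@dataclass
class BirdTrajectory:
    """Per-bird timestamped 3-D track with validity mask and velocity."""

    bird_id: int
    t: np.ndarray
    position: np.ndarray          # (n, 3) east/north/up, metres
    accuracy_ok: np.ndarray       # raw quality flag
    valid: np.ndarray             # post-cleaning validity mask
    trimmed: bool = False
    _velocity: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bird_id: int) -> "BirdTrajectory":
        """Build a track from a (t, east, north, up, accuracy) table."""
        acc = df["accuracy"].to_numpy(float) > 0.5
        return cls(
            bird_id=bird_id,
            t=df["t"].to_numpy(float),
            position=df[["east", "north", "up"]].to_numpy(float),
            accuracy_ok=acc,
            valid=acc.copy(),
        )

    @property
    def rate_hz(self) -> float:
        if len(self.t) < 2:
            return float("nan")
        return 1.0 / np.median(np.diff(self.t))

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0] + 1.0 / self.rate_hz) if len(self.t) else 0.0

    @property
    def velocity(self) -> np.ndarray:
        """Central-difference velocity over 1 s (5 fixes at 5 Hz).

        The wide stencil stabilises the flight-direction frame against
        5 Hz jitter.  NaN where the stencil touches an invalid sample.
        """
        if self._velocity is None:
            self._velocity = _central_velocity(self.t, self.position, self.valid)
        return self._velocity

    def as_track_dict(self) -> dict:
        return {
            "t": self.t,
            "position": self.position,
            "velocity": self.velocity,
            "valid": self.valid & np.isfinite(self.velocity).all(axis=1),
        }


def _central_velocity(t, p, valid):
    n = len(t)
    v = np.full((n, 3), np.nan)
    if n < 5:
        return v
    k = 2
    idx = np.arange(k, n - k)
    dt = (t[idx + k] - t[idx - k])[:, None]
    v[idx] = (p[idx + k] - p[idx - k]) / dt
    ok = valid.copy()
    stencil_ok = np.ones(n, dtype=bool)
    for off in range(-k, k + 1):
        stencil_ok[idx] &= ok[idx + off]
    v[~stencil_ok] = np.nan
    return v


def _check_table(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = np.flatnonzero(~np.isfinite(df[list(required)].to_numpy(float)).all(axis=1))
    if bad.size:
        raise ParseError(f"{path}: malformed row at line {bad[0] + 2}")
    tt = df["t"].to_numpy(float)
    nonmono = np.flatnonzero(np.diff(tt) <= 0)
    if nonmono.size:
        i = int(nonmono[0]) + 1
        raise ParseError(
            f"{path}: non-monotone time at line {i + 2} (t={tt[i]:g} after t={tt[i - 1]:g})"
        )


def _bird_id(path) -> int:
    import re
    from pathlib import Path

    m = re.search(r"_(\d+)\.csv$", Path(path).name)
    if not m:
        raise ParseError(f"{path}: cannot infer bird id from filename")
    return int(m.group(1))


def load_tracks(paths) -> list[BirdTrajectory]:
    """Load trajectory files into typed tracks (sorted by bird id)."""
    out = []
    for path in sorted(paths, key=str):
        df = pd.read_csv(path)
        _check_table(df, ("t", "east", "north", "up", "accuracy"), path)
        acc = df["accuracy"].to_numpy(float) > 0.5
        out.append(
            BirdTrajectory(
                bird_id=_bird_id(path),
                t=df["t"].to_numpy(float),
                position=df[["east", "north", "up"]].to_numpy(float),
                accuracy_ok=acc,
                valid=acc.copy(),
            )
        )
    return out


def load_accel(paths) -> dict[int, pd.DataFrame]:
    """Load 20 Hz acceleration files, keyed by bird id."""
    out = {}
    for path in sorted(paths, key=str):
        df = pd.read_csv(path)
        _check_table(df, ("t", "ax", "ay", "az"), path)
        out[_bird_id(path)] = df
    return out


def load_hr(paths) -> dict[int, pd.DataFrame]:
    """Load heart-rate (bpm) files, keyed by bird id."""
    out = {}
    for path in sorted(paths, key=str):
        df = pd.read_csv(path)
        _check_table(df, ("t", "bpm"), path)
        out[_bird_id(path)] = df
    return out


def clean_trajectory(track: BirdTrajectory, cfg: CleaningConfig) -> BirdTrajectory:
    """Apply the cleaning rules; returns a new track (idempotent).

    Trims ``trim_s`` at both ends (once — a trimmed track is not
    re-trimmed), masks low-accuracy fixes, linearly interpolates masked
    gaps strictly shorter than ``max_gap_interp_s`` and optionally masks
    thermalling windows.  If trimming leaves under 2 s of data a warning
    is issued and the (possibly empty) track returned.
    """
    t, p = track.t, track.position.copy()
    acc = track.accuracy_ok.copy()
    if not track.trimmed and len(t):
        keep = (t >= t[0] + cfg.trim_s) & (t <= t[-1] - cfg.trim_s)
        t, p, acc = t[keep], p[keep], acc[keep]
    valid = acc.copy()
    if len(t) and (t[-1] - t[0]) < 2.0:
        warnings.warn(
            f"bird {track.bird_id}: under 2 s of data retained after trimming", stacklevel=2
        )
    if len(t) == 0:
        warnings.warn(f"bird {track.bird_id}: empty track after trimming", stacklevel=2)
        return BirdTrajectory(track.bird_id, t, p, acc, valid, trimmed=True)

    dt = np.median(np.diff(t)) if len(t) > 1 else 0.0
    # interpolate masked runs strictly shorter than the gap limit
    # (whole-sample comparison, immune to floating-point clock drift)
    max_gap_samples = int(round(cfg.max_gap_interp_s / dt)) if dt else 0
    runs = _runs(~valid)
    for start, stop in runs:
        if (stop - start) < max_gap_samples and start > 0 and stop < len(t):
            for j in range(3):
                p[start:stop, j] = np.interp(t[start:stop], [t[start - 1], t[stop]],
                                             [p[start - 1, j], p[stop, j]])
            valid[start:stop] = True
    out = BirdTrajectory(track.bird_id, t, p, acc, valid, trimmed=True)
    if cfg.exclude_thermals:
        mask = detect_thermalling(
            out,
            rotation_deg=cfg.thermal_rotation_deg,
            window_s=cfg.thermal_window_s,
            climb_ms=cfg.thermal_climb_ms,
        )
        out = replace(out, valid=out.valid & ~mask, _velocity=None)
    return out


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_thermalling(
    track: BirdTrajectory,
    rotation_deg: float = 360.0,
    window_s: float = 20.0,
    climb_ms: float = 0.5,
) -> np.ndarray:
    """Flag samples inside circling-climb windows.

    Thermalling is circling flight: a window of ``window_s`` is flagged
    when the cumulative unsigned heading change exceeds
    ``rotation_deg`` while the mean climb rate exceeds ``climb_ms``.
    Returns a boolean mask (empty on straight flight).
    """
    v = track.velocity
    n = len(track.t)
    mask = np.zeros(n, dtype=bool)
    if n < 3:
        return mask
    heading = np.arctan2(v[:, 0], v[:, 1])
    # NaN headings (undefined velocity) would poison the unwrap from
    # that sample onwards; hold the last defined heading instead
    heading = pd.Series(heading).ffill().bfill().to_numpy()
    if not np.isfinite(heading).any():
        return mask
    dh = np.abs(np.diff(np.unwrap(heading)))
    dh[~np.isfinite(dh)] = 0.0
    crot = np.concatenate([[0.0], np.cumsum(dh)])
    dt = np.median(np.diff(track.t))
    w = max(int(round(window_s / dt)), 2)
    for i in range(0, n - w + 1):
        rot = np.degrees(crot[i + w - 1] - crot[i])
        climb = (track.position[i + w - 1, 2] - track.position[i, 2]) / (track.t[i + w - 1] - track.t[i])
        if rot >= rotation_deg and climb >= climb_ms:
            mask[i : i + w] = True
    return mask


@dataclass
class AlignedStreams:
    """All proxies for one bird on the 5 Hz trajectory clock.

    Columns of ``table``: t, vedba (g), flap_frac (fraction of the
    0.2 s bin labelled flapping), flapping (majority label), hr (bpm,
    NaN if the bird carries no logger), valid.  Masked samples are
    excluded from every downstream computation.
    """

    bird_id: int
    table: pd.DataFrame
    stream_offset_s: float


def estimate_stream_offset(
    track: BirdTrajectory,
    flap20: np.ndarray,
    accel_t: np.ndarray,
    max_lag_s: float = 3.0,
    highpass_s: float = 2.0,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Accelerometer-vs-GNSS clock offset, seconds, by cross-correlation.

    Gliding birds sit slightly lower, so the glide envelope of the
    heave stream and the altitude share structure in the 0.5-2 Hz
    glide-event band.  Both series are high-passed at ``highpass_s``
    (removing the much slower station-keeping wander) and the lag
    maximising their (sign-flipped) normalised cross-correlation
    estimates the stream offset.  Positive = acceleration stream lags
    the trajectory.

    Returns ``(offset_s, peak_correlation, lags_s, correlations)``; the
    full correlation profile lets callers demand that an out-of-
    tolerance peak clearly beats everything near zero lag before
    excluding a bird.
    """
    from scipy.ndimage import uniform_filter1d

    dt = 1.0 / track.rate_hz
    glide5 = 1.0 - np.interp(track.t, accel_t, flap20.astype(float))
    alt = track.position[:, 2]
    ok = np.isfinite(alt) & track.valid
    if ok.sum() < 50:
        raise AlignmentError("not enough overlapping valid samples to estimate offset")
    win = max(int(round(highpass_s / dt)), 3)

    def _hp(x):
        filled = pd.Series(np.where(ok, x, np.nan)).interpolate(limit_direction="both").to_numpy()
        return filled - uniform_filter1d(filled, win, mode="nearest")

    a = np.where(ok, _hp(glide5), 0.0)
    b = np.where(ok, -_hp(alt), 0.0)
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        zl = np.array([0.0])
        return 0.0, 0.0, zl, zl
    max_lag = int(round(max_lag_s / dt))
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.array([np.dot(a[max(0, -l): len(a) - max(0, l)],
                          b[max(0, l): len(b) - max(0, -l)]) for l in lags]) / denom
    k = int(np.argmax(cc))
    return float(lags[k] * dt), float(cc[k]), lags * dt, cc


def align_streams(
    track: BirdTrajectory,
    accel: pd.DataFrame,
    hr: pd.DataFrame | None = None,
    cfg: CleaningConfig | None = None,
    vedba_window_s: float = 4.0,
) -> AlignedStreams:
    """Aggregate 20 Hz proxies and heart rate onto the 5 Hz clock.

    20 Hz quantities (VeDBA, flap labels) are averaged over each 0.2 s
    trajectory bin; heart rate is binned or sample-and-held to the same
    clock.  A bird whose accelerometer/GNSS offset exceeds the
    tolerance raises :class:`StreamOffsetError` and should be dropped.
    """
    cfg = cfg or CleaningConfig()
    if len(track.t) == 0:
        raise AlignmentError("empty track")
    at = accel["t"].to_numpy(float)
    lo, hi = max(track.t[0], at[0]), min(track.t[-1], at[-1])
    if hi <= lo:
        raise AlignmentError("no overlapping time support between track and acceleration")
    rate20 = 1.0 / np.median(np.diff(at))
    ved20 = signals.vedba(accel[["ax", "ay", "az"]].to_numpy(float), rate20, vedba_window_s)
    flap20 = signals.classify_flap_glide(accel["az"].to_numpy(float), rate20)

    offset, peak_corr, lags, cc = estimate_stream_offset(track, flap20, at)
    # exclude only on clear evidence: the out-of-tolerance peak must
    # decisively beat the best correlation within the tolerance
    if abs(offset) > cfg.max_stream_offset_s:
        inside = np.abs(lags) <= cfg.max_stream_offset_s
        r_inside = float(cc[inside].max()) if inside.any() else 0.0
        if peak_corr >= max(1.5 * max(r_inside, 0.0), 0.04):
            raise StreamOffsetError(
                f"bird {track.bird_id}: stream offset {offset:.2f} s exceeds "
                f"{cfg.max_stream_offset_s:.2f} s tolerance "
                f"(r={peak_corr:.2f} vs {r_inside:.2f} near zero lag)"
            )

    dt5 = 1.0 / track.rate_hz
    # mean over each 0.2 s trajectory bin [t, t + dt5)
    bins = np.floor((at - track.t[0]) / dt5 + 1e-9).astype(int)
    inside = (bins >= 0) & (bins < len(track.t))
    ved5 = _bin_mean(ved20[inside], bins[inside], len(track.t))
    flap5 = _bin_mean(flap20[inside].astype(float), bins[inside], len(track.t))

    if hr is not None and len(hr):
        ht = hr["t"].to_numpy(float)
        hb = np.floor((ht - track.t[0]) / dt5 + 1e-9).astype(int)
        hin = (hb >= 0) & (hb < len(track.t))
        hr5 = _bin_mean(hr["bpm"].to_numpy(float)[hin], hb[hin], len(track.t))
        hr5 = pd.Series(hr5).ffill().to_numpy()  # sample-and-hold sparse series
    else:
        hr5 = np.full(len(track.t), np.nan)

    table = pd.DataFrame(
        {
            "t": track.t,
            "vedba": ved5,
            "flap_frac": flap5,
            "flapping": flap5 >= 0.5,
            "hr": hr5,
            "valid": track.valid & np.isfinite(ved5),
        }
    )
    return AlignedStreams(bird_id=track.bird_id, table=table, stream_offset_s=offset)


def _bin_mean(values, bins, n_bins):
    s = np.bincount(bins, weights=values, minlength=n_bins).astype(float)
    c = np.bincount(bins, minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore"):
        out = s / c
    return out
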