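"""Flying bouts: the analysis units of the in-wake comparison.

A bout is a maximal run of constant flying position (in-wake or not)
— and, when in-wake, constant leader — on the 5 Hz clock, with a
minimum duration (default 2 s).  Invalid gaps shorter than 1 s are
bridged when the same (state, leader) flanks them; a brief excursion
to the other state always splits the bout (the bridging rule applies
to *missing data*, not to state flips).  Gliding phases longer than
5 s are excluded from all summaries (they generally follow soaring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wakeflight import signals
from wakeflight.preprocessing import AlignedStreams

__all__ = ["BoutConfig", "Bout", "extract_bouts", "apply_glide_exclusion", "summarize_bouts"]


@dataclass(frozen=True)
class BoutConfig:
    min_duration_s: float = 2.0     # alternate analysis: 5.0
    max_gap_interp_s: float = 1.0
    max_glide_s: float = 5.0
    # heart-rate plausibility screen (replaces a visual check)
    hr_range_bpm: tuple[float, float] = (100.0, 700.0)
    hr_max_jump_bpm: float = 150.0
    # heart rate adjusts with a lag; the first hr_settle_s of each bout
    # are excluded from the bout-mean heart rate
    hr_settle_s: float = 1.0

    def __post_init__(self):
        if min(self.min_duration_s, self.max_gap_interp_s, self.max_glide_s) < 0:
            raise ValueError("bout thresholds must be non-negative")


@dataclass
class Bout:
    """One flying bout with (optionally) summarised proxies."""

    bird_id: int
    in_wake: bool
    leader_id: int | None
    t_start: float
    t_end: float
    duration_s: float
    i_start: int
    i_stop: int                      # slice [i_start, i_stop) on the 5 Hz clock
    mean_vedba: float = np.nan
    flap_proportion: float = np.nan
    mean_hr: float = np.nan
    hr_plausible: bool = True
    effective_wbf: float = np.nan
    flapping_freq: float = np.nan
    n_peaks: int = 0


def extract_bouts(states: pd.DataFrame, cfg: BoutConfig | None = None,
                  bird_id: int | None = None) -> list[Bout]:
    """Maximal constant-(state, leader) runs, bridged and filtered.

    ``states`` carries columns ``t, in_wake, leader`` and optionally
    ``valid`` on the 5 Hz clock for one bird.  Invalid runs strictly
    shorter than ``max_gap_interp_s`` are bridged when flanked by the
    same (state, leader); runs shorter than ``min_duration_s`` are
    dropped.  Duration counts samples times the clock step, so 10
    samples at 5 Hz make a 2.0 s bout.
    """
    cfg = cfg or BoutConfig()
    if len(states) == 0:
        return []
    t = states["t"].to_numpy(float)
    inw = states["in_wake"].to_numpy(bool)
    lead = states["leader"].to_numpy(int) if "leader" in states else np.full(len(t), -1)
    valid = states["valid"].to_numpy(bool) if "valid" in states else np.ones(len(t), bool)
    if bird_id is None:
        bird_id = int(states["bird"].iloc[0]) if "bird" in states else -1
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.2

    key = np.where(inw, lead, -1)  # leader only meaningful in-wake
    state_key = np.stack([inw.astype(int), key])

    # rules compare whole samples, immune to floating-point clock drift
    max_gap_samples = int(round(cfg.max_gap_interp_s / dt))
    min_bout_samples = int(round(cfg.min_duration_s / dt))

    # bridge invalid runs strictly under the gap limit with equal flanks
    valid = valid.copy()
    for start, stop in _runs(~valid):
        if (stop - start) < max_gap_samples and start > 0 and stop < len(t):
            if (state_key[:, start - 1] == state_key[:, stop]).all():
                valid[start:stop] = True
                inw[start:stop] = inw[start - 1]
                key[start:stop] = key[start - 1]

    bouts: list[Bout] = []
    for start, stop in _runs(valid):
        i = start
        while i < stop:
            j = i
            while j < stop and inw[j] == inw[i] and key[j] == key[i]:
                j += 1
            dur = (j - i) * dt
            if (j - i) >= min_bout_samples:
                bouts.append(
                    Bout(
                        bird_id=bird_id,
                        in_wake=bool(inw[i]),
                        leader_id=int(key[i]) if inw[i] else None,
                        t_start=float(t[i]),
                        t_end=float(t[j - 1] + dt),
                        duration_s=float(dur),
                        i_start=i,
                        i_stop=j,
                    )
                )
            i = j
    return bouts


def _runs(mask: np.ndarray):
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


def apply_glide_exclusion(glide: np.ndarray, rate_hz: float,
                          max_glide_s: float = 5.0) -> np.ndarray:
    """Validity mask excluding contiguous glide runs longer than 5 s.

    Long glides generally follow soaring or altitude loss and are not
    comparable flight; they are masked out of every downstream summary.
    Returns ``True`` for retained samples.
    """
    glide = np.asarray(glide, dtype=bool)
    keep = np.ones(glide.size, dtype=bool)
    for start, stop in _runs(glide):
        if (stop - start) / rate_hz > max_glide_s:
            keep[start:stop] = False
    return keep


def summarize_bouts(
    bouts: list[Bout],
    aligned: AlignedStreams,
    cfg: BoutConfig | None = None,
    heave20: np.ndarray | None = None,
    accel_rate_hz: float = 20.0,
    glide_keep5: np.ndarray | None = None,
    peak_times: np.ndarray | None = None,
) -> list[Bout]:
    """Fill per-bout summaries from the aligned 5 Hz streams.

    Per bout: mean VeDBA and flap proportion over valid,
    non-glide-excluded samples; mean heart rate (excluding the first
    ``hr_settle_s`` of the bout — heart rate adjusts with a lag) with a
    plausibility screen (bpm range and jump limits) replacing the
    study's visual check; wingbeat metrics from the 20 Hz heave when
    supplied.  Bouts with zero valid samples after masking are dropped.
    """
    cfg = cfg or BoutConfig()
    tab = aligned.table
    ved = tab["vedba"].to_numpy(float)
    flap_frac = tab["flap_frac"].to_numpy(float)
    hr = tab["hr"].to_numpy(float)
    valid = tab["valid"].to_numpy(bool)
    if glide_keep5 is not None:
        valid = valid & glide_keep5
    dt = float(np.median(np.diff(tab["t"].to_numpy(float))))
    rate5 = 1.0 / dt
    out: list[Bout] = []
    for b in bouts:
        sl = slice(b.i_start, b.i_stop)
        ok = valid[sl]
        if not ok.any():
            continue
        b.mean_vedba = float(np.nanmean(ved[sl][ok]))
        b.flap_proportion = float(np.nanmean(flap_frac[sl][ok]))
        hseg = hr[sl]
        settle = int(round(cfg.hr_settle_s * rate5))
        hr_ok = ok.copy()
        hr_ok[: min(settle, max(len(hr_ok) - 1, 0))] = False
        hvals = hseg[hr_ok]
        hvals = hvals[np.isfinite(hvals)]
        if hvals.size:
            b.mean_hr = float(hvals.mean())
            lo, hi = cfg.hr_range_bpm
            jumps = np.abs(np.diff(hvals)) if hvals.size > 1 else np.array([0.0])
            b.hr_plausible = bool(
                (hvals >= lo).all() and (hvals <= hi).all()
                and (jumps <= cfg.hr_max_jump_bpm).all()
            )
        if heave20 is not None:
            k = int(round(accel_rate_hz / rate5))
            seg = heave20[b.i_start * k : b.i_stop * k]
            if peak_times is not None:
                # peaks detected once on the continuous stream: no
                # boundary loss on short bouts
                n_pk = int(np.count_nonzero(
                    (peak_times >= b.t_start) & (peak_times < b.t_end)))
                b.n_peaks = n_pk
                b.effective_wbf = n_pk / b.duration_s
            elif seg.size:
                b.effective_wbf = signals.effective_wingbeat_frequency(seg, accel_rate_hz)
                b.n_peaks = int(round(b.effective_wbf * seg.size / accel_rate_hz))
            if seg.size and b.flap_proportion >= 0.5 and b.duration_s >= 2.0:
                try:
                    b.flapping_freq = signals.flapping_frequency(seg, accel_rate_hz)
                except ValueError:
                    b.flapping_freq = np.nan
        out.append(b)
    return out


def bouts_to_frame(bouts: list[Bout], **extra) -> pd.DataFrame:
    """Bout list -> tidy table (one row per bout)."""
    df = pd.DataFrame(
        {
            "bird": [b.bird_id for b in bouts],
            "in_wake": [b.in_wake for b in bouts],
            "leader": [b.leader_id if b.leader_id is not None else -1 for b in bouts],
            "t_start": [b.t_start for b in bouts],
            "duration": [b.duration_s for b in bouts],
            "mean_vedba": [b.mean_vedba for b in bouts],
            "flap_prop": [b.flap_proportion for b in bouts],
            "mean_hr": [b.mean_hr for b in bouts],
            "hr_plausible": [b.hr_plausible for b in bouts],
            "ewbf": [b.effective_wbf for b in bouts],
            "flap_freq": [b.flapping_freq for b in bouts],
        }
    )
    for k, v in extra.items():
        df[k] = v
    return df
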