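"""Fuzzy inference system for in-wake classification.

The upwash region behind a flying bird has gradual, not crisp,
boundaries, so the in-wake/not-in-wake decision is modelled with a
single-rule Mamdani-style fuzzy system: three trapezoidal membership
functions over the follower's offset behind a frontal candidate —
lateral distance from the leader's midline ``|dy|``, longitudinal
distance behind ``-dx``, and vertical offset ``dz`` — combined with a
minimum (AND).  The in-wake degree of a follower is the maximum over
all frontal candidates, defuzzified at a crisp threshold; the arg-max
candidate is the leader.

Two parameter sets are supported: a *pre-defined* set motivated by
fixed-wing wake theory (upwash outboard of the wingtip vortex, at about
pi*b/8 from the midline for wingspan b) and a *re-defined* set derived
from the densest observed follower positions
(:func:`redefine_from_density`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from wakeflight.geometry import DensitySummary, RelativePosition

__all__ = [
    "FuzzyVariable",
    "FisConfig",
    "WakeState",
    "membership",
    "membership_grid",
    "infer_states",
    "infer_states_table",
    "redefine_from_density",
]


@dataclass(frozen=True)
class FuzzyVariable:
    """Trapezoidal membership function 0 -> 1 -> 1 -> 0 on one axis.

    Breakpoints ``a <= b <= c <= d`` in metres: membership ramps up on
    [a, b], sits at 1 on the plateau [b, c] and ramps down on [c, d].
    """

    name: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if not (self.a <= self.b <= self.c <= self.d):
            raise ValueError(f"{self.name}: breakpoints must be non-decreasing, got "
                             f"({self.a}, {self.b}, {self.c}, {self.d})")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.b > self.a:
            rising = (x >= self.a) & (x < self.b)
            out[rising] = (x[rising] - self.a) / (self.b - self.a)
        plateau = (x >= self.b) & (x <= self.c)
        out[plateau] = 1.0
        if self.d > self.c:
            falling = (x > self.c) & (x <= self.d)
            out[falling] = (self.d - x[falling]) / (self.d - self.c)
        return out if out.ndim else float(out)


def _default_lateral():
    return FuzzyVariable("lateral", 0.45, 0.6, 1.1, 1.4)


def _default_longitudinal():
    return FuzzyVariable("longitudinal", 0.3, 0.8, 6.0, 10.0)


def _default_vertical():
    return FuzzyVariable("vertical", -1.0, -0.5, 0.5, 1.0)


@dataclass(frozen=True)
class FisConfig:
    """One fuzzy rule: in-wake <=> lateral AND longitudinal AND vertical.

    ``lateral`` is evaluated at ``|dy|`` (mirrored, so the wake on both
    sides is covered), ``longitudinal`` at the distance behind the
    leader ``-dx``, ``vertical`` at ``dz``.  ``crisp_threshold`` is the
    defuzzification cut (conventional 0.5).
    """

    lateral: FuzzyVariable = field(default_factory=_default_lateral)
    longitudinal: FuzzyVariable = field(default_factory=_default_longitudinal)
    vertical: FuzzyVariable = field(default_factory=_default_vertical)
    crisp_threshold: float = 0.5
    set_name: str = "pre-defined"
    wingspan_m: float = 1.5

    def __post_init__(self):
        if not (0.0 < self.crisp_threshold <= 1.0):
            raise ValueError("crisp_threshold must be in (0, 1]")

    def to_yaml(self) -> str:
        d = {
            "set_name": self.set_name,
            "crisp_threshold": self.crisp_threshold,
            "wingspan_m": self.wingspan_m,
            "variables": {
                v.name: [v.a, v.b, v.c, v.d]
                for v in (self.lateral, self.longitudinal, self.vertical)
            },
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FisConfig":
        d = yaml.safe_load(text)
        v = d["variables"]
        return cls(
            lateral=FuzzyVariable("lateral", *v["lateral"]),
            longitudinal=FuzzyVariable("longitudinal", *v["longitudinal"]),
            vertical=FuzzyVariable("vertical", *v["vertical"]),
            crisp_threshold=d["crisp_threshold"],
            set_name=d["set_name"],
            wingspan_m=d.get("wingspan_m", 1.5),
        )


@dataclass(frozen=True)
class WakeState:
    """Crisp flying position of one bird at one timestamp."""

    bird_id: int
    t: float
    in_wake: bool
    leader_id: int | None
    degree: float

    def __post_init__(self):
        if self.in_wake and self.leader_id is None:
            raise ValueError("in-wake state requires a leader")
        if not self.in_wake and self.leader_id is not None:
            raise ValueError("not-in-wake state cannot name a leader")


def membership_grid(dx, dy, dz, cfg: FisConfig):
    """Vectorised in-wake membership of offsets behind one candidate.

    ``dx, dy, dz`` are follower-minus-leader offsets in the candidate's
    flight frame.  The degree is the min over the three trapezoids at
    ``(|dy|, -dx, dz)``; offsets not behind the candidate (``dx >= 0``)
    have degree 0 by contract.
    """
    dx = np.asarray(dx, dtype=float)
    deg = np.minimum(
        cfg.lateral(np.abs(dy)),
        np.minimum(cfg.longitudinal(-dx), cfg.vertical(dz)),
    )
    return np.where(dx < 0, deg, 0.0)


def membership(offset: RelativePosition, cfg: FisConfig) -> float:
    """In-wake membership degree in [0, 1] of one dyad offset."""
    return float(membership_grid(offset.dx, offset.dy, offset.dz, cfg))


def infer_states(relpos: list[RelativePosition], cfg: FisConfig) -> WakeState:
    """Crisp wake state of one follower from all its frontal candidates.

    Degree is the max over candidates; the bird is in-wake iff the
    degree reaches ``cfg.crisp_threshold``, behind the arg-max candidate
    (ties by smaller Euclidean distance, then lower id).
    """
    if not relpos:
        raise ValueError("no relative positions supplied")
    fol = relpos[0].follower_id
    t = relpos[0].t
    best_deg, best = 0.0, None
    for r in relpos:
        if r.follower_id != fol:
            raise ValueError("relative positions mix followers")
        if not r.ahead:
            continue
        deg = membership(r, cfg)
        if deg > best_deg or (
            best is not None
            and deg == best_deg
            and deg > 0
            and (r.euclidean, r.leader_id) < (best.euclidean, best.leader_id)
        ):
            best_deg, best = deg, r
    if best is not None and best_deg >= cfg.crisp_threshold:
        return WakeState(fol, t, True, best.leader_id, best_deg)
    return WakeState(fol, t, False, None, best_deg)


def infer_states_table(dyads, cfg: FisConfig, max_ahead: float = 20.0):
    """Wake states for every (bird, timestamp) of a dyad offset table.

    ``dyads`` is the DataFrame from :func:`wakeflight.geometry.dyad_offsets`.
    Returns a DataFrame ``t, bird, in_wake, leader, degree`` covering
    every follower row present in the input.  Vectorised: membership is
    evaluated for all dyad rows at once, then reduced per
    (t, follower) with the arg-max candidate rule (ties by distance,
    then lower leader id).
    """
    import pandas as pd

    d = dyads.copy()
    deg = membership_grid(d["dx"].to_numpy(), d["dy"].to_numpy(), d["dz"].to_numpy(), cfg)
    deg = np.where(d["ahead"].to_numpy() & (d["dist"].to_numpy() <= max_ahead), deg, 0.0)
    d["degree"] = deg
    # arg-max by (degree desc, dist asc, leader asc)
    d = d.sort_values(["t", "follower", "degree", "dist", "leader"],
                      ascending=[True, True, False, True, True], kind="stable")
    best = d.groupby(["t", "follower"], sort=True).first().reset_index()
    in_wake = best["degree"] >= cfg.crisp_threshold
    out = pd.DataFrame(
        {
            "t": best["t"],
            "bird": best["follower"].astype(int),
            "in_wake": in_wake,
            "leader": np.where(in_wake, best["leader"], -1).astype(int),
            "degree": best["degree"],
        }
    )
    return out


def redefine_from_density(summary: DensitySummary, template: FisConfig | None = None) -> FisConfig:
    """Re-derive the fuzzy set from the densest observed positions.

    The trapezoid plateau [b, c] on each axis is set to the axis-aligned
    bounding box of the 25% highest-density region of the mirrored
    follower offsets; the ramps extend to the 50% region's box.  The
    offsets feeding the density are (dx, dy, dz) with dy mirrored, so
    the lateral variable reads the box directly in |dy|, and the
    longitudinal variable reads it in distance-behind (-dx).
    """
    if template is None:
        template = FisConfig()
    if 0.25 not in summary.boxes or 0.5 not in summary.boxes:
        raise ValueError("density summary must include the 25% and 50% levels")
    lo25, hi25 = summary.boxes[0.25]
    lo50, hi50 = summary.boxes[0.5]
    if np.any(hi25 < lo25):
        raise ValueError("empty 25% density region")

    def trap(name, lo_p, hi_p, lo_r, hi_r):
        a, d = min(lo_r, lo_p), max(hi_r, hi_p)
        return FuzzyVariable(name, a, lo_p, hi_p, d)

    # axis 0 is dx (negative behind): convert to distance-behind -dx
    lon = trap("longitudinal", -hi25[0], -lo25[0], -hi50[0], -lo50[0])
    lat = trap("lateral", lo25[1], hi25[1], lo50[1], hi50[1])
    ver = trap("vertical", lo25[2], hi25[2], lo50[2], hi50[2])
    return replace(template, lateral=lat, longitudinal=lon, vertical=ver, set_name="re-defined")
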