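"""Relative-position geometry of a flock in the leader's flight frame.

Every ordered pair of birds (follower, leader) gets an offset expressed
in the leader's flight frame: ``dx`` forward along the leader's
horizontal velocity (negative = behind), ``dy`` to the leader's right,
``dz`` up.  On top of the dyad table the module provides nearest
neighbour / nearest frontal queries, lateral mirroring, and
highest-density-region volumes from a 3-D kernel density estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlightFrame",
    "RelativePosition",
    "DensitySummary",
    "flight_frames",
    "dyad_offsets",
    "relative_positions",
    "nearest_neighbour",
    "nearest_frontal",
    "mirror_lateral",
    "density_volumes",
]

#: horizontal speed below which a flight frame is undefined (m/s)
MIN_FRAME_SPEED = 1.0


@dataclass(frozen=True)
class FlightFrame:
    """Orthonormal frame anchored at a bird: forward / right / up.

    ``forward`` is the unit horizontal velocity, ``up`` the world up
    axis, ``right`` their horizontal complement.  Using the horizontal
    (not 3-D) velocity keeps ``dz`` a true altitude difference.
    """

    origin: np.ndarray
    forward: np.ndarray
    right: np.ndarray
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def to_frame(self, point: np.ndarray) -> np.ndarray:
        """World point -> (dx, dy, dz) in this frame."""
        d = np.asarray(point, dtype=float) - self.origin
        return np.array([d @ self.forward, d @ self.right, d @ self.up])


@dataclass(frozen=True)
class RelativePosition:
    """Follower-minus-leader offset in the leader's flight frame (m)."""

    follower_id: int
    leader_id: int
    t: float
    dx: float
    dy: float
    dz: float
    euclidean: float
    coplanar: bool
    #: candidate ahead of the follower along the follower's own flight direction
    ahead: bool = False


def flight_frames(position: np.ndarray, velocity: np.ndarray, min_speed: float = MIN_FRAME_SPEED):
    """Vectorised flight frames for an (n, 3) track.

    Returns ``(forward, right, valid)`` where ``forward``/``right`` are
    (n, 3) horizontal unit vectors and ``valid`` flags samples whose
    horizontal speed exceeds ``min_speed`` (the frame is undefined for
    a hovering or vertically moving bird).
    """
    v = np.asarray(velocity, dtype=float)
    hspeed = np.hypot(v[:, 0], v[:, 1])
    valid = np.isfinite(hspeed) & (hspeed > min_speed)
    with np.errstate(invalid="ignore", divide="ignore"):
        fx = v[:, 0] / hspeed
        fy = v[:, 1] / hspeed
    forward = np.column_stack([fx, fy, np.zeros_like(fx)])
    # right-hand side of the bird: rotate forward by -90 deg about up
    right = np.column_stack([fy, -fx, np.zeros_like(fx)])
    forward[~valid] = np.nan
    right[~valid] = np.nan
    return forward, right, valid


def dyad_offsets(
    tracks: dict[int, dict[str, np.ndarray]],
    coplanar_band: float = 0.75,
    min_speed: float = MIN_FRAME_SPEED,
) -> pd.DataFrame:
    """Offsets of every ordered dyad over the full shared clock.

    Parameters
    ----------
    tracks
        Mapping ``bird_id -> {"t", "position", "velocity", "valid"}``
        with all birds on one 5 Hz clock.  ``position``/``velocity`` are
        (n, 3) east/north/up arrays.
    coplanar_band
        Half-wingspan altitude band (default 0.75 m) below which a dyad
        counts as co-planar.

    Returns
    -------
    DataFrame with one row per (timestamp, follower, leader) where both
    birds are valid and the leader's frame is defined; columns
    ``t, follower, leader, dx, dy, dz, dist, coplanar, ahead``.
    """
    ids = sorted(tracks)
    if len(ids) < 2:
        return pd.DataFrame(
            columns=["t", "follower", "leader", "dx", "dy", "dz", "dist", "coplanar", "ahead"]
        )
    frames = {}
    for b in ids:
        tr = tracks[b]
        fwd, rgt, fr_ok = flight_frames(tr["position"], tr["velocity"], min_speed)
        frames[b] = (fwd, rgt, fr_ok & np.asarray(tr["valid"], bool))
    t = np.asarray(tracks[ids[0]]["t"], dtype=float)
    chunks = []
    for lead in ids:
        fwd_l, rgt_l, ok_l = frames[lead]
        p_l = tracks[lead]["position"]
        for fol in ids:
            if fol == lead:
                continue
            fwd_f, _, ok_f = frames[fol]
            p_f = tracks[fol]["position"]
            ok = ok_l & ok_f
            if not ok.any():
                continue
            d = p_f - p_l
            dx = np.einsum("ij,ij->i", d, fwd_l)
            dy = np.einsum("ij,ij->i", d, rgt_l)
            dz = d[:, 2]
            dist = np.sqrt(np.einsum("ij,ij->i", d, d))
            # candidate (the leader column) ahead of the follower along
            # the follower's own flight direction, strictly
            ahead = np.einsum("ij,ij->i", -d, fwd_f) > 0
            idx = np.flatnonzero(ok)
            chunks.append(
                pd.DataFrame(
                    {
                        "t": t[idx],
                        "follower": fol,
                        "leader": lead,
                        "dx": dx[idx],
                        "dy": dy[idx],
                        "dz": dz[idx],
                        "dist": dist[idx],
                        "coplanar": np.abs(dz[idx]) <= coplanar_band,
                        "ahead": ahead[idx],
                    }
                )
            )
    if not chunks:
        return pd.DataFrame(
            columns=["t", "follower", "leader", "dx", "dy", "dz", "dist", "coplanar", "ahead"]
        )
    out = pd.concat(chunks, ignore_index=True)
    return out.sort_values(["t", "follower", "leader"], kind="stable", ignore_index=True)


def relative_positions(
    tracks: dict[int, dict[str, np.ndarray]],
    t: float,
    coplanar_band: float = 0.75,
    min_speed: float = MIN_FRAME_SPEED,
) -> list[RelativePosition]:
    """All ordered dyads at one timestamp, as :class:`RelativePosition`."""
    ids = sorted(tracks)
    out: list[RelativePosition] = []
    tt = np.asarray(tracks[ids[0]]["t"], dtype=float)
    i = int(np.argmin(np.abs(tt - t)))
    if abs(tt[i] - t) > 1e-6:
        raise ValueError(f"timestamp {t} not on the shared clock")
    sub = {
        b: {
            "t": tt[i : i + 1],
            "position": tr["position"][i : i + 1],
            "velocity": tr["velocity"][i : i + 1],
            "valid": np.asarray(tr["valid"], bool)[i : i + 1],
        }
        for b, tr in tracks.items()
    }
    df = dyad_offsets(sub, coplanar_band=coplanar_band, min_speed=min_speed)
    for row in df.itertuples():
        out.append(
            RelativePosition(
                follower_id=int(row.follower),
                leader_id=int(row.leader),
                t=float(t),
                dx=float(row.dx),
                dy=float(row.dy),
                dz=float(row.dz),
                euclidean=float(row.dist),
                coplanar=bool(row.coplanar),
                ahead=bool(row.ahead),
            )
        )
    return out


def nearest_neighbour(relpos: list[RelativePosition], follower: int):
    """Nearest bird to ``follower`` in Euclidean distance.

    Ties break to the lower bird id (deterministic).  Returns
    ``(bird_id, distance)`` or ``None`` for a single-bird flock.
    """
    cands = [r for r in relpos if r.follower_id == follower]
    if not cands:
        return None
    best = min(cands, key=lambda r: (r.euclidean, r.leader_id))
    return best.leader_id, best.euclidean


def nearest_frontal(
    relpos: list[RelativePosition],
    follower: int,
    coplanar_band: float = 0.75,
    max_ahead: float = 20.0,
):
    """Nearest bird strictly ahead of ``follower``, or ``None``.

    "Ahead" means the candidate lies forward of the follower along the
    follower's own flight direction; candidates further than
    ``max_ahead`` metres are not considered leaders.
    """
    cands = [
        r
        for r in relpos
        if r.follower_id == follower and r.ahead and r.euclidean <= max_ahead
    ]
    if not cands:
        return None
    best = min(cands, key=lambda r: (r.euclidean, r.leader_id))
    return best


def mirror_lateral(offsets):
    """Reflect offsets onto the right half-plane: ``dy := |dy|``.

    Accepts an (n, 3) array of (dx, dy, dz) or a DataFrame with a
    ``dy`` column; returns the same type with ``min(dy) >= 0``.
    """
    if isinstance(offsets, pd.DataFrame):
        out = offsets.copy()
        out["dy"] = out["dy"].abs()
        return out
    arr = np.array(offsets, dtype=float)
    arr[:, 1] = np.abs(arr[:, 1])
    return arr


@dataclass
class DensitySummary:
    """Highest-density-region volumes of a 3-D offset cloud."""

    levels: tuple[float, ...]
    volumes_m3: dict[float, float]
    #: axis-aligned bounding box of each region: level -> (lo (3,), hi (3,))
    boxes: dict[float, tuple[np.ndarray, np.ndarray]]
    bandwidth: np.ndarray
    n: int
    grid_shape: tuple[int, int, int]

    def volume(self, level: float) -> float:
        return self.volumes_m3[level]


def _scott_bandwidth(x: np.ndarray) -> np.ndarray:
    n, d = x.shape
    sd = x.std(axis=0, ddof=1)
    return sd * n ** (-1.0 / (d + 4))


def density_volumes(
    offsets: np.ndarray,
    levels=(0.25, 0.5, 0.75),
    grid_size: int = 64,
    pad_bandwidths: float = 3.0,
    bandwidth_scale: float = 1.0,
) -> DensitySummary:
    """Volumes of the smallest regions holding given probability masses.

    A Gaussian product-kernel density (Scott's rule per axis, optionally
    scaled) is evaluated exactly on a ``grid_size``³ grid spanning the
    data range padded by ``pad_bandwidths`` bandwidths.  For each level
    the highest-density cells are accumulated until they contain that
    fraction of the (grid-normalised) mass; the region volume is the
    cell count times the cell volume.
    """
    x = np.asarray(offsets, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("offsets must be an (n, 3) array")
    n = x.shape[0]
    if n < 100:
        raise ValueError(f"need at least 100 offsets for a density estimate, got {n}")
    h = _scott_bandwidth(x) * float(bandwidth_scale)
    if np.any(h <= 0) or not np.all(np.isfinite(h)):
        raise ValueError("degenerate point cloud: zero variance along an axis (bandwidth failure)")
    lo = x.min(axis=0) - pad_bandwidths * h
    hi = x.max(axis=0) + pad_bandwidths * h
    axes = [np.linspace(lo[j], hi[j], grid_size) for j in range(3)]
    cell = np.prod([(a[1] - a[0]) for a in axes])

    # separable product kernel: density(g) = mean_i prod_j K_j(g_j - x_ij)
    dens = np.zeros((grid_size,) * 3)
    chunk = 512
    for s in range(0, n, chunk):
        xs = x[s : s + chunk]
        ker = [
            np.exp(-0.5 * ((axes[j][:, None] - xs[None, :, j]) / h[j]) ** 2) / (h[j] * np.sqrt(2 * np.pi))
            for j in range(3)
        ]
        dens += np.einsum("xi,yi,zi->xyz", ker[0], ker[1], ker[2], optimize=True)
    dens /= n

    mass = dens * cell
    mass_flat = mass.ravel()
    order = np.argsort(mass_flat)[::-1]
    csum = np.cumsum(mass_flat[order]) / mass_flat.sum()
    volumes: dict[float, float] = {}
    boxes: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    grids = np.meshgrid(*axes, indexing="ij")
    for lev in levels:
        k = int(np.searchsorted(csum, lev) + 1)
        sel = order[:k]
        volumes[lev] = k * cell
        mask = np.zeros(mass_flat.size, dtype=bool)
        mask[sel] = True
        mask = mask.reshape(dens.shape)
        box_lo = np.array([g[mask].min() for g in grids])
        box_hi = np.array([g[mask].max() for g in grids])
        boxes[lev] = (box_lo, box_hi)
    return DensitySummary(
        levels=tuple(levels),
        volumes_m3=volumes,
        boxes=boxes,
        bandwidth=h,
        n=n,
        grid_shape=(grid_size,) * 3,
    )
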