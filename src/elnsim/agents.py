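"""Motile and fixed cell agents: kinds, walks, and state transitions.

Five motile kinds move off-lattice in continuous 2-D space: resting
antigen-presenting cells (APC_OFF) drift toward the tumor, activated
marginal-zone APC (APC_M) away from it and toward the ELN patch, inactive
T cells random-walk (optionally fleeing the tumor) and sense the ELN field,
active T cells chase the tumor, and TILs are active T cells that crossed
the tumor boundary.  Reticular fibroblast cells (RFC) are fixed; contact
with an APC_M switches them on.  There is no spatial exclusion: cells can
get arbitrarily close to each other.

Per time step a motile cell takes an unbiased kinetic step -- length
uniform on [0, v_kin * dt], angle uniform -- plus, when biased, a tactic
step of length uniform on [0, bias * v_tac * dt] along the fixed bias
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .neighbors import pairs_within

__all__ = ["Kind", "MotilityParams", "CellArrays", "TransitionEvents",
           "random_walk_step", "tactic_step", "transition_cells"]


class Kind(IntEnum):
    APC_OFF = 0
    APC_M = 1
    T_INACTIVE = 2
    T_ACTIVE = 3
    TIL = 4
    RFC_OFF = 5
    RFC_ON = 6


MOTILE_KINDS = (Kind.APC_OFF, Kind.APC_M, Kind.T_INACTIVE, Kind.T_ACTIVE,
                Kind.TIL)


@dataclass(frozen=True)
class MotilityParams:
    """Speeds (µm/min) and directed-walk mode of one cell kind."""

    kinetic_speed: float
    tactic_speed: float
    bias_mode: str = "none"  # toward_tumor | away_from_tumor | toward_eln | none

    def __post_init__(self) -> None:
        if self.kinetic_speed < 0 or self.tactic_speed < 0:
            raise ValueError("speeds must be non-negative")


def _unit_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """n random unit vectors (uniform angle, via normalized Gaussian pairs)."""
    z = rng.standard_normal((n, 2))
    norm = np.sqrt(z[:, 0]**2 + z[:, 1]**2)
    norm[norm == 0.0] = 1.0
    return z / norm[:, None]


def random_walk_step(positions: np.ndarray, kinetic_speed, dt: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unbiased kinetic step: uniform length in [0, v dt], uniform angle."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = positions.shape[0]
    length = rng.random(n) * np.asarray(kinetic_speed, dtype=float) * dt
    return positions + length[:, None] * _unit_directions(rng, n)


def tactic_step(positions: np.ndarray, directions: np.ndarray, tactic_speed,
                bias_scale, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Directed step: uniform length in [0, bias * v dt] along ``directions``.

    ``directions`` are unit vectors (or zero vectors, meaning no detected
    gradient and hence no tactic displacement).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if dt <= 0:
        raise ValueError("dt must be positive")
    bias = np.asarray(bias_scale, dtype=float)
    if np.any(bias < 0) or np.any(bias > 1):
        raise ValueError("bias_scale must lie in [0, 1]")
    n = positions.shape[0]
    length = rng.random(n) * bias * np.asarray(tactic_speed, dtype=float) * dt
    return positions + length[:, None] * directions


class CellArrays:
    """Struct-of-arrays store for the motile agents of one simulation.

    Arrays are over-allocated (capacity doubling) so that per-step influx
    does not copy the whole population; the public attributes are views of
    the live prefix.
    """

    def __init__(self, capacity: int = 1024) -> None:
        self._cap = capacity
        self.n = 0
        self._pos = np.empty((capacity, 2), dtype=np.float32)
        self._kind = np.empty(capacity, dtype=np.int8)
        self._age = np.empty(capacity, dtype=np.float64)
        self._nact = np.empty(capacity, dtype=np.int32)
        self._ids = np.empty(capacity, dtype=np.int64)
        self._next_id = 0

    def __len__(self) -> int:
        return self.n

    @property
    def pos(self) -> np.ndarray:
        return self._pos[:self.n]

    @property
    def kind(self) -> np.ndarray:
        return self._kind[:self.n]

    @property
    def age(self) -> np.ndarray:
        return self._age[:self.n]

    @property
    def nact(self) -> np.ndarray:
        return self._nact[:self.n]

    @property
    def ids(self) -> np.ndarray:
        return self._ids[:self.n]

    def _reserve(self, extra: int) -> None:
        need = self.n + extra
        if need <= self._cap:
            return
        cap = self._cap
        while cap < need:
            cap *= 2
        for name in ("_pos", "_kind", "_age", "_nact", "_ids"):
            old = getattr(self, name)
            shape = (cap,) + old.shape[1:]
            new = np.empty(shape, dtype=old.dtype)
            new[:self.n] = old[:self.n]
            setattr(self, name, new)
        self._cap = cap

    def append(self, kind: Kind, positions: np.ndarray) -> None:
        positions = np.atleast_2d(np.asarray(positions))
        m = positions.shape[0]
        if m == 0:
            return
        self._reserve(m)
        s = slice(self.n, self.n + m)
        self._pos[s] = positions
        self._kind[s] = int(kind)
        self._age[s] = 0.0
        self._nact[s] = 0
        self._ids[s] = self._next_id + np.arange(m, dtype=np.int64)
        self._next_id += m
        self.n += m

    def remove(self, mask: np.ndarray) -> None:
        """Drop cells where ``mask`` is True, preserving relative order."""
        if not mask.any():
            return
        keep = ~mask
        m = int(keep.sum())
        for name in ("_pos", "_kind", "_age", "_nact", "_ids"):
            arr = getattr(self, name)
            arr[:m] = arr[:self.n][keep]
        self.n = m

    def counts(self) -> dict[Kind, int]:
        kinds = self.kind
        return {k: int(np.count_nonzero(kinds == int(k)))
                for k in MOTILE_KINDS}


@dataclass
class TransitionEvents:
    """Per-step bookkeeping of conversions, for tests and logging."""

    n_apc_converted: int = 0
    n_t_activated: int = 0
    n_apc_m_exhausted: int = 0
    n_til_formed: int = 0
    n_til_expired: int = 0
    n_til_inside: int = 0  # TILs inside the tumor disc after this step
    new_rfc_indices: list[int] = field(default_factory=list)


def transition_cells(cells: CellArrays, tumor_radius: float,
                     rfc_pos: np.ndarray, rfc_on: np.ndarray, *,
                     activation_distance: float = 15.0,
                     apc_m_capacity: int = 3,
                     til_lifespan: float = 1440.0,
                     tumor_center=(0.0, 0.0)) -> TransitionEvents:
    """Apply all state transitions once, in the fixed order (a, c, b, d, e).

    (a) APC_OFF inside the tumor disc collect antigen and become APC_M;
    (c) an APC_M within the activation distance of a resting RFC switches
    it on; (b) inactive T cells within the activation distance of an APC_M
    are activated, nearest pair first (ties broken by lower cell id), one
    activating APC per T cell per step, and an APC_M that has used up its
    activation capacity is removed; (d) active T cells inside the tumor
    disc become TILs; (e) TILs older than their lifespan are removed.
    A non-positive radius means the tumor has no interior, so (a) and (d)
    convert nothing.  ``rfc_on`` is updated in place.
    """
    ev = TransitionEvents()
    kind = cells.kind
    pos = cells.pos
    center = np.asarray(tumor_center, dtype=float)
    dx = pos[:, 0] - center[0]
    dy = pos[:, 1] - center[1]
    r2 = dx * dx + dy * dy
    if tumor_radius > 0:
        inside = r2 <= tumor_radius * tumor_radius
    else:
        inside = np.zeros(len(cells), dtype=bool)

    # (a) antigen collection
    conv = inside & (kind == int(Kind.APC_OFF))
    kind[conv] = int(Kind.APC_M)
    cells.age[conv] = 0.0
    ev.n_apc_converted = int(conv.sum())

    is_apcm = kind == int(Kind.APC_M)
    apcm_idx = np.flatnonzero(is_apcm)

    # (c) RFC activation by APC_M contact: the spatial hash is built over
    # the big APC_M set; resting RFC are the queries
    off_idx = np.flatnonzero(~rfc_on)
    if off_idx.size and apcm_idx.size:
        iq, _, _ = pairs_within(rfc_pos[off_idx], pos[apcm_idx],
                                activation_distance)
        hit = np.unique(off_idx[iq])
        rfc_on[hit] = True
        ev.new_rfc_indices = [int(j) for j in hit]

    # (b) T-cell activation, nearest pairs first
    t_idx = np.flatnonzero(kind == int(Kind.T_INACTIVE))
    exhausted = np.zeros(len(cells), dtype=bool)
    if t_idx.size and apcm_idx.size:
        iq, jd, dist = pairs_within(pos[t_idx], pos[apcm_idx],
                                    activation_distance)
        if iq.size:
            ti = t_idx[iq]
            mi = apcm_idx[jd]
            order = np.lexsort((cells.ids[mi], cells.ids[ti], dist))
            remaining: dict[int, int] = {}
            for a, b in zip(ti[order], mi[order]):
                if kind[a] != int(Kind.T_INACTIVE):
                    continue  # already activated this step
                left = remaining.get(b, apc_m_capacity - int(cells.nact[b]))
                if left <= 0:
                    continue
                kind[a] = int(Kind.T_ACTIVE)
                cells.age[a] = 0.0
                cells.nact[b] += 1
                remaining[b] = left - 1
                ev.n_t_activated += 1
                if remaining[b] == 0:
                    exhausted[b] = True
    ev.n_apc_m_exhausted = int(exhausted.sum())

    # (d) boundary crossing into the tumor
    til = inside & (kind == int(Kind.T_ACTIVE))
    kind[til] = int(Kind.TIL)
    cells.age[til] = 0.0
    ev.n_til_formed = int(til.sum())

    # (e) TIL expiry
    is_til = kind == int(Kind.TIL)
    expired = is_til & (cells.age > til_lifespan)
    ev.n_til_expired = int(expired.sum())
    ev.n_til_inside = int((is_til & inside & ~expired).sum())

    cells.remove(exhausted | expired)
    return ev
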