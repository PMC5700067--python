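"""Simulation engine: initialization, influx, stepping, recording.

One step advances the model by ``dt_min`` minutes in a fixed order:
influx of new APC_OFF and inactive T cells into the annulus around the
tumor, movement of every motile cell (kinetic walk plus directed terms),
state transitions (antigen collection, RFC activation, T-cell activation,
TIL formation/expiry), the tumor radius update, then recording.  Given a
configuration and seed the trajectory is fully deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .agents import CellArrays, Kind, _unit_directions, transition_cells
from .config import SimConfig
from .field import GaussianFieldRaster, GradientField, GaussianSource
from .tumor import GrowthParams, update_radius

__all__ = ["Simulation", "TimeSeries", "run_simulation"]

logger = logging.getLogger(__name__)

_COUNT_COLUMNS = {
    "n_apc_off": Kind.APC_OFF,
    "n_apc_m": Kind.APC_M,
    "n_t_inactive": Kind.T_INACTIVE,
    "n_t_active": Kind.T_ACTIVE,
    "n_til": Kind.TIL,
}

_NO_FIELD = np.zeros((1, 1), dtype=np.float32)


@njit(cache=True)
def _move_kernel(pos, kind, v_kin, v_tac, bias_sign, radius, dt,
                 toward_offset, toward_decay, away_margin,
                 grad_x, grad_y, fx0, fy0, fspacing, fnx, fny, khalf,
                 u_kin, z, u_tac):
    """One kinetic + one tactic step per cell, in place.

    ``toward_decay`` < 0 means no decay; ``away_margin`` < 0 means the
    away bias applies everywhere.  The ELN field is bilinearly sampled
    from the gradient rasters (``fnx`` = 0 means no field).
    """
    has_field = fnx > 0
    finv = 1.0 / fspacing
    for i in range(pos.shape[0]):
        k = kind[i]
        x = pos[i, 0]
        y = pos[i, 1]
        r = np.sqrt(x * x + y * y)

        # tumor-directed term
        sg = bias_sign[k]
        dirx = 0.0
        diry = 0.0
        if sg != 0.0 and r > 0.0:
            if sg < 0.0:
                d = r - radius - toward_offset
                if d > 0.0 and toward_decay > 0.0:
                    sg *= np.exp(-d / toward_decay)
            elif (k == 1 and away_margin >= 0.0
                  and r > radius + away_margin):
                # APC_M seek vasculature in the tumor neighborhood only
                sg = 0.0
            dirx = sg * x / r
            diry = sg * y / r

        # ELN-gradient term (APC_M and inactive T cells only)
        if has_field and (k == 1 or k == 2):
            fx = (x - fx0) * finv
            fy = (y - fy0) * finv
            if 0.0 <= fx <= fnx - 1 and 0.0 <= fy <= fny - 1:
                ix = min(int(fx), fnx - 2)
                iy = min(int(fy), fny - 2)
                tx = fx - ix
                ty = fy - iy
                gx = ((1 - tx) * (1 - ty) * grad_x[ix, iy]
                      + tx * (1 - ty) * grad_x[ix + 1, iy]
                      + (1 - tx) * ty * grad_x[ix, iy + 1]
                      + tx * ty * grad_x[ix + 1, iy + 1])
                gy = ((1 - tx) * (1 - ty) * grad_y[ix, iy]
                      + tx * (1 - ty) * grad_y[ix + 1, iy]
                      + (1 - tx) * ty * grad_y[ix, iy + 1]
                      + tx * ty * grad_y[ix + 1, iy + 1])
                # saturating bias |g|/(|g|+K) along the unit gradient
                scale = 1.0 / (np.sqrt(gx * gx + gy * gy) + khalf)
                dirx += gx * scale
                diry += gy * scale

        norm = np.sqrt(dirx * dirx + diry * diry)
        if norm > 1.0:
            dirx /= norm
            diry /= norm

        zx = z[i, 0]
        zy = z[i, 1]
        zn = np.sqrt(zx * zx + zy * zy)
        if zn == 0.0:
            zn = 1.0
        l_kin = u_kin[i] * v_kin[k] * dt
        l_tac = u_tac[i] * v_tac[k] * dt
        pos[i, 0] = x + l_kin * zx / zn + l_tac * dirx
        pos[i, 1] = y + l_kin * zy / zn + l_tac * diry


@dataclass
class TimeSeries:
    """Recorded per-step trajectory of one seeded run."""

    time_min: np.ndarray
    radius_um: np.ndarray
    counts: dict[str, np.ndarray]  # per _COUNT_COLUMNS key
    n_rfc_on: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        data = {"time_min": self.time_min, "radius_um": self.radius_um}
        data.update(self.counts)
        data["n_rfc_on"] = self.n_rfc_on
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path)
        counts = {k: df[k].to_numpy() for k in _COUNT_COLUMNS}
        return cls(df["time_min"].to_numpy(), df["radius_um"].to_numpy(),
                   counts, df["n_rfc_on"].to_numpy())

    @property
    def time_days(self) -> np.ndarray:
        return self.time_min / 1440.0

    @property
    def peak_radius(self) -> float:
        return float(self.radius_um.max())

    @property
    def peak_day(self) -> float:
        return float(self.time_days[int(np.argmax(self.radius_um))])

    @property
    def final_radius(self) -> float:
        return float(self.radius_um[-1])


class Simulation:
    """State of one seeded run; ``run()`` executes it to completion."""

    def __init__(self, config: SimConfig, seed: int | None = None):
        self.config = config
        self.seed = config.seed if seed is None else seed
        self.rng = np.random.default_rng(self.seed)
        self.time_min = 0.0
        self.radius = config.initial_radius
        self.growth = GrowthParams(config.growth_rate, config.kill_rate)
        self.cells = CellArrays()
        self.n_escaped = 0
        self._influx_residual = {"apc": 0.0, "t": 0.0}

        # speed lookup tables indexed by Kind
        self._v_kin = np.zeros(len(Kind), dtype=np.float32)
        self._v_tac = np.zeros(len(Kind), dtype=np.float32)
        for kinds, vk, vt in (
                ((Kind.APC_OFF,), config.apc_off_kinetic_speed,
                 config.apc_off_tactic_speed),
                ((Kind.APC_M,), config.apc_m_kinetic_speed,
                 config.apc_m_tactic_speed),
                ((Kind.T_INACTIVE, Kind.T_ACTIVE, Kind.TIL),
                 config.t_kinetic_speed, config.t_tactic_speed)):
            for k in kinds:
                self._v_kin[k] = vk
                self._v_tac[k] = vt

        # tumor-bias direction per kind: -1 toward the center, +1 away
        self._bias_sign = np.zeros(len(Kind), dtype=np.float32)
        self._bias_sign[Kind.APC_OFF] = -1.0
        self._bias_sign[Kind.T_ACTIVE] = -1.0
        self._bias_sign[Kind.TIL] = -1.0
        self._bias_sign[Kind.APC_M] = 1.0
        if config.inactive_t_bias == "away_from_tumor":
            self._bias_sign[Kind.T_INACTIVE] = config.inactive_t_bias_scale

        # ELN patch: fixed RFC, all initially off
        self.patch_center = np.array([config.tumor_eln_distance, 0.0])
        if config.rfc_count > 0:
            rad = config.rfc_patch_radius * np.sqrt(
                self.rng.random(config.rfc_count))
            dirs = _unit_directions(self.rng, config.rfc_count)
            self.rfc_pos = self.patch_center + rad[:, None] * dirs
            if (config.tumor_eln_distance
                    < config.initial_radius + config.rfc_patch_radius):
                warnings.warn("RFC patch overlaps the initial tumor disc",
                              stacklevel=2)
        else:
            self.rfc_pos = np.empty((0, 2))
        self.rfc_on = np.zeros(config.rfc_count, dtype=bool)
        self.raster = GaussianFieldRaster(
            center=tuple(self.patch_center),
            half_extent=config.rfc_patch_radius,
            spacing=config.field_grid_spacing,
            sigma=config.gaussian_sigma) if config.rfc_count else None

        # initial motile cells enter through the influx annulus
        self.cells.append(Kind.APC_OFF,
                          self._sample_annulus(config.initial_apc))
        self.cells.append(Kind.T_INACTIVE,
                          self._sample_annulus(config.initial_t))

    # -- helpers -----------------------------------------------------------

    def _sample_annulus(self, n: int) -> np.ndarray:
        """Uniform-by-area positions in the influx annulus at current R."""
        if n == 0:
            return np.empty((0, 2))
        ri = max(0.0, self.radius + self.config.annulus_inner_offset)
        ro = self.radius + self.config.annulus_outer_offset
        rad = np.sqrt(self.rng.random(n) * (ro**2 - ri**2) + ri**2)
        return rad[:, None] * _unit_directions(self.rng, n)

    def _influx_count(self, which: str, rate: float) -> int:
        if rate <= 0:
            return 0
        mean = rate * self.config.dt_min
        if self.config.influx_mode == "poisson":
            return int(self.rng.poisson(mean))
        acc = self._influx_residual[which] + mean
        n = int(acc)
        self._influx_residual[which] = acc - n
        return n

    def eln_field(self) -> GradientField:
        """Analytic view of the current ELN field (active sources only)."""
        cfg = self.config
        sources = [GaussianSource(x, y, cfg.gaussian_amplitude,
                                  cfg.gaussian_sigma)
                   for (x, y) in self.rfc_pos[self.rfc_on]]
        return GradientField(sources, tumor_center=(0.0, 0.0),
                             tumor_radius=self.radius)

    # -- one step ----------------------------------------------------------

    def _move(self) -> None:
        """Move every motile cell by one kinetic plus one tactic step.

        A fused, single-precision equivalent of composing
        ``random_walk_step`` and ``tactic_step`` per kind, compiled with
        numba (the loop runs every simulated minute over tens of
        thousands of agents).  The directed terms -- tumor bias by kind,
        ELN-gradient bias for APC_M and inactive T cells -- are summed as
        vectors; a combined direction with norm above 1 is rescaled to
        unit length so the tactic displacement never exceeds v_tac * dt.
        Bias directions are evaluated at start-of-step positions.
        """
        cfg = self.config
        cells = self.cells
        n = len(cells)
        if n == 0:
            return

        u_kin = self.rng.random(n, dtype=np.float32)
        z = self.rng.standard_normal((n, 2), dtype=np.float32)
        u_tac = self.rng.random(n, dtype=np.float32)

        if self.raster is not None and self.raster.n_sources:
            grad_x, grad_y = self.raster.grad_x, self.raster.grad_y
            fx0, fy0, fsp = self.raster.x0, self.raster.y0, self.raster.spacing
            fnx, fny = self.raster.nx, self.raster.ny
        else:
            grad_x = grad_y = _NO_FIELD
            fx0 = fy0 = 0.0
            fsp = 1.0
            fnx = fny = 0

        _move_kernel(
            cells.pos, cells.kind, self._v_kin, self._v_tac, self._bias_sign,
            self.radius, cfg.dt_min,
            cfg.toward_bias_offset_um,
            -1.0 if cfg.toward_bias_decay_um is None else cfg.toward_bias_decay_um,
            -1.0 if cfg.away_bias_margin_um is None else cfg.away_bias_margin_um,
            grad_x, grad_y, fx0, fy0, fsp, fnx, fny, self.config.khalf,
            u_kin, z, u_tac)

    def step(self) -> None:
        cfg = self.config
        # influx (APC first, then T cells; fixed draw order)
        self.cells.append(Kind.APC_OFF, self._sample_annulus(
            self._influx_count("apc", cfg.influx_rate_apc)))
        self.cells.append(Kind.T_INACTIVE, self._sample_annulus(
            self._influx_count("t", cfg.influx_rate_t)))

        self._move()

        events = transition_cells(
            self.cells, self.radius, self.rfc_pos, self.rfc_on,
            activation_distance=cfg.activation_distance,
            apc_m_capacity=cfg.apc_m_capacity,
            til_lifespan=cfg.til_lifespan_min)
        if self.raster is not None:
            for j in events.new_rfc_indices:
                self.raster.add_source(self.rfc_pos[j, 0], self.rfc_pos[j, 1],
                                       cfg.gaussian_amplitude)

        if cfg.escape_radius_um is not None:
            # outward-drifting kinds past the horizon have left for good
            # (distant vasculature/lymphatics); they can never re-enter play
            drifting = ((self.cells.kind == int(Kind.APC_M))
                        | (self.cells.kind == int(Kind.T_INACTIVE)))
            if drifting.any():
                rr = np.linalg.norm(self.cells.pos[drifting], axis=1)
                if (rr > cfg.escape_radius_um).any():
                    gone = np.zeros(len(self.cells), dtype=bool)
                    gone[np.flatnonzero(drifting)[rr > cfg.escape_radius_um]] = True
                    self.n_escaped += int(gone.sum())
                    self.cells.remove(gone)

        self.cells.age[:] = self.cells.age + cfg.dt_min
        self.radius = update_radius(self.radius, events.n_til_inside,
                                    self.growth, cfg.dt_min)
        self.time_min += cfg.dt_min

    def til_count(self) -> int:
        """TILs currently inside the tumor disc (the L of the growth law)."""
        til = self.cells.kind == int(Kind.TIL)
        if not til.any() or self.radius <= 0:
            return 0
        inside = np.linalg.norm(self.cells.pos[til], axis=1) <= self.radius
        return int(inside.sum())

    # -- full run ----------------------------------------------------------

    def run(self, snapshot_every_min: float | None = None) -> TimeSeries:
        cfg = self.config
        n_steps = int(round(cfg.total_time_min / cfg.dt_min))
        stride = max(1, int(round(cfg.record_every_min / cfg.dt_min)))
        snap_stride = (None if snapshot_every_min is None
                       else max(1, int(round(snapshot_every_min / cfg.dt_min))))
        self.snapshots: list[pd.DataFrame] = []

        times, radii, rfc_counts = [], [], []
        counts: dict[str, list[int]] = {k: [] for k in _COUNT_COLUMNS}

        def record():
            times.append(self.time_min)
            radii.append(self.radius)
            by_kind = self.cells.counts()
            for col, k in _COUNT_COLUMNS.items():
                counts[col].append(by_kind[k])
            rfc_counts.append(int(self.rfc_on.sum()))

        def snapshot(step):
            self.snapshots.append(pd.DataFrame({
                "step": step, "id": self.cells.ids,
                "kind": [Kind(k).name for k in self.cells.kind],
                "x": self.cells.pos[:, 0], "y": self.cells.pos[:, 1]}))

        record()
        if snap_stride:
            snapshot(0)
        for i in range(1, n_steps + 1):
            self.step()
            if i % stride == 0:
                record()
            if snap_stride and i % snap_stride == 0:
                snapshot(i)

        ts = TimeSeries(np.asarray(times), np.asarray(radii),
                        {k: np.asarray(v) for k, v in counts.items()},
                        np.asarray(rfc_counts))
        logger.info(
            "run seed=%d config=%s peak_radius=%.1f peak_day=%.2f final_radius=%.1f",
            self.seed, cfg.digest(), ts.peak_radius, ts.peak_day,
            ts.final_radius)
        return ts


def run_simulation(config: SimConfig, seed: int | None = None,
                   **run_kwargs) -> TimeSeries:
    """Execute one seeded run and return its recorded time series."""
    return Simulation(config, seed=seed).run(**run_kwargs)
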