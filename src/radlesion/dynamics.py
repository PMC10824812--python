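"""Jump–diffusion simulation of the lesion configuration.

Between jumps every lesion performs an independent (reflected) Brownian
motion with drift inside the nucleus; jumps are scheduled with one
exponential clock per channel: channel h fires at

    inf { t : ∫₀ᵗ h̄(ν(s)) ds ≥ E_h },   E_h ~ Exp(1),

where h̄ is the channel total over the current configuration.  After any
jump all clocks are redrawn (memorylessness).  Two execution paths produce
the law of the process:

* **static** (σ = μ = 0): lesion positions never change between jumps, so
  the channel totals are exactly constant there and the clock construction
  is simulated event-to-event without any time discretisation.
* **diffusive**: positions are advanced by reflected Euler–Maruyama steps
  of length ``dt`` and the channel totals are frozen over each step; the
  integrated hazard is accumulated against the clock thresholds and the
  firing time located by linear interpolation within the step.  This is
  first-order in ``dt`` and exact when the rates are position-independent.

An optional protracted-irradiation source inserts dose events (each
creating a Poisson number of new lesions around a fresh track) at the exact
times of a Poisson process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import kinetics
from .geometry import Domain
from .kinetics import ChannelRates, RateModel, total_channel_rates
from .state import TYPE_X, TYPE_Y, EventRecord, SystemState

__all__ = [
    "DiffusionSpec",
    "SchedulerConfig",
    "Trajectory",
    "ChannelClocks",
    "diffuse_step",
    "next_event",
    "simulate",
]

_CHANNELS = ("repair", "death", "pair")


@dataclass(frozen=True)
class DiffusionSpec:
    """Per-type diffusion scale σ [μm·h^(−1/2)] and drift μ [μm/h].

    Scalars give isotropic motion; the default (all zero) keeps lesions
    static, matching the numerical preset.
    """

    sigma_x: float = 0.0
    sigma_y: float = 0.0
    mu_x: tuple[float, ...] | float = 0.0
    mu_y: tuple[float, ...] | float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_x < 0 or self.sigma_y < 0:
            raise ValueError("diffusion scales must be nonnegative")

    @property
    def is_active(self) -> bool:
        mu = np.r_[np.atleast_1d(self.mu_x), np.atleast_1d(self.mu_y)]
        return bool(self.sigma_x or self.sigma_y or np.any(mu))


@dataclass(frozen=True)
class SchedulerConfig:
    """Time stepping: diffusion/rate-refresh step, horizon, snapshots."""

    t_end: float
    dt: float = 1e-3
    snapshot_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.t_end < 0:
            raise ValueError("t_end must be nonnegative")
        for s in self.snapshot_times:
            if not 0 <= s <= self.t_end:
                raise ValueError("snapshot times must lie in [0, t_end]")


@dataclass
class Trajectory:
    """Event log, snapshots and final state of one simulated path."""

    initial: SystemState
    events: list[EventRecord]
    snapshots: list[SystemState]
    final: SystemState
    seed: int | None = None

    def counts(self):
        from .state import counts_series

        return counts_series(self.initial, self.events)


@dataclass
class ChannelClocks:
    """Exponential thresholds E_h and accumulated hazards Λ_h per channel."""

    thresholds: dict[str, float]
    hazards: dict[str, float]

    @classmethod
    def draw(cls, rng: np.random.Generator) -> "ChannelClocks":
        return cls(
            thresholds={ch: float(rng.exponential()) for ch in _CHANNELS},
            hazards={ch: 0.0 for ch in _CHANNELS},
        )

    def redraw(self, rng: np.random.Generator) -> None:
        for ch in _CHANNELS:
            self.thresholds[ch] = float(rng.exponential())
            self.hazards[ch] = 0.0


def diffuse_step(
    state: SystemState,
    dt: float,
    spec: DiffusionSpec,
    domain: Domain,
    rng: np.random.Generator,
) -> SystemState:
    """One reflected Euler–Maruyama step for every lesion independently."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.n_total == 0 or not spec.is_active:
        return SystemState(state.time + dt, state.ids, state.types, state.positions, state.next_id)
    d = state.positions.shape[1]
    pos = state.positions.copy()
    for code, sigma in ((TYPE_X, spec.sigma_x), (TYPE_Y, spec.sigma_y)):
        mask = state.types == code
        if not mask.any():
            continue
        mu = np.broadcast_to(np.atleast_1d(np.asarray(
            spec.mu_x if code == TYPE_X else spec.mu_y, float)), (d,))
        n = int(mask.sum())
        step = mu * dt + sigma * math.sqrt(dt) * rng.standard_normal((n, d))
        pos[mask] = domain.reflect(pos[mask] + step)
    return SystemState(state.time + dt, state.ids, state.types, pos, state.next_id)


def next_event(
    totals: dict[str, float],
    clocks: ChannelClocks,
    t: float,
    dt: float,
) -> tuple[float, str] | None:
    """First clock crossing within [t, t + dt) with rates frozen at ``totals``.

    If a channel fires, its firing time is located by linear interpolation
    of the integrated hazard and all hazards are advanced to that time; the
    caller must then redraw the clocks.  Otherwise all hazards accumulate
    the full step and ``None`` is returned.
    """
    best_ch, best_time = None, math.inf
    for ch in _CHANNELS:
        rate = totals[ch]
        if rate < 0:
            raise RuntimeError(f"negative total rate for channel {ch}")
        if rate > 0:
            t_cross = t + (clocks.thresholds[ch] - clocks.hazards[ch]) / rate
            if t_cross < best_time:
                best_ch, best_time = ch, t_cross
    if best_ch is None or best_time >= t + dt:
        for ch in _CHANNELS:
            clocks.hazards[ch] += totals[ch] * dt
        return None
    for ch in _CHANNELS:
        clocks.hazards[ch] += totals[ch] * (best_time - t)
    return best_time, best_ch


# ---------------------------------------------------------------------------
# engines: rate bookkeeping + event application

class _GenericEngine:
    """Recomputes channel totals from scratch after every mutation.

    Correct for every kernel/form combination; O(N²) per refresh.
    """

    def __init__(self, state: SystemState, model: RateModel, domain: Domain):
        self.state = state
        self.model = model
        self.domain = domain
        self._rates: ChannelRates = total_channel_rates(state, model)

    def totals(self) -> dict[str, float]:
        r = self._rates
        return {"repair": r.r_bar, "death": r.a_bar, "pair": r.b_bar}

    def set_positions(self, state: SystemState) -> None:
        self.state = state
        self._rates = total_channel_rates(state, self.model)

    def fire(self, channel: str, t: float, rng: np.random.Generator) -> EventRecord:
        st, model = self.state, self.model
        if channel == "pair":
            i, j = kinetics.sample_target("pair", self._rates, rng)
            q1, q2 = st.positions[i], st.positions[j]
            if kinetics.interaction_is_lethal(q1, q2, model, rng):
                q = kinetics.place_b(q1, q2, model.placement_b, rng)
                ev = EventRecord(t, "pair_lethal",
                                 (int(st.ids[i]), int(st.ids[j])), ((TYPE_Y, q),))
            else:
                ev = EventRecord(t, "pair_repair",
                                 (int(st.ids[i]), int(st.ids[j])), ())
        elif channel == "repair":
            i = kinetics.sample_target("repair", self._rates, rng)
            ev = EventRecord(t, "repair", (int(st.ids[i]),), ())
        else:
            i = kinetics.sample_target("death", self._rates, rng)
            q = kinetics.place_a(st.positions[i], model.placement_a, self.domain, rng)
            ev = EventRecord(t, "death", (int(st.ids[i]),), ((TYPE_Y, q),))
        from .state import apply_event

        self.state = apply_event(self.state, ev)
        self._rates = total_channel_rates(self.state, model)
        return ev

    def insert(self, t: float, x_pos: np.ndarray, y_pos: np.ndarray) -> EventRecord:
        produced = tuple((TYPE_X, q) for q in np.atleast_2d(x_pos) if len(x_pos)) + tuple(
            (TYPE_Y, q) for q in np.atleast_2d(y_pos) if len(y_pos)
        )
        ev = EventRecord(t, "dose", (), produced)
        from .state import apply_event

        self.state = apply_event(self.state, ev)
        self._rates = total_channel_rates(self.state, self.model)
        return ev

    def snapshot(self, t: float) -> SystemState:
        s = self.state
        return SystemState(t, s.ids.copy(), s.types.copy(), s.positions.copy(), s.next_id)


class _StaticEngine:
    """Incremental rate bookkeeping for static lesions.

    Valid when positions never move between jumps and the kernels are the
    default ball (or zero) counts over both lesion types with the pair rate
    constant or a step in the separation.  Neighbour sets are maintained
    under removals and insertions so each event costs O(degree), not O(N²).
    """

    def __init__(self, state: SystemState, model: RateModel, domain: Domain):
        self.model = model
        self.domain = domain
        n0 = state.n_total
        cap = max(2 * n0 + 64, 256)
        self.d = state.positions.shape[1] if state.positions.size else domain.dimension
        self.pos = np.zeros((cap, self.d))
        self.types = np.full(cap, -1, np.int8)
        self.alive = np.zeros(cap, bool)
        self.lesion_ids = np.full(cap, -1, np.int64)
        self.pos[:n0] = state.positions
        self.types[:n0] = state.types
        self.alive[:n0] = True
        self.lesion_ids[:n0] = state.ids
        self.n_rows = n0
        self.next_id = state.next_id

        m = model
        self._homog = m.is_position_independent
        self._kernel_zero = m.repair_kernel.kind == "zero"
        self._rk = m.repair_kernel.r_d_um
        self._pair_step = m.pair_form == "step"
        self._rb = m.pair_r_d_um

        self.r_rates = np.zeros(cap)
        self.a_rates = np.zeros(cap)
        self.deg_b = np.zeros(cap, np.int64)
        self.nbr_k: dict[int, set[int]] = {}
        self.nbr_b: dict[int, set[int]] = {}
        self.n_pairs = 0
        self._build(state)

    # -- construction -------------------------------------------------------
    def _build(self, state: SystemState) -> None:
        n0 = self.n_rows
        rows = np.arange(n0)
        if not self._homog and not self._kernel_zero and n0:
            tree = cKDTree(self.pos[:n0])
            for i, j in tree.query_pairs(self._rk * (1 - 1e-12)):
                self.nbr_k.setdefault(i, set()).add(j)
                self.nbr_k.setdefault(j, set()).add(i)
        if self._pair_step and n0:
            x_rows = rows[self.types[:n0] == TYPE_X]
            if len(x_rows) > 1:
                tree = cKDTree(self.pos[x_rows])
                for a, b in tree.query_pairs(self._rb * (1 - 1e-12)):
                    i, j = int(x_rows[a]), int(x_rows[b])
                    self.nbr_b.setdefault(i, set()).add(j)
                    self.nbr_b.setdefault(j, set()).add(i)
                    self.deg_b[i] += 1
                    self.deg_b[j] += 1
                    self.n_pairs += 1
        for i in rows[self.types[:n0] == TYPE_X]:
            self.r_rates[i] = self._r_of(int(i))
            self.a_rates[i] = self._a_of(int(i))
        self.r_bar = float(self.r_rates[: self.n_rows].sum())
        self.a_bar = float(self.a_rates[: self.n_rows].sum())

    def _v(self, row: int) -> float:
        if self._kernel_zero:
            return 0.0
        return len(self.nbr_k.get(row, ())) / self.model.density_scale

    def _r_of(self, row: int) -> float:
        m = self.model
        return m.r0 if m.repair_form == "constant" else m.r0 * (1 + 1 / (self._v(row) + 1))

    def _a_of(self, row: int) -> float:
        m = self.model
        return m.a0 if m.death_form == "constant" else m.a0 * (1 - 1 / (self._v(row) + 1))

    # -- totals -------------------------------------------------------------
    @property
    def n_x(self) -> int:
        return int(np.count_nonzero(self.alive[: self.n_rows] & (self.types[: self.n_rows] == TYPE_X)))

    def totals(self) -> dict[str, float]:
        m = self.model
        if self._pair_step:
            b_bar = m.b0 * self.n_pairs
        else:
            nx = self.n_x
            b_bar = m.b0 * nx * (nx - 1) / 2.0
        return {"repair": self.r_bar, "death": self.a_bar, "pair": b_bar}

    # -- mutations ----------------------------------------------------------
    def _grow(self, extra: int) -> None:
        cap = len(self.types)
        if self.n_rows + extra <= cap:
            return
        new_cap = max(2 * cap, self.n_rows + extra)
        pad = new_cap - cap
        self.pos = np.vstack([self.pos, np.zeros((pad, self.d))])
        self.types = np.concatenate([self.types, np.full(pad, -1, np.int8)])
        self.alive = np.concatenate([self.alive, np.zeros(pad, bool)])
        self.lesion_ids = np.concatenate([self.lesion_ids, np.full(pad, -1, np.int64)])
        self.r_rates = np.concatenate([self.r_rates, np.zeros(pad)])
        self.a_rates = np.concatenate([self.a_rates, np.zeros(pad)])
        self.deg_b = np.concatenate([self.deg_b, np.zeros(pad, np.int64)])

    def _refresh_x_rates(self, row: int) -> None:
        old_r, old_a = self.r_rates[row], self.a_rates[row]
        self.r_rates[row] = self._r_of(row)
        self.a_rates[row] = self._a_of(row)
        self.r_bar += self.r_rates[row] - old_r
        self.a_bar += self.a_rates[row] - old_a

    def _remove(self, row: int) -> None:
        self.alive[row] = False
        if self.types[row] == TYPE_X:
            self.r_bar -= self.r_rates[row]
            self.a_bar -= self.a_rates[row]
            self.r_rates[row] = 0.0
            self.a_rates[row] = 0.0
            for k in self.nbr_b.pop(row, set()):
                self.nbr_b[k].discard(row)
                self.deg_b[k] -= 1
                self.n_pairs -= 1
            self.deg_b[row] = 0
        for k in self.nbr_k.pop(row, set()):
            self.nbr_k[k].discard(row)
            if self.alive[k] and self.types[k] == TYPE_X:
                self._refresh_x_rates(k)

    def _insert(self, q: np.ndarray, type_code: int) -> int:
        self._grow(1)
        row = self.n_rows
        self.n_rows += 1
        self.pos[row] = q
        self.types[row] = type_code
        self.alive[row] = True
        self.lesion_ids[row] = self.next_id
        self.next_id += 1
        live = np.flatnonzero(self.alive[:row])
        if not self._homog and not self._kernel_zero and len(live):
            dist = np.linalg.norm(self.pos[live] - q, axis=1)
            close = live[dist < self._rk]
            if len(close):
                self.nbr_k[row] = set(int(k) for k in close)
                for k in close:
                    self.nbr_k.setdefault(int(k), set()).add(row)
                    if self.types[k] == TYPE_X:
                        self._refresh_x_rates(int(k))
        if type_code == TYPE_X:
            if self._pair_step and len(live):
                xl = live[self.types[live] == TYPE_X]
                if len(xl):
                    dist = np.linalg.norm(self.pos[xl] - q, axis=1)
                    close = xl[dist < self._rb]
                    if len(close):
                        self.nbr_b[row] = set(int(k) for k in close)
                        for k in close:
                            self.nbr_b.setdefault(int(k), set()).add(row)
                            self.deg_b[k] += 1
                            self.n_pairs += 1
                        self.deg_b[row] = len(close)
            self.r_rates[row] = self._r_of(row)
            self.a_rates[row] = self._a_of(row)
            self.r_bar += self.r_rates[row]
            self.a_bar += self.a_rates[row]
        return row

    # -- event firing -------------------------------------------------------
    def _sample_row(self, weights: np.ndarray, rng: np.random.Generator) -> int:
        c = np.cumsum(weights[: self.n_rows])
        if c[-1] <= 0:
            raise RuntimeError("channel fired with an all-zero rate table")
        return int(np.searchsorted(c, rng.uniform(0.0, c[-1])))

    def _sample_pair(self, rng: np.random.Generator) -> tuple[int, int]:
        if self._pair_step:
            i = self._sample_row(self.deg_b.astype(float), rng)
            nbrs = sorted(self.nbr_b[i])
            j = nbrs[rng.integers(len(nbrs))]
            return i, j
        live = np.flatnonzero(self.alive[: self.n_rows] & (self.types[: self.n_rows] == TYPE_X))
        i_, j_ = rng.choice(len(live), size=2, replace=False)
        return int(live[i_]), int(live[j_])

    def fire(self, channel: str, t: float, rng: np.random.Generator) -> EventRecord:
        m = self.model
        if channel == "pair":
            i, j = self._sample_pair(rng)
            q1, q2 = self.pos[i].copy(), self.pos[j].copy()
            lid_i, lid_j = int(self.lesion_ids[i]), int(self.lesion_ids[j])
            self._remove(i)
            self._remove(j)
            if kinetics.interaction_is_lethal(q1, q2, m, rng):
                q = kinetics.place_b(q1, q2, m.placement_b, rng)
                self._insert(q, TYPE_Y)
                return EventRecord(t, "pair_lethal", (lid_i, lid_j), ((TYPE_Y, q),))
            return EventRecord(t, "pair_repair", (lid_i, lid_j), ())
        if channel == "repair":
            if self.model.repair_form == "constant":
                live = np.flatnonzero(self.alive[: self.n_rows] & (self.types[: self.n_rows] == TYPE_X))
                i = int(live[rng.integers(len(live))])
            else:
                i = self._sample_row(self.r_rates, rng)
            lid = int(self.lesion_ids[i])
            self._remove(i)
            return EventRecord(t, "repair", (lid,), ())
        # death
        if self.model.death_form == "constant":
            live = np.flatnonzero(self.alive[: self.n_rows] & (self.types[: self.n_rows] == TYPE_X))
            i = int(live[rng.integers(len(live))])
        else:
            i = self._sample_row(self.a_rates, rng)
        q1 = self.pos[i].copy()
        lid = int(self.lesion_ids[i])
        self._remove(i)
        q = kinetics.place_a(q1, m.placement_a, self.domain, rng)
        self._insert(q, TYPE_Y)
        return EventRecord(t, "death", (lid,), ((TYPE_Y, q),))

    def insert(self, t: float, x_pos: np.ndarray, y_pos: np.ndarray) -> EventRecord:
        produced = []
        for q in np.atleast_2d(x_pos) if len(x_pos) else []:
            self._insert(q, TYPE_X)
            produced.append((TYPE_X, q))
        for q in np.atleast_2d(y_pos) if len(y_pos) else []:
            self._insert(q, TYPE_Y)
            produced.append((TYPE_Y, q))
        return EventRecord(t, "dose", (), tuple(produced))

    def snapshot(self, t: float) -> SystemState:
        live = np.flatnonzero(self.alive[: self.n_rows])
        return SystemState(
            t,
            self.lesion_ids[live].copy(),
            self.types[live].copy(),
            self.pos[live].copy(),
            self.next_id,
        )


def _static_engine_supported(model: RateModel) -> bool:
    if model.is_position_independent:
        return True
    if model.pair_form not in ("constant", "step"):
        return False
    for k in (model.repair_kernel, model.death_kernel):
        if k.kind not in ("zero", "ball") or k.include_focal:
            return False
        if set(k.types_counted) != {"X", "Y"}:
            return False
    return model.repair_kernel == model.death_kernel


# ---------------------------------------------------------------------------
# the simulator

def simulate(
    initial_state: SystemState,
    domain: Domain,
    model: RateModel,
    diffusion: DiffusionSpec | None = None,
    scheduler: SchedulerConfig | None = None,
    irradiation=None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Simulate the lesion process on [t0, t_end].

    Parameters
    ----------
    initial_state
        Configuration at the start time (positions must lie in Q̄).
    irradiation
        Optional :class:`radlesion.irradiation.ProtractedIrradiation`
        inserting dose events at Poisson times.
    rng, seed
        Either a seeded generator or an integer seed (exactly one source of
        randomness).  Identical seed + configuration give a bit-identical
        trajectory.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if scheduler is None:
        raise ValueError("a SchedulerConfig is required")
    diffusion = diffusion or DiffusionSpec()
    if initial_state.n_total and not np.all(domain.contains(initial_state.positions)):
        raise ValueError("initial lesion positions must lie inside the domain")

    # independent sub-streams so optional outputs cannot perturb the event law
    ss = np.random.SeedSequence(entropy=int(rng.integers(2**63)))
    rng_dose, rng_events, rng_diff = (np.random.default_rng(s) for s in ss.spawn(3))

    dose_times: list[float] = []
    if irradiation is not None:
        dose_times = list(irradiation.schedule(rng_dose))

    static = not diffusion.is_active
    if static and _static_engine_supported(model):
        engine = _StaticEngine(initial_state, model, domain)
    else:
        engine = _GenericEngine(initial_state, model, domain)

    t0 = initial_state.time
    t_end = scheduler.t_end
    snap_times = sorted(s for s in scheduler.snapshot_times)
    events: list[EventRecord] = []
    snapshots: list[SystemState] = []
    clocks = ChannelClocks.draw(rng_events)

    dose_iter = iter(dose_times + [math.inf])
    next_dose = next(dose_iter)
    while next_dose < t0:  # doses before the start time are ignored
        next_dose = next(dose_iter)
    snap_iter = iter(snap_times + [math.inf])
    next_snap = next(snap_iter)
    while next_snap < t0:  # snapshot times before the start are meaningless
        next_snap = next(snap_iter)

    t = t0
    next_grid = math.inf if static else t0 + scheduler.dt
    while t < t_end:
        seg_end = min(next_grid, next_dose, next_snap, t_end)
        # events within [t, seg_end) at rates frozen for the current positions
        while True:
            fired = next_event(engine.totals(), clocks, t, seg_end - t)
            if fired is None:
                t = seg_end
                break
            t_ev, channel = fired
            events.append(engine.fire(channel, t_ev, rng_events))
            clocks.redraw(rng_events)
            t = t_ev
        if t >= t_end:
            break
        if t == next_snap:
            snapshots.append(engine.snapshot(t))
            next_snap = next(snap_iter)
        if t == next_dose:
            xq, yq = irradiation.sample_event(domain, rng_dose)
            events.append(engine.insert(t, xq, yq))
            clocks.redraw(rng_events)
            next_dose = next(dose_iter)
        if not static and t == next_grid:
            engine.set_positions(
                diffuse_step(engine.snapshot(t), scheduler.dt, diffusion, domain, rng_diff)
            )
            next_grid += scheduler.dt

    if next_snap == t_end:
        snapshots.append(engine.snapshot(t_end))
    final = engine.snapshot(t_end)
    return Trajectory(initial_state, events, snapshots, final, seed)
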