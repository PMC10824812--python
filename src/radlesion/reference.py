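"""Non-spatial reference models for lesion kinetics.

These are the well-mixed counterparts of the spatial simulator and serve as
oracles in cross-model verification:

* the microdosimetric master equation (MME) for the joint pmf p(t, y, x) of
  lethal/sub-lethal lesion counts, with transitions

      (y, x) → (y,   x−1)   at r·x                  (repair)
      (y, x) → (y+1, x−1)   at a·x                  (death)
      (y, x) → (y+1, x−2)   at p·β·x(x−1)           (pair, lethal)
      (y, x) → (y,   x−2)   at (1−p)·β·x(x−1)       (pair, complete exchange)

* an exact stochastic simulation (Gillespie) of the same jump chain;
* the mean-lesion-number ODEs (MKM):  dȳ/dt = a·x̄ + b·x̄²,
  dx̄/dt = −(a+r)·x̄ − 2b·x̄², and their linear reduction with closed form;
* the spatially homogeneous mean-field limit with a protracted source.

Pair-rate convention: β multiplies x(x−1), i.e. ordered pairs.  The spatial
simulator sums a constant b0 over *unordered* pairs (total b0·x(x−1)/2), so
the cross-model mapping is β = b0/2 — applied by callers, never silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.sparse.linalg import expm_multiply

__all__ = [
    "MMEConfig",
    "PmfTrajectory",
    "mme_solve",
    "ssa_nonspatial",
    "ssa_ensemble_final",
    "mkm_solve",
    "mkm_closed_form",
    "meanfield_protracted",
    "survival_probability",
]


@dataclass(frozen=True)
class MMEConfig:
    """Rates and truncation for the master equation.

    ``beta`` multiplies x(x−1) (ordered-pair convention).  ``y_mode`` is
    ``full`` (track y on [0, y_max]) or ``survival_collapsed`` (track only
    x and a single absorbing "dead" flag — enough for survival curves).
    """

    r: float
    a: float
    beta: float
    p: float = 1.0
    x_max: int = 100
    y_max: int | None = None
    y_mode: str = "full"

    def __post_init__(self) -> None:
        if min(self.r, self.a, self.beta) < 0:
            raise ValueError("rates must be nonnegative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.y_mode not in ("full", "survival_collapsed"):
            raise ValueError("y_mode must be 'full' or 'survival_collapsed'")


@dataclass
class PmfTrajectory:
    """pmf slices over time on the truncated lattice.

    ``values`` has shape (T, y_max+1, x_max+1) in full mode, or
    (T, x_max+2) in collapsed mode where the last entry is the absorbed
    (dead) mass and entry k < x_max+1 is P(alive, x = k).
    """

    times: np.ndarray
    values: np.ndarray
    mode: str

    def x_marginal(self, k: int) -> np.ndarray:
        """Marginal pmf of x at output index k (full mode only)."""
        if self.mode != "full":
            raise ValueError("x marginal requires full mode")
        return self.values[k].sum(axis=0)


def _full_generator(cfg: MMEConfig, y_max: int) -> sparse.csr_matrix:
    ny, nx = y_max + 1, cfg.x_max + 1

    def idx(y, x):
        return y * nx + x

    rows, cols, vals = [], [], []

    def add(src, dst, rate):
        rows.append(dst)
        cols.append(src)
        vals.append(rate)
        rows.append(src)
        cols.append(src)
        vals.append(-rate)

    for y in range(ny):
        for x in range(nx):
            s = idx(y, x)
            if x >= 1:
                add(s, idx(y, x - 1), cfg.r * x)
                if y + 1 <= y_max:
                    add(s, idx(y + 1, x - 1), cfg.a * x)
            if x >= 2:
                pair = cfg.beta * x * (x - 1)
                if y + 1 <= y_max:
                    add(s, idx(y + 1, x - 2), cfg.p * pair)
                add(s, idx(y, x - 2), (1 - cfg.p) * pair)
    n = ny * nx
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _collapsed_generator(cfg: MMEConfig) -> sparse.csr_matrix:
    # states: x = 0..x_max alive, plus one absorbing dead state
    nx = cfg.x_max + 1
    dead = nx
    rows, cols, vals = [], [], []

    def add(src, dst, rate):
        rows.append(dst)
        cols.append(src)
        vals.append(rate)
        rows.append(src)
        cols.append(src)
        vals.append(-rate)

    for x in range(nx):
        if x >= 1:
            add(x, x - 1, cfg.r * x)
            add(x, dead, cfg.a * x)
        if x >= 2:
            pair = cfg.beta * x * (x - 1)
            add(x, dead, cfg.p * pair)
            add(x, x - 2, (1 - cfg.p) * pair)
    n = nx + 1
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def mme_solve(
    cfg: MMEConfig,
    initial: tuple[int, int] | np.ndarray,
    times: np.ndarray,
) -> PmfTrajectory:
    """Propagate the master-equation pmf to the requested output times.

    ``initial`` is either a (y0, x0) point mass or a full pmf array of shape
    (y_max+1, x_max+1) (full mode) / (x_max+2,) (collapsed).  The linear
    system p' = A p is advanced with Krylov matrix-exponential products, so
    mass is conserved to near machine precision on the closed lattice.
    """
    times = np.asarray(times, float)
    if cfg.y_mode == "full":
        if isinstance(initial, tuple):
            y0, x0 = initial
            y_max = cfg.y_max if cfg.y_max is not None else y0 + cfg.x_max
            p0 = np.zeros((y_max + 1, cfg.x_max + 1))
            p0[y0, x0] = 1.0
        else:
            p0 = np.asarray(initial, float)
            y_max = p0.shape[0] - 1
        gen = _full_generator(cfg, y_max)
        vec = p0.ravel()
        shape = p0.shape
    else:
        if isinstance(initial, tuple):
            y0, x0 = initial
            vec = np.zeros(cfg.x_max + 2)
            if y0 > 0:
                vec[-1] = 1.0  # already carrying a lethal lesion: dead
            else:
                vec[x0] = 1.0
        else:
            vec = np.asarray(initial, float).copy()
        gen = _collapsed_generator(cfg)
        shape = (cfg.x_max + 2,)

    out = np.empty((len(times),) + shape)
    t_prev = 0.0
    v = vec
    for k, t in enumerate(times):
        if t < t_prev:
            raise ValueError("output times must be nondecreasing")
        if t > t_prev:
            v = expm_multiply(gen * (t - t_prev), v)
            t_prev = t
        out[k] = np.clip(v, -1e-12, None).reshape(shape)
    return PmfTrajectory(times, out, cfg.y_mode)


def ssa_nonspatial(
    cfg: MMEConfig,
    x0: int,
    y0: int,
    t_end: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact Gillespie simulation of one path of the well-mixed jump chain.

    Returns (event times, x path, y path) including the initial state.
    """
    t, x, y = 0.0, x0, y0
    ts, xs, ys = [0.0], [x0], [y0]
    while True:
        w_r, w_a = cfg.r * x, cfg.a * x
        w_b = cfg.beta * x * (x - 1)
        total = w_r + w_a + w_b
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        u = rng.uniform(0.0, total)
        if u < w_r:
            x -= 1
        elif u < w_r + w_a:
            x -= 1
            y += 1
        else:
            x -= 2
            if rng.uniform() <= cfg.p:
                y += 1
        ts.append(t)
        xs.append(x)
        ys.append(y)
    return np.array(ts), np.array(xs), np.array(ys)


def ssa_ensemble_final(
    cfg: MMEConfig,
    x0: int,
    y0: int,
    t_end: float,
    n_paths: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Final (x, y) of many independent Gillespie paths, vectorised by rounds."""
    x = np.full(n_paths, x0, np.int64)
    y = np.full(n_paths, y0, np.int64)
    t = np.zeros(n_paths)
    active = np.ones(n_paths, bool)
    while active.any():
        idx = np.flatnonzero(active)
        w_r = cfg.r * x[idx]
        w_a = cfg.a * x[idx]
        w_b = cfg.beta * x[idx] * (x[idx] - 1)
        total = w_r + w_a + w_b
        dead = total <= 0
        active[idx[dead]] = False
        idx = idx[~dead]
        if not len(idx):
            break
        total = total[~dead]
        t[idx] += rng.exponential(1.0, size=len(idx)) / total
        done = t[idx] >= t_end
        active[idx[done]] = False
        idx = idx[~done]
        total = total[~done]
        if not len(idx):
            continue
        u = rng.uniform(0.0, 1.0, size=len(idx)) * total
        w_r, w_a = cfg.r * x[idx], cfg.a * x[idx]
        repair = u < w_r
        death = (~repair) & (u < w_r + w_a)
        pair = ~(repair | death)
        x[idx[repair]] -= 1
        x[idx[death]] -= 1
        y[idx[death]] += 1
        pid = idx[pair]
        x[pid] -= 2
        lethal = rng.uniform(size=len(pid)) <= cfg.p
        y[pid[lethal]] += 1
    return x, y


def mkm_solve(
    r: float,
    a: float,
    b: float,
    x0: float,
    y0: float,
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean lesion numbers (x̄, ȳ) from the MKM ODE system."""
    times = np.asarray(times, float)

    def rhs(_t, s):
        xb, _ = s
        return [-(a + r) * xb - 2 * b * xb**2, a * xb + b * xb**2]

    sol = solve_ivp(rhs, (0.0, float(times[-1]) if len(times) else 0.0),
                    [x0, y0], t_eval=times, rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"MKM ODE solve failed: {sol.message}")
    return sol.y[0], sol.y[1]


def mkm_closed_form(
    r: float, a: float, b: float, x0: float, y0: float, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed form of the linearised system: x̄ decays exponentially and ȳ
    follows by quadrature of a·x̄ + b·x̄² (the x̄² loss term is dropped)."""
    t = np.asarray(times, float)
    k = a + r
    xb = x0 * np.exp(-k * t)
    yb = y0 + (a * x0 / k) * (1 - np.exp(-k * t)) + (b * x0**2 / (2 * k)) * (
        1 - np.exp(-2 * k * t)
    )
    return xb, yb


def meanfield_protracted(
    r: float,
    a: float,
    beta_mf: float,
    p: float,
    source_x: float,
    source_y: float,
    t_irr: float,
    x0: float,
    y0: float,
    times: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially homogeneous mean-field densities under a protracted source.

        dx̄/dt = −(a+r)·x̄ − 2·β_mf·x̄² + S_X·1{t ≤ T_irr}
        dȳ/dt =  a·x̄ + p·β_mf·x̄²      + S_Y·1{t ≤ T_irr}

    with constant creation rates S_X = ḋ·E[ξ^X], S_Y = ḋ·E[ξ^Y] during the
    irradiation window.  β_mf uses the ordered-pair convention (= b0/2 for
    the spatial simulator's constant per-unordered-pair rate b0).
    """
    times = np.asarray(times, float)
    if min(source_x, source_y) < 0:
        raise ValueError("sources must be nonnegative")

    def rhs(t, s, sx, sy):
        xb, _ = s
        return [-(a + r) * xb - 2 * beta_mf * xb**2 + sx,
                a * xb + p * beta_mf * xb**2 + sy]

    # integrate in two spans so the source switch-off is not smoothed over
    t_end = float(times[-1]) if len(times) else 0.0
    t_split = min(max(t_irr, 0.0), t_end)
    xs, ys = np.empty_like(times), np.empty_like(times)
    at_zero = times == 0.0
    xs[at_zero], ys[at_zero] = x0, y0
    state = np.array([float(x0), float(y0)])
    for lo, hi, on in ((0.0, t_split, True), (t_split, t_end, False)):
        if hi <= lo:
            continue
        sol = solve_ivp(
            rhs, (lo, hi), state, dense_output=True,
            args=(source_x if on else 0.0, source_y if on else 0.0),
            rtol=rtol, atol=atol, method="LSODA",
        )
        if not sol.success:
            raise RuntimeError(f"mean-field ODE solve failed: {sol.message}")
        mask = (times > lo) & (times <= hi)
        if mask.any():
            vals = sol.sol(times[mask])
            xs[mask], ys[mask] = vals[0], vals[1]
        state = sol.y[:, -1]
    return xs, ys


def survival_probability(traj: PmfTrajectory) -> np.ndarray:
    """S(t) = P(no lethal lesion at t) from a pmf trajectory."""
    if traj.mode == "full":
        return traj.values[:, 0, :].sum(axis=1)
    return traj.values[:, :-1].sum(axis=1)
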