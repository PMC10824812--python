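"""Large-population rescaling and empirical limit verification.

With a scaling parameter K the per-capita picture u^K = ν^K/K is kept
comparable across system sizes by rescaling

    a^K(q, v) = a(q, v/K),   r^K(q, v) = r(q, v/K),
    b^K(q1, q2, v) = b(q1, q2, v/K)/K,   ḋ^K = K·ḋ,

with the initial lesion number scaled ∝ K.  As K → ∞ the rescaled process
converges to a deterministic mean-field dynamic and the fluctuations of
⟨1, u^K⟩ have variance ∝ 1/K.  In the spatially homogeneous setting the
limit is the protracted mean-field ODE of :mod:`radlesion.reference`, which
this module uses as the reference curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import DiffusionSpec, SchedulerConfig, Trajectory, simulate
from .geometry import Domain
from .irradiation import ProtractedIrradiation, ProtractedSpec
from .kinetics import RateModel
from .reference import meanfield_protracted
from .state import SystemState

__all__ = ["ScalingConfig", "rescale", "counts_at", "convergence_experiment", "variance_slope"]


@dataclass(frozen=True)
class ScalingConfig:
    """One convergence study: base system, K ladder, replicate budget."""

    domain: Domain
    model: RateModel
    k_values: tuple[int, ...]
    x0_base: int
    y0_base: int = 0
    irradiation: ProtractedIrradiation | None = None
    diffusion: DiffusionSpec = field(default_factory=DiffusionSpec)
    t_end: float = 1.0
    output_times: tuple[float, ...] = (0.5, 1.0)
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        ks = list(self.k_values)
        if len(set(ks)) != len(ks) or any(k < 1 for k in ks):
            raise ValueError("K values must be distinct integers >= 1")


def rescale(
    model: RateModel,
    irradiation: ProtractedIrradiation | None,
    k: int,
) -> tuple[RateModel, ProtractedIrradiation | None]:
    """Rescaled rate model and irradiation source for population size K."""
    if k < 1:
        raise ValueError("K must be >= 1")
    model_k = replace(model, b0=model.b0 / k, density_scale=model.density_scale * k)
    irr_k = None
    if irradiation is not None:
        prot = irradiation.protracted
        irr_k = ProtractedIrradiation(
            ProtractedSpec(prot.dose_rate_events_per_h * k, prot.t_irr_h),
            irradiation.micro,
            irradiation.track,
        )
    return model_k, irr_k


def counts_at(traj: Trajectory, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(N^X, N^Y) at the requested times from the piecewise-constant path."""
    series = traj.counts()
    t = series["t_h"].to_numpy()
    idx = np.searchsorted(t, np.asarray(times, float), side="right") - 1
    idx = np.clip(idx, 0, len(t) - 1)
    return series["n_x"].to_numpy()[idx], series["n_y"].to_numpy()[idx]


def convergence_experiment(config: ScalingConfig) -> pd.DataFrame:
    """Ensemble means/variances of (N^X/K, N^Y/K) against the ODE limit.

    Requires the spatially homogeneous setting (position-independent rates)
    so the mean-field ODE is the correct reference.
    """
    if not config.model.is_position_independent:
        raise ValueError("convergence experiment requires position-independent rates")
    times = np.asarray(config.output_times, float)
    m = config.model
    if config.irradiation is not None:
        prot = config.irradiation.protracted
        micro = config.irradiation.micro
        mean_zf = micro.z_f_gy
        src_x = prot.dose_rate_events_per_h * micro.kappa_per_gy * mean_zf
        src_y = prot.dose_rate_events_per_h * micro.lambda_per_gy * mean_zf
        t_irr = prot.t_irr_h
    else:
        src_x = src_y = 0.0
        t_irr = 0.0
    p_const = m.p if isinstance(m.p, (int, float)) else 1.0
    ode_x, ode_y = meanfield_protracted(
        m.r0, m.a0, m.b0 / 2.0, p_const, src_x, src_y, t_irr,
        config.x0_base, config.y0_base, times,
    )

    ss = np.random.SeedSequence(config.seed)
    rows = []
    for k in config.k_values:
        model_k, irr_k = rescale(m, config.irradiation, k)
        ux = np.empty((config.n_replicates, len(times)))
        uy = np.empty_like(ux)
        child = ss.spawn(1)[0]
        rep_seeds = child.spawn(config.n_replicates)
        for rep, rs in enumerate(rep_seeds):
            rng = np.random.default_rng(rs)
            init = SystemState.from_positions(
                config.domain.uniform_sample(rng, size=k * config.x0_base),
                config.domain.uniform_sample(rng, size=k * config.y0_base)
                if config.y0_base
                else None,
            )
            traj = simulate(
                init, config.domain, model_k, config.diffusion,
                SchedulerConfig(t_end=config.t_end), irr_k, rng=rng,
            )
            nx, ny = counts_at(traj, times)
            ux[rep] = nx / k
            uy[rep] = ny / k
        for j, t in enumerate(times):
            rows.append(
                {
                    "K": k,
                    "t_h": t,
                    "mean_ux": ux[:, j].mean(),
                    "var_ux": ux[:, j].var(ddof=1),
                    "se_ux": ux[:, j].std(ddof=1) / np.sqrt(config.n_replicates),
                    "mean_uy": uy[:, j].mean(),
                    "var_uy": uy[:, j].var(ddof=1),
                    "ode_x": ode_x[j],
                    "ode_y": ode_y[j],
                }
            )
    return pd.DataFrame(rows)


def variance_slope(table: pd.DataFrame, t: float) -> float:
    """OLS slope of log Var[N^X(t)/K] on log K (−1 under 1/K scaling)."""
    sub = table[np.isclose(table["t_h"], t)]
    if len(sub) < 2:
        raise ValueError("need at least two K values at the requested time")
    return float(np.polyfit(np.log(sub["K"].to_numpy(float)),
                            np.log(sub["var_ux"].to_numpy(float)), 1)[0])
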