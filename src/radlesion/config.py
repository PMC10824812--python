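"""Run configuration: TOML schema, validation, and the built-in preset.

Units are fixed package-wide: lengths in μm, times in hours, doses in Gy.

The ``carbon_10gy`` preset is the reference numerical scenario: a circular
nucleus of radius 5 μm receiving 10 Gy from a monoenergetic carbon-ion
field (z_F = 0.04 Gy, κ = 50 Gy⁻¹, λ = κ/100), crowding-dependent repair
and death rates (r = 4 h⁻¹, a = 0.1 h⁻¹) counting damage within
r_d = 0.5 μm, a step pair-interaction rate (b = 0.1 h⁻¹) inside the same
radius with lethal outcome (p = 1), lethal lesions placed at the midpoint
of the interacting pair, death in place, and static lesions (σ = 0).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

import numpy as np

from .dynamics import DiffusionSpec, SchedulerConfig
from .geometry import Domain
from .irradiation import (
    F1Spectrum,
    MicrodosimetrySpec,
    ProtractedIrradiation,
    ProtractedSpec,
    TrackModel,
)
from .kinetics import KernelSpec, PlacementA, PlacementB, RateModel

__all__ = ["RunConfig", "load_config", "preset_carbon_10gy"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunConfig:
    """Fully validated inputs for one simulation run."""

    domain: Domain
    model: RateModel
    diffusion: DiffusionSpec
    scheduler: SchedulerConfig
    micro: MicrodosimetrySpec | None = None
    track: TrackModel = field(default_factory=TrackModel)
    protracted: ProtractedIrradiation | None = None


def preset_carbon_10gy(
    t_end: float = 1.0, protracted_t_irr: float | None = None
) -> RunConfig:
    """The reference numerical scenario (see module docstring)."""
    domain = Domain("disk2d", 5.0)
    kernel = KernelSpec(kind="ball", r_d_um=0.5)
    model = RateModel(
        r0=4.0,
        a0=0.1,
        b0=0.1,
        p=1.0,
        repair_form="crowding",
        death_form="crowding",
        pair_form="step",
        pair_r_d_um=0.5,
        repair_kernel=kernel,
        death_kernel=kernel,
        placement_a=PlacementA(kind="in_place"),
        placement_b=PlacementB(kind="midpoint"),
    )
    micro = MicrodosimetrySpec(
        dose_gy=10.0, z_f_gy=0.04, kappa_per_gy=50.0, lambda_per_gy=0.5,
        f1=F1Spectrum(kind="gamma", z_f_gy=0.04, shape=1.0),
    )
    track = TrackModel()
    protracted = None
    if protracted_t_irr is not None:
        protracted = ProtractedIrradiation(
            ProtractedSpec.from_dose(micro.dose_gy, protracted_t_irr, micro.z_f_gy),
            micro,
            track,
        )
    return RunConfig(
        domain=domain,
        model=model,
        diffusion=DiffusionSpec(),
        scheduler=SchedulerConfig(t_end=t_end),
        micro=micro,
        track=track,
        protracted=protracted,
    )


_SECTIONS = {
    "preset", "domain", "rates", "kernel", "placement", "diffusion",
    "scheduler", "irradiation",
}


def _check_keys(section: str, table: dict, allowed: set[str]) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration.

    A ``preset`` key seeds every section with the named preset; explicit
    sections then override it field by field.  Unknown keys are rejected.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")

    base: RunConfig | None = None
    if "preset" in raw:
        if raw["preset"] != "carbon_10gy":
            raise ConfigError(f"unknown preset {raw['preset']!r}")
        base = preset_carbon_10gy()

    try:
        dom_tbl = raw.get("domain", {})
        _check_keys("domain", dom_tbl, {"shape", "radius_um", "center"})
        if dom_tbl:
            domain = Domain(
                dom_tbl.get("shape", "disk2d"),
                dom_tbl.get("radius_um", 5.0),
                dom_tbl.get("center"),
            )
        elif base is not None:
            domain = base.domain
        else:
            domain = Domain("disk2d", 5.0)

        kern_tbl = raw.get("kernel", {})
        _check_keys("kernel", kern_tbl, {
            "kind", "r_d_um", "eps_um", "eps2_um", "weight1", "weight2",
            "include_focal", "types",
        })
        kern_kwargs = {k: v for k, v in kern_tbl.items() if k != "types"}
        if "types" in kern_tbl:
            kern_kwargs["types_counted"] = tuple(kern_tbl["types"])
        kernel = (
            KernelSpec(**kern_kwargs)
            if kern_tbl
            else (base.model.repair_kernel if base else KernelSpec())
        )

        pl_tbl = raw.get("placement", {})
        _check_keys("placement", pl_tbl, {
            "a", "a_eps_um", "b", "b_endpoint_j", "b_alphas", "b_probs",
        })
        placement_a = (
            PlacementA(pl_tbl.get("a", "in_place"), pl_tbl.get("a_eps_um", 0.1))
            if pl_tbl
            else (base.model.placement_a if base else PlacementA())
        )
        placement_b = (
            PlacementB(
                pl_tbl.get("b", "midpoint"),
                pl_tbl.get("b_endpoint_j", 0),
                tuple(pl_tbl.get("b_alphas", ())),
                tuple(pl_tbl.get("b_probs", ())),
            )
            if pl_tbl
            else (base.model.placement_b if base else PlacementB())
        )

        rate_tbl = raw.get("rates", {})
        _check_keys("rates", rate_tbl, {
            "r0", "a0", "b0", "p", "repair_form", "death_form", "pair_form",
            "pair_r_d_um", "pair_eps_um", "pair_eps2_um", "pair_b1", "pair_b2",
        })
        model_base = base.model if base else RateModel()
        model = RateModel(
            r0=rate_tbl.get("r0", model_base.r0),
            a0=rate_tbl.get("a0", model_base.a0),
            b0=rate_tbl.get("b0", model_base.b0),
            p=rate_tbl.get("p", model_base.p),
            repair_form=rate_tbl.get("repair_form", model_base.repair_form),
            death_form=rate_tbl.get("death_form", model_base.death_form),
            pair_form=rate_tbl.get("pair_form", model_base.pair_form),
            pair_r_d_um=rate_tbl.get("pair_r_d_um", model_base.pair_r_d_um),
            pair_eps_um=rate_tbl.get("pair_eps_um", model_base.pair_eps_um),
            pair_eps2_um=rate_tbl.get("pair_eps2_um", model_base.pair_eps2_um),
            pair_b1=rate_tbl.get("pair_b1", model_base.pair_b1),
            pair_b2=rate_tbl.get("pair_b2", model_base.pair_b2),
            repair_kernel=kernel,
            death_kernel=kernel,
            placement_a=placement_a,
            placement_b=placement_b,
        )

        diff_tbl = raw.get("diffusion", {})
        _check_keys("diffusion", diff_tbl, {"sigma_x", "sigma_y", "mu_x", "mu_y"})
        diffusion = DiffusionSpec(
            sigma_x=diff_tbl.get("sigma_x", 0.0),
            sigma_y=diff_tbl.get("sigma_y", 0.0),
            mu_x=tuple(np.atleast_1d(diff_tbl.get("mu_x", 0.0)).tolist()),
            mu_y=tuple(np.atleast_1d(diff_tbl.get("mu_y", 0.0)).tolist()),
        ) if diff_tbl else (base.diffusion if base else DiffusionSpec())

        sch_tbl = raw.get("scheduler", {})
        _check_keys("scheduler", sch_tbl, {"t_end", "dt", "snapshot_times"})
        scheduler = SchedulerConfig(
            t_end=sch_tbl.get("t_end", base.scheduler.t_end if base else 1.0),
            dt=sch_tbl.get("dt", base.scheduler.dt if base else 1e-3),
            snapshot_times=tuple(sch_tbl.get("snapshot_times", ())),
        )

        irr_tbl = raw.get("irradiation", {})
        _check_keys("irradiation", irr_tbl, {
            "dose_gy", "z_f_gy", "kappa_per_gy", "lambda_per_gy", "f1",
            "f1_shape", "r_core_um", "r_penumbra_um", "boundary_mode",
            "mode", "t_irr_h",
        })
        micro = base.micro if base else None
        track = base.track if base else TrackModel()
        protracted = base.protracted if base else None
        if irr_tbl:
            z_f = irr_tbl.get("z_f_gy", micro.z_f_gy if micro else 0.04)
            f1 = F1Spectrum(
                kind=irr_tbl.get("f1", "gamma"),
                z_f_gy=z_f,
                shape=irr_tbl.get("f1_shape", 1.0),
            )
            micro = MicrodosimetrySpec(
                dose_gy=irr_tbl.get("dose_gy", 10.0),
                z_f_gy=z_f,
                kappa_per_gy=irr_tbl.get("kappa_per_gy", 50.0),
                lambda_per_gy=irr_tbl.get("lambda_per_gy", 0.5),
                f1=f1,
            )
            track = TrackModel(
                r_core_um=irr_tbl.get("r_core_um", 0.01),
                r_penumbra_um=irr_tbl.get("r_penumbra_um", 1.0),
                boundary_mode=irr_tbl.get("boundary_mode", "resample"),
            )
            if irr_tbl.get("mode", "instantaneous") == "protracted":
                t_irr = irr_tbl.get("t_irr_h")
                if t_irr is None:
                    raise ConfigError("protracted irradiation requires t_irr_h")
                protracted = ProtractedIrradiation(
                    ProtractedSpec.from_dose(micro.dose_gy, t_irr, micro.z_f_gy),
                    micro,
                    track,
                )
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        domain=domain,
        model=model,
        diffusion=diffusion,
        scheduler=scheduler,
        micro=micro,
        track=track,
        protracted=protracted,
    )
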