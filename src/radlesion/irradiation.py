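"""Microdosimetric generation of radiation-induced damage.

At micrometre scale the energy imparted to a nucleus is stochastic: a dose
D [Gy] is delivered by a Poisson number ν of particle traversals of mean
D/z_F, where z_F is the fluence-average specific energy (the mean of the
single-event specific-energy spectrum f₁).  Each traversal deposits a
specific energy z ~ f₁ and induces Poisson(κ·z) sub-lethal and Poisson(λ·z)
lethal lesions (linear yields κ, λ [Gy⁻¹]).  Lesions are placed radially
around the track centre following the amorphous-track radial dose profile

    D(ρ) = C_c                for ρ ≤ R_c        (core)
         = C_p / ρ²           for R_c < ρ ≤ R_p  (penumbra)
         = 0                  beyond R_p,

continuous at R_c and normalised over the disc of radius R_p.  The marginal
lesion-count law that results is a microdosimetric generalisation of the
Neyman (Poisson-of-Poissons) distribution.

Protracted irradiation replaces the instantaneous snapshot by a Poisson
process of damage-creating events at rate ḋ = D/(T_irr·z_F) on [0, T_irr];
each event is one traversal sampled exactly as above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import Domain
from .state import SystemState

__all__ = [
    "F1Spectrum",
    "MicrodosimetrySpec",
    "TrackModel",
    "ProtractedSpec",
    "ProtractedIrradiation",
    "sample_track_count",
    "sample_radial_offset",
    "radial_cdf",
    "core_mass_fraction",
    "generate_initial_damage",
    "multi_event_distribution",
    "p0_pmf",
    "protracted_schedule",
    "sample_dose_event",
]


@dataclass(frozen=True)
class F1Spectrum:
    """Single-event specific-energy spectrum f₁(z) with mean z_F [Gy].

    kinds: ``delta`` (all events deposit exactly z_F — analytic reference),
    ``gamma`` (shape k, mean z_F; k = 1 is the exponential-like spectrum
    used as default), ``tabulated`` (two-column z grid / density).
    """

    kind: str = "gamma"
    z_f_gy: float = 0.04
    shape: float = 1.0
    z_grid: np.ndarray | None = None
    density: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("delta", "gamma", "tabulated"):
            raise ValueError(f"unknown f1 kind {self.kind!r}")
        if not self.z_f_gy > 0:
            raise ValueError("z_F must be positive")
        if self.kind == "gamma" and not self.shape > 0:
            raise ValueError("gamma shape must be positive")
        if self.kind == "tabulated":
            z = np.asarray(self.z_grid, float)
            f = np.asarray(self.density, float)
            if z.ndim != 1 or z.shape != f.shape or len(z) < 2:
                raise ValueError("tabulated f1 needs matching 1-D z grid and density")
            if np.any(np.diff(z) <= 0) or np.any(f < 0):
                raise ValueError("tabulated f1 must have increasing z and density >= 0")
            mass = np.trapezoid(f, z)
            mean = np.trapezoid(f * z, z)
            if abs(mass - 1.0) > 1e-6:
                raise ValueError(f"tabulated f1 integrates to {mass}, not 1")
            if abs(mean - self.z_f_gy) > 1e-6 * max(1.0, self.z_f_gy):
                raise ValueError(f"tabulated f1 has mean {mean}, not z_F={self.z_f_gy}")
            object.__setattr__(self, "z_grid", z)
            object.__setattr__(self, "density", f)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "delta":
            return np.full(size, self.z_f_gy)
        if self.kind == "gamma":
            return rng.gamma(self.shape, self.z_f_gy / self.shape, size=size)
        cdf = np.concatenate([[0.0], np.cumsum(
            0.5 * (self.density[1:] + self.density[:-1]) * np.diff(self.z_grid))])
        cdf /= cdf[-1]
        return np.interp(rng.uniform(size=size), cdf, self.z_grid)

    def on_grid(self, z: np.ndarray) -> np.ndarray:
        """Density evaluated on a uniform grid (delta spectra have no density)."""
        if self.kind == "delta":
            raise ValueError("delta f1 has no Lebesgue density; handled analytically")
        if self.kind == "gamma":
            return stats.gamma.pdf(z, a=self.shape, scale=self.z_f_gy / self.shape)
        return np.interp(z, self.z_grid, self.density, left=0.0, right=0.0)

    def cdf(self, z: np.ndarray) -> np.ndarray:
        if self.kind == "delta":
            return (np.asarray(z, float) >= self.z_f_gy).astype(float)
        if self.kind == "gamma":
            return stats.gamma.cdf(z, a=self.shape, scale=self.z_f_gy / self.shape)
        dens = np.asarray(self.density)
        grid = np.asarray(self.z_grid)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
        cum /= cum[-1]
        return np.interp(z, grid, cum, left=0.0, right=1.0)

    def cell_masses(self, z: np.ndarray) -> np.ndarray:
        """Probability mass per grid cell [z_i − dz/2, z_i + dz/2).

        CDF differences make discrete means exact to O(dz²), unlike point
        sampling of the density.
        """
        dz = z[1] - z[0]
        edges = np.concatenate([[max(z[0] - dz / 2, 0.0)], z + dz / 2])
        return np.diff(self.cdf(edges))


@dataclass(frozen=True)
class MicrodosimetrySpec:
    """Dose, spectrum and lesion yields for damage induction.

    Defaults follow the reference scenario: D = 10 Gy delivered by a
    carbon-ion field with z_F = 0.04 Gy, sub-lethal yield κ = 50 Gy⁻¹ and
    lethal yield λ = κ/100.
    """

    dose_gy: float = 10.0
    z_f_gy: float = 0.04
    kappa_per_gy: float = 50.0
    lambda_per_gy: float = 0.5
    f1: F1Spectrum = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dose_gy < 0 or self.kappa_per_gy < 0 or self.lambda_per_gy < 0:
            raise ValueError("dose and yields must be nonnegative")
        if not self.z_f_gy > 0:
            raise ValueError("z_F must be positive")
        if self.f1 is None:
            object.__setattr__(self, "f1", F1Spectrum(kind="gamma", z_f_gy=self.z_f_gy))
        elif abs(self.f1.z_f_gy - self.z_f_gy) > 1e-12:
            raise ValueError("f1 mean must equal z_F")

    @property
    def mean_events(self) -> float:
        """Mean number of traversals D/z_F."""
        return self.dose_gy / self.z_f_gy


@dataclass(frozen=True)
class TrackModel:
    """Amorphous-track radial profile: core R_c, penumbra edge R_p [μm].

    The preset R_c = 0.01 μm, R_p = 1 μm is a package default for
    low-energy carbon ions; only the normalised radial *shape* matters for
    lesion placement, so the core/penumbra amplitudes are fixed by
    continuity at R_c and unit mass on the disc of radius R_p.
    ``boundary_mode``: ``resample`` re-draws offsets that fall outside the
    nucleus (preserving per-track lesion counts), ``discard`` drops them.
    """

    r_core_um: float = 0.01
    r_penumbra_um: float = 1.0
    boundary_mode: str = "resample"

    def __post_init__(self) -> None:
        if not 0 < self.r_core_um < self.r_penumbra_um:
            raise ValueError("need 0 < R_c < R_p")
        if self.boundary_mode not in ("resample", "discard"):
            raise ValueError("boundary_mode must be 'resample' or 'discard'")


def core_mass_fraction(track: TrackModel) -> float:
    """Probability that a lesion lands in the core, ∫₀^Rc D(ρ)ρ dρ / ∫₀^Rp.

    With the continuous profile the 2-D radial density ∝ D(ρ)·ρ carries mass
    R_c²/2 in the core and R_c²·ln(R_p/R_c) in the penumbra, giving
    0.5 / (0.5 + ln(R_p/R_c)).
    """
    return 0.5 / (0.5 + math.log(track.r_penumbra_um / track.r_core_um))


def radial_cdf(track: TrackModel, rho: np.ndarray) -> np.ndarray:
    """CDF of the radial offset: quadratic in the core, log in the penumbra."""
    rho = np.asarray(rho, float)
    fc = core_mass_fraction(track)
    rc, rp = track.r_core_um, track.r_penumbra_um
    out = np.where(
        rho <= rc,
        fc * (rho / rc) ** 2,
        fc + (1 - fc) * np.log(np.maximum(rho, rc) / rc) / math.log(rp / rc),
    )
    return np.clip(out, 0.0, 1.0)


def sample_radial_offset(
    track: TrackModel, rng: np.random.Generator, size: int | None = None
) -> np.ndarray | float:
    """Inverse-CDF draw of the radial distance ρ from the track centre."""
    u = rng.uniform(size=1 if size is None else size)
    fc = core_mass_fraction(track)
    rc, rp = track.r_core_um, track.r_penumbra_um
    rho = np.where(
        u < fc,
        rc * np.sqrt(u / fc),
        rc * np.exp((u - fc) / (1 - fc) * math.log(rp / rc)),
    )
    return float(rho[0]) if size is None else rho


def sample_track_count(micro: MicrodosimetrySpec, rng: np.random.Generator) -> int:
    """Number of traversals ν ~ Poisson(D/z_F)."""
    return int(rng.poisson(micro.mean_events))


def _place_around(
    center: np.ndarray,
    count: int,
    track: TrackModel,
    domain: Domain,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Radial placement of ``count`` lesions around one 2-D track centre."""
    if count == 0:
        return np.empty((0, 2))
    if domain.dimension != 2:
        raise ValueError("amorphous-track placement requires a 2-D (disk) nucleus")
    def draw(n: int) -> tuple[np.ndarray, np.ndarray]:
        rho = sample_radial_offset(track, rng, size=n)
        phi = rng.uniform(0.0, 2 * np.pi, size=n)
        pts = center + np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])
        return pts, domain.contains(pts)

    if track.boundary_mode == "discard":
        pts, inside = draw(count)
        return pts[inside]
    out = np.empty((count, 2))
    filled = 0
    for _ in range(max_tries):
        pts, inside = draw(count - filled)
        kept = pts[inside]
        out[filled : filled + len(kept)] = kept
        filled += len(kept)
        if filled == count:
            return out
    raise RuntimeError("radial placement failed to land inside the nucleus")


def generate_initial_damage(
    micro: MicrodosimetrySpec,
    track: TrackModel,
    domain: Domain,
    rng: np.random.Generator,
    return_track_ids: bool = False,
):
    """Sample the t = 0 lesion configuration for an instantaneous dose D.

    Steps: draw ν ~ Poisson(D/z_F) traversals, place their centres uniformly
    on the nucleus, draw z_i ~ f₁ per traversal, draw ξ^X_i ~ Poisson(κ·z_i)
    and ξ^Y_i ~ Poisson(λ·z_i) lesion counts, and place each lesion at the
    track centre plus an amorphous-track radial offset with uniform angle.
    """
    nu = sample_track_count(micro, rng)
    centers = domain.uniform_sample(rng, size=nu) if nu else np.empty((0, domain.dimension))
    z = micro.f1.sample(rng, nu)
    xi_x = rng.poisson(micro.kappa_per_gy * z) if nu else np.empty(0, int)
    xi_y = rng.poisson(micro.lambda_per_gy * z) if nu else np.empty(0, int)
    x_parts, y_parts, tx, ty = [], [], [], []
    for i in range(nu):
        px = _place_around(centers[i], int(xi_x[i]), track, domain, rng)
        py = _place_around(centers[i], int(xi_y[i]), track, domain, rng)
        x_parts.append(px)
        y_parts.append(py)
        tx.append(np.full(len(px), i))
        ty.append(np.full(len(py), i))
    xq = np.vstack(x_parts) if x_parts else np.empty((0, domain.dimension))
    yq = np.vstack(y_parts) if y_parts else np.empty((0, domain.dimension))
    state = SystemState.from_positions(xq, yq)
    if not return_track_ids:
        return state
    track_ids = np.concatenate(tx + ty) if (tx or ty) else np.empty(0, int)
    return state, track_ids


# ---------------------------------------------------------------------------
# specific-energy distributions and the initial count pmf

def multi_event_distribution(
    f1: F1Spectrum,
    z_grid: np.ndarray,
    nu: int | None = None,
    dose: float | None = None,
) -> tuple[np.ndarray, float]:
    """ν-fold convolution f_ν of f₁, or the Poisson-ν dose mixture f(z|D).

    ``z_grid`` must be uniform, start at 0 and resolve f₁ (mass loss beyond
    the grid < 1e−6).  Returns the density on the grid plus the probability
    atom at z = 0 (the ν = 0 no-event case; zero when ``nu`` is given).
    The returned density integrates to 1 − atom within 1e−6.
    """
    from scipy.signal import fftconvolve

    z = np.asarray(z_grid, float)
    dz = z[1] - z[0]
    if abs(z[0]) > 1e-12 or np.max(np.abs(np.diff(z) - dz)) > 1e-9 * dz:
        raise ValueError("z_grid must be uniform and start at 0")
    masses = f1.cell_masses(z)
    loss = 1.0 - masses.sum()
    if loss > 1e-6:
        raise ValueError(f"grid too coarse/short for f1: mass loss {loss:.3e}")
    masses = masses / masses.sum()

    if nu is not None:
        if nu < 1:
            raise ValueError("nu must be >= 1")
        out = masses.copy()
        for _ in range(nu - 1):
            out = fftconvolve(out, masses)[: len(z)]
        return out / dz, 0.0

    if dose is None:
        raise ValueError("give either nu or dose")
    m1 = dose / f1.z_f_gy
    nu_max = int(stats.poisson.ppf(1 - 1e-9, m1)) + 1 if m1 > 0 else 0
    weights = stats.poisson.pmf(np.arange(nu_max + 1), m1)
    mix = np.zeros_like(z)
    f_nu = masses.copy()
    for n in range(1, nu_max + 1):
        if n > 1:
            f_nu = fftconvolve(f_nu, masses)[: len(z)]
        mix += weights[n] * f_nu
    return mix / dz, float(weights[0])


def p0_pmf(
    micro: MicrodosimetrySpec,
    x_max: int,
    y_max: int,
    z_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Joint pmf of the initial (x sub-lethal, y lethal) lesion counts.

    Mixes Poisson(κz) × Poisson(λz) over the multi-event specific-energy
    distribution at dose D — the microdosimetric Neyman-type law.  For the
    delta spectrum the ν-sum is evaluated exactly; otherwise the z-mixture
    is integrated on ``z_grid``.  Returns ``(pmf[x, y], truncation deficit)``.
    """
    x = np.arange(x_max + 1)
    y = np.arange(y_max + 1)
    m1 = micro.mean_events
    if micro.f1.kind == "delta":
        nu_max = int(stats.poisson.ppf(1 - 1e-12, m1)) + 1 if m1 > 0 else 0
        pmf = np.zeros((x_max + 1, y_max + 1))
        for n in range(nu_max + 1):
            w = stats.poisson.pmf(n, m1)
            zx = micro.kappa_per_gy * n * micro.z_f_gy
            zy = micro.lambda_per_gy * n * micro.z_f_gy
            pmf += w * np.outer(stats.poisson.pmf(x, zx), stats.poisson.pmf(y, zy))
    else:
        if z_grid is None:
            z_hi = (m1 + 10 * math.sqrt(max(m1, 1.0))) * micro.z_f_gy * 3
            z_grid = np.linspace(0.0, z_hi, 4096)
        mix, atom = multi_event_distribution(micro.f1, z_grid, dose=micro.dose_gy)
        dz = z_grid[1] - z_grid[0]
        px = stats.poisson.pmf(x[:, None], micro.kappa_per_gy * z_grid[None, :])
        py = stats.poisson.pmf(y[:, None], micro.lambda_per_gy * z_grid[None, :])
        pmf = np.einsum("xz,yz,z->xy", px, py, mix) * dz
        pmf[0, 0] += atom
    deficit = float(1.0 - pmf.sum())
    if deficit > 1e-6:
        import warnings

        warnings.warn(f"p0_pmf truncation deficit {deficit:.3e} exceeds 1e-6")
    return pmf, deficit


# ---------------------------------------------------------------------------
# protracted irradiation

@dataclass(frozen=True)
class ProtractedSpec:
    """Poisson damage-event process: rate ḋ [events/h] on [0, T_irr]."""

    dose_rate_events_per_h: float
    t_irr_h: float

    def __post_init__(self) -> None:
        if self.dose_rate_events_per_h < 0 or not math.isfinite(self.dose_rate_events_per_h):
            raise ValueError("event rate must be finite and nonnegative")
        if self.t_irr_h < 0:
            raise ValueError("irradiation period must be nonnegative")

    @classmethod
    def from_dose(cls, dose_gy: float, t_irr_h: float, z_f_gy: float) -> "ProtractedSpec":
        """ḋ = D / (T_irr · z_F): the event rate delivering dose D over T_irr."""
        return cls(dose_gy / (t_irr_h * z_f_gy), t_irr_h)


def protracted_schedule(
    prot: ProtractedSpec, rng: np.random.Generator
) -> np.ndarray:
    """Sorted event times of the homogeneous Poisson process on [0, T_irr]."""
    n = rng.poisson(prot.dose_rate_events_per_h * prot.t_irr_h)
    return np.sort(rng.uniform(0.0, prot.t_irr_h, size=n))


def sample_dose_event(
    micro: MicrodosimetrySpec,
    track: TrackModel,
    domain: Domain,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One traversal: uniform track centre, z ~ f₁, Poisson lesion counts,
    amorphous-track radial placement.  Returns (X positions, Y positions)."""
    center = domain.uniform_sample(rng)
    z = float(micro.f1.sample(rng, 1)[0])
    xi_x = int(rng.poisson(micro.kappa_per_gy * z))
    xi_y = int(rng.poisson(micro.lambda_per_gy * z))
    xq = _place_around(center, xi_x, track, domain, rng)
    yq = _place_around(center, xi_y, track, domain, rng)
    return xq, yq


@dataclass(frozen=True)
class ProtractedIrradiation:
    """Bundle consumed by the simulator: schedule + per-event damage law."""

    protracted: ProtractedSpec
    micro: MicrodosimetrySpec
    track: TrackModel = field(default_factory=TrackModel)

    def schedule(self, rng: np.random.Generator) -> np.ndarray:
        return protracted_schedule(self.protracted, rng)

    def sample_event(self, domain: Domain, rng: np.random.Generator):
        return sample_dose_event(self.micro, self.track, domain, rng)
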