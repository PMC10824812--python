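"""Reaction rates, spatial interaction kernels, and placement measures.

Three jump channels act on sub-lethal lesions X:

* repair   X → ∅         at per-lesion rate r(q, v)
* death    X → Y         at per-lesion rate a(q, v)
* pairwise X + X → Y/∅   at per-pair rate b(q1, q2); the outcome is lethal
  with probability p (else both lesions are removed — "complete exchange")

where v = ⟨Γ_q, ν⟩ is a kernel-weighted local lesion count.  The crowding
forms used in the numerical preset are

    r(q, v) = r0 · (1 + 1/(v + 1))        ∈ [r0, 2·r0]
    a(q, v) = a0 · (1 − 1/(v + 1))        ∈ [0, a0]

with v the number of other lesions strictly within a ball of radius r_d:
crowded damage is repaired more slowly and is more likely to turn lethal.
Pair rates may be constant, a step within r_d, a Gaussian of the separation,
or a two-Gaussian sum with an enhanced short-range core and a fat tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .geometry import Domain
from .state import TYPE_X, TYPE_Y, SystemState

__all__ = [
    "KernelSpec",
    "RateModel",
    "PlacementA",
    "PlacementB",
    "ChannelRates",
    "local_count",
    "repair_rate",
    "death_rate",
    "pair_rate",
    "interaction_is_lethal",
    "total_channel_rates",
    "sample_target",
    "place_a",
    "place_b",
]

_TYPE_BY_NAME = {"X": TYPE_X, "Y": TYPE_Y}


@dataclass(frozen=True)
class KernelSpec:
    """Spatial kernel Γ_q weighting lesions around a focal position.

    kind:
        ``zero``            Γ ≡ 0 (rates become position-independent),
        ``ball``            1{|q − q̄| < r_d} (strict inequality),
        ``gaussian``        exp(−|q − q̄|²/2ε²),
        ``double_gaussian`` w1·exp(−|·|²/2ε1²) + w2·exp(−|·|²/2ε2²).
    include_focal:
        whether the focal lesion itself contributes to its own count
        (default False — a lesion responds to *other* lesions).
    types_counted:
        which lesion marks contribute (default both X and Y).
    """

    kind: str = "ball"
    r_d_um: float = 0.5
    eps_um: float = 0.5
    eps2_um: float = 1.0
    weight1: float = 1.0
    weight2: float = 0.0
    include_focal: bool = False
    types_counted: tuple[str, ...] = ("X", "Y")

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "ball", "gaussian", "double_gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "ball" and not self.r_d_um > 0:
            raise ValueError("ball kernel radius must be positive")
        if self.kind in ("gaussian", "double_gaussian") and not self.eps_um > 0:
            raise ValueError("gaussian kernel width must be positive")
        if self.kind == "double_gaussian" and (
            self.weight1 < 0 or self.weight2 < 0 or not self.eps2_um > 0
        ):
            raise ValueError("double_gaussian needs nonnegative weights, positive widths")

    def weights(self, distances: np.ndarray) -> np.ndarray:
        d = np.asarray(distances, float)
        if self.kind == "zero":
            return np.zeros_like(d)
        if self.kind == "ball":
            return (d < self.r_d_um).astype(float)
        if self.kind == "gaussian":
            return np.exp(-(d**2) / (2.0 * self.eps_um**2))
        return self.weight1 * np.exp(-(d**2) / (2.0 * self.eps_um**2)) + (
            self.weight2 * np.exp(-(d**2) / (2.0 * self.eps2_um**2))
        )


@dataclass(frozen=True)
class PlacementA:
    """Sampling measure m^a for the position of the Y lesion made by death.

    ``in_place`` (Dirac at the dying lesion), ``uniform_ball`` or
    ``gaussian_ball`` within distance eps_um, re-drawn until inside Q̄.
    """

    kind: str = "in_place"
    eps_um: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("in_place", "uniform_ball", "gaussian_ball"):
            raise ValueError(f"unknown placement kind {self.kind!r}")
        if self.kind != "in_place" and not self.eps_um > 0:
            raise ValueError("placement radius must be positive")


@dataclass(frozen=True)
class PlacementB:
    """Sampling measure m^b for the Y lesion made by a lethal pair event.

    The support is the segment between the interacting lesions:
    ``midpoint``, ``endpoint`` (j = 0 or 1), ``discrete`` (positions
    α_j·q1 + (1−α_j)·q2 with probabilities p_j), or ``segment_uniform``
    (α ~ U(0, 1)).
    """

    kind: str = "midpoint"
    endpoint_j: int = 0
    alphas: tuple[float, ...] = ()
    probs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("midpoint", "endpoint", "discrete", "segment_uniform"):
            raise ValueError(f"unknown placement kind {self.kind!r}")
        if self.kind == "endpoint" and self.endpoint_j not in (0, 1):
            raise ValueError("endpoint_j must be 0 or 1")
        if self.kind == "discrete":
            if len(self.alphas) != len(self.probs) or not self.alphas:
                raise ValueError("discrete placement needs matching alphas/probs")
            if abs(sum(self.probs) - 1.0) > 1e-12:
                raise ValueError("discrete placement probabilities must sum to 1")
            if any(a < 0 or a > 1 for a in self.alphas):
                raise ValueError("alphas must lie in [0, 1]")


@dataclass(frozen=True)
class RateModel:
    """Base rates, functional forms, kernels and placements for all channels.

    ``density_scale`` is the large-population parameter K: kernel-weighted
    local counts are divided by it before entering the crowding forms
    (identity at the default K = 1).
    """

    r0: float = 4.0
    a0: float = 0.1
    b0: float = 0.1
    p: float | Callable[[np.ndarray, np.ndarray], float] = 1.0
    repair_form: str = "constant"     # constant | crowding
    death_form: str = "constant"      # constant | crowding
    pair_form: str = "step"           # constant | step | gaussian | double_gaussian
    pair_r_d_um: float = 0.5
    pair_eps_um: float = 0.5
    pair_eps2_um: float = 1.0
    pair_b1: float = 1.0
    pair_b2: float = 0.0
    repair_kernel: KernelSpec = field(default_factory=KernelSpec)
    death_kernel: KernelSpec = field(default_factory=KernelSpec)
    placement_a: PlacementA = field(default_factory=PlacementA)
    placement_b: PlacementB = field(default_factory=PlacementB)
    density_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.r0, self.a0, self.b0) < 0:
            raise ValueError("base rates must be nonnegative")
        for form, name in ((self.repair_form, "repair"), (self.death_form, "death")):
            if form not in ("constant", "crowding"):
                raise ValueError(f"unknown {name} form {form!r}")
        if self.pair_form not in ("constant", "step", "gaussian", "double_gaussian"):
            raise ValueError(f"unknown pair form {self.pair_form!r}")
        if isinstance(self.p, (int, float)) and not 0.0 <= self.p <= 1.0:
            raise ValueError("interaction death probability p must lie in [0, 1]")
        if not self.density_scale >= 1:
            raise ValueError("density_scale must be >= 1")

    @property
    def is_position_independent(self) -> bool:
        """True when every channel rate is independent of lesion positions."""
        forms_const = self.repair_form == "constant" and self.death_form == "constant"
        return forms_const and self.pair_form == "constant"

    def p_value(self, q1: np.ndarray, q2: np.ndarray) -> float:
        val = self.p(q1, q2) if callable(self.p) else float(self.p)
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"p({q1}, {q2}) = {val} outside [0, 1]")
        return val


# ---------------------------------------------------------------------------
# local counts and per-channel rates

def local_count(
    q: np.ndarray,
    state: SystemState,
    kernel: KernelSpec,
    focal_id: int | None = None,
) -> float:
    """Kernel-weighted lesion count ⟨Γ_q, ν⟩ around position ``q``.

    The focal lesion (identified by ``focal_id``) is excluded unless the
    kernel says otherwise.
    """
    if kernel.kind == "zero" or state.n_total == 0:
        return 0.0
    codes = {_TYPE_BY_NAME[t] for t in kernel.types_counted}
    mask = np.isin(state.types, list(codes))
    if focal_id is not None and not kernel.include_focal:
        mask &= state.ids != focal_id
    if not mask.any():
        return 0.0
    d = np.linalg.norm(state.positions[mask] - np.asarray(q, float), axis=1)
    return float(kernel.weights(d).sum())


def _crowding(base: float, v: np.ndarray | float, sign: int) -> np.ndarray | float:
    return base * (1.0 + sign / (np.asarray(v, float) + 1.0))


def repair_rate(q: np.ndarray, state: SystemState, model: RateModel,
                focal_id: int | None = None) -> float:
    """Per-lesion repair rate r(q, v) [h⁻¹]."""
    if model.repair_form == "constant":
        return model.r0
    v = local_count(q, state, model.repair_kernel, focal_id) / model.density_scale
    return float(_crowding(model.r0, v, +1))


def death_rate(q: np.ndarray, state: SystemState, model: RateModel,
               focal_id: int | None = None) -> float:
    """Per-lesion death (X → Y) rate a(q, v) [h⁻¹]."""
    if model.death_form == "constant":
        return model.a0
    v = local_count(q, state, model.death_kernel, focal_id) / model.density_scale
    return float(_crowding(model.a0, v, -1))


def pair_rate(q1: np.ndarray, q2: np.ndarray, model: RateModel) -> float:
    """Per-unordered-pair interaction rate b(q1, q2) [h⁻¹]; symmetric."""
    d = float(np.linalg.norm(np.asarray(q1, float) - np.asarray(q2, float)))
    return float(_pair_rate_from_distance(np.array([d]), model)[0])


def _pair_rate_from_distance(d: np.ndarray, model: RateModel) -> np.ndarray:
    if model.pair_form == "constant":
        return np.full_like(d, model.b0, dtype=float)
    if model.pair_form == "step":
        return model.b0 * (d < model.pair_r_d_um)
    g1 = model.pair_b1 / np.sqrt(2 * np.pi * model.pair_eps_um**2) * np.exp(
        -(d**2) / (2 * model.pair_eps_um**2)
    )
    if model.pair_form == "gaussian":
        return g1
    g2 = model.pair_b2 / np.sqrt(2 * np.pi * model.pair_eps2_um**2) * np.exp(
        -(d**2) / (2 * model.pair_eps2_um**2)
    )
    return g1 + g2


def interaction_is_lethal(q1: np.ndarray, q2: np.ndarray, model: RateModel,
                          rng: np.random.Generator) -> bool:
    """Bernoulli(p(q1, q2)) outcome of a pair interaction: lethal or exchange."""
    return bool(rng.uniform() <= model.p_value(q1, q2))


# ---------------------------------------------------------------------------
# channel totals and categorical target sampling

@dataclass
class ChannelRates:
    """Channel totals r̄, ā, b̄ plus the per-target tables used for sampling.

    ``pair_uniform`` marks the homogeneous case where every unordered X–X
    pair carries the same rate and pairs are sampled uniformly.
    """

    r_bar: float
    a_bar: float
    b_bar: float
    x_indices: np.ndarray                 # indices into state arrays, X lesions
    repair_rates: np.ndarray | None       # per X lesion; None ⇒ uniform r0
    death_rates: np.ndarray | None
    pair_pairs: np.ndarray | None         # (m, 2) index pairs into x_indices
    pair_rates: np.ndarray | None
    pair_uniform: bool

    @property
    def total(self) -> float:
        return self.r_bar + self.a_bar + self.b_bar


def total_channel_rates(state: SystemState, model: RateModel) -> ChannelRates:
    """Channel totals over the current configuration (pairs counted once).

    r̄ = Σ_i r(q_i, v_i),  ā = Σ_i a(q_i, v_i)  over X lesions, and
    b̄ = Σ_{i1 < i2} b(q_i1, q_i2) over unordered X–X pairs.
    """
    x_idx = np.flatnonzero(state.types == TYPE_X)
    n = len(x_idx)
    if n == 0:
        return ChannelRates(0.0, 0.0, 0.0, x_idx, None, None, None, None, True)
    xq = state.positions[x_idx]

    if model.repair_form == "constant" and model.death_form == "constant":
        rep = None
        dth = None
        r_bar = model.r0 * n
        a_bar = model.a0 * n
    else:
        counted = {_TYPE_BY_NAME[t] for t in model.repair_kernel.types_counted}
        mask = np.isin(state.types, list(counted))
        targets = state.positions[mask]
        target_ids = state.ids[mask]
        dmat = cdist(xq, targets)
        w = model.repair_kernel.weights(dmat)
        if not model.repair_kernel.include_focal:
            w[state.ids[x_idx][:, None] == target_ids[None, :]] = 0.0
        v = w.sum(axis=1) / model.density_scale
        rep = (
            np.full(n, model.r0)
            if model.repair_form == "constant"
            else _crowding(model.r0, v, +1)
        )
        # the death kernel is evaluated with the same ball unless it differs
        if model.death_kernel == model.repair_kernel:
            v_d = v
        else:
            counted_d = {_TYPE_BY_NAME[t] for t in model.death_kernel.types_counted}
            mask_d = np.isin(state.types, list(counted_d))
            dmat_d = cdist(xq, state.positions[mask_d])
            w_d = model.death_kernel.weights(dmat_d)
            if not model.death_kernel.include_focal:
                w_d[state.ids[x_idx][:, None] == state.ids[mask_d][None, :]] = 0.0
            v_d = w_d.sum(axis=1) / model.density_scale
        dth = (
            np.full(n, model.a0)
            if model.death_form == "constant"
            else _crowding(model.a0, v_d, -1)
        )
        r_bar = float(rep.sum())
        a_bar = float(dth.sum())

    if model.pair_form == "constant" or n < 2:
        b_bar = model.b0 * n * (n - 1) / 2.0
        return ChannelRates(r_bar, a_bar, b_bar, x_idx, rep, dth, None, None, True)

    dvec = pdist(xq)
    rates = _pair_rate_from_distance(dvec, model)
    nz = np.flatnonzero(rates > 0)
    iu, ju = np.triu_indices(n, k=1)
    pairs = np.column_stack([iu[nz], ju[nz]])
    pr = rates[nz]
    return ChannelRates(
        r_bar, a_bar, float(pr.sum()), x_idx, rep, dth, pairs, pr, False
    )


def sample_target(channel: str, rates: ChannelRates, rng: np.random.Generator):
    """Draw the lesion (or pair) that fired, ∝ its individual rate.

    Returns an index into the state arrays for repair/death, or a pair of
    indices for the pairwise channel.
    """
    n = len(rates.x_indices)
    if channel == "repair":
        if rates.r_bar <= 0:
            raise RuntimeError("repair channel fired with zero total rate")
        if rates.repair_rates is None:
            k = rng.integers(n)
        else:
            k = _categorical(rates.repair_rates, rng)
        return int(rates.x_indices[k])
    if channel == "death":
        if rates.a_bar <= 0:
            raise RuntimeError("death channel fired with zero total rate")
        if rates.death_rates is None:
            k = rng.integers(n)
        else:
            k = _categorical(rates.death_rates, rng)
        return int(rates.x_indices[k])
    if channel == "pair":
        if rates.b_bar <= 0:
            raise RuntimeError("pair channel fired with zero total rate")
        if rates.pair_uniform:
            i = rng.integers(n)
            j = rng.integers(n - 1)
            if j >= i:
                j += 1
            return int(rates.x_indices[i]), int(rates.x_indices[j])
        k = _categorical(rates.pair_rates, rng)
        i, j = rates.pair_pairs[k]
        return int(rates.x_indices[i]), int(rates.x_indices[j])
    raise ValueError(f"unknown channel {channel!r}")


def _categorical(weights: np.ndarray, rng: np.random.Generator) -> int:
    total = weights.sum()
    if total <= 0:
        raise RuntimeError("all-zero rate table")
    u = rng.uniform(0.0, total)
    return int(np.searchsorted(np.cumsum(weights), u))


# ---------------------------------------------------------------------------
# placement measures

def place_a(
    q1: np.ndarray,
    placement: PlacementA,
    domain: Domain,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Sample the position of the Y lesion created by death at ``q1``.

    Ball placements are re-drawn until inside Q̄ (truncation renormalises
    the density over the domain).
    """
    q1 = np.asarray(q1, float)
    if placement.kind == "in_place":
        return q1.copy()
    d = domain.dimension
    for _ in range(max_tries):
        if placement.kind == "uniform_ball":
            step = rng.uniform(-placement.eps_um, placement.eps_um, size=d)
            if np.linalg.norm(step) >= placement.eps_um:
                continue
        else:  # gaussian_ball: bell-shaped, truncated to the open ball
            step = rng.normal(0.0, placement.eps_um / 2.0, size=d)
            if np.linalg.norm(step) >= placement.eps_um:
                continue
        q = q1 + step
        if domain.contains(q):
            return q
    raise RuntimeError("placement rejection sampling failed to find a point in Q")


def place_b(
    q1: np.ndarray,
    q2: np.ndarray,
    placement: PlacementB,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the Y position on the segment between an interacting pair.

    The segment lies inside the convex Q̄, so no boundary handling is needed.
    """
    q1 = np.asarray(q1, float)
    q2 = np.asarray(q2, float)
    if placement.kind == "midpoint":
        alpha = 0.5
    elif placement.kind == "endpoint":
        alpha = 1.0 if placement.endpoint_j == 0 else 0.0
    elif placement.kind == "discrete":
        j = _categorical(np.asarray(placement.probs, float), rng)
        alpha = placement.alphas[j]
    else:
        alpha = rng.uniform()
    return alpha * q1 + (1.0 - alpha) * q2
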