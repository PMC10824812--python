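# radlesion

Spatial stochastic simulation of radiation-induced DNA damage kinetics and
repair in a cell nucleus, for computational radiobiologists studying how the
spatial clustering of lesions shapes repair and cell inactivation — e.g. in
ion-beam radiotherapy planning, space radioprotection, or FLASH-effect
modelling.

## The model

The state is a marked point measure ν(t) = Σᵢ δ_{(qᵢ, sᵢ)} over positions
qᵢ in a closed convex nucleus Q (a disk of radius 5 μm by default) and marks
sᵢ ∈ {X, Y}: **X** are sub-lethal (repairable) lesions, **Y** lethal ones.
Between jumps each lesion follows a reflected Brownian motion; jumps occur
through four channels:

* **repair** X → ∅ at rate r(q, v),
* **death**  X → Y at rate a(q, v),
* **pairwise interaction** X + X → Y with probability p (a lethal cluster)
  or → ∅ with probability 1 − p (complete exchange), at per-pair rate
  b(q₁, q₂),
* **dose** ∅ → ξ^X X + ξ^Y Y at event rate ḋ = D/(T_irr·z_F) during
  protracted irradiation.

Here v = ⟨Γ_q, ν⟩ is a kernel-weighted local lesion count: in the default
crowding forms r(q, v) = r·(1 + 1/(v+1)) and a(q, v) = a·(1 − 1/(v+1)),
with v the number of other lesions within r_d = 0.5 μm, crowded damage
repairs more slowly and converts to lethal more readily.  The pair rate is
a step b·1{|q₁−q₂| < r_d} (Gaussian and double-Gaussian forms are also
available), and the new lethal lesion is placed at the midpoint of the pair.

Initial damage is microdosimetric: a dose D is delivered by ν ~
Poisson(D/z_F) particle traversals placed uniformly on the nucleus; each
deposits a specific energy z ~ f₁(z) and creates Poisson(κz) sub-lethal and
Poisson(λz) lethal lesions, placed radially by the amorphous-track profile
(uniform core to R_c, 1/ρ² penumbra to R_p).  The resulting count law is a
microdosimetric generalisation of the Neyman (Poisson-of-Poissons)
distribution.

The non-spatial limits are included as verification oracles: the
microdosimetric master equation for p(t, y, x), an exact Gillespie chain,
the mean-lesion ODEs (dȳ = a·x̄ + b·x̄², dx̄ = −(a+r)·x̄ − 2b·x̄²), and the
spatially homogeneous mean-field limit with a protracted source, to which
the rescaled process ν^K/K converges with fluctuation variance ∝ 1/K.

## Worked example

```python
import numpy as np
from radlesion.config import preset_carbon_10gy
from radlesion.dynamics import SchedulerConfig, simulate
from radlesion.irradiation import generate_initial_damage
from radlesion.reference import MMEConfig, mme_solve, survival_probability

cfg = preset_carbon_10gy()          # 10 Gy carbon ions, z_F = 0.04 Gy
rng = np.random.default_rng(7)
initial = generate_initial_damage(cfg.micro, cfg.track, cfg.domain, rng)
print(f"initial damage: {initial.n_x} sub-lethal, {initial.n_y} lethal lesions")
traj = simulate(initial, cfg.domain, cfg.model, cfg.diffusion,
                SchedulerConfig(t_end=1.0), rng=rng)
print(f"after 1 h: {traj.final.n_x} sub-lethal, {traj.final.n_y} lethal "
      f"({len(traj.events)} events)")

mme = MMEConfig(r=4.0, a=0.1, beta=0.05, p=1.0, x_max=30)
s = survival_probability(mme_solve(mme, (0, 30), np.array([1.0, 8.0])))
print(f"well-mixed survival S(1 h) = {s[0]:.4f}, S(8 h) = {s[1]:.4f}")
```

prints

```
initial damage: 548 sub-lethal, 6 lethal lesions
after 1 h: 2 sub-lethal, 32 lethal (529 events)
well-mixed survival S(1 h) = 0.0041, S(8 h) = 0.0041
```

The 10 Gy field creates ≈ κ·D = 500 sub-lethal lesions; after an hour of
kinetics nearly all have repaired or converted, leaving 32 lethal lesions
(this cell does not survive).  The master-equation example shows survival
saturating once every sub-lethal lesion has resolved.

A command-line interface mirrors the library
(`radlesion simulate|irradiate|mme|meanfield|scaling`), reading TOML
configurations (`preset = "carbon_10gy"`) and writing CSV outputs with a
JSON sidecar recording the seed and config hash.

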