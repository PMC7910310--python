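# cdcpol

Bulk–surface reaction–diffusion modelling of Cdc42-driven cell polarisation.

During polarisation (e.g. bud-site selection in budding yeast), the active,
GTP-bound form of the GTPase Cdc42 accumulates in a single membrane patch —
the *pole*.  `cdcpol` implements a dimensionless, mass-conserved
activator–inhibitor model of this process for researchers studying pattern
formation in cell biology: the cell is the unit ball, the membrane carries the
active form *u* and the inactive form *v*, and a well-mixed cytosolic pool *V*
(the GDI-bound form) couples to the membrane through a conservation
functional:

    ∂u/∂τ = Δ_Γ u + γ f(u, v)                      f(u, v) = c2·v − u + u²·v
    ∂v/∂τ = d Δ_Γ v + γ(−f(u, v) + q(u, v, V))     q(u, v, V) = c1·V·(c_max − (u+v)) − c_minus1·v
    V[u + v] = V0 − (1/|Ω|) ∫_Γ (u + v) ds

The package provides:

* **Steady-state analysis** (`cdcpol.homogeneous`) — all positive steady
  states via a degree-6 polynomial, trapping-region and necessary-condition
  checks, stiff ODE integration of the well-mixed system.
* **Turing classification** (`cdcpol.turing`) — dispersion relation over
  spherical-harmonic degrees (k² = l(l+1)), classic vs non-classic
  diffusion-driven instability, and parameter-plane region maps.  *Classic*
  instability needs unequal membrane diffusivities (d > 1); *non-classic*
  instability arises from the bulk–surface mass coupling and persists at
  d = 1.
* **Surface simulation** (`cdcpol.surface_sim`) — IMEX finite-element solver
  (cotangent Laplace–Beltrami, lumped mass) on an icosphere, exact discrete
  mass conservation, seeded noisy initial conditions, stationarity-based
  termination.
* **Pole quantification** (`cdcpol.pole_metrics`) — threshold/connected-
  component pole recognition, pole count and relative area, u_max/u_min,
  polarisation time, and multi-seed sweep quantiles.
* **CLI** (`cdcpol`) — `steady`, `classify`, `map`, `simulate`, `sweep`
  subcommands with flat key=value config files, CSV/JSON/VTK/PNG output and
  reproducible run manifests.

## Worked example

```python
import numpy as np
from cdcpol import (ModelParams, SimOptions, find_steady_states,
                    classify_params, simulate_to_polarisation)

params = ModelParams(c1=0.05, c_minus1=0.04, c2=0.45,
                     c_max=3.0, V0=6.0, gamma=25.0, d=10.0)

for ss in find_steady_states(params):
    print(f"u*={ss.u_star:.4f} v*={ss.v_star:.4f} V*={ss.V_star:.4f} "
          f"stable={ss.homogeneous_stable}")
print("classification:", classify_params(params))

traj, report = simulate_to_polarisation(params, SimOptions(subdivisions=4, seed=1))
print(f"poles={report.pole_count} area={report.relative_pole_area:.3f} "
      f"u_max={report.u_max:.3f} u_min={report.u_min:.3f} "
      f"tau_final={report.tau_final:.2f}")
```

prints

```
u*=1.2263 v*=0.6276 V*=0.4381 stable=True
u*=2.7404 v*=0.3443 V*=-3.2539 stable=False
classification: classic
poles=1 area=0.260 u_max=3.657 u_min=0.400 tau_final=7.20
```

The first steady state is the biologically relevant one (positive cytosolic
concentration, stable without diffusion, inside the necessary-condition
bracket (√c2, min(c_max, V0/3))).  The parameter set is a *classic* Turing
point: with d = 10 a band of spherical-harmonic modes is unstable, and the
simulation grows a single pole covering ≈ 26% of the membrane where the
active-form concentration peaks at u_max ≈ 3.7 (roughly nine times the
minimum).  Increasing γ (larger cells — γ scales with membrane area) admits
more unstable modes and hence multiple poles; increasing d sharpens the pole.

Same from the shell:

```sh
cdcpol classify --c1 0.05 --c-1 0.04 --c2 0.45 --d 10      # -> classic
cdcpol simulate --c1 0.05 --c-1 0.04 --c2 0.45 --subdivisions 4 --seed 1 --outdir run1
cdcpol map --resolution 100 --outdir map_out               # region map (CSV + PNG)
```

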