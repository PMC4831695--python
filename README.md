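# uparsim

A free-boundary PDE model of recurrent breast-tumor growth centered on the
plasminogen activation system (uPA, its receptor uPAR, and the inhibitor
PAI-1), with:

* a **parameter layer** that re-derives every estimated rate constant from
  its molecular-weight, half-life and steady-state anchors, so the baseline
  table is auditable rather than hard-coded;
* a **radially symmetric moving-mesh simulator** for the 17 coupled
  reaction–diffusion–advection fields (9 cytokines/proteases, 4 cell
  species, oxygen, MMP/TIMP, ECM) with a free boundary moved by the tissue
  velocity that enforces the constant-total-cell-density constraint;
* **biomarker maps**: the forward surfaces `R(R0, t)` and total-uPAR-mass
  `U(R0, t)` over a grid of initial radii, plus the inverse lookup from a
  measured uPAR mass at a known time to the initial and current radius;
* **sensitivity analysis**: Latin hypercube sampling over the production
  parameters and partial rank correlation (PRCC) of the day-600 radius.

## CLI

```sh
uparsim params show                 # baseline table with units
uparsim params derive               # tabled vs recomputed derivations
uparsim params validate my.yaml     # schema + positivity validation

uparsim simulate --r0 0.01 --days 600 --scheme implicit-split --out traj.csv
# writes traj.csv (per time/node), traj_summary.csv (R, Ave, TM per time),
# traj.manifest.json (config + parameter hash)

uparsim map build --r0-min 0.01 --r0-max 0.05 --n-r0 17 --days 1000 --out bm
uparsim map invert  --map bm --upar 1e-12 --day 100
uparsim map predict --map bm --r0 0.02 --day 400

uparsim sensitivity run --n 1000 --seed 42 --day 600 --out prcc.csv
```

Exit codes: 0 success, 2 validation/config error, 3 numerical failure,
4 out-of-range query.

## Layout

```
src/uparsim/
  parameters.py    # baseline table + derivation chain (EstimationContext)
  mesh.py          # moving radial mesh, nonuniform stencils, laplacian
  model_core.py    # 17 reaction RHS, chemotaxis, velocity, boundary terms
  solver.py        # explicit (reference) and implicit-split schemes, driver
  observables.py   # Ave/TM, Trajectory, biomarker map build/invert/predict
  sensitivity.py   # Latin hypercube + PRCC
  cli_io.py        # run config, manifests, test fixtures
  cli.py           # click CLI (console script: uparsim)
```

Solver notes: the paper-style explicit scheme is kept for fidelity testing
but its parabolic stability bound (`tau <= min(h)^2 / 2D`) is ~5e-8 day at
baseline diffusivities, so production runs use operator splitting —
positivity-preserving semi-implicit reactions (the MMP/TIMP mutual
depletion reaches ~1e4/day and is intractable explicitly) plus
backward-Euler conservative finite-volume diffusion — which converges to
the explicit trajectory as the step shrinks.
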