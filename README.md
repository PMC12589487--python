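# ggcx-motion

Quantitative analysis of coupled conformational motions in γ-glutamyl
carboxylase (GGCX), the ER membrane enzyme that carboxylates the Glu
residues of vitamin K-dependent proteins such as coagulation factors FIX
and FX. In enhanced-sampling MD the luminal helix H2 (on the
propeptide-binding domain PBD-2) intermittently reorients while the TM5–TM6
"Cap" loop (residues D220–S246), which shields the vitamin K pocket, moves
away from its initial position — and the two motions track each other with
a temporal delay. This package provides the machinery to measure and test
that coupling on any trajectory, plus a synthetic-trajectory generator with
implanted ground truth so every stage is verifiable without cluster-scale
MD.

It is aimed at structural biologists and simulation scientists who have
trajectories (multi-model PDB, or DCD/XTC with an MDAnalysis install) or
deposited coordinate models and want numbers, not pictures.

## What it computes

For a trajectory superposed on a rigid core:

- **cos θ(t)** — cosine of the angle between the helix axis at frame *t*
  and its reference-frame axis. The axis is the principal axis of the
  helix Cα coordinates, signed N→C; cos θ = 1 means unchanged orientation.
- **dr(t)** — Euclidean displacement (Å) of a selection's center of mass
  from its reference-frame position, `dr(t) = ‖COM(t) − COM(t₀)‖`.
- **RMSF per residue** — `RMSF_i = sqrt(mean_t ‖x_i(t) − x̄_i‖²)` about the
  time-mean (or a fixed-frame) position, with an exclusion mask for
  terminal/loop residues, and replicate summaries (mean, min–max spread).
- **RMSD(t)** — per-frame RMSD to a reference frame, fitted or unfitted.
- **Temporal-delay-compensated correlation** — a scan over integer-sample
  lags L computes the Pearson coefficient of the overlapping samples of
  cos θ(t) and dr(t + L); the reported delay optimizes |r| (ties: smallest
  |lag|). A positive lag means dr trails cos θ. Significance comes from a
  circular block-rotation permutation null that preserves autocorrelation.
- **Domain rotation between static structures** — superpose on a shared
  rigid core, then Kabsch on the domain alone; the angle is
  `arccos((trace(R) − 1)/2)`. Plus atom–atom distances by
  (chain, resid, name).

The synthetic generator builds a rigid-core + helix + cap Cα model and
implants a lag-coupled motion pair with a target Pearson correlation ρ,
an Ornstein–Uhlenbeck latent signal, and Gaussian coordinate noise; the
implanted lag, ρ, angles and displacements are returned as ground truth.

## Worked example

```python
from ggcx_motion import (
    SyntheticTruth, gen_template, gen_coupled_trajectory,
    select, align_trajectory, cos_theta_series, dr_series,
    smooth, estimate_lag, lag_significance,
    CORE_EXPR, HELIX_EXPR, CAP_EXPR,
)

truth = SyntheticTruth(lag_ns=45.0, coupling_rho=-0.7, seed=7)
template = gen_template(seed=7)
traj, theta_true, d_true = gen_coupled_trajectory(template, truth)

aligned = align_trajectory(traj, select(template, CORE_EXPR))
cos_theta = cos_theta_series(aligned, select(template, HELIX_EXPR))
dr = dr_series(aligned, select(template, CAP_EXPR))

x, y = smooth(cos_theta, 1.0), smooth(dr, 1.0)
res = estimate_lag(x, y, max_lag_ns=80.0)
p = lag_significance(x, y, res.lag_ns, n_permutations=199, seed=7)
print(f"implanted: lag {truth.lag_ns} ns, rho {truth.coupling_rho}")
print(f"estimated: lag {res.lag_ns:.1f} ns, r {res.r_at_lag:.3f}, "
      f"p = {p:.3f} ({res.n_overlap} overlapping frames)")
```

Output:

```
implanted: lag 45.0 ns, rho -0.7
estimated: lag 45.0 ns, r -0.698, p = 0.005 (1150 overlapping frames)
```

The 160 ns trajectory (1600 frames at 0.1 ns) carries a helix/cap coupling
with correlation −0.7 in which the cap trails the helix by 45 ns. After
rigid-core alignment the lag scan recovers the delay exactly and the
delay-compensated correlation to within sampling error; the permutation
p-value (199 block rotations) is the smallest attainable, 1/200.

The same pipeline runs from the shell:

```sh
ggcx-motion synth trajectory --frames 1600 --dt 0.1 --lag 45 --rho -0.7 \
    --seed 7 --out traj.pdb --truth truth.json
ggcx-motion analyze --config config.yaml
ggcx-motion compare --a model_a.pdb --b model_b.pdb \
    --core "resid 1-199 and name CA" --domain "resid 500-599 and name CA" \
    --distance "A:217:NZ,A:53:CD"
```

`analyze` writes `report.json` (lag, correlations at the chosen lag and at
lag 0, raw and smoothed, p-value, the full lag–correlation curve, RMSF and
RMSD summaries, config echo, version and seed) plus `costheta.csv`,
`dr.csv`, `rmsf.csv` and `rmsd.csv`.

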