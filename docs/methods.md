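# Methods

## The measurement model

The package treats a conformational-coupling question as a time-series
problem on two scalar order parameters derived from an aligned trajectory.
All geometry is measured after superposing every frame on a user-chosen
rigid core (weighted Kabsch, reflection-excluded), because both order
parameters are defined relative to "initial" positions and are meaningless
if global tumbling or drift is left in. The core selection is deliberately
mandatory configuration: which atoms count as rigid is a scientific choice
the software cannot make.

**Helix orientation, cos θ.** The helix axis is the principal axis
(largest-variance singular vector) of the centered helix Cα coordinates,
with the sign fixed so the vector points from the N-terminal-half centroid
toward the C-terminal-half centroid. For an ideal α-helix (1.5 Å rise,
100°/residue) the principal axis coincides with the screw axis up to a
finite-length tilt that decays with helix length; it is the more robust
choice for short helices compared with averaging per-turn vectors. The
order parameter is the dot product with the reference-frame axis, clipped
to [−1, 1]; at the reference frame the value is set to 1 identically.
Degenerate inputs (fewer than 4 points, or no unique principal axis within
a 1e-6 relative singular-value gap) raise, naming the offending frame.
Cα-only is the default atom choice; a selection is free to use backbone
atoms instead.

**Cap displacement, dr.** The Euclidean distance between the selection's
center of mass at frame *t* and at the reference frame. Geometric (equal
weights) by default; mass weighting uses a fixed internal element-mass
table (standard atomic weights) so results cannot drift with an external
dependency, and an element missing from the table is an error rather than
a silently assumed mass.

**RMSF / RMSD.** RMSF is computed per residue from a one-atom-per-residue
selection, about the time-mean position by default (the minimal-variance
reference; a fixed-frame reference is available and is never smaller).
Residue exclusions — terminal stubs, ill-defined loops — are an explicit
list plus a "first *n*" convenience; excluded residues keep their values
and are only masked from summaries, so nothing is hidden. Replicate
profiles are summarized as per-residue mean and min–max spread, with a
mask that is the union of the replicate masks. RMSD to the reference frame
is offered unfitted (measures total excursion in the aligned frame) and
fitted (per-frame Kabsch on the same selection; never larger).

**Delay and correlation.** The delay between cos θ and dr is estimated by
an exhaustive scan of integer-sample lags in ±max_lag: at each lag the
Pearson coefficient of the overlapping samples is computed, and the lag
optimizing the objective (default: largest |r|) is returned. Positive lag
means dr trails cos θ. Peak/valley matching (`find_extrema`, prominence
based) is provided for visual corroboration, not as the estimator. Ties
are broken toward the smallest |lag|, then negative before positive —
parsimony first. One consequence worth knowing: for strictly periodic
signals the true delay is aliased modulo the period, and the tie-break
reports the smallest-magnitude alias.

**Raw vs smoothed.** The scan is typically run on smoothed series and the
pipeline reports both the smoothed and the raw delay-compensated
correlation. Smoothing is a centered moving average (or Savitzky–Golay)
whose edge windows shrink symmetrically — no invented padding values; a
constant series passes through unchanged. The window must be chosen
against the signal's correlation time: wide enough to suppress
frame-to-frame measurement noise, and well below the autocorrelation time
of the motion being measured, otherwise the correlation estimate is
attenuated and its variance inflated. The CLI default of 5 ns is sized for
slowly varying signals on a 160 ns window. Under the synthetic study
conditions (latent correlation time 0.5 ns, below) no window satisfies
both demands — spatial averaging over the helix and cap atoms already
suppresses per-frame measurement noise — so the recovery analyses run the
lag scan on the raw series, and the pipeline always reports raw and
smoothed correlations side by side.

**Significance.** MD frames are autocorrelated, so an i.i.d. shuffle null
is anticonservative. The permutation null here circularly rotates the
overlapped second series by whole blocks (block length defaulting to the
estimated 1/e autocorrelation time), which preserves each series'
autocorrelation exactly while destroying the cross-correlation.
`p = (1 + #{|r_perm| ≥ |r_obs|}) / (n_permutations + 1)`. Rotation offsets
are drawn in +k / n−k pairs, which makes the p-value exactly symmetric
under exchanging the two series when the permutation count is even.

**Static comparisons.** The domain-rotation angle between two models
follows the standard domain-motion convention: pair atoms by
(chain, resid, name) on Cα within each selection (unpaired residues are
dropped and counted), superpose model B on model A using the core pairs,
then run Kabsch on the domain pairs alone; the angle is
`arccos((trace(R) − 1)/2)`, and below 1e-4° the rotation axis is reported
as undefined rather than as noise. The angle is symmetric in argument
order. Conditioning matters: a nearly linear domain (a single helix)
poorly constrains rotation about its own axis, so small-angle comparisons
should use domains with three-dimensional extent.

## The synthetic generator

The generator stands in for enhanced-sampling trajectories that are not
distributable; the analysis only assumes two autocorrelated, lag-coupled
signals riding on a rigid body, and that is exactly what is built.

**Template.** A single-chain Cα model: a seeded globular cloud of core
atoms (~15 Å radius, residues from 1), a compact cap cluster ending at
residue 246 (so the default 27 residues span 220–246, mirroring the
D220–S246 Cap), and an ideal α-helix in the 500s attached at the core
surface. Module-level selection expressions (`CORE_EXPR`, `HELIX_EXPR`,
`CAP_EXPR`) match any template.

**Coupled motion.** A stationary Ornstein–Uhlenbeck latent signal s(t)
(unit variance, relaxation time τ) drives the helix. Two transforms keep
the *measured* observables linearly coupled at the implanted correlation,
which a naive "angle proportional to s" construction would not achieve
(cos of a sign-symmetric angle is even in s, and a norm-type displacement
is rectified):

- the opening coordinate is u(t) = Φ(s(t)) ∈ (0, 1) (normal CDF), and the
  helix swings about its attachment point, perpendicular to its measured
  axis, by the angle with `cos θ(t) = 1 − (1 − cos A)·u(t)` — linear in u
  by construction, with A the maximum opening angle;
- the cap translates along a fixed direction by a non-negative
  displacement linear in `c(t) = −sign(ρ)·|ρ|·z(t − lag) + √(1−ρ²)·ε(t)`,
  where z is the standardized u and ε an independent, identically
  transformed OU signal.

The population Pearson correlation between cos θ(t) and dr(t + lag) is
then exactly ρ, and with ρ = ±1 and zero noise the sample correlation and
the integer-frame lag are recovered exactly. Frame 0 is the undisturbed
template — the natural reference where cos θ = 1 and dr = 0 hold
identically, and coordinate noise is omitted from it so reference
exactness survives noisy runs. Core atoms receive isotropic Gaussian
jitter (RMSF = σ√3), helix and cap atoms an additional noise term.
Everything is deterministic given the seed.

**Default conditions.** 1600 frames at 0.1 ns (160 ns), lag 45 ns,
ρ = −0.7, helix amplitude 40°, cap amplitude 12 Å, coordinate noise 0.3 Å,
core jitter 0.3 Å. The latent relaxation time defaults to τ = 0.5 ns: a
single 160 ns window then carries roughly T/2τ ≈ 160 effective samples,
which puts the sampling standard error of r̂ near 0.04 — the scale a
160 ns observation needs for a ±0.1 statement about ρ to be meaningful.
A `large_motion_truth` preset (60° swing, 20 Å cap excursions, 0.5 Å core
jitter) produces the fluctuation contrast regime in which mobile residues
exceed 5 Å RMSF while the core stays near 1 Å.

**What the generator does not emulate.** Real aMD physics: no force
field, no boost-potential reweighting, no membrane. Cap motion is a rigid
translation (dr measures only the COM), the helix swings as a rigid body
about a fixed hinge in a fixed plane, and the latent process mixes faster
than real intermittent opening events, which cluster on tens of
nanoseconds. Passing tests therefore demonstrate that the *measurement
chain* is correct and well-calibrated — not that any particular biological
system behaves this way, and slow real signals on a short window will
carry far fewer effective samples than the synthetic defaults.

## Numerical choices

- Kabsch uses the quaternion solver with a determinant-+1 guarantee;
  degenerate (collinear) point sets raise rather than return an arbitrary
  rotation. RMSD is recomputed from transformed coordinates, not taken
  from the solver's internal residual.
- PDB round-trips are exact to the format's 1e-3 Å precision; selection
  resolution is deterministic and order-preserving; altloc policy defaults
  to highest occupancy with ties toward altloc "A"; insertion codes ride
  along with author residue numbers, which are never renumbered.
- Time-series CSV export is long-format, time-major then metric-name
  ordered, with `repr`-precision floats, so write→read→write is
  byte-stable.
- The lag scan requires a shared uniform time grid and a minimum overlap
  (default 10 samples); lags whose overlap is constant are skipped rather
  than scored as r = 0. Zero variance anywhere a correlation is requested
  is an error, never a silent 0.
- Non-integer lags are rounded to the nearest sample with a warning.
- JSON reports are serialized with sorted keys; identical config + seed +
  input reproduce byte-identical reports.

## Known limitations

- The lag estimator assumes one dominant delay; oscillatory couplings
  alias (see above) and multi-timescale couplings return only the
  |r|-optimal lag, though the full lag–correlation curve is reported for
  inspection.
- The block-permutation p-value is exact-level only up to the block-length
  choice; a block far shorter than the true correlation time is
  anticonservative.
- Domain rotations between real deposited models depend on the chosen
  core/domain selections (the software reports paired-atom counts and
  RMSDs so that sensitivity can be checked, but cannot choose the
  selections).
- No secondary-structure assignment, PCA/normal-mode analysis, flexible
  alignment, or trajectory formats beyond multi-model PDB and the optional
  MDAnalysis-backed DCD/XTC readers.
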