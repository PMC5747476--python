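# Methods

## The physical model

The embryonic zebrafish trunk microvasculature is, topologically, a
ladder.  The dorsal aorta (DA) runs from the heart toward the tail; at
each somite boundary an intersegmental vessel (Se) climbs to the dorsal
longitudinal anastomotic vessel (DLAV); the posterior cardinal vein (PCV)
mirrors the DA, and the DA and PCV connect directly at the tail.  Pairing
each intersegmental artery with a vein and invoking bilateral symmetry
puts every SeA/SeV junction (and the DA–PCV anastomosis) at one common
pressure, which may be shifted to zero, and leaves no flow in the DLAV.
The model therefore keeps only the arterial half: `n` DA segments in
series (vertices `1..n+1`), one Se vessel per DA vertex, prescribed
volumetric inflow `F` at vertex 1, and pressure zero on every Se top and
at the tail junction.

Flow in every vessel is quasi-steady, low-Reynolds-number Poiseuille
flow: the Womersley number of the largest trunk vessels is
`Wo = sqrt(2 pi f d^2 / nu) ≈ 1.9e-2` at heart rate `f = 2 /s`, diameter
`d = 12 um` and kinematic viscosity `nu = 5e-6 m^2/s`, and the entry
length `U d^2 / nu ≈ 0.086 um` is negligible against any vessel length.
(`flow_diagnostics` reports the bare `U d^2/nu` scale without a
prefactor.)  A vessel of length `l` and radius `r` then has bare
resistance `R0 = 8 mu l / (pi r^4)`, and a fine vessel occupied by `n`
red blood cells has

    R(n) = R0 + n * alpha_c,

where the occlusion strength `alpha_c` — the intrinsic hydraulic
resistance of one cell squeezing through the vessel — is treated as a
phenomenological per-vessel constant to be estimated from data.  The
occlusive term applies only to Se vessels: the aorta is several cell
diameters wide, so its cells contribute only through the whole-blood
viscosity, and mutant shunt vessels are explicitly occlusion-free.

Units are g–um–s throughout (1 cP = 1e-6 g/(um s)), which makes
resistance come out in g/(um^4 s), the unit in which occlusion strengths
are quoted.  Pressures are never converted to Pa or mmHg.

Two viscosity modes are exposed:

* `continuum_whole_blood` — whole-blood viscosity `mu_wb = 5 cP`
  everywhere, no occlusive term.  This is the plain hydraulic resistor
  network used for the short-circuit prediction.
* `plasma_cells` — plasma (`mu_pl = 1 cP`) in the Se vessels plus the
  per-cell term `n alpha_c`; whole blood in DA/tail/shunt vessels.  This
  is the law the discrete traffic model and the mean-field model use.
  The paper's resistance law poses `R0` with plasma viscosity for narrow
  vessels, and we verified that this convention — not a whole-blood-bare
  variant — reproduces the ~11-fold dissipation cost of tuning.

## Default geometry

No public geometry table is deposited, so the package synthesizes one
pinned to the printed uniform-ladder conductances: DA segments 108 um
long at the mean measured radius 6 um (per-segment whole-blood
conductance `kappa1 ≈ 9.4e5 um^4 s/g`) and Se vessels 142 um long with
radius 2.9 um (`kappa2 ≈ 3.9e4 um^4 s/g`).  The remaining free scale is
the caudal stretch where the tapering DA narrows into the anastomosis
with the vein; its radius (4.3 um) is fixed so the no-occlusion model
reproduces the observed ~11-fold flow contrast between first and last
Se.  A strict linear 6→3 um taper across all segments was rejected: it
contradicts `kappa1` being the *mean* segment conductance and produces a
~46-fold contrast.  `uniform=True` removes the caudal narrowing and
yields the exact uniform ladder of the analytic model.

## Analytic ladder

For the uniform ladder, flux conservation at interior DA vertices gives
the constant-coefficient recurrence
`-kappa1 p_{i-1} + (2 kappa1 + kappa2) p_i - kappa1 p_{i+1} = 0` with
general solution `p_i = C+ xi_+^i + C- xi_-^i`, where `xi_±` solve
`xi^2 - (2 + lambda) xi + 1 = 0` and `lambda = kappa2/kappa1 ≈ 0.04`.
The roots are computed stably (`xi_+` from the quadratic formula with a
cancellation-free discriminant `lambda (lambda + 4)`, then
`xi_- = 1/xi_+`); `lambda = 0` falls back to the degenerate
linear-in-`i` solution.  Boundary conditions are `p_{n+1} = 0` and
`F = kappa2 p_1 + kappa1 (p_1 - p_2)`.  For every `lambda > 0` one root
is strictly inside (0, 1), so exponential decay of Se fluxes — the first
Se short-circuiting the ladder — is unavoidable without feedback.  The
reflected (growing) mode from the grounded tail penetrates several rungs
(`xi_- ≈ 0.82` decays slowly), so the pure decaying mode matches the
exact solution to 5% only over roughly the first five vertices, and to
~20% at the caudal end.

## Discrete traffic model

Every cell trajectory is simulated with time step `dt = 0.1 s` over
1000 s by default.  Per step: cell counts → resistances via `R(n)`;
Kirchhoff solve (dense symmetric solve with a hard 1e-10 relative
residual check; sparse above 200 unknowns); plug-flow advection
`v = Q/(pi r^2)` with the unused fraction of `dt` carried across
vertices; Bernoulli branching proportional to instantaneous outgoing
flows (Zweifach–Fung partitioning and the Fåhræus velocity offset are
deliberately suppressed — the model isolates the occlusive feedback);
cells leaving through any grounded vertex re-enter at the inflow vertex
within the same step and face the same branch choice there, so cell
number is conserved exactly.  Resistances are frozen at the step's
initial counts.  A cell arriving at a vertex with no outgoing flow (a
measure-zero stagnation event) parks at the vertex.  One seeded
generator drives the whole run; every output records its seed.

Two emergent properties matter for interpretation.  First, flow-ratio
branching at equal cell and plasma velocity preserves concentration, so
the mean Se occupancy equilibrates near `rho V_se` (~11 cells at
`rho = 0.003 um^-3`), denser than the 1–2 cells seen in live embryos;
the sparsity of real Se traffic reflects partitioning effects the model
deliberately omits.  The feedback nevertheless redistributes *fluxes*
exactly as intended.  Second, with the measured occlusion profile the
caudal-most Se — smallest `alpha_c` over a plasma-bare resistance —
retains a local flux excess in this synthesized geometry; uniformization
is cleanest over the first ten rungs.

Cell count defaults to `rho * V_network` (≈560 cells in the default
geometry) rather than a hard-coded census, because the conserved count
divided by network volume *is* the steady-state concentration and the
physically binding condition is `rho = 0.003 um^-3`; an explicit
`n_cells` (e.g. 990) is honored when given.  The default inflow
`F = 1.5e4 um^3/s` is fit — as in the source experiments, where inflow
was calibrated to the measured mean fine-vessel flux — so that the mean
per-Se cell flux under the measured profile is ~2 cells/s, the scale
implied by the observed concentrations and transit times.

## Mean-field model

The reduced network keeps four vessels: aorta to the first Se (`R1`),
first Se (`R2`), remaining aorta/tail (`R3`), last Se (`R4`), with
well-mixed continuum occupancies `n = rho V` so
`R2 = R2^0 + rho V2 alpha2`, `R4 = R4^0 + rho V4 alpha4`.  Kirchhoff at
the two junctions gives a 2x2 system; eliminating pressures yields

    Q4/Q2 = (R2^0 + V2 rho alpha2)/(R4^0 + V4 rho alpha4)
            * (1 + R1/R3 + R1/(R4^0 + V4 rho alpha4))^(-1).

The implementation treats the direct 2x2 solve as ground truth and the
closed form as a verified convenience (they agree to 1e-12 under
property tests).  With the stated geometric relations `R2^0 ≈ 2 R4^0`,
`V2 ≈ 2 V4`, `R1 ≈ 11 R3` (defaults: `l2 = 2 l4 = 284 um`,
`l1 = 11 l3 = 1188 um`) the second factor is bounded by 1/12, so only
`alpha2 >> alpha4` can level the supply.  Dissipation is the three-term
sum: Poiseuille losses in the aorta (whole blood) and in the cell-free
Se plasma, plus the per-cell lubrication term
`rho (Q2^2 V2 alpha2 + Q4^2 V4 alpha4)`; it equals `sum R_i Q_i^2`
exactly and matches the generic network decomposition on the same
4-vessel topology.  The tradeoff curve rescales `F` at each `alpha2` to
hold `Q2 + Q4` fixed and normalizes dissipation to 1 at
`alpha2 = alpha4`.

## Inference

**Occlusion strengths.**  At a fixed vessel pressure drop, `R(n)` makes
`1/v` linear in occupancy `n`.  The intercept is pinned at the modelled
cell-free velocity `1/v0` (from a network solve with zero cells — plasma
in the fine vessels), leaving one free parameter; the slope converts as
`alpha_c = slope * v0 * R0` with `R0` the same bare resistance that
produced `v0`.  Pinning the intercept to the *plasma* baseline, rather
than to the whole-blood continuum, is required for usable
signal-to-noise: against whole blood the per-cell signal at
`alpha_c = 1e-6` is ~4% per cell and 25%-accurate recovery from 200
noisy observations is statistically impossible.  The 95% CI propagates
the slope's standard error; negative slopes clip `alpha_c` to 0 with a
quality flag instead of erroring.  The per-vessel estimates are then
summarized by unweighted OLS against Se index; this fitted line is the
"measured" linear profile the simulator consumes.

**Entry-time feedback.**  Without feedback, cell entries are Poisson and
inter-entry intervals exponential.  Occupancy suppression depletes
intervals shorter than the transit time `tau = 0.3 s` (the measured mean
Se transit; exposed as a flag).  Two models are fit by MLE on unbinned
intervals (binning is for plotting only): a pure exponential (k = 1) and
a composite density, uniform with mass `w` on `[0, tau)` and shifted
exponential on `[tau, inf)` (k = 2, `tau` fixed); both are scored by
`AICc = -2 lnL + 2k + 2k(k+1)/(n-k-1)`.  The composite MLEs separate
(`w* = n_short/n`, `lam* = 1/mean(x_long - tau)`), and at the boundary
`w = 1 - e^(-lam tau)` the composite reproduces the exponential
likelihood up to an `O((lam tau)^2)` shape mismatch below `tau`.
Calibration on synthetic streams of ~800 intervals: AICc selects the
generating model in >= 90 of 100 seeded runs either way.

**Short-interval test.**  The exponential is fit to the intervals above
`tau` alone (memorylessness makes the shifted MLE consistent under the
null) and extrapolated below: each of the N intervals is short with
probability `q = 1 - e^(-lam tau)`, giving `expected = N q` against the
observed short count.  The published analysis used a Fisher exact test
whose 2x2 construction is not specified; this implementation instead
uses a two-sided normal test whose variance adds the binomial term
`N q (1-q)` and the delta-method contribution of the estimated rate —
without that correction the test is anti-conservative.  Under the null
the p-value is Uniform(0,1) to KS distance < 0.03 at 500 replicates of
800 intervals.

**Flux uniformity.**  Per-Se flux summaries (mean ± across-fish SD) are
bootstrapped: each replicate draws per-Se fluxes from
`Normal(mean_i, sd_i)` and regresses them on Se index; reported are the
slope mean ± SD and the pointwise 95% envelope of the regression lines.
Uniform supply shows up as a slope distribution straddling zero.

## Sweep

The occlusion profile is parameterized by the head-to-tail contrast
`delta_alpha` with linear interpolation and the *last* Se anchored at
the smallest measured strength `3.0e-7` (anchoring the tail keeps the
comparison network's minimum resistance physical; the published
definition fixes only the difference).  For each `(delta_alpha, rho)`
grid point the inflow is recalibrated (secant on 2–3 short replicate
runs) so the total Se *cell* flux — not volumetric flux — matches the
reference point, the measured contrast at `rho = 0.003`; CV and
time-averaged dissipation are averaged over seeds, the latter normalized
by the reference.  The per-`rho` CV minimum is interior (too little
contrast and the first Se short-circuits; too much and the tail is
over-perfused) and traces a single curve across `rho`.
`tuned_vs_uniform_dissipation` compares the measured profile against the
uniform-anchor profile at equal total cell supply; at full scale
(1000 s, dt 0.1 s, three seeds) the ratio is ~11 with a Monte-Carlo
standard error below 1%.

## Synthetic data

The generators emulate the four observation types the analyses consume:
a geometry table (the defaults above, with optional truncated-normal
spacing jitter — factors are redrawn if non-positive, which biases the
mean by well under 5% at the tested amplitudes); velocity/occupancy
observations (`v = v0 R0/(R0 + n alpha)` with median-one lognormal
noise, so neither `v` nor `1/v` is grossly biased; occupancies default
to Poisson with mean 1, matching the observed 0–2-cells-typical,
up-to-5 support, with the traffic simulator's denser self-organized
occupancy distribution available as an option); entry-time streams (a
thinned renewal process: Poisson candidates, candidates within one
transit time of the last accepted entry kept with the suppression
probability); and Gaussian per-fish flux replicates summarized across a
6-fish cohort.  Every generator is a deterministic function of its
arguments and seed.

What passing tests on these data do *not* show: the generators share the
package's own forward models, so recovery tests validate the inference
machinery (identifiability, calibration, noise propagation), not the
biological correctness of the occlusion law; and none of the generators
emulate cardiac-cycle pulsatility, tracking error structure, or the
cell-partitioning biases noted above.

## Problem sizes and numerical choices

Default study conditions are a 12-Se ladder, 1000 simulated seconds at
dt = 0.1 s, and three seeds per condition; the test suite exercises the
same code paths at 30–1000 s and grids of 4–7 contrast values, sizes
chosen to keep a full desk run in minutes.  Exactness tolerances are
1e-12 (closed forms vs direct solves), 1e-10 (linear-system residuals,
conservation, energy identity); stochastic checks use seeded replicates
with thresholds recorded in the tests themselves.  Degenerate inputs are
rejected with named errors (missing geometry rows, non-positive
dimensions, singular systems, negative counts); measure-zero runtime
ties (stagnation points) have a fixed symmetric rule.

## Known limitations

* The synthesized geometry stands in for the unavailable measured table;
  quantities tied to the caudal boundary (the last one or two Se) are
  the most geometry-sensitive, and the measured-profile CV is dominated
  by the last rung here.
* The model's Se occupancy (~`rho V`) exceeds observed occupancy
  several-fold, as discussed above.
* No pulsatility, no compliant walls, no cell–cell mechanics beyond the
  linear occlusion law, no phase separation, no oxygen transport.
* The optimal contrast at physiological density in this geometry
  (~1e-5) sits below the measured endpoint difference (~2.8e-5), though
  well within the same decade-wide valley of low CV.
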