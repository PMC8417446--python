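# Methods

## The measurement being modeled

Arterial spin labeling (ASL) measures cerebral perfusion by magnetically
inverting arterial blood water below the brain and imaging the tiny signal
difference the labeled water produces after it arrives in tissue. Two
parameters are estimated per voxel: cerebral blood flow (CBF, ml/100 g/min)
and arterial transit time (ATT, s). In *time-encoded* (Hadamard) pCASL the
labeling train is split into `N` sub-boli whose label/control states across
`N+1` acquisitions follow the columns of a pruned Sylvester Hadamard
matrix; a linear decode then yields one perfusion-weighted (PW) image per
sub-bolus, each with its own effective post-labeling delay (PLD), giving
multi-delay data at no extra scan time.

The package implements the seven-block reference scheme: base PLD 500 ms,
block durations 1175/683/482/374/305/257/224 ms in play order, effective
PLDs 2825/2142/1660/1286/981/724/500 ms (base PLD plus the summed durations
of all later-played blocks).

## Scheme design

**Hadamard matrix.** Sylvester doubling, all-ones column removed. Rows are
encoded acquisitions, columns sub-boli; every column has equally many +1
(label) and −1 (control) states, so static tissue cancels exactly in the
decode `PW_j = (2/N_enc) Σ_r M[r,j] S_r`, which recovers the difference
signal ΔM_j exactly on noiseless input.

**T1 compensation.** Early sub-boli decay longer before readout, so their
durations are lengthened until every block delivers the same signal
`w = (1 − e^{−τ/T1b}) e^{−PLD/T1b}`. The solver works outward from the
readout; the common level is fixed either by anchoring the last-played
duration or by constraining the total train length (the level then found by
bisection; train length is monotone in the level). The printed reference
durations sum to exactly 3.5 s, and the total-duration solve at T1b =
1.65 s reproduces each printed block within 1.1%, while the anchored solve
drifts to ~7% on the first block — the total-length constraint appears to
be the operative design rule, so both are exposed. The printed durations
themselves satisfy the equal-signal property to max/min ≤ 1.02.

**Background suppression.** Static tissue is modeled as saturated at the
labeling-train onset (Mz(0)=0; this is what makes the single-inversion
closed form `t* = T − T1 ln(2/(1−r+e^{−T/T1}))` hold), relaxing toward
equilibrium with ideal instantaneous inversions at the pulse times. The
optimizer places `n` pulses in the preparation window (label train + base
PLD, 4.0 s for the reference scheme) to bring the end-of-window Mz of every
compartment (defaults GM/WM/CSF T1 = 1.3/0.9/4.3 s) to +10% of
equilibrium. The default objective is the worst compartment's absolute
deviation (minimax), which equalizes residuals across compartments — with
two pulses all three land within 0.10 ± 0.019, whereas the sum-of-squares
optimum (also available as `objective="ssq"`) leaves one compartment at
0.078. Search is deterministic: exhaustive 20 ms coarse grid over ordered
pulse tuples, Nelder-Mead polish to sub-0.1 ms resolution; tests verify it
never loses to an exhaustive 1 ms grid.

## Kinetic model

The general kinetic model with a plug-flow bolus and no dispersion. For a
pCASL sub-bolus of duration τ read out at time `t` after its label onset:

    ΔM(t) = 0                                                   t < Δt
    ΔM(t) = 2 M0a f α T1t e^{−Δt/T1b} (1 − e^{−(t−Δt)/T1t})     Δt ≤ t < Δt+τ
    ΔM(t) = [plateau] · e^{−(t−Δt−τ)/T1t}                       t ≥ Δt+τ

with `f` converted internally from ml/100 g/min to ml/g/s. The PASL (FAIR,
fixed bolus length) variant decays the label at blood T1 from the single
inversion until arrival. Both are validated against independent numeric
quadrature of the delivery–decay integral to 1e-6 relative. Defaults:
T1 blood 1.65 s at 3 T, apparent tissue T1 fixed at 1.3 s (not
flow-dependent — keeps the fitter well-posed), λ = 0.9 ml/g, α = 0.85
(pCASL) / 0.98 (PASL). One consequence of T1t < T1b worth knowing: in the
decay phase the signal *rises* slightly with ATT (the label shelters in
slower-decaying blood), so the intuitive "later arrival = less signal"
monotonicity holds strictly only while arrival cuts into the bolus, and the
T1-compensated transit curve is exactly flat only when the post-arrival
decay matches the compensation T1.

## Synthetic cohort

The generator emulates the statistical structure of a two-scanner
test-retest study of healthy elderly, not anatomy.

* **Phantom**: concentric ellipsoids — cortical GM shell, WM core, CSF
  ventricles — plus eight ellipsoidal deep-GM ROIs (bilateral hippocampus,
  amygdala, caudate, accumbens); tissue fractions ramp at interfaces so
  boundary voxels are genuinely mixed. Default grid 32×32×16 at 3.3 mm.
  Truth maps: GM 70, WM 28 ml/100 g/min; GM ATT 1.4 s, WM 1.53 s (a 0.13 s
  GM→WM transit lag); per-ROI means follow reported elderly-cohort values; voxel
  scatter 5 ml/100 g/min and 0.05 s.
* **Cohort**: 26 subjects (15 female), ages ~N(68.3, 6.3²) clipped to
  [56, 84]; session 1 on "skyra", session 2 on "mmr" ~78 days later; two
  runs per session. Fixed effects: CBF −0.35 (ml/100 g/min)/yr and +6 for
  women; ATT +0.010 s/yr and −0.08 s for women; +0.05 s ATT on the skyra
  system. Random components: subject (CBF lognormal σ 0.10, ATT 0.05 s,
  drawn jointly with correlation −0.5 so longer transit co-occurs with
  lower flow), session (0.02 / 0.020 s), run (0.035 / 0.015 s). The run
  SDs put the GM two-run wsCV in the 3–6% range reported for this sequence family; the ATT
  components keep the scanner offset detectable by a between-subject GLM
  at n=26 (this caps the post-covariate residual at ~0.06 s, so the total
  between-subject ATT SD comes out ≈0.10 s, a little under the ~0.13
  reported in vivo).
* **Noise**: i.i.d. Gaussian per voxel per volume. `noise_sigma="auto"`
  calibrates the raw SD so the decoded per-voxel GM tSNR averages 1.72
  across sub-bolus PLDs (`σ_raw = mean GM ΔM / 1.72 / (2/√N_enc)`). The
  measured tSNR (7 cycles) reads ~15–20% above the analytic target because
  the finite-sample SD estimate is biased low; it stays inside the 1.1–2.3
  band used by the tests. There is no spatial autocorrelation, no
  physiological (cardiac/respiratory) noise, and motion exists only as a
  trace (random walk + drift, y-translation scaled to scanner-specific
  means 0.33/0.49 mm, capped at 2 mm/2°) — it never corrupts the images.
  Passing tests therefore show the *estimation chain* is correct and that
  the injected effect structure is recoverable; they do not show robustness
  to structured in-vivo noise.
* **M0**: five PD-weighted volumes (inflated non-steady-state dummy + 2 AP
  + 2 PA, no distortion simulated), TR 6 s nominal.

Everything is a pure function of its seed; the pipeline derives stage seeds
from the master seed by CRC32 of `"seed:stage:subject:session:run"`.

## Quantification

Cycles are averaged before fitting (tSNR uses the unaveraged cycles). Per
masked voxel the fit minimizes

    Σ_j (PW_j − ΔM_j(f, Δt))² + s² (Δt − μ)² / σ²

with the data normalized by the local arterial M0 (`M0/λ`) so `f` comes out
in ml/100 g/min; μ = 1.3 s (pCASL GM prior; 1.0 s for PASL), σ = 0.3 s, and
the prior weight `s` is the estimated noise SD of the averaged data (from
cycle-to-cycle scatter), so the prior contributes about one noise-SD per
prior-SD of deviation and vanishes on noiseless data (an infinitesimal
floor breaks flat-objective ties toward the prior mean, e.g. for all-zero
voxels). This penalized least squares stands in for the variational-Bayes
fit used with in-vivo data: same model, same prior intent, deterministic.

Because the model is linear in `f`, the flow is profiled out in closed form
for every candidate ATT (variable projection) on a dense 2 ms grid over
[0.3, 2.8] s with `f` clipped to [0, 300]; a parabolic step then refines
between grid points. The optimum therefore can never be worse than any
grid candidate — the coarse-grid oracle invariant holds by construction —
and the whole volume fits in a few matrix products (~0.1 s per
acquisition). Noiseless recovery is ≤0.5% in both parameters; at the
calibrated noise level, 200 GM-like voxels recover CBF with <5% median
error and ATT within 50 ms.

Known bias: the ATT prior shrinks weak-signal estimates toward 1.3 s, so
the fitted WM ATT sits below truth and the cohort GM→WM lag reads ~0.07 s
against a generated 0.13 s. A variational-Bayes fitter with the same prior
shows the same behavior; contrast tests against generator truth use the
noiseless path.

**PVC**: linear-regression partial volume correction — within each (default
3×3×3) neighborhood, solve `CBF ≈ pv_gm·C_gm + pv_wm·C_wm` by least
squares from local sums (computed by convolution); rank-deficient
neighborhoods fall back to the single-tissue solve or are flagged and
withheld. Exact on exactly-specified linear mixtures.

**ROIs**: GM/WM masks threshold the tissue fractions at 0.9 and binarize;
subcortical ROIs come from the label volume; means are taken over
converged voxels only.

## Statistics

* **wsCV** (two runs): per subject `wsVar = (x₁−x₂)²/2`,
  `wsMean = (x₁+x₂)/2`; reported as `100·√(mean(wsVar/wsMean²))`. The
  square root makes it a CV in percent; the squared variant is exposed via
  `sqrt=False`. Scale-invariant; zero iff runs identical.
* **ICC**: two-way ANOVA decomposition; default two-way mixed, single
  measures, consistency `(MS_subj − MS_err)/(MS_subj + MS_err)` with the
  F-distribution 95% CI; absolute agreement available. Cross-checked
  against an independent sums-of-squares oracle and pingouin to 1e-10.
* **Normality gate**: Shapiro–Wilk at α=0.05; failing ROIs are flagged so
  parametric results carry a listed-for-completeness marker.
* **Group test**: one-way ANOVA (equals t² for two groups).
* **Factor test**: OLS with categorical scanner/gender + continuous age,
  type-II F per factor. Null-simulation type-I error 5% ± 2%.
* **ATT–CBF correlation**: Pearson, with the partial variant residualizing
  both on the covariates. No multiple-testing correction anywhere (the
  analysis it mirrors applied none); p-values are raw.
* **Exclusions**: subjects with GM CBF < 20 ml/100 g/min in any run are
  dropped per analysis and logged.

In the full replication, ICC values come out higher (~0.92–0.94 for GM)
than the in-vivo ~0.70–0.75 because the generator's between-session
variance is small relative to its between-subject variance; the wsCV
scale, the ATT-more-reliable-than-CBF ordering, the negative ATT–CBF
correlation, the GM/WM CBF ratio (~2.5), and the scanner ATT offset
detection all reproduce.

## Problem sizes

Default pipeline: 32×32×16 phantom, 26 subjects × 2 sessions × 2 runs, 7
cycles × 8 encodings. The 20-seed replication suite runs at 24×24×12 with
everything else at defaults (~15 s per replication). The voxelwise fitter
and the simulators are fully vectorized; a full default replication runs in
well under a minute on one core.

## Limitations

Schematic geometry (no anatomy, no registration/distortion problems by
construction); plug-flow bolus without dispersion; fixed apparent tissue
T1; no arterial blood volume component; motion is summarized, not applied;
i.i.d. noise only. These are the places where in-vivo behavior will differ
from what the test suite can certify.
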