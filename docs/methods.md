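# Methods

This note documents the models, conventions and design choices behind the
`mnc` pipeline: what each stage computes, which parameters matter, what the
synthetic cohort generator does and does not emulate, and where genuinely
open design decisions were resolved.

## Spectral processing

**Band-pass.** Signals are band-limited with a zero-phase FFT brick wall:
every Fourier bin with frequency outside `[lo_hz, hi_hz]` (edges
*inclusive*) is zeroed and the record inverse-transformed. A brick wall was
chosen over IIR/FIR designs because it is exactly idempotent, introduces no
phase distortion anywhere in the passband — the property a phase-lag
statistic depends on — and is fully determined by the band edges (no order
or ripple parameters). The default bands are theta 4–8 Hz, lower alpha
8–10 Hz and upper alpha 10–13 Hz; bands are configurable and validated
against Nyquist.

**Instantaneous phase.** Phase is the angle of the analytic signal
(Hilbert construction, `scipy.signal.hilbert`), wrapped to (−π, π].
Identically-zero channels raise an error rather than returning arbitrary
phase. Phase is computed **per epoch after segmentation**, not on the
continuous record, so analytic-signal edge artefacts never leak across
epoch boundaries; the first and last 1/16 of each epoch are additionally
excluded from the PLI average by default (`edge_trim`), which removes the
residual edge bias at the cost of ~12% of the samples.

**Epoching.** Non-overlapping consecutive epochs of `epoch_samples`
(default 4096 at 625 Hz, i.e. 6.5536 s); the trailing remainder is
discarded and a record shorter than one epoch is an error.

## Connectivity

The phase lag index of a pair is `|mean_t sign(wrap(φ_i − φ_j))|` with
differences wrapped into (−π, π]. Samples whose wrapped difference is
exactly 0 or π contribute sign 0. This convention (a) realizes the
statistic's purpose — consistently-signed *nonzero* lags score high, while
zero-lag coupling, the signature of volume conduction / field spread, is
invisible; and (b) makes the self-PLI exactly 0. The wrapping convention
is fixed and all phase arithmetic is modulo-2π safe.

Per-epoch matrices are averaged entrywise into a subject's epoch-averaged
matrix; RSN connectivity is the mean PLI over the unordered ROI pairs
*within* that RSN, and global connectivity the mean over all pairs. For
these linear summaries the order of epoch-averaging and pair-averaging is
immaterial; it matters for tree metrics (below), so the pipeline fixes the
order explicitly: PLI per epoch → average matrices → RSN/global means.

The all-pairs PLI inner loop is a numba kernel (with an equivalent numpy
fallback); a readable numpy `pli_pair` serves as the behavioural reference
and the two are cross-checked in the tests.

## Minimum spanning tree

"Minimum spanning tree based on the PLI" is implemented as the
**maximum**-total-PLI tree — the strongest connections form the backbone —
equivalently the minimum spanning tree of any strictly decreasing
transform of PLI (verified as a test invariant with 1/(PLI+ε)). Kruskal's
algorithm runs on edges sorted by descending weight; ties are broken by
lexicographic (i, j) pair order, making the tree deterministic even though
finite-sample PLI values can collide (uniqueness of the MST is only
guaranteed for unique weights).

Metrics, with N nodes and m = N − 1 edges:

| metric | definition | star (N=10) | path (N=10) |
|---|---|---|---|
| `degree_max` | max degree / m | 1.0 | 2/9 |
| `leaf_fraction` | #degree-1 nodes L / m | 1.0 | 2/9 |
| `eccentricity_mean` | mean hop eccentricity / m | 0.2111 | — |
| `bc_max` | max betweenness / ((N−1)(N−2)/2) | 1.0 | — |
| `tree_hierarchy` | T_H = L / (2 m BC_max), BC_max normalized | 0.5 | → 0 |

The normalizations are fixed here (the original analysis tools do not
publish theirs); per-epoch raw values are recoverable from the tree itself,
which is exportable as an edge list. Betweenness and eccentricity are
computed on the unweighted tree (paths in a tree are unique) via networkx.
A 2-node tree has an undefined BC normalization and raises a degenerate
input error. Subject profiles are **metrics per epoch, then averaged** —
not metrics of the averaged matrix, which is a different (nonlinear)
quantity.

## Cognition

Raw scores are standardized against the matched healthy-control stratum,
`z = (raw − mean)/SD`, negated for tests where higher raw is worse
(orientation is battery metadata), so higher z is always better. Domain
composites are unweighted means of member-test z-scores over six domains;
the aggregation rule is a package default, as is the packaged battery of
one synthetic test per domain — both are configuration, replaceable by a
real battery description. Impairment is flagged at z ≤ −1.5 (the boundary
value counts as impaired).

## Statistics

Both tests are written from first principles; scipy implementations serve
only as independent cross-checks in the test suite.

**Mann–Whitney U** uses the convention U = #{(x, y) : x > y} + ½·ties (the
first sample's statistic, computed from midranks). The p-value is exact —
the full null distribution of U over all C(n1+n2, n1) rank labelings via
the standard two-sample recursion — whenever there are no ties and
n1·n2 ≤ 400 (which covers the 20-vs-20 design), exact by explicit
enumeration when ties are present and C(n1+n2, n1) is small, and otherwise
a normal approximation with tie and continuity corrections. Group
comparisons default to one-tailed (patients worse); correlations to
two-tailed.

**Kendall tau-b** is (C − D)/√((n0 − t_x)(n0 − t_y)) with the usual tie
terms. The default p-value is the normal approximation on the
tie-corrected variance of S = C − D (no continuity correction); an exact
full-permutation option exists for n ≤ 8. The asymptotic default is a
deliberate calibration choice at the study's n = 20: the exact two-sided
p-distribution has atoms of ≈0.05 near the centre of the S-lattice, which
makes exact p-values visibly non-uniform under the null at small n, while
the asymptotic p centres the lattice and is null-uniform to within the
Kolmogorov–Smirnov tolerance used in the tests.

No multiple-comparison correction is applied by default, matching the
exploratory character of small-cohort RSN analyses; Benjamini–Hochberg
adjusted p-values can be added to the output tables with a flag.

## Synthetic cohort generator

The generator exists so every downstream stage can be exercised, with
known ground truth, at the study's scale: 20 patients and 20 matched
controls, 78 cortical ROIs, five 4096-sample epochs at 625 Hz, per-band
series. Controls carry cognition only (the emulated design has no control
MEG); a flag enables control MEG for other uses.

**Signal model.** Each subject is a network of phase oscillators updated
once per sample:

    θ_i(t+1) = θ_i(t) + 2π f_i/fs + Σ_j K_ij sin((θ_j + c_j) − (θ_i + c_i)) + ξ_i(t)

with natural frequencies f_i drawn uniformly inside the central 90% of the
target band, coupling K_ij = κ between ROIs of the designated RSN (the
DMN, by default, in the theta band) and a weak background elsewhere,
Gaussian phase noise ξ, and per-ROI intrinsic phase offsets c_i drawn
uniformly from [0, `coupling_lag_rad`). The observed signal is sin(θ_i)
plus white measurement noise. A 1024-sample transient is discarded.

The heterogeneous offsets are the load-bearing choice. Coupling aligns the
*offset-corrected* phases, so synchronized ROIs hold persistent pairwise
lags c_j − c_i: PLI rises monotonically with κ and saturates at 1. With a
single common lag inside the sine instead, the lag cancels out of the
symmetric pair dynamics (dΔ = Δω − 2κ cos δ · sin Δ), strong coupling locks
pairs at *zero* lag, and PLI becomes a narrow non-monotone resonance in κ —
unusable as ground truth for a monotone brain–behaviour link. Pairs whose
offset difference happens to land near 0 remain PLI-invisible; that is the
statistic working as intended, not a generator defect.

**Default operating point** (chosen once, by sweeping the κ→PLI response):
background coupling 2·10⁻⁴ per step (aggregate background stays well below
the frequency spread, so no spurious global locking), phase noise SD 0.3
per step (decorrelates uncoupled pairs; regularizes the locking
transition), measurement noise SD 0.2, κ_s uniform on [0.01, 0.04] —
the rising flank of the response, where within-DMN theta PLI spans ≈0.3 to
≈0.8 and between-subject κ differences dominate PLI estimation noise
(rank correlation κ↔PLI ≈ 0.79 at five epochs). Stability requires the
per-step coupling row sum below 1; configurations violating it are
rejected.

**Cognition link.** Each subject's working-memory latent is built by a
Gaussian copula on κ_s: with ρ = sin(π·effect/2), the population Kendall
tau between κ_s and the working-memory z equals `effect` exactly; the
measured-PLI tau is slightly attenuated by estimation noise (≈0.45
observed at effect 0.5 and n = 200). The other five domains are
independent N(0,1). Patients receive a −0.55 SD working-memory mean shift.
At n = 20/20 the exact one-tailed Mann–Whitney test has power ≈0.50
against that shift, so the deficit is detected in about half of simulated
cohorts — matching a single observed p in the 0.03–0.05 range, i.e. an
effect at the detection edge. Raw scores are latent·10 + 50 (negated for
timed tests), with (50, 10) as the control norms.

**What the generator does not emulate:** 1/f spectra and broadband
background, amplitude dynamics and amplitude–phase coupling, artefacts
(and hence artefact rejection), head-position and source-leakage effects,
realistic inter-regional delay structure, and covariance between cognitive
domains. Passing tests therefore demonstrate the correctness and
calibration of the *analysis machinery* under a controlled oscillatory
model — not the physiological realism of the signals.

## Pipeline conventions

- The brain–behaviour stage runs on the patient group and, by default,
  only for domains whose group comparison reaches p < 0.05 (the
  conditional-analysis design); `all_domains` overrides.
- Full runs are byte-reproducible for a fixed seed: all randomness derives
  from one `numpy.random.SeedSequence`, tables are written with a fixed
  float format, and the manifest records a config hash instead of
  timestamps.
- Problem sizes used in the shipped tests: oracle equivalences run
  exhaustively at N ≤ 7 nodes (200 instances) and N ≤ 12 for metric
  cross-checks; statistical null calibration uses 2000 replicates at
  n = 20; cohort-level checks use 50 full-scale cohorts for effect
  recovery and 200 reduced cohorts (16 ROIs with a 12-member DMN — the RSN
  size, not the ROI count, sets the coupling operating range) for null
  calibration.

## Known limitations

- The FFT brick wall assumes the record is long relative to the band edges;
  very short records leak.
- The atlas ships with literature-based DMN/FPN memberships on the
  78-region cortical AAL scheme; studies with their own RSN definitions
  should supply an atlas JSON.
- Exact Mann–Whitney p-values with ties fall back to explicit enumeration
  and are limited to small samples; the tie-corrected normal approximation
  is used beyond that.
- MST metrics are global only; nodal metrics and tree-overlap measures are
  out of scope, as are other connectivity estimators (wPLI, amplitude
  envelope correlation, coherence).
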