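# Methods

## The measurement problem

A protein concentrated in chromocenters can be "dynamic" in two distinct
senses: it can move *within* the compartment, and it can *exchange* with
the nucleoplasm. Whole-compartment photobleaching only measures the
second; partial-compartment bleaching and inverse FRAP (bleaching
everything except one focus) separate the two. `hrdquant` quantifies
both, together with steady-state partitioning, so that a construct's
phenotype is summarized by a small feature vector: partition coefficient,
fractional recovery at 5 s and 100 s, mobile fraction, internal remixing
time, and apparent efflux rate.

## The reaction–diffusion–binding simulator

The synthetic-data layer exists to provide inputs with exact ground
truth. It is a deterministic continuum model on a 2D pixel lattice
(default 64×64 at 0.15 µm/px, an elliptical nucleus of radii
3.9 × 3.2 µm containing five circular chromocenters of radius
0.5–0.9 µm):

* Free molecules diffuse inside the nucleus with `D_free` (default
  1 µm²/s; deliberately modest, since free diffusion is never the
  rate-limiting step in the regimes of interest) with reflecting
  boundaries, integrated by a flux-form explicit scheme that conserves
  mass to floating-point rounding at every step. The step obeys
  `dt ≤ px²/(4·D)`.
* Binding sites form a top-hat density map (default 30 sites/px inside
  chromocenters, zero outside; ~10⁴ sites total). Binding is mass-action
  with a finite site pool, `db/dt = k_on·f·(S−b) − k_off·b`, so
  partitioning saturates once copy number approaches site number. There
  is no membrane, potential barrier, or phase boundary at the
  chromocenter edge.
* Bound molecules may hop between adjacent lattice positions within the
  contiguous site region with a small `D_bound`. This models direct
  site-to-site transfer (facilitated dissociation between densely packed
  chromatin binding sites). It is the mechanism that decouples the two
  timescales: internal mixing proceeds at `D_bound` without unbinding,
  while escape to the nucleoplasm always requires a true `k_off` event.
  A two-field scheme whose bound state is strictly immobile cannot
  reproduce the observed separation — under local-equilibrium binding
  both the internal mixing time and the compartment exchange time carry
  the same retardation factor `(1 + k_on·S/k_off)`, so their ratio is
  set by geometry alone (a factor of a few, never hundreds). Bound-state
  hopping restricted to the site lattice preserves the "no barrier"
  premise: retention is still purely a consequence of binding kinetics.

Because free molecules equilibrate across the nucleus quickly, the full
steady state has uniform free concentration `c` solving the mass balance
`c·A + Σ S·c/(c+K_d) = N` (monotone in `c`; solved by bracketed root
finding). Photobleaching simulations start at this fixed point, verify
stationarity (relative drift < 1e−6 over a short run-in), then evolve
only the fluorescent (free, bound) pair against the stationary total
occupancy — exact for the linear fluorescent subsystem and half the
cost. Bleaching is an instantaneous multiplication of both fluorescent
fields by `bleach_depth` inside the ROI; fluorescent mass is conserved
at every other step and recorded per frame.

### Kinetic presets

The presets encode the three phenotype classes seen across the construct
panel; their parameters are the study conditions, fixed up front:

| preset | k_on·S/k_off | k_off (1/s) | D_bound (µm²/s) | behavior |
|---|---|---|---|---|
| `retentive` | ≈ 9 | 1.2e−4 | 0.025 | PC ≈ 10; internal remixing ~tens of s; efflux ~0.5–0.7 %/min |
| `exchanging` | ≈ 3 | 0.35 | 0 | PC ≈ 4; full recovery of a bleached focus within tens of s |
| `unbound` | 0 | — | 0 | PC = 1; diffusion-limited recovery in seconds |

The two calibrated constants in the retentive preset derive from the
reported wild-type phenomenology rather than from fitted data: `k_off`
is set so the maximal unbinding-limited efflux is ~0.7 %/min, and
`D_bound` so a half-bleached 0.9-µm focus reaches 95% of its remixing
plateau in roughly half a minute.

### What the generator does and does not emulate

Emulated: chromocenter foci over a dimmer nucleoplasm with Poisson shot
noise and optional Gaussian read noise; a DNA counterstain channel whose
contrast is independent of protein partitioning; two-state
bleach-and-recover kinetics with conserved mass; acquisition
photobleaching as a per-frame multiplicative loss; expression series
with saturable sites; HRD-like sequences with planted motifs, exact
spacing, and composition-controlled linkers.

Not emulated: 3D optics (point-spread blur, z-sectioning), photophysics
(blinking, reversible bleaching), chromatin motion, cell-to-cell
variation in nuclear geometry, partial-volume pixels at compartment
edges, and liquid–liquid phase-separation energetics. Passing tests
therefore demonstrate correctness of the quantification chain and the
qualitative binding-site retention mechanism, not the microscope realism
of any particular dataset.

## FRAP quantification choices

* The scanning-photobleach normalization is anchored at the **first
  post-bleach** frame, while the relative-fluorescence denominator is the
  **pre-bleach** intensity; the two anchors intentionally follow the
  standard protocol's asymmetric convention, and both are exposed as
  keyword arguments.
* Double-exponential fits re-zero time at the bleach, bound amplitudes in
  [0, 1.5] and time constants in [1e−3, 1e4] s, and use 8 multi-starts on
  a log-spaced τ grid, tie-broken by residual sum of squares, with a
  flagged single-exponential fallback. Mobile fraction is clipped to
  [0, 1.05] to tolerate noise overshoot.
* `recovery_at` reports *fractional* recovery referenced to the
  post-bleach minimum, so constructs with different bleach depths are
  comparable; the raw relative-fluorescence value is recoverable from the
  curve itself.
* Inverse FRAP uses its own chain (`process_ifrap`): the spared-region
  trace is ratioed to the whole-cell trace frame-wise and scaled to 1 at
  the first post-bleach frame; the efflux rate is the negated OLS slope
  of percent intensity on minutes over the analysis window (default
  30 min — long windows dilute the initial free-pool washout transient).
  Turnover time is `100 / rate` and the equilibration ratio divides it by
  the internal remixing time, which is itself defined as the first
  crossing of 95% of the fitted recovery plateau (the plateau-fraction
  threshold is this package's operationalization of a quantity usually
  read off a kymograph).

## Partitioning choices

Weka-style trained segmentation is replaced by a deterministic
three-class intensity model: multi-Otsu thresholds (with exact level
splitting when the histogram has only three values) plus small-object
removal. For proteins with PC ≈ 1 the protein channel is featureless, so
the counterstain channel is segmented and its labels transferred. The
ground-truth-mask path (`masks_from_ground_truth`) isolates formula
correctness from segmentation quality. Cells whose corrected nucleoplasm
signal is within 3 background standard deviations of zero are flagged
rather than silently dropped. Normalized scatter plots divide both axes
by the construct-wise shared maximum of corrected intensities (keeping
the y = x diagonal meaningful as PC = 1); per-axis normalization is
switchable and the choice is recorded in the output metadata. Image
stacks are reduced by maximum projection; per-construct summaries emit
both means and medians since box-plot conventions differ.

## Panel analysis choices

Clustering uses Euclidean distance and average linkage on per-column
z-scored features (population SD), with the tree cut at k and labels
renumbered by decreasing mean PC so runs are deterministic and
row-order-invariant. Distance and linkage are configurable; the default
is the standard heatmap convention. Mobile fraction is available as a
fourth feature but excluded from the default feature set (it is displayed
alongside, not clustered on). Pairwise group comparisons use the Wilcoxon
rank-sum (Mann–Whitney) test with the exact null when sample sizes and
ties allow, reported both raw and Holm-adjusted; the adjustment is this
package's addition, which is why raw values are always reported
alongside.

## Sequence-analysis choices

* Motif grammars are formalized as: Φ1 `[VI]-x-L`, His-Cys
  `H-x4-C-x{3,4}-C` (amphibian `H-x{3,4}-C-x{13,14}-C`), Φ2
  `L-x{5,6}-V-x-L`, Φ3 `L-x5-V-x-L`, PxVxL `P-x-V-x-L`. Every
  alternative span of a variable-gap grammar is enumerated, overlapping
  hits included; `X` is legal input but never matches a constrained
  position. Flanking positions (−6/−7, e.g. the primate
  threonine–histidine pair upstream of Φ1) are descriptive annotations,
  not match constraints.
* Gap convention: residues strictly between motif spans, so the
  conserved mammalian spacing is gap 0 (Φ1→His-Cys, abutting) and gap 1
  (His-Cys→Φ2, one intervening residue). Architecture calls resolve
  ambiguity by minimal total span, then leftmost, and report remaining
  valid chains as alternatives; incomplete architectures are legal
  outputs.
* The disorder-promoting residue set is {A, R, G, Q, S, P, E, K}
  (configurable); histidine is uncharged in NCPR/FCR by default
  (configurable). Conformational classes are assigned from FCR bands
  calibrated against a five-member reference linker series with
  functional lengths 13, 22.5, 34.3, 53.9, 66.6 Å spanning compact
  globule → intermediate → Flory random coil → self-avoiding random
  coil; the band edges ship as an editable table
  (`seqfeat.CONFORMATIONAL_CLASSES`) since only the endpoints are pinned
  by the reference series. The functional lengths are literature
  constants, not computed here.
* Coordinates are 1-based inclusive in every sequence-facing output.

## Sequence generator

Linker composition is achieved by counting: positive (K/R), negative
(D/E, preferring E when the disorder-promoting budget is unmet), and
uncharged residues drawn from pools that exclude V, I, L, H, C so the
planted motifs are the only intended matches. Realized NCPR/FCR/DP
fractions land within ±0.05 of target plus one counting unit (1/length).
Infeasible targets (|NCPR| > FCR) are rejected at spec construction.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed; pipeline runs spawn
per-stage seeds from the master seed via `numpy.random.SeedSequence` and
write a manifest with the config hash and a SHA-256 of every output
file, so identical configs give identical manifests for deterministic
stages.

The shipped analyses use desk-scale problem sizes chosen to make every
property measurable with comfortable margins: a 64×64 lattice,
100-second conventional FRAP at 2-s frames, a 30-minute inverse FRAP at
30-s frames, 45-cell Monte-Carlo estimator checks, and a
seven-point expression series spanning 0.04×–10× the binding-site count.

## Known limitations

The continuum scheme yields mean-field curves only (no per-cell kinetic
noise; rendered Poisson noise is read-out noise, not molecular noise).
The bound-hopping coefficient is an effective parameter, not derived
from chromatin structure. Three-class segmentation assumes a
single-nucleus crop with visible background. The double-exponential
model is empirical — its time constants are not rate constants of the
binding model, which is why the simulator's ground truth, not the fit,
anchors the estimator tests.
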