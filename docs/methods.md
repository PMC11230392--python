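# Methods

`foragekit` analyses naturalistic foraging in a two-phase home-base assay:
a mouse lives in a home cage connected by a tunnel to a square arena with
four sand pots. In the 30-minute **Exploration** phase food sits in Pot2;
in the 30-minute **Foraging** phase (4 h later) the food is moved to Pot4
and buried, so the animal's behavior mixes goal-directed search with
memory responses toward the former patch. The package covers five stages:
cohort simulation, excursion segmentation, featurization, module
discovery, and the statistical battery. All statistics treat the mouse as
the unit of analysis.

## Arena geometry

Coordinates are centimetres, origin at the arena's lower-left corner.
Defaults: a 60 × 60 cm arena; a 12 × 12 cm home cage below it joined by a
6 × 8 cm tunnel; four pots of radius 5 cm at (12,12), (12,48), (48,48),
(48,12) (Pot1..Pot4); a centred "center" zone covering one third of the
arena side; everything else in the arena is "perimeter". Zone labels are
assigned per sample with precedence home > tunnel > pot > center >
perimeter; positions outside all zones are `out_of_bounds` and counted in
a QC report rather than rejected. Arena dimensions, pot layout and the
sampling rate are not fixed by the assay description we emulate, so all
are configurable; the defaults above are typical for mouse open-field
hardware.

## Synthetic cohorts

The simulator exists because the downstream methods need data with known
ground truth. Each mouse × phase timeline alternates home-cage dwells
(exponential, default mean 35 s; 90 s in the `paper_like` preset) with
round-trip excursions drawn from a mixture of **archetypes**. An
archetype fixes a zone itinerary, a duration and speed distribution, a
tortuosity level (Ornstein–Uhlenbeck heading noise, κ = 2 s⁻¹, σ = 1.2 ×
tortuosity), a digging probability, and a center-vs-wall routing bias.
Paths are generated by waypoint traversal at 5 Hz: the mouse steers
toward the next waypoint with OU-perturbed heading while in the arena and
travels straight in the tunnel corridor. If the realised travel time is
shorter than the drawn duration, the remainder is spent dwelling — at the
last pot of the itinerary when the archetype digs (slow jitter within the
pot radius, which also drives the dig-proxy measure), otherwise at the
farthest waypoint. An excursion that would be cut off by phase end is not
emitted; home dwell fills the gap, so every simulated excursion starts
and ends inside the home zone by construction.

Mixture weights are `softmax(base_logits[phase] + group_shift)` per
genotype × sex × age × phase cell, so group effects are planted as logit
shifts and recorded in the returned `GroundTruth` (per-excursion
archetype labels, group mixtures, second-guess profiles, gross-measure
shifts). Determinism comes from one global seed expanded with
`numpy.random.SeedSequence([seed, mouse, phase])`.

**Second-guessing.** Pot2 revisits during the Foraging phase are injected
as scheduled check excursions whose pot dwell in 1-minute bin *b* has
expectation `baseline + amplitude·1[b ∈ window]` for mice in the affected
groups (defaults: baseline 2 s/min, amplitude 10 s/min, window minutes
5–12, affected group aged wild-type females). Low-rate baseline dwell is
delivered as occasional ~8 s checks with matching per-bin expectation
rather than a visit every minute, keeping revisit counts realistic.

**Presets.** `paper_like`: 2 genotypes × 2 sexes × 2 ages, n = 24/cell
young and 12/cell aged (144 mice, matching the study scale of ~150), ten
kinematically distinct archetypes, phase-dependent base mixtures (no
Pot4-directed digging before food is buried there; novelty-driven center
exploration and long meanders only in Exploration), aged-knockout mixture
shifts concentrated in the Foraging phase, the second-guess peak in aged
wild-type females, and an age-related decrease in food consumed.
`null`: same archetypes, every group effect zero. `two_archetype_toy`:
two strongly separated archetypes (fast direct Pot4 visits vs slow,
tortuous Pot2 dig visits) and no effects.

The generator emulates zone-level routing, kinematic texture and planted
group differences; it does **not** emulate pose-level gait, tracking
dropouts, arena-edge wall-following dynamics, or inter-mouse variability
beyond the configured dispersions. Passing tests therefore demonstrate
the correctness and calibration of the analysis machinery on data whose
generating process is known — not that real tracking data satisfy the
same effect sizes.

## Segmentation

An excursion runs from the first sample after the mouse leaves the home
zone to the last sample before it re-enters (intervals half-open
`[t_start, t_end)`); tunnel samples count as neither home nor arena.
Home re-entry requires one full sample in the home zone. Excursions
shorter than `min_duration_s` (default 2 s) or penetrating less than
`min_penetration_cm` (default 5 cm, measured from the tunnel exit) are
flagged `too_short` / `shallow`; a sortie still open at phase end is
`unterminated`. Flagged excursions are retained in the table but
excluded from counts, features and statistics. The defaults are declared
choices — the assay description gives no minimum-excursion rule.

Gross measures per mouse × phase: valid-excursion count; latency to enter
the arena (phase duration if the mouse never leaves); total distance (sum
of consecutive-sample steps over the whole phase); relative time in
center (center seconds ÷ arena seconds, 0 if the arena is never entered).

## The 52-measure featurization

Each valid excursion (≥ 3 samples) is described by 52 measures in four
families — velocity (8), gait dynamics (12), trajectory geometry (16),
location (16); `measure_catalog()` lists them with units. The original
52-measure list behind this style of analysis is not public, so the
catalog here is a declared stand-in with the same family structure and
count, and is versioned so a user can substitute their own definitions.

Numerical conventions: speeds by central differences (`numpy.gradient`),
headings from consecutive displacement vectors, stops = speed < 2 cm/s
sustained ≥ 1 s, bursts = speed > 1.5 × the excursion mean, dig proxy =
time within a pot radius at < 1 cm/s. Spatial occupancy uses a square
grid with cell side equal to the pot radius anchored at the arena's
lower-left corner, so grid measures translate and scale with the
geometry. Tortuosity = path length ÷ max displacement from the tunnel
exit, capped at 50 when the displacement is under 1 cm. The "distance to
the current food pot" measure is phase-aware (Pot2 in Exploration, Pot4
in Foraging). Latency-type measures are censored at the excursion
duration when the event never happens.

Standardization is per-column z-scoring with the **population** SD
(divide by n), or a robust median/1.4826·MAD variant; zero-variance
columns are dropped, and the centers/scales/drops are stored so held-out
excursions can be projected identically. By construction all 52 measures
are invariant to translating the frame (with the geometry), length/speed
measures scale linearly with the coordinates, and time reversal swaps
entry and exit speeds while preserving totals — these are enforced by the
test suite.

## Module discovery

Modules are found by agglomerative clustering with Ward linkage on
Euclidean distance in the standardized feature space, over both phases
pooled. Labels are canonicalised (decreasing size, centroid tie-break)
so the partition is invariant to row order.

The module count K is selected by split-half reproducibility: for each
candidate K the rows are randomly halved `n_splits` times (default 20;
the pipeline uses 10), each half is clustered at K, every excursion is
assigned to each half's nearest centroid, the two half-solutions are
matched by Hungarian assignment on centroid distances, and each matched
pair scores the Jaccard overlap of its two member sets. Scores are
matched back to the full-data fit at that K, giving per-module stability
in [0, 1]. A candidate K is feasible when **every** module is at least
`min_size` (default 5) strong and at least `stability_threshold`
(default 0.5) stable; the chosen K is the largest feasible candidate.
Gating on the minimum rather than the mean is essential: a spurious
split of one real module can hide behind the other modules' high scores,
and the mean rule overclusters badly on planted-archetype data. All-equal
rows short-circuit to K = 1.

A caveat documented deliberately: behavioral feature spaces contain
reproducible continua (duration, speed, dig dwell), and Ward splits along
a continuum can be stable at the 0.5–0.9 level. The selected K therefore
counts *stereotyped, reproducible types*, which is generally finer than
the number of generating archetypes — consistent with real foraging
ethograms reporting dozens of modules. At threshold 0.95 only
fully-reproducible structure survives and the toy preset resolves to its
two planted archetypes exactly.

Phase occupancy: a module is expressed in a phase when at least
`occupancy_min` of its excursions fall there (operation default 1; the
pipeline uses 5 so that a single stray cross-phase assignment does not
flip a phase-unique module to shared); the Venn counts
(shared / Exploration-only / Foraging-only) always sum to K. Embeddings
(PCA, or a diffusion-map with adaptive-bandwidth gaussian kNN kernel,
symmetrised, row-normalised and powered 3 steps) are presentation-layer
only — no statistic consumes them.

## Statistical battery

* **Expression and diversity.** Per mouse × phase: module counts, totals,
  frequencies (sum to 1). Diversity = distinct modules ÷ total
  excursions, averaged over phases within mouse, then regressed per sex
  on age × genotype (OLS, coefficient t-tests).
* **Module-wise differential expression.** Within each sex × age × phase
  stratum, each module's per-mouse frequencies are compared between
  genotypes by a two-sided rank-sum test: exact p by tie-aware
  enumeration over all group assignments when min(n₁,n₂) ≤ 8, otherwise
  the tie-corrected normal approximation. Benjamini–Hochberg adjustment
  is applied across the modules of the stratum and significance is
  called at q < 0.2. The per-stratum significant-module counts feed a
  linear model `count ~ phase * age + sex`; the phase × age interaction
  is the reported test.
* **Gross measures.** Each of the six measures (center time, distance,
  excursion count, latency, food consumed, sand displaced) is modelled by
  OLS on age × genotype × sex × phase with cluster-robust (by mouse)
  covariance for the repeated phase factor; Holm-adjusted per-cell
  genotype contrasts are added wherever a genotype-involving term is
  significant.
* **Second-guessing.** Per-minute Pot2 dwell (bin b covers
  `[60(b−1), 60b)` s; 30 bins; per-bin values bounded by 60 s) is
  modelled with `statsmodels` MixedLM: dwell ~ genotype·sex·age +
  genotype·age·bin (bin numeric, centred), random intercept per mouse,
  REML, Wald z tests. The two reported terms are the genotype × sex ×
  age and genotype × age × bin interactions. Singular fits fall back to
  OLS with mouse-clustered errors (noted in the output). Cumulative
  curves are emitted alongside for plotting.
* **Genotype prediction.** Per-mouse profiles (6 gross measures + module
  frequencies) are z-scored; PCA retains components to 90% cumulative
  variance, capped at 10 **and at n/10** — with ~30 mice per stratum the
  asymptotic likelihood-ratio χ² is badly anti-conservative at 10
  parameters, and the events-per-parameter cap restores ~5% type-I error
  while keeping power against shifts along dominant profile axes.
  Logistic regression of genotype on the retained PCs is tested against
  the intercept-only model (likelihood ratio); per-PC Wald p-values and
  McFadden pseudo-R² (the package's tagged "variance explained" metric)
  are reported. Perfect separation triggers a ridge-stabilised refit,
  flagged in the result.

Degenerate inputs are resolved explicitly: all-constant rank-sum groups
give p = 1; a perfect linear fit with a ~zero coefficient reports p = 1
(no signal) rather than NaN; empty strata raise errors naming the
stratum.

## Validation batteries and problem sizes

The test suite validates each stage against independent oracles:
segmentation against an exhaustive per-sample reference; features against
closed-form kinematics and the invariance suite; exact rank-sum p against
brute-force enumeration up to 6 × 6; BH against the direct step-up
formula; clustering against planted Gaussian archetypes (5 types at ≥ 8σ:
K = 5, ARI ≥ 0.95 in ≥ 19/20 seeds).

The statistical batteries run at the cohort sizes they are calibrated
for: module FDR with 40 modules and n = 15/group over 200 simulations
(balanced planted design: three modules ×3 up from base frequency 0.02,
two ÷3 down from 0.09, conserving planted mass so the other 35 modules
are exactly null under the compositional model; mean total 45 excursions
per mouse, Dirichlet concentration 600); second-guessing with n = 12/cell
over 100 power and 100 null simulations at amplitude 20 s/bin (the
series-level generator is used here — trajectory simulation would only
add Monte-Carlo noise around the same planted profile); PCA-logistic
with n = 15/group over 200 simulations, profiles drawn from a 5-factor
latent structure with the 1.5 SD shift on the third factor (behavior
profiles are strongly correlated in practice; with isotropic
high-dimensional noise at this n the top sample eigenvectors are noise
and no PCA-based method could see the shift). End-to-end determinism is
checked by running a reduced cohort twice and comparing SHA-256 checksums
of every artifact, plus one full 144-mouse run for scale.

## Known limitations

* The 52-measure catalog is a documented stand-in, not the original list.
* K selection counts reproducible types, not generating archetypes; on
  continua it refines rather than recovers the archetype count.
* MixedLM Wald tests use the normal approximation (no Satterthwaite
  degrees of freedom).
* Frequencies are compositional; the rank-sum tests ignore the induced
  negative coupling, which matters when planted shifts are large and
  unbalanced (the FDR battery uses a balanced design for exactly this
  reason).
* Excursion-level pseudo-replication is handled only by per-mouse
  aggregation, matching the mouse-level unit of the original analyses.
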