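# Methods

## Pipeline model

The pipeline treats network definition as a two-constraint screening
problem: a cortical region enters the symptom network only if it is
(i) structurally wired to the hippocampal seed and (ii) its functional
connectivity (FC) to that seed carries information about the behavioral
score.

**Structural screen.** Tractography value maps are compared against
`fraction × max(map)` per subject, inclusive at the boundary
(`>=`), so the maximum-attaining unit is always retained and an
all-equal positive map keeps every unit rather than degenerating. The
default fraction is 0.15, the field-standard choice for probabilistic
tractography count maps. How per-subject decisions combine into a group
statement is genuinely underdetermined in practice, so the consensus
fraction is an explicit parameter (default 0.5: a region counts as
wired when suprathreshold in at least half the subjects). Voxel-level
maps reduce to regions by counting suprathreshold voxels and flagging
regions with at least `min_voxels` (default 1). Thresholding is scale
invariant; raising either the fraction or the consensus can only shrink
the retained set.

**Functional screen.** FC is the Fisher z of the full Pearson
correlation (partial correlation deliberately not used). Diagonals are
stored as NaN sentinels and excluded downstream; |r| = 1 between
distinct regions is treated as a degenerate input (duplicated signal)
unless the caller explicitly clips at 1 − 1e−7. Per hemisphere, the
selection GLM is a Gaussian-identity fit of the score on all ipsilateral
seed-cortex z values, the group indicator, and group-by-FC products.
Wald statistics use a t reference with residual degrees of freedom. The
default selection statistic is the simple slope of a designated group
(the HC reference by default), which makes the selection invariant to
how the group factor is coded and gives exactly one test per FC term —
the property that makes the null false-positive rate interpretable.
Interaction-based and either-group-slope rules are available as
configuration. No multiplicity correction is applied at the selection
step (recorded in the selection-rule metadata); corrections enter only
in the downstream family-tested analyses. The hippocampal seed is an
unconditional member of its own network.

**Graph layer.** Binarization keeps the `round(s·n(n−1)/2)` largest
off-diagonal weights (round half away from zero), ties broken by weight
descending then lexicographic node pair, so results are deterministic.
Conventions for the eight global properties, chosen once and surfaced
in the API docs because toolboxes differ:

- Cp: mean nodal clustering, degree < 2 contributing 0.
- Lp: mean shortest-path length over *connected* node pairs (an
  alternative largest-component-only convention would change values on
  disconnected graphs; connected-pairs was chosen because it uses all
  available path information at low sparsity).
- Eglobal: mean inverse shortest-path length, 1/∞ = 0, which handles
  disconnection without special-casing.
- Elocal: mean over nodes of the global efficiency of the
  neighbor-induced subgraph (0 for degree < 2).
- Assortativity: Pearson correlation of endpoint degrees over both edge
  orientations; NaN sentinel when endpoint degrees have no variance
  (regular graphs, stars).
- Hierarchy: β in `C ∝ k^(−β)` by least squares of log C on log k over
  nodes with degree ≥ 2 and positive clustering; NaN with fewer than 3
  eligible nodes or a single distinct degree.
- Synchronization: eigenratio `λ2/λmax` of the combinatorial Laplacian
  of the largest connected component (not its reciprocal); NaN for
  components smaller than 3.
- Sigma: `(Cp/⟨Cp_rand⟩)/(Lp/⟨Lp_rand⟩)` over degree-preserving
  double-edge-swap nulls, 10·|E| attempted swaps per null, 100 nulls by
  default (the null count is not dictated by any reporting convention;
  100 keeps the Monte-Carlo error of the ratio well below the
  between-subject spread). When no swap is admissible (complete graph)
  the nulls equal the graph and sigma is exactly 1.

AUC uses the trapezoidal rule on the actual grid spacing. NaN gaps are
dropped pointwise before integration and the fraction of defined grid
points is recorded per metric (`<metric>__coverage`); a curve more than
half undefined has NaN AUC. On very small networks (4–6 nodes) sigma and
hierarchy are undefined at many sparsity levels — this is a property of
tiny graphs, not an implementation artifact, and it is why the
group-by-property GLM skips near-constant or mostly-undefined AUC
columns (recorded in `attrs["skipped"]`) instead of reporting
ill-conditioned coefficients. An exactly constant property still raises
a collinearity error.

**Statistics layer.** Cohen's d uses the pooled-SD formula with the
normal-approximation CI `d ± z · sqrt(1/n1 + 1/n2 + d²/(2(n1+n2)))` and
is reported as an absolute value. Group tests default to the classical
equal-variance t-test (Welch behind a flag) and chi-square without
continuity correction. Bonferroni families are declared explicitly per
analysis (`p_adj = min(1, m·p)`). Moderation analysis mean-centers x
and m before forming the product (the conventional default for
moderated regression), reports both the raw interaction coefficient and
the fully standardized one (all three variables z-scored before the
product) so either reporting convention is inspectable, and builds the
interaction CI by case-resampling percentile bootstrap — 5000 draws by
default, batched over resamples with per-resample normal equations, and
fully determined by `rng_seed`. Simple slopes are evaluated at the
moderator mean ∓ 1 SD. BCa intervals were considered and left out: the
percentile interval is the simplest method whose coverage we can verify
by simulation, and the engine's replicated coverage at n = 200 is ≈
0.94–0.95 against the nominal 0.95.

## Synthetic cohort generator

The generator emulates the minimal data-generating process the pipeline
consumes; it is *not* a BOLD or diffusion simulator.

- **Time series:** T × R standard normal noise with a single-factor
  construction per planted pair: `target = r·seed + sqrt(1−r²)·noise`,
  `r = tanh(z_latent)`, `z_latent ~ N(latent_z_mean, latent_z_sd)` per
  subject. The population correlation of a planted pair is exactly `r`;
  everything downstream consumes only second-order statistics, so no
  temporal structure is modeled. Each target region is driven by at most
  one seed, hence per-seed target sets must be disjoint (validated).
- **Score:** `intercept + Σ β_group(pair)·z_sample(pair) +
  age_beta·(age − 67.5) + ecog_beta·(ecog − mean) +
  gamma·(age − 67.5)·z_sample(moderator) + N(0, noise_sd)`. The score
  uses each subject's *sample* Fisher z, not the latent value, so with
  `noise_sd = 0` the generated scores are exactly reconstructible from
  the generated data — the conservation property that makes stage
  composition exactly testable.
- **Structural maps:** planted targets draw `U(0.4, 1.0)` × scale,
  background `U(0, 0.05)` × scale, with a per-subject-seed scale jitter
  `U(0.5, 2)`. Since `0.05 < 0.15 × 0.4`, the 15%-of-max rule recovers
  the planted set for *every* admissible draw; widening the background
  range past the margin is how tests probe consensus behavior under
  violation.
- **Covariates:** age uniform on [55, 80] years; the daily-function
  (ECog-like) score Gaussian with mean 19.6, SD 6.4 — values seeded from
  typical elderly-cohort summaries.
- **Randomness:** one root seed split per subject by counter
  (`SeedSequence(seed, spawn_key=(i,))`), so enlarging a cohort never
  perturbs already-generated subjects.

### Named study conditions

- `study_config`: 58 HC vs 73 aMCI, seven planted effects with slope
  magnitudes 3.2–7.3 (matching the magnitudes a real cohort of this
  design reports), latent z mean 0.35 / SD 0.2, score noise SD 1.5,
  mild covariate slopes, moderation slope −0.05 through the right
  temporal-pole pair. At these settings per-pair power is deliberately
  moderate — the realistic regime.
- `strong_recovery_config`: n = 60 + 60, T = 200, all left-hemisphere
  candidates planted with |slope| ≥ 3.2, latent SD 0.3, noise SD 1.5,
  zero covariate/moderation slopes. A pilot power calculation (slope SE
  ≈ noise_sd / (√n_group · SD(z)) ≈ 0.63) puts per-pair power near
  0.997, so exact set recovery exceeds 90% by design, not tuning.
  Effects are confined to one hemisphere so that each per-hemisphere
  model contains all of its generating terms; with effects in both
  hemispheres the other hemisphere's terms act as omitted variables and
  exact zero-noise reconstruction is impossible by construction.
- `null_config`: structurally connected pairs with real FC variation
  but all slopes, covariate effects and moderation set to zero and pure
  Gaussian score noise — the condition under which the selection test's
  t-statistics are exactly calibrated.
- `zero_noise_config`: the strong regime with `noise_sd = 0`.

## What passing tests do and do not show

The generator plants exactly the structure the pipeline models: linear
FC-score coupling on the Fisher-z scale, Gaussian noise, stationary
series, no confounding between FC and covariates, no site or motion
artifacts, and structural maps whose margins make the threshold rule
exact. Passing tests therefore demonstrate correctness of the
computations and calibration under the assumed model — they do not
certify behavior under preprocessing artifacts, non-Gaussian noise,
FC-covariate confounding, or real tractography noise, where the
consensus fraction and selection rule become substantive choices.

## Problem sizes

Replication studies run at sizes chosen to pin the Monte-Carlo error
well below the bands they check: 200 cohorts for recovery (binomial SE
≈ 0.7% near a 99% rate), 200 null cohorts × 5 FC terms = 1000 tests for
the false-positive rate (SE ≈ 0.7%), 500 replicates for bootstrap-CI
coverage (SE ≈ 1%), 50 seeded graphs for oracle equivalence, and 31-point
sparsity grids throughout. The acceptance script uses 150/150/500
replicates for the same quantities.

## Known limitations

- Scores are unbounded linear constructs; real recall scores live on
  0–12 and are discrete. The GLM family is Gaussian-identity for the
  same reason the analysis treats the score as continuous.
- Graph metrics on networks below ~8 nodes are dominated by sentinel
  values; the pipeline reports them faithfully but group inference on
  such AUCs is mostly vacuous.
- The moderation engine detects the study-condition planted moderation
  (|gamma| = 0.05) only weakly at n = 131 — a power statement, visible
  directly in driver 06's output.
- `run_all` analyzes the left-hemisphere network in its graph stage
  (the symptom-defined network of interest); the right network is
  identified and persisted but not graph-analyzed by default.
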