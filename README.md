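# symnetmap

Mapping a symptom-based cortico-hippocampal network under a joint
structural-functional constraint, with graph-theoretic and moderation
analyses — built for researchers studying memory decline in amnestic
mild cognitive impairment (aMCI) who want the full analysis chain
testable against planted ground truth.

## The problem and the method

Long-term delayed recall (the AVLT part-5 score) is the symptom that
best separates aMCI patients from healthy controls (HC). The pipeline
defines the cortical-hippocampal network that carries this symptom in
four steps and then characterizes it:

1. **Structural constraint.** Per subject and hippocampal seed, a
   tractography connectivity value map over cortical targets is
   thresholded at 15% of its maximum (`value >= 0.15 * max`); a region
   is a candidate node when it is suprathreshold in at least a consensus
   fraction (default 0.5) of subjects.
2. **Functional connectivity.** FC between regions *i, j* is the Fisher
   z of the Pearson correlation of their mean time series,
   `z_ij = atanh(r_ij)`.
3. **Node selection.** Per hemisphere, a Gaussian-identity GLM

   `score ~ b0 + b_g·group + Σ_k b_k·z_k + Σ_k c_k·(group × z_k)`

   relates the score to the ipsilateral seed-cortex FC values. With HC
   as reference, `b_k` is the HC simple slope and `b_k + c_k` the aMCI
   slope; a candidate joins the network when its simple-slope p-value is
   below alpha (0.05) and it is consensus structurally connected.
4. **Graph properties.** Each subject's network FC matrix is binarized
   at every sparsity `s` in 0.15–0.45 (step 0.01, 31 levels) by keeping
   the `round(s·n(n−1)/2)` strongest edges, and eight global properties
   are computed per level — assortativity, hierarchy (exponent of
   `C ∝ k^(−β)`), synchronization (Laplacian eigenratio `λ2/λmax`),
   small-world sigma `(Cp/Cp_rand)/(Lp/Lp_rand)` against
   degree-preserving rewired nulls, Cp, Lp, Eglobal, Elocal — each
   summarized by its trapezoidal AUC over the grid.

Downstream statistics mirror a case-control study: two-sample tests with
Cohen's d, Bonferroni-corrected Pearson correlations, per-property
group-by-property GLMs on the AUCs, and moderated regression
(`y ~ x + m + x·m`, mean-centered) with percentile-bootstrap CIs (5000
case resamples) for the interaction.

Because no public cohort exists for this design, `symnetmap.synthetic`
generates cohorts with planted ground truth — latent seed-cortex FC,
group-specific FC→score slopes, guaranteed-margin structural maps, and
an age-by-FC moderation term — so every stage is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic cohort (58 HC vs 73 aMCI, seven planted seed-cortex effects
with slope magnitudes 3.2–7.3) and write tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_structural_constraint.py
...
python analysis/07_recovery_calibration.py
```

Driver 04 prints the identified networks, e.g.:

```
HIP.L: selected ['HIP.L', 'PCUN.L', 'SFGdor.L', 'SOG.L', 'SPG.L']
     planted ['LING.L', 'PCUN.L', 'SFGdor.L', 'SOG.L', 'SPG.L'] -> differs
HIP.R: selected ['HIP.R', 'SMA.R']
     planted ['SMA.R', 'STGp.R'] -> differs
```

At study-realistic sample size and noise the selection recovers most but
not all planted nodes — exactly the regime where single-cohort node sets
should be read cautiously. Driver 07 quantifies the operating
characteristics in the strong-effect regime:

```
planted-node recovery rate (strong effects, 200 replicates): 0.995
FC-term false-positive rate at alpha 0.05 (global null, 1000 tests): 0.055
```

i.e. when every structurally connected candidate carries a slope of
magnitude ≥ 3 the planted node set is recovered essentially always,
while under the global null the selection test rejects at its nominal 5%
level.

A library-level example of the effect-size engine:

```python
>>> from symnetmap import cohens_d
>>> cohens_d(6.71, 1.88, 58, 2.07, 1.47, 73)   # delayed recall, HC vs aMCI
EffectSize(d=2.7895..., ci_low=2.303..., ci_high=3.275...)
```

a ~2.8-SD group separation — delayed recall is by far the strongest
discriminator among the cohort's cognitive scores.

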