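# Methods

## Scope and model

qsarize fits multiple linear regression (MLR) QSAR models,
Y = a0 + Σ aᵢXᵢ, for small congeneric series — the regime where a chemist
has a few dozen analogues of one scaffold and wants an interpretable model
with honest validation rather than a black-box learner. The workflow is
fixed: parse SDF + activities → compute descriptors and fingerprints → drop
unusable descriptor columns → optional correlation filter → train/test
split → forward selection on the training set → OLS fit → validation →
applicability-domain (AD) assessment → prediction for up to two new sets.

Assumptions worth stating: activities are on a single consistent scale
(pIC50; IC50 µM inputs are converted as −log10), the compounds form one
chemical series so that a global linear model in a few descriptors is
plausible, and the user has verified structures beforehand (no tautomer or
protonation standardization is attempted).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `test_ratio` | 0.2 | fraction drawn per activity stratum into the test set |
| `correlation_threshold` | 1.0 | pairs with \|Pearson r\| ≥ threshold are thinned; 1.0 disables removal |
| `n_descriptors` (k) | max(2, n_train // 5) | the one-in-five rule: at least five training compounds per fitted coefficient guards against chance correlation |
| `ad_threshold` | 3 | a compound with any model descriptor ≥ 3 training standard deviations from the training mean (\|S_ki\| ≥ 3, inclusive) is outside the domain |
| `fingerprint_bits` | 1024 | hashed path-based (Daylight-style) fingerprints; only relative similarities matter |
| `seed` | 0 | seeds a dedicated `numpy` Generator for the test-set draw; no global random state is touched |

All thresholds of the reliability verdict (Q² > 0.5, R² > 0.8,
R²_pred > 0.6, strict) and the overtraining gap (R² − Q² > 0.3) are the
conventional rough reliability criteria for MLR QSAR and are fixed
constants, not tuning knobs.

## Design choices where the design was open

- **Activity-stratified splitting.** "Selection based on the activities" is
  implemented as quantile stratification: compounds sorted by activity are
  cut into min(5, n//5) equal strata and round(ratio × size) compounds are
  drawn per stratum. This keeps the test set spread over the activity range.
  The global activity minimum and maximum are forced into training so the
  test set never extrapolates — common QSAR practice.
- **Forward-selection objective.** Greedy reduction of training RSS
  (equivalently, R² gain), ties toward earlier column order. Candidates
  whose addition would make the design rank-deficient, *or* would give some
  training compound leverage 1 (e.g. a column constant except for one
  compound, which makes that compound's LOO prediction undefined), are
  skipped: a model this package cannot LOO-validate is not a useful model
  here.
- **Selection outside the LOO loop.** LOO refits re-estimate coefficients
  but not the descriptor set. This matches the pipeline order (selection
  happens once, on the full training set) and is the cheap, conventional
  variant; it makes Q² optimistically biased relative to a full
  selection-inside-LOO scheme. Users should read Q² accordingly.
- **Correlation filter.** Pearson correlation on raw descriptor values,
  computed before the split on the whole table. From each offending pair
  the member with the larger mean absolute correlation to all remaining
  columns is dropped (caret-style), ties toward the later column; the
  boundary is inclusive (≥ threshold). With the default threshold of 1.0
  nothing is removed and redundant columns are instead handled by the
  rank/leverage guards during selection.
- **AD rule.** Only the standardized-descriptor rule gates applicability
  (inclusive at the threshold, by absolute value). Tanimoto similarity is
  reported but never gates: there is no principled universal similarity
  cutoff. The `Tanimoto_*_sum` result attributes are per-compound
  (max, mean, min) summary tables — the maximum answers "is there any
  training compound like this one", the mean and minimum describe the
  spread.
- **Two all-zero fingerprints** compare as similarity 1 (no bit
  distinguishes them); this convention only matters for pathological
  featureless inputs.
- **3D descriptors** are computed only when *every* molecule of a set has
  3D coordinates; otherwise those columns are zero for all molecules. This
  keeps training and prediction sets column-compatible; mixed sets trigger
  a warning. Zero-filled 3D columns are then constant and are removed by
  `drop_invalid` before modeling.

## Numerics

- OLS is fit by `statsmodels` on an explicit intercept-augmented design
  after a rank check that names the collinear columns.
- LOO residuals use the exact hat-matrix identity e_i/(1 − h_ii) rather
  than n refits; the test suite verifies equality with literal refits to
  1e-10.
- Standard deviations for standardization use the sample (ddof = 1)
  convention, training compounds only.
- Quantile strata are formed with `numpy.array_split` over the stable
  activity sort, so ties are resolved deterministically by file order;
  per-stratum test counts use floor(x + 0.5) rounding.
- Degenerate inputs fail loudly: empty molecule lists, all-constant
  descriptor tables, test activities all equal to the training mean,
  rank-deficient designs and unit leverages all raise with a message
  naming the offending stage or columns.

## The synthetic series generator

`SyntheticSpec`/`generate_series` builds a para-substituted benzanilide
scaffold decorated with one of ~50 small substituents (methyl … cyclohexyl,
phenyl, CF₃, halogens, small ethers/amines), computes real RDKit
descriptors, and plants a linear activity on k_true = 3 of them:
pIC50 = 2.8 + Σ effectᵢ·zᵢ + N(0, noise_sd), with effects (1.0, −0.8, 0.6)
on *standardized* descriptors (so effect sizes are scale-free regardless of
raw descriptor units) and noise_sd = 0.1 pIC50 — effect-to-noise ratios of
6–10, i.e. a clearly modelable series with activities spanning roughly
1.5–4, as in a typical reported inhibitor series. Informative descriptors
are drawn seeded from columns with enough distinct values and pairwise
|r| < 0.5, so the planted signal is identifiable.

`generate_newset` mimics the follow-up-compound scenario: `in_domain`
re-uses substituents of mid-activity training compounds (descriptor values
inside the training range by construction); `out_of_domain` grafts
substituents far larger than anything in the pool (C24 chains, branched
C37), pushing size-sensitive descriptors many training standard deviations
out.

What the generator does *not* emulate: real binding physics (the planted
activity is literally linear in descriptors), experimental error structure
(noise is i.i.d. Gaussian), activity cliffs, 3D conformational diversity
(all structures are 2D), or assay censoring. Passing tests therefore
demonstrate that the statistical machinery is correct and that the workflow
recovers a linear signal when one exists — not that real series of this
size will yield reliable models.

## Problem sizes

The default suite and examples use series of 30–40 compounds with an ~20%
test draw, k = 6 selected descriptors from ~150 usable columns, 50-replicate
recovery simulations at n = 40 with 20 noise descriptors, and seed sweeps
over 20 seeds — sizes representative of real congeneric-series QSAR
practice, where datasets of 20–50 analogues are the norm.

## Known limitations

- Q² is optimistic when many descriptors are screened (selection bias, see
  above); the seed search compounds this by picking the best of many
  splits. Both are faithful to the mirrored workflow and are standard
  criticisms of it.
- Descriptor-set parity with any other descriptor engine (e.g. the CDK
  descriptor set) is not attempted; the math is descriptor-agnostic and the
  group tags are a static name-based classification of RDKit's set.
- The explicit-index and seeded split routes cannot both reproduce a given
  published partition unless the original seed semantics are known.
- No PLS, machine-learning regressors, y-randomization, or leverage
  (Williams-plot) AD; the AD verdict rests on the standardized-descriptor
  rule alone.
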