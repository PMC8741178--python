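# Methods

## Problem and model

Proteins adsorb to ssDNA-wrapped single-walled carbon nanotubes from a
biofluid, forming a corona whose composition is measured by label-free
LC-MS/MS. `nanocorona` treats corona membership as a binary classification
problem over sequence-derived descriptors: the positive (in-corona) class
is defined operationally from abundance data, and a tree-ensemble learns
the mapping from physicochemical/exposure features to that label.

## Corona labeling

Membership is decided by two criteria, applied in order:

1. **Enrichment** — A_corona > A_biofluid (strict). Enrichment on the
   particle relative to the fluid is direct evidence of adsorption.
2. **Abundance threshold** — the non-enriched proteins' corona abundances
   are modeled as an exponential decay n = n₀·exp(−kA); the cutoff is
   A_threshold = p/k, the abundance at which the decay has fallen by
   exp(−p). A protein with A_corona > A_threshold is in the corona even if
   depleted: substantial depletion can coexist with a large absolute
   amount in the corona.

The default rate estimate is the exponential MLE k̂ = 1/mean(A_corona over
non-enriched proteins with A > 0), which is deterministic and bin-free. A
histogram mode (ordinary least squares on log bin counts, √n equal-width
bins, recovering n₀ as well) is retained because the decay could equally
be fitted to binned counts; both give the same p/k scaling but different
finite-sample k̂. Which binning the original analysis used is not
decidable from the available description, so the bin-free estimator is the
default.

Conventions: strict `>` at both comparisons (a tie at exactly A_threshold
is out); proteins with zero corona abundance and no enrichment are always
out; the default power is p = 2.25, the value at which the downstream
classifier's accuracy/AUC/precision/recall trade-off is best in the
original sweep of p ∈ [0, 3.5]. Labels are invariant to rescaling all
abundance columns by any c > 0, since k̂ scales as 1/c — abundance units
only need to be internally consistent.

## Feature set

The default registry has 75 features in six groups:

| group | count | contents |
|---|---|---|
| aa_fraction | 20 | fraction of each standard residue |
| global | 8 | length, molecular weight, aromaticity, instability index, GRAVY, pI, charge at pH 7, mean flexibility |
| structure | 4 | helix {V,I,Y,F,W,L}, turn {N,P,G,S}, sheet {E,M,A,L}, non-structure remainder |
| exposure_vs_total | 20 | exposed residues of each type / all standard residues |
| exposure_vs_exposed | 20 | exposed residues of each type / all exposed residues |
| exposure_global | 3 | mean RSA, total ASA, exposed fraction |

Numerical conventions, chosen as the de-facto standards of the
sequence-analysis toolkit this field uses:

- Hydropathy: Kyte–Doolittle. Instability: Guruprasad DIWV dipeptide
  weights, 10/L × Σ. Isoelectric point: bisection on the
  Henderson–Hasselbalch net charge with the Bjellqvist pKa set, 0.01 pH
  tolerance. Molecular weight: average residue masses minus one water per
  peptide bond.
- Flexibility: Vihinen normalized B-factor scale, nine-residue window with
  center-peaked symmetric weights (0.25, 0.4375, 0.625, 0.8125, 1.0,
  mirrored) normalized by their sum; the profile is averaged over all
  L − 8 full windows. For L < 9 the unweighted mean of the per-residue
  scale is used (logged). A homopolymer scores exactly its residue's scale
  value.
- The structure propensity sets overlap (L in helix and sheet, A in
  sheet), so the four fractions need not sum to 1; non-structure is
  exactly 1 − fraction(union). The aggregate of the windowed flexibility
  profile is the mean (the natural choice where no aggregate is
  specified).
- Ambiguous residues X/B/Z/U/O are kept in the sequence but excluded from
  every numerator and denominator, keeping all fractions normalized over
  standard residues.

Min-max scaling maps each feature to [0, 1]; a constant feature maps to 0
and unseen values are clipped. By default the fit uses the complete table
before any train/test splitting — this replicates the original processing
order and means the scaler sees test rows (a mild, bounded leak since only
two scalars per feature cross the split); fitting on the training split
only is supported and preferable for new studies.

## Solvent exposure

Real runs ingest NetSurfP 2.0 CSV exports. A residue is exposed iff
RSA ≥ 0.25 (inclusive), NetSurfP's own exposed/buried convention; the
cutoff is configurable because the original processing does not state it.
When no exposure file is given, a deterministic stand-in assigns exposure
probability logistic(−hydropathy) per residue — hydrophilic residues
surface-seeking — thresholded at 0.5 (or Bernoulli-sampled under a seed),
with RSA placed on the consistent side of the 0.25 cutoff and
ASA = RSA × maximal ASA (Tien et al. theoretical set). This heuristic
exists so fixtures and tests run offline; it has no scientific standing,
and feature tables carry an `exposure_source` provenance column
(netsurfp / heuristic / none) so downstream users can tell which predictor
produced the exposure block.

## Classifier and validation

Random forest, 700 trees, entropy criterion, unlimited depth, behind a
pluggable factory keyed by `ClassifierConfig.kind`. The in-corona class is
the minority; each training split is augmented with SMOTE before fitting:
synthetic minority points x_i + u·(x_j − x_i) with x_j among the 12
nearest minority neighbors (Euclidean distance in the scaled space),
u ~ U(0, 1), up to a 0.7:1 minority/majority ratio. SMOTE is applied
strictly inside the training split; an explicit leakage mode (oversample
first, then split) exists only to quantify how much that classic mistake
inflates recall.

Validation: stratified shuffle split, 100 repeats, 10% held out, scoring
accuracy, probability-rank ROC AUC, precision and recall with the
in-corona class positive. Aggregates are the mean and a percentile
(2.5/97.5) 95% CI over splits — percentile rather than normal-theory
because split scores are bounded and skewed near 1. A single-class test
split (possible only in degenerate configurations) leaves that split's
AUC missing and excluded. Cross-biofluid transfer trains on all of fluid A
and tests on random stratified subsets of fluid B sized to 10% of the
combined corpus: f = 0.1·n_total/n_B, capped at 1. Grid search wraps the
same validation (reduced repeats) and maximizes a chosen metric
(precision by default); ties prefer fewer trees, then shallower depth. The
shipped default grid is modest and makes no claim to replicate any
particular published search.

Prediction: probability = fraction of trees voting in-corona;
in-corona ⇔ probability ≥ 0.5 (ties in).

## Feature analysis

The ANOVA F statistic is computed from its definition (between-group mean
square over within-group mean square; for two groups F = t² of the
pooled-variance t) rather than delegated, with F ≡ 0 for a globally
constant feature and +∞ when only the within-group variance vanishes; ties
in the ranking break lexicographically. Staged feature addition re-runs
the full validation on the top-n features for n = 1..m under a shared seed
stream, so the n = m row is bit-identical to a plain validation run.
Downstream analyses default to the top 38 features, the count at which
classifier performance peaks before declining slightly with the full set.
Impurity importances are the ensemble's mean impurity decrease, normalized
to sum 1. Class-conditional KDEs use Gaussian kernels with Scott's
variance-based bandwidth on a 256-point grid over [0, 1]; each curve is
renormalized by its trapezoid integral over the grid because a Gaussian
KDE evaluated on a bounded interval loses tail mass at the boundaries.

## Synthetic data

The generator emulates the study conditions every test runs under:

- **Sequences**: residues i.i.d. from UniProt-average frequencies; the
  in-corona class doubles glycine and halves leucine frequency
  (renormalized) — the composition contrast the real corona exhibits.
  Default 200 proteins per class, lengths uniform in [80, 300].
- **Abundances**: non-enriched proteins A_corona ~ Exp(k_true = 0.01) with
  A_biofluid = A_corona·U(1, 3) (never enriched); enriched proteins
  A_biofluid ~ Exp(k_true) with A_corona = A_biofluid·U(1.5, 5). In full
  scenarios the enriched subset is the true in-corona class, so the
  planted signal survives abundance-based labeling; standalone abundance
  draws use a Bernoulli(0.3) enriched fraction, matching the ~30%
  in-corona prevalence of the real corpus.
- **Exposure**: heuristic per-residue calls, seeded.

What the generator does **not** emulate: dipeptide/secondary structure
along the chain (instability and flexibility behave as noise features),
MS missing-value mechanisms, batch effects, or correlated abundance
structure. Passing tests therefore demonstrate that the pipeline's
machinery — descriptors, threshold fit, imbalance correction, validation
plumbing — is correct and recovers planted signals; they do not certify
classification accuracy on real proteomes.

## Problem sizes and numerics

Validation-heavy analyses in the test-suite and the acceptance script run
at the generator's default scale (400 proteins, 75 features, 100 splits,
700 trees) for the headline quantities, and at reduced tree/split counts
where only a structural identity (determinism, staged-curve equality) is
being checked, since those identities hold for any configuration. The
staged-curve identity is exercised on a 6-feature subset for the same
reason. Null-scenario AUC is a property of one finite dataset: for a
fixed 400-protein draw the 100-split mean AUC concentrates near 0.5 but
retains a dataset-level spread of a few hundredths, which is why the
chance band is stated as [0.45, 0.55] rather than a point.

## Known limitations

- The registry is a faithful reconstruction of the descriptor families,
  not a certified copy of any published 91-feature table; it is
  configurable for exact matching if such a table is available.
- The heuristic exposure predictor is a plumbing stand-in; conclusions
  about exposure features on real data require NetSurfP runs.
- Min-max scaling before splitting is the replicated default but is a
  known (mild) information leak; prefer the fit-on-train mode for new
  work.
- Probabilities are raw tree-vote fractions, uncalibrated.
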