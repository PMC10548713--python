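# Methods

## Problem and representation

The unit of classification is an 11-residue peptide window centered on a
candidate arginine (half-width γ = 5, configurable). Positives are windows
whose central R carries the methylation class under study (mono- or
di-methylarginine); negatives are the remaining R-centered windows of the
same proteins. Windows that would extend past a protein terminus are padded
with `X` rather than discarded, so annotated sites near termini are kept
and every window has the same length; `X` is inert in every feature
computation. Whether the original benchmarks padded or discarded terminal
sites is not documented anywhere we know of, so results on termini-heavy
data may differ between tools.

Two dataset rules are worth stating explicitly:

* arginines annotated with *any* methylation class are excluded from the
  negative pool, even when building the other class's dataset — a
  di-methylated arginine is not an unmodified one;
* negative windows whose residue string is identical to some positive
  window are dropped (they would plant label contradictions), but
  duplicate negatives are otherwise retained, so the negative pool is not
  silently shrunk.

Class balance is restored, when requested, by uniform random
under-sampling of the majority class, seeded.

## Feature system (434 dimensions)

**AAC (20).** `A_i = N_i / l` with `l` the full window length (11),
alphabetical residue order. Pads contribute nothing to the numerator but
stay in the denominator, which keeps terminal windows on the same scale as
internal ones.

**DPC (400).** Ordered adjacent-pair counts over the 400 standard
dipeptides, also divided by `l`. Dividing by `l` rather than the pair
count `l − 1` is deliberate — it is the convention this feature system is
defined with — and a `dpc_denominator="l-1"` switch exists for sensitivity
checks. Pairs containing a pad are not counted.

**ITB (4).** Four entropies of the window's residue distribution
`p_i = N_i / l`, in bits (base-2 logs throughout):

* Shannon: `SE = −Σ p_i log2 p_i`
* Havrda–Charvát: `HE = (2^(1−α) − 1)^(−1) (Σ p_i^α − 1)`
* Rényi: `RE = (1 − α)^(−1) log2 Σ p_i^α`
* Arimoto: `AE = (2^(α−1) − 1)^(−1) ((Σ p_i^(1/α))^α − 1)`

with the conventions `0·log 0 = 0` and zero-probability terms omitted.
The order parameter α must be positive and ≠ 1; the default is α = 2 (the
collision-entropy choice), recorded in model metadata, because no
canonical value is established for this application. Relative forms
against the uniform background `p0 = 1/20` and the information gain
`SE − relative SE` are computed by `entropy_block` and available as extra
features, but are not part of the 434-vector, which uses exactly
[SE, HE, RE, AE]. Numerical notes: for a *proper* distribution (no pads,
Σp = 1) HE, RE and AE all converge to SE as α → 1, and the implementation
reproduces this to 1e-3 bits at α = 1 ± 1e-4; for padded windows Σp < 1
and the HE/AE limits legitimately differ from SE. The relative Arimoto
form contains `p0^(1/(α−1))`, which explodes as α → 1; it is evaluated in
log space and saturates to ±inf instead of overflowing.

**PP (10).** ProtParam-style descriptors of the de-padded residue string,
in order: isoelectric point, molecular weight, aromaticity, instability
index, GRAVY, extinction coefficient (reduced), extinction coefficient
(oxidized), helix fraction, turn fraction, sheet fraction. The underlying
constants ship as versioned TSV assets with literature citations
(Kyte–Doolittle hydropathy; the Guruprasad 400-entry DIWV table;
Bjellqvist pKa values; standard average residue masses; Gill–von Hippel /
Pace 280 nm coefficients Trp 5500, Tyr 1490, cystine 125 M⁻¹cm⁻¹).
Details:

* pI: Henderson–Hasselbalch net charge with position-specific terminal
  pKa values, bisection on pH ∈ [0, 14] to a bracket of 0.01 (or
  |charge| < 1e-4). Unlike some implementations we do not clamp the search
  interval, so arginine-rich peptides can report pI > 12.
* Instability index: `10/L · Σ DIWV(pair)` over adjacent non-pad pairs,
  `L` the non-pad length; values above 40 flag instability.
* Extinction: the oxidized variant assumes `floor(nC/2)` cystine bridges;
  reporting both variants is what makes the block 10-dimensional for the
  nine named properties.
* Secondary-structure fractions use the classic ProtParam residue classes
  (helix VIYFWL, turn NGPS, sheet EMAL). Newer revisions of these classes
  exist (e.g. current biopython uses EMALK/NPGSD/VIYFWLT); we pin the
  classic convention and bundle it as data.

Nine of the ten descriptors are linear or near-linear functions of window
composition at fixed length — an important caveat when reading feature
attributions, since they correlate strongly with the AAC block.

## Classifiers and training protocol

The default classifier is `RandomForestClassifier` with the tuned
hyperparameters n_estimators 250, max_depth 40, max_features log2,
min_samples_split 3, max_samples 1.0. The forest itself is a vetted
library implementation; the contract is bagged randomized trees with
seedable, probability-valued output. DT/SVM/KNN/NB baselines use library
defaults (SVM with probability outputs enabled), all recorded in run
manifests. `grid_search` performs an exhaustive search scored by mean
stratified-CV accuracy — a single non-nested CV over the training data —
with ties broken toward the first-listed candidate; the shipped grids are
the standard 11 tree counts {10, 50, …, 500} and 10 depths {10, …, 100}.

## Evaluation

Threshold metrics (ACC, SEN, SP, precision, F1, MCC) are computed directly
from their defining ratios at probability threshold 0.5 (configurable);
any zero-denominator metric reports 0 and is flagged `degenerate` rather
than raising or returning NaN. ROC and PR curves sweep the unique scores
with ties grouped; areas are trapezoidal, which makes the AUC equal to the
Mann–Whitney pairwise statistic and invariant under monotone score
transforms.

Cross-validation is stratified k-fold (default k = 10) with per-fold
metrics averaged across folds — the "mean of ten models" convention — and
a pooled-confusion mode behind a flag, since both conventions are common
and they differ on imbalanced folds. Repeated CV (default 50×) reshuffles
with seed `master + r` for repeat r, so one repeat reproduces a plain
k-fold run exactly; the reported std is across per-repeat means. The
imbalance protocol is a stratified 70/30 split with under-sampling applied
to the training portion only; the test portion keeps the natural class
ratio, where the PR curve — whose random baseline is the positive
prevalence — is the informative summary. The feature-ablation runner
cross-validates one model per feature-block combination, defaulting to the
standard eleven combinations of {AAC, PP, DPC, ITB}.

## Explanation

Attributions are Shapley values of the positive-class probability against
a seeded background (default 100 training rows, recorded in metadata). For
tree ensembles we compute the *interventional* Shapley values exactly: for
each (foreground, background, leaf) triple the coalition game is an
AND-game whose Shapley contribution has a closed form, and summing over
leaves and averaging over the background gives attributions whose total
telescopes to `f(x) − mean f(background)`. Local accuracy therefore holds
to float precision (audited at 1e-6; observed ~1e-14), and dummy features
receive exactly zero. We chose the interventional formulation over
path-dependent tree traversal because its baseline semantics are explicit
and it does not leak attribution onto features merely encountered on tree
paths. One implementation subtlety: scikit-learn trees compare
float32-cast inputs against float64 thresholds, and the kernel mirrors
that cast so samples sitting exactly on a threshold route identically.
The kernel is numba-compiled; cost is O(visited leaves × path length) per
(sample, background) pair per tree (~2 s for 50 samples × 100 background
rows × 250 trees).

Non-tree models fall back to a seeded permutation estimator, which also
satisfies local accuracy exactly (each permutation's marginal
contributions telescope) but is only stochastically exact per feature.

Global summaries rank features by mean |attribution| (ties broken
alphabetically), tally block membership of the top-k, and export
(feature value, attribution) pairs with value quartiles for beeswarm-style
plots; a small matplotlib helper renders them, but plot rendering is not
part of the core pipeline.

## Synthetic benchmark generator

The generator emulates the one robust, explanation-level finding about
arginine methylation contexts: methylated arginines sit in glycine-rich
RG/RGG-like neighborhoods, so glycine composition and the RG dipeptide are
the discriminative features a sound pipeline should recover. Positive
windows force each position adjacent to the central R to glycine with
probability `signal_strength` (creating RG and GR dipeptides) and draw the
remaining flanks with a mild glycine enrichment (0.15 × signal_strength);
negatives draw all flanks from the background (default uniform). The
enrichment of non-adjacent flanks is deliberately mild so that the
adjacency motif — not a diffuse composition shift — is the defining class
difference; with a strong diffuse shift, correlated descriptors (molecular
weight, turn fraction, entropies) absorb much of the attribution and the
planted dipeptide becomes unidentifiable, which would defeat the
generator's purpose of providing a known explanation ground truth.

At `signal_strength = 0` positives and negatives are exchangeable,
providing a calibrated null (cross-validated AUC ≈ 0.5). The protein-level
generator emits random proteins (100–500 residues), annotates a subset of
their arginines (all of them in the imbalanced regime: ~1 positive per 27
negative R sites, mimicking realistic site prevalence) and rewrites the
surrounding flanks with the same signal, then round-trips through the
FASTA/annotation readers.

What the generator does *not* emulate: evolutionary conservation, real
methyltransferase substrate specificity beyond the compositional proxy,
protein-level sequence redundancy, or realistic residue background
frequencies. Passing the end-to-end tests therefore shows that the
pipeline recovers a planted compositional signal and calibrates correctly
on a null — not that it attains any particular accuracy on biological
benchmarks, which depend on curated data this package does not ship.
Because the planted signal lives in composition space it necessarily leaks
into the entropy block (glycine enrichment lowers Shannon entropy), so
entropy-only models are weak but not exactly at chance; the ablation
ordering (all blocks ≥ entropy-only) is the meaningful comparison.

## Problem sizes and numerical choices

The reference synthetic conditions used by the test suite and the
acceptance script are 200 + 200 windows at signal strength 0.8 (seed 42),
a 100-row background and 50 explained samples for attribution audits, and
a ~30-protein imbalanced benchmark (~500–900 R sites) for the 70/30
protocol — sizes at which every protocol, including full 10-fold CV with
the 250-tree forest, runs in seconds while leaving clear margins between
signal, null and chance. Other fixed choices: probability threshold 0.5
for threshold metrics; under-sampling and fold shuffling driven by
explicit integer seeds; report JSONs formatted at 6 significant digits so
identical runs are byte-identical.

## Known limitations

* The 434-vector is composition-heavy; only DPC carries local order, so
  windows with equal composition and pair counts are indistinguishable.
* The two-extinction reading of the 10-entry physicochemical block is an
  interpretation (nine properties are named for a 10-wide block); it
  follows the convention of reporting both redox variants.
* pI, MW, instability and GRAVY on an 11-mer are descriptors of a peptide
  fragment, not of the parent protein; they are features, not predictions
  about the protein.
* Real-data performance claims require real benchmarks (UniProt-derived,
  redundancy-reduced); this package reproduces protocols, not published
  benchmark numbers.
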