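# Methods

## Duplex-stability encoding

A core promoter is the 100-nt window −80…+20 around the transcription
start site; TSS-relative coordinates skip 0 and the TSS is +1. The window
is encoded by replacing each of its 99 overlapping dinucleotides with a
nearest-neighbor duplex free energy ΔG°₃₇ (kcal/mol, stored signed and
negative; "higher stability feature value" therefore means a *less*
stable, AT-richer stack). Feature *j* carries the TSS-relative position
of the dinucleotide's 5′ base, so downstream reports can speak of
"position −27" directly.

The default table is the unified oligonucleotide nearest-neighbor ΔG°₃₇
set (37 °C, 1 M NaCl), shipped as a plain text config
(`src/promdds/data/unified_nn_dg37.txt`, `XY: value` lines). The table is
deliberately data, not code: nearest-neighbor parameterizations differ
across temperature/salt conditions, and any 16-entry alternative can be
loaded with `load_dds_table`. Validation requires exactly the 16 ACGT
dinucleotides, finite values, and no duplicates; the shipped values are
closed under reverse complement (a stack and its complement are the same
duplex).

Ambiguous bases are rejected by default (strict policy); an optional
`ambiguous="mean"` policy substitutes the table mean for any dinucleotide
touching a non-ACGT base. Strictness is the default because silently
imputed features would contaminate training data.

## Sequence handling

FASTA I/O goes through Biopython; TSS tables are TSV with columns
(contig, tss_1based, strand, id) — 1-based TSS input is the convention of
transcriptome maps, converted internally to 0-based half-open forward
coordinates. Window extraction returns the 5′→3′ sequence on the
annotated strand (reverse-complemented for minus-strand genes); windows
falling off a contig raise a boundary error, and batch extraction skips
and logs them so window accounting stays conservative
(n_windows = n_annotated + n_skipped).

Negative controls are per-sequence shuffles. The default is a uniform
mononucleotide permutation (single-pass generator permutation), which
preserves length and base composition; a dinucleotide-preserving mode
(random Eulerian walk on the doublet transition graph) is available for
sensitivity checks but is not the default, mononucleotide shuffling being
the simplest reading of "a shuffled version". Datasets built from
positives are exactly 1:1 balanced by construction.

## Synthetic study conditions

The generator emulates the archaeal core-promoter architecture at desk
scale. Background bases are i.i.d. at a configurable GC fraction
(default 0.5). The default planted elements are

| element | pattern | position | planting probability |
|---|---|---|---|
| BRE (purine pair) | `RR` | −33…−32 | 0.5 |
| TATA-box | `TTTAWA` | −31…−26 | 0.8 |
| PPE | `WW` | −11…−10 | 0.5 |

Each element is planted independently with its probability; IUPAC codes
are sampled uniformly over their allowed bases. Overlapping element
definitions are rejected at spec construction. The BRE is shipped as the
2-nt purine pair adjacent to the TATA-box rather than a longer motif so
the default elements tile −33…−26 without overlap.

The separable scenario used by the acceptance checks plants only the
TATA-box, with probability 1, at −31…−26: positives then deterministically
carry six AT-only stacks at fixed positions while their shuffles carry
AT-rich stacks at random positions, which is learnable but not trivial
(the classes share global composition exactly).

Toy genomes embed generated promoter windows verbatim (alternating
strands, reverse-complemented on −) between i.i.d. intergenic filler, so
extraction round-trips bit-identically by construction — that round-trip
is itself a test of the coordinate arithmetic.

What the generator does *not* emulate: positional drift of the TATA-box,
organism-specific dinucleotide autocorrelation, transcription-factor
binding sites outside the core elements, and genome-scale base
composition heterogeneity. Passing tests therefore demonstrate that the
pipeline recovers planted positional AT-richness signals; they do not
certify performance on real archaeal data.

## Classification and evaluation

The classifier is sklearn's `SVC` with the RBF kernel at its default
hyperparameters (C = 1.0, γ = "scale", i.e. 1/(n_features · Var X)); no
feature standardization is applied by default, with an opt-in flag that
z-scores inside each training fold (leakage-safe). Polynomial, linear and
sigmoid kernels are selectable; none is privileged in the evaluation
code. Benchmark baselines (LDA, CART, KNN) run at library defaults on
byte-identical fold assignments, verified by a fold hash.

Evaluation is stratified 10-fold cross-validation (0.9/0.1 train/test per
fold). Per-fold metrics are accuracy, precision, recall, specificity (as
percentages), Cohen's κ, and trapezoid AUC over the full ROC sweep; folds
are averaged as mean ± sd. A metric whose denominator is zero is reported
as NaN, never as 0. The decision threshold is 0 on the signed decision
function; probability calibration is out of scope.

## Shapley explanation

The explained model function is the signed SVM decision value, not the
hard label — a continuous output makes attributions informative and the
efficiency identity meaningful.

*Exact engine.* For M ≤ 15 features, all 2^M coalitions are enumerated
and φ_i = Σ_S |S|!(M−|S|−1)!/M! · (f(S∪{i}) − f(S)), with masked inputs
taking the instance's value where the coalition is 1 and a background
reference where 0. This engine is the oracle for the estimator and for
the axiom tests (efficiency to 1e−10, symmetry, dummy).

*Kernel estimator.* For M = 99, coalitions are sampled with subset sizes
drawn proportional to the aggregated Shapley kernel
(M−1)/(C(M,s)·s·(M−s))·C(M,s) ∝ 1/(s(M−s)) and uniform membership given
size, so sampled rows enter the weighted least squares with equal
residual weights. The all-ones and all-zeros coalitions are always
included: the all-zeros output fixes the base value φ₀ and the all-ones
output enforces efficiency exactly, by eliminating the last coefficient
(φ_M = f(x) − φ₀ − Σφ_i) from the regression. With all 2^M coalitions
supplied, the estimator reproduces the exact values to solver round-off
(the regression formulation of the Shapley value); the test suite checks
agreement to 1e−6 at M ≤ 10. Default budget is 2M + 2048 coalitions per
instance — a standard accuracy/cost balance at M = 99.

*Background reference.* The masked model needs a value for absent
features; the default is the feature-wise mean of a seeded 100-row sample
of the training matrix. A single mean keeps the masked model at one
evaluation per coalition, which is what makes explaining 100 instances at
M = 99 cheap. The reference is a genuinely open choice (different
references shift φ₀ and redistribute small credit); it is exposed as a
parameter for sensitivity analysis.

*Summaries.* Global importance is mean |φ| per position (ties broken
upstream-first), with a directional summary splitting instances at each
feature's median value. Dinucleotide-class impact averages φ over
AT-composed (AA/AT/TA/TT), GC-composed (GG/GC/CG/CC) and mixed features.
Per-instance reports list the top-k (default 9) positions by |φ|.
Explaining "100 non-repeated random promoters" (without-replacement
sampling, seeded) is the default batch design.

## Motif scanning and consensus extraction

IUPAC scanning is position-exact and case-insensitive; a sequence counts
once if any 5′ offset inside the search window (default −32…−24 for
TATA accounting) matches. Presence fractions are therefore monotone
non-decreasing in window width.

Consensus extraction slides a fixed-width frame (default 6; 6–8 is the
TATA-appropriate range) across a window and keeps the frame maximizing
summed column information content Σ p·log₂(p/q) against a zero-order
background q estimated from the input sequences — an explicit,
reproducible criterion standing in for interactive motif-discovery
pipelines. Each column emits the smallest IUPAC code covering ≥ 75% of
its bases; the threshold yields compact degenerate codes while tolerating
noise.

## Annotation scanning

A trained model annotates extracted upstream windows with a 0/1 label and
the retained decision score (users can re-threshold). Per-organism
summaries report window counts, predicted counts and percent, AT%, and
optionally motif presence and the mean stability profile of the predicted
set. Outputs are FASTA + BED (0-based half-open, strand and score
columns) + TSV. The Pearson correlation between per-organism predicted
counts and AT% uses the same correlation routine as profile comparison.
Profile comparison reports each set's peak as the least-negative mean
position; with a model trained on balanced data and windows carrying no
signal, the predicted fraction sits near the 50% base rate — that
behavior is deliberate and surfaced rather than hidden.

## Problem sizes and determinism

The shipped study conditions are 500 promoters per class for
classification (10-fold CV), 100 explained instances at 2M + 2048
coalitions each, 50 reseeded shuffled-control draws for profile nulls,
and 10 synthetic organisms × 150 windows for the scan correlation; the
full acceptance recomputation completes in well under a minute on one
CPU. Every stochastic step takes an explicit seed (generator draws,
shuffles, fold assignment, coalition sampling, background subsampling);
repeated runs with one seed are bit-identical. Derived per-instance seeds
are folded modulo 2³¹.

## Known limitations

- The encoding carries no strand-asymmetric information beyond the
  nearest-neighbor table itself; promoters on both strands are handled by
  extraction, not by the model.
- Kernel-SHAP variance at the default coalition budget is small for
  positional rankings but individual φ_i for weak features remain noisy;
  exact values are only feasible for M ≤ 15.
- The consensus extractor is a single-motif, fixed-width, zero-or-one
  occurrence model; it does not attempt expectation-maximization
  discovery or E-values.
- Synthetic validation bounds what can be claimed about real genomes (see
  the generator section); applying a model trained on one organism set to
  distant genomes inherits all the usual domain-shift caveats.
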