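# promdds

Archaeal promoter annotation from DNA duplex stability.

Archaeal core promoters are compositionally distinctive: an AT-rich
TATA-box around position −27 upstream of the transcription start site
(TSS), flanked by a BRE element (−33/−32) and a promoter-proximal element
(−11/−10). Because AT dinucleotide stacks hold the double helix together
more weakly than GC stacks, this architecture leaves a thermodynamic
fingerprint that a classifier can learn without any motif alignment.
`promdds` is a toolkit for researchers annotating regulatory regions in
archaeal (or other AT-signal-driven) genomes: it encodes promoters as
duplex-stability profiles, trains and evaluates a classifier against
shuffled negative controls, explains its decisions position by position
with Shapley values, and scans upstream regions of annotated genomes for
putative promoters.

## The method

**Encoding.** A core-promoter window spanning −80…+20 around the TSS
(100 nt; positions skip 0, TSS = +1) is slid over with two-nucleotide
windows. Each dinucleotide *s*<sub>i</sub>*s*<sub>i+1</sub> is replaced by
its nearest-neighbor free energy ΔG°₃₇(*s*<sub>i</sub>*s*<sub>i+1</sub>)
in kcal/mol, giving a fixed-length vector of 99 features labeled by
TSS-relative position (−80…+19). The default parameter set is the unified
oligonucleotide nearest-neighbor table; any 16-entry table can be
substituted from a plain config file.

**Classification.** An RBF-kernel support-vector machine (C = 1,
γ = "scale") separates promoters from per-sequence shuffled negatives
(1:1 class balance), evaluated by stratified 10-fold cross-validation
with accuracy, precision, recall, specificity, Cohen's κ, ROC and AUC.
Polynomial/linear/sigmoid kernels and LDA/CART/KNN baselines are
available for benchmarking on identical folds.

**Explanation.** Feature attributions are Shapley values
φ<sub>i</sub> = Σ<sub>S⊆N∖{i}</sub> |S|!(|N|−|S|−1)!/|N|! ·
(f<sub>S∪{i}</sub>(x) − f<sub>S</sub>(x)), computed two ways: exact
enumeration of all 2^M coalitions (the oracle, M ≤ 15) and the
kernel-weighted least-squares estimator for the full 99 features, with
the efficiency identity φ₀ + Σφ<sub>i</sub> = f(x) enforced as an
equality constraint. Attributions are summarized as global positional
importance, AT-class vs GC-class dinucleotide impact, and per-instance
top-k reports.

**Scanning.** A trained model annotates TSS-anchored upstream windows of
whole genomes; per-organism summaries report window counts, percent
predicted as promoters, AT composition, TATA-consensus presence
(IUPAC scanning, e.g. `TTTAWA` in −32…−24), and longitudinal stability
profiles of the predicted set.

## Worked example

```python
import numpy as np
from promdds import *
from promdds.dds import FeatureMatrix
from promdds.shapley import align_matrix

spec = PromoterModelSpec(seed=0)            # TATA at -31..-26, BRE, PPE
promoters = generate_promoters(spec, 300, seed=0)
dataset = build_labeled_dataset(promoters, seed=1)   # + shuffled negatives
X = encode_batch(dataset.records)
y = np.array([r.label for r in dataset.records])
print(X.values.shape)                        # (600, 99)

report = stratified_cv(X.values, y, k=10, seed=2)
print(report.mean["accuracy"], report.mean["auc"])
# 86.0 % accuracy, 0.92 AUC (+/- 3.5 and 0.03 across folds)

model = train_classifier(X, y, kernel="rbf", seed=3)
pos = FeatureMatrix(values=X.values[y == 1], position_labels=X.position_labels,
                    ids=tuple(np.array(X.ids)[y == 1]))
bg = background_reference(X.values, size=100, seed=4)
expl = explain_sample(model, pos, bg, n_explain=50, seed=5)
gi = global_importance(expl, align_matrix(pos, expl))
print([int(p) for p in gi.ranking()[:5]])
# [-29, -27, -31, -28, -12]

print(motif_presence(promoters, "TTTAWA", window=(-32, -24)).fraction)
# 0.817
```

The cross-validated SVM reaches 86% accuracy and 0.92 AUC on this
synthetic set, and the five most important positions by mean |φ| fall in
the planted TATA-box (−31…−27) and at the promoter-proximal element
(−12) — the model's decisions track exactly the elements the generator
planted. The motif-presence fraction (0.817) recovers the 0.8 planting
probability plus background chance matches.

The same workflow is available from the shell:

```sh
promdds --seed 3 run-all --outdir run/
promdds encode promoters.fasta --out features.tsv
promdds scan genome.fasta tss.tsv --model run/model.joblib --outdir scan/
```

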