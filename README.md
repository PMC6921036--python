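# cppqsar

QSAR modeling of cell-penetrating peptides (CPPs) on an amino-acid
z-scale, with a companion one-compartment intravenous-infusion
pharmacokinetic model.

CPPs are short (< 40 residue), typically polycationic and often
amphipathic peptides that cross cell membranes and can ferry covalently
attached drug cargo into cells. Predicting whether a candidate sequence
is a CPP from its physicochemical makeup is a classic peptide-QSAR
problem, and this package implements the full pipeline for it:

1. **z-scale construction** (`cppqsar.zscale`) — each of the 20 natural
   amino acids is reduced to three principal-property scores
   (z1 ≈ size/shape, z2 ≈ polarity/lipophilicity, z3 ≈ charge) by PCA of
   an autoscaled residues × physicochemical-properties table. A
   published three-component scale ships as packaged data;
   `build_scale` reconstructs scales of the same kind from any table.
2. **Peptide descriptors** (`cppqsar.descriptors`) — whole-sequence
   descriptors on that scale: mean z-scores; the z-scale helical moment
   μ = |Σₙ Hₙ e^{i n δ}| (the Eisenberg hydrophobic-moment construction
   with the hydrophilicity scale replaced by each z-component, δ = 100°
   per residue for an α-helix); |N-terminal − C-terminal| mean
   differences at three truncation depths; side-chain steric bulk; net
   hydrogen-bond donation; Arg/His/Lys/Asp/Glu counts, total and mean
   net charge; and the hydrophilic-residue ratio.
3. **Dataset assembly** (`cppqsar.datasets`) — deduplication, class
   balancing by seeded random deletion, six terminal-truncation dataset
   variants and a random 50 % train/test split.
4. **PLS-DA classification** (`cppqsar.plsda`) — a NIPALS partial
   least squares regression of the 0/1 class code on the autoscaled
   descriptor matrix, thresholded at 0.5; cross-validated
   Q² = 1 − PRESS/TSS; and held-out sensitivity, specificity, accuracy
   and Matthews correlation coefficient (×100):

   MCC = 100 · (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

5. **Infusion pharmacokinetics** (`cppqsar.pk`) — the analytic
   one-compartment model for a constant-rate IV infusion,
   C(t) = (F·R₀/CL)(1 − e^(−kt)) during infusion and mono-exponential
   decay after it, with AUC₀₋∞ = F·Dose/CL and
   Cmax = (F·R₀/CL)(1 − e^(−k·T_inf)).
6. **Synthetic corpora** (`cppqsar.synthetic`) — labeled peptide sets
   with CPP-like positives (cationic, anion-depleted, optionally
   amphipathic) and random negatives, plus low-rank property tables
   with known latent scores, so the entire pipeline is testable with no
   external data.

## Worked example

```python
import numpy as np
from cppqsar import (GeneratorConfig, generate_corpus, split, descriptor_table,
                     load_published_scale, fit, evaluate, q2,
                     GEMCITABINE, simulate_infusion)

scale = load_published_scale()
corpus = generate_corpus(GeneratorConfig(n_per_class=450, separation="strong", seed=17))
train, test = split(corpus, fraction=0.5, seed=17)
X_train = descriptor_table(list(train.peptides), scale)
X_test = descriptor_table(list(test.peptides), scale)
model = fit(X_train.to_numpy(), np.array(train.labels), n_components=3,
            feature_names=list(X_train.columns),
            training_sequences=train.sequences)
report = evaluate(model, X_test.to_numpy(), np.array(test.labels), test.sequences)
print("Q2 =", round(q2(X_train.to_numpy(), np.array(train.labels), 3, seed=17), 3))
print(report["counts"])
print({k: round(v, 1) for k, v in report["metrics"].items()})

profile = simulate_infusion(GEMCITABINE)
print({k: round(float(v), 4) for k, v in profile.summary().items()})
```

prints

```
Q2 = 0.738
{'tp': 205, 'tn': 222, 'fp': 15, 'fn': 8}
{'sensitivity': 96.2, 'specificity': 93.7, 'accuracy': 94.9, 'mcc': 89.8}
{'cmax_ug_per_ml': 6.0158, 'tmax_h': 1.0, 'auc_0_t_ug_h_per_ml': 7.4367, 'auc_0_inf_ug_h_per_ml': 7.4367}
```

The classifier recovers the held-out labels of the strongly separated
synthetic corpus almost perfectly (450 test peptides; 8 false negatives,
15 false positives), and its cross-validated Q² of 0.74 says roughly
three quarters of the response variance is predicted out-of-fold. The PK
block simulates a 1250 mg gemcitabine dose infused over 1 h
(clearance 168 L/h, central volume 1.45 L/kg at 70 kg body weight,
F = 0.99949): the plasma curve peaks at 6.02 µg/mL exactly at the end of
the infusion and carries a 24-h AUC of 7.4367 µg·h/mL — identical to
F·Dose/CL because elimination (k ≈ 1.66 h⁻¹) leaves no tail beyond 24 h.

The same pipeline is scriptable from the shell:

```sh
cppqsar synth --preset strong --seed 7 --out corpus.fasta
cppqsar dataset --in corpus.fasta --seed 7 --out-train train.csv --out-test test.csv
cppqsar descriptors --in train.csv --out dtrain.csv
cppqsar train --desc dtrain.csv --components 3 --seed 7 --out model.json
cppqsar evaluate --model model.json --test dtest.csv --out report.json
cppqsar pk --params gem.yaml --out profile.csv --summary summary.json
```

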