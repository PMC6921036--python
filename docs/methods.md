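# Methods

## Amino-acid z-scale

A z-scale assigns each natural amino acid a small vector of
principal-property scores so peptides can be treated numerically.
`build_scale` takes a residues × properties table, mean-centers and
unit-variance-scales every column (sample standard deviation,
ddof = 1 — the convention of standard chemometrics software), and
eigendecomposes the resulting correlation matrix. Residue scores are
projections onto the leading unit-norm eigenvectors; explained-variance
fractions are the corresponding eigenvalue shares. The decomposition is
deterministic (no iterative randomness), and autoscaling makes the
result invariant to per-property units and to pre-scaling of the input.

PCA signs are arbitrary, so components are oriented by anchor
properties chosen to match the components' usual interpretation:
molecular `volume` positive on z1 (size/shape), `QPlogPo/w` positive on
z2 (polarity/lipophilicity), net charge `Tot Q` positive on z3
(electronics). When an anchor is absent the largest-magnitude loading
is made positive.

Degenerate inputs: a table whose rows are all identical carries no
information after centering and yields all-zero scores; a table where
only *some* columns are constant raises an error naming the offending
columns (a constant property is almost always a data-preparation
mistake). `n_components` is capped at `min(n_residues − 1,
n_properties)`.

The packaged three-component scale (`data/zscale.csv`) is published
reference data for the 20 natural residues and is shipped verbatim; the
original 12-property input matrix behind it is not public, so that
scale cannot be regenerated and `build_scale` is validated on synthetic
tables with known latent structure instead. All downstream descriptor
math uses the packaged values and therefore does not depend on any
scale-construction convention.

## Peptide descriptors

Peptides are validated at construction against the 20-letter alphabet
(upper-cased; unknown characters reported with their position).
Termini are treated as capped (N-acetyl / C-amide), so only side chains
contribute charge: positives {Arg, Lys, His} at +1, negatives
{Asp, Glu} at −1. The positive/negative count ratio is undefined (NaN)
when a peptide has no anionic residues; in the numeric feature vector
that case is mapped to the positive count itself (denominator clamped
to 1) so model matrices stay finite.

The z-scale helical moment generalizes the Eisenberg hydrophobic
moment: with Hₙ the chosen z-component of residue n,

    μ = sqrt( (Σₙ Hₙ sin nδ)² + (Σₙ Hₙ cos nδ)² ),   n = 1…N,

with δ = 100° per residue (ideal α-helix) by default and exposed as a
parameter. μ is the modulus of a complex sum, hence non-negative,
invariant to the index origin, and — less obviously — invariant to
sequence reversal (reversal conjugates and rotates the sum). All three
z-components' moments are computed, since peptide amphipathicity can
express itself on any of them.

The hydrophilic ratio is the percentage of residues in
{R, K, D, E, N, Q, S}, rounded half-up to an integer. This is the
minimal standard hydrophilic set consistent with the published
reference ratios for Penetratin (63 %), Cys-Penetratin (59 %), pVEC
(44 %) and Cys-pVEC (42 %); note that **His is excluded** (including it
breaks pVEC's 44 %) and **Thr is excluded** — its membership is
undecidable from those four sequences, none of which contains Thr, Gly
(as hydrophilic candidate) or Tyr.

Side-chain steric bulk (mean non-hydrogen atoms) and net hydrogen-bond
donation (mean donors − acceptors) use packaged per-residue tables
(`data/sidechain.csv`). Heavy-atom counts follow standard residue
chemistry (Gly 0 … Trp 10). Donor/acceptor counts follow the
convention donors = side-chain N–H/O–H hydrogens, acceptors =
side-chain N/O acceptor sites (e.g. Arg 5/1, Lys 3/1, Asp 0/4,
Ser 1/2, Trp 1/0); the table is an editable CSV precisely because
donor/acceptor counting conventions differ between tools, and all tests
reference the packaged table rather than any external truth.

Terminal differences |mean_z(N-fragment) − mean_z(C-fragment)| are
computed for three fragmentations: halves (N-half gets the extra
residue of odd-length sequences), first/last 5, and first/last 10.
Sequences shorter than a fixed cut use the whole sequence for both
fragments — difference identically zero — with a warning, since no
defensible alternative exists for, say, a 4-mer's "first 10".

The full descriptor vector has 28 features in a fixed, documented order
(`DescriptorVector.feature_names()`), stable across peptides and runs.

## Dataset assembly

Deduplication keeps the first occurrence of each exact (case-normalized)
sequence; a sequence observed with *both* labels is contradictory
evidence and every copy is removed (and logged). Balancing deletes a
uniformly random (seeded) subset of the majority class down to the
minority size. The train/test split is simple random — deliberately
not stratified, since the motivating protocol describes a plain random
50 % extraction; a stratified variant exists behind a flag. Every
random operation appends its seed to the dataset's `seed_log`, so any
derived set is regenerable from its manifest.

Truncation follows the rule that the N-terminal half is the longer one
for odd lengths, so `n_half + c_half` reconstructs every sequence
exactly; `first_k`/`last_k` return the whole sequence when it is
shorter than k.

## PLS-DA

Class membership is coded 0/1 and regressed on the autoscaled
descriptor matrix by PLS1-NIPALS with deflation: per component, the
weight vector is iterated to convergence (change in weights < 1e−10,
cap 500 iterations — immediate for a univariate response, but the
general loop is kept), scores and loadings are extracted, and X and y
are deflated. Prediction uses the standard regression vector
B = W(PᵀW)⁻¹q on training-frozen centering/scaling statistics; class 1
is called when ŷ ≥ 0.5. The 0/1-coding-plus-threshold convention is
equivalent up to affine recoding to the class-coding conventions of
commercial chemometrics suites. Constant descriptor columns are kept
(with a warning) at unit scale: after centering they are identically
zero, so their weights and coefficients vanish and predictions equal
those of a model with the column dropped, while the fit/predict schema
stays stable.

Q² = 1 − PRESS/TSS with PRESS summed over out-of-fold squared errors
and TSS about the overall response mean. Folds (default 7, a common
chemometrics-software default) are assigned by seeded shuffle; each
fold's training part must contain both classes. When the component
count is not fixed by the user, it is chosen to maximize Q² over 1…10
and the selection trace is stored in the model metadata. Evaluation on
held-out data refuses any test sequence that also appears in training.

Performance metrics are reported on a 0–100 scale: sensitivity
100·TP/(TP+FN), specificity 100·TN/(TN+FP), accuracy
100·(TP+TN)/total, and MCC ×100. Metrics with zero denominators are
flagged undefined (NaN) rather than raised, so batch evaluation never
aborts on a degenerate confusion matrix.

## Pharmacokinetic model

The infusion model is the textbook one-compartment linear system:
V = Vc·BW, k = CL/V, R₀ = Dose/T_inf;
C(t) = (F·R₀/CL)(1 − e^(−kt)) while infusing and
C(T_inf)·e^(−k(t−T_inf)) afterwards. Closed forms:
AUC₀₋∞ = F·Dose/CL (independent of V and T_inf — mass balance
CL·AUC = F·Dose holds to machine precision) and
Cmax = (F·R₀/CL)(1 − e^(−k·T_inf)), attained exactly at the end of the
infusion. Units are mg, L, h; concentrations in µg/mL ≡ mg/L. The
default grid is 1441 points over 24 h (1-minute resolution) with the
infusion-end time always included, since the curve is not smooth there;
AUC₀₋ₜ is trapezoidal over the grid.

This deliberately simple model is a surrogate for full
physiologically-based simulations: for the gemcitabine reference
parameters (1250 mg, 1 h infusion, CL 168 L/h, Vc 1.45 L/kg, 70 kg,
F = 0.99949) it reproduces the reference AUC values exactly
(7.4367 µg·h/mL; 7.4405 at F = 1) and peptide-conjugate Cmax to
< 0.01 %, while its gemcitabine Cmax (6.02 µg/mL) sits ~1.2 % above the
reference full-PBPK value (5.9505) — tissue distribution that a
one-compartment model cannot represent accounts for the gap, which is
documented rather than fitted away. Plasma-protein binding,
blood/plasma ratio, liver concentrations and solubility are carried as
annotations only; no tissue model is implied.

## Synthetic data generator

`generate_corpus` emulates the *compositional* statistics that separate
CPPs from inactive peptides, not any real corpus's sequence
distribution. Positives draw residues i.i.d. with a configurable total
probability mass on Arg+Lys (presets: weak 0.20, moderate 0.32, strong
0.45 — bracketing the cationic content of canonical CPPs), Asp+Glu
reduced to 1 % total mass (known CPPs carry almost no anionic
residues), and His held at the 5 % background frequency (His is itself
cationic; letting the Arg/Lys boost dilute it would create a spurious
anti-His signal no real corpus has). Negatives are compositionally
near-uniform random peptides, matching the common practice of using
randomly generated sequences as the inactive class. With the
`amphipathic` flag, every ~3.6th position of a positive (i, i+3/i+4
spacing, the 100°-per-residue helical period) is overwritten with an
apolar residue {L, I, F, W}, giving positives a helical face and making
the z-scale moment genuinely discriminative. CPP-like shaping applies
only when a composition gap is requested; a null configuration
(equal cationic fractions, amphipathicity off) draws both classes from
one distribution, which is what makes chance-level classifier behavior
on null data a meaningful check. Lengths are uniform on a configured
range (default 5–30 residues, the typical CPP regime; default corpus
size 450 + 450, matching the scale of the motivating balanced corpus
of 900 CPPs). Classes use disjoint random streams spawned from one
seed, and generated sets are exactly deduplicated within and across
classes.

What passing tests on this corpus do and do not show: they demonstrate
that the descriptor set carries the charge/amphipathicity signal and
that the PLS-DA machinery extracts it; they do not certify performance
on experimentally validated CPP corpora, whose negatives are partly
real (not random) sequences and whose positives are far more
heterogeneous than an i.i.d. composition model.

`generate_property_table` builds residues × properties tables as
orthonormal centered latent scores × orthonormal loadings with
geometrically decaying component strengths (4, 2, 1), plus i.i.d.
Gaussian noise. Loading rows are rotated pairwise (preserving column
orthogonality) until every property receives equal signal variance, so
the correlation-matrix PCA downstream is a uniform rescale of the
generating structure and per-component score recovery is well defined.
The generating scores are returned for recovery tests.

## Numerical and design notes

- Mean z-scores of any peptide lie inside the per-component min/max of
  the scale (convexity of the mean) — used as a property test.
- The published per-*peptide* z-scores of the four reference CPPs are
  **not** the simple sequence means of the per-residue scale (the
  projection that produced them is not disclosed); they are therefore
  not used as an assertion surface anywhere. The sequence-mean value
  for Penetratin z1 (2.1898) is asserted against an independent
  hand-summation oracle instead.
- Half-up rounding for the hydrophilic ratio matches the published
  62.5 → 63 behavior; Python's bankers' rounding would give 62.
- NIPALS orthogonality of score vectors and monotone decrease of the
  deflated-X norm in the component count are asserted as invariants;
  predictions are cross-checked against an independent PLS
  implementation to 1e−10.
- Test problem sizes (450 + 450 corpora × 20 seeds for classifier
  recovery, 50 seeds for PCA recovery, 10⁵-point PK grids) were chosen
  so the whole suite runs in well under a minute while keeping
  stochastic margins wide; the recovery medians sit ~5–25 points above
  their bounds.

## Known limitations

- The z-scale cannot be regenerated from public data; `build_scale` is
  validated only on synthetic tables.
- Position-specific (per-residue) modeling, secondary-structure
  prediction, OPLS/kernel-PLS variants and multiclass discrimination
  are out of scope.
- The PK surrogate has no absorption, tissue-partitioning or
  protein-binding mechanics; it is valid exactly for IV infusion with
  linear elimination.
- The hydrophilic-set membership of Thr/Gly/Tyr is conventionally
  excluded/excluded/excluded here but is empirically unconstrained by
  the four reference peptides.
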