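# Methods

## Model

A protein is represented six ways. Three descriptors use only the
sequence; three use the PSI-BLAST position-specific scoring matrix
(PSSM), an L×20 log-odds profile whose columns follow the alphabetical
one-letter residue order everywhere in this package (profiles read from
PSI-BLAST files are re-mapped from the file's own column header).

Each descriptor is min–max scaled per dimension on the training samples
(test values clipped to [0, 1], constant dimensions mapped to 0) and
converted to an RBF Gram matrix. The six kernels are combined convexly
with weights learned by centered kernel alignment and the combined
kernel is used by a soft-margin SVM in precomputed-kernel mode.

### Sequence descriptors

**GE** maps residues to 6 physicochemical classes
({A,V,L,I,M,C}, {F,W,Y,H}, {S,T,N,Q}, {K,R}, {D,E}, {G,P}), partitions
the sequence by successive halving into 1+2+4+8 = 15 segments (earlier
segments absorb remainders), and records per segment the 6 class
compositions and the 15 unordered adjacent-pair transition frequencies:
15 × 21 = 315 values.

**MCD** maps residues to 7 classes
({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}), cuts the
sequence into quarters Q1–Q4, and evaluates the composition /
transition / distribution (C/T/D) triple (7 + 21 + 35 = 63 values) on 14
regions: the 10 contiguous runs (Q1, Q2, Q3, Q4, Q12, Q23, Q34, Q123,
Q234, Q1234) and the 4 discontinuous unions Q1∪Q3, Q2∪Q4, Q1∪Q4,
Q1∪Q2∪Q4, giving 14 × 63 = 882. Discontinuous regions are concatenated
before counting transitions. The distribution descriptor records, per
class, the positions (as fractions of region length) of the 1st, 25%,
50%, 75% and 100% occurrences (ceil rank convention); an absent class
contributes five zeros. The published description of these two
descriptors names them without construction detail, so the groupings and
the region list are explicit conventions of this package, kept as
module-level constants so they can be swapped without touching the
encoders.

**NMBAC** evaluates, for six physicochemical properties
(hydrophobicity, hydrophilicity, side-chain volume, polarity,
polarizability, solvent-accessible surface area; raw values shipped as a
packaged TSV), the lagged autocorrelation
(1/(L−d)) Σᵢ P(sᵢ)P(sᵢ₊d) for lags d = 1..lg. Properties are
standardized to mean 0, sd 1 over the 20 residues before use — the
"normalized" in the name; tests pin the standardization invariant rather
than the raw numbers, so updating the table is a data change only.

### Profile descriptors

**PsePSSM** standardizes each PSSM column over positions (population sd;
constant columns → 0) and emits the 20 column means followed, lag-major,
by θ_{j,t} = (1/(L−t)) Σᵢ (m_{i,j} − m_{i+t,j})² for t = 1..lag. Both
blocks use the standardized matrix (single convention).

**PSSM-AB** splits the rows into 20 contiguous blocks (leading blocks
absorb remainders, the same rule as MCD/GE segmentation) and emits each
block's 20 column means.

**PSSM-DWT** runs a 4-level db4 wavelet cascade (symmetric padding) down
each raw column and emits (max, min, mean, sd) of the approximation
coefficients at each level. The cascade is applied level by level, so
any benchmark-length sequence (≥ 50 residues) decomposes without
truncation warnings; detail coefficients are excluded by default.
Wavelet, level count and statistics are configuration options.

## Kernel combination

For kernels K₁..K_m and labels y, with U = I − (1/N)𝟙𝟙ᵀ:

* aᵢ = ⟨U Kᵢ U, y yᵀ⟩_F, computed as yᵀ(U Kᵢ U)y — the N×N outer product
  y yᵀ is never materialized, and centering is done by row/column mean
  subtraction rather than multiplying by U.
* M_ef = ⟨U K_e U, U K_f U⟩_F — a Gram matrix under the Frobenius inner
  product, hence PSD.
* W_ij = cosine similarity of the **raw** kernels (a config switch uses
  the centered ones; M already owns the centered products, so raw is the
  default), D = diag(row sums), L = D − W.

The weights solve min_β βᵀ(M + λL)β − 2βᵀa on the simplex. The QP is
solved by SLSQP with the analytic gradient from the uniform start, after
dividing the objective by the data magnitude so the solver's absolute
tolerances are meaningful at any N (the minimizer is invariant to this
scaling). SLSQP is deterministic; the solution is checked in tests
against an exhaustive simplex grid (step 0.02). Weight components in
[−10⁻⁹, 0) are clipped to 0 and the vector renormalized; larger
violations raise. Since RBF kernels are strictly positive, W is fully
connected and β(λ) → uniform as λ → ∞; at λ = 0 the program reduces to
plain centered-alignment maximization.

λ defaults to 0.8. Note the magnitudes: a and M scale like N², while L
is O(m), so at benchmark sample sizes the Laplacian term is a mild
regularizer rather than a dominant force; the smoothing-limit tests use
λ up to 10⁶ to probe the asymptote.

## SVM

The dual (0 ≤ αᵢ ≤ C, Σαᵢyᵢ = 0) is delegated to libsvm via
scikit-learn's `SVC(kernel="precomputed")`; the stored model keeps the
full signed coefficient vector yᵢαᵢ and the bias so KKT feasibility is
auditable, and a generic QP solver re-derives the toy-problem dual in
tests to pin the two routes together. sign(0) → +1 by convention.
C defaults to 2 and is shared between weighting strategies. No class
weighting is applied for mildly imbalanced data. Training kernels are
checked symmetric (1e−8) and PSD (−1e−6 relative) before fitting.

## Evaluation

ACC, SN, SP and MCC come from the pooled confusion matrix of all
held-out predictions (one matrix per run, not per-fold averages); MCC is
0 when its denominator vanishes. AUC uses the midrank tie convention.
Sensitivity at fixed specificity scans all score thresholds and returns
the highest sensitivity whose specificity meets the target; the
all-negative operating point (specificity 1, sensitivity 0) is always
included, so every target ≤ 1 is reachable.

Cross-validation refits everything — scalers, kernel weights, the SVM —
inside each training fold; held-out feature values cannot influence the
learned weights (verified by a perturbation audit). k-fold CV is
stratified with a logged seed; k = N dispatches to leave-one-out, where
stratification is impossible. Whether weights should be re-learned per
fold or fixed globally is ambiguous in the benchmark protocol; per-fold
estimation is the default because it is leakage-free, and
`fit_fold` can be driven with externally supplied weights to reproduce
the global reading.

## Synthetic data

`make_fixture_dataset` emulates a DBP benchmark: positive-class
sequences are enriched in basic/aromatic residues (K, R, H, W, Y) in
proportion to `signal_strength` ∈ [0, 1], and each record carries a
synthetic PSSM whose column means shift by ±3·signal log-odds units
along a fixed direction aligned with that enrichment, plus a +4
conservation bump on the native residue and integer-rounded Gaussian
noise, clipped to [−10, 10]. The shift direction is fixed (not
seed-dependent) so datasets generated with different seeds are samples
of one distribution and independent-test evaluation is meaningful.
Defaults: 60 + 60 samples, lengths 60–120, signal 0.8 — a regime where
the planted signal is strong and the pipeline separates the classes
essentially perfectly, chosen so that end-to-end tests assert signal
*recovery*, not calibrated difficulty.

What the generator does **not** emulate: real phylogenetic correlation
structure in profiles (columns are conditionally independent given the
class), domain architecture, sequence redundancy, or the subtler
composition differences of real DBP benchmarks. Passing end-to-end
tests therefore demonstrates that the machinery is correct and
leakage-free, not that the published benchmark accuracies transfer; real
evaluation needs the published datasets plus PSI-BLAST profiles.

A note on leave-one-out under the null: with balanced no-signal data,
LOOCV accuracy falls well below 0.5, because each training fold's
majority class is the opposite of the held-out label — a known LOOCV
artifact, not a defect. Null sanity checks therefore use 5-fold CV
(accuracy and AUC near 0.5).

## Numerical conventions

* Population (divide-by-N) standard deviation everywhere.
* Remainders in any contiguous partition go to the leading parts.
* Min–max feature scaling; the default γ grid spans 2⁻⁵..2⁵, consistent
  with unit-scaled features.
* Grid search over C breaks ties toward the smaller value.
* PSSM files: the 20 log-odds columns are used; weighted-percent columns
  and information-content fields are parsed and discarded. Rows may
  carry 20, 40 or 42 numeric fields (log-odds only, log-odds + percents,
  or the full PSI-BLAST dialect).

## Limitations

* GE/MCD constructions are conventions (the descriptor family is
  standard; the exact groupings vary across the literature).
* The shipped γ, C, λ defaults were tuned on PDB1075-scale data and are
  starting points, not universal constants; `grid_search_C` and the λ
  grid (0..1 step 0.05) re-tune them per dataset.
* Running PSI-BLAST and redundancy reduction (25% identity) are upstream
  steps outside this package.
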