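# Methods

`acetylsite` predicts lysine acetylation sites from local sequence
context.  This note describes the statistical machinery, the default
parameters and why they were chosen, what the synthetic benchmark does
and does not emulate, and the numerical conventions adopted where the
method leaves the choice open.

## The prediction unit

Every candidate site is represented by a peptide *window* of length
`L = 2n + 1` centered on a lysine, default `n = 7` (15-mer), matching
the −7…+7 flank range commonly analyzed for acetylation substrate
specificity.  Windows running off a protein terminus are padded with
`'-'`; encoders treat the pad as a 21st symbol (one-hot and PWM) or as a
zero row (BLOSUM62, ASA, PSSM), and composition encoders skip it.
Ambiguity codes (B, Z, X) and selenocysteine (U) are accepted in input
sequences and pooled with the pad into the shared "other" slot.

## Dataset construction

Nonacetylated lysines vastly outnumber acetylated ones, so the negative
set is reduced to exactly the positive-set size before training.  The
reduction clusters negative windows into K = |positives| groups by
k-medoids under the distance `1 − identity` and keeps each cluster's
medoid.  Sequence identity is not a vector-space metric, so medoids
(actual windows) are used rather than centroids; the alternating
k-medoids algorithm (assign to nearest medoid, recompute each cluster's
in-cluster medoid, iterate to convergence or 50 sweeps) is deterministic
given the seed.  A seeded random subsample (`method="sample"`) is
available for very large negative sets because all-pairs identity is
quadratic.

Pairwise identity is computed from the optimal global alignment under
BLOSUM62 with gap open −11 / extend −1 (the classic BLAST pairwise
defaults), as identical aligned pairs divided by alignment columns.
Biopython's `PairwiseAligner` charges the open score for the first
gapped column, a one-column difference from tools that charge
`open + k·extend`; this only shifts alignments in contrived cases.

Homology between a training and a test set is removed in two stages:
proteins above 30% global identity are homologous, and a test site is
discarded only when, additionally, its window is byte-identical to a
window of the homologous training protein.  Duplicate records of the
same (accession, position) collapse to the first occurrence; records
with conflicting labels are an error.

Cross-validation folds are stratified by label with per-class fold sizes
differing by at most one.

## MDD motif clustering

Maximal dependence decomposition recursively partitions the aligned
positive windows into motif subgroups.  For flank positions `A_i`, `A_j`
the residues are coarse-grained into five chemical property groups —
polar (G,S,T,C,Q,N), acidic (D,E), basic (K,R,H), hydrophobic
(A,V,L,I,P,M), aromatic (F,Y,W) — and dependence is measured by the
Pearson chi-square statistic on the 5×5 co-occurrence table:

    χ²(A_i, A_j) = Σ_m Σ_n (X_mn − E_mn)² / E_mn,   E_mn = X_mR·X_Cn / X

Cells with zero expected count contribute nothing.  Windows with a pad
or ambiguity code at either position are excluded from that pair's
table.  The published dependence threshold is χ² > 34.3 for the 5×5
table (16 degrees of freedom), described as the P ≤ 0.01 cutoff; note
the df = 16 upper-0.01 critical value is ≈ 32.0 and 34.3 is closer to
the upper-0.005 point.  The constant 34.3 is used verbatim.  In null
calibration on 1000 i.i.d. uniform windows this makes exceedances rarer
than the nominal 1%, which only errs on the conservative side.

At each tree node the split position maximizes `S_i = Σ_{j≠i} χ²(A_i,
A_j)` among positions with at least one pairwise χ² above threshold
(ties: nearest the center, then N-terminal).  The split group at that
position is the property group with the largest summed positive
observed-minus-expected mass across the position's pairwise tables — a
deterministic, data-driven reading of "the occurrence of basic amino
acids" style splits.  Members carrying that group at that position go to
the "with" branch, everything else (including pads) to "without".
Recursion stops when a node is smaller than `max_cluster_size` or no
pair is significant.  The default `max_cluster_size` is
`ceil(N/5)`, sized so a few-hundred-sequence set yields a handful of
subgroups; it should be tuned per dataset.  The center position is never
split (it is always K).  The procedure involves no randomness, so
repeated runs are identical.

## Feature encodings

Seven schemes (see `acetylsite.encode` for the exact layouts): one-hot
(21·L), BLOSUM62 rows (20·L), amino-acid composition (20), adjacent
ordered pair composition (400 = 20×20), PWM lookup (L), accessible
surface area (L, consumed from a precomputed sidecar — no structure
predictor is bundled), and PSI-BLAST PSSM rows (20·L).  Choices the
underlying description leaves open:

- the PWM is built from positive training fragments only, with add-one
  smoothing over the 21-symbol alphabet, so columns are strictly
  positive and sum to 1;
- PSSM log-odds scores are squashed through the logistic `1/(1+e^−x)`
  to (0, 1) — standard conditioning for RBF-SVM inputs — with pad
  positions set to exactly 0;
- pair composition counts adjacent ordered pairs only; gapped pairs are
  out of scope.

Scheme combinations concatenate, e.g. `B62+AAPC` (300 + 400 = 700).

## Models and evaluation

Classifiers are soft-margin RBF-kernel SVMs.  `gamma` and `cost` are
tuned by grid search over `gamma ∈ 2^−15 … 2^3`, `cost ∈ 2^−5 … 2^15`
in powers of 4 (standard RBF practice), ties resolved toward the
smaller cost then the smaller gamma.  Evaluation is repeated stratified
five-fold cross-validation (default 30 runs): within a run every sample
is tested exactly once and the five test folds pool into a single
confusion matrix.  Because "best model" can mean either, the summary
reports both the per-run mean ± sd and the best run.

Metrics: Sn = TP/(TP+FN), Sp = TN/(TN+FP), Pre = TP/(TP+FP),
Acc = (TP+TN)/total, MCC = (TP·TN − FN·FP)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
A metric with a zero denominator is reported as undefined (MCC as 0
with a flag) rather than silently clamped.

With an MDD tree, one classifier is trained per leaf on the leaf's
positives against an equal number of negatives routed down the same
tree, so negatives share the leaf's flank context; if too few negatives
route to a leaf the shortfall is filled by a seeded random draw from
the remaining negatives.  At prediction time a window is routed to its
leaf first, then scored; the decision threshold is 0 on the signed SVM
score, with no probability calibration.

## Composition-bias analysis

Per flank position and residue, positive-vs-negative frequency is
compared by a two-sided two-proportion z-test with continuity
correction (deterministic and asymptotically equivalent to the
t-over-binary-indicators convention of two-sample logo tools).  No
multiple-testing correction is applied, again matching those tools; at
α = 0.01 over 14 positions × 20 residues the expected fraction of
spurious flags stays below a few percent, which the test suite bounds
at 3% under label shuffling.  Ties (exactly equal frequencies) are
never flagged.

## Synthetic benchmark

The generator emulates the *shape* of a curated acetylation study:
background proteins drawn i.i.d. from a residue composition (uniform by
default — the cleanest null for chi-square calibration; a SwissProt-like
table is bundled), positive sites planted on interior lysines by
resampling their flanks, untouched lysines as negatives, and a
ground-truth motif label per planted site.

A motif entry `(offset, group, p)` makes the planted residue come from
the property group with probability exactly `p` (the complement is
drawn from the background renormalized over non-group residues), so
`p` equal to the group's background mass is exactly indistinguishable
from background and `p = 0` excludes the group — the "without"
structure an MDD split produces.  The default benchmark plants two
mutually exclusive motif classes of 150 sites each on 15-mers, plus 300
background negatives:

- `basic_downstream`: K/R/H at +1, +2, +3 (p = 0.95 each), acidic
  excluded at −3…−1 — a histone-like K-rich downstream flank;
- `acidic_upstream`: D/E at −3, −2, −1 (p = 0.95), basic excluded at
  +1…+3 — a nonhistone-like acidic upstream flank.

Multi-position motifs with adjacent enriched columns are what real
acetylation subgroups look like (K-X-K patterns, D/E stretches), and
they matter methodologically: adjacent enrichment is what gives the
pair-composition encoding its signal, and cross-position coupling is
what MDD's chi-square detects.  With these defaults MDD recovers the
planted partition with ≈98% clustering purity, and the whole-set AAPC
model reaches ≈0.9 pooled CV accuracy.

What the generator does **not** emulate: real flank compositions and
their correlations, shared evolutionary ancestry (every synthetic
protein is independent, so homology filtering is exercised only by
dedicated tests), multi-label sites, disorder/structure context behind
ASA, or realistic PSSM profiles.  Passing on synthetic data therefore
demonstrates the machinery is correct and self-consistent, not that any
particular accuracy transfers to curated UniProt data.

## Problem sizes used in the checks

The automated checks run the default benchmark (600 windows), 20
generator seeds for motif recovery, 1000 windows for null calibration,
and 5-run five-fold CV with full grid search for the whole-set vs
per-leaf comparison — sizes chosen so the full pipeline, including
tuning, is exercised end to end at desk scale.

## Known limitations

- K-medoids balancing is quadratic in the negative count; use
  `method="sample"` beyond a few thousand negatives.
- The 30%-identity homolog filter compares full protein sequences; for
  multi-domain proteins a local-alignment criterion would be stricter.
- Leaf models need at least two positives; very small
  `max_cluster_size` values are rejected with a pointer to raise it.
- PWM-scheme bundles cannot be applied to new FASTA input through the
  CLI because prediction would need the training PWM; use the library
  API and pass the `EncodingContext`.
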