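# Methods

## The classification problem

Sequential tri-disulfide peptides (STPs) are small toxins whose six
motif cysteines form the sequential pairing C1–C4, C2–C5, C3–C6,
yielding an unusually compact and stable fold (knottins/ICKs,
cyclotides, and non-knotted members such as scorpion-toxin-like
peptides). Members share function and fold but very little sequence
identity, which defeats homology search. `stpscan` classifies chains
as STP / non-STP from primary sequence alone, using a hand-crafted
motif grammar plus a small feature calculus feeding an RBF SVM.

## Motif grammar

All cysteines of a chain are indexed 1-based; loop lengths
ΔC(i,i+1) count residues strictly *between* consecutive cysteines
(so adjacent cysteines have a loop of 0). The rule cascade:

1. fewer than six cysteines → no motif;
2. the global minimum loop over the whole chain is found, ties broken
   toward the N-terminus (deterministic left-to-right reading);
3. min ΔC > 3 → no motif;
4. a six-cysteine window is anchored so the minimum pair plays role
   C3–C4. When fewer than two cysteines lie downstream the role
   shifts up (C4–C5, then C5–C6), consuming more upstream cysteines;
   when fewer than two lie upstream, the role slides down, which
   necessarily lands the pair at C1–C2/C2–C3 and triggers rule 5.
   With ≥ 6 cysteines some window always exists, so the defensive
   `cannot_anchor` verdict is unreachable in practice;
5. if the anchored window's own minimum loop lies between C1–C2 or
   C2–C3 the motif is disregarded — short N-terminal CXC/CXXC spacing
   characterises ferredoxin-, rubredoxin- and iron-sulfur-type
   electron-transport proteins rather than STPs.

Exactly one window is reported per chain (around the global minimum
pair); the classifier consumes one feature vector per chain, so
multi-window enumeration is deliberately out of scope. Invalidity is a
value with an enumerated reason, never an exception. The scanner is
verified against an independently written brute-force oracle that
enumerates all candidate windows and applies the rules literally
(10,000 random chains, lengths 20–160, 0–12 cysteines).

Ambiguity codes X/B/Z/U are accepted and treated as ordinary
non-cysteine residues: only cysteine identity matters to the grammar,
and the scanner is provably invariant to non-cysteine identity
(property-tested).

## Features

* Proximity lengths P1 = ΔC(1,4), P2 = ΔC(2,5), P3 = ΔC(3,6) — the
  sequence spans between would-be disulfide partners, counted strictly
  between the two cysteines for consistency with the loop convention.
  Invalid motifs are assigned P1 = P2 = P3 = 0 and flow through the
  same normalisation; the resulting low NP values are informative
  rather than special-cased.
* Normalised proximity NP_j = 100 / (|P_j − x̄P_j| + 10) ∈ (0, 10],
  where x̄P_j is the mean P_j over training positives with valid
  motifs. NP = 10 exactly on the mean and 5 at a deviation of 10
  residues. The means are refitted from the training positives of each
  fit (including inside every CV/subsampling split) and persisted with
  the model.
* Least loop length ratio: min window loop / chain length ∈ [0, 1);
  0 for invalid motifs.
* Inter-loop presence: 1 iff the motif is valid and both C4–C5 and
  C5–C6 contain at least one residue (the loop geometry reported for
  ICKs and cyclotides).
* Residue frequencies (count/length, keeping the 9–160-residue range
  comparable) for C, S, H, K, L.

Feature sets 1–6 are declaratively configured. Only set 6 — the three
NP values, the ratio, the flag and the five frequencies — has a
canonical composition; sets 1–5 are non-canonical nested subsets kept
for sweeps (1: frequencies; 2: NP; 3: NP+freq C; 4: NP+ratio+flag;
5: set 4 + freq C).

## Classifier and evaluation

SVC (libsvm) with RBF kernel; gamma = 0.1 and cost C = 0.1 by default,
with a tuned gamma preset of 0.0587 exposed but never applied
implicitly. Features are standardised to zero mean / unit variance
from the training data; the scaler travels with the model. The
decision threshold is the margin sign — no probability calibration.

Repeated random subsampling draws, per iteration, 100 positives and
300 negatives without replacement for training and evaluates on the
complement (44/93 at the default 144/393 class sizes); iterations are
independent. Because the aggregation of such protocols is ambiguous in
general, the report carries both the per-iteration metric means ± sd
and the pooled-confusion-matrix metrics; ROC/AUC pools held-out
decision values across iterations. Stratified k-fold (default k = 10)
is available as the alternative protocol. With a fixed seed the whole
train/evaluate path is reproducible bit-for-bit.

Metric conventions: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP), accuracy (TP+TN)/total, MCC with the standard
four-margin denominator. Any zero denominator yields NaN with a
warning — never a silent 0 — and NaN iterations are excluded from the
per-iteration means. The ROC sweep groups tied scores into a single
step and AUC is the trapezoidal area, cross-checked in tests against
an independent implementation.

## Synthetic data

The generator emulates only what the classifier consumes:

* **Positives** (default 144): exactly six cysteines; the minimum loop
  (0–3 residues) at C3–C4; the other four loops 1–12 residues above
  the minimum; lengths from a clipped normal (mean 42.2, sd 15.7,
  range 23–143), matching the descriptive profile of curated STP
  chains. Every positive passes the grammar by construction.
* **Negatives** (default 393): a mixture of random peptides with 0–6
  unconstrained cysteines (rejection-sampled so none passes the
  grammar), ferredoxin-like decoys whose shortest loop sits among the
  first two cysteine pairs, and six-cysteine chains with all loops
  longer than three residues; lengths clipped normal (63.2 ± 25.9,
  range 9–160). Default decoy fraction 0.3, long-loop fraction 0.2 —
  chosen so each rejection rule of the grammar is exercised in any
  moderate sample.
* **Hard mode**: negatives that *pass* the grammar but draw their
  non-minimum loops from a much broader range (up to ~30 residues), so
  their proximity lengths overlap the positives' only partially. This
  removes the motif-validity shortcut and forces the NP features to
  carry the signal; held-out accuracy lands between chance and the
  near-perfect default setting.

Background composition is uniform over the 19 non-cysteine standard
residues; cysteines are placed only deliberately. What passing tests
on these fixtures shows is that the pipeline is correct and that the
features separate classes that differ in motif geometry; it does not
show field performance on real proteomes, where negatives include
naturally cysteine-rich non-toxin folds with realistic residue
composition.

Default problem sizes used throughout the tests and the acceptance
script — 144/393 chains, 100/300 training draws, 200 iterations —
mirror the protocol the method targets; a full run takes a few seconds
on one CPU.

## Numerical and design notes

* Loop/anchoring tie-breaks are always toward the N-terminus; the rule
  order (global minimum first, then anchoring, then the positional
  discard applied to the anchored window) is one consistent reading of
  the grammar, and the test oracle implements the same reading
  independently so the equivalence check is meaningful.
* Redundancy filtering (`dedup_by_identity`) uses greedy scanning with
  global Needleman–Wunsch identity (match 1 / mismatch 0 / gap −1,
  matches over alignment length). It is a deterministic plumbing
  utility, explicitly *not* a CD-HIT reimplementation.
* Constant feature columns under standardisation get unit scale
  (scikit-learn's convention), avoiding division by zero.
* Model files are joblib archives with an explicit format version;
  loading validates the payload and fails loudly on truncation or
  foreign content.
* The no-signal control uses disjoint chains from one distribution
  split into two arbitrary classes. Duplicating one set as both
  classes is *not* a chance-level control for a kernel SVM: each
  held-out chain's duplicate sits in training with the opposite label
  and the measured accuracy collapses far below 0.5 through
  memorisation leakage.

## Known limitations

* The grammar reports a single anchored window; chains with several
  plausible motifs are represented by the one around the global
  minimum loop.
* Disulfide connectivity is inferred, never verified: structural
  confirmation (e.g. from PDB coordinates) is out of scope.
* Feature sets 1–5 are reconstructions for sweep purposes, not
  canonical definitions.
* Reported-value reproduction on the original curated chain sets
  requires those FASTA files (place them at `data/supplement1.fasta`
  and `data/supplement2.fasta`); they are not redistributable with
  this repository, so the corresponding check fails until provided.
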