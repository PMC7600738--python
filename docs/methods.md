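# Methods

## MAP4 fingerprint

A molecule (always the canonical, stereochemistry-free form — enantiomers
and E/Z isomers collapse before fingerprinting) is decomposed into
*shingles*: for every unordered pair of heavy atoms (i, j) connected by a
bond path and for each radius r ∈ {1, 2}, one token

    env_r(i) | d(i,j) | env_r(j)

where `env_r(·)` is the canonical SMILES of the circular substructure of
radius r rooted at the atom and `d` is the shortest-path distance in bonds.
The two environments are ordered lexicographically so the token is
symmetric in the pair. At the molecular boundary, where no radius-r
environment exists, the largest available environment is used, so any
molecule with at least two bonded heavy atoms has a non-empty shingle set;
molecules without a bonded atom pair are rejected. Shingles are a *set*
(no multiplicities). The exact token syntax is frozen and versioned
(`MAP4-NPM4-1`); signature files record the version and refuse to mix.

MinHashing: the base integer of a token is the first 8 bytes of the SHA-1
digest of its UTF-8 text, reduced modulo p = 2³¹ − 1. The 1024 hash
functions are universal-hash transforms hᵢ(x) = (aᵢx + bᵢ) mod p with
coefficients drawn once from a fixed seed (42); signature position i holds
the minimum of hᵢ over the molecule's tokens. This construction is
deterministic across platforms (golden signatures are asserted in the test
suite) and keeps all arithmetic inside 64-bit integers. The estimator
ŝ = (matching positions)/1024 is the standard MinHash estimate of the
Jaccard similarity of the token sets; per pair its error is binomial,
sd ≤ 0.5/√1024 ≈ 0.016, and the suite verifies |ŝ − J| ≤ 0.094 (3σ) for
≥99% of a 200-pair calibration panel with mean signed error within ±0.01.

Because the shingle syntax and hash family are package choices, signatures
are comparable only within this package, not numerically identical to other
MAP4 implementations; all downstream quantities (similarities, maps,
kernels) are well defined regardless.

## Chemical-space maps

The LSH forest holds 32 prefix trees; each tree owns a 32-position slice of
a fixed random permutation of the 1024 signature positions and stores the
inserted signatures as sorted key tuples. A query walks prefix lengths from
32 downward, pooling molecules that share the prefix in any tree, until at
least max(4k, 64) candidates are found, then ranks the pool by the exact
estimated similarity; if the prefixes spread degenerately, it falls back to
scanning. Retrieval is deterministic given the seed and insertion order;
mean top-20 recall versus brute force is ≥ 0.8 on the 500-molecule test
condition.

The kNN graph takes each molecule's top k = 20 neighbors (defaults follow
the reference configuration n_trees = 32, k = 20), symmetrizes by edge
union, and weights edges by estimated Jaccard distance recomputed from the
signatures. Kruskal's algorithm with union-find produces the minimum
spanning forest; edges are scanned in (weight, min ID, max ID) order, so
ties resolve identically on every platform. A disconnected graph yields a
forest and reports its component count; an optional flag joins components
through their cheapest crossing edge. The radial tree layout (root =
highest-degree node, ties to the smallest ID; angular spans proportional
to subtree leaf counts) is a plain deterministic drawing heuristic — it
makes no claim to reproduce force-directed layouts and exists so exported
maps can be eyeballed without external tooling.

## Properties

Descriptors are RDKit's standard implementations: MolWt, FractionCSP3,
NumHAcceptors/NumHDonors, Crippen MolLogP, TPSA. The same HBA/HBD values
feed both the report and the rule-of-five check (flag false only when more
than one of MW > 500, AlogP > 5, HBD > 5, HBA > 10 is violated); no
separate Lipinski-specific N+O counts are used, and this choice is
deliberate — the reported and the rule-checked values should not disagree.

The Joback boiling point is T = 198.2 + Σᵢ Nᵢ·t_bᵢ Kelvin. The
group-contribution table ships with the package
(`src/npmap4/data/joback_tb.tsv`): the published Joback–Reid t_b constants,
each paired with a SMARTS pattern written for this package. Assignment is
most-specific-first with atom claiming: rows are tried in order
(multi-atom carbonyl groups before bare oxygens, ring variants
distinguished from chain variants), a match counts only if none of its
atoms is already claimed, and then claims all of them — making the
assignment exhaustive and non-overlapping. Atoms no group types (e.g. the
oxygen of water, noble gases, ring tertiary amines) contribute zero and
trigger a logged coverage warning rather than silent omission. Amides are
typed as carbonyl + amine groups, the standard practice when no dedicated
amide group exists in the table. Known published estimates are reproduced
(ethanol 337.5 K, benzene 358.6 K).

Substructure classes come from two fixed SMARTS patterns used verbatim: a
dipeptide backbone
`[NX3,NX4+][CH1,CH2][CX3](=[OX1])[NX3,NX4+][CH1,CH2][CX3](=[OX1])[O,N]`
and a glycoside moiety `[CR][OR][CHR]([OR0,NR0])[CR]`; a structure matching
both is a glycopeptide, matching neither is `none`. The tests cross-check
both patterns against Open Babel as an independent SMARTS engine.

For map coloring, continuous values can be clamped to display bounds
(MW ≤ 1000 Da, T_b ≤ 2000 K, HBD ≤ 10, AlogP ∈ [−2, 8], TPSA ≤ 500 Å²;
other properties unclamped) and converted to fractional (average) ranks,
where tied values share the mean of the ranks they span.

## Origin classifiers

All three models are binary with "bacterium" as the positive class and a
0.5 probability threshold (exactly 0.5 classifies positive). Labels are
encoded bacterium = 1 internally so that model selection always maximizes
ROC AUC for that class. Class weights are inversely proportional to class
frequency. Hyperparameter selection is an explicit stratified 5-fold CV
loop — each fold leaves out 20% of the training set — that slices
precomputed kernel/distance matrices on both axes; ties keep the earliest
grid value, so the chosen hyperparameters and all downstream predictions
are reproducible from the seed alone.

* MAP4 kernel SVM: SVC on the similarity kernel K(i,j) = ŝ(i,j),
  C ∈ {0.1, 1, 10, 100, 1000}. The estimated-Jaccard kernel is not
  guaranteed positive semidefinite; the solver accepts it in practice and
  any failure surfaces as an error rather than a silent coercion.
  Probabilities are Platt (sigmoid) calibration fitted on internal
  cross-validated decision values (`CalibratedClassifierCV`,
  `ensemble=False`).
* MAP4 k-NN: distance 1 − ŝ, k ∈ {5, 7, 9, 11}, unweighted vote — the
  positive probability is the fraction of bacterial neighbors. Neighbor
  ties are broken by training insertion order (stable sort), a detail the
  generic library search leaves unspecified.
* Physchem SVM: RBF kernel on MW, fsp3C, HBA, HBD, AlogP, TPSA and Joback
  T_b, standardized with a scaler fitted on training data only;
  zero-variance columns are dropped with a warning. C and γ by grid
  search, γ ∈ {0.01, 0.1, 1, 10, 100}; Platt calibration as above.

Prediction output includes both class probabilities (complementary by
construction), the thresholded label, and the nearest training molecule
with its estimated Jaccard distance — a transparency feature: high
confidence next to a large nearest-neighbor distance deserves suspicion.

Evaluation implements the standard formulas — precision TP/(TP+FP), recall
TP/(TP+FN), TNR TN/(TN+FP), F1 as their harmonic mean, balanced accuracy
(TPR+TNR)/2, MCC with the square-root denominator, ROC AUC by trapezoidal
integration over all thresholds. Degenerate denominators report 0 with an
explicit flag. The test suite checks parity against an independent
pairwise-probability AUC and the sklearn implementations.

## Synthetic data

The generator assembles molecules from a fragment grammar: chain units are
SMILES fragments whose first and last atoms accept one more single bond,
so any concatenation is valid by construction. Units are drawn until a
target mass is reached; an O-glycoside pyranose terminates a molecule with
probability 0.15, otherwise a hydroxyl. Defaults emulate the statistical
shape of a microbial NP collection: two balanced origin classes, sizes
70–2900 Da (right-skewed, median ≈ 450 Da), peptide and glycoside
chemotypes.

Signal modes define the study conditions:

* `substructure` (default): bacteria assemble from amino-acid-like residue
  units, fungi from polyketide/aromatic extenders, both with shared
  decoration units and identical size distributions — the class signal is
  substructural only.
* `property`: both classes share one vocabulary and mixing ratio; only the
  target-mass distributions differ, by default means 550 vs 650 Da with
  sd 100. The shift is deliberately modest and heavily overlapping: it
  represents a weak bulk-property-only difference of the kind real origin
  classes exhibit, the regime in which a direct descriptor readout beats a
  substructure sketch. A polarity-ratio variant at matched size
  (`mw_means=None`) and arbitrary mass shifts (e.g. 300 vs 900 Da) are
  available through the configuration.
* `none`: one distribution for both classes; a permutation test in the
  suite confirms the classes are statistically indistinguishable in
  similarity space.

What the generator does *not* emulate: biosynthetic plausibility (linkage
chemistry can be exotic, e.g. O–N bonds where units abut), stereochemistry
(stripped throughout the pipeline anyway), realistic scaffold diversity,
and database artifacts such as salts or charged species. Passing tests
therefore demonstrate algorithmic correctness and recoverability of
constructed signals at realistic sizes — not performance on any real
collection, which depends on the real classes' separation.

## Numerical and scale choices

* Signature length fixed at 1024; hash-family seed fixed at 42 and recorded
  in signature file headers.
* Pairwise similarity matrices are computed in row chunks (~40 MB working
  set) so large collections stream through bounded memory.
* Test-suite problem sizes — 200 calibration pairs, 500 molecules for
  retrieval recall, 200 molecules per class for classifier recovery, 100
  random 50-node graphs for the spanning-tree oracle — are the package's
  chosen study conditions: large enough for stable statistics, small
  enough that the full suite runs in about a minute and a half on one CPU.
* Dual-origin duplicate resolution, train/test splitting, CV folds, and
  all generator draws derive from explicit integer seeds; identical seeds
  give identical datasets, folds, hyperparameters and predictions.

## Known limitations

* Signatures are not numerically interchangeable with other MAP4
  implementations (different frozen token syntax and hash family).
* The Joback table types common organic functional groups; exotic atoms
  degrade the estimate toward the intercept (with a logged warning) rather
  than failing.
* The LSH forest targets collections up to a few tens of thousands of
  molecules; its sorted-list prefix trees are simple, not the most
  memory-compact choice.
* Origin classification is strictly binary (bacterium vs fungus); a
  non-microbial structure will still be assigned one of the two classes,
  with the nearest-neighbor distance as the only built-in warning signal.
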