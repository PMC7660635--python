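# Methods

## The selection problem

Kinase-specific phosphorylation-site prediction encodes each candidate
acceptor residue (S, T or Y) by the physicochemical properties of its
flanking sequence window. With a window of 21 residues and 10 properties
per residue the feature space has 200 dimensions, most of which are
irrelevant for any particular kinase; wrapper feature selection — scoring
candidate subsets by the cross-validated performance of the downstream
classifier — both improves the Matthews correlation coefficient (MCC) of
the fitted model and exposes which window positions carry the kinase's
substrate specificity. `antsel` implements such a wrapper around a hybrid
metaheuristic: an ant colony system (ACS) on a binary select/skip digraph,
refined each iteration by a genetic algorithm (GA).

## Encoding

Each amino acid maps to 10 min-max-normalized property values: the five
factor-analytic scores of Atchley et al. (polarity, secondary structure,
molecular volume, codon diversity, electrostatic charge) and five classic
scales (Kyte–Doolittle hydropathy, side-chain heavy-atom count,
Chou–Fasman helix and strand propensities, codon count). The center
residue of a window is fixed by construction (it is always the model's
acceptor residue) and is dropped, so a window of odd width W encodes to
(W−1)·10 features, laid out position-major (−(W−1)/2 … −1, +1 … +(W−1)/2)
and property-minor; feature names such as `pos+1:hydrophobicity` make the
layout self-describing. Sites near a terminus are padded with `X`, encoded
as the per-property mean of the 20 normalized values so that padding is
information-neutral. Negative sites are mined as all unannotated residues
of the model's acceptor type, pooled across proteins, and sampled without
replacement to a 1:1 ratio against the positives (the raw candidate pool
is an order of magnitude larger and would dominate training otherwise).

An optional greedy redundancy filter (longest-first, ungapped identity
over the shorter sequence, shared-5-mer prescreen) can remove
near-duplicate sequences before excision. It is a deliberately simple
surrogate for clustering-based tools and is off by default; it operates on
whole sequences, before fragments are cut.

## Heuristic values

Four per-feature scorers provide the prior importance η used by the ants:
random-forest mean decrease in Gini impurity (MDGI, the default; averaged
over 10 independently seeded forests of 500 trees each — the averaging is
what stabilizes the ranking, measured Spearman ≈ 0.9 between master
seeds), absolute Pearson correlation with the label, information gain
under 10 equal-width bins on [0, 1], and the two-class discrimination
F-score (μ₊−μ₋)²/(s₊²+s₋²) with a large finite cap when the within-class
variance vanishes. Scores are clamped at 10⁻⁶ of their maximum so that
η^β is always positive and edge probabilities stay well defined; η₀, the
heuristic of every skip edge, is the mean of the clamped scores so both
edges share a scale. If no feature discriminates at all the scorer falls
back to a flat positive prior.

## The search

Every feature i has a select edge (E1) and a skip edge (E0) carrying
pheromone τ[i,1], τ[i,0] (both initialized to τ0). An ant visits features
in index order and picks an edge with probability

    p(i,j) = τ[i,j]^α · η[i,j]^β / Σ_j' τ[i,j']^α · η[i,j']^β ,

with η[i,1] = η_i and η[i,0] = η₀. Three transition rules are provided:

* **binary** — always sample p(i,j);
* **pseudo-random** (classical ACS) — with probability q0 take the greedy
  argmax of τ^α·η^β, else sample;
* **full pseudo-random** (default) — with probability q0 take the *skip*
  edge outright, else sample. The gate prunes features whose heuristic
  value alone would keep them selected, roughly halving subset sizes at
  equal fitness in our benchmarks (direction consistent with the
  pseudo-random rule comparison in the acceptance suite).

After each edge choice the local update τ ← (1−ρ)τ + ρτ0 decays the
traversed edge toward τ0 (shared graph: later ants in the same iteration
see the decay; a batched mode applies the updates after the tour
completes). Subset fitness is the pooled MCC of the wrapped classifier
under stratified 5-fold cross-validation with folds fixed by the run
seed; an empty subset scores the sentinel −1 and is never fitted. Each
iteration the evaluated colony is evolved by a GA (tournament-2
selection, single-point crossover at rate 0.7, per-bit mutation at
0.1/chromosome-length, elitism); evolved ants compete with the raw tours
and the incumbent for *global best*, but the next colony is always
reconstructed from the pheromone graph — the GA only informs the global
update. The global update evaporates every edge by (1−ρ) and deposits

    Δτ = MCC(S_best) + (1 − |S_best| / n)

on the select edges of the global best ant's features, rewarding accurate
*and* small subsets; a negative-MCC best ant drains its own path. A floor
τ_min = 10⁻⁶·τ0 keeps all pheromones strictly positive (the deposit can
be negative). Global best replacement requires strictly higher fitness,
or equal fitness with strictly fewer features; the incumbent wins exact
ties, so the best-fitness trace is non-decreasing by construction.

Defaults follow the reference configuration: 10 iterations × 30 ants,
α = 0.8, β = 2.0, τ0 = 1, ρ = 0.2, q0 = 0.35; GA population 30,
10 generations, crossover 0.7, mutation 0.1. ACS iterations and GA
generations are independent counters. A single user seed fans out into
named substreams (balancing, folds, tours, GA, generators) via a CRC-based
derivation, so every subsystem is independently reproducible.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/N and
MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)). A zero factor in
the MCC denominator yields 0 (standard convention); an empty class leaves
Sn or Sp undefined (reported as missing). Fold confusion counts are
pooled (micro-averaged) before computing metrics; per-fold averaging is
available but changes the reported MCC slightly on small folds. k = 1 is
a degenerate single-pass holdout. The classifier registry holds seven
scikit-learn reference classifiers spanning the tree, rule, meta, lazy,
function and Bayes families (decision tree, depth-4 rule table, AdaBoost,
kNN, logistic regression, RBF-SVM, Gaussian naive Bayes); Weka-era names
map onto the nearest of these (BFTree/SimpleCart → decision tree,
DecisionTable → rule table, MultiBoostAB → boosted trees, RBFNetwork →
RBF-SVM, SimpleLogistic → logistic, NaiveBayes → naive Bayes). No attempt
is made to reproduce Weka's implementations bit for bit.

## Baselines

The plain-GA baseline runs the same GA engine from a random
Bernoulli(0.5) population with no pheromone or heuristic guidance,
population 30 and generations matched to the colony search's evaluation
budget. The simulated-annealing baseline uses a single-bit-flip
neighborhood, geometric cooling (T0 = 0.2 — the order of typical MCC
differences between neighboring subsets — cooling factor 0.99), and
returns the best state visited. Both consume the same memoized evaluator
as the main search so comparisons isolate the search strategy.

## Synthetic data

The tabular generator plants `n_informative` class-shifted Gaussian
features (mean shift = effect size × within-class SD) among
class-independent noise, balances classes and rescales every feature to
[0, 1] to match the encoder's output range. The sequence generator emits
background-sampled proteins (fixed vertebrate-like residue frequencies)
with forced acceptor residues and position-specific motif draws around
positive sites — e.g. a proline forced at +1, emulating the conserved
flank of proline-directed kinase substrates — plus annotated background
negatives of the same residue type, in exactly the FASTA/TSV dialect the
encoder reads. Neither generator emulates homology between proteins,
compositional drift, disorder context or multi-position correlated
motifs, so passing tests demonstrate correct recovery of planted
position-specific signal, not performance on real proteomes.

## Benchmark sizes and test design

The test and acceptance suites run: the exhaustive-optimum check on
6-feature problems (80 samples, every one of the 63 non-empty subsets
brute-forced with the same evaluator; reference search configuration;
20 seeds), planted recovery on the 500×50/5-informative instance (scaled
configuration: 12 ants × 6 iterations, GA 12×5; MDGI 3 repeats × 100
trees; 3-fold fitness; 20 seeds), the rule comparison on the same
instance (10 seeds), the strategy comparison on a deliberately harder
instance (300×100, 8 informative, effect size 1.0; the default instance
saturates all strategies near MCC 0.98 and cannot rank them), and the
end-to-end motif pipeline (30 proteins × 3 sites, window 21, reference
search configuration, MDGI at its 10×500 defaults; 10 seeds). Measured
orderings: search ≥ plain GA ≥ simulated annealing in median MCC, and
full rule < pseudo-random rule in mean subset size.

## Numerical choices and edge cases

Constant raw property columns are a hard error (cannot be min-max
normalized). Annotation/sequence mismatches fail loudly, listing every
offending (id, position). Non-standard residues other than `X` are an
error by default, optionally mapped to the pad vector. Zero-variance
features score 0 (then clamped) under PCC/IG/F-score. The q0 = 1 full
rule legitimately yields all-skip tours; the empty subset carries the −1
sentinel, and the CLI warns but exits cleanly. Prediction-time models are
stored as plain JSON (training-table path + feature names + classifier
name) and refit on load, keeping artifacts text-only and reproducible.

## Known limitations

The redundancy filter is not a substitute for proper clustering at scale
(quadratic comparisons, ungapped identity). Pheromone-graph updates are
sequential; tours within an iteration are independent only given the
graph snapshot, and no parallel execution semantics are defined. MDGI
importances from normalized mean-decrease-impurity inherit that
statistic's bias toward features with many split points, which is benign
here because all features share the bounded [0, 1] encoding. Reported
MCCs on synthetic benchmarks are not comparable to values on curated
phosphorylation corpora.
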