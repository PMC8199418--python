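# Methods

## Model

`fragpath` treats pathway assignment as profile matching. Each pathway is
summarized by a vector of per-fragment enrichment p-values (*Pv*), computed
with the upper-tail cumulative hypergeometric distribution against the whole
compound database as background: *M* database compounds, *K* carriers of the
fragment, *N* pathway members, *x* in-pathway carriers, *Pv* = P(X ≥ x). The
background is always the full database, including the pathway's own members
— the enrichment question is "is this fragment over-represented here relative
to everything we know", not relative to the complement.

A query compound's score against a pathway is the mean of −log *Pv* over the
fragments the query contains (natural log; the base only rescales scores and
cancels in z-scoring). Fragments the query lacks contribute nothing. The
assumptions are therefore: (i) presence/absence of fragments carries the
pathway signal (occurrence counts are ignored); (ii) fragments are scored
independently — correlated fragments (e.g. all subpaths of one scaffold) are
double-counted, which the null model partially absorbs because the same
correlations exist in the randomized background.

## Fragment vocabulary

Linear fragments are simple paths (no repeated atoms) of 2–7 heavy atoms,
labelled by the alternating sequence of atom labels and bond marks; a path
and its reverse map to one canonical label. Atom-centered fragments are an
atom with any subset of its direct neighbours totalling 2–4 atoms, labelled
by the centre plus the sorted (bond, neighbour) multiset. Aromatic bonds are
a distinct mark (`:`), perceived with RDKit's standard aromaticity model, so
kekulized and aromatic encodings of the same ring give identical fragments.
Formal charges are appended to atom labels (`O-`); hydrogens are implicit;
stereochemistry, isotopes and salt standardization are ignored. The label
grammar is this package's own — only set semantics matter downstream. The
default minimum linear size is 2 atoms (configurable to 1).

Both 2–4-atom-centered semantics ("every neighbour subset" vs "the full first
sphere truncated") appear in the literature for this fragment family; the
all-subsets variant is implemented, which is the more inclusive of the two.
Users comparing against other fragmentation tools should expect label- and
set-level differences.

## Zero p-values and unscorable compounds

*Pv* can underflow to exactly 0 in double precision for extreme enrichment at
large *M*. Such entries are floored at the profile's smallest nonzero *Pv*
divided by 50, applied per profile (the profile is the natural scope, since
*Pv* is defined per pathway; a global floor would couple unrelated pathways).
A compound carrying no vocabulary fragment cannot be scored; it receives
Sc = 0 and an `unscorable` flag rather than an error, so batch prediction
never aborts.

## Null model

Raw scores are incomparable across pathways, so each pathway gets a null
distribution *Sr* by randomizing the fingerprint matrix and re-scoring every
randomized row. The randomization permutes each fragment column independently
across compounds: this preserves exactly each fragment's database frequency
*K* — the quantity the hypergeometric test conditions on — while destroying
compound–fragment association. A whole-matrix shuffle is available as an
alternative (`scheme="shuffle"`) but does not preserve the per-fragment
marginals. Scores are pooled across all randomizations (rather than
summarizing per-randomization maxima); randomized rows that end up with no
fragment are dropped, since their conventional Sc = 0 would distort the fit.

The z-scored null is fitted with a maximum-Gumbel distribution by maximum
likelihood (location μ, scale σ), and p = 1 − exp(−exp(−(z − μ)/σ)). The
*maximum* orientation is deliberate: high scores indicate a match, so
significance must sit in the right tail (tools that fit minimum-EVDs would be
run on negated data). The MLE solves the one-dimensional profile-likelihood
equation for σ with Brent's method to 1e-10 from the moment estimate
sd·√6/π, then gets μ in closed form; it agrees with generic numerical MLE
to ~1e-12 and recovers known parameters within ±0.02 at n = 100,000.

**Adequacy of the extreme-value approximation.** The null score is a mean of
roughly *k* heavy-tailed terms, where *k* is the typical number of fragments
per compound. Its shape therefore moves along a gamma-like family: for *k*
around 8 (sparse fingerprints relative to the vocabulary) the z-scored null
has skewness ≈ 1.1, close to the Gumbel's 1.14, and null p-values are uniform
to a Kolmogorov–Smirnov distance of about 0.015 at n = 60,000. For dense
fingerprints (*k* ≈ 20+) the null approaches a Gaussian (skewness ≈ 0.5) and
the best-fitting Gumbel leaves a bulk misfit of KS ≈ 0.035. Rankings are
barely affected (p is monotone in z regardless), but absolute p-values in the
dense regime should be read as approximate. The calibration test in the suite
runs in the sparse regime for this reason.

Defaults: 10,000 randomizations for routine use (minutes on one CPU at
hundreds of compounds); 100,000 reproduces full-fidelity calibration at
proportional cost; below 1,000 a warning is logged because tail estimates get
noisy. Null scores are held as float32 (~4 MB per pathway per 1M scores).

## Prediction, ranking and evaluation

Pathways are ranked by increasing p-value, ties broken by decreasing z-score
then pathway id, so rankings are total and deterministic. The top-*n*
predictor family (n = 1..P) yields a pooled pair-level ROC: each
(compound, pathway) pair is one instance, predicted positive when the pathway
is within the compound's top *n*. AUC is the trapezoidal area of this sweep —
equivalent to a rank-score ROC, against which it is cross-checked in the
tests. Per-pathway AUC restricts instances to that pathway's column;
per-group and per-size-bin AUCs restrict analogously (size bins are
equal-frequency quantiles of the number of fragments per compound, default
8 bins). Whether to pool pairs or average per-compound curves was an open
choice; pooling was chosen because it derives the global, per-pathway and
per-subset views from one primitive.

Cross-validation partitions compounds into 10 folds by a seeded uniform
shuffle (not stratified by pathway); the assignment is recorded in the report
so the profile method and the k-NN baseline can be evaluated on exactly the
same partition. Per fold, profiles and null models are rebuilt from the nine
training folds only; the query compound is never part of the background when
it is being evaluated (in exploratory, non-CV use, leave-in scoring is the
default and `exclude=` provides leave-one-out). Pathways with fewer than two
training compounds in a fold are skipped for that fold with a warning.

The k-NN baseline ranks pathways by the best Tanimoto similarity among the
query's k nearest training compounds annotated to each pathway (k = 3 by
default); pathways not covered by the top-k follow, ordered by best
similarity over the whole database, so the ranking is total and the ROC sweep
well-defined. Max-similarity rather than neighbour voting was chosen because
a vote cannot order pathways beyond the k-th neighbour.

## Synthetic data

The planted-matrix generator emulates exactly the statistical structure the
enrichment test detects: each pathway owns a few dedicated fragment columns
present with probability `p_in` in members and `p_bg` elsewhere; all other
cells are background `Bernoulli(p_bg)`. Defaults (20 pathways × 30 compounds,
400 fragments, 5 enriched per pathway, 0.9 vs 0.05, 10% of compounds in two
pathways) describe a strong-signal desk-scale study that tenfold CV resolves
at AUC ≈ 0.99 in about a minute on one CPU. Setting `p_in = p_bg` gives the
pure null design used for calibration checks. Multi-pathway compounds sample
enriched columns from each of their pathways at `max(p_bg, p_in/2)` — a
mixed, diluted signal, which is why their AUC is systematically below that of
single-pathway compounds in the evaluation splits. `n_subfamilies = 2` splits
each pathway's members and enriched columns into disjoint sub-families:
pathway-coherent but pairwise-heterogeneous chemistry, the regime where
profile pooling beats nearest-neighbour similarity (the frozen comparison
design: 10 pathways × 16 compounds, 300 fragments, 6 enriched split over two
sub-families, 0.55 vs 0.08).

What the generator does *not* emulate: correlated fragments from shared
scaffolds, fragment-count structure, database-scale vocabulary sizes
(tens of thousands), or uneven pathway sizes. Passing tests on planted
matrices therefore demonstrate the statistical machinery, not chemistry; the
toy SMILES library (three scaffold families with a shared member and a
duplicated structure) covers the chemistry path end to end, and real-database
performance claims require real databases.

All generators, null models and CV runs are pure functions of their seeds;
reports record seeds and fold assignments.

## Numerical choices and limitations

- Hypergeometric tails come from `scipy.stats.hypergeom.sf(x−1, M, K, N)`
  (log-space internally); verified against exhaustive enumeration for all
  M ≤ 12.
- p-values from the Gumbel survival function use `expm1` and are clamped to
  (0, 1]; ties in ranking are impossible except for exactly identical
  profiles, which fall back to lexicographic pathway order.
- Long homologous series saturate presence/absence fingerprints (heptanoic
  and octanoic acid are identical above the 7-atom window); the
  identical-fingerprint merge treats them as one compound, which is the
  intended semantics but means the method cannot distinguish such homologues.
- The p-value floor makes scores depend mildly on the single smallest
  observed *Pv* in a profile; with 64-bit floats the floor triggers only at
  extreme enrichment (thousands of compounds).
- Runtime scales as (compounds × vocabulary × randomizations) per pathway
  for null building; the shared-randomization builder (`build_nulls`)
  amortizes the randomizations across pathways and is what the CV harness
  uses.
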