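# Methods

## Data model

The input is a flat table of fold-change observations: a *study* (one
experiment row), a PubMed ID, a disease, a miRNA, a minimum fold-change and
optionally a maximum. A (miRNA, disease) pair is a single network vertex
(*MD node*): the same miRNA under two diseases has two independent
expression profiles and therefore two vertices. Node order is lexicographic
by (disease, miRNA), so the universe is independent of input row order.

Parsing drops rows with no usable fold-change and rows whose fold-change
fields fail numeric parsing, counting both separately; miRNA and disease
names are case-folded and whitespace-trimmed but never alias-resolved.
Duplicate (study, miRNA, disease) rows collapse by averaging, consistent
with how dual values are treated elsewhere. Fold-changes are used exactly
as recorded — no log transform and no up/down sign injection.

## Expression matrices

Three schemes resolve dual-valued records into a studies × MD-nodes matrix:

- **average** — cell = mean(fc_min, fc_max) when both exist, else fc_min.
- **maxmin** — a study containing at least one dual-valued record is
  duplicated into a `:min` row and a `:max` row (single-valued records
  repeat their minimum in the max row), so both data points survive as
  separate samples.
- **missingmax** — a record lacking fc_max borrows the arithmetic mean of
  that MD node's fc_max values over all other studies where one was
  reported (its own fc_min if none exists anywhere), after which the
  average rule is applied.

Cells never observed in a study are explicitly missing (NaN), never
silently zero.

### Missing-cell policy

Downstream scorers need a policy for unobserved cells. Two are provided:

- `zero_fill`: an unobserved MD in a study is scored 0 — "no reported
  differential expression". This is required by the scorers that operate on
  a complete matrix (the MI family and the tree ensemble).
- `pairwise_complete`: each column pair is evaluated over the samples where
  both MDs were observed (pairs sharing fewer than 3 samples score 0).

The pipeline default gives the correlation family (Pearson, Spearman,
distance correlation) `pairwise_complete`, because these measures have a
natural per-pair definition and zero-filling is actively harmful there:
since each study observes one disease, any two columns of the same disease
share an identical zero block over all other diseases' samples, which
manufactures strong spurious correlation between *every* same-disease pair
and buries the real structure. The MI family and the tree ensemble use
`zero_fill` as stated.

## Inference algorithms

Six scorers produce N × N nonnegative matrices over the MD nodes (higher =
stronger predicted interaction; the diagonal is excluded downstream).

- **Pearson / Spearman** — absolute correlation. Absolute values are used
  because ranking rewards interaction strength, not sign, and keeps the
  scores comparable with the nonnegative MI family. Zero-variance columns
  score 0.
- **Distance correlation** — dCor(x, y) = dCov(x, y)/√(dVar(x)·dVar(y))
  with dCov² the mean elementwise product of the double-centered pairwise
  distance matrices; in [0, 1], constant columns score 0.
- **Mutual information** — plug-in (maximum-likelihood) MI in nats after
  equal-frequency discretization into ⌊√m⌋ bins (minimum 2, m = samples).
  Tied values share a bin (average-rank placement): splitting a run of
  identical values across bins by storage order would fabricate MI between
  any two columns sharing a long constant run — exactly what the
  zero-filled other-disease block is.
- **CLR** — each MI value is z-scored against the off-diagonal background
  of its row (clamped at 0; numerically flat backgrounds give z = 0) and
  the directions combine as √(z_i² + z_j²).
- **MRNETB** — per target, a predictor subset maximizing
  Q(S) = Σ_{j∈S} [MI(j, t) − mean_{k∈S\{j}} MI(j, k)] is sought by backward
  elimination (drop the variable whose removal most improves Q; at a tie
  the later variable drops, so of two duplicated predictors the first
  stays) followed by sequential replacement (best single swap while Q
  improves). A selected predictor's edge score is its objective term in
  the final subset, clamped at 0; the two directions symmetrize by
  elementwise maximum. On small instances the search attains the
  exhaustive-subset optimum (verified against brute force in tests).
- **GENIE3-style tree ensemble** — each column is regressed on all others
  with a 100-tree random forest sampling √p features per split;
  impurity-reduction importances, normalized to sum to 1 per target, become
  directed scores. Degenerate (constant) targets keep all-zero importances.
  Per-target seeds derive from the run seed, so output is reproducible.

Exact estimator settings are configurable (`MIEstimatorConfig.bin_count`,
`n_trees`); the defaults above follow the conventional choices of the
respective method families.

## Borda consensus

Each algorithm's scores over all directed off-diagonal edges are ranked
descending (ties share the average of the ranks they span — the standard
fractional resolution, since the Borda description assumes distinct ranks).
Rank r among n edges earns n − r Borda points, normalized by the maximum
n − 1 to [0, 1] (n = 1 maps to 1 by convention). The final confidence of an
edge is the mean of its K normalized Borda ranks; K is derived from the
configured algorithm list (default six), so ablations change the divisor
automatically.

Both orientations of each pair are ranked; symmetric scorers rank the two
orientations as exact ties, and the disease-network stage later collapses
them by maximum.

Two arithmetic modes exist because published worked examples of this scheme
truncate each normalized Borda rank to two decimals (2/3 carried as 0.66)
before averaging, which shifts a final rank of exactly 1/2 down to 0.49.
`paper_truncated` reproduces that convention digit-for-digit;
`exact` (the production default) keeps full precision.

## Validation against co-citation

A same-disease pair (M_a, M_b, D_x) is *validated* when at least one single
PubMed ID has records associating both miRNAs with that disease; records
are first deduplicated by (pmid, miRNA, disease). All other same-disease
pairs are *unverified* and counted as negatives in the curves, over the
same-disease edges of the consensus output (not the full pair universe).
Unverified often means merely "not yet studied", so precision is the
meaningful axis and recall is circumstantial. The sweep uses every distinct
score as a threshold and reports tp/fp/fn/tn, precision, recall, fpr, and
trapezoidal AUROC/AUPR.

## Disease networks and signatures

Edges are classified by whether the endpoints share the miRNA and/or the
disease (types 1–4); only type 3 (same disease, different miRNAs) feeds the
signature analysis, and type-1 self-loops are never used. Per disease, the
type-3 edges with confidence ≥ `min_confidence` (default 0.9; a
`top_fraction` mode computes the cutoff keeping the best fraction instead
— the two coincide only on particular datasets) form the DMIN, collapsing
directed duplicates to one undirected edge with the larger confidence. A
class signature is the intersection of the member DMINs' edge sets —
conservation requires the *edge*, not merely the vertices — with
weakest-link weights; connected components of the result can be reported
separately. Disease classes are user configuration; a default layout with
four cancer classes (gastrointestinal, endocrine, leukemia, nerve) is
bundled.

## Synthetic data generator

The generator emulates the record structure of PhenomiR-like databases:
multiple studies per disease, dual and single fold-change values, missing
(study, miRNA) cells, and study-scoped PMIDs. Within each study a planted
module of miRNAs draws fold-changes from a shared latent factor,
fc = loc + scale·(√ρ·z_study + √(1−ρ)·ε), giving pairwise module
correlation ≈ ρ; background miRNAs are independent noise. Defaults
(30 miRNAs, 3 diseases, 60 studies/disease, a 3-miRNA module at ρ = 0.9,
30% dual values, 10% missing cells, 50% co-citation) are a desk-scale
instance with strong planted structure that every scorer family can
detect, keeping a full pipeline run to tens of seconds on one CPU.
Identical configuration and seed give byte-identical record files.

What it does *not* emulate: real miRNA/disease vocabularies, realistic
fold-change marginals beyond location/scale, study-specific miRNA panels
(every generated study assays the full roster, minus missing cells), and
batch effects. Two consequences matter. First, passing recovery tests shows
the pipeline recovers latent-factor co-expression at the configured
strength, not that it would recover real signatures from real records.
Second, because studies assay everything, a co-cited study validates every
miRNA pair it contains, so at default scale the co-citation truth saturates
(all type-3 edges positive); the pipeline detects degenerate labels and
skips the curves rather than reporting meaningless ones. Validation logic
is exercised on small record sets where both label classes occur.

## Numerical choices and degeneracies

- Borda truncation uses `floor(round(x·100, 6))/100` so that binary float
  noise (0.66 stored as 0.6599…) cannot shift the truncated digit.
- CLR backgrounds with sd ≤ 1e-12·max(1, |mean|) are treated as exactly
  flat (z = 0): the std of identical floats is ~1e-16, not 0.
- MRNETB improvement comparisons use a 1e-12 epsilon; replacement is capped
  at 2p iterations (never observed to bind).
- Correlation pairs with < 3 shared samples, NaN correlations
  (zero variance), and dCor of constant columns all score 0.
- `interaction_space(n) = n²` sizes the ordered-pair universe without
  materializing it (4,343 nodes → 18,861,649 pairs).
- Empty datasets parse to empty universes; an unknown disease yields an
  empty DMIN with a warning; intersection of anything with an empty DMIN
  is empty.

## Known limitations

- The full-scale problem (thousands of MD nodes) is out of desk scope:
  MRNETB is O(p³) per target and the tree ensemble dominates runtime from a
  few hundred nodes; no parallel execution is provided.
- Only type-3 interactions are analyzed further; types 2 and 4 are exposed
  in the consensus output but not interpreted.
- The truth network inherits curation bias: absence of co-citation is not
  evidence of absence, so reported precision is a lower bound only in the
  idealized sense discussed above.
- No miRBase accession mapping or disease-ontology normalization: name
  variants of the same entity become distinct nodes.
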