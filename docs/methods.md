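# Methods

## Model

`termrank` treats disease-gene characterisation as a feature-selection
problem over functional terms. Each gene *g* in a labelled universe is
encoded by one feature per term: the −log₁₀ upper-tail hypergeometric
probability that *g*'s strict interaction-network neighbourhood *G₂*
overlaps the term's member set *G₁* at least as much as observed, against a
background of *N* genes. The binary target is membership in the positive
(disease) gene set. Terms are then ranked by the mutual information between
the discretized feature and the label — the maximum-relevance criterion of
the mRMR family — and a report is cut at an MI threshold chosen from the
features-vs-cutoff curve.

The method's assumptions are worth stating plainly:

* a gene's functional context is proxied by its *direct* neighbours (one
  hop; no diffusion or ancestor propagation over the GO graph);
* annotations are taken as given per term — no true-path propagation up the
  ontology, because the input format carries no ontology structure;
* enrichment p-values are used as *scores*, not as tests: no
  multiple-testing correction is applied, deliberately;
* MI ranking treats features independently (no redundancy term and no
  classifier downstream).

## Enrichment computation

The upper tail is inclusive of the observed overlap, P(X ≥ m), equivalently
the survival function at m − 1, evaluated with
`scipy.stats.hypergeom.sf` — never by naive floating-point summation of pmf
terms, which underflows catastrophically at genome scale. An exact
integer-arithmetic summation oracle exists in the test suite only and the
implementation is required to match it to ≤ 1e−9 relative error over the
complete grid of count configurations with N ≤ 25.

Numerical choices:

* `SCORE_CAP = 350`: −log₁₀ of roughly the smallest positive double. A
  tail probability that underflows to exactly 0 maps to the cap, keeping
  scores finite and comparable.
* an overlap of m = 0 gives P = 1 and a score of exactly 0 (this includes
  genes with empty neighbourhoods);
* scores below 1e−12 are stored as structural zeros in the sparse matrix —
  they are numerically meaningless and only bloat the triplet file.
* background *N* defaults to the size of the analyzed universe after
  restriction. The genome-wide constant this stands in for is a
  user-supplied choice (`--background-n`) when an absolute convention is
  preferred.

The matrix is assembled from the sparse overlap pattern
`adjacency @ annotation-incidence`, so only gene–term pairs with nonzero
overlap incur a tail evaluation.

## Sample restriction

Genes are dropped from the universe if (a) they are not network nodes, or
(b) neither they nor any of their neighbours carry any term annotation —
in case (b) the gene's feature vector would be identically zero and carries
no information. The restriction report counts drops at each step for both
the whole universe and the positive class, and the operation is idempotent.
Terms left with no member inside the restricted universe are removed from
the catalogue with a logged warning.

## Mutual-information estimator

The MI integral needs a density estimate for continuous features; we use
the discretization conventional in mRMR practice: three states at
mean ± k·sd per column (k = 1 by default, configurable), with the sample
(n−1) standard deviation, and a constant column mapping everything to the
middle state. MI is computed on the 2 × 3 contingency table in log base 2
(bits; base e available). Ties in MI — common once values are rounded for
display — are broken by catalogue column index, which makes the ranking
deterministic and reproducible. The reported table rounds MI to three
decimals but ranking and selection always use unrounded values; the TSV
carries an extra full-precision column so a written list can be re-filtered
losslessly.

With P positives among n genes the label entropy H(c) bounds every MI value
from above; at a 29 : 17,639 imbalance H(c) ≈ 0.0176 bits, which is why
realistic MI values in this setting are small numbers of millibits.

## Synthetic benchmark

The generator emulates the shape of a real study at desk scale. Defaults:
2,000 genes; 280 GO-like + 20 KEGG-like terms with log-uniform sizes in
[5, 200]; a background network from Poisson stub pairing with mean degree
20 (self-pairs and duplicate pairs rejected and re-paired); 25 positive
genes; 5 planted terms; rewiring fraction ρ = 0.5. These defaults are the
package's test conditions, chosen to reproduce the qualitative regime of a
genome-scale study — extreme class imbalance, heterogeneous term sizes, a
sparse network — at roughly one-tenth scale so a full pipeline run takes
seconds.

Signal is injected by *rewiring*: for each positive gene, a fraction ρ of
its incident edges has the far endpoint replaced by a uniformly drawn
member of a uniformly drawn planted term. Rewiring preserves the
positive's degree, so recovery cannot be driven by a degree confound — the
signal is purely in neighbourhood composition. With ρ = 0 the construction
is an exact null: positives are statistically exchangeable with negatives.

All randomness flows from one seeded `numpy.random.Generator` and files are
written in sorted order, so identical configurations give byte-identical
output.

What the generator does **not** emulate: STRING's confidence-score
distribution, degree heterogeneity (Poisson degrees are much more uniform
than real PPI hubs), the GO DAG's nested term structure, and correlated
annotations. Passing the recovery benchmark therefore shows the pipeline
detects neighbourhood-composition signal at realistic imbalance; it does
not certify behaviour under hub-dominated networks or strongly nested term
hierarchies.

## Pipeline and degenerate inputs

The pipeline is restrict → encode → rank → select, with every narrated
count logged. The MI cutoff is a user input (default 0.003) and the cutoff
curve is emitted so users can pick by inspection; no automatic elbow
detection is attempted, since the choice is intrinsically a judgement call.
Degenerate cases are handled explicitly: empty edge or annotation files and
empty positive lists are parse errors; a positive gene missing from the
universe is an error naming the offenders; a restriction that empties the
positive class aborts; an MI cutoff above the maximum yields an empty
selection with a warning rather than an error. Stage failures abort with
the stage name and remove partial outputs.

## Design choices made where the design was open

* **Edge-score threshold** defaults to "no filtering"; `--min-score` is
  exposed for confidence-scored networks. Unscored edges always pass.
* **MI log base** defaults to bits; published MI tables rarely state their
  base, and rounded values cannot disambiguate it, so it is configurable.
* **Discretization** at mean ± 1 sd into three states, as conventional for
  mRMR-style estimators; the multiplier is configurable.
* **Identifier systems** are out of scope: ids are opaque strings and users
  must pre-harmonise them (no Ensembl/symbol mapping).
* **CLI subcommands** (`generate`, `run`, `encode`, `rank`, `select`) are a
  thin layer over the library; the importable API is the primary surface.

## Known limitations

* Desk scale only: the matrix builder is in-memory (no chunking); a
  20k × 21k matrix is fine, but nothing larger was targeted.
* One-hop neighbourhoods only; no network propagation.
* The MI estimator's discretization is coarse by design; with very few
  positives the 2 × 3 table is sparse and MI estimates are noisy — ranks
  near the cutoff should be read with that in mind.
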