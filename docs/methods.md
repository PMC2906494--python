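# Methods

## Graph model

A structure is a finite, connected, loop-free undirected graph with a
vertex label (atom type) on every vertex and an edge label (bond type
`s/d/t/ar`) on every edge. Hydrogens are suppressed by default when
parsing SDF/SMILES — descriptor work in this tradition is done on
heavy-atom graphs — and multi-fragment records (salts) are rejected unless
the caller opts into keeping the largest fragment. Distances are
unweighted hop counts throughout; bond labels acquire numeric values only
inside the edge functional.

## Entropy measures

All measures are *partition-independent*: instead of partitioning a graph
invariant into equivalence classes, an information functional `f` assigns
every vertex a positive value, `p(v) = f(v)/Σ f(u)` defines a probability
distribution over vertices, and the descriptor is its Shannon entropy
(base 2, so the maximum is `log2 |V|` bits) or the scaled complement
`λ (log2 |V| − H)` with `λ = 1000` by default. The λ-measure vanishes
exactly when the functional is constant — in particular on uniformly
labeled vertex-transitive graphs — and grows with structural/label
heterogeneity.

### Functionals and coefficient schemes

* **Sphere functional** `f(v) = α^( Σ_{j=1}^{ρ} b_j |S_j(v)| )` with
  `α = 2` by default. Sphere coefficients are strictly decreasing and
  positive: `linear` gives `b_j = ρ − j + 1`, `exponential` gives
  `b_j = 2^(ρ−j)` (ρ = diameter). Exponentials are evaluated entirely in
  log space (`ln f = ln α · Σ b_j |S_j|`), with probabilities via a
  softmax, so large graphs cannot overflow.
* **Vertex-label sphere functional** inserts a per-label weight:
  `Σ_j Σ_ℓ b_j w(ℓ) |S_j^ℓ(v)|`. Weight schemes span hydrogen (lightest)
  to uranium (heaviest): `mass` uses `w(ℓ) = m_ℓ / m_U`, `inverse_mass`
  uses `w(ℓ) = m_H / m_ℓ`, `uniform` reduces the functional exactly to
  the unlabeled one. Atomic masses come from a bundled standard table;
  an element without a tabulated mass is an error, not a silent default.
* **Local-information-graph label functional**: the local information
  graph L(v, j) is the union of all shortest paths of length j starting
  at v (paths directed away from v, so a path and its reverse are not
  double-counted). With `γ_ℓ(v,j)` the number of its vertices carrying
  label ℓ, `f(v) = Σ_j Σ_ℓ c_ℓ γ_ℓ(v,j)`. The `c_ℓ` are normalised over
  the alphabet in use (Σ c_ℓ = 1), ranked by ascending atomic mass:
  `linear_rank` makes `c_r ∝ K − r + 1`, `exponential_rank` makes
  `c_r ∝ 2^(−r)`. This functional has no free exponent base — its point
  is fewer parameters.
* **Edge functional**: a path's weight is the sum of its bond values
  (`s=1, d=2, t=3, ar=1.5`; additive rather than multiplicative, keeping
  the level sums linear in edge multiplicities), `L_j(v)` sums the
  weights of the k_j shortest paths of length j, and
  `f^E(v) = Σ_j b_j L_j(v)`.
* **Combined measure**: the equal mixture
  `p = (p_vertex + p_edge)/2` of the two induced distributions, so both
  ingredients contribute identical total probability mass regardless of
  scale.

### Local information graphs without path explosion

Shortest paths are represented implicitly on the BFS shortest-path DAG:
upward path counts from the centre and downward extension counts to depth
j give the path count k_j and per-edge path multiplicities in polynomial
time; explicit enumeration is available on demand and a configurable cap
(default 10^6 paths) guards against pathological inputs. The test suite
proves the DAG formulation equal to explicit enumeration exhaustively on
every connected graph with up to 7 vertices and on random labeled graphs
with 8.

### Sphere truncation

Each functional accepts a cutoff k that drops all sphere/level terms with
j > k before normalisation. At k ≥ ρ the truncated measure equals the
full one exactly; the truncation study measures the sup-distance between
the empirical CDFs of truncated and full entropies over a corpus (via the
two-sample KS statistic). On 500 random molecule-like graphs the distance
falls below 0.05 by k = 3 and reaches 0 by k = 7 — a few neighbourhood
shells carry nearly all the structural information.

## Classical indices

Wiener index, cyclomatic number, and the orbit information content
(entropy of automorphism-orbit sizes; orbits computed exactly with BLISS'
colour-aware refinement-plus-backtracking search, vertex labels acting as
colours in labeled mode, with a configurable size budget of 128 vertices).
The six distance-information indices are individually named, documented
formulas over the distance matrix — the pair-distance entropy `I_D`, its
full-matrix variant `I_D0` (including the n diagonal zeros), the
magnitude-based `I_W = W log2 W − Σ_i k_i i log2 i`, the distance-degree
entropy `I_U`, and the mean per-vertex sphere-profile and
distance-complexity entropies `HV`, `HD`. Each is unit-tested against a
direct-from-matrix recomputation so any one formula can be corrected
without touching the others.

## Uniqueness analysis

Corpora are deduplicated up to isomorphism (topology only, or labels as
colours) by Weisfeiler-Lehman hashing with exact VF2 confirmation inside
hash buckets. The sensitivity index of a descriptor is
`S(I) = (|G| − N_I)/|G|` where `N_I` counts graphs whose value collides
with another graph's value; collisions use relative tolerance 1e−9 by
default (exact equality is selectable for integer-valued indices). On
synthetic corpora the labeled entropy measures rank near S = 1 while the
Wiener index and the orbit information content are highly degenerate,
reproducing the expected ordering.

## Supervised evaluation

Superindex vectors (default: 11 unlabeled + 5 labeled descriptors) feed
stratified 10-fold cross-validation of a 50-tree random forest and an
RBF-kernel SVM (grid search over cost {0.1, 1, 10, 100} and kernel width
{0.1, 1, 10}/m by inner 5-fold CV on each training part when enabled).
Features are standardised inside each training fold; the positive class is
label 1. Reported metrics come from the confusion matrix pooled over
folds, which keeps accuracy, sensitivity, specificity, precision and
F-measure mutually consistent by construction; per-fold vectors are
retained for the standard deviations of the random-subset experiment
(10 draws of 7 unlabeled descriptors vs 10 draws of 5 unlabeled + 2
labeled). Feature selection is CFS-style greedy forward search on the
merit `k r̄_cf / sqrt(k + k(k−1) r̄_ff)`.

## Synthetic data

* **Labeled cycles** parameterise a disorder axis — uniform, two-block,
  alternating, all-distinct labelings — on a fixed C_n topology, which is
  the cleanest setting for the monotone entropy-vs-disorder property.
* **Random molecules** are random attachment trees plus ring closures,
  degree capped at 4, atom types drawn from a carbon-biased alphabet and
  bonds from {single, double}. They are chemically plausible in size and
  branching only; no valence model beyond the degree cap is enforced.
* **Two-class corpus** (default 400 graphs): graphs come in pairs sharing
  one topology; the class-0 member gets a near-uniform carbon labeling
  with single bonds, the class-1 member a disordered labeling over a
  7-element alphabet with mixed bond orders. The class signal therefore
  lives entirely in the labels. Consequences worth knowing: unlabeled
  descriptors are *identical* within a pair, so unlabeled-only classifiers
  sit at or below chance — below, in fact, because a test graph's
  feature-identical twin usually sits in the training fold with the
  opposite label, a deliberate worst case for skeleton-only description.
  For the same reason pooled CV predictions are correlated, so the
  permutation-null accuracy is estimated as the mean over several label
  shuffles rather than from a single draw. Passing results on this corpus
  show that the pipeline detects label structure; they do not show that
  real mutagenicity data is this easy — real activity signals correlate
  with topology too and are far noisier.

## Numerical choices and limitations

* Entropies are in bits; `0 · log 0 = 0`; probability sums are stable to
  1e−12 via log-space softmax.
* Descriptor tables are TSV with 12 significant digits; integer-valued
  descriptors read back as floats.
* Coefficient schemes are frozen dataclasses — every knob (α, sphere
  coefficients, label weights, label mix, edge values, λ) is explicit,
  and none is learned from data.
* The exact automorphism search and the dedup canonicaliser are budgeted,
  not approximate: oversize inputs raise instead of degrading silently.
* Bond stereochemistry, charges, isotopes and V3000 Molfiles are out of
  scope; no descriptor here consumes them.
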