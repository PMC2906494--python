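# molentropy

Information-theoretic topological descriptors for vertex- and edge-labeled
molecular graphs, with a descriptor-uniqueness analysis and a supervised
QSAR evaluation harness.

## The problem

Most topological indices characterise only the *skeleton* of a molecule —
every atom and bond treated as equal. Real chemical graphs carry labels:
atom types on vertices, bond types on edges, and ignoring them throws away
exactly the information that distinguishes, say, an amide from an alkene
of the same shape. `molentropy` implements a family of *partition-
independent* graph entropy measures that incorporate those labels, the
classical indices they are compared against, and the machinery to evaluate
both: how unique are the descriptor values on a corpus, and how well do
descriptor vectors predict a binary activity class?

## The measures

Every measure starts from an *information functional* `f` that assigns each
vertex a positive value; normalising gives vertex probabilities and a graph
entropy

```
p(v) = f(v) / Σ_u f(u),      I_f(G) = − Σ_v p(v) log2 p(v),
I_f^λ(G) = λ (log2 |V| − I_f(G)),   λ = 1000.
```

Implemented functionals (S_j(v) is the j-sphere of v, the vertices at
distance exactly j):

* `f_sphere` — `α^(Σ_j b_j |S_j(v)|)` with strictly decreasing sphere
  coefficients `b_j` (linear or exponential); topology only.
* `f_sphere_vlabel` — the same with a per-atom-type weight `w(ℓ)` inside
  each sphere (atomic mass / inverse mass / uniform schemes).
* `f_local_vlabel` — counts atom-type occurrences inside the *local
  information graphs* (the union of all shortest paths of length j
  starting at v), mixed by normalised per-label coefficients; no free
  exponent base.
* `f_edge` — sums bond-value-weighted shortest-path weights per level
  (single = 1, double = 2, triple = 3, aromatic = 1.5).
* `f_combined` — equal mixture of a vertex-label and an edge-label
  distribution.

Classical comparison indices: Wiener index `W`, cyclomatic number `μ`,
orbit information content `I_orb` (entropy of automorphism-orbit sizes),
and the distance-matrix information indices `I_D, I_D0, I_W, I_U, HV, HD`.
The default 16-column *superindex* concatenates 11 unlabeled-graph and 5
labeled-graph descriptors per molecule.

## Worked example

`python examples/disorder_ordering.py` evaluates the vertex-label sphere
functional on 6-cycles of increasing label disorder:

```
C6 label configuration     entropy [bits]   lambda-measure
  uniform                      2.584963       0.000000
  blocks                       2.584940       0.022339
  alternating                  2.584810       0.152296
  all_distinct                 2.583688       1.274623
```

A uniformly labeled cycle is vertex-transitive, the functional is constant
and the entropy reaches its maximum log2 6 = 2.584963 bits exactly (the
λ-measure vanishes); every increase in label disorder lowers the entropy
and raises the λ-measure.

`python examples/classify_two_class.py` runs the full QSAR harness on the
synthetic two-class corpus (400 graphs; class = how disordered the
labeling is, topologies matched across classes):

```
  rf: acc  76.2  sens  72.5  spec  80.0  prec  78.4  F  75.3
 svm: acc  88.5  sens  83.5  spec  93.5  prec  92.8  F  87.9
label-shuffled rf accuracy: 44.5 (chance is 50)
```

Both a 50-tree random forest and an RBF-SVM recover the label-disorder
class far above chance, and shuffling the class labels destroys the
signal. `examples/sensitivity_study.py` and `examples/truncation_study.py`
show the descriptor-uniqueness ranking and how few neighbourhood spheres
the entropies actually need.

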