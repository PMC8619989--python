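# Methods

## The statistic and its decomposition

For integer-coded multinomial features X, Y and a conditioning set **Z**
observed on N samples, the log-likelihood-ratio (G) statistic of the
independence null X ⊥ Y | **Z** is

    G(X, Y | Z) = 2N Σ_{x,y,z} P(x,y,z) ln [ P(x,y|z) / (P(x|z) P(y|z)) ]

summed over cells with positive joint count, with natural logarithms
throughout; all entropies in this package are therefore in nats and no
base conversion ever occurs.  Rewriting the conditional probabilities over
joint ones and regrouping gives the identity used everywhere here:

    G(X, Y | Z) = 2N · I(X; Y | Z)
                = 2N · [ H(X,Z) + H(Y,Z) − H(X,Y,Z) − H(Z) ]

The right-hand side is a sum of empirical joint entropies, each a function
of the *set* of features it covers.  The Joint Entropy Table (JHT) caches
these terms under sorted index-tuple keys; a conditional test costs at most
four term lookups and an unconditional one three, since H(∅) = 0 by
convention (which makes the unconditional test a plain specialization
rather than a special case).  Equality with the canonical statistic is
exact up to floating-point rounding: the test suite and the acceptance
script both verify agreement to ~1e-12 relative over randomized fixtures.
Tiny negative values of the entropy sum (cancellation noise) are clamped to
zero before scaling; anything below −1e-9 is treated as a bug, not noise.

## Degrees of freedom

The χ² reference distribution needs a DoF count per test.  We use a
per-stratum zero-eliminating rule: for every conditioning configuration c
with positive support,

    DoF = Σ_c  max(r_x(c) − 1, 0) · max(r_y(c) − 1, 0)

where r_x(c) is the number of X-levels observed in stratum c.  Value levels
with zero support are excluded, which is why contingency tables are sparse
mappings with implicit zeros.  This is a reconstruction of the PC-family
convention of eliminating zero cells from the conditional PMFs; the exact
historical variants differ in detail, so the single rule above is used by
*all four* backends — interchangeability of backends is only meaningful if
they share one DoF method.  A test whose DoF sums to zero (a constant
feature, for instance) is uninformative: it returns p = 1 and an
"independent" verdict instead of consulting χ²(0).

Because the rule needs the zero pattern of the joint PMF, a pure
entropy-cache backend would have to re-count data for every test just for
DoF.  Instead, the DoF cache is filled at term-computation time: when the
PMF of a feature set S is built on a JHT miss, DoF values for *every*
unordered pair {a, b} ⊆ S given S ∖ {a, b} are computed and stored at once.
That moment is the only opportunity — the dataset is not consulted for S
again.  The fill generalizes the pairwise scheme to any |S| ≥ 2, since the
same "only opportunity" argument applies at every size.  Neither cache
evicts entries; memory is reported as entry counts, and the problem sizes
used here never need eviction.

## Counting backends

All backends implement one black-box API: given (x, y, z) as feature
indices, return (G, DoF).  The consumer — IPC-MB — never touches samples.

* **Direct counting** scans the dataset per test (the reference).
* **AD-trees** cache sample counts in an interleaved tree of count nodes
  and feature nodes over a fixed feature ordering.  Zero-count nodes are
  never created; the most common value (MCV) of every feature node is
  elided and reconstructed at query time as parent count minus stored
  siblings (ties elide the smallest value index, so rebuilds are
  deterministic); nodes whose count falls strictly below
  ceil(llt_percent/100 · N) become Leaf-Lists holding row indices that are
  scanned on demand, so llt = 0 disables Leaf-Lists entirely.  Static trees
  are fully expanded up front (and drop row indices outside Leaf-Lists);
  dynamic trees start as a bare root and expand only along queried
  branches, which keeps them no larger than the static tree.  Contingency
  tables are assembled by recursive descent honoring both optimizations.
* **dcMI** answers from the JHT/DoF cache as described above.

The central correctness property, enforced by the acceptance suite, is that
all backends produce identical G (to 1e-9 relative), identical DoF, and
identical verdicts — hence identical IPC-MB traces and test counts.

## Blanket discovery

IPC-MB recovers MB(T) = PC(T) ∪ SP(T).  Parent-child recognition tests each
candidate X against conditioning subsets of the shrinking candidate pool in
increasing size order (k = 0, 1, 2, …; lexicographic subset order over
sorted indices, so runs are reproducible and backend-comparable), removing
X on the first separating set and recording it as sepset(T, X).  A
symmetry pass keeps X only if T survives recognition from X's side over the
full feature set minus X — the conservative pool choice, preferring
correctness over test count at desk scale.

Spouse discovery iterates Y ∈ PC(X) for X ∈ PC(T), Y ∉ PC(T) ∪ {T}, and
declares Y a spouse when T and Y are dependent given sepset(T, Y) ∪ {X}.
The conditioning set matters: conditioning on PC(T) instead (a plausible
reading of the algorithm's informal description) opens colliders at *every*
child of T simultaneously, so non-spouse ancestors of children reach T
through paths like T → C ← W ← Y and are falsely admitted — on random 6–8
node DAGs this corrupted roughly one blanket in seven.  The
sepset-augmented set blocks all such paths while opening only the candidate
collider at X; with it, oracle-driven discovery recovers the graph-truth
blanket on every fixture tested (699/699 targets).  Both alternative
conditioning choices remain available via
`CITestConfig.spouse_conditioning`.

Validation follows the oracle method: run IPC-MB with exact d-separation on
a known network as the CI tester and require the result to equal the
graph-defined blanket.  d-separation itself is implemented as Bayes-ball
reachability (linear-time, no path enumeration) and is cross-checked in the
tests against networkx's independent implementation and against exhaustive
minimal-separating-set search on small networks.

## Synthetic data

Datasets are produced by ancestral sampling from discrete Bayesian
networks in topological order, one column per node, deterministic given an
integer seed; per-run child seeds derive from one experiment seed by a
splitmix-style mixing function (kept below 2³¹) so any table cell can be
reproduced in isolation.  Networks come either from BIF files (the
bnlearn-emitted subset of BIF 0.15; the reader is a small hand-written
recursive-descent parser) or from the bundled random generator: a random
topological order, up to `max_parents` parents per node, arities drawn
from a small range, and CPT rows drawn from a Dirichlet(0.5) smoothed away
from the simplex boundary so every value remains legal.  The generator's
defaults (6–12 nodes, ≤3 parents, arities 2–3, n = 2000–4000 in the
experiment harness; n = 20000 for finite-sample recovery checks) are the
desk-scale regime the correctness claims are exercised in.

What the synthetic generator does *not* emulate: real networks with
hub-dominated degree distributions, near-deterministic CPTs, latent
confounders, missing values, or sample-selection bias.  Passing tests
therefore demonstrate algorithmic and numerical correctness — exactness of
the decomposition, interchangeability of backends, fidelity of counts, and
oracle-exact blanket recovery — not robustness of constraint-based
discovery on messy real-world data, where finite-sample test errors
propagate into blanket errors in ways no counting backend can fix.

## Numerical and policy choices

* Significance: verdicts are "independent" iff p ≥ α (reject strictly
  below α); α defaults to 0.05 and is never adapted per test.
* An optional sample-size reliability heuristic (declare a test unreliable
  when N < factor × potential cell count) is exposed but off by default
  (factor 0), so results are driven by the statistic alone.
* Arities are inferred as max observed value + 1 but can be overridden by
  a JSON sidecar, since a legal value may be absent from a finite sample —
  this affects DoF through the zero-elimination rule.
* Feature ordering for AD-trees defaults to natural column order; queries
  are re-sorted internally, so callers never see the ordering.
* The empirical type-I error of the unconditional test at α = 0.05,
  n = 5000 over 500 replicates, falls in the expected binomial band around
  5% (measured by the acceptance script at run time).

## Known limitations

* No cache eviction: memory grows with the number of distinct feature
  sets tested, which is fine at the bundled problem sizes but not for
  hundreds of features at high conditioning orders.
* The DoF rule is one defensible reconstruction among several used in the
  PC literature; absolute p-values can differ across conventions even
  though all backends here agree with each other by construction.
* Dynamic AD-trees determine the MCV by counting all sibling values at
  expansion time, trading some work for exactness.
* Blanket recovery from finite samples degrades with weak edges and small
  n, as expected for any constraint-based method; the package guarantees
  only that every backend degrades *identically*.
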