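# Methods

## Model and scope

`crnconnect` works with reaction networks `a₁ⱼX₁ + … + aₙⱼXₙ → b₁ⱼX₁ + … +
bₙⱼXₙ` under mass-action kinetics, `ẋ = N v_κ(x)` with
`v_κ(x)_j = κ_j x^{A_j}`. Reactions with equal reactant and product are
rejected, so `N` has no zero column. The object of study is the
multistationarity region

    Ω = { (κ, c) : |V_{κ,>0} ∩ P_c| ≥ 2 },   P_c = { x ≥ 0 : W x = c },

and the tool certifies the *sufficient* condition for `Ω` to be path
connected; it can never certify disconnectedness. An inconclusive outcome
means exactly that.

The chain of reasoning: for a conservative network without relevant boundary
steady states, the sign of `g(x, κ) = (−1)^s det M_κ(x)` on the positive
steady-state set controls multistationarity (negative somewhere ⇒ the pair
`(κ, Wx)` enables it; positive on a whole class ⇒ excluded). The convex
parametrization `Ψ` turns `g` into a polynomial — the critical polynomial
`(−1)^s det M̃(h, λ)` — and a strict separating hyperplane of its signed
support implies that the negative region of the polynomial on the positive
orthant is path connected and dense in its closure, which transfers to `Ω`.

## Exact arithmetic policy

No sign that enters a mathematical conclusion is ever computed in floating
point. All linear algebra is over `fractions.Fraction` (with `sympy` for
rank/rref/nullspace); the LP solver is an exact rational phase-I revised
simplex with Bland's rule (termination guaranteed), returning either a
feasible point or a Farkas certificate. Double description for cone
generators is exact as well. Floats are accepted at the API boundary of
`evaluate_g` and converted exactly.

## Conservation matrix

`W` is canonicalized as the reduced row-echelon basis of the left kernel of
`N`. This fixes the pivot indices `i₁ < … < i_{n−s}` and therefore the rows
of `M̃` that are replaced, making the critical polynomial deterministic. For
all bundled networks the canonical `W` coincides with the published
conservation matrices.

## Conservativity and siphons

Strict positivity in `w N = 0, w > 0` is scale invariant, so the solver
decides `w N = 0, w ≥ 1` via the substitution `w = 1 + u, u ≥ 0` — an exact
equality-form feasibility problem. The same device decides, per minimal
siphon `Z`, the existence of `w ≥ 0` with `w N = 0`, positive exactly on
`Z`.

"Producing" in the siphon predicate is *gross* production (`b_ij > 0`), the
Petri-net convention: a catalyst that appears on both sides counts as
produced, and the predicate is then satisfied trivially through the
reactant. Minimal siphons are enumerated by depth-first search with
obligation branching: starting from each singleton, an unmet production
obligation is picked and every reactant species of the offending reaction is
tried in turn; branches containing an already-completed siphon are pruned.
The enumeration bound (default 22 species) turns pathological instances into
a clean error rather than an open-ended search. A brute-force subset filter
serves as the test oracle up to n = 12.

The criterion is sufficient only. The bundled cell-cycle module is the
deliberate counterexample kept in the panel: its mutual-activation loop
makes {C, M} a minimal siphon carried by no conservation vector, and the
face C = M = Wp = 0 really does contain steady states in classes that meet
the positive orthant. The pipeline therefore reports PRECONDITION_FAILED
for it, while its critical polynomial and separating hyperplane (which do
not depend on the precondition) are still available at the library level.

## Flux cone

Extreme rays of `ker(N) ∩ ℝ^r_{≥0}` are computed by double description:
start from a nullspace basis (pure lineality), intersect with one coordinate
halfspace at a time, splitting lineality on the first constraint that cuts
it and otherwise combining positive/negative generator pairs. No adjacency
bookkeeping is kept; instead the final generator set is filtered by the
minimal-support characterization of extremality, which is exact for
subspace-meets-orthant cones (a non-extreme vector's support strictly
contains some extreme support). Rays are normalized to primitive integer
vectors and sorted lexicographically, so the λ-variable indexing is
reproducible; signed-support counts are invariant under any positive
rescaling or permutation of rays. The published ray matrices are reproduced
in this canonical order (which happens to agree with the printed λ
numbering for the small networks).

`relative_interior_point` returns the sum of the extreme rays of a cone
given by homogeneous inequalities — any strictly positive combination of
rays lies in the relative interior — and is used as the independent
cross-check of the hyperplane decision on small instances.

## Critical polynomial

`M̃(h, λ)` has entries `h_j · Σ_k N_ik A_jk (Eλ)_k` in the Jacobian rows and
constants in the replaced conservation rows; every monomial of the
determinant has degree `s` in the `h` block and degree `s` in the `λ` block
(each of the `s` Jacobian rows contributes one `h` and one `λ`).

The determinant is expanded by a dynamic program over column subsets
(memoized Laplace expansion): rows are processed sparsest-first with the row
permutation sign tracked, states map used-column bitmasks to partial-minor
polynomials, and exponent vectors are packed into integers (6 bits per
variable) so that a monomial product is a single integer addition. On one
CPU this expands the full shared-kinase polynomial (5312 terms, 20
variables) in well under a second and the 19968-term polynomial of the fully
weakly irreversible cycle in a few hundred milliseconds.

A configurable term budget (default 4·10⁶ across all DP states) aborts a
blow-up with a dedicated error instead of exhausting memory; the pipeline
treats that error as the trigger for the network reduction. The three-layer
MAPK cascade is kept as a structural fixture and is not part of the
polynomial-level test corpus.

## Separating hyperplane

With rows `d_α = (−α, 1)` for `α ∈ σ₊` and `d_β = (β, −1)` for `β ∈ σ₋`,
the weak system is the cone `C = {x : Dx ≥ 0}` over `x = (v, a)`, and
strictness is `Σ_β d_β · x > 0`. Existence of a strict separator is
therefore the feasibility of `{Dx ≥ 0, c·x ≥ 1}` with `c = Σ_β d_β`. The
solver decides it through the Farkas alternative: either an exact `y ≥ 0`
with `Dᵀy = −c` exists — then every point of `C` keeps *all* negative
exponents on the hyperplane and no strict separator exists — or the simplex
terminates with a dual vector whose negation is a point of `C` violated by
`c`, i.e. a certificate hyperplane, which is re-verified against the
definition before being returned. This replaces enumerating the generators
of `C` (double description does not scale to the ~20 000 inequalities of
the largest supports) while preserving exactness; the generator-based
relative-interior procedure remains available and the two routes are checked
against each other on small supports in the test suite. Certificates are
canonical up to the simplex path; tests assert validity, not equality with
any particular published certificate (published certificates are verified
as such).

## Reduction

The removable pattern is matched syntactically: `X` is the sole product
(coefficient 1) of a reaction `P`, the sole reactant of one conversion
reaction, appears in exactly those three reactions, and `P` has an exact
reverse. All disjoint patterns are removed in one pass (the iterated
single-removal argument justifies this); candidates whose surrounding
complexes touch another selected intermediate are skipped — a conservative
reading that can only forfeit reduction opportunities. Labels are preserved
so removed reactions are reportable. Each removal deletes exactly one
extreme ray (the reversible-pair indicator), and reduced rays embed into the
full cone by zero padding; both facts are asserted as properties in the
tests.

A path-connectivity certificate for the reduced network lifts to the
original; a failure on the reduced network decides nothing, so the pipeline
never overwrites an original-network result with a reduced-network failure.

## Pipeline verdicts

* `PATH_CONNECTED` — preconditions hold and a strict separating hyperplane
  exists for the original or a reduced network.
* `EMPTY_REGION` — the critical polynomial has no negative coefficient (no
  parameter pair enables multistationarity; the empty region is trivially
  path connected), or the network is inconsistent (a zero row in the ray
  matrix means no positive steady states at all). Consistency is checked
  before the siphon criterion because the empty-region conclusion does not
  need the boundary analysis.
* `PRECONDITION_FAILED` — conservativity or the siphon criterion could not
  be established; reported as inconclusive-with-reason, never as a claim
  about the region.
* `INCONCLUSIVE` — no hyperplane for original or reduced network, or the
  term budget was exceeded with no reduction available.

Reduction policy: `auto` (original first, reduction on failure or budget
overflow — the default), `never`, `first`.

## Benchmark fixtures

Builders reproduce the published species and reaction orders wherever
reference matrices exist (cell cycle; hybrid histidine kinase; the reduced
shared-kinase and allosteric networks; the 18-reaction 3-site cycle).
Networks whose reaction lists are described only mechanistically (2-site
cycles and their weakly irreversible variants, different-phosphatase
families, ERK, shared kinase, two-layer MAPK, covalent regulation) are
reconstructed from the standard mechanisms; the correctness gate is the
species/reaction/ray counts and, where available, the exact signed-support
sizes — all reconstructions except covalent regulation also match the
reported signed-support sizes exactly. For the covalent-regulation motif
only coarse counts are published; the builder implements the reciprocal
scheme (one enzyme covalently activates the kinase and inactivates the
phosphatase via Michaelis–Menten steps; a shared demodifier reverses both),
matches (n, r, ℓ, ℓ̃) = (12, 14, 7, 3) and the qualitative
hyperplane outcomes, and its docstring states the reconstruction rule; its
signed-support sizes are intentionally not asserted.

Rate-label conventions follow the sources: per-site blocks
`k_{6(i−1)+1..6}` in the phosphorylation families, enzymatic triples
`(catalytic, binding, unbinding) = (k_{3j−2}, k_{3j−1}, k_{3j})` in the
cascades.

## Test design and problem sizes

The suite cross-validates every algorithm against an independent route:
extreme rays against exhaustive minimal-support search (r ≤ 8), minimal
siphons against the subset brute force (n ≤ 12), conservativity against a
positive-combination grid search, the hyperplane LP against the
generator-based relative-interior procedure, and the expanded critical
polynomial against the numeric Jacobian sign function at 50 random positive
integer points per network (both sides exact, so agreement is equality, not
approximation). Property tests use derandomized `hypothesis` generators for
parser round-trips and siphon enumeration on random small networks. The
full suite, including the complete benchmark panel with every full-network
polynomial up to ~20 000 terms, runs in about a minute on one CPU.

## Known limitations

* The method certifies connectivity only; NO-hyperplane outcomes are
  inconclusive about the region (two of the bundled networks are known to
  have, respectively, a disconnected region and an open status — both are
  reported INCONCLUSIVE here, as they should be).
* Per-parameter steady-state parametrizations (solving the steady-state
  equations for a subset of variables) are a manual workflow and are out of
  scope; only the convex parametrization is implemented.
* The siphon criterion is sufficient, not necessary (see the cell-cycle
  note above).
* Simplex pricing is Bland's rule throughout; large YES instances can take
  tens of seconds (the 5536-row shared-kinase LP is the slowest case in the
  suite). Exactness was preferred over pricing sophistication.
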