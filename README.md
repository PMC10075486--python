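# crnconnect

Symbolic certification that the **multistationarity region** of a mass-action
reaction network is path connected.

For a reaction network with stoichiometric matrix `N`, rate constants `κ` and
conservation relations `W x = c`, the parameters `(κ, c)` for which the system
has two or more positive steady states in one compatibility class form the
multistationarity region. Whether that region is connected decides what kind
of bistable switches the network can implement: a connected region yields
ordinary hysteresis, a disconnected one separates distinct biological
mechanisms. `crnconnect` decides connectivity *symbolically* — no sampling,
no numerics in any sign decision — for networks of the size of cell-signaling
motifs (phosphorylation cycles, cascades, hybrid histidine kinases).

## Method

1. **Preconditions.** Verify the network is conservative (`w N = 0` with
   `w > 0`, by exact LP) and that every minimal siphon supports a nonnegative
   conservation vector, which excludes boundary steady states in relevant
   compatibility classes.
2. **Critical polynomial.** Compute the extreme rays `E₁ … E_ℓ` of the flux
   cone `ker(N) ∩ ℝ^r_{≥0}` (exact double description). Along the convex
   parametrization `Ψ(h, λ) = (1/h, diag(h^{A₁}, …, h^{A_r}) E λ)` of the
   positive steady-state set, the Jacobian is
   `J̃(h, λ) = N diag(Eλ) Aᵀ diag(h)`; replacing the pivot rows by the rows
   of `W` gives `M̃(h, λ)`, and the **critical polynomial** is
   `(−1)^s det M̃(h, λ)` with `s = rank N`. Negative values of this
   polynomial on the positive orthant certify multistationarity.
3. **Separating hyperplane.** Split the exponent vectors of the critical
   polynomial by coefficient sign into `σ₊`, `σ₋`. If a hyperplane
   `v·μ = a` has all of `σ₊` on one side, all of `σ₋` on the other, and not
   all of `σ₋` on the hyperplane, the negativity region — and with it the
   multistationarity region — is path connected. Existence is decided by one
   exact-rational linear program with a certificate either way.
4. **Reduction.** If the determinant is too large or no hyperplane exists,
   reverse reactions of intermediates occurring in exactly three reactions
   (`A ⇌ X → B`) are removed; a positive verdict for the reduced network
   lifts to the original one.

## Worked example

The two-species network `X1 → X2`, `X2 → X1`, `2 X1 + X2 → 3 X1`:

```python
from crnconnect import build, check_connectivity, format_report

report = check_connectivity(build("running_example"))
print(format_report(report))
```

prints

```
n = 2
r = 3
The reaction network is conservative.
There are no relevant boundary steady states.
l = 2
Number of positive coefficients: 3
Number of negative coefficients: 1
The support set has a strict separating hyperplane.
All the conditions are satisfied.
We conclude that the parameter region of multistationarity
is path connected.
```

Here `n`, `r`, `l` are the numbers of species, reactions and flux-cone rays;
the critical polynomial is `h₁λ₂ − h₁λ₁ + h₂λ₁ + h₂λ₂` (3 positive
exponents, 1 negative), its support admits a strict separating hyperplane,
and the multistationarity region is therefore path connected.

The same check runs from the shell on a plain-text reaction list
(`#` comments, `A + B -> C` / `A <-> B` lines, optional `species:` header):

```
crnconnect check network.txt --reduce auto --report text
```

A panel of cell-signaling networks (multisite phosphorylation cycles with
one or several phosphatases, weakly irreversible variants, ERK regulation,
kinase-sharing and MAPK cascades, allosteric and covalent reciprocal enzyme
regulation, a cell-cycle module, a hybrid histidine kinase) is built in
`crnconnect.fixtures`; `build(name)` returns any of them as a
`ReactionNetwork`.

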