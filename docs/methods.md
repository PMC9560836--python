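# Methods

## The entropy functional

For a graph F with edge weights Λ(uv) > 0, define the index
I = Σ Λ(uv) and the entropy

    ENT_Λ(F) = log I − (1/I) Σ Λ(uv) log Λ(uv),

equivalently the Shannon entropy (natural logarithm; nats) of the
distribution p(uv) = Λ(uv)/I over edges. Two exact properties anchor the
implementation and its tests:

* **uniform collapse** — if all weights are equal (any single-class
  partition, or Randić with α = 0), ENT = log |E| exactly;
* **upper bound** — ENT ≤ log |E| always, with equality iff all weights
  are equal, and ENT is invariant under scaling all weights by c > 0.

Weights depend only on the (sorted) pair of endpoint labels, so the sum
collapses onto edge classes: ENT = log I − (1/I) Σ_i N_i Λ_i log Λ_i over
classes i with N_i edges. The classed path is the implementation; the
test suite re-evaluates the functional edge-by-edge with no classing as
an independent oracle (agreement demanded to 1e−12).

The ABC-type weight is read as √((a+b−2)/(a·b)). The radical is
typographically mangled in some published renderings of the formula, but
is forced by the worked numeric values (nine (4,4) edges give
ABC₄ = 9√6/4) and by the classic definition of the index.

## Graph operators

`subdivision` inserts one degree-2 vertex per edge (named by its source
edge in canonical order); `line_graph` takes edges to vertices, with the
canonical source-edge pair serving directly as the new vertex identifier,
so the edge↔vertex bijection needs no side table. Both operators return
new immutable graphs. Two count identities hold for every simple graph
and are asserted on all generated families and on seeded random fixtures:
|V(L(S(G)))| = 2|E(G)| and |E(L(S(G)))| = Σ_{v∈S(G)} C(deg v, 2). The
line graph is additionally checked against an O(m²) all-pairs
shared-endpoint construction and against networkx's implementation.

## Generators

All three families live on one integer hexagonal lattice: the hexagon at
axial (q, r) has center (3q, 2r+q) and six integer corner points, so
hexagons at neighboring axial coordinates share exactly one edge and
fusion is set union. This keeps every generator exact (no floating-point
geometry) and every output deterministic.

* **T(x)**: hexagon centers {(q, r) : q, r ≥ 0, q+r ≤ x−1}. Satisfies
  |V| = x²+4x+1, |E| = (3/2)x(x+3); degree-3 count x²+x−2.
* **H(x,y)**: centers {0..x−1} × {0..y−1}. |V| = 2(x+y+xy),
  |E| = 3xy+2x+2y−1; degree-3 count 2xy−2.
* **ZCS(x,y,z)**: an equiangular hexagonal macrocycle of hexagons with
  side lengths x, y, z, x, y, z (corner hexagons shared; such a hexagon
  closes for any side lengths because opposite sides are equal), plus a
  starphene: a central hexagon at axial (0, y−1) with three linear acene
  arms along lattice directions 120° apart, of y−2, x−2 and z−2 hexagons,
  each ending in the inner notch of an alternating ring corner, where the
  tip fuses with three ring hexagons. The published account of this
  family is figure-only, so the generator is specified by a structural
  contract instead: with s = x+y+z, |V| = 12s−54, |E| = 15s−63, degree
  histogram {2: 6s−36, 3: 6s−18}, and edge classes
  (2,2): 6, (2,3): 12s−84, (3,3): 3s+15. Every constructed instance is
  validated against the full contract at build time (violations raise,
  they are never patched), and the test grid covers all x, y, z ≥ 4 with
  s ≤ 30 — the contract holds for asymmetric parameters too, not only
  the x = y = z case the published degree-sum table is restricted to.
  One published order formula (36x−54) depends on x alone and equals
  12s−54 only when x = y = z; the validation report flags asymmetric
  instances instead of choosing between the two.

The regime x, y, z ≥ 4 is enforced with an explicit error: smaller
parameters leave too little room for the arms and are outside anything
the published tables cover.

## Printed vs direct mode

The published edge-partition tables (closed-form class counts as
polynomials in the parameters) are encoded as sympy expressions and
evaluated exactly; this is "printed" mode. "Direct" mode partitions the
constructed graph. The two are deliberately never merged, because the
published tables are not uniformly trustworthy:

* the degree-basis tables for H and ZCS, and the degree-sum tables for
  T (x ≥ 2, after reading a stray 'y' in one row as x — recorded as a
  note on the partition) and ZCS (x = y = z), are exactly consistent:
  class sums match the published edge counts and every class matches the
  constructed graph;
* the degree-basis table for T undercounts its (2,2) class — the printed
  2(x+3) against 3(x+3) in the graph — leaving its sum short of the
  published size by x+3;
* the degree-sum table for H (x, y > 1) sums short by 2x+2y−4, and the
  x = 1 variant disagrees with the graph in its (8,9) row (2(y−1)
  printed, 4(y−1) in the graph).

`partition_sum_discrepancy` exposes each gap symbolically;
`discrepancy_report` evaluates it at an instance and compares printed
vs direct classes and entropies. Downstream agreement with published
*numeric* tables is only claimed where the underlying partitions are
consistent.

The lift identity used as a cross-check on every family instance: for a
benzenoid G with m_ab edges of degree class (a,b) and n_2/n_3 vertices of
degree 2/3, the endpoint-degree classes of L(S(G)) are exactly
(2,2): m22+n2, (2,3): m23, (3,3): m33+3n3. (Each edge of G survives as
one edge between its two half-edges; each degree-d vertex contributes
C(d,2) edges among its incident half-edges, all in class (d,d).)

## Numeric-table reproduction

Tables of published entropy values are re-derived cell-by-cell in both
modes. Agreement is claimed at |Δ| ≤ 5e−4: half a unit in the last
printed decimal, with room for the source's own rounding of intermediate
index values (one published cell recomputes to 5.74327 against a printed
5.7432). Three kinds of defects in the source are handled explicitly
rather than papered over:

* three tables carry corrupted row labels (citation artifacts); their
  printed values are emitted with params "unresolved" and no agreement
  claim, while freshly computed rows over the natural grids are emitted
  separately;
* three cells of the Randić table for H(x,x) are misprinted (e.g. the
  [10,10] α=−1 cell prints 6.5370 where the value recomputes to 6.8537,
  far off the column's own monotone trend); printed and direct modes
  agree with each other to 1e−12 there, isolating the defect in the
  numeral, and the tests assert these cells are flagged as disagreements;
* the x = 1 triangular case uses a published convention (a single class
  of nine (4,4) degree-sum edges, ABC₄ entropy log 9 = 2.1972, GA₅
  entropy declared zero) that differs from the direct graph values
  (L(S(T₁)) is the 12-cycle; both entropies log 12). `special_case_T_x1`
  returns both, labelled.

## Numerical choices

Double precision throughout; values are rounded to 4 decimals only at
presentation. Classes with zero count are skipped (0·log 0 = 0);
negative or non-integer formula values in printed mode raise instead of
clamping; out-of-regime parameters raise an error naming the table's
stated constraint. JSON reports round floats to 10 decimals and sort
keys, so identical inputs serialize byte-identically.

## Fixtures and randomness

The scientific pipeline is fully deterministic. Randomness exists only
in `fixture_graphs(seed, n)`, which draws small (≤ 30-edge) test graphs —
Erdős–Rényi-style graphs, paths, cycles, and random connected hexagon
patches (benzenoid-like, degrees in {2,3}) — from a seeded `random.Random`.
These exercise the operator and partition identities on inputs with
isolated vertices, disconnection, bridges and leaves, which the benzenoid
generators never produce; they do not emulate any chemical dataset, so
passing tests certify the combinatorial identities, not chemistry.

## Problem sizes

Tests and the acceptance script run the full published grids: x, y up to
10 for T and H, all ZCS triples with component ≥ 4 and s ≤ 30, and 100+
fixture graphs for the brute-force oracles. The largest graph touched is
L(S(H(10,10))) with 975 edges; everything completes in seconds.

## Known limitations

Only the three families are generated; arbitrary benzenoids enter through
the edge-list/GraphML readers. The ZCS embedding is one concrete
realization of a figure-defined structure — any embedding meeting the
structural contract yields identical entropies, since the pipeline
consumes only degree data. Entropies based on eccentricity, matchings or
independent sets are out of scope.
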