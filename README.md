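# benzentropy

Degree-based graph entropies of line graphs of subdivided benzenoid
systems.

Benzenoid hydrocarbons are modelled as planar graphs of fused hexagonal
rings, with every carbon of degree 2 or 3. A family of structural
descriptors used in mathematical chemistry scores such a graph F by an
edge-weight function Λ and summarizes it two ways: as a **topological
index** I = Σ_{uv∈E} Λ(uv), and as a **graph information entropy**

    ENT_Λ(F) = log I − (1/I) · Σ_{uv∈E} Λ(uv) · log Λ(uv)     (nats),

the Shannon entropy of the edge distribution p(uv) = Λ(uv)/I. This package
computes both for the classic degree-based weights

| scheme | Λ(uv) | edge labels |
|---|---|---|
| Randić (α) | (d_u·d_v)^α | vertex degrees |
| ABC | √((d_u+d_v−2)/(d_u·d_v)) | vertex degrees |
| GA | 2√(d_u·d_v)/(d_u+d_v) | vertex degrees |
| ABC₄ | √((A_u+A_v−2)/(A_u·A_v)) | neighbor-degree sums A |
| GA₅ | 2√(A_u·A_v)/(A_u+A_v) | neighbor-degree sums A |

applied to **L(S(G))** — the line graph of the subdivision — of three
benzenoid families, each generated on an exact integer hexagonal lattice:

* `T(x)` — triangular benzenoid, rows of 1…x hexagons;
* `H(x,y)` — hexagonal parallelogram, an x-by-y rhombus of hexagons;
* `ZCS(x,y,z)` — zigzag-edge coronoid fused with starphene: a macrocyclic
  ring of hexagons with a three-armed starphene fused into its cavity
  (x, y, z ≥ 4).

Because all degrees lie in {2,3}, the edge partition of L(S(G)) by
endpoint degrees follows in closed form from G's own degree data
(the package's `benzenoid_lift`), and entropies reduce to sums over a
handful of edge classes. The package evaluates both the published
closed-form partition tables ("printed" mode) and the partitions of the
actually constructed graphs ("direct" mode), and reports every place the
two disagree — several published tables contain internal inconsistencies,
and the discrepancy report pins them down as polynomials in the family
parameters.

## Worked example

Randić entropy (α = 1) of the line graph of the subdivided
`ZCS(4,4,4)`:

```
$ benzentropy compute --family ZCS --x 4 --y 4 --z 4 \
      --scheme randic --alpha 1 --mode printed
{
  "edge_total": 315,
  "entropy_value": 5.719996567,
  "index_value": 2445.0,
  ...
  "scheme": "randic(alpha=1)",
  "source": "L(S(ZCS(4,4,4)))"
}
```

The 315 edges of L(S(ZCS(4,4,4))) fall into three degree classes —
(2,2): 42, (2,3): 60, (3,3): 213 — giving Randić index
42·4 + 60·6 + 213·9 = 2445 and entropy 5.7200 nats (the uniform upper
bound would be log 315 ≈ 5.7525). The same number is obtained in
`--mode direct`, which builds the 234-vertex graph explicitly.

The same computation as library calls:

```python
from benzentropy import (FamilySpec, WeightScheme, entropy,
                         printed_partition)

spec = FamilySpec("ZCS", 4, 4, 4)
p = printed_partition(spec, "degree")        # {(2,2): 42, (2,3): 60, (3,3): 213}
r = entropy(p, WeightScheme("randic", 1.0))
print(round(r.entropy_value, 4))             # 5.72
```

Auditing a family instance against the published tables:

```
$ benzentropy validate --family H --x 2 --y 2
```

reports, among other things, that the degree-basis partition table for
`H(x,y)` is exactly consistent (`sum_discrepancy_polynomial: "0"`) while
the degree-sum table undercounts the edge total by `2*x + 2*y - 4`
(= 4 edges at x = y = 2).

Other subcommands: `generate` (emit a family instance, or its S / L(S)
image, as edge-list TSV or GraphML), `partition`, `tables` (reproduce a
published numeric table as CSV with both modes and agreement flags).

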