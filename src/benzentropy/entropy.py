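"""Degree-based edge-weight schemes, topological indices, and the graph
information entropy built on them.

Every scheme assigns an edge with (sorted) endpoint-label pair (a, b) a
positive weight Λ(a, b):

====================  =======================  =========================
scheme                weight Λ(a, b)           labels
====================  =======================  =========================
``randic`` (α)        (a·b)^α                  vertex degrees
``abc``               √((a+b−2)/(a·b))         vertex degrees
``ga``                2√(a·b)/(a+b)            vertex degrees
``abc4``              √((a+b−2)/(a·b))         neighbor-degree sums
``ga5``               2√(a·b)/(a+b)            neighbor-degree sums
====================  =======================  =========================

The index is I = Σ_edges Λ and the entropy (in nats; natural logarithm
throughout) is

    ENT = log I − (1/I) · Σ_i N_i · Λ_i · log Λ_i,

i.e. the Shannon entropy of the distribution that gives each edge
probability Λ/I.  It collapses to log |E| whenever all weights are equal
and is bounded above by log |E| in general.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

from .errors import BasisMismatchError, DomainError, ParameterError
from .graph import MolecularGraph
from .partitions import DEGREE, DEGREE_SUM, EdgePartition, partition_edges

SCHEME_NAMES = ("randic", "abc", "ga", "abc4", "ga5")

#: Which edge-label basis each scheme is defined on.
SCHEME_BASIS = {
    "randic": DEGREE,
    "abc": DEGREE,
    "ga": DEGREE,
    "abc4": DEGREE_SUM,
    "ga5": DEGREE_SUM,
}


@dataclass(frozen=True)
class WeightScheme:
    """A named edge-weight function; ``alpha`` is required for (and only
    for) the Randić scheme.  The published tables use α ∈ {1, −1, ½, −½},
    but any real α is accepted."""

    name: str
    alpha: Optional[float] = None

    def __post_init__(self):
        if self.name not in SCHEME_NAMES:
            raise ParameterError(f"unknown scheme {self.name!r}; expected one of {SCHEME_NAMES}")
        if self.name == "randic" and self.alpha is None:
            raise ParameterError("randic scheme requires an exponent alpha")
        if self.name != "randic" and self.alpha is not None:
            raise ParameterError(f"scheme {self.name!r} takes no alpha")

    @property
    def basis(self) -> str:
        return SCHEME_BASIS[self.name]

    def __str__(self) -> str:
        if self.name == "randic":
            return f"randic(alpha={self.alpha:g})"
        return self.name


def edge_weight(scheme: WeightScheme, pair: Tuple[int, int]) -> float:
    """Weight Λ of one edge class; strictly positive on its domain."""
    a, b = pair
    if a < 1 or b < 1:
        raise DomainError(f"labels must be >= 1, got ({a}, {b})")
    if scheme.name == "randic":
        return float((a * b) ** scheme.alpha)
    if scheme.name in ("abc", "abc4"):
        if a + b <= 2:
            raise DomainError(f"ABC-type weight undefined for pair ({a}, {b})")
        return math.sqrt((a + b - 2) / (a * b))
    # ga / ga5
    return 2.0 * math.sqrt(a * b) / (a + b)


@dataclass(frozen=True)
class ClassContribution:
    pair: Tuple[int, int]
    count: int
    weight: float
    probability: float  # total probability mass of the class, N·Λ/I


@dataclass(frozen=True)
class EntropyResult:
    """Index value I = Σ Λ, entropy in nats, and per-class breakdown."""

    scheme: WeightScheme
    index_value: float
    entropy_value: float
    edge_total: int
    per_class: Tuple[ClassContribution, ...]

    def to_dict(self) -> dict:
        return {
            "scheme": str(self.scheme),
            "index_value": self.index_value,
            "entropy_value": self.entropy_value,
            "edge_total": self.edge_total,
            "per_class": [
                {"pair": list(c.pair), "count": c.count,
                 "weight": c.weight, "probability": c.probability}
                for c in self.per_class
            ],
        }


def _check_basis(p: EdgePartition, scheme: WeightScheme) -> None:
    if p.basis != scheme.basis:
        raise BasisMismatchError(
            f"scheme {scheme} is defined on the {scheme.basis!r} basis, "
            f"but the partition uses {p.basis!r}"
        )


def index_value(p: EdgePartition, scheme: WeightScheme) -> float:
    """Topological index I = Σ_i N_i · Λ_i over the partition's classes."""
    _check_basis(p, scheme)
    nz = p.nonzero()
    if not nz:
        raise DomainError("cannot evaluate an index on an empty edge partition")
    return sum(n * edge_weight(scheme, pair) for pair, n in nz.items())


def entropy(p: EdgePartition, scheme: WeightScheme) -> EntropyResult:
    """Graph information entropy ENT = log I − (1/I) Σ N·Λ·log Λ (nats).

    Only classes with a positive count contribute; the result equals the
    Shannon entropy of the edge distribution with probabilities Λ/I.
    """
    _check_basis(p, scheme)
    nz = p.nonzero()
    if not nz:
        raise DomainError("cannot evaluate entropy on an empty edge partition")
    weights = {pair: edge_weight(scheme, pair) for pair in nz}
    total_index = sum(n * weights[pair] for pair, n in nz.items())
    acc = sum(n * weights[pair] * math.log(weights[pair]) for pair, n in nz.items())
    value = math.log(total_index) - acc / total_index
    per_class = tuple(
        ClassContribution(
            pair=pair, count=n, weight=weights[pair],
            probability=n * weights[pair] / total_index,
        )
        for pair, n in nz.items()
    )
    return EntropyResult(
        scheme=scheme, index_value=total_index, entropy_value=value,
        edge_total=p.total, per_class=per_class,
    )


def entropy_from_graph(g: MolecularGraph, scheme: WeightScheme) -> EntropyResult:
    """Direct-mode entropy: partition ``g``'s edges on the scheme's basis,
    then evaluate the entropy functional."""
    if g.n_edges == 0:
        raise DomainError("entropy of a graph with no edges is undefined")
    return entropy(partition_edges(g, scheme.basis), scheme)
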