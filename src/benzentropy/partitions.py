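"""Edge partitions by endpoint label, and the printed partition tables.

Two strictly separated evaluation modes run through the whole package:

* **direct** — :func:`partition_edges` classes the edges of an actually
  constructed graph by the sorted pair of endpoint labels (vertex degrees,
  or neighbor-degree sums for the ABC4/GA5 schemes);
* **as-printed** — :func:`printed_partition` evaluates the published
  closed-form class counts (polynomials in the family parameters) without
  consulting any graph.

The printed tables are not all internally consistent: for the triangular
benzenoid the (2,2) class is printed as 2(x+3) where the constructed graph
has 3(x+3), and two of the degree-sum tables do not even sum to the printed
edge count.  As-printed mode therefore reproduces the formulas verbatim —
discrepancies are *reported* (:func:`compare_partitions`,
:func:`partition_sum_discrepancy`), never silently corrected.

:func:`benzenoid_lift` is the closed-form bridge between a benzenoid G
(degrees in {2, 3}) and the endpoint-degree partition of L(S(G)): each edge
of G with degree pair (a, b) survives as one (a, b) edge (the two half-edges
meet at the inserted degree-2 vertex), each degree-2 vertex of G contributes
one extra (2,2) edge and each degree-3 vertex three (3,3) edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import sympy as sp

from .errors import DomainError, ParameterError, RegimeError
from .generators import FamilySpec
from .graph import MolecularGraph

logger = logging.getLogger(__name__)

#: Basis tags: endpoint vertex degrees vs. neighbor-degree sums.
DEGREE = "degree"
DEGREE_SUM = "degsum"
BASES = (DEGREE, DEGREE_SUM)

_x, _y, _z = sp.symbols("x y z", positive=True, integer=True)
_s = _x + _y + _z


@dataclass(frozen=True)
class EdgePartition:
    """Multiset of unordered label-pair classes with nonnegative counts."""

    basis: str
    classes: Mapping[Tuple[int, int], int]
    total: int
    notes: tuple = ()

    @classmethod
    def build(cls, basis: str, classes: Mapping, notes: tuple = ()) -> "EdgePartition":
        cleaned = {tuple(sorted(map(int, k))): int(v) for k, v in classes.items()}
        return cls(basis=basis, classes=cleaned, total=sum(cleaned.values()), notes=notes)

    def __post_init__(self):
        if self.basis not in BASES:
            raise ParameterError(f"unknown basis {self.basis!r}; expected one of {BASES}")
        for (a, b), n in self.classes.items():
            if a > b:
                raise ParameterError(f"class key ({a}, {b}) is not canonical (a <= b)")
            if n < 0:
                raise ParameterError(f"negative count {n} for class ({a}, {b})")
        if self.total != sum(self.classes.values()):
            raise ParameterError("total does not match the sum of class counts")

    def nonzero(self) -> Dict[Tuple[int, int], int]:
        return {k: v for k, v in sorted(self.classes.items()) if v > 0}


def partition_edges(g: MolecularGraph, basis: str) -> EdgePartition:
    """Class every edge of ``g`` by the sorted pair of endpoint labels."""
    if basis == DEGREE:
        label = g.degree
    elif basis == DEGREE_SUM:
        label = g.neighbor_degree_sum
    else:
        raise ParameterError(f"unknown basis {basis!r}; expected one of {BASES}")
    classes: Dict[Tuple[int, int], int] = {}
    for u, v in g.edges:
        key = tuple(sorted((label(u), label(v))))
        classes[key] = classes.get(key, 0) + 1
    return EdgePartition.build(basis, classes)


# -- printed tables ---------------------------------------------------------


@dataclass(frozen=True)
class PrintedTable:
    """One published edge-partition table: closed-form class counts as
    polynomials in the family parameters, plus its stated validity regime."""

    table_id: int
    family: str
    basis: str
    classes: Mapping[Tuple[int, int], sp.Expr]
    regime: str                     # human-readable constraint
    notes: tuple = ()

    def admits(self, spec: FamilySpec) -> bool:
        if spec.family != self.family:
            return False
        x, y, z = spec.x, spec.y, spec.z
        return {
            1: lambda: True,
            2: lambda: x != 1,
            3: lambda: True,
            4: lambda: x > 1 and y > 1,
            5: lambda: x == 1 and y > 1,
            6: lambda: min(x, y, z) >= 4,
            7: lambda: x == y == z and x >= 4,
        }[self.table_id]()


PRINTED_TABLES: Dict[int, PrintedTable] = {
    1: PrintedTable(1, "T", DEGREE, {
        (2, 2): 2 * (_x + 3),
        (2, 3): 6 * (_x - 1),
        (3, 3): sp.Rational(3, 2) * (3 * _x**2 + _x - 4),
    }, regime="x >= 1"),
    2: PrintedTable(2, "T", DEGREE_SUM, {
        (4, 4): sp.Integer(9),
        (4, 5): sp.Integer(6),
        (5, 5): 3 * (_x - 2),
        (5, 8): 6 * (_x - 1),
        (8, 8): 3 * (_x - 1),
        (8, 9): 6 * (_x - 1),
        (9, 9): sp.Rational(3, 2) * (3 * _x**2 - 5 * _x + 2),
    }, regime="x != 1",
       notes=("row (5,8) is printed as 6(y-1) in a single-parameter family; "
              "x substituted for y",)),
    3: PrintedTable(3, "H", DEGREE, {
        (2, 2): 2 * (_x + _y + 4),
        (2, 3): 4 * (_x + _y - 2),
        (3, 3): 9 * _x * _y - 2 * _x - 2 * _y - 5,
    }, regime="x, y >= 1"),
    4: PrintedTable(4, "H", DEGREE_SUM, {
        (4, 4): sp.Integer(8),
        (4, 5): sp.Integer(8),
        (5, 5): 2 * (_x + _y - 4),
        (5, 8): 4 * (_x + _y - 2),
        (8, 8): 2 * (_x + _y - 2),
        (8, 9): 2 * (_x + _y - 2),
        (9, 9): 9 * _x * _y - 8 * _x - 8 * _y + 7,
    }, regime="x > 1 and y > 1"),
    5: PrintedTable(5, "H", DEGREE_SUM, {
        (4, 4): sp.Integer(10),
        (4, 5): sp.Integer(4),
        (5, 5): 2 * (_y - 2),
        (5, 8): 4 * (_y - 1),
        (8, 8): 2 * (_y - 1),
        (8, 9): 2 * (_y - 1),
        (9, 9): _y - 1,
    }, regime="x == 1 and y > 1"),
    6: PrintedTable(6, "ZCS", DEGREE, {
        (2, 2): 6 * (_s - 5),
        (2, 3): 12 * (_s - 7),
        (3, 3): 21 * _s - 39,
    }, regime="x, y, z >= 4"),
    7: PrintedTable(7, "ZCS", DEGREE_SUM, {
        (4, 4): sp.Integer(6),
        (4, 5): sp.Integer(12),
        (5, 5): 6 * (_s - 8),
        (5, 8): 12 * (_s - 7),
        (8, 8): 6 * (_s - 9),
        (8, 9): 12 * (_s - 5),
        (9, 9): 3 * (_s + 25),
    }, regime="x == y == z >= 4"),
}

#: Published closed forms for |E(L(S(·)))| per family.
PRINTED_LS_SIZE: Dict[str, sp.Expr] = {
    "T": sp.Rational(3, 2) * (3 * _x**2 + 7 * _x - 2),
    "H": 9 * _x * _y + 4 * _x + 4 * _y - 5,
    "ZCS": 39 * _s - 153,
}


def _subs(spec: FamilySpec) -> dict:
    return {_x: spec.x, _y: spec.y or 0, _z: spec.z or 0}


def table_for(spec: FamilySpec, basis: str) -> PrintedTable:
    """Select the printed table covering this family/basis/parameter
    combination, or raise :class:`RegimeError` naming the constraint."""
    candidates = [t for t in PRINTED_TABLES.values()
                  if t.family == spec.family and t.basis == basis]
    if not candidates:
        raise ParameterError(f"no printed table for family {spec.family}, basis {basis}")
    for t in candidates:
        if t.admits(spec):
            return t
    stated = "; ".join(f"Table {t.table_id}: {t.regime}" for t in candidates)
    raise RegimeError(
        f"{spec} is outside the stated validity regime of every printed "
        f"{basis}-basis table for family {spec.family} ({stated})"
    )


def printed_partition(spec: FamilySpec, basis: str,
                      table_id: Optional[int] = None) -> EdgePartition:
    """Evaluate the published class-count formulas at this instance's
    parameters — exactly, without consulting any graph.  Negative formula
    values raise instead of clamping."""
    if table_id is not None:
        table = PRINTED_TABLES[table_id]
        if not table.admits(spec):
            raise RegimeError(
                f"{spec} violates Table {table.table_id}'s stated regime: {table.regime}"
            )
    else:
        table = table_for(spec, basis)
    if table.notes:
        logger.info("Table %d as-printed notes: %s", table.table_id, "; ".join(table.notes))
    classes = {}
    for pair, expr in table.classes.items():
        val = expr.subs(_subs(spec))
        if not val.is_integer:
            raise DomainError(
                f"Table {table.table_id} class {pair} evaluates to non-integer "
                f"{val} at {spec}"
            )
        if val < 0:
            raise DomainError(
                f"Table {table.table_id} class {pair} evaluates to negative "
                f"count {val} at {spec}"
            )
        classes[pair] = int(val)
    return EdgePartition.build(table.basis, classes, notes=table.notes)


def partition_sum_discrepancy(table_id: int) -> sp.Expr:
    """Printed |E(L(S(·)))| minus the sum of the table's class counts, as a
    polynomial in the family parameters.  Zero for the internally
    consistent tables (2, 3, 6, 7); nonzero for Tables 1, 4, 5."""
    table = PRINTED_TABLES[table_id]
    return sp.expand(PRINTED_LS_SIZE[table.family] - sum(table.classes.values()))


def partition_sum_discrepancy_value(table_id: int, spec: FamilySpec) -> int:
    """The discrepancy polynomial evaluated at one instance's parameters."""
    val = partition_sum_discrepancy(table_id).subs(_subs(spec))
    return int(val)


# -- the lift identity ------------------------------------------------------


def benzenoid_lift(partition_of_g: EdgePartition, degree2_count: int,
                   degree3_count: int) -> EdgePartition:
    """Predicted endpoint-degree partition of L(S(G)) from the degree data
    of a benzenoid G: (2,2) → m22 + n2, (2,3) → m23, (3,3) → m33 + 3·n3."""
    if partition_of_g.basis != DEGREE:
        raise ParameterError("benzenoid_lift needs an endpoint-degree partition")
    if degree2_count < 0 or degree3_count < 0:
        raise ParameterError("vertex counts must be nonnegative")
    allowed = {(2, 2), (2, 3), (3, 3)}
    extra = set(partition_of_g.nonzero()) - allowed
    if extra:
        raise DomainError(
            f"benzenoid_lift applies to degree-{{2,3}} graphs only; "
            f"found classes {sorted(extra)}"
        )
    m = partition_of_g.classes
    return EdgePartition.build(DEGREE, {
        (2, 2): m.get((2, 2), 0) + degree2_count,
        (2, 3): m.get((2, 3), 0),
        (3, 3): m.get((3, 3), 0) + 3 * degree3_count,
    })


# -- comparison -------------------------------------------------------------


@dataclass(frozen=True)
class PartitionComparison:
    """Per-class deltas (b − a) between two partitions on the same basis."""

    basis: str
    class_deltas: Mapping[Tuple[int, int], int]
    total_a: int
    total_b: int
    agree: bool

    def to_dict(self) -> dict:
        return {
            "basis": self.basis,
            "class_deltas": {f"({a},{b})": d for (a, b), d in sorted(self.class_deltas.items())},
            "total_a": self.total_a,
            "total_b": self.total_b,
            "agree": self.agree,
        }


def compare_partitions(a: EdgePartition, b: EdgePartition) -> PartitionComparison:
    if a.basis != b.basis:
        raise ParameterError(f"basis mismatch: {a.basis} vs {b.basis}")
    keys = set(a.classes) | set(b.classes)
    deltas = {k: b.classes.get(k, 0) - a.classes.get(k, 0) for k in sorted(keys)}
    agree = all(d == 0 for d in deltas.values())
    return PartitionComparison(
        basis=a.basis, class_deltas=deltas,
        total_a=a.total, total_b=b.total, agree=agree,
    )
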