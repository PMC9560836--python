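"""Hexagonal-lattice generators for the three benzenoid families.

All three families are laid out on the same integer hexagonal lattice.  A
hexagon with axial coordinates ``(q, r)`` gets the six corner vertices

    (X-2, Y), (X-1, Y±1), (X+1, Y±1), (X+2, Y)   with  X = 3q, Y = 2r + q,

which are integer points of a sheared/scaled hex grid: two hexagons whose
axial coordinates are lattice neighbors automatically share exactly one
edge (two corners), so fusing rings is simply taking the union of their
corner cycles.

Families
--------
* ``triangular_benzenoid(x)`` — rows of 1, 2, …, x fused hexagons forming
  a triangle; x(x+1)/2 hexagons, |V| = x²+4x+1, |E| = (3/2)x(x+3).
* ``hexagonal_parallelogram(x, y)`` — an x-by-y rhombus of hexagons;
  |V| = 2(x+y+xy), |E| = 3xy+2x+2y−1.
* ``zcs(x, y, z)`` — zigzag-edge coronoid fused with starphene: a closed
  macrocyclic ring of hexagons (an equiangular hexagon with side lengths
  x, y, z, x, y, z, corners shared) whose cavity holds a three-armed
  starphene — a central hexagon with linear acene arms fused into the
  notches of three alternating ring corners.  With s = x+y+z it satisfies
  |V| = 12s−54, |E| = 15s−63, with 6s−36 degree-2 and 6s−18 degree-3
  vertices and endpoint-degree edge classes (2,2): 6, (2,3): 12s−84,
  (3,3): 3s+15.  Every instance is validated against this structural
  contract at build time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import GenerationError, ParameterError
from .graph import MolecularGraph

logger = logging.getLogger(__name__)

#: Axial-coordinate offsets of the six edge-sharing neighbors of a hexagon,
#: in counter-clockwise order (steps of 60 degrees).
HEX_DIRECTIONS: Sequence[tuple] = ((1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))


@dataclass(frozen=True)
class FamilySpec:
    """Identifies one instance of a benzenoid family: ``T`` (triangular
    benzenoid, parameter x), ``H`` (hexagonal parallelogram, x and y) or
    ``ZCS`` (zigzag-edge coronoid fused with starphene, x, y and z)."""

    family: str
    x: int
    y: Optional[int] = None
    z: Optional[int] = None

    def __post_init__(self):
        if self.family not in ("T", "H", "ZCS"):
            raise ParameterError(f"unknown family {self.family!r}; expected T, H or ZCS")
        need = {"T": 1, "H": 2, "ZCS": 3}[self.family]
        params = self.params
        if len(params) != need:
            raise ParameterError(
                f"family {self.family} takes {need} parameter(s), got {params}"
            )
        for p in params:
            if not isinstance(p, int) or isinstance(p, bool) or p < 1:
                raise ParameterError(f"parameters must be integers >= 1, got {params}")

    @property
    def params(self) -> tuple:
        return tuple(p for p in (self.x, self.y, self.z) if p is not None)

    def build(self) -> MolecularGraph:
        """Construct the benzenoid this spec identifies."""
        if self.family == "T":
            return triangular_benzenoid(self.x)
        if self.family == "H":
            return hexagonal_parallelogram(self.x, self.y)
        return zcs(self.x, self.y, self.z)

    def __str__(self) -> str:
        return f"{self.family}({','.join(map(str, self.params))})"


def hexagon_corners(q: int, r: int) -> list:
    """Integer corner coordinates of the hexagon at axial ``(q, r)``,
    in cyclic order."""
    X, Y = 3 * q, 2 * r + q
    return [
        (X - 2, Y), (X - 1, Y + 1), (X + 1, Y + 1),
        (X + 2, Y), (X + 1, Y - 1), (X - 1, Y - 1),
    ]


def benzenoid_from_hexagons(centers: Iterable) -> MolecularGraph:
    """Union of six-cycles of the hexagons at the given axial centers;
    hexagons at neighboring centers fuse along their shared edge."""
    edges = []
    for q, r in centers:
        c = hexagon_corners(q, r)
        for i in range(6):
            edges.append((c[i], c[(i + 1) % 6]))
    return MolecularGraph.from_edges(edges)


def _require_positive(name: str, *values: int) -> None:
    for v in values:
        if not isinstance(v, int) or isinstance(v, bool) or v < 1:
            raise ParameterError(f"{name}: parameters must be integers >= 1, got {values}")


def triangular_benzenoid(x: int) -> MolecularGraph:
    """Triangular benzenoid T_x: rows of 1..x hexagons (x(x+1)/2 in all)."""
    _require_positive("triangular_benzenoid", x)
    centers = [(q, r) for q in range(x) for r in range(x) if q + r <= x - 1]
    g = benzenoid_from_hexagons(centers)
    _check(g, "T_%d" % x,
           n_vertices=x * x + 4 * x + 1,
           n_edges=3 * x * (x + 3) // 2)
    return g


def hexagonal_parallelogram(x: int, y: int) -> MolecularGraph:
    """Hexagonal parallelogram H(x, y): an x-by-y rhombus of hexagons."""
    _require_positive("hexagonal_parallelogram", x, y)
    centers = [(q, r) for q in range(x) for r in range(y)]
    g = benzenoid_from_hexagons(centers)
    _check(g, "H(%d,%d)" % (x, y),
           n_vertices=2 * (x + y + x * y),
           n_edges=3 * x * y + 2 * x + 2 * y - 1)
    return g


def zcs_hexagon_centers(x: int, y: int, z: int) -> list:
    """Axial centers of the coronoid ring and the fused starphene."""
    ring = []
    p = (0, 0)
    for i, steps in enumerate((x - 1, y - 1, z - 1, x - 1, y - 1, z - 1)):
        dq, dr = HEX_DIRECTIONS[i]
        for _ in range(steps):
            ring.append(p)
            p = (p[0] + dq, p[1] + dr)
    if p != (0, 0):  # cannot happen: opposite sides are equal
        raise GenerationError("coronoid ring failed to close")
    # Starphene: central hexagon plus three acene arms pointing at the
    # notches of alternating ring corners.  The center sits at (0, y-1);
    # each arm stops one hexagon short of its corner, fusing into the
    # corner's inner notch.
    center = (0, y - 1)
    star = [center]
    for (dq, dr), length in (((0, -1), y - 2), ((1, 0), x - 2), ((-1, 1), z - 2)):
        star.extend((center[0] + k * dq, center[1] + k * dr) for k in range(1, length + 1))
    centers = ring + star
    if len(set(centers)) != len(centers):
        raise GenerationError(f"ZCS({x},{y},{z}): overlapping hexagons in layout")
    return centers


def zcs(x: int, y: int, z: int) -> MolecularGraph:
    """Zigzag-edge coronoid fused with starphene, ZCS(x, y, z).

    Only the regime x, y, z >= 4 is supported: there the construction is
    validated against the structural contract (order 12s−54, size 15s−63,
    degree counts, edge classes) that pins down everything the entropy
    pipeline consumes.
    """
    _require_positive("zcs", x, y, z)
    if min(x, y, z) < 4:
        raise ParameterError(
            f"zcs: parameters must satisfy x, y, z >= 4 (got {x}, {y}, {z}); "
            "smaller arms/sides are outside the validated regime"
        )
    g = benzenoid_from_hexagons(zcs_hexagon_centers(x, y, z))
    s = x + y + z
    _check(g, f"ZCS({x},{y},{z})",
           n_vertices=12 * s - 54,
           n_edges=15 * s - 63,
           degree_counts={2: 6 * s - 36, 3: 6 * s - 18},
           edge_classes={(2, 2): 6, (2, 3): 12 * s - 84, (3, 3): 3 * s + 15})
    return g


def zcs_validation_report(x: int, y: int, z: int) -> dict:
    """Structural check of a ZCS instance against its contract, including
    the note that the alternative order formula 36x−54 (a function of x
    alone) agrees with 12(x+y+z)−54 only when x = y = z."""
    g = zcs(x, y, z)
    s = x + y + z
    return {
        "family": f"ZCS({x},{y},{z})",
        "n_vertices": g.n_vertices,
        "n_edges": g.n_edges,
        "order_formula_symmetric": 12 * s - 54,
        "order_formula_x_only": 36 * x - 54,
        "x_only_formula_applies": x == y == z,
        "connected": g.is_connected(),
        "degree_counts": g.degree_counts(),
    }


def _edge_classes(g: MolecularGraph) -> dict:
    out: dict = {}
    for u, v in g.edges:
        key = tuple(sorted((g.degree(u), g.degree(v))))
        out[key] = out.get(key, 0) + 1
    return out


def _check(g: MolecularGraph, name: str, n_vertices: int, n_edges: int,
           degree_counts: Optional[dict] = None,
           edge_classes: Optional[dict] = None) -> None:
    """Validate a freshly generated family instance against its count
    contract; a violation is a bug in the layout, not a user error."""
    if g.n_vertices != n_vertices or g.n_edges != n_edges:
        raise GenerationError(
            f"{name}: got ({g.n_vertices}, {g.n_edges}) vertices/edges, "
            f"contract says ({n_vertices}, {n_edges})"
        )
    if not g.is_connected():
        raise GenerationError(f"{name}: generated graph is disconnected")
    degs = set(g.degree_counts())
    if not degs <= {2, 3}:
        raise GenerationError(f"{name}: degrees {sorted(degs)} outside {{2, 3}}")
    if degree_counts is not None and g.degree_counts() != degree_counts:
        raise GenerationError(
            f"{name}: degree histogram {g.degree_counts()} != {degree_counts}"
        )
    if edge_classes is not None and _edge_classes(g) != edge_classes:
        raise GenerationError(
            f"{name}: edge classes {_edge_classes(g)} != {edge_classes}"
        )
    logger.debug("%s passed structural validation", name)
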