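"""Seeded fixture graphs for oracle tests.

Deterministic small simple graphs (≤ 30 edges): random Erdős–Rényi-style
graphs, paths, cycles, and random connected benzenoid-like patches of the
hexagonal lattice (all degrees in {2, 3}).  Used by the test suite to
brute-force-check the line-graph, subdivision and partition identities.
"""

from __future__ import annotations

import random
from typing import List

from .errors import ParameterError
from .generators import HEX_DIRECTIONS, benzenoid_from_hexagons
from .graph import MolecularGraph


def _random_simple_graph(rng: random.Random) -> MolecularGraph:
    n = rng.randint(2, 10)
    possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = rng.randint(1, min(len(possible), 30))
    return MolecularGraph.from_edges(rng.sample(possible, m), isolated=range(n))


def _random_hex_patch(rng: random.Random) -> MolecularGraph:
    """Connected patch of 1–4 fused hexagons (benzenoid-like: degrees in
    {2, 3}, at most ~21 edges)."""
    centers = [(0, 0)]
    for _ in range(rng.randint(0, 3)):
        base = rng.choice(centers)
        dq, dr = rng.choice(HEX_DIRECTIONS)
        cand = (base[0] + dq, base[1] + dr)
        if cand not in centers:
            centers.append(cand)
    return benzenoid_from_hexagons(centers)


def _path(rng: random.Random) -> MolecularGraph:
    n = rng.randint(2, 12)
    return MolecularGraph.from_edges((i, i + 1) for i in range(n - 1))


def _cycle(rng: random.Random) -> MolecularGraph:
    n = rng.randint(3, 12)
    return MolecularGraph.from_edges((i, (i + 1) % n) for i in range(n))


def fixture_graphs(seed: int, n: int) -> List[MolecularGraph]:
    """``n`` deterministic small graphs drawn from the generator mix."""
    if n < 1:
        raise ParameterError("need at least one fixture graph")
    rng = random.Random(seed)
    makers = (_random_simple_graph, _random_hex_patch, _path, _cycle)
    return [makers[i % len(makers)](rng) for i in range(n)]
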