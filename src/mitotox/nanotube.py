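"""Finite single-walled carbon-nanotube graphs from Hamada indices.

A tube is the quotient of the graphene honeycomb lattice by the chiral
(roll-up) vector C = n*a1 + m*a2, truncated to an integer number of
translational unit cells along the tube axis.  Only the hydrogen-depleted
bond graph is produced: topological descriptors need connectivity, not
coordinates.  Tubes are open (no end caps); rim carbons have degree 2 and
interior carbons degree 3.

Carboxyl functionalization attaches -COOH fragments (heavy atoms C, O, O)
to rim carbons, mimicking acid-oxidized tube tips.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from math import gcd
from typing import Iterable, Literal

import networkx as nx

from .errors import CapacityError, InvalidSpecError

Topology = Literal["zigzag", "armchair", "chiral"]
Functionalization = Literal["pristine", "carboxyl"]

#: default number of carboxyl groups for acid-treated tubes (one per tip)
DEFAULT_N_COOH = 2


def classify_topology(n: int, m: int) -> Topology:
    """Classify a Hamada index pair: (n,0) zigzag, (n,n) armchair, else chiral."""
    if not isinstance(n, int) or not isinstance(m, int) or isinstance(n, bool) or isinstance(m, bool):
        raise InvalidSpecError(f"Hamada indices must be integers, got ({n!r}, {m!r})")
    if n < 1 or m < 0:
        raise InvalidSpecError(f"require n >= 1 and m >= 0, got ({n}, {m})")
    if m == 0:
        return "zigzag"
    if m == n:
        return "armchair"
    return "chiral"


@dataclass(frozen=True)
class NanotubeSpec:
    """A finite SWCNT: Hamada indices, length in unit cells, functionalization.

    Indices are canonicalized so that n >= m (a tube and its mirror image
    share one graph).
    """

    n: int
    m: int
    n_cells: int = 3
    functionalization: Functionalization = "pristine"
    n_cooh: int = 0

    def __post_init__(self) -> None:
        n, m = self.n, self.m
        if not isinstance(n, int) or not isinstance(m, int):
            raise InvalidSpecError(f"Hamada indices must be integers, got ({n!r}, {m!r})")
        if n < m:  # canonical orientation: (m,n) enantiomer -> (n,m)
            object.__setattr__(self, "n", m)
            object.__setattr__(self, "m", n)
        classify_topology(self.n, self.m)
        if self.n_cells < 1:
            raise InvalidSpecError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.functionalization not in ("pristine", "carboxyl"):
            raise InvalidSpecError(f"unknown functionalization {self.functionalization!r}")
        if self.functionalization == "pristine" and self.n_cooh != 0:
            raise InvalidSpecError("pristine tubes carry no carboxyl groups")
        if self.n_cooh < 0:
            raise InvalidSpecError("n_cooh must be >= 0")

    @property
    def category(self) -> Topology:
        return classify_topology(self.n, self.m)

    @classmethod
    def carboxylated(cls, n: int, m: int, n_cells: int = 3, n_cooh: int = DEFAULT_N_COOH) -> "NanotubeSpec":
        return cls(n, m, n_cells, "carboxyl", n_cooh)


@dataclass
class MolecularGraph:
    """Hydrogen-depleted molecular graph.

    Node attributes: ``element`` (symbol) and ``hydrogens`` (implicit H
    count, used by E-state descriptors).  nSK, the non-hydrogen atom count,
    equals the number of nodes by construction.
    """

    graph: nx.Graph
    meta: dict = field(default_factory=dict)

    @property
    def nsk(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def atoms(self) -> list[tuple[int, str]]:
        return [(i, d["element"]) for i, d in sorted(self.graph.nodes(data=True))]

    @property
    def bonds(self) -> list[tuple[int, int]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges())

    def degrees(self) -> dict[int, int]:
        return dict(self.graph.degree())

    def to_json(self) -> str:
        return json.dumps(
            {
                "atoms": [{"id": i, "element": el, "hydrogens": self.graph.nodes[i].get("hydrogens", 0)}
                          for i, el in self.atoms],
                "bonds": [list(b) for b in self.bonds],
                "meta": self.meta,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MolecularGraph":
        payload = json.loads(text)
        g = nx.Graph()
        for a in payload["atoms"]:
            g.add_node(int(a["id"]), element=a["element"], hydrogens=int(a.get("hydrogens", 0)))
        g.add_edges_from((int(u), int(v)) for u, v in payload["bonds"])
        return cls(g, payload.get("meta", {}))

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[int, int]], element: str = "C") -> "MolecularGraph":
        """Convenience constructor for test graphs: all atoms one element,
        implicit hydrogens filled by sp2 convention for carbon."""
        g = nx.Graph()
        g.add_edges_from(edges)
        for i in g.nodes:
            g.nodes[i]["element"] = element
            g.nodes[i]["hydrogens"] = max(0, 3 - g.degree(i)) if element == "C" else 0
        return cls(g)


def _translation_vector(n: int, m: int) -> tuple[int, int]:
    """Lattice coordinates (t1, t2) of the tube translation vector T."""
    d_r = gcd(2 * m + n, 2 * n + m)
    return (2 * m + n) // d_r, -((2 * n + m) // d_r)


def atoms_per_cell(n: int, m: int) -> int:
    """Carbon atoms in one translational unit cell: 4(n² + nm + m²)/d_R."""
    d_r = gcd(2 * m + n, 2 * n + m)
    return 4 * (n * n + n * m + m * m) // d_r


def build_nanotube_graph(spec: NanotubeSpec) -> MolecularGraph:
    """Roll the honeycomb lattice into the finite tube graph of ``spec``.

    Lattice sites are indexed (u, v, s) with sublattice s in {A, B}; site B
    sits at (u+1/3, v+1/3) in the (a1, a2) basis.  Exact rational axial (t,
    units of the translation vector T) and circumferential (c, units of the
    chiral vector C) coordinates select one fundamental domain: c in [0,1)
    (roll-up identification) and t in a window of height n_cells.

    The axial window offset is chosen deterministically (smallest midpoint
    between atom layers) so that the open ends cut as few bonds as
    possible; offsets leaving singly-coordinated rim atoms are rejected.
    For chiral tubes where every planar cut dangles some atoms, the best
    offset is taken and dangling atoms are pruned, so rim degrees are
    always 2.
    """
    import numpy as np

    n, m, cells = spec.n, spec.m, spec.n_cells
    t1, t2 = _translation_vector(n, m)
    den_t = t1 * m - t2 * n        # (T x C)/(a1 x a2) > 0
    den_cp = -(n * t2 - m * t1)    # -(C x T)/(a1 x a2) > 0
    # integer coordinates: t = T3/(3 den_t), c = C3/(3 den_cp)
    d_t3, d_c3 = 3 * den_t, 3 * den_cp

    def t3_of(u: int, v: int, s: int) -> int:
        return 3 * (u * m - v * n) + s * (m - n)

    def c3_of(u: int, v: int, s: int) -> int:
        return -(3 * (u * t2 - v * t1) + s * (t2 - t1))

    def canonical(u: int, v: int, s: int) -> tuple[int, int, int]:
        k = c3_of(u, v, s) // d_c3
        return u - k * n, v - k * m, s

    reach = n + m + (cells + 2) * (abs(t1) + abs(t2) + 2) + 3
    rng = np.arange(-reach, reach + 1)
    uu, vv = np.meshgrid(rng, rng, indexing="ij")
    sites: list[tuple[int, int, int]] = []
    t3s: list[int] = []
    for s in (0, 1):
        t3 = 3 * (uu * m - vv * n) + s * (m - n)
        c3 = -(3 * (uu * t2 - vv * t1) + s * (t2 - t1))
        mask = (c3 >= 0) & (c3 < d_c3) & (t3 >= -2 * d_t3) & (t3 < (cells + 2) * d_t3)
        for u, v, t in zip(uu[mask].tolist(), vv[mask].tolist(), t3[mask].tolist()):
            sites.append((u, v, s))
            t3s.append(t)

    site_t3 = dict(zip(sites, t3s))
    layers = sorted({t % d_t3 for t in t3s})
    # candidate window starts: midpoints between consecutive layers, as
    # fractions over 2*d_t3
    cand = [Fraction(layers[i] + layers[i + 1], 2 * d_t3) for i in range(len(layers) - 1)]
    cand.append(Fraction(layers[-1] + layers[0] + d_t3, 2 * d_t3))
    expected = atoms_per_cell(n, m) * cells

    def assemble(t0: Fraction) -> nx.Graph:
        lo_num, q = t0.numerator, t0.denominator
        chosen = [st for st in sites
                  if lo_num * d_t3 <= site_t3[st] * q < (lo_num + cells * q) * d_t3]
        assert len(chosen) == expected, (
            f"window holds {len(chosen)} atoms, expected {expected} for ({n},{m})x{cells}")
        chosen.sort(key=lambda st: (site_t3[st], c3_of(*st), st[2]))
        index = {st: i for i, st in enumerate(chosen)}
        g = nx.Graph()
        g.add_nodes_from((i, {"element": "C"}) for i in range(len(chosen)))
        for (u, v, s), i in index.items():
            if s == 0:  # A-site neighbours: B(u,v), B(u-1,v), B(u,v-1)
                for nb in ((u, v, 1), (u - 1, v, 1), (u, v - 1, 1)):
                    j = index.get(canonical(*nb))
                    if j is not None:
                        g.add_edge(i, j)
        return g

    best_g, best_score = None, (-1, Fraction(0))
    for t0 in cand:
        g = assemble(t0)
        degs = [d for _, d in g.degree()]
        n_ok = sum(d >= 2 for d in degs)
        if n_ok == len(degs):
            best_g = g
            break
        if (n_ok, -t0) > best_score:
            best_score, best_g = (n_ok, -t0), g
    g = best_g
    # prune dangling atoms left by cuts through chiral bond spirals
    while True:
        dangling = [i for i in g.nodes if g.degree(i) <= 1]
        if not dangling:
            break
        g.remove_nodes_from(dangling)
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    for i in g.nodes:  # rim CH carbons carry one implicit hydrogen
        g.nodes[i]["hydrogens"] = max(0, 3 - g.degree(i))

    mg = MolecularGraph(
        g,
        meta={
            "n": n,
            "m": m,
            "n_cells": cells,
            "category": spec.category,
            "functionalization": spec.functionalization,
            "n_cooh": spec.n_cooh,
        },
    )
    if spec.functionalization == "carboxyl":
        _attach_carboxyls(mg, spec.n_cooh)
    return mg


def _carboxyl_sites(g: nx.Graph, count: int) -> list[int]:
    """Deterministic rim-carbon selection: the max-distance rim pair first
    (ties broken by lowest atom ids), then farthest-point greedy."""
    rim = sorted(i for i in g.nodes if g.degree(i) == 2 and g.nodes[i]["element"] == "C")
    if count > len(rim):
        raise CapacityError(f"{count} carboxyl groups requested but only {len(rim)} rim carbons")
    if count == 0:
        return []
    dist = {i: nx.single_source_shortest_path_length(g, i) for i in rim}
    if count == 1:
        return [rim[0]]
    best = max(
        ((i, j) for i in rim for j in rim if i < j),
        key=lambda p: (dist[p[0]][p[1]], -p[0], -p[1]),
    )
    chosen = list(best)
    while len(chosen) < count:
        nxt = max(
            (i for i in rim if i not in chosen),
            key=lambda i: (min(dist[i][c] for c in chosen), -i),
        )
        chosen.append(nxt)
    return chosen


def _attach_carboxyls(mg: MolecularGraph, n_cooh: int) -> None:
    g = mg.graph
    sites = _carboxyl_sites(g, n_cooh)
    nxt = max(g.nodes) + 1
    for site in sites:
        c, o1, o2 = nxt, nxt + 1, nxt + 2
        nxt += 3
        g.add_node(c, element="C", hydrogens=0)
        g.add_node(o1, element="O", hydrogens=0)  # carbonyl O
        g.add_node(o2, element="O", hydrogens=1)  # hydroxyl O
        g.add_edge(site, c)
        g.add_edge(c, o1)
        g.add_edge(c, o2)
        g.nodes[site]["hydrogens"] = 0


_TABLE_RESOURCE = {"pristine": "table1_pristine.csv", "carboxyl": "table3_cooh.csv"}


def load_table(which: Functionalization):
    """The packaged observed/predicted/split table for one tube family,
    as a list of row dicts in printed order."""
    name = _TABLE_RESOURCE[which]
    text = resources.files("mitotox.data").joinpath(name).read_text()
    return list(csv.DictReader(text.splitlines()))


def enumerate_table_set(
    which: Functionalization, n_cells: int = 3, n_cooh: int = DEFAULT_N_COOH
) -> list[NanotubeSpec]:
    """The 45 (n, m) topologies of the study set, in printed order."""
    specs = []
    for row in load_table(which):
        n, m = int(row["n"]), int(row["m"])
        if which == "carboxyl":
            specs.append(NanotubeSpec(n, m, n_cells, "carboxyl", n_cooh))
        else:
            specs.append(NanotubeSpec(n, m, n_cells))
    return specs
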