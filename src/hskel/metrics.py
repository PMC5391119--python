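"""Size and complexity measures of a conversion, and graph serialization.

The input size of a system is ``zeta = n * m * <Z>`` where ``<Z> = n +
<sigma>`` is the mean number of active hyperplanes over the vertices; the
output graph is measured by its vertex count ``|V|`` and connectivity
``kappa = <X> / |V|`` with ``<X> = 2|E| / |V|`` the mean degree.  The
combined product ``kappa * zeta`` separates systems whose cost lies in
resolving degeneracy from those dominated by the traversal itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any

import networkx as nx

from .hrep import HRepresentation, HRepError
from .traversal import SkeletonGraph

__all__ = ["ConversionReport", "compute_metrics", "write_graph", "to_networkx"]

DIAMETER_CAP = 4000


def _fmt(x: Fraction) -> str:
    return str(x.numerator) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"


def _coords(key) -> str:
    return ",".join(_fmt(x) for x in key)


@dataclass
class ConversionReport:
    """All metrics of one finished conversion; a pure function of (G, H)."""

    n: int
    m: int
    n_vertices: int
    n_edges: int
    degree_histogram: dict[int, int]
    mean_degree: float          # <X> = 2|E| / |V|
    kappa: float                # <X> / |V|
    mean_active: float          # <Z> = n + <sigma>
    mean_sigma: float
    zeta: float                 # n * m * <Z>
    kappa_zeta: float
    edge_fraction: float        # |E| / |E(K_|V|)|
    diameter: int | None
    counters: dict[str, int] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    test_used: str = "algebraic"
    partial: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        d["degree_histogram"] = {str(k): v for k, v in sorted(self.degree_histogram.items())}
        return d


def to_networkx(G: SkeletonGraph) -> nx.Graph:
    """Deterministic networkx view of a skeleton graph (vertices sorted)."""
    g = nx.Graph()
    for key in sorted(G.vertices):
        v = G.vertices[key]
        g.add_node(key, sigma=v.sigma)
    for a, b in sorted(G.edges):
        g.add_edge(a, b)
    return g


def compute_metrics(G: SkeletonGraph, H: HRepresentation, *,
                    diameter_cap: int = DIAMETER_CAP) -> ConversionReport:
    """Populate a :class:`ConversionReport` for a completed conversion."""
    nv = len(G.vertices)
    ne = len(G.edges)
    degs = G.degrees()
    hist: dict[int, int] = {}
    for d in degs.values():
        hist[d] = hist.get(d, 0) + 1
    mean_deg = 2 * ne / nv if nv else 0.0
    kappa = mean_deg / nv if nv else 0.0
    mean_sigma = (sum(v.sigma for v in G.vertices.values()) / nv) if nv else 0.0
    mean_active = H.n + mean_sigma
    zeta = H.n * H.m * mean_active
    diameter = None
    if 1 < nv <= diameter_cap:
        g = to_networkx(G)
        if nx.is_connected(g):
            diameter = nx.diameter(g)
    complete_edges = nv * (nv - 1) / 2
    return ConversionReport(
        n=H.n, m=H.m, n_vertices=nv, n_edges=ne,
        degree_histogram=hist, mean_degree=mean_deg, kappa=kappa,
        mean_active=mean_active, mean_sigma=mean_sigma,
        zeta=zeta, kappa_zeta=kappa * zeta,
        edge_fraction=ne / complete_edges if complete_edges else 0.0,
        diameter=diameter,
        counters={
            "colaminarity_tests": G.counters.tests,
            "record_hits": G.counters.record_hits,
            "rejections": G.counters.rejections,
            "duplicates_merged": G.counters.duplicates_merged,
            "peak_intermediate_rays": G.counters.peak_rays,
        },
        timings=dict(G.timings),
        test_used=G.test_used,
        partial=G.partial,
    )


def write_graph(G: SkeletonGraph, fmt: str, path) -> None:
    """Serialize a skeleton graph deterministically.

    Vertices are sorted by their exact coordinates and numbered ``0..|V|-1``;
    coordinates are written as exact rational strings.  Formats: ``edgelist``
    (with a vertex table in comments), ``dot``, ``graphml`` and ``json``
    (full vertex records with active sets and degeneracies).
    """
    keys = sorted(G.vertices)
    idx = {k: i for i, k in enumerate(keys)}
    edges = sorted((idx[a], idx[b]) if idx[a] < idx[b] else (idx[b], idx[a])
                   for a, b in G.edges)
    if fmt == "edgelist":
        with open(path, "w", encoding="utf-8") as fh:
            for k in keys:
                fh.write(f"# v{idx[k]} {_coords(k)}\n")
            for a, b in edges:
                fh.write(f"{a} {b}\n")
    elif fmt == "dot":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("graph skeleton {\n")
            for k in keys:
                v = G.vertices[k]
                fh.write(f'  v{idx[k]} [coords="{_coords(k)}" sigma={v.sigma}];\n')
            for a, b in edges:
                fh.write(f"  v{a} -- v{b};\n")
            fh.write("}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for k in keys:
            g.add_node(idx[k], coords=_coords(k), sigma=G.vertices[k].sigma)
        for a, b in edges:
            g.add_edge(a, b)
        nx.write_graphml(g, path)
    elif fmt == "json":
        payload = {
            "vertices": [
                {
                    "id": idx[k],
                    "coords": [_fmt(x) for x in k],
                    "active": list(G.vertices[k].active),
                    "sigma": G.vertices[k].sigma,
                }
                for k in keys
            ],
            "edges": [list(e) for e in edges],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise HRepError(f"unknown graph format {fmt!r}")
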