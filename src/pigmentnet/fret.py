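"""Forster excitation-energy-transfer rates and networks.

For a donor/acceptor chlorophyll pair the transfer rate is

    k = C * kappa^2 / (n^4 * R^6)

with C the spectral-overlap factor (32.26 for Chl a -> Chl a transfer),
n the medium refractive index (1.55 for the protein matrix), R the
Mg-Mg distance expressed in nanometres, and kappa^2 the mutual dipole
orientation factor

    kappa^2 = [u_D . u_A - 3 (u_D . r) (u_A . r)]^2,

where u_D, u_A are unit Qy transition-dipole vectors (taken along the
NB -> ND nitrogen axis of the chlorin macrocycle) and r is the unit
donor-to-acceptor Mg-Mg vector.  With these units the rate comes out in
ps^-1 and the pairwise lifetime is tau = 1/k in ps, which puts
neighbouring-chlorophyll transfer (R ~ 1-2.3 nm) in the ~0.1-40 ps
range that the display (<40 ps) and fast-pathway (<20 ps) filters
address.  kappa^2 is invariant under flipping either dipole, so the
NB -> ND sign convention is immaterial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import GeometryThresholds, MembraneFrame  # noqa: F401
from .records import ComplexModel, PigmentRecord, Ring

__all__ = [
    "FretParameters",
    "PathwayThresholds",
    "FretEdge",
    "transition_dipole",
    "kappa_squared",
    "fret_rate",
    "build_network",
    "lifetime_filtered",
    "outer_to_inner_table",
    "export_graph",
    "import_graph",
]

ANGSTROM_PER_NM = 10.0


@dataclass(frozen=True)
class FretParameters:
    """Constants of the Forster rate expression.

    ``C`` is the Chl a -> Chl a spectral-overlap factor and ``n`` the
    refractive index; with R in nm the rate is in ps^-1 (the R unit is
    part of the parameter object so the convention is explicit).
    """

    C: float = 32.26
    n: float = 1.55
    r_unit: str = "nm"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")
        if self.r_unit not in ("nm", "angstrom"):
            raise ValueError("r_unit must be 'nm' or 'angstrom'")

    def r_from_angstrom(self, r_angstrom: float) -> float:
        if self.r_unit == "nm":
            return r_angstrom / ANGSTROM_PER_NM
        return r_angstrom


@dataclass(frozen=True)
class PathwayThresholds:
    """Lifetime filters (ps) for network views."""

    display_lifetime_max: float = 40.0
    fast_lifetime_max: float = 20.0

    def __post_init__(self) -> None:
        if not (0 < self.fast_lifetime_max <= self.display_lifetime_max):
            raise ValueError("require 0 < fast <= display lifetime")


@dataclass(frozen=True)
class FretEdge:
    donor: tuple
    acceptor: tuple
    R: float          # Mg-Mg distance, Angstrom
    kappa_sq: float
    rate: float       # ps^-1
    lifetime: float   # ps; inf when kappa_sq = 0


def transition_dipole(pigment: PigmentRecord) -> np.ndarray:
    """Unit Qy dipole vector along the NB -> ND axis."""
    if pigment.nb is None or pigment.nd is None:
        raise ValueError(f"pigment {pigment.pigment_id} has no NB/ND axis")
    d = pigment.nd - pigment.nb
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise ValueError(
            f"pigment {pigment.pigment_id}: NB and ND coincide; "
            "dipole direction undefined"
        )
    return d / norm


def kappa_squared(u_d: np.ndarray, u_a: np.ndarray, r_vec: np.ndarray) -> float:
    """Orientation factor for unit dipoles and a donor->acceptor vector.

    Result is in [0, 4]: 4 for collinear head-to-tail dipoles, 0 for
    mutually orthogonal geometry, 1 for parallel dipoles perpendicular
    to the separation vector.
    """
    r_norm = np.linalg.norm(r_vec)
    if r_norm < 1e-12:
        raise ValueError("zero-length donor-acceptor vector")
    r_hat = np.asarray(r_vec, dtype=float) / r_norm
    k = np.dot(u_d, u_a) - 3.0 * np.dot(u_d, r_hat) * np.dot(u_a, r_hat)
    return float(k * k)


def fret_rate(
    donor: PigmentRecord,
    acceptor: PigmentRecord,
    params: FretParameters = FretParameters(),
) -> FretEdge:
    """Pairwise Forster rate/lifetime for two chlorophylls."""
    r_vec = acceptor.mg - donor.mg
    r_angstrom = float(np.linalg.norm(r_vec))
    if r_angstrom < 1e-9:
        raise ValueError(
            f"coincident Mg atoms for {donor.pigment_id} and "
            f"{acceptor.pigment_id}"
        )
    k2 = kappa_squared(transition_dipole(donor), transition_dipole(acceptor),
                       r_vec)
    r = params.r_from_angstrom(r_angstrom)
    rate = params.C * k2 / (params.n ** 4 * r ** 6)
    lifetime = 1.0 / rate if rate > 0 else math.inf
    return FretEdge(donor=donor.pigment_id, acceptor=acceptor.pigment_id,
                    R=r_angstrom, kappa_sq=k2, rate=rate, lifetime=lifetime)


def _edge_category(a: PigmentRecord, b: PigmentRecord) -> str:
    sa, sb = a.subunit, b.subunit
    if sa is sb:
        return "intra_subunit"
    if sa.is_antenna and sb.is_antenna:
        if {sa.ring, sb.ring} == {Ring.INNER, Ring.OUTER}:
            return "inner_outer"
        if sa.ring is sb.ring and sa.ring is not Ring.NONE:
            return "intra_ring"
        return "antenna_antenna"
    if (sa.is_antenna and sb.is_core) or (sb.is_antenna and sa.is_core):
        return "antenna_core"
    if sa.is_core and sb.is_core:
        return "core_core"
    return "other"


def build_network(
    model: ComplexModel,
    params: FretParameters = FretParameters(),
    geometry_thresholds: GeometryThresholds = GeometryThresholds(),
    all_pairs: bool = False,
) -> nx.Graph:
    """Build the pairwise energy-transfer graph over chlorophylls.

    Nodes are chlorophylls (id ``chain/resnum``) annotated with subunit,
    role, ring and position; edges carry R (Angstrom), kappa^2, rate
    (ps^-1) and lifetime (ps).  The single-C rate expression is symmetric
    in donor/acceptor, so edges are stored once, undirected.  By default
    only pairs within the geometric pair cutoff get edges; ``all_pairs``
    computes the full dense set for diagnostics.
    """
    chls = model.chlorophylls()
    g = nx.Graph(name=model.name, C=params.C, n=params.n,
                 pair_cutoff=geometry_thresholds.pair_cutoff)
    for p in chls:
        g.add_node(p.key, chain_id=p.chain_id,
                   residue_number=p.residue_number,
                   role=p.subunit.role, ring=p.subunit.ring.value,
                   subunit_label=p.subunit.label,
                   x=float(p.mg[0]), y=float(p.mg[1]), z=float(p.mg[2]))
    if len(chls) < 2:
        return g
    if all_pairs:
        idx_pairs = ((i, j) for i in range(len(chls))
                     for j in range(i + 1, len(chls)))
    else:
        from scipy.spatial import cKDTree
        mg = np.array([p.mg for p in chls])
        idx_pairs = sorted(cKDTree(mg).query_pairs(
            r=geometry_thresholds.pair_cutoff))
    for i, j in idx_pairs:
        a, b = chls[i], chls[j]
        e = fret_rate(a, b, params)
        g.add_edge(a.key, b.key, R=e.R, kappa_sq=e.kappa_sq, rate=e.rate,
                   lifetime=e.lifetime, category=_edge_category(a, b),
                   weight=e.rate)
    return g


def lifetime_filtered(graph: nx.Graph, lifetime_max: float) -> nx.Graph:
    """Subgraph view (copy) keeping edges with lifetime < lifetime_max."""
    keep = [(u, v) for u, v, d in graph.edges(data=True)
            if d["lifetime"] < lifetime_max]
    out = nx.Graph(**graph.graph)
    out.add_nodes_from(graph.nodes(data=True))
    for u, v in keep:
        out.add_edge(u, v, **graph.edges[u, v])
    return out


def outer_to_inner_table(
    graph: nx.Graph,
    thresholds: PathwayThresholds = PathwayThresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank outer-ring -> inner-ring transfer edges by rate.

    Returns ``(edges, summary)``: ``edges`` has one row per inner/outer
    edge (donor = outer-ring chlorophyll), sorted by rate descending;
    ``summary`` aggregates per subunit pair (fastest edge and the number
    of edges under the fast-pathway lifetime cutoff).
    """
    rows = []
    for u, v, d in graph.edges(data=True):
        if d.get("category") != "inner_outer":
            continue
        nu, nv = graph.nodes[u], graph.nodes[v]
        if nu["ring"] == Ring.OUTER.value:
            outer_n, inner_n = (u, nu), (v, nv)
        else:
            outer_n, inner_n = (v, nv), (u, nu)
        rows.append({
            "donor_chl": outer_n[1]["residue_number"],
            "acceptor_chl": inner_n[1]["residue_number"],
            "donor_subunit": outer_n[1]["subunit_label"],
            "acceptor_subunit": inner_n[1]["subunit_label"],
            "donor_node": outer_n[0],
            "acceptor_node": inner_n[0],
            "R": d["R"],
            "kappa_sq": d["kappa_sq"],
            "rate": d["rate"],
            "lifetime": d["lifetime"],
        })
    cols = ["donor_chl", "acceptor_chl", "donor_subunit", "acceptor_subunit",
            "donor_node", "acceptor_node", "R", "kappa_sq", "rate", "lifetime"]
    if not rows:
        empty = pd.DataFrame(columns=cols)
        return empty, pd.DataFrame(
            columns=["donor_subunit", "acceptor_subunit", "fastest_rate",
                     "fastest_lifetime", "n_edges", "n_fast"])
    edges = (pd.DataFrame(rows, columns=cols)
             .sort_values("rate", ascending=False, kind="stable")
             .reset_index(drop=True))
    grp = edges.groupby(["donor_subunit", "acceptor_subunit"], sort=True)
    summary = grp.agg(
        fastest_rate=("rate", "max"),
        fastest_lifetime=("lifetime", "min"),
        n_edges=("rate", "size"),
        n_fast=("lifetime",
                lambda s: int((s < thresholds.fast_lifetime_max).sum())),
    ).reset_index()
    return edges, summary


def _finite_copy(graph: nx.Graph) -> nx.Graph:
    """Copy with non-finite edge attributes dropped (GEXF/GraphML-safe)."""
    g = nx.Graph(**{k: v for k, v in graph.graph.items()
                    if not isinstance(v, float) or math.isfinite(v)})
    g.add_nodes_from(graph.nodes(data=True))
    for u, v, d in graph.edges(data=True):
        g.add_edge(u, v, **{k: val for k, val in d.items()
                            if not isinstance(val, float) or math.isfinite(val)})
    return g


def export_graph(graph: nx.Graph, path, fmt: str = "gexf") -> None:
    """Write the network as GEXF (Gephi), GraphML or a TSV edge list."""
    path = str(path)
    if fmt == "gexf":
        nx.write_gexf(_finite_copy(graph), path)
    elif fmt == "graphml":
        nx.write_graphml(_finite_copy(graph), path)
    elif fmt == "tsv":
        rows = [{"source": u, "target": v, **d}
                for u, v, d in graph.edges(data=True)]
        cols = ["source", "target", "R", "kappa_sq", "rate", "lifetime",
                "category", "weight"]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown graph format {fmt!r}; "
                         "use 'gexf', 'graphml' or 'tsv'")


def import_graph(path, fmt: str = "gexf") -> nx.Graph:
    """Read back a graph written by :func:`export_graph`."""
    path = str(path)
    if fmt == "gexf":
        return nx.Graph(nx.read_gexf(path))
    if fmt == "graphml":
        return nx.Graph(nx.read_graphml(path))
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, r in df.iterrows():
            g.add_edge(str(r["source"]), str(r["target"]),
                       **{k: r[k] for k in df.columns
                          if k not in ("source", "target")})
        return g
    raise ValueError(f"unknown graph format {fmt!r}")
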