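"""Labelled vascular networks: arteries wired through named junction nodes.

An artery is a whole vessel between two network nodes (branching or
boundary), carried as a chain of monotonic-taper segments.  Wiring is by
*named* nodes rather than indices: each artery has a designated
proximal -> distal orientation and positive flow runs proximal to distal.
Boundary nodes (degree 1) are classified as inlets (by artery label;
default internal carotids and basilar) or outlets.

The interchange mesh format is tabular: one row per reconstructed segment
(artery, proximal/distal node, arc positions, end radii, optional wall and
reference-pressure columns) plus a node table with the junction incidence
signs.  CSV is the required dialect; XLSX (same two tables as sheets) is
also supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .reduction import Artery, ReconstructedSegment

__all__ = ["Junction", "VascularNetwork", "assemble_network", "write_mesh", "read_mesh"]

DEFAULT_INLET_LABELS = ("R ICA G1", "L ICA G1", "BA")


@dataclass(frozen=True)
class Junction:
    """A branching node: incident (artery label, end, sign) triples.

    ``end`` is ``"distal"`` or ``"proximal"``; the sign is +1 where the
    artery's distal end meets the node (positive flow enters the node) and
    -1 where its proximal end does (positive flow leaves the node).
    """

    node: str
    members: tuple[tuple[str, str, int], ...]

    @property
    def degree(self) -> int:
        return len(self.members)


@dataclass
class VascularNetwork:
    """Arteries plus their junction wiring and boundary classification."""

    arteries: dict[str, Artery]
    topology: dict[str, tuple[str, str]]  # label -> (proximal node, distal node)
    junctions: list[Junction] = field(default_factory=list)
    inlets: list[tuple[str, str]] = field(default_factory=list)   # (node, artery label)
    outlets: list[tuple[str, str]] = field(default_factory=list)  # (node, artery label)

    @property
    def labels(self) -> list[str]:
        return list(self.arteries)

    @property
    def inlet_labels(self) -> list[str]:
        return [lbl for _, lbl in self.inlets]

    @property
    def outlet_labels(self) -> list[str]:
        return [lbl for _, lbl in self.outlets]

    def total_length(self) -> float:
        return float(sum(a.length for a in self.arteries.values()))

    def mean_reference_area(self, label: str) -> float:
        """Spatially averaged reference cross-sectional area of one artery (cm^2).

        The average runs over the segment-wise linear radius profile; for a
        linear radius the exact segment mean of pi*r^2 is
        pi*(r0^2 + r0*r1 + r1^2)/3, combined length-weighted.
        """
        a = self.arteries[label]
        acc = 0.0
        for seg in a.segments:
            acc += seg.length * np.pi * (seg.r0**2 + seg.r0 * seg.r1 + seg.r1**2) / 3.0
        return float(acc / a.length)

    def with_arteries(self, new_arteries: Mapping[str, Artery]) -> "VascularNetwork":
        """Copy of the network with some arteries replaced (same wiring)."""
        arts = dict(self.arteries)
        for lbl, art in new_arteries.items():
            if lbl not in arts:
                raise ValidationError(f"unknown artery label {lbl!r}")
            arts[lbl] = art
        return VascularNetwork(arts, dict(self.topology), list(self.junctions),
                               list(self.inlets), list(self.outlets))


def assemble_network(
    arteries: Sequence[Artery],
    connectivity: Mapping[str, tuple[str, str]],
    inlet_labels: Iterable[str] = DEFAULT_INLET_LABELS,
) -> VascularNetwork:
    """Wire labelled arteries into a validated network.

    Parameters
    ----------
    arteries
        The reduced arteries; labels must be unique.
    connectivity
        ``label -> (proximal node, distal node)`` with named nodes.
    inlet_labels
        Artery labels whose free (proximal) end is an inflow boundary.
        Labels absent from the network are ignored, so the default works
        for sub-networks too.

    Raises
    ------
    ValidationError
        Listing duplicate labels, dangling ends, or disconnected parts.
    """
    problems: list[str] = []
    seen: set[str] = set()
    art_map: dict[str, Artery] = {}
    for art in arteries:
        if art.label in seen:
            problems.append(f"duplicate artery label {art.label!r}")
        seen.add(art.label)
        art_map[art.label] = art

    for lbl in art_map:
        if lbl not in connectivity:
            problems.append(f"artery {lbl!r} missing from connectivity")
    for lbl in connectivity:
        if lbl not in art_map:
            problems.append(f"connectivity references unknown artery {lbl!r}")
    if problems:
        raise ValidationError("; ".join(problems))

    g = nx.MultiGraph()
    for lbl, (n0, n1) in connectivity.items():
        if n0 == n1:
            problems.append(f"artery {lbl!r} connects node {n0!r} to itself")
        g.add_edge(n0, n1, label=lbl)
    if problems:
        raise ValidationError("; ".join(problems))
    if g.number_of_nodes() and not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValidationError(f"network is disconnected: components {comps}")

    incidence: dict[str, list[tuple[str, str, int]]] = {}
    for lbl, (n0, n1) in connectivity.items():
        incidence.setdefault(n0, []).append((lbl, "proximal", -1))
        incidence.setdefault(n1, []).append((lbl, "distal", +1))

    inlet_set = {l for l in inlet_labels if l in art_map}
    junctions, inlets, outlets = [], [], []
    for node, members in sorted(incidence.items()):
        if len(members) == 1:
            lbl, end, _ = members[0]
            if lbl in inlet_set and end == "proximal":
                inlets.append((node, lbl))
            else:
                outlets.append((node, lbl))
        else:
            junctions.append(Junction(node, tuple(sorted(members))))

    missing_inlets = [l for l in inlet_set
                      if l not in {lbl for _, lbl in inlets}]
    if missing_inlets:
        raise ValidationError(
            f"inlet arteries {missing_inlets} do not terminate at a free proximal node"
        )

    topo = {lbl: tuple(connectivity[lbl]) for lbl in art_map}
    return VascularNetwork(art_map, topo, junctions, inlets, outlets)


# ---------------------------------------------------------------------------
# Mesh interchange format
# ---------------------------------------------------------------------------

def _segment_table(net: VascularNetwork, params=None) -> pd.DataFrame:
    rows = []
    for lbl, art in net.arteries.items():
        n0, n1 = net.topology[lbl]
        beta = p0 = None
        if params is not None:
            row = params.lookup(lbl)
            beta, p0 = row.beta_pa_cm, row.p0_mmhg
        for k, seg in enumerate(art.segments):
            rows.append(
                dict(artery=lbl, segment=k, proximal_node=n0, distal_node=n1,
                     s0_cm=seg.s0, s1_cm=seg.s1, length_cm=seg.length,
                     r_prox_cm=seg.r0, r_dist_cm=seg.r1, gamma=seg.gamma,
                     beta_pa_cm=beta, p0_mmhg=p0)
            )
    return pd.DataFrame(rows)


def _node_table(net: VascularNetwork) -> pd.DataFrame:
    rows = []
    for j in net.junctions:
        for lbl, end, sign in j.members:
            rows.append(dict(node=j.node, kind="junction", artery=lbl, end=end, sign=sign))
    for node, lbl in net.inlets:
        rows.append(dict(node=node, kind="inlet", artery=lbl, end="proximal", sign=-1))
    for node, lbl in net.outlets:
        end = "distal" if net.topology[lbl][1] == node else "proximal"
        rows.append(dict(node=node, kind="outlet", artery=lbl, end=end,
                         sign=+1 if end == "distal" else -1))
    return pd.DataFrame(rows)


def write_mesh(net: VascularNetwork, path: str | Path, params=None) -> None:
    """Write the 1-D mesh. ``.csv`` writes ``<stem>.csv`` + ``<stem>_nodes.csv``;
    ``.xlsx`` writes both tables as sheets of one workbook."""
    path = Path(path)
    seg = _segment_table(net, params)
    nodes = _node_table(net)
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path) as xl:
            seg.to_excel(xl, sheet_name="segments", index=False)
            nodes.to_excel(xl, sheet_name="nodes", index=False)
    else:
        seg.to_csv(path, index=False, float_format="%.17g")
        nodes.to_csv(path.with_name(path.stem + "_nodes.csv"), index=False)


def read_mesh(path: str | Path) -> VascularNetwork:
    """Read a mesh written by :func:`write_mesh` back into a network."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        seg = pd.read_excel(path, sheet_name="segments")
        nodes = pd.read_excel(path, sheet_name="nodes")
    else:
        seg = pd.read_csv(path, float_precision="round_trip")
        nodes = pd.read_csv(path.with_name(path.stem + "_nodes.csv"))

    arteries, connectivity = [], {}
    for lbl, grp in seg.groupby("artery", sort=False):
        grp = grp.sort_values("segment")
        segs = [
            ReconstructedSegment(r.s0_cm, r.s1_cm, r.r_prox_cm, r.r_dist_cm,
                                 0.0 if pd.isna(r.gamma) else float(r.gamma))
            for r in grp.itertuples()
        ]
        arteries.append(Artery(str(lbl), segs))
        first = grp.iloc[0]
        connectivity[str(lbl)] = (str(first.proximal_node), str(first.distal_node))
    inlet_labels = [str(r.artery) for r in nodes.itertuples() if r.kind == "inlet"]
    return assemble_network(arteries, connectivity, inlet_labels)
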