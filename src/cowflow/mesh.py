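"""Finite-volume discretization of a vascular network.

Every reconstructed segment is cut into the fewest elements of size at
most ``max_elem`` (default 1 mm).  Pressure lives on nodes (element
endpoints), flow on elements — the classic staggered arrangement that
suppresses odd-even decoupling on collocated grids.  Nodes named in the
network topology are shared between arteries; a junction node carries a
single pressure unknown, which enforces static-pressure continuity, and a
zero-storage mass balance (sum of signed element flows = 0), which
enforces junction mass conservation to linear-solver precision.

Internally everything is CGS: cm, g, s, dyn/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constitutive import VesselParameterTable
from .errors import ConfigurationError
from .network import VascularNetwork
from .units import MMHG_TO_DYN_CM2, PA_CM_TO_CGS

__all__ = ["DiscreteMesh", "discretize"]


@dataclass
class DiscreteMesh:
    """Arrays describing the discrete staggered mesh (all CGS units)."""

    net: VascularNetwork
    n_nodes: int
    # per element
    node_l: np.ndarray
    node_r: np.ndarray
    h: np.ndarray            # element length (cm)
    beta: np.ndarray         # dyn/cm
    pref: np.ndarray         # P0 + Pext (dyn/cm^2)
    a0_l: np.ndarray         # reference area at left end (cm^2)
    a0_r: np.ndarray
    artery_of_element: np.ndarray     # index into vessel_labels
    vessel_labels: list[str]
    # node bookkeeping
    is_junction: np.ndarray           # bool per node
    node_names: dict[str, int]        # named (shared) nodes only
    # boundaries: (node id, element id, side 0=left/1=right, artery label)
    inlet_nodes: list[tuple[int, int, int, str]] = field(default_factory=list)
    outlet_nodes: list[tuple[int, int, int, str]] = field(default_factory=list)

    @property
    def n_elements(self) -> int:
        return self.h.size

    def elements_of(self, label: str) -> np.ndarray:
        idx = self.vessel_labels.index(label)
        return np.flatnonzero(self.artery_of_element == idx)

    def element_at(self, label: str, fraction: float) -> int:
        """Element index at a fractional arc position along an artery."""
        els = self.elements_of(label)
        return int(els[min(int(fraction * els.size), els.size - 1)])


def discretize(
    net: VascularNetwork,
    params: VesselParameterTable | None = None,
    max_elem: float = 0.1,
    pext_mmhg: float = 15.0,
) -> DiscreteMesh:
    """Build the discrete mesh with elements no longer than ``max_elem`` cm.

    Per segment the element count is ``ceil(length / max_elem)`` (fewest
    elements obeying the size cap); nodal reference areas are interpolated
    from the monotonic linear radius profile.
    """
    if params is None:
        params = VesselParameterTable.from_csv()
    if max_elem <= 0:
        raise ConfigurationError("max_elem must be > 0")

    node_names: dict[str, int] = {}
    incidence: dict[str, int] = {}
    for lbl, (n0, n1) in net.topology.items():
        for nm in (n0, n1):
            incidence[nm] = incidence.get(nm, 0) + 1
            if nm not in node_names:
                node_names[nm] = len(node_names)
    next_node = len(node_names)

    node_l, node_r, h, beta, pref, a0_l, a0_r, art_idx = ([] for _ in range(8))
    labels = list(net.arteries)

    for li, lbl in enumerate(labels):
        art = net.arteries[lbl]
        row = params.lookup(lbl)
        beta_cgs = row.beta_pa_cm * PA_CM_TO_CGS
        pref_cgs = (row.p0_mmhg + pext_mmhg) * MMHG_TO_DYN_CM2
        n0, n1 = net.topology[lbl]

        # arc positions of element boundaries along the whole artery
        s_bounds = [art.segments[0].s0]
        for seg in art.segments:
            n_el = max(1, math.ceil(seg.length / max_elem - 1e-12))
            s_bounds.extend(np.linspace(seg.s0, seg.s1, n_el + 1)[1:])
        s_bounds = np.asarray(s_bounds)
        r_nodes = art.radius_at(s_bounds)
        a_nodes = np.pi * r_nodes**2

        ids = np.empty(s_bounds.size, dtype=int)
        ids[0] = node_names[n0]
        ids[-1] = node_names[n1]
        n_interior = s_bounds.size - 2
        ids[1:-1] = np.arange(next_node, next_node + n_interior)
        next_node += n_interior

        for k in range(s_bounds.size - 1):
            node_l.append(ids[k])
            node_r.append(ids[k + 1])
            h.append(s_bounds[k + 1] - s_bounds[k])
            beta.append(beta_cgs)
            pref.append(pref_cgs)
            a0_l.append(a_nodes[k])
            a0_r.append(a_nodes[k + 1])
            art_idx.append(li)

    node_l = np.asarray(node_l)
    node_r = np.asarray(node_r)
    is_junction = np.zeros(next_node, dtype=bool)
    for nm, deg in incidence.items():
        if deg >= 2:
            is_junction[node_names[nm]] = True

    mesh = DiscreteMesh(
        net=net, n_nodes=next_node,
        node_l=node_l, node_r=node_r,
        h=np.asarray(h), beta=np.asarray(beta), pref=np.asarray(pref),
        a0_l=np.asarray(a0_l), a0_r=np.asarray(a0_r),
        artery_of_element=np.asarray(art_idx),
        vessel_labels=labels, is_junction=is_junction, node_names=node_names,
    )

    def _boundary_entry(node_name: str, lbl: str):
        nid = node_names[node_name]
        els = mesh.elements_of(lbl)
        first, last = int(els[0]), int(els[-1])
        if node_l[first] == nid:
            return (nid, first, 0, lbl)
        if node_r[last] == nid:
            return (nid, last, 1, lbl)
        raise ConfigurationError(f"boundary node {node_name!r} not an end of artery {lbl!r}")

    for node, lbl in net.inlets:
        mesh.inlet_nodes.append(_boundary_entry(node, lbl))
    for node, lbl in net.outlets:
        mesh.outlet_nodes.append(_boundary_entry(node, lbl))
    return mesh
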