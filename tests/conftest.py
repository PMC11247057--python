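"""Shared fixtures: small analytic networks and one full synthetic CoW run."""

import numpy as np
import pytest

from cowflow.boundary import InflowWaveform, WindkesselOutlet
from cowflow.centerline import Centerline
from cowflow.constitutive import ParamRow, VesselParameterTable
from cowflow.network import assemble_network
from cowflow.pipeline import RunConfig
from cowflow.reduction import reduce_centerline
from cowflow.solver import BoundaryConditions
from cowflow.synthetic import MorphometryTable, SyntheticPatientSpec, default_patient, generate_network


def straight_centerline(label: str, length: float, radius, n: int | None = None) -> Centerline:
    """Straight-line centerline; ``radius`` may be a scalar or per-point array."""
    n = n or max(2, int(length * 10) + 1)
    s = np.linspace(0.0, length, n)
    xyz = np.column_stack([s, np.zeros(n), np.zeros(n)])
    r = np.broadcast_to(np.asarray(radius, dtype=float), (n,)).copy()
    return Centerline.from_arrays(label, xyz, r)


def straight_vessel(label: str, length: float, radius: float, gamma: float = 0.01):
    return reduce_centerline(straight_centerline(label, length, radius), gamma)


def constant_wave(q: float, period: float = 0.5) -> InflowWaveform:
    return InflowWaveform(period=period, mean=q, peak=q,
                          signal=lambda t: np.full_like(np.asarray(t, float), q))


def single_vessel_setup(length=1.0, area=0.1, beta_pa_cm=1361224.0, q=1.0,
                        rt=5000.0, ct=1e-7, p0=90.0):
    """(network, params, bcs) for a single inlet->outlet vessel."""
    r = float(np.sqrt(area / np.pi))
    net = assemble_network([straight_vessel("V", length, r)], {"V": ("n0", "n1")},
                           inlet_labels=["V"])
    params = VesselParameterTable([ParamRow("V", 0.01, 1e6, beta_pa_cm, p0, rt, ct)])
    bcs = BoundaryConditions({"V": constant_wave(q)},
                             {"V": WindkesselOutlet.from_terminal(rt, ct)})
    return net, params, bcs


def y_network_setup(r_parent=0.2, r_d1=0.15, r_d2=0.15, rt1=8000.0, rt2=8000.0, q=2.0):
    """(network, params, bcs) for a Y-bifurcation with two Windkessel outlets."""
    arts = [straight_vessel("P", 1.0, r_parent),
            straight_vessel("D1", 1.2, r_d1),
            straight_vessel("D2", 1.2, r_d2)]
    conn = {"P": ("in", "j"), "D1": ("j", "o1"), "D2": ("j", "o2")}
    net = assemble_network(arts, conn, inlet_labels=["P"])
    params = VesselParameterTable([
        ParamRow("P", 0.03, 1.6e6, 113435.4, 90.0),
        ParamRow("D1", 0.03, 1.6e6, 113435.4, 90.0, rt1, 1e-7),
        ParamRow("D2", 0.03, 1.6e6, 113435.4, 90.0, rt2, 1e-7),
    ])
    bcs = BoundaryConditions({"P": constant_wave(q)},
                             {"D1": WindkesselOutlet.from_terminal(rt1, 1e-7),
                              "D2": WindkesselOutlet.from_terminal(rt2, 1e-7)})
    return net, params, bcs


@pytest.fixture(scope="session")
def cohort():
    return MorphometryTable.cohort()


@pytest.fixture(scope="session")
def params_table():
    return VesselParameterTable.from_csv()


@pytest.fixture(scope="session")
def mean_cow(cohort):
    """Deterministic cohort-mean anatomy (all SDs zero, no aneurysm)."""
    return generate_network(SyntheticPatientSpec(seed=0), cohort.zeroed_sd())


@pytest.fixture(scope="session")
def cow_run():
    """Full pulsatile protocol run (10 cycles, dt 2e-4 s, <=1 mm elements)
    on a cohort-sampled synthetic patient; shared across the suite."""
    from cowflow.pipeline import simulate

    net = generate_network(default_patient(seed=3))
    cfg = RunConfig()  # protocol defaults
    return simulate(net, cfg)
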