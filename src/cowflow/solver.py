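"""Implicit 1-D pulse-wave solver over the discrete vascular mesh.

Mass and momentum conservation with the algebraic tube law are advanced
with a second-order backward difference in time (backward Euler start-up)
and a staggered finite-volume scheme in space: nodal pressures, element
flows.  Each step solves the monolithic nonlinear system — all nodal
pressures, element flows, outlet flows and Windkessel capacitor pressures
— by Newton iteration with an analytically assembled sparse Jacobian and a
direct factorization.  The factorization is reused across iterations and
steps (chord iterations) and rebuilt only when convergence degrades, which
keeps the per-step cost at a couple of triangular solves.

The mass balance is written in conserved-volume form
``(d/dt) integral A dz + dQ = 0`` with ``A = A(P)`` from the tube law, so
wall storage is tracked exactly.  Junction nodes carry no storage: their
mass rows read ``sum of signed element flows = 0`` and are linear, hence
satisfied to linear-solver precision at every accepted step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .boundary import InflowWaveform, WindkesselOutlet, synthesize_inflow
from .constitutive import BloodProperties, VesselParameterTable
from .errors import ConfigurationError, ConvergenceError, UnphysicalStateError, ValidationError
from .mesh import DiscreteMesh, discretize
from .network import VascularNetwork
from .units import MMHG_TO_DYN_CM2, dyn_to_mmhg

__all__ = [
    "SolverSettings",
    "BoundaryConditions",
    "build_boundary_conditions",
    "TransientSolver",
    "SimulationResult",
    "run_simulation",
    "periodicity_metric",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings (defaults follow the study protocol)."""

    dt: float = 2e-4                 # s
    n_cycles: int = 10               # cardiac cycles simulated
    analysis_cycles: int = 2         # trailing cycles retained for analysis
    newton_tol: float = 1e-9         # scaled residual tolerance
    newton_max_iter: int = 20
    max_elem_cm: float = 0.1         # 1 mm element-size cap
    decimation: int = 5              # stride for stored nodal snapshots

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if not self.n_cycles >= self.analysis_cycles >= 1:
            raise ConfigurationError("need n_cycles >= analysis_cycles >= 1")


@dataclass
class BoundaryConditions:
    """Inflow waveform per inlet artery, Windkessel per outlet artery."""

    inflows: dict[str, InflowWaveform]
    outlets: dict[str, WindkesselOutlet]


def build_boundary_conditions(
    net: VascularNetwork,
    params: VesselParameterTable | None = None,
    period: float = 1.0,
    template: str = "pulse",
    split: float = 0.2,
    pv_mmhg: float = 10.0,
) -> BoundaryConditions:
    """Area-calibrated inflows and table-driven Windkessels for a network."""
    if params is None:
        params = VesselParameterTable.from_csv()
    inflows = {
        lbl: synthesize_inflow(net.mean_reference_area(lbl), period, template)
        for lbl in net.inlet_labels
    }
    outlets = {}
    for lbl in net.outlet_labels:
        row = params.lookup(lbl)
        if not row.is_terminal:
            raise ConfigurationError(
                f"outlet artery {lbl!r} has no terminal (R_t, C_t) parameters"
            )
        outlets[lbl] = WindkesselOutlet.from_terminal(row.rt_pa_s_cm3, row.ct_cm3_pa,
                                                      split=split, Pv=pv_mmhg)
    return BoundaryConditions(inflows, outlets)


class _Collapse(Exception):
    pass


@dataclass
class SolverState:
    """Current solution: nodal P, element Q, outlet states (CGS units)."""

    u: np.ndarray
    n_nodes: int
    n_elements: int
    n_outlets: int
    t: float = 0.0

    @property
    def P(self) -> np.ndarray:
        return self.u[: self.n_nodes]

    @property
    def Q(self) -> np.ndarray:
        return self.u[self.n_nodes : self.n_nodes + self.n_elements]

    @property
    def Q_out(self) -> np.ndarray:
        o = self.n_nodes + self.n_elements
        return self.u[o : o + self.n_outlets]

    @property
    def Pc(self) -> np.ndarray:
        o = self.n_nodes + self.n_elements + self.n_outlets
        return self.u[o : o + self.n_outlets]

    def pressure_mmhg(self) -> np.ndarray:
        return self.P / MMHG_TO_DYN_CM2


class TransientSolver:
    """Monolithic implicit integrator over one :class:`DiscreteMesh`."""

    def __init__(
        self,
        mesh: DiscreteMesh,
        bcs: BoundaryConditions,
        settings: SolverSettings | None = None,
        blood: BloodProperties | None = None,
        initial_pressure_mmhg: float | None = None,
    ):
        self.mesh = mesh
        self.bcs = bcs
        self.settings = settings or SolverSettings()
        self.blood = blood or BloodProperties()

        m = mesh
        nN, nE = m.n_nodes, m.n_elements
        self.nN, self.nE = nN, nE

        inlet_lbls = [lbl for _, _, _, lbl in m.inlet_nodes]
        missing = [l for l in inlet_lbls if l not in bcs.inflows]
        if missing:
            raise ValidationError(f"no inflow waveform for inlets {missing}")
        missing = [lbl for _, _, _, lbl in m.outlet_nodes if lbl not in bcs.outlets]
        if missing:
            raise ValidationError(f"no Windkessel for outlets {missing}")

        self.inflows = [bcs.inflows[lbl] for _, _, _, lbl in m.inlet_nodes]
        periods = {w.period for w in self.inflows}
        if len(periods) > 1:
            raise ConfigurationError(f"inflow waveforms disagree on period: {periods}")
        self.period = periods.pop() if periods else 1.0
        self.wk = [bcs.outlets[lbl] for _, _, _, lbl in m.outlet_nodes]
        self.nOut = len(self.wk)
        self.nU = nN + nE + 2 * self.nOut

        # --- element-end bookkeeping -------------------------------------
        deg = np.bincount(np.concatenate([m.node_l, m.node_r]), minlength=nN)
        interior = (deg == 2) & ~m.is_junction

        # storage weights (junction nodes carry none)
        self.w_l = np.where(m.is_junction[m.node_l], 0.0, 0.5 * m.h)
        self.w_r = np.where(m.is_junction[m.node_r], 0.0, 0.5 * m.h)

        # advective nodal flow: weights of own / neighbouring element flow
        self.wl_self = np.ones(nE)
        self.wl_oth = np.zeros(nE)
        self.oidx_l = np.arange(nE)
        self.wr_self = np.ones(nE)
        self.wr_oth = np.zeros(nE)
        self.oidx_r = np.arange(nE)
        prev_by_node = {int(m.node_r[j]): j for j in range(nE)}
        next_by_node = {int(m.node_l[j]): j for j in range(nE)}
        for j in range(nE):
            nl, nr = int(m.node_l[j]), int(m.node_r[j])
            if interior[nl]:
                self.wl_self[j] = 0.5
                self.wl_oth[j] = 0.5
                self.oidx_l[j] = prev_by_node[nl]
            if interior[nr]:
                self.wr_self[j] = 0.5
                self.wr_oth[j] = 0.5
                self.oidx_r[j] = next_by_node[nr]
        # prescribed inflow replaces the nodal flow at inlet ends
        self.inlet_side = []  # (element, side, inlet index)
        for k, (nid, el, side, _) in enumerate(m.inlet_nodes):
            self.inlet_side.append((el, side, k))
            if side == 0:
                self.wl_self[el] = 0.0
            else:
                self.wr_self[el] = 0.0

        self.out_nid = np.array([nid for nid, _, _, _ in m.outlet_nodes], dtype=int)
        self.in_nid = np.array([nid for nid, _, _, _ in m.inlet_nodes], dtype=int)
        self.R1c = np.array([w.R1 * 10.0 for w in self.wk])
        self.R2c = np.array([w.R2 * 10.0 for w in self.wk])
        self.Cc = np.array([w.C / 10.0 for w in self.wk])
        self.Pvc = np.array([w.Pv * MMHG_TO_DYN_CM2 for w in self.wk])

        # residual scaling
        peak = sum(w.peak for w in self.inflows) or 1.0
        self.qscale = max(peak, 1e-6)
        self.pscale = 100.0 * MMHG_TO_DYN_CM2

        # --- initial state ------------------------------------------------
        u0 = np.zeros(self.nU)
        if initial_pressure_mmhg is None:
            p_node = np.zeros(nN)
            cnt = np.zeros(nN)
            np.add.at(p_node, m.node_l, m.pref)
            np.add.at(cnt, m.node_l, 1.0)
            np.add.at(p_node, m.node_r, m.pref)
            np.add.at(cnt, m.node_r, 1.0)
            u0[:nN] = p_node / np.maximum(cnt, 1.0)
        else:
            u0[:nN] = initial_pressure_mmhg * MMHG_TO_DYN_CM2
        u0[nN + nE + self.nOut :] = np.array([w.pc for w in self.wk]) * MMHG_TO_DYN_CM2
        self.state = SolverState(u0, nN, nE, self.nOut)

        vol0 = self._volume(u0[:nN])
        self.hist = {
            "vol": [vol0.copy(), vol0.copy()],
            "q": [u0[nN : nN + nE].copy(), u0[nN : nN + nE].copy()],
            "pc": [self.state.Pc.copy(), self.state.Pc.copy()],
        }
        self.step_count = 0
        self._lu = None
        self._build_pattern()

    # --- tube-law helpers (CGS) ------------------------------------------
    def _areas(self, P):
        m = self.mesh
        sl = np.sqrt(m.a0_l) + (P[m.node_l] - m.pref) * m.a0_l / m.beta
        sr = np.sqrt(m.a0_r) + (P[m.node_r] - m.pref) * m.a0_r / m.beta
        if np.any(sl <= 1e-8) or np.any(sr <= 1e-8):
            raise _Collapse
        return sl * sl, sr * sr, 2.0 * sl * m.a0_l / m.beta, 2.0 * sr * m.a0_r / m.beta

    def _volume(self, P):
        al, ar, _, _ = self._areas(P)
        return (np.bincount(self.mesh.node_l, self.w_l * al, self.nN)
                + np.bincount(self.mesh.node_r, self.w_r * ar, self.nN))

    def _qin(self, t):
        cached = getattr(self, "_qin_cache", None)
        if cached is not None and cached[0] == t:
            return cached[1]
        q = np.array([float(w(t)) for w in self.inflows], dtype=float)
        self._qin_cache = (t, q)
        return q

    # --- residual ---------------------------------------------------------
    def _residual(self, u, t, a0, vol_hist, q_hist, pc_hist, want_parts=False):
        m, nN, nE = self.mesh, self.nN, self.nE
        dt = self.settings.dt
        rho, mu = self.blood.rho, self.blood.mu
        P = u[:nN]
        Q = u[nN : nN + nE]
        Qout = u[nN + nE : nN + nE + self.nOut]
        Pc = u[nN + nE + self.nOut :]

        al, ar, dal, dar = self._areas(P)
        aj = 0.5 * (al + ar)

        qnl = self.wl_self * Q + self.wl_oth * Q[self.oidx_l]
        qnr = self.wr_self * Q + self.wr_oth * Q[self.oidx_r]
        qin = self._qin(t)
        for el, side, k in self.inlet_side:
            if side == 0:
                qnl[el] += qin[k]
            else:
                qnr[el] += qin[k]

        fl = qnl * qnl / al
        fr = qnr * qnr / ar

        t1 = np.zeros(nE) if a0 == 0.0 else rho * m.h * (a0 * Q - q_hist) / (dt * aj)
        t2 = (rho / aj) * (fr - fl)
        t4 = 8.0 * np.pi * mu * m.h * Q / (aj * aj)
        r_mom = t1 + t2 + (P[m.node_r] - P[m.node_l]) + t4

        r_mass = np.bincount(m.node_l, Q, nN) - np.bincount(m.node_r, Q, nN)
        if a0 != 0.0:
            vol = (np.bincount(m.node_l, self.w_l * al, nN)
                   + np.bincount(m.node_r, self.w_r * ar, nN))
            r_mass += (a0 * vol - vol_hist) / dt
        np.subtract.at(r_mass, self.in_nid, qin)
        np.add.at(r_mass, self.out_nid, Qout)

        r_w1 = P[self.out_nid] - self.R1c * Qout - Pc
        r_w2 = -Qout + (Pc - self.Pvc) / self.R2c
        if a0 != 0.0:
            r_w2 = r_w2 + self.Cc * (a0 * Pc - pc_hist) / dt

        res = np.concatenate([
            r_mass / self.qscale,
            r_mom / self.pscale,
            r_w1 / self.pscale,
            r_w2 / self.qscale,
        ])
        if want_parts:
            parts = dict(al=al, ar=ar, dal=dal, dar=dar, aj=aj,
                         qnl=qnl, qnr=qnr, fl=fl, fr=fr, t1=t1, t2=t2, t4=t4)
            return res, parts
        return res

    # --- Jacobian ----------------------------------------------------------
    def _build_pattern(self):
        m, nN, nE, nOut = self.mesh, self.nN, self.nE, self.nOut
        qoff, ooff, poff = nN, nN + nE, nN + nE + nOut
        rows, cols = [], []

        def add(r, c):
            rows.append(np.asarray(r, dtype=int))
            cols.append(np.asarray(c, dtype=int))

        nodes = np.arange(nN)
        mom = nN + np.arange(nE)
        add(nodes, nodes)                         # G1 mass storage diag
        add(m.node_l, qoff + np.arange(nE))       # G2a
        add(m.node_r, qoff + np.arange(nE))       # G2b
        add(self.out_nid, ooff + np.arange(nOut))  # G3
        add(mom, m.node_l)                        # G4a
        add(mom, m.node_r)                        # G4b
        add(mom, qoff + np.arange(nE))            # G5
        add(mom, qoff + self.oidx_l)              # G6
        add(mom, qoff + self.oidx_r)              # G7
        w1 = nN + nE + np.arange(nOut)
        add(w1, self.out_nid)                     # G8a
        add(w1, ooff + np.arange(nOut))           # G8b
        add(w1, poff + np.arange(nOut))           # G8c
        w2 = nN + nE + nOut + np.arange(nOut)
        add(w2, poff + np.arange(nOut))           # G9a
        add(w2, ooff + np.arange(nOut))           # G9b
        self._jrows = np.concatenate(rows)
        self._jcols = np.concatenate(cols)

    def _jacobian(self, u, t, a0, parts):
        m, nN, nE, nOut = self.mesh, self.nN, self.nE, self.nOut
        dt = self.settings.dt
        rho, mu = self.blood.rho, self.blood.mu
        p = parts
        al, ar, dal, dar, aj = p["al"], p["ar"], p["dal"], p["dar"], p["aj"]

        sm = 1.0 / self.qscale  # mass & W2 row scale
        sp_ = 1.0 / self.pscale  # momentum & W1 row scale

        g1 = np.zeros(nN)
        if a0 != 0.0:
            g1 = (np.bincount(m.node_l, self.w_l * dal, nN)
                  + np.bincount(m.node_r, self.w_r * dar, nN)) * (a0 / dt)
        g1 = g1 * sm
        g2a = np.full(nE, 1.0) * sm
        g2b = np.full(nE, -1.0) * sm
        g3 = np.full(nOut, 1.0) * sm

        t12 = p["t1"] + p["t2"]
        g4a = (-1.0 + dal * (-0.5 * t12 / aj + rho * p["fl"] / (aj * al) - p["t4"] / aj)) * sp_
        g4b = (1.0 + dar * (-0.5 * t12 / aj - rho * p["fr"] / (aj * ar) - p["t4"] / aj)) * sp_
        g5 = (
            (0.0 if a0 == 0.0 else rho * m.h * a0 / (dt * aj))
            + (rho / aj) * (2.0 * p["qnr"] * self.wr_self / ar - 2.0 * p["qnl"] * self.wl_self / al)
            + 8.0 * np.pi * mu * m.h / (aj * aj)
        ) * sp_
        g6 = (-(rho / aj) * 2.0 * p["qnl"] * self.wl_oth / al) * sp_
        g7 = ((rho / aj) * 2.0 * p["qnr"] * self.wr_oth / ar) * sp_
        g8a = np.full(nOut, 1.0) * sp_
        g8b = -self.R1c * sp_
        g8c = np.full(nOut, -1.0) * sp_
        g9a = ((0.0 if a0 == 0.0 else self.Cc * a0 / dt) + 1.0 / self.R2c) * sm
        g9b = np.full(nOut, -1.0) * sm

        data = np.concatenate([g1, g2a, g2b, g3, g4a, g4b, g5, g6, g7, g8a, g8b, g8c, g9a, g9b])
        return sp.coo_matrix((data, (self._jrows, self._jcols)),
                             shape=(self.nU, self.nU)).tocsc()

    # --- stepping -----------------------------------------------------------
    def _coeffs(self):
        if self.step_count == 0:
            a0 = 1.0
            vol_hist = self.hist["vol"][0]
            q_hist = self.hist["q"][0]
            pc_hist = self.hist["pc"][0]
        else:
            a0 = 1.5
            vol_hist = 2.0 * self.hist["vol"][0] - 0.5 * self.hist["vol"][1]
            q_hist = 2.0 * self.hist["q"][0] - 0.5 * self.hist["q"][1]
            pc_hist = 2.0 * self.hist["pc"][0] - 0.5 * self.hist["pc"][1]
        return a0, vol_hist, q_hist, pc_hist

    def advance(self) -> SolverState:
        """Advance one time step; returns the updated state.

        Raises :class:`ConvergenceError` with the residual history if the
        Newton loop stalls, and :class:`UnphysicalStateError` on lumen
        collapse."""
        s = self.settings
        t_new = self.state.t + s.dt
        a0, vol_hist, q_hist, pc_hist = self._coeffs()
        if self.step_count == 1:
            self._lu = None  # scheme switches BE -> BDF2

        u = self.state.u.copy()
        history = []
        refreshed = False
        for it in range(s.newton_max_iter):
            try:
                res, parts = self._residual(u, t_new, a0, vol_hist, q_hist, pc_hist,
                                            want_parts=True)
            except _Collapse:
                raise UnphysicalStateError(
                    f"cross-sectional area collapsed at t={t_new:.6f}s"
                ) from None
            rnorm = float(np.max(np.abs(res)))
            history.append(rnorm)
            if rnorm < s.newton_tol:
                break
            # a factorization is reused across chord iterations and across
            # steps; rebuild only when convergence stalls on a stale one
            if self._lu is None or (it >= 2 and not refreshed):
                self._lu = spla.splu(self._jacobian(u, t_new, a0, parts))
                refreshed = True
            du = self._lu.solve(res)
            # backtrack on lumen collapse only; chord iterations need slack
            step = 1.0
            for _ in range(12):
                trial = u - step * du
                try:
                    self._areas(trial[: self.nN])
                except _Collapse:
                    step *= 0.5
                    continue
                break
            else:
                raise UnphysicalStateError(f"cannot avoid collapse at t={t_new:.6f}s")
            u = trial
        else:
            raise ConvergenceError(
                f"Newton failed at t={t_new:.6f}s after {s.newton_max_iter} iterations "
                f"(residual {history[-1]:.3e})",
                residual_history=history,
            )

        self.state.u = u
        self.state.t = t_new
        self.step_count += 1
        vol = self._volume(u[: self.nN])
        self.hist["vol"] = [vol, self.hist["vol"][0]]
        self.hist["q"] = [u[self.nN : self.nN + self.nE].copy(), self.hist["q"][0]]
        self.hist["pc"] = [self.state.Pc.copy(), self.hist["pc"][0]]
        return self.state

    def steady_residual(self, u: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Residual of the steady (time-derivative-free) system at state ``u``.

        Exposed so an independent root finder can be pointed at the same
        algebraic system the time integrator converges to."""
        try:
            return self._residual(u, t, 0.0, None, None, None)
        except _Collapse:
            raise UnphysicalStateError("area collapse in steady residual") from None


# ---------------------------------------------------------------------------
# Whole-run driver and results container
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Time series (analysis window) and per-vessel aggregates.

    Flows in cm^3/s, pressures in mmHg, areas in cm^2.  ``vessel_*`` arrays
    are (n_times, n_vessels) space-averaged signals; snapshots are decimated
    element-flow fields used for the periodicity metric and junction audits.
    """

    time: np.ndarray
    vessel_labels: list[str]
    vessel_Q: np.ndarray
    vessel_P: np.ndarray
    vessel_A: np.ndarray
    inlet_labels: list[str]
    inlet_Q: np.ndarray
    outlet_labels: list[str]
    outlet_Q: np.ndarray
    steps_per_cycle: int
    analysis_cycles: int
    decimation: int
    snapshots_Q: np.ndarray            # (n_snap, n_elements)
    max_junction_mass_residual: float
    probes: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def _last_cycle(self) -> slice:
        return slice(len(self.time) - self.steps_per_cycle, len(self.time))

    def aggregates(self) -> pd.DataFrame:
        """Per-vessel mean/peak flow, pressure and mean area over the last cycle."""
        sl = self._last_cycle()
        return pd.DataFrame(
            {
                "vessel": self.vessel_labels,
                "Q_mean": self.vessel_Q[sl].mean(axis=0),
                "P_mean": self.vessel_P[sl].mean(axis=0),
                "A_mean": self.vessel_A[sl].mean(axis=0),
                "Q_peak": self.vessel_Q[sl].max(axis=0),
                "P_peak": self.vessel_P[sl].max(axis=0),
            }
        ).set_index("vessel")

    def mean_flow(self, label: str) -> float:
        return float(self.vessel_Q[self._last_cycle(), self.vessel_labels.index(label)].mean())

    def mean_pressure(self, label: str) -> float:
        return float(self.vessel_P[self._last_cycle(), self.vessel_labels.index(label)].mean())

    def mean_area(self, label: str) -> float:
        return float(self.vessel_A[self._last_cycle(), self.vessel_labels.index(label)].mean())

    def inlet_mean_flows(self) -> dict[str, float]:
        sl = self._last_cycle()
        return {l: float(self.inlet_Q[sl, k].mean()) for k, l in enumerate(self.inlet_labels)}

    def outlet_mean_flows(self) -> dict[str, float]:
        sl = self._last_cycle()
        return {l: float(self.outlet_Q[sl, k].mean()) for k, l in enumerate(self.outlet_labels)}


def periodicity_metric(result: SimulationResult) -> float:
    """Relative L2 cycle-to-cycle difference of the nodal flow field.

    Uses the stored decimated element-flow snapshots of the last two
    analysis cycles; 0 means perfectly periodic."""
    snaps = result.snapshots_Q
    per_cycle = result.steps_per_cycle // result.decimation
    if snaps.shape[0] < 2 * per_cycle:
        raise ValidationError("need at least two stored cycles for the periodicity metric")
    c2 = snaps[-per_cycle:]
    c1 = snaps[-2 * per_cycle : -per_cycle]
    denom = float(np.linalg.norm(c1))
    return float(np.linalg.norm(c2 - c1) / denom) if denom > 0 else 0.0


def run_simulation(
    net: VascularNetwork,
    params: VesselParameterTable | None = None,
    settings: SolverSettings | None = None,
    bcs: BoundaryConditions | None = None,
    blood: BloodProperties | None = None,
    pext_mmhg: float = 15.0,
    probes: Mapping[str, tuple[str, float]] | None = None,
    initial_pressure_mmhg: float | None = None,
    periodicity_warn: float = 1e-3,
) -> SimulationResult:
    """Run ``n_cycles`` cardiac cycles and gather the analysis window.

    ``probes`` maps a name to ``(artery label, fraction)``; each probe's
    element flow and downstream nodal pressure are recorded at full rate
    over the whole run (useful for wave-timing studies).
    """
    settings = settings or SolverSettings()
    params = params or VesselParameterTable.from_csv()
    mesh = discretize(net, params, max_elem=settings.max_elem_cm, pext_mmhg=pext_mmhg)
    if bcs is None:
        bcs = build_boundary_conditions(net, params)
    solver = TransientSolver(mesh, bcs, settings, blood,
                             initial_pressure_mmhg=initial_pressure_mmhg)

    spc = int(round(solver.period / settings.dt))
    if abs(spc * settings.dt - solver.period) > 1e-9 * solver.period:
        log.warning("period %.6g not an integer multiple of dt %.3g", solver.period, settings.dt)
    n_steps = spc * settings.n_cycles
    n_keep = spc * settings.analysis_cycles
    start = n_steps - n_keep

    nV = len(mesh.vessel_labels)
    lv = np.bincount(mesh.artery_of_element, weights=mesh.h, minlength=nV)
    vQ = np.empty((n_keep, nV))
    vP = np.empty((n_keep, nV))
    vA = np.empty((n_keep, nV))
    times = np.empty(n_keep)
    in_q = np.empty((n_keep, len(mesh.inlet_nodes)))
    out_q = np.empty((n_keep, len(mesh.outlet_nodes)))
    n_snap = n_keep // settings.decimation
    snaps = np.empty((n_snap, mesh.n_elements))

    probe_defs = {}
    probe_out: dict[str, dict[str, np.ndarray]] = {}
    for name, (lbl, frac) in (probes or {}).items():
        el = mesh.element_at(lbl, frac)
        probe_defs[name] = el
        probe_out[name] = {
            "t": np.empty(n_steps), "Q": np.empty(n_steps), "P": np.empty(n_steps)
        }

    junc = np.flatnonzero(mesh.is_junction)
    max_junc_res = 0.0

    for step in range(n_steps):
        state = solver.advance()
        P, Q = state.P, state.Q
        for name, el in probe_defs.items():
            rec = probe_out[name]
            rec["t"][step] = state.t
            rec["Q"][step] = Q[el]
            rec["P"][step] = dyn_to_mmhg(P[mesh.node_r[el]])
        if step < start:
            continue
        i = step - start
        times[i] = state.t
        al, ar, _, _ = solver._areas(P)
        aj = 0.5 * (al + ar)
        pj = 0.5 * (P[mesh.node_l] + P[mesh.node_r])
        vQ[i] = np.bincount(mesh.artery_of_element, weights=mesh.h * Q, minlength=nV) / lv
        vP[i] = np.bincount(mesh.artery_of_element, weights=mesh.h * pj, minlength=nV) / lv / MMHG_TO_DYN_CM2
        vA[i] = np.bincount(mesh.artery_of_element, weights=mesh.h * aj, minlength=nV) / lv
        in_q[i] = solver._qin(state.t)
        out_q[i] = state.Q_out
        if i % settings.decimation == 0 and i // settings.decimation < n_snap:
            snaps[i // settings.decimation] = Q
            if junc.size:
                net_q = np.zeros(mesh.n_nodes)
                np.add.at(net_q, mesh.node_l, Q)
                np.add.at(net_q, mesh.node_r, -Q)
                tot_q = np.zeros(mesh.n_nodes)
                np.add.at(tot_q, mesh.node_l, np.abs(Q))
                np.add.at(tot_q, mesh.node_r, np.abs(Q))
                # net flow at a junction is (outgoing - incoming); sign flips
                # relative to the mass-row convention don't matter in modulus
                rel = np.abs(net_q[junc]) / np.maximum(tot_q[junc], 1e-300)
                max_junc_res = max(max_junc_res, float(rel.max()))

    result = SimulationResult(
        time=times,
        vessel_labels=mesh.vessel_labels,
        vessel_Q=vQ, vessel_P=vP, vessel_A=vA,
        inlet_labels=[lbl for _, _, _, lbl in mesh.inlet_nodes], inlet_Q=in_q,
        outlet_labels=[lbl for _, _, _, lbl in mesh.outlet_nodes], outlet_Q=out_q,
        steps_per_cycle=spc, analysis_cycles=settings.analysis_cycles,
        decimation=settings.decimation, snapshots_Q=snaps,
        max_junction_mass_residual=max_junc_res,
        probes=probe_out,
    )
    if settings.analysis_cycles >= 2:
        metric = periodicity_metric(result)
        if metric > periodicity_warn:
            log.warning("solution not periodic: cycle-to-cycle metric %.3e", metric)
    return result
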