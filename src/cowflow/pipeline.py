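"""Run configuration and pipeline orchestration.

`RunConfig` collects every tunable of the pipeline with defaults matching
the study protocol: time step 2e-4 s, 10 cardiac cycles with the last two
analysed, elements of at most 1 mm, blood density 1.04 g/cm^3 and
viscosity 0.04 poise, venous pressure 10 mmHg, external pressure 15 mmHg,
smoothness coefficient 0.01.  Configurations round-trip through YAML, and
every written bundle embeds the package version plus the full config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .centerline import Centerline, read_centerlines_csv, read_centerlines_json
from .constitutive import BloodProperties, VesselParameterTable
from .errors import ConfigurationError
from .longitudinal import ComparisonReport, network_smoothness_error
from .network import VascularNetwork, assemble_network
from .reduction import reduce_centerline
from .solver import (SimulationResult, SolverSettings, build_boundary_conditions,
                     periodicity_metric, run_simulation)
from .synthetic import CANONICAL_CONNECTIVITY

__all__ = ["RunConfig", "load_centerlines", "reduce_and_assemble", "simulate",
           "gamma_sweep", "write_simulation_bundle", "write_comparison_bundle"]

log = logging.getLogger(__name__)

GAMMA_SWEEP_LEVELS = (0.005, 0.01, 0.02, 0.03, 0.04, 0.05)


@dataclass(frozen=True)
class RunConfig:
    """All pipeline settings; defaults reproduce the study protocol."""

    gamma: float = 0.01
    dt: float = 2e-4
    n_cycles: int = 10
    analysis_cycles: int = 2
    max_elem_cm: float = 0.1
    period_s: float = 1.0
    waveform_template: str = "pulse"
    windkessel_split: float = 0.2
    venous_pressure_mmHg: float = 10.0
    external_pressure_mmHg: float = 15.0
    rho_g_cm3: float = 1.04
    mu_poise: float = 0.04
    use_table_beta: bool = False
    alpha_mode: str = "calibrate"   # "calibrate" | "fixed"
    alpha_fixed: float = 1.0
    newton_tol: float = 1e-9
    newton_max_iter: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.alpha_mode not in ("calibrate", "fixed"):
            raise ConfigurationError(f"alpha_mode must be calibrate|fixed, got {self.alpha_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # derived objects -------------------------------------------------------
    def solver_settings(self) -> SolverSettings:
        return SolverSettings(dt=self.dt, n_cycles=self.n_cycles,
                              analysis_cycles=self.analysis_cycles,
                              newton_tol=self.newton_tol,
                              newton_max_iter=self.newton_max_iter,
                              max_elem_cm=self.max_elem_cm)

    def blood(self) -> BloodProperties:
        return BloodProperties(rho=self.rho_g_cm3, mu=self.mu_poise)

    def params(self, path: str | Path | None = None) -> VesselParameterTable:
        return VesselParameterTable.from_csv(path, use_table_beta=self.use_table_beta)


def load_centerlines(path: str | Path) -> list[Centerline]:
    """Dispatch on extension: .json (package or Slicer dialect) or .csv."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_centerlines_csv(path)
    if path.name.lower().endswith(".mrk.json"):
        from .centerline import read_centerlines_mrk
        return read_centerlines_mrk(path)
    return read_centerlines_json(path)


def _load_connectivity(path: str | Path | None) -> dict[str, tuple[str, str]]:
    if path is None:
        return dict(CANONICAL_CONNECTIVITY)
    with open(path) as fh:
        raw = json.load(fh)
    return {lbl: (str(a), str(b)) for lbl, (a, b) in raw.items()}


def reduce_and_assemble(
    centerlines: list[Centerline], config: RunConfig,
    connectivity: dict[str, tuple[str, str]] | None = None,
    gamma: float | None = None,
) -> VascularNetwork:
    """Mesh-reduce each centerline and wire the network."""
    gamma = config.gamma if gamma is None else gamma
    arteries = [reduce_centerline(cl, gamma) for cl in centerlines]
    conn = connectivity or {
        cl.label: CANONICAL_CONNECTIVITY[cl.label] for cl in centerlines
    }
    conn = {lbl: conn[lbl] for lbl in (cl.label for cl in centerlines)}
    return assemble_network(arteries, conn)


def simulate(net: VascularNetwork, config: RunConfig,
             params: VesselParameterTable | None = None, **kwargs) -> SimulationResult:
    """Run the pulsatile simulation with config-derived boundary conditions."""
    params = params or config.params()
    bcs = build_boundary_conditions(net, params, period=config.period_s,
                                    template=config.waveform_template,
                                    split=config.windkessel_split,
                                    pv_mmhg=config.venous_pressure_mmHg)
    t0 = time.perf_counter()
    result = run_simulation(net, params=params, settings=config.solver_settings(),
                            bcs=bcs, blood=config.blood(),
                            pext_mmhg=config.external_pressure_mmHg, **kwargs)
    metric = periodicity_metric(result) if config.analysis_cycles >= 2 else float("nan")
    log.info("simulation: %d vessels, %d cycles, %.1f s wall, periodicity %.2e",
             len(net.arteries), config.n_cycles, time.perf_counter() - t0, metric)
    return result


def gamma_sweep(
    centerlines: list[Centerline], config: RunConfig,
    gammas=GAMMA_SWEEP_LEVELS,
    connectivity: dict[str, tuple[str, str]] | None = None,
    params: VesselParameterTable | None = None,
) -> pd.DataFrame:
    """Simulate at several smoothness levels; network mean-area differences.

    Returns a frame with one row per gamma: the number of segments in the
    mesh and eps_net, the length-weighted mean absolute relative difference
    of per-vessel mean areas against the smallest gamma."""
    params = params or config.params()
    areas_by_gamma: dict[float, dict[str, float]] = {}
    seg_counts: dict[float, int] = {}
    lengths: dict[str, float] = {}
    for g in sorted(gammas):
        net = reduce_and_assemble(centerlines, config, connectivity, gamma=g)
        seg_counts[g] = sum(len(a.segments) for a in net.arteries.values())
        res = simulate(net, config, params)
        areas_by_gamma[g] = {v: res.mean_area(v) for v in res.vessel_labels}
        if not lengths:
            lengths = {lbl: a.length for lbl, a in net.arteries.items()}
    eps = network_smoothness_error(areas_by_gamma, lengths)
    return pd.DataFrame(
        {"gamma": sorted(gammas),
         "n_segments": [seg_counts[g] for g in sorted(gammas)],
         "eps_net": [eps[g] for g in sorted(gammas)]}
    )


# ---------------------------------------------------------------------------
# Output bundles
# ---------------------------------------------------------------------------

def _write_manifest(out_dir: Path, config: RunConfig, extra: dict | None = None) -> None:
    manifest = {"cowflow_version": __version__, "config": config.to_dict()}
    manifest.update(extra or {})
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def write_simulation_bundle(result: SimulationResult, config: RunConfig,
                            out_dir: str | Path, stride: int = 10) -> None:
    """Aggregates, decimated tidy series, and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.aggregates().to_csv(out / "vessel_aggregates.csv")
    rows = []
    for i in range(0, len(result.time), stride):
        for v, lbl in enumerate(result.vessel_labels):
            rows.append((result.time[i], lbl, result.vessel_Q[i, v],
                         result.vessel_P[i, v], result.vessel_A[i, v]))
    pd.DataFrame(rows, columns=["t_s", "vessel", "Q_cm3_s", "P_mmHg", "A_cm2"]).to_csv(
        out / "vessel_series.csv", index=False)
    pd.DataFrame(result.outlet_Q[::stride], columns=result.outlet_labels).assign(
        t_s=result.time[::stride]).to_csv(out / "outlet_series.csv", index=False)
    _write_manifest(out, config, {"periodicity_metric": periodicity_metric(result),
                                  "max_junction_mass_residual": result.max_junction_mass_residual})


def write_comparison_bundle(report: ComparisonReport, config: RunConfig,
                            out_dir: str | Path) -> None:
    """Relative-variation tables plus scalar metrics as CSV + JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.variations.to_csv(out / "relative_variations.csv")
    report.absolute_flagged.to_csv(out / "absolute_change_flags.csv")
    scalars = {
        "alpha": report.alpha,
        "theta": report.theta,
        "outflow_fractions": report.outflow_fractions,
        "normalized_pressures": report.normalized_pressures,
    }
    with open(out / "comparison.json", "w") as fh:
        json.dump(scalars, fh, indent=1)
    _write_manifest(out, config)
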