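"""Longitudinal comparison of two scans of one patient.

Imaging resolution may drift between an initial scan and a follow-up, so
reference lumen areas are not directly comparable.  Assuming the brain's
metabolic demand — hence total mean inflow — is unchanged, a single
resolution scaling factor ``alpha`` is identified from the three inlet
arteries (right/left internal carotid, basilar) through the mean-inflow
power law ``Q_bar ~ A0bar^1.84``:

    alpha = ( sum_sc1 A0bar^1.84 / sum_sc2 A0bar^1.84 )^(1/1.84)

All follow-up reference areas are then multiplied by ``alpha`` (radii by
sqrt(alpha)) before simulation.  Comparison metrics: signed relative
variation eps_sc = (x_sc2 - x_sc1)/x_sc1 of per-vessel mean/peak flow and
pressure, the carotid inflow ratio theta, the outflow distribution among
outlets, min-max normalized mean pressures, and a sensitivity battery
(alpha=1, halved/doubled terminal resistance, halved/doubled Young's
modulus) summarized by eta, the relative error of eps_sc against the
calibrated reference case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constitutive import VesselParameterTable
from .errors import ConfigurationError, InvalidInputError, ValidationError
from .network import VascularNetwork
from .solver import SimulationResult, SolverSettings, run_simulation

__all__ = [
    "ScanPair",
    "resolution_alpha",
    "alpha_from_networks",
    "apply_alpha",
    "carotid_inflow_ratio",
    "relative_variation",
    "network_smoothness_error",
    "outflow_distribution",
    "normalized_pressure",
    "ComparisonReport",
    "compare_scans",
    "SensitivityCase",
    "sensitivity_battery",
]

log = logging.getLogger(__name__)

INFLOW_EXPONENT = 1.84
DEFAULT_INLETS = ("R ICA G1", "L ICA G1", "BA")
ZERO_BASELINE = 1e-12


def resolution_alpha(
    inlet_areas_sc1: Sequence[float] | Mapping[str, float],
    inlet_areas_sc2: Sequence[float] | Mapping[str, float],
) -> float:
    """Resolution scaling factor from the inlet mean reference areas (cm^2).

    Accepts the three areas as sequences or label-keyed mappings (matched
    by key when both are mappings)."""
    if isinstance(inlet_areas_sc1, Mapping) and isinstance(inlet_areas_sc2, Mapping):
        keys = sorted(inlet_areas_sc1)
        if sorted(inlet_areas_sc2) != keys:
            raise ConfigurationError(
                f"inlet sets differ between scans: {keys} vs {sorted(inlet_areas_sc2)}"
            )
        a1 = np.array([inlet_areas_sc1[k] for k in keys], dtype=float)
        a2 = np.array([inlet_areas_sc2[k] for k in keys], dtype=float)
    else:
        a1 = np.asarray(list(inlet_areas_sc1), dtype=float)
        a2 = np.asarray(list(inlet_areas_sc2), dtype=float)
    if a1.size == 0 or a1.size != a2.size:
        raise ConfigurationError("need matching non-empty inlet area sets")
    if np.any(a1 <= 0) or np.any(a2 <= 0):
        raise InvalidInputError("inlet areas must be > 0")
    num = np.sum(a1**INFLOW_EXPONENT)
    den = np.sum(a2**INFLOW_EXPONENT)
    return float((num / den) ** (1.0 / INFLOW_EXPONENT))


def alpha_from_networks(
    net1: VascularNetwork, net2: VascularNetwork,
    inlet_labels: Sequence[str] = DEFAULT_INLETS,
) -> float:
    """Resolution factor from two networks' inlet arteries."""
    for lbl in inlet_labels:
        if lbl not in net1.arteries or lbl not in net2.arteries:
            raise ConfigurationError(f"inlet artery {lbl!r} missing from a scan")
    a1 = {lbl: net1.mean_reference_area(lbl) for lbl in inlet_labels}
    a2 = {lbl: net2.mean_reference_area(lbl) for lbl in inlet_labels}
    return resolution_alpha(a1, a2)


def apply_alpha(net: VascularNetwork, alpha: float) -> VascularNetwork:
    """Scale every reference cross-sectional area by ``alpha``.

    Radii scale by sqrt(alpha); lengths, wall parameters and reference
    pressures are untouched."""
    if alpha <= 0:
        raise InvalidInputError(f"alpha must be > 0, got {alpha}")
    if alpha == 1.0:
        return net
    f = float(np.sqrt(alpha))
    return net.with_arteries({lbl: a.scaled_radii(f) for lbl, a in net.arteries.items()})


@dataclass
class ScanPair:
    """Two same-patient networks plus the resolution calibration."""

    scan1: VascularNetwork
    scan2: VascularNetwork
    alpha: float = 1.0

    @classmethod
    def calibrated(cls, scan1: VascularNetwork, scan2: VascularNetwork,
                   inlet_labels: Sequence[str] = DEFAULT_INLETS) -> "ScanPair":
        """Build a pair with alpha identified from the inlet areas."""
        missing = [l for l in inlet_labels if l not in scan1.arteries or l not in scan2.arteries]
        if missing:
            raise ConfigurationError(f"inlet arteries absent from a scan: {missing}")
        return cls(scan1, scan2, alpha_from_networks(scan1, scan2, inlet_labels))

    def scan2_scaled(self) -> VascularNetwork:
        return apply_alpha(self.scan2, self.alpha)


def carotid_inflow_ratio(result: SimulationResult) -> float:
    """theta = mean right over mean left internal carotid inflow."""
    flows = result.inlet_mean_flows()
    try:
        qr, ql = flows["R ICA G1"], flows["L ICA G1"]
    except KeyError as exc:
        raise ConfigurationError(f"carotid inlet missing from result: {exc}") from exc
    if abs(ql) < ZERO_BASELINE:
        raise InvalidInputError("left carotid mean flow is zero; theta undefined")
    return qr / ql


def relative_variation(x_sc1: float, x_sc2: float) -> float:
    """Signed relative variation (x2 - x1)/x1 between scans."""
    if abs(x_sc1) < ZERO_BASELINE:
        raise InvalidInputError(
            "baseline is (numerically) zero; relative variation undefined — "
            "report the absolute change instead"
        )
    return (x_sc2 - x_sc1) / x_sc1


def _variation_or_absolute(x1: float, x2: float) -> tuple[float, bool]:
    """(value, is_absolute_flag); absolute change is reported on zero baselines."""
    if abs(x1) < ZERO_BASELINE:
        return x2 - x1, True
    return (x2 - x1) / x1, False


def network_smoothness_error(
    results_by_gamma: Mapping[float, Mapping[str, float]],
    vessel_lengths: Mapping[str, float],
    reference_gamma: float | None = None,
) -> dict[float, float]:
    """Length-weighted network difference of mean areas per smoothness level.

    ``results_by_gamma`` maps each smoothness coefficient to the per-vessel
    time-and-space mean areas; the smallest gamma is the reference.  For
    each level, eps_net is the vessel-length-weighted average of the
    absolute relative mean-area differences against the reference.
    """
    gammas = sorted(results_by_gamma)
    if reference_gamma is None:
        reference_gamma = gammas[0]
    if reference_gamma not in results_by_gamma:
        raise ConfigurationError(f"reference gamma {reference_gamma} not among results")
    ref = results_by_gamma[reference_gamma]
    vessels = sorted(ref)
    total_l = sum(vessel_lengths[v] for v in vessels)
    out: dict[float, float] = {}
    for g in gammas:
        cur = results_by_gamma[g]
        if sorted(cur) != vessels:
            raise ValidationError(f"vessel set at gamma={g} differs from reference")
        eps = sum(
            (vessel_lengths[v] / total_l) * abs((cur[v] - ref[v]) / ref[v]) for v in vessels
        )
        out[g] = float(eps)
    return out


def outflow_distribution(result: SimulationResult) -> dict[str, float]:
    """Cycle-mean outlet flow as a fraction of total cycle-mean inflow."""
    total_in = sum(result.inlet_mean_flows().values())
    if total_in <= 0:
        raise InvalidInputError("total mean inflow is non-positive")
    return {lbl: q / total_in for lbl, q in result.outlet_mean_flows().items()}


def normalized_pressure(result: SimulationResult) -> dict[str, float]:
    """Min-max normalized per-vessel mean pressures, in [0, 1]."""
    agg = result.aggregates()["P_mean"]
    lo, hi = float(agg.min()), float(agg.max())
    if hi - lo < 1e-12:
        raise InvalidInputError("all vessel mean pressures equal; normalization degenerate")
    return {v: float((p - lo) / (hi - lo)) for v, p in agg.items()}


@dataclass
class ComparisonReport:
    """Products of a two-scan comparison."""

    alpha: float
    theta: dict[str, float]                       # per scan
    variations: pd.DataFrame                      # vessel x (Q_mean, P_mean, Q_peak, P_peak)
    absolute_flagged: pd.DataFrame                # same shape, True where absolute change reported
    outflow_fractions: dict[str, dict[str, float]]
    normalized_pressures: dict[str, dict[str, float]]

    def variation(self, vessel: str, quantity: str = "Q_mean") -> float:
        return float(self.variations.loc[vessel, quantity])


def compare_scans(
    pair: ScanPair,
    params: VesselParameterTable | None = None,
    settings: SolverSettings | None = None,
    results: tuple[SimulationResult, SimulationResult] | None = None,
    **run_kwargs,
) -> ComparisonReport:
    """Simulate both scans (scan 2 alpha-scaled) and tabulate the metrics.

    Pre-computed results may be injected via ``results`` to avoid re-running
    (used by the sensitivity battery)."""
    if results is None:
        r1 = run_simulation(pair.scan1, params=params, settings=settings, **run_kwargs)
        r2 = run_simulation(pair.scan2_scaled(), params=params, settings=settings, **run_kwargs)
    else:
        r1, r2 = results
    common = [v for v in r1.vessel_labels if v in r2.vessel_labels]
    dropped = set(r1.vessel_labels) ^ set(r2.vessel_labels)
    if dropped:
        log.warning("vessels present in only one scan are skipped: %s", sorted(dropped))
    a1, a2 = r1.aggregates(), r2.aggregates()
    quantities = ["Q_mean", "P_mean", "Q_peak", "P_peak"]
    vals = pd.DataFrame(index=common, columns=quantities, dtype=float)
    flags = pd.DataFrame(False, index=common, columns=quantities)
    for v in common:
        for q in quantities:
            val, flag = _variation_or_absolute(float(a1.loc[v, q]), float(a2.loc[v, q]))
            vals.loc[v, q] = val
            flags.loc[v, q] = flag
    return ComparisonReport(
        alpha=pair.alpha,
        theta={"sc1": carotid_inflow_ratio(r1), "sc2": carotid_inflow_ratio(r2)},
        variations=vals,
        absolute_flagged=flags,
        outflow_fractions={"sc1": outflow_distribution(r1), "sc2": outflow_distribution(r2)},
        normalized_pressures={"sc1": normalized_pressure(r1), "sc2": normalized_pressure(r2)},
    )


@dataclass
class SensitivityCase:
    """One perturbed re-run of the pair comparison."""

    case_id: str
    eps_sc: float | None = None
    eta: float | None = None
    band: str | None = None
    error: str | None = None


def classify_eta(eta: float) -> str:
    """Three-band classification of |eta|: yellow < 0.25 <= orange <= 0.5 < red."""
    a = abs(eta)
    if a < 0.25:
        return "yellow"
    if a <= 0.5:
        return "orange"
    return "red"


SENSITIVITY_CASES = ("reference", "alpha_1", "half_Rt", "double_Rt", "half_E", "double_E")


def sensitivity_battery(
    pair: ScanPair,
    vessel: str,
    params: VesselParameterTable | None = None,
    settings: SolverSettings | None = None,
    quantity: str = "Q_mean",
    **run_kwargs,
) -> list[SensitivityCase]:
    """Run the five perturbed pipelines and report eta for one vessel.

    Cases: ``alpha_1`` (no resolution calibration), ``half_Rt``/``double_Rt``
    (all terminal resistances scaled), ``half_E``/``double_E`` (all Young's
    moduli, hence wall stiffness, scaled).  ``eta`` is the relative error of
    the case's eps_sc against the calibrated reference; the reference case
    itself has eta = 0.  A failing sub-run is reported in its case entry
    while the others still return."""
    params = params or VesselParameterTable.from_csv()

    def eps_for(case_params: VesselParameterTable, alpha: float,
                r1_cache: dict) -> float:
        key = id(case_params)
        if key not in r1_cache:
            r1_cache[key] = run_simulation(pair.scan1, params=case_params,
                                           settings=settings, **run_kwargs)
        r1 = r1_cache[key]
        scan2 = apply_alpha(pair.scan2, alpha)
        r2 = run_simulation(scan2, params=case_params, settings=settings, **run_kwargs)
        rep = compare_scans(ScanPair(pair.scan1, pair.scan2, alpha),
                            params=case_params, settings=settings, results=(r1, r2))
        return rep.variation(vessel, quantity)

    cache: dict = {}
    cases: list[SensitivityCase] = []
    eps_ref: float | None = None
    specs = {
        "reference": (params, pair.alpha),
        "alpha_1": (params, 1.0),
        "half_Rt": (params.scaled(Rt_scale=0.5), pair.alpha),
        "double_Rt": (params.scaled(Rt_scale=2.0), pair.alpha),
        "half_E": (params.scaled(E_scale=0.5), pair.alpha),
        "double_E": (params.scaled(E_scale=2.0), pair.alpha),
    }
    for case_id in SENSITIVITY_CASES:
        case_params, alpha = specs[case_id]
        try:
            eps = eps_for(case_params, alpha, cache)
        except Exception as exc:  # noqa: BLE001 — per-case fault isolation
            cases.append(SensitivityCase(case_id, error=f"{type(exc).__name__}: {exc}"))
            if case_id == "reference":
                log.error("reference case failed; eta undefined for all cases")
            continue
        if case_id == "reference":
            eps_ref = eps
            cases.append(SensitivityCase(case_id, eps_sc=eps, eta=0.0, band=classify_eta(0.0)))
        elif eps_ref is None or abs(eps_ref) < ZERO_BASELINE:
            if eps_ref is not None and abs(eps - eps_ref) < ZERO_BASELINE:
                # the perturbation left the (degenerate) comparison untouched
                cases.append(SensitivityCase(case_id, eps_sc=eps, eta=0.0,
                                             band=classify_eta(0.0)))
            else:
                cases.append(SensitivityCase(case_id, eps_sc=eps,
                                             error="reference eps_sc unavailable or zero"))
        else:
            eta = (eps - eps_ref) / eps_ref
            cases.append(SensitivityCase(case_id, eps_sc=eps, eta=eta, band=classify_eta(eta)))
    return cases
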