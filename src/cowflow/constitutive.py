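"""Pressure-area tube law, wall elasticity, and the vessel parameter table.

The 1-D model is closed by an algebraic tube law relating lumen pressure to
cross-sectional area,

    P = P_ext + P_0 + (beta / A_0) * (sqrt(A) - sqrt(A_0)),

with wall elasticity coefficient ``beta = (4/3) * sqrt(pi) * E * h`` from
the Young's modulus ``E`` and wall thickness ``h``.  The law inverts in
closed form, and its analytic area-compliance ``C_A = dA/dP = 2 sqrt(A)
A_0 / beta`` enters the mass balance of the flow solver.

Quantities here are in the units the constitutive tables are quoted in
(beta in Pa.cm, pressures in mmHg, areas in cm^2); the solver converts to
CGS on mesh assembly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UnphysicalStateError
from .units import MMHG_TO_PA, pa_to_mmhg

__all__ = [
    "BloodProperties",
    "TubeLawParams",
    "beta_from_wall",
    "pressure_from_area",
    "area_from_pressure",
    "compliance",
    "wave_speed",
    "VesselParameterTable",
    "ParamRow",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BloodProperties:
    """Blood density (g/cm^3) and dynamic viscosity (poise)."""

    rho: float = 1.04
    mu: float = 0.04

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0:
            raise InvalidInputError("blood density and viscosity must be > 0")


def beta_from_wall(h: float, E: float) -> float:
    """Wall elasticity coefficient beta = (4/3) sqrt(pi) E h.

    ``h`` in cm, ``E`` in Pa; returns Pa.cm.  ``h = 0`` is accepted as the
    membrane-free limit (beta = 0); negative inputs are rejected.
    """
    if h < 0 or E <= 0:
        raise InvalidInputError(f"need h >= 0 and E > 0, got h={h}, E={E}")
    return (4.0 / 3.0) * np.sqrt(np.pi) * E * h


@dataclass(frozen=True)
class TubeLawParams:
    """Per-vessel tube-law coefficients.

    beta in Pa.cm, A0 in cm^2, P0/Pext in mmHg.  When the wall pair (E, h)
    is supplied it must be consistent with beta to 1%.
    """

    beta: float
    A0: float
    P0: float = 0.0
    Pext: float = 0.0
    E: float | None = None
    h: float | None = None

    def __post_init__(self):
        if self.beta <= 0 or self.A0 <= 0:
            raise InvalidInputError("beta and A0 must be > 0")
        if self.E is not None and self.h is not None:
            ref = beta_from_wall(self.h, self.E)
            if abs(self.beta - ref) > 0.01 * ref:
                raise InvalidInputError(
                    f"beta={self.beta} inconsistent with (4/3)sqrt(pi)*E*h={ref:.6g}"
                )

    @property
    def reference_pressure(self) -> float:
        """P_ext + P_0 (mmHg), the pressure at which A = A_0."""
        return self.Pext + self.P0


def pressure_from_area(A, p: TubeLawParams):
    """Tube-law pressure (mmHg) at cross-sectional area ``A`` (cm^2)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise InvalidInputError("area must be > 0")
    dp_pa = (p.beta / p.A0) * (np.sqrt(A) - np.sqrt(p.A0))  # Pa.cm/cm^2*cm = Pa
    out = p.Pext + p.P0 + pa_to_mmhg(dp_pa)
    return float(out) if out.ndim == 0 else out


def area_from_pressure(P, p: TubeLawParams):
    """Closed-form inverse of the tube law: area (cm^2) at pressure ``P`` (mmHg)."""
    P = np.asarray(P, dtype=float)
    dp_pa = (P - p.Pext - p.P0) * MMHG_TO_PA
    root = np.sqrt(p.A0) + dp_pa * p.A0 / p.beta
    if np.any(root <= 0):
        raise UnphysicalStateError(
            f"pressure {P} mmHg collapses the vessel (non-positive sqrt-area root)"
        )
    out = root**2
    return float(out) if out.ndim == 0 else out


def compliance(A, p: TubeLawParams):
    """Analytic area-compliance C_A = dA/dP = 2 sqrt(A) A0 / beta (cm^2/Pa)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise InvalidInputError("area must be > 0")
    out = 2.0 * np.sqrt(A) * p.A0 / p.beta
    return float(out) if out.ndim == 0 else out


def wave_speed(p: TubeLawParams, rho: float = 1.04) -> float:
    """Linearized pulse-wave speed at the reference state (cm/s).

    c^2 = A / (rho C_A) evaluated at A = A0 gives
    c = sqrt(beta sqrt(A0) / (2 rho A0)); beta is converted to CGS.
    """
    beta_cgs = p.beta * 10.0  # Pa.cm -> dyn/cm
    return float(np.sqrt(beta_cgs / (2.0 * rho * np.sqrt(p.A0))))


# ---------------------------------------------------------------------------
# Vessel parameter table (wall, reference pressure, terminal coefficients)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRow:
    """Resolved per-vessel constitutive and terminal parameters."""

    pattern: str
    h_cm: float
    E_pa: float
    beta_pa_cm: float
    p0_mmhg: float
    rt_pa_s_cm3: float | None = None
    ct_cm3_pa: float | None = None

    @property
    def is_terminal(self) -> bool:
        return self.rt_pa_s_cm3 is not None


_PATTERN_RE = re.compile(
    r"^(?P<side>R/L\s+|R\s+|L\s+)?(?P<family>[A-Za-z]+)(?:\s+G(?P<g0>\d+)(?:-G(?P<g1>\d+))?)?$"
)


def expand_pattern(pattern: str) -> list[str]:
    """Expand a row pattern like ``R/L MCA G1-G2`` to explicit labels."""
    m = _PATTERN_RE.match(pattern.strip())
    if not m:
        return [pattern.strip()]  # literal label, e.g. a test vessel name
    side = (m.group("side") or "").strip()
    sides = ["R", "L"] if side == "R/L" else [side] if side else [""]
    g0 = m.group("g0")
    gens = [""] if g0 is None else [f" G{g}" for g in range(int(g0), int(m.group("g1") or g0) + 1)]
    fam = m.group("family")
    return [f"{s} {fam}{g}".strip() for s in sides for g in gens]


class VesselParameterTable:
    """Lookup from artery label to wall/terminal parameters.

    By default ``beta`` is derived from the wall pair (h, E); rows whose
    quoted beta disagrees with that product are reported with a warning and
    the derived value wins unless ``use_table_beta=True``.
    """

    def __init__(self, rows: list[ParamRow]):
        self._rows = rows
        self._by_label: dict[str, ParamRow] = {}
        for row in rows:
            for lbl in expand_pattern(row.pattern):
                self._by_label[lbl] = row

    @classmethod
    def from_csv(cls, path: str | Path | None = None, use_table_beta: bool = False
                 ) -> "VesselParameterTable":
        """Load a table with columns ``vessels, h_cm, E_Pa, beta_Pa_cm,
        P0_mmHg, Rt_Pa_s_per_cm3, Ct_cm3_per_Pa`` (terminal columns blank
        for non-terminal rows).  ``path=None`` loads the packaged cohort
        table."""
        if path is None:
            ref = resources.files("cowflow.data").joinpath("vessel_parameters.csv")
            with resources.as_file(ref) as p:
                df = pd.read_csv(p)
        else:
            df = pd.read_csv(path)
        rows = []
        for rec in df.itertuples():
            derived = beta_from_wall(rec.h_cm, rec.E_Pa)
            table_beta = getattr(rec, "beta_Pa_cm", None)
            beta = derived
            if table_beta is not None and not pd.isna(table_beta):
                if abs(table_beta - derived) > 1e-3 * derived:
                    log.warning(
                        "row %r: quoted beta %.6g disagrees with (4/3)sqrt(pi)Eh = %.6g; using %s",
                        rec.vessels, table_beta, derived,
                        "quoted value" if use_table_beta else "derived value",
                    )
                if use_table_beta:
                    beta = float(table_beta)
            rt = None if pd.isna(rec.Rt_Pa_s_per_cm3) else float(rec.Rt_Pa_s_per_cm3)
            ct = None if pd.isna(rec.Ct_cm3_per_Pa) else float(rec.Ct_cm3_per_Pa)
            rows.append(ParamRow(rec.vessels, float(rec.h_cm), float(rec.E_Pa),
                                 beta, float(rec.P0_mmHg), rt, ct))
        return cls(rows)

    def lookup(self, label: str) -> ParamRow:
        try:
            return self._by_label[label]
        except KeyError:
            raise InvalidInputError(
                f"no parameter row matches artery {label!r}; known: {sorted(self._by_label)}"
            ) from None

    def scaled(self, E_scale: float = 1.0, Rt_scale: float = 1.0) -> "VesselParameterTable":
        """Copy with Young's moduli (hence beta) and/or terminal resistances scaled."""
        rows = []
        for r in self._rows:
            rows.append(replace(
                r,
                E_pa=r.E_pa * E_scale,
                beta_pa_cm=r.beta_pa_cm * E_scale,
                rt_pa_s_cm3=None if r.rt_pa_s_cm3 is None else r.rt_pa_s_cm3 * Rt_scale,
            ))
        return VesselParameterTable(rows)

    @property
    def rows(self) -> list[ParamRow]:
        return list(self._rows)
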