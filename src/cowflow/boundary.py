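"""Inflow calibration laws, waveform synthesis, and Windkessel outlets.

Inlet boundary flows are calibrated to the inlet vessel's spatially
averaged reference cross-sectional area ``A0bar`` (cm^2) through two
empirical power laws derived from in-vivo carotid measurements:

    peak flow  Q_hat = 70.80 * A0bar^1.7    (cm^3/s)
    mean flow  Q_bar = 48.21 * A0bar^1.84   (cm^3/s)

A periodic waveform template is then adjusted affinely so its cycle mean
and maximum hit both laws simultaneously.  Each outlet carries a 3-element
Windkessel (impedance resistance R1 in series with a parallel distal
resistance R2 and compliance C), with the total resistance split 20/80
between R1 and R2 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .units import MMHG_TO_PA, pa_to_mmhg

__all__ = [
    "mean_inflow_from_area",
    "peak_inflow_from_area",
    "InflowWaveform",
    "synthesize_inflow",
    "WindkesselOutlet",
    "windkessel_advance",
]

PEAK_COEFF, PEAK_EXP = 70.80, 1.7
MEAN_COEFF, MEAN_EXP = 48.21, 1.84

#: fraction of the cycle occupied by the systolic bump of the default template
SYSTOLIC_FRACTION = 0.35


def mean_inflow_from_area(A0bar: float) -> float:
    """Cycle-mean inflow (cm^3/s) from mean reference area (cm^2): 48.21 A^1.84."""
    if A0bar <= 0:
        raise InvalidInputError(f"reference area must be > 0, got {A0bar}")
    return MEAN_COEFF * A0bar**MEAN_EXP


def peak_inflow_from_area(A0bar: float) -> float:
    """Peak inflow (cm^3/s) from mean reference area (cm^2): 70.80 A^1.7."""
    if A0bar <= 0:
        raise InvalidInputError(f"reference area must be > 0, got {A0bar}")
    return PEAK_COEFF * A0bar**PEAK_EXP


@dataclass(frozen=True)
class InflowWaveform:
    """A periodic inflow signal with known cycle mean and maximum.

    ``signal`` maps time (s, any shape) to flow (cm^3/s); it is periodic
    with period ``period`` and C1-smooth for the built-in templates.
    """

    period: float
    mean: float
    peak: float
    signal: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def __call__(self, t):
        return self.signal(np.asarray(t, dtype=float))


def _pulse_template(T: float, q_mean: float, q_peak: float) -> InflowWaveform:
    # q(t) = a + b sin^2(pi u / s) on the systolic window u in [0, s), a in diastole.
    # cycle mean = a + b s/2, maximum = a + b; both constraints are hit exactly.
    s = SYSTOLIC_FRACTION
    b = (q_peak - q_mean) / (1.0 - s / 2.0)
    a = q_peak - b
    if a < 0:
        raise ConfigurationError(
            f"pulse template cannot reach peak/mean ratio {q_peak / q_mean:.3f} "
            "without negative diastolic flow"
        )

    def signal(t):
        u = np.mod(np.asarray(t, dtype=float) / T, 1.0)
        out = np.full_like(u, a, dtype=float)
        m = u < s
        out = np.where(m, a + b * np.sin(np.pi * u / s) ** 2, out)
        return out

    return InflowWaveform(T, q_mean, q_peak, signal)


def synthesize_inflow(A0bar: float, T: float = 1.0, template: str = "pulse") -> InflowWaveform:
    """Build an inlet waveform satisfying both inflow power laws.

    Templates: ``"pulse"`` (systolic sin^2 bump over a diastolic plateau,
    C1-periodic, non-negative) and ``"constant"`` (steady flow at the mean
    law; the peak constraint is deliberately dropped — useful for steady
    verification runs).
    """
    if A0bar <= 0 or T <= 0:
        raise InvalidInputError("A0bar and T must be > 0")
    q_mean = mean_inflow_from_area(A0bar)
    q_peak = peak_inflow_from_area(A0bar)
    if template == "constant":
        return InflowWaveform(T, q_mean, q_mean, lambda t: np.full_like(np.asarray(t, float), q_mean))
    if template != "pulse":
        raise ConfigurationError(f"unknown waveform template {template!r}")
    if q_peak < q_mean:
        raise ConfigurationError(
            f"infeasible constraints: required peak {q_peak:.4g} < mean {q_mean:.4g}"
        )
    return _pulse_template(T, q_mean, q_peak)


@dataclass
class WindkesselOutlet:
    """3-element Windkessel terminal: R1 + (R2 || C), venous pressure Pv.

    Resistances in Pa.s/cm^3, compliance in cm^3/Pa, pressures in mmHg.
    ``pc`` is the capacitor-node pressure state (mmHg).
    """

    R1: float
    R2: float
    C: float
    Pv: float = 10.0
    pc: float = field(default=None)  # type: ignore[assignment]
    _pc_prev: float | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.R1 < 0 or self.R2 <= 0 or self.C <= 0:
            raise InvalidInputError("need R1 >= 0, R2 > 0, C > 0")
        if self.pc is None:
            self.pc = self.Pv

    @classmethod
    def from_terminal(cls, Rt: float, Ct: float, split: float = 0.2, Pv: float = 10.0
                      ) -> "WindkesselOutlet":
        """Split a total terminal resistance 20/80 (by default) into R1/R2."""
        if not 0.0 <= split < 1.0:
            raise InvalidInputError(f"split must be in [0, 1), got {split}")
        return cls(R1=split * Rt, R2=(1.0 - split) * Rt, C=Ct, Pv=Pv)

    @property
    def Rt(self) -> float:
        return self.R1 + self.R2

    def steady_pressure(self, Q: float) -> float:
        """Asymptotic inlet pressure (mmHg) under constant inflow Q (cm^3/s)."""
        return self.Pv + pa_to_mmhg((self.R1 + self.R2) * Q)

    def reset(self, pc: float | None = None) -> None:
        self.pc = self.Pv if pc is None else pc
        self._pc_prev = None


def windkessel_advance(w: WindkesselOutlet, Q_in: float, dt: float) -> float:
    """Advance the RCR circuit one step and return the new inlet pressure (mmHg).

    The capacitor ODE ``C dPc/dt = Q - (Pc - Pv)/R2`` is integrated with a
    second-order backward difference (backward Euler on the first call, to
    match the flow solver's startup); the inlet pressure is
    ``P = Q R1 + Pc``.  State is kept in mmHg; the ODE runs in Pa.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    pc_n = w.pc * MMHG_TO_PA
    pv = w.Pv * MMHG_TO_PA
    if w._pc_prev is None:
        # backward Euler: (Pc' - Pc_n) C/dt = Q - (Pc' - Pv)/R2
        pc_new = (w.C / dt * pc_n + Q_in + pv / w.R2) / (w.C / dt + 1.0 / w.R2)
    else:
        pc_nm1 = w._pc_prev * MMHG_TO_PA
        # BDF2: C (1.5 Pc' - 2 Pc_n + 0.5 Pc_nm1)/dt = Q - (Pc' - Pv)/R2
        pc_new = (w.C / dt * (2.0 * pc_n - 0.5 * pc_nm1) + Q_in + pv / w.R2) / (
            1.5 * w.C / dt + 1.0 / w.R2
        )
    w._pc_prev = w.pc
    w.pc = pc_new / MMHG_TO_PA
    return (Q_in * w.R1 + pc_new) / MMHG_TO_PA
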