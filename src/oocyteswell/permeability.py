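"""Initial-rate permeability estimation.

The assay's estimators are linear maps from the initial relative swelling
rate d(V/V0)/dt:

    P_water  = [V0 * d(V/V0)/dt] / [S0 * V_w * (osm_in - osm_out)]
    P_solute = osm_total * [V0 * d(V/V0)/dt] / [S0 * (sol_out - sol_in)]

with osmolality converted to mol/cm^3 for P_water and the dimensionless
ratio osm_total/(sol_out - sol_in) for P_solute.  The slope is an ordinary
least-squares fit of V/V0 against time; by default the whole trace is used
(swelling at the permeability magnitudes of these assays is small and
near-linear over 10 min), an explicit window restricts the fit to an
initial segment.  Negative slopes (shrinking oocytes) pass through
unclamped — small negative permeabilities are part of the read-out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DegenerateFitError, InsufficientDataError, ZeroGradientError
from .geometry import VolumeTrace, trace_to_volume
from .swell_model import DiameterTrace
from .units import MOSM_TO_MOL_PER_CM3, P_REPORT_SCALE, V_W

logger = logging.getLogger(__name__)

__all__ = [
    "PhysConstants",
    "PermeabilityEstimate",
    "initial_rate",
    "p_water",
    "p_solute",
    "estimate_trace",
    "analyze_experiment",
    "ESTIMATE_COLUMNS",
]


@dataclass(frozen=True)
class PhysConstants:
    """Physical constants of the estimators (molar volume of water, cm^3/mol)."""

    v_w: float = V_W

    def __post_init__(self) -> None:
        if self.v_w <= 0:
            raise ConfigError("v_w must be > 0")


@dataclass(frozen=True)
class PermeabilityEstimate:
    """Per-oocyte estimate: fitted slope, fit window/quality and P in cm/s."""

    oocyte_id: str
    construct: str
    assay: str
    slope: float  # d(V/V0)/dt, 1/s
    fit_window: tuple[float, float]
    fit_r2: float
    n_points: int
    p_value_coeff: float  # cm/s

    @property
    def p_1e6(self) -> float:
        """Permeability on the conventional reporting scale (x 1e-6 cm/s)."""
        return self.p_value_coeff / P_REPORT_SCALE


def initial_rate(
    vtrace: VolumeTrace, window: Optional[Sequence[float]] = None
) -> tuple[float, float, tuple[float, float], int]:
    """OLS slope of relative volume against time.

    Returns ``(slope, r2, (t_start, t_end), n_points)``.  ``window`` is an
    inclusive [t_start, t_end] restriction; default is the full trace.
    """
    t = vtrace.times
    u = vtrace.rel_volume
    if window is not None:
        lo, hi = float(window[0]), float(window[1])
        if hi <= lo:
            raise ConfigError(f"fit window must have t_end > t_start, got ({lo}, {hi})")
        mask = (t >= lo) & (t <= hi)
        t, u = t[mask], u[mask]
    if len(t) < 3:
        raise InsufficientDataError(
            f"oocyte {vtrace.oocyte_id!r}: need >= 3 points in fit window, got {len(t)}"
        )
    tc = t - t.mean()
    sxx = float(np.dot(tc, tc))
    if sxx == 0.0:
        raise DegenerateFitError(f"oocyte {vtrace.oocyte_id!r}: zero time variance in window")
    slope = float(np.dot(tc, u - u.mean()) / sxx)
    resid = (u - u.mean()) - slope * tc
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(u - u.mean(), u - u.mean()))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return slope, r2, (float(t[0]), float(t[-1])), len(t)


def p_water(
    slope: float,
    v0: float,
    s0: float,
    osm_in: float,
    osm_out: float,
    const: PhysConstants = PhysConstants(),
) -> float:
    """Osmotic water permeability (cm/s) from the initial swelling rate.

    ``osm_in``/``osm_out`` in mOsmol/kg.  The sign follows the slope.
    """
    if osm_in == osm_out:
        raise ZeroGradientError("osm_in == osm_out: water permeability undefined")
    grad = (osm_in - osm_out) * MOSM_TO_MOL_PER_CM3
    return v0 * slope / (s0 * const.v_w * grad)


def p_solute(
    slope: float,
    v0: float,
    s0: float,
    osm_total: float,
    sol_out: float,
    sol_in: float = 0.0,
) -> float:
    """Solute permeability (cm/s) under an isotonic solute gradient.

    ``osm_total`` (mOsmol/kg) and the solute gradient (mM) enter only through
    their dimensionless ratio, e.g. 200/180 for the standard design.
    """
    if sol_out == sol_in:
        raise ZeroGradientError("sol_out == sol_in: solute permeability undefined")
    if osm_total <= 0:
        raise ConfigError("osm_total must be > 0")
    return osm_total * v0 * slope / (s0 * (sol_out - sol_in))


def estimate_trace(
    trace: DiameterTrace, window: Optional[Sequence[float]] = None
) -> PermeabilityEstimate:
    """Full per-oocyte estimation: diameters -> relative volume -> slope -> P."""
    vtrace = trace_to_volume(trace)
    slope, r2, win, n = initial_rate(vtrace, window)
    bath = trace.bath
    if bath.mode == "hypotonic":
        p = p_water(slope, vtrace.v0, vtrace.s0, bath.osm_in0, bath.osm_out)
    elif bath.mode == "isotonic_solute":
        p = p_solute(slope, vtrace.v0, vtrace.s0, bath.osm_total, bath.sol_out, bath.sol_in0)
    else:  # pragma: no cover - BathCondition validates mode
        raise ConfigError(f"unknown assay mode {bath.mode!r}")
    logger.debug(
        "oocyte %s (%s/%s): slope=%.3e 1/s, r2=%.4f, P=%.3f x1e-6 cm/s",
        trace.oocyte_id, trace.construct, bath.assay_label, slope, r2, p / P_REPORT_SCALE,
    )
    return PermeabilityEstimate(
        oocyte_id=trace.oocyte_id,
        construct=trace.construct,
        assay=bath.assay_label,
        slope=slope,
        fit_window=win,
        fit_r2=r2,
        n_points=n,
        p_value_coeff=p,
    )


ESTIMATE_COLUMNS = [
    "oocyte_id",
    "construct",
    "assay",
    "n_points",
    "t_start",
    "t_end",
    "slope_per_s",
    "fit_r2",
    "p_cm_per_s",
    "p_1e6",
]


def analyze_experiment(
    traces: Iterable[DiameterTrace], window: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Estimate permeability for every trace; one row per (oocyte, assay)."""
    rows = []
    for trace in traces:
        est = estimate_trace(trace, window)
        rows.append(
            {
                "oocyte_id": est.oocyte_id,
                "construct": est.construct,
                "assay": est.assay,
                "n_points": est.n_points,
                "t_start": est.fit_window[0],
                "t_end": est.fit_window[1],
                "slope_per_s": est.slope,
                "fit_r2": est.fit_r2,
                "p_cm_per_s": est.p_value_coeff,
                "p_1e6": est.p_1e6,
            }
        )
    if not rows:
        logger.warning("analyze_experiment called with no traces; returning empty table")
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
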