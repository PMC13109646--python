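"""Forward biophysical model of oocyte swelling (synthetic-data generator).

Two-compartment osmotic model.  Water crosses the membrane at a rate set by
the osmotic water permeability P_w and the transmembrane osmolality gap; in
an isotonic solute assay a permeant solute (glycerol, urea or boric acid)
additionally enters at a rate set by P_s and the solute gradient, raising
internal osmolality and dragging water in.  Volumes and surfaces follow the
apparent-sphere convention of the imaging assay (no membrane-folding factor).

Two gradient models are provided:

``constant``
    The estimators' own model world: the driving gradient and the surface
    area are frozen at their initial values, and in the solute assay water
    is assumed to equilibrate instantly, so volume tracks solute content
    (dV/dt = (dN_s/dt)/osm_total).  Trajectories are exactly linear and the
    initial-rate estimators invert this model exactly — it defines the
    parameter-recovery surface.

``dilution``
    The realistic model: internal concentrations are updated from conserved
    osmolyte amounts, C_in = (N_imp + N_s)/(V - vb*V0), so the gradient
    decays as the cell swells.  dV/dt = P_w S(V) V_w (C_in - C_out) and,
    for solute assays, dN_s/dt = P_s S(V) (C_s,out - C_s,in).  Used to
    quantify the bias of the constant-gradient estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import geometry
from .exceptions import ConfigError, EmptyGroupError, IntegrationFailureError
from .units import MOSM_TO_MOL_PER_CM3, P_REPORT_SCALE, V_W

logger = logging.getLogger(__name__)

__all__ = [
    "BathCondition",
    "SwellParams",
    "DiameterTrace",
    "AssayTruth",
    "ConstructSpec",
    "CohortSpec",
    "SimDefaults",
    "ASSAY_LABELS",
    "default_baths",
    "hypotonic_water_bath",
    "isotonic_solute_bath",
    "simulate_swelling",
    "generate_cohort",
]

#: canonical assay labels, in assay-panel order
ASSAY_LABELS = ("water", "glycerol", "urea", "boric_acid")

_SOLUTES = ("none", "glycerol", "urea", "boric_acid")
_MODES = ("hypotonic", "isotonic_solute")
_GRADIENT_MODELS = ("constant", "dilution")


@dataclass(frozen=True)
class BathCondition:
    """Assay mode and the osmotic / solute driving terms.

    Concentrations are given in the assay's conventional units: osmolality
    in mOsmol/kg, permeant-solute concentration in mM (numerically
    interchangeable under the dilute-solution convention).
    """

    mode: str
    osm_out: float
    osm_in0: float = 200.0
    osm_total: Optional[float] = None
    solute: str = "none"
    sol_out: float = 0.0
    sol_in0: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"unknown bath mode {self.mode!r}")
        if self.solute not in _SOLUTES:
            raise ConfigError(f"unknown solute {self.solute!r}")
        if self.osm_out <= 0:
            raise ConfigError("osm_out must be > 0")
        if self.mode == "hypotonic":
            if self.solute != "none" or self.sol_out != 0.0:
                raise ConfigError("hypotonic bath must have no permeant solute")
        else:
            if self.sol_out <= 0:
                raise ConfigError("isotonic_solute bath requires sol_out > 0")
            if self.solute == "none":
                raise ConfigError("isotonic_solute bath requires a named solute")
            if self.osm_total is None or self.osm_total <= 0:
                raise ConfigError("isotonic_solute bath requires osm_total > 0")

    @property
    def assay_label(self) -> str:
        """Assay panel this bath belongs to: 'water' or the solute name."""
        return "water" if self.mode == "hypotonic" else self.solute


def hypotonic_water_bath(osm_in0: float = 200.0, osm_out: float = 100.0) -> BathCondition:
    """Standard water assay: ND96-incubated oocyte moved to half-diluted ND96."""
    return BathCondition(mode="hypotonic", osm_out=osm_out, osm_in0=osm_in0)


def isotonic_solute_bath(
    solute: str,
    sol_out: float = 180.0,
    osm_total: float = 200.0,
    osm_in0: float = 200.0,
) -> BathCondition:
    """Isotonic substitution assay: 180 mM permeant solute replaces salt."""
    return BathCondition(
        mode="isotonic_solute",
        osm_out=osm_total,
        osm_in0=osm_in0,
        osm_total=osm_total,
        solute=solute,
        sol_out=sol_out,
    )


def default_baths() -> dict[str, BathCondition]:
    """The four-bath assay design keyed by assay label."""
    baths = {"water": hypotonic_water_bath()}
    for sol in ("glycerol", "urea", "boric_acid"):
        baths[sol] = isotonic_solute_bath(sol)
    return baths


@dataclass(frozen=True)
class SwellParams:
    """Ground-truth parameters for one simulated oocyte.

    ``p_water_true``/``p_solute_true`` are in cm/s.  ``p_water_true`` may be
    negative: water-injected control oocytes show a small background leak and
    estimation noise makes small negative values observable.  ``vb_frac`` is
    the osmotically inactive (non-osmotic) volume fraction of V0.
    """

    p_water_true: float
    p_solute_true: float = 0.0
    d0: float = 0.12  # cm (~1.2 mm oocyte)
    vb_frac: float = 0.0
    gradient_model: str = "dilution"
    noise_sd_frac: float = 0.001
    dt_sample: float = 30.0  # s
    duration: float = 600.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ConfigError("d0 must be > 0")
        if not 0.0 <= self.vb_frac < 1.0:
            raise ConfigError("vb_frac must lie in [0, 1)")
        if self.gradient_model not in _GRADIENT_MODELS:
            raise ConfigError(f"unknown gradient_model {self.gradient_model!r}")
        if self.dt_sample <= 0:
            raise ConfigError("dt_sample must be > 0")
        if self.duration < self.dt_sample:
            raise ConfigError("duration must be >= dt_sample")
        if self.noise_sd_frac < 0:
            raise ConfigError("noise_sd_frac must be >= 0")


@dataclass(frozen=True)
class DiameterTrace:
    """Timed diameter measurements (cm) for one oocyte."""

    oocyte_id: str
    construct: str
    bath: BathCondition
    times: np.ndarray
    diameters: np.ndarray
    truth: Optional[SwellParams] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.diameters, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "diameters", d)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("times and diameters must be 1-D of equal length")
        if len(t) < 3:
            raise ValueError("a trace needs at least 3 samples")
        if t[0] != 0.0:
            raise ValueError("times must start at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            raise ValueError("all diameters must be finite and > 0")


def _sample_times(params: SwellParams) -> np.ndarray:
    return np.arange(0.0, params.duration + 0.5 * params.dt_sample, params.dt_sample)


def _simulate_constant(params: SwellParams, bath: BathCondition, t: np.ndarray) -> np.ndarray:
    """Exactly linear volume course of the estimator-consistent model."""
    v0 = geometry.sphere_volume(params.d0)
    s0 = geometry.sphere_surface(params.d0)
    if bath.mode == "hypotonic":
        grad = (bath.osm_in0 - bath.osm_out) * MOSM_TO_MOL_PER_CM3
        rate = params.p_water_true * s0 * V_W * grad  # cm^3/s
    else:
        grad = (bath.sol_out - bath.sol_in0) * MOSM_TO_MOL_PER_CM3
        c_total = bath.osm_total * MOSM_TO_MOL_PER_CM3
        # solute influx through S0; water keeps the cell at osmotic equilibrium
        rate = params.p_solute_true * s0 * grad / c_total
    return v0 + rate * t


def _simulate_dilution(params: SwellParams, bath: BathCondition, t: np.ndarray) -> np.ndarray:
    v0 = geometry.sphere_volume(params.d0)
    vb = params.vb_frac * v0
    v_act0 = v0 - vb
    n_imp = bath.osm_in0 * MOSM_TO_MOL_PER_CM3 * v_act0
    c_out = bath.osm_out * MOSM_TO_MOL_PER_CM3
    pw = params.p_water_true

    if bath.mode == "hypotonic":

        def rhs(_t, y):
            v = y[0]
            c_in = n_imp / (v - vb)
            return [pw * geometry.surface_from_volume(v) * V_W * (c_in - c_out)]

        y0 = [v0]
    else:
        ps = params.p_solute_true
        cs_out = bath.sol_out * MOSM_TO_MOL_PER_CM3
        ns0 = bath.sol_in0 * MOSM_TO_MOL_PER_CM3 * v_act0

        def rhs(_t, y):
            v, ns = y
            v_act = v - vb
            s = geometry.surface_from_volume(v)
            c_in = (n_imp + ns) / v_act
            cs_in = ns / v_act
            return [pw * s * V_W * (c_in - c_out), ps * s * (cs_out - cs_in)]

        y0 = [v0, ns0]

    sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA", rtol=1e-8, atol=v0 * 1e-14)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise IntegrationFailureError(
            f"integration failed for params={params!r}, bath={bath!r}: {sol.message}"
        )
    return sol.y[0]


def simulate_swelling(
    params: SwellParams,
    bath: BathCondition,
    oocyte_id: str = "oocyte",
    construct: str = "sim",
) -> DiameterTrace:
    """Simulate one oocyte's diameter trace under the given bath.

    Samples every ``dt_sample`` seconds up to ``duration`` (t = 0 included),
    converts volume to apparent diameter and adds i.i.d. Gaussian measurement
    noise of sd ``noise_sd_frac * d0`` to each diameter.  The generating
    parameters are recorded on the returned trace.
    """
    t = _sample_times(params)
    if params.gradient_model == "constant":
        v = _simulate_constant(params, bath, t)
    else:
        v = _simulate_dilution(params, bath, t)
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise IntegrationFailureError(
            f"non-physical volume reached for params={params!r}, bath={bath!r}"
        )
    d = geometry.sphere_diameter(v)
    if params.noise_sd_frac > 0:
        rng = np.random.default_rng(params.seed)
        d = d + rng.normal(0.0, params.noise_sd_frac * params.d0, size=d.shape)
        if np.any(d <= 0):
            raise IntegrationFailureError(
                f"measurement noise produced a non-positive diameter for params={params!r}"
            )
    return DiameterTrace(
        oocyte_id=oocyte_id,
        construct=construct,
        bath=bath,
        times=t,
        diameters=d,
        truth=params,
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class AssayTruth:
    """Generating distribution of true permeability for one construct x assay.

    ``mean``/``sd`` are on the reporting scale (1e-6 cm/s), matching how
    cohort statistics are tabulated for these assays.
    """

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise EmptyGroupError("each construct x assay needs n >= 1 oocytes")
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")


@dataclass(frozen=True)
class ConstructSpec:
    """One construct (channel or control) with its per-assay truths."""

    construct: str
    assays: dict[str, AssayTruth]

    def __post_init__(self) -> None:
        for label in self.assays:
            if label not in ASSAY_LABELS:
                raise ConfigError(f"unknown assay label {label!r}")
        if not self.assays:
            raise ConfigError(f"construct {self.construct!r} has no assays")


@dataclass(frozen=True)
class SimDefaults:
    """Simulator settings shared by every oocyte of a cohort.

    Cohort generation defaults to the constant-gradient model with
    near-negligible measurement noise: the cohort surface exists to compare
    recovered permeabilities against their generating values, so the
    estimator-consistent model and a noise floor well below the biological
    spread keep that comparison direct.  The realistic per-trace defaults
    (dilution model, 0.1% diameter noise) remain on :class:`SwellParams`.
    """

    d0: float = 0.12
    vb_frac: float = 0.0
    gradient_model: str = "constant"
    noise_sd_frac: float = 1e-6
    dt_sample: float = 30.0
    duration: float = 600.0


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort design: constructs, baths, shared settings, master seed."""

    constructs: tuple[ConstructSpec, ...]
    baths: dict[str, BathCondition] = field(default_factory=default_baths)
    defaults: SimDefaults = field(default_factory=SimDefaults)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "constructs", tuple(self.constructs))
        if not self.constructs:
            raise ConfigError("cohort needs at least one construct")
        for cons in self.constructs:
            for label in cons.assays:
                if label not in self.baths:
                    raise ConfigError(
                        f"assay {label!r} of construct {cons.construct!r} "
                        "has no bath definition"
                    )


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw floored at -(mean + 3 sd) to exclude absurd trajectories."""
    if sd == 0.0:
        return mean
    floor = -(mean + 3.0 * sd)
    for _ in range(1000):
        x = float(rng.normal(mean, sd))
        if x >= floor:
            return x
    raise ConfigError(
        f"truncated draw failed for mean={mean}, sd={sd}: floor {floor} too high"
    )


def generate_cohort(spec: CohortSpec) -> tuple[list[DiameterTrace], pd.DataFrame]:
    """Simulate every oocyte of a cohort design.

    Each oocyte's true permeability is drawn from the construct's per-assay
    truncated normal; its trace is simulated under the matching bath.  Returns
    the traces and a manifest table of generating values.  Fully reproducible
    from the master seed: the seed sequence is spawned per construct x assay
    in specification order, so adding a construct does not perturb earlier
    draws within a run.
    """
    traces: list[DiameterTrace] = []
    rows: list[dict] = []
    ss = np.random.SeedSequence(spec.seed)
    dflt = spec.defaults
    for cons in spec.constructs:
        for label, truth in cons.assays.items():
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            bath = spec.baths[label]
            water_truth = cons.assays.get("water")
            for i in range(truth.n):
                p_true = _draw_truncated(rng, truth.mean, truth.sd) * P_REPORT_SCALE
                noise_seed = int(rng.integers(0, 2**31 - 1))
                if bath.mode == "hypotonic":
                    p_water, p_solute = p_true, 0.0
                else:
                    # water permeability only matters under the dilution model
                    p_water = (water_truth.mean * P_REPORT_SCALE) if water_truth else 0.0
                    p_solute = p_true
                params = SwellParams(
                    p_water_true=p_water,
                    p_solute_true=p_solute,
                    d0=dflt.d0,
                    vb_frac=dflt.vb_frac,
                    gradient_model=dflt.gradient_model,
                    noise_sd_frac=dflt.noise_sd_frac,
                    dt_sample=dflt.dt_sample,
                    duration=dflt.duration,
                    seed=noise_seed,
                )
                oocyte_id = f"{cons.construct}-{label}-{i + 1:03d}"
                traces.append(
                    simulate_swelling(params, bath, oocyte_id=oocyte_id, construct=cons.construct)
                )
                rows.append(
                    {
                        "oocyte_id": oocyte_id,
                        "construct": cons.construct,
                        "assay": label,
                        "p_true_1e6": p_true / P_REPORT_SCALE,
                        "noise_seed": noise_seed,
                    }
                )
    manifest = pd.DataFrame(rows, columns=["oocyte_id", "construct", "assay", "p_true_1e6", "noise_seed"])
    logger.info("generated cohort: %d traces across %d constructs", len(traces), len(spec.constructs))
    return traces, manifest


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a different master seed."""
    return replace(spec, seed=seed)
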