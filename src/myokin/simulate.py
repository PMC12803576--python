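"""Simulation protocols: resting steady state, workload ramp, readouts.

The resting state is found by stiff integration of the network ODEs followed
by a Newton polish in reduced coordinates (one dependent pool eliminated per
conserved moiety, so the root problem is non-singular and the solution stays
on the moiety manifold).  The workload ramp re-solves the steady state for a
stepwise-increasing ATP demand ``k_load``, warm-starting each step from the
previous one, until the ATP production rate converges to its maximal value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import ContractError, LoadParameters, NetworkModel

__all__ = [
    "SteadyState",
    "EnergyProfile",
    "RampStep",
    "solve_resting_state",
    "workload_ramp",
    "substrate_partition",
    "fa_glc_ratio",
    "respiratory_readouts",
    "scenario_suite",
    "extract_metabolic_features",
    "derive_atp_equivalents",
    "SteadyStateError",
]

#: steady state declared when max |dC/dt| / (|C| + atol) falls below this
STEADY_TOL = 1e-6
STEADY_ATOL = 1e-6

SUBSTRATE_CLASSES = ("fatty_acids", "glucose", "lactate_pyruvate", "ketones", "bcaa")
PARTITION_LEVELS = ("rest", "25%", "50%", "75%", "100%")


class SteadyStateError(RuntimeError):
    """Steady state could not be reached; carries the residual trace."""

    def __init__(self, message: str, residual_trace=None):
        super().__init__(message)
        self.residual_trace = list(residual_trace or [])


@dataclass
class SteadyState:
    """Converged stationary metabolic state of one patient model."""

    concentrations: dict[str, float]
    membrane_potential: float | None
    fluxes: dict[str, float]
    residual: float
    method: str
    k_load: float
    state_vector: np.ndarray = field(repr=False, default=None)


@dataclass
class RampStep:
    k_load: float
    atp_production: float
    o2_rate: float
    partition: dict[str, float]
    fa_glc: float


@dataclass
class EnergyProfile:
    """Per-patient bioenergetic readout of a workload-ramp simulation.

    Rates are mmol/L cell/h; the substrate partition is reported as fractions
    of total ATP-equivalent production (summing to 1) at rest and at 25, 50,
    75 and 100% of the maximal ATP production capacity.
    """

    resting_atp_rate: float
    max_atp_capacity: float
    peak_o2_rate: float
    atp_per_o2: float
    substrate_partition: dict[str, dict[str, float]]
    fa_glc_rest: float
    fa_glc_max: float
    ramp: list[RampStep] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    @property
    def atp_reserve(self) -> float:
        """Reserve is maximal capacity minus resting production, exactly."""
        return self.max_atp_capacity - self.resting_atp_rate


def _model_and_scale(patient) -> tuple[NetworkModel, dict[str, float] | None]:
    if isinstance(patient, NetworkModel):
        return patient, None
    base = getattr(patient, "base", None)
    if base is None:
        raise ContractError("expected a NetworkModel or PatientModel")
    return base, getattr(patient, "vmax_scale", None)


def _reduced_coords(model: NetworkModel, y0: np.ndarray):
    """Choose one dependent pool per moiety (the largest at y0) and return
    (independent state indices, list of (dep_index, total, other_indices))."""
    n_pool = len(model.state_ids)
    dep_info = []
    dep_set = set()
    for m in model.moieties:
        idx = [model._index[mem] for mem in m.members]
        dep = max(idx, key=lambda i: y0[i])
        others = [i for i in idx if i != dep]
        total = float(sum(y0[i] for i in idx))
        dep_info.append((dep, total, others))
        dep_set.add(dep)
    indep = [i for i in range(n_pool) if i not in dep_set]
    if model.has_membrane_potential:
        indep.append(n_pool)  # psi
    return indep, dep_info


def _convergence_residual(dy: np.ndarray, y: np.ndarray) -> float:
    return float(np.max(np.abs(dy) / (np.abs(y) + STEADY_ATOL)))


def _solve_steady(
    model: NetworkModel,
    plasma,
    vmax_scale: dict[str, float] | None,
    k_load: float,
    y0: np.ndarray | None = None,
    newton_first: bool = True,
    max_horizon: float = 2000.0,
) -> SteadyState:
    scale = dict(vmax_scale or {})
    base_load = model.reaction("R_LOAD").vmax if _has_load(model) else None
    if base_load is not None:
        scale["R_LOAD"] = scale.get("R_LOAD", 1.0) * k_load / base_load
    rhs, fluxes = model.compile(plasma, scale)
    y = model.initial_state() if y0 is None else np.array(y0, dtype=float)

    method = "newton"
    trace = []

    def try_newton(y_start):
        indep, dep_info = _reduced_coords(model, y_start)

        def assemble(z):
            y_full = y_start.copy()
            y_full[indep] = z
            for dep, total, others in dep_info:
                y_full[dep] = total - y_full[others].sum() if others else total
            return y_full

        def residual(z):
            return rhs(0.0, assemble(z))[indep]

        sol = root(residual, y_start[indep], method="hybr", options={"xtol": 1e-12})
        y_full = assemble(sol.x)
        if not sol.success or np.any(y_full[: len(model.state_ids)] < -1e-9):
            return None
        y_full[: len(model.state_ids)] = np.maximum(y_full[: len(model.state_ids)], 0.0)
        res = _convergence_residual(rhs(0.0, y_full), y_full)
        return (y_full, res) if res < 1e3 * STEADY_TOL else None

    result = None
    if newton_first:
        res0 = _convergence_residual(rhs(0.0, y), y)
        if res0 < STEADY_TOL:
            result = (y.copy(), res0)  # warm start is already stationary
        else:
            result = try_newton(y)
    if result is None:
        # stiff integration towards the attractor, then polish
        method = "integrate+newton"
        t = 0.0
        chunk = 20.0
        converged = False
        while t < max_horizon:
            ivp = solve_ivp(rhs, (0.0, chunk), y, method="BDF", rtol=1e-8, atol=1e-10)
            if not ivp.success:
                raise SteadyStateError(
                    f"integration failed at t={t + chunk:.1f} h: {ivp.message}", trace
                )
            y = ivp.y[:, -1]
            y[: len(model.state_ids)] = np.maximum(y[: len(model.state_ids)], 0.0)
            t += chunk
            res = _convergence_residual(rhs(0.0, y), y)
            trace.append(res)
            if res < STEADY_TOL:
                converged = True
                break
            result = try_newton(y)
            if result is not None:
                break
        if result is None:
            if not converged:
                if len(trace) >= 3 and trace[-1] > trace[-2] > trace[-3]:
                    raise SteadyStateError(
                        "residual increasing (oscillatory divergence?)", trace
                    )
                raise SteadyStateError(
                    f"no steady state within {max_horizon} h (residual {trace[-1]:.2e})",
                    trace,
                )
            result = (y, trace[-1])
    y_ss, res = result
    v = fluxes(y_ss)
    conc, psi = model.split_state(y_ss)
    return SteadyState(
        concentrations=dict(zip(model.state_ids, conc)),
        membrane_potential=psi,
        fluxes={r.id: float(v[j]) for j, r in enumerate(model.reactions)},
        residual=res,
        method=method,
        k_load=k_load,
        state_vector=y_ss,
    )


def _has_load(model: NetworkModel) -> bool:
    return any(r.id == "R_LOAD" for r in model.reactions)


def solve_resting_state(patient, plasma, load: LoadParameters | None = None) -> SteadyState:
    """Resting steady state of a patient model under a plasma scenario.

    Deterministic given inputs.  Raises :class:`SteadyStateError` (carrying
    the residual trace) on non-convergence.
    """
    model, scale = _model_and_scale(patient)
    k_load = load.k_load if load is not None else model.config["load"]["k_load_rest"]
    return _solve_steady(model, plasma, scale, k_load, newton_first=False)


# ---------------------------------------------------------------------------
# readouts
# ---------------------------------------------------------------------------

def derive_atp_equivalents(model: NetworkModel) -> dict[str, float]:
    """ATP-equivalent yield per mole of substrate, derived from the model's
    own stoichiometry along the configured canonical routes (ATP + P/O-weighted
    NADH and FADH2 coefficients)."""
    cfg = model.config["atp_equivalents"]
    po_n, po_f = cfg["p_o_nadh"], cfg["p_o_fadh2"]
    yields = {}
    for substrate, route in cfg["routes"].items():
        total = 0.0
        for rid, mult in route:
            s = model.reaction(rid).stoichiometry
            total += mult * (
                s.get("ATP_c", 0.0)
                + s.get("ATP_m", 0.0)
                + po_n * (s.get("NADH_c", 0.0) + s.get("NADH_m", 0.0))
                + po_f * s.get("FADH2_m", 0.0)
            )
        yields[substrate] = total
    return yields


def atp_production_rate(model: NetworkModel, fluxes: dict[str, float]) -> float:
    """Total ATP synthesis flux (sum of net ATP-producing reaction fluxes)."""
    total = 0.0
    for r in model.reactions:
        s = r.stoichiometry.get("ATP_c", 0.0) + r.stoichiometry.get("ATP_m", 0.0)
        contrib = s * fluxes[r.id]
        if contrib > 0:
            total += contrib
    return total


def o2_consumption_rate(model: NetworkModel, fluxes: dict[str, float]) -> float:
    return -sum(
        r.stoichiometry.get("O2", 0.0) * fluxes[r.id]
        for r in model.reactions
        if "O2" in r.stoichiometry
    )


def substrate_partition(
    state: SteadyState, yields: dict[str, float], model: NetworkModel
) -> dict[str, float]:
    """Fractional contribution of each substrate class to ATP-equivalent
    production, from uptake fluxes weighted by their full-oxidation yields.

    Net release (negative uptake) does not contribute; fractions sum to 1.
    """
    uptake_cfg = model.config["substrate_uptake"]
    equiv = {}
    for cls in SUBSTRATE_CLASSES:
        flux = sum(state.fluxes[rid] for rid in uptake_cfg[cls])
        equiv[cls] = max(flux, 0.0) * yields[cls]
    total = sum(equiv.values())
    if total <= 0:
        raise SteadyStateError("total ATP-equivalent production is zero; partition undefined")
    return {cls: equiv[cls] / total for cls in SUBSTRATE_CLASSES}


def fa_glc_ratio(partition: dict[str, float]) -> float:
    """Fatty-acid over glucose ATP-equivalents; +inf when glucose use is zero."""
    glc = partition["glucose"]
    if glc <= 0:
        return math.inf
    return partition["fatty_acids"] / glc


def _partition_or_none(state, yields, model):
    try:
        return substrate_partition(state, yields, model)
    except SteadyStateError:
        return None


def workload_ramp(
    patient,
    plasma,
    ramp_factor: float | None = None,
    convergence_eps: float | None = None,
    k_load_rest: float | None = None,
    max_steps: int = 40,
) -> EnergyProfile:
    """Stepwise-increasing ATP demand until ATP production converges.

    ``k_load`` is multiplied by ``ramp_factor`` per step starting from the
    resting demand; each steady state warm-starts from the previous one.  The
    maximal ATP production capacity is the converged production rate; if a
    step fails to converge (e.g. membrane-potential collapse) the capacity is
    taken at the last stable step and flagged in the diagnostics.
    """
    model, scale = _model_and_scale(patient)
    load_cfg = model.config["load"]
    ramp_factor = ramp_factor or load_cfg.get("ramp_factor", 1.25)
    eps = convergence_eps or load_cfg.get("convergence_eps", 1e-3)
    k_load = k_load_rest or load_cfg["k_load_rest"]
    if ramp_factor <= 1.0:
        raise ContractError("ramp schedule must be strictly increasing")

    yields = derive_atp_equivalents(model)
    rest = _solve_steady(model, plasma, scale, k_load, newton_first=False)
    rest_prod = atp_production_rate(model, rest.fluxes)
    rest_part = _partition_or_none(rest, yields, model)
    steps = [
        RampStep(
            k_load,
            rest_prod,
            o2_consumption_rate(model, rest.fluxes),
            rest_part or {c: 0.0 for c in SUBSTRATE_CLASSES},
            fa_glc_ratio(rest_part) if rest_part else math.nan,
        )
    ]
    diagnostics = {"converged": False, "flagged": None, "n_steps": 0}
    y_warm = rest.state_vector
    prev_prod = rest_prod
    for _ in range(max_steps):
        k_load *= ramp_factor
        try:
            ss = _solve_steady(model, plasma, scale, k_load, y0=y_warm)
        except SteadyStateError as exc:
            diagnostics["flagged"] = f"k_load={k_load:.1f} failed: {exc}"
            break
        prod = atp_production_rate(model, ss.fluxes)
        if prod < prev_prod:
            # beyond capacity: production declines under overdrive demand;
            # the converged maximum was reached at the previous step
            diagnostics["converged"] = True
            diagnostics["overdrive"] = {"k_load": k_load, "atp_production": prod}
            break
        part = _partition_or_none(ss, yields, model)
        steps.append(
            RampStep(
                k_load,
                prod,
                o2_consumption_rate(model, ss.fluxes),
                part or {c: 0.0 for c in SUBSTRATE_CLASSES},
                fa_glc_ratio(part) if part else math.nan,
            )
        )
        y_warm = ss.state_vector
        if prev_prod > 0 and (prod - prev_prod) / prev_prod < eps:
            diagnostics["converged"] = True
            prev_prod = max(prod, prev_prod)
            break
        prev_prod = max(prod, prev_prod)
    diagnostics["n_steps"] = len(steps) - 1

    max_capacity = max(s.atp_production for s in steps)
    peak_o2 = max(s.o2_rate for s in steps)
    final = steps[-1]
    atp_per_o2 = final.atp_production / final.o2_rate if final.o2_rate > 0 else math.nan

    partition = {"rest": steps[0].partition}
    prods = np.array([s.atp_production for s in steps])
    order = np.argsort(prods)
    for lvl, frac in zip(PARTITION_LEVELS[1:], (0.25, 0.5, 0.75, 1.0)):
        target = frac * max_capacity
        partition[lvl] = _interp_partition(steps, prods, order, target)
    return EnergyProfile(
        resting_atp_rate=rest_prod,
        max_atp_capacity=max_capacity,
        peak_o2_rate=peak_o2,
        atp_per_o2=atp_per_o2,
        substrate_partition=partition,
        fa_glc_rest=steps[0].fa_glc,
        fa_glc_max=final.fa_glc,
        ramp=steps,
        diagnostics=diagnostics,
    )


def _interp_partition(steps, prods, order, target):
    """Linear interpolation of partition fractions against ATP production."""
    out = {}
    xs = prods[order]
    for cls in SUBSTRATE_CLASSES:
        ys = np.array([steps[i].partition[cls] for i in order])
        out[cls] = float(np.interp(target, xs, ys))
    total = sum(out.values())
    if total > 0:
        out = {c: v / total for c, v in out.items()}
    return out


def respiratory_readouts(profile: EnergyProfile) -> tuple[float, float]:
    """(peak O2 consumption rate, ATP produced per mole O2 at max workload)."""
    if profile.peak_o2_rate <= 0:
        raise SteadyStateError("zero O2 flux; respiratory efficiency undefined")
    return profile.peak_o2_rate, profile.atp_per_o2


def scenario_suite(patient, scenarios) -> dict[str, EnergyProfile | Exception]:
    """Run the workload ramp for each plasma scenario; failures are recorded
    per scenario without aborting the suite.  Deterministic ordering."""
    out = {}
    for plasma in scenarios:
        try:
            out[plasma.name] = workload_ramp(patient, plasma)
        except Exception as exc:  # noqa: BLE001 - propagated per scenario
            out[plasma.name] = exc
    return out


def extract_metabolic_features(profiles: dict[str, dict]) -> "pandas.DataFrame":
    """Fixed-order feature table from per-patient, per-scenario profiles.

    ``profiles`` maps patient id -> {scenario name -> EnergyProfile}.  Missing
    or failed profiles yield NaN features and ``complete = False`` (rows are
    flagged, never dropped).  Column dictionary: ``<scenario>.<readout>`` for
    scalar readouts and ``<scenario>.part_<level>_<class>`` for partitions.
    """
    import pandas as pd

    scenario_names = sorted({s for per in profiles.values() for s in per})
    rows = {}
    for pid, per in profiles.items():
        row = {}
        complete = True
        for sc in scenario_names:
            prof = per.get(sc)
            ok = isinstance(prof, EnergyProfile)
            complete &= ok
            row[f"{sc}.resting_atp_rate"] = prof.resting_atp_rate if ok else np.nan
            row[f"{sc}.max_atp_capacity"] = prof.max_atp_capacity if ok else np.nan
            row[f"{sc}.atp_reserve"] = prof.atp_reserve if ok else np.nan
            row[f"{sc}.peak_o2_rate"] = prof.peak_o2_rate if ok else np.nan
            row[f"{sc}.atp_per_o2"] = prof.atp_per_o2 if ok else np.nan
            row[f"{sc}.fa_glc_rest"] = prof.fa_glc_rest if ok else np.nan
            row[f"{sc}.fa_glc_max"] = prof.fa_glc_max if ok else np.nan
            for lvl in PARTITION_LEVELS:
                for cls in SUBSTRATE_CLASSES:
                    key = f"{sc}.part_{lvl.rstrip('%')}_{cls}"
                    row[key] = prof.substrate_partition[lvl][cls] if ok else np.nan
        row["complete"] = complete
        rows[pid] = row
    return pd.DataFrame.from_dict(rows, orient="index")
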