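"""Target discovery by perturbation (metabolic control analysis).

For each reaction, the capacity (Vmax) is changed by +/-10% and the resting
steady state re-solved; the control coefficient reports the log-change of the
resting fatty-acid/glucose utilisation ratio per unit relative perturbation,

    c = ln(ratio_perturbed / ratio_baseline) / |ln(1 +/- delta)|

Sign convention: positive means the perturbation (in its stated direction)
raises FA/Glc.  In the '+' direction this equals the classical scaled
(log-log) control coefficient.  Cohort ranking uses the absolute mean over
patients; non-convergent perturbations are recorded as missing, never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import NetworkModel
from .simulate import (
    SteadyStateError,
    _model_and_scale,
    _solve_steady,
    derive_atp_equivalents,
    fa_glc_ratio,
    solve_resting_state,
    substrate_partition,
)

__all__ = [
    "ControlCoefficient",
    "ControlTable",
    "control_coefficient",
    "rank_targets",
    "fa_sweep",
    "carnitine_sweep",
]

DEFAULT_DELTA = 0.10
DEFAULT_FA_GRID = np.arange(0.3, 1.01, 0.1)
DEFAULT_CARNITINE_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)
#: relative forward difference below which the carnitine curve is saturated
SATURATION_THRESHOLD = 0.01
#: minimum fraction of patients with a finite coefficient for a reaction
#: to be rankable
MIN_COVERAGE = 0.70


@dataclass(frozen=True)
class ControlCoefficient:
    reaction_id: str
    patient_id: str
    direction: str  # '+10%' | '-10%'
    coefficient: float  # NaN = perturbed state did not converge


@dataclass
class ControlTable:
    """Long-format coefficients plus per-reaction, per-direction ranking."""

    coefficients: pd.DataFrame  # columns: reaction_id, patient_id, direction, coefficient
    summary: pd.DataFrame  # index reaction_id; abs_mean/rank per direction

    def top(self, k: int, direction: str) -> list[str]:
        col = f"rank_{direction}"
        sub = self.summary.dropna(subset=[col]).sort_values(col)
        return list(sub.index[:k])


def _rest_context(patient, plasma, k_load=None):
    model, scale = _model_and_scale(patient)
    if k_load is None:
        k_load = model.config["load"]["k_load_rest"]
    yields = derive_atp_equivalents(model)
    base = _solve_steady(model, plasma, scale, k_load, newton_first=False)
    ratio = fa_glc_ratio(substrate_partition(base, yields, model))
    return model, scale, yields, base, ratio, k_load


def control_coefficient(
    patient,
    plasma,
    reaction_id: str,
    delta: float = DEFAULT_DELTA,
    direction: str = "+",
    _ctx=None,
) -> ControlCoefficient:
    """Scaled control coefficient of the resting FA/Glc ratio with respect to
    one reaction's capacity; the perturbed solve is warm-started from the
    baseline resting state."""
    if direction not in ("+", "-"):
        raise ValueError("direction must be '+' or '-'")
    model, scale, yields, base, r0, k_load = (
        _ctx if _ctx is not None else _rest_context(patient, plasma)
    )
    factor = 1.0 + delta if direction == "+" else 1.0 - delta
    pert = dict(scale or {})
    pert[reaction_id] = pert.get(reaction_id, 1.0) * factor
    pid = getattr(patient, "sample_id", "reference")
    label = f"{direction}{delta:.0%}"
    try:
        ss = _solve_steady(model, plasma, pert, k_load, y0=base.state_vector)
        ratio = fa_glc_ratio(substrate_partition(ss, yields, model))
        c = math.log(ratio / r0) / abs(math.log(factor))
    except (SteadyStateError, ValueError, FloatingPointError):
        c = math.nan
    return ControlCoefficient(reaction_id, pid, label, c)


def rank_targets(
    patients,
    plasma,
    delta: float = DEFAULT_DELTA,
    include_unmapped: bool = False,
    min_coverage: float = MIN_COVERAGE,
) -> ControlTable:
    """Both-direction control screen over a cohort of patient models.

    By default only protein-mapped reactions are ranked (the screen looks for
    druggable protein targets; the ATP load and passive leaks are not).
    Reactions with finite coefficients in fewer than ``min_coverage`` of
    patients are left unranked.  Ranking is by absolute mean coefficient per
    direction, ties broken by reaction id; patient order does not matter.
    """
    if not patients:
        raise ValueError("need at least one patient")
    rows = []
    for patient in patients:
        ctx = _rest_context(patient, plasma)
        model = ctx[0]
        for rxn in model.reactions:
            if not include_unmapped and not rxn.protein_groups:
                continue
            for direction in ("+", "-"):
                cc = control_coefficient(patient, plasma, rxn.id, delta, direction, _ctx=ctx)
                rows.append(
                    {
                        "reaction_id": cc.reaction_id,
                        "patient_id": cc.patient_id,
                        "direction": cc.direction,
                        "coefficient": cc.coefficient,
                    }
                )
    coeffs = pd.DataFrame(rows).sort_values(
        ["reaction_id", "patient_id", "direction"], kind="stable"
    )
    coeffs = coeffs.reset_index(drop=True)

    summary = {}
    n_pat = coeffs["patient_id"].nunique()
    for direction, sub in coeffs.groupby("direction"):
        per_rxn = sub.groupby("reaction_id")["coefficient"]
        abs_mean = per_rxn.apply(lambda s: np.nanmean(np.abs(s)) if s.notna().any() else np.nan)
        signed_mean = per_rxn.mean()
        coverage = per_rxn.apply(lambda s: s.notna().mean())
        abs_mean[coverage < min_coverage] = np.nan
        order = abs_mean.to_frame("abs_mean")
        order["rid"] = order.index
        ranked = order.sort_values(["abs_mean", "rid"], ascending=[False, True], na_position="last")
        rank = pd.Series(np.nan, index=abs_mean.index)
        rank[ranked.index[ranked["abs_mean"].notna()]] = np.arange(
            1, ranked["abs_mean"].notna().sum() + 1
        )
        summary[f"abs_mean_{direction[0]}"] = abs_mean
        summary[f"mean_{direction[0]}"] = signed_mean
        summary[f"coverage_{direction[0]}"] = coverage
        summary[f"rank_{direction[0]}"] = rank
    table = pd.DataFrame(summary)
    table.attrs["n_patients"] = n_pat
    table.attrs["normalization"] = "log-log"
    return ControlTable(coefficients=coeffs, summary=table)


def fa_sweep(patient, plasma, fa_grid=None) -> pd.DataFrame:
    """Resting FA/Glc ratio across a plasma free-fatty-acid grid (mmol/L).

    The curve is expected monotone non-decreasing; violations beyond solver
    noise are flagged in the ``monotone`` attribute, not raised.
    """
    grid = np.asarray(DEFAULT_FA_GRID if fa_grid is None else fa_grid, dtype=float)
    model, scale, yields, base, _, k_load = _rest_context(patient, plasma)
    rows = []
    y0 = base.state_vector
    for fa in grid:
        try:
            ss = _solve_steady(model, plasma.override(fatty_acids=float(fa)), scale, k_load, y0=y0)
            ratio = fa_glc_ratio(substrate_partition(ss, yields, model))
            y0 = ss.state_vector
            rows.append({"fatty_acids": float(fa), "fa_glc": ratio, "converged": True})
        except SteadyStateError:
            rows.append({"fatty_acids": float(fa), "fa_glc": np.nan, "converged": False})
    curve = pd.DataFrame(rows)
    ok = curve["fa_glc"].dropna()
    curve.attrs["monotone"] = bool((np.diff(ok) >= -1e-6 * np.abs(ok[:-1])).all())
    return curve


def carnitine_sweep(
    patient,
    plasma,
    carnitine_grid=DEFAULT_CARNITINE_GRID,
    saturation_threshold: float = SATURATION_THRESHOLD,
) -> pd.DataFrame:
    """Resting FA/Glc versus total mitochondrial carnitine content (mmol/L).

    Each grid point resets the matrix carnitine moiety total and re-solves
    the resting state.  The returned frame carries ``saturation_point`` in its
    attrs: the first grid value whose forward relative difference falls below
    ``saturation_threshold`` (per mmol/L).
    """
    grid = sorted(float(c) for c in carnitine_grid)
    if grid[0] <= 0:
        raise ValueError("carnitine grid must be positive")
    model, scale = _model_and_scale(patient)
    rows = []
    for car in grid:
        m2 = model.copy()
        m2.set_moiety_total("carnitine_matrix", car)
        try:
            ss = _solve_steady(
                m2, plasma, scale, model.config["load"]["k_load_rest"], newton_first=False
            )
            ratio = fa_glc_ratio(substrate_partition(ss, derive_atp_equivalents(m2), m2))
            rows.append({"carnitine": car, "fa_glc": ratio, "converged": True})
        except SteadyStateError:
            rows.append({"carnitine": car, "fa_glc": np.nan, "converged": False})
    curve = pd.DataFrame(rows)
    sat = None
    vals = curve.set_index("carnitine")["fa_glc"]
    for (c1, r1), (c2, r2) in zip(vals.items(), list(vals.items())[1:]):
        if np.isfinite(r1) and np.isfinite(r2):
            if abs(r2 - r1) / (abs(r1) * (c2 - c1)) < saturation_threshold:
                sat = c1
                break
    curve.attrs["saturation_point"] = sat
    return curve
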