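"""Model/Results interface over the simulation machinery.

:class:`MyocardialEnergetics` is the user-facing model object: a kinetic
network (reference or proteomics-personalized) paired with a plasma scenario.
``fit()`` solves the resting state and runs the workload ramp, returning an
:class:`EnergeticsResults` that carries the bioenergetic estimates and
diagnostics; target screens and availability sweeps hang off the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .control import carnitine_sweep, fa_sweep, rank_targets
from .network import NetworkModel, build_reference_model
from .personalize import PatientModel, personalize_cohort
from .plasma import PlasmaProfile, preset_plasma
from .simulate import EnergyProfile, SteadyState, solve_resting_state, workload_ramp

__all__ = ["MyocardialEnergetics", "EnergeticsResults"]


class MyocardialEnergetics:
    """Patient-specific model of myocardial energy metabolism.

    Parameters
    ----------
    patient : NetworkModel or PatientModel
        The kinetic network; a PatientModel carries proteomics-derived
        per-reaction capacity scales on top of the reference network.
    plasma : PlasmaProfile or str
        The scenario (a preset name or a profile object).

    Examples
    --------
    >>> model = MyocardialEnergetics.reference("fasting")
    >>> res = model.fit()
    >>> print(res.summary())           # doctest: +SKIP
    """

    def __init__(self, patient, plasma: PlasmaProfile | str = "fasting"):
        self.patient = patient
        self.plasma = preset_plasma(plasma) if isinstance(plasma, str) else plasma

    @classmethod
    def reference(cls, plasma="fasting", config=None) -> "MyocardialEnergetics":
        """Control-average heart built from the shipped model definition."""
        return cls(build_reference_model(config), plasma)

    @classmethod
    def from_proteomics(
        cls, matrix, sample_id: str, plasma="fasting", model: NetworkModel | None = None
    ) -> "MyocardialEnergetics":
        """Personalize the reference network with one sample of a proteomics
        matrix (after QC and valid-value filtering over the whole cohort)."""
        base = model if model is not None else build_reference_model()
        patients, _, _ = personalize_cohort(base, matrix)
        by_id = {p.sample_id: p for p in patients}
        if sample_id not in by_id:
            raise KeyError(f"sample {sample_id!r} not present after QC filtering")
        return cls(by_id[sample_id], plasma)

    @property
    def network(self) -> NetworkModel:
        return self.patient.base if isinstance(self.patient, PatientModel) else self.patient

    def fit(self, **ramp_kwargs) -> "EnergeticsResults":
        """Solve the resting steady state and run the workload ramp."""
        rest = solve_resting_state(self.patient, self.plasma)
        profile = workload_ramp(self.patient, self.plasma, **ramp_kwargs)
        return EnergeticsResults(model=self, resting_state=rest, profile=profile)


@dataclass
class EnergeticsResults:
    """Fitted bioenergetic readout of one patient under one scenario."""

    model: MyocardialEnergetics
    resting_state: SteadyState
    profile: EnergyProfile
    _screens: dict = field(default_factory=dict, repr=False)

    # -- estimates ---------------------------------------------------------
    @property
    def resting_atp_rate(self) -> float:
        return self.profile.resting_atp_rate

    @property
    def max_atp_capacity(self) -> float:
        return self.profile.max_atp_capacity

    @property
    def atp_reserve(self) -> float:
        return self.profile.atp_reserve

    @property
    def fa_glc_rest(self) -> float:
        return self.profile.fa_glc_rest

    def to_frame(self) -> pd.DataFrame:
        p = self.profile
        rows = {
            "resting_atp_rate": p.resting_atp_rate,
            "max_atp_capacity": p.max_atp_capacity,
            "atp_reserve": p.atp_reserve,
            "peak_o2_rate": p.peak_o2_rate,
            "atp_per_o2": p.atp_per_o2,
            "fa_glc_rest": p.fa_glc_rest,
            "fa_glc_max": p.fa_glc_max,
            "membrane_potential": self.resting_state.membrane_potential,
        }
        return pd.DataFrame({"value": rows})

    def summary(self) -> str:
        """Human-readable summary table of the fitted energetic phenotype."""
        pid = getattr(self.model.patient, "sample_id", "reference")
        p = self.profile
        lines = [
            "      Myocardial Energetics Results",
            "=" * 46,
            f"patient:             {pid}",
            f"scenario:            {self.model.plasma.name}",
            f"converged:           {p.diagnostics.get('converged')}",
            "-" * 46,
            f"resting ATP rate     {p.resting_atp_rate:10.1f} mmol/L/h",
            f"max ATP capacity     {p.max_atp_capacity:10.1f} mmol/L/h",
            f"ATP reserve          {p.atp_reserve:10.1f} mmol/L/h",
            f"peak O2 rate         {p.peak_o2_rate:10.1f} mmol/L/h",
            f"ATP per O2           {p.atp_per_o2:10.2f} mol/mol",
            f"membrane potential   {self.resting_state.membrane_potential:10.1f} mV",
            f"FA/Glc (rest)        {p.fa_glc_rest:10.2f}",
            f"FA/Glc (max)         {p.fa_glc_max:10.2f}",
            "-" * 46,
            "substrate partition at rest:",
        ]
        for cls, frac in p.substrate_partition["rest"].items():
            lines.append(f"  {cls:<18} {100 * frac:6.2f} %")
        return "\n".join(lines)

    # -- follow-up analyses ------------------------------------------------
    def control_screen(self, **kwargs):
        """+/-10% control screen of the resting FA/Glc ratio (this patient)."""
        return rank_targets([self.model.patient], self.model.plasma, **kwargs)

    def sweep_fa(self, fa_grid=None):
        return fa_sweep(self.model.patient, self.model.plasma, fa_grid)

    def sweep_carnitine(self, carnitine_grid=None, **kwargs):
        grid = carnitine_grid
        if grid is None:
            return carnitine_sweep(self.model.patient, self.model.plasma, **kwargs)
        return carnitine_sweep(self.model.patient, self.model.plasma, grid, **kwargs)
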