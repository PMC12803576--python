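"""Synthetic cohort generation.

Emulates the statistical structure the analysis pipeline assumes, so every
stage runs end-to-end without any external download: log-normal label-free
protein intensities with cell-wise missingness, pathway-structured effect
sizes on the metabolic enzymes of heart-failure samples, planted QC
contamination, and LVAD outcome tables statistically coupled to the resting
FA/Glc ratio.  All generation is seeded; identical seeds give identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from .network import NetworkModel
from .personalize import ProteomicsMatrix
from .plasma import preset_plasma  # re-exported scenario presets

__all__ = ["CohortSpec", "generate_proteomics", "generate_outcomes", "preset_plasma"]

#: fixture convention reproducing the direction of the heart-failure shift:
#: beta-oxidation capacity down (~x0.6), glucose uptake/glycolysis up (~x1.3)
DEFAULT_HF_EFFECTS = {
    "FA_oxidation": {"log_fold": math.log(0.6), "sd": 0.10},
    "glycolysis": {"log_fold": math.log(1.3), "sd": 0.08},
}


@dataclass
class CohortSpec:
    """Generator settings for one synthetic cohort.

    ``outcome_slope`` / ``outcome_noise_sd`` couple the resting FA/Glc ratio
    to the absolute change in LVEF (percentage points per ratio unit);
    ``lvedd_slope`` couples it (positively) to the relative LVEDd reduction.
    """

    n_control: int = 20
    n_hf: int = 20
    seed: int = 0
    missing_rate: float = 0.08
    intensity_log_mean_range: tuple[float, float] = (12.0, 18.0)
    intensity_log_sd: float = 0.25
    hf_effects: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HF_EFFECTS.items()})
    qc_violation_fraction: float = 0.10
    n_background_proteins: int = 150
    outcome_intercept: float = -15.0
    outcome_slope: float = 10.0
    outcome_noise_sd: float = 2.0
    lvedd_intercept: float = -0.05
    lvedd_slope: float = 0.09
    lvedd_noise_sd: float = 0.025

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_hf < 1:
            raise ValueError("need at least one sample per group")
        if not 0 <= self.missing_rate <= 1 or not 0 <= self.qc_violation_fraction <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory; unseeded generation is not supported")


def _pathway_proteins(model: NetworkModel) -> dict[str, set]:
    out: dict[str, set] = {}
    for rxn in model.reactions:
        for pg in rxn.protein_groups:
            out.setdefault(rxn.pathway_tag, set()).add(pg)
    return out


def generate_proteomics(spec: CohortSpec, model: NetworkModel) -> ProteomicsMatrix:
    """Draw a proteomics matrix for ``spec`` against a model's protein map.

    Protein intensities are log-normal with protein-specific log-means; HF
    samples receive multiplicative pathway effects (drawn per patient and
    protein, so cohorts are heterogeneous); missingness is cell-wise; a
    configured fraction of samples gets planted haemoglobin/collagen QC
    violations.
    """
    rng = np.random.default_rng(spec.seed)
    mapped = sorted({pg for r in model.reactions for pg in r.protein_groups})
    background = [f"BG{i:04d}" for i in range(spec.n_background_proteins)]
    proteins = mapped + background
    by_pathway = _pathway_proteins(model)
    effect_of: dict[str, dict] = {}
    for tag, eff in (spec.hf_effects or {}).items():
        for pg in by_pathway.get(tag, ()):
            effect_of[pg] = eff

    lo, hi = spec.intensity_log_mean_range
    log_mu = rng.uniform(lo, hi, size=len(proteins))
    sample_ids = [f"C{i:03d}" for i in range(spec.n_control)] + [
        f"H{i:03d}" for i in range(spec.n_hf)
    ]
    groups = ["control"] * spec.n_control + ["HF"] * spec.n_hf

    data = np.empty((len(proteins), len(sample_ids)))
    for j, grp in enumerate(groups):
        logs = log_mu + rng.normal(0.0, spec.intensity_log_sd, size=len(proteins))
        if grp == "HF":
            for i, pg in enumerate(proteins):
                eff = effect_of.get(pg)
                if eff is not None:
                    logs[i] += rng.normal(eff["log_fold"], eff.get("sd", 0.0))
        data[:, j] = np.exp(logs)
    if spec.missing_rate > 0:
        mask = rng.random(data.shape) < spec.missing_rate
        data = np.where(mask, np.nan, data)

    hb = rng.uniform(0.0, 0.04, size=len(sample_ids))
    col = rng.uniform(0.0, 0.04, size=len(sample_ids))
    n_bad = int(round(spec.qc_violation_fraction * len(sample_ids)))
    if n_bad:
        bad = rng.choice(len(sample_ids), size=n_bad, replace=False)
        which = rng.random(n_bad) < 0.5
        hb[bad[which]] = rng.uniform(0.05, 0.30, size=which.sum())
        col[bad[~which]] = rng.uniform(0.05, 0.30, size=(~which).sum())

    intens = pd.DataFrame(data, index=proteins, columns=sample_ids)
    samples = pd.DataFrame(
        {"group": groups, "haemoglobin_fraction": hb, "collagen_fraction": col},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ProteomicsMatrix(intens, samples, provenance=f"synthetic cohort, seed={spec.seed}")


def generate_outcomes(
    patient_ids, faglc_values, spec: CohortSpec, seed: int | None = None
) -> pd.DataFrame:
    """LVAD outcome table coupled to per-patient resting FA/Glc ratios.

    delta-LVEF = intercept + slope * FA/Glc + Gaussian noise (clipped to
    physiologic bounds); the relative LVEDd reduction is generated analogously
    with positive coupling (higher FA/Glc, larger reduction).
    """
    patient_ids = list(patient_ids)
    faglc = np.asarray(list(faglc_values), dtype=float)
    if len(patient_ids) != len(faglc):
        raise ValueError("one FA/Glc value per patient required")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    n = len(patient_ids)

    lvef_pre = np.clip(rng.normal(20.0, 5.0, n), 5.0, 35.0)
    d_lvef = spec.outcome_intercept + spec.outcome_slope * faglc + rng.normal(
        0.0, spec.outcome_noise_sd, n
    )
    lvef_post = np.clip(lvef_pre + d_lvef, 0.0, 100.0)

    lvedd_pre = np.clip(rng.normal(70.0, 6.0, n), 45.0, 95.0)
    rel_red = spec.lvedd_intercept + spec.lvedd_slope * faglc + rng.normal(
        0.0, spec.lvedd_noise_sd, n
    )
    rel_red = np.clip(rel_red, -0.2, 0.6)
    lvedd_post = lvedd_pre * (1.0 - rel_red)

    weeks = np.clip(rng.lognormal(math.log(42.0), 0.6, n), 4.0, 200.0)
    return pd.DataFrame(
        {
            "patient_id": patient_ids,
            "lvef_pre": lvef_pre,
            "lvef_post": lvef_post,
            "lvedd_pre": lvedd_pre,
            "lvedd_post": lvedd_post,
            "weeks_to_followup": weeks,
        }
    )
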