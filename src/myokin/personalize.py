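"""Proteomics-based model personalization.

Turns a label-free proteomics intensity matrix into patient-specific models:
sample quality control (haemoglobin / collagen contamination), valid-value
filtering of protein groups, control-reference computation, and scaling of
per-reaction capacities

    Vmax_subject = Vmax_reference * E_subject / E_control

where E is the summed intensity of the protein groups mapped to a reaction,
E_control the mean over control samples.  Missing values are imputed from
group averages, or assumed unchanged from controls when a protein group has
no data at all; the imputation path is logged per reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import NetworkModel

__all__ = [
    "ProteomicsMatrix",
    "ControlReference",
    "PatientModel",
    "qc_filter_samples",
    "filter_valid_proteins",
    "compute_control_reference",
    "scale_vmax",
    "personalize_cohort",
]

#: printed thresholds: samples with <5% haemoglobin AND <5% collagen are kept
HB_MAX = 0.05
COLLAGEN_MAX = 0.05
#: protein groups with more than 70% valid values are retained
MIN_VALID_FRACTION = 0.70


@dataclass
class ProteomicsMatrix:
    """Intensity matrix (protein groups x samples) with sample metadata.

    ``intensities``: DataFrame, rows protein-group ids, columns sample ids,
    NaN encoding missing values.  ``samples``: DataFrame indexed by sample id
    with columns ``group`` ('control' | 'HF'), ``haemoglobin_fraction`` and
    ``collagen_fraction``.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValueError("sample metadata must match intensity columns")
        bad = self.samples[
            (self.samples["haemoglobin_fraction"] < 0)
            | (self.samples["haemoglobin_fraction"] > 1)
            | (self.samples["collagen_fraction"] < 0)
            | (self.samples["collagen_fraction"] > 1)
        ]
        if len(bad):
            raise ValueError(f"QC fractions outside [0,1] for {list(bad.index)}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative intensities")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def group_ids(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])

    def to_tsv(self, intensity_path, sidecar_path) -> None:
        self.intensities.to_csv(intensity_path, sep="\t", index_label="protein_group")
        self.samples.to_csv(sidecar_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, intensity_path, sidecar_path, provenance="") -> "ProteomicsMatrix":
        inten = pd.read_csv(intensity_path, sep="\t", index_col="protein_group")
        samples = pd.read_csv(sidecar_path, sep="\t", index_col="sample_id")
        samples.index = samples.index.astype(str)
        inten.columns = inten.columns.astype(str)
        return cls(inten, samples, provenance)


@dataclass
class ControlReference:
    """Mean intensity per protein group over the control samples."""

    mean_intensity: pd.Series
    n_controls: pd.Series
    excluded: list[str] = field(default_factory=list)

    def __contains__(self, pg: str) -> bool:
        return pg in self.mean_intensity.index


@dataclass
class PatientModel:
    """A network model with per-reaction Vmax scales for one sample."""

    base: NetworkModel
    vmax_scale: dict[str, float]
    sample_id: str
    imputation_log: dict[str, str]

    def __post_init__(self) -> None:
        for rid, s in self.vmax_scale.items():
            if not s > 0:
                raise ValueError(f"{self.sample_id}: non-positive scale for {rid}")


def qc_filter_samples(
    matrix: ProteomicsMatrix,
    hb_max: float = HB_MAX,
    col_max: float = COLLAGEN_MAX,
) -> tuple[ProteomicsMatrix, pd.DataFrame]:
    """Keep samples with haemoglobin and collagen fractions strictly below
    the thresholds; returns the filtered matrix and a rejection report."""
    meta = matrix.samples
    keep = (meta["haemoglobin_fraction"] < hb_max) & (meta["collagen_fraction"] < col_max)
    reasons = []
    for sid in meta.index[~keep]:
        why = []
        if meta.loc[sid, "haemoglobin_fraction"] >= hb_max:
            why.append(f"haemoglobin {meta.loc[sid, 'haemoglobin_fraction']:.3f} >= {hb_max}")
        if meta.loc[sid, "collagen_fraction"] >= col_max:
            why.append(f"collagen {meta.loc[sid, 'collagen_fraction']:.3f} >= {col_max}")
        reasons.append({"sample_id": sid, "reason": "; ".join(why)})
    report = pd.DataFrame(reasons, columns=["sample_id", "reason"])
    kept_ids = list(meta.index[keep])
    if not kept_ids:
        raise ValueError("QC filter rejected every sample")
    return (
        ProteomicsMatrix(matrix.intensities[kept_ids], meta.loc[kept_ids], matrix.provenance),
        report,
    )


def filter_valid_proteins(
    matrix: ProteomicsMatrix, min_valid_frac: float = MIN_VALID_FRACTION
) -> ProteomicsMatrix:
    """Retain protein groups whose valid-value fraction across all samples is
    strictly greater than ``min_valid_frac`` (idempotent)."""
    frac = matrix.intensities.notna().mean(axis=1)
    kept = matrix.intensities.index[frac > min_valid_frac]
    return ProteomicsMatrix(matrix.intensities.loc[kept], matrix.samples, matrix.provenance)


def compute_control_reference(
    matrix: ProteomicsMatrix, control_ids: list[str] | None = None
) -> ControlReference:
    """Arithmetic mean over valid control values per protein group; groups
    with no valid control value are excluded (and listed)."""
    if control_ids is None:
        control_ids = matrix.group_ids("control")
    if not control_ids:
        raise ValueError("need at least one control sample")
    ctrl = matrix.intensities[list(control_ids)]
    n_valid = ctrl.notna().sum(axis=1)
    mean = ctrl.mean(axis=1, skipna=True)
    excluded = list(mean.index[n_valid == 0])
    keep = n_valid > 0
    return ControlReference(mean[keep], n_valid[keep], excluded)


def _resolve_intensity(pg, sample_col, group_mean, reference):
    """(value, tier) for one protein group: measured -> group average ->
    unchanged-from-controls."""
    v = sample_col.get(pg, np.nan)
    if np.isfinite(v):
        return v, "measured"
    g = group_mean.get(pg, np.nan)
    if np.isfinite(g):
        return g, "group_average"
    return reference.mean_intensity.get(pg, np.nan), "control_default"


def scale_vmax(
    model: NetworkModel,
    matrix: ProteomicsMatrix,
    sample_id: str,
    reference: ControlReference,
) -> PatientModel:
    """Build a :class:`PatientModel` for one sample.

    Per reaction, E_subject sums the sample's intensities over the mapped
    protein groups and E_control the same sum over the control reference;
    the Vmax scale is their ratio.  Missing protein values are imputed from
    the sample's own cohort-group average; protein groups absent from the
    whole cohort contribute their control-reference value (scale-neutral).
    Reactions with no mapped protein group keep scale exactly 1.
    """
    if sample_id not in matrix.samples.index:
        raise KeyError(sample_id)
    group = matrix.samples.loc[sample_id, "group"]
    group_mean = matrix.intensities[matrix.group_ids(group)].mean(axis=1, skipna=True)
    sample_col = matrix.intensities[sample_id]

    scales: dict[str, float] = {}
    log: dict[str, str] = {}
    for rxn in model.reactions:
        if not rxn.protein_groups:
            scales[rxn.id] = 1.0
            log[rxn.id] = "control_default"
            continue
        e_subj = 0.0
        e_ctrl = 0.0
        tiers = []
        for pg in rxn.protein_groups:
            ref_val = reference.mean_intensity.get(pg, np.nan)
            if not np.isfinite(ref_val):
                # protein group missing in the whole cohort: assumed
                # unchanged from controls (neutral contribution)
                tiers.append("control_default")
                continue
            val, tier = _resolve_intensity(pg, sample_col, group_mean, reference)
            e_subj += val
            e_ctrl += ref_val
            tiers.append(tier)
        if e_ctrl == 0.0:
            if all(t == "control_default" for t in tiers):
                scales[rxn.id] = 1.0
                log[rxn.id] = "control_default"
                continue
            raise ValueError(
                f"reaction {rxn.id}: zero control reference for mapped proteins "
                "(should have been removed by the valid-value filter)"
            )
        scales[rxn.id] = e_subj / e_ctrl
        if all(t == "measured" for t in tiers):
            log[rxn.id] = "measured"
        elif all(t == "control_default" for t in tiers):
            log[rxn.id] = "control_default"
        else:
            log[rxn.id] = "group_average"
    return PatientModel(base=model, vmax_scale=scales, sample_id=sample_id, imputation_log=log)


def personalize_cohort(
    model: NetworkModel,
    matrix: ProteomicsMatrix,
    hb_max: float = HB_MAX,
    col_max: float = COLLAGEN_MAX,
    min_valid_frac: float = MIN_VALID_FRACTION,
) -> tuple[list[PatientModel], pd.DataFrame, ControlReference]:
    """QC filter -> valid-value filter -> control reference -> per-sample
    scaling, in the order the analysis pipeline applies them."""
    kept, report = qc_filter_samples(matrix, hb_max, col_max)
    kept = filter_valid_proteins(kept, min_valid_frac)
    reference = compute_control_reference(kept)
    patients = [scale_vmax(model, kept, sid, reference) for sid in kept.sample_ids]
    return patients, report, reference
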