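import numpy as np
import pytest

import myokin
from myokin.network import Compartment, MetabolitePool, NetworkModel, RateLaw, Reaction


@pytest.fixture(scope="session")
def reference_model():
    return myokin.build_reference_model()


@pytest.fixture(scope="session")
def fasting():
    return myokin.preset_plasma("fasting")


@pytest.fixture(scope="session")
def resting_state(reference_model, fasting):
    return myokin.solve_resting_state(reference_model, fasting)


@pytest.fixture(scope="session")
def reference_profile(reference_model, fasting):
    return myokin.workload_ramp(reference_model, fasting)


@pytest.fixture(scope="session")
def yields(reference_model):
    return myokin.derive_atp_equivalents(reference_model)


@pytest.fixture(scope="session")
def small_cohort(reference_model):
    """Seeded 6+6 synthetic cohort personalized against the reference."""
    spec = myokin.CohortSpec(n_control=6, n_hf=6, seed=11)
    matrix = myokin.generate_proteomics(spec, reference_model)
    patients, report, reference = myokin.personalize_cohort(reference_model, matrix)
    return {"spec": spec, "matrix": matrix, "patients": patients,
            "report": report, "reference": reference}


def make_toy_chain(vmaxes=(2.0, 3.0, 4.0), keqs=(5.0, 4.0, 10.0), s_ext=2.0, p_ext=0.05):
    """Three-reaction linear chain S -> A -> B -> P (reversible MM), one
    compartment, no membrane potential, no conserved moieties."""
    comps = {
        "extracellular": Compartment("extracellular", 1.0),
        "cytosol": Compartment("cytosol", 1.0),
    }
    pools = {
        "S": MetabolitePool("S", "extracellular", s_ext, is_boundary=True),
        "A": MetabolitePool("A", "cytosol", 0.5),
        "B": MetabolitePool("B", "cytosol", 0.5),
        "P": MetabolitePool("P", "extracellular", p_ext, is_boundary=True),
    }
    specs = [("R1", "S", "A"), ("R2", "A", "B"), ("R3", "B", "P")]
    reactions = [
        Reaction(
            id=rid,
            stoichiometry={sub: -1, prod: 1},
            compartment="cytosol",
            rate_law=RateLaw(
                "reversible_mm",
                {"substrates": {sub: 1.0}, "products": {prod: 1.0}, "keq": keq},
            ),
            vmax=v,
            protein_groups=[f"ENZ_{rid}"],
            pathway_tag="transport",
        )
        for (rid, sub, prod), v, keq in zip(specs, vmaxes, keqs)
    ]
    return NetworkModel(
        compartments=comps,
        pools=pools,
        reactions=reactions,
        moieties=[],
        config={"load": {"k_load_rest": 1.0}},
    )


@pytest.fixture()
def toy_chain():
    return make_toy_chain()


def toy_chain_rate(v, keq, s, p, km_s=1.0, km_p=1.0):
    """Independent re-statement of the reversible MM law used by the chain
    oracle (kept separate from the package implementation)."""
    a, b = s / km_s, p / km_p
    return v * (a - b / (keq * km_s / km_p)) / ((1 + a) + (1 + b) - 1)


def hf_like_scale(model, fa_factor=0.6, glc_factor=1.3):
    """Pathway-structured capacity scaling mimicking a failing heart; only
    protein-mapped reactions are scaled, as personalization would."""
    out = {}
    for r in model.reactions:
        if not r.protein_groups:
            continue
        if r.pathway_tag == "FA_oxidation":
            out[r.id] = fa_factor
        elif r.pathway_tag == "glycolysis":
            out[r.id] = glc_factor
    return out


class FakePatient:
    """Minimal PatientModel stand-in: a base network plus vmax scales."""

    def __init__(self, base, vmax_scale, sample_id="synthetic"):
        self.base = base
        self.vmax_scale = vmax_scale
        self.sample_id = sample_id


@pytest.fixture(scope="session")
def hf_patient(reference_model):
    return FakePatient(reference_model, hf_like_scale(reference_model), "hf_like")
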