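"""Reduced kinetic network of cardiomyocyte energy metabolism.

The model represents the catabolism of fatty acids, glucose, lactate/pyruvate,
ketone bodies and branched-chain amino acids (BCAA) down to oxidative
phosphorylation, with one lumped reaction per canonical step group.  It keeps
a four-compartment layout (extracellular, cytosol, mitochondrial matrix,
intermembrane space), an explicit carnitine shuttle, mitochondrial
electrophysiology (membrane potential as a state variable, proton/potassium
fluxes through Goldman-Hodgkin-Katz electrodiffusion), and short-term hormonal
regulation (insulin on GLUT4, catecholamines on configured phosphorylation
targets).

Concentrations are mmol per litre of compartment water; reaction fluxes are
mmol per litre cell per hour, so the ODE right-hand side applies a
compartment-volume correction ``dC_i/dt = (N v)_i / vol_i``.  Conserved
moieties (adenine nucleotides, NAD(H), FAD(H2), CoA and carnitine pools per
compartment) are declared explicitly and validated against the left null
space of the stoichiometric matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import yaml

__all__ = [
    "Compartment",
    "MetabolitePool",
    "RateLaw",
    "Reaction",
    "Moiety",
    "LoadParameters",
    "NetworkModel",
    "build_reference_model",
    "load_model_config",
    "reversible_mm_rate",
    "ghk_ion_flux",
    "atp_load_rate",
    "thermal_voltage_mv",
    "ModelStructureError",
    "UnknownMetaboliteError",
    "EvaluationError",
    "ContractError",
]

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/mol/K

#: below this |zFV/RT| the GHK flux switches to its first-order expansion
GHK_SERIES_THRESHOLD = 1e-4


class ModelStructureError(ValueError):
    """A reaction violates conservation structure (moiety / carbon / phosphate)."""


class UnknownMetaboliteError(KeyError):
    """A reaction or rate law references a metabolite id that does not exist."""


class EvaluationError(RuntimeError):
    """A rate law could not be evaluated (missing modifier, bad state)."""


class ContractError(ValueError):
    """Caller violated an interface contract (dimension mismatch etc.)."""


def thermal_voltage_mv(temperature: float) -> float:
    """RT/F in millivolts (~26.73 mV at 310 K)."""
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY


@dataclass(frozen=True)
class Compartment:
    id: str
    volume_fraction: float

    def __post_init__(self) -> None:
        if self.volume_fraction <= 0:
            raise ModelStructureError(
                f"compartment {self.id}: volume fraction must be positive"
            )


@dataclass
class MetabolitePool:
    """A metabolite in one compartment.

    ``is_boundary`` pools are clamped (to the plasma profile or a fixed
    config value) and never appear on the left-hand side of the ODE system.
    ``carbon``/``phosphorus`` feed the per-reaction element bookkeeping.
    """

    id: str
    compartment: str
    concentration: float
    is_boundary: bool = False
    charge: int = 0
    carbon: int = 0
    phosphorus: int = 0

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ModelStructureError(f"pool {self.id}: negative concentration")


@dataclass
class RateLaw:
    """Kinetic rate law of one (possibly lumped) reaction.

    kinds
    -----
    reversible_mm
        Generalised reversible Michaelis-Menten with a Haldane-consistent
        numerator (net rate is zero exactly at mass-action ratio = Keq) and
        multiplicative allosteric modifier factors.
    hill_allosteric
        Irreversible multiplicative saturation kinetics with optional Hill
        exponents, allosteric modifiers and a membrane-potential gate
        (used for the respiratory chain and the ATP synthase).
    ghk_ion_flux
        Goldman-Hodgkin-Katz electrodiffusion; ``vmax`` is the permeability.
    atp_load
        Generic hyperbolic ATP demand v = k_load * ATP / (ATP + Km).
    antiporter
        1:1 exchanger (ANT, carnitine translocase) with an optional
        membrane-potential-dependent equilibrium constant.
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = {"reversible_mm", "hill_allosteric", "ghk_ion_flux", "atp_load", "antiporter"}
        if self.kind not in kinds:
            raise ModelStructureError(f"unknown rate law kind {self.kind!r}")
        for key in ("substrates", "products"):
            for met, km in (self.params.get(key) or {}).items():
                km_val = km["km"] if isinstance(km, dict) else km
                if km_val <= 0:
                    raise ModelStructureError(f"Km for {met} must be positive")
        for mod in self.params.get("modifiers") or []:
            if mod.get("k", 1.0) <= 0:
                raise ModelStructureError("modifier Ka/Ki must be positive")
            if mod.get("hill", 1.0) < 1.0:
                raise ModelStructureError("Hill coefficient must be >= 1")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    compartment: str
    rate_law: RateLaw
    vmax: float
    protein_groups: list[str] = field(default_factory=list)
    pathway_tag: str = "transport"
    #: positive charge moved out of the mitochondrial matrix per unit flux
    charge_transfer: float = 0.0
    #: inorganic phosphate released to the clamped Pi pool per unit flux
    pi_release: float = 0.0

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ModelStructureError(f"reaction {self.id}: vmax must be >= 0")


@dataclass
class Moiety:
    """Named conserved pool (fixed total within one compartment)."""

    name: str
    members: list[str]
    total: float


@dataclass
class LoadParameters:
    """Hyperbolic ATP demand: v = k_load * ATP / (ATP + km_atp)."""

    k_load: float
    km_atp: float = 0.5

    def __post_init__(self) -> None:
        if self.k_load <= 0 or self.km_atp <= 0:
            raise ModelStructureError("load parameters must be positive")


# ---------------------------------------------------------------------------
# elementary rate laws
# ---------------------------------------------------------------------------

def atp_load_rate(load: LoadParameters, atp: float) -> float:
    """ATP consumption rate; 0 <= v < k_load, strictly increasing in ATP."""
    if atp < 0:
        raise EvaluationError("ATP concentration must be >= 0")
    return load.k_load * atp / (atp + load.km_atp)


def ghk_ion_flux(
    permeability: float,
    charge: int,
    voltage: float,
    c_in: float,
    c_out: float,
    temperature: float = 310.0,
) -> float:
    """Goldman-Hodgkin-Katz flux (efflux positive, i.e. in -> out).

    ``voltage`` is the inside-minus-outside membrane potential in mV.  At the
    Nernst potential the flux vanishes; in the limit voltage -> 0 the flux is
    continuous and reduces to Fick diffusion ``P (c_in - c_out)`` (a
    first-order series expansion is used below ``GHK_SERIES_THRESHOLD``).
    """
    if charge == 0:
        raise ContractError("GHK flux requires a charged species")
    u = charge * voltage / thermal_voltage_mv(temperature)
    if abs(u) < GHK_SERIES_THRESHOLD:
        return permeability * ((c_in - c_out) + 0.5 * u * (c_in + c_out))
    u = min(max(u, -500.0), 500.0)
    return permeability * u * (c_in - c_out * math.exp(-u)) / (-math.expm1(-u))


def _modifier_factor(modifiers: list[dict] | None, conc: Callable[[str], float]) -> float:
    factor = 1.0
    for mod in modifiers or []:
        c = mod["const"] if "const" in mod else conc(mod["met"])
        h = mod.get("hill", 1.0)
        x = (c / mod["k"]) ** h
        role = mod["role"]
        if role == "inhibitor":
            factor *= 1.0 / (1.0 + x)
        elif role == "activator":
            beta = mod.get("beta")
            if beta is None:
                factor *= x / (1.0 + x)
            else:
                factor *= 1.0 + beta * x / (1.0 + x)
        else:
            raise EvaluationError(f"unknown modifier role {role!r}")
    return factor


def reversible_mm_rate(reaction: Reaction, concentrations: dict[str, float]) -> float:
    """Generalised reversible Michaelis-Menten flux of ``reaction``.

    Haldane-consistent: the net rate is zero exactly when the mass-action
    ratio of the species named in the rate law equals Keq, and saturates at
    ``vmax`` (times the allosteric factor) for substrates >> Km, products = 0.
    """
    law = reaction.rate_law
    if law.kind != "reversible_mm":
        raise ContractError(f"{reaction.id} is not reversible_mm")

    def conc(met: str) -> float:
        try:
            return max(concentrations[met], 0.0)
        except KeyError as exc:
            raise EvaluationError(f"{reaction.id}: missing concentration for {met}") from exc

    subs = law.params["substrates"]
    prods = law.params["products"]
    keq = law.params.get("keq", 1.0)
    a = 1.0
    d_s = 1.0
    km_s = 1.0
    for met, km in subs.items():
        x = conc(met) / km
        a *= x
        d_s *= 1.0 + x
        km_s *= km
    b = 1.0
    d_p = 1.0
    km_p = 1.0
    for met, km in prods.items():
        x = conc(met) / km
        b *= x
        d_p *= 1.0 + x
        km_p *= km
    keq_hat = keq * km_s / km_p
    factor = _modifier_factor(law.params.get("modifiers"), conc)
    return reaction.vmax * factor * (a - b / keq_hat) / (d_s + d_p - 1.0)


def _hill_rate(reaction: Reaction, conc: Callable[[str], float], psi: float | None) -> float:
    law = reaction.rate_law
    v = 1.0
    for met, spec in law.params.get("substrates", {}).items():
        if isinstance(spec, dict):
            km, h = spec["km"], spec.get("hill", 1.0)
        else:
            km, h = spec, 1.0
        x = conc(met) ** h
        v *= x / (km ** h + x)
    v *= _modifier_factor(law.params.get("modifiers"), conc)
    gate = law.params.get("voltage_gate")
    if gate is not None:
        if psi is None:
            raise EvaluationError(f"{reaction.id}: voltage gate requires membrane potential")
        z = (psi - gate["v_half"]) / gate["slope"]
        z = min(max(z, -60.0), 60.0)
        sig = 1.0 / (1.0 + math.exp(-z))
        v *= sig if gate["mode"] == "activation" else 1.0 - sig
    return reaction.vmax * v


def _antiporter_rate(
    reaction: Reaction, conc: Callable[[str], float], psi: float | None, temperature: float
) -> float:
    p = reaction.rate_law.params
    xm, xc = p["export"]  # species exported matrix -> cytosol
    yc, ym = p["import"]  # species imported cytosol -> matrix
    fwd = (conc(xm) / (conc(xm) + p["km_export_m"])) * (conc(yc) / (conc(yc) + p["km_import_c"]))
    rev = (conc(xc) / (conc(xc) + p["km_export_c"])) * (conc(ym) / (conc(ym) + p["km_import_m"]))
    keq = p.get("keq0", 1.0)
    if p.get("psi_coupled", False):
        if psi is None:
            raise EvaluationError(f"{reaction.id}: psi-coupled antiporter needs membrane potential")
        u = psi / thermal_voltage_mv(temperature)
        keq *= math.exp(min(max(-reaction.charge_transfer * u, -500.0), 500.0))
    return reaction.vmax * (fwd - rev / keq)


# ---------------------------------------------------------------------------
# the network model
# ---------------------------------------------------------------------------

class NetworkModel:
    """Validated reaction network with ODE right-hand side.

    The state vector is the concentrations of all non-boundary pools followed
    by the mitochondrial membrane potential (if the model declares membrane
    charge fluxes).
    """

    def __init__(
        self,
        compartments: dict[str, Compartment],
        pools: dict[str, MetabolitePool],
        reactions: list[Reaction],
        moieties: list[Moiety],
        temperature: float = 310.0,
        capacitance: float = 1e-3,
        psi_init: float = 170.0,
        config: dict | None = None,
    ) -> None:
        self.compartments = compartments
        self.pools = pools
        self.reactions = reactions
        self.moieties = moieties
        self.temperature = temperature
        self.capacitance = capacitance
        self.psi_init = psi_init
        self.config = config or {}

        self.state_ids = [p.id for p in pools.values() if not p.is_boundary]
        self.boundary_ids = [p.id for p in pools.values() if p.is_boundary]
        self.has_membrane_potential = any(r.charge_transfer != 0.0 for r in reactions)
        self._index = {pid: i for i, pid in enumerate(self.state_ids)}
        self._validate()
        self._vols = np.array(
            [compartments[pools[pid].compartment].volume_fraction for pid in self.state_ids]
        )
        # dense stoichiometric matrix over non-boundary pools
        self.N = np.zeros((len(self.state_ids), len(reactions)))
        for j, rxn in enumerate(reactions):
            for met, coeff in rxn.stoichiometry.items():
                if met in self._index:
                    self.N[self._index[met], j] = coeff
        self.charge_vector = np.array([r.charge_transfer for r in reactions])

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        intra = [c for c in self.compartments.values() if c.id != "extracellular"]
        if abs(sum(c.volume_fraction for c in intra) - 1.0) > 1e-9:
            raise ModelStructureError("intracellular volume fractions must sum to 1")
        known = set(self.pools)
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in known:
                    raise UnknownMetaboliteError(f"reaction {rxn.id}: unknown metabolite {met!r}")
            for key in ("substrates", "products"):
                for met in rxn.rate_law.params.get(key) or {}:
                    if isinstance(met, str) and met not in known:
                        raise UnknownMetaboliteError(
                            f"reaction {rxn.id}: rate law references unknown {met!r}"
                        )
            carbon = sum(
                coeff * self.pools[met].carbon for met, coeff in rxn.stoichiometry.items()
            )
            if abs(carbon) > 1e-9:
                raise ModelStructureError(
                    f"reaction {rxn.id}: carbon imbalance ({carbon:+g} C per unit flux)"
                )
            phos = (
                sum(coeff * self.pools[met].phosphorus for met, coeff in rxn.stoichiometry.items())
                + rxn.pi_release
            )
            if abs(phos) > 1e-9:
                raise ModelStructureError(
                    f"reaction {rxn.id}: phosphate imbalance ({phos:+g} P per unit flux)"
                )
        for moiety in self.moieties:
            for met in moiety.members:
                if met not in known:
                    raise UnknownMetaboliteError(f"moiety {moiety.name}: unknown pool {met!r}")
                if self.pools[met].is_boundary:
                    raise ModelStructureError(
                        f"moiety {moiety.name}: boundary pool {met} cannot be conserved"
                    )
            comps = {self.pools[m].compartment for m in moiety.members}
            if len(comps) != 1:
                raise ModelStructureError(
                    f"moiety {moiety.name} spans compartments {comps}; totals would not "
                    "be conserved in concentration units"
                )
            for rxn in self.reactions:
                s = sum(rxn.stoichiometry.get(m, 0.0) for m in moiety.members)
                if abs(s) > 1e-9:
                    raise ModelStructureError(
                        f"reaction {rxn.id} breaks moiety {moiety.name!r} "
                        f"(net stoichiometry {s:+g}); moiety vector not in left null space"
                    )

    # -- state handling ----------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.state_ids) + (1 if self.has_membrane_potential else 0)

    def initial_state(self) -> np.ndarray:
        y = np.array([self.pools[pid].concentration for pid in self.state_ids])
        if self.has_membrane_potential:
            y = np.append(y, self.psi_init)
        return y

    def split_state(self, y: np.ndarray) -> tuple[np.ndarray, float | None]:
        if y.shape[0] != self.n_states:
            raise ContractError(
                f"state dimension {y.shape[0]} does not match model ({self.n_states})"
            )
        if self.has_membrane_potential:
            return y[:-1], float(y[-1])
        return y, None

    def moiety_totals(self, y: np.ndarray) -> dict[str, float]:
        conc, _ = self.split_state(y)
        return {
            m.name: float(sum(conc[self._index[mem]] for mem in m.members))
            for m in self.moieties
        }

    def set_moiety_total(self, name: str, total: float) -> None:
        """Rescale the member pools of a moiety to a new total (e.g. the
        carnitine sweep resets total mitochondrial carnitine)."""
        if total <= 0:
            raise ContractError("moiety total must be positive")
        for m in self.moieties:
            if m.name == name:
                old = sum(self.pools[mem].concentration for mem in m.members)
                for mem in m.members:
                    self.pools[mem].concentration *= total / old
                m.total = total
                return
        raise KeyError(name)

    # -- kinetics ----------------------------------------------------------

    def _regulation_multipliers(self, plasma) -> np.ndarray:
        """Per-reaction hormonal multipliers (insulin on GLUT4,
        catecholamines on the configured phosphorylation targets)."""
        mult = np.ones(len(self.reactions))
        reg = self.config.get("regulation", {})
        ins = reg.get("insulin")
        if ins is not None and plasma is not None:
            f = plasma.insulin / (plasma.insulin + ins["k"])
            for j, rxn in enumerate(self.reactions):
                if rxn.id in ins["targets"]:
                    mult[j] *= f
        cat = reg.get("catecholamine")
        if cat is not None and plasma is not None:
            f = 1.0 + cat["beta"] * plasma.catecholamine / (plasma.catecholamine + cat["k"])
            for j, rxn in enumerate(self.reactions):
                if rxn.id in cat["targets"]:
                    mult[j] *= f
        return mult

    def boundary_concentrations(self, plasma) -> dict[str, float]:
        """Clamped concentrations of all boundary pools for a plasma profile."""
        mapping = self.config.get("plasma_map", {})
        out = {}
        for pid in self.boundary_ids:
            fld = mapping.get(pid)
            if fld is None or plasma is None:
                out[pid] = self.pools[pid].concentration
            elif fld == "ketones":
                out[pid] = plasma.beta_hydroxybutyrate + plasma.acetoacetate
            else:
                out[pid] = getattr(plasma, fld)
        return out

    def compile(self, plasma=None, vmax_scale: dict[str, float] | None = None):
        """Build fast flux and RHS closures for fixed plasma/regulation.

        Returns ``(rhs, fluxes)`` where ``rhs(t, y)`` is suitable for
        ``scipy.integrate.solve_ivp`` and ``fluxes(y)`` returns the
        per-reaction flux vector (mmol/L cell/h).
        """
        boundary = self.boundary_concentrations(plasma)
        mult = self._regulation_multipliers(plasma)
        scale = np.ones(len(self.reactions))
        if vmax_scale:
            for j, rxn in enumerate(self.reactions):
                if rxn.id in vmax_scale:
                    scale[j] = vmax_scale[rxn.id]
        index = self._index
        temperature = self.temperature
        reactions = self.reactions
        n_pool = len(self.state_ids)
        has_psi = self.has_membrane_potential

        def fluxes(y: np.ndarray) -> np.ndarray:
            conc_vec = np.maximum(y[:n_pool], 0.0)
            psi = float(y[n_pool]) if has_psi else None
            state = dict(zip(self.state_ids, conc_vec))
            state.update(boundary)

            def conc(met: str) -> float:
                try:
                    return state[met]
                except KeyError as exc:
                    raise EvaluationError(f"missing concentration for {met}") from exc

            v = np.empty(len(reactions))
            for j, rxn in enumerate(reactions):
                base_vmax = rxn.vmax
                rxn.vmax = base_vmax * scale[j] * mult[j]
                try:
                    kind = rxn.rate_law.kind
                    if kind == "reversible_mm":
                        v[j] = reversible_mm_rate(rxn, state)
                    elif kind == "hill_allosteric":
                        v[j] = _hill_rate(rxn, conc, psi)
                    elif kind == "atp_load":
                        p = rxn.rate_law.params
                        atp = conc(p["atp"])
                        v[j] = rxn.vmax * atp / (atp + p.get("km", 0.5))
                    elif kind == "ghk_ion_flux":
                        p = rxn.rate_law.params
                        c_in = p["c_in"] if isinstance(p["c_in"], (int, float)) else conc(p["c_in"])
                        c_out = (
                            p["c_out"] if isinstance(p["c_out"], (int, float)) else conc(p["c_out"])
                        )
                        # psi is quoted matrix-negative-positive (ims minus
                        # matrix); GHK takes the inside-minus-outside voltage
                        v[j] = ghk_ion_flux(
                            rxn.vmax, p["charge"], -psi if psi is not None else 0.0,
                            c_in, c_out, temperature,
                        )
                    elif kind == "antiporter":
                        v[j] = _antiporter_rate(rxn, conc, psi, temperature)
                    else:  # pragma: no cover - guarded in RateLaw
                        raise EvaluationError(f"unknown rate law {kind}")
                finally:
                    rxn.vmax = base_vmax
            return v

        N = self.N
        vols = self._vols
        qv = self.charge_vector
        cap = self.capacitance

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            v = fluxes(y)
            dy = (N @ v) / vols
            if has_psi:
                dy = np.append(dy, (qv @ v) / cap)
            return dy

        return rhs, fluxes

    def ode_rhs(self, state: np.ndarray, plasma=None, vmax_scale=None) -> np.ndarray:
        """Derivative vector dC/dt (and dPsi/dt) at ``state``."""
        state = np.asarray(state, dtype=float)
        self.split_state(state)  # contract: dimension must match
        rhs, _ = self.compile(plasma, vmax_scale)
        return rhs(0.0, state)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def copy(self) -> "NetworkModel":
        import copy as _copy

        return _copy.deepcopy(self)


# ---------------------------------------------------------------------------
# configuration loading
# ---------------------------------------------------------------------------

def load_model_config(path=None) -> dict:
    """Read a model-definition YAML (the shipped reference by default)."""
    if path is None:
        ref = resources.files("myokin.data") / "reference_model.yaml"
        with ref.open("r") as fh:
            return yaml.safe_load(fh)
    with open(path) as fh:
        return yaml.safe_load(fh)


def build_reference_model(config: dict | str | None = None) -> NetworkModel:
    """Instantiate and validate a :class:`NetworkModel` from a config document.

    With no argument the shipped control-calibrated reference heart is built.
    Validation covers moiety left-null-space membership, carbon and phosphate
    bookkeeping and positivity of kinetic constants; a missing carnitine total
    defaults to 3.0 mmol/L of matrix volume (physiological content).
    """
    if config is None or isinstance(config, str):
        config = load_model_config(config)
    compartments = {
        c["id"]: Compartment(c["id"], c["volume_fraction"]) for c in config["compartments"]
    }
    pools = {}
    for p in config["pools"]:
        pools[p["id"]] = MetabolitePool(
            id=p["id"],
            compartment=p["compartment"],
            concentration=p["concentration"],
            is_boundary=p.get("boundary", False),
            charge=p.get("charge", 0),
            carbon=p.get("carbon", 0),
            phosphorus=p.get("phosphorus", 0),
        )
    reactions = []
    for r in config["reactions"]:
        reactions.append(
            Reaction(
                id=r["id"],
                stoichiometry=r["stoichiometry"],
                compartment=r.get("compartment", "cytosol"),
                rate_law=RateLaw(r["rate_law"]["kind"], r["rate_law"].get("params", {})),
                vmax=r["vmax"],
                protein_groups=r.get("protein_groups", []),
                pathway_tag=r.get("pathway_tag", "transport"),
                charge_transfer=r.get("charge_transfer", 0.0),
                pi_release=r.get("pi_release", 0.0),
            )
        )
    moieties = []
    seen = set()
    for m in config.get("moieties", []):
        moieties.append(Moiety(m["name"], m["members"], m.get("total", 0.0)))
        seen.add(m["name"])
    model = NetworkModel(
        compartments=compartments,
        pools=pools,
        reactions=reactions,
        moieties=moieties,
        temperature=config.get("temperature", 310.0),
        capacitance=config.get("capacitance", 1e-3),
        psi_init=config.get("psi_init", 170.0),
        config=config,
    )
    # default physiological carnitine content when the config omits it
    if "carnitine_matrix" in seen:
        m = next(m for m in model.moieties if m.name == "carnitine_matrix")
        if not m.total:
            model.set_moiety_total("carnitine_matrix", 3.0)
    # align declared totals with initial concentrations
    for m in model.moieties:
        current = sum(model.pools[mem].concentration for mem in m.members)
        if m.total and abs(current - m.total) > 1e-9 * max(1.0, m.total):
            for mem in m.members:
                model.pools[mem].concentration *= m.total / current
        elif not m.total:
            m.total = current
    return model
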