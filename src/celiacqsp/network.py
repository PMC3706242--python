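"""Reaction network of the celiac-disease immune-response model.

The model couples an innate cascade (gluten peptides activate intestinal
epithelial cells; activated IECs secrete zonulin and IL-15; IL-15 turns
intraepithelial lymphocytes into natural killers that, together with IF-21
and antibodies, destroy the epithelium) to an adaptive cascade (peptides
crossing the leaky epithelium are deamidated by TG-2, activate DQ2/DQ8
antigen-presenting cells, which activate T cells through a transient
compartment; activated T cells drive antibody synthesis).

The dynamics are ``dx/dt = N @ v(x)`` with an integer stoichiometric matrix
``N`` (species x reactions) and non-negative mass-action / saturation rate
laws ``v``.  Reaction ids follow the process-network numbering where one is
defined (r3, r4, r5, ...); bookkeeping in/outflows get descriptive ids.

Two variants exist: the *patient* model (16 species) and the *healthy*
model, in which IEC and IEL activation are identically zero and the
DQ2/DQ8 APC compartments are absent (14 species).  In consequence the
healthy model relaxes to a state with no activated cells, cytokines,
zonulin or antibodies on any diet.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "SPECIES",
    "HEALTHY_EXCLUDED",
    "SPECIES_COMPARTMENT",
    "PatientVariant",
    "Reaction",
    "ReactionNetwork",
    "ModelError",
    "build_network",
    "reaction_rates",
    "rhs",
]

#: the 16 state variables of the patient model, in canonical order
SPECIES = (
    "Glut_lum",  # gluten peptides in the intestinal lumen
    "Glut_lam",  # native gluten peptides in the lamina propria
    "dGlut",     # deamidated peptides (incl. TG-2--peptide complexes)
    "Zon",       # zonulin
    "IEC",       # mature intestinal epithelial cells
    "aIEC",      # activated IECs
    "IEL",       # intraepithelial lymphocytes
    "aIEL",      # activated IELs (natural killers)
    "IL15",      # interleukin-15
    "IF21",      # merged IFN-gamma + IL-21 pool
    "APC",       # DQ2/DQ8 antigen-presenting cells
    "aAPC",      # activated APCs
    "T",         # T cells (merged Th1 + Th17)
    "aTt",       # transient activated-T compartment (activation delay)
    "aT",        # activated T cells
    "Ab",        # antibodies to gluten peptides and TG-2
)

#: species absent from the healthy variant (no DQ2/DQ8 compartment)
HEALTHY_EXCLUDED = ("APC", "aAPC")

SPECIES_COMPARTMENT = {
    "Glut_lum": "lumen",
    "Zon": "lumen",
    "IEC": "epithelium",
    "aIEC": "epithelium",
    "IEL": "epithelium",
    "aIEL": "epithelium",
    "Glut_lam": "lamina",
    "dGlut": "lamina",
    "IL15": "lamina",
    "IF21": "lamina",
    "APC": "lamina",
    "aAPC": "lamina",
    "T": "lamina",
    "aTt": "lamina",
    "aT": "lamina",
    "Ab": "plasma",
}


class ModelError(ValueError):
    """Structural or domain error in network construction / evaluation."""


def _hill2(x: float, half: float) -> float:
    """Cooperative saturation x^2/(half^2 + x^2), overflow-safe."""
    if x <= 0.0:
        return 0.0
    r = x / half
    if r > 1e8:  # numerically saturated; avoids overflow in r*r
        return 1.0
    return r * r / (1.0 + r * r)


class PatientVariant(enum.Enum):
    PATIENT = "patient"
    HEALTHY = "healthy"


@dataclass(frozen=True)
class Reaction:
    """One process of the network.

    ``stoich`` maps species name to its integer stoichiometric coefficient;
    ``rate`` evaluates the velocity from a species-indexed vector; ``formula``
    is the same law as an infix expression over species and parameter names
    (used for SBML export and cross-checks).
    """

    rid: str
    name: str
    stoich: Mapping[str, int]
    rate: Callable[[np.ndarray], float]
    formula: str


class ReactionNetwork:
    """Stoichiometric matrix plus rate laws for one model variant."""

    def __init__(
        self,
        species: Sequence[str],
        reactions: Sequence[Reaction],
        params: ParameterSet,
        variant: PatientVariant,
        inflow_index: int,
    ):
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.params = params
        self.variant = variant
        self._inflow_index = inflow_index  # column of the gluten-inflow reaction
        self.index = {s: i for i, s in enumerate(self.species)}
        n = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        for j, rxn in enumerate(self.reactions):
            for sp, coeff in rxn.stoich.items():
                if sp not in self.index:
                    raise ModelError(
                        f"reaction {rxn.rid} references unknown species {sp!r}"
                    )
                n[self.index[sp], j] = coeff
        self.N = n

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def state(self, **values: float) -> np.ndarray:
        """Build a state vector from keyword species values (others zero)."""
        x = np.zeros(self.n_species)
        for name, v in values.items():
            if name not in self.index:
                raise ModelError(f"unknown species {name!r}")
            x[self.index[name]] = v
        return x

    def as_dict(self, x: np.ndarray) -> dict[str, float]:
        return {s: float(x[i]) for i, s in enumerate(self.species)}

    def with_inflow(self, inflow: float) -> "ReactionNetwork":
        """Copy of the network with the gluten inflow fixed to ``inflow``."""
        reactions = list(self.reactions)
        old = reactions[self._inflow_index]
        value = float(inflow)
        reactions[self._inflow_index] = Reaction(
            old.rid, old.name, old.stoich, lambda x: value, f"{value!r}"
        )
        return ReactionNetwork(
            self.species, reactions, self.params, self.variant, self._inflow_index
        )

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Vector of reaction velocities at a non-negative state."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_species,):
            raise ModelError(
                f"state has shape {x.shape}, expected ({self.n_species},)"
            )
        if np.any(x < 0):
            bad = [self.species[i] for i in np.nonzero(x < 0)[0]]
            raise ModelError(f"negative state component(s): {', '.join(bad)}")
        return np.array([rxn.rate(x) for rxn in self.reactions])

    def rhs(self, x: np.ndarray, t: float = 0.0) -> np.ndarray:
        """Time derivative ``N @ v(x)``; autonomous (t is ignored)."""
        return self.N @ self.rates(x)

    def _ode_rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        # solver-facing variant: tolerant of tiny negative excursions
        return self.N @ self.rates(np.maximum(x, 0.0))


def _check_complete(params: ParameterSet, names: Sequence[str]) -> None:
    from .parameters import ParameterError

    missing = [n for n in names if n not in params]
    if missing:
        raise ParameterError(f"missing parameter(s): {', '.join(missing)}")


def build_network(
    params: ParameterSet, variant: PatientVariant = PatientVariant.PATIENT
) -> ReactionNetwork:
    """Wire the full reaction network for one variant.

    The returned network bakes in the current parameter values; interventions
    therefore modify a :class:`ParameterSet` and rebuild.
    """
    if not isinstance(variant, PatientVariant):
        variant = PatientVariant(variant)
    healthy = variant is PatientVariant.HEALTHY

    from .parameters import PARAMETER_NAMES

    if healthy:
        # the DQ2/DQ8 compartment and its constants may legitimately be absent
        apc_only = {
            "k_apc_diff_basal", "k_apc_diff_il15", "k_il15_apc_half",
            "kd_apc", "kd_aapc", "k_apc_activation", "ec50_deam", "ec50_nat",
            "k_t_activation", "k_il15_aapc",
        }
        _check_complete(params, [n for n in PARAMETER_NAMES if n not in apc_only])
    else:
        _check_complete(params, PARAMETER_NAMES)

    species = tuple(s for s in SPECIES if not (healthy and s in HEALTHY_EXCLUDED))
    ix = {s: i for i, s in enumerate(species)}
    p = {name: params[name] for name in params}
    p["kdeg_if21"] = params.kdeg_if21

    def P(name: str) -> float:  # baked-in parameter value
        return p[name]

    reactions: list[Reaction] = []

    def add(rid, name, stoich, rate, formula):
        reactions.append(Reaction(rid, name, stoich, rate, formula))

    # --- lumen -----------------------------------------------------------
    inflow = P("inflow_gluten")
    add(
        "r_inflow", "gluten inflow (diet)",
        {"Glut_lum": +1},
        lambda x, k=inflow: k,
        "inflow_gluten",
    )
    inflow_index = len(reactions) - 1

    k = P("kdeg_glut_lum")
    add(
        "r_deg_glum", "luminal peptide degradation",
        {"Glut_lum": -1},
        lambda x, k=k, i=ix["Glut_lum"]: k * x[i],
        "kdeg_glut_lum * Glut_lum",
    )

    # --- paracellular transport (r13) ------------------------------------
    # additive zonulin + epithelial-deficit permeability; exactly zero when
    # zonulin is absent and the epithelium is at the healthy level
    kz, ki, iech = P("k_transport_zon"), P("k_transport_iec"), P("iec_healthy")
    add(
        "r13", "lumen -> lamina peptide transport",
        {"Glut_lum": -1, "Glut_lam": +1},
        lambda x, kz=kz, ki=ki, iech=iech, iz=ix["Zon"], ie=ix["IEC"], ig=ix["Glut_lum"]: (
            kz * x[iz] + ki * max(0.0, 1.0 - x[ie] / iech)
        ) * x[ig],
        "(k_transport_zon * Zon"
        " + k_transport_iec * max(0, 1 - IEC / iec_healthy)) * Glut_lum",
    )

    # --- lamina peptides ---------------------------------------------------
    k = P("kdeg_glut_lam")
    add(
        "r_deg_glam", "native lamina peptide degradation",
        {"Glut_lam": -1},
        lambda x, k=k, i=ix["Glut_lam"]: k * x[i],
        "kdeg_glut_lam * Glut_lam",
    )
    k33 = P("k_deam") * P("tg2_level")
    add(
        "r33", "TG-2 deamidation of lamina peptides",
        {"Glut_lam": -1, "dGlut": +1},
        lambda x, k=k33, i=ix["Glut_lam"]: k * x[i],
        "k_deam * tg2_level * Glut_lam",
    )
    k = P("kdeg_dglut")
    add(
        "r_deg_dglut", "deamidated peptide degradation",
        {"dGlut": -1},
        lambda x, k=k, i=ix["dGlut"]: k * x[i],
        "kdeg_dglut * dGlut",
    )

    # --- epithelium --------------------------------------------------------
    kmat, kiab = P("k_iec_maturation"), P("ki_ab_maturation")
    add(
        "r3", "IEC maturation (antibody-inhibited)",
        {"IEC": +1},
        lambda x, k=kmat, ki=kiab, ia=ix["Ab"]: k / (1.0 + x[ia] / ki),
        "k_iec_maturation / (1 + Ab / ki_ab_maturation)",
    )

    kd, ka, kb, kc = (
        P("kd_iec"), P("k_iec_death_aiel"), P("k_iec_death_if21"), P("k_iec_death_ab"),
    )
    death_formula = (
        "(kd_iec + k_iec_death_aiel * aIEL + k_iec_death_if21 * IF21"
        " + k_iec_death_ab * Ab)"
    )
    add(
        "r4", "IEC death (basal + effector-driven apoptosis)",
        {"IEC": -1},
        lambda x, kd=kd, ka=ka, kb=kb, kc=kc, ie=ix["IEC"], il=ix["aIEL"],
        ii=ix["IF21"], ia=ix["Ab"]: (
            kd + ka * x[il] + kb * x[ii] + kc * x[ia]
        ) * x[ie],
        f"{death_formula} * IEC",
    )

    if healthy:
        add("r5", "IEC activation (zero in healthy subjects)",
            {"IEC": -1, "aIEC": +1}, lambda x: 0.0, "0")
    else:
        k5, kd5, h5 = P("k_iec_activation"), P("kact_iec_half"), P("h_iec_activation")
        add(
            "r5", "IEC activation by lumen gluten",
            {"IEC": -1, "aIEC": +1},
            lambda x, k=k5, kd=kd5, h=h5, ie=ix["IEC"], ig=ix["Glut_lum"]: (
                k * x[ie] * x[ig] ** h / (kd ** h + x[ig] ** h)
            ),
            "k_iec_activation * IEC * Glut_lum**h_iec_activation"
            " / (kact_iec_half**h_iec_activation + Glut_lum**h_iec_activation)",
        )

    kda = P("kd_aiec")
    add(
        "r6", "activated-IEC death",
        {"aIEC": -1},
        lambda x, kd=kda, ka=ka, kb=kb, kc=kc, ie=ix["aIEC"], il=ix["aIEL"],
        ii=ix["IF21"], ia=ix["Ab"]: (
            kd + ka * x[il] + kb * x[ii] + kc * x[ia]
        ) * x[ie],
        "(kd_aiec + k_iec_death_aiel * aIEL + k_iec_death_if21 * IF21"
        " + k_iec_death_ab * Ab) * aIEC",
    )

    # --- zonulin ------------------------------------------------------------
    k = P("k_zon_syn")
    add(
        "r31", "zonulin synthesis by activated IECs",
        {"Zon": +1},
        lambda x, k=k, i=ix["aIEC"]: k * x[i],
        "k_zon_syn * aIEC",
    )
    k = P("kdeg_zon")
    add(
        "r_deg_zon", "zonulin degradation",
        {"Zon": -1},
        lambda x, k=k, i=ix["Zon"]: k * x[i],
        "kdeg_zon * Zon",
    )

    # --- IL-15 ---------------------------------------------------------------
    k7a = P("k_il15_aiec")
    if healthy:
        add(
            "r7", "IL-15 synthesis (activated IECs)",
            {"IL15": +1},
            lambda x, ka=k7a, i=ix["aIEC"]: ka * x[i],
            "k_il15_aiec * aIEC",
        )
    else:
        k7b = P("k_il15_aapc")
        add(
            "r7", "IL-15 synthesis (activated IECs + activated APCs)",
            {"IL15": +1},
            lambda x, ka=k7a, kb=k7b, i=ix["aIEC"], j=ix["aAPC"]: ka * x[i] + kb * x[j],
            "k_il15_aiec * aIEC + k_il15_aapc * aAPC",
        )
    k = P("kdeg_il15")
    add(
        "r_deg_il15", "IL-15 degradation",
        {"IL15": -1},
        lambda x, k=k, i=ix["IL15"]: k * x[i],
        "kdeg_il15 * IL15",
    )

    # --- IELs -----------------------------------------------------------------
    k = P("k_iel_source")
    add("r_src_iel", "IEL replenishment", {"IEL": +1}, lambda x, k=k: k,
        "k_iel_source")
    k = P("kd_iel")
    add(
        "r_deg_iel", "IEL death",
        {"IEL": -1},
        lambda x, k=k, i=ix["IEL"]: k * x[i],
        "kd_iel * IEL",
    )
    if healthy:
        add("r11", "IEL activation (zero in healthy subjects)",
            {"IEL": -1, "aIEL": +1}, lambda x: 0.0, "0")
    else:
        k11, k11h, h11 = (
            P("k_iel_activation"), P("k_il15_iel_half"), P("h_iel_activation"),
        )
        add(
            "r11", "IEL activation by IL-15",
            {"IEL": -1, "aIEL": +1},
            lambda x, k=k11, kh=k11h, h=h11, i=ix["IEL"], j=ix["IL15"]: (
                k * x[i] * x[j] ** h / (kh ** h + x[j] ** h)
            ),
            "k_iel_activation * IEL * IL15**h_iel_activation"
            " / (k_il15_iel_half**h_iel_activation + IL15**h_iel_activation)",
        )
    kd, kiarr = P("kd_aiel"), P("ki_il15_apoptosis")
    add(
        "r10", "activated-IEL apoptosis (arrested by IL-15)",
        {"aIEL": -1},
        lambda x, kd=kd, ki=kiarr, i=ix["aIEL"], j=ix["IL15"]: (
            kd * x[i] / (1.0 + x[j] / ki)
        ),
        "kd_aiel * aIEL / (1 + IL15 / ki_il15_apoptosis)",
    )

    # --- DQ2/DQ8 APC compartment (patient only) -------------------------------
    if not healthy:
        k160, k16, k16h = (
            P("k_apc_diff_basal"), P("k_apc_diff_il15"), P("k_il15_apc_half"),
        )
        add(
            "r16", "APC differentiation from monocytes (IL-15 stimulated)",
            {"APC": +1},
            lambda x, k0=k160, k1=k16, kh=k16h, j=ix["IL15"]: (
                k0 + k1 * x[j] / (kh + x[j])
            ),
            "k_apc_diff_basal"
            " + k_apc_diff_il15 * IL15 / (k_il15_apc_half + IL15)",
        )
        k = P("kd_apc")
        add(
            "r_deg_apc", "APC death",
            {"APC": -1},
            lambda x, k=k, i=ix["APC"]: k * x[i],
            "kd_apc * APC",
        )
        # cooperative (Hill-2) antigen response: the EC50s are the
        # half-activation concentrations; the sigmoidal onset makes the
        # response vanish quadratically at low antigen, which is what lets
        # a large native/deamidated EC50 ratio silence the antibody arm
        k18, e_d, e_n = P("k_apc_activation"), P("ec50_deam"), P("ec50_nat")
        add(
            "r18", "APC activation by native + deamidated antigen",
            {"APC": -1, "aAPC": +1},
            lambda x, k=k18, ed=e_d, en=e_n, i=ix["APC"], g=ix["Glut_lam"],
            d=ix["dGlut"]: k * x[i] * (
                _hill2(x[g], en) + _hill2(x[d], ed)
            ),
            "k_apc_activation * APC"
            " * (Glut_lam**2 / (ec50_nat**2 + Glut_lam**2)"
            " + dGlut**2 / (ec50_deam**2 + dGlut**2))",
        )
        k = P("kd_aapc")
        add(
            "r_deg_aapc", "activated-APC death",
            {"aAPC": -1},
            lambda x, k=k, i=ix["aAPC"]: k * x[i],
            "kd_aapc * aAPC",
        )

    # --- T cells ---------------------------------------------------------------
    k = P("k_t_source")
    add("r_src_t", "T-cell replenishment", {"T": +1}, lambda x, k=k: k,
        "k_t_source")
    k = P("kd_t")
    add(
        "r_deg_t", "T-cell death",
        {"T": -1},
        lambda x, k=k, i=ix["T"]: k * x[i],
        "kd_t * T",
    )
    if not healthy:
        k22, a, kifh = P("k_t_activation"), P("a_if21_boost"), P("k_if21_boost_half")
        add(
            "r22", "T-cell activation by activated APCs (IF-21 amplified)",
            {"T": -1, "aTt": +1},
            lambda x, k=k22, a=a, kh=kifh, i=ix["T"], j=ix["aAPC"], f=ix["IF21"]: (
                k * x[i] * x[j] * (1.0 + a * x[f] / (kh + x[f]))
            ),
            "k_t_activation * T * aAPC"
            " * (1 + a_if21_boost * IF21 / (k_if21_boost_half + IF21))",
        )
    k = P("k_t_transition")
    add(
        "r34", "transient -> activated T cells",
        {"aTt": -1, "aT": +1},
        lambda x, k=k, i=ix["aTt"]: k * x[i],
        "k_t_transition * aTt",
    )
    k = P("kd_at")
    add(
        "r_deg_at", "activated-T-cell death",
        {"aT": -1},
        lambda x, k=k, i=ix["aT"]: k * x[i],
        "kd_at * aT",
    )

    # --- IF-21 -------------------------------------------------------------------
    kt, kn = P("k_if21_at"), P("k_if21_aiel")
    add(
        "r23", "IF-21 synthesis by activated T cells and activated IELs",
        {"IF21": +1},
        lambda x, kt=kt, kn=kn, i=ix["aT"], j=ix["aIEL"]: kt * x[i] + kn * x[j],
        "k_if21_at * aT + k_if21_aiel * aIEL",
    )
    k = P("kdeg_if21")
    add(
        "r_deg_if21", "IF-21 degradation (mean of IFN-gamma and IL-21)",
        {"IF21": -1},
        lambda x, k=k, i=ix["IF21"]: k * x[i],
        "((kdeg_ifng + kdeg_il21) / 2) * IF21",
    )

    # --- antibodies ----------------------------------------------------------------
    ks, kab = P("k_ab_syn"), P("k_ab_pep_half")
    add(
        "r25", "antibody synthesis (activated T cells + lamina peptides)",
        {"Ab": +1},
        lambda x, k=ks, kh=kab, i=ix["aT"], g=ix["Glut_lam"], d=ix["dGlut"]: (
            k * x[i] * (x[g] + x[d]) / (kh + x[g] + x[d])
        ),
        "k_ab_syn * aT * (Glut_lam + dGlut)"
        " / (k_ab_pep_half + Glut_lam + dGlut)",
    )
    k = P("kdeg_ab")
    add(
        "r_deg_ab", "antibody degradation",
        {"Ab": -1},
        lambda x, k=k, i=ix["Ab"]: k * x[i],
        "kdeg_ab * Ab",
    )

    return ReactionNetwork(species, reactions, params, variant, inflow_index)


def load_species(path=None) -> "pd.DataFrame":
    """Species table (name, initial value, compartment, description).

    Defaults to the packaged table; a user table must provide at least the
    ``name``, ``initial_value`` and ``compartment`` columns and cover the
    canonical species.
    """
    import pandas as pd

    if path is None:
        import importlib.resources

        ref = importlib.resources.files("celiacqsp.data").joinpath("species.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"name", "initial_value", "compartment"}
    if missing := required - set(df.columns):
        raise ModelError(f"species table lacks columns: {sorted(missing)}")
    unknown = set(df["name"]) - set(SPECIES)
    if unknown:
        raise ModelError(f"unknown species in table: {sorted(unknown)}")
    if (df["initial_value"] < 0).any():
        raise ModelError("species initial values must be non-negative")
    return df


def initial_state_from_table(net: ReactionNetwork, table=None) -> np.ndarray:
    """Initial state vector built from a species table."""
    df = load_species(table) if not hasattr(table, "columns") else table
    values = dict(zip(df["name"], df["initial_value"]))
    return np.array([values.get(s, 0.0) for s in net.species], dtype=float)


def reaction_rates(net: ReactionNetwork, state: np.ndarray) -> np.ndarray:
    """Velocity vector at ``state`` (module-level convenience wrapper)."""
    return net.rates(state)


def rhs(net: ReactionNetwork, state: np.ndarray, t: float = 0.0) -> np.ndarray:
    """Time derivative ``N @ v`` at ``state``."""
    return net.rhs(state, t)
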