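"""Kinetic parameters of the celiac-disease immune-response model.

The patient model carries exactly 54 parameters: rate constants, levels and
half-saturation thresholds of the innate (epithelium / IEL / zonulin / IL-15)
and adaptive (APC / T-cell / antibody) arms.  Each parameter has a value, a
unit, a provenance tag and, for calibrated parameters, a 95% confidence
interval used by the robustness scan.

Units: time is measured in days; all species levels are in arbitrary
concentration units ("au") whose scale is pinned by the observable
normalisation (healthy epithelium = 100% villous area, gluten-diet steady
state = 100% antibody level).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "Parameter",
    "ParameterSet",
    "ParameterError",
    "PARAMETER_NAMES",
    "N_PARAMETERS",
    "load_parameters",
    "save_parameters",
    "default_parameters",
]

SOURCE_TAGS = ("literature", "assumed", "calculated", "fitted")

#: canonical order of the 54 patient-model parameters
PARAMETER_NAMES = (
    # diet and lumen
    "inflow_gluten",        # gluten-peptide inflow on a gluten-containing diet [au/d]
    "inflow_gfd",           # residual inflow on a gluten-free diet (<20 ppm trace) [au/d]
    "kdeg_glut_lum",        # luminal peptide degradation / washout [1/d]
    # paracellular transport into the lamina propria
    "k_transport_zon",      # zonulin-dependent permeability [1/(au*d)]
    "k_transport_iec",      # epithelial-deficit-dependent permeability [1/d]
    # lamina peptides and deamidation
    "kdeg_glut_lam",        # native lamina peptide degradation [1/d]
    "kdeg_dglut",           # deamidated peptide degradation [1/d]
    "k_deam",               # TG-2 deamidation rate constant [1/(au*d)]
    "tg2_level",            # TG-2 level in the lamina propria [au]
    # intestinal epithelial cells
    "k_iec_maturation",     # maturation influx from crypt precursors [au/d]
    "ki_ab_maturation",     # antibody inhibition constant of maturation [au]
    "kd_iec",               # basal IEC death constant [1/d]
    "kd_aiec",              # basal activated-IEC death constant [1/d]
    "k_iec_activation",     # IEC activation by lumen gluten [1/d]
    "kact_iec_half",        # receptor-occupancy threshold of activation [au]
    "h_iec_activation",     # Hill coefficient of IEC activation [-]
    "k_iec_death_aiel",     # IEC killing by activated IELs [1/(au*d)]
    "k_iec_death_if21",     # IEC apoptosis by IF-21 [1/(au*d)]
    "k_iec_death_ab",       # IEC apoptosis by antibodies [1/(au*d)]
    "iec_healthy",          # healthy-subject mature IEC level [au]
    # zonulin
    "k_zon_syn",            # zonulin synthesis by activated IECs [1/d]
    "kdeg_zon",             # zonulin degradation [1/d]
    # IL-15
    "k_il15_aiec",          # IL-15 synthesis by activated IECs [1/d]
    "k_il15_aapc",          # IL-15 synthesis by activated APCs [1/d]
    "kdeg_il15",            # IL-15 degradation [1/d]
    # intraepithelial lymphocytes
    "k_iel_source",         # IEL replenishment [au/d]
    "kd_iel",               # IEL death [1/d]
    "k_iel_activation",     # IEL activation by IL-15 [1/d]
    "k_il15_iel_half",      # IL-15 half-saturation of IEL activation [au]
    "h_iel_activation",     # Hill coefficient of IEL activation [-]
    "kd_aiel",              # activated-IEL apoptosis [1/d]
    "ki_il15_apoptosis",    # IL-15 apoptosis-arrest constant [au]
    # antigen-presenting cells (DQ2/DQ8)
    "k_apc_diff_basal",     # IL-15-independent APC differentiation [au/d]
    "k_apc_diff_il15",      # IL-15-stimulated APC differentiation [au/d]
    "k_il15_apc_half",      # IL-15 half-saturation of differentiation [au]
    "kd_apc",               # APC death [1/d]
    "kd_aapc",              # activated-APC death [1/d]
    "k_apc_activation",     # APC activation by antigen [1/d]
    "ec50_deam",            # EC50 of activation by deamidated peptides [au]
    "ec50_nat",             # EC50 of activation by native peptides [au]
    # T cells (merged Th1 + Th17)
    "k_t_source",           # T-cell replenishment [au/d]
    "kd_t",                 # T-cell death [1/d]
    "k_t_activation",       # T-cell activation by activated APCs [1/(au*d)]
    "a_if21_boost",         # IF-21 amplification of T-cell activation [-]
    "k_if21_boost_half",    # IF-21 half-saturation of the amplification [au]
    "k_t_transition",       # transient-compartment maturation [1/d]
    "kd_at",                # activated-T-cell death [1/d]
    # IF-21 (merged IFN-gamma + IL-21)
    "k_if21_at",            # IF-21 synthesis by activated T cells [1/d]
    "k_if21_aiel",          # IF-21 synthesis by activated IELs [1/d]
    "kdeg_ifng",            # IFN-gamma degradation [1/d]
    "kdeg_il21",            # IL-21 degradation [1/d]
    # antibodies (anti-gluten + anti-TG-2)
    "k_ab_syn",             # antibody synthesis constant (ksab) [1/d]
    "k_ab_pep_half",        # lamina-peptide half-saturation of synthesis [au]
    "kdeg_ab",              # antibody degradation [1/d]
)

N_PARAMETERS = len(PARAMETER_NAMES)


class ParameterError(ValueError):
    """Raised for malformed or inconsistent parameter sets."""


@dataclass(frozen=True)
class Parameter:
    """A single named kinetic constant."""

    name: str
    value: float
    unit: str = "au"
    source: str = "fitted"
    ci_lo: float | None = None
    ci_hi: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ParameterError(f"parameter {self.name!r} is negative: {self.value}")
        if self.source not in SOURCE_TAGS:
            raise ParameterError(
                f"parameter {self.name!r} has unknown source tag {self.source!r}"
            )
        if (self.ci_lo is None) != (self.ci_hi is None):
            raise ParameterError(f"parameter {self.name!r} has a one-sided CI")
        if self.ci_lo is not None:
            if not (self.ci_lo <= self.value <= self.ci_hi):
                raise ParameterError(
                    f"parameter {self.name!r}: CI [{self.ci_lo}, {self.ci_hi}] "
                    f"does not contain the value {self.value}"
                )


class ParameterSet(Mapping[str, float]):
    """Immutable mapping of parameter name -> value with metadata.

    Behaves as a ``Mapping[str, float]`` for rate-law evaluation; metadata
    (unit, source tag, confidence interval) is reachable via :meth:`meta`.
    """

    def __init__(self, parameters: Iterable[Parameter], *, expect_full: bool = True):
        params: dict[str, Parameter] = {}
        for p in parameters:
            if p.name in params:
                raise ParameterError(f"duplicate parameter {p.name!r}")
            params[p.name] = p
        self._params = params
        if expect_full:
            missing = [n for n in PARAMETER_NAMES if n not in params]
            if missing:
                raise ParameterError(f"missing parameters: {', '.join(missing)}")

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return self._params[name].value
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._params)

    def __len__(self) -> int:
        return len(self._params)

    def __repr__(self) -> str:
        return f"ParameterSet({len(self)} parameters)"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._params == other._params

    # -- metadata ---------------------------------------------------------
    def meta(self, name: str) -> Parameter:
        try:
            return self._params[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    @property
    def fitted_names(self) -> tuple[str, ...]:
        return tuple(n for n, p in self._params.items() if p.source == "fitted")

    # -- derived constants ------------------------------------------------
    @property
    def kdeg_if21(self) -> float:
        """Degradation constant of the merged IFN-gamma/IL-21 pool.

        Defined as the average of the two individual cytokine constants.
        """
        return 0.5 * (self["kdeg_ifng"] + self["kdeg_il21"])

    # -- functional updates ------------------------------------------------
    def with_values(self, **updates: float) -> "ParameterSet":
        """Return a copy with the given parameter values replaced."""
        new = dict(self._params)
        for name, value in updates.items():
            if name not in new:
                raise ParameterError(f"unknown parameter {name!r}")
            new[name] = replace(new[name], value=float(value), ci_lo=None, ci_hi=None)
        return ParameterSet(new.values(), expect_full=False)

    def scaled(self, name: str, factor: float) -> "ParameterSet":
        return self.with_values(**{name: self[name] * factor})

    # -- (de)serialisation -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": p.name,
                "value": p.value,
                "unit": p.unit,
                "source": p.source,
                "ci_lo": p.ci_lo,
                "ci_hi": p.ci_hi,
            }
            for p in self._params.values()
        ]
        return pd.DataFrame(rows)


def _frame_to_parameters(df: pd.DataFrame) -> list[Parameter]:
    required = {"name", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"parameter table lacks columns: {sorted(missing)}")
    dupes = df["name"][df["name"].duplicated()].tolist()
    if dupes:
        raise ParameterError(f"duplicate parameter rows: {sorted(set(dupes))}")
    params = []
    for row in df.itertuples(index=False):
        ci_lo = getattr(row, "ci_lo", None)
        ci_hi = getattr(row, "ci_hi", None)
        ci_lo = None if ci_lo is None or pd.isna(ci_lo) else float(ci_lo)
        ci_hi = None if ci_hi is None or pd.isna(ci_hi) else float(ci_hi)
        params.append(
            Parameter(
                name=str(row.name),
                value=float(row.value),
                unit=str(getattr(row, "unit", "au")),
                source=str(getattr(row, "source", "fitted")),
                ci_lo=ci_lo,
                ci_hi=ci_hi,
            )
        )
    return params


def load_parameters(path, *, expect_full: bool = False) -> ParameterSet:
    """Load a parameter table from tab-separated plain text.

    Columns: ``name  value  unit  source  ci_lo  ci_hi`` (the last four are
    optional).  A count different from the canonical 54 is permitted (reduced
    test models) unless ``expect_full`` is set.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    pset = ParameterSet(_frame_to_parameters(df), expect_full=expect_full)
    if not expect_full and len(pset) != N_PARAMETERS:
        import warnings

        warnings.warn(
            f"parameter table has {len(pset)} entries, expected {N_PARAMETERS}",
            stacklevel=2,
        )
    return pset


def save_parameters(pset: ParameterSet, path) -> None:
    pset.to_frame().to_csv(path, sep="\t", index=False)


def default_parameters() -> ParameterSet:
    """The package's calibrated default parameter set (54 parameters)."""
    ref = importlib.resources.files("celiacqsp.data").joinpath("parameters.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_parameters(path, expect_full=True)
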