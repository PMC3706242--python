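"""Diet protocols, drug interventions and prediction scenarios.

Five candidate therapies are modelled as parameter changes, following the
way each drug acts on the network:

==================== ========================================================
kind                 effect at strength s in [0, 1]
==================== ========================================================
tg2_inhibitor        TG-2 level in the lamina propria scaled by (1 - s)
ifng_antibody        IF-21 (IFN-gamma + IL-21) degradation scaled by 1/(1-s)
il15_antibody        IL-15 degradation scaled by 1/(1-s)
permeability_inhibitor  IEC activation constant scaled by (1 - s)
dq2_blocker          APC activation constant scaled by (1 - s)
==================== ========================================================

Strength 1 is the complete effect (the target level or process reaches
zero).  Outcomes are reported as normalised observables against the
*untreated* gluten-diet and healthy references.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    Observables,
    References,
    SimulationError,
    compute_references,
    observables,
    simulate,
    steady_state,
)
from .network import PatientVariant, build_network
from .parameters import ParameterSet

__all__ = [
    "DietProtocol",
    "InterventionSpec",
    "ScenarioResult",
    "INTERVENTION_KINDS",
    "run_diet_switch",
    "apply_intervention",
    "intervention_endpoint",
    "dose_response",
    "ec50_ratio_scan",
    "robustness_scan",
]

INTERVENTION_KINDS = (
    "tg2_inhibitor",
    "ifng_antibody",
    "il15_antibody",
    "permeability_inhibitor",
    "dq2_blocker",
)

#: cap on the degradation-rate scale of the antibody therapies at strength=1
#: (keeps the ODE finite; the cytokine level is then numerically zero)
_MAX_DEG_SCALE = 1e6

#: antibody level (% of gluten-diet steady state) treated as "near zero"
AB_NEAR_ZERO_PCT = 5.0
#: antibody level treated as "antibodies have appeared"
AB_APPEARED_PCT = 10.0


@dataclass(frozen=True)
class DietProtocol:
    """Piecewise-constant gluten inflow.

    ``phases`` is a sequence of ``(switch_time_days, level)`` with strictly
    increasing times starting at 0; ``level`` is ``"gluten"``, ``"gfd"`` or a
    non-negative inflow value in au/day.
    """

    phases: tuple[tuple[float, object], ...]

    def __init__(self, phases: Sequence[tuple[float, object]]):
        phases = tuple((float(t), lvl) for t, lvl in phases)
        if not phases or phases[0][0] != 0.0:
            raise ValueError("protocol must start with a phase at t=0")
        times = [t for t, _ in phases]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("switch times must be strictly increasing")
        object.__setattr__(self, "phases", phases)

    def inflow(self, level, params: ParameterSet) -> float:
        if level == "gluten":
            return params["inflow_gluten"]
        if level == "gfd":
            return params["inflow_gfd"]
        value = float(level)
        if value < 0:
            raise ValueError("gluten inflow must be non-negative")
        return value

    @classmethod
    def constant(cls, level) -> "DietProtocol":
        return cls([(0.0, level)])

    @classmethod
    def switch(cls, from_level, to_level, at: float) -> "DietProtocol":
        return cls([(0.0, from_level), (float(at), to_level)])


@dataclass(frozen=True)
class InterventionSpec:
    """One drug applied at a given strength."""

    kind: str
    strength: float = 1.0

    def __post_init__(self):
        if self.kind not in INTERVENTION_KINDS:
            raise ValueError(
                f"unknown intervention {self.kind!r}; "
                f"expected one of {INTERVENTION_KINDS}"
            )
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")


@dataclass(frozen=True)
class ScenarioResult:
    """Trajectory plus endpoint observables of one scenario run."""

    trajectory: object
    endpoint: Observables
    intervention: InterventionSpec | None = None
    diagnostics: dict = field(default_factory=dict)


def apply_intervention(params: ParameterSet, spec: InterventionSpec) -> ParameterSet:
    """Return a parameter set with the drug effect applied.

    Strength 0 returns an identical set; all untouched parameters are
    bit-identical copies.
    """
    s = spec.strength
    if s == 0.0:
        return params
    if spec.kind == "tg2_inhibitor":
        return params.scaled("tg2_level", 1.0 - s)
    if spec.kind == "permeability_inhibitor":
        return params.scaled("k_iec_activation", 1.0 - s)
    if spec.kind == "dq2_blocker":
        return params.scaled("k_apc_activation", 1.0 - s)
    scale = _MAX_DEG_SCALE if s >= 1.0 else min(1.0 / (1.0 - s), _MAX_DEG_SCALE)
    if spec.kind == "ifng_antibody":
        return params.with_values(
            kdeg_ifng=params["kdeg_ifng"] * scale,
            kdeg_il21=params["kdeg_il21"] * scale,
        )
    if spec.kind == "il15_antibody":
        return params.scaled("kdeg_il15", scale)
    raise AssertionError("unreachable")


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float, *,
                    above: bool) -> float | None:
    """Linear-interpolated first time y crosses ``level`` (None if never)."""
    hit = y > level if above else y < level
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(t[0])
    t0, t1, y0, y1 = t[i - 1], t[i], y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def run_diet_switch(
    params: ParameterSet,
    protocol: DietProtocol,
    horizon: float,
    *,
    refs: References | None = None,
    points_per_day: float = 1.0,
) -> ScenarioResult:
    """Simulate a diet protocol from the steady state of its first phase.

    Reports, in ``diagnostics``, the times (days after the *last* switch) at
    which the antibody level first falls below 5% and first exceeds 10% of
    the gluten-diet steady-state level.
    """
    if refs is None:
        refs = compute_references(params)
    last_switch = protocol.phases[-1][0]
    if horizon <= last_switch:
        raise ValueError(
            f"horizon {horizon} d does not cover the last switch at "
            f"{last_switch} d"
        )
    base_net = build_network(params, PatientVariant.PATIENT)

    net0 = base_net.with_inflow(protocol.inflow(protocol.phases[0][1], params))
    x = steady_state(net0, refs.x_gluten)

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    bounds = [t for t, _ in protocol.phases] + [float(horizon)]
    for (t_start, level), t_end in zip(protocol.phases, bounds[1:]):
        net = base_net.with_inflow(protocol.inflow(level, params))
        n_pts = max(int(round((t_end - t_start) * points_per_day)), 10)
        grid = np.linspace(t_start, t_end, n_pts + 1)
        seg = simulate(net, x, grid)
        x = seg.final_state
        keep = slice(0, None) if not times else slice(1, None)
        times.append(seg.t[keep])
        states.append(seg.x[keep])

    from .dynamics import Trajectory

    traj = Trajectory(
        t=np.concatenate(times), x=np.vstack(states),
        species=base_net.species, params=params,
        variant=PatientVariant.PATIENT,
    )
    ab_pct = 100.0 * traj.series("Ab") / refs.ref_ab
    after = traj.t >= last_switch
    t_rel = traj.t[after] - last_switch
    ab_after = ab_pct[after]
    diagnostics = {
        "t_ab_below_5pct": _first_crossing(
            t_rel, ab_after, AB_NEAR_ZERO_PCT, above=False),
        "t_ab_above_10pct": _first_crossing(
            t_rel, ab_after, AB_APPEARED_PCT, above=True),
    }
    endpoint = observables(traj.final_state, base_net, refs.ref_ab, refs.ref_iec)
    return ScenarioResult(trajectory=traj, endpoint=endpoint,
                          diagnostics=diagnostics)


def intervention_endpoint(
    params: ParameterSet,
    spec: InterventionSpec,
    *,
    refs: References | None = None,
) -> Observables:
    """New steady state reached under treatment, as normalised observables.

    Treatment starts from the untreated gluten-diet steady state; observables
    are measured against the untreated references.
    """
    if refs is None:
        refs = compute_references(params)
    treated = apply_intervention(params, spec)
    net = build_network(treated, PatientVariant.PATIENT)
    try:
        x = steady_state(net, refs.x_gluten)
    except SimulationError as err:
        if err.x_last is None:
            raise
        x = err.x_last  # best 2-year-integration state, reported as endpoint
    return observables(x, net, refs.ref_ab, refs.ref_iec)


def dose_response(
    params: ParameterSet,
    kind: str,
    strengths: Sequence[float],
    *,
    refs: References | None = None,
) -> pd.DataFrame:
    """Endpoint observables over a grid of intervention strengths."""
    if refs is None:
        refs = compute_references(params)
    rows = []
    for s in strengths:
        obs = intervention_endpoint(params, InterventionSpec(kind, float(s)),
                                    refs=refs)
        rows.append({
            "kind": kind,
            "strength": float(s),
            "antibody_pct": obs.antibody_pct,
            "villous_area_pct": obs.villous_area_pct,
        })
    return pd.DataFrame(rows)


def _refit_ksab(params: ParameterSet, ref_ab: float, x_guess,
                *, rtol: float = 1e-4, max_iter: int = 40) -> ParameterSet:
    """1-D re-validation: scale the antibody synthesis constant until the
    untreated gluten-diet antibody level equals ``ref_ab``.

    The steady-state antibody level is nearly proportional to ksab (the only
    feedback is the weak antibody effect on the epithelium), so fixed-point
    rescaling converges in a few steps.
    """
    p = params
    x = np.asarray(x_guess, dtype=float)
    for _ in range(max_iter):
        net = build_network(p, PatientVariant.PATIENT)
        x = steady_state(net, x)
        ab = x[net.index["Ab"]]
        if ab <= 0:
            raise SimulationError("antibody level vanished during ksab re-fit")
        if abs(ab - ref_ab) <= rtol * ref_ab:
            return p
        p = p.scaled("k_ab_syn", ref_ab / ab)
    raise SimulationError("ksab re-fit did not converge")


def ec50_ratio_scan(
    params: ParameterSet,
    ratios: Sequence[float] = (1, 5, 10, 20, 40, 80, 160),
    *,
    refs: References | None = None,
) -> pd.DataFrame:
    """Sensitivity of TG-2 inhibition to native/deamidated immunogenicity.

    For each ratio r the native-peptide EC50 is set to r times the (fixed)
    deamidated-peptide EC50; the antibody synthesis constant is re-fitted so
    the untreated gluten-diet antibody level is restored (model
    re-validation); then complete TG-2 inhibition is applied and the
    residual antibody level recorded.
    """
    if any(r < 1 for r in ratios):
        raise ValueError("EC50 ratios must be >= 1")
    if refs is None:
        refs = compute_references(params)
    rows = []
    for r in ratios:
        p_r = params.with_values(ec50_nat=float(r) * params["ec50_deam"])
        row = {"ratio": float(r)}
        try:
            p_r = _refit_ksab(p_r, refs.ref_ab, refs.x_gluten)
            obs = intervention_endpoint(
                p_r, InterventionSpec("tg2_inhibitor", 1.0), refs=refs)
            row.update(
                ksab=p_r["k_ab_syn"],
                antibody_pct=obs.antibody_pct,
                villous_area_pct=obs.villous_area_pct,
                converged=True,
            )
        except SimulationError as err:
            row.update(ksab=np.nan, antibody_pct=np.nan,
                       villous_area_pct=np.nan, converged=False,
                       error=str(err))
        rows.append(row)
    return pd.DataFrame(rows)


def robustness_scan(
    params: ParameterSet,
    spec: InterventionSpec,
    n_draws: int,
    seed: int,
    *,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Endpoint distribution under parameter uncertainty.

    Draws parameter values independently and uniformly within their 95%
    confidence boxes (parameters without a CI stay fixed), recomputes the
    normalisation references per draw, and returns one row per draw plus the
    draw outcome.  Failed draws (non-convergent steady states) are recorded,
    not fatal.  Deterministic for a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [n for n in params
                 if params.meta(n).ci_lo is not None]
    rows = []
    for i in range(n_draws):
        draw = {
            n: rng.uniform(params.meta(n).ci_lo, params.meta(n).ci_hi)
            for n in names
        }
        p_i = params.with_values(**draw)
        row: dict = {"draw": i, **{f"p_{k}": v for k, v in draw.items()}}
        try:
            refs_i = compute_references(p_i)
            obs = intervention_endpoint(p_i, spec, refs=refs_i)
            row.update(antibody_pct=obs.antibody_pct,
                       villous_area_pct=obs.villous_area_pct, ok=True)
        except (SimulationError, ValueError) as err:
            row.update(antibody_pct=np.nan, villous_area_pct=np.nan,
                       ok=False, error=str(err))
        rows.append(row)
    return pd.DataFrame(rows)


def robustness_summary(draws: pd.DataFrame) -> pd.DataFrame:
    """Quantile summary of a robustness scan."""
    ok = draws[draws["ok"]]
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    out = {
        "quantile": qs,
        "antibody_pct": np.quantile(ok["antibody_pct"], qs) if len(ok) else
        [math.nan] * len(qs),
        "villous_area_pct": np.quantile(ok["villous_area_pct"], qs) if len(ok)
        else [math.nan] * len(qs),
    }
    return pd.DataFrame(out)
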