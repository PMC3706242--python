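"""Numerical integration, steady states and normalised observables.

Time is in days.  The two disease read-outs are

* ``antibody_pct`` — plasma antibody level as a percentage of the untreated
  gluten-diet steady state (100% by construction), and
* ``villous_area_pct`` — villous area as a percentage of the healthy
  subject, proxied by the mature-IEC level (the only villous-mass variable
  in the model; epithelial death and maturation drive every villous-area
  statement the model makes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import ModelError, PatientVariant, ReactionNetwork, build_network
from .parameters import ParameterSet

__all__ = [
    "Trajectory",
    "Observables",
    "SimulationError",
    "simulate",
    "steady_state",
    "observables",
    "References",
    "compute_references",
    "default_initial_state",
]

#: default solver tolerances (stiff system; relative / absolute)
RTOL = 1e-8
ATOL = 1e-10
#: residual norm below which a state counts as steady
STEADY_TOL = 1e-9
#: horizon used by the integrate-to-steady-state fallback [days]
STEADY_HORIZON = 6000.0


class SimulationError(RuntimeError):
    """Integration or root-finding failure; carries the last good state."""

    def __init__(self, message: str, t_last: float | None = None,
                 x_last: np.ndarray | None = None):
        super().__init__(message)
        self.t_last = t_last
        self.x_last = x_last


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course on a strictly increasing grid of days."""

    t: np.ndarray                 # (n_t,)
    x: np.ndarray                 # (n_t, n_species), clipped at zero
    species: tuple[str, ...]
    params: ParameterSet
    variant: PatientVariant

    def __post_init__(self):
        if np.any(np.diff(self.t) <= 0):
            raise ModelError("trajectory time grid must be strictly increasing")

    def series(self, name: str) -> np.ndarray:
        return self.x[:, self.species.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.x[-1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.x, columns=list(self.species))
        df.insert(0, "time", self.t)
        return df


@dataclass(frozen=True)
class Observables:
    """Normalised disease read-outs of a single state."""

    antibody_pct: float
    villous_area_pct: float


def default_initial_state(net: ReactionNetwork) -> np.ndarray:
    """A benign starting point: quiescent tissue with healthy epithelium.

    Small seeds in the cellular pools keep the solver away from the trivial
    all-zero manifold; the attracting steady state does not depend on them.
    """
    p = net.params
    x = net.state(
        IEC=p["iec_healthy"],
        IEL=p["k_iel_source"] / p["kd_iel"],
        T=p["k_t_source"] / p["kd_t"],
    )
    if "APC" in net.index:
        x[net.index["APC"]] = 1e-3
    return x


def simulate(
    net: ReactionNetwork,
    x0: np.ndarray,
    t_grid: np.ndarray,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the stiff ODE system over ``t_grid`` (days).

    Outputs are clipped at zero; the solver itself may transiently dip a few
    ``atol`` below zero, which is within the contract of the model state.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ModelError("t_grid must be a strictly increasing 1-D array")
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (net.n_species,):
        raise ModelError(f"x0 has shape {x0.shape}, expected ({net.n_species},)")
    if np.any(x0 < 0):
        raise ModelError("x0 must be non-negative")

    sol = solve_ivp(
        net._ode_rhs,
        (t_grid[0], t_grid[-1]),
        x0,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        t_last = float(sol.t[-1]) if sol.t.size else float(t_grid[0])
        x_last = sol.y[:, -1] if sol.t.size else x0
        raise SimulationError(
            f"integration failed at t={t_last:.3g} d: {sol.message}",
            t_last=t_last,
            x_last=np.maximum(x_last, 0.0),
        )
    return Trajectory(
        t=sol.t, x=np.maximum(sol.y.T, 0.0), species=net.species,
        params=net.params, variant=net.variant,
    )


def _integrate_to_rest(net, x, horizon):
    t0 = 0.0
    span = horizon
    for _ in range(3):
        traj = simulate(net, x, np.linspace(t0, t0 + span, 60))
        x = traj.final_state
        if np.linalg.norm(net.rhs(x), ord=np.inf) < 10 * STEADY_TOL:
            break
        span *= 2
    return x


def steady_state(
    net: ReactionNetwork,
    x_guess: np.ndarray | None = None,
    *,
    tol: float = STEADY_TOL,
) -> np.ndarray:
    """Solve ``rhs(x) = 0`` for a non-negative steady state.

    Newton-type root solving from ``x_guess``; if that fails or lands on a
    negative or non-steady root, falls back to long integration (several
    simulated years) followed by a final polish.
    """
    if x_guess is None:
        x_guess = default_initial_state(net)
    x_guess = np.asarray(x_guess, dtype=float)
    if np.any(x_guess < 0):
        raise ModelError("x_guess must be non-negative")

    scale = np.maximum(np.abs(x_guess), 1e-3)

    def fun(z):
        return net._ode_rhs(0.0, np.maximum(z, 0.0)) / scale

    def accept(z):
        z = np.asarray(z, dtype=float)
        if np.any(z < -1e-12 * np.maximum(scale, 1.0)):
            return None
        z = np.maximum(z, 0.0)
        if np.linalg.norm(net.rhs(z), ord=np.inf) < tol * max(1.0, scale.max()):
            return z
        return None

    sol = root(fun, x_guess, method="hybr", tol=1e-13)
    found = accept(sol.x) if sol.success else None
    if found is None:
        # integration fallback: relax towards the attractor, then polish
        x_rest = _integrate_to_rest(net, x_guess, STEADY_HORIZON)
        sol = root(fun, x_rest, method="hybr", tol=1e-13)
        found = accept(sol.x) if sol.success else None
        if found is None:
            found = accept(x_rest)
        if found is None:
            raise SimulationError(
                "steady state did not converge; consider a longer "
                "integration-to-steady-state horizon",
                t_last=STEADY_HORIZON,
                x_last=x_rest,
            )
    return found


def observables(state: np.ndarray, net: ReactionNetwork,
                ref_ab: float, ref_iec: float) -> Observables:
    """Normalise a state into percentage read-outs.

    ``ref_ab`` is the antibody level at the untreated gluten-diet steady
    state, ``ref_iec`` the healthy mature-IEC level; both must be positive.
    """
    if not (ref_ab > 0 and ref_iec > 0):
        raise ValueError("reference levels must be positive")
    state = np.asarray(state, dtype=float)
    ab = state[net.index["Ab"]]
    iec = state[net.index["IEC"]]
    return Observables(
        antibody_pct=100.0 * ab / ref_ab,
        villous_area_pct=100.0 * iec / ref_iec,
    )


@dataclass(frozen=True)
class References:
    """Normalisation anchors shared by every scenario of one parameter set."""

    ref_ab: float            # antibody level, untreated patient on gluten diet
    ref_iec: float           # mature-IEC level, healthy subject
    x_gluten: np.ndarray     # untreated gluten-diet steady state
    x_healthy: np.ndarray    # healthy steady state (healthy-variant layout)


def compute_references(params: ParameterSet) -> References:
    """Anchor the percentage scales of a parameter set.

    Recomputed from scratch (two steady states) whenever parameters change,
    e.g. per robustness draw.
    """
    healthy_net = build_network(params, PatientVariant.HEALTHY)
    x_h = steady_state(healthy_net)
    patient_net = build_network(params, PatientVariant.PATIENT)
    x_g = steady_state(patient_net)
    ref_ab = float(x_g[patient_net.index["Ab"]])
    ref_iec = float(x_h[healthy_net.index["IEC"]])
    if ref_ab <= 0:
        raise SimulationError(
            "untreated gluten-diet steady state has no antibodies; "
            "parameter set cannot anchor the antibody scale"
        )
    return References(ref_ab=ref_ab, ref_iec=ref_iec, x_gluten=x_g, x_healthy=x_h)
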