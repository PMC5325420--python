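"""Right-hand side evaluation and fixed-step RK4 integration.

The kinetics follow saturating (Michaelis-Menten) edge terms.  For an
activating edge j -> i the rate is

    V_ji * (1 - X_i) / (g_i * K_ji + (1 - X_i)) * X_j

so the inactive fraction (1 - X_i) is the substrate.  For an inhibiting
edge the default ("deactivation") convention uses the active fraction as
substrate,

    V_ji * X_i / (g_i * K_ji + X_i) * X_j        (V_ji < 0)

which models enzymatic deactivation of X_i and keeps every trajectory
nonnegative.  The literal form, in which (1 - X_i) saturates inhibiting
edges too, is available via ``inhibition="literal"`` for comparison; it
can drive states negative and is not the default.

A drug targeting species i acts as a competitive inhibitor: it inflates
every Michaelis constant of i's activation routes by the factor
g_i = 1 + dose / K_D, including the receptor input constants K_A / K_C
when the target is A or C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .model_core import (
    DrugRegimen,
    KineticParameters,
    ModuleTopology,
    Species,
    StimulusProfile,
    N_SPECIES,
)

__all__ = [
    "Trajectory",
    "drug_factor",
    "drug_factors",
    "rhs",
    "simulate",
    "integrated_output",
]

_INHIBITION_MODES = ("deactivation", "literal")


def drug_factor(
    species,
    regimen: DrugRegimen,
    t: float,
    params: KineticParameters,
) -> float:
    """Michaelis-constant inflation factor g_i of one species at time t.

    g_i = 1 + (sum of doses of active entries targeting the species)/K_D;
    doses of multiple entries on one target add, and an entry is active
    once t >= t_on.  Equals 1 for untargeted species and for the empty
    regimen.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    sp = Species.parse(species)
    total = 0.0
    for e in regimen.entries:
        if e.target is sp and t >= e.t_on:
            total += e.dose
    return 1.0 + total / params.K_D


def drug_factors(
    regimen: DrugRegimen, t: float, params: KineticParameters
) -> np.ndarray:
    """Vector of g_i for all five species at time t."""
    g = np.ones(N_SPECIES)
    for e in regimen.entries:
        if t >= e.t_on:
            g[e.target.idx] += e.dose / params.K_D
    return g


def _input_vector(
    t: float,
    params: KineticParameters,
    stimuli: tuple[StimulusProfile, StimulusProfile],
    g: np.ndarray,
) -> np.ndarray:
    """Receptor input f_i(t): saturating response of A to G1 and C to G2."""
    g1, g2 = stimuli
    f = np.zeros(N_SPECIES)
    s1 = g1(t)
    if s1 > 0:
        f[Species.A.idx] = params.V_A * s1 / (g[Species.A.idx] * params.K_A + s1)
    s2 = g2(t)
    if s2 > 0:
        f[Species.C.idx] = params.V_C * s2 / (g[Species.C.idx] * params.K_C + s2)
    return f


def rhs(
    X: np.ndarray,
    t: float,
    topology: ModuleTopology,
    params: KineticParameters,
    stimuli: tuple[StimulusProfile, StimulusProfile],
    regimen: DrugRegimen = DrugRegimen(),
    inhibition: str = "deactivation",
) -> np.ndarray:
    """Time derivative of the five activation fractions."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("state contains non-finite values")
    if inhibition not in _INHIBITION_MODES:
        raise ValueError(
            f"inhibition must be one of {_INHIBITION_MODES}, got {inhibition!r}"
        )
    Vpos = np.where(topology.V > 0, topology.V, 0.0)
    Vneg = np.where(topology.V < 0, topology.V, 0.0)
    Ksafe = np.where(topology.V != 0, topology.K, 1.0)
    g = drug_factors(regimen, t, params)
    f_vec = _input_vector(t, params, stimuli, g)
    return _rhs_core(
        X, Vpos, Vneg, Ksafe, g, f_vec, params.d,
        literal=(inhibition == "literal"),
    )


def _rhs_core(X, Vpos, Vneg, Ksafe, g, f_vec, d, literal):
    one_minus = 1.0 - X
    gK = Ksafe * g[np.newaxis, :]
    denom_act = gK + one_minus[np.newaxis, :]
    if literal:
        dX = one_minus * (X @ ((Vpos + Vneg) / denom_act))
    else:
        denom_inh = gK + X[np.newaxis, :]
        dX = one_minus * (X @ (Vpos / denom_act)) + X * (X @ (Vneg / denom_inh))
    dX += f_vec
    dX -= d * X
    return dX


@dataclass(frozen=True)
class Trajectory:
    """Simulated state time courses on a uniform grid.

    ``states[k]`` is the five-vector (A, B, C, D, O) at ``times[k]``.
    """

    times: np.ndarray
    states: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        if self.states.shape != (self.times.size, N_SPECIES):
            raise ValueError("states must be (len(times), 5)")
        if self.times.size < 2 or self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must start at 0 and strictly increase")

    def species(self, which) -> np.ndarray:
        """Time course of one species."""
        return self.states[:, Species.parse(which).idx]

    @property
    def T(self) -> float:
        return float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-form table (time, species, value + provenance columns)."""
        n = self.times.size
        frames = []
        for sp in Species:
            frames.append(pd.DataFrame({
                "time": self.times,
                "species": sp.name,
                "value": self.states[:, sp.idx],
            }))
        df = pd.concat(frames, ignore_index=True)
        for key in ("module_id", "regimen", "stimulus"):
            if key in self.metadata:
                df[key] = self.metadata[key]
        return df


def simulate(
    topology: ModuleTopology,
    params: KineticParameters | None = None,
    stimuli: tuple[StimulusProfile, StimulusProfile] | None = None,
    regimen: DrugRegimen = DrugRegimen(),
    T: float = 100.0,
    h: float = 0.01,
    X0: np.ndarray | None = None,
    inhibition: str = "deactivation",
) -> Trajectory:
    """Integrate the module kinetics with classical fixed-step RK4.

    Parameters
    ----------
    topology : ModuleTopology
        Module to simulate.
    params : KineticParameters, optional
        Kinetic constants; standard values if omitted.
    stimuli : (StimulusProfile, StimulusProfile), optional
        G1 and G2 profiles; the basic S0 pulse pair if omitted.
    regimen : DrugRegimen
        Drug treatment; empty means untreated.
    T, h : float
        Horizon and step (defaults 100 and 0.01); T/h must be integral
        within rounding.
    X0 : array, optional
        Initial activation fractions (default: all zero).
    inhibition : str
        "deactivation" (default) or "literal"; see module docstring.

    Raises
    ------
    FloatingPointError
        If the state becomes non-finite, naming the time of blow-up.
    """
    from .model_core import stimulus_library

    if params is None:
        params = KineticParameters()
    if stimuli is None:
        stimuli = stimulus_library()["S0"]
    if inhibition not in _INHIBITION_MODES:
        raise ValueError(
            f"inhibition must be one of {_INHIBITION_MODES}, got {inhibition!r}"
        )
    if T <= 0 or h <= 0:
        raise ValueError("T and h must be positive")
    n_steps = int(round(T / h))
    if abs(n_steps * h - T) > 1e-9 * max(1.0, T):
        raise ValueError(f"T={T} is not an integral multiple of h={h}")

    if X0 is None:
        X = np.zeros(N_SPECIES)
    else:
        X = np.asarray(X0, dtype=float).copy()
        if X.shape != (N_SPECIES,):
            raise ValueError("X0 must have shape (5,)")

    Vpos = np.where(topology.V > 0, topology.V, 0.0)
    Vneg = np.where(topology.V < 0, topology.V, 0.0)
    Ksafe = np.where(topology.V != 0, topology.K, 1.0)
    literal = inhibition == "literal"

    times = np.empty(n_steps + 1)
    states = np.empty((n_steps + 1, N_SPECIES))
    times[0] = 0.0
    states[0] = X
    half = 0.5 * h
    sixth = h / 6.0
    d = params.d
    for k in range(n_steps):
        t = k * h
        # the stimulus and drug factor are piecewise constant, so they are
        # sampled once per step (at the midpoint): each RK4 step then
        # integrates a smooth system, and input breakpoints that fall on
        # grid points are handled exactly instead of being smeared by
        # inconsistent stage sampling
        g = drug_factors(regimen, t + half, params)
        f_vec = _input_vector(t + half, params, stimuli, g)
        k1 = _rhs_core(X, Vpos, Vneg, Ksafe, g, f_vec, d, literal)
        k2 = _rhs_core(X + half * k1, Vpos, Vneg, Ksafe, g, f_vec, d, literal)
        k3 = _rhs_core(X + half * k2, Vpos, Vneg, Ksafe, g, f_vec, d, literal)
        k4 = _rhs_core(X + h * k3, Vpos, Vneg, Ksafe, g, f_vec, d, literal)
        X = X + sixth * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(X)):
            raise FloatingPointError(
                f"state became non-finite at t={(k + 1) * h:.4f}"
            )
        times[k + 1] = (k + 1) * h
        states[k + 1] = X

    metadata = {
        "module_id": topology.module_id,
        "crosstalk_scale": topology.crosstalk_scale,
        "regimen": regimen.label,
        "stimulus": f"{stimuli[0].name}/{stimuli[1].name}",
        "params_digest": params.digest(),
        "T": T,
        "h": h,
        "inhibition": inhibition,
    }
    return Trajectory(times=times, states=states, metadata=metadata)


def integrated_output(traj: Trajectory, T: float = 100.0) -> float:
    """Integrated output IO = integral of O(t) over [0, T] (trapezoid rule).

    The trajectory grid must cover [0, T]; integration stops at T even if
    the trajectory extends further.
    """
    if traj.T < T - 1e-9:
        raise ValueError(
            f"trajectory covers [0, {traj.T}], cannot integrate to T={T}"
        )
    mask = traj.times <= T + 1e-12
    t = traj.times[mask]
    o = traj.species(Species.O)[mask]
    return float(np.trapezoid(o, t))
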