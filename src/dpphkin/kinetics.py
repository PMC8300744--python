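"""Reaction scheme of the DPPH* scavenging assay as an ODE system.

The stable radical DPPH* (2,2-diphenyl-1-picrylhydrazyl) is bleached by an
antioxidant AOH through a second-order hydrogen-transfer step,

    AOH + DPPH*  --k1-->  AO* + DPPH-H,

optionally followed by a side reaction in which the transient antioxidant
radical AO* quenches a second DPPH*,

    AO* + DPPH*  --k2-->  products.

Internal units are molar and seconds throughout; micromolar/minute
conversions belong at the I/O boundary.  The side-reaction products are
lumped into a single inert species ``p2`` so that the antioxidant mass
balance aoh + ao + p2 = aoh0 can be checked; DPPH-H is never tracked
because it does not feed back into the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateParameters",
    "InitialState",
    "TimeGrid",
    "ConcentrationTrace",
    "IntegrationError",
    "InvalidStateError",
    "reaction_rhs",
    "simulate_decay",
    "closed_form_simple_decay",
]

#: concentrations more negative than this (M) are treated as genuinely
#: invalid rather than integrator round-off
NEGATIVE_TOL = 1e-15

#: default integrator tolerances (relative; absolute in M)
RTOL = 1e-8
ATOL = 1e-12


class InvalidStateError(ValueError):
    """A species concentration is negative beyond round-off tolerance."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the solver message as diagnostics."""


@dataclass(frozen=True)
class RateParameters:
    """Second-order rate constants of the scheme, in M^-1 s^-1.

    ``include_side=False`` selects the one-reaction scheme; ``k2`` is then
    treated as exactly zero regardless of its stored value.
    """

    k1: float
    k2: float = 0.0
    include_side: bool = True

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError(f"k1 must be positive, got {self.k1}")
        if self.k2 < 0:
            raise ValueError(f"k2 must be non-negative, got {self.k2}")

    @property
    def effective_k2(self) -> float:
        return self.k2 if self.include_side else 0.0


@dataclass(frozen=True)
class InitialState:
    """Initial concentrations in M: DPPH*, antioxidant AOH, transient AO*."""

    dpph0: float
    aoh0: float
    ao0: float = 0.0

    def __post_init__(self) -> None:
        if not self.dpph0 > 0:
            raise ValueError(f"dpph0 must be positive, got {self.dpph0}")
        if self.aoh0 < 0 or self.ao0 < 0:
            raise ValueError("aoh0 and ao0 must be non-negative")


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing observation times in seconds, starting at 0."""

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("time grid needs at least 2 points")
        if t[0] < 0 or np.any(t < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @classmethod
    def regular(cls, duration: float, step: float = 1.0) -> "TimeGrid":
        """Uniform grid 0..duration at ``step`` second spacing (1 Hz default)."""
        return cls(np.arange(0.0, duration + 0.5 * step, step))


@dataclass(frozen=True)
class ConcentrationTrace:
    """Time-resolved species concentrations (M) on a shared grid (s)."""

    times: np.ndarray
    dpph: np.ndarray
    aoh: np.ndarray
    ao: np.ndarray
    p2: np.ndarray = field(default=None)  # lumped side-reaction product

    def __post_init__(self) -> None:
        if self.p2 is None:
            object.__setattr__(self, "p2", np.zeros_like(np.asarray(self.dpph)))


def reaction_rhs(state, params: RateParameters):
    """Time derivatives (M/s) of (dpph, aoh, ao, p2) under the scheme.

    The first reaction consumes AOH and DPPH* at rate k1*[AOH][DPPH*]; the
    side reaction consumes AO* and DPPH* at k2*[AO*][DPPH*] and deposits the
    flux into the lumped product p2.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state[:3] < -NEGATIVE_TOL):
        raise InvalidStateError(f"negative concentrations in state {state[:3]}")
    dpph, aoh, ao = np.clip(state[:3], 0.0, None)
    k2 = params.effective_k2
    r1 = params.k1 * aoh * dpph
    r2 = k2 * ao * dpph
    return np.array([-r1 - r2, -r1, r1 - r2, r2])


def simulate_decay(
    params: RateParameters,
    init: InitialState,
    grid: TimeGrid,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> ConcentrationTrace:
    """Integrate the scheme over the grid with a stiff-capable adaptive solver.

    Returns the full :class:`ConcentrationTrace` including the lumped
    side-reaction product, so mass balance aoh + ao + p2 = aoh0 holds to
    integrator tolerance.  Raises :class:`IntegrationError` on solver
    failure.
    """
    y0 = [init.dpph0, init.aoh0, init.ao0, 0.0]
    k2 = params.effective_k2
    k1 = params.k1

    def rhs(t, y):
        # trial states inside the solver may dip slightly negative; clip
        # rather than raise (the public reaction_rhs validates instead)
        dpph, aoh, ao = np.clip(y[:3], 0.0, None)
        r1 = k1 * aoh * dpph
        r2 = k2 * ao * dpph
        return (-r1 - r2, -r1, r1 - r2, r2)

    sol = solve_ivp(
        rhs,
        (grid.times[0], grid.times[-1]),
        y0,
        method="LSODA",
        t_eval=grid.times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    y = sol.y
    # round-off clipping only (up to ~10x the absolute tolerance); anything
    # more negative is a solver defect
    y = np.where((y < 0) & (y > -10 * atol), 0.0, y)
    return ConcentrationTrace(times=sol.t, dpph=y[0], aoh=y[1], ao=y[2], p2=y[3])


def closed_form_simple_decay(k1: float, dpph0: float, aoh0: float, t) -> np.ndarray:
    """Analytic [DPPH*](t) for the one-reaction scheme.

    For unequal initial concentrations the mixed second-order integrated
    rate law applies: with d = dpph0 - aoh0,

        [DPPH*](t) = dpph0 * d / (dpph0 - aoh0 * exp(-d * k1 * t)),

    which recovers dpph0 at t=0 and tends to d when DPPH* is in excess.
    Equal initial concentrations degenerate to 1/(1/c0 + k1*t).
    """
    if not k1 > 0:
        raise ValueError("k1 must be positive")
    if dpph0 < 0 or aoh0 < 0:
        raise ValueError("initial concentrations must be non-negative")
    t = np.asarray(t, dtype=float)
    if aoh0 == 0:
        return np.full_like(t, dpph0)
    delta = dpph0 - aoh0
    # the two branches agree in the delta->0 limit; switch on relative gap
    if abs(delta) < 1e-12 * max(dpph0, aoh0):
        return 1.0 / (1.0 / dpph0 + k1 * t)
    return dpph0 * delta / (dpph0 - aoh0 * np.exp(-delta * k1 * t))
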