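"""Linear four-compartment kinetics of an orally or intravenously dosed drug.

The structural model has a gut depot (oral dosing only), a central plasma
compartment, one lumped peripheral tissue compartment, and a cumulative
urine compartment::

    dY_depot/dt  = -ka * Y_depot
    dY_plasma/dt = +F * ka * Y_depot - Cl * C_plasma - Q * C_plasma + Q * Y_peri / V3
    dY_peri/dt   = +Q * C_plasma - Q * Y_peri / V3
    dY_urine/dt  = +Cl * C_plasma

with ``C_plasma = Y_plasma / V2``.  Amounts are in µmol, volumes in litres,
clearances in L/h, rates in 1/h, time in hours.  Bioavailability F scales
the depot-to-plasma transfer (not the depot initial condition), so for a
gavage dose D the absorbed mass asymptote is ``F * D``; an IV bolus is
placed directly into plasma and bypasses both the depot and F.

Because the system is linear with constant coefficients, :func:`solve`
evaluates the matrix exponential exactly rather than stepping an ODE
integrator.  A vectorised bi-exponential fast path used by the estimation
and simulation modules lives at the bottom of this file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PKParameters",
    "MicroConstants",
    "DoseEvent",
    "CompartmentState",
    "RadiationEffect",
    "Trajectory",
    "micro_constants",
    "disposition_eigenvalues",
    "terminal_half_life",
    "apply_radiation",
    "auc_infinity",
    "solve",
]


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters of the two-compartment model.

    Attributes
    ----------
    ka : float
        First-order absorption rate from the gut depot (1/h).
    F : float
        Oral bioavailability, the fraction of a gavage dose reaching
        systemic circulation, in (0, 1].
    Cl : float
        Renal clearance out of plasma into urine (L/h).
    Q : float
        Inter-compartmental clearance between plasma and the lumped
        peripheral tissues (L/h).
    V2 : float
        Apparent central (plasma) volume (L).
    V3 : float
        Apparent peripheral volume (L).
    """

    ka: float
    F: float
    Cl: float
    Q: float
    V2: float
    V3: float

    def __post_init__(self) -> None:
        if not self.ka > 0:
            raise ValueError(f"absorption rate ka must be > 0, got {self.ka}")
        if not 0 < self.F <= 1:
            raise ValueError(f"bioavailability F must be in (0, 1], got {self.F}")
        if self.Cl < 0 or self.Q < 0:
            raise ValueError("clearances Cl and Q must be >= 0")
        if not (self.V2 > 0 and self.V3 > 0):
            raise ValueError("volumes V2 and V3 must be > 0")


@dataclass(frozen=True)
class MicroConstants:
    """Micro-rate reparameterisation: k10 = Cl/V2, k12 = Q/V2, k21 = Q/V3 (1/h)."""

    k10: float
    k12: float
    k21: float

    def __post_init__(self) -> None:
        if min(self.k10, self.k12, self.k21) < 0:
            raise ValueError("micro-constants must be >= 0")


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: amount in µmol, route 'gavage' or 'iv', time in h."""

    amount: float
    route: str
    time: float = 0.0

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.route not in ("gavage", "iv"):
            raise ValueError(f"route must be 'gavage' or 'iv', got {self.route!r}")
        if self.time < 0:
            raise ValueError("dose time must be >= 0")


@dataclass(frozen=True)
class CompartmentState:
    """Amounts (µmol) in each compartment and the plasma concentration (µmol/L)."""

    depot: float
    plasma: float
    peri: float
    urine: float
    conc_plasma: float


@dataclass(frozen=True)
class RadiationEffect:
    """Multiplicative irradiated/control ratios on ka, Cl, Q and F."""

    r_ka: float
    r_Cl: float
    r_Q: float
    r_F: float

    def __post_init__(self) -> None:
        if min(self.r_ka, self.r_Cl, self.r_Q, self.r_F) <= 0:
            raise ValueError("radiation ratios must be > 0")


@dataclass(frozen=True)
class Trajectory:
    """Model solution on a time grid; arrays are aligned with ``times``."""

    times: np.ndarray
    depot: np.ndarray
    plasma: np.ndarray
    peri: np.ndarray
    urine: np.ndarray
    conc_plasma: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    def states(self) -> Iterator[CompartmentState]:
        for i in range(len(self.times)):
            yield CompartmentState(
                depot=float(self.depot[i]),
                plasma=float(self.plasma[i]),
                peri=float(self.peri[i]),
                urine=float(self.urine[i]),
                conc_plasma=float(self.conc_plasma[i]),
            )


def micro_constants(p: PKParameters) -> MicroConstants:
    """Convert the clearance/volume parameterisation to micro-rates."""
    return MicroConstants(k10=p.Cl / p.V2, k12=p.Q / p.V2, k21=p.Q / p.V3)


def disposition_eigenvalues(mc: MicroConstants) -> tuple[float, float]:
    """Eigenvalue magnitudes (alpha >= beta >= 0) of the plasma/peripheral block.

    alpha and beta are the (negated) eigenvalues of the 2x2 disposition
    matrix, i.e. the roots of ``x**2 - (k10+k12+k21) x + k10*k21``.  They
    satisfy ``alpha + beta = k10 + k12 + k21`` and ``alpha * beta = k10 * k21``.
    """
    s = mc.k10 + mc.k12 + mc.k21
    prod = mc.k10 * mc.k21
    disc = math.sqrt(max(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + disc)
    # beta computed from the product for accuracy when disc ~ s
    beta = prod / alpha if alpha > 0 else 0.0
    return alpha, beta


def terminal_half_life(p: PKParameters) -> float:
    """Terminal (beta-phase) half-life ln(2)/beta in hours.

    The slow eigenvalue governs the late log-linear decline of the plasma
    concentration; with substantial peripheral binding it can be far longer
    than the early-phase decline.
    """
    _, beta = disposition_eigenvalues(micro_constants(p))
    if beta <= 0:
        raise ValueError("model has no terminal elimination phase (beta = 0)")
    return math.log(2.0) / beta


def apply_radiation(p: PKParameters, r: RadiationEffect) -> PKParameters:
    """Typical parameters of the irradiated group: ratios multiply ka, Cl, Q, F.

    Volumes carry no radiation effect.  Raises if the scaled bioavailability
    would exceed 1.
    """
    new_F = p.F * r.r_F
    if new_F > 1:
        raise ValueError(f"scaled bioavailability {new_F:.4g} exceeds 1")
    return replace(p, ka=p.ka * r.r_ka, Cl=p.Cl * r.r_Cl, Q=p.Q * r.r_Q, F=new_F)


def auc_infinity(p: PKParameters, d: DoseEvent) -> float:
    """Exact AUC(0, inf) of the plasma concentration, µmol·h/L.

    All absorbed drug eventually leaves through urine, so
    ``Cl * integral(C_plasma) = F_route * dose`` and the AUC is
    ``F * dose / Cl`` for gavage and ``dose / Cl`` for IV.  Returns ``inf``
    for a non-eliminating model (Cl = 0).
    """
    if p.Cl == 0:
        return math.inf
    f = p.F if d.route == "gavage" else 1.0
    return f * d.amount / p.Cl


def _rate_matrix(p: PKParameters, route: str) -> np.ndarray:
    mc = micro_constants(p)
    f = p.F if route == "gavage" else 1.0
    return np.array(
        [
            [-p.ka, 0.0, 0.0, 0.0],
            [f * p.ka, -(mc.k10 + mc.k12), mc.k21, 0.0],
            [0.0, mc.k12, -mc.k21, 0.0],
            [0.0, mc.k10, 0.0, 0.0],
        ]
    )


def solve(p: PKParameters, d: DoseEvent, times: Sequence[float]) -> Trajectory:
    """Exact trajectory of the four compartments at the requested times.

    The system is linear and time-invariant, so the solution is
    ``y(t) = expm(A (t - t_dose)) y0`` evaluated exactly per time point;
    no step-size control is involved.  For gavage the depot holds the full
    dose at the dose time and F scales the depot-to-plasma transfer; for IV
    the full dose is placed in plasma and F plays no role.

    Parameters
    ----------
    times : sequence of float
        Non-decreasing times (h), all >= the dose time.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    if np.any(t < d.time):
        raise ValueError("all output times must be >= the dose time")

    a = _rate_matrix(p, d.route)
    if d.route == "gavage":
        y0 = np.array([d.amount, 0.0, 0.0, 0.0])
    else:
        y0 = np.array([0.0, d.amount, 0.0, 0.0])

    out = np.empty((len(t), 4))
    for i, ti in enumerate(t):
        out[i] = expm(a * (ti - d.time)) @ y0
    # clip tiny negative round-off in amounts
    out[np.abs(out) < 1e-300] = 0.0
    return Trajectory(
        times=t,
        depot=out[:, 0],
        plasma=out[:, 1],
        peri=out[:, 2],
        urine=out[:, 3],
        conc_plasma=out[:, 1] / p.V2,
    )


# ---------------------------------------------------------------------------
# Vectorised closed-form fast path
#
# Used by the likelihood and the simulator, where the same bi-exponential
# profile must be evaluated for hundreds of animals at once.  All inputs are
# broadcastable numpy arrays.  Setting Q = 0 (hence k12 = k21 = 0) reduces the
# expressions to the one-compartment model, which is how the nested reduced
# model is evaluated.
# ---------------------------------------------------------------------------


def _ein(lam: np.ndarray, t: np.ndarray) -> np.ndarray:
    """(1 - exp(-lam t)) / lam, continuous at lam = 0."""
    lam = np.asarray(lam, dtype=float)
    safe = np.where(lam > 1e-300, lam, 1.0)
    return np.where(lam > 1e-300, -np.expm1(-safe * t) / safe, t)


def _eigenvalues(k10, k12, k21):
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    # keep the two eigenvalues numerically separated
    disc = np.maximum(disc, 1e-12 * np.maximum(s, 1e-300))
    alpha = 0.5 * (s + disc)
    return alpha, s - alpha, disc


def iv_profiles(k10, k12, k21, V2, dose, t) -> tuple[np.ndarray, np.ndarray]:
    """IV-bolus plasma concentration (µmol/L) and cumulative urine (µmol)."""
    alpha, beta, disc = _eigenvalues(k10, k12, k21)
    ca = (alpha - k21) / disc
    cb = (k21 - beta) / disc
    plasma = dose * (ca * np.exp(-alpha * t) + cb * np.exp(-beta * t))
    urine = dose * k10 * (ca * _ein(alpha, t) + cb * _ein(beta, t))
    return plasma / V2, urine


def po_profiles(ka, F, k10, k12, k21, V2, dose, t) -> tuple[np.ndarray, np.ndarray]:
    """First-order-absorption plasma concentration and cumulative urine.

    When the absorption rate collides with a disposition eigenvalue it is
    nudged by one part in 1e6 to keep the partial-fraction form finite;
    exact confluence is handled by :func:`solve`.
    """
    alpha, beta, _ = _eigenvalues(k10, k12, k21)
    scale = np.maximum(alpha, ka)
    collide = (np.abs(ka - alpha) < 1e-9 * scale) | (np.abs(ka - beta) < 1e-9 * scale)
    ka = np.where(collide, ka * (1.0 + 1e-6), ka)
    ca = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
    cb = (k21 - beta) / ((ka - beta) * (alpha - beta))
    ck = (k21 - ka) / ((alpha - ka) * (beta - ka))
    amt = F * dose * ka
    plasma = amt * (
        ca * np.exp(-alpha * t) + cb * np.exp(-beta * t) + ck * np.exp(-ka * t)
    )
    urine = amt * k10 * (ca * _ein(alpha, t) + cb * _ein(beta, t) + ck * _ein(ka, t))
    return plasma / V2, urine


def conc_and_urine(
    ka,
    F,
    k10,
    k12,
    k21,
    V2,
    dose,
    is_iv,
    t,
) -> tuple[np.ndarray, np.ndarray]:
    """Plasma concentration (µmol/L) and cumulative urine amount (µmol) at t.

    Closed-form bi-/tri-exponential solution, broadcast over all arguments.
    ``is_iv`` is a boolean array selecting the IV bolus solution; elsewhere
    the gavage (depot) solution with bioavailability ``F`` is used.
    """
    ka, F, k10, k12, k21, V2, dose, is_iv, t = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (ka, F, k10, k12, k21, V2, dose)),
        np.asarray(is_iv, dtype=bool),
        np.asarray(t, dtype=float),
    )
    c_iv, u_iv = iv_profiles(k10, k12, k21, V2, dose, t)
    c_po, u_po = po_profiles(ka, F, k10, k12, k21, V2, dose, t)
    return np.where(is_iv, c_iv, c_po), np.where(is_iv, u_iv, u_po)
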