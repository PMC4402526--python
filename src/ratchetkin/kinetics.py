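"""Steady-state kinetics of the nucleotide-incorporation cycle under load.

The nucleotide-incorporation cycle of a replicative DNA polymerase is modeled
as a small unicyclic Markov scheme in which exactly one step carries the
mechanical translocation by one nucleotide and therefore feels the external
load ``F``.  Three coupling schemes are implemented:

* **Model 1** — translocation is power-stroked by dNTP binding; the binding
  and unbinding rates are load dependent.
* **Model 2** — translocation is power-stroked by PPi release; the PPi
  release rate is the only load-dependent rate.
* **Model 3** — a Brownian (thermal) ratchet: the dNTP/PPi-free enzyme
  diffuses between pre- and post-translocated positions, and binding of the
  incoming dNTP rectifies the motion by pinning the post-translocated state.

Load-dependent rates follow the Bell/Arrhenius form
``k(F) = k(0)·exp(F·d/kBT)`` where ``d`` is the distance over which the load
acts.  Loads are *signed*: ``F > 0`` aids translocation, ``F < 0`` hinders
it.  Forward translocation uses ``+d_T``, backward translocation ``−d_mT``.

The Model-3 velocity is expressed through the force-decomposed
Michaelis–Menten form

    1/v = a + b·e^{−F·d_b/kBT} + (r + s·e^{−F·d_s/kBT}) / [dNTP]

whose six coefficients map algebraically onto the cycle rates
(``a = 1/k_cat``, ``b = 1/k_T(0)``, ``r = (1 + k_off/k_cat)/k_on``,
``s/r = k_mT(0)/k_T(0)``, ``d_b = d_T``, ``d_s = d_T + d_mT``).

Every closed form in this module is checked elsewhere against
:func:`unicycle_steady_state`, a brute-force linear solve of the cycle's
master equation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KBT_22C",
    "Constants",
    "RatchetRates",
    "Model1Rates",
    "Model2Rates",
    "MMCoefficients",
    "LandscapeResult",
    "OccupancyResult",
    "PHI29_COEFFS",
    "PHI29_RATES",
    "InvalidParameterError",
    "DegenerateCycleError",
    "bell_rate",
    "velocity_model1",
    "velocity_model2",
    "velocity_model3",
    "unicycle_steady_state",
    "model1_cycle",
    "model2_cycle",
    "model3_cycle",
    "coefficients_from_rates",
    "rates_from_coefficients",
    "occupancy",
    "translocation_landscape",
    "rupture_force",
]

#: Thermal energy at 22 degC in pN.nm.
KBT_22C = 4.075


class InvalidParameterError(ValueError):
    """A rate, distance or thermal energy outside its physical domain."""


class DegenerateCycleError(RuntimeError):
    """The cycle's master equation is singular (e.g. all rates zero)."""


@dataclass(frozen=True)
class Constants:
    """Thermal constants. ``kBT`` in pN.nm; ``temperature`` in K (metadata)."""

    kBT: float = KBT_22C
    temperature: float = 295.15

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise InvalidParameterError("kBT must be positive")


def _serializable(obj) -> dict:
    return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in asdict(obj).items()}


@dataclass(frozen=True)
class RatchetRates:
    """Model-3 (Brownian ratchet) cycle rates and force distances.

    Parameters
    ----------
    k_on : float
        dNTP binding rate, per uM per s.
    k_off : float
        dNTP unbinding rate, per s (0 allowed: binding treated as committed).
    k_cat : float
        Lumped condensation + chemistry rate, per s (rate limiting).
    k_ppi : float
        PPi release rate, per s; much faster than ``k_cat`` and lumped into
        the 3-state cycle unless explicitly requested.
    k_T0, k_mT0 : float
        Forward / backward translocation rates at zero load, per s.
    d_T, d_mT : float
        Distances (nm) from the pre-translocated position to the transition
        state and from the transition state to the post-translocated
        position; their sum is the mechanical step size delta.
    """

    k_on: float = 5.0
    k_off: float = 0.0
    k_cat: float = 120.0
    k_ppi: float = 1.0e4
    k_T0: float = 670.0
    k_mT0: float = 420.0
    d_T: float = 0.35
    d_mT: float = 0.05

    def __post_init__(self) -> None:
        for name in ("k_on", "k_cat", "k_ppi", "k_T0", "k_mT0"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.k_off < 0:
            raise InvalidParameterError("k_off must be >= 0")
        if self.d_T < 0 or self.d_mT < 0:
            raise InvalidParameterError("distances must be >= 0")
        if self.k_ppi < 10 * self.k_cat:
            warnings.warn(
                "k_ppi < 10*k_cat: PPi release is assumed fast; lumping it "
                "into a 3-state cycle may be inaccurate",
                stacklevel=2,
            )

    @property
    def delta(self) -> float:
        """Mechanical step size (nm), pre- to post-translocated."""
        return self.d_T + self.d_mT

    def to_json(self) -> str:
        return json.dumps(_serializable(self))

    @classmethod
    def from_json(cls, text: str) -> "RatchetRates":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class Model1Rates:
    """Power-stroke-by-binding cycle: k_on(F), k_off(F) load dependent."""

    k_on0: float
    k_off0: float
    k_cat: float
    d_on: float = 0.35
    d_off: float = 0.0

    def __post_init__(self) -> None:
        if self.k_on0 <= 0 or self.k_cat <= 0:
            raise InvalidParameterError("k_on0 and k_cat must be positive")
        if self.k_off0 < 0:
            raise InvalidParameterError("k_off0 must be >= 0")
        if self.d_on < 0 or self.d_off < 0:
            raise InvalidParameterError("distances must be >= 0")

    def to_json(self) -> str:
        return json.dumps(_serializable(self))

    @classmethod
    def from_json(cls, text: str) -> "Model1Rates":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class Model2Rates:
    """Power-stroke-by-PPi-release cycle: k_ppi(F) load dependent."""

    k_on: float
    k_off: float
    k_cat: float
    k_mcat: float
    k_ppi0: float
    d_ppi: float = 0.35

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_cat, self.k_ppi0) <= 0:
            raise InvalidParameterError("k_on, k_cat, k_ppi0 must be positive")
        if self.k_off < 0 or self.k_mcat < 0:
            raise InvalidParameterError("k_off, k_mcat must be >= 0")
        if self.d_ppi < 0:
            raise InvalidParameterError("d_ppi must be >= 0")

    def to_json(self) -> str:
        return json.dumps(_serializable(self))

    @classmethod
    def from_json(cls, text: str) -> "Model2Rates":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class MMCoefficients:
    """The six coefficients of the force-decomposed Michaelis-Menten form.

    ``a`` and ``b`` (s) decompose 1/V_max(F); ``r`` and ``s_coef`` (s.uM,
    divided by [dNTP] in the velocity expression) decompose K_M(F)/V_max(F);
    ``d_b`` and ``d_s`` (nm) are the respective force-coupling distances.
    """

    a: float = 0.0084
    b: float = 0.0015
    r: float = 0.19
    s_coef: float = 0.12
    d_b: float = 0.35
    d_s: float = 0.40

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.r, self.s_coef) <= 0:
            raise InvalidParameterError("a, b, r, s_coef must be positive")
        if self.d_b < 0 or self.d_s < 0:
            raise InvalidParameterError("d_b, d_s must be >= 0")

    def to_json(self) -> str:
        return json.dumps(_serializable(self))

    @classmethod
    def from_json(cls, text: str) -> "MMCoefficients":
        return cls(**json.loads(text))


#: Published best-fit coefficients for the Phi29 DNA polymerase cycle.
PHI29_COEFFS = MMCoefficients()

#: Published cycle rates for the Phi29 DNA polymerase (derived from the
#: coefficients; k_off ~ 0 and k_ppi fast are the standard assumptions).
PHI29_RATES = RatchetRates()


@dataclass(frozen=True)
class LandscapeResult:
    """Translocation free-energy landscape at a given load.

    ``delta`` nm; ``K_delta`` dimensionless; ``dG_trans`` and
    ``barrier_shift`` in kBT units.
    """

    delta: float
    K_delta: float
    dG_trans: float
    barrier_shift: float


@dataclass(frozen=True)
class OccupancyResult:
    """Steady-state occupancies of the cycle, split free vs dNTP/PPi-bound."""

    M_free: float
    M_bound: float
    per_state: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary force law


def bell_rate(k0, d, F, kBT: float = KBT_22C):
    """Bell/Arrhenius load-dependent rate ``k0 * exp(F*d/kBT)``.

    ``F`` is the signed load (pN, aiding positive); ``d`` the signed
    distance (nm): forward rates use ``+d``, backward rates ``-d``.
    Accepts scalars or arrays in ``F``.
    """
    k0 = np.asarray(k0, dtype=float)
    if np.any(k0 <= 0):
        raise InvalidParameterError("k0 must be positive")
    if kBT <= 0:
        raise InvalidParameterError("kBT must be positive")
    out = k0 * np.exp(np.asarray(F, dtype=float) * d / kBT)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Closed-form velocities


def velocity_model3(F, dNTP, coeffs: MMCoefficients = PHI29_COEFFS,
                    kBT: float = KBT_22C):
    """Brownian-ratchet replication velocity (nt/s) at signed load F (pN).

    Evaluates 1/v = a + b e^{-F d_b/kBT} + (r + s e^{-F d_s/kBT})/[dNTP].
    Returns 0 where ``dNTP == 0`` (the cycle cannot close).
    """
    F = np.asarray(F, dtype=float)
    dNTP = np.asarray(dNTP, dtype=float)
    if np.any(dNTP < 0):
        raise InvalidParameterError("dNTP must be >= 0")
    inv_vmax = coeffs.a + coeffs.b * np.exp(-F * coeffs.d_b / kBT)
    km_term = coeffs.r + coeffs.s_coef * np.exp(-F * coeffs.d_s / kBT)
    with np.errstate(divide="ignore"):
        inv_v = inv_vmax + km_term / dNTP
    v = np.where(dNTP > 0, 1.0 / inv_v, 0.0)
    return v if v.ndim else float(v)


def velocity_model1(F, dNTP, rates: Model1Rates, kBT: float = KBT_22C):
    """Power-stroke-by-binding velocity: V_max = k_cat independent of load."""
    F = np.asarray(F, dtype=float)
    dNTP = np.asarray(dNTP, dtype=float)
    if np.any(dNTP < 0):
        raise InvalidParameterError("dNTP must be >= 0")
    k_on = bell_rate(rates.k_on0, rates.d_on, F, kBT)
    k_off = (bell_rate(rates.k_off0, -rates.d_off, F, kBT)
             if rates.k_off0 > 0 else np.zeros_like(F, dtype=float))
    with np.errstate(divide="ignore"):
        inv_v = 1.0 / rates.k_cat + (1.0 + k_off / rates.k_cat) / (k_on * dNTP)
    v = np.where(dNTP > 0, 1.0 / inv_v, 0.0)
    return v if v.ndim else float(v)


def velocity_model2(F, dNTP, rates: Model2Rates, kBT: float = KBT_22C):
    """Power-stroke-by-PPi-release velocity: k_ppi(F) the only load term."""
    F = np.asarray(F, dtype=float)
    dNTP = np.asarray(dNTP, dtype=float)
    if np.any(dNTP < 0):
        raise InvalidParameterError("dNTP must be >= 0")
    k_ppi = bell_rate(rates.k_ppi0, rates.d_ppi, F, kBT)
    back = 1.0 + rates.k_mcat / k_ppi
    with np.errstate(divide="ignore"):
        inv_v = (1.0 / k_ppi
                 + back / rates.k_cat
                 + (1.0 + (rates.k_off / rates.k_cat) * back)
                 / (rates.k_on * dNTP))
    v = np.where(dNTP > 0, 1.0 / inv_v, 0.0)
    return v if v.ndim else float(v)


# ---------------------------------------------------------------------------
# Brute-force steady state of an N-state unicyclic scheme


def unicycle_steady_state(forward, backward):
    """Steady state of an N-state cycle by direct linear solve.

    Parameters
    ----------
    forward, backward : sequence of float, length N
        ``forward[i]`` is the rate i -> i+1 (mod N); ``backward[i]`` the
        rate i+1 -> i (mod N).

    Returns
    -------
    velocity : float
        Net cycle flux (cycles per second; equal across all edges).
    occupancies : ndarray
        Per-state steady-state fractions summing to 1.
    """
    f = np.asarray(forward, dtype=float)
    b = np.asarray(backward, dtype=float)
    n = f.size
    if n < 2 or b.size != n:
        raise InvalidParameterError("need N >= 2 matched forward/backward rates")
    if np.any(f < 0) or np.any(b < 0):
        raise InvalidParameterError("rates must be >= 0")
    if not np.any(f > 0):
        raise DegenerateCycleError("no forward rate is positive")

    # Generator: dp/dt = Q p, Q[j, i] = rate i -> j for j != i.
    Q = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        Q[j, i] += f[i]
        Q[i, i] -= f[i]
        Q[i, j] += b[i]
        Q[j, j] -= b[i]
    A = Q.copy()
    A[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    try:
        p = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DegenerateCycleError("singular master equation") from exc
    if not np.all(np.isfinite(p)):
        raise DegenerateCycleError("non-finite steady state")
    velocity = float(f[0] * p[0] - b[0] * p[1 % n])
    return velocity, p


def model3_cycle(rates: RatchetRates, F: float, dNTP: float,
                 kBT: float = KBT_22C, lump_ppi: bool = True):
    """Edge rates of the ratchet cycle for :func:`unicycle_steady_state`.

    States (3-state, PPi release lumped): ``pre`` (free, pre-translocated),
    ``post`` (free, post-translocated), ``bound`` (dNTP-bound).  The
    4-state variant appends an explicit PPi-bound state drained by k_ppi.
    """
    kT = bell_rate(rates.k_T0, rates.d_T, F, kBT)
    kmT = bell_rate(rates.k_mT0, -rates.d_mT, F, kBT)
    if lump_ppi:
        forward = [kT, rates.k_on * dNTP, rates.k_cat]
        backward = [kmT, rates.k_off, 0.0]
        states = ["pre", "post", "bound"]
    else:
        forward = [kT, rates.k_on * dNTP, rates.k_cat, rates.k_ppi]
        backward = [kmT, rates.k_off, 0.0, 0.0]
        states = ["pre", "post", "bound", "ppi"]
    return forward, backward, states


def model1_cycle(rates: Model1Rates, F: float, dNTP: float,
                 kBT: float = KBT_22C):
    """2-state power-stroke-by-binding cycle (free -> bound -> free)."""
    k_on = bell_rate(rates.k_on0, rates.d_on, F, kBT)
    k_off = (bell_rate(rates.k_off0, -rates.d_off, F, kBT)
             if rates.k_off0 > 0 else 0.0)
    return [k_on * dNTP, rates.k_cat], [k_off, 0.0], ["free", "bound"]


def model2_cycle(rates: Model2Rates, F: float, dNTP: float,
                 kBT: float = KBT_22C):
    """3-state power-stroke-by-PPi-release cycle (free -> bound -> ppi)."""
    k_ppi = bell_rate(rates.k_ppi0, rates.d_ppi, F, kBT)
    forward = [rates.k_on * dNTP, rates.k_cat, k_ppi]
    backward = [rates.k_off, rates.k_mcat, 0.0]
    return forward, backward, ["free", "bound", "ppi"]


# ---------------------------------------------------------------------------
# Coefficient <-> rate algebra


def coefficients_from_rates(rates: RatchetRates) -> MMCoefficients:
    """Map ratchet cycle rates to the six Michaelis-Menten coefficients."""
    r = (1.0 + rates.k_off / rates.k_cat) / rates.k_on
    return MMCoefficients(
        a=1.0 / rates.k_cat,
        b=1.0 / rates.k_T0,
        r=r,
        s_coef=r * rates.k_mT0 / rates.k_T0,
        d_b=rates.d_T,
        d_s=rates.d_T + rates.d_mT,
    )


def rates_from_coefficients(coeffs: MMCoefficients,
                            k_off_over_kcat: float = 0.0,
                            k_ppi: float = 1.0e4) -> RatchetRates:
    """Invert the coefficient map; exact round trip with the forward map.

    ``k_off_over_kcat`` resolves the (1 + k_off/k_cat) factor inside ``r``
    (0 by default, i.e. binding treated as committed); ``k_ppi`` is passed
    through since the coefficients carry no information about it.
    """
    if coeffs.d_s < coeffs.d_b:
        raise InvalidParameterError(
            "d_s < d_b would imply a negative transition-to-post distance")
    k_cat = 1.0 / coeffs.a
    k_T0 = 1.0 / coeffs.b
    k_on = (1.0 + k_off_over_kcat) / coeffs.r
    return RatchetRates(
        k_on=k_on,
        k_off=k_off_over_kcat * k_cat,
        k_cat=k_cat,
        k_ppi=k_ppi,
        k_T0=k_T0,
        k_mT0=k_T0 * coeffs.s_coef / coeffs.r,
        d_T=coeffs.d_b,
        d_mT=coeffs.d_s - coeffs.d_b,
    )


# ---------------------------------------------------------------------------
# Derived quantities


def occupancy(rates: RatchetRates, F: float, dNTP: float,
              kBT: float = KBT_22C, lump_ppi: bool = True) -> OccupancyResult:
    """Steady-state occupancies split into dNTP/PPi-free vs -bound.

    With the 3-state (lumped PPi) cycle the identity
    ``M_bound = v / k_cat`` holds, since the bound state drains at k_cat.
    """
    forward, backward, states = model3_cycle(rates, F, dNTP, kBT, lump_ppi)
    _, p = unicycle_steady_state(forward, backward)
    per_state = {s: float(x) for s, x in zip(states, p)}
    m_free = per_state["pre"] + per_state["post"]
    return OccupancyResult(M_free=m_free, M_bound=1.0 - m_free,
                           per_state=per_state)


def translocation_landscape(rates: RatchetRates, F: float = 0.0,
                            kBT: float = KBT_22C) -> LandscapeResult:
    """Free-energy landscape of the translocation step at signed load F.

    ``K_delta(F) = k_T(F)/k_mT(F)``; ``dG_trans = -ln K_delta`` (kBT units;
    negative when the post-translocated state is favored).  Opposing load
    tilts the landscape by ``-F*delta`` and raises the barrier by
    ``-F*d_T``.
    """
    kT = bell_rate(rates.k_T0, rates.d_T, F, kBT)
    kmT = bell_rate(rates.k_mT0, -rates.d_mT, F, kBT)
    K = kT / kmT
    return LandscapeResult(
        delta=rates.delta,
        K_delta=K,
        dG_trans=-math.log(K),
        barrier_shift=-F * rates.d_T / kBT,
    )


def rupture_force(coeffs: MMCoefficients = PHI29_COEFFS, dNTP: float = 500.0,
                  v_detach: float = 7.0, kBT: float = KBT_22C,
                  f_max: float = 200.0):
    """Hindering-load magnitude (pN) at which velocity falls to v_detach.

    Solves ``velocity_model3(F, dNTP) = v_detach`` on ``[-f_max, 0]`` by
    bracketed root finding; the velocity is strictly increasing in F so the
    root is unique.  Returns ``None`` when the zero-load velocity is already
    at or below ``v_detach`` (no root: the enzyme never reaches the
    detachment criterion under hindering load alone).
    """
    if v_detach <= 0:
        raise InvalidParameterError("v_detach must be positive")
    v0 = velocity_model3(0.0, dNTP, coeffs, kBT)
    if v0 <= v_detach:
        return None
    g = lambda F: velocity_model3(F, dNTP, coeffs, kBT) - v_detach
    root = brentq(g, -f_max, 0.0, xtol=1e-6)
    return float(-root)
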