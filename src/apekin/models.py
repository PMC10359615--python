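"""Closed-form kinetic, binding, FRET and mass-distribution models.

Every function here is a pure evaluator used both by the fitting layer
(:mod:`apekin.fitkit`) and by the synthetic-data generators
(:mod:`apekin.synthgen`).  Units are fixed across the public surface:
concentrations in nM, time in s, rates in s^-1, masses in kDa.  Unit
conversion, if any, happens at I/O.

The models
----------
* Multiple-turnover burst kinetics: ``product = A(1 - exp(-kobs*t)) + vss*t``
  where ``A`` is the burst amplitude (concentration of actively engaged
  enzyme), ``kobs`` the first-order rate of the exponential (cleavage)
  phase and ``vss`` the steady-state velocity.  The steady-state rate
  constant is ``kss = vss/A`` (interpreted as product release).
* Single-turnover kinetics: single or double rising exponentials.
* Tight binding: the Morrison quadratic for the complex concentration
  ``AB`` given total enzyme ``AT``, total DNA ``BT`` and the apparent
  dissociation constant, valid when free and total concentrations cannot
  be equated.
* FRET proximity ratio ``E = I_665 / (I_665 + I_563)`` and the predicted
  no-interaction value obtained by summing component emission spectra
  channel-wise before taking the ratio.
* A Gaussian mixture for mass-photometry histograms of the form
  ``f(x) = sum_n a_n * exp(-((x - b_n)/c_n)^2)``.  Note the exponent has
  no 1/2 factor, so ``c = sigma * sqrt(2)`` relative to a conventional
  Gaussian and the component area is ``a * c * sqrt(pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "KineticParams",
    "BiexpParams",
    "BindingParams",
    "GaussianComponent",
    "EmissionRead",
    "FoldChange",
    "eval_burst",
    "eval_single_exp",
    "eval_double_exp",
    "steady_state_rate",
    "fold_change",
    "morrison_bound",
    "efret",
    "efret_ratio",
    "predicted_no_interaction_efret",
    "eval_gaussian_mixture",
    "SQRT_PI",
]

SQRT_PI = math.sqrt(math.pi)


def _check_nonneg_time(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


@dataclass
class KineticParams:
    """Burst-model parameters.

    ``kss`` defaults to ``vss/A`` (the defining identity); an explicit
    value may be supplied by callers that carry a mechanistically derived
    steady-state constant (see :mod:`apekin.mechsim`).
    """

    A: float
    kobs: float
    vss: float = 0.0
    kss: float | None = None
    se_A: float = float("nan")
    se_kobs: float = float("nan")
    se_vss: float = float("nan")
    se_kss: float = float("nan")

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("burst amplitude A must be >= 0")
        if self.kobs <= 0:
            raise ValueError("kobs must be > 0")
        if self.vss < 0:
            raise ValueError("vss must be >= 0")
        if self.kss is None:
            self.kss = steady_state_rate(self.vss, self.A) if self.A > 0 else 0.0


@dataclass
class BiexpParams:
    """Double-exponential parameters, stored amplitude-ordered (A >= B).

    ``major_rate`` is the rate of the larger-amplitude component; when the
    two phases describe distinct enzyme sub-populations this is the rate
    of the major population.
    """

    A: float
    k1: float
    B: float
    k2: float
    se_A: float = float("nan")
    se_k1: float = float("nan")
    se_B: float = float("nan")
    se_k2: float = float("nan")

    def __post_init__(self) -> None:
        if self.A < 0 or self.B < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("rates must be > 0")
        if self.B > self.A:
            self.A, self.B = self.B, self.A
            self.k1, self.k2 = self.k2, self.k1
            self.se_A, self.se_B = self.se_B, self.se_A
            self.se_k1, self.se_k2 = self.se_k2, self.se_k1

    @property
    def major_rate(self) -> float:
        return self.k1


@dataclass
class BindingParams:
    """Tight-binding titration parameters (all concentrations in nM)."""

    AT: float
    BT: float
    KD_app: float
    AB: float
    se_KD_app: float = float("nan")

    def __post_init__(self) -> None:
        if self.KD_app < 0:
            raise ValueError("KD_app must be >= 0")
        if not (0.0 <= self.AB <= min(self.AT, self.BT) * (1 + 1e-9) + 1e-12):
            raise ValueError("complex concentration must lie in [0, min(AT, BT)]")


@dataclass
class GaussianComponent:
    """One mixture component: amplitude ``a`` (counts), mean ``b`` and
    width parameter ``c`` (both in kDa, or contrast units pre-calibration).
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("amplitude must be >= 0")
        if self.c <= 0:
            raise ValueError("width parameter must be > 0")

    @property
    def sigma(self) -> float:
        """Conventional Gaussian standard deviation, ``c / sqrt(2)``."""
        return self.c / math.sqrt(2.0)

    @property
    def area(self) -> float:
        """Integral of the component, ``a * c * sqrt(pi)``."""
        return self.a * self.c * SQRT_PI


@dataclass
class EmissionRead:
    """Simultaneous donor (563 nm) / acceptor (665 nm) intensities."""

    I563: float
    I665: float
    t: float | None = None

    def __post_init__(self) -> None:
        if self.I563 < 0 or self.I665 < 0:
            raise ValueError("intensities must be >= 0")


@dataclass(frozen=True)
class FoldChange:
    """Dimensionless fold change (>= 1) plus its direction."""

    fold: float
    direction: str  # "increase" | "decrease" | "none"
    se: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("fold must be >= 1")
        if self.direction not in ("increase", "decrease", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if (self.direction == "none") != (self.fold == 1):
            raise ValueError("direction 'none' iff fold == 1")


# ---------------------------------------------------------------------------
# kinetic evaluators


def eval_burst(t, p: KineticParams):
    """Biphasic multiple-turnover product curve A(1-exp(-kobs t)) + vss t (nM)."""
    t = _check_nonneg_time(t)
    return p.A * (1.0 - np.exp(-p.kobs * t)) + p.vss * t


def eval_single_exp(t, A: float, kobs: float):
    """Single rising exponential A(1-exp(-kobs t)); asymptote A, half-rise ln2/kobs."""
    if A < 0:
        raise ValueError("A must be >= 0")
    if kobs <= 0:
        raise ValueError("kobs must be > 0")
    t = _check_nonneg_time(t)
    return A * (1.0 - np.exp(-kobs * t))


def eval_double_exp(t, p: BiexpParams):
    """Sum of two rising exponentials; asymptote A + B."""
    t = _check_nonneg_time(t)
    return p.A * (1.0 - np.exp(-p.k1 * t)) + p.B * (1.0 - np.exp(-p.k2 * t))


def steady_state_rate(vss: float, A: float) -> float:
    """Steady-state rate constant kss = vss / A (s^-1)."""
    if A <= 0:
        raise ValueError("burst amplitude must be > 0 to define kss")
    return vss / A


def fold_change(ref: float, val: float) -> FoldChange:
    """Fold change between two rates, always reported as a ratio >= 1.

    ``direction`` records whether ``val`` is larger ("increase"), smaller
    ("decrease") or equal ("none") relative to the reference rate.
    """
    if ref <= 0 or val <= 0:
        raise ValueError("rates must be positive")
    if val == ref:
        return FoldChange(1.0, "none")
    if val < ref:
        return FoldChange(ref / val, "decrease")
    return FoldChange(val / ref, "increase")


# ---------------------------------------------------------------------------
# binding


def morrison_bound(AT, BT, KD):
    """Tight-binding (Morrison) complex concentration AB in nM.

    Algebraically ``((AT+BT+KD) - sqrt((AT+BT+KD)^2 - 4 AT BT)) / 2`` but
    evaluated in the cancellation-free form
    ``2 AT BT / ((AT+BT+KD) + sqrt((AT+BT+KD)^2 - 4 AT BT))`` which is
    stable as KD -> 0.  Accepts scalars or arrays.
    """
    AT = np.asarray(AT, dtype=float)
    BT = np.asarray(BT, dtype=float)
    KD = np.asarray(KD, dtype=float)
    if np.any(AT < 0) or np.any(BT < 0) or np.any(KD < 0):
        raise ValueError("AT, BT and KD must be >= 0")
    s = AT + BT + KD
    disc = np.sqrt(np.maximum(s * s - 4.0 * AT * BT, 0.0))
    denom = s + disc
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(denom > 0, 2.0 * AT * BT / np.where(denom > 0, denom, 1.0), 0.0)
    return ab if ab.ndim else float(ab)


# ---------------------------------------------------------------------------
# FRET


def efret(read: EmissionRead) -> float:
    """Proximity ratio I665 / (I665 + I563), in [0, 1]."""
    return efret_ratio(read.I665, read.I563)


def efret_ratio(I665, I563):
    """Vectorized proximity ratio; raises if a denominator is zero."""
    I665 = np.asarray(I665, dtype=float)
    I563 = np.asarray(I563, dtype=float)
    total = I665 + I563
    if np.any(total <= 0):
        raise ValueError("I563 + I665 must be > 0 to evaluate E_FRET")
    out = I665 / total
    return out if out.ndim else float(out)


def predicted_no_interaction_efret(rpa_read: EmissionRead, dna_read: EmissionRead) -> float:
    """Predicted E_FRET when the labeled components do not interact.

    The individual emission spectra are summed channel-wise and the ratio
    is taken on the summed channels — identical to ``efret`` of the
    channel-sum read.
    """
    return efret_ratio(rpa_read.I665 + dna_read.I665, rpa_read.I563 + dna_read.I563)


# ---------------------------------------------------------------------------
# mass-photometry mixture


def eval_gaussian_mixture(x, comps: Sequence[GaussianComponent]):
    """Mixture f(x) = sum_n a_n exp(-((x-b_n)/c_n)^2)  (no 1/2 in the exponent)."""
    if not comps:
        raise ValueError("component list must be non-empty")
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    for comp in comps:
        z = (x - comp.b) / comp.c
        out = out + comp.a * np.exp(-z * z)
    return out if out.ndim else float(out)
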