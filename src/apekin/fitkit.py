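"""Nonlinear least-squares fitting and derived-parameter analysis.

This is the inference stage of the pipeline: burst / exponential fits of
cleavage time courses, Morrison tight-binding fits of EMSA titrations,
FRET plateau and titration analysis, Gaussian-mixture decomposition of
mass-photometry histograms, and replicate aggregation with fold-change
propagation.

Fitting contract
----------------
All fits use trust-region-reflective least squares (via lmfit) with
positivity bounds on rates and amplitudes, data-driven initial guesses,
and up to five multiplicatively jittered restarts on non-convergence.
Residuals are unweighted, matching common gel/plate quantification
practice.  Standard errors come from the estimated covariance at the
optimum.

Warnings rather than silent failure
-----------------------------------
* ``low-separation``: a burst fit where kobs is less than 10-fold above
  kss; the exponential and linear phases are then hard to separate and
  kobs is unreliable.
* ``tight-binding``: a Morrison fit where the estimated KD is below the
  fixed DNA concentration, or its relative standard error exceeds 25%;
  the titration cannot resolve affinities much below the probe
  concentration.
* ``degenerate-biexp``: a double-exponential fit whose rates collapsed
  or whose minor amplitude vanished; a single exponential is refit.
* ``residual-structure``: a Wald-Wolfowitz runs test on residual signs
  rejects randomness (p < 0.01), suggesting model misspecification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.special import erfc

from .models import (
    BindingParams,
    BiexpParams,
    FoldChange,
    GaussianComponent,
    KineticParams,
    efret_ratio,
    eval_gaussian_mixture,
    fold_change,
    morrison_bound,
)

__all__ = [
    "TimeCourse",
    "BindingTitration",
    "FretTrace",
    "TitrationCurve",
    "FitResult",
    "ReplicateStats",
    "ContrastCalibration",
    "fit_burst",
    "fit_single_exp",
    "fit_double_exp",
    "fit_morrison",
    "emsa_fraction_bound",
    "plateau_efret",
    "normalize_titration",
    "inhibition_midpoint",
    "fit_gaussian_mixture",
    "population_fractions",
    "calibrate_contrast",
    "calibrate_from_peaks",
    "aggregate_replicates",
    "fold_change_with_error",
]

_JITTER = (1.0, 0.3, 3.0, 0.1, 10.0)  # deterministic restart ladder


# ---------------------------------------------------------------------------
# containers


@dataclass
class TimeCourse:
    """Replicated product-formation time course.

    ``regime`` is ``"multiple_turnover"`` (substrate in excess; biphasic)
    or ``"single_turnover"`` (enzyme in excess; exponential).  At least
    six distinct time points are required for any fit.
    """

    t: np.ndarray
    product: np.ndarray
    replicate: np.ndarray
    regime: str
    E0: float
    S0: float
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if self.regime not in ("multiple_turnover", "single_turnover"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if np.any(self.t < 0):
            raise ValueError("time must be >= 0")
        if len({self.t.shape, self.product.shape, self.replicate.shape}) != 1:
            raise ValueError("t, product and replicate must have equal length")

    def n_distinct_times(self) -> int:
        return np.unique(self.t).size


@dataclass
class BindingTitration:
    """EMSA titration: bound complex (nM) versus total enzyme (nM)."""

    AT: np.ndarray
    bound: np.ndarray
    replicate: np.ndarray
    BT: float = 5.0
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.AT = np.asarray(self.AT, dtype=float)
        self.bound = np.asarray(self.bound, dtype=float)
        self.replicate = np.asarray(self.replicate)
        if self.BT <= 0:
            raise ValueError("BT must be > 0")
        if np.any(self.AT < 0):
            raise ValueError("enzyme concentrations must be >= 0")


@dataclass
class FretTrace:
    """Time-ordered donor/acceptor intensity trace (default 0.17 s cadence)."""

    t: np.ndarray
    I563: np.ndarray
    I665: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.I563 = np.asarray(self.I563, dtype=float)
        self.I665 = np.asarray(self.I665, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    def efret(self) -> np.ndarray:
        return efret_ratio(self.I665, self.I563)


@dataclass
class TitrationCurve:
    """Signal versus titrant amount, with optional high/low anchors."""

    x: np.ndarray
    y: np.ndarray
    sem: np.ndarray | None = None
    ymax: float | None = None
    ymin: float | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
        if np.any(self.x < 0):
            raise ValueError("titrant amounts must be >= 0")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("titrant amounts must be strictly increasing")


@dataclass
class FitResult:
    params: object
    se: dict
    residual_ss: float
    converged: bool
    warnings: list = field(default_factory=list)


@dataclass(frozen=True)
class ReplicateStats:
    mean: float
    sd: float
    sem: float
    n: int
    warnings: tuple = ()


# ---------------------------------------------------------------------------
# internals


def _stderr(par) -> float:
    return float(par.stderr) if par.stderr is not None else float("nan")


def _fit_with_restarts(model: lmfit.Model, y, t, params: lmfit.Parameters,
                       sigma=None):
    """TRF fit with a deterministic multiplicative restart ladder."""
    weights = None if sigma is None else 1.0 / np.asarray(sigma, dtype=float)
    best = None
    for factor in _JITTER:
        p = params.copy()
        for name in p:
            if p[name].vary:
                val = params[name].value * factor
                p[name].value = float(np.clip(val, p[name].min or -np.inf, p[name].max or np.inf))
        try:
            res = model.fit(y, p, t=t, method="least_squares", weights=weights)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
        # a near-interpolating fit cannot be improved by another start
        if best.success and best.chisqr <= 1e-12 * float(np.sum(np.square(y))):
            break
    if best is None or not best.success:
        raise RuntimeError(f"fit did not converge after {len(_JITTER)} restarts")
    return best


def _runs_test_pvalue(resid: np.ndarray) -> float:
    """Two-sided Wald-Wolfowitz runs test on residual signs (normal approx)."""
    signs = np.sign(resid[resid != 0])
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    if n1 == 0 or n2 == 0:
        return 0.0  # all one sign: maximally structured
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / math.sqrt(var)
    return float(erfc(abs(z) / math.sqrt(2.0)))


def _require_points(tc: TimeCourse, regime: str) -> None:
    if tc.regime != regime:
        raise ValueError(f"time course regime is {tc.regime!r}, expected {regime!r}")
    if tc.n_distinct_times() < 6:
        raise ValueError("at least 6 distinct time points are required")


def _tail_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope/intercept of the last third of the (time-sorted) data."""
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    cut = max(len(ts) - max(len(ts) // 3, 2), 0)
    slope, intercept = np.polyfit(ts[cut:], ys[cut:], 1)
    return float(slope), float(intercept)


def _rise_rate_guess(t: np.ndarray, y: np.ndarray, amplitude: float) -> float:
    """kobs guess from a log-linear fit of the early rise toward `amplitude`."""
    order = np.argsort(t)
    ts, ys = t[order], y[order]
    mask = (ts > 0) & (ys < 0.95 * amplitude) & (ys > 0)
    ts, ys = ts[mask], ys[mask]
    n_early = max(len(ts) // 3, 3)
    ts, ys = ts[:n_early], ys[:n_early]
    if len(ts) >= 2 and amplitude > 0:
        frac = np.clip(1.0 - ys / amplitude, 1e-12, 1.0)
        slope = np.polyfit(ts, np.log(frac), 1)[0]
        if slope < 0:
            return -float(slope)
    pos = t[t > 0]
    return 1.0 / float(np.median(pos)) if pos.size else 1.0


# ---------------------------------------------------------------------------
# kinetic fits


def fit_burst(tc: TimeCourse, sigma=None) -> FitResult:
    """Fit the biphasic burst model A(1-exp(-kobs t)) + vss t.

    kss is derived as vss/A with first-order error propagation.  The
    ``low-separation`` warning fires when kobs/kss < 10.  ``sigma``
    (per-point noise sd, same length as the data) switches the fit to
    inverse-variance weighting — appropriate when the noise model is
    known, e.g. for synthetic recovery studies; the default is the
    unweighted fit used for instrument data of unknown error structure.
    """
    _require_points(tc, "multiple_turnover")
    t, y = tc.t, tc.product

    vss0, A0 = _tail_line(t, y)
    A0 = max(A0, 0.05 * float(np.max(y)))
    vss0 = max(vss0, 1e-12)
    kobs0 = _rise_rate_guess(t, np.clip(y - vss0 * t, 0.0, None), A0)

    model = lmfit.Model(lambda t, A, kobs, vss: A * (1 - np.exp(-kobs * t)) + vss * t)
    params = model.make_params(A=A0, kobs=kobs0, vss=vss0)
    params["A"].set(min=1e-12)
    params["kobs"].set(min=1e-12)
    params["vss"].set(min=0.0)
    res = _fit_with_restarts(model, y, t, params, sigma=sigma)

    A = res.params["A"].value
    kobs = res.params["kobs"].value
    vss = res.params["vss"].value
    se_A, se_kobs, se_vss = (_stderr(res.params[k]) for k in ("A", "kobs", "vss"))
    kss = vss / A
    rel = 0.0
    if vss > 0 and A > 0 and np.isfinite(se_A) and np.isfinite(se_vss):
        rel = math.sqrt((se_vss / vss) ** 2 + (se_A / A) ** 2)
    se_kss = kss * rel if rel else float("nan")

    warnings = []
    if kss > 0 and kobs / kss < 10:
        warnings.append("low-separation")
    kp = KineticParams(A=A, kobs=kobs, vss=vss, se_A=se_A, se_kobs=se_kobs,
                       se_vss=se_vss, se_kss=se_kss)
    return FitResult(kp, {"A": se_A, "kobs": se_kobs, "vss": se_vss, "kss": se_kss},
                     float(res.chisqr), True, warnings)


def fit_single_exp(tc: TimeCourse, sigma=None) -> FitResult:
    """Fit the single-turnover exponential A(1-exp(-kobs t)).

    ``sigma`` enables inverse-variance weighting as in :func:`fit_burst`.
    """
    _require_points(tc, "single_turnover")
    t, y = tc.t, tc.product

    A0 = float(np.max(y))
    kobs0 = _rise_rate_guess(t, y, A0)
    model = lmfit.Model(lambda t, A, kobs: A * (1 - np.exp(-kobs * t)))
    params = model.make_params(A=max(A0, 1e-6), kobs=kobs0)
    params["A"].set(min=1e-12)
    params["kobs"].set(min=1e-12)
    res = _fit_with_restarts(model, y, t, params, sigma=sigma)

    A = res.params["A"].value
    kobs = res.params["kobs"].value
    se_A, se_kobs = _stderr(res.params["A"]), _stderr(res.params["kobs"])
    warnings = []
    if _runs_test_pvalue(res.residual) < 0.01:
        warnings.append("residual-structure")
    kp = KineticParams(A=A, kobs=kobs, vss=0.0, se_A=se_A, se_kobs=se_kobs)
    return FitResult(kp, {"A": se_A, "kobs": se_kobs}, float(res.chisqr), True, warnings)


def fit_double_exp(tc: TimeCourse) -> FitResult:
    """Fit the double exponential A(1-exp(-k1 t)) + B(1-exp(-k2 t)).

    Components are returned amplitude-ordered; the major rate is the rate
    of the larger-amplitude component.  When the two rates collapse
    (relative difference < 5%) or the minor amplitude vanishes, a
    ``degenerate-biexp`` warning is attached and a single exponential is
    refit instead.
    """
    _require_points(tc, "single_turnover")
    t, y = tc.t, tc.product

    A_tot = float(np.max(y))
    k0 = _rise_rate_guess(t, y, A_tot)
    model = lmfit.Model(
        lambda t, A, k1, B, k2: A * (1 - np.exp(-k1 * t)) + B * (1 - np.exp(-k2 * t))
    )
    params = model.make_params(A=0.7 * A_tot, k1=k0 / 5.0, B=0.3 * A_tot, k2=k0 * 5.0)
    for name in ("A", "B", "k1", "k2"):
        params[name].set(min=1e-12)
    res = _fit_with_restarts(model, y, t, params)

    A, k1 = res.params["A"].value, res.params["k1"].value
    B, k2 = res.params["B"].value, res.params["k2"].value
    rate_collapse = abs(k1 - k2) / max(k1, k2) < 0.05
    minor_vanished = min(A, B) < 0.02 * max(A, B)
    if rate_collapse or minor_vanished:
        single = fit_single_exp(tc)
        single.warnings = ["degenerate-biexp"] + single.warnings
        return single

    bp = BiexpParams(
        A=A, k1=k1, B=B, k2=k2,
        se_A=_stderr(res.params["A"]), se_k1=_stderr(res.params["k1"]),
        se_B=_stderr(res.params["B"]), se_k2=_stderr(res.params["k2"]),
    )
    se = {"A": bp.se_A, "k1": bp.se_k1, "B": bp.se_B, "k2": bp.se_k2}
    return FitResult(bp, se, float(res.chisqr), True, [])


# ---------------------------------------------------------------------------
# binding


def fit_morrison(titration: BindingTitration) -> FitResult:
    """Fit the Morrison tight-binding quadratic with BT fixed.

    Raises when the titration is saturation-only (all points > 95% bound)
    since KD is then unidentifiable; flags ``tight-binding`` when the
    estimated KD falls below BT or its relative standard error exceeds
    25% — the regime where an apparent affinity below the probe DNA
    concentration cannot be pinned down.
    """
    AT, bound, BT = titration.AT, titration.bound, titration.BT
    nonzero = AT > 0
    if nonzero.any() and np.all(bound[nonzero] > 0.95 * BT):
        raise ValueError(
            "titration is saturation-only (all points > 95% bound); KD is "
            "unidentifiable — extend the titration to sub-stoichiometric enzyme"
        )

    frac = np.clip(bound / BT, 0.0, 1.0)
    order = np.argsort(AT)
    KD0 = float(np.interp(0.5, frac[order], AT[order]))
    KD0 = max(KD0, 1e-3)

    model = lmfit.Model(lambda t, KD: morrison_bound(t, BT, KD))
    params = model.make_params(KD=KD0)
    params["KD"].set(min=1e-9)
    res = _fit_with_restarts(model, bound, AT, params)

    KD = res.params["KD"].value
    se_KD = _stderr(res.params["KD"])
    warnings = []
    if KD < BT or (np.isfinite(se_KD) and se_KD / KD > 0.25):
        warnings.append("tight-binding")
    bp = BindingParams(AT=float(np.max(AT)), BT=BT, KD_app=KD,
                       AB=float(morrison_bound(np.max(AT), BT, KD)), se_KD_app=se_KD)
    return FitResult(bp, {"KD_app": se_KD}, float(res.chisqr), True, warnings)


def emsa_fraction_bound(free_band: float, total_band: float, BT: float) -> float:
    """Bound complex (nM) from free/total band intensities: BT(1 - free/total)."""
    if total_band <= 0:
        raise ValueError("total band intensity must be > 0")
    if not 0 <= free_band <= total_band:
        raise ValueError("free band intensity must lie in [0, total]")
    return BT * (1.0 - free_band / total_band)


# ---------------------------------------------------------------------------
# FRET


def plateau_efret(trace: FretTrace, window: float = 60.0, tol: float = 0.02):
    """Average E_FRET over the earliest stable trailing region.

    Operationalizes "constant for at least ``window`` seconds": finds the
    earliest start index whose trailing segment (to the end of the trace,
    at least ``window`` long) is stable, and returns its (mean, sd).
    Stability requires both the relative sd and the linear drift across
    the segment to be <= ``tol`` of the mean — the drift term is needed
    because a slow monotone ramp can have an arbitrarily small sd while
    never settling.
    """
    t = trace.t
    if t[-1] - t[0] < window:
        raise ValueError("trace shorter than the required plateau window")
    e = trace.efret()
    for i in range(len(t)):
        if t[-1] - t[i] < window:
            break
        seg, ts = e[i:], t[i:]
        mean = float(np.mean(seg))
        if mean == 0:
            continue
        sd = float(np.std(seg, ddof=1))
        drift = abs(np.polyfit(ts, seg, 1)[0]) * (ts[-1] - ts[0])
        if sd / abs(mean) <= tol and drift / abs(mean) <= tol:
            return mean, sd
    raise RuntimeError("no plateau: no window satisfied the stability criterion")


def normalize_titration(curve: TitrationCurve) -> TitrationCurve:
    """Map a titration onto [0, 1] using its high/low anchors.

    y' = (y - ymin)/(ymax - ymin), so the no-titrant anchor maps to 1 and
    the fully-disengaged prediction maps to 0.
    """
    if curve.ymax is None or curve.ymin is None:
        raise ValueError("both ymax and ymin anchors are required")
    span = curve.ymax - curve.ymin
    if span <= 0:
        raise ValueError("ymax must exceed ymin")
    y = (curve.y - curve.ymin) / span
    sem = curve.sem / span if curve.sem is not None else None
    return TitrationCurve(x=curve.x.copy(), y=y, sem=sem, ymax=1.0, ymin=0.0,
                          truth=curve.truth)


def inhibition_midpoint(curve: TitrationCurve) -> float:
    """Titrant amount at 50% of a normalized, monotone-decreasing curve.

    Linear interpolation between the two points bracketing y = 0.5.
    """
    y = curve.y
    diffs = np.diff(y)
    bad = np.nonzero(diffs > 0)[0]
    if bad.size:
        raise ValueError(f"curve is not monotone decreasing (first violation at index {bad[0] + 1})")
    above = np.nonzero(y >= 0.5)[0]
    below = np.nonzero(y <= 0.5)[0]
    if above.size == 0 or below.size == 0:
        raise ValueError("0.5 is not bracketed by the curve")
    i = above[-1]
    if y[i] == 0.5:
        return float(curve.x[i])
    j = i + 1
    frac = (y[i] - 0.5) / (y[i] - y[j])
    return float(curve.x[i] + frac * (curve.x[j] - curve.x[i]))


# ---------------------------------------------------------------------------
# mass photometry


def fit_gaussian_mixture(bin_centers, counts, n: int) -> FitResult:
    """Least-squares Gaussian-mixture fit to a binned mass histogram.

    The mixture is sum_n a_n exp(-((x-b_n)/c_n)^2); components are
    returned mean-ordered.  A ``component-collapse`` warning is attached
    when two fitted means sit closer than half the wider component.
    """
    if n not in (1, 2, 3):
        raise ValueError("n must be 1, 2 or 3")
    x = np.asarray(bin_centers, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size < 5 * (3 * n):
        raise ValueError(f"need at least {5 * 3 * n} bins for a {n}-component fit")

    means0 = _initial_means(x, y, n)
    total_w = float(np.sum(y))
    sd_all = math.sqrt(max(np.sum(y * (x - np.sum(x * y) / total_w) ** 2) / total_w, 1e-12))
    c0 = max(sd_all / n, (x[1] - x[0]) * 2)

    params = lmfit.Parameters()
    for i, b0 in enumerate(means0):
        a0 = max(float(np.interp(b0, x, y)), 1e-6)
        params.add(f"a{i}", value=a0, min=0.0)
        params.add(f"b{i}", value=b0, min=float(x[0]), max=float(x[-1]))
        params.add(f"c{i}", value=c0, min=(x[1] - x[0]) / 2)

    def _mix(t, **kw):
        out = np.zeros_like(t)
        for i in range(n):
            z = (t - kw[f"b{i}"]) / kw[f"c{i}"]
            out = out + kw[f"a{i}"] * np.exp(-z * z)
        return out

    model = lmfit.Model(_mix)
    res = _fit_with_restarts(model, y, x, params)

    comps = sorted(
        (
            GaussianComponent(
                a=res.params[f"a{i}"].value,
                b=res.params[f"b{i}"].value,
                c=res.params[f"c{i}"].value,
            )
            for i in range(n)
        ),
        key=lambda comp: comp.b,
    )
    se = {
        f"{name}{i}": _stderr(res.params[f"{name}{i}"])
        for i in range(n)
        for name in ("a", "b", "c")
    }
    warnings = []
    for i in range(len(comps) - 1):
        if abs(comps[i + 1].b - comps[i].b) < max(comps[i].c, comps[i + 1].c) / 2:
            warnings.append("component-collapse")
            break
    return FitResult(comps, se, float(res.chisqr), True, warnings)


def _initial_means(x: np.ndarray, y: np.ndarray, n: int) -> list[float]:
    """Peak-based initial means, padded with weighted quantiles if needed."""
    if len(y) >= 5:
        smooth = np.convolve(y, np.ones(3) / 3, mode="same")
    else:
        smooth = y
    from scipy.signal import find_peaks

    idx, props = find_peaks(smooth, prominence=0.02 * float(np.max(smooth)))
    idx = idx[np.argsort(props["prominences"])[::-1]][:n]
    means = sorted(float(x[i]) for i in idx)
    if len(means) < n:
        cdf = np.cumsum(y) / np.sum(y)
        for q in np.linspace(0.15, 0.85, n):
            cand = float(np.interp(q, cdf, x))
            if all(abs(cand - m) > (x[-1] - x[0]) / (4 * n) for m in means):
                means.append(cand)
            if len(means) == n:
                break
        while len(means) < n:
            means.append(float(x[len(x) // 2]))
    return sorted(means)


def population_fractions(comps) -> np.ndarray:
    """Area-based population fractions a_i c_i / sum_j a_j c_j (sum to 1)."""
    areas = np.array([comp.a * comp.c for comp in comps], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("all component areas are zero")
    return areas / total


@dataclass(frozen=True)
class ContrastCalibration:
    """Affine contrast-to-mass map: mass_kDa = slope * contrast + intercept."""

    slope: float
    intercept: float
    residuals: tuple

    def __call__(self, contrast):
        return self.slope * np.asarray(contrast, dtype=float) + self.intercept


def calibrate_from_peaks(peak_contrasts, standard_masses) -> ContrastCalibration:
    """Affine contrast-to-mass map from located peak centers (least squares).

    With exactly two peaks the map interpolates both exactly.
    """
    masses = np.sort(np.asarray(standard_masses, dtype=float))
    contrasts = np.sort(np.asarray(peak_contrasts, dtype=float))
    if masses.size < 2 or contrasts.size != masses.size:
        raise ValueError("need >= 2 standard peaks, one contrast per mass")
    slope, intercept = np.polyfit(contrasts, masses, 1)
    resid = masses - (slope * contrasts + intercept)
    return ContrastCalibration(float(slope), float(intercept), tuple(float(r) for r in resid))


def calibrate_contrast(standard_events, standard_masses, bins: int = 80) -> ContrastCalibration:
    """Contrast-to-mass calibration from a known multi-peak mass standard.

    The standard's contrast events are histogrammed, decomposed with the
    Gaussian mixture, and the peak centers regressed against the known
    masses via :func:`calibrate_from_peaks`.
    """
    masses = np.asarray(standard_masses, dtype=float)
    if masses.size < 2:
        raise ValueError("at least 2 standard peaks are required")
    events = np.asarray(standard_events, dtype=float)
    counts, edges = np.histogram(events, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fit = fit_gaussian_mixture(centers, counts, n=int(masses.size))
    return calibrate_from_peaks([comp.b for comp in fit.params], masses)


# ---------------------------------------------------------------------------
# replicate statistics


def aggregate_replicates(values) -> ReplicateStats:
    """Mean, sample sd and sem of replicate values (warn when n = 2)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("at least 2 replicates are required")
    warnings = ("n=2: below the recommended 3 replicates",) if vals.size == 2 else ()
    sd = float(np.std(vals, ddof=1))
    return ReplicateStats(
        mean=float(np.mean(vals)), sd=sd, sem=sd / math.sqrt(vals.size),
        n=int(vals.size), warnings=warnings,
    )


def fold_change_with_error(ref: tuple[float, float], val: tuple[float, float]) -> FoldChange:
    """Fold change with first-order ratio-propagated standard error.

    ``ref`` and ``val`` are (rate, se) pairs;
    se_fold = fold * sqrt((se_ref/ref)^2 + (se_val/val)^2).
    """
    r, se_r = ref
    v, se_v = val
    fc = fold_change(r, v)
    se = fc.fold * math.sqrt((se_r / r) ** 2 + (se_v / v) ** 2)
    return FoldChange(fc.fold, fc.direction, se)
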