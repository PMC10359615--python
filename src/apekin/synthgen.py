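"""Seeded synthetic-data generators for every experiment in the pipeline.

Each generator evaluates the corresponding closed-form model (or the
mechanistic simulator) at the standard experimental design and adds
seeded Gaussian noise, so the full analysis chain can be exercised and
validated by parameter recovery without any instrument data.  Every
generator is deterministic under its seed and records the generating
truth on the returned container (``truth`` attribute), enabling blind
recovery tests.

Noise model: proportional Gaussian with an additive floor,
``y' = y (1 + cv z1) + floor z2`` with independent standard-normal z.
The default cv of 3% reflects typical replicate scatter of quantified
gel band intensities; the floor is 0.5 nM for concentration signals and
0.005 for dimensionless (E_FRET / fraction) signals.

Standard designs (all concentrations nM):
multiple turnover DNA 100 / enzyme 30, single turnover enzyme 500 /
DNA 50, EMSA DNA 5 with enzyme titrated 0-2000, FRET DNA 25 with RPA 75,
three replicates, rapid-quench time grids starting at 0.002 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitkit import BindingTitration, TimeCourse, TitrationCurve
from .mechsim import MechanismScheme, simulate_turnover_ode
from .models import (
    BiexpParams,
    KineticParams,
    eval_burst,
    eval_double_exp,
    eval_single_exp,
    morrison_bound,
)

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "gen_timecourse",
    "gen_emsa_titration",
    "gen_fret_exchange_titration",
    "gen_competition_titration",
    "gen_mass_events",
    "gen_product_formation_panel",
]


@dataclass(frozen=True)
class NoiseModel:
    """Proportional Gaussian noise with additive floor; seed is mandatory."""

    seed: int
    cv: float = 0.03
    floor: float = 0.5  # additive sd for concentration (nM) signals
    floor_frac: float = 0.005  # additive sd for dimensionless signals

    def __post_init__(self) -> None:
        if self.cv < 0 or self.floor < 0 or self.floor_frac < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, y: np.ndarray, rng: np.random.Generator, floor: float | None = None) -> np.ndarray:
        floor = self.floor if floor is None else floor
        return y * (1.0 + self.cv * rng.standard_normal(y.shape)) + floor * rng.standard_normal(y.shape)

    def sigma(self, y, floor: float | None = None) -> np.ndarray:
        """Per-point noise sd implied by the model (for weighted fitting)."""
        floor = self.floor if floor is None else floor
        return np.sqrt((self.cv * np.asarray(y, dtype=float)) ** 2 + floor**2)


@dataclass(frozen=True)
class ExperimentDesign:
    """Standard concentrations, grids and replicate counts."""

    mt_dna: float = 100.0
    mt_enzyme: float = 30.0
    st_enzyme: float = 500.0
    st_dna: float = 50.0
    emsa_dna: float = 5.0
    emsa_enzyme_max: float = 2000.0
    fret_dna: float = 25.0
    fret_rpa: float = 75.0
    t_min: float = 0.002  # rapid-quench minimum mixing time, s
    n_timepoints: int = 30
    n_titration_points: int = 16
    n_reps: int = 3

    def time_grid(self, kobs: float, horizon_factor: float = 10.0) -> np.ndarray:
        """Log-spaced rapid-quench grid resolving a rate of ``kobs``.

        Spans t_min to horizon_factor/kobs so the exponential phase is
        sampled densely and the linear (steady-state) phase is covered.
        """
        if kobs <= 0:
            raise ValueError("kobs must be > 0")
        t_max = max(horizon_factor / kobs, self.t_min * 50)
        return np.geomspace(self.t_min, t_max, self.n_timepoints)

    def emsa_grid(self) -> np.ndarray:
        """Enzyme titration grid: 0 plus log-spaced points up to the maximum."""
        return np.concatenate(
            [[0.0], np.geomspace(0.25, self.emsa_enzyme_max, self.n_titration_points - 1)]
        )


def _truth_dict(params) -> dict:
    if isinstance(params, KineticParams):
        return {"model": "burst", "A": params.A, "kobs": params.kobs,
                "vss": params.vss, "kss": params.kss}
    if isinstance(params, BiexpParams):
        return {"model": "double_exp", "A": params.A, "k1": params.k1,
                "B": params.B, "k2": params.k2}
    if isinstance(params, MechanismScheme):
        return {"model": "mechanism", "k_chem": params.k_chem, "k_rel": params.k_rel,
                "kon": params.kon, "koff": params.koff}
    raise TypeError(f"unsupported truth type {type(params).__name__}")


def gen_timecourse(
    truth,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    n_reps: int | None = None,
    regime: str = "multiple_turnover",
    t_grid: np.ndarray | None = None,
) -> TimeCourse:
    """Replicated product time course from a kinetic truth.

    ``truth`` is a :class:`KineticParams` (burst model; multiple
    turnover), :class:`BiexpParams` (double exponential; single turnover)
    or :class:`MechanismScheme` (simulated by the mass-action ODE).  A
    plain KineticParams with vss = 0 under the single-turnover regime
    yields a single exponential.
    """
    design = design or ExperimentDesign()
    noise = noise if noise is not None else NoiseModel(seed=0, cv=0.0, floor=0.0, floor_frac=0.0)
    n_reps = design.n_reps if n_reps is None else n_reps
    rng = noise.rng()

    if regime == "multiple_turnover":
        E0, S0 = design.mt_enzyme, design.mt_dna
    elif regime == "single_turnover":
        E0, S0 = design.st_enzyme, design.st_dna
    else:
        raise ValueError(f"unknown regime {regime!r}")

    if isinstance(truth, KineticParams):
        if regime == "single_turnover" and truth.vss > 0:
            raise ValueError("single-turnover truth must have vss = 0")
        if t_grid is None:
            t_grid = design.time_grid(truth.kobs)
        clean = eval_burst(t_grid, truth)
    elif isinstance(truth, BiexpParams):
        if regime != "single_turnover":
            raise ValueError("double-exponential truth requires the single-turnover regime")
        if t_grid is None:
            t_grid = design.time_grid(min(truth.k1, truth.k2))
        clean = eval_double_exp(t_grid, truth)
    elif isinstance(truth, MechanismScheme):
        if t_grid is None:
            t_grid = design.time_grid(truth.k_chem + truth.k_rel)
        clean = simulate_turnover_ode(truth, E0, S0, t_grid)
    else:
        raise TypeError(f"unsupported truth type {type(truth).__name__}")

    t = np.tile(t_grid, n_reps)
    rep = np.repeat(np.arange(n_reps), t_grid.size)
    prod = np.clip(noise.apply(np.tile(clean, n_reps), rng), 0.0, None)
    return TimeCourse(t=t, product=prod, replicate=rep, regime=regime,
                      E0=E0, S0=S0, truth=_truth_dict(truth))


def gen_emsa_titration(
    KD: float,
    design: ExperimentDesign | None = None,
    noise: NoiseModel | None = None,
    n_reps: int | None = None,
) -> BindingTitration:
    """EMSA titration with noise applied to the free-band fraction."""
    if KD < 0:
        raise ValueError("KD must be >= 0")
    design = design or ExperimentDesign()
    noise = noise if noise is not None else NoiseModel(seed=0, cv=0.0, floor=0.0, floor_frac=0.0)
    n_reps = design.n_reps if n_reps is None else n_reps
    rng = noise.rng()

    AT = design.emsa_grid()
    BT = design.emsa_dna
    bound = morrison_bound(AT, np.full_like(AT, BT), np.full_like(AT, KD))
    free_frac = 1.0 - bound / BT

    at_all = np.tile(AT, n_reps)
    rep = np.repeat(np.arange(n_reps), AT.size)
    noisy_free = np.clip(
        noise.apply(np.tile(free_frac, n_reps), rng, floor=noise.floor_frac), 0.0, 1.0
    )
    return BindingTitration(AT=at_all, bound=BT * (1.0 - noisy_free), replicate=rep,
                            BT=BT, truth={"KD_app": KD})


def gen_fret_exchange_titration(
    ymax: float = 0.475,
    ymin: float = 0.204,
    mode: str = "full_exchange",
    x_grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
) -> TitrationCurve:
    """E_FRET exchange titration versus [titrant]/[DNA] ratio.

    ``full_exchange`` decays from the high-FRET anchor toward the
    predicted no-interaction value (complete displacement of the labeled
    protein); ``no_exchange`` stays at the high anchor within noise (the
    labeled protein is never displaced).
    """
    if ymax <= ymin:
        raise ValueError("ymax must exceed ymin")
    if mode not in ("full_exchange", "no_exchange"):
        raise ValueError(f"unknown mode {mode!r}")
    noise = noise if noise is not None else NoiseModel(seed=0, cv=0.0, floor=0.0, floor_frac=0.0)
    rng = noise.rng()
    if x_grid is None:
        x_grid = np.linspace(0.0, 12.0, 13)
    x_grid = np.asarray(x_grid, dtype=float)

    if mode == "no_exchange":
        clean = np.full_like(x_grid, ymax)
    else:
        x_c = max(float(x_grid[-1]) / 5.0, 1e-9)
        clean = ymin + (ymax - ymin) * np.exp(-x_grid / x_c)
    y = noise.apply(clean, rng, floor=noise.floor_frac)
    return TitrationCurve(x=x_grid, y=y, ymax=ymax, ymin=ymin,
                          truth={"mode": mode, "ymax": ymax, "ymin": ymin})


def gen_competition_titration(
    L: float = 25.0,
    rpa_active: float | None = None,
    rel_affinity: float = 1.0,
    C_grid: np.ndarray | None = None,
    noise: NoiseModel | None = None,
) -> TitrationCurve:
    """Normalized self-competition titration under proportional partitioning.

    With limiting active protein, the labeled-bound fraction partitions
    in proportion to weighted site concentrations:
    ``y = L / (L + rel_affinity * C)``.  The abscissa is the competitor
    fraction of total DNA, ``C / (C + L)``, so identical affinities put
    the 50% crossing exactly at 0.5.
    """
    if L <= 0:
        raise ValueError("labeled DNA concentration must be > 0")
    if rel_affinity <= 0:
        raise ValueError("relative affinity must be > 0")
    if rpa_active is not None and rpa_active > L:
        raise ValueError("proportional partitioning assumes limiting protein (rpa_active <= L)")
    noise = noise if noise is not None else NoiseModel(seed=0, cv=0.0, floor=0.0, floor_frac=0.0)
    rng = noise.rng()
    if C_grid is None:
        C_grid = np.linspace(0.0, 8.0 * L, 201)
    C_grid = np.asarray(C_grid, dtype=float)

    y_clean = L / (L + rel_affinity * C_grid)
    x = C_grid / (C_grid + L)
    y = noise.apply(y_clean, rng, floor=noise.floor_frac)
    return TitrationCurve(x=x, y=y, ymax=1.0, ymin=0.0,
                          truth={"L": L, "rel_affinity": rel_affinity})


def gen_mass_events(
    weights,
    means_kda,
    sigmas,
    n_events: int,
    seed: int,
) -> np.ndarray:
    """I.i.d. landing-event masses from a Gaussian mixture.

    ``sigmas`` are conventional standard deviations (the histogram fit's
    ``c`` parameter equals sigma * sqrt(2)).
    """
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means_kda, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    if n_events < 100:
        raise ValueError("need at least 100 events")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n_events, p=weights)
    return rng.normal(means[comp], sigmas[comp])


def gen_product_formation_panel(
    k_base: float,
    ratios=(1, 5, 10),
    timepoints=(30.0, 60.0, 600.0),
    noise: NoiseModel | None = None,
    suppression: float = 1.0,
    n_reps: int = 3,
):
    """Percent-product panel across enzyme:DNA ratios and time points.

    Emulates end-point cleavage assays on protein-coated substrate:
    product follows a pseudo-first-order approach
    ``100 (1 - exp(-k_base * ratio / suppression * t))`` where
    ``suppression`` >= 1 models reduced accessibility of the abasic site
    when the single-stranded region is protein-bound.  Returns a records
    array of (ratio, time_s, replicate, percent).
    """
    if k_base <= 0 or suppression < 1:
        raise ValueError("k_base must be > 0 and suppression >= 1")
    noise = noise if noise is not None else NoiseModel(seed=0, cv=0.0, floor=0.0, floor_frac=0.0)
    rng = noise.rng()
    rows = []
    for ratio in ratios:
        for t in timepoints:
            clean = 100.0 * (1.0 - np.exp(-k_base * ratio / suppression * t))
            vals = np.clip(
                noise.apply(np.full(n_reps, clean), rng, floor=noise.floor_frac * 100),
                0.0, 100.0,
            )
            rows.extend((float(ratio), float(t), r, float(v)) for r, v in enumerate(vals))
    return pd.DataFrame(rows, columns=["ratio", "time_s", "replicate", "percent"])
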