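"""CSV schemas, config handling and report tables.

Interchange format is plain CSV with a header row, optionally preceded
by ``#``-prefixed metadata lines; generators record their truth
parameters as ``# truth: {json}`` so downstream recovery harnesses can
compare blindly-fitted estimates against the generating values.

Schemas (column names, units normalized to nM / s / kDa):

========== ==========================================================
timecourse time_s, replicate, product_nM (or product_fraction)
titration  enzyme_nM, free_intensity, total_intensity, [replicate]
           -- or -- x_ratio, efret
trace      t_s, I563, I665
spectrum   wavelength_nm, intensity
events     mass_kDa  -- or --  contrast
========== ==========================================================
"""

from __future__ import annotations

import hashlib
import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitkit import BindingTitration, FretTrace, TimeCourse, fold_change_with_error
from .models import KineticParams

__all__ = [
    "RunConfig",
    "read_table",
    "write_table",
    "to_timecourse",
    "to_binding_titration",
    "to_fret_trace",
    "report_kinetics",
    "kinetics_from_rates",
    "format_rate",
]

_SCHEMAS: dict[str, list[list[str]]] = {
    # each entry: list of acceptable required-column groups
    "timecourse": [["time_s", "replicate", "product_nM"],
                   ["time_s", "replicate", "product_fraction"]],
    "titration": [["enzyme_nM", "free_intensity", "total_intensity"],
                  ["x_ratio", "efret"]],
    "trace": [["t_s", "I563", "I665"]],
    "spectrum": [["wavelength_nm", "intensity"]],
    "events": [["mass_kDa"], ["contrast"]],
}


@dataclass
class RunConfig:
    """Run configuration; unknown keys in a YAML file are rejected."""

    experiment: str = "timecourse"
    seed: int = 1
    cv: float = 0.03
    floor: float = 0.5
    n_reps: int = 3
    regime: str = "multiple_turnover"
    weighting: str = "unweighted"
    restarts: int = 5
    out_dir: str = "."
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _match_schema(schema: str, columns) -> list[str]:
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(_SCHEMAS)}")
    cols = set(columns)
    for group in _SCHEMAS[schema]:
        if cols.issuperset(group):
            return group
    missing = [c for c in _SCHEMAS[schema][0] if c not in cols]
    raise ValueError(
        f"file does not satisfy schema {schema!r}: missing column(s) {missing} "
        f"(acceptable column sets: {_SCHEMAS[schema]})"
    )


def read_table(path: str | Path, schema: str) -> tuple[pd.DataFrame, dict | None]:
    """Read and validate a schema'd CSV; returns (frame, truth metadata).

    Metadata lines start with ``#``; a ``# truth: {...}`` line is parsed
    as JSON and surfaced to the caller.  Non-numeric cells and (for the
    trace schema) unsorted time stamps raise errors naming the offending
    data row.
    """
    path = Path(path)
    truth = None
    header_lines = 0
    with path.open() as fh:
        raw = fh.readlines()
    for line in raw:
        if not line.startswith("#"):
            break
        header_lines += 1
        stripped = line[1:].strip()
        if stripped.startswith("truth:"):
            truth = json.loads(stripped[len("truth:"):])
    df = pd.read_csv(_stdio.StringIO("".join(raw[header_lines:])))
    group = _match_schema(schema, df.columns)

    for col in group:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"non-numeric value in column {col!r} at data row {row}")
        if coerced.isna().any():
            row = int(np.nonzero(coerced.isna().to_numpy())[0][0])
            raise ValueError(f"missing value in column {col!r} at data row {row}")
        df[col] = coerced

    if schema == "trace":
        dt = np.diff(df["t_s"].to_numpy())
        if np.any(dt <= 0):
            row = int(np.nonzero(dt <= 0)[0][0]) + 1
            raise ValueError(f"trace time stamps not strictly increasing at data row {row}")
    return df, truth


def write_table(df: pd.DataFrame, path: str | Path, truth: dict | None = None) -> None:
    """Write a CSV, prefixing a ``# truth:`` metadata line when given."""
    path = Path(path)
    with path.open("w") as fh:
        if truth is not None:
            fh.write(f"# truth: {json.dumps(truth, sort_keys=True)}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# frame -> domain containers


def to_timecourse(df: pd.DataFrame, regime: str, E0: float, S0: float,
                  truth: dict | None = None) -> TimeCourse:
    col = "product_nM" if "product_nM" in df.columns else "product_fraction"
    product = df[col].to_numpy(dtype=float)
    if col == "product_fraction":
        product = product * S0
    return TimeCourse(t=df["time_s"].to_numpy(dtype=float), product=product,
                      replicate=df["replicate"].to_numpy(), regime=regime,
                      E0=E0, S0=S0, truth=truth)


def to_binding_titration(df: pd.DataFrame, BT: float = 5.0,
                         truth: dict | None = None) -> BindingTitration:
    free_frac = df["free_intensity"].to_numpy(float) / df["total_intensity"].to_numpy(float)
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else np.zeros(len(df), int)
    return BindingTitration(AT=df["enzyme_nM"].to_numpy(float),
                            bound=BT * (1.0 - free_frac), replicate=rep, BT=BT,
                            truth=truth)


def to_fret_trace(df: pd.DataFrame) -> FretTrace:
    return FretTrace(t=df["t_s"].to_numpy(float), I563=df["I563"].to_numpy(float),
                     I665=df["I665"].to_numpy(float))


# ---------------------------------------------------------------------------
# reporting


def format_rate(value: float, se: float) -> str:
    """Rate +/- se with 2 significant figures on the error."""
    if not np.isfinite(se) or se == 0:
        return f"{value:.3g}"
    return f"{value:.3g} ± {se:.2g}"


def report_kinetics(fits: dict, reference) -> pd.DataFrame:
    """Kinetics summary table with fold changes relative to a reference.

    ``fits`` maps a row label to a :class:`KineticParams` (fitted or
    published).  ``reference`` is either a single label (all rows
    compared against that substrate) or a mapping label -> reference
    label (each mutant row compared against its matched wild type).
    Reference rows render their fold columns as "–".  Fold changes are
    formatted to 1 decimal; full precision is kept in the numeric
    columns.
    """
    if isinstance(reference, str):
        if reference not in fits:
            raise ValueError(f"reference {reference!r} not among fits")
        ref_map = {label: reference for label in fits}
    else:
        ref_map = dict(reference)
        missing = [r for r in ref_map.values() if r not in fits]
        if missing:
            raise ValueError(f"reference label(s) not among fits: {sorted(set(missing))}")

    rows = []
    for label, p in fits.items():
        ref_label = ref_map.get(label)
        row = {
            "label": label,
            "kobs": p.kobs, "kobs_se": p.se_kobs,
            "kss": p.kss, "kss_se": p.se_kss,
            "kobs_str": format_rate(p.kobs, p.se_kobs),
            "kss_str": format_rate(p.kss, p.se_kss),
        }
        if ref_label is None or ref_label == label:
            row.update(kobs_fold=np.nan, kobs_fold_se=np.nan, kobs_fold_str="–",
                       kss_fold=np.nan, kss_fold_se=np.nan, kss_fold_str="–")
        else:
            ref = fits[ref_label]
            for name in ("kobs", "kss"):
                rv, rse = getattr(ref, name), getattr(ref, f"se_{name}")
                v, se = getattr(p, name), getattr(p, f"se_{name}")
                rse = rse if np.isfinite(rse) else 0.0
                se = se if np.isfinite(se) else 0.0
                fc = fold_change_with_error((rv, rse), (v, se))
                row[f"{name}_fold"] = fc.fold
                row[f"{name}_fold_se"] = fc.se
                row[f"{name}_fold_str"] = f"{fc.fold:.1f} ± {fc.se:.1f}"
        rows.append(row)
    return pd.DataFrame(rows)


def kinetics_from_rates(table: dict) -> dict[str, KineticParams]:
    """Build report inputs from a (kobs, se, kss, se) table of published rates.

    The burst amplitude is arbitrary for fold-change purposes; vss is set
    consistent with kss at A = 30 nM.
    """
    out = {}
    for label, (kobs, se_kobs, kss, se_kss) in table.items():
        out[label] = KineticParams(A=30.0, kobs=kobs, vss=kss * 30.0,
                                   se_kobs=se_kobs, se_kss=se_kss)
    return out
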