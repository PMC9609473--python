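"""CSV interchange for release curves and fitted-results tables.

Curve files are plain CSV (comma, ``.`` decimal, UTF-8, header
required) with a ``time_h`` column and either ``conversion`` or
``absorbance``.  Experiment metadata and the absorbance calibration
travel in a YAML sidecar sharing the curve's basename
(``curve.csv`` + ``curve.meta.yaml``).  Results tables are CSV with one
row per fitted curve plus a run-metadata sidecar for provenance.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitDiagnostics, ReleaseCurve, fit_release_curve
from .models import ExperimentCondition, RateConstants
from .simulate import SyntheticSpec, absorbance_to_conversion

__all__ = [
    "RESULTS_COLUMNS",
    "sidecar_path",
    "write_release_csv",
    "read_release_csv",
    "fit_results_table",
    "write_results_csv",
    "read_results_csv",
]

#: Fixed column order of a results table: one row per fitted curve.
RESULTS_COLUMNS: List[str] = [
    "label",
    "temperature_K",
    "pH",
    "x_aa",
    "copolymer_conc_g_mL",
    "xi_inf",
    "K",
    "k_total_per_h",
    "k1_per_h",
    "k_minus1_per_h",
    "k_minus1_prime_L_mol_h",
    "r_squared",
    "n_used",
    "n_excluded",
]


def sidecar_path(path: Union[str, Path]) -> Path:
    """Metadata sidecar location for a curve or results CSV."""
    p = Path(path)
    return p.with_suffix(".meta.yaml")


def _condition_to_dict(cond: ExperimentCondition) -> dict:
    return {
        "temperature_K": cond.temperature,
        "pH": cond.pH,
        "x_aa": cond.x_aa,
        "copolymer_conc_g_mL": cond.copolymer_conc,
        "drug_load_g_mL": cond.drug_load,
        "label": cond.label,
    }


def _condition_from_dict(d: dict) -> ExperimentCondition:
    return ExperimentCondition(
        temperature=float(d["temperature_K"]),
        pH=float(d["pH"]),
        x_aa=float(d["x_aa"]),
        copolymer_conc=float(d["copolymer_conc_g_mL"]),
        drug_load=float(d.get("drug_load_g_mL", 1e-3)),
        label=str(d.get("label", "")),
    )


def write_release_csv(
    curve: ReleaseCurve,
    path: Union[str, Path],
    spec: Optional[SyntheticSpec] = None,
    calibration: Optional[Tuple[float, float]] = None,
    float_format: str = "%.12g",
) -> Path:
    """Write a release curve and its metadata sidecar.

    When ``calibration=(slope, offset)`` is given the signal column is
    written as ``absorbance`` instead of ``conversion`` and the
    calibration is recorded in the sidecar so the reader can invert it.
    When the curve came from :class:`~doxrelease.simulate.SyntheticSpec`,
    pass ``spec`` to record the ground truth, noise level and seed.
    """
    p = Path(path)
    meta: dict = {"format": "doxrelease-curve", "version": __version__}
    if curve.condition is not None:
        meta["condition"] = _condition_to_dict(curve.condition)
    if spec is not None:
        meta["generation"] = {
            "k1_per_h": spec.truth.k1,
            "k_minus1_per_h": spec.truth.k_minus1,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        }
    if calibration is not None:
        slope, offset = calibration
        if not slope > 0:
            raise ValueError(f"calibration slope must be positive, got {slope}")
        meta["calibration"] = {"slope": float(slope), "offset": float(offset)}
        df = pd.DataFrame({"time_h": curve.times, "absorbance": slope * curve.xi + offset})
    else:
        df = pd.DataFrame({"time_h": curve.times, "conversion": curve.xi})
    df.to_csv(p, index=False, float_format=float_format)
    sidecar_path(p).write_text(yaml.safe_dump(meta, sort_keys=False), encoding="utf-8")
    return p


def read_release_csv(path: Union[str, Path]) -> ReleaseCurve:
    """Read and validate a release curve CSV (plus optional sidecar).

    Raises
    ------
    ValueError
        On missing columns, non-monotone times (the offending data row
        is named), conversions outside [0, 1], or an absorbance column
        without a calibration sidecar.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such curve file: {p}")
    try:
        df = pd.read_csv(p)
    except Exception as exc:  # surface the parser's own row diagnostics
        raise ValueError(f"{p}: cannot parse CSV: {exc}") from exc
    if "time_h" not in df.columns:
        raise ValueError(f"{p}: missing required column 'time_h' (found {list(df.columns)})")

    meta: dict = {}
    sp = sidecar_path(p)
    if sp.exists():
        meta = yaml.safe_load(sp.read_text(encoding="utf-8")) or {}

    if "conversion" in df.columns:
        xi = df["conversion"].to_numpy(dtype=float)
    elif "absorbance" in df.columns:
        cal = meta.get("calibration")
        if cal is None:
            raise ValueError(
                f"{p}: column 'absorbance' requires a calibration in the sidecar {sp.name}"
            )
        xi = absorbance_to_conversion(
            df["absorbance"].to_numpy(dtype=float), float(cal["slope"]), float(cal.get("offset", 0.0))
        )
    else:
        raise ValueError(f"{p}: need a 'conversion' or 'absorbance' column")

    times = df["time_h"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        # file line of the violating point: +1 header, +1 one-based, +1
        # because diff index i flags point i+1
        raise ValueError(
            f"{p}: time_h is not strictly increasing at row {bad[0] + 3} "
            f"(t={float(times[bad[0] + 1])} after t={float(times[bad[0]])})"
        )
    out_of_range = np.nonzero((xi < 0) | (xi > 1))[0]
    if out_of_range.size:
        raise ValueError(
            f"{p}: conversion outside [0, 1] at row {out_of_range[0] + 2} "
            f"(value {float(xi[out_of_range[0]])})"
        )
    condition = _condition_from_dict(meta["condition"]) if "condition" in meta else None
    return ReleaseCurve(times=times, xi=xi, condition=condition)


def fit_results_table(
    curves: Iterable[ReleaseCurve],
    method: str = "nonlinear",
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Fit each curve and assemble one results row per curve."""
    rows = []
    curves = list(curves)
    if labels is not None and len(labels) != len(curves):
        raise ValueError("labels must match the number of curves")
    for i, curve in enumerate(curves):
        rc, diag = fit_release_curve(curve, method=method, full_output=True)
        cond = curve.condition
        label = labels[i] if labels is not None else (cond.label if cond else f"curve{i}")
        rows.append(
            {
                "label": label,
                "temperature_K": cond.temperature if cond else np.nan,
                "pH": cond.pH if cond else np.nan,
                "x_aa": cond.x_aa if cond else np.nan,
                "copolymer_conc_g_mL": cond.copolymer_conc if cond else np.nan,
                "xi_inf": diag.equilibrium.xi_inf,
                "K": rc.K,
                "k_total_per_h": rc.k_total,
                "k1_per_h": rc.k1,
                "k_minus1_per_h": rc.k_minus1,
                "k_minus1_prime_L_mol_h": rc.k_minus1_prime
                if rc.k_minus1_prime is not None
                else np.nan,
                "r_squared": diag.linear.r_squared if diag.linear else np.nan,
                "n_used": diag.linear.n_used if diag.linear else 0,
                "n_excluded": diag.linear.n_excluded if diag.linear else 0,
            }
        )
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


def write_results_csv(
    table: pd.DataFrame,
    path: Union[str, Path],
    run_metadata: Optional[dict] = None,
) -> Path:
    """Write a results table plus a provenance sidecar (inputs, version)."""
    p = Path(path)
    missing = [c for c in RESULTS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    table.to_csv(p, index=False, float_format="%.12g")
    meta = {"format": "doxrelease-results", "version": __version__}
    if run_metadata:
        meta["run"] = run_metadata
    sidecar_path(p).write_text(yaml.safe_dump(meta, sort_keys=False), encoding="utf-8")
    return p


def read_results_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a results table, checking the fixed column contract."""
    p = Path(path)
    df = pd.read_csv(p)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{p}: results table missing columns: {missing}")
    return df
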