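"""Paper-style outputs: strategy comparison tables, unit conversions, figure data."""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .microsim import RunResult
from .psa import PSAResult

__all__ = [
    "compare_strategies",
    "qalys_to_days_per_person_year",
    "export_figure_data",
    "write_manifest",
]

DAYS_PER_YEAR = 365.25

_COMPARE_ROWS = [
    ("extended_anticoagulation", lambda r: r.proportion_treated * r.n),
    ("recurrent_vte", lambda r: r.recurrences),
    ("clinically_relevant_bleeding", lambda r: r.bleeds),
    ("deaths", lambda r: r.deaths),
    ("qalys", lambda r: r.qalys),
]


def compare_strategies(run_soc: RunResult, run_opt: RunResult) -> pd.DataFrame:
    """Guideline standard of care vs optimal-ratio assignment, per cohort.

    Differences are recomputed as optimal − standard of care; percent is
    relative to the standard-of-care value.
    """
    if run_soc.n != run_opt.n:
        raise ValueError(
            f"cohort sizes differ: standard of care n={run_soc.n}, optimal n={run_opt.n}"
        )
    rows = []
    for name, get in _COMPARE_ROWS:
        soc, opt = float(get(run_soc)), float(get(run_opt))
        diff = opt - soc
        rows.append(
            {
                "outcome": name,
                "standard_of_care": soc,
                "optimal_ratio": opt,
                "difference": diff,
                "percent_difference": 100.0 * diff / soc if soc != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("outcome")


def qalys_to_days_per_person_year(
    delta_qalys: float, n_persons: int, horizon_years: float
) -> float:
    """Express a cohort QALY difference as days in perfect health per person-year."""
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    if horizon_years <= 0:
        raise ValueError("horizon_years must be positive")
    return delta_qalys / n_persons / horizon_years * DAYS_PER_YEAR


def export_figure_data(result, out_dir) -> list[Path]:
    """Write tidy long-format CSVs for plotting.

    For a ratio sweep (DataFrame): one file with columns
    (ratio, metric, value).  For a :class:`PSAResult`: per-ratio mean
    curves plus the per-replication (optimal ratio, QALYs) scatter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if isinstance(result, pd.DataFrame):
        long = result.melt(id_vars="ratio", var_name="metric", value_name="value")
        path = out_dir / "ratio_sweep_long.csv"
        long.to_csv(path, index=False)
        written.append(path)
    elif isinstance(result, PSAResult):
        if result.reps == 0:
            raise ValueError("PSA result holds no replications; nothing to export")
        curves = result.per_ratio_means().melt(
            id_vars="ratio", var_name="metric", value_name="value"
        )
        path = out_dir / "psa_per_ratio_means_long.csv"
        curves.to_csv(path, index=False)
        written.append(path)
        scatter = pd.DataFrame(
            {
                "replication": np.arange(1, result.reps + 1),
                "optimal_ratio": result.per_rep_optimal,
                "qalys_at_optimum": result.per_rep_optimal_qalys,
            }
        )
        path = out_dir / "psa_optimal_scatter.csv"
        scatter.to_csv(path, index=False)
        written.append(path)
        path = out_dir / "psa_convergence_trace.csv"
        result.convergence_trace().to_csv(path, index=False)
        written.append(path)
    else:
        raise TypeError(f"cannot export figure data from {type(result).__name__}")
    return written


def write_manifest(out_dir, seed: int, config: dict, timings: dict | None = None) -> Path:
    """Record seed, config hash and environment for bitwise reproduction."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "timings": timings or {},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
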