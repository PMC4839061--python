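"""Reading tension datasets from delimited text and writing result reports.

Input files are comma- or tab-separated with a header row. One column holds
the concentration (in a declared unit — never inferred) and one or more
columns hold the measured tension; multiple tension columns are treated as
replicates and averaged, with a warning when a row's replicate coefficient
of variation exceeds the 3 % reproducibility bound.

Reports mirror the two standard result tables: a parameter block (Gamma_inf,
area per molecule, beta, K, anchor, CMC per model) and an error block (the
seven goodness-of-fit metrics per model), written both as aligned plain text
and as machine-readable JSON with a deterministic field order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import MEASUREMENT_TOLERANCE, TensionDataset
from .errors import ErrorSuite
from .fitting import FitResult
from .isotherms import format_area
from .segmentation import RegionSplit

__all__ = [
    "AnalysisConfig",
    "CONCENTRATION_UNITS",
    "read_dataset",
    "write_dataset",
    "write_report",
    "render_parameter_table",
    "render_error_table",
]

logger = logging.getLogger("tensiofit")

#: Factors converting each accepted concentration unit to mol/m^3.
CONCENTRATION_UNITS = {
    "mol/L": 1e3,
    "mmol/L": 1.0,
    "umol/L": 1e-3,
    "mol/m3": 1.0,
}


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run (file paths, units, models)."""

    input_path: Optional[str] = None
    concentration_unit: str = "mmol/L"
    temperature: float = 298.15
    gamma0: float = 72.0
    n: float = 1.0
    models: tuple = ("gibbs", "langmuir", "frumkin")
    segmentation: str = "auto"  # auto | manual | none
    breakpoints: tuple = ()
    output_dir: Optional[str] = None
    seed: int = 0
    concentration_column: str = "concentration"
    tension_prefix: str = "tension"

    def __post_init__(self) -> None:
        if self.concentration_unit not in CONCENTRATION_UNITS:
            raise ValueError(
                f"unknown concentration unit {self.concentration_unit!r}; "
                f"choose from {sorted(CONCENTRATION_UNITS)}"
            )
        if self.temperature <= 0 or self.gamma0 <= 0:
            raise ValueError("temperature and gamma0 must be positive")


class ParseError(ValueError):
    """Malformed input file (missing columns, bad cells); names row numbers."""


def read_dataset(path, config: AnalysisConfig, label: str = "") -> TensionDataset:
    """Read a delimited gamma-C file into a validated dataset.

    The file must have a header naming ``config.concentration_column`` and at
    least one column starting with ``config.tension_prefix``; several tension
    columns are averaged as replicates. Concentrations are converted from
    ``config.concentration_unit`` to mol/m^3 and rows are sorted ascending.
    Row numbers in error messages are 0-based data rows.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]

    if config.concentration_column not in df.columns:
        raise ParseError(
            f"missing concentration column {config.concentration_column!r} "
            f"in {path} (found {list(df.columns)})"
        )
    tension_cols = [c for c in df.columns if c.startswith(config.tension_prefix)]
    if not tension_cols:
        raise ParseError(
            f"no tension column starting with {config.tension_prefix!r} in {path}"
        )

    def _numeric(col: str) -> np.ndarray:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise ParseError(f"non-numeric value in column {col!r} at row {bad[0]}")
        return vals

    conc = _numeric(config.concentration_column)
    tensions = np.column_stack([_numeric(c) for c in tension_cols])

    for name, arr in ((config.concentration_column, conc), ("tension", tensions)):
        bad = np.nonzero(~np.all(np.atleast_2d(arr.T) > 0, axis=0))[0]
        if bad.size:
            raise ParseError(f"non-positive {name} at row {bad[0]}")

    if len(tension_cols) > 1:
        logger.warning(
            "averaging %d replicate tension columns %s",
            len(tension_cols), tension_cols,
        )
        cv = tensions.std(axis=1, ddof=1) / tensions.mean(axis=1)
        for row in np.nonzero(cv > MEASUREMENT_TOLERANCE)[0]:
            logger.warning(
                "row %d: replicate CV %.1f%% exceeds the %.0f%% "
                "reproducibility bound",
                row, 100 * cv[row], 100 * MEASUREMENT_TOLERANCE,
            )
    gamma = tensions.mean(axis=1)

    conc_si = conc * CONCENTRATION_UNITS[config.concentration_unit]
    return TensionDataset(
        conc_si, gamma, config.temperature, config.gamma0,
        label=label or str(path),
    )


def write_dataset(dataset: TensionDataset, path, config: AnalysisConfig) -> None:
    """Write a dataset back to CSV in the config's concentration unit."""
    factor = CONCENTRATION_UNITS[config.concentration_unit]
    pd.DataFrame({
        config.concentration_column: dataset.concentrations / factor,
        config.tension_prefix: dataset.tensions,
    }).to_csv(path, index=False, float_format="%.12g")


def _result_record(res: FitResult, concentration_unit: str) -> dict:
    factor = CONCENTRATION_UNITS[concentration_unit]
    rec = {
        "model": res.model_id,
        "gamma_inf_umol_m2": res.params.gamma_inf * 1e6,
        "area_A2": res.area,
        "area_reported": format_area(res.area),
        "beta": None if res.model_id in ("gibbs", "langmuir", "modified_langmuir")
        else res.params.beta,
        "K": None if not np.isfinite(res.params.K) else res.params.K * factor,
        "K_unit": f"1/({concentration_unit})",
        "n_points": res.n_points,
        "converged": res.converged,
        "errors": res.errors.as_dict(),
    }
    if res.anchor is not None:
        rec["anchor"] = {
            "c_12": res.anchor.c_12 / factor,
            "gamma_12": res.anchor.gamma_12,
            "coverage_12_umol_m2": None if res.anchor.coverage_12 is None
            else res.anchor.coverage_12 * 1e6,
        }
    return rec


_ERROR_LABELS = ("rmse", "sse", "cfef", "mpsd", "are", "eabs", "ape")


def render_parameter_table(results: Sequence[FitResult]) -> str:
    """Aligned text table of Gamma_inf, area, beta and K per model."""
    header = f"{'model':<18}{'Ginf(umol/m2)':>14}{'A(A^2)':>9}{'beta':>8}{'K':>12}"
    rows = [header, "-" * len(header)]
    for r in results:
        beta = "-" if r.model_id in ("gibbs", "langmuir", "modified_langmuir") \
            else f"{r.params.beta:.2f}"
        k = "-" if not np.isfinite(r.params.K) else f"{r.params.K:.4g}"
        rows.append(
            f"{r.model_id:<18}{r.params.gamma_inf * 1e6:>14.2f}"
            f"{format_area(r.area):>9}{beta:>8}{k:>12}"
        )
    return "\n".join(rows)


def render_error_table(results: Sequence[FitResult]) -> str:
    """Aligned text table of the seven error metrics per model."""
    header = f"{'metric':<8}" + "".join(f"{r.model_id:>18}" for r in results)
    rows = [header, "-" * len(header)]
    for name in _ERROR_LABELS:
        vals = "".join(f"{getattr(r.errors, name):>18.4g}" for r in results)
        rows.append(f"{name.upper():<8}{vals}")
    return "\n".join(rows)


def write_report(
    results: Sequence[FitResult],
    split: Optional[RegionSplit],
    out_dir,
    concentration_unit: str = "mmol/L",
) -> dict:
    """Write JSON + plain-text report for a set of fits.

    Returns the JSON-serializable report dict. Regenerating the report from
    the same results is byte-identical.
    """
    if not results:
        raise ValueError("no fit results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    factor = CONCENTRATION_UNITS[concentration_unit]
    report = {
        "concentration_unit": concentration_unit,
        "results": [_result_record(r, concentration_unit) for r in results],
    }
    if split is not None:
        report["segmentation"] = {
            "degenerate": split.degenerate,
            "n_segments": split.n_segments,
            "slopes_mN_m_per_ln": list(split.slopes),
            "sse": split.sse,
            "cmc": None if split.cmc is None else split.cmc / factor,
            "anchor": None if split.anchor is None else {
                "c_12": split.anchor.c_12 / factor,
                "gamma_12": split.anchor.gamma_12,
            },
        }
    (out / "results.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    text = render_parameter_table(results) + "\n\n" + render_error_table(results) + "\n"
    (out / "report.txt").write_text(text)
    return report
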