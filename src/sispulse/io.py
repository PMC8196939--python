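"""Config parsing and CSV writers.

Config files are flat ``key = value`` text with exactly the nine model
parameter keys (A, d, beta, v, theta, c, b, q, S_T); '#' starts a
comment.  All CSV output carries a '#'-prefixed header block with the
full parameter set and package version, and floats are printed at 12
significant digits so independent implementations can be diffed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import __version__
from .params import PARAM_NAMES, ModelParams, ParamError

__all__ = ["load_config", "save_config", "format_float", "write_table_csv", "write_report_csv"]


class ConfigError(ValueError):
    pass


def load_config(path) -> ModelParams:
    """Parse a key=value config file into a validated ModelParams."""
    seen: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in PARAM_NAMES:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        if key in seen:
            raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
        try:
            seen[key] = float(val.strip())
        except ValueError:
            raise ConfigError(f"{path}:{lineno}: non-numeric value for {key!r}: {val.strip()!r}") from None
    missing = [k for k in PARAM_NAMES if k not in seen]
    if missing:
        raise ConfigError(f"{path}: missing keys: {missing}")
    try:
        return ModelParams(**seen)
    except ParamError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_config(p: ModelParams, path) -> None:
    lines = [f"{k} = {format_float(getattr(p, k))}" for k in PARAM_NAMES]
    Path(path).write_text("\n".join(lines) + "\n")


def format_float(x: float) -> str:
    return f"{x:.12g}"


def _header_lines(p: ModelParams, extra: dict | None = None) -> list[str]:
    lines = [f"# sispulse {__version__}"]
    lines.append("# " + ", ".join(f"{k}={format_float(getattr(p, k))}" for k in PARAM_NAMES))
    for k, v in (extra or {}).items():
        val = format_float(v) if isinstance(v, float) else str(v)
        lines.append(f"# {k} = {val}")
    return lines


def write_table_csv(df: pd.DataFrame, path, p: ModelParams, extra: dict | None = None) -> None:
    """Write a DataFrame as CSV with a commented parameter header."""
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(p, extra)) + "\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def write_report_csv(report, path) -> None:
    """Serialize an EquilibriumReport: scalar header block + one row per
    equilibrium (S, I, multiplicity, H, stability)."""
    scalars = {
        "R0": report.R0, "Rhat0": report.Rhat0, "A1": report.A1,
        "a1": report.a1, "a2": report.a2, "Delta": report.Delta,
        "case": report.case, "dfe_S": report.dfe[0], "dfe_I": report.dfe[1],
        "dfe_stable": report.dfe_stable,
    }
    rows = [
        {"S": e.S, "I": e.I, "multiplicity": e.multiplicity, "H": e.H, "stability": e.stability}
        for e in report.endemics
    ]
    df = pd.DataFrame(rows, columns=["S", "I", "multiplicity", "H", "stability"])
    write_table_csv(df, path, report.params, extra=scalars)
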