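"""CSV readers/validators, run configuration, and result documents.

All tabular inputs are comma-separated UTF-8 with a header row.  Units are
fixed per schema (concentrations M, potentials mV in an explicitly suffixed
column, depths Angstrom, time s); converters live only at this boundary.
Validation collects *all* violations and raises one :class:`SchemaError`
listing them with line numbers (header = line 1).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, SchemaError
from .titration import OBSERVABLE_KINDS, TitrationSeries

SCHEMAS: Dict[str, Dict[str, object]] = {
    "titration": {"required": ("guest_total_M", "observable"),
                  "optional": ("observable_kind", "sigma")},
    "zeta": {"required": ("condition", "zeta_mV", "temperature_K"), "optional": ()},
    "quenching": {"required": ("quencher", "F_over_F0", "mole_fraction"),
                  "optional": ("depth_A",)},
    "trace": {"required": ("time_s",), "optional": ("ratio", "I460", "I403")},
}

_NUMERIC = {"guest_total_M", "observable", "sigma", "zeta_mV", "temperature_K",
            "F_over_F0", "mole_fraction", "depth_A", "time_s", "ratio",
            "I460", "I403"}


def _sniff_dialect(path: Path, violations: List[str]) -> None:
    header = path.open("r", encoding="utf-8").readline()
    if ";" in header and "," not in header:
        violations.append(
            "line 1: semicolon-delimited file; inputs must be comma-separated "
            "UTF-8 (dialect rule)")


def load_and_validate(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against one of the registered schemas."""
    path = Path(path)
    if schema not in SCHEMAS:
        raise ConfigurationError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    if not path.exists():
        raise SchemaError([f"file not found: {path}"])
    violations: List[str] = []
    _sniff_dialect(path, violations)
    if violations:
        raise SchemaError(violations)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise SchemaError([f"unparseable CSV: {exc}"]) from exc
    spec = SCHEMAS[schema]
    for col in spec["required"]:
        if col not in df.columns:
            violations.append(f"line 1: missing required column {col!r}")
    if schema == "trace" and "ratio" not in df.columns and not (
            "I460" in df.columns and "I403" in df.columns):
        violations.append("line 1: trace needs either 'ratio' or both 'I460' and 'I403'")
    if violations:
        raise SchemaError(violations)

    for col in df.columns:
        if col in _NUMERIC:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            for i in bad:
                violations.append(f"line {i + 2}: non-numeric value in {col!r}: "
                                  f"{df.loc[i, col]!r}")
            df[col] = coerced

    # row-level range checks
    if schema == "titration" and "guest_total_M" in df.columns:
        g = df["guest_total_M"].to_numpy()
        for i in np.flatnonzero(g < 0):
            violations.append(f"line {i + 2}: guest_total_M must be >= 0")
        diffs = np.diff(g)
        for i in np.flatnonzero(diffs <= 0):
            violations.append(f"line {i + 3}: titrant grid not strictly increasing "
                              "(sort rows by guest_total_M)")
        if "observable_kind" in df.columns:
            for i, k in enumerate(df["observable_kind"]):
                if k not in OBSERVABLE_KINDS:
                    violations.append(f"line {i + 2}: unknown observable_kind {k!r}")
    if schema == "quenching":
        f = df["F_over_F0"].to_numpy()
        for i in np.flatnonzero(~((f > 0) & (f <= 1))):
            violations.append(f"line {i + 2}: F_over_F0 must be in (0, 1]")
        m = df["mole_fraction"].to_numpy()
        for i in np.flatnonzero(~((m > 0) & (m <= 1))):
            violations.append(f"line {i + 2}: mole_fraction must be in (0, 1]")
    if schema == "zeta":
        z = df["zeta_mV"].to_numpy()
        for i in np.flatnonzero(np.abs(z) >= 300):
            violations.append(f"line {i + 2}: |zeta_mV| must be < 300")
    if schema == "trace":
        t = df["time_s"].to_numpy()
        for i in np.flatnonzero(np.diff(t) <= 0):
            violations.append(f"line {i + 3}: time_s must be strictly increasing")
        if "ratio" not in df.columns:
            df["ratio"] = df["I460"] / df["I403"]
    if violations:
        raise SchemaError(violations)
    return df


def write_titration_csv(series: TitrationSeries, path) -> None:
    df = pd.DataFrame({"guest_total_M": series.guest_totals,
                       "observable": series.observables,
                       "observable_kind": series.observable_kind})
    if series.sigma is not None:
        df["sigma"] = series.sigma
    df.to_csv(path, index=False)


def read_titration_series(path, host_total: float, observable_kind: Optional[str] = None,
                          **meta) -> TitrationSeries:
    df = load_and_validate(path, "titration")
    if observable_kind is None:
        if "observable_kind" not in df.columns:
            raise ConfigurationError("observable_kind neither in file nor given")
        kinds = set(df["observable_kind"])
        if len(kinds) != 1:
            raise ConfigurationError(f"mixed observable kinds in file: {sorted(kinds)}")
        observable_kind = kinds.pop()
    return TitrationSeries.from_dataframe(df, observable_kind, host_total, **meta)


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_KEYS = {
    "experiment", "files", "model", "fixed", "seed", "output_dir",
    "host_total_M", "sulfate_total_M", "ksp_M2", "ka_s", "se_ka_s",
    "competitor", "competitor_total_M", "competitor_charge", "reporter_charge",
    "correct", "temperature_K", "eps_r", "shear_plane_A", "electrolyte",
    "quencher_depths_A", "mole_fraction", "area_per_lipid_A2",
    "calibration", "vesicle", "window_s", "rate_mode",
    "anion", "anion_conc_M", "lipid_conc_M", "carrier_mole_fraction",
}


@dataclass
class RunConfig:
    """Structured run configuration loaded from YAML.

    Unknown keys are rejected; every override is echoed verbatim into the
    output report's ``assumptions`` block so paper-gap defaults stay
    auditable.
    """

    experiment: str = ""
    raw: Dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("run config must be a YAML mapping")
        unknown = set(data) - _CONFIG_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(experiment=str(data.get("experiment", "")), raw=data)

    def get(self, key, default=None):
        return self.raw.get(key, default)

    def require(self, key):
        if key not in self.raw:
            raise ConfigurationError(f"config key {key!r} is required for this command")
        return self.raw[key]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result_document(path, result: Dict[str, object],
                          assumptions: Dict[str, object]) -> None:
    """Write the machine-readable JSON result document for one run."""
    doc = {"result": _jsonable(result), "assumptions": _jsonable(assumptions)}
    Path(path).write_text(json.dumps(doc, indent=2, allow_nan=True) + "\n",
                          encoding="utf-8")
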