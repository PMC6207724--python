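"""Table readers/writers, configuration and the JSON report.

All on-disk formats are plain delimited text (comma or tab, auto-detected)
with case-insensitive headers that carry units as suffixes:

* peak lists      — ``residue_id, atom_group, delta_h_ppm, delta_n_ppm``
* exclusion list  — one residue_id per line
* traces          — ``time_s, signal`` (metadata in a YAML sidecar)
* rate tables     — ``ligand_uM, k_fast_s, k_fast_se, k_slow_s, k_slow_se``
* activity tables — ``substrate_uM, k_obs_s, sd_s``
* dose-response   — ``inhibitor_uM, pct_inhibition, sd``

Reports are JSON with full-precision numbers; every report embeds the
resolved configuration, package version and seeds for provenance.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binding_kinetics import RateVsConc, Trace
from .enzyme_kinetics import RatePoint
from .errors import ParseError
from .nmr_populations import ExclusionList, Peak, PeakSet

REPORT_SCHEMA_VERSION = "1"

_FLOAT_FMT = "%.12g"


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=str(path))
    text = path.read_text()
    if not text.strip():
        raise ParseError("empty file", path=str(path))
    header = text.splitlines()[0]
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    try:
        df = pd.read_csv(_io.StringIO(text), sep=sep, skipinitialspace=True)
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"could not parse table: {exc}", path=str(path)) from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_table(path, required: list, optional: list = ()) -> pd.DataFrame:
    """Read a delimited table, validating headers and numeric cells.

    ``required``/``optional`` are lower-case column names; extra columns are
    kept.  Non-numeric cells in required numeric columns raise a
    :class:`ParseError` naming the first offending line.
    """
    df = _read_delimited(path)
    for col in required:
        if col not in df.columns:
            raise ParseError(
                f"missing required column {col!r} (found: {list(df.columns)})",
                path=str(path),
            )
    for col in list(required) + [c for c in optional if c in df.columns]:
        if col in ("atom_group", "assignment"):
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based indexing
            raise ParseError(
                f"non-numeric value {df.loc[bad[0], col]!r} in column {col!r}",
                path=str(path),
                line=int(bad[0]) + 2,
            )
        if coerced.isna().any():
            raise ParseError(
                f"empty cell in column {col!r}",
                path=str(path),
                line=int(df.index[coerced.isna()][0]) + 2,
            )
        df[col] = coerced
    return df


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def read_peak_list(path, label: str) -> PeakSet:
    df = read_table(
        path,
        required=["residue_id", "delta_h_ppm", "delta_n_ppm"],
        optional=["atom_group"],
    )
    peaks = []
    for _, row in df.iterrows():
        peaks.append(
            Peak(
                residue_id=int(row["residue_id"]),
                delta_h=float(row["delta_h_ppm"]),
                delta_n=float(row["delta_n_ppm"]),
                atom_group=str(row.get("atom_group", "backbone-NH"))
                if "atom_group" in df.columns
                else "backbone-NH",
            )
        )
    return PeakSet(label, peaks)


def write_peak_list(peakset: PeakSet, path) -> None:
    df = pd.DataFrame(peakset.to_records())
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_assignment_shifts(path, label: str) -> PeakSet:
    """Import a simple two-column (assignment, shift) dialect.

    Rows look like ``123.HN, 8.23`` / ``123.N, 120.4``; the HN and N rows
    of one residue are paired into a peak.
    """
    df = read_table(path, required=["assignment", "shift"], optional=[])
    shifts: dict = {}
    for _, row in df.iterrows():
        assignment = str(row["assignment"]).strip()
        try:
            rid_s, atom = assignment.rsplit(".", 1)
            rid = int(rid_s)
        except ValueError as exc:
            raise ParseError(
                f"malformed assignment {assignment!r}", path=str(path)
            ) from exc
        shifts.setdefault(rid, {})[atom.upper()] = float(row["shift"])
    peaks = []
    for rid, atoms in sorted(shifts.items()):
        if "HN" in atoms and "N" in atoms:
            peaks.append(Peak(rid, atoms["HN"], atoms["N"]))
    return PeakSet(label, peaks)


def read_exclusions(path) -> ExclusionList:
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=str(path))
    ids = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            ids.append(int(line))
        except ValueError as exc:
            raise ParseError(
                f"invalid residue id {line!r}", path=str(path), line=ln
            ) from exc
    return ExclusionList.from_iterable(ids)


# ---------------------------------------------------------------------------
# Traces and rate tables
# ---------------------------------------------------------------------------

def read_trace(path, meta: dict | None = None) -> Trace:
    df = read_table(path, required=["time_s", "signal"])
    sidecar = Path(path).with_suffix(".yaml")
    merged = {}
    if sidecar.exists():
        loaded = yaml.safe_load(sidecar.read_text()) or {}
        if not isinstance(loaded, dict):
            raise ParseError("trace sidecar must be a mapping", path=str(sidecar))
        merged.update(loaded)
    if meta:
        merged.update(meta)
    return Trace(
        time=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        meta=merged,
    )


def write_trace(trace: Trace, path) -> None:
    pd.DataFrame({"time_s": trace.time, "signal": trace.signal}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    if trace.meta:
        safe = {
            k: v for k, v in trace.meta.items() if isinstance(v, (int, float, str))
        }
        Path(path).with_suffix(".yaml").write_text(yaml.safe_dump(safe))


def read_rate_table(path) -> RateVsConc:
    df = read_table(
        path,
        required=["ligand_um", "k_fast_s"],
        optional=["k_fast_se", "k_slow_s", "k_slow_se"],
    )
    def col(name):
        return df[name].to_numpy() if name in df.columns else None

    return RateVsConc(
        ligand_conc=df["ligand_um"].to_numpy(),
        k_fast=df["k_fast_s"].to_numpy(),
        k_fast_se=col("k_fast_se"),
        k_slow=col("k_slow_s"),
        k_slow_se=col("k_slow_se"),
    )


def write_rate_table(data: RateVsConc, path) -> None:
    out = {"ligand_uM": data.ligand_conc, "k_fast_s": data.k_fast}
    if data.k_fast_se is not None:
        out["k_fast_se"] = data.k_fast_se
    if data.k_slow is not None:
        out["k_slow_s"] = data.k_slow
    if data.k_slow_se is not None:
        out["k_slow_se"] = data.k_slow_se
    pd.DataFrame(out).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_activity_table(path) -> list:
    df = read_table(path, required=["substrate_um", "k_obs_s"], optional=["sd_s"])
    sd = df["sd_s"] if "sd_s" in df.columns else pd.Series(0.0, index=df.index)
    return [
        RatePoint(float(s), float(k), float(e))
        for s, k, e in zip(df["substrate_um"], df["k_obs_s"], sd)
    ]


def write_activity_table(points, path) -> None:
    pd.DataFrame(
        {
            "substrate_uM": [p.substrate for p in points],
            "k_obs_s": [p.k_obs for p in points],
            "sd_s": [p.sd for p in points],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_dose_table(path):
    df = read_table(
        path, required=["inhibitor_um", "pct_inhibition"], optional=["sd"]
    )
    sd = df["sd"].to_numpy() if "sd" in df.columns else None
    return df["inhibitor_um"].to_numpy(), df["pct_inhibition"].to_numpy(), sd


def write_dose_table(doses, responses, path, sd=None) -> None:
    out = {"inhibitor_uM": doses, "pct_inhibition": responses}
    if sd is not None:
        out["sd"] = sd
    pd.DataFrame(out).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Configuration and reports
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Resolved configuration of a full pipeline run.

    Unknown keys in a config file are rejected; all resolved values are
    serialised into the output report for provenance.
    """

    preset: str = "wt"
    seed: int = 0
    angle_tol_deg: float = 10.0
    min_b_ppm: float = 0.03
    convention: str = "closed"
    substrate_uM: float = 500.0
    enzyme_uM: float = 0.01
    k_close_35C: float = 5.8
    out_dir: str | None = None
    verbosity: int = 0
    engine: dict = field(
        default_factory=lambda: {
            "kcat1": 370.0,
            "kcat2": 185.0,
            "kd1": 110.0,
            "kd2": 800.0,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParseError("config must be a key-value mapping", path=str(path))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(
                f"unknown config keys: {sorted(unknown)} (known: {sorted(known)})",
                path=str(path),
            )
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_report(report: dict, path=None) -> str:
    """Serialise a report to JSON (full precision); returns the JSON text."""
    from . import __version__

    payload = {"schema_version": REPORT_SCHEMA_VERSION, "package_version": __version__}
    payload.update(report)
    text = json.dumps(payload, indent=2, default=_json_default)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
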