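"""Table and parameter-file I/O.

Tables are tab-separated UTF-8 with a required header and ``#`` comment
lines — the dialect of curated proteome exports, robust to Greek letters
and dashes in probe names.  Unit-suffixed headers (``_nm``, ``_da``,
``_kda``, ``_um2s``) are converted to the package's canonical units (nm,
Da, um^2/s) on read.  Fitted parameters round-trip through a small JSON
document carrying provenance (source-data hash, optional timestamp).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Environment, SdvrcParams
from .fitting import ProbeMeasurement, probe_from_dc
from .proteome import DcRecord, ProteinRecord, dc_table_frame

__all__ = [
    "SchemaError",
    "IncompatibleParamsError",
    "RunConfig",
    "read_table",
    "write_table",
    "read_probe_table",
    "read_proteome_table",
    "write_proteome_table",
    "write_dc_table",
    "write_params",
    "read_params",
]

PARAMS_FORMAT_VERSION = 1

#: header-suffix unit conversions into canonical columns
_UNIT_ALIASES = {
    "mass_da": ("mass_kda", 1000.0),
    "chain_mass_da": ("chain_mass_kda", 1000.0),
    "M_total_da": ("M_total_kda", 1000.0),
}


class SchemaError(ValueError):
    """The table header does not provide a mandatory column."""


class IncompatibleParamsError(ValueError):
    """A parameter file is missing keys or has an unsupported version."""


@dataclass
class RunConfig:
    """Shared run options threaded through the command-line entry points."""

    T: float | None = None
    eta0: float | None = None
    molecule_class: str = "protein"
    seed: int = 0
    full_precision: bool = False

    def environment(self) -> Environment:
        env = Environment()
        return Environment(
            T=self.T if self.T is not None else env.T,
            eta0=self.eta0 if self.eta0 is not None else env.eta0,
        )


def read_table(path, required=(), numeric=()) -> pd.DataFrame:
    """Read a tab-separated table into canonical units.

    ``required`` columns must be present after alias resolution (a
    ``*_kda`` column satisfies a ``*_da`` requirement and is converted);
    ``numeric`` columns are parsed as floats with row-accurate error
    reporting.  Unknown columns pass through untouched.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for canonical, (alias, factor) in _UNIT_ALIASES.items():
        if canonical not in df.columns and alias in df.columns:
            converted = _to_float(df, alias, path) * factor
            df = df.drop(columns=[alias]).assign(**{canonical: converted})
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    for col in numeric:
        if col in df.columns:
            df[col] = _to_float(df, col, path)
    return df


def _to_float(df: pd.DataFrame, col: str, path) -> pd.Series:
    try:
        return df[col].astype(float)
    except ValueError:
        for i, v in df[col].items():
            try:
                float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: unparsable value {v!r} in column {col!r}, data row {i + 1}"
                ) from None
        raise


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_probe_table(path, env: Environment = Environment()) -> list[ProbeMeasurement]:
    """Read calibration probes.

    Needs ``name`` and ``radius_nm`` plus either ``ln_ratio`` directly or a
    cytoplasmic DC column ``D_cyto_um2s`` (with optional ``D0_um2s``; the
    dilute-solution DC otherwise follows from the radius), from which
    ``ln_ratio = ln(D0/Dcyto)`` is computed.
    """
    df = read_table(
        path,
        required=("name", "radius_nm"),
        numeric=("radius_nm", "ln_ratio", "D_cyto_um2s", "D0_um2s", "mass_kda"),
    )
    if "ln_ratio" not in df.columns and "D_cyto_um2s" not in df.columns:
        raise SchemaError(f"{path}: need an ln_ratio or a D_cyto_um2s column")
    probes = []
    for _, row in df.iterrows():
        mass = float(row["mass_kda"]) if "mass_kda" in df.columns and pd.notna(row.get("mass_kda")) else None
        if "ln_ratio" in df.columns and pd.notna(row["ln_ratio"]):
            probes.append(
                ProbeMeasurement(
                    name=row["name"], r_p=row["radius_nm"], ln_ratio=row["ln_ratio"], M=mass
                )
            )
        else:
            d0 = row["D0_um2s"] if "D0_um2s" in df.columns and pd.notna(row.get("D0_um2s")) else None
            probes.append(
                probe_from_dc(
                    row["name"], row["radius_nm"], row["D_cyto_um2s"], D0=d0, env=env, M=mass
                )
            )
    return probes


def _parse_subunits(cell: str) -> list[tuple[str, int]]:
    # "ACC1:4;ACC2:1" -> [("ACC1", 4), ("ACC2", 1)]
    if not cell or pd.isna(cell):
        return []
    out = []
    for part in str(cell).split(";"):
        part = part.strip()
        if not part:
            continue
        chain, _, copies = part.partition(":")
        out.append((chain.strip(), int(copies) if copies else 1))
    return out


def read_proteome_table(path) -> list[ProteinRecord]:
    """Read a proteome annotation table into ProteinRecords.

    Columns: ``accession``, ``chain_mass_da`` (or ``_kda``), optional
    ``name``, ``localization``, ``subunits`` (``chain:copies`` pairs joined
    by ``;``), ``pathway`` and ``sec_partner``.
    """
    df = read_table(
        path, required=("accession", "chain_mass_da"), numeric=("chain_mass_da",)
    )
    records = []
    for _, row in df.iterrows():
        records.append(
            ProteinRecord(
                accession=row["accession"],
                chain_mass=row["chain_mass_da"],
                name=row.get("name", "") if pd.notna(row.get("name", "")) else "",
                localization=row.get("localization", "cytoplasmic") or "cytoplasmic",
                subunits=_parse_subunits(row.get("subunits", "")),
                pathway=row.get("pathway", "none") if pd.notna(row.get("pathway", "none")) else "none",
                sec_partner=row.get("sec_partner") if pd.notna(row.get("sec_partner")) else None,
            )
        )
    return records


def write_proteome_table(records: list[ProteinRecord], path) -> None:
    df = pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "name": [r.name for r in records],
            "chain_mass_da": [r.chain_mass for r in records],
            "localization": [r.localization for r in records],
            "subunits": [";".join(f"{c}:{k}" for c, k in r.subunits) for r in records],
            "pathway": [r.pathway for r in records],
            "sec_partner": [r.sec_partner or "" for r in records],
        }
    )
    write_table(df, path)


def write_dc_table(records: list[DcRecord], path, full_precision: bool = True) -> None:
    df = dc_table_frame(records)
    if not full_precision:
        df["radius_nm"] = df["radius_nm"].round(2)
        for col in ("D0_um2s", "ln_ratio", "Dcyto_um2s"):
            df[col] = [float(f"{v:.3g}") for v in df[col]]
    write_table(df, path)


def write_params(
    path,
    params: SdvrcParams,
    env: Environment = Environment(),
    source: str = "",
    source_data: bytes | None = None,
    timestamp: bool = True,
) -> None:
    """Write fitted parameters plus environment and provenance as JSON."""
    doc = {
        "format_version": PARAMS_FORMAT_VERSION,
        "xi_nm": params.xi,
        "Rh_nm": params.Rh_env,
        "a": params.a,
        "T_K": env.T,
        "eta0_Pa_s": env.eta0,
        "provenance": {
            "source": source,
            "data_sha256": hashlib.sha256(source_data).hexdigest() if source_data else None,
            "created": datetime.now(timezone.utc).isoformat() if timestamp else None,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def read_params(path) -> tuple[SdvrcParams, Environment, dict]:
    """Read a parameter file; lossless inverse of :func:`write_params`."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    version = doc.get("format_version")
    if version != PARAMS_FORMAT_VERSION:
        raise IncompatibleParamsError(
            f"{path}: unsupported parameter-file version {version!r}"
        )
    try:
        params = SdvrcParams(doc["xi_nm"], doc["Rh_nm"], doc["a"])
        env = Environment(T=doc["T_K"], eta0=doc["eta0_Pa_s"])
    except KeyError as exc:
        raise IncompatibleParamsError(f"{path}: missing key {exc}") from None
    return params, env, doc.get("provenance", {})
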