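"""Reading and writing the five MIMIC-shaped event tables.

The package works on a *canonical* internal schema (lower-case column names
listed in :data:`REQUIRED_FIELDS`/:data:`OPTIONAL_FIELDS`) and ships a
default mapping from MIMIC-III v1.4 column names.  ``ITEMID`` codes are
translated to electrolyte names through an editable item-code table, so a
user pointing the pipeline at real ``LABEVENTS``/``INPUTEVENTS_MV`` extracts
only has to adjust the code lists, never the pipeline.

Every row either becomes a typed record or is counted in a
:class:`~repleteaudit.model.ValidationReport` under a named rejection
reason; rows are never silently dropped.
"""

from __future__ import annotations

import os
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .model import ELECTROLYTES, ValidationReport

KINDS = ("lab", "repletion", "stay", "diagnosis")

#: Canonical required fields per table kind.  For event tables either
#: ``electrolyte`` or a raw ``item_id`` (resolved through ``item_map``)
#: must be present.
REQUIRED_FIELDS: dict[str, tuple[str, ...]] = {
    "lab": ("subject_id", "stay_id", "electrolyte", "charttime", "value"),
    "repletion": ("subject_id", "stay_id", "electrolyte", "ordertime", "dose"),
    "stay": ("stay_id", "subject_id", "unit_type", "intime", "outtime", "age_years"),
    "diagnosis": ("subject_id", "stay_id", "icd9_code", "seq_num"),
}

OPTIONAL_FIELDS: dict[str, tuple[str, ...]] = {
    "lab": ("unit_type", "value_unit", "source_flag"),
    "repletion": ("dose_unit", "route"),
    "stay": ("weight_kg",),
    "diagnosis": (),
}

_TIME_FIELDS: dict[str, tuple[str, ...]] = {
    "lab": ("charttime",),
    "repletion": ("ordertime",),
    "stay": ("intime", "outtime"),
    "diagnosis": (),
}

#: Default column-name mappings from MIMIC-III v1.4 (Metavision-era) tables
#: to the canonical schema, keyed by kind.  ``age_years`` does not exist in
#: raw ``ICUSTAYS`` (it requires a DOB join); extracts are expected to carry
#: a precomputed ``AGE`` column.
MIMIC_SCHEMA_MAPS: dict[str, dict[str, str]] = {
    "lab": {
        "SUBJECT_ID": "subject_id",
        "ICUSTAY_ID": "stay_id",
        "ITEMID": "item_id",
        "CHARTTIME": "charttime",
        "VALUENUM": "value",
        "VALUEUOM": "value_unit",
        "FLAG": "source_flag",
    },
    "repletion": {
        "SUBJECT_ID": "subject_id",
        "ICUSTAY_ID": "stay_id",
        "ITEMID": "item_id",
        "STARTTIME": "ordertime",
        "AMOUNT": "dose",
        "AMOUNTUOM": "dose_unit",
        "ORDERCATEGORYNAME": "route",
    },
    "stay": {
        "ICUSTAY_ID": "stay_id",
        "SUBJECT_ID": "subject_id",
        "FIRST_CAREUNIT": "unit_type",
        "INTIME": "intime",
        "OUTTIME": "outtime",
        "AGE": "age_years",
        "WEIGHT": "weight_kg",
    },
    "diagnosis": {
        "SUBJECT_ID": "subject_id",
        "HADM_ID": "stay_id",
        "ICD9_CODE": "icd9_code",
        "SEQ_NUM": "seq_num",
    },
}

#: Default item-code tables.  A code may map to several electrolytes joined
#: by ``+`` (combination products such as potassium phosphate); such rows
#: are expanded to one record per electrolyte.
DEFAULT_LAB_ITEM_MAP: dict[str, str] = {
    "50971": "potassium",
    "50960": "magnesium",
    "50970": "phosphate",
}
DEFAULT_REPLETION_ITEM_MAP: dict[str, str] = {
    "225166": "potassium",   # potassium chloride
    "222011": "magnesium",   # magnesium sulfate
    "225834": "phosphate",   # sodium phosphate
    "225827": "potassium+phosphate",  # potassium phosphate
}


def _apply_schema_map(raw: pd.DataFrame, schema_map: Mapping[str, str] | None) -> pd.DataFrame:
    if schema_map is None:
        return raw
    return raw.rename(columns=dict(schema_map))


def read_events_table(
    path: str | os.PathLike,
    kind: str,
    schema_map: Mapping[str, str] | None = None,
    item_map: Mapping[str, str] | None = None,
    stays: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read one CSV table into the canonical schema.

    Parameters
    ----------
    path
        CSV file (RFC-4180, UTF-8, header row).
    kind
        One of ``lab``, ``repletion``, ``stay``, ``diagnosis``.
    schema_map
        ``{file column -> canonical field}`` rename map.  ``None`` means the
        file already uses canonical names.  Use
        ``MIMIC_SCHEMA_MAPS[kind]`` for MIMIC-III v1.4 extracts.
    item_map
        ``{item code -> electrolyte}`` used when the mapped table carries an
        ``item_id`` column instead of ``electrolyte``.
    stays
        Optional canonical stay table; when given, lab/repletion rows whose
        timestamp falls outside the owning stay's in/out interval are
        rejected with reason ``outside_stay_interval``.

    Returns
    -------
    (records, report)
        Canonical-schema DataFrame of accepted rows and the row-accounting
        report (``accepted + rejected == read``).
    """
    if kind not in KINDS:
        raise ConfigError(f"unknown table kind {kind!r}; expected one of {KINDS}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    df = _apply_schema_map(raw, schema_map)

    required = list(REQUIRED_FIELDS[kind])
    needs_electrolyte = "electrolyte" in required
    if needs_electrolyte and "electrolyte" not in df.columns and "item_id" in df.columns:
        required.remove("electrolyte")  # resolved from item_id below
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(
            f"{kind} table {path!r} is missing required column(s) "
            f"{', '.join(missing)} after schema mapping"
        )

    report = ValidationReport(n_rows_read=len(df))
    keep = pd.Series(True, index=df.index)

    def _reject(mask: pd.Series, reason: str) -> None:
        mask = mask & keep
        n = int(mask.sum())
        if n:
            report.reject(reason, n)
            keep[mask] = False

    # electrolyte resolution
    if needs_electrolyte:
        if "electrolyte" not in df.columns:
            codes = df["item_id"].astype(str).str.strip()
            table = dict(item_map) if item_map is not None else (
                DEFAULT_LAB_ITEM_MAP if kind == "lab" else DEFAULT_REPLETION_ITEM_MAP
            )
            df = df.assign(electrolyte=codes.map({str(k): v for k, v in table.items()}))
            _reject(df["electrolyte"].isna(), "unknown_item_code")
        else:
            elec = df["electrolyte"].astype(str).str.strip().str.lower()
            df = df.assign(electrolyte=elec)
            valid = elec.isin(ELECTROLYTES) | elec.str.contains(r"\+", regex=True)
            _reject(~valid, "unknown_electrolyte")

    # timestamps -> minute resolution
    for col in _TIME_FIELDS[kind]:
        parsed = pd.to_datetime(df[col], errors="coerce", format="mixed")
        _reject(df[col].notna() & parsed.isna(), "unparseable_timestamp")
        _reject(df[col].isna(), "missing_timestamp")
        df[col] = parsed.dt.floor("min")

    # numeric fields
    def _numeric(col: str, required_value: bool) -> None:
        parsed = pd.to_numeric(df[col], errors="coerce")
        _reject(df[col].notna() & parsed.isna(), f"non_numeric_{col}")
        if required_value:
            _reject(df[col].isna(), f"missing_{col}")
        df[col] = parsed

    if kind == "lab":
        _numeric("value", required_value=True)
        _reject(~np.isfinite(df["value"].to_numpy(dtype=float)) & keep, "non_numeric_value")
        _reject(df["value"] <= 0, "nonpositive_value")
    elif kind == "repletion":
        _numeric("dose", required_value=True)
        _reject(df["dose"] < 0, "negative_dose")
    elif kind == "stay":
        _numeric("age_years", required_value=False)
        _reject(df["age_years"] < 0, "negative_age")
        if "weight_kg" in df.columns:
            _numeric("weight_kg", required_value=False)
        _reject(~(df["intime"] < df["outtime"]), "invalid_stay_interval")
    elif kind == "diagnosis":
        _numeric("seq_num", required_value=True)
        _reject(df["seq_num"] < 1, "invalid_seq_num")

    if stays is not None and kind in ("lab", "repletion"):
        tcol = _TIME_FIELDS[kind][0]
        bounds = stays.set_index("stay_id")[["intime", "outtime"]]
        joined = df[["stay_id", tcol]].join(bounds, on="stay_id")
        inside = (
            joined["intime"].isna()
            | ((joined[tcol] >= joined["intime"]) & (joined[tcol] <= joined["outtime"]))
        )
        _reject(~inside, "outside_stay_interval")

    out = df.loc[keep].copy()
    cols = [c for c in REQUIRED_FIELDS[kind] + OPTIONAL_FIELDS[kind] if c in out.columns]
    out = out[cols].reset_index(drop=True)
    if kind == "diagnosis" and len(out):
        out["seq_num"] = out["seq_num"].astype(int)

    # expand combination repletion products ("potassium+phosphate") into one
    # record per constituent electrolyte
    if kind == "repletion" and len(out) and out["electrolyte"].str.contains(r"\+").any():
        out = out.assign(electrolyte=out["electrolyte"].str.split("+")).explode(
            "electrolyte", ignore_index=True
        )
        out = out[out["electrolyte"].isin(ELECTROLYTES)].reset_index(drop=True)

    report.check()
    return out, report


def write_summary_table(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write any tabular result as deterministic CSV.

    Column order is preserved, quoting is minimal RFC-4180, line terminator
    is ``\\n``; two writes of the same frame are byte-identical.  Timestamps
    serialize as ``YYYY-MM-DD HH:MM:SS`` so a written event table round-trips
    through :func:`read_events_table`.
    """
    if records is None:
        raise DataError("refusing to write a null table")
    try:
        records.to_csv(path, index=False, lineterminator="\n", date_format="%Y-%m-%d %H:%M:%S")
    except OSError as exc:
        raise DataError(f"cannot write summary table to {path!r}: {exc}") from exc
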