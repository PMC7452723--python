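"""Delimited-table readers and provenance-stamped JSON writers.

Tables must declare concentration units — either a per-table unit column
(``concentration_unit``) or a bracketed/suffixed unit in the column header
(``p_total[nM]`` / ``p_total_nM``). Everything is converted to molar on
ingest and each conversion is recorded in the ingest log; binding
equilibria depend on concentrations in M, and ambiguity here is the
single most common unit error in the literature.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CompetitionSeries, KineticTrace, TitrationSeries

__all__ = ["UNIT_FACTORS", "read_table", "write_results", "read_results"]

SCHEMA_VERSION = "1"

UNIT_FACTORS = {
    "M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
    "nM": 1e-9, "pM": 1e-12, "fM": 1e-15,
}

TIME_FACTORS = {"s": 1.0, "sec": 1.0, "min": 60.0, "hr": 3600.0, "h": 3600.0}

_UNIT_RE = re.compile(r"^(?P<base>.+?)(?:\[(?P<u1>[^\]]+)\]|_(?P<u2>[fpnuµm]?M))$")

_SCHEMAS = {
    "titration": {"conc": "p_total", "required": ["p_total", "fraction_bound"]},
    "kinetic": {"conc": "p_total", "required": ["time", "fraction_bound"]},
    "competition": {"conc": "c_total",
                    "required": ["c_total", "fraction_bound"]},
}


def _split_unit(colname: str):
    m = _UNIT_RE.match(colname.strip())
    if not m:
        return colname.strip(), None
    unit = m.group("u1") or m.group("u2")
    if unit in UNIT_FACTORS or unit in TIME_FACTORS:
        return m.group("base").strip(), unit
    return colname.strip(), None


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, comment="#", skipinitialspace=True)


def _to_molar(df: pd.DataFrame, base: str, unit: str | None, path,
              log: list) -> np.ndarray:
    vals = pd.to_numeric(df[base], errors="coerce")
    bad = vals.index[vals.isna() & df[base].notna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable values in column {base!r} "
                         f"(file line(s) {rows})")
    if unit is None:
        if "concentration_unit" in df.columns:
            units = df["concentration_unit"].astype(str).str.strip()
            unknown = sorted(set(units) - set(UNIT_FACTORS))
            if unknown:
                raise ValueError(f"{path}: unknown concentration unit(s) "
                                 f"{unknown} in concentration_unit column")
            factors = units.map(UNIT_FACTORS).to_numpy()
            log.append(f"{base}: per-row units from concentration_unit column")
            return vals.to_numpy(dtype=float) * factors
        raise ValueError(
            f"{path}: no unit declared for column {base!r} — use a header "
            f"unit ('{base}[nM]' or '{base}_nM') or a concentration_unit "
            "column")
    log.append(f"{base}: converted from {unit} (x{UNIT_FACTORS[unit]:g})")
    return vals.to_numpy(dtype=float) * UNIT_FACTORS[unit]


def read_table(path, schema: str, **series_kwargs):
    """Read a delimited table into domain containers.

    ``schema`` is one of ``titration`` (returns a list of TitrationSeries,
    one per replicate), ``kinetic`` (a KineticTrace; requires ``p_total``
    and ``mode`` in the file or ``series_kwargs``) or ``competition`` (a
    CompetitionSeries; requires ``p_total`` and ``kd_labeled``). Returns
    ``(objects, ingest_log)``.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; "
                         f"choose from {sorted(_SCHEMAS)}")
    df = _read_delimited(path)
    log: list[str] = []

    colmap = {}
    for col in df.columns:
        base, unit = _split_unit(col)
        colmap[base] = (col, unit)
        if col != base:
            df = df.rename(columns={col: base})

    required = _SCHEMAS[schema]["required"]
    for base in required:
        if base not in df.columns:
            raise ValueError(f"{path}: missing required column {base!r}")

    def conc(base, required_col=True):
        if base not in df.columns:
            if required_col:
                raise ValueError(f"{path}: missing column {base!r}")
            return None
        return _to_molar(df, base, colmap.get(base, (base, None))[1],
                         path, log)

    frac = pd.to_numeric(df["fraction_bound"], errors="coerce")
    if frac.isna().any():
        rows = ", ".join(str(i + 2) for i in frac.index[frac.isna()][:5])
        raise ValueError(f"{path}: unparseable fraction_bound values "
                         f"(file line(s) {rows})")
    frac = frac.to_numpy(dtype=float)

    if schema == "titration":
        p = conc("p_total")
        r_low = conc("r_total_low", required_col=False)
        r_high = conc("r_total_high", required_col=False)
        if r_low is None:
            r_single = conc("r_total", required_col=False)
            if r_single is not None:
                r_low = r_high = r_single
                log.append("r_total: single value used as low = high bound")
        if r_low is not None and r_high is None:
            r_high = r_low
        rep = (df["replicate"].to_numpy()
               if "replicate" in df.columns else np.zeros(len(df), int))
        dup = pd.DataFrame({"p": p, "rep": rep}).duplicated()
        if dup.any():
            rows = ", ".join(str(i + 2) for i in np.flatnonzero(dup)[:5])
            raise ValueError(f"{path}: duplicate (concentration, replicate) "
                             f"keys at file line(s) {rows}")
        out = []
        for rid in np.unique(rep):
            m = rep == rid
            kw = dict(series_kwargs)
            if "time" in df.columns and "incubation_time" not in kw:
                kw["incubation_time"] = float(df.loc[m, "time"].iloc[0])
            if "temperature" in df.columns and "temperature" not in kw:
                kw["temperature"] = float(df.loc[m, "temperature"].iloc[0])
            out.append(TitrationSeries(
                p_total=p[m], fraction_bound=frac[m],
                r_total_low=float(r_low[m][0]) if r_low is not None else 0.0,
                r_total_high=(float(r_high[m][0])
                              if r_high is not None else None),
                replicate_id=int(rid), **kw))
        return out, log

    if schema == "kinetic":
        t = pd.to_numeric(df["time"], errors="coerce").to_numpy(dtype=float)
        t_unit = colmap.get("time", ("time", None))[1]
        if t_unit in TIME_FACTORS:
            t = t * TIME_FACTORS[t_unit]
            log.append(f"time: converted from {t_unit}")
        p_total = series_kwargs.pop("p_total", None)
        if p_total is None:
            pcol = conc("p_total", required_col=False)
            if pcol is None:
                raise ValueError(f"{path}: p_total required (column or "
                                 "keyword) for kinetic schema")
            p_total = float(pcol[0])
        mode = series_kwargs.pop("mode", "association")
        return KineticTrace(t=t, fraction_bound=frac, p_total=p_total,
                            mode=mode, **series_kwargs), log

    # competition
    c = conc("c_total")
    p_total = series_kwargs.pop("p_total", None)
    if p_total is None:
        pcol = conc("p_total", required_col=False)
        if pcol is None:
            raise ValueError(f"{path}: p_total required (column or keyword) "
                             "for competition schema")
        p_total = float(pcol[0])
    kd_labeled = series_kwargs.pop("kd_labeled", None)
    if kd_labeled is None:
        raise ValueError("kd_labeled keyword required for competition schema")
    return CompetitionSeries(c_total=c, fraction_bound=frac,
                             p_total=p_total, kd_labeled=kd_labeled,
                             **series_kwargs), log


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_results(results, path, seed: int | None = None,
                  inputs: list | None = None,
                  config: dict | None = None) -> dict:
    """Write results (FitResult/verdict/report dicts) as provenance-stamped JSON.

    The emitted block carries the schema version, the RNG seed, SHA-256
    digests of every input file and the governing configuration — enough
    to reproduce the run exactly. Returns the written document.
    """
    if not isinstance(results, (list, tuple)):
        results = [results]
    payload = []
    for r in results:
        payload.append(r.to_dict() if hasattr(r, "to_dict") else r)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "input_digests": {str(p): _digest(p) for p in (inputs or [])},
        "config": config or {},
        "results": payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
    return doc


def read_results(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported results schema "
                         f"{doc.get('schema_version')!r}")
    return doc
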