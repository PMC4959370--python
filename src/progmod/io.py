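"""Readers/writers for the pipeline's external formats.

Expression matrices travel as tab-separated text with genes (or probes)
in rows and a header row of sample identifiers; in memory they are pandas
DataFrames indexed by gene with one column per sample.  Clinical tables
are TSV with one row per sample carrying a non-negative survival time, a
binary event indicator and optional categorical covariates (ER status,
TNBC flag, grade, TP53 status, intrinsic subtype ...).  Gene modules are
serialized as GMT gene sets (two lines per module, ``_high``/``_low``)
and, with provenance, as JSON.

Probe-level matrices are collapsed to gene level by taking the per-sample
median over the probes mapped to each gene; probes absent from the map
are dropped (the count is logged).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .modules import PrognosticModule

logger = logging.getLogger(__name__)

__all__ = [
    "load_expression",
    "load_probe_map",
    "collapse_probes",
    "load_survival",
    "align",
    "write_modules_gmt",
    "read_modules_gmt",
    "write_modules_json",
    "read_modules_json",
    "write_results_json",
]


def _check_expression(df: pd.DataFrame, drop_missing: bool = False) -> pd.DataFrame:
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dups[:5]}")
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][:1]
        raise ValueError(
            f"non-numeric expression value at gene {row.tolist()}, sample {col!r}"
        )
    if df.isna().any().any():
        if drop_missing:
            n0 = len(df)
            df = df.dropna(axis=0)
            logger.info("dropped %d genes with missing values", n0 - len(df))
        else:
            g = df.index[df.isna().any(axis=1)][:5].tolist()
            raise ValueError(
                f"missing expression values (e.g. genes {g}); "
                "re-load with drop_missing=True to discard those genes"
            )
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("expression matrix contains non-finite values")
    return df


def load_probe_map(path) -> pd.Series:
    """Two-column TSV probe->gene mapping (many probes to one gene)."""
    pm = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if pm.shape[1] < 2:
        raise ValueError(f"{path}: probe map needs two columns (probe, gene)")
    pm = pm.iloc[:, :2].dropna()
    if pm.iloc[:, 0].duplicated().any():
        raise ValueError(f"{path}: probes mapped to more than one gene")
    return pd.Series(pm.iloc[:, 1].values, index=pm.iloc[:, 0].values, name="gene")


def collapse_probes(df: pd.DataFrame, probe_map: pd.Series) -> pd.DataFrame:
    """Collapse probe rows to gene rows by the per-sample median.

    Probes absent from the map are dropped with a logged count.  With a
    one-to-one map the values are unchanged (rows are relabeled).
    """
    mapped = df.index.isin(probe_map.index)
    n_dropped = int((~mapped).sum())
    if n_dropped:
        logger.info("dropped %d probes absent from the probe map", n_dropped)
    sub = df.loc[mapped]
    genes = probe_map.reindex(sub.index)
    out = sub.groupby(genes.values).median()
    out.index.name = df.index.name or "gene"
    return out


def load_expression(
    path,
    probe_map: pd.Series | None = None,
    *,
    transpose: bool = False,
    drop_missing: bool = False,
) -> pd.DataFrame:
    """Load a genes-x-samples expression TSV (header = sample IDs).

    With ``probe_map``, probe rows sharing a gene are collapsed to their
    per-sample median.  ``transpose=True`` accepts samples-in-rows input.
    Duplicate sample IDs and non-numeric cells are rejected; missing
    values are rejected unless ``drop_missing`` removes those genes.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if not transpose and len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample IDs: {dups[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    df = _check_expression(df, drop_missing=drop_missing)
    if probe_map is not None:
        df = collapse_probes(df, probe_map)
    elif df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs without a probe map: {dups[:5]}")
    return df


def load_survival(
    path,
    *,
    sample_col: str = "sample",
    time_col: str = "time",
    event_col: str = "event",
    covariate_cols: list[str] | None = None,
    na_values=("NA", "na", ""),
) -> pd.DataFrame:
    """Load a clinical TSV into a sample-indexed table.

    The result has columns ``time`` (non-negative float), ``event``
    (0/1 int) and any covariate columns, with unknown covariate values
    stored as missing.  Negative times and non-binary event codes are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={sample_col: str}, na_values=list(na_values),
                     keep_default_na=True)
    for col in (sample_col, time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} not found")
    if df[sample_col].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs")
    out = df.set_index(sample_col)
    out.index.name = "sample"
    time = pd.to_numeric(out[time_col], errors="coerce")
    if time.isna().any() or (time < 0).any():
        raise ValueError(f"{path}: column {time_col!r} must be non-negative numbers")
    event = pd.to_numeric(out[event_col], errors="coerce")
    if event.isna().any() or not event.isin([0, 1]).all():
        raise ValueError(f"{path}: column {event_col!r} must be 0/1")
    keep = covariate_cols
    if keep is None:
        keep = [c for c in out.columns if c not in (time_col, event_col)]
    res = pd.DataFrame({"time": time.astype(float), "event": event.astype(int)},
                       index=out.index)
    for c in keep:
        if c not in out.columns:
            raise ValueError(f"{path}: covariate column {c!r} not found")
        res[c] = out[c].astype("object").where(out[c].notna(), np.nan)
    return res


def align(expr: pd.DataFrame, surv: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both tables to the shared samples, in expression order.

    Idempotent; raises on an empty intersection.
    """
    common = expr.columns[expr.columns.isin(surv.index)]
    if len(common) == 0:
        raise ValueError("no samples shared between expression and clinical tables")
    logger.info("aligned on %d shared samples", len(common))
    out_surv = surv.loc[common]
    out_surv.index.name = surv.index.name
    return expr.loc[:, common], out_surv


def write_modules_gmt(modules, path) -> None:
    """Write modules as GMT gene sets: two lines per module, with the
    high-side (over-expressed in poor survival) genes under the suffix
    ``_high`` and the low-side genes under ``_low``."""
    modules = list(modules)
    if not modules:
        raise ValueError("no modules to write")
    path = Path(path)
    with path.open("w") as fh:
        for m in modules:
            name = m.label.replace(" ", "_")
            fh.write("\t".join([f"{name}_high", "over-expressed in poor survival",
                                *m.high_genes]) + "\n")
            fh.write("\t".join([f"{name}_low", "under-expressed in poor survival",
                                *m.low_genes]) + "\n")


def read_modules_gmt(path) -> list[PrognosticModule]:
    """Read modules written by :func:`write_modules_gmt` (pairs of
    ``_high``/``_low`` gene-set lines sharing a stem)."""
    sides: dict[str, dict[str, tuple[str, ...]]] = {}
    order: list[str] = []
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, genes = parts[0], tuple(parts[2:])
            for suffix in ("_high", "_low"):
                if name.endswith(suffix):
                    stem = name[: -len(suffix)]
                    if stem not in sides:
                        sides[stem] = {}
                        order.append(stem)
                    sides[stem][suffix[1:]] = genes
                    break
    out = []
    for stem in order:
        d = sides[stem]
        if "high" not in d or "low" not in d:
            raise ValueError(f"{path}: module {stem!r} lacks a _high/_low pair")
        out.append(PrognosticModule(label=stem.replace("_", " "),
                                    high_genes=d["high"], low_genes=d["low"]))
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_results_json(obj, path) -> None:
    """JSON dump that understands numpy scalars/arrays; round-trips
    losslessly through :func:`json.load` for plain structures."""
    try:
        with Path(path).open("w") as fh:
            json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
            fh.write("\n")
    except OSError as err:
        raise OSError(f"cannot write results to {path}: {err}") from err


def write_modules_json(modules, path) -> None:
    payload = [m.to_dict() for m in modules]
    write_results_json(payload, path)


def read_modules_json(path) -> list[PrognosticModule]:
    with Path(path).open() as fh:
        payload = json.load(fh)
    return [PrognosticModule.from_dict(d) for d in payload]
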