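"""Readers and writers for the tabular formats used across the pipeline.

Conventions
-----------
* Beta / detection-P matrices: TSV, probes as rows, first column ``probe_id``,
  remaining columns are sample IDs. ``.gz`` suffix triggers gzip compression.
* Sample sheets and probe annotation: CSV with a header row.
* Summary statistics: TSV, one row per probe.
* GMT: tab-separated ``name<TAB>description<TAB>member...`` lines.
* BED: 0-based half-open; internal coordinates are 1-based inclusive and are
  converted on write (start-1, end) and back on read.
* Every file written here carries ``#`` header comment lines recording the
  package version, a config hash and the seed; readers skip them.

Missing values are encoded as ``NA``.
"""

from __future__ import annotations

import gzip
import hashlib

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__

NA_REP = "NA"


def config_hash(obj) -> str:
    """Short deterministic hash of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed=None, config=None, extra: Mapping | None = None) -> str:
    lines = [f"# methvar_version={__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        lines.append(f"# config_hash={config_hash(config)}")
    for key, val in (extra or {}).items():
        lines.append(f"# {key}={val}")
    return "\n".join(lines) + "\n"


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _write_df(df: pd.DataFrame, path, sep: str, index: bool, **header_kw) -> None:
    with _open_text(path, "w") as fh:
        fh.write(provenance_header(**header_kw))
        df.to_csv(fh, sep=sep, index=index, na_rep=NA_REP)


def _read_table(path, sep: str, index_col=None) -> pd.DataFrame:
    with _open_text(path, "r") as fh:
        return pd.read_csv(fh, sep=sep, comment="#", index_col=index_col,
                           na_values=[NA_REP], keep_default_na=False)


# ---------------------------------------------------------------------------
# matrices

def write_beta_matrix(beta: pd.DataFrame, path, **header_kw) -> None:
    df = beta.copy()
    df.index.name = "probe_id"
    _write_df(df, path, sep="\t", index=True, **header_kw)


def read_beta_matrix(path) -> pd.DataFrame:
    df = _read_table(path, sep="\t", index_col="probe_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe IDs in matrix: {dupes[:10]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in matrix: {dupes[:10]}")
    return df


write_detection_p = write_beta_matrix
read_detection_p = read_beta_matrix


# ---------------------------------------------------------------------------
# sample sheet / annotation / ground truth

def write_samplesheet(sheet: pd.DataFrame, path, **header_kw) -> None:
    df = sheet.copy()
    df.index.name = "sample_id"
    _write_df(df, path, sep=",", index=True, **header_kw)


def read_samplesheet(path) -> pd.DataFrame:
    df = _read_table(path, sep=",", index_col="sample_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in sample sheet: {dupes[:10]}")
    return df


def write_annotation(annotation: pd.DataFrame, path, **header_kw) -> None:
    df = annotation.copy()
    df.index.name = "probe_id"
    _write_df(df, path, sep=",", index=True, **header_kw)


def read_annotation(path) -> pd.DataFrame:
    df = _read_table(path, sep=",", index_col="probe_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe IDs in annotation: {dupes[:10]}")
    return df


def write_ground_truth(truth: pd.DataFrame, path, **header_kw) -> None:
    df = truth.copy()
    df.index.name = "probe_id"
    _write_df(df, path, sep="\t", index=True, **header_kw)


def read_ground_truth(path) -> pd.DataFrame:
    return _read_table(path, sep="\t", index_col="probe_id")


# ---------------------------------------------------------------------------
# summary statistics

def write_summary_stats(stats: pd.DataFrame, path, **header_kw) -> None:
    df = stats.copy()
    df.index.name = "probe_id"
    _write_df(df, path, sep="\t", index=True, **header_kw)


def read_summary_stats(path) -> pd.DataFrame:
    return _read_table(path, sep="\t", index_col="probe_id")


# ---------------------------------------------------------------------------
# GMT gene sets

def write_gmt(sets: Mapping[str, Sequence[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with _open_text(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, NA_REP)
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with _open_text(path, "r") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, description, "
                                 f"members): {line[:80]!r}")
            if parts[0] in sets:
                raise ValueError(f"duplicate gene-set name: {parts[0]}")
            sets[parts[0]] = parts[2:]
    return sets


# ---------------------------------------------------------------------------
# BED intervals (internal 1-based inclusive <-> file 0-based half-open)

def write_bed(intervals: pd.DataFrame, path, **header_kw) -> None:
    """``intervals`` columns: chrom, start, end (1-based inclusive) + extras."""
    df = intervals.copy()
    if (df["start"] > df["end"]).any():
        raise ValueError("interval with start > end")
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    with _open_text(path, "w") as fh:
        fh.write(provenance_header(**header_kw))
        df.to_csv(fh, sep="\t", index=False, header=False, na_rep=NA_REP)


def read_bed(path, names: Sequence[str] = ("chrom", "start", "end", "name")) -> pd.DataFrame:
    with _open_text(path, "r") as fh:
        raw = [ln.rstrip("\n").split("\t") for ln in fh
               if ln.strip() and not ln.startswith(("#", "track", "browser"))]
    if not raw:
        return pd.DataFrame(columns=list(names))
    width = max(len(r) for r in raw)
    cols = list(names)[:width] + [f"col{i}" for i in range(len(names), width)]
    df = pd.DataFrame([r + [None] * (width - len(r)) for r in raw], columns=cols)
    df["start"] = df["start"].astype(int) + 1  # back to 1-based inclusive
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise ValueError("BED interval with non-positive length")
    return df
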