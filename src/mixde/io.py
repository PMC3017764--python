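"""Readers and writers for the pipeline's delimited text formats.

All tables are tab-separated with a header row, except probe BED files
(standard headerless BED4) and BLAST hit files (outfmt-6 style, 12 unnamed
columns; only query id, subject id and bit score are consumed).  Gene models
use a BED12-like TSV with columns ``chrom, start, end, gene_name, accession,
strand, exon_starts, exon_sizes`` (0-based half-open, absolute exon starts,
comma-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

GENE_MODEL_COLUMNS = ["chrom", "start", "end", "gene_name", "accession",
                      "strand", "exon_starts", "exon_sizes"]

BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_qc_table(qc: pd.DataFrame, path) -> Path:
    """QC table with failed spots printed as literal zero readings."""
    out = qc.copy()
    out["log2_intensity"] = np.where(out["passed"],
                                     out["log2_intensity"], 0.0)
    return write_table(out, path)


def read_qc_table(path) -> pd.DataFrame:
    """Re-read a QC table, restoring failed spots to missing-for-modelling."""
    qc = read_table(path)
    qc["passed"] = qc["passed"].astype(bool)
    qc.loc[~qc["passed"], "log2_intensity"] = np.nan
    return qc


def write_bed(probes: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    probes[["chrom", "start", "end", "probe_id"]].to_csv(
        path, sep="\t", index=False, header=False)
    return path


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "probe_id"])
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"malformed BED interval in {path}")
    return df


def write_gene_models(genes: pd.DataFrame, path) -> Path:
    return write_table(genes[GENE_MODEL_COLUMNS], path)


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    return df


def write_blast6(hits: pd.DataFrame, path) -> Path:
    """Write best hits as tabular BLAST (outfmt 6); filler fields zeroed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = pd.DataFrame({c: 0 for c in BLAST6_COLUMNS}, index=hits.index)
    out["qseqid"] = hits["probe_id"].to_numpy()
    out["sseqid"] = hits["gene_name"].to_numpy()
    out["bitscore"] = hits["bitscore"].to_numpy()
    out.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_blast6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
    return pd.DataFrame({"probe_id": df["qseqid"],
                         "gene_name": df["sseqid"],
                         "bitscore": df["bitscore"]})


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(o)}")
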