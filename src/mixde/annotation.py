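"""Deterministic probe-to-gene-name assignment over precomputed tables.

Inputs are a probe alignment table (BED-like, 0-based half-open), bovine and
human gene-model tables with exon structure, and a best-hit BLAST table.  The
four assignment rules are applied in order:

1. A probe overlapping a bovine *exon* whose gene name is not LOC/MGC-prefixed
   takes that name; among several such genes, the lowest accession wins.
2. If the bovine overlap is LOC/MGC-named, or there is no bovine overlap, the
   overlapping human gene name is used (lowest accession on ties).  A LOC/MGC
   bovine name with no human alternative is retained.
3. With no overlap at all, the nearest gene on the probe's chromosome is used
   (bovine models first, human models when the chromosome has none).
4. A best BLAST hit whose name disagrees with a step-1/2 choice flags the
   probe for manual curation; the chosen name is retained.

Strand is ignored.  "Lowest accession" compares the integer after the
alphabetic prefix, falling back to full lexicographic order.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

LOC_PREFIXES = ("LOC", "MGC")

_ACC_RE = re.compile(r"^([A-Za-z_]*)(\d+)")


def accession_key(accession: str):
    """Sort key implementing numeric-after-prefix accession ordering."""
    m = _ACC_RE.match(str(accession))
    if m:
        return (0, int(m.group(2)), str(accession))
    return (1, 0, str(accession))


def _parse_exons(row) -> list[tuple[int, int]]:
    starts = [int(s) for s in str(row["exon_starts"]).split(",") if s != ""]
    sizes = [int(s) for s in str(row["exon_sizes"]).split(",") if s != ""]
    return [(s, s + l) for s, l in zip(starts, sizes)]


def validate_intervals(genes: pd.DataFrame) -> None:
    if (genes["start"] >= genes["end"]).any():
        raise ValueError("malformed gene interval (start >= end)")
    for _, row in genes.iterrows():
        exons = _parse_exons(row)
        exons_sorted = sorted(exons)
        for (s, e) in exons:
            if s >= e:
                raise ValueError(f"malformed exon in {row['gene_name']}")
        for (s1, e1), (s2, e2) in zip(exons_sorted, exons_sorted[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {row['gene_name']}")


def overlap_genes(probe: dict, genes: pd.DataFrame) -> pd.DataFrame:
    """All genes whose span intersects the probe, labelled exon or intron.

    Half-open intervals: [a, b) and [c, d) intersect iff a < d and c < b.
    A gene counts as exon-overlap when any exon intersects the probe,
    otherwise intron-overlap.
    """
    sub = genes[(genes["chrom"] == probe["chrom"])
                & (genes["start"] < probe["end"])
                & (probe["start"] < genes["end"])]
    rows = []
    for _, g in sub.iterrows():
        kind = "intron"
        for (s, e) in _parse_exons(g):
            if s < probe["end"] and probe["start"] < e:
                kind = "exon"
                break
        rows.append({"gene_name": g["gene_name"], "accession": g["accession"],
                     "overlap_kind": kind})
    return pd.DataFrame(rows, columns=["gene_name", "accession", "overlap_kind"])


def nearest_gene(probe: dict, genes: pd.DataFrame):
    """Gene minimising the interval gap to the probe; ties by lowest accession.

    Returns ``(gene_name, distance)`` or ``None`` when the chromosome has no
    gene.
    """
    sub = genes[genes["chrom"] == probe["chrom"]]
    if len(sub) == 0:
        return None
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    dist = np.maximum(0, np.maximum(starts - probe["end"],
                                    probe["start"] - ends))
    best = dist.min()
    cand = sub[dist == best]
    row = min(cand.itertuples(), key=lambda r: accession_key(r.accession))
    return row.gene_name, int(best)


def _is_provisional(name: str) -> bool:
    return any(str(name).startswith(p) for p in LOC_PREFIXES)


def _lowest(df: pd.DataFrame) -> pd.Series:
    return df.loc[df["accession"].map(accession_key).idxmin()]


def assign_gene(probe: dict, bovine_overlaps: pd.DataFrame,
                human_overlaps: pd.DataFrame, nearest, blast_name) -> dict:
    """Apply the four-rule cascade to one probe.

    ``nearest`` is the (name, distance) pair from :func:`nearest_gene` (or
    None); ``blast_name`` is the best-hit subject name (or None).
    """
    result = {"probe_id": probe["probe_id"], "gene_name": None,
              "decision_step": "unassigned", "flagged": False,
              "overlap_kind": "none"}
    name, step, kind = None, None, "none"

    bov_exon = bovine_overlaps[bovine_overlaps["overlap_kind"] == "exon"] \
        if len(bovine_overlaps) else bovine_overlaps
    named_exon = bov_exon[~bov_exon["gene_name"].map(_is_provisional)] \
        if len(bov_exon) else bov_exon

    if len(named_exon):
        chosen = _lowest(named_exon)
        name, step, kind = chosen["gene_name"], "1", "exon"
    else:
        if len(human_overlaps):
            chosen = _lowest(human_overlaps)
            name, step, kind = chosen["gene_name"], "2", chosen["overlap_kind"]
        elif len(bovine_overlaps):
            # LOC/MGC (or intron-only) bovine name retained at step 2
            chosen = _lowest(bovine_overlaps)
            name, step, kind = chosen["gene_name"], "2", chosen["overlap_kind"]
        elif nearest is not None:
            name, step, kind = nearest[0], "3", "none"

    if name is not None and step in ("1", "2") and blast_name is not None \
            and str(blast_name) != str(name):
        result["flagged"] = True
        step = "4-flagged"

    if name is not None:
        result["gene_name"] = name
        result["decision_step"] = step
        result["overlap_kind"] = kind
    return result


class ProbeAnnotator(BaseEstimator):
    """Rule-engine transformer: probe alignments in, name assignments out."""

    def __init__(self):
        pass

    def fit(self, bovine_genes: pd.DataFrame, human_genes: pd.DataFrame,
            blast_hits: pd.DataFrame | None = None):
        validate_intervals(bovine_genes)
        validate_intervals(human_genes)
        self.bovine_genes_ = bovine_genes.reset_index(drop=True)
        self.human_genes_ = human_genes.reset_index(drop=True)
        if blast_hits is None or len(blast_hits) == 0:
            self.blast_best_ = {}
        else:
            best = blast_hits.sort_values(
                "bitscore", ascending=False).drop_duplicates("probe_id")
            self.blast_best_ = dict(zip(best["probe_id"], best["gene_name"]))
        return self

    def transform(self, probes: pd.DataFrame) -> pd.DataFrame:
        if (probes["start"] >= probes["end"]).any():
            raise ValueError("malformed probe interval (start >= end)")
        rows = []
        for _, p in probes.iterrows():
            probe = p.to_dict()
            bov = overlap_genes(probe, self.bovine_genes_)
            hum = overlap_genes(probe, self.human_genes_)
            near = nearest_gene(probe, self.bovine_genes_)
            if near is None:
                near = nearest_gene(probe, self.human_genes_)
            blast = self.blast_best_.get(probe["probe_id"])
            rows.append(assign_gene(probe, bov, hum, near, blast))
        return pd.DataFrame(rows, columns=["probe_id", "gene_name",
                                           "decision_step", "flagged",
                                           "overlap_kind"])


def annotate_probes(probes, bovine_genes, human_genes,
                    blast_hits=None) -> pd.DataFrame:
    """One-shot annotation of a probe table."""
    ann = ProbeAnnotator().fit(bovine_genes, human_genes, blast_hits)
    return ann.transform(probes)


def summarise_annotation(results: pd.DataFrame) -> dict:
    """Counts by name category: LOC, MGC, properly named gene, none."""
    counts = {"LOC": 0, "MGC": 0, "gene": 0, "none": 0}
    for name in results["gene_name"]:
        if name is None or (isinstance(name, float) and np.isnan(name)):
            counts["none"] += 1
        elif str(name).startswith("LOC"):
            counts["LOC"] += 1
        elif str(name).startswith("MGC"):
            counts["MGC"] += 1
        else:
            counts["gene"] += 1
    return counts
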