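import numpy as np
import pandas as pd
import pytest

import mixde
from mixde.annotation import (accession_key, assign_gene, nearest_gene,
                              overlap_genes, summarise_annotation,
                              validate_intervals)

EXPECTED_CORE = {
    # probe_id: (gene_name, decision_step, flagged)
    "p01": ("KRT5", "1", False),
    "p02": ("DSG1", "1", False),
    "p03": ("DSC1", "2", False),
    "p04": ("PKP1", "2", False),
    "p05": ("KRT10", "2", False),
    "p06": ("GJB5", "3", False),
    "p07": ("FLG", "2", False),
    "p08": ("LOC517777", "2", False),
    "p09": ("IVL", "3", False),
    "p10": ("SPRR3", "3", False),
    "p11": ("DSP", "4-flagged", True),
    "p12": (None, "unassigned", False),
}


def oracle_annotate(probes, bovine, human, blast):
    """Independent brute-force re-statement of the four rules."""
    def exons(row):
        starts = [int(s) for s in str(row["exon_starts"]).split(",") if s]
        sizes = [int(s) for s in str(row["exon_sizes"]).split(",") if s]
        return list(zip(starts, [a + b for a, b in zip(starts, sizes)]))

    def hits(p, genes, exon_only):
        out = []
        for _, g in genes.iterrows():
            if g["chrom"] != p["chrom"]:
                continue
            if not (g["start"] < p["end"] and p["start"] < g["end"]):
                continue
            in_exon = any(s < p["end"] and p["start"] < e
                          for s, e in exons(g))
            if exon_only and not in_exon:
                continue
            out.append((accession_key(g["accession"]), g["gene_name"]))
        return [name for _, name in sorted(out)]

    def nearest(p, genes):
        best = None
        for _, g in genes.iterrows():
            if g["chrom"] != p["chrom"]:
                continue
            d = max(0, g["start"] - p["end"], p["start"] - g["end"])
            key = (d, accession_key(g["accession"]))
            if best is None or key < best[0]:
                best = (key, g["gene_name"])
        return best[1] if best else None

    best_blast = {}
    for _, b in blast.sort_values("bitscore", ascending=False).iterrows():
        best_blast.setdefault(b["probe_id"], b["gene_name"])

    results = {}
    for _, p in probes.iterrows():
        named_exon = [n for n in hits(p, bovine, exon_only=True)
                      if not n.startswith(("LOC", "MGC"))]
        name, step = None, "unassigned"
        if named_exon:
            name, step = named_exon[0], "1"
        elif hits(p, human, exon_only=False):
            name, step = hits(p, human, exon_only=False)[0], "2"
        elif hits(p, bovine, exon_only=False):
            name, step = hits(p, bovine, exon_only=False)[0], "2"
        else:
            near = nearest(p, bovine) or nearest(p, human)
            if near:
                name, step = near, "3"
        flagged = (step in ("1", "2") and p["probe_id"] in best_blast
                   and best_blast[p["probe_id"]] != name)
        if flagged:
            step = "4-flagged"
        results[p["probe_id"]] = (name, step, flagged)
    return results


class TestFixtureAssignments:
    def test_core_probes_frozen_expectations(self, annotation_fixtures):
        fx = annotation_fixtures
        res = mixde.annotate_probes(fx["probes"], fx["bovine_genes"],
                                    fx["human_genes"], fx["blast_hits"])
        res = res.set_index("probe_id")
        for pid, (name, step, flagged) in EXPECTED_CORE.items():
            row = res.loc[pid]
            got_name = None if pd.isna(row["gene_name"]) else row["gene_name"]
            assert got_name == name, pid
            assert row["decision_step"] == step, pid
            assert bool(row["flagged"]) == flagged, pid

    def test_matches_brute_force_oracle(self, annotation_fixtures):
        fx = annotation_fixtures
        res = mixde.annotate_probes(fx["probes"], fx["bovine_genes"],
                                    fx["human_genes"], fx["blast_hits"])
        want = oracle_annotate(fx["probes"], fx["bovine_genes"],
                               fx["human_genes"], fx["blast_hits"])
        for _, row in res.iterrows():
            name, step, flagged = want[row["probe_id"]]
            got_name = None if pd.isna(row["gene_name"]) else row["gene_name"]
            assert got_name == name, row["probe_id"]
            assert row["decision_step"] == step, row["probe_id"]
            assert bool(row["flagged"]) == flagged, row["probe_id"]

    def test_row_order_invariance(self, annotation_fixtures):
        fx = annotation_fixtures
        base = mixde.annotate_probes(fx["probes"], fx["bovine_genes"],
                                     fx["human_genes"], fx["blast_hits"])
        shuffled = mixde.annotate_probes(
            fx["probes"],
            fx["bovine_genes"].sample(frac=1, random_state=3),
            fx["human_genes"].sample(frac=1, random_state=4),
            fx["blast_hits"].sample(frac=1, random_state=5))
        pd.testing.assert_frame_equal(base, shuffled)


class TestPrimitives:
    GENES = pd.DataFrame([
        {"chrom": "chr1", "start": 100, "end": 200, "gene_name": "A",
         "accession": "NM_2", "strand": "+", "exon_starts": "100",
         "exon_sizes": "100"},
        {"chrom": "chr1", "start": 400, "end": 500, "gene_name": "B",
         "accession": "NM_1", "strand": "+", "exon_starts": "400",
         "exon_sizes": "100"},
    ])

    def test_overlap_half_open(self):
        # probe ending exactly at a gene start does not overlap
        assert len(overlap_genes({"chrom": "chr1", "start": 50, "end": 100},
                                 self.GENES)) == 0
        assert len(overlap_genes({"chrom": "chr1", "start": 199, "end": 210},
                                 self.GENES)) == 1

    def test_intron_label(self):
        genes = self.GENES.assign(exon_starts="100", exon_sizes="10")
        ov = overlap_genes({"chrom": "chr1", "start": 150, "end": 160}, genes)
        assert ov["overlap_kind"].tolist() == ["intron"]

    def test_nearest_gene_distances(self):
        name, dist = nearest_gene({"chrom": "chr1", "start": 250, "end": 260},
                                  self.GENES)
        assert (name, dist) == ("A", 50)
        # equidistant at 300..300: gaps 100 both sides -> accession NM_1 wins
        name, dist = nearest_gene({"chrom": "chr1", "start": 300, "end": 300},
                                  self.GENES)
        assert (name, dist) == ("B", 100)
        assert nearest_gene({"chrom": "chrX", "start": 0, "end": 10},
                            self.GENES) is None

    def test_overlapping_gene_distance_zero(self):
        name, dist = nearest_gene({"chrom": "chr1", "start": 150, "end": 160},
                                  self.GENES)
        assert dist == 0

    @pytest.mark.parametrize("a,b", [
        ("NM_2", "NM_10"), ("XM_5", "XM_50"), ("NM_1", "ZZ9999999")])
    def test_accession_ordering(self, a, b):
        assert accession_key(a) < accession_key(b)

    def test_accession_non_numeric_falls_back(self):
        assert accession_key("abc") > accession_key("NM_999999")

    def test_malformed_intervals_rejected(self):
        bad = self.GENES.copy()
        bad.loc[0, "end"] = 50
        with pytest.raises(ValueError):
            validate_intervals(bad)
        bad2 = self.GENES.copy()
        bad2.loc[0, "exon_sizes"] = "0"
        with pytest.raises(ValueError):
            validate_intervals(bad2)
        probes = pd.DataFrame([{"chrom": "chr1", "start": 10, "end": 5,
                                "probe_id": "x"}])
        with pytest.raises(ValueError):
            mixde.annotate_probes(probes, self.GENES, self.GENES.iloc[:0])


class TestAssignGene:
    def test_blast_agreement_not_flagged(self):
        ov = pd.DataFrame([{"gene_name": "KRT5", "accession": "NM_1",
                            "overlap_kind": "exon"}])
        empty = ov.iloc[:0]
        res = assign_gene({"probe_id": "p"}, ov, empty, None, "KRT5")
        assert res["decision_step"] == "1" and not res["flagged"]

    def test_blast_never_flags_step3(self):
        empty = pd.DataFrame(columns=["gene_name", "accession", "overlap_kind"])
        res = assign_gene({"probe_id": "p"}, empty, empty, ("IVL", 10), "DSC2")
        assert res["decision_step"] == "3" and not res["flagged"]


class TestSummarise:
    def test_category_counts(self, annotation_fixtures):
        fx = annotation_fixtures
        res = mixde.annotate_probes(fx["probes"], fx["bovine_genes"],
                                    fx["human_genes"], fx["blast_hits"])
        counts = summarise_annotation(res)
        assert sum(counts.values()) == len(res)  # conservation
        assert counts["LOC"] == 1
        assert counts["MGC"] == 0
        assert counts["none"] == 1

    def test_small_example(self):
        res = pd.DataFrame({"gene_name": ["KRT5", "LOC1", "MGC2", None]})
        assert summarise_annotation(res) == {"LOC": 1, "MGC": 1, "gene": 1,
                                             "none": 1}
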