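"""Synthetic data with the statistical structure of a dye-swap two-colour microarray study.

The generator emulates a 4-chip x 4-array x 2-dye loop design over three cattle
horn phenotypes (Polled, Horned, Scurred) and two sexes: every spot's
background-corrected log2 intensity decomposes as

    y = mu + C + G + AG + DG + HG + SG + eps

with a fixed comparison effect C per (chip, array, dye) channel and i.i.d.
normal random effects for gene (G), array-position x gene (AG), dye x gene
(DG), phenotype x gene (HG) and sex x gene (SG).  A configurable fraction of
probes carries planted phenotype effects (the ground truth for recovery
tests), and a configurable fraction of spots is engineered to fail the
signal-to-noise or mean/median-agreement quality filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

PHENOTYPES = ("Polled", "Horned", "Scurred")
SEXES = ("M", "F")
DYES = ("red", "green")
CONTRASTS = ("PvH", "PvS", "HvS")

#: phenotype pairs behind each contrast (first minus second)
CONTRAST_PAIRS = {"PvH": ("Polled", "Horned"),
                  "PvS": ("Polled", "Scurred"),
                  "HvS": ("Horned", "Scurred")}

# 11-animal roster mirroring the study's imbalance: 4 polled, 3 horned,
# 4 scurred; 6 males, 5 females.  Interleaved by phenotype so that small
# designs still see more than one phenotype.
_ROSTER = [
    ("P1", "Polled", "M"), ("H1", "Horned", "M"), ("S1", "Scurred", "F"),
    ("P2", "Polled", "F"), ("H2", "Horned", "F"), ("S2", "Scurred", "M"),
    ("P3", "Polled", "M"), ("H3", "Horned", "M"), ("S3", "Scurred", "F"),
    ("P4", "Polled", "F"), ("S4", "Scurred", "M"),
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Variances are on the squared-log2-intensity scale.  Defaults are chosen so
    that planted effects of ``de_effect_size`` log2 units are recoverable at a
    1% mixture-model FDR at a desk-scale probe count (~2,000 probes).
    """

    n_chips: int = 4
    n_arrays_per_chip: int = 4
    n_dyes: int = 2
    n_probes: int = 2000
    n_phenotypes: int = 3
    n_sexes: int = 2
    mu: float = 7.4
    var_g: float = 1.0
    var_ag: float = 0.05
    var_dg: float = 0.05
    var_hg: float = 0.02
    var_sg: float = 0.05
    var_e: float = 0.1
    c_effect_sd: float = 0.3
    dye_bias: float = 0.93
    de_fraction: float = 0.05
    de_effect_size: float = 1.5
    background_mean: float = 80.0
    background_sd_scale: float = 5.0
    bad_spot_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_dyes != 2:
            raise ValueError("two-colour design requires exactly 2 dyes")
        if self.n_phenotypes != 3:
            raise ValueError("design is defined for 3 horn phenotypes")
        if self.n_chips < 1 or self.n_arrays_per_chip < 1 or self.n_probes < 1:
            raise ValueError("counts must be positive")
        for name in ("var_g", "var_ag", "var_dg", "var_hg", "var_sg", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0.0 <= self.bad_spot_fraction <= 1.0:
            raise ValueError("bad_spot_fraction must be in [0, 1]")
        if self.background_sd_scale < 0 or self.background_mean < 0:
            raise ValueError("background statistics must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Assign animals to the (chip, array, dye) channel slots.

    Each array carries two distinct animals, one per dye channel.  Dye labels
    alternate across an animal's hybridisations so that no animal used more
    than once sees a single dye only, and animals are interleaved by phenotype
    so that phenotype and sex are not confounded with chip.

    Returns a design table with one row per channel:
    ``chip, array, dye, animal, phenotype, sex``.
    """
    config.validate()
    n_arrays = config.n_chips * config.n_arrays_per_chip
    roster = _ROSTER
    if len(roster) < 2:
        raise ValueError("dye-swap design needs at least two animals")

    rows = []
    last_dye: dict[str, str] = {}
    uses: dict[str, list[str]] = {a[0]: [] for a in roster}
    cursor = 0
    for chip in range(1, config.n_chips + 1):
        for array in range(1, config.n_arrays_per_chip + 1):
            a1 = roster[cursor % len(roster)]
            a2 = roster[(cursor + 1) % len(roster)]
            cursor += 2
            # each animal prefers the dye opposite to its previous one
            want1 = _other(last_dye.get(a1[0]))
            want2 = _other(last_dye.get(a2[0]))
            if want1 != want2 or want1 is None:
                d1 = want1 or "red"
                d2 = "green" if d1 == "red" else "red"
                if want2 is not None and want1 is None:
                    d2 = want2
                    d1 = "green" if d2 == "red" else "red"
            else:
                d1 = want1
                d2 = "green" if d1 == "red" else "red"
            for (animal, d) in ((a1, d1), (a2, d2)):
                rows.append({"chip": chip, "array": array, "dye": d,
                             "animal": animal[0], "phenotype": animal[1],
                             "sex": animal[2]})
                last_dye[animal[0]] = d
                uses[animal[0]].append(d)

    design = pd.DataFrame(rows)
    _repair_dye_balance(design, uses)
    n_levels = len(design)
    expected = config.n_chips * config.n_arrays_per_chip * config.n_dyes
    if n_levels != expected:
        raise RuntimeError("internal error: comparison-level count mismatch")
    return design


def _other(dye):
    if dye is None:
        return None
    return "green" if dye == "red" else "red"


def _repair_dye_balance(design: pd.DataFrame, uses: dict) -> None:
    """Flip whole-array dye pairs until every multiply-used animal saw both dyes."""
    for _ in range(len(design)):
        bad = [a for a, ds in _animal_dyes(design).items()
               if len(ds) >= 2 and len(set(ds)) == 1]
        if not bad:
            return
        animal = bad[0]
        hit = design[design["animal"] == animal].iloc[0]
        mask = (design["chip"] == hit["chip"]) & (design["array"] == hit["array"])
        design.loc[mask, "dye"] = design.loc[mask, "dye"].map(
            {"red": "green", "green": "red"})
    if any(len(ds) >= 2 and len(set(ds)) == 1
           for ds in _animal_dyes(design).values()):
        raise ValueError("impossible dye balance for this design size")


def _animal_dyes(design: pd.DataFrame) -> dict:
    return design.groupby("animal")["dye"].apply(list).to_dict()


def simulate_spots(design: pd.DataFrame, config: SimulationConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw spot-level linear-scale intensities under the additive log2 model.

    Returns ``(spots, truth)``: one spot row per probe per channel with
    foreground mean/median and background mean/SD attached, and a truth table
    with the planted per-phenotype log2 deviations and per-contrast DE flags.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_p = config.n_probes
    n_chan = len(design)

    # fixed comparison effects: spread plus a green-vs-red channel offset
    c_eff = rng.normal(0.0, config.c_effect_sd, n_chan)
    dye_sign = np.where(design["dye"].to_numpy() == "green", 0.5, -0.5)
    c_eff = c_eff + config.dye_bias * dye_sign

    g = rng.normal(0.0, np.sqrt(config.var_g), n_p)
    ag = rng.normal(0.0, np.sqrt(config.var_ag), (n_p, config.n_arrays_per_chip))
    dg = rng.normal(0.0, np.sqrt(config.var_dg), (n_p, 2))
    hg = rng.normal(0.0, np.sqrt(config.var_hg), (n_p, 3))
    sg = rng.normal(0.0, np.sqrt(config.var_sg), (n_p, 2))

    # planted phenotype-specific deviations on a de_fraction of probes
    delta = np.zeros((n_p, 3))
    n_de = int(round(config.de_fraction * n_p))
    de_probes = rng.choice(n_p, size=n_de, replace=False)
    which_ph = rng.integers(0, 3, n_de)
    signs = rng.choice([-1.0, 1.0], n_de)
    delta[de_probes, which_ph] = signs * config.de_effect_size
    hg_total = hg + delta

    arr_idx = design["array"].to_numpy() - 1
    dye_idx = np.where(design["dye"].to_numpy() == "green", 1, 0)
    ph_idx = design["phenotype"].map({p: i for i, p in enumerate(PHENOTYPES)}).to_numpy()
    sex_idx = design["sex"].map({s: i for i, s in enumerate(SEXES)}).to_numpy()

    eps = rng.normal(0.0, np.sqrt(config.var_e), (n_p, n_chan))
    log2_signal = (config.mu
                   + c_eff[None, :]
                   + g[:, None]
                   + ag[:, arr_idx]
                   + dg[:, dye_idx]
                   + hg_total[:, ph_idx]
                   + sg[:, sex_idx]
                   + eps)

    probe_ids = np.array([f"probe_{i:06d}" for i in range(n_p)])
    spots = pd.DataFrame({
        "probe_id": np.repeat(probe_ids, n_chan),
        "chip": np.tile(design["chip"].to_numpy(), n_p),
        "array": np.tile(design["array"].to_numpy(), n_p),
        "dye": np.tile(design["dye"].to_numpy(), n_p),
    })
    corrected = np.exp2(log2_signal).ravel()
    spots["fg_mean"] = config.background_mean + corrected
    spots["fg_median"] = spots["fg_mean"]
    spots["bg_mean"] = config.background_mean
    spots["bg_sd"] = config.background_sd_scale

    # engineer QC failures: half via inflated background SD (s <= 1), half via
    # a discrepant foreground median (r < 0.85)
    n_spots = len(spots)
    n_bad = int(round(config.bad_spot_fraction * n_spots))
    bad = rng.choice(n_spots, size=n_bad, replace=False)
    snr_bad = bad[: n_bad // 2]
    r_bad = bad[n_bad // 2:]
    fg = spots["fg_mean"].to_numpy().copy()
    bg = spots["bg_mean"].to_numpy()
    bg_sd = spots["bg_sd"].to_numpy().copy()
    fg_med = spots["fg_median"].to_numpy().copy()
    bg_sd[snr_bad] = 2.0 * (fg[snr_bad] - bg[snr_bad])
    fg_med[r_bad] = 0.5 * fg[r_bad]
    spots["bg_sd"] = bg_sd
    spots["fg_median"] = fg_med

    truth = pd.DataFrame({
        "probe_id": probe_ids,
        "hg_polled": delta[:, 0],
        "hg_horned": delta[:, 1],
        "hg_scurred": delta[:, 2],
    })
    ph_col = {"Polled": "hg_polled", "Horned": "hg_horned", "Scurred": "hg_scurred"}
    for contrast, (a, b) in CONTRAST_PAIRS.items():
        truth[f"de_{contrast}"] = truth[ph_col[a]] != truth[ph_col[b]]
    return spots, truth


def simulate_qpcr(n_animals_per_phenotype: int = 4,
                  delta_ddct_truth=None,
                  n_replicates: int = 3,
                  noise_sd: float = 0.3,
                  animal_sd: float = 0.25,
                  target: str = "DSC1",
                  reference: str = "GAPDH",
                  base_ct_target: float = 24.0,
                  base_ct_reference: float = 18.0,
                  seed: int = 0) -> pd.DataFrame:
    """Simulate qPCR Ct readings for one target/reference gene pair.

    ``delta_ddct_truth`` sets the target gene's per-phenotype Ct offset: a
    mapping ``{phenotype: offset}`` (missing phenotypes get 0), or a scalar
    applied to the Polled phenotype.  The true ddCt of a contrast (A, B) is
    then ``offset[A] - offset[B]``.  Animal effects are shared between target
    and reference within an animal, so they cancel exactly in a balanced
    difference-of-differences.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if delta_ddct_truth is None:
        offsets = {p: 0.0 for p in PHENOTYPES}
    elif np.isscalar(delta_ddct_truth):
        offsets = {"Polled": float(delta_ddct_truth), "Horned": 0.0, "Scurred": 0.0}
    else:
        offsets = {p: float(delta_ddct_truth.get(p, 0.0)) for p in PHENOTYPES}

    rng = np.random.default_rng(seed)
    rows = []
    for phenotype in PHENOTYPES:
        for a in range(1, n_animals_per_phenotype + 1):
            animal_id = f"{phenotype[0]}{a:02d}"
            a_eff = rng.normal(0.0, animal_sd) if animal_sd > 0 else 0.0
            for gene, base in ((target, base_ct_target),
                               (reference, base_ct_reference)):
                mean = base + a_eff
                if gene == target:
                    mean += offsets[phenotype]
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                    rows.append({"animal_id": animal_id,
                                 "phenotype": phenotype,
                                 "gene": gene,
                                 "replicate": rep,
                                 "ct": mean + noise})
    return pd.DataFrame(rows)


def generate_annotation_fixtures(n_probes: int = 12, seed: int = 0) -> dict:
    """Interval and BLAST fixture tables exercising every annotation rule branch.

    Returns a dict with keys ``probes`` (BED-like), ``bovine_genes``,
    ``human_genes`` (gene models with exon structure) and ``blast_hits``.
    Coordinates are 0-based half-open.  The first twelve probes
    deterministically cover: plain bovine-exon overlap; multi-gene overlap
    resolved by lowest accession; LOC and MGC fallthrough to a human name;
    LOC with no human overlap; human-only overlap; intron-only overlap;
    nearest-gene with and without an equidistant tie; discordant BLAST
    flagging; and a fully unannotatable probe.
    """
    rng = np.random.default_rng(seed)
    off = int(rng.integers(0, 1000)) * 10  # shifts all coordinates; branches invariant

    def gene(name, acc, chrom, start, end, exons):
        return {"chrom": chrom, "start": start + off, "end": end + off,
                "gene_name": name, "accession": acc, "strand": "+",
                "exon_starts": ",".join(str(s + off) for s, _ in exons),
                "exon_sizes": ",".join(str(l) for _, l in exons)}

    bovine = [
        gene("KRT5", "NM_001008663", "chr1", 1000, 2000, [(1000, 400), (1600, 400)]),
        # two overlapping named genes, distinct accessions (probe p02)
        gene("DSG1", "NM_000200", "chr2", 1000, 2000, [(1000, 1000)]),
        gene("DSG3", "NM_000300", "chr2", 1500, 2500, [(1500, 1000)]),
        gene("LOC511234", "XM_600001", "chr3", 1000, 2000, [(1000, 1000)]),
        gene("MGC12345", "XM_600002", "chr4", 1000, 2000, [(1000, 1000)]),
        gene("LOC517777", "XM_600003", "chr8", 1000, 2000, [(1000, 1000)]),
        # intron-only overlap: exons flank the probe (p07)
        gene("TCHH", "NM_000700", "chr7", 1000, 3000, [(1000, 200), (2500, 500)]),
        # nearest-gene candidates on chr9
        gene("IVL", "NM_000901", "chr9", 100, 900, [(100, 800)]),
        gene("LOR", "NM_000902", "chr9", 2000, 2800, [(2000, 800)]),
        # equidistant pair on chr10, tie broken by accession
        gene("SPRR3", "NM_001010", "chr10", 100, 1000, [(100, 900)]),
        gene("CSTA", "NM_001020", "chr10", 2000, 3000, [(2000, 1000)]),
        gene("DSP", "NM_000800", "chr11", 1000, 2000, [(1000, 1000)]),
    ]
    human = [
        gene("DSC1", "NM_024421", "chr3", 900, 2100, [(900, 1200)]),
        gene("PKP1", "NM_000299", "chr4", 900, 2100, [(900, 1200)]),
        gene("KRT10", "NM_000421", "chr5", 1000, 2000, [(1000, 1000)]),
        gene("KRT17", "NM_000422", "chr5", 1400, 2400, [(1400, 1000)]),
        gene("FLG", "NM_002016", "chr7", 900, 3100, [(900, 2200)]),
        # chr6 has no bovine gene: nearest-gene falls back to the human set
        gene("GJB5", "NM_005268", "chr6", 2000, 2600, [(2000, 600)]),
    ]

    core = [
        ("p01", "chr1", 1100, 1160),   # step 1: bovine exon, named -> KRT5
        ("p02", "chr2", 1600, 1660),   # step 1 multi-overlap -> lowest accession DSG1
        ("p03", "chr3", 1100, 1160),   # step 2: LOC bovine + human -> DSC1
        ("p04", "chr4", 1100, 1160),   # step 2: MGC bovine + human -> PKP1
        ("p05", "chr5", 1500, 1560),   # step 2: no bovine, two human -> lowest acc KRT10
        ("p06", "chr6", 1100, 1160),   # step 3 via human fallback -> nearest GJB5
        ("p07", "chr7", 1500, 1560),   # intron-only bovine -> falls through to human FLG
        ("p08", "chr8", 1100, 1160),   # LOC bovine, no human -> LOC name kept
        ("p09", "chr9", 1000, 1060),   # step 3: nearest gene IVL (gap 100 vs 940)
        ("p10", "chr10", 1400, 1600),  # step 3 equidistant tie -> SPRR3 (lower accession)
        ("p11", "chr11", 1100, 1160),  # step 1 name DSP, BLAST says DSC2 -> flagged
        ("p12", "chr12", 100, 160),    # no genes, no blast -> unassigned
    ]
    probes = [{"chrom": c, "start": s + off, "end": e + off, "probe_id": pid}
              for pid, c, s, e in core]

    # filler probes land on the plain step-1 gene
    for i in range(12, n_probes):
        s = 1000 + int(rng.integers(0, 900))
        probes.append({"chrom": "chr1", "start": s + off, "end": s + 60 + off,
                       "probe_id": f"p{i + 1:02d}"})

    blast = pd.DataFrame([
        {"probe_id": "p01", "gene_name": "KRT5", "bitscore": 120.0},
        {"probe_id": "p11", "gene_name": "DSC2", "bitscore": 110.0},
    ])
    return {"probes": pd.DataFrame(probes),
            "bovine_genes": pd.DataFrame(bovine),
            "human_genes": pd.DataFrame(human),
            "blast_hits": blast}
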