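"""Reference inputs from the motivating grey-cattle study design.

The raw genotypes behind the original 15-grey vs 4-non-grey cattle scan
are not publicly deposited, so the study's printed summaries — the breed
panel with sample sizes, and the per-marker occurrence table of the
convergent-selection scan (counts of significant contrasts per reference
breed, marker positions on ARS-UCD1.2, the +/-250 kbp considered
intervals, and their gene content) — serve as reference inputs for
report-format checks and for re-deriving every derived number in the
reproduction script.
"""

from __future__ import annotations

from .genotype_io import LocusInfo

#: Test ("grey") breeds with number of genotyped animals.
GREY_BREED_SIZES: dict[str, int] = {
    "Chianina": 23,
    "Corsa": 32,
    "Croatian Podolian": 24,
    "Garfagnina": 23,
    "Gascon": 20,
    "Guelmoise": 24,
    "Hungarian Grey": 24,
    "Italian Podolian": 24,
    "Marchigiana": 22,
    "Maremmana": 24,
    "Piedmontese": 20,
    "Romagnola": 21,
    "Turkish Grey": 23,
    "Tyrolean Grey": 50,
    "Ukrainian Grey": 48,
}

#: Reference ("non-grey") breeds with number of genotyped animals.
REFERENCE_BREED_SIZES: dict[str, int] = {
    "Holstein": 24,
    "Limousin": 35,
    "Angus": 20,
    "Charolais": 33,
}

#: Column order of the per-reference occurrence counts below.
REFERENCE_ORDER: list[str] = ["Angus", "Charolais", "Holstein", "Limousin"]

#: Markers significant (q < 0.05) in >= 15 of the 60 contrasts:
#: (chrom, snp_id, (angus, charolais, holstein, limousin), position_bp,
#:  (interval_start, interval_end), genes)
REPORTED_OUTLIERS: list[tuple] = [
    ("2", "Hapmap49624-BTA-47893", (0, 0, 0, 15), 6_760_630,
     (6_510_630, 7_010_630),
     ["PMS1", "ORMDL1", "OSGEPL1", "ANKAR", "ASNSD1", "SLC40A1",
      "LOC100848294", "WDR75"]),
    ("4", "Hapmap53144-ss46525999", (0, 0, 15, 0), 76_874_783,
     (76_624_783, 77_124_783),
     ["MYO1G", "LOC112446527", "PURB", "MIR4657", "H2AFV", "PPIA", "ZMIZ2",
      "LOC112446406", "OGDH", "TMED4", "DDX56", "NPC1L1", "NUDCD3",
      "LOC104972146", "CAMK2B", "YKT6"]),
    ("14", "BTB-01532239", (2, 10, 9, 0), 22_781_305,
     (22_531_305, 23_031_305), ["XKR4", "TRNAT-AGU"]),
    ("14", "BTB-01530788", (3, 9, 10, 9), 22_867_321,
     (22_617_321, 23_117_321), ["XKR4", "TRNAT-AGU", "TMEM68", "TGS1"]),
    ("14", "BTB-00557532", (6, 10, 9, 11), 22_986_080,
     (22_736_080, 23_236_080), ["XKR4", "TRNAT-AGU", "TMEM68", "TGS1", "LYN"]),
    ("14", "Hapmap46986-BTA-34282", (2, 3, 2, 9), 23_630_896,
     (23_380_896, 23_880_896),
     ["CHCHD7", "SDR16C5", "SDR16C6", "PENK", "LOC112449660", "IMPAD1"]),
    ("14", "Hapmap46735-BTA-86653", (2, 12, 0, 13), 23_725_488,
     (23_475_488, 23_975_488),
     ["SDR16C6", "PENK", "LOC112449660", "IMPAD1"]),
    ("14", "ARS-BFGL-NGS-36089", (1, 5, 0, 10), 24_019_648,
     (23_769_648, 24_269_648), ["LOC112449660", "IMPAD1"]),
    ("14", "Hapmap30932-BTC-011225", (0, 11, 0, 8), 25_082_860,
     (24_832_860, 25_332_860), ["LOC107133116", "TOX", "TRNAC-GCA"]),
    ("14", "BTB-01280026", (4, 9, 0, 4), 25_354_206,
     (25_104_206, 25_604_206), ["TOX", "TRNAC-GCA"]),
    ("14", "Hapmap27934-BTC-065223", (0, 10, 0, 5), 25_472_332,
     (25_222_332, 25_722_332), ["TOX"]),
    ("26", "ARS-BFGL-NGS-11271", (2, 0, 13, 0), 23_039_524,
     (22_789_524, 23_289_524),
     ["LDB1", "PPRC1", "LOC112444554", "NOLC1", "LOC112444524",
      "LOC101902227", "LOC785229", "ELOVL3", "PITX3", "GBF1", "NFKB2",
      "PSD", "FBXL15", "CUEDC2", "LOC112444535", "MIR146B", "MFSD13A",
      "ACTR1A", "SUFU", "TRIM8"]),
]

#: Additional genes inside the BTA14 interval delimited by the outermost
#: retained markers (beyond those in the per-marker windows above).
EXTENDED_BTA14_GENES: list[str] = [
    "RPS20", "LOC112449628", "LOC112449630", "MOS", "PLAG1", "FAM110B",
    "LOC101902490", "UBXN2B", "CYP7A1", "TRNAG-CCC", "LOC112449629",
    "SDCBP", "LOC112449508", "NSMAF",
]


def reported_loci() -> list[LocusInfo]:
    """The retained markers as mapped loci."""
    return [
        LocusInfo(chrom=row[0], snp_id=row[1], position_bp=row[3])
        for row in REPORTED_OUTLIERS
    ]


def bta14_loci() -> list[LocusInfo]:
    """The retained markers on cattle chromosome 14."""
    return [loc for loc in reported_loci() if loc.chrom == "14"]


def unique_candidate_genes() -> set[str]:
    """Union of window gene lists and the extended BTA14 interval genes."""
    genes: set[str] = set(EXTENDED_BTA14_GENES)
    for row in REPORTED_OUTLIERS:
        genes.update(row[5])
    return genes
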