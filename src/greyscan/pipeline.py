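"""End-to-end orchestration: QC -> per-pair scans -> aggregation -> annotation.

A run is configured once (paths plus QC/MCMC/thresholds), logs per-stage
survivor counts, caches per-pair posteriors keyed by content hashes so an
interrupted design run resumes where it stopped, and writes four
artifacts into the output directory: ``qc_report.json``, per-pair
posterior TSVs under ``pairs/``, ``occurrence.tsv``, and ``report.tsv``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bayescan_engine import MCMCConfig
from .genotype_io import GenotypeDataset, read_ped_map
from .multicohort import (
    ContrastDesign,
    apply_occurrence_threshold,
    build_contrasts,
    min_count_from_fraction,
    occurrence_table,
    run_all_contrasts,
)
from .quality_control import QCConfig, run_qc
from .regions_annotation import (
    genes_in_regions,
    read_gene_annotation,
    report_table,
    snp_window,
)

logger = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH = 250_000


@dataclass
class PipelineConfig:
    ped: str = ""
    map: str = ""
    design: str = ""  # YAML with grey_breeds / reference_breeds lists
    annotation: str | None = None
    outdir: str = "greyscan_out"
    qc: QCConfig = field(default_factory=QCConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    q_threshold: float = 0.05
    min_count: int | None = 15
    min_fraction: float | None = None  # used when min_count is None
    half_width: int = DEFAULT_HALF_WIDTH

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        qc = QCConfig(**raw.pop("qc", {}))
        mcmc = MCMCConfig(**raw.pop("mcmc", {}))
        return cls(qc=qc, mcmc=mcmc, **raw)


def read_design(path: str | Path) -> ContrastDesign:
    """Breed-design file: YAML (or two-column TSV tagged grey/reference)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"} or "grey_breeds:" in text:
        raw = yaml.safe_load(text)
        return build_contrasts(raw["grey_breeds"], raw["reference_breeds"])
    grey, ref = [], []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2 or fields[1] not in {"grey", "reference"}:
            raise ValueError(f"{path}:{lineno}: expected '<breed>\\t<grey|reference>'")
        (grey if fields[1] == "grey" else ref).append(fields[0])
    return build_contrasts(grey, ref)


def resolve_min_count(config: PipelineConfig, n_pairs: int) -> int:
    """Absolute occurrence threshold; an absolute count wins over a fraction."""
    if config.min_count is not None:
        return config.min_count
    if config.min_fraction is not None:
        return min_count_from_fraction(n_pairs, config.min_fraction)
    return min_count_from_fraction(n_pairs, 0.25)


def run_pipeline(
    config: PipelineConfig, dataset: GenotypeDataset | None = None,
    design: ContrastDesign | None = None,
) -> Path:
    """Run the full analysis; returns the output directory.

    ``dataset``/``design`` may be passed in memory (tests, simulations) in
    place of the configured file paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if dataset is None:
        logger.info("reading genotypes: %s / %s", config.ped, config.map)
        dataset = read_ped_map(config.ped, config.map)
    if design is None:
        design = read_design(config.design)
    logger.info(
        "input: %d individuals, %d loci, %d pairs",
        dataset.n_individuals, dataset.n_loci, design.n_pairs,
    )

    qc_ds, qc_report = run_qc(dataset, config.qc)
    logger.info(
        "QC: kept %d individuals, %d loci",
        qc_report.n_individuals_kept, qc_report.n_loci_kept,
    )
    (outdir / "qc_report.json").write_text(
        json.dumps(qc_report.as_dict(), indent=2) + "\n"
    )

    per_pair = run_all_contrasts(
        qc_ds, design, config.mcmc, config.q_threshold,
        cache_dir=outdir / "pairs",
    )

    occ = occurrence_table(per_pair, design)
    loci_by_id = {loc.snp_id: loc for loc in qc_ds.loci}
    min_count = resolve_min_count(config, design.n_pairs)
    retained = apply_occurrence_threshold(occ, min_count, loci_by_id)
    logger.info(
        "aggregation: %d markers significant somewhere, %d retained at >= %d contrasts",
        len(occ.snp_ids), len(retained), min_count,
    )

    occ_lines = ["snp_id\t" + "\t".join(occ.reference_breeds) + "\tOVERALL"]
    for i, s in enumerate(occ.snp_ids):
        occ_lines.append(
            s + "\t" + "\t".join(str(int(c)) for c in occ.counts[i])
            + f"\t{int(occ.overall[i])}"
        )
    (outdir / "occurrence.tsv").write_text("\n".join(occ_lines) + "\n")

    windows = [snp_window(loci_by_id[s], config.half_width) for s in retained]
    genes = (
        read_gene_annotation(config.annotation) if config.annotation else []
    )
    annotated = genes_in_regions(windows, genes)
    retained_occ = occurrence_table(
        {k: v & set(retained) for k, v in per_pair.items()}, design,
        snp_ids=retained,
    )
    (outdir / "report.tsv").write_text(
        report_table(retained_occ, annotated, loci_by_id)
    )
    logger.info("report written: %s", outdir / "report.tsv")
    return outdir
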