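"""SNP-array quality control: autosome restriction, per-individual and
per-locus call-rate filters, and a minor-allele-frequency filter.

Semantics follow the standard PLINK-style commands: an individual or locus
is removed when its missing-call fraction strictly exceeds the threshold
(``--mind`` / ``--geno`` 0.1), and a locus is kept when its MAF is at least
the threshold (``--maf`` 0.01).  Filters are applied in the order
autosomes -> individuals -> locus call rate -> MAF, so locus statistics are
computed on the retained individual set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeDataset

#: Bos taurus autosome labels
CATTLE_AUTOSOMES = frozenset(str(c) for c in range(1, 30))


class EmptyDatasetError(ValueError):
    """All individuals or all loci were removed by QC."""


@dataclass
class QCConfig:
    max_locus_missing: float = 0.1
    max_indiv_missing: float = 0.1
    min_maf: float = 0.01
    autosomes: frozenset[str] = CATTLE_AUTOSOMES

    def __post_init__(self) -> None:
        for name in ("max_locus_missing", "max_indiv_missing", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        self.autosomes = frozenset(str(c) for c in self.autosomes)


@dataclass
class QCReport:
    n_individuals_removed: int = 0
    n_loci_removed_call_rate: int = 0
    n_loci_removed_maf: int = 0
    n_loci_removed_nonautosomal: int = 0
    n_individuals_kept: int = 0
    n_loci_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def filter_nonautosomal(
    dataset: GenotypeDataset, autosomes: frozenset[str] | set[str]
) -> GenotypeDataset:
    """Keep only loci on the given autosome labels, preserving order."""
    autosomes = {str(c) for c in autosomes}
    keep = [l for l, loc in enumerate(dataset.loci) if loc.chrom in autosomes]
    return dataset.subset_loci(keep)


def filter_individuals(
    dataset: GenotypeDataset, max_indiv_missing: float
) -> GenotypeDataset:
    """Remove individuals whose missing-call fraction exceeds the threshold."""
    if dataset.n_loci == 0:
        raise ValueError("cannot compute individual call rates with 0 loci")
    miss = (dataset.calls == MISSING).mean(axis=1)
    keep = np.flatnonzero(miss <= max_indiv_missing)
    return dataset.subset_individuals(keep)


def filter_loci_call_rate(
    dataset: GenotypeDataset, max_locus_missing: float
) -> GenotypeDataset:
    """Remove loci whose missing-call fraction exceeds the threshold."""
    if dataset.n_individuals == 0:
        return dataset.subset_loci([])
    miss = (dataset.calls == MISSING).mean(axis=0)
    keep = np.flatnonzero(miss <= max_locus_missing)
    return dataset.subset_loci(keep)


def minor_allele_frequencies(dataset: GenotypeDataset) -> np.ndarray:
    """MAF per locus over non-missing calls; 0.0 where nothing is called."""
    called = dataset.calls != MISSING
    n_alleles = 2 * called.sum(axis=0)
    a = np.where(called, dataset.calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, a / np.maximum(n_alleles, 1), 0.0)
    return np.minimum(freq, 1.0 - freq)


def filter_maf(dataset: GenotypeDataset, min_maf: float) -> GenotypeDataset:
    """Keep loci whose minor allele frequency is at least ``min_maf``."""
    maf = minor_allele_frequencies(dataset)
    keep = np.flatnonzero(maf >= min_maf)
    return dataset.subset_loci(keep)


def run_qc(
    dataset: GenotypeDataset, config: QCConfig | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the full QC cascade and report per-stage removal counts.

    Raises :class:`EmptyDatasetError` if nothing survives.
    """
    config = config or QCConfig()
    report = QCReport()

    ds = filter_nonautosomal(dataset, config.autosomes)
    report.n_loci_removed_nonautosomal = dataset.n_loci - ds.n_loci
    if ds.n_loci == 0:
        raise EmptyDatasetError("all loci removed by the autosome filter")

    ds2 = filter_individuals(ds, config.max_indiv_missing)
    report.n_individuals_removed = ds.n_individuals - ds2.n_individuals
    if ds2.n_individuals == 0:
        raise EmptyDatasetError("all individuals removed by the call-rate filter")

    ds3 = filter_loci_call_rate(ds2, config.max_locus_missing)
    report.n_loci_removed_call_rate = ds2.n_loci - ds3.n_loci

    ds4 = filter_maf(ds3, config.min_maf)
    report.n_loci_removed_maf = ds3.n_loci - ds4.n_loci
    if ds4.n_loci == 0:
        raise EmptyDatasetError("all loci removed by QC")

    report.n_individuals_kept = ds4.n_individuals
    report.n_loci_kept = ds4.n_loci
    return ds4, report
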