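"""Grey x non-grey contrast design, per-pair scans, and occurrence aggregation.

Each test (grey) breed is contrasted against each reference (non-grey)
breed; a marker's evidence for convergent selection is the number of
pairwise contrasts in which it is significant (q-value below threshold).
Markers significant in at least a minimum number of contrasts (15 of 60 in
the motivating design, i.e. 25%) are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .bayescan_engine import (
    MCMCConfig,
    LocusPosterior,
    read_posteriors,
    run_mcmc,
    significant_loci,
    write_posteriors,
)
from .genotype_io import AlleleCountTable, GenotypeDataset, allele_counts

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    """Invalid contrast design (overlapping or missing breed lists)."""


@dataclass
class ContrastDesign:
    grey_breeds: list[str]
    reference_breeds: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.grey_breeds) & set(self.reference_breeds)
        if overlap:
            raise DesignError(f"breeds in both lists: {sorted(overlap)}")
        if not self.pairs:
            self.pairs = [
                (g, r) for g in self.grey_breeds for r in self.reference_breeds
            ]
        if len(self.pairs) != len(self.grey_breeds) * len(self.reference_breeds):
            raise DesignError("pairs must be the full grey x reference product")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class OccurrenceTable:
    """Per-marker counts of significant contrasts, split by reference breed."""

    reference_breeds: list[str]
    snp_ids: list[str]
    counts: np.ndarray  # (n_snps, n_reference) int64
    total_contrasts: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.snp_ids), len(self.reference_breeds)):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative occurrence count")
        if (self.overall > self.total_contrasts).any():
            raise ValueError("overall count exceeds number of contrasts")

    @property
    def overall(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def row(self, snp_id: str) -> dict[str, int]:
        i = self.snp_ids.index(snp_id)
        d = {r: int(self.counts[i, j]) for j, r in enumerate(self.reference_breeds)}
        d["OVERALL"] = int(self.overall[i])
        return d


def build_contrasts(
    grey_breeds: Sequence[str], reference_breeds: Sequence[str]
) -> ContrastDesign:
    """Full Cartesian product of test and reference breeds, grey-major order."""
    if not grey_breeds or not reference_breeds:
        raise DesignError("both breed lists must be non-empty")
    return ContrastDesign(
        grey_breeds=list(grey_breeds), reference_breeds=list(reference_breeds)
    )


def pair_seed(master_seed: int, grey: str, reference: str) -> int:
    """Deterministic per-pair seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{grey}|{reference}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _safe_name(label: str) -> str:
    return "".join(c if c.isalnum() or c in "-." else "_" for c in label)


def load_pair_posteriors(
    cache_dir: str | Path,
) -> dict[tuple[str, str], list[LocusPosterior]]:
    """Read per-pair posterior TSVs written by :func:`scan_pair`.

    Pair identity is parsed from the ``<grey>__<reference>__<hash>.tsv``
    file names (sanitized labels); the latest file per pair wins.
    """
    out: dict[tuple[str, str], list[LocusPosterior]] = {}
    for path in sorted(Path(cache_dir).glob("*__*__*.tsv")):
        grey, ref, _ = path.stem.split("__", 2)
        out[(grey, ref)] = read_posteriors(path)
    return out


def _cache_key(
    grey: str, reference: str, counts: AlleleCountTable, config: MCMCConfig
) -> str:
    h = hashlib.sha256()
    h.update(f"{grey}|{reference}".encode())
    h.update(json.dumps(config.__dict__, sort_keys=True, default=str).encode())
    h.update(np.ascontiguousarray(counts.a).tobytes())
    h.update(np.ascontiguousarray(counts.n).tobytes())
    h.update("\x00".join(loc.snp_id for loc in counts.loci).encode())
    return h.hexdigest()[:24]


def scan_pair(
    dataset: GenotypeDataset,
    grey: str,
    reference: str,
    config: MCMCConfig,
    cache_dir: str | Path | None = None,
) -> list[LocusPosterior]:
    """Run the outlier scan for one grey/reference pair (cached if asked).

    The pair's chain seed is derived deterministically from ``config.seed``
    and the breed names, so a full design run is reproducible pair by pair.
    """
    counts = allele_counts(dataset, [grey, reference])
    cfg = MCMCConfig(**{**config.__dict__, "seed": pair_seed(config.seed, grey, reference)})
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)
        stem = f"{_safe_name(grey)}__{_safe_name(reference)}"
        path = cache_dir / f"{stem}__{_cache_key(grey, reference, counts, cfg)}.tsv"
        if path.exists():
            logger.info("cache hit for pair (%s, %s)", grey, reference)
            return read_posteriors(path)
    post = run_mcmc(counts, cfg)
    if cache_dir is not None:
        write_posteriors(post, path)
    return post


def run_all_contrasts(
    dataset: GenotypeDataset,
    design: ContrastDesign,
    config: MCMCConfig | None = None,
    q_threshold: float = 0.05,
    cache_dir: str | Path | None = None,
) -> dict[tuple[str, str], set[str]]:
    """Significant-marker sets per (grey, reference) pair.

    Any per-pair failure aborts the run; nothing is skipped silently.
    """
    config = config or MCMCConfig()
    present = set(dataset.breed_labels)
    missing = [
        b
        for b in list(design.grey_breeds) + list(design.reference_breeds)
        if b not in present
    ]
    if missing:
        raise DesignError(f"design breeds absent from dataset: {missing}")

    results: dict[tuple[str, str], set[str]] = {}
    for k, (grey, ref) in enumerate(design.pairs):
        logger.info("scanning pair %d/%d: %s vs %s", k + 1, design.n_pairs, grey, ref)
        try:
            post = scan_pair(dataset, grey, ref, config, cache_dir=cache_dir)
        except Exception:
            logger.error("scan failed for pair (%s, %s); aborting", grey, ref)
            raise
        results[(grey, ref)] = significant_loci(post, q_threshold)
    return results


def occurrence_table(
    per_pair_results: dict[tuple[str, str], set[str]],
    design: ContrastDesign,
    snp_ids: Sequence[str] | None = None,
) -> OccurrenceTable:
    """Count, per marker, significant contrasts per reference breed.

    ``snp_ids`` optionally fixes the marker universe (markers significant
    nowhere then appear as all-zero rows); by default only markers
    significant in at least one contrast are tabulated.
    """
    missing_pairs = [p for p in design.pairs if p not in per_pair_results]
    if missing_pairs:
        raise ValueError(f"results missing for pairs: {missing_pairs[:3]}...")
    if snp_ids is not None:
        all_snps = list(snp_ids)
    else:
        all_snps = sorted(
            set().union(*per_pair_results.values()) if per_pair_results else set()
        )
    ref_index = {r: j for j, r in enumerate(design.reference_breeds)}
    snp_index = {s: i for i, s in enumerate(all_snps)}
    counts = np.zeros((len(all_snps), len(design.reference_breeds)), dtype=np.int64)
    for (grey, ref), snps in per_pair_results.items():
        j = ref_index[ref]
        for s in snps:
            counts[snp_index[s], j] += 1
    return OccurrenceTable(
        reference_breeds=list(design.reference_breeds),
        snp_ids=all_snps,
        counts=counts,
        total_contrasts=design.n_pairs,
    )


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (0, f"{int(chrom):09d}") if chrom.isdigit() else (1, chrom)


def apply_occurrence_threshold(
    table: OccurrenceTable,
    min_count: int = 15,
    loci_by_id: dict[str, "object"] | None = None,
) -> list[str]:
    """Markers significant in at least ``min_count`` contrasts overall.

    Sorted by chromosome then position when ``loci_by_id`` (snp_id ->
    LocusInfo) is given, else by marker name.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = [
        s for s, c in zip(table.snp_ids, table.overall) if c >= min_count
    ]
    if loci_by_id is not None:
        kept.sort(
            key=lambda s: (
                _chrom_sort_key(loci_by_id[s].chrom),
                loci_by_id[s].position_bp,
            )
        )
    else:
        kept.sort()
    return kept


def min_count_from_fraction(n_pairs: int, fraction: float) -> int:
    """Absolute occurrence threshold from a fraction of the contrast count."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    return int(np.ceil(fraction * n_pairs))
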