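"""PED/MAP genotype panels and per-population allele counts.

Genotypes are biallelic SNP-array calls stored as copies of the per-locus
A allele (0, 1, 2) with ``MISSING`` (-1) for no-calls.  The A allele is the
first non-missing allele character seen in the file at that locus; the
downstream differentiation test is symmetric under allele relabelling, so
this orientation is a pure bookkeeping choice.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Sequence

import numpy as np

MISSING: int = -1
#: PED missing-allele symbol
_MISSING_ALLELE = "0"


class PedMapFormatError(ValueError):
    """Structural problem in a PED/MAP file pair."""


class GenotypeDataError(ValueError):
    """Inconsistent genotype content (e.g. >2 alleles at a locus)."""


@dataclass(frozen=True)
class LocusInfo:
    """A mapped SNP: chromosome label, marker name, 1-based physical position."""

    chrom: str
    snp_id: str
    position_bp: int

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"position_bp must be >= 1, got {self.position_bp}")


@dataclass
class GenotypeDataset:
    """Individuals x loci matrix of A-allele dosages with breed labels.

    ``calls[i, l]`` counts copies of the A allele for individual *i* at
    locus *l*; ``MISSING`` marks a no-call.  ``allele_labels[l]`` holds the
    (A, B) allele characters; "0" stands for an allele never observed.
    """

    individuals: list[tuple[str, str]]  # (individual_id, breed_label)
    loci: list[LocusInfo]
    calls: np.ndarray  # int8, shape (n_individuals, n_loci)
    allele_labels: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.individuals)}, {len(self.loci)})"
            )
        if not self.allele_labels:
            self.allele_labels = [("A", "B")] * len(self.loci)
        if len(self.allele_labels) != len(self.loci):
            raise ValueError("allele_labels length mismatch")
        for _, breed in self.individuals:
            if not breed:
                raise ValueError("empty breed label")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype codes restricted to {0, 1, 2, MISSING}")
        ids = [loc.snp_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id values must be unique within a dataset")

    # -- convenience -----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def breed_labels(self) -> list[str]:
        """Breed label per individual, in matrix row order."""
        return [b for _, b in self.individuals]

    def breeds(self) -> list[str]:
        """Distinct breed labels in order of first appearance."""
        seen: dict[str, None] = {}
        for _, b in self.individuals:
            seen.setdefault(b)
        return list(seen)

    def subset_individuals(self, rows: Sequence[int]) -> "GenotypeDataset":
        rows = list(rows)
        return GenotypeDataset(
            individuals=[self.individuals[i] for i in rows],
            loci=list(self.loci),
            calls=self.calls[rows, :].copy(),
            allele_labels=list(self.allele_labels),
        )

    def subset_loci(self, cols: Sequence[int]) -> "GenotypeDataset":
        cols = list(cols)
        return GenotypeDataset(
            individuals=list(self.individuals),
            loci=[self.loci[c] for c in cols],
            calls=self.calls[:, cols].copy(),
            allele_labels=[self.allele_labels[c] for c in cols],
        )

    def subset_breeds(self, breeds: Sequence[str]) -> "GenotypeDataset":
        wanted = set(breeds)
        missing = wanted - set(self.breed_labels)
        if missing:
            raise KeyError(f"breed labels not in dataset: {sorted(missing)}")
        rows = [i for i, (_, b) in enumerate(self.individuals) if b in wanted]
        return self.subset_individuals(rows)


@dataclass
class AlleleCountTable:
    """Per-population sufficient statistics of the differentiation test.

    ``a[l, j]`` counts A alleles at locus *l* in population *j* and
    ``n[l, j]`` the total called alleles (twice the non-missing diploid
    genotypes), so ``0 <= a <= n`` and ``n`` is even.
    """

    populations: list[str]
    loci: list[LocusInfo]
    a: np.ndarray  # int64, (n_loci, n_pops)
    n: np.ndarray  # int64, (n_loci, n_pops)

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        shape = (len(self.loci), len(self.populations))
        if self.a.shape != shape or self.n.shape != shape:
            raise ValueError("a/n shape mismatch with loci x populations")
        if ((self.a < 0) | (self.a > self.n)).any():
            raise ValueError("require 0 <= a <= n")
        if (self.n % 2 != 0).any():
            raise ValueError("called-allele totals must be even")

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_map(map_path: str | Path) -> list[LocusInfo]:
    loci: list[LocusInfo] = []
    with _open_text(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PedMapFormatError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, snp_id, _cm, bp = fields
            loci.append(LocusInfo(chrom=chrom, snp_id=snp_id, position_bp=int(bp)))
    return loci


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read a whitespace-delimited PED/MAP pair into a :class:`GenotypeDataset`.

    The PED family-ID column is taken as the breed label.  The A allele at
    each locus is the first non-missing allele character encountered while
    scanning individuals in file order; a genotype with any missing allele
    ("0") is coded ``MISSING``.
    """
    loci = _read_map(map_path)
    n_loci = len(loci)

    individuals: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    # per-locus observed allele characters, in order of first appearance
    alleles: list[list[str]] = [[] for _ in range(n_loci)]

    with _open_text(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_loci:
                raise PedMapFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_loci} columns "
                    f"for {n_loci} mapped loci, got {len(fields)}"
                )
            breed, indiv_id = fields[0], fields[1]
            individuals.append((indiv_id, breed))
            row = np.full(n_loci, MISSING, dtype=np.int8)
            for l in range(n_loci):
                a1, a2 = fields[6 + 2 * l], fields[7 + 2 * l]
                if a1 == _MISSING_ALLELE or a2 == _MISSING_ALLELE:
                    continue
                obs = alleles[l]
                for al in (a1, a2):
                    if al not in obs:
                        obs.append(al)
                        if len(obs) > 2:
                            raise GenotypeDataError(
                                f"locus {loci[l].snp_id}: more than 2 distinct "
                                f"alleles observed ({obs})"
                            )
                row[l] = (a1 == obs[0]) + (a2 == obs[0])
            rows.append(row)

    calls = (
        np.vstack(rows) if rows else np.empty((0, n_loci), dtype=np.int8)
    )
    labels = [
        (obs[0] if obs else _MISSING_ALLELE, obs[1] if len(obs) > 1 else _MISSING_ALLELE)
        for obs in alleles
    ]
    return GenotypeDataset(
        individuals=individuals, loci=loci, calls=calls, allele_labels=labels
    )


def write_ped_map(
    dataset: GenotypeDataset, ped_path: str | Path, map_path: str | Path
) -> None:
    """Write a dataset as a PED/MAP pair re-readable by :func:`read_ped_map`."""
    with _open_text(map_path, "wt") as fh:
        for loc in dataset.loci:
            fh.write(f"{loc.chrom} {loc.snp_id} 0 {loc.position_bp}\n")

    with _open_text(ped_path, "wt") as fh:
        for i, (indiv_id, breed) in enumerate(dataset.individuals):
            fields = [breed, indiv_id, "0", "0", "0", "-9"]
            for l in range(dataset.n_loci):
                call = dataset.calls[i, l]
                a_lab, b_lab = dataset.allele_labels[l]
                if call == MISSING:
                    fields += [_MISSING_ALLELE, _MISSING_ALLELE]
                else:
                    fields += [a_lab] * int(call) + [b_lab] * (2 - int(call))
            fh.write(" ".join(fields) + "\n")


def allele_counts(
    dataset: GenotypeDataset, populations: Sequence[str]
) -> AlleleCountTable:
    """Tabulate A-allele counts and called-allele totals per population.

    Raises ``KeyError`` for a breed label absent from the dataset.
    """
    labels = np.asarray(dataset.breed_labels)
    present = set(labels.tolist())
    unknown = [p for p in populations if p not in present]
    if unknown:
        raise KeyError(f"breed labels not in dataset: {unknown}")

    n_loci = dataset.n_loci
    a = np.zeros((n_loci, len(populations)), dtype=np.int64)
    n = np.zeros_like(a)
    for j, pop in enumerate(populations):
        sub = dataset.calls[labels == pop, :]
        called = sub != MISSING
        a[:, j] = np.where(called, sub, 0).sum(axis=0)
        n[:, j] = 2 * called.sum(axis=0)
    return AlleleCountTable(
        populations=list(populations), loci=list(dataset.loci), a=a, n=n
    )


def write_allele_counts(table: AlleleCountTable, path: str | Path) -> None:
    """One row per locus: snp_id then alternating a_j, n_j per population."""
    with _open_text(path, "wt") as fh:
        header = ["snp_id"]
        for pop in table.populations:
            header += [f"a_{pop}", f"n_{pop}"]
        fh.write("\t".join(header) + "\n")
        for l, loc in enumerate(table.loci):
            row = [loc.snp_id]
            for j in range(len(table.populations)):
                row += [str(table.a[l, j]), str(table.n[l, j])]
            fh.write("\t".join(row) + "\n")


def iter_breed_rows(dataset: GenotypeDataset) -> Iterator[tuple[str, list[int]]]:
    """Yield (breed, row indices) in order of first appearance."""
    order: dict[str, list[int]] = {}
    for i, (_, b) in enumerate(dataset.individuals):
        order.setdefault(b, []).append(i)
    yield from order.items()
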