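"""Synthetic multi-breed SNP panels with convergent selection signals.

Breed allele frequencies follow the Balding-Nichols model: given an
ancestral frequency p and a breed-level differentiation F, the breed
frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), so its mean is p and its
variance F p (1-p).  Breed differentiation is logistic(beta_j) at neutral
loci; at "selected" loci every grey breed instead draws around a shared
derived frequency with differentiation logistic(alpha + beta_j), which
makes the same locus differentiated against every reference breed — the
convergence signature the multi-cohort scan aggregates.

Genotypes are Hardy-Weinberg draws Binomial(2, freq) with i.i.d. missing
calls.  Defaults emulate a downsampled BovineSNP50-style design: 15 grey
and 4 reference breeds of 24 animals, 1000 autosomal loci, 2% of loci
convergently selected with locus effect 2.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_io import MISSING, GenotypeDataset, LocusInfo


@dataclass
class SyntheticConfig:
    n_grey: int = 15
    n_reference: int = 4
    n_per_breed: int = 24
    n_loci: int = 1000
    frac_selected: float = 0.02
    alpha_selected: float = 2.5
    beta_mean: float = -2.0
    beta_sd: float = 0.3
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_selected <= 1.0:
            raise ValueError("frac_selected must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        for name in ("n_grey", "n_reference", "n_per_breed", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def grey_breeds(self) -> list[str]:
        return [f"GREY{i + 1:02d}" for i in range(self.n_grey)]

    @property
    def reference_breeds(self) -> list[str]:
        return [f"REF{i + 1:02d}" for i in range(self.n_reference)]


@dataclass
class TruthLabels:
    selected: np.ndarray  # (n_loci,) 0/1
    alpha: np.ndarray  # realized locus effects
    beta: np.ndarray  # per-breed effects, grey breeds first
    ancestral_p: np.ndarray
    breeds: list[str] = field(default_factory=list)


def balding_nichols_freq(
    p: float | np.ndarray, fst: float | np.ndarray, rng: np.random.Generator
) -> float | np.ndarray:
    """Draw breed frequencies Beta(p(1-F)/F, (1-p)(1-F)/F); broadcasting ok."""
    p = np.asarray(p, dtype=float)
    fst = np.asarray(fst, dtype=float)
    if ((p <= 0) | (p >= 1)).any() or ((fst <= 0) | (fst >= 1)).any():
        raise ValueError("p and fst must lie strictly inside (0, 1)")
    scale = (1.0 - fst) / fst
    draw = rng.beta(p * scale, (1.0 - p) * scale)
    return draw if draw.ndim else float(draw)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(config: SyntheticConfig | None = None) -> tuple[GenotypeDataset, TruthLabels]:
    """Simulate a multi-breed panel; fully reproducible from ``config.seed``."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    breeds = config.grey_breeds + config.reference_breeds
    n_breeds = len(breeds)

    lo, hi = config.ancestral_freq_range
    p = rng.uniform(lo, hi, size=L)
    beta = rng.normal(config.beta_mean, config.beta_sd, size=n_breeds)

    n_sel = round(config.frac_selected * L)
    selected = np.zeros(L, dtype=np.int64)
    if n_sel:
        selected[rng.choice(L, size=n_sel, replace=False)] = 1
    alpha = np.where(selected == 1, config.alpha_selected, 0.0)

    # shared derived frequency driving convergent differentiation in grey breeds
    p_derived = np.clip(p + 0.5, 0.05, 0.95)

    freqs = np.empty((n_breeds, L))
    for j in range(n_breeds):
        is_grey = j < config.n_grey
        centre = np.where((selected == 1) & is_grey, p_derived, p)
        fst = _logistic(np.where((selected == 1) & is_grey, alpha, 0.0) + beta[j])
        freqs[j] = balding_nichols_freq(centre, fst, rng)
    freqs = np.clip(freqs, 1e-9, 1.0 - 1e-9)

    n_ind = n_breeds * config.n_per_breed
    calls = np.empty((n_ind, L), dtype=np.int8)
    individuals: list[tuple[str, str]] = []
    row = 0
    for j, breed in enumerate(breeds):
        g = rng.binomial(2, freqs[j], size=(config.n_per_breed, L)).astype(np.int8)
        calls[row : row + config.n_per_breed] = g
        for i in range(config.n_per_breed):
            individuals.append((f"{breed}_{i + 1:03d}", breed))
        row += config.n_per_breed

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    # ~50k-SNP-array style map: loci spread over 29 autosomes
    chroms = [str(c) for c in range(1, 30)]
    loci = [
        LocusInfo(
            chrom=chroms[l % 29],
            snp_id=f"SYN-{l + 1:06d}",
            position_bp=1_000_000 + (l // 29) * 50_000,
        )
        for l in range(L)
    ]
    dataset = GenotypeDataset(
        individuals=individuals,
        loci=loci,
        calls=calls,
        allele_labels=[("A", "G")] * L,
    )
    truth = TruthLabels(
        selected=selected, alpha=alpha, beta=beta, ancestral_p=p, breeds=breeds
    )
    return dataset, truth


def write_truth(truth: TruthLabels, dataset: GenotypeDataset, path: str | Path) -> None:
    """Ground-truth TSV: snp_id, selected flag, realized alpha, ancestral p."""
    with open(path, "wt") as fh:
        fh.write("snp_id\tselected\talpha\tancestral_p\n")
        for l, loc in enumerate(dataset.loci):
            fh.write(
                f"{loc.snp_id}\t{int(truth.selected[l])}\t{truth.alpha[l]:.6g}"
                f"\t{truth.ancestral_p[l]:.6g}\n"
            )


def hudson_fst(a1: np.ndarray, n1: np.ndarray, a2: np.ndarray, n2: np.ndarray) -> float:
    """Hudson's F_ST estimator averaged over loci (ratio of averages).

    Used as an independent check that simulated differentiation matches the
    logistic(beta) levels the generator targets.
    """
    ok = (n1 > 1) & (n2 > 1)
    p1, p2 = a1[ok] / n1[ok], a2[ok] / n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1[ok] - 1) - p2 * (1 - p2) / (n2[ok] - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].sum() / den[keep].sum())
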