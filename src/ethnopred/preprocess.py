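"""SNP quality-control filters applied before tree learning.

Three exclusion criteria, each independently flagged so a SNP can fall in
several categories; the filtered matrix drops the union:

a. call rate below 100% — any NoCall in any sample disqualifies the SNP,
   which is what guarantees the tree learner never sees missing values;
b. non-autosomal location (X, Y, MT or an unknown chromosome);
c. significant deviation from Hardy–Weinberg equilibrium under Pearson's
   chi-squared test (1 df, no continuity correction), nominal p < 0.05.

The HWE test is by default performed *within each labeled population* and a
SNP is flagged if it deviates in any of them.  Testing the pooled sample
instead would flag exactly the ancestry-informative SNPs the classifier
needs, because allele-frequency differences between populations produce a
heterozygote deficit in the pooled counts (the Wahlund effect); the pooled
scope remains available as an explicit option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotype_io import (
    AUTOSOMES, GenotypeMatrix, HET, HOM_MAJOR, HOM_MINOR, NOCALL,
    PopulationLabels,
)

__all__ = ["FilterConfig", "FilterReport", "call_rate", "hwe_chi2",
           "genotype_counts", "filter_snps"]


@dataclass(frozen=True)
class FilterConfig:
    """Which criteria to apply and how to test HWE."""

    require_full_call_rate: bool = True
    autosomes_only: bool = True
    hwe_alpha: float = 0.05
    hwe_scope: str = "per_population_union"  # or "pooled", or "off"

    def __post_init__(self) -> None:
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must be in (0, 1)")
        if self.hwe_scope not in ("per_population_union", "pooled", "off"):
            raise ValueError(f"unknown hwe_scope {self.hwe_scope!r}")


@dataclass(frozen=True)
class FilterReport:
    """Per-criterion flag counts plus the union actually removed."""

    n_total: int
    n_callrate_flagged: int
    n_nonautosomal_flagged: int
    n_hwe_flagged: int
    n_filtered: int

    @property
    def n_unfiltered(self) -> int:
        return self.n_total - self.n_filtered

    def to_rows(self) -> list[tuple[str, int]]:
        """Report rows in the shape of the standard filtering table."""
        return [
            ("SNPs with Call Rate < 100%", self.n_callrate_flagged),
            ("SNPs on X, Y, MT, or unknown chromosome", self.n_nonautosomal_flagged),
            ("SNPs deviating from HWE (p < alpha)", self.n_hwe_flagged),
            ("Filtered SNPs", self.n_filtered),
            ("Unfiltered SNPs", self.n_unfiltered),
            ("Total SNPs", self.n_total),
        ]


def call_rate(matrix: GenotypeMatrix, snp_id: str) -> float:
    """Fraction of samples with a non-NoCall genotype at ``snp_id``."""
    col = matrix.calls[:, matrix.snp_index(snp_id)]
    if len(col) == 0:
        raise ValueError("matrix has no samples")
    return float((col != NOCALL).mean())


def hwe_chi2(n_AA: int, n_AB: int, n_BB: int) -> tuple[float, float]:
    """Pearson goodness-of-fit of genotype counts to Hardy–Weinberg.

    Expected counts are ``n*(p^2, 2pq, q^2)`` at the sample allele frequency
    ``p = (2*n_AA + n_AB) / (2n)``; the statistic has 1 degree of freedom
    (three cells, one estimated parameter).  A monomorphic sample fits HWE
    exactly and returns ``(0.0, 1.0)``.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("negative genotype counts")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("no genotype observations")
    p = (2 * n_AA + n_AB) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_AB, n_BB], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def genotype_counts(matrix: GenotypeMatrix,
                    sample_mask: np.ndarray | None = None) -> np.ndarray:
    """Per-SNP (n_AA, n_AB, n_BB) counts, NoCalls excluded; shape (L, 3)."""
    calls = matrix.calls if sample_mask is None else matrix.calls[sample_mask]
    return np.stack([(calls == g).sum(axis=0)
                     for g in (HOM_MAJOR, HET, HOM_MINOR)], axis=1)


def _hwe_flags(matrix: GenotypeMatrix, labels: PopulationLabels | None,
               config: FilterConfig) -> np.ndarray:
    if config.hwe_scope == "off":
        return np.zeros(matrix.n_snps, dtype=bool)
    if config.hwe_scope == "per_population_union":
        if labels is None:
            raise ValueError("per_population_union HWE scope requires labels")
        groups = []
        sample_pop = [labels.assignment[s] for s in matrix.samples]
        for pop in labels.class_order:
            mask = np.array([p == pop for p in sample_pop])
            if mask.any():
                groups.append(mask)
    else:
        groups = [np.ones(matrix.n_samples, dtype=bool)]
    flags = np.zeros(matrix.n_snps, dtype=bool)
    for mask in groups:
        counts = genotype_counts(matrix, mask)
        for j in range(matrix.n_snps):
            nAA, nAB, nBB = (int(c) for c in counts[j])
            if nAA + nAB + nBB == 0:
                continue
            _, p = hwe_chi2(nAA, nAB, nBB)
            flags[j] |= p < config.hwe_alpha
    return flags


def filter_snps(matrix: GenotypeMatrix,
                labels: PopulationLabels | None = None,
                config: FilterConfig | None = None,
                ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the three exclusion criteria; return the kept matrix + report.

    The report counts each criterion independently (overlap allowed) and the
    union of flagged SNPs; the returned matrix keeps exactly the SNPs flagged
    by no criterion, in their original order.  Filtering is idempotent.
    """
    config = config or FilterConfig()
    L = matrix.n_snps
    callrate_flags = np.zeros(L, dtype=bool)
    if config.require_full_call_rate:
        callrate_flags = (matrix.calls == NOCALL).any(axis=0)
    nonauto_flags = np.zeros(L, dtype=bool)
    if config.autosomes_only:
        nonauto_flags = np.array(
            [s.chromosome not in AUTOSOMES for s in matrix.snps])
    hwe_flags = _hwe_flags(matrix, labels, config)
    union = callrate_flags | nonauto_flags | hwe_flags
    report = FilterReport(
        n_total=L,
        n_callrate_flagged=int(callrate_flags.sum()),
        n_nonautosomal_flagged=int(nonauto_flags.sum()),
        n_hwe_flagged=int(hwe_flags.sum()),
        n_filtered=int(union.sum()),
    )
    kept = [s.snp_id for s, f in zip(matrix.snps, union) if not f]
    return matrix.subset_snps(kept), report
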