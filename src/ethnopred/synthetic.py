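"""Synthetic structured-population genotype data (Balding–Nichols model).

Each SNP draws an ancestral minor-allele frequency ``pi ~ Uniform(lo, hi)``;
population ``k`` then draws its own frequency from
``Beta(pi*(1-F)/F, (1-pi)*(1-F)/F)``, whose mean is ``pi`` and whose spread
around it is governed by the divergence parameter ``F`` (the F_ST of the
model; ``F = 0`` degenerates to no divergence).  Genotypes are the
minor-allele dosage ``Binomial(2, freq)`` — i.e. exact Hardy–Weinberg
proportions within each population at its true frequency — coded against a
fixed per-SNP allele pair.  Calls are independently masked to NoCall with
probability ``u``.

The generator emulates population structure only: sites are independent (no
linkage disequilibrium), populations are unadmixed, and missingness is
uncorrelated across SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, NOCALL, PopulationLabels, SnpRecord

__all__ = ["SyntheticSpec", "CaseControlSpec", "simulate_populations",
           "simulate_from_truth", "simulate_case_control"]

_ALLELES = "ACGT"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a structured-population genotype simulation.

    ``fst`` may be a scalar (shared by all populations) or one value per
    population.  ``nonautosomal_snps`` appends that many extra SNPs placed on
    X/Y/MT (round-robin) to exercise the chromosome filter.
    """

    n_populations: int = 3
    samples_per_population: int | tuple[int, ...] = 200
    n_snps: int = 1000
    fst: float | tuple[float, ...] = 0.15
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    nocall_rate: float = 0.0
    nonautosomal_snps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
        if not 0.0 <= self.nocall_rate < 1.0:
            raise ValueError("nocall_rate must be in [0, 1)")
        for f in self._fst_list():
            if not 0.0 <= f < 1.0:
                raise ValueError("fst must be in [0, 1)")
        if min(self._counts()) < 1:
            raise ValueError("samples_per_population must be >= 1")

    def _counts(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_population, int):
            return (self.samples_per_population,) * self.n_populations
        counts = tuple(self.samples_per_population)
        if len(counts) != self.n_populations:
            raise ValueError("samples_per_population length != n_populations")
        return counts

    def _fst_list(self) -> tuple[float, ...]:
        if isinstance(self.fst, (int, float)):
            return (float(self.fst),) * self.n_populations
        fsts = tuple(float(f) for f in self.fst)
        if len(fsts) != self.n_populations:
            raise ValueError("fst length != n_populations")
        return fsts


@dataclass(frozen=True)
class CaseControlSpec(SyntheticSpec):
    """A :class:`SyntheticSpec` plus per-population case fractions.

    No SNP has a true phenotype effect: any association signal downstream is
    pure population stratification.
    """

    case_fraction_per_population: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        fracs = self.case_fraction_per_population
        if len(fracs) != self.n_populations:
            raise ValueError("need one case fraction per population")
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("case fractions must be in [0, 1]")


def _make_snps(n_snps: int, nonautosomal: int,
               rng: np.random.Generator) -> tuple[SnpRecord, ...]:
    snps = []
    extra = ("X", "Y", "MT")
    for j in range(n_snps + nonautosomal):
        if j < n_snps:
            chrom = str(j % 22 + 1)
        else:
            chrom = extra[(j - n_snps) % 3]
        a, b = rng.choice(len(_ALLELES), size=2, replace=False)
        snps.append(SnpRecord(f"snp{j:05d}", chrom, 1000 * (j + 1),
                              _ALLELES[a], _ALLELES[b]))
    return tuple(snps)


def simulate_from_truth(snps: tuple[SnpRecord, ...], truth: np.ndarray,
                        samples_per_population, nocall_rate: float,
                        seed: int, pop_names=None,
                        sample_prefix: str = "S") -> tuple[GenotypeMatrix,
                                                           PopulationLabels]:
    """Draw a cohort from fixed per-population per-SNP minor-allele
    frequencies (rows of ``truth``: populations; columns: SNPs).

    Used to draw train and test cohorts from the same underlying
    populations.
    """
    truth = np.asarray(truth, dtype=float)
    K, L = truth.shape
    if L != len(snps):
        raise ValueError("truth width != number of SNPs")
    counts = ((samples_per_population,) * K
              if isinstance(samples_per_population, int)
              else tuple(samples_per_population))
    pop_names = tuple(pop_names) if pop_names else tuple(
        f"POP{k + 1}" for k in range(K))
    rng = np.random.default_rng(seed)
    blocks, samples, assignment = [], [], {}
    for k in range(K):
        dosage = rng.binomial(2, truth[k], size=(counts[k], L)).astype(np.int8)
        blocks.append(dosage)
        for i in range(counts[k]):
            sid = f"{pop_names[k]}_{sample_prefix}{i:04d}"
            samples.append(sid)
            assignment[sid] = pop_names[k]
    calls = np.concatenate(blocks, axis=0)
    if nocall_rate > 0:
        mask = rng.random(calls.shape) < nocall_rate
        calls[mask] = NOCALL
    matrix = GenotypeMatrix(tuple(samples), snps, calls)
    labels = PopulationLabels(pop_names, assignment)
    return matrix, labels


def simulate_populations(spec: SyntheticSpec) -> tuple[GenotypeMatrix,
                                                       PopulationLabels,
                                                       np.ndarray]:
    """Simulate K diverged populations; returns (matrix, labels, truth).

    ``truth`` is the (K, L) array of per-population minor-allele frequencies
    actually used, so tests can verify the generator's marginals.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_snps + spec.nonautosomal_snps
    snps = _make_snps(spec.n_snps, spec.nonautosomal_snps, rng)
    lo, hi = spec.ancestral_freq_range
    pi = rng.uniform(lo, hi, size=L)
    truth = np.empty((spec.n_populations, L))
    for k, F in enumerate(spec._fst_list()):
        if F == 0.0:
            truth[k] = pi
        else:
            c = (1.0 - F) / F
            truth[k] = rng.beta(pi * c, (1.0 - pi) * c)
    matrix, labels = simulate_from_truth(
        snps, truth, spec._counts(), spec.nocall_rate,
        seed=int(rng.integers(2**31)))
    return matrix, labels, truth


def simulate_case_control(spec: CaseControlSpec) -> tuple[GenotypeMatrix,
                                                          PopulationLabels,
                                                          dict[str, int],
                                                          np.ndarray]:
    """Simulate a stratified case–control cohort.

    Returns (matrix, labels, phenotypes, truth) where ``phenotypes`` maps
    sample id to 1 (case) or 0 (control), drawn per sample from its
    population's case fraction.
    """
    matrix, labels, truth = simulate_populations(spec)
    rng = np.random.default_rng(spec.seed + 1)
    frac = dict(zip(labels.class_order, spec.case_fraction_per_population))
    phenotypes = {s: int(rng.random() < frac[labels.assignment[s]])
                  for s in matrix.samples}
    return matrix, labels, phenotypes, truth
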