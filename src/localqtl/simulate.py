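"""Synthetic population generator: pedigree, LD-structured genotypes, QTL, phenotypes.

The generator emulates the statistical structure of a cattle breeding
population genotyped at two panel densities: a multi-generation pedigree, LD
that decays with physical distance, a dense panel and a 14x sparser panel
over the same genome, QTL taken as every m-th ordered SNP of the sparse
panel, and noiseless (h² = 1) phenotypes equal to a QTL dosage or the sum of
all QTL dosages.

Founder haplotypes follow a Gaussian-copula first-order Markov process along
each chromosome: a latent AR(1) with per-interval correlation
``ld_rho ** (distance_bp / reference_distance)`` is thresholded at the
allele-frequency quantile, so marginal allele frequencies are exact and
allele correlation decays monotonically with physical distance.
Descendants receive recombinant parental gametes (gene dropping) under a
Haldane map at 1 cM/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import (
    UNKNOWN_PARENT,
    DataValidationError,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    PhenotypeVector,
    QTLSet,
)

__all__ = [
    "make_marker_map",
    "simulate_pedigree",
    "simulate_founder_haplotypes",
    "FounderHaplotypes",
    "gene_drop",
    "select_qtl",
    "simulate_phenotype",
    "maf",
    "thin_panel",
    "simulate_study",
    "StudyData",
]


def make_marker_map(
    n_chromosomes: int = 10,
    markers_per_chromosome: int = 500,
    spacing_bp: int = 50_000,
    prefix: str = "SNP",
) -> MarkerMap:
    """Evenly spaced multi-chromosome map; markers named ``{prefix}_{chrom}_{i}``."""
    import pandas as pd

    rows = []
    for c in range(1, n_chromosomes + 1):
        for i in range(markers_per_chromosome):
            rows.append((f"{prefix}_{c}_{i + 1}", c, (i + 1) * spacing_bp))
    return MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"]))


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_mating: int,
    seed: int,
) -> Pedigree:
    """Random-mating multi-generation pedigree.

    Founders have unknown parents.  Each later generation is produced by
    pairing the previous generation into sire x dam matings at random (half
    the generation serves as sires, half as dams) with
    ``offspring_per_mating`` offspring each.  Deterministic given ``seed``.
    """
    if n_founders < 2 or n_founders % 2:
        raise ValueError("n_founders must be an even integer >= 2")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if offspring_per_mating < 1:
        raise ValueError("offspring_per_mating must be >= 1")
    rng = np.random.default_rng(seed)

    ids = [f"G0I{i + 1:05d}" for i in range(n_founders)]
    sire = [UNKNOWN_PARENT] * n_founders
    dam = [UNKNOWN_PARENT] * n_founders
    gen = [0] * n_founders
    prev = list(range(n_founders))

    for g in range(1, n_generations + 1):
        order = rng.permutation(len(prev))
        half = len(prev) // 2
        sires = [prev[i] for i in order[:half]]
        dams = [prev[i] for i in order[half : 2 * half]]
        newborn = []
        child = 0
        for s, d in zip(sires, dams):
            for _ in range(offspring_per_mating):
                child += 1
                newborn.append(len(ids))
                ids.append(f"G{g}I{child:05d}")
                sire.append(s)
                dam.append(d)
                gen.append(g)
        prev = newborn

    return Pedigree(ids, np.array(sire), np.array(dam), np.array(gen))


@dataclass
class FounderHaplotypes:
    """Phased founder haplotypes: alleles[f, h, j] in {0, 1}, h in {0, 1}."""

    alleles: np.ndarray  # (n_founders, 2, n_markers) uint8
    allele_freq: np.ndarray  # frequency of allele 1 per marker
    map: MarkerMap

    @property
    def n_founders(self) -> int:
        return self.alleles.shape[0]


def simulate_founder_haplotypes(
    marker_map: MarkerMap,
    n_founders: int,
    maf_low: float,
    maf_high: float,
    ld_rho: float,
    seed: int,
    reference_distance: float | None = None,
) -> FounderHaplotypes:
    """Draw founder haplotypes with distance-decaying LD.

    Allele-1 frequencies are uniform on [maf_low, maf_high].  Along each
    chromosome a latent standard-normal AR(1) with per-interval correlation
    ``ld_rho ** (d_bp / reference_distance)`` is thresholded at the
    allele-frequency quantile; chromosomes are independent.  With
    ``ld_rho = 0`` all markers are independent.  ``reference_distance``
    defaults to the mean adjacent within-chromosome spacing.
    """
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("need 0 <= ld_rho < 1")
    rng = np.random.default_rng(seed)
    p = len(marker_map)
    chrom = marker_map.chromosomes
    pos = marker_map.positions_bp.astype(np.float64)

    gaps = np.diff(pos)
    within = np.diff(chrom) == 0
    if reference_distance is None:
        if not within.any():
            reference_distance = 1.0
        else:
            reference_distance = float(gaps[within].mean())

    # latent AR(1) coefficient per interval; 0 at chromosome boundaries
    r = np.zeros(p)
    if p > 1:
        r[1:][within] = ld_rho ** (gaps[within] / reference_distance)

    freq = rng.uniform(maf_low, maf_high, size=p)
    thresh = stats.norm.ppf(freq)

    n_hap = 2 * n_founders
    z = np.empty((n_hap, p))
    eps = rng.standard_normal((n_hap, p))
    z[:, 0] = eps[:, 0]
    for j in range(1, p):
        z[:, j] = r[j] * z[:, j - 1] + np.sqrt(1.0 - r[j] ** 2) * eps[:, j]

    alleles = (z < thresh).astype(np.uint8).reshape(n_founders, 2, p)
    return FounderHaplotypes(alleles, freq, marker_map)


def _recombination_fractions(marker_map: MarkerMap, cm_per_mb: float) -> np.ndarray:
    """Per-interval Haldane crossover probability; 0.5 at chromosome starts.

    The leading 0.5 makes the starting parental haplotype of each chromosome
    an independent coin flip, so one Bernoulli vector per gamete encodes both
    chromosome starts and crossovers.
    """
    p = len(marker_map)
    c = np.full(p, 0.5)
    if p > 1:
        gaps = np.diff(marker_map.positions_bp.astype(np.float64))
        within = np.diff(marker_map.chromosomes) == 0
        d_morgan = gaps * cm_per_mb / 1e6 / 100.0
        c[1:][within] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan[within]))
    return c


def gene_drop(
    founders: FounderHaplotypes,
    pedigree: Pedigree,
    marker_map: MarkerMap,
    seed: int,
    cm_per_mb: float = 1.0,
    return_haplotypes: bool = False,
):
    """Drop founder haplotypes through the pedigree with recombination.

    Each non-founder inherits one recombinant gamete per parent;
    recombination between adjacent markers follows Haldane's map function
    c = 0.5·(1 − exp(−2d)) with d in Morgans (``cm_per_mb`` cM per Mb,
    default 1).  Returns a :class:`GenotypeMatrix` of dosages (and the full
    phased haplotypes when ``return_haplotypes``).
    """
    if len(founders.map) != len(marker_map):
        raise DataValidationError("founder haplotypes and map disagree on marker count")
    founder_rows = np.flatnonzero(pedigree.is_founder)
    if len(founder_rows) != founders.n_founders:
        raise DataValidationError(
            f"pedigree has {len(founder_rows)} founders but haplotypes for {founders.n_founders}"
        )
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    p = len(marker_map)
    c = _recombination_fractions(marker_map, cm_per_mb)

    hap = np.empty((n, 2, p), dtype=np.uint8)
    founder_of = {row: k for k, row in enumerate(founder_rows)}
    for i in range(n):
        if pedigree.sire[i] == UNKNOWN_PARENT and pedigree.dam[i] == UNKNOWN_PARENT:
            hap[i] = founders.alleles[founder_of[i]]
            continue
        for which, parent in ((0, pedigree.sire[i]), (1, pedigree.dam[i])):
            if parent == UNKNOWN_PARENT:
                raise DataValidationError("half-unknown parentage is not supported")
            switch = rng.random(p) < c
            choose = np.cumsum(switch) % 2  # which parental haplotype at each marker
            hap[i, which] = hap[parent][choose, np.arange(p)]

    dosage = hap.sum(axis=1).astype(np.int8)
    geno = GenotypeMatrix(dosage, list(pedigree.ids), marker_map)
    if return_haplotypes:
        return geno, hap
    return geno


def select_qtl(genotypes: GenotypeMatrix, spacing_m: int) -> QTLSet:
    """Designate every ``spacing_m``-th ordered SNP as a QTL, dropping monomorphic ones.

    Candidates are the markers at 1-based panel positions m, 2m, ...;
    candidates that are monomorphic in the population are removed (the
    synthetic analogue of retaining only polymorphic candidate QTL).
    """
    if spacing_m < 2:
        raise ValueError("spacing_m must be >= 2")
    candidates = np.arange(spacing_m, genotypes.n_markers + 1, spacing_m) - 1
    mafs = genotypes.maf()[candidates]
    kept = candidates[mafs > 0]
    if len(kept) == 0:
        raise ValueError("all candidate QTL are monomorphic")
    return QTLSet(kept, spacing_m)


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    qtl: QTLSet,
    mode: str,
    target_qtl: int | None = None,
) -> PhenotypeVector:
    """Noiseless phenotype: one QTL dosage column, or the dosage sum over all QTL.

    No residual is ever added, so heritability is exactly 1 and prediction
    accuracy measures recovery of genetic merit itself.
    """
    if mode == "single":
        if target_qtl is None:
            raise ValueError("single mode requires target_qtl")
        if target_qtl not in qtl.indices:
            raise ValueError(f"target_qtl {target_qtl} not in the QTL set")
        y = genotypes.dosage[:, target_qtl].astype(np.float64)
    elif mode == "summed":
        y = genotypes.dosage[:, qtl.indices].sum(axis=1).astype(np.float64)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PhenotypeVector(y, mode, qtl, target_qtl)


def maf(dosage_column: np.ndarray) -> float:
    """Minor allele frequency of one dosage column: min(f, 1 − f), f = Σdosage / 2n."""
    col = np.asarray(dosage_column, dtype=np.float64)
    if col.size == 0:
        raise ValueError("empty dosage column")
    f = col.sum() / (2.0 * col.size)
    return float(min(f, 1.0 - f))


def thin_panel(
    genotypes: GenotypeMatrix,
    keep_every: int,
    qtl: QTLSet | None = None,
) -> GenotypeMatrix:
    """Sparse-panel analogue: keep every ``keep_every``-th marker in panel order.

    Designated QTL markers are always retained so both densities share the
    QTL.  ``keep_every = 1`` returns an identical matrix.
    """
    if keep_every < 1:
        raise ValueError("keep_every must be >= 1")
    keep = np.arange(0, genotypes.n_markers, keep_every)
    if qtl is not None:
        keep = np.union1d(keep, qtl.indices)
    return genotypes.subset_markers(keep)


@dataclass
class StudyData:
    """One simulated study: pedigree, dense + sparse panels sharing a QTL set."""

    pedigree: Pedigree
    dense: GenotypeMatrix | None
    sparse: GenotypeMatrix
    qtl_sparse: QTLSet
    qtl_dense: QTLSet | None

    def panel(self, name: str) -> tuple[GenotypeMatrix, QTLSet]:
        if name == "sparse":
            return self.sparse, self.qtl_sparse
        if name == "dense":
            if self.dense is None:
                raise ValueError("study was simulated without a dense panel")
            return self.dense, self.qtl_dense
        raise ValueError(f"unknown panel {name!r}")


def simulate_study(
    seed: int,
    n_founders: int = 200,
    n_generations: int = 4,
    offspring_per_mating: int = 2,
    n_chromosomes: int = 10,
    markers_per_chromosome: int = 500,
    spacing_bp: int = 50_000,
    density_ratio: int = 1,
    qtl_spacing: int = 250,
    maf_low: float = 0.01,
    maf_high: float = 0.5,
    ld_rho: float = 0.9,
    reference_distance: float = 50_000.0,
    cm_per_mb: float = 1.0,
) -> StudyData:
    """End-to-end simulation of a two-density study population.

    The genome is laid out at the *dense* spacing ``spacing_bp /
    density_ratio`` with ``markers_per_chromosome * density_ratio`` markers
    per chromosome; the sparse panel keeps every ``density_ratio``-th marker
    (50 K-like), emulating a 14:1 dense:sparse density ratio when
    ``density_ratio = 14``.  QTL are every ``qtl_spacing``-th ordered SNP of
    the *sparse* panel.  With ``density_ratio = 1`` only the sparse panel is
    produced.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)

    dense_map = make_marker_map(
        n_chromosomes,
        markers_per_chromosome * density_ratio,
        max(spacing_bp // density_ratio, 1),
    )
    ped = simulate_pedigree(n_founders, n_generations, offspring_per_mating, int(seeds[0]))
    founders = simulate_founder_haplotypes(
        dense_map, ped.n_founders, maf_low, maf_high, ld_rho, int(seeds[1]),
        reference_distance=reference_distance,
    )
    dense = gene_drop(founders, ped, dense_map, int(seeds[2]), cm_per_mb=cm_per_mb)

    if density_ratio == 1:
        sparse = dense
        qtl_sparse = select_qtl(sparse, qtl_spacing)
        return StudyData(ped, None, sparse, qtl_sparse, None)

    sparse = thin_panel(dense, density_ratio)
    qtl_sparse = select_qtl(sparse, qtl_spacing)
    qtl_dense = qtl_sparse.in_panel(sparse.map, dense.map)
    return StudyData(ped, dense, sparse, qtl_sparse, qtl_dense)
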