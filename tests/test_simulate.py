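"""Synthetic-data generator: pedigrees, LD decay, gene dropping, QTL, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from localqtl.datatypes import UNKNOWN_PARENT, MarkerMap, GenotypeMatrix, Pedigree, QTLSet
from localqtl.simulate import (
    FounderHaplotypes,
    _recombination_fractions,
    gene_drop,
    maf,
    make_marker_map,
    select_qtl,
    simulate_founder_haplotypes,
    simulate_pedigree,
    simulate_phenotype,
    simulate_study,
    thin_panel,
)


def _hap_r2(alleles: np.ndarray, i: int, j: int) -> float:
    """Squared allele correlation between two loci over a haplotype sample."""
    a, b = alleles[:, i].astype(float), alleles[:, j].astype(float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


class TestPedigree:
    def test_two_founders_one_mating(self):
        ped = simulate_pedigree(2, 1, 1, seed=0)
        assert len(ped) == 3
        assert set(ped.ids[:2]) == {"G0I00001", "G0I00002"}
        assert {ped.sire[2], ped.dam[2]} == {0, 1}

    @pytest.mark.parametrize(
        "founders,gens,off",
        [(10, 0, 2), (1, 1, 1), (3, 1, 1), (4, 1, 0)],
    )
    def test_preconditions_rejected(self, founders, gens, off):
        with pytest.raises(ValueError):
            simulate_pedigree(founders, gens, off, seed=1)

    def test_seed_determinism(self):
        a = simulate_pedigree(20, 3, 2, seed=7)
        b = simulate_pedigree(20, 3, 2, seed=7)
        assert a.ids == b.ids
        assert (a.sire == b.sire).all() and (a.dam == b.dam).all()

    def test_generation_structure(self):
        ped = simulate_pedigree(20, 2, 2, seed=1)
        assert ped.n_founders == 20
        assert (ped.generation[ped.is_founder] == 0).all()
        # every non-founder's parents are in the previous generation
        nf = ~ped.is_founder
        for i in np.flatnonzero(nf):
            assert ped.generation[ped.sire[i]] == ped.generation[i] - 1
            assert ped.generation[ped.dam[i]] == ped.generation[i] - 1


class TestFounderHaplotypes:
    def test_degenerate_frequency_bounds_rejected(self, tiny_map):
        with pytest.raises(ValueError):
            simulate_founder_haplotypes(tiny_map, 10, 0.0, 0.5, 0.5, seed=1)
        with pytest.raises(ValueError):
            simulate_founder_haplotypes(tiny_map, 10, 0.3, 0.2, 0.5, seed=1)
        with pytest.raises(ValueError):
            simulate_founder_haplotypes(tiny_map, 10, 0.1, 0.5, 1.0, seed=1)

    def test_fixed_half_frequency_recovered(self, tiny_map):
        h = simulate_founder_haplotypes(tiny_map, 5000, 0.5, 0.5, 0.0, seed=2)
        realized = h.alleles.reshape(10_000, len(tiny_map)).mean(axis=0)
        se = np.sqrt(0.25 / 10_000)
        assert (np.abs(realized - 0.5) < 3 * se + 1e-12).all()

    def test_rho_zero_gives_independence(self, tiny_map):
        h = simulate_founder_haplotypes(tiny_map, 5000, 0.2, 0.5, 0.0, seed=3)
        alleles = h.alleles.reshape(10_000, len(tiny_map))
        r2 = [_hap_r2(alleles, j, j + 1) for j in range(9)]
        # under independence E[r2] ~ 1/(n-1); allow generous slack
        assert np.nanmean(r2) < 5.0 / 10_000

    def test_adjacent_r2_exceeds_distant(self):
        mm = make_marker_map(1, 60, 50_000)
        h = simulate_founder_haplotypes(mm, 5000, 0.1, 0.5, 0.95, seed=4,
                                        reference_distance=50_000)
        alleles = h.alleles.reshape(10_000, 60)
        adj = np.nanmean([_hap_r2(alleles, j, j + 1) for j in range(59)])
        far = np.nanmean([_hap_r2(alleles, j, j + 50) for j in range(10)])
        assert adj > far

    def test_r2_decay_monotone_in_binned_distance(self):
        """Mean r2 is non-increasing over distance bins up to sampling noise."""
        mm = make_marker_map(1, 60, 50_000)
        h = simulate_founder_haplotypes(mm, 5000, 0.1, 0.5, 0.9, seed=5,
                                        reference_distance=50_000)
        alleles = h.alleles.reshape(10_000, 60)
        by_sep = []
        for sep in (1, 2, 5, 10, 25, 50):
            vals = [_hap_r2(alleles, j, j + sep) for j in range(0, 60 - sep, 3)]
            by_sep.append(np.nanmean(vals))
        assert (np.diff(by_sep) <= 0.01).all()

    def test_chromosomes_independent(self, tiny_map):
        h = simulate_founder_haplotypes(tiny_map, 5000, 0.3, 0.5, 0.95, seed=6)
        alleles = h.alleles.reshape(10_000, 20)
        # last marker of chr1 vs first of chr2
        assert _hap_r2(alleles, 9, 10) < 5.0 / 10_000


class TestGeneDrop:
    def _forced_founders(self, tiny_map, codes):
        """Two founders with constant haplotypes given by per-founder allele codes."""
        p = len(tiny_map)
        alleles = np.stack(
            [np.stack([np.full(p, a, np.uint8), np.full(p, b, np.uint8)]) for a, b in codes]
        )
        return FounderHaplotypes(alleles, np.full(p, 0.5), tiny_map)

    def test_forced_transmission(self, tiny_map):
        ped = simulate_pedigree(2, 1, 1, seed=0)
        # both parents homozygous 1/1 -> offspring dosage 2 everywhere
        founders = self._forced_founders(tiny_map, [(1, 1), (1, 1)])
        geno = gene_drop(founders, ped, tiny_map, seed=1)
        assert (geno.dosage[2] == 2).all()
        # parents 0/0 and 1/1 -> offspring dosage 1 everywhere
        founders = self._forced_founders(tiny_map, [(0, 0), (1, 1)])
        geno = gene_drop(founders, ped, tiny_map, seed=1)
        assert (geno.dosage[2] == 1).all()

    def test_zero_map_distance_coinherits(self, tiny_map):
        """With a null genetic map each chromosome is transmitted whole."""
        ped = simulate_pedigree(2, 1, 1, seed=3)
        rng = np.random.default_rng(0)
        alleles = rng.integers(0, 2, size=(2, 2, len(tiny_map))).astype(np.uint8)
        founders = FounderHaplotypes(alleles, np.full(len(tiny_map), 0.5), tiny_map)
        _, hap = gene_drop(founders, ped, tiny_map, seed=5, cm_per_mb=0.0,
                           return_haplotypes=True)
        for parent, gamete in ((ped.sire[2], hap[2, 0]), (ped.dam[2], hap[2, 1])):
            for chrom in (1, 2):
                idx = tiny_map.chromosome_indices(chrom)
                match0 = (gamete[idx] == hap[parent, 0, idx]).all()
                match1 = (gamete[idx] == hap[parent, 1, idx]).all()
                assert match0 or match1

    def test_mendelian_consistency(self, small_study):
        """Every transmitted allele exists in the parent at that locus."""
        from localqtl.simulate import simulate_founder_haplotypes, simulate_pedigree

        ped = simulate_pedigree(20, 2, 2, seed=9)
        mm = make_marker_map(2, 40, 50_000)
        founders = simulate_founder_haplotypes(mm, 20, 0.1, 0.5, 0.9, seed=10)
        _, hap = gene_drop(founders, ped, mm, seed=11, return_haplotypes=True)
        for i in np.flatnonzero(~ped.is_founder):
            for which, parent in ((0, ped.sire[i]), (1, ped.dam[i])):
                ok = (hap[i, which] == hap[parent, 0]) | (hap[i, which] == hap[parent, 1])
                assert ok.all()

    def test_recombination_fractions(self, tiny_map):
        c = _recombination_fractions(tiny_map, cm_per_mb=1.0)
        assert c[0] == 0.5 and c[10] == 0.5  # chromosome starts
        d = 50_000 / 1e6 / 100  # Morgans between adjacent markers
        assert np.isclose(c[1], 0.5 * (1 - np.exp(-2 * d)))

    def test_missing_founder_haplotypes_rejected(self, tiny_map):
        ped = simulate_pedigree(4, 1, 1, seed=0)
        founders = self._forced_founders(tiny_map, [(0, 0), (1, 1)])  # only 2 of 4
        with pytest.raises(Exception):
            gene_drop(founders, ped, tiny_map, seed=0)


class TestQTLAndPhenotype:
    def test_every_mth_marker(self):
        mm = make_marker_map(1, 5000, 1000)
        dosage = np.ones((4, 5000), dtype=np.int8)
        dosage[0] = 0  # polymorphic everywhere
        geno = GenotypeMatrix(dosage, ["a", "b", "c", "d"], mm)
        qtl = select_qtl(geno, 100)
        assert len(qtl) == 50
        assert (qtl.indices == np.arange(100, 5001, 100) - 1).all()

    def test_candidate_count_at_scale(self):
        # 54,555 ordered markers at spacing 1000 yield 54 candidates
        assert len(np.arange(1000, 54_555 + 1, 1000)) == 54

    def test_monomorphic_candidates_dropped(self):
        mm = make_marker_map(1, 100, 1000)
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(10, 100)).astype(np.int8)
        dosage[:, 19] = 0  # first candidate monomorphic
        geno = GenotypeMatrix(dosage, [f"i{k}" for k in range(10)], mm)
        qtl = select_qtl(geno, 20)
        assert len(qtl) == 4
        assert 19 not in qtl.indices

    def test_single_mode_equals_dosage_column(self, small_study):
        d = small_study
        q = int(d.qtl_sparse.indices[0])
        ph = simulate_phenotype(d.sparse, d.qtl_sparse, "single", q)
        assert (ph.y == d.sparse.dosage[:, q]).all()
        assert np.corrcoef(ph.y, d.sparse.dosage[:, q])[0, 1] == 1.0

    def test_summed_mode(self):
        mm = make_marker_map(1, 4, 1000)
        dosage = np.array([[0, 0, 2, 0], [1, 0, 1, 0]], dtype=np.int8)
        geno = GenotypeMatrix(dosage, ["a", "b"], mm)
        qtl = QTLSet(np.array([0, 2]), spacing_m=2)
        ph = simulate_phenotype(geno, qtl, "summed")
        assert (ph.y == [2, 2]).all()

    def test_single_requires_target(self, small_study):
        with pytest.raises(ValueError):
            simulate_phenotype(small_study.sparse, small_study.qtl_sparse, "single")

    @pytest.mark.parametrize(
        "column,expected",
        [((0, 1, 2, 2, 1), 0.4), ((0, 0, 0), 0.0), ((1, 1, 1, 1), 0.5)],
    )
    def test_maf(self, column, expected):
        assert maf(np.array(column)) == pytest.approx(expected)


class TestThinPanel:
    def test_identity(self, small_study):
        out = thin_panel(small_study.sparse, 1)
        assert (out.dosage == small_study.sparse.dosage).all()

    def test_arithmetic(self):
        mm = make_marker_map(1, 1400, 1000)
        dosage = np.zeros((2, 1400), dtype=np.int8)
        dosage[0] = 1
        geno = GenotypeMatrix(dosage, ["a", "b"], mm)
        assert thin_panel(geno, 14).n_markers == 100

    def test_qtl_always_retained(self):
        mm = make_marker_map(1, 100, 1000)
        dosage = np.tile(np.array([0, 1], dtype=np.int8)[:, None], (1, 100))
        geno = GenotypeMatrix(dosage, ["a", "b"], mm)
        qtl = QTLSet(np.array([13]), spacing_m=14)  # not divisible by keep_every
        out = thin_panel(geno, 14, qtl=qtl)
        assert "SNP_1_14" in out.map.marker_ids


class TestStudy:
    def test_seed_determinism(self):
        kw = dict(n_founders=20, n_generations=2, n_chromosomes=2,
                  markers_per_chromosome=30, qtl_spacing=10)
        a = simulate_study(seed=5, **kw)
        b = simulate_study(seed=5, **kw)
        assert (a.sparse.dosage == b.sparse.dosage).all()
        assert (a.qtl_sparse.indices == b.qtl_sparse.indices).all()

    def test_two_density_panels_share_qtl(self):
        d = simulate_study(seed=8, n_founders=20, n_generations=2, n_chromosomes=2,
                           markers_per_chromosome=20, density_ratio=14, qtl_spacing=10)
        assert d.dense.n_markers == 14 * d.sparse.n_markers
        sparse_ids = d.qtl_sparse.marker_ids(d.sparse.map)
        dense_ids = d.qtl_dense.marker_ids(d.dense.map)
        assert list(sparse_ids) == list(dense_ids)
        # same dosages at the shared QTL columns
        assert (d.sparse.dosage[:, d.qtl_sparse.indices]
                == d.dense.dosage[:, d.qtl_dense.indices]).all()
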