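"""LD coefficients, EM haplotype frequencies and block collapsing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locushub.ld import (
    LdPair,
    LdUndefinedError,
    MissingLdError,
    Locus,
    Snp,
    collapse_blocks,
    estimate_haplotype_freqs,
    haplotype_freqs_phased,
    ld_pair,
    ld_pairs_from_genotypes,
    ld_pairs_from_haplotypes,
    name_locus,
)


def _snps(n, chrom="1", spacing=1000):
    return [Snp(f"rs{i}", chrom, 1000 + i * spacing) for i in range(n)]


def _pair(a, b, r2=0.0, d_prime=0.0):
    return LdPair(a, b, 0.5, 0.5, 0.25, 0.0, d_prime, r2)


class TestLdPair:
    @pytest.mark.parametrize(
        "p_a,p_b,p_ab,d,d_prime,r2",
        [
            (0.5, 0.5, 0.5, 0.25, 1.0, 1.0),  # perfect LD
            (0.5, 0.5, 0.25, 0.0, 0.0, 0.0),  # equilibrium
            (0.5, 0.5, 0.4, 0.15, 0.6, 0.36),  # hand arithmetic
        ],
    )
    def test_known_triples(self, p_a, p_b, p_ab, d, d_prime, r2):
        pair = ld_pair(p_a, p_b, p_ab)
        assert pair.d == pytest.approx(d, abs=1e-12)
        assert pair.d_prime == pytest.approx(d_prime, abs=1e-12)
        assert pair.r2 == pytest.approx(r2, abs=1e-12)

    def test_monomorphic_is_undefined_not_numeric_failure(self):
        with pytest.raises(LdUndefinedError):
            ld_pair(0.0, 0.5, 0.0)
        with pytest.raises(LdUndefinedError):
            ld_pair(0.5, 1.0, 0.5)

    @given(
        p_a=st.floats(0.01, 0.99),
        p_b=st.floats(0.01, 0.99),
        t=st.floats(0.0, 1.0),
    )
    @settings(max_examples=300, derandomize=True)
    def test_bounds_hold_for_any_valid_triple(self, p_a, p_b, t):
        lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
        p_ab = lo + t * (hi - lo)
        pair = ld_pair(p_a, p_b, p_ab)
        assert 0.0 <= pair.r2 <= 1.0
        assert 0.0 <= pair.d_prime <= 1.0
        assert pair.r2 <= pair.d_prime**2 + 1e-9


class TestHaplotypeFreqs:
    def test_phased_direct_count(self):
        hap_a = np.array([1] * 50 + [0] * 50)
        hap_b = np.array([1] * 50 + [0] * 50)
        assert haplotype_freqs_phased(hap_a, hap_b) == (0.5, 0.5, 0.5)

    def test_phased_all_four_haplotypes_equal(self):
        hap_a = np.array([1, 1, 0, 0] * 25)
        hap_b = np.array([1, 0, 1, 0] * 25)
        p_a, p_b, p_ab = haplotype_freqs_phased(hap_a, hap_b)
        assert (p_a, p_b, p_ab) == (0.5, 0.5, 0.25)

    def test_em_matches_grid_search_oracle(self):
        """EM on a double-heterozygote-rich table vs exhaustive likelihood grid."""
        rng = np.random.default_rng(11)
        # generate genotypes from known haplotype frequencies with real LD
        p11, p10, p01, p00 = 0.35, 0.15, 0.15, 0.35
        haps = rng.choice(4, size=(400, 2), p=[p11, p10, p01, p00])
        allele_a = (haps < 2).astype(int)  # haplotypes 0,1 carry allele A
        allele_b = ((haps == 0) | (haps == 2)).astype(int)
        geno_a, geno_b = allele_a.sum(1), allele_b.sum(1)
        p_a, p_b, p_ab = estimate_haplotype_freqs(geno_a, geno_b)

        # oracle: maximize the multinomial genotype likelihood over a p_AB grid
        counts = np.zeros((3, 3))
        for i, j in zip(geno_a, geno_b):
            counts[i, j] += 1

        def loglik(pab):
            h = np.array(
                [pab, p_a - pab, p_b - pab, 1 - p_a - p_b + pab]
            )
            if (h <= 0).any():
                return -np.inf
            # genotype probabilities under random union of haplotypes
            probs = np.zeros((3, 3))
            hap_allele_a = np.array([1, 1, 0, 0])
            hap_allele_b = np.array([1, 0, 1, 0])
            for x in range(4):
                for y in range(4):
                    probs[hap_allele_a[x] + hap_allele_a[y], hap_allele_b[x] + hap_allele_b[y]] += h[x] * h[y]
            return float((counts * np.log(probs + 1e-300)).sum())

        lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
        grid = np.linspace(lo + 1e-9, hi - 1e-9, 200001)
        best = grid[int(np.argmax([loglik(g) for g in grid[:: 1000]]) * 1000)]
        fine = grid[(grid > best - 0.01) & (grid < best + 0.01)]
        best = fine[np.argmax([loglik(g) for g in fine])]
        assert p_ab == pytest.approx(best, abs=1e-4)

    def test_em_monomorphic_raises(self):
        with pytest.raises(LdUndefinedError):
            estimate_haplotype_freqs(np.zeros(20), np.array([0, 1, 2, 1] * 5))

    def test_phased_and_em_agree_on_large_samples(self):
        """Unphased EM converges to the phased LD as n grows.

        The two estimates differ only through double-heterozygote phase
        resolution, a sampling effect of order 1/sqrt(n); at n = 5000 the
        residual gap is within 0.01 on r2 and D'.
        """
        from locushub.sim import SimulationConfig, simulate_genotypes

        cfg = SimulationConfig(
            snp_map=[("rs0", "1", 1000), ("rs1", "1", 2000)],
            n_populations=1,
            n_samples_per_pop=5000,
            block_spec=[([0, 1], 0.7)],
            seed=5,
        )
        panel = simulate_genotypes(cfg)["pop1"]
        snps = _snps(2)
        phased = ld_pairs_from_haplotypes(snps, panel.haplotypes, panel.snp_ids)
        em = ld_pairs_from_genotypes(snps, panel.dosages.astype(float), panel.snp_ids)
        key = frozenset(("rs0", "rs1"))
        assert em[key].r2 == pytest.approx(phased[key].r2, abs=1e-2)
        assert em[key].d_prime == pytest.approx(phased[key].d_prime, abs=1e-2)


class TestCollapseBlocks:
    def test_full_ld_merges_all(self):
        snps = _snps(3)
        ld = {
            frozenset((a.rsid, b.rsid)): _pair(a.rsid, b.rsid, r2=1.0, d_prime=1.0)
            for a, b in itertools.combinations(snps, 2)
        }
        loci = collapse_blocks(snps, ld)
        assert len(loci) == 1 and loci[0].member_snps == ["rs0", "rs1", "rs2"]

    def test_no_ld_keeps_singletons(self):
        snps = _snps(3)
        ld = {
            frozenset((a.rsid, b.rsid)): _pair(a.rsid, b.rsid)
            for a, b in itertools.combinations(snps, 2)
        }
        assert len(collapse_blocks(snps, ld)) == 3

    def test_chain_closes_transitively(self):
        snps = _snps(3)
        ld = {
            frozenset(("rs0", "rs1")): _pair("rs0", "rs1", r2=0.9),
            frozenset(("rs1", "rs2")): _pair("rs1", "rs2", d_prime=0.85),
            frozenset(("rs0", "rs2")): _pair("rs0", "rs2", r2=0.1),
        }
        loci = collapse_blocks(snps, ld)
        assert len(loci) == 1 and loci[0].member_snps == ["rs0", "rs1", "rs2"]

    def test_missing_entry_is_an_error_not_a_missing_edge(self):
        snps = _snps(2)
        with pytest.raises(MissingLdError):
            collapse_blocks(snps, {})

    def test_undefined_ld_entry_is_tolerated(self):
        snps = _snps(2)
        loci = collapse_blocks(snps, {frozenset(("rs0", "rs1")): None})
        assert len(loci) == 2

    def test_cross_chromosome_never_merges(self):
        snps = [Snp("rs0", "1", 1000), Snp("rs1", "2", 1000)]
        assert len(collapse_blocks(snps, {})) == 2

    def test_gwas_flag_propagates(self):
        snps = [Snp("rs0", "1", 1000, gwas_flag=True), Snp("rs1", "1", 1500)]
        ld = {frozenset(("rs0", "rs1")): _pair("rs0", "rs1", r2=0.95)}
        (locus,) = collapse_blocks(snps, ld)
        assert locus.gwas_flag

    def test_raising_thresholds_only_refines(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            snps = _snps(n)
            ld = {}
            for a, b in itertools.combinations(snps, 2):
                r2 = float(rng.random())
                ld[frozenset((a.rsid, b.rsid))] = _pair(
                    a.rsid, b.rsid, r2=r2, d_prime=float(np.sqrt(r2))
                )
            loose = collapse_blocks(snps, ld, r2_min=0.5, dprime_min=0.5)
            tight = collapse_blocks(snps, ld, r2_min=0.8, dprime_min=0.8)
            loose_of = {s: i for i, l in enumerate(loose) for s in l.member_snps}
            for locus in tight:  # each tight locus sits inside one loose locus
                assert len({loose_of[s] for s in locus.member_snps}) == 1


class TestNameLocus:
    annotation = [
        ("CELSR2", "1", 109_792_000, 109_818_000),
        ("PSRC1", "1", 109_822_000, 109_826_000),
        ("PANK1", "10", 91_340_000, 91_400_000),
    ]

    def test_two_gene_span_joined_in_genomic_order(self):
        locus = Locus("", "1", 109_800_000, 109_824_000)
        assert name_locus(locus, self.annotation) == "CELSR2/PSRC1"

    def test_no_gene_falls_back_to_coordinates(self):
        locus = Locus("", "10", 91_352_000, 91_353_000)
        assert name_locus(locus, []) == "10:91352000-91353000"

    def test_single_gene(self):
        locus = Locus("", "10", 91_352_850, 91_352_850)
        assert name_locus(locus, self.annotation) == "PANK1"
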