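import itertools
import math

import numpy as np
import pytest

from pooldyn import formats, popgen
from pooldyn.popgen import (
    PoolSpec,
    WindowSpec,
    classify_coding_sites,
    delta_theta,
    make_site_state,
    site_pi,
    tajima_d,
    window_pi_syn_nonsyn,
    window_stats,
)


def brute_force_pairwise(counts):
    """Mean pairwise difference over all read pairs — independent oracle."""
    reads = []
    for base, n in zip("ATCG", counts):
        reads.extend(base * n)
    pairs = list(itertools.combinations(reads, 2))
    if not pairs:
        return float("nan")
    return sum(a != b for a, b in pairs) / len(pairs)


class TestSitePi:
    def test_monomorphic_is_zero(self, small_pool, site_factory):
        state = make_site_state(site_factory((50, 0, 0, 0)), 0, small_pool)
        assert site_pi(state, small_pool) == 0.0

    def test_balanced_site_matches_brute_force(self, b1_pool, site_factory):
        state = make_site_state(site_factory((5, 5, 0, 0)), 0, b1_pool)
        value = site_pi(state, b1_pool)
        assert value == pytest.approx((10 / 9) * 0.5, abs=1e-12)
        assert value == pytest.approx(brute_force_pairwise((5, 5, 0, 0)), abs=1e-12)

    def test_min_count_removes_minor_allele(self, small_pool, site_factory):
        state = make_site_state(site_factory((9, 1, 0, 0)), 0, small_pool)
        assert site_pi(state, small_pool) == 0.0

    def test_b1_equals_brute_force_randomly(self, rng, b1_pool, site_factory):
        for _ in range(200):
            counts = tuple(int(x) for x in rng.integers(0, 8, size=4))
            if sum(counts) < 2:
                continue
            state = make_site_state(site_factory(counts), 0, b1_pool)
            assert site_pi(state, b1_pool) == pytest.approx(
                brute_force_pairwise(counts), abs=1e-12
            )

    def test_low_coverage_is_nan(self, site_factory):
        pool = PoolSpec("p", 10, min_count=1, min_coverage=1)
        state = make_site_state(site_factory((1, 0, 0, 0)), 0, pool)
        assert math.isnan(site_pi(state, pool))

    def test_nucleotide_relabeling_invariance(self, rng, small_pool, site_factory):
        for _ in range(50):
            counts = tuple(int(x) for x in rng.integers(0, 20, size=4))
            if sum(counts) < small_pool.min_coverage:
                continue
            perm = rng.permutation(4)
            state = make_site_state(site_factory(counts), 0, small_pool)
            shuffled = make_site_state(
                site_factory(tuple(counts[i] for i in perm)), 0, small_pool
            )
            assert site_pi(state, small_pool) == pytest.approx(
                site_pi(shuffled, small_pool), abs=1e-12
            )


class TestCorrections:
    def test_detection_correction_is_one_at_b1(self):
        for c, n in [(10, 40), (60, 40), (37, 21)]:
            assert popgen.detection_correction(1, c, n) == pytest.approx(1.0)

    def test_pi_correction_b1_is_pool_factor(self):
        # with no detection threshold only the (n-1)/n pool factor remains
        for c, n in [(20, 10), (60, 40)]:
            assert popgen.pi_correction(1, c, n) == pytest.approx((n - 1) / n)

    def test_watterson_denominator_approaches_harmonic(self):
        # very deep coverage, b=1: every segregating site is detected
        n = 12
        a_n = sum(1 / i for i in range(1, n))
        assert popgen.watterson_denominator(1, 5000, n) == pytest.approx(a_n, rel=1e-3)

    def test_corrections_shrink_with_min_count(self):
        assert popgen.watterson_denominator(2, 60, 40) < popgen.watterson_denominator(1, 60, 40)
        assert popgen.pi_correction(2, 60, 40) < popgen.pi_correction(1, 60, 40)

    def test_undetectable_coverage_is_zero(self):
        assert popgen.watterson_denominator(2, 3, 40) == 0.0


class TestTajima:
    def test_n2_degenerate_numerator_zero(self):
        # a1 = 1 for n = 2 so pi-sum 1 and S = 1 cancel exactly
        assert tajima_d(1.0, 1, 2) == 0.0

    def test_no_snps_is_nan(self):
        assert math.isnan(tajima_d(0.0, 0, 10))

    def test_negative_when_pi_below_theta(self):
        assert tajima_d(0.5, 10, 20) < 0

    def test_constants_match_integer_harmonics(self):
        k = popgen.tajima_constants(10)
        assert k["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)), abs=1e-12)
        assert k["a2"] == pytest.approx(sum(1 / i**2 for i in range(1, 10)), abs=1e-10)


class TestDeltaTheta:
    def test_equilibrium_identity(self):
        assert delta_theta(1e-4, 1e-4) == 0.0

    def test_all_singleton_limit(self):
        assert delta_theta(0.0, 1e-4) == 1.0

    def test_inversion_against_reported_ratio(self):
        assert delta_theta(1.3e-4, 2.2807e-4) == pytest.approx(0.43, abs=5e-3)

    def test_zero_theta_is_nan(self):
        assert math.isnan(delta_theta(0.0, 0.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            delta_theta(-1e-4, 1e-4)

    def test_monotonicity(self, rng):
        # antitone in pi at fixed theta, isotone in theta at fixed pi
        theta = 2e-4
        pis = np.sort(rng.uniform(0, 3e-4, size=20))
        values = [delta_theta(p, theta) for p in pis]
        assert all(a >= b for a, b in zip(values, values[1:]))
        pi = 1e-4
        thetas = np.sort(rng.uniform(1e-5, 3e-4, size=20))
        values = [delta_theta(pi, t) for t in thetas]
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestWindowStats:
    def _run(self, sites, pool, size=100, min_cov_frac=0.01):
        window = WindowSpec(size, size, min_cov_frac)
        return list(window_stats(sites, window, pool))

    def test_zero_snp_window(self, small_pool, site_factory):
        sites = [site_factory((30, 0, 0, 0), pos=p) for p in range(1, 51)]
        (w,) = self._run(sites, small_pool)
        assert w.pi == 0.0 and w.theta_w == 0.0
        assert math.isnan(w.tajima_d)

    def test_covered_fraction_threshold(self, small_pool, site_factory):
        sites = [site_factory((30, 0, 0, 0), pos=p) for p in range(1, 11)]
        window = WindowSpec(100, 100, 0.5)
        (w,) = window_stats(sites, window, small_pool)
        assert w.n_valid_sites == 10
        assert math.isnan(w.pi)  # 10% coverage < 50% floor

    def test_unsorted_input_rejected(self, small_pool, site_factory):
        sites = [site_factory((30, 0, 0, 0), pos=5), site_factory((30, 0, 0, 0), pos=3)]
        with pytest.raises(ValueError, match="sorted"):
            list(window_stats(iter(sites), WindowSpec(100, 100, 0.1), small_pool))

    def test_chromosome_reappearance_rejected(self, small_pool, site_factory):
        sites = [
            site_factory((30, 0, 0, 0), chrom="a", pos=1),
            site_factory((30, 0, 0, 0), chrom="b", pos=1),
            site_factory((30, 0, 0, 0), chrom="a", pos=2),
        ]
        with pytest.raises(ValueError, match="reappears"):
            list(window_stats(iter(sites), WindowSpec(100, 100, 0.1), small_pool))

    def test_delta_theta_consistency(self, rng, small_pool):
        from conftest import random_sites

        sites = random_sites(rng, n=300, max_count=30)
        for w in self._run(iter(sites), small_pool, size=1000):
            if not math.isnan(w.delta_theta) and w.theta_w > 0:
                assert w.delta_theta == pytest.approx(1 - w.pi / w.theta_w)

    def test_relabeling_invariance_of_window_stats(self, rng, small_pool):
        from conftest import random_sites

        sites = random_sites(rng, n=200, max_count=30)
        perm = [2, 0, 3, 1]
        relabeled = [
            formats.SiteCounts(
                s.chrom, s.pos, s.ref,
                tuple(tuple(pool[i] for i in perm) + pool[4:] for pool in s.counts),
            )
            for s in sites
        ]
        a = self._run(iter(sites), small_pool, size=1000)
        b = self._run(iter(relabeled), small_pool, size=1000)
        for wa, wb in zip(a, b):
            assert wa.pi == pytest.approx(wb.pi, nan_ok=True)
            assert wa.theta_w == pytest.approx(wb.theta_w, nan_ok=True)


GENOME = {"sc1": "NNNNNNNNN" + "ATGGGATTTTGCTAA" + "NNNN"}
# CDS at positions 10..24: ATG GGA TTT TGC TAA


def _cds_features():
    fs = formats.FeatureSet()
    fs.add(formats.Feature("sc1", 10, 24, "CDS", "+", 0, "t1"))
    return fs


class TestCodingClassification:
    def test_third_position_of_gga_is_fourfold(self):
        contexts = classify_coding_sites(_cds_features(), GENOME)
        ctx = contexts[("sc1", 15)]  # 3rd base of GGA
        assert ctx.codon == "GGA" and ctx.offset == 2
        assert ctx.syn_length == 1.0

    def test_third_position_of_ttt(self):
        contexts = classify_coding_sites(_cds_features(), GENOME)
        ctx = contexts[("sc1", 18)]  # 3rd base of TTT: only TTC synonymous
        assert ctx.syn_length == pytest.approx(1 / 3)

    def test_second_positions_are_nonsynonymous(self):
        contexts = classify_coding_sites(_cds_features(), GENOME)
        for pos in (11, 14, 17, 20):  # 2nd codon positions of non-stop codons
            assert contexts[("sc1", pos)].syn_length == 0.0

    def test_enumeration_against_genetic_code(self):
        # syn fraction at every position of every sense codon, brute-forced
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        code = dict(table.forward_table)
        for stop in table.stop_codons:
            code[stop] = "*"
        rng = np.random.default_rng(0)
        for _ in range(30):
            codon = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
            offset = int(rng.integers(0, 3))
            expected = sum(
                code[codon[:offset] + b + codon[offset + 1:]] == code[codon]
                for b in "ACGT" if b != codon[offset]
            ) / 3
            assert popgen._syn_fraction(codon, offset) == pytest.approx(expected)

    def test_minus_strand_codons(self):
        genome = {"sc1": "N" + "TTACATCGGCAT" + "N"}
        # minus strand CDS 2..13 -> revcomp = ATGCCGATGTAA
        fs = formats.FeatureSet()
        fs.add(formats.Feature("sc1", 2, 13, "CDS", "-", 0, "t1"))
        contexts = classify_coding_sites(fs, genome)
        # last genomic base of the CDS is the first codon base (A of ATG)
        assert contexts[("sc1", 13)].codon == "ATG"
        assert contexts[("sc1", 13)].offset == 0

    def test_incomplete_cds_rejected_when_flagged(self):
        fs = formats.FeatureSet()
        fs.add(formats.Feature("sc1", 10, 23, "CDS", "+", 0, "t1"))
        with pytest.raises(ValueError, match="divisible by 3"):
            classify_coding_sites(fs, GENOME, allow_incomplete=False)

    def test_conflicting_frames_excluded(self):
        fs = _cds_features()
        fs.add(formats.Feature("sc1", 11, 22, "CDS", "+", 0, "t2"))
        contexts = classify_coding_sites(fs, GENOME)
        # overlap region has conflicting codon phases -> excluded
        for pos in range(11, 23):
            assert ("sc1", pos) not in contexts


class TestPiSynNonsyn:
    def test_window_without_cds(self, small_pool, site_factory):
        sites = [site_factory((30, 0, 0, 0), pos=p) for p in range(1, 9)]
        rows = window_pi_syn_nonsyn(
            sites, {}, WindowSpec(100, 100, 0.01), small_pool
        )
        assert rows == []

    def test_fourfold_snp_ratio(self, small_pool, site_factory):
        contexts = classify_coding_sites(_cds_features(), GENOME)
        # SNP at sc1:15 (GGA 3rd position, 4-fold): G/A 15:15
        sites = [site_factory((15, 0, 0, 15), pos=15, ref="G")]
        # pad with invariant coding sites
        for pos in (10, 11, 12, 13, 14, 16, 17, 18):
            base = GENOME["sc1"][pos - 1]
            idx = "ATCG".index(base)
            counts = [0, 0, 0, 0]
            counts[idx] = 30
            sites.append(site_factory(tuple(counts), pos=pos, ref=base))
        sites.sort(key=lambda s: s.pos)
        (row,) = window_pi_syn_nonsyn(
            sites, contexts, WindowSpec(100, 100, 0.01), small_pool
        )
        syn_total = sum(
            contexts[("sc1", p)].syn_length for p in range(10, 19)
        )
        state = make_site_state(sites[5], 0, small_pool)
        expected = site_pi(state, small_pool) / syn_total
        assert row.pi_syn == pytest.approx(expected)
        assert row.pi_nonsyn == 0.0

    def test_all_synonymous_window_has_zero_nonsyn(self, small_pool, site_factory):
        contexts = classify_coding_sites(_cds_features(), GENOME)
        sites = [site_factory((15, 0, 0, 15), pos=15, ref="G")]
        for pos in (10, 11, 12):  # invariant sites contributing nonsyn length
            base = GENOME["sc1"][pos - 1]
            counts = [0, 0, 0, 0]
            counts["ATCG".index(base)] = 30
            sites.append(site_factory(tuple(counts), pos=pos, ref=base))
        sites.sort(key=lambda s: s.pos)
        (row,) = window_pi_syn_nonsyn(
            sites, contexts, WindowSpec(100, 100, 0.0001), small_pool
        )
        assert row.pi_nonsyn == 0.0
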