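import collections
import math

import numpy as np
import pytest

from pooldyn import formats, synthio
from pooldyn.formats import Feature, FeatureSet, TEHierarchy
from pooldyn.mobilome import (
    DEFAULT_TELOMERE_MOTIFS,
    REF_CLASS,
    SV_CLASS,
    PairEvidence,
    SignatureParams,
    TEInsertion,
    build_te_merged_reference,
    detect_te_insertions,
    frequency_spectrum,
    read_pair_evidence,
    repeat_landscape,
    telomere_scan,
    unique_insertions,
    window_composition,
    write_pair_evidence,
)
from pooldyn.popgen import WindowSpec

HIER = TEHierarchy({"teA": ("famA", "LTR"), "teB": ("famB", "LINE"),
                    "cons1": ("famX", "LTR")})


def cluster(chrom, center, strand, family, n_te, n_ref, span=1, start=None):
    """Point evidence spread over a short run around a breakpoint side."""
    pairs = []
    base = center if start is None else start
    for i in range(n_te):
        pairs.append(PairEvidence(chrom, base + i % 5, strand, family, 40, span))
    for i in range(n_ref):
        pairs.append(PairEvidence(chrom, base + i % 5, strand, REF_CLASS, 40, span))
    return pairs


class TestMergedReference:
    def test_empty_inputs_identity(self):
        genome = {"s1": "ACGT" * 10}
        merged, prov = build_te_merged_reference(genome, FeatureSet(), {}, HIER)
        assert merged == genome and prov == {}

    def test_masked_span_length(self):
        genome = {"s1": "A" * 200}
        fs = FeatureSet()
        fs.add(Feature("s1", 51, 150, "repeat"))
        merged, _ = build_te_merged_reference(genome, fs, {}, HIER)
        assert merged["s1"].count("N") == 100
        assert merged["s1"][49] == "A" and merged["s1"][50] == "N"
        assert merged["s1"][149] == "N" and merged["s1"][150] == "A"

    def test_library_appended_with_provenance(self):
        genome = {"s1": "ACGT"}
        lib = {"teA": "GGGG", "teB": "CCCC"}
        merged, prov = build_te_merged_reference(genome, FeatureSet(), lib, HIER)
        assert len(merged) == 3
        assert prov["teA"] == ("famA", "LTR")

    def test_unknown_library_id_rejected(self):
        with pytest.raises(KeyError, match="hierarchy"):
            build_te_merged_reference(
                {"s1": "ACGT"}, FeatureSet(), {"mystery": "AAAA"}, HIER
            )


class TestDetect:
    PARAMS = SignatureParams()

    def test_no_te_pairs_empty(self):
        pairs = [PairEvidence("c1", p, "+", REF_CLASS, 40) for p in range(1, 500, 7)]
        assert detect_te_insertions(pairs, self.PARAMS, 1) == []

    def test_simple_insertion_called(self):
        pairs = sorted(
            cluster("c1", 990, "+", "famA", 8, 2) + cluster("c1", 1006, "-", "famA", 8, 2),
            key=lambda p: p.pos,
        )
        (ins,) = detect_te_insertions(pairs, self.PARAMS, 1, HIER)
        assert ins.paired
        assert abs(ins.pos - 1000) <= 15
        assert ins.frequency == pytest.approx(0.8, abs=0.05)
        assert ins.order == "LTR"

    def test_distant_signatures_not_paired(self):
        pairs = sorted(
            cluster("c1", 1000, "+", "famA", 5, 0) + cluster("c1", 1400, "-", "famA", 5, 0),
            key=lambda p: p.pos,
        )
        insertions = detect_te_insertions(pairs, self.PARAMS, 1)
        assert len(insertions) == 2
        assert not any(i.paired for i in insertions)

    def test_mapq_filter(self):
        pairs = [PairEvidence("c1", 100 + i, "+", "famA", 5) for i in range(5)]
        assert detect_te_insertions(pairs, self.PARAMS, 1) == []

    def test_min_count_filter(self):
        pairs = [PairEvidence("c1", 100, "+", "famA", 40)]
        assert detect_te_insertions(pairs, self.PARAMS, 1) == []

    def test_otherte_contamination_discards(self):
        clean = sorted(cluster("c1", 100, "+", "famA", 5, 0), key=lambda p: p.pos)
        dirty = sorted(
            clean + cluster("c1", 100, "+", "famB", 3, 0), key=lambda p: p.pos
        )
        assert len(detect_te_insertions(clean, self.PARAMS, 1)) == 1
        called = detect_te_insertions(dirty, self.PARAMS, 1)
        assert all(i.family not in ("famA",) or False for i in called) or called == [] \
            or all(abs(i.pos - 100) > 50 for i in called if i.family == "famA")

    def test_structvar_contamination_discards(self):
        pairs = cluster("c1", 100, "+", "famA", 5, 0)
        pairs += [PairEvidence("c1", 100 + i % 5, "+", SV_CLASS, 40) for i in range(3)]
        pairs.sort(key=lambda p: p.pos)
        assert detect_te_insertions(pairs, self.PARAMS, 1) == []

    def test_unsorted_evidence_rejected(self):
        pairs = [
            PairEvidence("c1", 100, "+", "famA", 40),
            PairEvidence("c1", 50, "+", "famA", 40),
        ]
        with pytest.raises(ValueError, match="sorted"):
            detect_te_insertions(pairs, self.PARAMS, 1)

    def test_subsampling_seed_reproducible(self):
        ev, _ = synthio.simulate_te_evidence(20, [0.5], physical_coverage=40, rng_seed=9)
        a = detect_te_insertions(ev, self.PARAMS, rng_seed=4)
        b = detect_te_insertions(ev, self.PARAMS, rng_seed=4)
        assert [(i.chrom, i.pos, i.family, i.frequency) for i in a] == [
            (i.chrom, i.pos, i.family, i.frequency) for i in b
        ]

    def test_no_upsampling_below_target(self):
        # 4 pairs per side < target 10: support equals the raw pair count
        pairs = sorted(
            cluster("c1", 990, "+", "famA", 4, 0) + cluster("c1", 1006, "-", "famA", 4, 0),
            key=lambda p: p.pos,
        )
        (ins,) = detect_te_insertions(pairs, self.PARAMS, 1)
        assert ins.support == 8
        assert ins.frequency == 1.0


class TestEvidenceTable:
    def test_round_trip(self):
        pairs = [PairEvidence("c1", 5, "+", "famA", 30, 160),
                 PairEvidence("c1", 9, "-", REF_CLASS, 20, 160)]
        assert read_pair_evidence(write_pair_evidence(pairs)) == pairs


class TestUnique:
    def make(self, pop_positions, family="famA"):
        return {
            pop: [TEInsertion("c1", p, family, frequency=0.5) for p in positions]
            for pop, positions in pop_positions.items()
        }

    def test_single_population_all_unique(self):
        per_pop = self.make({"A": [100, 500]})
        unique = unique_insertions(per_pop)
        assert len(unique["A"]) == 2

    def test_shared_event_within_tolerance_excluded(self):
        per_pop = self.make({"A": [100], "B": [110]})
        unique = unique_insertions(per_pop, tolerance=25)
        assert unique["A"] == [] and unique["B"] == []

    def test_separate_events_outside_tolerance(self):
        per_pop = self.make({"A": [100], "B": [200]})
        unique = unique_insertions(per_pop, tolerance=25)
        assert len(unique["A"]) == 1 and len(unique["B"]) == 1

    def test_different_families_never_merge(self):
        per_pop = {
            "A": [TEInsertion("c1", 100, "famA", frequency=0.5)],
            "B": [TEInsertion("c1", 100, "famB", frequency=0.5)],
        }
        unique = unique_insertions(per_pop)
        assert len(unique["A"]) == 1 and len(unique["B"]) == 1

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            unique_insertions({"A": []}, tolerance=-1)


class TestSpectrum:
    def test_all_fixed(self):
        ins = [TEInsertion("c", 1, "f", frequency=1.0) for _ in range(5)]
        s = frequency_spectrum(ins)
        assert s.fixed_fraction == 1.0 and s.high_fraction == 1.0

    def test_worked_example(self):
        ins = [TEInsertion("c", i, "f", frequency=f)
               for i, f in enumerate([0.1, 0.2, 0.6, 1.0], 1)]
        s = frequency_spectrum(ins)
        assert s.low_fraction == 0.5
        assert s.high_fraction == 0.5
        assert s.fixed_fraction == 0.25

    def test_empty_is_nan(self):
        s = frequency_spectrum([])
        assert math.isnan(s.low_fraction) and math.isnan(s.fixed_fraction)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            frequency_spectrum([], n_bins=1)


class TestLandscape:
    CONSENSUS = "".join("ATCG"[i] for i in np.random.default_rng(3).integers(0, 4, 400))

    def test_verbatim_reads_in_bin_zero(self):
        reads = [self.CONSENSUS[i: i + 200] for i in (0, 100, 200)]
        bins = repeat_landscape(reads, {"cons1": self.CONSENSUS}, HIER,
                                sample_coverage=1.0, genome_size=600, rng_seed=1)
        assert {b.bin for b in bins} == {0}
        assert sum(b.proportion for b in bins) == pytest.approx(1.0)

    def test_unmatched_reads_excluded(self):
        rng = np.random.default_rng(8)
        junk = ["".join("ATCG"[i] for i in rng.integers(0, 4, 200)) for _ in range(5)]
        reads = [self.CONSENSUS[:200]] + junk
        bins = repeat_landscape(reads, {"cons1": self.CONSENSUS}, HIER,
                                sample_coverage=1.0,
                                genome_size=sum(len(r) for r in reads), rng_seed=1)
        assert sum(b.proportion for b in bins) <= 1.0
        assert sum(b.proportion for b in bins) == pytest.approx(200 / 1200)

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            repeat_landscape(["ACGT"], {}, HIER)

    def test_reverse_complement_reads_match(self):
        comp = str.maketrans("ACGT", "TGCA")
        read = self.CONSENSUS[:200].translate(comp)[::-1]
        bins = repeat_landscape([read], {"cons1": self.CONSENSUS}, HIER,
                                sample_coverage=1.0, genome_size=200, rng_seed=1)
        assert [b.bin for b in bins] == [0]


class TestComposition:
    LENGTHS = {"s1": 1000}
    WINDOW = WindowSpec(1000, 1000, 0.5)

    def test_full_repeat_window(self):
        fs = FeatureSet()
        fs.add(Feature("s1", 1, 1000, "repeat", order="LTR"))
        df = window_composition(fs, self.WINDOW, self.LENGTHS)
        assert df.loc[0, "LTR"] == 1.0

    def test_overlapping_exons_merged(self):
        fs = FeatureSet()
        fs.add(Feature("s1", 100, 200, "exon"))
        fs.add(Feature("s1", 150, 250, "exon"))
        df = window_composition(fs, self.WINDOW, self.LENGTHS)
        assert df.loc[0, "exon"] == pytest.approx(0.151)

    def test_empty_annotation_zero(self):
        df = window_composition(FeatureSet(), self.WINDOW, self.LENGTHS)
        assert df.loc[0, ["DNA", "LTR", "LINE", "Unknown", "other", "exon"]].sum() == 0

    def test_ordering_and_split_invariance(self):
        fs1 = FeatureSet()
        fs1.add(Feature("s1", 100, 400, "repeat", order="DNA"))
        fs2 = FeatureSet()
        fs2.add(Feature("s1", 251, 400, "repeat", order="DNA"))
        fs2.add(Feature("s1", 100, 250, "repeat", order="DNA"))
        a = window_composition(fs1, self.WINDOW, self.LENGTHS)
        b = window_composition(fs2, self.WINDOW, self.LENGTHS)
        assert a.loc[0, "DNA"] == b.loc[0, "DNA"]

    def test_truncated_window_denominator(self):
        lengths = {"s1": 1500}
        window = WindowSpec(1000, 1000, 0.5)
        fs = FeatureSet()
        fs.add(Feature("s1", 1001, 1500, "repeat", order="LTR"))
        df = window_composition(fs, window, lengths)
        assert df.loc[1, "end"] == 1500
        assert df.loc[1, "LTR"] == 1.0


class TestTelomere:
    def test_tandem_motif_count(self):
        genome = {"s1": "AACCT" * 100}
        counts, _ = telomere_scan(genome, ("AACCT",), window=1000)
        assert counts.loc[0, "AACCT"] == 100

    def test_motif_free_sequence_unflagged(self):
        rng = np.random.default_rng(1)
        # exclude A to keep every motif absent
        genome = {"s1": "".join("CGG"[i] for i in rng.integers(0, 3, 50_000))}
        _, flags = telomere_scan(genome, DEFAULT_TELOMERE_MOTIFS, window=5000)
        assert flags == []

    def test_capped_scaffold_flagged_at_both_ends(self):
        rng = np.random.default_rng(2)
        body = "".join("ATCG"[i] for i in rng.integers(0, 4, 80_000))
        cap = "AACCT" * 400
        genome = {"s1": cap + body + cap}
        _, flags = telomere_scan(genome, ("AACCT",), window=10_000)
        ends = {(f.chrom, f.end) for f in flags}
        assert ("s1", "start") in ends and ("s1", "end") in ends
        assert len(ends) == 2

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            telomere_scan({"s1": "ACGT"}, ("AAXX",))

    def test_reverse_complement_counted(self):
        genome = {"s1": "AGGTT" * 50}  # revcomp of AACCT
        counts, _ = telomere_scan(genome, ("AACCT",), window=1000)
        assert counts.loc[0, "AACCT"] == 50
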