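"""Seed-site scanning, predictor combination, and positional lncRNA targets."""

import numpy as np
import pytest
from Bio.Seq import Seq

from spongeworks.targets import (
    LENIENT_CLASSES,
    STRICT_CLASSES,
    assign_cis_targets,
    combine_predictions,
    find_antisense_targets,
    find_seed_sites,
    seed_patterns,
)
from spongeworks.types import TranscriptRecord


def oracle_scan(mirna: str, target: str):
    """Position-by-position windowed scan; independent of the str.find route."""
    m = mirna.upper().replace("U", "T")
    core = str(Seq(m[1:7]).reverse_complement())
    flank_m8 = str(Seq(m[7]).reverse_complement())
    out = []
    for p in range(len(target) - 5):
        if target[p : p + 6] != core:
            continue
        m8 = p > 0 and target[p - 1] == flank_m8
        a1 = p + 6 < len(target) and target[p + 6] == "A"
        if m8 and a1:
            out.append((p, p + 7, "8mer"))
        elif m8:
            out.append((p, p + 6, "7mer-m8"))
        elif a1:
            out.append((p + 1, p + 7, "7mer-A1"))
        else:
            out.append((p + 1, p + 6, "6mer"))
    return out


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestSeedSites:
    LET7 = "UGAGGUAGUAGGUUGUAUAGUU"

    def test_canonical_8mer_example(self):
        target = "GGG" + "CTACCTCA" + "GGG"
        sites = find_seed_sites({"let7": self.LET7}, {"t": target})
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.site_class) == (4, 11, "8mer")

    def test_no_complementary_substring_gives_empty(self):
        assert find_seed_sites({"let7": self.LET7}, {"t": "G" * 100}) == []

    @pytest.mark.parametrize(
        "tail,expected",
        [("A", "7mer-A1"), ("G", "6mer")],
    )
    def test_class_hierarchy_without_m8(self, tail, expected):
        pats = seed_patterns(self.LET7)
        target = "GGG" + pats["6mer"] + tail + "GG"
        sites = find_seed_sites({"let7": self.LET7}, {"t": target})
        assert [s.site_class for s in sites] == [expected]

    def test_7mer_m8_without_a1(self):
        pats = seed_patterns(self.LET7)
        target = "GG" + pats["7mer-m8"] + "GGG"
        sites = find_seed_sites({"let7": self.LET7}, {"t": target})
        assert [s.site_class for s in sites] == ["7mer-m8"]

    def test_site_class_filter(self):
        target = "GGG" + "CTACCTCA" + "GGG"
        strict = find_seed_sites(
            {"let7": self.LET7}, {"t": target}, site_classes=STRICT_CLASSES
        )
        assert [s.site_class for s in strict] == ["8mer"]
        only6 = find_seed_sites(
            {"let7": self.LET7}, {"t": target}, site_classes={"6mer"}
        )
        assert only6 == []  # the occurrence is an 8mer, not reported as 6mer

    def test_short_mirna_rejected(self):
        with pytest.raises(ValueError):
            find_seed_sites({"m": "ACGUACG"}, {"t": "ACGT" * 10})

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(99)
        mirnas = {f"m{i}": _random_seq(rng, 22) for i in range(10)}
        targets = {f"t{j}": _random_seq(rng, 500) for j in range(50)}
        got = {
            (s.mirna_id, s.target_id, s.start, s.end, s.site_class)
            for s in find_seed_sites(mirnas, targets)
        }
        # oracle_scan emits 1-based inclusive spans already
        want = {
            (mid, tid, a, b, cls)
            for mid, mseq in mirnas.items()
            for tid, tseq in targets.items()
            for a, b, cls in oracle_scan(mseq, tseq)
        }
        assert got == want


class TestCombinePredictions:
    def test_intersection_and_union_semantics(self):
        a = {"m1": {"g1", "g2"}}
        b = {"m1": {"g2", "g3"}}
        assert combine_predictions([a, b], mode="intersection") == {"m1": {"g2"}}
        assert combine_predictions([a, b], mode="union") == {"m1": {"g1", "g2", "g3"}}

    def test_single_predictor_identity(self):
        a = {"m1": {"g1"}, "m2": set()}
        assert combine_predictions([a]) == a

    def test_empty_intersection_allowed(self):
        out = combine_predictions([{"m1": {"g1"}}, {"m1": {"g2"}}])
        assert out == {"m1": set()}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            combine_predictions([{}], mode="xor")


def _span(tid, start, end, strand="+", chrom="chr1", seq=None):
    return TranscriptRecord(
        id=tid,
        gene_id=f"g-{tid}",
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        sequence=seq,
        exons=[(start, end)],
    )


class TestCisTargets:
    def test_gap_within_window_upstream(self):
        lnc = _span("l1", 100_000, 101_000)
        gene = _span("g1", 95_500, 96_000)
        pairs = assign_cis_targets([lnc], [gene])
        assert len(pairs) == 1
        assert pairs[0].relation == "upstream"
        assert pairs[0].distance == -3_999

    @pytest.mark.parametrize("gene_start,paired", [(61_001, True), (61_002, False)])
    def test_window_boundary_inclusive(self, gene_start, paired):
        lnc = _span("l1", 50_000, 51_000)
        gene = _span("g1", gene_start, gene_start + 500)
        pairs = assign_cis_targets([lnc], [gene], window=10_000)
        assert bool(pairs) is paired  # gap 10,000 paired; 10,001 not

    def test_overlap_distance_zero(self):
        pairs = assign_cis_targets(
            [_span("l1", 100, 500)], [_span("g1", 400, 900)]
        )
        assert pairs[0].distance == 0 and pairs[0].relation == "overlap"

    def test_other_chromosome_unpaired(self):
        pairs = assign_cis_targets(
            [_span("l1", 100, 500)], [_span("g1", 100, 500, chrom="chr2")]
        )
        assert pairs == []

    def test_translation_invariance(self):
        lnc, gene = _span("l1", 50_000, 51_000), _span("g1", 58_000, 59_000)
        base = assign_cis_targets([lnc], [gene])
        shift = 7_777
        moved = assign_cis_targets(
            [_span("l1", 50_000 + shift, 51_000 + shift)],
            [_span("g1", 58_000 + shift, 59_000 + shift)],
        )
        assert [(p.gene_id, p.distance, p.relation) for p in base] == [
            (p.gene_id, p.distance, p.relation) for p in moved
        ]


class TestAntisenseTargets:
    def test_same_span_opposite_strand(self):
        lnc = _span("l1", 100, 400, strand="+", seq="ACGT" * 75 + "A")
        t = _span("t1", 100, 400, strand="-", seq="TGCA" * 75 + "T")
        pairs = find_antisense_targets([lnc], [t])
        assert len(pairs) == 1 and pairs[0].overlap == 301

    def test_same_strand_overlap_not_paired(self):
        lnc = _span("l1", 100, 400, strand="+")
        t = _span("t1", 200, 500, strand="+")
        assert find_antisense_targets([lnc], [t]) == []

    def test_adjacent_non_overlapping_not_paired(self):
        lnc = _span("l1", 100, 400, strand="+")
        t = _span("t1", 401, 700, strand="-")
        assert find_antisense_targets([lnc], [t]) == []

    def test_complementarity_score_detects_perfect_run(self):
        a = "AAAA" + "GGGGGGGG" + "TTTT"
        b = "CCCC" + "CCCCCCCC" + "GGGG"  # revcomp(b) contains GGGGGGGG
        lnc = _span("l1", 100, 100 + len(a) - 1, strand="+", seq=a)
        t = _span("t1", 100, 100 + len(b) - 1, strand="-", seq=b)
        pairs = find_antisense_targets([lnc], [t])
        assert pairs[0].complementarity >= 8
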