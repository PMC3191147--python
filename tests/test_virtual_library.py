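from __future__ import annotations

import numpy as np
import pytest

from mmsdk.genome_assets import GenomeSequence, IntervalAnnotation, reverse_complement
from mmsdk.virtual_library import (
    CGIRegion,
    annotate_sites,
    build_library,
    build_virtual_fragments,
    extract_virtual_tags,
    filter_unique_tags,
    find_sites,
    mappable_fragment_count,
    predict_cgi_promoters,
)
from oracles import brute_force_digest, naive_cgi_scan, naive_find


def random_genome(rng, length, gc=0.42):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


class TestFindSites:
    def test_single_and_adjacent_occurrences(self):
        assert [s.start for s in find_sites(GenomeSequence("c", "AAACGCGTAA"),
                                            "ACGCGT")] == [2]
        assert [s.start for s in find_sites(GenomeSequence("c", "CATGCATG"),
                                            "CATG")] == [0, 4]

    def test_overlapping_occurrences_reported(self):
        # CATGCATG contains CATG at 0 and 4; ACACACA style overlap for a
        # custom motif
        assert [s.start for s in find_sites(GenomeSequence("c", "AAAAA"),
                                            "AA")] == [0, 1, 2, 3]

    def test_n_never_matches(self):
        assert find_sites(GenomeSequence("c", "ACGNGT"), "ACGCGT") == []

    def test_motif_validation(self):
        with pytest.raises(ValueError):
            find_sites(GenomeSequence("c", "ACGT"), "ACN")
        with pytest.raises(ValueError):
            find_sites(GenomeSequence("c", "ACGT"), "")

    @pytest.mark.parametrize("motif", ["ACGCGT", "CATG"])
    def test_palindrome_scan_is_strand_complete(self, motif, rng):
        seq = random_genome(rng, 5000)
        fwd = [s.start for s in find_sites(GenomeSequence("c", seq), motif)]
        rev = [s.start for s in
               find_sites(GenomeSequence("c", reverse_complement(seq)), motif)]
        # site at i on the reverse strand maps to len - i - len(motif)
        assert sorted(len(seq) - i - len(motif) for i in rev) == fwd


class TestFragments:
    def test_one_site_two_fragments(self):
        seq = "CATG" + "A" * 10 + "ACGCGT" + "T" * 8 + "CATG"
        _, frags, _, summary = build_library([GenomeSequence("c1", seq)])
        assert [(f.start, f.end, f.side) for f in frags] == [
            (0, 20, "left"), (14, 32, "right")]
        assert all(f.has_nla_end for f in frags)
        assert summary.n_end_losses == 0

    def test_nla_free_interval_yields_shared_fragment(self):
        seq = ("CATG" + "A" * 30 + "ACGCGT" + "G" * 25 + "ACGCGT"
               + "C" * 30 + "CATG")
        _, frags, _, summary = build_library([GenomeSequence("c1", seq)])
        sides = sorted(f.side for f in frags)
        assert sides == ["left", "mlu_mlu", "right"]
        shared = next(f for f in frags if f.side == "mlu_mlu")
        assert not shared.has_nla_end
        assert len(shared.mlu_site_ids) == 2
        assert summary.n_nla_free_intervals == 1
        # the frozen accounting: the two facing fragments are replaced by an
        # untagged shared one, so the mappable count drops by exactly 2
        assert summary.n_fragments_mappable == mappable_fragment_count(
            2, 1) - summary.n_end_losses

    def test_missing_chromosome_end_nla_loses_that_side(self):
        seq = "A" * 10 + "ACGCGT" + "T" * 8 + "CATG"  # no upstream CATG
        _, frags, _, summary = build_library([GenomeSequence("c1", seq)])
        assert [f.side for f in frags] == ["right"]
        assert summary.n_end_losses == 1

    def test_unsorted_input_rejected(self):
        g = [GenomeSequence("c1", "CATG" + "A" * 30 + "ACGCGT" + "C" * 30
                            + "CATG")]
        mlu = find_sites(g[0], "ACGCGT")
        nla = list(reversed(find_sites(g[0], "CATG")))
        with pytest.raises(ValueError, match="sorted"):
            build_virtual_fragments(g, mlu, nla)

    def test_brute_force_digestion_oracle_random_sequences(self, rng):
        """Fragments and tags match an independent all-pairs scanner."""
        for trial in range(30):
            seq = random_genome(rng, 4000, gc=0.5)
            g = [GenomeSequence("c", seq)]
            _, frags, lib, _ = build_library(g)
            exp_frags, exp_tags = brute_force_digest(seq)
            got_frags = sorted((f.start, f.end, f.side) for f in frags)
            assert got_frags == sorted(exp_frags)
            got_tags = sorted((t.sequence, t.strand)
                              for t in lib.mappable + lib.ambiguous)
            exp = sorted((t[3], t[4]) for t in exp_tags)
            assert got_tags == exp


class TestTags:
    def test_left_tag_reads_plus_strand_from_catg(self):
        interior = "ACGTACGTACGTACGTACGT"  # 20 bases
        seq = "CATG" + interior + "ACGCGT" + "T" * 20 + "CATG"
        _, _, lib, _ = build_library([GenomeSequence("c1", seq)])
        left = next(t for t in lib.mappable if t.strand == "+")
        assert left.sequence == interior[:17]

    def test_right_tag_is_reverse_complement_of_interior_end(self):
        interior = "ACGTACGTACGTACGTA"  # exactly 17
        seq = "CATG" + "A" * 20 + "ACGCGT" + interior + "CATG"
        _, _, lib, _ = build_library([GenomeSequence("c1", seq)])
        right = next(t for t in lib.mappable if t.strand == "-")
        assert right.sequence == reverse_complement(interior)

    def test_short_interior_produces_no_tag(self):
        seq = "CATG" + "A" * 10 + "ACGCGT" + "T" * 30 + "CATG"
        _, frags, lib, summary = build_library([GenomeSequence("c1", seq)])
        assert len(lib.mappable) == 1  # right side only
        assert summary.dropped_short == 1

    def test_tags_per_site_at_most_two(self, dataset):
        from collections import Counter
        tags = dataset.library.mappable + dataset.library.ambiguous
        per_site = Counter(t.mlu_site_id for t in tags)
        assert set(per_site.values()) <= {1, 2}

    def test_unique_filter_removes_all_copies(self):
        seq = ("CATG" + "A" * 17 + "ACGCGT" + "T" * 30
               + "CATG" + "A" * 17 + "ACGCGT" + "G" * 30 + "CATG")
        _, _, lib, _ = build_library([GenomeSequence("c1", seq)])
        dup_seqs = {t.sequence for t in lib.ambiguous}
        assert "A" * 17 in dup_seqs
        assert all(t.sequence not in dup_seqs for t in lib.mappable)
        assert all(not t.unique for t in lib.ambiguous)
        assert all(t.unique for t in lib.mappable)

    def test_all_distinct_input_is_identity(self, dataset):
        tags = dataset.library.mappable
        relib = filter_unique_tags(tags)
        assert [t.sequence for t in relib.mappable] == [t.sequence for t in tags]
        assert relib.ambiguous == []


class TestCGI:
    def test_planted_cg_rich_region_recovered(self, rng):
        bg = "".join(rng.choice(list("AT"), size=3000))
        seq = bg[:1200] + "CG" * 400 + bg[1200:]
        regions = predict_cgi_promoters([GenomeSequence("c", seq)])
        assert len(regions) == 1
        r = regions[0]
        # recovered region covers the planted island at [1200, 2000)
        assert r.start <= 1200 and r.end >= 2000
        assert r.gc_fraction > 0.5 and r.obs_exp_cpg > 0.6

    def test_poly_a_chromosome_has_no_islands(self):
        assert predict_cgi_promoters([GenomeSequence("c", "A" * 2000)]) == []

    def test_short_chromosome_is_silent(self):
        assert predict_cgi_promoters([GenomeSequence("c", "CG" * 100)]) == []

    def test_window_scan_matches_naive_oracle(self, rng):
        for trial in range(5):
            # patchy sequence: GC-rich blocks in AT background
            parts = []
            for _ in range(6):
                parts.append("".join(rng.choice(list("AT"), size=400)))
                parts.append("".join(rng.choice(
                    list("ACGT"), size=700, p=[0.15, 0.35, 0.35, 0.15])))
            seq = "".join(parts)
            got = [(r.start, r.end) for r in
                   predict_cgi_promoters([GenomeSequence("c", seq)])]
            assert got == naive_cgi_scan(seq)

    def test_emitted_regions_re_satisfy_all_criteria(self, dataset):
        for r in predict_cgi_promoters(dataset.truth.genome):
            assert r.end - r.start > 500
            assert r.gc_fraction > 0.5
            assert r.obs_exp_cpg > 0.6

    def test_simulator_planted_islands_recovered(self, dataset):
        predicted = predict_cgi_promoters(dataset.truth.genome)
        recovered = 0
        for iv in dataset.truth.cgi_intervals:
            for r in predicted:
                if r.chrom_id != iv.chrom_id:
                    continue
                ov = min(r.end, iv.end) - max(r.start, iv.start)
                if (ov >= 0.5 * (iv.end - iv.start)
                        and ov >= 0.5 * (r.end - r.start)):
                    recovered += 1
                    break
        assert recovered >= 0.9 * len(dataset.truth.cgi_intervals)


class TestAnnotateSites:
    def _sites(self, *starts):
        return [s for start in starts
                for s in [__import__("mmsdk").RestrictionSite(
                    "c1", start, "MluI", "ACGCGT")]]

    def test_cgi_and_repeat_membership(self):
        sites = self._sites(100)
        cgis = [CGIRegion("c1", 50, 103, 0.6, 1.0)]  # 3 bp overlap
        repeats = [IntervalAnnotation("c1", 90, 110, "SINE/MIR")]
        ann = annotate_sites(sites, cgis, repeats, [])[0]
        assert ann.in_cgi_promoter
        assert ann.repeat_class == "SINE/MIR"
        assert ann.nearest_gene is None

    def test_no_overlap_no_cgi(self):
        sites = self._sites(100)
        cgis = [CGIRegion("c1", 0, 100, 0.6, 1.0)]  # half-open: no overlap
        assert not annotate_sites(sites, cgis, [], [])[0].in_cgi_promoter

    def test_repeat_tie_largest_overlap_then_coordinate(self):
        sites = self._sites(100)
        repeats = [IntervalAnnotation("c1", 99, 106, "LINE/L1"),   # full 6
                   IntervalAnnotation("c1", 101, 104, "SINE/MIR")]  # 3 bp
        assert annotate_sites(sites, [], repeats, [])[0].repeat_class == "LINE/L1"
        # equal overlap: first by coordinate wins
        repeats = [IntervalAnnotation("c1", 102, 120, "B_class"),
                   IntervalAnnotation("c1", 80, 104, "A_class")]
        # both overlap 4 bases? [100,106) vs [102,120): 4; vs [80,104): 4
        assert annotate_sites(sites, [], repeats, [])[0].repeat_class == "A_class"

    def test_nearest_gene_distance_and_ties(self):
        sites = self._sites(100)
        genes = [IntervalAnnotation("c1", 1106, 2000, "far"),
                 IntervalAnnotation("c1", 206, 300, "near")]
        ann = annotate_sites(sites, [], [], genes)[0]
        assert ann.nearest_gene == "near"
        assert ann.distance_to_gene == 100
        # overlapping gene: distance 0
        genes.append(IntervalAnnotation("c1", 95, 105, "ov"))
        ann = annotate_sites(sites, [], [], genes)[0]
        assert ann.nearest_gene == "ov" and ann.distance_to_gene == 0


def test_fragment_intervals_stay_inside_chromosomes(dataset):
    lengths = {g.chrom_id: len(g) for g in dataset.truth.genome}
    _, frags, _, _ = build_library(dataset.truth.genome)
    for f in frags:
        assert 0 <= f.start < f.end <= lengths[f.chrom_id]
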