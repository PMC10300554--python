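"""Unit tests for Capture-C read processing, with independent oracles."""

import numpy as np
import pytest

from asomics.capturec import (
    BaitSet,
    Ditag,
    ReferenceIndex,
    SubRead,
    bin_counts,
    classify_ditag,
    count_reporters,
    deduplicate,
    digest_read,
    find_dpnii_sites,
    map_subread,
    median_top_scores,
    merge_read_pairs,
    process_read_pair,
    reverse_complement,
    summarize_tracks,
)


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------


def brute_force_sites(seq):
    return [i for i in range(len(seq) - 3) if seq[i : i + 4] == "GATC"]


class TestDigestion:
    def test_sites_match_brute_force_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            assert find_dpnii_sites(seq) == brute_force_sites(seq)

    def test_pieces_concatenate_to_input(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=150))
            assert "".join(digest_read(seq)) == seq

    def test_internal_pieces_start_with_gatc(self):
        pieces = digest_read("AAAGATCTTTTGATCCCC")
        assert pieces == ["AAA", "GATCTTTT", "GATCCCC"]

    def test_site_at_position_zero_does_not_split(self):
        assert digest_read("GATCAAA") == ["GATCAAA"]

    def test_no_site_returns_whole_read(self):
        assert digest_read("AAATTTCCC") == ["AAATTTCCC"]

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            digest_read("")


# ---------------------------------------------------------------------------
# reference index
# ---------------------------------------------------------------------------


class TestReferenceIndex:
    def test_fragments_tile_each_chromosome(self, tiny_ref):
        for chrom, seq in tiny_ref.sequences.items():
            frags = tiny_ref.chrom_fragments(chrom)
            assert frags[0].start == 0
            assert frags[-1].end == len(seq)
            for f1, f2 in zip(frags, frags[1:]):
                assert f1.end == f2.start

    def test_known_layout(self, tiny_ref):
        starts = [f.start for f in tiny_ref.chrom_fragments("chr1")]
        assert starts == [0, 60, 110]
        assert [f.start for f in tiny_ref.chrom_fragments("chr2")] == [0, 80]

    def test_fragment_at_boundaries(self, tiny_ref):
        assert tiny_ref.fragment_at("chr1", 59).start == 0
        assert tiny_ref.fragment_at("chr1", 60).start == 60
        with pytest.raises(ValueError):
            tiny_ref.fragment_at("chr1", 10_000)

    def test_internal_fragments_start_with_gatc(self, small_ref):
        firsts = small_ref.first_fragment_ids()
        for frag in small_ref.fragments:
            seq = small_ref.sequences[frag.chrom][frag.start : frag.end]
            if frag.fragment_id in firsts:
                continue
            assert seq.startswith("GATC")

    def test_locate_agrees_with_full_scan(self, small_ref):
        rng = np.random.default_rng(3)
        genome = small_ref.sequences["chr1"]
        for _ in range(20):
            start = int(rng.integers(0, len(genome) - 30))
            probe = genome[start : start + 30]
            hits = small_ref.locate(probe, max_hits=10)
            fwd = [i for i in range(len(genome) - 29)
                   if genome[i : i + 30] == probe]
            rc = reverse_complement(probe)
            rev = [i for i in range(len(genome) - 29)
                   if genome[i : i + 30] == rc]
            assert sorted(p for _, p, s in hits if s == "+") == fwd
            assert sorted(p for _, p, s in hits if s == "-") == rev

    def test_locate_finds_reverse_strand(self, small_ref):
        probe = reverse_complement(small_ref.sequences["chr1"][500:530])
        hits = small_ref.locate(probe)
        assert hits == [("chr1", 500, "-")]


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------


class TestMerging:
    def brute_force_merge(self, r1, r2, min_overlap=10, density=0.25):
        """Independent oracle: maximise matched bases over all overlaps."""
        rc2 = reverse_complement(r2)
        best, best_o = None, None
        for o in range(min_overlap, min(len(r1), len(r2)) + 1):
            mm = sum(x != y for x, y in zip(r1[len(r1) - o :], rc2[:o]))
            if mm <= density * o and (best is None or o - mm > best):
                best, best_o = o - mm, o
        return None if best_o is None else r1 + rc2[best_o:]

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            mol_len = int(rng.integers(75, 131))
            mol = "".join(rng.choice(list("ACGT"), size=mol_len))
            r1, r2 = mol[:75], reverse_complement(mol[-75:])
            assert merge_read_pairs(r1, r2) == self.brute_force_merge(r1, r2)

    def test_exact_overlap_reconstructs_molecule(self):
        rng = np.random.default_rng(6)
        mol = "".join(rng.choice(list("ACGT"), size=100))
        assert merge_read_pairs(mol[:75], reverse_complement(mol[-75:])) == mol

    def test_minimum_overlap_respected(self):
        rng = np.random.default_rng(8)
        r1 = "".join(rng.choice(list("ACGT"), size=40))
        # only a 5-base perfect tail overlap exists, below min_overlap=10
        r1 = r1[:-5] + "CCCCC"
        assert merge_read_pairs(r1, "GGGGG" + "A" * 35, min_overlap=10) is None

    def test_tolerates_mismatches_within_density(self):
        rng = np.random.default_rng(9)
        mol = "".join(rng.choice(list("ACGT"), size=110))
        r1, r2 = mol[:75], list(reverse_complement(mol[-75:]))
        # corrupt 3 bases inside the 40-base true overlap (density 0.075)
        for i in (5, 15, 25):
            r2[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r2[i]]
        merged = merge_read_pairs(r1, "".join(r2))
        assert merged is not None and len(merged) == 110
        assert merged[:75] == r1  # read1 wins at mismatches

    def test_empty_read_raises(self):
        with pytest.raises(ValueError):
            merge_read_pairs("", "ACGT")


# ---------------------------------------------------------------------------
# sub-read mapping
# ---------------------------------------------------------------------------


class TestMapping:
    def test_unique_hit_gets_quality_42(self, small_ref):
        seq = small_ref.sequences["chr1"][1000:1030]
        sub = map_subread(SubRead(seq, "r1"), small_ref)
        assert sub.uniqueness == "unique"
        assert sub.mapq == 42
        assert (sub.chrom, sub.start, sub.strand) == ("chr1", 1000, "+")

    def test_planted_repeat_maps_ambiguous_quality_0(self):
        rng = np.random.default_rng(10)
        core = "".join(rng.choice(list("ACGT"), size=25))
        filler1 = "".join(rng.choice(list("ACGT"), size=500))
        filler2 = "".join(rng.choice(list("ACGT"), size=500))
        genome = filler1 + core + filler2 + core + filler1[:100]
        ref = ReferenceIndex({"chr1": genome})
        # oracle: count occurrences by full scan
        occ = sum(
            genome[i : i + 25] == core for i in range(len(genome) - 24)
        )
        assert occ >= 2
        sub = map_subread(SubRead(core, "r1"), ref)
        assert sub.uniqueness == "multi"
        assert sub.mapq == 0

    def test_short_subread_flagged_not_searched(self, small_ref):
        sub = map_subread(SubRead("ACGTACGTACGTACGTACG", "r1"), small_ref)
        assert sub.short and sub.uniqueness == "none"

    def test_junction_gatc_trim_rescues_reverse_orientation_piece(self, small_ref):
        # a GATC-prefixed probe whose body exists in the genome but whose
        # GATC belongs to the upstream fragment on this orientation
        body = small_ref.sequences["chr1"][2001:2031]
        assert small_ref.locate("GATC" + body) == []
        sub = map_subread(SubRead("GATC" + body, "r1"), small_ref)
        assert sub.uniqueness == "unique"
        assert sub.junction_trimmed
        assert sub.start == 2001

    def test_unmappable_sequence_stays_unmapped(self, small_ref):
        sub = map_subread(SubRead("N" * 30, "r1"), small_ref)
        assert sub.uniqueness == "none"


# ---------------------------------------------------------------------------
# ditag classification
# ---------------------------------------------------------------------------


def _mapped(ref, chrom, pos, parent="r1", strand="+"):
    return SubRead("x" * 25, parent, chrom=chrom, start=pos, strand=strand,
                   uniqueness="unique", mapq=42)


class TestClassification:
    @pytest.fixture
    def baits(self, tiny_ref):
        return BaitSet.from_fragments(tiny_ref, [1], ids=["b1"])

    def test_two_distant_fragments_is_valid(self, tiny_ref, baits):
        dt = classify_ditag(
            [_mapped(tiny_ref, "chr1", 65), _mapped(tiny_ref, "chr2", 100)],
            tiny_ref, baits,
        )
        assert dt.category == "valid"
        assert dt.bait_ids == ("b1",)

    def test_same_fragment_twice_is_self_ligation(self, tiny_ref, baits):
        dt = classify_ditag(
            [_mapped(tiny_ref, "chr1", 10), _mapped(tiny_ref, "chr1", 30)],
            tiny_ref, baits,
        )
        assert dt.category == "self_ligation"

    def test_single_subread_is_uninformative(self, tiny_ref, baits):
        dt = classify_ditag([_mapped(tiny_ref, "chr1", 10)], tiny_ref, baits)
        assert dt.category == "uninformative"

    def test_adjacent_fragments_is_re_ligation(self, tiny_ref, baits):
        dt = classify_ditag(
            [_mapped(tiny_ref, "chr1", 10), _mapped(tiny_ref, "chr1", 70)],
            tiny_ref, baits,
        )
        assert dt.category == "re_ligation"

    def test_same_id_distance_different_chrom_is_valid(self, tiny_ref, baits):
        # chr1 fragment 2 and chr2 fragment 3 are id-adjacent but unlinked
        dt = classify_ditag(
            [_mapped(tiny_ref, "chr1", 120), _mapped(tiny_ref, "chr2", 10)],
            tiny_ref, baits,
        )
        assert dt.category == "valid"

    def test_low_quality_precedence(self, tiny_ref, baits):
        bad = SubRead("x" * 25, "r1", chrom="chr1", start=10, strand="+",
                      uniqueness="multi", mapq=0)
        dt = classify_ditag([bad, _mapped(tiny_ref, "chr2", 100)], tiny_ref, baits)
        assert dt.category == "low_quality"

    def test_short_subread_precedence_over_low_quality(self, tiny_ref, baits):
        short = SubRead("x" * 5, "r1", short=True)
        bad = SubRead("x" * 25, "r1", uniqueness="multi", mapq=0)
        dt = classify_ditag([short, bad], tiny_ref, baits)
        assert dt.category == "short_subread"

    def test_empty_subread_list_raises(self, tiny_ref, baits):
        with pytest.raises(ValueError):
            classify_ditag([], tiny_ref, baits)


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


class TestDeduplication:
    def _dt(self, parent, frags):
        return Ditag(parent, tuple(frags), "valid")

    def test_repeat_fragment_sets_flagged(self):
        dts = [
            self._dt("r1", [("chr1", 1, "+"), ("chr1", 5, "+")]),
            self._dt("r2", [("chr1", 5, "+"), ("chr1", 1, "+")]),  # same set
            self._dt("r3", [("chr1", 1, "+"), ("chr1", 6, "+")]),
        ]
        out = deduplicate(dts)
        assert [d.duplicate for d in out] == [False, True, False]

    def test_idempotent(self):
        dts = [self._dt("r1", [("chr1", 1, "+")])] * 3
        once = deduplicate(dts)
        twice = deduplicate(once)
        assert [d.duplicate for d in once] == [d.duplicate for d in twice]

    def test_empty_fragment_sets_never_duplicates(self):
        dts = [Ditag("r1", (), "low_quality"), Ditag("r2", (), "low_quality")]
        assert [d.duplicate for d in deduplicate(dts)] == [False, False]


# ---------------------------------------------------------------------------
# reporter counting
# ---------------------------------------------------------------------------


class TestReporterCounting:
    @pytest.fixture
    def setup(self, small_ref):
        frags = small_ref.chrom_fragments("chr1")
        bait = frags[20]
        baits = BaitSet.from_fragments(small_ref, [bait.fragment_id], ids=["b1"])
        return small_ref, baits, bait

    def _valid(self, parent, fids, ref):
        frags = [(ref.fragment_by_id(f).chrom, f, "+") for f in fids]
        return Ditag(parent, tuple(frags), "valid")

    def test_reporter_counted_per_bait(self, setup):
        ref, baits, bait = setup
        dts = deduplicate([self._valid("r1", [bait.fragment_id, bait.fragment_id + 5], ref)])
        track = count_reporters(dts, baits, ref)
        assert track.counts[("b1", bait.fragment_id + 5)] == 1

    def test_exclusion_zone_skipped(self, setup):
        ref, baits, bait = setup
        dts = deduplicate([self._valid("r1", [bait.fragment_id, bait.fragment_id + 1], ref)])
        track = count_reporters(dts, baits, ref)
        assert track.total == 0
        assert track.qc["excluded_zone"] == 1

    def test_duplicates_not_counted(self, setup):
        ref, baits, bait = setup
        dt = self._valid("r1", [bait.fragment_id, bait.fragment_id + 5], ref)
        dts = deduplicate([dt, self._valid("r2", [bait.fragment_id, bait.fragment_id + 5], ref)])
        track = count_reporters(dts, baits, ref)
        assert track.counts[("b1", bait.fragment_id + 5)] == 1
        assert track.qc["duplicate"] == 1

    def test_bait_to_bait_set_aside(self, small_ref):
        frags = small_ref.chrom_fragments("chr1")
        b1, b2 = frags[20], frags[40]
        baits = BaitSet.from_fragments(
            small_ref, [b1.fragment_id, b2.fragment_id], ids=["b1", "b2"]
        )
        dt = Ditag("r1", (("chr1", b1.fragment_id, "+"), ("chr1", b2.fragment_id, "+")), "valid")
        track = count_reporters(deduplicate([dt]), baits, small_ref)
        assert track.total == 0
        assert track.qc["bait_to_bait"] == 1

    def test_unbaited_valid_tracked_in_qc(self, setup):
        ref, baits, bait = setup
        dts = deduplicate([self._valid("r1", [bait.fragment_id + 30, bait.fragment_id + 40], ref)])
        track = count_reporters(dts, baits, ref)
        assert track.total == 0
        assert track.qc["valid_unbaited"] == 1


# ---------------------------------------------------------------------------
# summarisation
# ---------------------------------------------------------------------------


class TestSummaries:
    def test_median_top_scores_small_cases(self):
        # 10 scores -> top decile is the single maximum
        assert median_top_scores(range(1, 11), 0.1) == 10
        # 20 scores -> top two, median is their mean
        assert median_top_scores(range(1, 21), 0.1) == 19.5
        with pytest.raises(ValueError):
            median_top_scores([], 0.1)

    def test_bin_counts_anchor_at_zero(self, small_ref):
        from asomics.capturec import ReporterTrack

        track = ReporterTrack()
        frag = small_ref.chrom_fragments("chr1")[10]
        track.counts[("b1", frag.fragment_id)] = 7
        binned = bin_counts(track, small_ref, "b1", bin_size=400)
        expected_bin = int(frag.midpoint // 400) * 400
        assert binned[("chr1", expected_bin)] == 7

    def test_group_mean_sd_and_region_score(self, small_ref):
        from asomics.capturec import ReporterTrack

        frag = small_ref.chrom_fragments("chr1")[10]
        tracks = {}
        for sample, n in (("s1", 4), ("s2", 8), ("s3", 6)):
            t = ReporterTrack()
            t.counts[("b1", frag.fragment_id)] = n
            tracks[sample] = t
        groups = {"s1": "case", "s2": "case", "s3": "control"}
        region = ("chr1", 0, 8000)
        table, summaries = summarize_tracks(tracks, groups, small_ref, "b1", region)
        b = int(frag.midpoint // 400) * 400
        row = table[table["start"] == b].iloc[0]
        assert row["case_mean"] == 6.0
        assert row["case_sd"] == 2.0  # population SD of (4, 8)
        assert row["control_mean"] == 6.0
        # top decile of 20 bins = 2 bins, one carrying all the signal
        assert summaries["case"] == 3.0

    def test_empty_region_raises(self, small_ref):
        with pytest.raises(ValueError):
            summarize_tracks({}, {}, small_ref, "b1", ("chr1", 100, 100))


# ---------------------------------------------------------------------------
# read-pair driver
# ---------------------------------------------------------------------------


class TestProcessReadPair:
    def test_three_fragment_molecule_classified_valid(self, small_ref, small_baits):
        bait = next(iter(small_baits))
        bait_frag = small_ref.fragment_by_id(bait.fragment_id)
        rep = small_ref.fragment_by_id(bait.fragment_id + 10)
        bys = small_ref.fragment_by_id(bait.fragment_id + 30)
        seq = small_ref.sequences["chr1"]
        mol = (
            seq[bait_frag.end - 30 : bait_frag.end]
            + seq[rep.start : rep.start + 40]
            + seq[bys.start : bys.start + 40]
        )
        r1, r2 = mol[:75], reverse_complement(mol[-75:])
        dt, merged = process_read_pair("r1", r1, r2, small_ref, small_baits)
        assert merged
        assert dt.category == "valid"
        assert set(dt.fragment_ids) == {
            bait.fragment_id, bait.fragment_id + 10, bait.fragment_id + 30
        }

    def test_mate_order_swap_gives_same_fragments(self, small_ref, small_baits):
        bait = next(iter(small_baits))
        bait_frag = small_ref.fragment_by_id(bait.fragment_id)
        rep = small_ref.fragment_by_id(bait.fragment_id + 10)
        bys = small_ref.fragment_by_id(bait.fragment_id + 30)
        seq = small_ref.sequences["chr1"]
        mol = (
            seq[bait_frag.end - 30 : bait_frag.end]
            + seq[rep.start : rep.start + 40]
            + seq[bys.start : bys.start + 40]
        )
        r1, r2 = mol[:75], reverse_complement(mol[-75:])
        dt_fwd, _ = process_read_pair("r1", r1, r2, small_ref, small_baits)
        dt_rev, _ = process_read_pair("r1", r2, r1, small_ref, small_baits)
        assert set(dt_fwd.fragment_ids) == set(dt_rev.fragment_ids)
        assert dt_fwd.category == dt_rev.category == "valid"
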