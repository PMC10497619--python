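"""Library design: selection, proximity filtering, assembly, coverage math."""

import numpy as np
import pytest

from barrierscreen import library_design as ld

from _oracles import min_boundary_distance


def _cand(id, score, category="CTCF", seq="ACGT" * 20, interval=None):
    return ld.CandidateElement(
        id=id, category=category, affinity_score=score, sequence=seq, interval=interval
    )


class TestRankSelect:
    def test_top_and_bottom_selection(self):
        pool = [_cand(i, s) for i, s in zip("abcde", [9, 7, 5, 3, 1])]
        top = ld.rank_select(pool, "CTCF", 2, from_top=True)
        bottom = ld.rank_select(pool, "CTCF", 2, from_top=False)
        assert [c.id for c in top] == ["a", "b"]
        assert [c.id for c in bottom] == ["e", "d"]

    def test_overdraw_raises_with_category_named(self):
        with pytest.raises(ld.LibrarySizeError, match="CTCF"):
            ld.rank_select([_cand("a", 1)], "CTCF", 2)

    def test_top_bottom_partition_matches_sort_oracle(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(size=500)
        pool = [_cand(f"c{i:03d}", s) for i, s in enumerate(scores)]
        top = ld.rank_select(pool, "CTCF", 450, from_top=True)
        bottom = ld.rank_select(pool, "CTCF", 50, from_top=False)
        assert {c.id for c in top} | {c.id for c in bottom} == {c.id for c in pool}
        assert not ({c.id for c in top} & {c.id for c in bottom})
        # brute-force oracle: plain sort by (score, id)
        ranked = sorted(pool, key=lambda c: (-c.affinity_score, c.id))
        assert [c.id for c in top] == [c.id for c in ranked[:450]]

    def test_ties_broken_lexicographically(self):
        pool = [_cand("b", 5), _cand("a", 5), _cand("c", 1)]
        assert [c.id for c in ld.rank_select(pool, "CTCF", 2)] == ["a", "b"]


class TestLadProximity:
    def test_element_near_boundary(self):
        el = _cand("m", 0, "MIR", interval=ld.GenomicInterval("chr1", 1000, 1250))
        near, far = ld.lad_proximity_filter(
            [el], [ld.GenomicInterval("chr1", 4000, 90000)], 5000
        )
        assert [e.id for e in near] == ["m"] and far == []

    def test_chromosome_mismatch_is_far(self):
        el = _cand("m", 0, "MIR", interval=ld.GenomicInterval("chr2", 1000, 1250))
        near, far = ld.lad_proximity_filter(
            [el], [ld.GenomicInterval("chr1", 4000, 90000)], 5000
        )
        assert near == [] and [e.id for e in far] == ["m"]

    def test_missing_interval_raises(self):
        with pytest.raises(ValueError, match="interval"):
            ld.lad_proximity_filter([_cand("m", 0, "MIR")], [], 5000)

    def test_partition_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(13)
        lads = []
        pos = 0
        for _ in range(10):
            pos += int(rng.integers(20_000, 100_000))
            length = int(rng.integers(30_000, 200_000))
            lads.append(ld.GenomicInterval(f"chr{rng.integers(1, 3)}", pos, pos + length))
            pos += length
        elements = []
        for i in range(200):
            start = int(rng.integers(0, 2_000_000))
            elements.append(
                _cand(
                    f"m{i}",
                    0,
                    "MIR",
                    interval=ld.GenomicInterval(
                        f"chr{rng.integers(1, 3)}", start, start + 250
                    ),
                )
            )
        near, far = ld.lad_proximity_filter(elements, lads, 5000)
        near_ids = {e.id for e in near}
        assert near_ids | {e.id for e in far} == {e.id for e in elements}
        for el in elements:
            pts = [
                p
                for lad in lads
                if lad.chrom == el.interval.chrom
                for p in (lad.start, lad.end)
            ]
            expect_near = min_boundary_distance(el.interval.start, el.interval.end, pts) < 5000
            assert (el.id in near_ids) == expect_near

    def test_element_deep_inside_lad_is_far(self):
        # inside a LAD but 50 kb from the nearest edge: not boundary-proximal
        el = _cand("m", 0, "MIR", interval=ld.GenomicInterval("chr1", 50_000, 50_250))
        lad = ld.GenomicInterval("chr1", 0, 200_000)
        near, far = ld.lad_proximity_filter([el], [lad], 5000)
        assert near == [] and [e.id for e in far] == ["m"]

    def test_element_spanning_boundary_has_distance_zero(self):
        el = _cand("m", 0, "MIR", interval=ld.GenomicInterval("chr1", 3900, 4150))
        near, _ = ld.lad_proximity_filter(
            [el], [ld.GenomicInterval("chr1", 4000, 90_000)], 1
        )
        assert [e.id for e in near] == ["m"]


class TestRandomElements:
    def test_requested_count_length_and_exclusion(self):
        els = ld.generate_random_elements(50, 250, seed=1)
        assert len(els) == 50
        for e in els:
            assert len(e.sequence) == 250
            assert "CGTCTC" not in e.sequence and "GAGACG" not in e.sequence

    def test_empty_request(self):
        assert ld.generate_random_elements(0, 250, seed=1) == []

    def test_base_composition_is_uniform(self):
        els = ld.generate_random_elements(1000, 30, seed=7)
        counts = np.zeros((30, 4))
        idx = {b: i for i, b in enumerate("ACGT")}
        for e in els:
            for pos, b in enumerate(e.sequence):
                counts[pos, idx[b]] += 1
        # binomial 3-sigma band around n*p (the Esp3I rejection bias is
        # negligible at this length)
        sigma = np.sqrt(1000 * 0.25 * 0.75)
        assert np.abs(counts - 250).max() <= 3.6 * sigma

    def test_impossible_exclusion_raises(self):
        with pytest.raises(ld.GenerationError):
            ld.generate_random_elements(
                1, 10, excluded_sites=["A", "C", "G", "T"], seed=0, max_attempts=50
            )

    def test_reproducible_for_fixed_seed(self):
        a = ld.generate_random_elements(5, 100, seed=9)
        b = ld.generate_random_elements(5, 100, seed=9)
        assert [x.sequence for x in a] == [x.sequence for x in b]


class TestAdjustLength:
    def test_centered_trim_even_excess(self):
        el = _cand("x", 0, seq="A" * 5 + "C" * 250 + "A" * 5)
        out = ld.adjust_length(el, 250)
        assert out.sequence == "C" * 250

    def test_identity_when_exact(self):
        el = _cand("x", 0, seq="ACGT" * 62 + "AC")
        assert ld.adjust_length(el, 250).sequence == el.sequence

    def test_odd_excess_keeps_extra_base_at_five_prime(self):
        seq = "".join(np.random.default_rng(3).choice(list("ACGT"), 251))
        out = ld.adjust_length(_cand("x", 0, seq=seq), 250)
        assert out.sequence == seq[0:250]  # extra base trimmed from 3' side

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="below core length"):
            ld.adjust_length(_cand("x", 0, seq="ACGT"), 250)


class TestAssembleOligo:
    def test_flanked_oligo_is_300_bp(self):
        el = ld.LibraryElement("x", "RANDOM", "A" * 250)
        out = ld.assemble_oligo(el, "G" * 25, "C" * 25)
        assert len(out.oligo_sequence) == 300
        assert out.oligo_sequence == "G" * 25 + "A" * 250 + "C" * 25

    def test_zero_flank_identity(self):
        el = ld.LibraryElement("x", "RANDOM", "ACGT")
        assert ld.assemble_oligo(el, "", "", flank_total=0).oligo_sequence == "ACGT"

    def test_inconsistent_flanks_raise(self):
        el = ld.LibraryElement("x", "RANDOM", "ACGT")
        with pytest.raises(ValueError, match="flank"):
            ld.assemble_oligo(el, "G" * 20, "C" * 25)

    def test_core_found_at_flank_offset(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            core = "".join(rng.choice(list("ACGT"), 40))
            lf = "".join(rng.choice(list("ACGT"), rng.integers(0, 20)))
            rf = "".join(rng.choice(list("ACGT"), 8))
            out = ld.assemble_oligo(
                ld.LibraryElement("x", "RANDOM", core), lf, rf, len(lf) + len(rf)
            )
            assert out.oligo_sequence.find(core) <= len(lf)
            assert out.oligo_sequence[len(lf) : len(lf) + 40] == core


class TestCoverageArithmetic:
    @pytest.mark.parametrize(
        "cfu,size,expected", [(472_000, 1000, 472.0), (842_000, 1000, 842.0), (0, 10, 0.0)]
    )
    def test_fold_coverage(self, cfu, size, expected):
        assert ld.fold_coverage(cfu, size) == expected

    def test_fold_coverage_zero_library_raises(self):
        with pytest.raises(ZeroDivisionError):
            ld.fold_coverage(100, 0)

    def test_expected_clones(self):
        assert ld.expected_clones(24, 600_000, 0.004) == 57_600
        assert ld.expected_clones(0, 600_000, 0.004) == 0

    def test_expected_clones_bad_efficiency(self):
        with pytest.raises(ValueError):
            ld.expected_clones(1, 1, 1.5)

    def test_linearity_in_counts(self):
        base = ld.expected_clones(3, 1000, 0.1)
        assert ld.expected_clones(6, 1000, 0.1) == 2 * base
        assert ld.fold_coverage(500, 100) == 5 * ld.fold_coverage(100, 100)


class TestAssembleLibrary:
    def test_quota_conservation(self, designed_library):
        from collections import Counter

        counts = Counter(el.category_label for el in designed_library)
        assert counts == {
            "CTCF-High": 450,
            "CTCF-Low": 50,
            "MIR-LAD_bound": 30,
            "MIR-random": 420,
            "RANDOM": 50,
        }
        assert len(designed_library) == 1000

    def test_uniform_lengths_and_no_excluded_sites(self, designed_library):
        spec = ld.LibrarySpec()
        for el in designed_library:
            assert len(el.core_sequence) == 250
            assert len(el.oligo_sequence) == 300
            assert el.core_sequence in el.oligo_sequence
            assert not ld.contains_excluded_site(el.oligo_sequence, spec.excluded_sites)

    def test_unique_ids(self, designed_library):
        ids = [el.id for el in designed_library]
        assert len(set(ids)) == len(ids)


class TestIO:
    def test_candidate_table_round_trip(self, tmp_path):
        cands = [
            _cand("a", 1.5, "CTCF"),
            _cand("m", 0.0, "MIR", interval=ld.GenomicInterval("chr2", 10, 300, "+")),
        ]
        path = tmp_path / "cands.tsv"
        ld.write_candidate_table(cands, path)
        back = ld.read_candidate_table(path)
        assert back == cands

    def test_bed_round_trip(self, tmp_path):
        ivs = [ld.GenomicInterval("chr1", 0, 100), ld.GenomicInterval("chr2", 5, 50)]
        path = tmp_path / "lads.bed"
        ld.write_bed(ivs, path)
        assert ld.read_bed(path) == ivs

    def test_library_fasta_and_manifest(self, tmp_path, small_library):
        fa = tmp_path / "lib.fasta"
        ld.write_library_fasta(small_library, fa, oligo=True)
        back = ld.read_library_fasta(fa, oligo=True)
        assert [el.id for el in back] == [el.id for el in small_library]
        assert [el.oligo_sequence for el in back] == [
            el.oligo_sequence for el in small_library
        ]
        mf = tmp_path / "manifest.tsv"
        ld.write_manifest(small_library, mf)
        df = ld.read_manifest(mf)
        assert len(df) == len(small_library)
        assert (df["oligo_length"] == 100).all()
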