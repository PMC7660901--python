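"""Interrupted-gene detection: identity filtering, fragment grouping,
strand/window rules, origin spanning and rotation invariance."""

import pytest

from pak.fixtures import SplitGeneSpec, make_split_gene_records
from pak.interrupted_genes import (
    InterruptedParams,
    detect_interrupted,
    filter_low_identity_hsps,
)
from pak.model import (
    AlignmentRecord,
    DataError,
    Feature,
    FeatureSet,
    GenomeSequence,
    Hsp,
)


def _hsp(s_lo, s_hi, ident=None, alen=None, bits=200.0):
    alen = alen or (s_hi - s_lo + 1)
    ident = ident if ident is not None else int(alen * 0.9)
    return Hsp(1, alen, s_lo, s_hi, ident, alen, 1e-20, bits)


class TestIdentityFilter:
    def test_below_threshold_discarded(self):
        rec = AlignmentRecord("q", "s", [_hsp(1, 100, ident=20, alen=100)])
        assert filter_low_identity_hsps([rec]) == []

    def test_exactly_threshold_retained(self):
        rec = AlignmentRecord("q", "s", [_hsp(1, 100, ident=30, alen=100)])
        (out,) = filter_low_identity_hsps([rec])
        assert len(out.hsps) == 1

    def test_record_dropped_when_all_hsps_fail(self):
        rec = AlignmentRecord(
            "q", "s", [_hsp(1, 100, ident=10, alen=100), _hsp(1, 50, ident=40, alen=50)]
        )
        (out,) = filter_low_identity_hsps([rec])
        assert len(out.hsps) == 1 and out.hsps[0].identities == 40

    def test_idempotent_and_monotone(self):
        recs = [
            AlignmentRecord("q", "s", [_hsp(1, 100, ident=i, alen=100)])
            for i in (10, 30, 50, 90)
        ]
        once = filter_low_identity_hsps(recs)
        assert filter_low_identity_hsps(once) == once
        stricter = filter_low_identity_hsps(recs, 0.6)
        loose_ids = {r.hsps[0].identities for r in once}
        strict_ids = {r.hsps[0].identities for r in stricter}
        assert strict_ids <= loose_ids


def _scene(positions, strands=None, subject_intervals=None):
    """Build (records, features, genome) for fragments at given genomic
    positions hitting one subject."""
    strands = strands or ["+"] * len(positions)
    subject_intervals = subject_intervals or [
        (1 + 130 * i, 120 + 130 * i) for i in range(len(positions))
    ]
    fs = FeatureSet()
    records = []
    for i, ((a, b), st, (lo, hi)) in enumerate(
        zip(positions, strands, subject_intervals)
    ):
        qid = f"q{i}"
        fs.add(Feature(qid, "CDS", "g", a, b, st))
        records.append(AlignmentRecord(qid, "subj", [_hsp(lo, hi)]))
    genome = GenomeSequence("g", "A" * 40_000)
    return records, fs, genome


class TestDetect:
    def test_two_fragments_ordered_along_subject(self):
        records, fs, genome = _scene([(5000, 5900), (7900, 8800)])
        (cand,) = detect_interrupted(records, fs, genome, InterruptedParams())
        assert [f.feature_id for f in cand.fragments] == ["q0", "q1"]
        assert cand.genomic_gaps_nt == [1999]
        assert cand.subject_intervals == [(1, 120), (131, 250)]

    def test_single_query_is_not_a_candidate(self):
        records, fs, genome = _scene([(5000, 5900)])
        assert detect_interrupted(records, fs, genome, InterruptedParams()) == []

    def test_opposite_strands_rejected(self):
        records, fs, genome = _scene([(5000, 5900), (7900, 8800)], strands=["+", "-"])
        assert detect_interrupted(records, fs, genome, InterruptedParams()) == []

    def test_unresolvable_query_id_is_an_error(self):
        records, fs, genome = _scene([(5000, 5900), (7900, 8800)])
        records.append(AlignmentRecord("ghost", "subj", [_hsp(1, 50)]))
        with pytest.raises(DataError, match="ghost"):
            detect_interrupted(records, fs, genome, InterruptedParams())

    def test_window_boundary_15kb_needs_wider_window(self):
        records, fs, genome = _scene([(5000, 5900), (20_901, 21_800)])
        assert detect_interrupted(records, fs, genome, InterruptedParams()) == []
        wide = InterruptedParams(max_sep_nt=20_000)
        (cand,) = detect_interrupted(records, fs, genome, wide)
        assert cand.subject_id == "subj"

    def test_overlapping_subject_intervals_need_negative_sep_min(self):
        records, fs, genome = _scene(
            [(5000, 5900), (7900, 8800)],
            subject_intervals=[(1, 120), (100, 220)],  # 21-residue overlap
        )
        assert detect_interrupted(records, fs, genome, InterruptedParams(sep_min=0)) == []
        allow = InterruptedParams(sep_min=-30)
        (cand,) = detect_interrupted(records, fs, genome, allow)
        assert len(cand.fragments) == 2

    def test_positive_sep_min_requires_subject_separation(self):
        records, fs, genome = _scene(
            [(5000, 5900), (7900, 8800)],
            subject_intervals=[(1, 120), (126, 245)],  # separation of 5
        )
        assert len(detect_interrupted(records, fs, genome, InterruptedParams(sep_min=5))) == 1
        assert detect_interrupted(records, fs, genome, InterruptedParams(sep_min=6)) == []


class TestFixtureScenarios:
    def test_split_gene_detected_and_noise_ignored(self):
        fx = make_split_gene_records(SplitGeneSpec(seed=2))
        records = filter_low_identity_hsps(fx.records)
        cands = detect_interrupted(records, fx.features, fx.genome, InterruptedParams())
        assert [c.subject_id for c in cands] == [fx.split_subject]
        (cand,) = cands
        assert [f.feature_id for f in cand.fragments] == fx.split_queries
        assert not cand.spans_origin

    def test_noise_only_scene_gives_no_candidates(self):
        fx = make_split_gene_records(SplitGeneSpec(seed=3))
        noise = [r for r in fx.records if r.subject_id != fx.split_subject]
        cands = detect_interrupted(
            filter_low_identity_hsps(noise), fx.features, fx.genome, InterruptedParams()
        )
        assert cands == []

    def test_origin_spanning_needs_circular_flag(self):
        fx = make_split_gene_records(SplitGeneSpec(seed=4, across_origin=True))
        records = filter_low_identity_hsps(fx.records)
        linear = detect_interrupted(records, fx.features, fx.genome, InterruptedParams())
        assert fx.split_subject not in [c.subject_id for c in linear]
        circ = detect_interrupted(
            records, fx.features, fx.genome, InterruptedParams(circular=True)
        )
        (cand,) = [c for c in circ if c.subject_id == fx.split_subject]
        assert cand.spans_origin
        # fragments at 200..900 and L-800..L-50: wrap distance is 249 nt
        assert cand.genomic_gaps_nt == [249]

    @pytest.mark.parametrize("offset", [1, 137, 9000, 25_000])
    def test_rotation_invariance_on_circular_genome(self, offset):
        fx = make_split_gene_records(SplitGeneSpec(seed=5))
        L = len(fx.genome)
        params = InterruptedParams(circular=True)

        def rotate(fs: FeatureSet) -> FeatureSet:
            out = FeatureSet()
            for f in fs:
                f2 = f.copy()
                f2.start = (f.start - 1 + offset) % L + 1
                f2.end = (f.end - 1 + offset) % L + 1
                if f2.start > f2.end:  # fragment would split: skip this offset
                    pytest.skip("rotation splits a feature")
                out.add(f2)
            return out

        genome_rot = GenomeSequence(fx.genome.id, fx.genome.seq[-offset:] + fx.genome.seq[:-offset])
        records = filter_low_identity_hsps(fx.records)
        base = detect_interrupted(records, fx.features, fx.genome, params)
        rot = detect_interrupted(records, rotate(fx.features), genome_rot, params)

        def key(cands):
            return sorted(
                (c.subject_id, tuple(f.feature_id for f in c.fragments),
                 tuple(c.genomic_gaps_nt))
                for c in cands
            )

        assert key(base) == key(rot)

    def test_output_invariants_hold(self):
        fx = make_split_gene_records(SplitGeneSpec(seed=6))
        cands = detect_interrupted(
            filter_low_identity_hsps(fx.records), fx.features, fx.genome,
            InterruptedParams(),
        )
        for c in cands:
            assert len(c.fragments) >= 2
            assert len({f.strand for f in c.fragments}) == 1
            assert all(g <= 10_000 for g in c.genomic_gaps_nt)
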