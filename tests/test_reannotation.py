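"""Coverage merging, distal-end detection and integration rules."""
import numpy as np
import pytest

from utrtar.models import GenomicInterval, TranscriptModel
from utrtar.reannotation import (
    CoverageTrack,
    ReannotationParams,
    ReannotationResult,
    apply_reannotations,
    downstream_clip_bounds,
    merge_replicates,
    propose_distal_end,
)

from conftest import dense_track, mean_coverage_oracle

PARAMS = ReannotationParams()


def _utr_model(tid="t", utr=(1000, 2000), strand="+", cds=300):
    """Single-exon-UTR transcript; the terminal exon ends at the UTR end."""
    s, e = utr
    if strand == "+":
        exons = [GenomicInterval("c", s - cds - 100, s - 100, strand),
                 GenomicInterval("c", s - 50, e, strand)]
        utr3 = [GenomicInterval("c", s, e, strand)]
    else:
        exons = [GenomicInterval("c", s, e + 50, strand),
                 GenomicInterval("c", e + 100, e + 100 + cds, strand)]
        utr3 = [GenomicInterval("c", s, e, strand)]
    m = TranscriptModel(tid, f"g_{tid}", "protein_coding", exons=exons, utr3=utr3)
    m.validate()
    return m


def _track(ivs, chrom="c"):
    return CoverageTrack({chrom: ivs})


class TestCoverageTrack:
    def test_bedgraph_round_trip_exact(self, tmp_path):
        track = _track([(0, 10, 6), (15, 40, 2.5), (40, 60, 1)])
        path = tmp_path / "a.bedgraph"
        track.write_bedgraph(path)
        assert CoverageTrack.read_bedgraph(path).intervals == track.intervals

    def test_zero_intervals_dropped_and_neighbours_coalesced(self):
        track = _track([(0, 10, 2), (10, 20, 2), (20, 30, 0)])
        assert track.intervals["c"] == [(0, 20, 2.0)]

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError):
            _track([(0, 10, 1), (5, 15, 1)])

    def test_values_defaults_to_zero_off_track(self):
        track = _track([(5, 8, 3)])
        assert list(track.values("c", 0, 10)) == [0, 0, 0, 0, 0, 3, 3, 3, 0, 0]
        assert list(track.values("absent", 0, 3)) == [0, 0, 0]

    def test_from_array_run_length_encoding(self):
        arr = np.array([0, 0, 2, 2, 3, 0, 1])
        track = CoverageTrack.from_array("c", arr, offset=100)
        assert track.intervals["c"] == [(102, 104, 2.0), (104, 105, 3.0), (106, 107, 1.0)]


class TestMergeReplicates:
    def test_single_track_identity(self):
        track = _track([(0, 10, 6), (20, 30, 2)])
        assert merge_replicates([track]).intervals == track.intervals

    def test_mean_over_same_interval(self):
        merged = merge_replicates([_track([(0, 10, 2)]), _track([(0, 10, 4)])])
        assert merged.intervals["c"] == [(0, 10, 3.0)]

    def test_partial_overlap_atomic_segments(self):
        merged = merge_replicates([_track([(0, 10, 6)]), _track([(5, 15, 2)])])
        assert merged.intervals["c"] == [(0, 5, 3.0), (5, 10, 4.0), (10, 15, 1.0)]

    def test_empty_track_list_rejected(self):
        with pytest.raises(ValueError):
            merge_replicates([])

    def test_against_per_base_oracle_on_random_sparse_tracks(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tracks = []
            for _t in range(int(rng.integers(1, 5))):
                n_iv = int(rng.integers(1, 12))
                ivs = []
                pos = 0
                for _i in range(n_iv):
                    pos += int(rng.integers(0, 800))
                    end = pos + int(rng.integers(1, 500))
                    if end > 9900:
                        break
                    ivs.append((pos, end, float(rng.integers(0, 8))))
                    pos = end
                tracks.append(_track(ivs))
            merged = merge_replicates(tracks)
            np.testing.assert_allclose(
                dense_track(merged, "c", 10000),
                mean_coverage_oracle(tracks, "c", 10000),
            )


class TestProposeDistalEnd:
    def _flat_track(self, lo, hi, depth=20.0):
        return _track([(lo, hi, depth)])

    def test_coverage_matching_annotation_is_unchanged(self):
        model = _utr_model()
        res = propose_distal_end(model, self._flat_track(700, 2000), PARAMS)
        assert res.outcome == "unchanged"
        assert res.new_distal_end == res.old_distal_end == 2000

    def test_extension_past_annotated_end(self):
        model = _utr_model()
        res = propose_distal_end(model, self._flat_track(700, 2400), PARAMS)
        assert res.outcome == "extended"
        assert abs(res.bases_delta - 400) <= PARAMS.window_w
        assert res.new_distal_end == 2000 + res.bases_delta

    def test_truncation_when_coverage_stops_early(self):
        model = _utr_model()
        res = propose_distal_end(model, self._flat_track(700, 1500), PARAMS)
        assert res.outcome == "truncated"
        assert abs(res.bases_delta + 500) <= PARAMS.window_w

    def test_noise_free_recovery_is_exact(self):
        # step-edge coverage is recovered to the base by the refinement pass
        model = _utr_model()
        for true_end in (1480, 2000, 2333):
            res = propose_distal_end(model, self._flat_track(700, true_end), PARAMS)
            new = res.new_distal_end if res.outcome != "unchanged" else 2000
            if abs(true_end - 2000) > PARAMS.min_delta:
                assert new == true_end

    def test_minus_strand_mirror(self):
        model = _utr_model(strand="-")
        res = propose_distal_end(model, self._flat_track(600, 2300), PARAMS)
        assert res.outcome == "extended"
        assert res.bases_delta == 400
        assert res.new_distal_end == 600

    def test_strand_symmetry_of_delta(self):
        # same geometry mirrored around the chromosome midpoint
        L = 3000
        plus = _utr_model(utr=(1000, 2000), strand="+")
        minus = _utr_model(utr=(L - 2000, L - 1000), strand="-")
        track_plus = self._flat_track(700, 2350)
        track_minus = _track([(L - 2350, L - 700, 20.0)])
        res_p = propose_distal_end(plus, track_plus, PARAMS)
        res_m = propose_distal_end(minus, track_minus, PARAMS)
        assert res_p.outcome == res_m.outcome == "extended"
        assert res_p.bases_delta == res_m.bases_delta

    def test_no_coverage_is_skipped_not_error(self):
        model = _utr_model()
        res = propose_distal_end(model, CoverageTrack(), PARAMS)
        assert (res.outcome, res.skip_reason) == ("skipped", "no_coverage")
        assert res.new_distal_end == res.old_distal_end

    def test_multi_exon_and_missing_utr_are_skipped(self):
        multi = _utr_model()
        multi.utr3 = [GenomicInterval("c", 1000, 1400, "+"),
                      GenomicInterval("c", 1500, 2000, "+")]
        none = _utr_model()
        none.utr3 = []
        track = self._flat_track(700, 2000)
        assert propose_distal_end(multi, track, PARAMS).skip_reason == "multi_exon_utr"
        assert propose_distal_end(none, track, PARAMS).skip_reason == "no_utr_annotation"

    def test_extension_clipped_at_downstream_gene(self):
        model = _utr_model()
        track = self._flat_track(700, 4000)
        res = propose_distal_end(model, track, PARAMS, clip_at=2600)
        assert res.outcome == "extended"
        assert res.new_distal_end <= 2600

    def test_extension_clipped_at_chromosome_end(self):
        model = _utr_model()
        res = propose_distal_end(model, self._flat_track(700, 2500), PARAMS,
                                 chrom_length=2200)
        assert res.new_distal_end <= 2200

    def test_depth_scaling_never_turns_truncation_into_extension(self):
        # noise-free monotone depth property
        model = _utr_model()
        track = self._flat_track(700, 1500, depth=20.0)
        assert propose_distal_end(model, track, PARAMS).outcome == "truncated"
        for s in (0.5, 0.2, 0.1, 0.04):
            res = propose_distal_end(model, track.scale(s), PARAMS)
            assert res.outcome in ("truncated", "skipped")


class TestApplyReannotations:
    def test_rule_gates_and_edge_preservation(self):
        models = {
            "multi": _utr_model("multi"),
            "noutr": _utr_model("noutr"),
            "lowtpm": _utr_model("lowtpm"),
            "hitpm": _utr_model("hitpm"),
        }
        models["multi"].utr3 = [GenomicInterval("c", 1000, 1400, "+"),
                                GenomicInterval("c", 1500, 2000, "+")]
        models["noutr"].utr3 = []
        results = [
            ReannotationResult("multi", 2000, 1500, "truncated", bases_delta=-500),
            ReannotationResult("noutr", -1, 1500, "extended", bases_delta=500),
            ReannotationResult("lowtpm", 2000, 1500, "truncated", bases_delta=-500),
            ReannotationResult("hitpm", 2000, 1500, "truncated", bases_delta=-500),
        ]
        tpm = {"lowtpm": 2.0, "hitpm": 7.0}
        new_models, final = apply_reannotations(
            list(models.values()), results, tpm, PARAMS
        )
        outcome = {r.transcript_id: (r.outcome, r.skip_reason) for r in final}
        assert outcome["multi"] == ("skipped", "multi_exon_utr")
        assert outcome["noutr"] == ("skipped", "no_utr_annotation")
        assert outcome["lowtpm"] == ("skipped", "low_expression_truncation")
        assert outcome["hitpm"] == ("truncated", "none")
        by_tid = {m.transcript_id: m for m in new_models}
        assert by_tid["hitpm"].utr3 == [GenomicInterval("c", 1000, 1500, "+")]
        assert by_tid["hitpm"].exons[-1].end == 1500
        # 5' UTR edges untouched everywhere
        for tid, m in by_tid.items():
            if m.utr3:
                assert m.utr3_five_prime_edge() == models[tid].utr3_five_prime_edge()
        # untouched models are structurally identical
        assert by_tid["multi"].utr3 == models["multi"].utr3
        assert by_tid["noutr"].exons == models["noutr"].exons

    def test_extension_not_gated_by_expression(self):
        model = _utr_model("x")
        res = ReannotationResult("x", 2000, 2400, "extended", bases_delta=400)
        new_models, final = apply_reannotations([model], [res], {}, PARAMS)
        assert final[0].outcome == "extended"
        assert new_models[0].utr3[0].end == 2400
        assert new_models[0].exons[-1].end == 2400

    def test_missing_tpm_blocks_truncation(self):
        model = _utr_model("x")
        res = ReannotationResult("x", 2000, 1500, "truncated", bases_delta=-500)
        _nm, final = apply_reannotations([model], [res], {}, PARAMS)
        assert final[0].skip_reason == "low_expression_truncation"

    def test_unknown_transcript_in_results_rejected(self):
        with pytest.raises(ValueError, match="unknown transcript"):
            apply_reannotations(
                [_utr_model("x")],
                [ReannotationResult("ghost", 0, 0, "unchanged")],
                {}, PARAMS,
            )

    def test_minus_strand_truncation_moves_start_only(self):
        model = _utr_model("m", strand="-")
        res = ReannotationResult("m", 1000, 1400, "truncated", bases_delta=-400)
        new_models, _f = apply_reannotations([model], [res], {"m": 10.0}, PARAMS)
        assert new_models[0].utr3 == [GenomicInterval("c", 1400, 2000, "-")]
        assert new_models[0].exons[0].start == 1400
        assert new_models[0].utr3_five_prime_edge() == 2000


class TestDownstreamClip:
    def test_nearest_same_strand_gene_bounds_search(self):
        a = _utr_model("a", utr=(1000, 2000), strand="+")
        b = _utr_model("b", utr=(6000, 7000), strand="+")
        c = _utr_model("c", utr=(6000, 7000), strand="-")
        bounds = downstream_clip_bounds([a, b, c])
        # a's extension must stop at b's gene span start (b's upstream exon)
        assert bounds["a"] == b.span[0]
        assert "b" not in bounds  # nothing downstream of b on '+'


class TestParams:
    def test_invalid_parameter_combinations_rejected(self):
        with pytest.raises(ValueError):
            ReannotationParams(window_w=10, step=20)
        with pytest.raises(ValueError):
            ReannotationParams(cov_fraction=0.0)
        with pytest.raises(ValueError):
            ReannotationParams(min_delta=-1)
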