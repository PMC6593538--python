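"""Pooling (single-linkage per ROI) and consensus/panel ground truth."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfstudy.errors import (
    IncompleteTruthError,
    PoolingAmbiguityError,
    TruthConflictError,
)
from mfstudy.model import Mark
from mfstudy.pooling import (
    PoolingConfig,
    auto_consensus_truth,
    merge_adjudication,
    pool_marks,
    reference_multiplicity,
)


def mark(reader, modality, x, y=50.0, slide="S1", roi="S1-ROI1"):
    return Mark(reader, modality, slide, roi, float(x), float(y))


class TestPoolMarks:
    def test_marks_within_radius_form_one_candidate(self):
        cands, matrix = pool_marks([mark("R1", "m", 10.0), mark("R2", "m", 14.0)])
        assert len(cands) == 1
        assert matrix.marks.sum() == 2

    def test_marks_beyond_radius_stay_separate(self):
        cands, _ = pool_marks([mark("R1", "m", 10.0), mark("R2", "m", 35.0)])
        assert len(cands) == 2

    def test_chaining_joins_transitively(self):
        cands, _ = pool_marks(
            [mark("R1", "m", 0.0), mark("R2", "m", 8.0), mark("R3", "m", 16.0)]
        )
        assert len(cands) == 1

    def test_candidates_never_span_rois(self):
        # same coordinates but different ROIs -> never pooled together
        a = mark("R1", "m", 10.0, roi="S1-ROI1")
        b = mark("R2", "m", 10.0, roi="S1-ROI2")
        cands, _ = pool_marks([a, b])
        assert len(cands) == 2

    def test_centroid_is_mean_of_member_positions(self):
        cands, _ = pool_marks([mark("R1", "m", 10.0, 20.0), mark("R2", "m", 14.0, 28.0)])
        assert cands[0].centroid_x_um == pytest.approx(12.0)
        assert cands[0].centroid_y_um == pytest.approx(24.0)

    def test_same_reader_modality_in_one_cluster_is_ambiguous(self):
        with pytest.raises(PoolingAmbiguityError):
            pool_marks([mark("R1", "m", 10.0), mark("R1", "m", 13.0)])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 25))
    def test_matches_graph_connected_components(self, seed, n):
        """Single-linkage pooling equals connected components of the <=radius graph."""
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 120, size=(n, 2))
        radius = float(rng.uniform(3, 25))
        # unique (reader, modality) per mark avoids the ambiguity error
        marks = [mark(f"R{i}", "m", x, y) for i, (x, y) in enumerate(xy)]
        cands, _ = pool_marks(marks, PoolingConfig(match_radius_um=radius))

        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(xy[i] - xy[j])) <= radius:
                    g.add_edge(i, j)
        expected = {
            frozenset((round(xy[i][0], 6), round(xy[i][1], 6)) for i in comp)
            for comp in nx.connected_components(g)
        }
        got = {
            frozenset((round(m.x_um, 6), round(m.y_um, 6)) for m in c.member_marks)
            for c in cands
        }
        assert got == expected

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        marks = [
            mark(f"R{i % 4}", f"m{i % 3}", rng.uniform(0, 150), rng.uniform(0, 150))
            for i in range(30)
        ]
        cands_a, _ = pool_marks(marks)
        shuffled = list(marks)
        rng.shuffle(shuffled)
        cands_b, _ = pool_marks(shuffled)
        key = lambda c: (c.candidate_id, frozenset((m.x_um, m.y_um) for m in c.member_marks))
        assert sorted(map(key, cands_a)) == sorted(map(key, cands_b))


class TestMultiplicityAndConsensus:
    def test_study_shaped_histogram(self, study_shaped_matrix, small_design):
        hist = reference_multiplicity(study_shaped_matrix, small_design)
        assert list(hist.counts_by_multiplicity) == [60, 28, 13, 17, 8, 29]
        assert hist.n_reference_detected == 95
        assert hist.n_reference_only_missed == 60

    def test_all_zero_reference_column_lands_in_k0(self, small_design):
        from conftest import make_matrix

        arr = np.zeros((5, 5, 10), dtype=np.int8)
        arr[0, 0, :] = 1  # scanner marks only
        hist = reference_multiplicity(make_matrix(arr), small_design)
        assert hist.counts_by_multiplicity[0] == 10
        assert hist.n_reference_detected == 0

    def test_consensus_thresholds(self, study_shaped_matrix, small_design):
        assert len(auto_consensus_truth(study_shaped_matrix, small_design, 4)) == 37
        assert len(auto_consensus_truth(study_shaped_matrix, small_design, 5)) == 29
        assert len(auto_consensus_truth(study_shaped_matrix, small_design, 1)) == 95

    def test_consensus_is_monotone_in_threshold(self, study_shaped_matrix, small_design):
        sets = [
            auto_consensus_truth(study_shaped_matrix, small_design, k) for k in range(1, 6)
        ]
        for lower, higher in zip(sets, sets[1:]):
            assert higher <= lower

    def test_random_matrix_histogram_matches_direct_recount(self, small_design):
        from conftest import make_matrix

        rng = np.random.default_rng(11)
        arr = (rng.uniform(size=(5, 5, 40)) < 0.4).astype(np.int8)
        arr[0, 0, arr.sum(axis=(0, 1)) == 0] = 1  # every candidate marked somewhere
        matrix = make_matrix(arr)
        hist = reference_multiplicity(matrix, small_design)
        mic = matrix.modality_index("microscope")
        direct = [0] * 6
        for c in range(arr.shape[2]):
            direct[int(sum(arr[r, mic, c] for r in range(5)))] += 1
        assert list(hist.counts_by_multiplicity) == direct


class TestMergeAdjudication:
    def _pool(self, matrix):
        return matrix.candidates

    def test_study_arithmetic_37_auto_plus_37_panel_gives_74(
        self, study_shaped_matrix, small_design
    ):
        auto = auto_consensus_truth(study_shaped_matrix, small_design, 4)
        rest = [c for c in study_shaped_matrix.candidate_ids if c not in auto]
        assert len(rest) == 118
        panel = {cid: (i < 37) for i, cid in enumerate(rest)}
        truth = merge_adjudication(auto, panel, self._pool(study_shaped_matrix))
        assert truth.n_true == 74
        assert truth.n_false == 81

    def test_empty_panel_with_full_auto_coverage(self, study_shaped_matrix, small_design):
        auto = set(study_shaped_matrix.candidate_ids)
        truth = merge_adjudication(auto, {}, self._pool(study_shaped_matrix))
        assert truth.n_true == study_shaped_matrix.n_candidates

    def test_all_false_panel_keeps_only_auto(self, study_shaped_matrix, small_design):
        auto = auto_consensus_truth(study_shaped_matrix, small_design, 4)
        panel = {c: False for c in study_shaped_matrix.candidate_ids if c not in auto}
        truth = merge_adjudication(auto, panel, self._pool(study_shaped_matrix))
        assert truth.n_true == len(auto)

    def test_uncovered_candidate_is_an_error(self, study_shaped_matrix, small_design):
        auto = auto_consensus_truth(study_shaped_matrix, small_design, 4)
        with pytest.raises(IncompleteTruthError):
            merge_adjudication(auto, {}, self._pool(study_shaped_matrix))

    def test_panel_contradicting_auto_conflicts_unless_overridden(
        self, study_shaped_matrix, small_design
    ):
        auto = auto_consensus_truth(study_shaped_matrix, small_design, 4)
        panel = {c: c not in auto for c in study_shaped_matrix.candidate_ids}
        some_auto = next(iter(auto))
        panel[some_auto] = False
        with pytest.raises(TruthConflictError):
            merge_adjudication(auto, panel, self._pool(study_shaped_matrix))
        truth = merge_adjudication(
            auto, panel, self._pool(study_shaped_matrix), auto_wins=True
        )
        assert truth.labels[some_auto] is True
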