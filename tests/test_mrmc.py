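"""Accuracy, jackknife covariance, reader-averaged analysis and Holm."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_matrix
from mfstudy.errors import (
    DegenerateJackknifeError,
    DegenerateTruthError,
    InsufficientDataError,
)
from mfstudy.model import TruthSet
from mfstudy.mrmc import (
    AUCMatrix,
    CovMatrix,
    auc_matrix,
    binary_auc,
    holm_adjust,
    jackknife_cov,
    reader_averaged_analysis,
    sens_spec,
)


def truth_for(matrix, labels):
    ids = matrix.candidate_ids
    return TruthSet(
        labels=dict(zip(ids, map(bool, labels))),
        provenance={c: "panel" for c in ids},
    )


def study_truth(n_true=74, n_false=81):
    """A study-shaped pool: first n_true candidates true, rest false."""
    n = n_true + n_false
    labels = [True] * n_true + [False] * n_false
    return n, labels


class TestSensSpec:
    def test_study_shaped_hand_division(self):
        n, labels = study_truth()
        arr = np.zeros((1, 2, n), dtype=np.int8)
        arr[0, 0, :60] = 1  # 60 of the 74 true
        arr[0, 0, 74:84] = 1  # 10 of the 81 false
        arr[0, 1, :] = 1  # padding modality keeps every candidate in the pool
        matrix = make_matrix(arr, modalities=["m", "pad"])
        s = sens_spec(arr[0, 0], truth_for(matrix, labels), matrix.candidate_ids)
        assert s.sensitivity == pytest.approx(0.8108, abs=1e-4)
        assert s.specificity == pytest.approx(0.8765, abs=1e-4)
        assert (s.tp, s.fp) == (60, 10)

    def test_mark_everything_and_nothing(self):
        n, labels = study_truth(5, 7)
        arr = np.ones((1, 1, n), dtype=np.int8)
        matrix = make_matrix(arr, modalities=["m"])
        truth = truth_for(matrix, labels)
        s_all = sens_spec(np.ones(n), truth, matrix.candidate_ids)
        assert (s_all.sensitivity, s_all.specificity) == (1.0, 0.0)
        s_none = sens_spec(np.zeros(n), truth, matrix.candidate_ids)
        assert (s_none.sensitivity, s_none.specificity) == (0.0, 1.0)

    def test_single_class_truth_is_degenerate(self):
        arr = np.ones((1, 1, 4), dtype=np.int8)
        matrix = make_matrix(arr, modalities=["m"])
        with pytest.raises(DegenerateTruthError):
            sens_spec(arr[0, 0], truth_for(matrix, [True] * 4), matrix.candidate_ids)


class TestBinaryAUC:
    def test_average_of_se_and_sp(self):
        n, labels = study_truth(10, 10)
        arr = np.zeros((1, 2, n), dtype=np.int8)
        arr[0, 0, :8] = 1
        arr[0, 0, 10:14] = 1
        arr[0, 1, :] = 1
        matrix = make_matrix(arr, modalities=["m", "pad"])
        s = sens_spec(arr[0, 0], truth_for(matrix, labels), matrix.candidate_ids)
        assert binary_auc(s) == pytest.approx((0.8 + 0.6) / 2)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_trapezoidal_roc_area(self, seed):
        """(Se+Sp)/2 is the area of the one-threshold ROC polygon."""
        rng = np.random.default_rng(seed)
        se, sp = rng.uniform(0, 1, size=2)
        fpr = np.array([0.0, 1.0 - sp, 1.0])
        tpr = np.array([0.0, se, 1.0])
        trapezoid = float(np.trapezoid(tpr, fpr))
        s = type("S", (), {"sensitivity": se, "specificity": sp})
        assert binary_auc(s) == pytest.approx(trapezoid)


class TestAUCMatrix:
    def test_reproduces_engineered_accuracy_column(self):
        """Integer tp/fp counts over 74/81 candidates hit printed accuracies."""
        targets = [0.764, 0.778, 0.806, 0.842, 0.802]
        n, labels = study_truth()
        arr = np.zeros((5, 2, n), dtype=np.int8)
        arr[:, 1, :] = 1  # padding modality keeps every candidate in the pool
        for r, t in enumerate(targets):
            found = False
            for tp in range(75):
                for fp in range(82):
                    if abs((tp / 74 + 1 - fp / 81) / 2 - t) < 5e-4:
                        arr[r, 0, :tp] = 1
                        arr[r, 0, 74 : 74 + fp] = 1
                        found = True
                        break
                if found:
                    break
            assert found
        matrix = make_matrix(arr, modalities=["microscope", "pad"])
        aucs = auc_matrix(matrix, truth_for(matrix, labels))
        assert np.round(aucs.auc[:, 0], 3) == pytest.approx(targets, abs=1e-9)

    def test_identical_readers_give_constant_rows(self):
        n, labels = study_truth(6, 6)
        row = np.zeros(n, dtype=np.int8)
        row[:4] = 1
        pad = np.ones(n, dtype=np.int8)
        arr = np.stack([np.stack([row, row, pad])] * 3)  # 3 readers x (2 modalities + pad)
        matrix = make_matrix(arr, modalities=["a", "b", "pad"])
        aucs = auc_matrix(matrix, truth_for(matrix, labels))
        assert np.ptp(aucs.auc[:, :2]) == 0.0

    def test_matches_per_cell_recomputation(self):
        rng = np.random.default_rng(8)
        n = 50
        labels = rng.uniform(size=n) < 0.5
        labels[:2] = [True, False]
        arr = (rng.uniform(size=(3, 2, n)) < 0.5).astype(np.int8)
        arr[0, 0, arr.sum(axis=(0, 1)) == 0] = 1
        matrix = make_matrix(arr, modalities=["a", "b"])
        truth = truth_for(matrix, labels)
        aucs = auc_matrix(matrix, truth)
        for r in range(3):
            for m in range(2):
                cell = binary_auc(sens_spec(arr[r, m], truth, matrix.candidate_ids))
                assert aucs.auc[r, m] == cell


class TestJackknifeCov:
    def _random_matrix(self, seed, n=40, readers=2, modalities=2, slides=4):
        rng = np.random.default_rng(seed)
        labels = rng.uniform(size=n) < 0.5
        arr = (rng.uniform(size=(readers, modalities, n)) < 0.5).astype(np.int8)
        arr[0, 0, arr.sum(axis=(0, 1)) == 0] = 1
        matrix = make_matrix(
            arr,
            modalities=[f"m{i}" for i in range(modalities)],
            slides=[f"S{i}" for i in range(slides)],
        )
        # keep both classes on every slide-deletion
        labels[: 2 * slides] = ([True, False] * slides)[: 2 * slides]
        return matrix, truth_for(matrix, labels)

    def test_duplicated_modality_blocks_are_identical(self):
        matrix, truth = self._random_matrix(3, modalities=3)
        arr = matrix.marks.copy()
        arr[:, 1, :] = arr[:, 0, :]  # modality m1 := m0
        arr[:, 2, :] = 1  # padding modality keeps every candidate in the pool
        dup = make_matrix(arr, modalities=["m0", "m1", "pad"], slides=["S0", "S1", "S2", "S3"])
        cov = jackknife_cov(dup, truth_for(dup, truth.label_vector(dup.candidate_ids)))
        assert np.allclose(cov.block("m0", "m0"), cov.block("m0", "m1"))
        assert np.allclose(cov.block("m0", "m0"), cov.block("m1", "m1"))

    def test_three_slide_instance_matches_plain_loop_enumeration(self):
        matrix, truth = self._random_matrix(5, n=24, slides=3)
        cov = jackknife_cov(matrix, truth)

        # independent oracle: recompute every leave-one-slide AUC matrix with
        # plain Python loops and apply the jackknife covariance formula
        slides = list(dict.fromkeys(matrix.candidate_slides))
        ids = matrix.candidate_ids
        labels = dict(zip(ids, truth.label_vector(ids)))
        thetas = []
        for g in slides:
            keep = [i for i, c in enumerate(matrix.candidates) if c.slide_id != g]
            cells = []
            for r in range(len(matrix.readers)):
                for m in range(len(matrix.modalities)):
                    tp = sum(1 for i in keep if labels[ids[i]] and matrix.marks[r, m, i])
                    fp = sum(1 for i in keep if not labels[ids[i]] and matrix.marks[r, m, i])
                    nt = sum(1 for i in keep if labels[ids[i]])
                    nf = len(keep) - nt
                    cells.append((tp / nt + 1 - fp / nf) / 2)
            thetas.append(cells)
        thetas = np.array(thetas)
        g = len(slides)
        mean = thetas.mean(axis=0)
        expected = np.zeros((thetas.shape[1], thetas.shape[1]))
        for i in range(thetas.shape[1]):
            for j in range(thetas.shape[1]):
                expected[i, j] = (g - 1) / g * np.sum(
                    (thetas[:, i] - mean[i]) * (thetas[:, j] - mean[j])
                )
        assert np.allclose(cov.cov, expected)

    def test_degenerate_deletion_names_the_slide(self):
        # all true candidates live on one slide
        n = 12
        labels = [False] * n
        arr = np.ones((1, 1, n), dtype=np.int8)
        matrix = make_matrix(arr, modalities=["m"], slides=["S1", "S2", "S3"])
        for i, c in enumerate(matrix.candidates):
            if c.slide_id == "S2":
                labels[i] = True
        with pytest.raises(DegenerateJackknifeError, match="S2"):
            jackknife_cov(matrix, truth_for(matrix, labels))

    def test_needs_two_clusters(self):
        matrix, truth = self._random_matrix(9, n=10, slides=1)
        with pytest.raises(InsufficientDataError):
            jackknife_cov(matrix, truth)


class TestReaderAveragedAnalysis:
    def _identity_cov(self, readers, modalities, scale=1e-4):
        k = len(readers) * len(modalities)
        return CovMatrix(cov=np.eye(k) * scale, readers=readers, modalities=modalities)

    def test_printed_column_averages(self):
        readers = [f"R{i}" for i in range(1, 6)]
        modalities = ["scannerA", "microscope"]
        auc = np.array(
            [
                [0.713, 0.764],
                [0.700, 0.778],
                [0.704, 0.806],
                [0.691, 0.842],
                [0.698, 0.802],
            ]
        )
        aucs = AUCMatrix(auc=auc, readers=readers, modalities=modalities)
        res = reader_averaged_analysis(
            aucs, self._identity_cov(readers, modalities), "microscope"
        )
        avg = res.modality_summary.set_index("modality")["avg_auc"]
        assert round(avg["microscope"], 3) == 0.798
        assert round(avg["scannerA"], 3) == 0.701

    def test_identical_modalities_give_zero_delta_p_one(self):
        readers = ["R1", "R2"]
        modalities = ["a", "b"]
        aucs = AUCMatrix(
            auc=np.array([[0.8, 0.8], [0.7, 0.7]]), readers=readers, modalities=modalities
        )
        # perfectly correlated cells across the two modalities
        block = np.array([[4e-4, 1e-4], [1e-4, 4e-4]])
        cov = np.block([[block, block], [block, block]])
        # reorder to reader-major layout: cells (R1,a),(R1,b),(R2,a),(R2,b)
        perm = [0, 2, 1, 3]
        cov = cov[np.ix_(perm, perm)]
        cm = CovMatrix(cov=cov, readers=readers, modalities=modalities)
        with pytest.warns(UserWarning, match="non-positive variance"):
            res = reader_averaged_analysis(aucs, cm, "a")
        row = res.comparisons.iloc[0]
        assert row["delta_vs_reference"] == 0.0
        assert row["p_value"] == pytest.approx(1.0)

    def test_ci_contains_point_estimate(self):
        matrixes = np.random.default_rng(1)
        readers = ["R1", "R2", "R3"]
        modalities = ["a", "b"]
        auc = matrixes.uniform(0.6, 0.9, size=(3, 2))
        a = matrixes.uniform(-1, 1, size=(6, 6))
        cov = a @ a.T * 1e-5
        res = reader_averaged_analysis(
            AUCMatrix(auc=auc, readers=readers, modalities=modalities),
            CovMatrix(cov=cov, readers=readers, modalities=modalities),
            "a",
        )
        for row in res.modality_summary.itertuples(index=False):
            assert row.ci_low <= row.avg_auc <= row.ci_high


class TestHolm:
    def test_printed_pvalues_reject_three_of_four(self):
        flags = holm_adjust([0.001, 0.009, 0.001, 0.062], alpha=0.05)
        assert list(flags) == [True, True, True, False]

    def test_all_ones_reject_nothing(self):
        assert not holm_adjust([1.0, 1.0, 1.0]).any()

    def test_two_borderline_pvalues_both_retained(self):
        assert list(holm_adjust([0.04, 0.04], alpha=0.05)) == [False, False]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8), st.integers(0, 10**6))
    def test_matches_hand_stepdown_and_dominates_bonferroni(self, pvals, _):
        alpha = 0.05
        flags = holm_adjust(pvals, alpha)
        # hand step-down oracle
        order = sorted(range(len(pvals)), key=lambda i: pvals[i])
        expected = [False] * len(pvals)
        for step, idx in enumerate(order):
            if pvals[idx] <= alpha / (len(pvals) - step):
                expected[idx] = True
            else:
                break
        assert list(flags) == expected
        bonferroni = [p <= alpha / len(pvals) for p in pvals]
        assert all(f or not b for f, b in zip(flags, bonferroni))

    def test_monotone_in_pvalues(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            p = rng.uniform(size=5)
            flags = holm_adjust(p)
            i = rng.integers(5)
            p2 = p.copy()
            p2[i] *= rng.uniform()
            flags2 = holm_adjust(p2)
            assert flags2.sum() >= flags.sum()
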