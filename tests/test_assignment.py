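import numpy as np
import pytest

from phenogate import (
    CellFeatureMatrix,
    SignatureMatrix,
    annotate,
    categorize,
    deconvolve,
)


def _mat(values, normalized=True):
    values = np.asarray(values, dtype=float)
    return CellFeatureMatrix(
        values=values, cell_ids=[f"c{i}" for i in range(values.shape[0])],
        marker_names=[f"M{j}" for j in range(values.shape[1])],
        normalized=normalized,
    )


def _sig(weights, types):
    return SignatureMatrix(
        weights=np.asarray(weights, dtype=float),
        marker_names=[f"M{j}" for j in range(len(weights))],
        cell_type_names=types,
    )


class TestCategorize:
    @pytest.mark.parametrize("row,label,category,candidates", [
        ((0, 1, 0), "T2", "clean", ("T2",)),
        ((1, 1, 0), "Unknown", "mixed", ("T1", "T2")),
        ((0, 0, 0), "Unknown", "unknown", ()),
    ])
    def test_row_categories(self, row, label, category, candidates):
        assign = categorize(np.array([row]), ["T1", "T2", "T3"], ["c0"])
        assert assign.labels[0] == label
        assert assign.categories[0] == category
        assert assign.candidate_sets[0] == candidates

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            categorize(np.array([[0, 2]]), ["A", "B"], ["c0"])

    def test_conservation_of_counts(self, rng):
        B = rng.integers(0, 2, size=(50, 4))
        assign = categorize(B, list("ABCD"), [f"c{i}" for i in range(50)])
        counts = assign.counts()
        assert sum(counts.values()) == 50


def _two_type_setup(mixed_rows, x_rows, y_rows):
    """Clean X cells, clean Y cells, and mixed X|Y cells on two markers;
    marker M2 belongs to neither signature."""
    values = np.array(x_rows + y_rows + mixed_rows, dtype=float)
    mat = _mat(values)
    sig = _sig([[1, 0], [0, 1], [0, 0]], ["X", "Y"])
    n_x, n_y, n_m = len(x_rows), len(y_rows), len(mixed_rows)
    labels = ["X"] * n_x + ["Y"] * n_y + ["Unknown"] * n_m
    categories = ["clean"] * (n_x + n_y) + ["mixed"] * n_m
    from phenogate import CellAssignment
    assign = CellAssignment(
        cell_ids=mat.cell_ids, labels=np.array(labels, dtype=object),
        categories=np.array(categories, dtype=object),
        candidate_sets=[("X",)] * n_x + [("Y",)] * n_y + [("X", "Y")] * n_m,
        cell_type_names=["X", "Y"],
    )
    return assign, mat, sig


class TestDeconvolve:
    def test_zero_distance_anchor_wins(self):
        with pytest.warns(UserWarning):
            assign, mat, sig = _two_type_setup(
                mixed_rows=[[5.0, 0.0, 9.9]],
                x_rows=[[5.0, 0.0, 0.0]], y_rows=[[0.0, 5.0, 0.0]])
        out = deconvolve(assign, mat, sig, k_neighbors=1)
        assert out.labels[-1] == "X"
        assert out.categories[-1] == "mixed_resolved"

    def test_majority_of_three_nearest(self):
        with pytest.warns(UserWarning):
            assign, mat, sig = _two_type_setup(
                mixed_rows=[[2.0, 2.0, 0.0]],
                x_rows=[[0.0, 0.0, 0.0]] * 3,
                y_rows=[[10.0, 10.0, 0.0]] * 3)
        out = deconvolve(assign, mat, sig, k_neighbors=3)
        assert out.labels[-1] == "X"

    def test_no_anchors_left_unresolved(self):
        from phenogate import CellAssignment
        mat = _mat([[1.0, 1.0]])
        sig = _sig([[1, 0], [0, 1]], ["X", "Y"])
        assign = CellAssignment(
            cell_ids=mat.cell_ids,
            labels=np.array(["Unknown"], dtype=object),
            categories=np.array(["mixed"], dtype=object),
            candidate_sets=[("X", "Y")], cell_type_names=["X", "Y"])
        with pytest.warns(UserWarning, match="no clean anchors"):
            out = deconvolve(assign, mat, sig)
        assert out.labels[0] == "Unknown"
        assert out.categories[0] == "unresolved_mixed"

    def test_clean_labels_never_altered(self):
        with pytest.warns(UserWarning):
            assign, mat, sig = _two_type_setup(
                mixed_rows=[[2.0, 2.0, 0.0]],
                x_rows=[[0.0, 0.0, 0.0]] * 3,
                y_rows=[[10.0, 10.0, 0.0]] * 3)
        out = deconvolve(assign, mat, sig, k_neighbors=3)
        np.testing.assert_array_equal(out.labels[:-1], assign.labels[:-1])

    def test_distance_uses_only_candidate_markers(self):
        # perturbing the non-signature marker M2 must not change the result
        with pytest.warns(UserWarning):
            assign, mat, sig = _two_type_setup(
                mixed_rows=[[2.0, 2.0, 0.0]],
                x_rows=[[0.0, 0.0, 0.0]] * 3,
                y_rows=[[10.0, 10.0, 0.0]] * 3)
        base = deconvolve(assign, mat, sig, k_neighbors=3).labels.copy()
        mat.values[:, 2] = np.linspace(-100, 100, mat.n_cells)
        out = deconvolve(assign, mat, sig, k_neighbors=3).labels
        np.testing.assert_array_equal(base, out)

    def test_invalid_k_rejected(self):
        with pytest.warns(UserWarning):
            assign, mat, sig = _two_type_setup(
                mixed_rows=[[1.0, 1.0, 0.0]],
                x_rows=[[0.0, 0.0, 0.0]], y_rows=[[2.0, 2.0, 0.0]])
        with pytest.raises(ValueError, match="k_neighbors"):
            deconvolve(assign, mat, sig, k_neighbors=0)

    def test_matches_brute_force_knn_oracle(self, rng):
        n_anchor, n_mixed = 60, 30
        values = rng.normal(size=(n_anchor + n_mixed, 3))
        mat = _mat(values)
        sig = _sig([[1, 0], [0, 1], [0, 0]], ["X", "Y"])
        labels = np.array(
            ["X"] * 30 + ["Y"] * 30 + ["Unknown"] * n_mixed, dtype=object)
        categories = np.array(
            ["clean"] * n_anchor + ["mixed"] * n_mixed, dtype=object)
        from phenogate import CellAssignment
        assign = CellAssignment(
            cell_ids=mat.cell_ids, labels=labels, categories=categories,
            candidate_sets=[("X",)] * 30 + [("Y",)] * 30
            + [("X", "Y")] * n_mixed,
            cell_type_names=["X", "Y"])
        out = deconvolve(assign, mat, sig, k_neighbors=5)
        # brute force: all-pairs distances on the two signature markers
        sub = values[:, :2]
        for i in range(n_anchor, n_anchor + n_mixed):
            d = np.linalg.norm(sub[:n_anchor] - sub[i], axis=1)
            nearest = np.argsort(d, kind="stable")[:5]
            lab, cnt = np.unique(labels[nearest], return_counts=True)
            winners = lab[cnt == cnt.max()]
            if winners.size == 1:
                assert out.labels[i] == winners[0]
            else:
                assert out.labels[i] in winners


class TestAnnotate:
    def test_all_types_recovered_on_synthetic(self, five_type_data,
                                              five_type_annotated):
        mat, sig, truth = five_type_data
        assign, thresholds, mc = five_type_annotated
        assert set(truth["label"]) <= set(assign.labels)

    def test_category_conservation(self, five_type_annotated):
        assign, _, _ = five_type_annotated
        counts = assign.counts()
        assert sum(counts.values()) == len(assign.cell_ids)
        assert "mixed" not in counts  # all mixed cells were resolved or flagged

    def test_rerun_is_identical(self, five_type_data):
        mat, sig, truth = five_type_data
        a1, t1, m1 = annotate(mat, sig, band=(0.01, 0.05), seed=1)
        a2, t2, m2 = annotate(mat, sig, band=(0.01, 0.05), seed=1)
        np.testing.assert_array_equal(a1.labels, a2.labels)
        np.testing.assert_array_equal(m1.assignment, m2.assignment)
        assert t1.to_frame().equals(t2.to_frame())

    def test_absent_type_stays_minor_and_real_types_survive(self,
                                                            five_type_data):
        # a ghost type whose signature marker carries pure noise: the
        # micro-clusters still organize cells along that marker, so the
        # ghost attracts a bounded minority of cells; the real types'
        # labels must remain dominant and correct
        mat, sig, truth = five_type_data
        weights = np.hstack([sig.weights, np.zeros((sig.weights.shape[0], 1))])
        weights[-1, :] = 0.0
        weights[-1, -1] = 1.0  # last marker becomes the ghost's signature
        ghost_sig = SignatureMatrix(weights=weights,
                                    marker_names=sig.marker_names,
                                    cell_type_names=sig.cell_type_names
                                    + ["Ghost"])
        assign, thresholds, _ = annotate(mat, ghost_sig, band=(0.01, 0.05),
                                         seed=1)
        n_ghost = int((assign.labels == "Ghost").sum())
        assert n_ghost <= 0.15 * mat.n_cells
        ref = truth.set_index("cell_id")["label"]
        agree = np.mean(assign.labels == ref.loc[assign.cell_ids].to_numpy())
        assert agree > 0.8

    def test_flat_ctr_type_makes_no_positive_calls(self, five_type_data):
        # a type whose only signature marker has zero variance: its CTR
        # column is constant after z-scoring, the threshold is degenerate
        # and the pipeline must call no cell positive for it
        mat, sig, truth = five_type_data
        values = np.hstack([mat.values, np.full((mat.n_cells, 1), 7.0)])
        from phenogate import CellFeatureMatrix
        flat_mat = CellFeatureMatrix(
            values=values, cell_ids=mat.cell_ids,
            marker_names=mat.marker_names + ["FLAT"], modality="proteomics")
        weights = np.zeros((sig.weights.shape[0] + 1, sig.weights.shape[1] + 1))
        weights[:-1, :-1] = sig.weights
        weights[-1, -1] = 1.0
        flat_sig = SignatureMatrix(weights=weights,
                                   marker_names=flat_mat.marker_names,
                                   cell_type_names=sig.cell_type_names
                                   + ["Flat"])
        with pytest.warns(UserWarning):
            assign, thresholds, _ = annotate(flat_mat, flat_sig,
                                             band=(0.01, 0.05), seed=1)
        assert thresholds.entries["Flat"].degenerate
        assert np.isinf(thresholds.theta("Flat"))
        assert int((assign.labels == "Flat").sum()) == 0

    def test_unnormalized_rejected_when_normalize_none(self, five_type_data):
        mat, sig, _ = five_type_data
        with pytest.raises(ValueError, match="not normalized"):
            annotate(mat, sig, normalize="none")


class TestSignatureAnnotator:
    def test_fit_predict_and_attributes(self, five_type_data):
        from phenogate import SignatureAnnotator
        mat, sig, truth = five_type_data
        est = SignatureAnnotator(signature=sig, band=(0.01, 0.05), seed=1)
        labels = est.fit_predict(mat)
        assert labels.shape == (mat.n_cells,)
        assert hasattr(est, "thresholds_") and hasattr(est, "microclusters_")
        np.testing.assert_array_equal(est.predict(), labels)
        truth_lab = truth.set_index("cell_id")["label"]
        agree = np.mean(labels == truth_lab.loc[mat.cell_ids].to_numpy())
        assert agree > 0.9

    def test_get_set_params_round_trip(self):
        from phenogate import SignatureAnnotator
        est = SignatureAnnotator(k_neighbors=7)
        assert est.get_params()["k_neighbors"] == 7
        est.set_params(seed=42)
        assert est.seed == 42

    def test_unfitted_predict_rejected(self):
        from phenogate import SignatureAnnotator
        with pytest.raises(ValueError, match="not fitted"):
            SignatureAnnotator().predict()
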