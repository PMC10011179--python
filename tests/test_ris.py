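"""Correlation matrices, the greedy container scan and superposition search."""

import numpy as np
import pytest

import hsidrought as hd
from hsidrought.ris import CorrMatrix, greedy_container, superposition_search


def hand_simulate_container(R, ref, threshold=0.3, max_members=4):
    """Independent re-enactment of the scan: admit in ascending index order
    iff weakly correlated with everything already admitted, then rank by
    |r| against the reference."""
    admitted = []
    for j in range(R.shape[0]):
        if j == ref or len(admitted) >= max_members:
            continue
        ok = abs(R[j, ref]) <= threshold and all(abs(R[j, m]) <= threshold for m in admitted)
        if ok:
            admitted.append(j)
    admitted.sort(key=lambda j: (abs(R[j, ref]), j))
    return [ref] + admitted


def _corr(R):
    R = np.asarray(R, float)
    np.fill_diagonal(R, 1.0)
    return CorrMatrix(r=(R + R.T) / 2, wavelengths=np.arange(R.shape[0], dtype=float))


class TestImageCorrelation:
    def _cube_two_bands(self, x, y):
        data = np.stack([np.asarray(x, float).reshape(2, 2),
                         np.asarray(y, float).reshape(2, 2)], axis=-1)
        return hd.HyperCube(data, np.array([500.0, 600.0]))

    def test_band_with_itself_is_one(self):
        cube = self._cube_two_bands([0, 1, 2, 3], [0, 1, 2, 3])
        m = hd.image_correlation(cube, np.ones((2, 2), bool), [0, 1])
        assert m.r[0, 0] == 1.0
        assert np.isclose(m.r[0, 1], 1.0)

    def test_negated_band_is_minus_one(self):
        cube = self._cube_two_bands([0, 1, 2, 3], [3, 2, 1, 0])
        m = hd.image_correlation(cube, np.ones((2, 2), bool), [0, 1])
        assert np.isclose(m.r[0, 1], -1.0)

    def test_four_pixel_hand_computation(self):
        # x=(0,1,2,3), y=(1,0,3,2): cov=0.75, var=1.25 each -> r=0.6
        cube = self._cube_two_bands([0, 1, 2, 3], [1, 0, 3, 2])
        m = hd.image_correlation(cube, np.ones((2, 2), bool), [0, 1])
        assert np.isclose(m.r[0, 1], 0.6)

    def test_zero_variance_band_flagged_as_zero(self):
        cube = self._cube_two_bands([0, 1, 2, 3], [5, 5, 5, 5])
        m = hd.image_correlation(cube, np.ones((2, 2), bool), [0, 1])
        assert m.r[0, 1] == 0.0
        assert m.qc_zero_variance == [1]

    def test_single_pixel_mask_rejected(self):
        cube = self._cube_two_bands([0, 1, 2, 3], [1, 0, 3, 2])
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="2 in-mask"):
            hd.image_correlation(cube, mask, [0, 1])


class TestGreedyContainer:
    def test_identity_matrix_admits_first_four_in_scan_order(self):
        corr = _corr(np.zeros((6, 6)))
        assert greedy_container(corr, 2) == [2, 0, 1, 3, 4]

    def test_all_strong_correlations_leave_container_with_reference_only(self):
        corr = _corr(np.full((6, 6), 0.9))
        assert greedy_container(corr, 0) == [0]

    def test_hand_worked_mixed_matrix(self):
        # reference 0; scan: 1 admitted (|r|=0.2), 2 fails vs ref (0.31),
        # 3 passes ref (0.25) but fails vs 1 (0.5), 4 admitted (0.1 vs ref,
        # 0.29 vs 1), 5 admitted (0.05 vs ref, 0.1 vs 1, 0.2 vs 4);
        # ranked by |r| with reference: 5 (0.05), 4 (0.1), 1 (0.2)
        R = np.zeros((6, 6))
        R[1, 0] = 0.2
        R[2, 0] = 0.31
        R[3, 0] = 0.25
        R[3, 1] = 0.5
        R[4, 0] = 0.1
        R[4, 1] = 0.29
        R[5, 0] = 0.05
        R[5, 1] = 0.1
        R[5, 4] = 0.2
        R = R + R.T
        corr = _corr(R.copy())
        expected = [0, 5, 4, 1]
        assert greedy_container(corr, 0) == expected
        assert greedy_container(corr, 0) == hand_simulate_container(corr.r, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_hand_simulation_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 9)
        A = rng.uniform(-1, 1, (n, n))
        R = (A + A.T) / 2
        corr = _corr(R.copy())
        ref = int(rng.integers(n))
        assert greedy_container(corr, ref) == hand_simulate_container(corr.r, ref)

    def test_members_pairwise_weakly_correlated(self, rng):
        A = rng.uniform(-1, 1, (8, 8))
        corr = _corr(((A + A.T) / 2).copy())
        out = greedy_container(corr, 3, threshold=0.3)
        for i in out[1:]:
            for j in out:
                if i != j:
                    assert abs(corr.r[i, j]) <= 0.3

    def test_max_members_cap(self):
        corr = _corr(np.zeros((9, 9)))
        assert len(greedy_container(corr, 0, max_members=4)) == 5

    def test_invalid_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            greedy_container(_corr(np.zeros((4, 4))), 7)


class TestSuperpositionSearch:
    def _run(self, accs):
        spectra = np.zeros((6, 2))
        labels = np.repeat([0, 1], 3)
        feats = {k: np.full((6, 1), float(k)) for k in range(1, len(accs) + 1)}

        def extractor(k):
            return feats[k]

        acc_iter = iter(accs)

        def evaluator(X, y):
            return next(acc_iter)

        return superposition_search(spectra, labels, [600.0, 650.0, 700.0][: len(accs)],
                                    extractor, evaluator)

    def test_single_candidate_selects_k1(self):
        ris = self._run([0.8])
        assert ris.k_selected == 1
        assert ris.member_wls == []

    def test_tie_resolves_to_smaller_k(self):
        # accuracy sequence (0.8, 0.9, 0.9) -> k = 2
        ris = self._run([0.8, 0.9, 0.9])
        assert ris.k_selected == 2
        assert ris.wavelengths == [600.0, 650.0]
        assert ris.accuracy_trace == [0.8, 0.9, 0.9]

    def test_second_channel_signal_pushes_k_to_two(self):
        # the 2nd image channel carries the only class signal
        rng = np.random.default_rng(0)
        labels = np.repeat([0, 1, 2], 12)
        spectra = rng.normal(0, 1, (36, 3))
        chan2 = labels[:, None] * 5.0 + rng.normal(0, 0.1, (36, 1))

        def extractor(k):
            cols = [rng.normal(0, 1, (36, 1))]
            if k >= 2:
                cols.append(chan2)
            return np.hstack(cols[:k])

        from hsidrought.band_select import cv_fitness

        def evaluator(X, y):
            return cv_fitness(X, y, np.arange(X.shape[1]), folds=3)

        hits = 0
        for _ in range(5):
            ris = superposition_search(spectra, labels, [500.0, 550.0, 600.0],
                                       extractor, evaluator)
            hits += ris.k_selected >= 2
        assert hits >= 4

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            superposition_search(np.zeros((2, 1)), np.array([0, 1]), [],
                                 lambda k: None, lambda X, y: 0.0)
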