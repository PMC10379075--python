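"""Mahalanobis screening: distance oracle, threshold rule, recovery."""

import numpy as np
import pytest

from freshnir import (
    GeneratorConfig,
    generate_dataset,
    inject_outliers,
    mahalanobis_distances,
    remove_outliers,
    select_threshold,
)
from freshnir.core import SpectraSet
from freshnir.outlier_screen import DEFAULT_E_GRID, threshold_report


def dense_mahalanobis_oracle(T):
    """Direct dense-matrix evaluation of the score-space distance."""
    t_bar = T.mean(axis=0)
    M = np.cov(T, rowvar=False, ddof=1)
    Minv = np.linalg.inv(np.atleast_2d(M))
    return np.array([
        np.sqrt((t - t_bar) @ Minv @ (t - t_bar)) for t in T
    ])


def spectra_from_scores(T, rng):
    """Embed a score matrix into channel space via a random full-rank map.

    The Mahalanobis distance is invariant to invertible linear maps of
    the scores, so the embedded spectra must reproduce the score-space
    oracle exactly.
    """
    n, k = T.shape
    Q, _ = np.linalg.qr(rng.normal(size=(40, k)))
    X = T @ Q.T + rng.normal(size=40)  # constant channel offsets
    wl = 700.0 + 10.0 * np.arange(40)
    ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    return SpectraSet(X, wl, ids)


class TestDistances:
    def test_one_dimensional_scores_reduce_to_z_scores(self, rng):
        T = np.array([[-1.0], [0.0], [1.0]])
        np.testing.assert_allclose(
            dense_mahalanobis_oracle(T), [1.0, 0.0, 1.0], atol=1e-12
        )
        spectra = spectra_from_scores(T, rng)
        d, _ = mahalanobis_distances(spectra, n_pcs=1)
        np.testing.assert_allclose(d, [1.0, 0.0, 1.0], atol=1e-10)

    def test_matches_dense_matrix_oracle(self, rng):
        T = rng.normal(size=(20, 5)) @ np.diag([3.0, 2.0, 1.5, 1.0, 0.5])
        spectra = spectra_from_scores(T, rng)
        d, model = mahalanobis_distances(spectra, n_pcs=5)
        np.testing.assert_allclose(d, dense_mahalanobis_oracle(T), atol=1e-10)
        assert model.n_pcs == 5

    def test_whitened_scores_give_euclidean_distance(self, rng):
        T = rng.normal(size=(50, 3))
        # whiten to exactly identity sample covariance
        T = T - T.mean(axis=0)
        L = np.linalg.cholesky(np.cov(T, rowvar=False, ddof=1))
        W = T @ np.linalg.inv(L).T
        np.testing.assert_allclose(
            dense_mahalanobis_oracle(W),
            np.linalg.norm(W - W.mean(axis=0), axis=1),
            atol=1e-10,
        )

    def test_invariant_to_channelwise_centering(self, rng):
        T = rng.normal(size=(15, 3))
        spectra = spectra_from_scores(T, rng)
        shifted = spectra.with_absorbance(
            spectra.absorbance - spectra.absorbance.mean(axis=0)
        )
        d1, _ = mahalanobis_distances(spectra, n_pcs=3)
        d2, _ = mahalanobis_distances(shifted, n_pcs=3)
        np.testing.assert_allclose(d1, d2, atol=1e-9)


class TestThreshold:
    def test_direct_evaluation_of_threshold_formula(self):
        ids = np.array(["a", "b", "c"], dtype=object)
        rep = threshold_report(np.array([1.0, 0.0, 1.0]), e=1.0, sample_ids=ids)
        assert rep.d_mean == pytest.approx(2.0 / 3.0)
        assert rep.d_sd == pytest.approx(np.sqrt(1.0 / 3.0))
        assert rep.d_threshold == pytest.approx(2.0 / 3.0 + np.sqrt(1.0 / 3.0))
        assert rep.removed_ids == []  # max distance 1 < 1.244

    def test_large_e_removes_nothing(self, rng):
        d = rng.uniform(0.1, 2.0, size=30)
        ids = np.array([f"s{i}" for i in range(30)], dtype=object)
        rep = threshold_report(d, e=50.0, sample_ids=ids)
        assert rep.removed_ids == []

    def test_removed_count_monotone_in_e(self, rng):
        d = rng.gamma(2.0, 1.0, size=200)
        ids = np.array([f"s{i}" for i in range(200)], dtype=object)
        counts = [len(threshold_report(d, e, ids).removed_ids)
                  for e in DEFAULT_E_GRID]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


@pytest.fixture(scope="module")
def screened():
    cfg = GeneratorConfig(seed=11, n_channels=400,
                          wavelength_step_nm=1920.0 / 399)
    spectra, reference, _ = generate_dataset(cfg)
    sd = spectra.absorbance.std()
    corrupted, injected = inject_outliers(spectra, 10, 20 * sd, seed=11)
    d, model = mahalanobis_distances(corrupted)
    report = select_threshold(
        d, DEFAULT_E_GRID, corrupted, reference,
        target="tvbn", n_pcs=model.n_pcs, seed=11,
    )
    return corrupted, reference, report, set(int(i) for i in injected)


class TestRecovery:
    def test_recovers_injected_gross_outliers(self, screened):
        corrupted, _, report, injected = screened
        removed = set(np.flatnonzero(
            np.isin(corrupted.sample_ids, report.removed_ids)
        ))
        assert len(removed & injected) >= 9
        assert len(removed - injected) <= 5

    def test_removal_drops_rows_and_keeps_alignment(self, screened):
        corrupted, reference, report, _ = screened
        out_s, out_r = remove_outliers(corrupted, reference, report)
        assert out_s.n_samples == 180 - len(report.removed_ids)
        np.testing.assert_array_equal(out_s.sample_ids, out_r.sample_ids)
        # surviving rows are untouched
        keep = ~np.isin(corrupted.sample_ids, report.removed_ids)
        np.testing.assert_array_equal(out_s.absorbance,
                                      corrupted.absorbance[keep])

    def test_empty_report_is_identity(self, screened):
        corrupted, reference, report, _ = screened
        empty = threshold_report(report.distances, 100.0, corrupted.sample_ids)
        out_s, out_r = remove_outliers(corrupted, reference, empty)
        assert out_s.n_samples == corrupted.n_samples
        assert list(out_r.sample_ids) == list(reference.sample_ids)

    def test_unknown_id_rejected(self, screened):
        corrupted, reference, report, _ = screened
        bad = threshold_report(report.distances, 100.0, corrupted.sample_ids)
        bad.removed_ids = ["nonexistent"]
        with pytest.raises(KeyError):
            remove_outliers(corrupted, reference, bad)
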