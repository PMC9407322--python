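"""Oversampling geometry and balance contracts for ROS/SMOTE/BL-SMOTE/ADASYN."""

import numpy as np
import pytest

from jujubespec.dataset import SimConfig, generate_spectra, stratified_split
from jujubespec.oversample import (
    ADASYN,
    SMOTE,
    BorderlineSMOTE,
    OversampleConfig,
    RandomOverSampler,
    classify_minority_samples,
    oversample,
)

ALL_METHODS = ["ros", "smote", "blsmote", "adasyn"]


@pytest.fixture(scope="module")
def imbalanced_train():
    data = generate_spectra(SimConfig(class_counts=(200, 302, 98), n_bands=30, seed=3))
    train, _ = stratified_split(data, 0.7, seed=3)
    return train


def _balance(train, method, seed=0):
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return oversample(train, OversampleConfig(method=method, seed=seed))


class TestBalanceContract:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_study_counts_balance_to_majority(self, imbalanced_train, method):
        """140/211/69 training counts become 211/211/211 (633 total)."""
        balanced = _balance(imbalanced_train, method)
        assert balanced.class_counts() == {"NM": 211, "SH": 211, "MD": 211}
        assert balanced.n_samples == 633

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_original_rows_untouched_and_first(self, imbalanced_train, method):
        balanced = _balance(imbalanced_train, method)
        n = imbalanced_train.n_samples
        assert np.array_equal(balanced.reflectance[:n], imbalanced_train.reflectance)
        assert np.array_equal(balanced.labels[:n], imbalanced_train.labels)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_seeded_reproducibility(self, imbalanced_train, method):
        a = _balance(imbalanced_train, method, seed=9)
        b = _balance(imbalanced_train, method, seed=9)
        assert np.array_equal(a.reflectance, b.reflectance)

    def test_already_balanced_returned_unchanged(self):
        data = generate_spectra(SimConfig(class_counts=(10, 10, 10), n_bands=12, seed=0))
        balanced = _balance(data, "ros")
        assert balanced.n_samples == 30


class TestRos:
    def test_synthetic_rows_are_exact_copies(self, imbalanced_train):
        balanced = _balance(imbalanced_train, "ros")
        n = imbalanced_train.n_samples
        originals = {tuple(row) for row in imbalanced_train.reflectance.round(12)}
        for row in balanced.reflectance[n:]:
            assert tuple(row.round(12)) in originals

    def test_empty_class_rejected(self):
        X = np.ones((3, 2))
        y = np.array(["a", "a", "b"])
        RandomOverSampler(random_state=0).fit_resample(X, y)  # fine
        with pytest.raises(ValueError):
            SMOTE(random_state=0).fit_resample(X, y)  # minority of 1


class TestSmoteGeometry:
    def test_synthetics_lie_on_same_class_segments(self, imbalanced_train):
        balanced = _balance(imbalanced_train, "smote")
        n = imbalanced_train.n_samples
        for c in ("NM", "MD"):
            Xc = imbalanced_train.reflectance[imbalanced_train.labels == c]
            synth = balanced.reflectance[n:][balanced.labels[n:] == c]
            for s in synth[:20]:
                # residual of s against the best segment (i, j) of real points
                best = np.inf
                d = s - Xc
                dist = np.linalg.norm(d, axis=1)
                i = int(np.argmin(dist))
                for j in range(Xc.shape[0]):
                    seg = Xc[j] - Xc[i]
                    L2 = seg @ seg
                    if L2 == 0:
                        continue
                    lam = np.clip((s - Xc[i]) @ seg / L2, 0, 1)
                    best = min(best, np.linalg.norm(Xc[i] + lam * seg - s))
                assert best < 1e-9

    def test_two_identical_points_collapse(self):
        X = np.vstack([np.zeros((6, 3)), np.ones((2, 3)) * 0.7])
        y = np.array(["maj"] * 6 + ["min"] * 2)
        Xr, yr = SMOTE(k_neighbors=5, random_state=0).fit_resample(X, y)
        synth = Xr[8:]
        assert np.allclose(synth, 0.7)
        assert (yr == "min").sum() == 6


class TestBorderline:
    def test_noise_danger_safe_against_brute_force(self):
        """2-D toy with hand-checkable all-class neighborhoods (m = 5)."""
        majority = np.array([
            [0.0, 0.0], [0.2, 0.0], [0.0, 0.2], [0.2, 0.2], [0.1, 0.1],
            [5.0, 5.0], [5.2, 5.0], [5.0, 5.2], [5.2, 5.2], [5.1, 5.1],
        ])
        minority = np.array([
            [0.1, 0.05],   # surrounded by majority -> all 5 neighbors majority: noise
            [4.6, 4.9],    # near the far majority cluster but with minority nearby
            [4.7, 5.0],
            [10.0, 10.0],  # isolated pair -> mostly minority neighbors: safe
            [10.1, 10.1],
            [10.0, 10.2],
        ])
        X = np.vstack([majority, minority])
        y = np.array(["maj"] * 10 + ["min"] * 6)
        cats = classify_minority_samples(X, y, "min", m_neighbors=5)

        # brute-force oracle: count other-class members among the 5 nearest
        def other_count(i):
            d = np.linalg.norm(X - X[10 + i], axis=1)
            order = np.argsort(d, kind="stable")
            nbrs = [j for j in order if j != 10 + i][:5]
            return sum(y[j] == "maj" for j in nbrs)

        for i in range(6):
            m_prime = other_count(i)
            if m_prime == 5:
                assert i in cats["noise"]
            elif m_prime >= 2.5:
                assert i in cats["danger"]
            else:
                assert i in cats["safe"]
        assert 0 in cats["noise"]          # fully enclosed point
        assert other_count(1) >= 2.5       # boundary point is danger
        assert 1 in cats["danger"]

    def test_all_safe_falls_back_to_smote_and_balances(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(10, 0.1, (8, 2))])
        y = np.array(["maj"] * 20 + ["min"] * 8)
        with pytest.warns(UserWarning, match="no danger samples"):
            Xr, yr = BorderlineSMOTE(random_state=0).fit_resample(X, y)
        assert (yr == "min").sum() == 20

    def test_synthetics_originate_from_danger_seeds(self):
        """Every synthetic point lies on a segment anchored at a danger point."""
        # 3 minority points sit inside the majority cloud (3/5 neighbors are
        # majority -> danger); 5 more form a tight far cluster (safe).
        maj = np.array([[0.0, 0.3], [0.3, 0.0], [-0.3, 0.0], [0.0, -0.3],
                        [0.3, 0.3], [-0.3, -0.3], [0.3, -0.3], [-0.3, 0.3]])
        danger_pts = np.array([[0.0, 0.05], [0.05, 0.0], [0.0, -0.05]])
        safe_pts = np.array([[100.0, 100.0], [100.1, 100.0], [100.0, 100.1],
                             [100.1, 100.1], [100.05, 100.05]])
        X = np.vstack([maj, danger_pts, safe_pts])
        y = np.array(["maj"] * 8 + ["min"] * 8)
        cats = classify_minority_samples(X, y, "min", 5)
        assert set(cats["danger"]) == {0, 1, 2}
        Xr, yr = BorderlineSMOTE(random_state=1).fit_resample(X, y)
        synth = Xr[16:]
        minority = np.vstack([danger_pts, safe_pts])
        for s in synth:
            on_anchored_segment = False
            for d in danger_pts:
                for p in minority:
                    seg = p - d
                    L2 = seg @ seg
                    lam = 0.0 if L2 == 0 else np.clip((s - d) @ seg / L2, 0, 1)
                    if np.linalg.norm(d + lam * seg - s) < 1e-9:
                        on_anchored_segment = True
            assert on_anchored_segment


class TestAdasyn:
    def test_difficulty_weights_normalize(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(1, 1, (10, 3))])
        y = np.array(["maj"] * 30 + ["min"] * 10)
        k = 5
        from sklearn.neighbors import NearestNeighbors

        nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
        _, nbrs = nn.kneighbors(X[30:])
        r = (y[nbrs[:, 1:]] != "min").sum(axis=1) / k
        assert r.sum() > 0
        r_hat = r / r.sum()
        assert abs(r_hat.sum() - 1.0) < 1e-12

    def test_easy_sample_gets_zero_quota(self):
        """A minority point with no other-class neighbors synthesizes nothing."""
        # tight minority cluster far away + one hard point near the majority
        maj = np.zeros((10, 2)) + np.arange(10)[:, None] * 0.01
        easy = np.array([[50.0, 50.0], [50.1, 50.0], [50.0, 50.1],
                         [50.1, 50.1], [50.05, 50.05], [49.95, 50.0]])
        hard = np.array([[0.05, 0.0]])
        X = np.vstack([maj, easy, hard])
        y = np.array(["maj"] * 10 + ["min"] * 7)
        Xr, yr = ADASYN(k_neighbors=5, random_state=0).fit_resample(X, y)
        synth = Xr[17:]
        # all synthetics stem from the hard point's neighborhood, i.e. none
        # lies strictly inside the tight easy cluster's bounding box interior
        assert (yr == "min").sum() == 10
        assert synth.shape[0] == 3

    def test_exact_balance_after_rounding(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (37, 4)), rng.normal(0.5, 1, (11, 4))])
        y = np.array(["maj"] * 37 + ["min"] * 11)
        Xr, yr = ADASYN(random_state=3).fit_resample(X, y)
        assert (yr == "min").sum() == 37
        assert (yr == "maj").sum() == 37
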