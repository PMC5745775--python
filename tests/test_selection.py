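import numpy as np
import pandas as pd
import pytest

from homst.dynamics import PairIndex
from homst.selection import (
    abnormal_nodes,
    bh_select,
    feature_matrix,
    ks_two_sample,
    relief_weights,
    select_features,
)


def _fm(x, labels, n_nodes=None, metrics=("degree",)):
    """Wrap a plain array as a (node, metric)-columned feature matrix."""
    x = np.asarray(x, dtype=float)
    n_nodes = n_nodes or x.shape[1] // len(metrics)
    cols = pd.MultiIndex.from_product(
        [range(n_nodes), metrics], names=["node", "metric"]
    )
    fm = pd.DataFrame(x, columns=cols)
    fm.attrs["labels"] = np.asarray(labels, dtype=int)
    return fm


class TestKSTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3, 4], [1, 2, 3, 4])
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3, 4], [10, 11, 12, 13])
        assert d == 1.0

    def test_ecdf_sup_difference(self):
        d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1, 2, 3])

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(loc=0.5, size=12)
        d1, _ = ks_two_sample(a, b)
        d2, _ = ks_two_sample(np.exp(a), np.exp(b))
        assert d1 == pytest.approx(d2)


class TestBHSelect:
    def test_step_up_thresholds_by_hand(self):
        # thresholds kq/m: 0.0125, 0.025, 0.0375, 0.05
        mask = bh_select([0.01, 0.02, 0.04, 0.5], q=0.05)
        assert mask.tolist() == [True, True, False, False]

    def test_all_ones_reject_none(self):
        assert not bh_select([1.0] * 5).any()

    def test_all_zeros_reject_all(self):
        assert bh_select([0.0] * 5).all()

    def test_monotone_in_p(self, rng):
        p = rng.uniform(size=40)
        mask = bh_select(p, q=0.1)
        if mask.any():
            assert p[mask].max() <= p[~mask].min() or not (~mask).any()

    def test_empirical_fdr_controlled(self, rng):
        """Null+signal mixtures: realized false-discovery fraction stays
        near the nominal level on average."""
        fdps = []
        for _ in range(50):
            null_p = rng.uniform(size=800)
            signal_p = rng.beta(0.05, 10, size=200)
            p = np.r_[null_p, signal_p]
            mask = bh_select(p, q=0.05)
            n_false = mask[:800].sum()
            fdps.append(n_false / max(mask.sum(), 1))
        assert np.mean(fdps) <= 0.05 + 0.02


class TestSelectFeatures:
    def test_constant_feature_never_selected(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 7.0
        fm = _fm(x, [0] * 10 + [1] * 10)
        table = select_features(fm, q=0.05)
        assert table.iloc[1]["D"] == 0.0
        assert not table.iloc[1]["selected"]

    def test_injected_effect_is_selected(self, rng):
        x = rng.normal(size=(40, 10))
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        x[labels == 1, 4] += 4.0  # strong shift in one feature
        table = select_features(_fm(x, labels), q=0.05)
        assert table.iloc[4]["selected"]
        assert table["selected"].sum() <= 3

    def test_null_cohorts_select_almost_nothing(self, rng):
        total = 0
        for _ in range(50):
            x = rng.normal(size=(16, 30))
            total += select_features(_fm(x, [0] * 8 + [1] * 8), q=0.05)["selected"].sum()
        assert total / 50 < 0.5

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            select_features(_fm(rng.normal(size=(6, 4)), [1] * 6))


class TestAbnormalNodes:
    def _selection(self, sig_pattern):
        metrics = ["degree", "eccentricity", "betweenness"]
        idx = pd.MultiIndex.from_product(
            [range(len(sig_pattern)), metrics], names=["node", "metric"]
        )
        flat = [s for row in sig_pattern for s in row]
        return pd.DataFrame(
            {
                "D": 0.5,
                "p": [0.001 if s else 0.8 for s in flat],
                "selected": flat,
            },
            index=idx,
        )

    def test_two_of_three_rule(self):
        sel = self._selection([
            (True, True, False),   # node 0: reported
            (True, False, False),  # node 1: not reported
            (False, False, False),
        ])
        report = abnormal_nodes(sel, PairIndex(4))
        assert report.index.tolist() == [0]
        assert (report.loc[0, "roi_i"], report.loc[0, "roi_j"]) == (0, 1)

    def test_no_significant_features_empty_report(self):
        sel = self._selection([(False, False, False)] * 3)
        assert abnormal_nodes(sel).empty


class TestRelief:
    def test_separating_feature_gets_maximal_weight(self):
        # two clusters split by feature 0; feature 1 is constant noise-free
        x = np.array([[0.0, 5.0], [0.1, 5.0], [1.0, 5.0], [0.9, 5.0]])
        fm = _fm(x, [0, 0, 1, 1], n_nodes=2)
        w, _ = relief_weights(fm, seed=0)
        assert w.iloc[0] > 0
        assert w.iloc[0] == w.max()

    def test_hand_traced_updates(self):
        """4 points, 1 feature, range 1: nearest hits are at distance 0.1
        for every point; nearest misses at 0.9, 0.8, 0.8, 0.9.  Summed
        updates (0.8 + 0.7 + 0.7 + 0.8) / 4 visits = 0.75."""
        x = np.array([[0.0], [0.1], [0.9], [1.0]])
        fm = _fm(x, [0, 0, 1, 1])
        w, mean = relief_weights(fm, seed=3)
        assert w.iloc[0] == pytest.approx(0.75)
        assert mean == pytest.approx(0.75)

    def test_constant_feature_weight_zero(self, rng):
        x = rng.normal(size=(12, 3))
        x[:, 2] = 1.0
        w, _ = relief_weights(_fm(x, [0] * 6 + [1] * 6), seed=1)
        assert w.iloc[2] == 0.0

    def test_permuted_labels_mean_near_zero(self, rng):
        means = []
        for rep in range(20):
            x = rng.normal(size=(16, 8))
            labels = rng.permutation([0] * 8 + [1] * 8)
            _, mean = relief_weights(_fm(x, labels), seed=rep)
            means.append(mean)
        assert abs(np.mean(means)) < 0.1

    def test_reproducible_and_feature_order_invariant(self, rng):
        x = rng.normal(size=(10, 4))
        labels = [0] * 5 + [1] * 5
        fm = _fm(x, labels)
        w1, _ = relief_weights(fm, seed=9)
        w2, _ = relief_weights(fm, seed=9)
        pd.testing.assert_series_equal(w1, w2)
        perm = [2, 0, 3, 1]
        fm_p = _fm(x[:, perm], labels)
        w3, _ = relief_weights(fm_p, seed=9)
        np.testing.assert_allclose(w3.to_numpy(), w1.to_numpy()[perm])

    def test_single_member_class_rejected(self, rng):
        with pytest.raises(ValueError):
            relief_weights(_fm(rng.normal(size=(3, 2)), [0, 0, 1]), seed=0)


class TestFeatureMatrixAssembly:
    def test_columns_and_labels(self, rng):
        tables = []
        for _ in range(4):
            tables.append(
                pd.DataFrame(
                    {
                        "degree": [1, 2, 1],
                        "eccentricity": [2, 1, 2],
                        "betweenness": [0.0, 1.0, 0.0],
                    },
                    index=pd.Index(range(3), name="node"),
                )
            )
        fm = feature_matrix(tables, [0, 0, 1, 1])
        assert fm.shape == (4, 9)
        assert fm.columns.names == ["node", "metric"]
        assert fm[(1, "betweenness")].tolist() == [1.0] * 4
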