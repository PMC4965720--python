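"""Count-weighted bags of embeddings, window concatenation, feature
budgets, the count baseline, and the label-leakage guard."""

import numpy as np
import pytest

import semforest as sf
from semforest.corpus import DataType

from conftest import make_episode


def dataset_of(episodes, target_code="ADE_X"):
    return sf.LabeledDataset(
        episodes=list(episodes),
        labels=np.arange(len(episodes)) % 2,
        target_code=target_code,
    )


class TestEmbedEpisode:
    def test_count_weighting(self, hand_ensemble):
        ep = make_episode(
            words=(), diagnoses=(("dgA", 0), ("dgA", 1)), drugs=(), measurements=()
        )
        vec = sf.embed_episode(ep, hand_ensemble, window=1)
        # diagnosis block = 2 * [2, 1]; all other blocks zero
        np.testing.assert_array_equal(vec, [0, 0, 4, 2, 0, 0, 0, 0])

    def test_out_of_vocabulary_contributes_zero(self, hand_ensemble):
        ep = make_episode(
            words=(("unknown",),), diagnoses=(("nope", 0),),
            drugs=(("alien", 0),), measurements=(("mystery", 0),),
        )
        vec = sf.embed_episode(ep, hand_ensemble, window=1)
        np.testing.assert_array_equal(vec, np.zeros(8))

    def test_mixed_counts(self, hand_ensemble):
        ep = make_episode(
            words=(), diagnoses=(),
            drugs=(("rxA", 0), ("rxB", 0), ("rxB", 1), ("rxB", 2)),
            measurements=(),
        )
        vec = sf.embed_episode(ep, hand_ensemble, window=1)
        # drug block = 1*[1,1] + 3*[-1,2]
        np.testing.assert_array_equal(vec[4:6], [-2, 7])

    def test_linearity_over_event_multisets(self, hand_ensemble):
        ep1 = make_episode(
            words=(("pain",),), diagnoses=(("dgA", 0),),
            drugs=(("rxA", 0),), measurements=(("msA", 0),),
        )
        ep2 = make_episode(
            words=(("head", "pain"),), diagnoses=(("dgB", 1),),
            drugs=(("rxB", 1),), measurements=(("msA", 1),),
        )
        merged = make_episode(  # exact multiset union of ep1 and ep2
            words=(("pain",), ("head", "pain")),
            diagnoses=(("dgA", 0), ("dgB", 1)),
            drugs=(("rxA", 0), ("rxB", 1)),
            measurements=(("msA", 0), ("msA", 1)),
        )
        np.testing.assert_allclose(
            sf.embed_episode(merged, hand_ensemble, 2),
            sf.embed_episode(ep1, hand_ensemble, 2)
            + sf.embed_episode(ep2, hand_ensemble, 2),
            atol=1e-12,
        )

    def test_unknown_window_rejected(self, hand_ensemble):
        with pytest.raises(KeyError):
            sf.embed_episode(make_episode(), hand_ensemble, window=9)


class TestTransform:
    def test_shape_and_rows(self, hand_ensemble):
        eps = [
            make_episode(episode_id=f"e{i}", diagnoses=(("dgA", 0),) * (i + 1))
            for i in range(3)
        ]
        ds = dataset_of(eps)
        out = sf.transform_dataset(ds, hand_ensemble, 1)
        assert out.matrix.shape == (3, 8)  # V=2, T=4
        for i, ep in enumerate(eps):
            np.testing.assert_allclose(
                out.matrix[i], sf.embed_episode(ep, hand_ensemble, 1)
            )

    def test_empty_dataset(self, hand_ensemble):
        ds = sf.LabeledDataset([], np.array([], dtype=int), "t")
        out = sf.transform_dataset(ds, hand_ensemble, 1)
        assert out.matrix.shape == (0, 8)

    def test_concat_windows_order_and_blocks(self, hand_ensemble):
        ds = dataset_of([make_episode()])
        both = sf.concat_windows(ds, hand_ensemble, [2, 1])
        assert both.n_features == 16
        assert both.windows == (1, 2)
        # ascending window order regardless of argument order
        w1 = sf.transform_dataset(ds, hand_ensemble, 1)
        np.testing.assert_allclose(both.matrix[:, :8], w1.matrix)
        # block bookkeeping: slicing by blocks reassembles the matrix
        reassembled = np.hstack([
            both.matrix[:, start:stop]
            for (_, _, start, stop) in both.block_index
        ])
        np.testing.assert_array_equal(reassembled, both.matrix)
        starts = [s for (_, _, s, _) in both.block_index]
        stops = [e for (_, _, _, e) in both.block_index]
        assert starts == [0, 2, 4, 6, 8, 10, 12, 14]
        assert stops == [2, 4, 6, 8, 10, 12, 14, 16]

    def test_single_window_equals_transform(self, hand_ensemble):
        ds = dataset_of([make_episode()])
        np.testing.assert_array_equal(
            sf.concat_windows(ds, hand_ensemble, [2]).matrix,
            sf.transform_dataset(ds, hand_ensemble, 2).matrix,
        )

    def test_empty_window_list_rejected(self, hand_ensemble):
        with pytest.raises(ValueError):
            sf.concat_windows(dataset_of([make_episode()]), hand_ensemble, [])


class TestFeatureBudget:
    @pytest.mark.parametrize(
        "strategy,V,T,P,expected",
        [
            (sf.Strategy.FDR, 200, 4, 10, (8000, 89)),
            (sf.Strategy.RDR_FS, 200, 4, 10, (8000, 28)),
            (sf.Strategy.RDR_ALL, 200, 4, 10, (8000, 800)),
            (sf.Strategy.RDR_FS, 1, 1, 1, (1, 1)),
        ],
    )
    def test_budgets(self, strategy, V, T, P, expected):
        assert sf.feature_budget(strategy, V, T, P) == expected


class TestBagOfEvents:
    def test_counts_and_target_removed(self):
        ep = make_episode(
            words=(("pain",),),
            diagnoses=(("c", 0), ("c", 1), ("ADE_X", 1)),
        )
        ds = dataset_of([ep])
        out = sf.bag_of_events(ds)
        cols = dict(zip(out.columns, out.matrix.toarray()[0]))
        assert cols[(DataType.DIAGNOSIS, "c")] == 2
        assert cols[(DataType.WORD, "pain")] == 1
        assert (DataType.DIAGNOSIS, "ADE_X") not in cols
        # conservation: c x2 + pain + default rxA + default msA = 5
        assert out.matrix.sum() == 5

    def test_row_sums_conserve_events(self, small_dataset):
        out = sf.bag_of_events(small_dataset)
        expected = []
        for ep in small_dataset.episodes:
            total = 0
            for dt in DataType:
                toks = ep.tokens(dt)
                if dt is DataType.DIAGNOSIS:
                    toks = [t for t in toks if t != small_dataset.target_code]
                total += len(toks)
            expected.append(total)
        np.testing.assert_array_equal(
            np.asarray(out.matrix.sum(axis=1)).ravel(), expected
        )


class TestLeakageGuard:
    def test_features_invariant_to_target_code_count(self, hand_ensemble):
        base = make_episode(diagnoses=(("dgA", 0),))
        spiked = make_episode(
            diagnoses=(("dgA", 0), ("ADE_X", 1), ("ADE_X", 2))
        )
        ds_base = dataset_of([base])
        ds_spiked = dataset_of([spiked])
        np.testing.assert_array_equal(
            sf.concat_windows(ds_base, hand_ensemble, [1, 2]).matrix,
            sf.concat_windows(ds_spiked, hand_ensemble, [1, 2]).matrix,
        )
        b1 = sf.bag_of_events(ds_base)
        b2 = sf.bag_of_events(ds_spiked)
        assert b1.columns == b2.columns
        np.testing.assert_array_equal(
            b1.matrix.toarray(), b2.matrix.toarray()
        )
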