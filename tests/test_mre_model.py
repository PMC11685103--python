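import numpy as np
import pytest

from mretarget import mre_model, nn
from mretarget.errors import ConfigurationError, DataError
from mretarget.feature_builder import BUNDLE_SHAPES
from mretarget.mre_model import (
    BranchSpec,
    ModelSpec,
    ablation_variants,
    build_model,
    default_branch_spec,
    score_mres,
    train_mre_model,
)

from .oracles import conv_chain_lengths


class TestBuildModel:
    def test_default_summary(self):
        net = build_model(ModelSpec(region="UTR3"))
        summary = net.summary()
        branches = {r["branch"] for r in summary} - {"head"}
        assert branches == {"mre", "chimera", "duplex", "fold", "conservation"}
        dense = [r for r in summary if r["type"] == "dense" and r["layer"] != "output"]
        assert [r["nodes"] for r in dense] == [90, 55, 35]
        out = [r for r in summary if r["layer"] == "output"]
        assert len(out) == 1 and out[0]["channels"] == 1
        assert out[0]["activation"] == "sigmoid"
        grus = [r for r in summary if r["type"] == "gru"]
        assert len(grus) == 5
        assert all(r["units"] == 24 and r["dropout"] == 0.1 for r in grus)
        pools = [r for r in summary if r["type"] == "pool"]
        assert pools and all(r["pool_size"] == 2 for r in pools)

    def test_single_branch_ablation_buildable(self):
        spec = ModelSpec(region="UTR3", branches=(default_branch_spec("chimera"),))
        net = build_model(spec)
        branches = {r["branch"] for r in net.summary()} - {"head"}
        assert branches == {"chimera"}
        dense = [r for r in net.summary() if r["type"] == "dense" and r["layer"] != "output"]
        assert [r["nodes"] for r in dense] == [90, 55, 35]

    @pytest.mark.parametrize("name", mre_model.BRANCH_NAMES)
    def test_layer_arithmetic_matches_closed_form(self, name):
        spec = default_branch_spec(name)
        net = build_model(ModelSpec(region="UTR3", branches=(spec,)))
        got = [
            (r["type"], r["output_len"])
            for r in net.summary()
            if r["branch"] == name and r["type"] in ("conv", "pool")
        ]
        expected = conv_chain_lengths(
            BUNDLE_SHAPES[name][0], spec.conv_layers, spec.pool_size
        )
        assert got == expected

    def test_conservation_conv1_example(self):
        # kernel 9, stride 3 on length 150: floor((150-9)/3)+1 = 48, pool -> 24
        spec = default_branch_spec("conservation")
        net = build_model(ModelSpec(region="UTR3", branches=(spec,)))
        rows = [r for r in net.summary() if r["branch"] == "conservation"]
        assert rows[0]["output_len"] == 48
        assert rows[1]["type"] == "pool" and rows[1]["output_len"] == 24

    def test_bad_arithmetic_names_layer(self):
        bad = BranchSpec(name="chimera", conv_layers=((16, 40, 2), (32, 40, 3)))
        with pytest.raises(ConfigurationError, match="chimera.*conv layer 2"):
            build_model(ModelSpec(region="UTR3", branches=(bad,)))

    def test_summary_lengths_match_actual_forward(self):
        """The reported arithmetic must agree with a real forward pass."""
        spec = ModelSpec(region="UTR3")
        net = build_model(spec)
        x = {
            name: np.random.default_rng(0).random((3, *BUNDLE_SHAPES[name]))
            for name in spec.branch_names()
        }
        out = net.forward(x, train=False)
        assert out.shape == (3,)

    def test_unknown_branch_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown branch"):
            BranchSpec(name="mystery", conv_layers=((8, 3, 1),))

    def test_no_branches_rejected(self):
        with pytest.raises(ConfigurationError, match="at least one"):
            ModelSpec(region="UTR3", branches=())


def _tiny_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    arrays = {
        name: rng.random((n, *BUNDLE_SHAPES[name])) for name in mre_model.BRANCH_NAMES
    }
    labels = np.array([0, 1] * (n // 2))
    # make the conservation branch informative
    arrays["conservation"][labels == 1] += 0.5
    return arrays, labels


class TestTraining:
    def test_single_class_rejected(self):
        arrays, _ = _tiny_data()
        spec = ModelSpec(region="UTR3", epochs=1, seed=0)
        net = build_model(spec)
        with pytest.raises(DataError, match="both classes"):
            train_mre_model(net, (arrays, np.ones(40)), spec)

    def test_seed_reproducibility_epoch1(self):
        arrays, labels = _tiny_data()
        losses = []
        for _ in range(2):
            spec = ModelSpec(region="UTR3", epochs=1, seed=5, batch_size=16)
            net = build_model(spec)
            trained = train_mre_model(net, (arrays, labels), spec)
            losses.append(trained.history[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_history_and_early_stop_fields(self):
        arrays, labels = _tiny_data()
        spec = ModelSpec(region="UTR3", epochs=3, seed=1, batch_size=16,
                         learning_rate=1e-3)
        trained = train_mre_model(build_model(spec), (arrays, labels), spec)
        assert 1 <= len(trained.history) <= 3
        for h in trained.history:
            assert {"epoch", "train_loss", "val_loss", "val_auc"} <= set(h)


@pytest.fixture(scope="module")
def trained():
    arrays, labels = _tiny_data(n=60, seed=3)
    spec = ModelSpec(region="UTR3", epochs=2, seed=3, batch_size=16,
                     learning_rate=1e-3)
    return train_mre_model(build_model(spec), (arrays, labels), spec), arrays


class TestScoring:
    def test_scores_in_unit_interval(self, trained):
        model, arrays = trained
        scores = score_mres(model, arrays)
        assert scores.shape == (60,)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_batch_size_invariance(self, trained):
        model, arrays = trained
        s1 = score_mres(model, arrays, batch_size=7)
        s2 = score_mres(model, arrays, batch_size=60)
        assert np.max(np.abs(s1 - s2)) < 1e-5

    def test_shape_mismatch_names_branch(self, trained):
        model, arrays = trained
        bad = dict(arrays)
        bad["duplex"] = bad["duplex"][:, :10, :]
        with pytest.raises(DataError, match="duplex"):
            score_mres(model, bad)


class TestAblation:
    def test_eight_variants(self):
        variants = ablation_variants(ModelSpec(region="UTR3"))
        assert len(variants) == 8
        names = [v.name for v in variants]
        assert len(set(names)) == 8
        assert {"chimera_conservation", "chimera_duplex", "no_fold"} <= set(names)
        singles = [v for v in variants if len(v.branches) == 1]
        assert len(singles) == 5

    def test_all_variants_buildable(self):
        for v in ablation_variants(ModelSpec(region="UTR3")):
            net = build_model(v)
            assert net.summary()


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        arrays, labels = _tiny_data(n=40, seed=2)
        spec = ModelSpec(region="CDS", epochs=1, seed=2, batch_size=16)
        trained = train_mre_model(build_model(spec), (arrays, labels), spec)
        before = score_mres(trained, arrays)
        mre_model.save_model(trained, tmp_path / "model")
        loaded = mre_model.load_model(tmp_path / "model")
        after = score_mres(loaded, arrays)
        np.testing.assert_allclose(before, after, atol=1e-12)
        assert loaded.spec.region == "CDS"
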