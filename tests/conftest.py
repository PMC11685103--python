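import numpy as np
import pytest

from mretarget import core_io, mre_model, synthetic_data
from mretarget.core_io import SeqRecord, TranscriptModel

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"


@pytest.fixture(scope="session")
def let7a():
    return SeqRecord("let-7a-5p", LET7A)


@pytest.fixture()
def utr_transcript():
    """Simple single-region transcript: 3' UTR covers the whole sequence."""

    def make(seq, tid="t1", gene="g1"):
        seq = core_io.normalize_seq(seq)
        return TranscriptModel(tid, gene, seq, cds=(0, 0), utr3=(0, len(seq)))

    return make


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted MRE dataset shared by feature/model unit tests."""
    cfg = synthetic_data.SimConfig(n_pos=60, n_neg=60, seed=13)
    return synthetic_data.generate_mre_dataset(cfg)


# ---------------------------------------------------------------------------
# Acceptance-scale fixtures (built once per session; used by test_acceptance)
# ---------------------------------------------------------------------------

ACCEPT_SEED = 7
ACCEPT_TRAIN_KW = dict(
    epochs=16, early_stop_patience=6, learning_rate=1e-3, batch_size=64,
    seed=ACCEPT_SEED,
)


@pytest.fixture(scope="session")
def accept_dataset():
    cfg = synthetic_data.SimConfig(n_pos=2000, n_neg=2000, seed=ACCEPT_SEED)
    return synthetic_data.generate_mre_dataset(cfg)


@pytest.fixture(scope="session")
def accept_split(accept_dataset):
    """Stratified 85/15 train/test split of the acceptance dataset."""
    ds = accept_dataset
    rng = np.random.default_rng(ACCEPT_SEED)
    test_idx, train_idx = [], []
    for cls in (0, 1):
        idx = rng.permutation(np.flatnonzero(ds.labels == cls))
        n_test = int(round(len(idx) * 0.15))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    train_idx = np.concatenate(train_idx)
    test_idx = np.concatenate(test_idx)
    return {
        "xtr": {k: v[train_idx] for k, v in ds.arrays.items()},
        "ytr": ds.labels[train_idx],
        "xte": {k: v[test_idx] for k, v in ds.arrays.items()},
        "yte": ds.labels[test_idx],
    }


@pytest.fixture(scope="session")
def accept_full_model(accept_split):
    spec = mre_model.ModelSpec(region="UTR3", **ACCEPT_TRAIN_KW)
    net = mre_model.build_model(spec)
    return mre_model.train_mre_model(
        net, (accept_split["xtr"], accept_split["ytr"]), spec
    )
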