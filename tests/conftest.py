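import numpy as np
import pytest

from cbamhar.evaluation import macro_f1
from cbamhar.experiments import parse_name
from cbamhar.model import ModelConfig, TrainConfig, build_model, train
from cbamhar.synthetic import make_benchmark


@pytest.fixture(scope="session")
def separable6():
    """The seeded separable 6-class benchmark (599 windows, 9 signals)."""
    return make_benchmark("separable6", seed=1)


@pytest.fixture(scope="session")
def benchmark_scores(separable6):
    """Best validation macro-F1 of the full backbone trained for up to 20
    epochs, without attention and with one setting of each attention mode.

    Session-scoped because each training run takes tens of seconds; the
    scores feed both the training-sanity and the end-to-end pipeline
    checks.
    """
    ds = separable6
    scores = {}
    for name in ("wo_attention", "w_CHatt3(8)", "w_SPatt3(5)",
                 "w_CHSPatt1(16)(3)"):
        spec = parse_name(name)
        cfg = ModelConfig(
            window_length=ds.window_shape[0],
            n_signals=ds.window_shape[1],
            n_classes=ds.n_classes,
            attention=(spec,) if spec else (),
            seed=1,
        )
        model, history = train(build_model(cfg), ds,
                               TrainConfig(max_epochs=20, seed=1))
        scores[name] = max(history["val_macro_f1"])
    return scores
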