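import numpy as np
import pytest

from itcep.encoders import build_aapp_table
from itcep.fixtures import MotifSpec, make_labeled_dataset
from itcep.model import ModelConfig, build_itcep_model, encode_features, train_model


@pytest.fixture(scope="session")
def tiny_config():
    """Reduced widths/epochs so training-dependent tests stay fast; the
    convolutional structure is unchanged."""
    return ModelConfig(module_dense=32, fusion_dense=(64, 32), epochs=3, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    records, repertoire = make_labeled_dataset(6, 8, MotifSpec(strength=0.9), seed=11)
    return records, repertoire


@pytest.fixture(scope="session")
def trained_tiny(small_dataset, tiny_config):
    records, _ = small_dataset
    positives = [r for r in records if r.label == 1]
    aapp = build_aapp_table(positives)
    peptides = sorted({r.peptide for r in positives})
    x1, x2 = encode_features(records, "onehot-aapp", aapp, None, peptides)
    net = build_itcep_model(tiny_config)
    model = train_model(net, x1, x2, [r.label for r in records], tiny_config)
    return model, aapp, peptides, records
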