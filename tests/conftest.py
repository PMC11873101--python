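import numpy as np
import pytest

from sliceclr import (ConfusionMatrix, ConvNeXtBackbone, PhantomSpec,
                      ProbeConfig, SSLConfig, extract_features,
                      generate_cohort, predict_scan, prepare_slices,
                      train_probe, train_ssl)
from sliceclr.backbone import TEST_TINY


@pytest.fixture(scope="session")
def small_cohort():
    """4 participants/class, 2 scans each, default phantom conditions."""
    spec = PhantomSpec(scans_per_participant=2, seed=123)
    return spec, generate_cohort(spec, 4)


@pytest.fixture(scope="session")
def cohort_slices(small_cohort):
    _, cohort = small_cohort
    slices = []
    for v in cohort.volumes:
        slices.extend(prepare_slices(v, 12))
    return slices


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def recovery_run():
    """Scaled-down end-to-end run shared across test modules.

    Phantoms with 40% regional atrophy, NNCLR pretraining of the reduced
    backbone, frozen linear probe, majority voting on a held-out phantom
    cohort of 20 scans per class.
    """
    n_keep = 20
    train = generate_cohort(PhantomSpec(effect_size=0.4, seed=11), 10)
    test = generate_cohort(PhantomSpec(effect_size=0.4, seed=12), 20)
    classes = tuple(sorted(train.manifest["diagnosis"].unique()))
    train_slices = []
    for v in train.volumes:
        train_slices.extend(prepare_slices(v, n_keep))

    extractor = ConvNeXtBackbone(TEST_TINY, seed=7)
    extractor, _, trace = train_ssl(
        extractor, train_slices,
        SSLConfig(epochs=60, batch_size=64, lr=1e-4, seed=7))

    feats = extract_features(extractor, train_slices)
    fcols = [c for c in feats.columns if c.startswith("f")]
    probe_cfg = ProbeConfig(n_classes=2, class_names=classes, epochs=100,
                            seed=7)
    head = train_probe(feats[fcols].to_numpy(), feats["label"].tolist(),
                       probe_cfg)

    def confusion(backbone, head_model):
        y_true, y_pred = [], []
        for v in test.volumes:
            p = predict_scan(backbone, head_model, v, n_keep, classes)
            y_true.append(v.label)
            y_pred.append(p.final_label)
        return ConfusionMatrix.from_labels(y_true, y_pred, classes)

    return {"extractor": extractor, "head": head, "trace": trace,
            "classes": classes, "train_slices": train_slices,
            "train_volumes": train.volumes, "test_volumes": test.volumes,
            "probe_cfg": probe_cfg, "confusion": confusion,
            "fcols": fcols, "n_keep": n_keep}
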