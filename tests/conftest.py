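import numpy as np
import pytest

import ldu


@pytest.fixture(scope="session")
def fast_base_spec() -> ldu.BaseClassifierSpec:
    """Desk-scale member recipe shared across training tests."""
    return ldu.BaseClassifierSpec()


@pytest.fixture(scope="session")
def mixed_cohort():
    """Standard mixed-regime cohort: easy / ambiguous / overconfident-wrong."""
    table = ldu.generate(ldu.GeneratorConfig(n_per_class=500, seed=42))
    train, test = ldu.split(table, 0.7, seed=42)
    return train, test


@pytest.fixture(scope="session")
def mixed_ensemble(mixed_cohort, fast_base_spec):
    train, _ = mixed_cohort
    return ldu.train_ensemble(train, fast_base_spec, K=5, master_seed=7)


@pytest.fixture(scope="session")
def mixed_outputs(mixed_cohort, mixed_ensemble):
    train, test = mixed_cohort
    return ldu.predict(mixed_ensemble, train), ldu.predict(mixed_ensemble, test)


@pytest.fixture(scope="session")
def stage2_features(mixed_outputs):
    out_train, out_test = mixed_outputs
    return (
        ldu.build_stage2_features(out_train),
        ldu.build_stage2_features(out_test),
    )


def make_output(probs: np.ndarray, labels=None) -> ldu.EnsembleOutput:
    """Hand-built EnsembleOutput for decision-rule tests."""
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    n, k = probs.shape
    ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    label = None if labels is None else np.asarray(labels, dtype=int)
    return ldu.EnsembleOutput(ids, probs, member_seeds=list(range(k)), label=label)
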