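import pytest

from sdrvitals import lab_accuracy_experiment


@pytest.fixture(scope="session")
def lab_experiment():
    """The 30-trial lab-conditions accuracy experiment, run once per session.

    Shared between the accuracy acceptance check and the covariate-null
    analysis; takes a couple of minutes, dominated by the 30 end-to-end
    pipeline runs.
    """
    return lab_accuracy_experiment(n_trials=30, seed=1)
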