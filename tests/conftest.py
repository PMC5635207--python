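import pytest

from dcwqsar import DcwRegressor, load_fixture


@pytest.fixture(scope="session")
def fixture_set():
    return load_fixture()


@pytest.fixture(scope="session")
def split1(fixture_set):
    """The four sets of the packaged dataset under its printed markers."""
    return {
        label: fixture_set.subset(label)
        for label in ("subtraining", "invtraining", "calibration", "validation")
    }


@pytest.fixture(scope="session")
def quick_model(split1):
    """A cheaply trained hybrid model on the packaged dataset, shared across
    tests that need any trained model (not a converged one)."""
    est = DcwRegressor(mode="hybrid", n_epochs=3, random_state=0)
    est.fit(split1["subtraining"], X_invisible=split1["invtraining"])
    return est
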