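import numpy as np
import pytest

import cppscreen as cs


@pytest.fixture(scope="session")
def cpp111():
    return cs.load_bundled("cpp111")


@pytest.fixture(scope="session")
def noncpp34():
    return cs.load_bundled("noncpp34")


@pytest.fixture(scope="session")
def validation13():
    return cs.load_bundled("validation13")


@pytest.fixture(scope="session")
def freq_model():
    return cs.default_frequency_model()


@pytest.fixture(scope="session")
def charge_toy_dataset():
    """Balanced toy problem where class = sign of net charge.

    Positive class: arginine/lysine-rich peptides; negative class:
    aspartate/glutamate-rich. Separable on the charge features alone.
    """
    rng = np.random.default_rng(7)
    peps = []
    y = []
    for i in range(30):
        n_charge = rng.integers(3, 8)
        n_pad = rng.integers(5, 10)
        pad = "".join(rng.choice(list("AGSTLV"), size=n_pad))
        pos_seq = "".join(rng.choice(list("RK"), size=n_charge)) + pad
        neg_seq = "".join(rng.choice(list("DE"), size=n_charge)) + pad
        peps.append(cs.Peptide(f"pos_{i}", pos_seq, cs.Label.CPP))
        y.append(1)
        peps.append(cs.Peptide(f"neg_{i}", neg_seq, cs.Label.NON_CPP))
        y.append(-1)
    X = cs.feature_table(peps)
    return X, np.array(y), peps
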