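import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from normcard import FixtureSpec, make_model, slj_like_model


@pytest.fixture(scope="session")
def no_model():
    """Gaussian, intercept-only: mu = 100 (identity), sigma = 15 (log)."""
    import numpy as np
    from normcard import NormModel, OutcomeSpec, ParameterBlock, PredictorSpec

    return NormModel(
        family_id="NO",
        outcome=OutcomeSpec(name="iq", support="real"),
        predictors=(PredictorSpec(name="x1", valid_range=(0.0, 1.0)),),
        blocks={
            "mu": ParameterBlock("identity", 100.0, (("x1", 0.0),)),
            "sigma": ParameterBlock("log", float(np.log(15.0))),
        },
    )


@pytest.fixture(scope="session")
def bct_spline_model():
    return make_model(FixtureSpec(family_id="BCT", seed=7,
                                  splines={"mu": (3, 8), "sigma": (3, 8)}))


@pytest.fixture(scope="session")
def slj_model():
    return slj_like_model()


@pytest.fixture(scope="session")
def all_family_models():
    return {
        fam: make_model(FixtureSpec(family_id=fam, seed=11 + i,
                                    splines={"mu": (3, 6)}))
        for i, fam in enumerate(["NO", "BCCG", "BCPE", "BCT"])
    }
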