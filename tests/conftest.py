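import warnings

import pytest

import pvsignal as pv


@pytest.fixture(scope="session")
def raw_fixture():
    return pv.anti_vegf_fixture()


@pytest.fixture(scope="session")
def filtered_fixture(raw_fixture):
    kept, log = pv.apply_inclusion_filters(raw_fixture)
    return kept, log


@pytest.fixture(scope="session")
def fixture_screen(filtered_fixture):
    """Disproportionality screen over the worked-example pair set."""
    kept, _ = filtered_fixture
    pairs = pv.build_pairs(kept)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pv.DisproportionalityScreen.from_pairs(
            pairs, min_a=1, prior=pv.IcPrior(n_mc=50_000), seed=7
        ).fit()


@pytest.fixture(scope="session")
def small_synthetic():
    """A small clean synthetic report set for recount-style oracles."""
    cfg = pv.SyntheticConfig(n_reports=400, seed=3)
    return pv.generate_reports(cfg)
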