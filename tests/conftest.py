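import numpy as np
import pytest

from relnxpress import ExpressionModel, generate_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study, fixed seed, shared across the suite."""
    return generate_bundle(seed=7)


@pytest.fixture(scope="session")
def noiseless_bundle():
    """All noise and covariate effects switched off; exact mean recovery."""
    expr = ExpressionModel(
        polya_sd=0.0,
        retention_sd=0.0,
        ph_effect_on_skipping=0.0,
        pmi_effect_on_polya=0.0,
        use_gxs_cells=False,
        aei_base_sd=0.0,
        total_expr_log2_sd=0.0,
        ct_noise_sd=0.0,
        peak_noise_cv=0.0,
        bias_slope=0.0,
        aspe_noise_sd=0.0,
    )
    return generate_bundle(expression=expr, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
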