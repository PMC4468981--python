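import numpy as np
import pandas as pd
import pytest

from searchprime import behavior, design, preprocess


@pytest.fixture(scope="session")
def exp1b_design():
    return design.build_design("exp1b")


@pytest.fixture(scope="session")
def exp1b_sequence(exp1b_design):
    return design.generate_trial_sequence(exp1b_design, 7)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced exp1b cohort (8 participants) for pipeline-level tests."""
    preset = behavior.get_preset("exp1b")
    cohort, awareness = behavior.generate_cohort(preset, 42, n_participants=8)
    return cohort, awareness


@pytest.fixture(scope="session")
def small_corrected(small_cohort):
    corrected, report = preprocess.preprocess_cohort(small_cohort[0])
    return corrected, report


@pytest.fixture()
def toy_anova_data():
    """Tiny balanced two-participant table for BF oracle checks."""
    rng = np.random.default_rng(5)
    return pd.DataFrame({
        "participant": [0] * 4 + [1] * 4,
        "repetition_type": ["repetition", "switch"] * 4,
        "target_type": ["bias_color", "bias_color", "other_color",
                        "other_color"] * 2,
        "zrt_corrected": rng.standard_normal(8) + np.array([0.0, 0.5] * 4),
    })
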