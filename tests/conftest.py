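import numpy as np
import pytest

from mnar_elicit import (
    AnchorScores,
    ArmSummary,
    PanelGenConfig,
    TrialGenConfig,
    build_expert_prior,
    generate_panel,
    generate_trial,
    linear_pool,
)


@pytest.fixture(scope="session")
def worked_example_arms():
    """Arm summaries of the illustrative two-arm trial: observed means
    0.76 (SE 0.02) / 0.69 (SE 0.03), missing proportions 0.18 / 0.24."""
    evar = ArmSummary(mu=0.76, se_mu=0.02, pi=0.18, label="EEVAR")
    open_ = ArmSummary(mu=0.69, se_mu=0.03, pi=0.24, label="OPEN")
    return evar, open_


@pytest.fixture(scope="session")
def anchors():
    return AnchorScores(open_observed=65.0, evar_observed=73.0)


@pytest.fixture(scope="session")
def panel(anchors):
    """A 26-expert synthetic panel (9 nurses, 17 doctors) with known truth."""
    return generate_panel(PanelGenConfig(seed=42), anchors=anchors)


@pytest.fixture(scope="session")
def panel_priors(panel):
    return [build_expert_prior(r, panel.anchors) for r in panel.responses]


@pytest.fixture(scope="session")
def panel_pool(panel_priors):
    return linear_pool(panel_priors)


@pytest.fixture(scope="session")
def small_trial():
    cfg = TrialGenConfig(n_per_arm=150, seed=7)
    return generate_trial(cfg)
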