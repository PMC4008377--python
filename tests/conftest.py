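import numpy as np
import pandas as pd
import pytest

from printpair import (
    GenConfig,
    ModelSpec,
    PanelConfig,
    fit_glmm,
    generate_known,
    simulate_features,
    simulate_panel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def whorl_print():
    """One clean synthetic whorl with mask and annotation."""
    return generate_known(GenConfig(pattern_class="whorl", seed=3))


@pytest.fixture(scope="session")
def small_panel():
    """A 100-pair simulated panel with known generating parameters."""
    feats = simulate_features(100, ["x1", "x2"], np.random.default_rng(8))
    cfg = PanelConfig(
        beta0=2.5, beta={"x1": 0.6, "x2": -0.4},
        var_print=1.5, var_expert=0.3, seed=9, experts_per_pair=10,
    )
    trials = simulate_panel(feats, cfg).data
    return feats, trials, cfg


@pytest.fixture(scope="session")
def small_panel_fit(small_panel):
    feats, trials, _ = small_panel
    spec = ModelSpec("correct", ["x1", "x2"], ["printID"])
    return fit_glmm(spec, trials, feats), feats, trials


def make_trials_csv(path, n_total=40, n_no_decision=4, n_no_rating=2):
    """Write a trial CSV with given counts of decision-absent and
    rating-absent rows; returns expected retained count."""
    rows = []
    for i in range(n_total):
        pair = f"P{i % (n_total // 2):03d}"
        expert = f"E{i // (n_total // 2):02d}"
        no_decision = i < n_no_decision
        no_rating = n_no_decision <= i < n_no_decision + n_no_rating
        rows.append({
            "pair_id": pair,
            "expert_id": expert,
            "is_match": i % 2 == 0,
            "judged_match": "" if no_decision else (i % 2 == 0),
            "difficulty": "" if (no_decision or no_rating) else 1 + i % 6,
            "confidence": "" if (no_decision or no_rating) else 1 + (i + 3) % 6,
            "response_time": 30.0 + i,
            "timed_out": no_decision,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
    return n_total - n_no_decision
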