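import numpy as np
import pandas as pd
import pytest

from swaylab.io_config import RunConfig
from swaylab.preprocess import preprocess_trial
from swaylab.synthetic import SwayKnobs, gen_sway_trial


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def sway_trial():
    """One default 60 s / 500 Hz synthetic trial."""
    return gen_sway_trial(SwayKnobs(), seed=11)


@pytest.fixture(scope="session")
def clean_pair(sway_trial, cfg):
    """Preprocessed (ML, AP) clean signals of the session trial."""
    ml, ap, verdict = preprocess_trial(sway_trial, cfg)
    assert verdict.passed
    return ml, ap


def balanced_table(n_per_group: int, seed: int, effects: dict | None = None) -> pd.DataFrame:
    """Small balanced 2×2×2 measure table with optional injected effects."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for g_i, g in enumerate(("YO", "YN")):
        for s in range(n_per_group):
            subj = rng.normal(0, 1.0)
            for c_i, c in enumerate(("firm", "foam")):
                for v_i, v in enumerate((1, 2)):
                    val = (
                        10.0
                        + subj
                        + effects.get("group", 0.0) * g_i
                        + effects.get("condition", 0.0) * c_i
                        + effects.get("visit", 0.0) * v_i
                        + effects.get("group x condition", 0.0) * g_i * c_i
                        + rng.normal(0, 0.5)
                    )
                    rows.append(
                        {
                            "subject": f"{g}{s + 1:02d}",
                            "group": g,
                            "condition": c,
                            "visit": v,
                            "value": val,
                        }
                    )
    return pd.DataFrame(rows)
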