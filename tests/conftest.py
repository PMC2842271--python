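import numpy as np
import pandas as pd
import pytest

import fructrisk as fr

# ---------------------------------------------------------------------------
# Hand-built 3-food / 5-commodity fixture with spreadsheet-checkable numbers.
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def tiny_nutrients() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "commodity_id": ["APPLE", "ORANGE", "OJ", "SUGAR", "CORN"],
            "fructose_per_100g": [6.0, 2.25, np.nan, 0.0, 0.0],
            "carb_per_100g": [14.0, 11.54, 10.0, 100.0, 100.0],
            "sucrose_per_100g": [0.0, 0.0, 0.0, 100.0, 0.0],
            "is_added_sugar": [False, False, False, True, True],
            "sweetener_class": ["none", "none", "none", "cane_beet", "corn_sweetener"],
            "family_id": [None, None, "ORANGE", None, None],
        }
    )


@pytest.fixture(scope="session")
def tiny_composition() -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("F_FRUIT", "APPLE", 0.5),
            ("F_FRUIT", "OJ", 0.4),
            ("F_SODA", "CORN", 0.11),
            ("F_SODA", "OJ", 0.05),
            ("F_DESSERT", "SUGAR", 0.3),
            ("F_DESSERT", "APPLE", 0.2),
        ],
        columns=["food_id", "commodity_id", "fraction"],
    )


@pytest.fixture(scope="session")
def tiny_recalls() -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("S1", "F_FRUIT", 200.0, True),
            ("S1", "F_SODA", 100.0, True),
            ("S2", "F_DESSERT", 150.0, True),
        ],
        columns=["subject_id", "food_id", "grams_consumed", "reliable"],
    )


@pytest.fixture(scope="session")
def tiny_energy() -> pd.Series:
    return pd.Series({"S1": 2000.0, "S2": 1500.0})


# ---------------------------------------------------------------------------
# Small generated scenario, shared across test modules.
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_scenario():
    cfg = fr.ScenarioConfig(n_subjects=400, seed=11)
    tables = fr.generate_scenario(cfg)
    return cfg, tables


@pytest.fixture(scope="session")
def mid_cohort():
    """Prepared analysis cohort with planted alcohol/fiber effects."""
    cfg = fr.ScenarioConfig(
        n_subjects=6000,
        seed=5,
        effect_log_odds={
            "alcohol": (0.0, 0.1, 0.35, float(np.log(1.8))),
            "fiber": (0.0, -0.25, -0.5, float(np.log(0.45))),
        },
    )
    tables = fr.generate_scenario(cfg)
    subjects, recalls, _ = fr.exclude(tables["subjects"], tables["recalls"])
    energy = subjects.set_index("subject_id")["energy_kcal"]
    intakes, _ = fr.estimate_intakes(
        recalls, tables["composition"], tables["nutrients"], fr.SweetenerMix(), energy
    )
    cohort, meta = fr.build_cohort(subjects, intakes, fr.CDC_SCHEME)
    return cohort, meta, tables["truth"]
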