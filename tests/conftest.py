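import numpy as np
import pandas as pd
import pytest

from dietgxe.simulate import SimulationTruth, simulate_genotypes, simulate_phenotypes


@pytest.fixture(scope="session")
def small_genotypes():
    return simulate_genotypes(30, 200, ("uniform", 0.05, 0.5), seed=11)


@pytest.fixture(scope="session")
def balanced_panel():
    """10 lines x 2 diets x 2 ages x 3 reps x 5 flies, all terms present."""
    truth = SimulationTruth(
        n_lines=10,
        var_components={"line": 1.0, "line:age": 0.5, "line:diet": 0.5,
                        "line:age:diet": 0.25, "rep": 0.2, "e": 2.0},
        seed=3,
    )
    return simulate_phenotypes(truth, None, n_reps=3, flies_per_rep=5)


@pytest.fixture()
def toy_two_way():
    """3 lines x 2 diets x 2 observations per cell, printed integers."""
    rows = []
    data = {
        ("L1", "control"): [10, 12], ("L1", "restricted"): [8, 9],
        ("L2", "control"): [14, 13], ("L2", "restricted"): [12, 14],
        ("L3", "control"): [9, 8], ("L3", "restricted"): [10, 7],
    }
    for (line, diet), vals in data.items():
        for i, v in enumerate(vals):
            rows.append({"line_id": line, "diet": diet, "age_days": 7,
                         "replicate": i + 1, "trait": float(v)})
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_phenotype_table():
    """Minimal healthspan table exercising the balancing rules."""
    rows = []
    for line, diets in [("A", ("control", "restricted")), ("B", ("control",))]:
        for diet in diets:
            for age in (7, 16, 25, 34):
                rows.append({"line_id": line, "diet": diet, "age_days": age,
                             "replicate": 1, "dry_weight_mg": 0.18})
    return pd.DataFrame(rows)


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
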