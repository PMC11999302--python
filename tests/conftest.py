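import numpy as np
import pandas as pd
import pytest

from svikit import IndicatorTable, load_hierarchy, load_preset

MINI_HIERARCHY_YAML = """
name: mini
hazard: flood
dimensions:
  - {id: sensitivity, label: Sensitivity}
  - {id: adaptive_capacity, label: Adaptive Capacity}
  - {id: enhanced_exposure, label: Enhanced Exposure}
domains:
  - {id: d_age, label: Age, dimension: sensitivity}
  - {id: d_health, label: Health, dimension: sensitivity}
  - {id: d_income, label: Income, dimension: adaptive_capacity}
  - {id: d_tenure, label: Tenure, dimension: adaptive_capacity}
  - {id: d_housing, label: Housing, dimension: enhanced_exposure}
  - {id: d_env, label: Environment, dimension: enhanced_exposure}
indicators:
  - {id: over_75, label: Over 75, domain: d_age, direction: vulnerability_increasing}
  - {id: poor_health, label: Poor health, domain: d_health, direction: vulnerability_increasing}
  - {id: unemployment, label: Unemployment, domain: d_income, direction: vulnerability_increasing}
  - {id: renting, label: Renting, domain: d_tenure, direction: vulnerability_increasing}
  - {id: old_dwellings, label: Old dwellings, domain: d_housing, direction: vulnerability_increasing}
  - {id: tree_cover, label: Tree cover, domain: d_env, direction: vulnerability_reducing}
"""

# hand-written 5-area fixture: plausible census-like percentages
MINI_TABLE = pd.DataFrame(
    {
        "over_75": [8.0, 12.0, 5.5, 20.0, 9.5],
        "poor_health": [2.0, 4.5, 1.0, 6.0, 3.0],
        "unemployment": [6.0, 14.0, 4.0, 18.0, 9.0],
        "renting": [25.0, 55.0, 15.0, 70.0, 35.0],
        "old_dwellings": [10.0, 40.0, 5.0, 60.0, 20.0],
        "tree_cover": [30.0, 8.0, 45.0, 3.0, 18.0],
    },
    index=pd.Index(["A1", "A2", "A3", "A4", "A5"], name="area_id"),
)


@pytest.fixture(scope="session")
def cork():
    return load_preset("cork_flood")


@pytest.fixture(scope="session")
def logrono():
    return load_preset("logrono_heat")


@pytest.fixture(scope="session")
def milan():
    return load_preset("milan_heat")


@pytest.fixture(scope="session")
def mini_cfg():
    return load_hierarchy(MINI_HIERARCHY_YAML)


@pytest.fixture()
def mini_table():
    return IndicatorTable(MINI_TABLE.copy())


def make_random_fixture(rng: np.random.Generator):
    """A random small hierarchy + complete table, plus the pieces the naive
    oracle needs.  Used for the implementation-vs-oracle equivalence sweep."""
    dims = ["sensitivity", "adaptive_capacity", "enhanced_exposure"]
    n_domains = int(rng.integers(3, 7))
    domains = []
    indicators = []
    for d in range(n_domains):
        dom = f"dom{d}"
        dim = dims[d % 3] if d < 3 else dims[int(rng.integers(0, 3))]
        domains.append({"id": dom, "dimension": dim})
        for j in range(int(rng.integers(1, 4))):
            direction = (
                "vulnerability_reducing"
                if rng.random() < 0.25
                else "vulnerability_increasing"
            )
            indicators.append(
                {"id": f"i{d}_{j}", "domain": dom, "direction": direction}
            )
    doc = {
        "name": "random",
        "hazard": "flood",
        "dimensions": [{"id": d} for d in dims],
        "domains": domains,
        "indicators": indicators,
    }
    import yaml

    cfg = load_hierarchy(yaml.safe_dump(doc))
    n_areas = int(rng.integers(5, 21))
    values = rng.normal(50, 10, size=(n_areas, len(indicators)))
    df = pd.DataFrame(
        values,
        index=pd.Index([f"A{i}" for i in range(n_areas)], name="area_id"),
        columns=[i["id"] for i in indicators],
    )
    return cfg, IndicatorTable(df)
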