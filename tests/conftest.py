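import numpy as np
import pandas as pd
import pytest

from assemblage.core_data import CountTable, SampleFrame
from assemblage.synthetic_data import Bundle, ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def toy_bundle() -> Bundle:
    """Small but structurally complete scenario used across modules."""
    cfg = ScenarioConfig(
        n_stations=3,
        n_otus_pool=80,
        n_cultures_per_station=8,
        n_functions=15,
        seed=42,
    )
    return generate_scenario(cfg)


@pytest.fixture(scope="session")
def neutral_bundle() -> Bundle:
    cfg = ScenarioConfig(
        n_stations=3,
        n_otus_pool=80,
        n_cultures_per_station=10,
        selection_strength=0.0,
        phylo_signal=0.0,
        competition_strength=0.0,
        seed=11,
    )
    return generate_scenario(cfg)


@pytest.fixture
def tiny_table() -> CountTable:
    return CountTable(
        ("s1", "s2", "s3"),
        ("o1", "o2", "o3", "o4"),
        np.array([[3, 0, 1, 17], [4, 2, 0, 0], [0, 0, 5, 5]]),
    )


@pytest.fixture
def tiny_frame() -> SampleFrame:
    df = pd.DataFrame(
        {
            "kind": ["source", "culture", "culture"],
            "station": ["A", "A", "A"],
            "habitat": ["sediment", "sediment", "sediment"],
            "source_sample_id": [pd.NA, "s1", "s1"],
            "salinity": [30.0, 30.0, 30.0],
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return SampleFrame(df)


# ----------------------------------------------------------------------------
# independent oracles (brute force; kept deliberately naive)
# ----------------------------------------------------------------------------

def oracle_mpd_within(present: list[int], dist: np.ndarray) -> float:
    pairs = [(i, j) for i in present for j in present if i < j]
    if not pairs:
        return float("nan")
    return sum(dist[i, j] for i, j in pairs) / len(pairs)


def oracle_mpd_between(a: list[int], b: list[int], dist: np.ndarray) -> float:
    if not a or not b:
        return float("nan")
    return sum(dist[i, j] for i in a for j in b) / (len(a) * len(b))


def oracle_c_score(inc: np.ndarray, normalise: bool) -> float:
    occupied = [j for j in range(inc.shape[1]) if inc[:, j].sum() > 0]
    units = []
    for x, i in enumerate(occupied):
        for j in occupied[x + 1:]:
            ri = int(inc[:, i].sum())
            rj = int(inc[:, j].sum())
            s = int(((inc[:, i] > 0) & (inc[:, j] > 0)).sum())
            cu = (ri - s) * (rj - s)
            units.append(cu / (ri * rj) if normalise else cu)
    return sum(units) / len(units)


def oracle_bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    sa = {i for i, v in enumerate(a) if v > 0}
    sb = {i for i, v in enumerate(b) if v > 0}
    return 1.0 - 2.0 * len(sa & sb) / (len(sa) + len(sb))
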