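import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dietsel.io import OtuTable, SampleFrame, TaxonomyMap
from dietsel.simulate import SimConfig, simulate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_table() -> OtuTable:
    return OtuTable(
        pd.DataFrame(
            [[3, 0], [1, 2]],
            index=["s1", "s2"],
            columns=["otuA", "otuB"],
            dtype=np.int64,
        )
    )


@pytest.fixture
def taxonomy() -> TaxonomyMap:
    mk = TaxonomyMap.canonicalise
    return TaxonomyMap(
        {
            "otuA": mk(["Eukaryota", "Chlorophyta", "Chlorophyceae", "", "", "Chlorella"]),
            "otuB": mk(["Eukaryota", "Chlorophyta", "Chlorophyceae", "", "", "Scenedesmus"]),
            "otuC": mk(["Eukaryota", "Chlorophyta"]),
            "otuD": mk(["Eukaryota"]),
            "otuP": mk(["Eukaryota", "Rotifera", "Eurotatoria", "Ploima",
                        "Synchaetidae", "Polyarthra"]),
        }
    )


@pytest.fixture(scope="session")
def sim_study():
    return simulate_study(SimConfig(seed=7))


@pytest.fixture
def small_meta() -> SampleFrame:
    rows = []
    for s in (1, 2):
        for season in ("Dec", "Jun"):
            rows.append((f"P{s}_{season}", f"S{s}", season, "gut"))
            rows.append((f"A{s}_{season}", f"S{s}", season, "water"))
    df = pd.DataFrame(rows, columns=["sample_id", "site", "season", "compartment"])
    return SampleFrame(df.set_index("sample_id"))
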