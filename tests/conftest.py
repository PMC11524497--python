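import numpy as np
import pandas as pd
import pytest

import dungprint as dp
from dungprint.synthetic import default_age_control_points


@pytest.fixture(scope="session")
def dung_library() -> dp.SteroidTable:
    """Reference dung library at the published per-species sample sizes."""
    return dp.generate_dung_library(seed=0)


@pytest.fixture(scope="session")
def reference_model(dung_library):
    """Fitted zoostanol ordination + 3-cluster model on the reference library."""
    profiles = dp.zoostanol_profiles(dung_library)
    model = dp.fit_pca(profiles, n_components=4)
    clusters = dp.hcpc_cluster(model.training_scores, k=3)
    return model, clusters


@pytest.fixture(scope="session")
def age_model() -> dp.AgeModel:
    """Deterministic age model through the packaged control points."""
    return dp.build_age_model(default_age_control_points())


def make_table(values: dict[str, list[float]], species: list[str] | None = None,
               depths: list[float] | None = None) -> dp.SteroidTable:
    """Small hand-built steroid table; dung when species given, else sediment."""
    df = pd.DataFrame(values)
    df.index = pd.Index([f"s{i}" for i in range(len(df))], name="sample_id")
    if species is not None:
        meta = pd.DataFrame(
            {"source": "dung", "species": species, "depth_cm": np.nan}, index=df.index
        )
    else:
        meta = pd.DataFrame(
            {
                "source": "sediment",
                "species": np.nan,
                "depth_cm": depths if depths is not None else np.arange(len(df), dtype=float),
            },
            index=df.index,
        )
    return dp.SteroidTable(df, meta, units="ug_per_g" if species is not None else "ng_per_g")
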