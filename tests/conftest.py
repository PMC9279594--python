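import numpy as np
import pandas as pd
import pytest

from stemsen.fpkm import ExpressionMatrix


def make_matrix(series_by_feature, cultures=("C0",), status=None):
    """Build an ExpressionMatrix from {feature_id: (v0, v1, ...)} replicated per culture."""
    rows = []
    for culture in cultures:
        for fid, vals in series_by_feature.items():
            rows.append(
                {
                    "feature_id": fid,
                    "culture_id": culture,
                    "status": (status or {}).get(fid, "ok"),
                    **{f"t{i}": v for i, v in enumerate(vals)},
                }
            )
    return ExpressionMatrix(pd.DataFrame(rows))


@pytest.fixture
def toy_matrix():
    """Small single-culture matrix with a constant housekeeping gene."""
    return make_matrix(
        {
            "GAPDH": (100.0, 100.0, 100.0),
            "UP1": (10.0, 20.0, 40.0),
            "DOWN1": (40.0, 20.0, 10.0),
            "FLAT1": (10.0, 10.0, 10.0),
            "WOBBLE": (10.0, 20.0, 15.0),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
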