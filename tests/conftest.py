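import numpy as np
import pytest

import arealrisk as ar
from arealrisk.befa import BefaConfig, befa_fit


def square_feature(fid, x0, y0, side=1.0):
    return {
        "type": "Feature",
        "properties": {"id": fid},
        "geometry": {
            "type": "Polygon",
            "coordinates": [
                [
                    [x0, y0],
                    [x0 + side, y0],
                    [x0 + side, y0 + side],
                    [x0, y0 + side],
                    [x0, y0],
                ]
            ],
        },
    }


def grid_geojson(rows, cols):
    feats = [
        square_feature(f"A{r * cols + c:02d}", float(c), float(r))
        for r in range(rows)
        for c in range(cols)
    ]
    return {"type": "FeatureCollection", "features": feats}


@pytest.fixture
def path3():
    return ar.build_adjacency_from_edgelist(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture
def path5():
    ids = list("ABCDE")
    return ar.build_adjacency_from_edgelist(
        ids, list(zip(ids[:-1], ids[1:]))
    )


@pytest.fixture
def path4():
    ids = list("ABCD")
    return ar.build_adjacency_from_edgelist(ids, list(zip(ids[:-1], ids[1:])))


# -- shared expensive fixtures ------------------------------------------

RECOVERY_ALLOCATION = (1, 1, 1, 2, 2, 2)
RECOVERY_LOADINGS = (0.9, -0.9, 0.9, 0.9, -0.9, 0.9)


@pytest.fixture(scope="session")
def befa_recovery():
    """Strong two-factor covariate data (m=200) plus a fitted posterior."""
    X, scores = ar.simulate_covariates(
        200, RECOVERY_ALLOCATION, RECOVERY_LOADINGS, (0.44,) * 6, seed=7
    )
    post = befa_fit(
        ar.standardize(X),
        BefaConfig(K_max=3, n_iter=10_000, n_warmup=4_000, seed=3),
    )
    return X, scores, post


@pytest.fixture(scope="session")
def default_pipeline_run(tmp_path_factory):
    """One full pipeline run with the default (study-protocol) config."""
    out = tmp_path_factory.mktemp("pipeline_default")
    result = ar.run_pipeline({"seed": 1}, output_dir=out)
    assert result.exit_code == 0, result.manifest.get("error")
    return result
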