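import numpy as np
import pytest
from shapely.geometry import Polygon

from geosurv.geometry import DistrictMap
from geosurv.simulate import make_grid_map


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def grid9():
    """3x3 grid of 1 km square districts, all in one region."""
    return make_grid_map(9, "west", cell_km=1.0, n_cols=3)


@pytest.fixture
def grid50():
    return make_grid_map(50, "west", cell_km=20.0, n_cols=10)


def map_from_centroids(centroids, region="west", half=10.0):
    """DistrictMap with tiny squares centred on arbitrary points (test helper)."""
    centroids = np.asarray(centroids, dtype=float)
    polys = tuple(Polygon([(x - half, y - half), (x + half, y - half),
                           (x + half, y + half), (x - half, y + half)])
                  for x, y in centroids)
    ids = tuple(f"D{i}" for i in range(len(centroids)))
    return DistrictMap(ids=ids, names=ids, region=region, polygons=polys,
                       centroids=centroids)


@pytest.fixture
def centroid_map_factory():
    return map_from_centroids
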