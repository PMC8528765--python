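import numpy as np
import pytest

from otrack.instruments import Catalog, Instrument, ItemResponse, default_catalog


@pytest.fixture(scope="session")
def catalog() -> Catalog:
    return default_catalog()


def make_responses(scale, values, missing_items=()):
    """Build ItemResponse objects for a scale from a list of values.

    ``values`` align with ``scale.item_ids``; items listed in
    ``missing_items`` are marked missing.
    """
    out = []
    for item_id, v in zip(scale.item_ids, values):
        miss = item_id in missing_items or v is None
        out.append(ItemResponse(scale.instrument, item_id,
                                None if miss else v, missing=miss))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
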