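import numpy as np
import pytest

import desmoquant as dq


@pytest.fixture(scope="session")
def monolayer_clean():
    """Noise-free monolayer with a wide enriched border (ratio 3)."""
    params = dq.MonolayerParams(image_shape=(256, 256), n_cells=5,
                                enrichment_ratio=3.0, border_width_px=7,
                                rng_seed=2)
    return dq.generate_monolayer(params)


@pytest.fixture(scope="session")
def two_cell_mask():
    """Two half-plane cells split by a vertical line at column 32."""
    labels = np.ones((64, 64), dtype=np.int32)
    labels[:, 32:] = 2
    return dq.CellLabelMask(labels)
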