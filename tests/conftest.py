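import numpy as np
import pandas as pd
import pytest

from tme_evolve.synthetic import DEFAULT_CELL_TYPES, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small staged dataset shared across tests (3 ROIs/stage, 150 cells)."""
    cfg = SimConfig(n_rois_per_stage=3, cells_per_roi=150, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def flat_two_type_config():
    """Two cell types, flat composition, no interaction — a null spatial model."""
    types = ("alpha", "beta")
    comp = pd.DataFrame(0.5, index=["normal", "hyperplasia"], columns=list(types))
    markers = pd.DataFrame(1.0, index=list(types), columns=["m1", "m2"])
    return SimConfig(
        n_rois_per_stage=2,
        stages=("normal", "hyperplasia"),
        cell_types=types,
        composition_by_stage=comp,
        marker_means=markers,
        cells_per_roi=200,
        seed=7,
    )


def make_grid_cells(labels, spacing=10.0, roi_id="roi0"):
    """Deterministic square-grid cell table for hand-checkable geometry."""
    n = len(labels)
    side = int(np.ceil(np.sqrt(n)))
    xs = [(i % side) * spacing for i in range(n)]
    ys = [(i // side) * spacing for i in range(n)]
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "roi_id": roi_id,
            "x_um": xs,
            "y_um": ys,
            "cell_type": list(labels),
        }
    )
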