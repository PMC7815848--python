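import numpy as np
import pytest

import visishape as vs


@pytest.fixture(scope="session")
def shape_set():
    """The ten-shape coordinate benchmark set (20 nodes each)."""
    return vs.standard_shape_set()


@pytest.fixture(scope="session")
def shape_set_graphs(shape_set):
    return [vs.graph_from_points(ns.points, source_id=name) for name, ns in shape_set]


@pytest.fixture(scope="session")
def shape_set_classes(shape_set):
    return [ns.label for _, ns in shape_set]


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 4-cell lobed tissue phantom."""
    return vs.make_tissue_phantom(4, lobed=True, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def segmented_clean_phantom(clean_phantom):
    tissue = vs.segment_image(clean_phantom.image, resolution=clean_phantom.resolution)
    return clean_phantom, tissue


@pytest.fixture(scope="session")
def lobed_cell_k5():
    return vs.make_lobed_cell(5, 40.0, 0.3, resolution=1.0)
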