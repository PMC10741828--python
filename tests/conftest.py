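import numpy as np
import pytest

from dynlat import RoiAtlas, SubjectTimeSeries, WindowSpec, generate_atlas


@pytest.fixture(scope="session")
def atlas90():
    return generate_atlas(90)


@pytest.fixture(scope="session")
def atlas8():
    """Tiny atlas: 8 ROIs, 2 subnetworks per hemisphere."""
    return generate_atlas(8, subnetworks=("A", "B"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def wspec():
    return WindowSpec(50, 1)


@pytest.fixture
def random_ts(atlas8, rng):
    """Unstructured random series on the tiny atlas."""
    return SubjectTimeSeries(
        values=rng.standard_normal((120, atlas8.n_rois)),
        tr_seconds=2.0,
        roi_ids=atlas8.roi_ids,
        subject_id="rand01",
    )


def mirrored_atlas(atlas: RoiAtlas) -> RoiAtlas:
    return atlas.relabeled_swapped()
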