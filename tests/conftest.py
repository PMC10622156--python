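import numpy as np
import pytest

import seagrassmap as sm


@pytest.fixture(scope="session")
def truth_field():
    """Patchy truth field with a northern land strip (the workhorse fixture)."""
    return sm.generate_truth_field(
        128, 128, 2.0, patch_scale=20.0, target_cover=0.4,
        land_band_width=8, seed=7,
    )


@pytest.fixture(scope="session")
def rendered(truth_field):
    scene, rois = sm.render_scene(truth_field, sm.default_spectra(0.0010), seed=7)
    return scene, rois


@pytest.fixture()
def uniform_truth():
    """Factory for fields with spatially uniform cover (no land)."""

    def make(cover_value: float, n: int = 32) -> sm.TruthField:
        grid = sm.GridSpec(width=n, height=n, cell_size=2.0, origin_y=n * 2.0)
        return sm.TruthField(
            cover=np.full((n, n), cover_value),
            grid=grid,
            land_mask=np.zeros((n, n), dtype=bool),
            seed=0,
        )

    return make


@pytest.fixture()
def general_classmap():
    """Factory for hand-laid-out collapsed class maps."""

    def make(labels: np.ndarray) -> sm.ClassMap:
        labels = np.asarray(labels, dtype=np.int16)
        h, w = labels.shape
        grid = sm.GridSpec(width=w, height=h, cell_size=1.0, origin_y=float(h))
        return sm.ClassMap(labels=labels, grid=grid, catalog=sm.GENERAL_CLASSES)

    return make
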