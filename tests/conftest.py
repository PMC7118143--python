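import numpy as np
import pytest

from shapepath import synthgen as sg


@pytest.fixture(scope="session")
def hc_cells():
    """A fixed healthy-control-like simulated field (12 cells, 49 frames)."""
    scen = sg.hc_like(n_cells=12, rng_seed=3)
    return scen, sg.simulate_tracks(scen)


@pytest.fixture(scope="session")
def hc_rendered(hc_cells):
    """Rendered frame pairs for the fixed field, default imaging noise."""
    _, cells = hc_cells
    return cells, sg.render_frames(cells, (760, 1088), rng_seed=5)


def single_cell(major=12.0, minor=8.0, orientation=30.0, center=(24.0, 24.0), n_frames=2):
    """A stationary ground-truth cell for rendering fixtures."""
    return sg.GroundTruthCell(
        cell_id=0,
        xy=np.array([list(center)] * n_frames, dtype=float),
        major_px=np.full(n_frames, float(major)),
        minor_px=np.full(n_frames, float(minor)),
        orientation_deg=np.full(n_frames, float(orientation)),
        heading_deg=np.zeros(n_frames),
    )
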