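import numpy as np
import pytest

import polycontact as pc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calf_model():
    return pc.load_model("calf")


@pytest.fixture
def square_model():
    """Unit square centered on the tag, forward +x: rotation-friendly template."""
    return pc.PlanarModel(
        reference_point=np.array([0.0, 0.0]),
        forward_direction_deg=0.0,
        parts={
            "body": np.array([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]])
        },
    )


@pytest.fixture
def simple_track():
    """One individual walking east 1 m/s on a 1-s grid."""
    return pc.make_fixes([("a", t, float(t), 0.0) for t in range(10)])


def run_scenario(name):
    """Drive a scripted scenario through the full pipeline; return bouts."""
    cfg = pc.scripted_contact_scenario(name)
    true_fixes, noisy_fixes, flags = pc.simulate_tracks(cfg)
    grid = pc.GridSpec(
        interval=cfg.interval,
        start=cfg.start_time,
        end=cfg.start_time + cfg.interval * cfg.n_timesteps,
    )
    model = pc.scenario_model(name)
    spth = pc.SCENARIO_SPTH[name]
    if model is None:
        dist = pc.pairwise_distances(true_fixes, [("point", "point")])
        return pc.extract_bouts(pc.detect_contacts(dist, spth), grid), grid
    states = pc.estimate_heading(true_fixes, 0.0)
    series = pc.derive_polygons(true_fixes, states, model)
    if name == "visual_crossing":
        net = pc.build_visual_network(series, true_fixes, spth, grid)
        return net.bouts, grid
    dist = pc.pairwise_distances(series, [("head", "head"), ("head", "posterior")])
    return pc.extract_bouts(pc.detect_contacts(dist, spth), grid), grid
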