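import numpy as np
import pytest

import limbshape as ls
from limbshape.simulate import fixture_tree
from limbshape.trees import write_newick


@pytest.fixture(scope="session")
def template():
    cfg, scheme = ls.make_template_limb()
    return cfg, scheme


@pytest.fixture(scope="session")
def calibrated_fixture_tree():
    topo, ages, clades = fixture_tree()
    tree = ls.time_calibrate(topo, ages, mbl=1.0)
    return tree


@pytest.fixture(scope="session")
def fixture_newick(calibrated_fixture_tree):
    return write_newick(calibrated_fixture_tree)


def random_configs(n, template_cfg, scale=0.01, seed=0, rigid=False):
    """Small random deformations of the template, optionally with random
    rigid motions applied so superimposition has work to do."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        pts = template_cfg.points + scale * rng.standard_normal(
            template_cfg.points.shape)
        if rigid:
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] = -q[:, 0]
            pts = pts @ q.T + rng.normal(scale=5.0, size=3)
        out.append(template_cfg.with_points(pts, specimen_id=f"s{i}",
                                            taxon_id=f"t{i}"))
    return out


@pytest.fixture()
def small_configs(template):
    cfg, _ = template
    return random_configs(5, cfg, seed=42, rigid=True)
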