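import numpy as np
import pytest

from graymorph.swc import CellReconstruction, SwcNode
from graymorph.synthetic import SyntheticCellSpec, generate_cell


@pytest.fixture(scope="session")
def default_cell():
    """One generator cell with default parameters and its ground truth."""
    return generate_cell(SyntheticCellSpec(), seed=1)


@pytest.fixture(scope="session")
def plain_cell():
    """A cell with no undulation/beading: exact per-branch recovery."""
    spec = SyntheticCellSpec(undulation_amplitude=0.0, beading_amplitude=0.0)
    return generate_cell(spec, seed=5)


def make_cell(rows):
    """Build a CellReconstruction from (id, type, x, y, z, r, parent) tuples."""
    nodes = {
        r[0]: SwcNode(r[0], r[1], float(r[2]), float(r[3]), float(r[4]),
                      float(r[5]), r[6])
        for r in rows
    }
    root = next(i for i, n in nodes.items() if n.parent_id is None)
    return CellReconstruction(nodes, root, {"node_order": [r[0] for r in rows]})


@pytest.fixture
def y_cell():
    """Soma + trunk + symmetric Y bifurcation (daughters at ±45° in-plane)."""
    s = np.sin(np.pi / 4)
    rows = [(1, 1, 0, 0, 0, 1.0, None), (2, 3, 5, 0, 0, 0.5, 1),
            (3, 3, 10, 0, 0, 0.5, 2)]
    nid = 4
    for sign in (+1, -1):
        parent = 3
        for k in range(1, 6):
            rows.append(
                (nid, 3, 10 + 2 * k * s, sign * 2 * k * s, 0, 0.5, parent)
            )
            parent = nid
            nid += 1
    return make_cell(rows)
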