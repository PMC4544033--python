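import math

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import line as draw_line

from vimtrace.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """A fast 256-px field with a handful of cells."""
    return SimulationConfig(field_shape=(256, 256), n_nuclei=4,
                            fibers_per_cell=3.0, seed=0)


def random_tree_mask(seed, shape=(220, 220)):
    """Random planar tree rendered as 1-px digital lines.

    Every internal node has degree >= 3 (a degree-2 node is not a
    branchpoint of a skeleton, so it would not delimit segments), arm
    angles are separated, and every arm keeps > 2 px clearance from all
    previously drawn pixels, so the rendered mask's branchpoint
    decomposition has exactly one segment per tree edge.

    Returns (mask, n_edges).
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape

    for _attempt in range(300):
        occ = np.zeros(shape, bool)
        root = (rows // 2 + int(rng.integers(-15, 15)),
                cols // 2 + int(rng.integers(-15, 15)))
        n_edges = 0

        def try_attach(node, existing_angles, n_children):
            nonlocal n_edges
            added = []
            angles = list(existing_angles)
            for _ in range(n_children):
                for _try in range(80):
                    ang = rng.uniform(0, 2 * math.pi)
                    if any(abs((ang - a + math.pi) % (2 * math.pi) - math.pi) < 0.85
                           for a in angles):
                        continue
                    length = rng.uniform(14, 26)
                    r2 = int(round(node[0] + length * math.sin(ang)))
                    c2 = int(round(node[1] + length * math.cos(ang)))
                    if not (4 <= r2 < rows - 4 and 4 <= c2 < cols - 4):
                        continue
                    rr, cc = draw_line(node[0], node[1], r2, c2)
                    if occ.any():
                        dist = ndi.distance_transform_edt(~occ)
                        if np.any(dist[rr[4:], cc[4:]] <= 2.5):
                            continue
                    occ[rr, cc] = True
                    angles.append(ang)
                    added.append(((r2, c2), (ang + math.pi) % (2 * math.pi)))
                    n_edges += 1
                    break
                else:
                    return None
            return added

        kids = try_attach(root, [], 3)
        if kids is None:
            continue
        leaves = list(kids)
        failed = False
        for _ in range(int(rng.integers(0, 3))):
            if not leaves:
                break
            node, in_ang = leaves.pop(int(rng.integers(0, len(leaves))))
            kids = try_attach(node, [in_ang], int(rng.integers(2, 4)))
            if kids is None:
                failed = True
                break
            leaves.extend(kids)
        if not failed:
            return occ, n_edges
    raise RuntimeError("tree generation failed")
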