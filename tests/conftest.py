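import numpy as np
import pytest

from ossimetry import phantom as ph


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive; see module tests)
# ---------------------------------------------------------------------------

def face_count_area_vox(mask: np.ndarray) -> float:
    """Exposed voxel faces, in voxel^2 (counts every bone/background face)."""
    mask = np.asarray(mask, dtype=np.int8)
    area = 0
    for ax in range(3):
        area += np.abs(np.diff(mask, axis=ax)).sum()
        first = [slice(None)] * 3
        last = [slice(None)] * 3
        first[ax] = 0
        last[ax] = -1
        area += mask[tuple(first)].sum() + mask[tuple(last)].sum()
    return float(area)


def flood_fill_components(binary: np.ndarray) -> list[int]:
    """6-connected component sizes by explicit BFS flood fill."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    sizes = []
    coords = np.argwhere(binary)
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for start in map(tuple, coords):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        n = 0
        while stack:
            z, y, x = stack.pop()
            n += 1
            for dz, dy, dx in steps:
                q = (z + dz, y + dy, x + dx)
                if (0 <= q[0] < binary.shape[0] and 0 <= q[1] < binary.shape[1]
                        and 0 <= q[2] < binary.shape[2]
                        and binary[q] and not seen[q]):
                    seen[q] = True
                    stack.append(q)
        sizes.append(n)
    return sorted(sizes, reverse=True)


def sphere_mask(n: int, r: float) -> np.ndarray:
    c = (n - 1) / 2.0
    z, y, x = np.ogrid[:n, :n, :n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= r * r


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def sphere50():
    """Solid sphere, r = 50 um at 2 um voxels (r = 25 voxels)."""
    return ph.make_ossicle("sphere", {"radius_um": 50.0}, 2.0, seed=0)


@pytest.fixture(scope="session")
def hollow_sphere80():
    """Sphere r = 80 um with a 25% sealed cavity, for erosion tests."""
    return ph.make_ossicle("sphere", {"radius_um": 80.0}, 2.0, seed=0,
                           cavity_fraction=0.25)


@pytest.fixture(scope="session")
def eroded_pair(hollow_sphere80):
    spec = ph.ErosionSpec(target_bvtv_drop=0.11, removal_prob=0.2,
                          max_iters=200, seed=1)
    return hollow_sphere80, ph.erode_phantom(hollow_sphere80, spec)
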