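import numpy as np
import pytest

from lesiontrack.synthetic import (
    DSPConfig,
    MyeloidSpec,
    PhantomConfig,
    generate_dsp_counts,
    generate_voxel_phantom,
)
from lesiontrack.types import MYELOID_STATES


@pytest.fixture(scope="session")
def state_phantoms():
    """One noiseless phantom per myeloid organizational state."""
    out = {}
    for st in MYELOID_STATES:
        cfg = PhantomConfig(myeloid_spec=(MyeloidSpec.for_state(st),), seed=7)
        channels, truth = generate_voxel_phantom(cfg)
        out[st] = (cfg, channels, truth)
    return out


@pytest.fixture(scope="session")
def dsp_default():
    cfg = DSPConfig(seed=5)
    counts, annotation, truth = generate_dsp_counts(cfg)
    return cfg, counts, annotation, truth


def flood_fill_components(mask: np.ndarray) -> list[int]:
    """Brute-force 26-connected (3D) / 8-connected (2D) component sizes.

    Independent BFS oracle for the labelling used by the segmenters.
    """
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros(mask.shape, dtype=bool)
    offsets = [
        idx
        for idx in np.ndindex(*(3,) * mask.ndim)
        if any(i != 1 for i in idx)
    ]
    offsets = [tuple(i - 1 for i in idx) for idx in offsets]
    sizes = []
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        stack = [start]
        visited[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for off in offsets:
                q = tuple(a + b for a, b in zip(p, off))
                if all(0 <= c < s for c, s in zip(q, mask.shape)) and mask[q] and not visited[q]:
                    visited[q] = True
                    stack.append(q)
        sizes.append(size)
    return sorted(sizes)
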