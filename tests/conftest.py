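import numpy as np
import pytest

from adhesioquant.synthetic import SyntheticImageSpec


@pytest.fixture
def basic_spec():
    """A well-separated, high-contrast 5-spot cell image recipe."""
    return SyntheticImageSpec(seed=42)


@pytest.fixture
def quiet_spec():
    """Noise-free recipe for exact-value checks."""
    return SyntheticImageSpec(n_punctae=0, background_sd=0.0, seed=0)


def brute_force_spot_count(image, in_cell_level, amplitude):
    """Independent spot counter: classify pixels above half the spot
    amplitude over the in-cell level, then flood-fill (8-connected) with a
    hand-rolled BFS.  Used as the detection oracle on synthetic images."""
    px = image.pixels.astype(float)
    hot = px > in_cell_level + amplitude / 2.0
    seen = np.zeros_like(hot, dtype=bool)
    n = 0
    rows, cols = np.nonzero(hot)
    for r0, c0 in zip(rows, cols):
        if seen[r0, c0]:
            continue
        n += 1
        stack = [(r0, c0)]
        seen[r0, c0] = True
        while stack:
            r, c = stack.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < hot.shape[0] and 0 <= cc < hot.shape[1]
                            and hot[rr, cc] and not seen[rr, cc]):
                        seen[rr, cc] = True
                        stack.append((rr, cc))
    return n
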