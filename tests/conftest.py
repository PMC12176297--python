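import numpy as np
import pytest

from xiquant import simulate


@pytest.fixture
def small_image_params():
    """A small, fast stack: two mid-sized nuclei in a 32x96x96 field."""
    return simulate.ImageSimParams(
        stack_shape=(32, 96, 96),
        n_nuclei=2,
        nucleus_radii=(1.2, 1.6),
    )


def match_truth_to_segmented(truth, summaries, nuclei, max_dist_um=2.0):
    """Pair ground-truth nuclei with segmented ones by centroid proximity."""
    pairs = []
    for nt in truth.nuclei:
        if nt.touches_edge:
            continue
        best, best_d = None, np.inf
        for s, n in zip(summaries, nuclei):
            d = np.linalg.norm(np.array(n.centroid_um) - np.array(nt.centroid_um))
            if d < best_d:
                best_d, best = d, (nt, s, n)
        if best is not None and best_d < max_dist_um:
            pairs.append(best)
    return pairs
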