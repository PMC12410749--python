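import numpy as np
import pytest

from allinsam.synthdata import render_patch
from allinsam.types import ClassAnnotationSet


@pytest.fixture
def patch_clean():
    """Noiseless two-class patch with its instance ground truth."""
    return render_patch(128, 128, [5, 5], 0.0, seed=11)


@pytest.fixture
def patch_noisy():
    """Two-class patch at the default imaging noise level."""
    return render_patch(128, 128, [6, 6], 0.05, seed=3)


def truth_annotations(inst, n_classes=2):
    masks = {c: inst.class_mask(c).astype(np.uint8) for c in range(1, n_classes + 1)}
    return ClassAnnotationSet(masks, "truth")
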