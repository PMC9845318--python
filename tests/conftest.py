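import numpy as np
import pytest

from glottalgap import BACKGROUND, GLOTTIS, LEFT_FOLD, RIGHT_FOLD, LabeledFrame


def make_frame(width=256, height=256, frame_index=0):
    """All-background frame of the given size."""
    return LabeledFrame(
        np.zeros((height, width), dtype=np.uint8), frame_index=frame_index
    )


def paint_rect(frame, label, x0, x1, y0, y1):
    """Label every pixel whose cell lies in [x0, x1) x [y0, y1) (lower-left origin)."""
    frame.labels[int(y0) : int(y1), int(x0) : int(x1)] = label
    return frame


def vertical_larynx_frame(
    width=256,
    height=256,
    fold_y=(20, 200),
    glottis_y=(50, 150),
    glottis_halfwidth=5,
    fold_halfwidth=40,
    cx=None,
):
    """Axis-aligned test larynx: two fold bands with a rectangular glottis slit."""
    cx = width // 2 if cx is None else cx
    fr = make_frame(width, height)
    paint_rect(fr, LEFT_FOLD, cx - fold_halfwidth, cx, *fold_y)
    paint_rect(fr, RIGHT_FOLD, cx, cx + fold_halfwidth, *fold_y)
    if glottis_halfwidth > 0:
        paint_rect(
            fr, GLOTTIS, cx - glottis_halfwidth, cx + glottis_halfwidth, *glottis_y
        )
    return fr


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
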