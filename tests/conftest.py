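import pytest

from polypval import Box, Dataset
from polypval.synth import generate_study

from _utils import image, mask_from_strings, pred, ref, small_study_spec


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Two images, three references, three predictions — hand-checkable.

    img1 holds a 4x4 square polyp and a 2x10 flat strip; img2 holds a U-shaped
    (non-convex) polyp. Predictions: an exact box on the square (conf .9), a
    stray box (conf .8), and a decent box on the U (conf .7).
    """
    images = [image("img1", 32, 32, "c1", "p1"),
              image("img2", 32, 32, "c2", "p2")]
    square = mask_from_strings("1111", "1111", "1111", "1111", x0=4, y0=4)
    strip = mask_from_strings("1111111111", "1111111111", x0=10, y0=20)
    u_shape = mask_from_strings("101", "101", "111", x0=12, y0=12)
    references = [
        ref("r_square", "img1", square, "protruded"),
        ref("r_strip", "img1", strip, "flat"),
        ref("r_u", "img2", u_shape, "flat"),
    ]
    predictions = [
        pred("p_square", "img1", Box(4, 4, 8, 8), 0.9),
        pred("p_stray", "img1", Box(24, 0, 30, 6), 0.8),
        pred("p_u", "img2", Box(12, 12, 15, 15), 0.7),
    ]
    return Dataset(images=images, references=references, predictions=predictions)


@pytest.fixture(scope="session")
def small_study():
    """One seeded small synthetic study shared by read-only tests."""
    return generate_study(small_study_spec(seed=123))
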