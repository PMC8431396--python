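import numpy as np
import pytest

from pdl1score.stain import ODImage
from pdl1score.synthetic import SlideRecipe, generate_slide


def small_recipe(seed: int = 0, **kwargs) -> SlideRecipe:
    """A 3x3-tile slide: fast enough for unit and CLI tests."""
    defaults = dict(width_um=768.0, height_um=768.0, n_tumor_tiles=4,
                    target_tps=30.0, target_ics=2.0, seed=seed)
    defaults.update(kwargs)
    return SlideRecipe(**defaults)


@pytest.fixture(scope="session")
def small_slide():
    """One rendered small slide plus its ground truth (shared, read-only)."""
    image, truth = generate_slide(small_recipe(seed=5))
    return image, truth


@pytest.fixture(scope="session")
def small_slide_od(small_slide):
    from pdl1score.stain import rgb_image_to_od
    image, truth = small_slide
    return rgb_image_to_od(image), truth


def uniform_od_image(shape=(160, 160), value_h=0.5, value_d=0.0, mpp=0.5) -> ODImage:
    return ODImage(od_h=np.full(shape, value_h), od_d=np.full(shape, value_d),
                   mpp=mpp, background_rgb=(255.0, 255.0, 255.0))


@pytest.fixture(scope="session")
def tiny_models():
    """Small tissue + cell models trained on synthetic data (shared)."""
    from pdl1score.pipeline import train_models_from_synthetic
    return train_models_from_synthetic(
        seed=123, n_tiles_per_class=12,
        training_recipes=[small_recipe(seed=1001, target_tps=40.0)])
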