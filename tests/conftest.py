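"""Shared fixtures: synthetic datasets and the session-level pipeline runs.

The end-to-end runs are expensive relative to unit tests, so the easy-run
report and the hard-fixture ablation grid are computed once per session and
shared by the integration and acceptance tests.
"""

import warnings

import pytest
from hypothesis import settings

import taxofeat as tf

settings.register_profile("stable", deadline=None, derandomize=True)
settings.load_profile("stable")

# study conditions for the synthetic datasets (seeds pinned for reproducibility)
EASY_SPEC = tf.FixtureSpec(
    n_categories=4,
    images_per_category=12,
    images_per_specimen=4,
    difficulty="easy",
    seed=0,
)
HARD_SPEC = tf.FixtureSpec(
    n_categories=4,
    images_per_category=20,
    images_per_specimen=4,
    difficulty="hard",
    seed=0,
)
EASY_CONFIG = tf.PipelineConfig(image_size=128, scheme="global", fusion=("c4",))
HARD_BASE_CONFIG = tf.PipelineConfig(image_size=128, scheme="global")

ABLATION_VARIANTS = [
    {"pooling_mode": "average", "fusion": ("c5",)},
    {"pooling_mode": "max", "fusion": ("c5",)},
    {"pooling_mode": "average", "fusion": ("c3",)},
    {"pooling_mode": "average", "fusion": ("c4",)},
    {"pooling_mode": "average", "fusion": ("c3", "c4", "c5")},
]


@pytest.fixture(scope="session")
def easy_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("easy_fixtures")
    return tf.generate_image_dataset(EASY_SPEC, out)


@pytest.fixture(scope="session")
def hard_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("hard_fixtures")
    return tf.generate_image_dataset(HARD_SPEC, out)


@pytest.fixture(scope="session")
def easy_run(easy_manifest):
    """10-fold CV of c4 global-average + signed-sqrt + linear SVM on easy fixtures."""
    report, plan = tf.evaluate(easy_manifest, EASY_CONFIG)
    return report, plan


@pytest.fixture(scope="session")
def hard_ablation(hard_manifest):
    """Pooling-mode and fusion ablation grid on the hard fixtures."""
    with warnings.catch_warnings():
        # near-inseparable variants may hit the solver's iteration cap; the
        # fitted model is still deterministic and usable
        warnings.simplefilter("ignore")
        return tf.run_grid(hard_manifest, HARD_BASE_CONFIG, ABLATION_VARIANTS)
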