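import numpy as np
import pytest

import survmixer as sm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_collection():
    """Six pathways of 2-4 genes; fits a 2px-patch, 3x3-grid layout."""
    return sm.PathwayCollection.from_lists(
        [
            ("pwA", ["g1", "g2", "g3"]),
            ("pwB", ["g4", "g5"]),
            ("pwC", ["g2", "g6", "g7", "g8"]),  # g2 shared with pwA
            ("pwD", ["g9"]),
            ("pwE", ["g10", "g11", "g12"]),
            ("pwF", ["g13", "g14"]),
        ]
    )


@pytest.fixture
def small_layout(small_collection):
    return sm.build_layout(small_collection, patch_side=2, grid_side=3)


@pytest.fixture
def small_matrix(small_collection, rng):
    genes = sm.union_genes(small_collection) + ["unused1", "unused2"]
    samples = [f"s{i}" for i in range(10)]
    values = rng.uniform(size=(len(samples), len(genes)))
    return sm.ExpressionMatrix(samples, genes, values)


@pytest.fixture(scope="session")
def tiny_trained():
    """A quickly trained model on a tiny separable synthetic cohort.

    Labels come directly from the latent effect-pathway activity (no
    survival-time noise), so the task is genuinely learnable at this size.
    Shared session-wide; treat as read-only.
    """
    spec = sm.SyntheticSpec(
        n_samples=80, n_pathways=7, size_min=2, size_max=4,
        n_background_genes=5, effect_pathways=(0,), noise_sd=0.2, seed=7,
    )
    coll = sm.generate_collection(spec)
    cohort = sm.generate_cohort(spec, coll)
    images = sm.build_images(cohort.expression, coll, patch_side=2, grid_side=3)
    y = (cohort.activities[:, 0] > 0).astype(int)
    cfg = sm.ModelConfig(
        channels=8, n_blocks=2, patch_kernel=2, patch_stride=2,
        epochs=12, learning_rate=3e-3, seed=0,
    )
    model, history = sm.train_model(images.images, y, cfg, images.layout)
    return {
        "spec": spec, "collection": coll, "cohort": cohort, "images": images,
        "labels": y, "cfg": cfg, "model": model, "history": history,
    }
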