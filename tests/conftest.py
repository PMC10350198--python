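import numpy as np
import pytest

from lesionsubtype.cnn import (CNNConfig, TrainingSchedule, build_cnn,
                               train_cnn, predict_and_latent)
from lesionsubtype.morphomap import preprocess_cohort
from lesionsubtype.partitions import categorize, split_train_validation
from lesionsubtype.synthetic import (CohortSpec, build_anatomy_template,
                                     generate_cohort)


@pytest.fixture(scope="session")
def small_template():
    return build_anatomy_template((24, 28, 24), voxel_size_mm=2.0, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """24 subjects on a small grid: cheap input for plumbing tests."""
    spec = CohortSpec(n_subjects=24, grid_shape=(24, 28, 24), n_subtypes=2,
                      seed=5)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def separable_cohort():
    """Noise-free cohort: severity is a deterministic function of lesion
    volume and atrophy burden, so classes are learnable."""
    spec = CohortSpec(n_subjects=60, noise_sd=0.0, seed=11)
    cohort = generate_cohort(spec)
    X, box, meta = preprocess_cohort(
        [s.tissue_masks for s in cohort.subjects],
        [s.lesion_mask for s in cohort.subjects],
        voxel_size_mm=2.0, factor=4)
    cats, y = categorize(cohort.ground_truth["wab_aq"].to_numpy())
    return {"cohort": cohort, "X": X, "box": box, "cats": cats, "y": y}


@pytest.fixture(scope="session")
def trained_fixture_cnn(separable_cohort):
    """One CNN trained on the separable cohort's stratified 70/30 split."""
    X, y, cats = (separable_cohort[k] for k in ("X", "y", "cats"))
    tr, va = split_train_validation(np.arange(len(y)), cats, 0.3, seed=2)
    model = build_cnn(CNNConfig(complexity_level=1, input_shape=X.shape[1:]),
                      seed=3)
    trained = train_cnn(model, X[tr], y[tr], X[va], y[va],
                        TrainingSchedule(total_epochs=40, early_stop_patience=40),
                        seed=3, base_rate=1e-2)
    proba, latent = predict_and_latent(trained, X)
    return {"trained": trained, "proba": proba, "latent": latent,
            "train_idx": tr, "val_idx": va}
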