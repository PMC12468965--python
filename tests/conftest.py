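import numpy as np
import pytest

from pleuradx import cohort as cohort_mod
from pleuradx.rendering import RenderedCandidateSet, target_encoding


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small separable phantom cohort shared across tests (read-only)."""
    cfg = cohort_mod.CohortConfig(n_patients_per_class=8, slices_mean=3,
                                  image_size=64, class_effect=6, seed=7)
    images, records = cohort_mod.generate_cohort(cfg)
    return cfg, images, records


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_candidates(z_rows, labels, corrupt=None, seed=0):
    """Candidate sets whose three images are target encodings of z, with
    optional per-kind corruption applied by ``corrupt(kind, img, i)``."""
    out = []
    for i, (z, lab) in enumerate(zip(z_rows, labels)):
        base = target_encoding(np.asarray(z))
        images = {}
        for kind in ("decoder", "gan", "nerv"):
            img = base.copy()
            if corrupt is not None:
                img = corrupt(kind, img, i)
            images[kind] = img
        out.append(RenderedCandidateSet(sample_id=f"s{i}", label=lab,
                                        images=images))
    return out
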