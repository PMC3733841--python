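"""Shared fixtures: phantom specs, template, and the simulated study cohort.

The expensive objects (the 31-subject reference cohort fitted from noisy
acquisitions, and the held-out subjects) are session-scoped so the deviation,
lesion and atlas tests share one simulation.
"""

import numpy as np
import pytest

from qmap import (
    CohortSpec,
    PhantomSpec,
    build_reference,
    default_template,
    fit_volume,
    make_cohort,
)

# study conditions: reference group of 31, acquisition noise ~2% of white
# matter signal, anatomy fixed in template space (the null-calibration and
# lesion analyses test the statistics, not the registration, which has its
# own recovery tests)
REF_SEED = 11
HOLDOUT_SEED = 99
NOISE_SIGMA = 1.4


def aligned_cohort_spec(n_subjects: int, master_seed: int, **kwargs) -> CohortSpec:
    return CohortSpec(
        n_subjects=n_subjects,
        jitter_rotation_deg=0.0,
        jitter_translation_mm=0.0,
        jitter_log_zoom=0.0,
        jitter_shear=0.0,
        noise_sigma=NOISE_SIGMA,
        master_seed=master_seed,
        **kwargs,
    )


@pytest.fixture(scope="session")
def canonical_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-resolution phantom for tests that iterate many times."""
    return PhantomSpec(shape=(40, 50, 40), voxel_size_mm=2.6, head_radii_mm=(42.0, 53.0, 37.0))


@pytest.fixture(scope="session")
def template(canonical_spec):
    return default_template(canonical_spec)


def fit_and_release(subjects):
    """Fit each subject's series, dropping the raw data to bound memory."""
    fits = []
    for s in subjects:
        fits.append(fit_volume(s.series, mask=s.labels.labels > 0))
        s.series = None
    return fits


@pytest.fixture(scope="session")
def reference_cohort(canonical_spec):
    """31 phantom subjects in template space, fitted from noisy acquisitions."""
    _, subjects = make_cohort(canonical_spec, aligned_cohort_spec(31, REF_SEED))
    fits = fit_and_release(subjects)
    return subjects, fits


@pytest.fixture(scope="session")
def reference_atlas(reference_cohort):
    _, fits = reference_cohort
    return build_reference(fits)


@pytest.fixture(scope="session")
def heldout_fits(canonical_spec):
    """Held-out subjects drawn from the same population as the reference."""
    _, subjects = make_cohort(canonical_spec, aligned_cohort_spec(30, HOLDOUT_SEED))
    fits = fit_and_release(subjects)
    return subjects, fits


@pytest.fixture(scope="session")
def parenchyma_interior(reference_cohort):
    """Eroded parenchyma mask (GM + WM + deep nuclei away from boundaries)."""
    from scipy import ndimage

    subjects, _ = reference_cohort
    paren = np.isin(subjects[0].labels.labels, (2, 3, 5, 6, 7))
    return ndimage.binary_erosion(paren, iterations=1)
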