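import pytest

import vatslice as v
from vatslice.synthetic import default_profile_models


@pytest.fixture(scope="session")
def small_cohort():
    """600 participants drawn from the default calibration."""
    return v.generate_participants(600, seed=101)


@pytest.fixture(scope="session")
def noise_free_models():
    return default_profile_models(noise_sd=0.0, shape_jitter=0.0)


@pytest.fixture(scope="session")
def one_geometry(small_cohort):
    return v.generate_geometry(small_cohort.iloc[0], seed=7)


@pytest.fixture(scope="session")
def standardized_cohort(small_cohort, noise_free_models):
    """Noise-free standardized profile matrix with group assignments for a
    moderate cohort (session-scoped: several tests share it)."""
    from vatslice import cohort as ca

    profiles, geometries = v.generate_cohort_profiles(
        small_cohort, seed=102, models=noise_free_models)
    matrix = v.standardize_cohort(profiles, geometries)
    retained, _ = ca.apply_exclusions(small_cohort)
    groups = ca.assign_groups_frame(retained)
    groups = groups.loc[groups.index.intersection(matrix.index)]
    return matrix.loc[groups.index], groups


def make_landmarks(fh=15.0, l5=144.0, gap=38.0):
    """Simple valid landmark set: vertebral centers ``gap`` mm apart."""
    vertebrae = ["L5", "L4", "L3", "L2", "L1", "Th12", "Th11", "Th10"]
    pos = {"FH": fh}
    for i, lab in enumerate(vertebrae):
        pos[lab] = l5 + i * gap
    discs = ["L5/4", "L4/3", "L3/2", "L2/1", "L1/Th12", "Th12/11", "Th11/10"]
    for i, lab in enumerate(discs):
        pos[lab] = 0.5 * (pos[vertebrae[i]] + pos[vertebrae[i + 1]])
    return v.SpineLandmarks(pos)


@pytest.fixture
def simple_landmarks():
    return make_landmarks()
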