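import math
import warnings

import numpy as np
import pytest

from epiclonal import CohortSpec, generate_blood_reference, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def spec() -> CohortSpec:
    """Small cohort for unit tests: 3 patients, 2000 probes, 2 subclones."""
    return CohortSpec(n_patients=3, n_probes=2000, seed=11)


@pytest.fixture(scope="session")
def cohort(spec):
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def blood(spec):
    return generate_blood_reference(12, spec)


def analytic_gaps(spec: CohortSpec) -> tuple[float, float]:
    """Aggressiveness gaps scaled to a synthetic cohort's distance geometry.

    The published 10/20-unit gaps refer to ~396k-probe distances. For a
    synthetic cohort the expected excess distance (dist2) of a focus from a
    different subclone than the metastasis is derived from the planted
    parameters: with m shifted probes per subclone (disjoint sets) and
    magnitude s over P probes with noise sd sigma,

        E[d1^2] ~ 2 P sigma^2
        E[d2^2] ~ 2 P sigma^2 + 2 m s^2

    The gaps are placed at one and two thirds of the expected dist2 so that
    same-subclone foci (dist2 ~ 0) fall in the aggressive band and
    different-subclone foci beyond the undecided band.
    """
    P = spec.n_probes
    m = round(spec.shift_probe_fraction * P)
    d1 = math.sqrt(2 * P * spec.noise_sd**2)
    d2 = math.sqrt(2 * P * spec.noise_sd**2 + 2 * m * spec.shift_magnitude**2)
    expected_dist2 = d2 - d1
    return expected_dist2 / 3.0, 2.0 * expected_dist2 / 3.0


def tumor_samples(sheet) -> list[str]:
    return list(sheet.loc[sheet["tissue_type"].isin(["T", "PL"]), "sample_id"])
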