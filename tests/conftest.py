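import numpy as np
import pandas as pd
import pytest

from cutrel import (
    CohortSpec,
    EstimationSettings,
    ExamGeneratorConfig,
    ResponseMatrix,
    fit_pcm,
    generate_exam_spec,
    simulate_responses,
    wle_theta,
)
from cutrel.synthetic import MTF, TYPE_A, ItemSpec


def make_matrix(values, kinds=None, item_ids=None):
    """Response matrix from a plain nested list."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if kinds is None:
        kinds = [MTF if np.any(values[:, j] == 0.5) else TYPE_A for j in range(k)]
    if item_ids is None:
        item_ids = [f"i{j + 1}" for j in range(k)]
    frame = pd.DataFrame(
        values, index=[f"p{v + 1}" for v in range(n)], columns=item_ids
    )
    return ResponseMatrix(frame, list(kinds))


def dichotomous_items(difficulties):
    return tuple(
        ItemSpec(f"i{j + 1}", TYPE_A, 5, (float(b),))
        for j, b in enumerate(difficulties)
    )


@pytest.fixture(scope="session")
def mixed_exam():
    """Mid-sized mixed-format exam used by several estimation tests."""
    config = ExamGeneratorConfig(n_items=30, mtf_fraction=0.3)
    return generate_exam_spec(config, seed=11)


@pytest.fixture(scope="session")
def mixed_fit(mixed_exam):
    """Responses, fit and WLE abilities for the mid-sized exam."""
    responses = simulate_responses(mixed_exam, CohortSpec(n_examinees=400), seed=12)
    fit = fit_pcm(responses)
    estimates = wle_theta(fit, responses)
    return responses, fit, estimates


@pytest.fixture(scope="session")
def quick_settings():
    return EstimationSettings(tol=1e-5, max_iter=500)
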