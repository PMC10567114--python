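"""Shared fixtures: one small simulated cohort reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from cfmosaic import build_reference, default_profiles
from cfmosaic.features import extract_cohort_features
from cfmosaic.simulate import CohortDesign, simulate_cohort_frames


@pytest.fixture(scope="session")
def reference():
    return build_reference(seed=7, n_chrom=2, chrom_length=100_000)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def cohort():
    """20 healthy + 20 liver + 5 of each other cancer class, 20k fragments."""
    design = CohortDesign(
        class_counts={
            "healthy": 20, "liver": 20,
            "breast": 5, "colorectal": 5, "gastric": 5, "lung": 5,
        },
        fragments_per_sample=20_000,
        master_seed=11,
    )
    return simulate_cohort_frames(design)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    """Raw (un-normalized) nine-group feature set of the shared cohort."""
    return extract_cohort_features(cohort)


@pytest.fixture(scope="session")
def cohort_labels(cohort):
    return cohort["labels"].set_index("sample_id")["class_label"]


@pytest.fixture(scope="session")
def planted_frame():
    """Five classes, each with its own high-mean feature block (one per group).

    Used for separability, chance-level and explainer recovery checks: the
    class signal of class ``k`` lives entirely in group ``Gk``.
    """
    rng = np.random.default_rng(5)
    n_per, d = 16, 8
    classes = [f"class{k}" for k in range(5)]
    cols = [f"G{k}:f{j}" for k in range(5) for j in range(d)]
    blocks, labels = [], []
    for ci in range(5):
        x = rng.normal(size=(n_per, 5 * d)) * 0.3
        x[:, ci * d : (ci + 1) * d] += 2.0
        blocks.append(x)
        labels += [classes[ci]] * n_per
    frame = pd.DataFrame(
        np.vstack(blocks), index=[f"s{i:03d}" for i in range(5 * n_per)], columns=cols
    )
    return frame, pd.Series(labels, index=frame.index), classes
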