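import numpy as np
import pandas as pd
import pytest

from iitscreen import GeneratorParams, generate_cohort
from iitscreen.cohort import CANONICAL_COLUMNS


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort at the study size."""
    return generate_cohort(GeneratorParams(n=797, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort for distributional checks."""
    return generate_cohort(GeneratorParams(n=10_000, seed=23))


@pytest.fixture
def cohort_csv(tmp_path):
    """Write rows (dicts of canonical columns) to a cohort CSV; returns the path."""

    def _write(rows, name="cohort.csv"):
        path = tmp_path / name
        df = pd.DataFrame(rows)
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = ""
        df.loc[:, list(CANONICAL_COLUMNS)].to_csv(path, index=False)
        return path

    return _write


def random_scores_labels(rng, n_max=50, ties=True):
    """A random small ROC instance with both classes present."""
    n = rng.integers(4, n_max + 1)
    if ties and rng.random() < 0.5:
        scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
    else:
        scores = rng.normal(size=n)
    labels = rng.random(size=n) < rng.uniform(0.2, 0.8)
    if labels.all():
        labels[rng.integers(n)] = False
    if not labels.any():
        labels[rng.integers(n)] = True
    return scores, labels
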