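"""Shared fixtures: every dataset is generated programmatically."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from methcovar.core_io import BetaMatrix, SampleRecord, SampleType
from methcovar.synthetic_data import (
    SimulationConfig,
    default_class_fractions,
    simulate_dataset,
)

warnings.filterwarnings("ignore", category=FutureWarning)


def null_fractions(**overrides: float) -> dict[str, float]:
    """Class-fraction dict with all mass on ``null`` unless overridden."""
    fractions = {k: 0.0 for k in default_class_fractions()}
    fractions["null"] = 1.0 - sum(overrides.values())
    fractions.update(overrides)
    return fractions


@pytest.fixture(scope="session")
def small_dataset():
    """Blood-only dataset: 60 sites, 15 families, all site classes."""
    return simulate_dataset(SimulationConfig(n_sites=60, seed=11))


@pytest.fixture(scope="session")
def epithelial_dataset():
    """Full 8-sample-type dataset with strong type separation."""
    return simulate_dataset(
        SimulationConfig(n_sites=120, seed=23, include_epithelial=True)
    )


@pytest.fixture()
def tiny_matrix():
    values = np.array([[0.1, 0.2], [0.5, 0.6], [0.9, 0.8]])
    return BetaMatrix(["cgA", "cgB", "cgC"], ["s1", "s2"], values)


@pytest.fixture()
def two_type_sheet():
    records = []
    for i in range(4):
        ind = f"ind{i}"
        fam = f"fam{i // 2}"
        for t in (SampleType.WHOLE_BLOOD, SampleType.MONOCYTES):
            records.append(
                SampleRecord(
                    sample_id=f"{ind}_{t.value}",
                    individual_id=ind,
                    family_id=fam,
                    sample_type=t,
                )
            )
    return records
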