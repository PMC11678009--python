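"""Shared fixtures: small hand-built tables and a bank of generated studies."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from chemotyper import (
    GeneratorConfig,
    MetaboliteTable,
    SampleMetadata,
    TableState,
    generate_dataset,
    median_normalize,
    preprocess_pipeline,
)

warnings.filterwarnings("ignore", message="replicate groups with fewer than 3")
warnings.filterwarnings("ignore", message="fewer complete donor rows")

#: seeds used by every multi-replicate stochastic check
BANK_SEEDS = (1, 2, 3)


def make_table(
    values, sample_ids=None, metabolite_ids=None, state=TableState.RAW
) -> MetaboliteTable:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    metabolite_ids = metabolite_ids or [f"M{j + 1}" for j in range(m)]
    return MetaboliteTable(
        pd.DataFrame(values, index=sample_ids, columns=metabolite_ids), state
    )


def make_metadata(
    sample_ids,
    genotype=None,
    condition=None,
    time_das=None,
    replicate=None,
) -> SampleMetadata:
    n = len(sample_ids)
    frame = pd.DataFrame(
        {
            "genotype": genotype or ["g1"] * n,
            "condition": condition or ["normoxia"] * n,
            "time_das": time_das or [3] * n,
            "replicate": replicate or list(range(1, n + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SampleMetadata(frame)


def two_class_metadata(n_per_class: int, prefix: str = "s") -> SampleMetadata:
    ids = [f"{prefix}{i + 1}" for i in range(2 * n_per_class)]
    return make_metadata(
        ids,
        condition=["normoxia"] * n_per_class + ["hypoxia"] * n_per_class,
        replicate=list(range(1, n_per_class + 1)) * 2,
    )


class Study:
    """One generated study with its preprocessing products."""

    def __init__(self, seed: int, **overrides):
        self.config = GeneratorConfig(seed=seed, **overrides)
        (self.table, self.metadata, self.annotation,
         self.sets, self.truth) = generate_dataset(self.config)
        self.processed, self.report = preprocess_pipeline(self.table, self.metadata)
        self.normalized, _ = median_normalize(self.table)


@pytest.fixture(scope="session")
def study_bank() -> dict[int, Study]:
    """Generated studies at default settings for the seeds in BANK_SEEDS."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {seed: Study(seed) for seed in BANK_SEEDS}


@pytest.fixture(scope="session")
def study(study_bank) -> Study:
    return study_bank[BANK_SEEDS[0]]
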