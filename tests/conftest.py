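"""Shared fixtures: small simulated cohorts and sequence sets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ceraxis.synthetic import (
    SyntheticConfig,
    simulate_cohort,
    simulate_qpcr,
    simulate_sequences,
)


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    return SyntheticConfig(rng_seed=11)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """Default-scale cohort: (matrices, design, truth)."""
    return simulate_cohort(default_cfg)


@pytest.fixture(scope="session")
def sequences(default_cfg, cohort):
    _, _, truth = cohort
    return simulate_sequences(default_cfg, truth)


@pytest.fixture(scope="session")
def qpcr(default_cfg, cohort):
    matrices, design, truth = cohort
    return simulate_qpcr(default_cfg, truth, matrices, design)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_matrix(values, sample_ids, feature_ids, rna_class):
    from ceraxis.containers import ExpressionMatrix

    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=feature_ids,
                     columns=sample_ids),
        rna_class,
    )


@pytest.fixture()
def tiny_design() -> pd.Series:
    return pd.Series(
        ["responder"] * 3 + ["nonresponder"] * 3,
        index=["R1", "R2", "R3", "N1", "N2", "N3"],
        name="group",
    )
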