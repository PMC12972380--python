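"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metmodnet.io import IonCountMatrix, SampleMeta
from metmodnet.simulate import SimulationConfig, simulate_cohort


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast cohort: one 30-metabolite module + 30 background metabolites."""
    defaults = dict(
        seed=seed,
        n_metabolites=60,
        module_sizes=(30,),
        n_high_cv=3,
        n_forced_high_missing=4,
        n_shared_response=5,
        n_group_response=4,
        missing_rate=0.02,
        outlier_rate=0.005,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """No planted effects of any kind: for type-I calibration."""
    defaults = dict(
        seed=seed,
        n_metabolites=40,
        module_sizes=(30,),
        group_module_shift={},
        n_high_cv=0,
        n_forced_high_missing=0,
        n_shared_response=0,
        n_group_response=0,
        missing_rate=0.0,
        outlier_rate=0.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def clean_cohort():
    """No missingness/outliers/planted QC failures: QC should exclude nothing."""
    cfg = small_config(
        seed=7, n_high_cv=0, n_forced_high_missing=0, missing_rate=0.0, outlier_rate=0.0
    )
    return simulate_cohort(cfg)


def toy_meta(n_subjects: int = 6, groups=("control", "endurance"), n_ref: int = 2) -> SampleMeta:
    """Minimal single-batch metadata: n subjects x 2 timepoints + refs."""
    rows = []
    for i in range(n_subjects):
        g = groups[i % len(groups)]
        for tp, suff in (("baseline", "base"), ("post", "post")):
            rows.append((f"s{i}_{suff}", f"subj{i}", "experimental", g, tp, "batch1"))
    for r in range(n_ref):
        rows.append((f"ref{r}", "", "reference_serum", "", "", "batch1"))
    return SampleMeta(pd.DataFrame(rows, columns=list(SampleMeta.COLUMNS)))


def toy_matrix(values: np.ndarray, met_ids=None, sample_ids=None, log_scale=False) -> IonCountMatrix:
    values = np.asarray(values, dtype=float)
    met_ids = met_ids or [f"m{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return IonCountMatrix(
        pd.DataFrame(values, index=met_ids, columns=sample_ids), log_scale=log_scale
    )
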