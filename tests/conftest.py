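"""Shared fixtures: hand-built count matrices and the default synthetic cohort."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ncaging import CountMatrix, SimDesign, Thresholds, simulate_aging_cohort


def make_cm(counts: dict[str, list[int]], features: list[str],
            tissues: list[str] | None = None,
            ages: list[float] | None = None,
            cohort: str = "aging", groups: list[str] | None = None,
            total_reads: list[int] | None = None) -> CountMatrix:
    """Build a CountMatrix from a sample_id -> counts-column mapping."""
    sids = list(counts)
    n = len(sids)
    tissues = tissues or ["liver"] * n
    ages = ages or [3.0] * n
    groups = groups or (["none"] * n if cohort == "aging" else ["IY"] * n)
    total_reads = total_reads or [5_000_000] * n
    samples = pd.DataFrame({
        "sample_id": sids, "tissue": tissues, "age_months": ages,
        "sex": ["M"] * n, "cohort": [cohort] * n, "group": groups,
        "total_aligned_reads": total_reads})
    df = pd.DataFrame(counts,
                      index=pd.Index(features, name="feature_id")
                      ).astype(np.int64)
    return CountMatrix(counts=df, samples=samples)


@pytest.fixture(scope="session")
def default_design() -> SimDesign:
    return SimDesign(seed=1)


@pytest.fixture(scope="session")
def default_cohort(default_design):
    cohort = simulate_aging_cohort(default_design)
    cohort.cm.normalize()
    return cohort


@pytest.fixture(scope="session")
def thresholds() -> Thresholds:
    return Thresholds()
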