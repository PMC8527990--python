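"""Shared fixtures: hand-built micro tables and seeded synthetic studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from distdecay.model import RANKS, CountTable, StudyDesign
from distdecay.synth import SyntheticSpec, generate_synthetic_study


def make_count_table(counts: dict[str, list[int]], samples: list[str],
                     lineages: dict[str, tuple] | None = None) -> CountTable:
    """Build a CountTable from {taxon: column of counts} over ``samples``."""
    df = pd.DataFrame(counts, index=samples)
    lin = pd.DataFrame.from_dict(lineages or {}, orient="index",
                                 columns=list(RANKS))
    return CountTable(df, lin)


def make_design(samples: dict[str, tuple[str, str, int]],
                facilities: dict[str, dict]) -> StudyDesign:
    """Build a StudyDesign from {sample: (facility, bioreactor, month)}."""
    s = pd.DataFrame.from_dict(
        samples, orient="index", columns=["facility", "bioreactor", "month"])
    f = pd.DataFrame.from_dict(facilities, orient="index")
    return StudyDesign(s, f)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Desk-scale study: 8 facilities, 10 bioreactors, 6 months, 80 taxa."""
    return SyntheticSpec(
        seed=8, n_facilities=8, bioreactors_per_facility={"C": 2, "G": 2},
        n_months=6, n_taxa=80, sequencing_depth=600)


@pytest.fixture(scope="session")
def small_study(small_spec):
    return generate_synthetic_study(small_spec)


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    """The full emulated design (20 facilities / 25 bioreactors / 12 months)."""
    return SyntheticSpec(seed=1)


@pytest.fixture(scope="session")
def default_study(default_spec):
    return generate_synthetic_study(default_spec)
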