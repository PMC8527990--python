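"""Shared data model for the distance-decay analysis pipeline.

The pipeline revolves around four carriers:

* :class:`CountTable` — a samples × taxa non-negative integer matrix with a
  ranked taxonomic lineage per taxon (the community profile).
* :class:`StudyDesign` — the sampling design: which facility/bioreactor/month
  each sample belongs to, plus per-facility coordinates and environmental
  covariates (flow rate, TKN, CBOD, ...).
* ``skbio.DistanceMatrix`` — labelled symmetric matrices used for community
  dissimilarity, geographic distance and environmental difference alike.
* ``skbio.TreeNode`` — the rooted phylogeny used for weighted UniFrac.

Fit results (:class:`DecayFit`, :class:`TemporalClass`, ...) are small frozen
dataclasses so that every number a driver script prints can be traced to one
object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

#: Ranks stored for every taxon, coarsest first.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

#: Placeholder used for missing ranks.
UNCLASSIFIED = "unclassified"

#: Facility metadata columns that are coordinates, not environmental variables.
COORD_COLUMNS: tuple[str, str] = ("latitude", "longitude")


class DataModelError(ValueError):
    """Raised when an artifact violates a data-model invariant."""


@dataclass
class CountTable:
    """Samples × taxa integer count matrix with per-taxon lineages.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per taxon id.
        Values must be non-negative integers.
    lineages
        DataFrame indexed by taxon id with the six columns of :data:`RANKS`.
        Missing ranks are stored as ``"unclassified"``.
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise DataModelError(f"duplicate sample id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise DataModelError(f"duplicate taxon id: {dup!r}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise DataModelError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise DataModelError("counts must be non-negative")
        missing = self.counts.columns.difference(self.lineages.index)
        if len(missing):
            filler = pd.DataFrame(
                UNCLASSIFIED, index=missing, columns=list(RANKS)
            )
            self.lineages = pd.concat([self.lineages, filler])
        self.lineages = self.lineages.reindex(self.counts.columns)[list(RANKS)]
        self.lineages = self.lineages.fillna(UNCLASSIFIED)

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def totals(self) -> pd.Series:
        """Per-sample sequence totals."""
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts scaled to per-sample fractions; errors on zero-total rows."""
        totals = self.totals()
        if (totals == 0).any():
            bad = totals.index[totals == 0][0]
            raise DataModelError(f"sample {bad!r} has zero total count")
        return self.counts.div(totals, axis=0)

    def lineage_strings(self) -> pd.Series:
        """Semicolon-joined full lineage per taxon."""
        return self.lineages.apply(";".join, axis=1)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)].copy(), self.lineages)

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        cols = [t for t in self.taxon_ids if t in set(taxon_ids)]
        return CountTable(self.counts[cols].copy(), self.lineages.loc[cols])


@dataclass
class StudyDesign:
    """Sampling design: sample → (facility, bioreactor, month) and facility metadata.

    ``samples`` is indexed by sample id with columns ``facility``,
    ``bioreactor``, ``month`` (integer, 0-based from study start).
    ``facilities`` is indexed by facility id with ``latitude``/``longitude``
    plus any number of environmental variables (NaN marks a missing value).
    """

    samples: pd.DataFrame
    facilities: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"facility", "bioreactor", "month"}
        if not required.issubset(self.samples.columns):
            raise DataModelError(
                f"sample table needs columns {sorted(required)}"
            )
        unknown = set(self.samples["facility"]) - set(self.facilities.index)
        if unknown:
            raise DataModelError(
                f"samples reference unknown facilities: {sorted(unknown)}"
            )
        if (self.samples["month"] < 0).any():
            raise DataModelError("month index must be >= 0")
        for col, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180)):
            if col not in self.facilities.columns:
                raise DataModelError(f"facility table needs column {col!r}")
            vals = self.facilities[col].astype(float)
            bad = vals[(vals < lo) | (vals > hi)]
            if len(bad):
                raise DataModelError(
                    f"{col} out of range for facility {bad.index[0]!r}: {bad.iloc[0]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def facility_ids(self) -> list[str]:
        return list(self.facilities.index)

    @property
    def env_variables(self) -> list[str]:
        return [c for c in self.facilities.columns if c not in COORD_COLUMNS]

    def facility_of(self, sample_id: str) -> str:
        return self.samples.at[sample_id, "facility"]

    def samples_of_facility(self, facility: str) -> list[str]:
        return list(self.samples.index[self.samples["facility"] == facility])

    def bioreactors(self) -> list[str]:
        return sorted(self.samples["bioreactor"].unique())

    def subset_samples(self, sample_ids: Sequence[str]) -> "StudyDesign":
        return StudyDesign(self.samples.loc[list(sample_ids)].copy(), self.facilities)


@dataclass(frozen=True)
class DecayFit:
    """A fitted log-log power law ``log10(y) = slope*log10(x) + intercept``.

    ``slope`` is the spatial community shift rate β (or the taxon-volume
    exponent z); ``pearson_rho`` and ``p_value`` describe the linearity of the
    log-log relationship (two-sided t-test on ρ with n−2 df).
    """

    slope: float
    intercept: float
    pearson_rho: float
    p_value: float
    n_pairs: int
    scale_range_km: tuple[float, float] | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        return 10.0 ** (self.intercept + self.slope * np.log10(np.asarray(x, float)))


@dataclass(frozen=True)
class SubgroupMasks:
    """Occupancy-defined community subgroups.

    * ``universal`` — phylotypes detected (count > 0) in every analysed sample.
    * ``ubiquitous`` — phylotypes detected in at least one sample of every
      facility.  Universal colonizers are by construction ubiquitous.
    * ``archaea`` — phylotypes whose domain rank is ``Archaea``.
    """

    universal: frozenset[str]
    ubiquitous: frozenset[str]
    archaea: frozenset[str]
    occupancy_samples: pd.Series = field(repr=False, default=None)
    occupancy_facilities: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.universal <= self.ubiquitous:
            raise DataModelError("universal colonizers must be ubiquitous")


@dataclass(frozen=True)
class MantelResult:
    rho_s: float
    p_value: float
    n_permutations: int
    n_entities: int


@dataclass(frozen=True)
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    f_stat: float
    p_value: float
    groups: tuple[str, ...]

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within


@dataclass(frozen=True)
class VarpartResult:
    """Variation-partitioning fractions of community inertia.

    Fractions are of the total chi-square inertia: pure spatial effect
    (space | env), pure environmental effect (env | space), their shared
    (spatially structured environmental) component, and the unexplained
    remainder.  Small negative shared fractions can arise and are reported
    as computed.
    """

    pure_space: float
    pure_env: float
    shared: float
    unexplained: float
    p_space: float | None = None
    p_env: float | None = None
    p_full: float | None = None

    def __post_init__(self) -> None:
        total = self.pure_space + self.pure_env + self.shared + self.unexplained
        if abs(total - 1.0) > 1e-9:
            raise DataModelError(f"varpart fractions sum to {total}, not 1")


@dataclass(frozen=True)
class TemporalClass:
    """Seasonal-dynamics classification of one bioreactor.

    ``label`` is ``cyclic`` when the quadratic model of dissimilarity vs
    time interval is significant, concave (a < 0) and peaks between 5 and 8
    months; ``linear`` when the linear model is significant; ``both`` /
    ``neither`` accordingly.
    """

    bioreactor: str
    linear_slope: float
    linear_p: float
    quad_a: float
    quad_b: float
    quad_c: float
    quad_p: float
    axis_of_symmetry: float | None
    label: str
    n_pairs: int


def as_distance_matrix(values: np.ndarray, labels: Sequence[str],
                       tol: float = 1e-9) -> DistanceMatrix:
    """Build a validated DistanceMatrix, symmetrizing within ``tol``.

    Asymmetry beyond ``tol`` (absolute) is an error; within tolerance the
    matrix is symmetrized by averaging so downstream code sees an exactly
    symmetric, zero-diagonal matrix.
    """
    values = np.asarray(values, dtype=float)
    asym = np.abs(values - values.T).max() if values.size else 0.0
    if asym > tol:
        raise DataModelError(f"matrix asymmetric beyond tolerance: {asym:.3g}")
    sym = (values + values.T) / 2.0
    np.fill_diagonal(sym, 0.0)
    if (sym < 0).any():
        raise DataModelError("distance matrix entries must be >= 0")
    return DistanceMatrix(sym, ids=list(labels))
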