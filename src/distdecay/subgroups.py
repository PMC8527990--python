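"""Rarefaction, genus-level collapsing, and occupancy-defined subgroups.

Profiles are analysed at a fixed sequencing depth: every sample is subsampled
without replacement to the chosen depth and samples with fewer sequences are
dropped.  OTU-level and genus-phylotype-level analyses use different default
depths (4,336 and 7,805 sequences respectively), reflecting the lower richness
of genus-level profiles.

Three occupancy-defined subgroups are used downstream to separate environmental
selection from dispersal limitation:

* **universal colonizers** — phylotypes detected in *every* analysed sample;
* **ubiquitous phylotypes** — phylotypes detected at least once in *every*
  facility (a superset of the universal colonizers);
* **Archaea** — phylotypes whose domain-rank classification is ``Archaea``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import CountTable, DataModelError, StudyDesign, SubgroupMasks

log = logging.getLogger(__name__)

#: Default rarefaction depth for OTU-level profiles.
OTU_DEPTH = 4336
#: Default rarefaction depth for genus-level phylotype profiles.
PHYLOTYPE_DEPTH = 7805


def subsample_counts(table: CountTable, depth: int, seed: int) -> CountTable:
    """Rarefy every sample to exactly ``depth`` sequences without replacement.

    Samples whose total is below ``depth`` are dropped (and logged).  Each
    retained row is an exact uniform multiset draw of size ``depth`` from the
    sample's sequence pool (multivariate hypergeometric).  All-zero taxon
    columns are retained; masking them is the caller's choice.  Deterministic
    given ``seed``.
    """
    if depth <= 0:
        raise DataModelError(f"rarefaction depth must be positive, got {depth}")
    totals = table.totals()
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(dropped):
        log.warning("rarefaction to %d dropped %d sample(s): %s",
                    depth, len(dropped), ", ".join(map(str, dropped)))
    if not len(keep):
        raise DataModelError(f"all samples have fewer than {depth} sequences")

    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.n_taxa), dtype=np.int64)
    for i, sample in enumerate(keep):
        row = table.counts.loc[sample].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=list(keep), columns=table.taxon_ids)
    return CountTable(counts, table.lineages)


def collapse_to_genus(table: CountTable) -> CountTable:
    """Merge taxa sharing the full six-rank lineage into genus-level phylotypes.

    The merged taxon id is the semicolon-joined lineage string; per-sample
    totals are conserved.  Lineages differing at any rank (including
    ``unclassified`` placeholders) stay distinct.
    """
    lineage = table.lineage_strings()
    collapsed = table.counts.T.groupby(lineage).sum().T
    lineages = (
        table.lineages.assign(_key=lineage)
        .drop_duplicates("_key")
        .set_index("_key")
        .reindex(collapsed.columns)
    )
    return CountTable(collapsed, lineages)


def compute_subgroups(table: CountTable, design: StudyDesign) -> SubgroupMasks:
    """Compute universal/ubiquitous/Archaea masks and occupancy vectors.

    "Detected" means count > 0 in the analysed (rarefied) table.  Occupancy is
    reported both as the number of samples and the number of facilities in
    which each taxon occurs.
    """
    if table.n_samples == 0 or table.n_taxa == 0:
        raise DataModelError("empty count table")
    shared = [s for s in table.sample_ids if s in design.samples.index]
    if not shared:
        raise DataModelError("count table and study design share no samples")
    counts = table.counts.loc[shared]
    present = counts > 0

    occupancy_samples = present.sum(axis=0)
    universal = frozenset(occupancy_samples.index[occupancy_samples == len(shared)])

    facility = design.samples.loc[shared, "facility"]
    per_facility = present.groupby(facility).any()
    occupancy_facilities = per_facility.sum(axis=0)
    n_fac = per_facility.shape[0]
    ubiquitous = frozenset(occupancy_facilities.index[occupancy_facilities == n_fac])

    archaea = frozenset(table.lineages.index[table.lineages["domain"] == "Archaea"])
    return SubgroupMasks(
        universal=universal,
        ubiquitous=ubiquitous,
        archaea=archaea,
        occupancy_samples=occupancy_samples,
        occupancy_facilities=occupancy_facilities,
    )


def subgroup_relative_abundance(table: CountTable, mask) -> pd.Series:
    """Per-sample fraction of sequences belonging to ``mask`` taxa."""
    mask = set(mask)
    unknown = mask - set(table.taxon_ids)
    if unknown:
        raise DataModelError(f"mask taxa not in table: {sorted(unknown)[:3]}")
    totals = table.totals()
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise DataModelError(f"sample {bad!r} has zero total count")
    cols = [t for t in table.taxon_ids if t in mask]
    return table.counts[cols].sum(axis=1) / totals


def occupancy_table(masks: SubgroupMasks) -> pd.DataFrame:
    """Tidy per-taxon occupancy table (taxon, n_samples, n_facilities)."""
    return pd.DataFrame({
        "n_samples": masks.occupancy_samples,
        "n_facilities": masks.occupancy_facilities,
    })
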