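"""Alpha diversity, community dissimilarity, geographic and environmental distance.

Community dissimilarity is computed at three levels of information: presence/
absence (Sørensen), relative abundance (Bray-Curtis) and phylogeny-weighted
abundance (weighted UniFrac).  Geographic distance is great-circle (haversine,
R = 6371 km) on facility coordinates; environmental difference matrices are
absolute pairwise differences of annual-average facility covariates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .model import CountTable, DataModelError, StudyDesign, as_distance_matrix

EARTH_RADIUS_KM = 6371.0


def alpha_diversity(table: CountTable) -> pd.DataFrame:
    """Observed richness R and Shannon index H (natural log) per sample.

    R counts taxa with nonzero counts; H = −Σ p_i ln p_i over the sample's
    relative abundances.  Intended for rarefied tables so that R and H are
    comparable across samples.
    """
    rel = table.relative_abundance().to_numpy()
    richness = (rel > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(rel > 0, rel * np.log(rel), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"richness": richness.astype(int), "shannon": shannon},
        index=table.sample_ids,
    )


def beta_dissimilarity(table: CountTable, metric: str) -> DistanceMatrix:
    """Sørensen or Bray-Curtis dissimilarity matrix over samples.

    Sørensen = 1 − 2|A∩B|/(|A|+|B|) on presence sets (Dice dissimilarity);
    Bray-Curtis = Σ|x−y| / Σ(x+y) on counts.  Both lie in [0, 1].
    """
    if table.n_samples < 2:
        raise DataModelError("need at least 2 samples for beta diversity")
    if (table.totals() == 0).any():
        bad = table.totals().idxmin()
        raise DataModelError(f"sample {bad!r} has zero total count")
    x = table.counts.to_numpy(float)
    if metric in ("braycurtis", "bray_curtis"):
        cond = pdist(x, metric="braycurtis")
    elif metric == "sorensen":
        cond = pdist(x > 0, metric="dice")
    else:
        raise DataModelError(f"unknown beta-diversity metric: {metric!r}")
    return as_distance_matrix(squareform(cond), table.sample_ids)


def weighted_unifrac(table: CountTable, tree: TreeNode,
                     normalized: bool = True) -> DistanceMatrix:
    """Weighted UniFrac distance matrix over samples.

    Raw weighted UniFrac sums, over branches, branch length times the absolute
    difference in the fraction of each sample's sequences descending from that
    branch.  The normalized variant divides by the abundance-weighted sum of
    root-to-tip distances, giving values in [0, 1].  Every taxon with nonzero
    counts must be a leaf of ``tree``.
    """
    tips = {t.name for t in tree.tips()}
    nonzero = table.counts.columns[(table.counts > 0).any(axis=0)]
    missing = [t for t in nonzero if t not in tips]
    if missing:
        raise DataModelError(f"taxa missing from tree: {missing[:5]}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise DataModelError("tree has negative branch lengths")
    present = [t for t in table.taxon_ids if t in tips]
    sub = table.counts[present]
    dm = beta_diversity(
        "weighted_unifrac",
        sub.to_numpy(),
        ids=table.sample_ids,
        taxa=present,
        tree=tree,
        normalized=normalized,
        validate=True,
    )
    return dm


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between decimal-degree coordinates."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geographic_distance_km(design: StudyDesign) -> DistanceMatrix:
    """Facility × facility great-circle distance matrix in km."""
    fac = design.facilities
    if fac[["latitude", "longitude"]].isna().any().any():
        bad = fac.index[fac[["latitude", "longitude"]].isna().any(axis=1)][0]
        raise DataModelError(f"facility {bad!r} is missing coordinates")
    lat = fac["latitude"].to_numpy(float)
    lon = fac["longitude"].to_numpy(float)
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    return as_distance_matrix(d, design.facility_ids, tol=1e-6)


def env_difference_matrix(design: StudyDesign, variable: str
                          ) -> tuple[DistanceMatrix, list[str]]:
    """|v_i − v_j| facility difference matrix for one environmental variable.

    Facilities missing the variable are excluded (their pairs would all be
    undefined) and returned in the second element so callers can report them.
    """
    if variable not in design.env_variables:
        raise DataModelError(
            f"unknown environmental variable {variable!r}; "
            f"known: {design.env_variables}"
        )
    vals = design.facilities[variable].astype(float)
    excluded = list(vals.index[vals.isna()])
    vals = vals.dropna()
    if len(vals) < 2:
        raise DataModelError(f"fewer than 2 facilities have {variable!r}")
    v = vals.to_numpy()
    d = np.abs(v[:, None] - v[None, :])
    return as_distance_matrix(d, list(vals.index), tol=1e-6), excluded
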