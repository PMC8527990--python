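"""Synthetic studies with planted spatial, environmental and seasonal structure.

The generator emulates the *output* of a 16S amplicon survey of activated-sludge
bioreactors: a rarefied genus-level count table over a 20-facility /
25-bioreactor / 12-month design, facility metadata with spatially
autocorrelated environmental covariates, and a random phylogeny with the
Archaea forming a clade.

Community structure is niche-based.  Each taxon has a lognormal
rank-abundance baseline, a taxon-specific response to one spatially
autocorrelated environmental field (total Kjeldahl nitrogen of the influent,
the planted driver), and spatially autocorrelated residual variation.  Because
nearby facilities share similar environments and residual fields, community
dissimilarity rises with distance; the realized Bray-Curtis decay slope is
calibrated to the planted β by a pilot fit and a single correction of the
distance-dependent variance.  Designated bioreactors additionally carry a
12-month sinusoidal cycle (two orthogonal taxon-loading phases, so the
community traces a closed annual loop), and all bioreactors drift slowly in a
reactor-specific direction.

All randomness flows from one seed through independently spawned child
streams, so every sub-draw is reproducible on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .decay import decay_fit_from_pairs, facility_annual_mean, facility_pair_table
from .metrics import beta_dissimilarity, geographic_distance_km, haversine_km
from .model import CountTable, DataModelError, StudyDesign

log = logging.getLogger(__name__)

#: Facility ids of the emulated design (A..T).
FACILITY_IDS = tuple("ABCDEFGHIJKLMNOPQRST")

#: Parallel-bioreactor multiplicities: two facilities with 2 reactors, one
#: with 4, the rest with 1 (25 bioreactors in total).
DEFAULT_BIOREACTORS = {"C": 2, "G": 2, "S": 4}

ENV_VARIABLES = (
    "flow_rate", "pH", "mean_cell_residence_time",
    "CBOD_in", "TSS_in", "phosphorus_in", "TKN_in",
    "pH_out", "CBOD_out", "TSS_out", "phosphorus_out",
    "NH3_out", "NOx_out", "TKN_out",
)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study.

    Defaults mirror the emulated survey: 20 facilities within ~442 km,
    25 bioreactors, 12 monthly samples, 300 genus-level phylotypes rarefied
    to 7,805 sequences, a planted decay slope β = 0.12, and a seasonal cycle
    in roughly half of the bioreactors.
    """

    seed: int
    n_facilities: int = 20
    bioreactors_per_facility: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BIOREACTORS))
    n_months: int = 12
    n_taxa: int = 300
    planted_beta: float = 0.12
    decay_intercept: float = -0.55
    noise_sd: float = 0.05
    env_gradient_strength: float = 0.55
    seasonal_amplitude: float = 0.55  # abundance-weighted log-abundance displacement
    cyclic_bioreactors: frozenset[str] | None = None
    drift_rate: float = 0.015
    sequencing_depth: int = 7805
    archaea_fraction: float = 0.11
    archaea_mean_abundance: float = 0.003
    # niche-model nuisance parameters (natural-log abundance scale)
    sad_sd: float = 2.0
    occupancy_gradient: float = 1.8
    occupancy_noise_sd: float = 1.8
    spatial_noise_sd: float = 0.55
    corr_length_km: float = 150.0
    bioreactor_noise_sd: float = 0.06
    sample_noise_sd: float = 0.30
    max_taxon_share: float = 0.35
    max_distance_km: float = 442.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DataModelError("a seed is mandatory")
        if self.n_facilities < 2 or self.n_months < 1 or self.n_taxa < 2:
            raise DataModelError("facility/month/taxon counts must be >= their minima")
        if self.planted_beta < 0:
            raise DataModelError("planted_beta must be >= 0")

    def facility_ids(self) -> list[str]:
        base = list(FACILITY_IDS)
        if self.n_facilities <= len(base):
            return base[: self.n_facilities]
        return base + [f"F{i}" for i in range(len(base), self.n_facilities)]

    def bioreactor_ids(self) -> list[tuple[str, str]]:
        """(facility, bioreactor) pairs in deterministic order."""
        out = []
        for fac in self.facility_ids():
            k = self.bioreactors_per_facility.get(fac, 1)
            for j in range(1, k + 1):
                out.append((fac, f"{fac}{j}"))
        return out

    def resolved_cyclic(self) -> frozenset[str]:
        """Designated cyclic bioreactors.

        Default: all bioreactors of every other facility (~half the reactors).
        Seasonality is facility-driven (shared influent), so parallel
        bioreactors of one facility cycle together.
        """
        if self.cyclic_bioreactors is not None:
            return frozenset(self.cyclic_bioreactors)
        cyclic_fac = set(self.facility_ids()[::2])
        return frozenset(r for fac, r in self.bioreactor_ids()
                         if fac in cyclic_fac)


# ---------------------------------------------------------------------------
# direct power-law pair generator
# ---------------------------------------------------------------------------

def generate_powerlaw_pairs(beta: float, c: float, sigma: float, n: int,
                            seed: int, d_range: tuple[float, float] = (11.0, 442.0)
                            ) -> pd.DataFrame:
    """Facility-pair-shaped (D, DS) draws from DS = 10^(c + β·log10 D + ε).

    D is log-uniform on ``d_range`` km and ε ~ Normal(0, σ²).  DS values are
    clipped into (0, 1]; more than 10% clipping triggers a warning.  Returns a
    DataFrame with columns ``d_km`` and ``ds_mean`` (facility-pair-table shape).
    """
    if n < 3:
        raise DataModelError(f"need n >= 3 pairs, got {n}")
    rng = np.random.default_rng(seed)
    lo, hi = d_range
    d = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
    eps = rng.normal(0.0, sigma, size=n)
    ds = 10 ** (c + beta * np.log10(d) + eps)
    clipped = int(((ds > 1.0) | (ds <= 0.0)).sum())
    if clipped > 0.1 * n:
        log.warning("%.0f%% of generated DS values clipped into (0, 1]",
                    100 * clipped / n)
    ds = np.clip(ds, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"d_km": d, "ds_mean": ds})


# ---------------------------------------------------------------------------
# full synthetic study
# ---------------------------------------------------------------------------

def _spatial_field(coords_km: np.ndarray, corr_length: float,
                   rng: np.random.Generator, n_fields: int = 1) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field(s) with exp(−D/L) correlation."""
    n = coords_km.shape[0]
    d = np.sqrt(((coords_km[:, None, :] - coords_km[None, :, :]) ** 2).sum(-1))
    k = np.exp(-d / corr_length) + 1e-8 * np.eye(n)
    chol = np.linalg.cholesky(k)
    z = rng.standard_normal((n, n_fields))
    return chol @ z


def _random_clade_newick(names: list[str], rng: np.random.Generator) -> str:
    """Random coalescent-style topology over ``names`` with exponential waits."""
    nodes = [(name, 0.0) for name in names]  # (newick, height)
    k = len(nodes)
    height = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        height += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, h_j) = nodes.pop(j)
        (nwk_i, h_i) = nodes.pop(i)
        merged = (f"({nwk_i}:{height - h_i:.6f},{nwk_j}:{height - h_j:.6f})")
        nodes.append((merged, height))
    return nodes[0][0]


def _build_tree(taxon_ids: list[str], archaea: list[str],
                rng: np.random.Generator) -> TreeNode:
    bacteria = [t for t in taxon_ids if t not in set(archaea)]
    parts = []
    for clade in (bacteria, archaea):
        if len(clade) == 0:
            continue
        if len(clade) == 1:
            parts.append(f"{clade[0]}:1.0")
        else:
            parts.append(f"{_random_clade_newick(list(clade), rng)}:1.0")
    newick = f"({','.join(parts)});" if len(parts) > 1 else f"{parts[0]};"
    return TreeNode.read([newick])


def _facility_coordinates(spec: SyntheticSpec,
                          rng: np.random.Generator) -> pd.DataFrame:
    """Facilities uniform in a box rescaled so max pairwise distance ≈ target."""
    n = spec.n_facilities
    lat0, lon0 = 45.5, -94.5  # mid-latitude study region
    lat = lat0 + rng.uniform(-1.0, 1.0, n)
    lon = lon0 + rng.uniform(-1.5, 1.5, n)
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    scale = spec.max_distance_km / d.max()
    lat = lat0 + (lat - lat0) * scale
    lon = lon0 + (lon - lon0) * scale
    return pd.DataFrame({"latitude": lat, "longitude": lon},
                        index=spec.facility_ids())


def _environment(spec: SyntheticSpec, coords: pd.DataFrame,
                 rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Facility metadata table; TKN_in is the spatially structured driver."""
    n = spec.n_facilities
    lat = coords["latitude"].to_numpy()
    lon = coords["longitude"].to_numpy()
    km_x = (lon - lon.mean()) * 111.195 * np.cos(np.radians(lat.mean()))
    km_y = (lat - lat.mean()) * 111.195
    xy = np.column_stack([km_x, km_y])
    e = _spatial_field(xy, spec.corr_length_km, rng, 1)[:, 0]

    env = pd.DataFrame(index=coords.index)
    env["flow_rate"] = 10 ** rng.normal(0.8, 0.6, n)          # MGD-scale
    env["pH"] = rng.normal(7.1, 0.2, n)
    env["mean_cell_residence_time"] = 10 ** rng.normal(1.0, 0.25, n)  # days
    env["CBOD_in"] = rng.normal(180.0, 40.0, n)
    env["TSS_in"] = rng.normal(220.0, 50.0, n)
    env["phosphorus_in"] = rng.normal(6.0, 1.5, n)
    env["TKN_in"] = 40.0 + 8.0 * e                            # planted driver
    env["pH_out"] = rng.normal(7.0, 0.15, n)
    env["CBOD_out"] = rng.normal(6.0, 2.0, n)
    env["TSS_out"] = rng.normal(8.0, 3.0, n)
    env["phosphorus_out"] = rng.normal(1.0, 0.4, n)
    env["NH3_out"] = 1.5 + 0.9 * e + 0.5 * rng.standard_normal(n)
    env["NOx_out"] = rng.normal(12.0, 3.0, n)
    env["TKN_out"] = 3.0 + 0.8 * e + 0.4 * rng.standard_normal(n)
    return env, e


def generate_synthetic_study(spec: SyntheticSpec
                             ) -> tuple[CountTable, StudyDesign, TreeNode]:
    """Generate a full synthetic study (count table, design, phylogeny).

    Deterministic given ``spec.seed``.  The distance-dependent variance is
    calibrated (one pilot fit, one correction) so the realized facility-pair
    Bray-Curtis decay slope lies within ±25% of ``spec.planted_beta``.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(8)
    rng_geo, rng_env, rng_taxa, rng_field, rng_reactor, rng_sample, \
        rng_counts_seed, rng_tree = (np.random.default_rng(s) for s in streams)

    coords = _facility_coordinates(spec, rng_geo)
    env, e_field = _environment(spec, coords, rng_env)
    facilities = pd.concat([coords, env], axis=1)

    n_t = spec.n_taxa
    taxon_ids = [f"P{i:04d}" for i in range(n_t)]
    n_arch = int(round(spec.archaea_fraction * n_t))
    archaea_ids = taxon_ids[n_t - n_arch:]
    lineages = _lineages(taxon_ids, archaea_ids, rng_taxa)

    # taxon-level parameters; Archaea share the SAD shape but are shifted so
    # their expected total share of the community is archaea_mean_abundance
    n_bact = n_t - n_arch
    base_b = np.sort(rng_taxa.normal(0.0, spec.sad_sd, n_bact))[::-1]
    base_a = rng_taxa.normal(0.0, spec.sad_sd, n_arch)
    if n_arch:
        target = spec.archaea_mean_abundance
        shift = np.log(target / (1 - target)
                       * np.exp(base_b).sum() / np.exp(base_a).sum())
        base_a = base_a + shift
    base = np.concatenate([base_b, base_a])
    gains = rng_taxa.normal(0.0, 1.0, n_t)
    # occupancy channel: the rare half of the community additionally responds
    # strongly to the environmental field, so detection (presence/absence) of
    # rare taxa is spatially structured while their Bray-Curtis mass stays
    # negligible — this is what makes Sørensen decay alongside Bray-Curtis
    rank_frac = np.argsort(np.argsort(-base)) / max(n_t - 1, 1)
    occ_mask = (rank_frac > 0.5).astype(float)
    occ_gains = rng_taxa.normal(0.0, 1.0, n_t) * occ_mask * spec.occupancy_gradient

    # facility-level spatially autocorrelated residual fields (one per taxon)
    lat = coords["latitude"].to_numpy()
    lon = coords["longitude"].to_numpy()
    km_x = (lon - lon.mean()) * 111.195 * np.cos(np.radians(lat.mean()))
    km_y = (lat - lat.mean()) * 111.195
    xy = np.column_stack([km_x, km_y])
    eta = _spatial_field(xy, spec.corr_length_km, rng_field, n_t)
    occ_eta = (_spatial_field(xy, spec.corr_length_km, rng_field, n_t)
               * occ_mask * spec.occupancy_noise_sd)

    reactors = spec.bioreactor_ids()
    cyclic = spec.resolved_cyclic()
    reactor_offset = {r: rng_reactor.normal(0.0, spec.bioreactor_noise_sd, n_t)
                      for _, r in reactors}
    # drift and seasonal loadings are facility-level: parallel bioreactors
    # share their influent, so they drift and cycle together
    drift_dir = {f: rng_reactor.normal(0.0, 1.0, n_t)
                 for f in spec.facility_ids()}
    season_sin = {f: rng_reactor.normal(0.0, 1.0, n_t)
                  for f in spec.facility_ids()}
    season_cos = {f: rng_reactor.normal(0.0, 1.0, n_t)
                  for f in spec.facility_ids()}

    sample_rows = []
    for fac, reactor in reactors:
        for m in range(spec.n_months):
            sample_rows.append((f"{reactor}_m{m:02d}", fac, reactor, m))
    sample_meta = pd.DataFrame(
        sample_rows, columns=["sample_id", "facility", "bioreactor", "month"]
    ).set_index("sample_id")
    sample_noise = rng_sample.normal(0.0, spec.sample_noise_sd,
                                     (len(sample_meta), n_t))
    counts_seed = int(rng_counts_seed.integers(0, 2**31 - 1))

    fac_index = {f: i for i, f in enumerate(spec.facility_ids())}

    def build(kappa: float) -> CountTable:
        rng_counts = np.random.default_rng(counts_seed)
        # facility core profiles; temporal loadings are normalized by their
        # abundance-weighted magnitude so the planted drift/seasonal effect
        # sizes are comparable across facilities and seeds
        fac_core = {}
        wnorm = {}
        for fac in spec.facility_ids():
            f_i = fac_index[fac]
            core = (base
                    + kappa * spec.env_gradient_strength * gains * e_field[f_i]
                    + kappa * spec.spatial_noise_sd * eta[f_i]
                    + np.minimum(kappa * (occ_gains * e_field[f_i]
                                          + occ_eta[f_i]), 1.0))
            # cap single-taxon dominance: hyper-dominated profiles are both
            # unrealistic for activated sludge and numerically inert under
            # relative-abundance metrics
            p = np.exp(core - core.max())
            p /= p.sum()
            for _ in range(8):
                if p.max() <= spec.max_taxon_share:
                    break
                top = int(np.argmax(p))
                core[top] -= np.log(p[top] / spec.max_taxon_share)
                p = np.exp(core - core.max())
                p /= p.sum()
            fac_core[fac] = core
            wnorm[fac] = {
                "drift": drift_dir[fac] / max((p * np.abs(drift_dir[fac])).sum(), 1e-12),
                "sin": season_sin[fac] / max((p * np.abs(season_sin[fac])).sum(), 1e-12),
                "cos": season_cos[fac] / max((p * np.abs(season_cos[fac])).sum(), 1e-12),
            }
        rows = np.empty((len(sample_meta), n_t), dtype=np.int64)
        for i, (sid, row) in enumerate(sample_meta.iterrows()):
            r = row["bioreactor"]
            m = row["month"]
            fac = row["facility"]
            loga = (fac_core[fac]
                    + reactor_offset[r]
                    + spec.drift_rate * m * wnorm[fac]["drift"]
                    + sample_noise[i])
            if r in cyclic:
                phase = 2 * np.pi * m / 12.0
                loga = loga + spec.seasonal_amplitude / np.sqrt(2) * (
                    wnorm[fac]["sin"] * np.sin(phase)
                    + wnorm[fac]["cos"] * np.cos(phase))
            p = np.exp(loga - loga.max())
            p /= p.sum()
            rows[i] = rng_counts.multinomial(spec.sequencing_depth, p)
        counts = pd.DataFrame(rows, index=list(sample_meta.index),
                              columns=taxon_ids)
        return CountTable(counts, lineages)

    design = StudyDesign(sample_meta, facilities)

    table = build(1.0)
    kappa = 1.0
    if spec.planted_beta > 0 and spec.n_facilities >= 4 and spec.n_months >= 1:
        pilot = _realized_beta(table, design)
        if not np.isfinite(pilot) or pilot <= 0:
            raise DataModelError(
                "calibration infeasible: pilot decay slope is not positive; "
                "increase env_gradient_strength or spatial_noise_sd")
        target = spec.planted_beta
        if abs(pilot - target) / target > 0.05:
            # slope responds ~linearly to the spatial-variance scale near 1
            kappa = float(np.clip(target / pilot, 0.3, 3.0))
            table = build(kappa)
            log.info("decay calibration: pilot slope %.4f, kappa %.3f", pilot, kappa)
            realized = _realized_beta(table, design)
            if abs(realized - target) / target > 0.15 and realized > 0:
                # large corrections are sublinear; refine once with the local
                # response exponent estimated from the two measured points
                p_exp = np.log(realized / pilot) / np.log(kappa)
                p_exp = float(np.clip(p_exp, 0.3, 3.0))
                kappa = float(np.clip(kappa * (target / realized) ** (1 / p_exp),
                                      0.2, 5.0))
                table = build(kappa)
                log.info("decay recalibration: realized %.4f, kappa %.3f",
                         realized, kappa)

    tree = _build_tree(taxon_ids, archaea_ids, rng_tree)
    return table, design, tree


def _realized_beta(table: CountTable, design: StudyDesign) -> float:
    ds = beta_dissimilarity(table, "braycurtis")
    pairs = facility_annual_mean(ds, design, month_matched=True)
    geo = geographic_distance_km(design)
    pairs = facility_pair_table(pairs, geo)
    return decay_fit_from_pairs(pairs).slope


def _lineages(taxon_ids: list[str], archaea_ids: list[str],
              rng: np.random.Generator) -> pd.DataFrame:
    arch = set(archaea_ids)
    rows = {}
    for i, t in enumerate(taxon_ids):
        if t in arch:
            rows[t] = ("Archaea", "Euryarchaeota", f"Class{i % 3:02d}",
                       f"Order{i % 5:02d}", f"Family{i % 11:03d}", f"Genus{i:04d}")
        else:
            rows[t] = ("Bacteria", f"Phylum{i % 12:02d}", f"Class{i % 23:02d}",
                       f"Order{i % 37:02d}", f"Family{i % 61:03d}", f"Genus{i:04d}")
    from .model import RANKS
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
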