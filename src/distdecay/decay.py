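"""Distance-decay and taxon-volume power-law regressions.

The central statistic is the spatial community shift rate β, the slope of

    log10(DS) = β · log10(D) + c

where DS is the annual-average community dissimilarity between two facilities
and D their geographic distance.  The taxon-volume exponent z is the analogous
slope of log10(richness) on log10(flow rate).  Linearity of each model is
summarised by Pearson's ρ of the log-transformed pairs with a two-sided
t-test p-value.

Facility-pair dissimilarities average over all cross-facility sample pairs
(all bioreactor combinations); by default only pairs of samples collected in
the same month enter the annual average, so spatial turnover is not conflated
with seasonal turnover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .model import CountTable, DataModelError, DecayFit, StudyDesign

log = logging.getLogger(__name__)


def fit_log_log(x, y, scale_range_km: tuple[float, float] | None = None) -> DecayFit:
    """Ordinary least squares of log10(y) on log10(x).

    Pairs with a nonpositive coordinate are excluded beforehand (and logged);
    at least 3 pairs must remain.  The p-value is the two-sided t-test on
    Pearson's ρ of the log-transformed pairs, t = ρ√((n−2)/(1−ρ²)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataModelError("x and y must have the same length")
    ok = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~ok).sum())
    if n_excluded:
        log.warning("fit_log_log excluded %d nonpositive/non-finite pair(s)", n_excluded)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise DataModelError(f"need >= 3 positive pairs for a log-log fit, got {n}")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0:
        raise DataModelError("zero variance in log10(x)")
    if np.ptp(ly) == 0:
        # flat response: slope 0 by convention, no linear association
        return DecayFit(0.0, float(ly[0]), 0.0, 1.0, n, scale_range_km)
    res = stats.linregress(lx, ly)
    return DecayFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_rho=float(res.rvalue),
        p_value=float(res.pvalue),
        n_pairs=n,
        scale_range_km=scale_range_km,
    )


# ---------------------------------------------------------------------------
# facility-pair annual averaging
# ---------------------------------------------------------------------------

def facility_annual_mean(sample_ds: DistanceMatrix, design: StudyDesign,
                         month_matched: bool = True) -> pd.DataFrame:
    """Average sample-level dissimilarities into unordered facility pairs.

    For each facility pair the annual-average dissimilarity is the arithmetic
    mean over all cross-facility sample pairs (covering every bioreactor
    combination).  With ``month_matched`` (default) only pairs of samples
    collected in the same month enter the mean.  Pairs with no qualifying
    sample pair are dropped and logged.

    Returns a DataFrame with columns ``facility_i``, ``facility_j`` (i < j
    lexicographically), ``ds_mean``, ``n_sample_pairs``.
    """
    ids = list(sample_ds.ids)
    known = [s for s in ids if s in design.samples.index]
    if len(known) != len(ids):
        missing = sorted(set(ids) - set(known))
        raise DataModelError(f"samples absent from study design: {missing[:5]}")
    meta = design.samples.loc[ids]
    fac = meta["facility"].to_numpy()
    month = meta["month"].to_numpy()
    d = sample_ds.data

    facilities = sorted(set(fac))
    rows = []
    dropped = []
    for a_idx, fa in enumerate(facilities):
        ia = np.flatnonzero(fac == fa)
        if not len(ia):
            continue
        for fb in facilities[a_idx + 1:]:
            ib = np.flatnonzero(fac == fb)
            block = d[np.ix_(ia, ib)]
            if month_matched:
                match = month[ia][:, None] == month[ib][None, :]
                vals = block[match]
            else:
                vals = block.ravel()
            if len(vals) == 0:
                dropped.append((fa, fb))
                continue
            rows.append((fa, fb, float(np.mean(vals)), int(len(vals))))
    if dropped:
        log.warning("dropped %d facility pair(s) with no qualifying sample pairs: %s",
                    len(dropped), dropped[:5])
    return pd.DataFrame(rows, columns=["facility_i", "facility_j",
                                       "ds_mean", "n_sample_pairs"])


def facility_pair_table(pairs: pd.DataFrame, geo: DistanceMatrix,
                        env_diffs: dict[str, DistanceMatrix] | None = None
                        ) -> pd.DataFrame:
    """Attach geographic distance (km) and env differences to a pair table."""
    out = pairs.copy()
    out["d_km"] = [
        geo[fi, fj] for fi, fj in zip(out["facility_i"], out["facility_j"])
    ]
    for name, dm in (env_diffs or {}).items():
        have = set(dm.ids)
        out[f"diff_{name}"] = [
            dm[fi, fj] if fi in have and fj in have else np.nan
            for fi, fj in zip(out["facility_i"], out["facility_j"])
        ]
    return out


def pairs_to_matrix(pairs: pd.DataFrame, value_col: str = "ds_mean") -> DistanceMatrix:
    """Assemble a facility-level DistanceMatrix from a complete pair table."""
    facilities = sorted(set(pairs["facility_i"]) | set(pairs["facility_j"]))
    pos = {f: i for i, f in enumerate(facilities)}
    m = np.full((len(facilities), len(facilities)), np.nan)
    np.fill_diagonal(m, 0.0)
    for _, row in pairs.iterrows():
        i, j = pos[row["facility_i"]], pos[row["facility_j"]]
        m[i, j] = m[j, i] = row[value_col]
    if np.isnan(m).any():
        missing = int(np.isnan(m).sum() / 2)
        raise DataModelError(
            f"pair table is incomplete: {missing} facility pair(s) missing")
    from .model import as_distance_matrix
    return as_distance_matrix(m, facilities)


def decay_fit_from_pairs(pairs: pd.DataFrame) -> DecayFit:
    """Fit the distance-decay power law from a facility-pair table."""
    usable = pairs[pairs["d_km"] > 0]
    n_zero = len(pairs) - len(usable)
    if n_zero:
        log.warning("excluded %d co-located facility pair(s) (D = 0) from decay fit",
                    n_zero)
    return fit_log_log(usable["d_km"], usable["ds_mean"])


# ---------------------------------------------------------------------------
# taxon-volume relationship
# ---------------------------------------------------------------------------

def taxon_volume_fit(alpha: pd.DataFrame, design: StudyDesign,
                     volume_variable: str = "flow_rate") -> DecayFit:
    """Taxon-volume exponent z: log-log fit of richness on facility flow rate.

    ``alpha`` is the per-sample diversity table (column ``richness``); per
    bioreactor the mean richness over months is regressed on the facility's
    flow rate.  Bioreactors whose facility lacks a flow rate are excluded
    with a warning.
    """
    shared = [s for s in alpha.index if s in design.samples.index]
    meta = design.samples.loc[shared]
    rich = alpha.loc[shared, "richness"]
    per_reactor = rich.groupby(meta["bioreactor"]).mean()
    fac_of_reactor = meta.groupby("bioreactor")["facility"].first()
    if volume_variable not in design.facilities.columns:
        raise DataModelError(f"facility table has no column {volume_variable!r}")
    volume = design.facilities[volume_variable]

    r_vals, v_vals = [], []
    for reactor, r in per_reactor.items():
        v = volume.get(fac_of_reactor[reactor], np.nan)
        if not np.isfinite(v) or v <= 0:
            log.warning("bioreactor %s excluded from taxon-volume fit: no flow rate",
                        reactor)
            continue
        r_vals.append(r)
        v_vals.append(v)
    return fit_log_log(v_vals, r_vals)


# ---------------------------------------------------------------------------
# sliding-window scale analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowResult:
    lo_km: float
    hi_km: float
    fit: DecayFit
    spearman_distance: float
    spearman_distance_p: float
    spearman_covariate: float | None = None
    spearman_covariate_p: float | None = None


def sliding_window_decay(pairs: pd.DataFrame, width_km: float = 200.0,
                         step_km: float = 10.0, start_km: float = 10.0,
                         covariate: str | None = None,
                         min_pairs: int = 10) -> list[WindowResult]:
    """Distance-decay fits within a sliding geographic-distance window.

    Windows are [lo, lo + width) for lo = start, start + step, ... and the
    ladder stops at the first window holding fewer than ``min_pairs`` pairs.
    Each window reports the log-log decay fit of its member pairs plus
    Spearman rank correlations of the untransformed dissimilarity against
    distance and (optionally) against an environmental difference column
    ``diff_<covariate>`` of the pair table.
    """
    if pairs.empty:
        raise DataModelError("empty facility-pair table")
    d = pairs["d_km"].to_numpy(float)
    results: list[WindowResult] = []
    lo = float(start_km)
    d_max = d.max()
    cov_col = f"diff_{covariate}" if covariate else None
    if cov_col and cov_col not in pairs.columns:
        raise DataModelError(f"pair table has no column {cov_col!r}")
    while lo <= d_max:
        hi = lo + width_km
        member = pairs[(d >= lo) & (d < hi)]
        if len(member) < min_pairs:
            break
        fit = fit_log_log(member["d_km"], member["ds_mean"],
                          scale_range_km=(lo, hi))
        rho_d, p_d = stats.spearmanr(member["d_km"], member["ds_mean"])
        rho_c = p_c = None
        if cov_col:
            sub = member.dropna(subset=[cov_col])
            if len(sub) >= 4:
                rho_c, p_c = stats.spearmanr(sub[cov_col], sub["ds_mean"])
                rho_c, p_c = float(rho_c), float(p_c)
        results.append(WindowResult(lo, hi, fit, float(rho_d), float(p_d),
                                    rho_c, p_c))
        lo += step_km
    if not results:
        raise DataModelError(
            f"no window of width {width_km} from {start_km} holds "
            f">= {min_pairs} pairs")
    return results


def windows_to_frame(windows: list[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "lo_km": w.lo_km, "hi_km": w.hi_km,
            "beta": w.fit.slope, "intercept": w.fit.intercept,
            "pearson_rho": w.fit.pearson_rho, "p_value": w.fit.p_value,
            "n_pairs": w.fit.n_pairs,
            "spearman_distance": w.spearman_distance,
            "spearman_distance_p": w.spearman_distance_p,
            "spearman_covariate": w.spearman_covariate,
            "spearman_covariate_p": w.spearman_covariate_p,
        }
        for w in windows
    ])


# ---------------------------------------------------------------------------
# monthly decay series
# ---------------------------------------------------------------------------

def monthly_decay_series(sample_ds: DistanceMatrix, design: StudyDesign,
                         geo: DistanceMatrix, alpha: float = 0.001
                         ) -> pd.DataFrame:
    """Per-month distance-decay fits (facility-averaged within each month).

    Months with fewer than 3 facility pairs are reported as insufficient
    (NaN fit columns); months failing the significance level ``alpha`` are
    flagged, not dropped.
    """
    ids = list(sample_ds.ids)
    meta = design.samples.loc[ids]
    rows = []
    for m in sorted(meta["month"].unique()):
        month_samples = [s for s in ids if meta.at[s, "month"] == m]
        sub_design = design.subset_samples(month_samples)
        if len(month_samples) >= 2:
            sub = sample_ds.filter(month_samples)
            pairs = facility_annual_mean(sub, sub_design, month_matched=True)
            pairs = facility_pair_table(pairs, geo)
            pairs = pairs[pairs["d_km"] > 0]
        else:
            pairs = pd.DataFrame(columns=["d_km", "ds_mean"])
        if len(pairs) < 3:
            rows.append({"month": m, "beta": np.nan, "intercept": np.nan,
                         "pearson_rho": np.nan, "p_value": np.nan,
                         "n_pairs": len(pairs), "significant": False,
                         "sufficient": False})
            continue
        fit = fit_log_log(pairs["d_km"], pairs["ds_mean"])
        rows.append({"month": m, "beta": fit.slope, "intercept": fit.intercept,
                     "pearson_rho": fit.pearson_rho, "p_value": fit.p_value,
                     "n_pairs": fit.n_pairs,
                     "significant": bool(fit.p_value < alpha),
                     "sufficient": True})
    return pd.DataFrame(rows)
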