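"""Correlation and matrix-permutation statistics.

Covers the multivariate toolkit of the analysis: Spearman and partial Spearman
rank correlation, Mantel tests between distance matrices, AMOVA on a distance
matrix, chi-square (CCA) variation partitioning of community composition into
pure-spatial / pure-environmental / shared / unexplained fractions, and the
two-tailed Wilcoxon rank-sum test.

Permutation procedures are deterministic given a seed.  The study-wide
significance level is α = 0.001, chosen conservatively because large numbers
of pairwise comparisons can make weak correlations "significant".
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

from .model import AmovaResult, DataModelError, MantelResult, VarpartResult

log = logging.getLogger(__name__)

#: Study-wide significance level.
ALPHA = 0.001


# ---------------------------------------------------------------------------
# Spearman / partial Spearman
# ---------------------------------------------------------------------------

def spearman(x, y, control=None) -> tuple[float, float]:
    """Spearman rank correlation, optionally partialling out a control variable.

    Plain: Pearson correlation of average-ranked data with the usual
    t-approximation p-value.  Partial: the first-order partial correlation
    formula applied to rank correlations, with p from a t-test on n−3 df.
    Missing values are removed pairwise (listwise across the triple when a
    control is given).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if control is None:
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        _check_spearman_input(x, y)
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)

    z = np.asarray(control, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[ok], y[ok], z[ok]
    _check_spearman_input(x, y, z)
    r_xy = stats.spearmanr(x, y).statistic
    r_xz = stats.spearmanr(x, z).statistic
    r_yz = stats.spearmanr(y, z).statistic
    denom = np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    if denom == 0:
        # control fully determines x or y in rank: partial correlation is 0
        return 0.0, 1.0
    rho = (r_xy - r_xz * r_yz) / denom
    rho = float(np.clip(rho, -1.0, 1.0))
    n = len(x)
    df = n - 3
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p


def _check_spearman_input(*arrays) -> None:
    n = len(arrays[0])
    if n < 4:
        raise DataModelError(f"need >= 4 complete observations, got {n}")
    for a in arrays:
        if np.ptp(a) == 0:
            raise DataModelError("constant vector: rank correlation undefined")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(a: DistanceMatrix, b: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, alternative: str = "greater",
           strict: bool = False) -> MantelResult:
    """Mantel test with Spearman rank correlation between two distance matrices.

    ``b``'s rows/columns are permuted simultaneously; p is the one-sided
    upper-tail permutation probability by default (positive association being
    the working hypothesis throughout).  With ``strict=False`` the matrices
    are aligned on their shared labels, so facilities lacking an environmental
    value are dropped pairwise.
    """
    shared = sorted(set(a.ids) & set(b.ids))
    if strict and set(a.ids) != set(b.ids):
        raise DataModelError("distance matrices have different labels")
    if len(shared) < 4:
        raise DataModelError(f"need >= 4 shared entities, got {len(shared)}")
    if len(shared) < len(a.ids) or len(shared) < len(b.ids):
        log.info("mantel: aligned to %d shared entities", len(shared))
    rho, p, n = _skbio_mantel(
        a.filter(shared), b.filter(shared),
        method="spearman", permutations=n_perm,
        alternative=alternative, strict=True, seed=seed,
    )
    return MantelResult(rho_s=float(rho), p_value=float(p),
                        n_permutations=n_perm, n_entities=int(n))


def mantel_battery(ds: DistanceMatrix,
                   against: dict[str, DistanceMatrix],
                   n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Mantel tests of one dissimilarity matrix against many difference matrices."""
    rows = []
    for i, (name, other) in enumerate(against.items()):
        res = mantel(ds, other, n_perm=n_perm, seed=seed + i)
        # permutation p-values bottom out at exactly 1/(n_perm+1), so the
        # rejection rule is p <= alpha
        rows.append({"variable": name, "rho_s": res.rho_s, "p_value": res.p_value,
                     "n_entities": res.n_entities, "significant": res.p_value <= ALPHA})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _ss_within(d2: np.ndarray, group_indices: list[np.ndarray]) -> float:
    ss = 0.0
    for idx in group_indices:
        block = d2[np.ix_(idx, idx)]
        ss += block.sum() / 2.0 / len(idx)
    return ss


def amova(dm: DistanceMatrix, groups, n_perm: int = 1000,
          seed: int = 0) -> AmovaResult:
    """Analysis of molecular variance on a distance matrix.

    Distance-based (Excoffier-style) formulation: SS_total = Σ_{i<j} d²/N,
    SS_within sums the analogous within-group terms, SS_among is their
    difference, and F = (SS_among/df_among)/(SS_within/df_within).  The
    p-value permutes group labels: p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1).
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = pd.Series(groups).reindex(list(dm.ids))
    if groups.isna().any():
        bad = groups.index[groups.isna()][0]
        raise DataModelError(f"no group for entity {bad!r}")
    labels = groups.to_numpy()
    names = sorted(set(labels))
    if len(names) < 2:
        raise DataModelError("AMOVA needs >= 2 groups")
    sizes = {g: int((labels == g).sum()) for g in names}
    singles = [g for g, n in sizes.items() if n < 2]
    if singles:
        raise DataModelError(f"singleton group(s): {singles}")

    d2 = dm.data ** 2
    n = len(labels)
    ss_total = d2.sum() / 2.0 / n
    idx = [np.flatnonzero(labels == g) for g in names]
    ss_within = _ss_within(d2, idx)
    ss_among = ss_total - ss_within
    df_among = len(names) - 1
    df_within = n - len(names)
    if ss_within == 0:
        f_obs = np.inf if ss_among > 0 else 0.0
    else:
        f_obs = (ss_among / df_among) / (ss_within / df_within)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pidx = [perm[i] for i in idx]
        ssw = _ss_within(d2, pidx)
        ssa = ss_total - ssw
        f_perm = np.inf if ssw == 0 and ssa > 0 else (
            0.0 if ssw == 0 else (ssa / df_among) / (ssw / df_within))
        if f_perm >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return AmovaResult(ss_among=float(ss_among), ss_within=float(ss_within),
                       df_among=df_among, df_within=df_within,
                       f_stat=float(f_obs), p_value=float(p),
                       groups=tuple(names))


def amova_exhaustive_p(dm: DistanceMatrix, groups) -> float:
    """Exact AMOVA p-value by enumerating all label permutations (tiny n only)."""
    groups = pd.Series(groups).reindex(list(dm.ids))
    labels = groups.to_numpy()
    names = sorted(set(labels))
    d2 = dm.data ** 2
    n = len(labels)
    ss_total = d2.sum() / 2.0 / n
    df_among = len(names) - 1
    df_within = n - len(names)

    def f_of(lab: np.ndarray) -> float:
        idx = [np.flatnonzero(lab == g) for g in names]
        ssw = _ss_within(d2, idx)
        ssa = ss_total - ssw
        if ssw == 0:
            return np.inf if ssa > 0 else 0.0
        return (ssa / df_among) / (ssw / df_within)

    f_obs = f_of(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if f_of(labels[list(perm)]) >= f_obs:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# CCA variation partitioning
# ---------------------------------------------------------------------------

def _chi_square_matrix(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Standardized chi-square residual matrix Q̄ of a community table.

    Returns (Q̄, row weights r, total inertia = ||Q̄||²).
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise DataModelError("community table must be non-negative")
    total = y.sum()
    if total <= 0:
        raise DataModelError("community table sums to zero")
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise DataModelError("community table has an all-zero row or column")
    expected = np.outer(r, c)
    qbar = (p - expected) / np.sqrt(expected)
    inertia = float((qbar**2).sum())
    return qbar, r, inertia


def _weighted_basis(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the r-weighted, weighted-centered predictor space."""
    x = np.asarray(x, dtype=float)
    mean = (r[:, None] * x).sum(axis=0) / r.sum()
    xw = np.sqrt(r)[:, None] * (x - mean)
    u, s, _ = np.linalg.svd(xw, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size and s[0] > 0 else 0
    return u[:, :rank]


def _constrained_inertia(qbar: np.ndarray, r: np.ndarray, x: np.ndarray,
                         condition: np.ndarray | None = None
                         ) -> tuple[float, int]:
    """Inertia of Q̄ explained by x (optionally after removing `condition`).

    Returns (constrained inertia, rank of the constraint space).
    """
    q = qbar
    if condition is not None:
        uz = _weighted_basis(condition, r)
        q = q - uz @ (uz.T @ q)
        xw = np.sqrt(r)[:, None] * (np.asarray(x, float) -
                                    (r[:, None] * np.asarray(x, float)).sum(0) / r.sum())
        # rank cutoff must be relative to the predictor scale *before*
        # residualization, or predictors inside the conditioned space would
        # leave pure-noise directions behind
        scale = np.linalg.norm(xw, 2) if xw.size else 0.0
        xw = xw - uz @ (uz.T @ xw)
        u, s, _ = np.linalg.svd(xw, full_matrices=False)
        rank = int((s > max(scale, 1e-300) * 1e-8).sum()) if s.size else 0
        ux = u[:, :rank]
    else:
        ux = _weighted_basis(x, r)
    fitted = ux @ (ux.T @ q)
    return float((fitted**2).sum()), ux.shape[1]


def _cca_perm_p(qbar: np.ndarray, r: np.ndarray, x: np.ndarray,
                condition: np.ndarray | None, n_perm: int,
                rng: np.random.Generator) -> float:
    """Permutation p-value for a (partial) CCA model, permuting predictor rows."""
    n = qbar.shape[0]
    i_obs, rank = _constrained_inertia(qbar, r, x, condition)
    if rank == 0:
        return 1.0
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = np.asarray(x, float)[perm]
        cp = None if condition is None else np.asarray(condition, float)
        i_perm, _ = _constrained_inertia(qbar, r, xp, cp)
        if i_perm >= i_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def cca_varpart(community: pd.DataFrame, env: pd.DataFrame, space: pd.DataFrame,
                n_perm: int = 999, seed: int = 0) -> VarpartResult:
    """Partial-CCA variation partitioning of community composition.

    ``community`` is a facility × taxa abundance table; ``env`` and ``space``
    are facility × predictor tables (rows aligned by index).  Inertia is the
    chi-square statistic of the community table divided by its grand total;
    constrained inertia comes from r-weighted regression of the standardized
    chi-square residuals on the predictors.  Fractions of total inertia:

    * ``pure_space`` = inertia(space | env) / total
    * ``pure_env``   = inertia(env | space) / total
    * ``shared``     = inertia(env + space)/total − pure_space − pure_env
    * ``unexplained``= 1 − inertia(env + space)/total

    Each constrained model gets a permutation p-value (rows of the predictor
    table permuted; deterministic given ``seed``).
    """
    idx = community.index
    if not (idx.equals(env.index) and idx.equals(space.index)):
        if set(idx) == set(env.index) == set(space.index):
            env = env.loc[idx]
            space = space.loc[idx]
        else:
            raise DataModelError("community/env/space tables index different facilities")
    if env.isna().any().any() or space.isna().any().any():
        raise DataModelError("predictor tables must be complete (no missing values)")
    n = len(idx)
    k = env.shape[1] + space.shape[1]
    if k > n - 1:
        raise DataModelError(f"{k} predictors for {n} rows: need k <= n-1")

    qbar, r, total = _chi_square_matrix(community.to_numpy())
    if total <= 1e-12:
        raise DataModelError("zero community inertia (rows are proportional): "
                             "variation partitioning is degenerate")
    xe = env.to_numpy(float)
    xs = space.to_numpy(float)
    both = np.hstack([xe, xs])

    i_env_given_space, _ = _constrained_inertia(qbar, r, xe, condition=xs)
    i_space_given_env, _ = _constrained_inertia(qbar, r, xs, condition=xe)
    i_full, _ = _constrained_inertia(qbar, r, both)

    pure_env = i_env_given_space / total
    pure_space = i_space_given_env / total
    explained = i_full / total
    shared = explained - pure_env - pure_space
    unexplained = 1.0 - explained

    rng = np.random.default_rng(seed)
    p_env = _cca_perm_p(qbar, r, xe, xs, n_perm, rng)
    p_space = _cca_perm_p(qbar, r, xs, xe, n_perm, rng)
    p_full = _cca_perm_p(qbar, r, both, None, n_perm, rng)

    return VarpartResult(pure_space=pure_space, pure_env=pure_env,
                         shared=shared, unexplained=unexplained,
                         p_space=p_space, p_env=p_env, p_full=p_full)


def cca_constrained_fraction(community: pd.DataFrame, predictors: pd.DataFrame,
                             condition: pd.DataFrame | None = None) -> float:
    """Fraction of total inertia explained by a (partial) CCA model."""
    qbar, r, total = _chi_square_matrix(community.to_numpy())
    cond = None if condition is None else condition.to_numpy(float)
    inertia, _ = _constrained_inertia(qbar, r, predictors.to_numpy(float), cond)
    return inertia / total


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-tailed Wilcoxon rank-sum test with normal approximation.

    Uses average ranks with tie correction and no continuity correction.
    Returns (Z, two-sided p).  If every value is tied across both groups the
    test is degenerate: Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 3 or ny < 3:
        raise DataModelError("each group needs >= 3 observations")
    combined = np.concatenate([x, y])
    n = nx + ny
    ranks = stats.rankdata(combined)
    w = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(z), p
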