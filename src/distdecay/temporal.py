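"""Seasonal community dynamics: time-interval dissimilarity regressions.

Within each bioreactor, every pair of monthly samples yields one observation
(Δmonths, dissimilarity).  A monotone increase of dissimilarity with time
interval (significant linear fit) indicates directional drift; a rise-and-fall
profile (significant concave quadratic fit peaking near half a year) indicates
a seasonal cycle in which the community returns toward its earlier state after
~12 months.  Each bioreactor is labelled ``linear``, ``cyclic``, ``both`` or
``neither``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .model import DataModelError, StudyDesign, TemporalClass

log = logging.getLogger(__name__)

#: Minimum number of samples for a bioreactor to be analysed.
MIN_SAMPLES = 6
#: Minimum number of (Δ, DS) pairs for the regressions.
MIN_PAIRS = 6
#: Months within which the quadratic axis of symmetry counts as seasonal.
AXIS_WINDOW = (5.0, 8.0)


def interval_dissimilarity_series(sample_ds: DistanceMatrix, design: StudyDesign,
                                  bioreactor: str,
                                  min_samples: int = MIN_SAMPLES) -> pd.DataFrame:
    """All within-bioreactor sample pairs as (delta_months, ds) rows.

    Pairs with identical collection months (Δ < 1) are excluded.  Raises if
    the bioreactor is unknown or has fewer than ``min_samples`` samples.
    """
    meta = design.samples
    if bioreactor not in set(meta["bioreactor"]):
        raise DataModelError(f"unknown bioreactor {bioreactor!r}")
    ids = [s for s in sample_ds.ids
           if s in meta.index and meta.at[s, "bioreactor"] == bioreactor]
    if len(ids) < min_samples:
        raise DataModelError(
            f"bioreactor {bioreactor!r} has {len(ids)} samples; "
            f"need >= {min_samples}")
    months = meta.loc[ids, "month"].to_numpy()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            delta = abs(int(months[i]) - int(months[j]))
            if delta >= 1:
                rows.append((delta, float(sample_ds[ids[i], ids[j]])))
    return pd.DataFrame(rows, columns=["delta_months", "ds"])


def _ols_f_test(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS fit with intercept; returns (coefficients, model F-test p-value)."""
    n, k = x.shape
    design_m = np.column_stack([np.ones(n), x])
    coef, _, rank, _ = np.linalg.lstsq(design_m, y, rcond=None)
    fitted = design_m @ coef
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    df_model = rank - 1
    df_resid = n - rank
    if df_model < 1 or df_resid < 1 or ss_tot == 0:
        return coef, 1.0
    if ss_res == 0:
        return coef, 0.0
    f = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid)
    p = float(stats.f.sf(f, df_model, df_resid))
    return coef, p


def classify_temporal_pattern(series: pd.DataFrame, bioreactor: str = "",
                              alpha: float = 0.001,
                              axis_window: tuple[float, float] = AXIS_WINDOW
                              ) -> TemporalClass:
    """Label a bioreactor's (Δmonths, DS) series as linear/cyclic/both/neither.

    Fits DS ~ Δ (linear) and DS ~ Δ + Δ² (quadratic) by OLS and tests each
    model with an ANOVA F-test.  ``cyclic`` requires the quadratic model to be
    significant at ``alpha``, concave (a < 0), and to peak (axis of symmetry
    −b/2a) within ``axis_window`` months; ``linear`` requires the linear model
    to be significant.  Both conditions → ``both``; neither → ``neither``.
    """
    if len(series) < MIN_PAIRS:
        raise DataModelError(
            f"need >= {MIN_PAIRS} pairs to classify, got {len(series)}")
    delta = series["delta_months"].to_numpy(float)
    ds = series["ds"].to_numpy(float)
    if np.ptp(delta) == 0:
        raise DataModelError("degenerate design: all time intervals equal")

    lin_coef, lin_p = _ols_f_test(delta[:, None], ds)
    quad_coef, quad_p = _ols_f_test(np.column_stack([delta, delta**2]), ds)
    c0, b, a = quad_coef
    axis = float(-b / (2 * a)) if a != 0 else None

    is_linear = lin_p < alpha
    is_cyclic = (
        quad_p < alpha and a < 0 and axis is not None
        and axis_window[0] <= axis <= axis_window[1]
    )
    if is_linear and is_cyclic:
        label = "both"
    elif is_cyclic:
        label = "cyclic"
    elif is_linear:
        label = "linear"
    else:
        label = "neither"
    return TemporalClass(
        bioreactor=bioreactor,
        linear_slope=float(lin_coef[1]), linear_p=float(lin_p),
        quad_a=float(a), quad_b=float(b), quad_c=float(c0),
        quad_p=float(quad_p), axis_of_symmetry=axis,
        label=label, n_pairs=len(series),
    )


def classify_all_bioreactors(sample_ds: DistanceMatrix, design: StudyDesign,
                             alpha: float = 0.001,
                             axis_window: tuple[float, float] = AXIS_WINDOW
                             ) -> pd.DataFrame:
    """Classify every bioreactor with enough samples; skip and log the rest."""
    rows = []
    for reactor in design.bioreactors():
        try:
            series = interval_dissimilarity_series(sample_ds, design, reactor)
            cls = classify_temporal_pattern(series, reactor, alpha, axis_window)
        except DataModelError as exc:
            log.warning("skipping bioreactor %s: %s", reactor, exc)
            rows.append({"bioreactor": reactor, "label": "insufficient",
                         "n_pairs": 0, "linear_slope": np.nan, "linear_p": np.nan,
                         "quad_a": np.nan, "quad_b": np.nan, "quad_c": np.nan,
                         "quad_p": np.nan, "axis_of_symmetry": np.nan})
            continue
        rows.append({
            "bioreactor": reactor, "label": cls.label, "n_pairs": cls.n_pairs,
            "linear_slope": cls.linear_slope, "linear_p": cls.linear_p,
            "quad_a": cls.quad_a, "quad_b": cls.quad_b, "quad_c": cls.quad_c,
            "quad_p": cls.quad_p, "axis_of_symmetry": cls.axis_of_symmetry,
        })
    return pd.DataFrame(rows)
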