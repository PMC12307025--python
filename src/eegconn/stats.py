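"""Statistical stage: group comparisons and fluency regressions.

Four model families relate graph metrics to verbal-fluency counts, one
per construct:

* ``dwpli``        — overall connectedness: z(dwPLI) * age + sex
* ``segregation``  — z(clustering) * age + z(modularity) * age + sex
* ``smallworld``   — z(small-world index) * age + sex
* ``integration``  — z(path length) * age + sex

Age group and sex are treatment coded (younger and female as reference
levels), numeric predictors are z-scaled before fitting, and each model
is refit once after removing high-leverage rows (hat diagonal above
2(p+1)/n).  Models are fit per band and per outcome (semantic and letter
fluency), giving 4 families x 4 bands x 2 outcomes = 32 summaries; no
multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats

from .spectral import BAND_NAMES

__all__ = [
    "FAMILY_METRICS",
    "ModelSummary",
    "wilcoxon_ranksum",
    "detect_score_outliers",
    "fit_model",
    "leverage_filter_refit",
    "run_all_models",
    "metrics_to_analysis_table",
]

FAMILY_METRICS = {
    "dwpli": ["dwpli_mean"],
    "segregation": ["clustering", "modularity"],
    "smallworld": ["small_world"],
    "integration": ["path_length"],
}


@dataclass
class ModelSummary:
    """OLS fit summary for one family x band x outcome model."""

    model_id: str
    family: str
    band: str
    outcome: str
    coefficients: dict[str, tuple[float, float, float, float]]  # est, se, t, p
    adjusted_r2: float
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_used: int
    n_leverage_removed: int = 0
    # internals needed for the leverage refit; not part of the report
    _design: pd.DataFrame | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"Effect": name, "Estimate": est, "SE": se, "t value": t,
             "p value": p}
            for name, (est, se, t, p) in self.coefficients.items()
        ]
        return pd.DataFrame(rows)


def wilcoxon_ranksum(x, y, exact: bool | None = None
                     ) -> tuple[float, float, float]:
    """Two-sided Wilcoxon rank-sum test with effect size.

    Returns ``(W, p, effect_r)`` where W is the Mann-Whitney statistic of
    ``x`` (rank sum of x minus its minimum), p uses midranks and the
    normal approximation with continuity correction, and
    ``effect_r = |Z| / sqrt(n_x + n_y)``.  For groups of at most 10
    without ties an exact p by enumeration of rank assignments is
    available (``exact=True``; ``exact=None`` auto-selects it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one observation")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    rx = ranks[:nx].sum()
    w = rx - nx * (nx + 1) / 2.0  # Mann-Whitney U of x

    # normal approximation with tie correction and continuity correction
    mu = nx * ny / 2.0
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return float(w), 1.0, 0.0
    z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var) if w != mu else 0.0
    p_norm = min(1.0, 2.0 * sstats.norm.sf(abs(z)))

    has_ties = np.any(tie_counts > 1)
    if exact is None:
        exact = (max(nx, ny) <= 10) and not has_ties
    if exact and not has_ties:
        u_values = [
            sum(sorted(comb)) - nx * (nx + 1) / 2.0
            for comb in itertools.combinations(range(1, n + 1), nx)
        ]
        u_values = np.asarray(u_values)
        lo = np.mean(u_values <= w)
        hi = np.mean(u_values >= w)
        p = min(1.0, 2.0 * min(lo, hi))
    else:
        p = p_norm
    effect_r = abs(z) / math.sqrt(n)
    return float(w), float(p), float(effect_r)


def detect_score_outliers(scores, k: float = 3.0) -> np.ndarray:
    """Indices of scores further than ``k`` sample SDs from the mean."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need at least 3 scores")
    sd = scores.std(ddof=1)
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(scores - scores.mean()) > k * sd)


def _zscale(v: pd.Series) -> pd.Series:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError(f"column {v.name!r} is constant; cannot scale")
    return (v - v.mean()) / sd


def _build_design(table: pd.DataFrame, metrics: list[str], band: str,
                  outcome: str, scale: bool = True
                  ) -> tuple[pd.DataFrame, pd.Series]:
    cols = [f"{band}_{m}" for m in metrics]
    needed = cols + [outcome, "age_group", "sex"]
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise KeyError(f"missing columns: {missing_cols}")
    df = table[needed + (["subject_id"] if "subject_id" in table.columns
                         else [])].dropna(subset=needed)
    y = df[outcome].astype(float)
    design = pd.DataFrame(index=df.index)
    design["Intercept"] = 1.0
    age = (df["age_group"] == "older").astype(float)
    male = (df["sex"] == "male").astype(float)
    for m, col in zip(metrics, cols):
        v = df[col].astype(float)
        design[m] = _zscale(v) if scale else v
    design["age"] = age
    design["sex"] = male
    for m in metrics:
        design[f"{m}:age"] = design[m] * age
    return design, y


def _fit_ols(design: pd.DataFrame, y: pd.Series, model_id: str, family: str,
             band: str, outcome: str, n_removed: int = 0) -> ModelSummary:
    n, ncol = design.shape
    if n < ncol + 1:
        raise ValueError(
            f"{model_id}: only {n} complete rows for {ncol} parameters")
    x = design.to_numpy()
    rank = np.linalg.matrix_rank(x)
    if rank < ncol:
        # name the collinear columns by checking rank drop per column
        collinear = [
            design.columns[k] for k in range(ncol)
            if np.linalg.matrix_rank(np.delete(x, k, axis=1)) == rank
        ]
        raise ValueError(f"{model_id}: rank-deficient design; "
                         f"collinear columns: {collinear}")
    res = sm.OLS(y.to_numpy(), x).fit()
    coeffs = {
        name: (float(res.params[k]), float(res.bse[k]),
               float(res.tvalues[k]), float(res.pvalues[k]))
        for k, name in enumerate(design.columns)
    }
    return ModelSummary(
        model_id=model_id, family=family, band=band, outcome=outcome,
        coefficients=coeffs,
        adjusted_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue), f_pvalue=float(res.f_pvalue),
        df_model=int(res.df_model), df_resid=int(res.df_resid),
        n_used=n, n_leverage_removed=n_removed,
        _design=design, _y=y.to_numpy(),
    )


def fit_model(table: pd.DataFrame, family: str, band: str, outcome: str,
              scale: bool = True) -> ModelSummary:
    """Fit one family x band x outcome OLS model on listwise-complete rows."""
    if family not in FAMILY_METRICS:
        raise ValueError(f"unknown family {family!r}")
    metrics = FAMILY_METRICS[family]
    design, y = _build_design(table, metrics, band, outcome, scale=scale)
    model_id = f"{family}:{band}:{outcome}"
    return _fit_ols(design, y, model_id, family, band, outcome)


def hat_diagonal(design: pd.DataFrame) -> np.ndarray:
    """Diagonal of the hat matrix X (X'X)^-1 X' via QR."""
    q, _ = np.linalg.qr(design.to_numpy())
    return np.sum(q ** 2, axis=1)


def leverage_filter_refit(model: ModelSummary) -> ModelSummary:
    """Remove high-leverage rows once and refit.

    A row is a leverage point when its hat diagonal exceeds 2(p+1)/n with
    p the number of non-intercept predictors.  Predictor scaling is not
    recomputed after removal; only the refit summary is reported.
    """
    if model._design is None:
        raise ValueError("model carries no design; refit from fit_model")
    design, y = model._design, model._y
    n, ncol = design.shape
    p = ncol - 1  # non-intercept predictors
    threshold = 2.0 * (p + 1) / n
    hat = hat_diagonal(design)
    keep = hat <= threshold
    n_removed = int(n - keep.sum())
    if keep.sum() <= ncol:
        raise ValueError(
            f"{model.model_id}: leverage filtering leaves too few rows")
    if n_removed == 0:
        return model
    design2 = design.loc[keep]
    y2 = pd.Series(y[keep], index=design2.index)
    return _fit_ols(design2, y2, model.model_id, model.family, model.band,
                    model.outcome, n_removed=n_removed)


def run_all_models(table: pd.DataFrame, bands=BAND_NAMES,
                   outcomes=("semantic_fluency", "letter_fluency"),
                   leverage_filter: bool = True) -> list[ModelSummary]:
    """All model families across bands and outcomes.

    Bands whose metric columns are absent are skipped with a warning; a
    full table yields 4 families x 4 bands x 2 outcomes = 32 summaries.
    """
    out: list[ModelSummary] = []
    for band in bands:
        have = any(c.startswith(f"{band}_") for c in table.columns)
        if not have:
            warnings.warn(f"no metric columns for band {band!r}; "
                          f"its models are skipped", stacklevel=2)
            continue
        for family in FAMILY_METRICS:
            for outcome in outcomes:
                try:
                    fit = fit_model(table, family, band, outcome)
                    if leverage_filter:
                        fit = leverage_filter_refit(fit)
                except ValueError as err:
                    warnings.warn(f"{family}:{band}:{outcome} not fit: "
                                  f"{err}", stacklevel=2)
                    continue
                out.append(fit)
    return out


def metrics_to_analysis_table(metrics: pd.DataFrame,
                              behaviour: pd.DataFrame) -> pd.DataFrame:
    """Join long-format metrics with the behavioural table, wide per band.

    ``metrics`` columns: subject_id, band, dwpli_mean, clustering,
    modularity, path_length, small_world.  The result has one row per
    subject with ``{band}_{measure}`` metric columns.
    """
    value_cols = [c for c in metrics.columns
                  if c not in ("subject_id", "band", "n_null")]
    wide = metrics.pivot(index="subject_id", columns="band",
                         values=value_cols)
    wide.columns = [f"{band}_{measure}" for measure, band in wide.columns]
    wide = wide.reset_index()
    return behaviour.merge(wide, on="subject_id", how="inner")
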