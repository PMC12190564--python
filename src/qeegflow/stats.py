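"""Baseline-referenced longitudinal inference and inter-rater agreement.

The primary model is a linear mixed-effects model on baseline-subtracted
global feature values (delta = value - subject baseline): time point enters
as a categorical fixed effect with NO global intercept, so each
coefficient is directly that time point's mean change from baseline; the
subject is a random intercept; estimation is REML.  Wald z tests per time
point are Benjamini-Hochberg adjusted within one metric x band family
(optionally across families).  Complementary non-parametrics: the
Friedman test across time points and exact Wilcoxon signed-rank post hocs
versus baseline.  Ordinal rater agreement uses weighted Cohen's kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .preprocess import TIMEPOINTS

NON_BASELINE = tuple(tp for tp in TIMEPOINTS if tp != "baseline")
RATING_LEVELS = (0, 1, 2)  # W < S < I
RATING_LETTERS = {"W": 0, "S": 1, "I": 2}


@dataclass
class LMMResult:
    metric: str
    band: str
    table: pd.DataFrame  # per time point: estimate, se, z, p, p_bh
    subject_var: float
    residual_var: float
    reml: bool
    converged: bool
    singular: bool


@dataclass
class TestResult:
    method: str
    statistic: float
    p: float
    n: int
    extra: dict = field(default_factory=dict)


def delta_from_baseline(
    features: pd.DataFrame, baseline: str = "baseline"
) -> pd.DataFrame:
    """Per-subject baseline-subtracted GLOBAL values.

    Returns rows (subject, timepoint != baseline, metric, band, delta);
    subjects without a baseline value are dropped for that metric.
    """
    g = features[features.channel == "GLOBAL"]
    wide = g.pivot_table(index=["subject", "metric", "band"],
                         columns="timepoint", values="value")
    if baseline not in wide.columns:
        raise ValueError("no baseline values in feature table")
    rows = []
    for (subject, metric, band), r in wide.iterrows():
        if pd.isna(r.get(baseline, np.nan)):
            continue
        for tp in r.index:
            if tp == baseline or pd.isna(r[tp]):
                continue
            rows.append((subject, tp, metric, band, r[tp] - r[baseline]))
    return pd.DataFrame(rows, columns=["subject", "timepoint", "metric", "band", "delta"])


def fit_lmm(
    delta: pd.DataFrame,
    metric: str,
    band: str,
    timepoints: tuple = NON_BASELINE,
) -> LMMResult:
    """REML mixed model: delta ~ 0 + C(timepoint) + (1 | subject)."""
    d = delta[(delta.metric == metric) & (delta.band == band)].copy()
    if d.subject.nunique() < 2 or d.timepoint.nunique() < 2:
        raise ValueError("need >= 2 subjects and >= 2 time points")
    tps = [tp for tp in timepoints if tp in set(d.timepoint)]
    exog = pd.get_dummies(pd.Categorical(d.timepoint, categories=tps), dtype=float)
    converged, singular = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(d.delta.to_numpy(), exog.to_numpy(), groups=d.subject.to_numpy())
        try:
            fit = model.fit(reml=True)
            converged = bool(fit.converged)
        except Exception:
            fit = model.fit(reml=True, method="nm", maxiter=500)
            converged = bool(fit.converged)
    subject_var = float(np.squeeze(np.asarray(fit.cov_re)))
    singular = subject_var <= 1e-12
    est = fit.fe_params
    se = fit.bse_fe
    z = est / se
    p = 2 * sps.norm.sf(np.abs(z))
    if not converged:
        p = np.full_like(p, np.nan)
    table = pd.DataFrame({
        "timepoint": tps,
        "estimate": np.asarray(est),
        "se": np.asarray(se),
        "z": np.asarray(z),
        "p": p,
    })
    table["p_bh"] = bh_adjust(table["p"].to_numpy()) if np.isfinite(p).all() else np.nan
    return LMMResult(
        metric=metric, band=band, table=table,
        subject_var=subject_var, residual_var=float(fit.scale),
        reml=True, converged=converged, singular=singular,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def friedman_test(values: np.ndarray) -> TestResult:
    """Friedman chi-square for an n-subjects x k-conditions matrix.

    chi2 = 12 / (n k (k+1)) * sum_j R_j^2 - 3 n (k+1) with average ranks
    for ties (no tie correction, so an all-tied matrix gives chi2 = 0,
    p = 1); p from the chi-square distribution with k - 1 df.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 3:
        raise ValueError("need >= 2 subjects and >= 3 conditions")
    if np.isnan(v).any():
        raise ValueError("missing cells")
    n, k = v.shape
    ranks = sps.rankdata(v, axis=1)
    rj = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * (rj ** 2).sum() - 3.0 * n * (k + 1)
    p = float(sps.chi2.sf(stat, k - 1))
    return TestResult(method="friedman", statistic=float(stat), p=p, n=n,
                      extra={"k": k, "rank_sums": rj.tolist()})


def friedman_from_features(features: pd.DataFrame, metric: str, band: str,
                           timepoints: tuple = TIMEPOINTS) -> TestResult:
    """Friedman test on GLOBAL values across all eight time points."""
    g = features[(features.channel == "GLOBAL") & (features.metric == metric)
                 & (features.band == band)]
    wide = g.pivot_table(index="subject", columns="timepoint", values="value")
    return friedman_test(wide[list(timepoints)].to_numpy())


def wilcoxon_posthoc(
    delta: pd.DataFrame, metric: str, band: str,
    timepoints: tuple = NON_BASELINE,
) -> list:
    """Exact two-sided Wilcoxon signed-rank of delta vs 0 per time point
    (zero differences dropped, Wilcoxon's rule), BH-adjusted across the
    seven time points."""
    d = delta[(delta.metric == metric) & (delta.band == band)]
    results = []
    for tp in timepoints:
        x = d.loc[d.timepoint == tp, "delta"].to_numpy()
        nz = x[x != 0]
        if nz.size == 0:
            results.append(TestResult("wilcoxon", 0.0, 1.0, 0, {"timepoint": tp}))
            continue
        stat, p = sps.wilcoxon(nz, zero_method="wilcox",
                               alternative="two-sided", method="exact")
        results.append(TestResult("wilcoxon", float(stat), float(p), nz.size,
                                  {"timepoint": tp}))
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.extra["p_bh"] = float(a)
    return results


# ---------------------------------------------------------------- ratings

def load_rating_table(path=None) -> pd.DataFrame:
    """Rating table with ordinal codes W=0 < S=1 < I=2.

    Without a path, loads the packaged six-subject qualitative EEG-change
    table (36 rated cells at 1h-1d).  Accepts letter or integer codes.
    """
    if path is None:
        src = resources.files("qeegflow") / "data" / "qualitative_ratings.csv"
        df = pd.read_csv(src.open())
    else:
        df = pd.read_csv(path)
    for col in ("rater1", "rater2", "consensus"):
        if df[col].dtype == object:
            df[col] = df[col].str.strip().map(RATING_LETTERS)
        if df[col].isna().any() or not df[col].isin(RATING_LEVELS).all():
            raise ValueError(f"invalid ordinal codes in column {col}")
    return df


def weighted_kappa(ratings: pd.DataFrame, weighting: str = "linear") -> TestResult:
    """Weighted Cohen's kappa between the two raters.

    Linear weights w_ij = 1 - |i-j|/(k-1) ("equal spacing"); quadratic
    w_ij = 1 - (|i-j|/(k-1))^2.  Chance agreement from the product of the
    raters' marginals.  Degenerate marginals (a rater at a single
    category matching the other exactly) leave kappa undefined (NaN).
    """
    if weighting not in ("linear", "quadratic"):
        raise ValueError("weighting must be 'linear' or 'quadratic'")
    r1 = ratings["rater1"].to_numpy()
    r2 = ratings["rater2"].to_numpy()
    if r1.size < 2:
        raise ValueError("need at least 2 rated cells")
    if np.array_equal(r1, r2):
        # perfect agreement, by convention 1 even when a rater used a
        # single category (the chance-corrected ratio is otherwise 0/0)
        kappa = 1.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            kappa = cohen_kappa_score(r1, r2, labels=list(RATING_LEVELS),
                                      weights=weighting)
    return TestResult(method="kappa", statistic=float(kappa), p=np.nan,
                      n=int(r1.size), extra={"weighting": weighting})
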