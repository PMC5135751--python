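"""Association analyses between genetic exposures and outcomes.

Implements the analysis scheme of the study: logistic regression of the
binary treatment response (good/moderate vs no EULAR response) or of
case/control status on continuous scores, control-referenced quartile
categories, shared-epitope status and individual markers; variance explained
(block R²) in continuous delta outcomes from linear regression; adjustment
for age, sex and five genotype principal components; stratification by ACPA
status; and the post-hoc sensitivity analyses (excluding etanercept,
restricting the evaluation window to 2-5 months, high baseline disease
activity, good-vs-none contrast).

Wald 95% confidence intervals and p-values are reported; fits with
quasi-separation or empty cells are flagged NA rather than raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binom, f as f_dist, norm

from ._logistic import fit_logistic_scan

log = logging.getLogger(__name__)

Z95 = norm.ppf(0.975)

SENSITIVITY_MODES = ("excl_etanercept", "window_2_5m", "high_das28", "good_vs_none")


@dataclass
class AssociationResult:
    """One estimated contrast (a row of a results table)."""

    exposure: str
    contrast: str
    outcome: str
    stratum: str
    estimand: str  # "OR" or "R2"
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    adjusted_for: tuple[str, ...] = ()
    note: str = ""

    @property
    def is_na(self) -> bool:
        return not np.isfinite(self.estimate)


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Tidy one-row-per-result table."""
    return pd.DataFrame(
        [
            {
                "exposure": r.exposure,
                "contrast": r.contrast,
                "outcome": r.outcome,
                "stratum": r.stratum,
                "estimand": r.estimand,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "n": r.n,
                "adjusted_for": ",".join(r.adjusted_for),
                "note": r.note,
            }
            for r in results
        ]
    )


def compute_pcs(dosage_matrix: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k principal-component scores of a column-standardized dosage matrix.

    Zero-variance markers are dropped. Sign convention: the largest-magnitude
    loading of each component is positive, which makes scores reproducible
    across equivalent runs. Raises if k exceeds the matrix rank.
    """
    x = dosage_matrix.to_numpy(dtype=float)
    sd = x.std(axis=0)
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    if k == 0:
        return pd.DataFrame(index=dosage_matrix.index)
    if k > min(x.shape):
        raise ValueError(f"k={k} exceeds rank bound {min(x.shape)}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    if k > np.sum(s > 1e-10):
        raise ValueError(f"k={k} exceeds matrix rank {int(np.sum(s > 1e-10))}")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(
        scores, index=dosage_matrix.index, columns=[f"pc{i + 1}" for i in range(k)]
    )


def _design(data: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Covariate design block with an intercept; sex dummy-coded."""
    cols = {"const": np.ones(len(data))}
    for c in covariates:
        if c == "sex":
            cols["sex_M"] = (data["sex"].astype(str) == "M").astype(float)
        else:
            cols[c] = pd.to_numeric(data[c], errors="raise").astype(float)
    return pd.DataFrame(cols, index=data.index)


def _listwise(data: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    present = [c for c in cols if c in data.columns]
    return data.dropna(subset=present)


def _na_result(**kw) -> AssociationResult:
    return AssociationResult(
        estimate=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan, **kw
    )


def _fit_logit(y: np.ndarray, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray] | None:
    """statsmodels Logit fit; None on separation / non-convergence."""
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return None
    if not res.mle_retvals.get("converged", False):
        return None
    se = res.bse.to_numpy() if hasattr(res.bse, "to_numpy") else np.asarray(res.bse)
    if np.any(~np.isfinite(se)) or np.any(se > 100) or np.any(np.abs(res.params) > 25):
        return None
    return np.asarray(res.params), se


def logistic_assoc(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
    stratum: str = "overall",
    categorical: bool = False,
    reference: str | None = None,
    per_sd: bool = False,
) -> list[AssociationResult]:
    """Logistic association of a binary outcome with one exposure.

    Continuous exposures yield a single per-unit (or, with ``per_sd=True``,
    per-SD) odds ratio. Categorical exposures are dummy-coded against
    ``reference`` (default: first category in sorted order), one result per
    contrast. Strata with only one outcome level, empty cells or separation
    give NA-flagged results.
    """
    use_cols = [outcome, exposure, *covariates]
    df = _listwise(data, use_cols)
    y = pd.to_numeric(df[outcome], errors="raise").to_numpy(dtype=float)
    base_kw = dict(exposure=exposure, outcome=outcome, stratum=stratum, estimand="OR")
    adj = tuple(covariates)
    if len(df) == 0 or len(np.unique(y)) < 2:
        contrast = "linear" if not categorical else "all"
        return [
            _na_result(contrast=contrast, n=len(df), adjusted_for=adj, note="empty_stratum", **base_kw)
        ]

    X = _design(df, covariates)
    if not categorical:
        x = pd.to_numeric(df[exposure], errors="raise").to_numpy(dtype=float)
        label = "linear"
        if per_sd:
            sd = x.std(ddof=0)
            if sd == 0:
                return [_na_result(contrast="per-SD", n=len(df), adjusted_for=adj, note="constant_exposure", **base_kw)]
            x = (x - x.mean()) / sd
            label = "per-SD"
        X[exposure] = x
        fit = _fit_logit(y, X)
        if fit is None:
            return [_na_result(contrast=label, n=len(df), adjusted_for=adj, note="separation", **base_kw)]
        params, se = fit
        b, s = params[-1], se[-1]
        return [
            AssociationResult(
                contrast=label,
                estimate=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * s)),
                ci_high=float(np.exp(b + Z95 * s)),
                p=float(2 * norm.sf(abs(b / s))),
                n=len(df),
                adjusted_for=adj,
                **base_kw,
            )
        ]

    col = df[exposure]
    if isinstance(col.dtype, pd.CategoricalDtype):
        levels = [str(l) for l in col.cat.categories]
    else:
        levels = sorted(col.astype(str).unique())
    ref = str(reference) if reference is not None else levels[0]
    if ref not in levels:
        raise ValueError(f"reference {ref!r} not among exposure levels {levels}")
    observed = set(col.astype(str).unique())
    others = [l for l in levels if l != ref]
    estimable = [l for l in others if l in observed] if ref in observed else []
    fit = None
    if estimable:
        dummies = pd.get_dummies(col.astype(str))[estimable].astype(float)
        X = pd.concat([X, dummies.set_axis(X.index)], axis=1)
        fit = _fit_logit(y, X)
    out = []
    for lev in others:
        contrast = f"{lev}-vs-{ref}"
        if lev not in estimable:
            out.append(_na_result(contrast=contrast, n=len(df), adjusted_for=adj,
                                  note="empty_cell", **base_kw))
            continue
        if fit is None:
            out.append(_na_result(contrast=contrast, n=len(df), adjusted_for=adj, note="separation", **base_kw))
            continue
        i = estimable.index(lev)
        params, se = fit
        b = params[len(params) - len(estimable) + i]
        s = se[len(params) - len(estimable) + i]
        out.append(
            AssociationResult(
                contrast=contrast,
                estimate=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * s)),
                ci_high=float(np.exp(b + Z95 * s)),
                p=float(2 * norm.sf(abs(b / s))),
                n=len(df),
                adjusted_for=adj,
                **base_kw,
            )
        )
    return out


def linear_r2(
    data: pd.DataFrame,
    outcome: str,
    exposure_block: Sequence[str],
    covariates: Sequence[str] = (),
    stratum: str = "overall",
) -> AssociationResult:
    """Variance in a continuous outcome explained by an exposure block.

    Reports the block R² — the increase in R² when the exposures are added
    to the covariate-only model — with the F-test p-value for the block.
    With no covariates and a single exposure this equals the squared Pearson
    correlation. Collinear block columns are dropped (aliased), logged.
    """
    block = list(exposure_block)
    df = _listwise(data, [outcome, *block, *covariates])
    base_kw = dict(
        exposure="+".join(block), contrast="block", outcome=outcome, stratum=stratum, estimand="R2"
    )
    adj = tuple(covariates)
    y = pd.to_numeric(df[outcome], errors="raise").to_numpy(dtype=float)
    Xc = _design(df, covariates)
    Xf = Xc.copy()
    for c in block:
        Xf[c] = pd.to_numeric(df[c], errors="raise").to_numpy(dtype=float)
    # drop aliased block columns
    rank = np.linalg.matrix_rank(Xf.to_numpy())
    if rank < Xf.shape[1]:
        keep, cols = [], Xc.shape[1]
        cur = Xc.to_numpy()
        for c in block:
            cand = np.column_stack([cur, Xf[c].to_numpy()])
            if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(cur):
                cur = cand
                keep.append(c)
            else:
                log.info("linear_r2: dropping aliased exposure column %r", c)
        Xf = pd.concat([Xc, Xf[keep]], axis=1)
        block = keep
    n_params = Xf.shape[1]
    if len(df) <= n_params or not block:
        return _na_result(n=len(df), adjusted_for=adj, note="insufficient_data", **base_kw)
    full = sm.OLS(y, Xf).fit()
    red = sm.OLS(y, Xc).fit()
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return _na_result(n=len(df), adjusted_for=adj, note="constant_outcome", **base_kw)
    r2_block = float(red.ssr - full.ssr) / tss
    df_num = len(block)
    df_den = len(df) - n_params
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(f_dist.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else np.nan
    return AssociationResult(
        estimate=r2_block,
        ci_low=np.nan,
        ci_high=np.nan,
        p=p,
        n=len(df),
        adjusted_for=adj,
        **base_kw,
    )


@dataclass
class ScanSummary:
    """Chance-expectation summary for a family of individual-marker tests."""

    family: str
    n_tests: int
    n_significant: int  # raw p < 0.05
    band_low: int
    band_high: int

    @property
    def within_band(self) -> bool:
        return self.band_low <= self.n_significant <= self.band_high


def binomial_band(n_tests: int, alpha: float = 0.05, coverage: float = 0.95) -> tuple[int, int]:
    """Central `coverage` interval of Binomial(n_tests, alpha)."""
    if n_tests == 0:
        return (0, 0)
    lo = int(binom.ppf((1 - coverage) / 2, n_tests, alpha))
    hi = int(binom.ppf(1 - (1 - coverage) / 2, n_tests, alpha))
    return lo, hi


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaN-safe)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps)
    adj = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def scan_individual(
    data: pd.DataFrame,
    exposures: Sequence[str],
    outcome: str,
    covariates: Sequence[str] = (),
    stratum: str = "overall",
    family: str = "markers",
) -> tuple[list[AssociationResult], ScanSummary]:
    """Per-marker logistic associations plus an expected-by-chance summary.

    Each exposure column (dosage 0/1/2 or residue dosage) is tested in its
    own adjusted logistic model via the batched fitter. Results carry raw
    Wald p-values and a Benjamini-Hochberg FDR within the family (stored in
    the note field as ``fdr=``); the summary counts raw p < 0.05 against the
    central 95% Binomial(n_tests, 0.05) band.
    """
    exposures = list(exposures)
    if not exposures:
        return [], ScanSummary(family=family, n_tests=0, n_significant=0, band_low=0, band_high=0)
    df = _listwise(data, [outcome, *covariates])
    y = pd.to_numeric(df[outcome], errors="raise").to_numpy(dtype=float)
    adj = tuple(covariates)
    if len(df) == 0 or len(np.unique(y)) < 2:
        results = [
            _na_result(
                exposure=e, contrast="per-copy", outcome=outcome, stratum=stratum,
                estimand="OR", n=len(df), adjusted_for=adj, note="empty_stratum",
            )
            for e in exposures
        ]
        return results, ScanSummary(family=family, n_tests=len(exposures), n_significant=0,
                                    band_low=0, band_high=0)
    X = _design(df, covariates).to_numpy(dtype=float)
    g = df[exposures].to_numpy(dtype=float)
    fit = fit_logistic_scan(y, X, g)
    fdr = bh_fdr(fit.p)
    results = []
    for j, e in enumerate(exposures):
        kw = dict(exposure=e, contrast="per-copy", outcome=outcome, stratum=stratum, estimand="OR")
        if not fit.converged[j]:
            results.append(_na_result(n=len(df), adjusted_for=adj, note=str(fit.note[j]), **kw))
            continue
        b, s = fit.beta[j], fit.se[j]
        results.append(
            AssociationResult(
                estimate=float(np.exp(b)),
                ci_low=float(np.exp(b - Z95 * s)),
                ci_high=float(np.exp(b + Z95 * s)),
                p=float(fit.p[j]),
                n=len(df),
                adjusted_for=adj,
                note=f"fdr={fdr[j]:.4g}",
                **kw,
            )
        )
    n_sig = int(np.nansum(fit.p < 0.05))
    lo, hi = binomial_band(len(exposures))
    summary = ScanSummary(
        family=family, n_tests=len(exposures), n_significant=n_sig, band_low=lo, band_high=hi
    )
    return results, summary


def apply_sensitivity_filter(data: pd.DataFrame, mode: str) -> tuple[pd.DataFrame, str]:
    """Filter/redefine the analysis table for a sensitivity mode.

    Returns the filtered table and the outcome column to analyse
    (``response`` except for good_vs_none, which restricts to good/none
    subjects and contrasts good vs none).
    """
    if mode not in SENSITIVITY_MODES:
        raise ValueError(f"unknown sensitivity mode {mode!r}; choose from {SENSITIVITY_MODES}")
    if mode == "excl_etanercept":
        return data[data["drug"] != "etanercept"], "response"
    if mode == "window_2_5m":
        return data[(data["eval_day"] >= 60) & (data["eval_day"] <= 150)], "response"
    if mode == "high_das28":
        return data[data["das28_baseline"] > 5.1], "response"
    sub = data[data["eular"].isin(["good", "none"])].copy()
    sub["response_good"] = (sub["eular"] == "good").astype(int)
    return sub, "response_good"


def run_sensitivity(
    data: pd.DataFrame,
    mode: str,
    exposures: Sequence[str],
    covariates: Sequence[str] = (),
    quartile_exposures: Sequence[str] = (),
) -> list[AssociationResult]:
    """Re-estimate the main response contrasts on a sensitivity-filtered sample."""
    sub, outcome = apply_sensitivity_filter(data, mode)
    out: list[AssociationResult] = []
    for e in exposures:
        out.extend(
            logistic_assoc(sub, outcome, e, covariates, stratum=mode, per_sd=True)
        )
    for e in quartile_exposures:
        out.extend(
            logistic_assoc(
                sub, outcome, e, covariates, stratum=mode, categorical=True, reference="Q1"
            )
        )
    return out
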