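"""Genome-wide polygenic p-value-threshold scan.

Estimates per-SNP disease associations in the full case-control sample,
builds genetic risk scores from the SNPs passing each of a nested series of
association p-value thresholds (weights = the lnORs from the disease scan,
never from the response data), and profiles the variance explained in each
treatment-response delta outcome by the score at each threshold.

By design the scan weights are estimated in the same case-control sample
they are applied to, mirroring the in-sample design of the source analysis;
this overfits the *disease* R² but is irrelevant for the *response* R²,
since the response outcome plays no role in the weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._logistic import fit_logistic_scan
from .association import _design, linear_r2

log = logging.getLogger(__name__)

#: Nested thresholds: genome-wide significance, moderate association, all markers.
DEFAULT_THRESHOLDS: tuple[float, ...] = (5e-8, 5e-4, 5e-3, 5e-2, 1.0)


@dataclass
class DiseaseScan:
    """Per-SNP case-control logistic fit results."""

    table: pd.DataFrame  # index snp_id: lnor, se, p, note
    adjusted_for: tuple[str, ...] = ()

    @property
    def excluded(self) -> pd.Index:
        return self.table.index[self.table["lnor"].isna()]


@dataclass
class ThresholdScan:
    """Score matrix and R² profile of the threshold series."""

    thresholds: tuple[float, ...]
    snp_sets: dict[float, list[str]] = field(default_factory=dict)
    scores: pd.DataFrame | None = None  # subjects x thresholds
    profile: pd.DataFrame | None = None  # threshold, outcome, r2, p, n


def disease_scan(
    dosages: pd.DataFrame,
    is_case: Sequence[bool],
    covariate_frame: pd.DataFrame | None = None,
    covariates: Sequence[str] = (),
) -> DiseaseScan:
    """Additive per-SNP logistic case/control scan.

    Monomorphic or non-convergent SNPs get NA estimates and are logged;
    they are excluded from downstream score building.
    """
    y = np.asarray(is_case, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("disease_scan requires both cases and controls")
    if covariate_frame is not None and covariates:
        X = _design(covariate_frame.loc[dosages.index], covariates).to_numpy(dtype=float)
    else:
        X = np.ones((len(dosages), 1))
        covariates = ()
    fit = fit_logistic_scan(y, X, dosages.to_numpy(dtype=float))
    table = pd.DataFrame(
        {"lnor": fit.beta, "se": fit.se, "p": fit.p, "note": fit.note},
        index=pd.Index(dosages.columns, name="snp_id"),
    )
    n_na = int(table["lnor"].isna().sum())
    if n_na:
        log.info("disease_scan: %d of %d SNPs NA-flagged (%s)", n_na, len(table),
                 ", ".join(sorted(set(table.loc[table['lnor'].isna(), 'note']))))
    return DiseaseScan(table=table, adjusted_for=tuple(covariates))


def build_threshold_scores(
    scan: DiseaseScan,
    dosages: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> ThresholdScan:
    """Per-subject score at each threshold: Σ over SNPs with p < t of lnOR·dosage.

    SNP sets are nested across increasing thresholds by construction. NA
    SNPs from the scan never enter any score.
    """
    thresholds = tuple(thresholds)
    if not thresholds:
        raise ValueError("threshold list is empty")
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    tbl = scan.table.loc[scan.table["lnor"].notna()]
    tbl = tbl.loc[tbl.index.intersection(dosages.columns)]
    out = ThresholdScan(thresholds=thresholds)
    scores = {}
    for t in thresholds:
        sel = tbl.index[tbl["p"] < t].tolist()
        out.snp_sets[t] = sel
        if sel:
            scores[t] = dosages[sel].to_numpy(dtype=float) @ tbl.loc[sel, "lnor"].to_numpy()
        else:
            scores[t] = np.zeros(len(dosages))
    out.scores = pd.DataFrame(scores, index=dosages.index)
    return out


def r2_profile(
    scan: ThresholdScan,
    outcome_table: pd.DataFrame,
    delta_outcomes: Sequence[str],
    covariates: Sequence[str] = (),
) -> ThresholdScan:
    """Variance in each delta outcome explained by the score at each threshold.

    Joins scores and outcomes on subject id; outcomes that are entirely
    missing are omitted with a log entry. Returns the same ThresholdScan
    with its profile table filled in.
    """
    if scan.scores is None:
        raise ValueError("run build_threshold_scores first")
    df = outcome_table.set_index("subject_id") if "subject_id" in outcome_table.columns else outcome_table
    common = scan.scores.index.intersection(df.index)
    rows = []
    for outcome in delta_outcomes:
        if outcome not in df.columns or df.loc[common, outcome].notna().sum() == 0:
            log.info("r2_profile: outcome %r all-missing, omitted", outcome)
            continue
        for t in scan.thresholds:
            merged = df.loc[common].copy()
            merged["_score"] = scan.scores.loc[common, t]
            if merged["_score"].std(ddof=0) == 0:
                # empty SNP set (threshold below the smallest scan p-value):
                # a constant score explains no variance
                rows.append(
                    {"threshold": t, "outcome": outcome, "r2": 0.0, "p": np.nan,
                     "n": int(merged[outcome].notna().sum())}
                )
                continue
            res = linear_r2(merged, outcome, ["_score"], covariates)
            rows.append(
                {"threshold": t, "outcome": outcome, "r2": res.estimate, "p": res.p, "n": res.n}
            )
    scan.profile = pd.DataFrame(rows)
    return scan


def plot_profile(profile: pd.DataFrame, path: str) -> None:
    """Dot plot of R² against the score p-value threshold, per outcome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for outcome, sub in profile.groupby("outcome"):
        sub = sub.sort_values("threshold")
        ax.plot(np.log10(sub["threshold"]), sub["r2"], "o-", label=outcome, alpha=0.8)
    ax.set_xlabel("log10 p-value threshold of SNP inclusion")
    ax.set_ylabel(r"$R^2$ in disease-activity change")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
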