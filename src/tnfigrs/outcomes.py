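"""Treatment-response outcome derivation.

From a longitudinal visit table this module selects the baseline visit
(within ±7 days of treatment start) and the evaluation visit (2-8 months
after start, closest to 5 months among visits with complete DAS28 data),
computes the 4-variable DAS28-ESR, classifies the EULAR response
(good / moderate / none), and forms the eight change-from-baseline outcomes
(ΔDAS28, ΔCRP, ΔESR, ΔSJC, ΔTJC, ΔVAS-global, ΔVAS-pain, ΔHAQ), with
improvement negative by the evaluation − baseline convention.

The DAS28-ESR form is used because the register records ESR at every visit
and it is the Swedish standard; CRP is kept as a separate delta outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: delta outcome name → visit column (DAS28 handled separately).
DELTA_MEASURES: dict[str, str] = {
    "DAS28": "das28",
    "CRP": "crp",
    "ESR": "esr",
    "SJC": "sjc28",
    "TJC": "tjc28",
    "VASglobal": "vas_global",
    "VASpain": "vas_pain",
    "HAQ": "haq",
}

#: columns that must be present and non-missing for a valid DAS28.
DAS28_COMPONENTS = ("tjc28", "sjc28", "esr", "vas_global")

VISIT_COLUMNS = (
    "subject_id",
    "days_since_treatment_start",
    "drug",
    "tjc28",
    "sjc28",
    "esr",
    "crp",
    "vas_global",
    "vas_pain",
    "haq",
)


def das28(tjc28, sjc28, esr, vas_global):
    """4-variable DAS28-ESR.

    DAS28 = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.70*ln(ESR) + 0.014*GH

    Accepts scalars or arrays; NaN components propagate to NaN. Raises
    ValueError for ESR <= 0 (log undefined) or joint counts outside [0, 28]
    or VAS outside [0, 100].
    """
    t = np.asarray(tjc28, dtype=float)
    s = np.asarray(sjc28, dtype=float)
    e = np.asarray(esr, dtype=float)
    g = np.asarray(vas_global, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((t < 0) | (t > 28)) or np.any((s < 0) | (s > 28)):
            raise ValueError("joint counts must be within [0, 28]")
        if np.any(e <= 0):
            raise ValueError("ESR must be > 0 (ln undefined)")
        if np.any((g < 0) | (g > 100)):
            raise ValueError("VAS global must be within [0, 100]")
    out = 0.56 * np.sqrt(t) + 0.28 * np.sqrt(s) + 0.70 * np.log(e) + 0.014 * g
    return out.item() if np.isscalar(tjc28) and np.isscalar(esr) else out


def eular_response(das28_baseline, das28_eval):
    """EULAR response class from baseline and attained DAS28.

    With improvement Δ = baseline − eval:
      good:     Δ > 1.2 and eval ≤ 3.2
      none:     Δ ≤ 0.6, or (Δ ≤ 1.2 and eval > 5.1)
      moderate: otherwise
    Boundary conventions (Δ > 1.2 strict, eval ≤ 3.2 inclusive, eval > 5.1
    strict) follow the published criterion. NaN input raises ValueError.
    """
    b = np.asarray(das28_baseline, dtype=float)
    e = np.asarray(das28_eval, dtype=float)
    if np.any(~np.isfinite(b)) or np.any(~np.isfinite(e)):
        raise ValueError("DAS28 values must be finite for EULAR classification")
    imp = b - e
    good = (imp > 1.2) & (e <= 3.2)
    none = (imp <= 0.6) | ((imp <= 1.2) & (e > 5.1))
    out = np.where(good, "good", np.where(none, "none", "moderate"))
    if b.ndim == 0:
        return out.item()
    return out


@dataclass
class VisitSelection:
    """Per-subject baseline/evaluation rows plus the exclusion log."""

    baseline: pd.DataFrame
    evaluation: pd.DataFrame
    excluded: pd.DataFrame  # columns: subject_id, reason


def select_visits(
    visits: pd.DataFrame,
    window_days: tuple[int, int] = (60, 240),
    target_day: int = 150,
    baseline_tolerance: int = 7,
) -> VisitSelection:
    """Select baseline and evaluation visits for each subject.

    baseline: the visit with |day| <= baseline_tolerance, ties broken by
    smaller |day| then by earlier day. evaluation: among follow-up visits in
    the window with all four DAS28 components non-missing (and ESR > 0), the
    one minimizing |day − target_day|, ties broken by the earlier visit.
    Subjects lacking either visit are excluded (returned, and logged), not
    an error. The result is independent of input row order.
    """
    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise ValueError(f"visit table missing columns: {sorted(missing)}")
    day = pd.to_numeric(visits["days_since_treatment_start"], errors="raise")
    if not np.all(np.isfinite(day.to_numpy(dtype=float))):
        raise ValueError("malformed days_since_treatment_start values")
    v = visits.copy()
    v["days_since_treatment_start"] = day.astype(int)

    base_cand = v[v["days_since_treatment_start"].abs() <= baseline_tolerance].copy()
    base_cand["_absday"] = base_cand["days_since_treatment_start"].abs()
    base_cand = base_cand.sort_values(
        ["subject_id", "_absday", "days_since_treatment_start"], kind="mergesort"
    )
    baseline = base_cand.groupby("subject_id", sort=True).head(1).drop(columns="_absday")

    lo, hi = window_days
    valid = np.ones(len(v), dtype=bool)
    for col in DAS28_COMPONENTS:
        x = pd.to_numeric(v[col], errors="coerce")
        valid &= x.notna().to_numpy()
    valid &= pd.to_numeric(v["esr"], errors="coerce").fillna(0).to_numpy() > 0
    in_window = (v["days_since_treatment_start"] >= lo) & (v["days_since_treatment_start"] <= hi)
    eval_cand = v[valid & in_window.to_numpy()].copy()
    eval_cand["_dist"] = (eval_cand["days_since_treatment_start"] - target_day).abs()
    eval_cand = eval_cand.sort_values(
        ["subject_id", "_dist", "days_since_treatment_start"], kind="mergesort"
    )
    evaluation = eval_cand.groupby("subject_id", sort=True).head(1).drop(columns="_dist")

    all_subjects = pd.Index(sorted(v["subject_id"].unique()))
    have_base = pd.Index(baseline["subject_id"])
    have_eval = pd.Index(evaluation["subject_id"])
    keep = have_base.intersection(have_eval)
    reasons = []
    for sid in all_subjects.difference(keep):
        why = []
        if sid not in have_base:
            why.append("no baseline visit within tolerance")
        if sid not in have_eval:
            why.append("no valid evaluation visit in window")
        reasons.append((sid, "; ".join(why)))
    excluded = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    if len(excluded):
        log.info("select_visits: excluded %d of %d subjects", len(excluded), len(all_subjects))
    baseline = baseline[baseline["subject_id"].isin(keep)].reset_index(drop=True)
    evaluation = evaluation[evaluation["subject_id"].isin(keep)].reset_index(drop=True)
    return VisitSelection(baseline=baseline, evaluation=evaluation, excluded=excluded)


def compute_deltas(baseline_row: pd.Series, eval_row: pd.Series) -> dict[str, float]:
    """Change-from-baseline map (evaluation − baseline) for the 8 measures.

    DAS28 is derived from the component columns of each row. A measure
    missing in either row yields a missing (NaN) delta, logged.
    """
    if baseline_row.get("subject_id") != eval_row.get("subject_id"):
        raise ValueError("baseline and evaluation rows must belong to the same subject")
    rows = {}
    for which, row in (("baseline", baseline_row), ("eval", eval_row)):
        r = row.copy()
        try:
            r["das28"] = das28(r["tjc28"], r["sjc28"], r["esr"], r["vas_global"])
        except (ValueError, KeyError):
            r["das28"] = np.nan
        rows[which] = r
    deltas = {}
    for name, col in DELTA_MEASURES.items():
        b = rows["baseline"].get(col, np.nan)
        e = rows["eval"].get(col, np.nan)
        d = float(e) - float(b) if pd.notna(b) and pd.notna(e) else np.nan
        if np.isnan(d):
            log.info("missing delta %s for subject %s", name, baseline_row.get("subject_id"))
        deltas[name] = d
    return deltas


def derive_outcomes(
    visits: pd.DataFrame,
    window_days: tuple[int, int] = (60, 240),
    target_day: int = 150,
    baseline_tolerance: int = 7,
) -> pd.DataFrame:
    """Full response-outcome table, one row per evaluable subject.

    Columns: subject_id, drug, baseline_day, eval_day, das28_baseline,
    das28_eval, eular, response (good/moderate=1 vs none=0) and the eight
    d_* delta outcomes. Subjects without a valid baseline or evaluation
    visit are excluded (see select_visits).
    """
    sel = select_visits(visits, window_days, target_day, baseline_tolerance)
    base = sel.baseline.set_index("subject_id")
    ev = sel.evaluation.set_index("subject_id")
    idx = base.index

    def _das(df: pd.DataFrame) -> pd.Series:
        return pd.Series(
            das28(df["tjc28"].to_numpy(float), df["sjc28"].to_numpy(float),
                  df["esr"].to_numpy(float), df["vas_global"].to_numpy(float)),
            index=df.index,
        )

    d0 = _das(base.loc[idx])
    d1 = _das(ev.loc[idx])
    out = pd.DataFrame(index=idx)
    out["drug"] = base["drug"]
    out["baseline_day"] = base["days_since_treatment_start"].astype(int)
    out["eval_day"] = ev.loc[idx, "days_since_treatment_start"].astype(int)
    out["das28_baseline"] = d0
    out["das28_eval"] = d1
    out["eular"] = eular_response(d0.to_numpy(), d1.to_numpy())
    out["response"] = (out["eular"] != "none").astype(int)
    for name, col in DELTA_MEASURES.items():
        if name == "DAS28":
            out["d_DAS28"] = d1 - d0
        else:
            b = pd.to_numeric(base.loc[idx, col], errors="coerce")
            e = pd.to_numeric(ev.loc[idx, col], errors="coerce")
            out[f"d_{name}"] = e - b
    return out.reset_index().rename(columns={"index": "subject_id"})
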