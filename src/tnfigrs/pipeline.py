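"""End-to-end pipeline: simulate → score → outcomes → associate → polygenic.

Produces an artifact directory with the cohort files, the per-subject risk
score panel, the derived response outcomes, tidy association tables (the
disease-risk, response, haplotype and variance-explained analyses), the
polygenic threshold profile with its plot, and a provenance log with package
versions and the seed. Reruns with the same config are numerically identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import association, grs, hla, io, outcomes, polygenic
from .association import (
    AssociationResult,
    logistic_assoc,
    linear_r2,
    results_frame,
    run_sensitivity,
    scan_individual,
)
from .config import SimulationConfig
from .synthetic_cohort import Cohort, SimulatedStudy, generate_cohort

log = logging.getLogger(__name__)

RESPONSE_STRATA = ("overall", "ACPA+", "ACPA-")
DELTA_COLUMNS = tuple(f"d_{m}" for m in outcomes.DELTA_MEASURES)
GRS_AA_BLOCK = ("grs_snp", "grs_pos11", "grs_pos13", "grs_pos71", "grs_pos74", "se_copies")


@dataclass
class AnalysisConfig:
    """Outcome-derivation and association settings."""

    window_days: tuple[int, int] = (60, 240)
    target_day: int = 150
    baseline_tolerance: int = 7
    n_pcs: int = 5
    adjust: tuple[str, ...] = ("age", "sex")  # PCs appended per n_pcs
    sensitivity: tuple[str, ...] = ("excl_etanercept", "window_2_5m", "high_das28", "good_vs_none")
    thresholds: tuple[float, ...] = polygenic.DEFAULT_THRESHOLDS
    reference_haplotype: str = "PRAA"
    min_haplotype_carriers: int = 10


@dataclass
class RunConfig:
    """Single-YAML pipeline configuration. Unknown keys are rejected."""

    seed: int = 0
    mode: str = "simulate"  # or "files"
    cohort_dir: str | None = None  # required in files mode
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and not self.cohort_dir:
            raise ValueError("mode='files' requires cohort_dir")

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs = dict(data)
        sim = kwargs.get("simulation", {})
        if isinstance(sim, Mapping):
            sim = dict(sim)
            sim.setdefault("seed", kwargs.get("seed", 0))
            kwargs["simulation"] = SimulationConfig.from_dict(sim)
        ana = kwargs.get("analysis", {})
        if isinstance(ana, Mapping):
            aknown = {f.name for f in fields(AnalysisConfig)}
            aunknown = set(ana) - aknown
            if aunknown:
                raise ValueError(f"unknown analysis keys: {sorted(aunknown)}")
            ana = dict(ana)
            for key in ("window_days", "adjust", "sensitivity", "thresholds"):
                if key in ana and isinstance(ana[key], list):
                    ana[key] = tuple(ana[key])
            kwargs["analysis"] = AnalysisConfig(**ana)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


def haplotype_copy_columns(cohort: Cohort) -> pd.DataFrame:
    """Per-haplotype carried-copy counts (0/1/2), one column per haplotype."""
    subj = cohort.subjects
    haps = sorted(set(subj["hap1"]) | set(subj["hap2"]))
    out = {}
    for h in haps:
        out[f"hap_{h}"] = (subj["hap1"] == h).astype(int) + (subj["hap2"] == h).astype(int)
    return pd.DataFrame(out, index=subj.index)


def build_response_table(
    cohort: Cohort,
    scores: pd.DataFrame,
    outcome_table: pd.DataFrame,
    n_pcs: int = 5,
) -> pd.DataFrame:
    """Analysis table for treatment-response models.

    One row per evaluable treated patient with outcome columns, scores,
    quartiles, SE status, haplotype copies, demographics, ACPA status and
    principal components computed from the genotypes of the treated sample
    (genome-wide panel when available, candidate SNPs otherwise).
    """
    out = outcome_table.set_index("subject_id")
    treated = out.index
    subj = cohort.subjects.loc[treated]
    df = pd.concat([out, scores.loc[treated], haplotype_copy_columns(cohort).loc[treated]], axis=1)
    df["age"] = subj["age"]
    df["sex"] = subj["sex"]
    df["acpa_positive"] = subj["acpa_positive"]
    df["any_se"] = (df["se_copies"] >= 1).astype(int)
    geno = cohort.panel_dosages if cohort.panel_dosages is not None else cohort.snp_dosages
    if n_pcs:
        pcs = association.compute_pcs(geno.loc[treated], k=n_pcs)
        df = pd.concat([df, pcs], axis=1)
    return df


def build_disease_table(cohort: Cohort, scores: pd.DataFrame, n_pcs: int = 5) -> pd.DataFrame:
    """Analysis table for case/control (disease-risk) models."""
    subj = cohort.subjects
    df = pd.concat([subj[["is_case", "acpa_positive", "age", "sex"]], scores], axis=1)
    df["is_case"] = df["is_case"].astype(int)
    geno = cohort.panel_dosages if cohort.panel_dosages is not None else cohort.snp_dosages
    if n_pcs:
        df = pd.concat([df, association.compute_pcs(geno, k=n_pcs)], axis=1)
    return df


def _stratify(df: pd.DataFrame, stratum: str, disease: bool = False) -> pd.DataFrame:
    if stratum == "overall":
        return df
    want = stratum == "ACPA+"
    acpa = df["acpa_positive"]
    if disease:
        # ACPA-stratified disease risk: the ACPA subset of cases vs all controls
        keep = (df["is_case"] == 0) | (acpa.notna() & (acpa.astype("boolean") == want))
    else:
        keep = acpa.notna() & (acpa.astype("boolean") == want)
    return df[keep.astype(bool)]


def covariate_list(analysis: AnalysisConfig) -> list[str]:
    return list(analysis.adjust) + [f"pc{i + 1}" for i in range(analysis.n_pcs)]


def disease_association_tables(
    disease_df: pd.DataFrame, analysis: AnalysisConfig
) -> pd.DataFrame:
    """Disease-risk analogues: linear (per-SD) and quartile ORs per score and stratum."""
    cov = covariate_list(analysis)
    rows: list[AssociationResult] = []
    for stratum in RESPONSE_STRATA:
        sub = _stratify(disease_df, stratum, disease=True)
        for score, qcol in (("grs_snp", "q_grs_snp"), ("grs_haplotype", "q_grs_haplotype")):
            rows.extend(logistic_assoc(sub, "is_case", score, cov, stratum=stratum, per_sd=True))
            rows.extend(
                logistic_assoc(
                    sub, "is_case", qcol, cov, stratum=stratum, categorical=True, reference="Q1"
                )
            )
    return results_frame(rows)


def response_association_tables(
    response_df: pd.DataFrame, analysis: AnalysisConfig
) -> pd.DataFrame:
    """Response analogues: per-SD and quartile GRS ORs plus any-SE, per stratum."""
    cov = covariate_list(analysis)
    rows: list[AssociationResult] = []
    for stratum in RESPONSE_STRATA:
        sub = _stratify(response_df, stratum)
        for score, qcol in (("grs_snp", "q_grs_snp"), ("grs_haplotype", "q_grs_haplotype")):
            rows.extend(logistic_assoc(sub, "response", score, cov, stratum=stratum, per_sd=True))
            rows.extend(
                logistic_assoc(
                    sub, "response", qcol, cov, stratum=stratum, categorical=True, reference="Q1"
                )
            )
        rows.extend(logistic_assoc(sub, "response", "any_se", cov, stratum=stratum))
    return results_frame(rows)


def haplotype_association_table(
    response_df: pd.DataFrame, analysis: AnalysisConfig
) -> pd.DataFrame:
    """Individual-haplotype response ORs against the reference haplotype.

    All non-reference haplotype copy counts enter one joint logistic model;
    haplotypes with fewer carriers than ``min_haplotype_carriers`` in the
    stratum are NA-flagged (sparse cells), mirroring register-scale tables.
    """
    cov = covariate_list(analysis)
    ref = analysis.reference_haplotype
    hap_cols = sorted(c for c in response_df.columns if c.startswith("hap_"))
    rows: list[AssociationResult] = []
    for stratum in RESPONSE_STRATA:
        sub = _stratify(response_df, stratum)
        usable, sparse = [], []
        for c in hap_cols:
            if c == f"hap_{ref}":
                continue
            (sparse, usable)[int((sub[c] > 0).sum() >= analysis.min_haplotype_carriers)].append(c)
        for c in sparse:
            rows.append(
                association._na_result(
                    exposure=c.removeprefix("hap_"),
                    contrast=f"per-copy-vs-{ref}",
                    outcome="response",
                    stratum=stratum,
                    estimand="OR",
                    n=int(len(sub)),
                    adjusted_for=tuple(cov),
                    note="sparse_cell",
                )
            )
        if not usable or sub["response"].nunique() < 2:
            for c in usable:
                rows.append(
                    association._na_result(
                        exposure=c.removeprefix("hap_"), contrast=f"per-copy-vs-{ref}",
                        outcome="response", stratum=stratum, estimand="OR",
                        n=int(len(sub)), adjusted_for=tuple(cov), note="empty_stratum",
                    )
                )
            continue
        X = association._design(sub, cov)
        for c in usable:
            X[c] = sub[c].astype(float)
        fit = association._fit_logit(sub["response"].to_numpy(dtype=float), X)
        q = X.shape[1] - len(usable)
        for i, c in enumerate(usable):
            kw = dict(
                exposure=c.removeprefix("hap_"), contrast=f"per-copy-vs-{ref}",
                outcome="response", stratum=stratum, estimand="OR",
            )
            if fit is None:
                rows.append(association._na_result(n=len(sub), adjusted_for=tuple(cov),
                                                   note="separation", **kw))
                continue
            params, se = fit
            b, s = params[q + i], se[q + i]
            from scipy.stats import norm

            rows.append(
                AssociationResult(
                    estimate=float(np.exp(b)),
                    ci_low=float(np.exp(b - association.Z95 * s)),
                    ci_high=float(np.exp(b + association.Z95 * s)),
                    p=float(2 * norm.sf(abs(b / s))),
                    n=len(sub),
                    adjusted_for=tuple(cov),
                    **kw,
                )
            )
    return results_frame(rows)


def r2_association_tables(response_df: pd.DataFrame, analysis: AnalysisConfig) -> pd.DataFrame:
    """Variance-explained analogues: block R² of the SNP GRS alone and of the
    SNP GRS + amino-acid scores + SE block, per delta outcome and stratum."""
    cov = covariate_list(analysis)
    rows: list[AssociationResult] = []
    blocks = {"grs_snp": ["grs_snp"], "grs_snp+grs_aa+se": list(GRS_AA_BLOCK)}
    for stratum in RESPONSE_STRATA:
        sub = _stratify(response_df, stratum)
        for label, block in blocks.items():
            for d in DELTA_COLUMNS:
                r = linear_r2(sub, d, block, cov, stratum=stratum)
                r.exposure = label
                rows.append(r)
    return results_frame(rows)


def snp_scan_tables(
    response_df: pd.DataFrame,
    cohort: Cohort,
    analysis: AnalysisConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Individual SNP and residue response scans with chance-expectation summaries."""
    cov = covariate_list(analysis)
    snp_cols = list(cohort.snp_dosages.columns)
    df = pd.concat([response_df, cohort.snp_dosages.loc[response_df.index]], axis=1)
    res = cohort.residue_dosages()
    residue_cols = []
    for pos in hla.POSITIONS:
        block = res[pos].loc[response_df.index]
        for col in block.columns:
            name = f"pos{pos}_{col}"
            df[name] = block[col].to_numpy()
            residue_cols.append(name)
    # residues carried by anyone in the treated sample only
    residue_cols = [c for c in residue_cols if df[c].sum() > 0]
    all_rows, summaries = [], []
    for stratum in RESPONSE_STRATA:
        sub = _stratify(df, stratum)
        for family, cols in (("snps", snp_cols), ("residues", residue_cols)):
            results, summary = scan_individual(
                sub, cols, "response", cov, stratum=stratum, family=family
            )
            all_rows.extend(results)
            summaries.append(
                {
                    "stratum": stratum,
                    "family": family,
                    "n_tests": summary.n_tests,
                    "n_p_lt_0.05": summary.n_significant,
                    "band_low": summary.band_low,
                    "band_high": summary.band_high,
                    "within_band": summary.within_band,
                }
            )
    return results_frame(all_rows), pd.DataFrame(summaries)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage and write the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("tnfigrs")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline(config: RunConfig, out: Path) -> Path:
    ana = config.analysis

    def stage(name: str):
        log.info("stage %s", name)

    stage("simulate")
    if config.mode == "simulate":
        study = generate_cohort(config.simulation)
        cohort, visits, weights = study.cohort, study.visits, study.weights
        io.write_cohort(cohort, visits, out / "cohort")
        io.write_weights(weights, out / "cohort")
    else:
        cohort, visits = io.read_cohort(config.cohort_dir)
        weights = io.read_weights(config.cohort_dir)
    log.info("cohort: %d cases, %d controls, %d visits",
             int(cohort.case_mask.sum()), int((~cohort.case_mask).sum()), len(visits))

    stage("score")
    scores = grs.score_panel(
        cohort.snp_dosages,
        cohort.subjects["hap1"],
        cohort.subjects["hap2"],
        weights,
        control_mask=~cohort.case_mask,
    )
    scores.to_csv(out / "scores.csv")

    stage("outcomes")
    outcome_table = outcomes.derive_outcomes(
        visits, ana.window_days, ana.target_day, ana.baseline_tolerance
    )
    outcome_table.to_csv(out / "outcomes.csv", index=False)
    log.info("outcomes: %d treated, %d evaluable", int(cohort.case_mask.sum()), len(outcome_table))

    stage("associate")
    assoc_dir = out / "associations"
    assoc_dir.mkdir(exist_ok=True)
    disease_df = build_disease_table(cohort, scores, ana.n_pcs)
    disease_association_tables(disease_df, ana).to_csv(assoc_dir / "disease_grs.csv", index=False)
    response_df = build_response_table(cohort, scores, outcome_table, ana.n_pcs)
    response_association_tables(response_df, ana).to_csv(
        assoc_dir / "response_grs.csv", index=False
    )
    haplotype_association_table(response_df, ana).to_csv(
        assoc_dir / "response_haplotypes.csv", index=False
    )
    r2_association_tables(response_df, ana).to_csv(assoc_dir / "response_r2.csv", index=False)
    scan_tbl, scan_summary = snp_scan_tables(response_df, cohort, ana)
    scan_tbl.to_csv(assoc_dir / "individual_scan.csv", index=False)
    scan_summary.to_csv(assoc_dir / "scan_summary.csv", index=False)
    cov = covariate_list(ana)
    for mode in ana.sensitivity:
        rows = run_sensitivity(
            response_df, mode, ["grs_snp", "grs_haplotype"], cov,
            quartile_exposures=["q_grs_snp", "q_grs_haplotype"],
        )
        results_frame(rows).to_csv(assoc_dir / f"sensitivity_{mode}.csv", index=False)

    stage("polygenic")
    if cohort.panel_dosages is not None:
        poly_dir = out / "polygenic"
        poly_dir.mkdir(exist_ok=True)
        scan = polygenic.disease_scan(
            cohort.panel_dosages,
            cohort.subjects["is_case"].to_numpy(dtype=bool),
            covariate_frame=disease_df,
            covariates=cov,
        )
        scan.table.to_csv(poly_dir / "scan.tsv", sep="\t")
        ts = polygenic.build_threshold_scores(scan, cohort.panel_dosages, ana.thresholds)
        ts = polygenic.r2_profile(ts, response_df.reset_index(names="subject_id"),
                                  list(DELTA_COLUMNS), cov)
        ts.profile.to_csv(poly_dir / "profile.csv", index=False)
        polygenic.plot_profile(ts.profile, str(poly_dir / "profile.png"))

    provenance = {
        "seed": config.seed,
        "mode": config.mode,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_cases": int(cohort.case_mask.sum()),
        "n_controls": int((~cohort.case_mask).sum()),
        "n_evaluable": int(len(outcome_table)),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
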