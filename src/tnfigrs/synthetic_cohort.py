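"""Synthetic case-control and treated-cohort generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without any registry download:

* an incident case-control sample in which per-SNP log odds ratios and
  HLA-DRB1 haplotype weights act on ACPA-positive disease risk only
  (ACPA-negative cases and controls are drawn from base allele frequencies),
  under a logistic disease model whose intercept is solved numerically to
  hit the configured population prevalence;
* optional latent-ancestry axes mixed into the allele frequencies so that
  principal-component adjustment has something to adjust for;
* a treated sub-cohort (all cases) with one baseline visit within a few
  days of TNFi start and one or more follow-up visits, whose changes from
  baseline are drawn from a correlated multivariate-normal improvement
  model anchored to the observed cohort means (ΔDAS28 ≈ −1.5, ...);
* a configurable (default zero) genetic effect on good/moderate EULAR
  response, injected exactly on the logit scale: the responder indicator is
  drawn from expit(c + β·z) with z the standardized driving score, and the
  evaluation-visit deltas are then drawn from the improvement model
  conditioned on the implied EULAR binary.

Case genotypes are sampled exactly from the logistic disease model using an
exponentially tilted proposal (per-SNP binomial / per-haplotype categorical
tilting by exp(lnOR)) followed by an accept step with probability
1/(1+exp(α+s)); at a 1% prevalence virtually every proposal is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import hla, outcomes
from ._rng import substream
from .config import DELTA_COMPONENTS, DRUG_PROBS, DRUGS, SimulationConfig
from .grs import WeightSet


@dataclass
class Cohort:
    """Case-control sample with genotypes, HLA haplotypes and demographics.

    `subjects` is indexed by subject_id with columns is_case, acpa_positive
    (nullable boolean; missing for controls), age, sex, hap1, hap2.
    """

    subjects: pd.DataFrame
    snp_dosages: pd.DataFrame
    panel_dosages: pd.DataFrame | None = None

    def residue_dosages(self) -> dict[int, pd.DataFrame]:
        """Per-position residue dosages implied by the haplotype pairs."""
        return {
            pos: df.set_axis(self.subjects.index)
            for pos, df in hla.residue_dosages(
                self.subjects["hap1"], self.subjects["hap2"]
            ).items()
        }

    @property
    def case_mask(self) -> np.ndarray:
        return self.subjects["is_case"].to_numpy(dtype=bool)


@dataclass
class SimulatedStudy:
    """Bundle returned by generate_cohort: data plus generative ground truth."""

    cohort: Cohort
    visits: pd.DataFrame
    weights: WeightSet
    config: SimulationConfig
    truth: dict


def _tilted_maf(f: np.ndarray, lnor: np.ndarray) -> np.ndarray:
    """Allele frequency of the exp(lnOR)-tilted binomial."""
    e = np.exp(lnor)
    return f * e / (f * e + (1.0 - f))


def _ancestry_freqs(
    base: np.ndarray, u: np.ndarray | None, loadings: np.ndarray | None
) -> np.ndarray:
    if u is None or loadings is None or u.size == 0:
        return np.broadcast_to(base, (1, base.size)) if base.ndim == 1 else base
    f = base[None, :] + u @ loadings
    return np.clip(f, 0.01, 0.99)


def _draw_dosages(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """n x m dosage draws; freqs is (m,) shared or (n, m) per-subject."""
    if freqs.ndim == 1:
        return rng.binomial(2, freqs[None, :].repeat(n, axis=0))
    return rng.binomial(2, freqs)


def _residue_weights_from_haplotypes(
    freqs: dict[str, float], lnors: dict[str, float]
) -> dict[tuple[int, str], float]:
    """Frequency-weighted mean haplotype lnOR per residue, used as the
    stand-in for published residue weights (consistent with the haplotype
    weights by construction)."""
    out: dict[tuple[int, str], float] = {}
    for k, pos in enumerate(hla.POSITIONS):
        for res in hla.RESIDUE_ALPHABET[pos]:
            num = sum(freqs[h] * lnors[h] for h in freqs if h[k] == res)
            den = sum(freqs[h] for h in freqs if h[k] == res)
            out[(pos, res)] = num / den if den > 0 else 0.0
    return out


def _solve_disease_intercept(
    rng: np.random.Generator,
    mafs: np.ndarray,
    snp_lnor: np.ndarray,
    hap_lnor: np.ndarray,
    hap_probs: np.ndarray,
    prevalence: float,
    n_cal: int = 4000,
) -> float:
    """Intercept α such that the population mean of expit(α + s) equals the
    configured prevalence, estimated on a Monte-Carlo calibration sample."""
    g = _draw_dosages(rng, mafs, n_cal)
    s = g @ snp_lnor
    hap_idx = rng.choice(len(hap_probs), p=hap_probs, size=(n_cal, 2))
    s = s + hap_lnor[hap_idx].sum(axis=1)

    def deficit(alpha: float) -> float:
        return float(expit(alpha + s).mean() - prevalence)

    return brentq(deficit, -50.0, 20.0, xtol=1e-10)


def _sample_cases(
    rng: np.random.Generator,
    n: int,
    mafs: np.ndarray,
    snp_lnor: np.ndarray,
    hap_lnor: np.ndarray,
    hap_probs: np.ndarray,
    alpha: float,
    n_axes: int,
    loadings: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact sampler for ACPA-positive case genotypes under the logistic
    disease model (tilted proposal + accept with prob 1/(1+exp(α+s)))."""
    tilted_hap = hap_probs * np.exp(hap_lnor)
    tilted_hap = tilted_hap / tilted_hap.sum()
    got_g, got_h, got_u = [], [], []
    n_left = n
    for _ in range(200):
        batch = max(256, int(n_left * 1.2))
        u = rng.standard_normal((batch, n_axes)) if n_axes else np.zeros((batch, 0))
        f = _ancestry_freqs(mafs, u if n_axes else None, loadings)
        if f.shape[0] == 1:
            f = np.broadcast_to(f, (batch, mafs.size))
        ft = _tilted_maf(f, snp_lnor[None, :])
        g = rng.binomial(2, ft)
        hap_idx = rng.choice(len(hap_probs), p=tilted_hap, size=(batch, 2))
        s = g @ snp_lnor + hap_lnor[hap_idx].sum(axis=1)
        accept = rng.random(batch) < 1.0 / (1.0 + np.exp(alpha + s))
        got_g.append(g[accept])
        got_h.append(hap_idx[accept])
        got_u.append(u[accept])
        n_left = n - sum(len(x) for x in got_g)
        if n_left <= 0:
            break
    else:  # pragma: no cover - acceptance is ~1 at realistic prevalence
        raise RuntimeError("case sampling failed to converge")
    g = np.concatenate(got_g)[:n]
    h = np.concatenate(got_h)[:n]
    u = np.concatenate(got_u)[:n]
    return g, h, u


def _round_haq(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 8) / 8, 0.0, 3.0)


def _realize_followup(base: dict[str, np.ndarray], delta: np.ndarray) -> dict[str, np.ndarray]:
    """Apply a 7-component delta draw to baseline measures, with counts
    rounded and clamped to [0, 28], VAS to [0, 100], HAQ to the 1/8 grid,
    ESR kept integer >= 1 and CRP >= 0."""
    d = {name: delta[:, i] for i, name in enumerate(DELTA_COMPONENTS)}
    out = {}
    out["tjc28"] = np.clip(np.round(base["tjc28"] + d["tjc"]), 0, 28).astype(int)
    out["sjc28"] = np.clip(np.round(base["sjc28"] + d["sjc"]), 0, 28).astype(int)
    out["esr"] = np.maximum(1, np.round(base["esr"] * np.exp(d["ln_esr"]))).astype(int)
    out["crp"] = np.maximum(0.0, np.round(base["crp"] * np.exp(d["ln_crp"]), 1))
    out["vas_global"] = np.clip(np.round(base["vas_global"] + d["vas_global"]), 0, 100).astype(int)
    out["vas_pain"] = np.clip(np.round(base["vas_pain"] + d["vas_pain"]), 0, 100).astype(int)
    out["haq"] = _round_haq(base["haq"] + d["haq"])
    return out


def generate_cohort(config: SimulationConfig) -> SimulatedStudy:
    """Generate the case-control cohort and the treated-cohort visit table.

    Deterministic given ``config.seed``: every stage draws from its own
    named substream, so e.g. changing the panel size does not perturb the
    clinical draws.
    """
    config.validate()
    seed = config.seed

    # --- genetic architecture ------------------------------------------
    rng_maf = substream(seed, "maf")
    mafs = rng_maf.uniform(*config.maf_range, size=config.n_snps)
    panel_mafs = rng_maf.uniform(*config.maf_range, size=config.n_panel_snps)

    rng_eff = substream(seed, "effects")
    if config.snp_lnor is None:
        snp_lnor = np.abs(rng_eff.normal(config.snp_lnor_mean, config.snp_lnor_sd, config.n_snps))
    else:
        snp_lnor = np.asarray(config.snp_lnor, dtype=float)
    panel_lnor = (
        np.zeros(config.n_panel_snps)
        if config.panel_lnor is None
        else np.asarray(config.panel_lnor, dtype=float)
    )

    hap_freqs = hla.normalized_haplotype_freqs(config.hla_haplotype_freqs)
    haplotypes = sorted(hap_freqs)
    hap_probs = np.array([hap_freqs[h] for h in haplotypes])
    hap_lnor = np.array([config.hla_haplotype_lnor[h] for h in haplotypes], dtype=float)

    rng_anc = substream(seed, "ancestry")
    k = config.n_pcs_structure
    loadings = rng_anc.normal(0.0, config.ancestry_shift_sd, (k, config.n_snps)) if k else None
    panel_loadings = (
        rng_anc.normal(0.0, config.ancestry_shift_sd, (k, config.n_panel_snps)) if k else None
    )

    n_acpa_pos = int(round(config.n_cases * config.acpa_pos_fraction))
    n_acpa_neg = config.n_cases - n_acpa_pos

    # --- case / control genotypes --------------------------------------
    panel_causal = np.nonzero(panel_lnor)[0]
    eff_lnor = np.concatenate([snp_lnor, panel_lnor[panel_causal]])
    eff_mafs = np.concatenate([mafs, panel_mafs[panel_causal]])
    rng_cal = substream(seed, "intercept")
    alpha = _solve_disease_intercept(
        rng_cal, eff_mafs, eff_lnor, hap_lnor, hap_probs, config.disease_prevalence
    )

    rng_case = substream(seed, "genotypes_cases")
    eff_loadings = None
    if k:
        extra = rng_anc.normal(0.0, config.ancestry_shift_sd, (k, panel_causal.size))
        eff_loadings = np.concatenate([loadings, extra], axis=1)
    g_pos, hap_pos, u_pos = _sample_cases(
        rng_case, n_acpa_pos, eff_mafs, eff_lnor, hap_lnor, hap_probs, alpha, k, eff_loadings
    )

    rng_base = substream(seed, "genotypes_base")

    def base_draw(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        u = rng_base.standard_normal((n, k)) if k else np.zeros((n, 0))
        f = _ancestry_freqs(mafs, u if k else None, loadings)
        if f.shape[0] == 1:
            f = np.broadcast_to(f, (n, mafs.size))
        g = rng_base.binomial(2, f)
        hidx = rng_base.choice(len(hap_probs), p=hap_probs, size=(n, 2))
        return g, hidx, u

    g_neg, hap_neg, u_neg = base_draw(n_acpa_neg)
    g_ctrl, hap_ctrl, u_ctrl = base_draw(config.n_controls)

    snp_mat = np.concatenate([g_pos[:, : config.n_snps], g_neg, g_ctrl])
    hap_idx = np.concatenate([hap_pos, hap_neg, hap_ctrl])
    u_all = np.concatenate([u_pos, u_neg, u_ctrl])

    # --- panel dosages --------------------------------------------------
    rng_panel = substream(seed, "panel")
    n_total = config.n_cases + config.n_controls
    panel_mat = None
    if config.n_panel_snps:
        f = _ancestry_freqs(panel_mafs, u_all if k else None, panel_loadings)
        if f.shape[0] == 1:
            f = np.broadcast_to(f, (n_total, panel_mafs.size))
        panel_mat = rng_panel.binomial(2, f)
        if panel_causal.size:
            # causal panel SNPs of ACPA+ cases were drawn jointly with risk
            panel_mat[:n_acpa_pos, panel_causal] = g_pos[:, config.n_snps :]

    # --- assemble cohort -------------------------------------------------
    ids = pd.Index([f"S{i + 1:05d}" for i in range(n_total)], name="subject_id")
    rng_demo = substream(seed, "demographics")
    subjects = pd.DataFrame(index=ids)
    subjects["is_case"] = np.r_[np.ones(config.n_cases, bool), np.zeros(config.n_controls, bool)]
    acpa = np.array([True] * n_acpa_pos + [False] * n_acpa_neg + [None] * config.n_controls)
    subjects["acpa_positive"] = pd.array(acpa, dtype="boolean")
    subjects["age"] = np.round(rng_demo.normal(config.age_mean, config.age_sd, n_total), 1)
    subjects["sex"] = np.where(rng_demo.random(n_total) < config.female_fraction, "F", "M")
    hap_arr = np.array(haplotypes, dtype=object)
    subjects["hap1"] = hap_arr[hap_idx[:, 0]]
    subjects["hap2"] = hap_arr[hap_idx[:, 1]]

    snp_ids = [f"rs{100000 + i}" for i in range(config.n_snps)]
    snp_dosages = pd.DataFrame(snp_mat, index=ids, columns=snp_ids)
    panel_ids = [f"chip{j:05d}" for j in range(config.n_panel_snps)]
    panel_dosages = (
        pd.DataFrame(panel_mat, index=ids, columns=panel_ids) if panel_mat is not None else None
    )
    cohort = Cohort(subjects=subjects, snp_dosages=snp_dosages, panel_dosages=panel_dosages)

    weights = WeightSet(
        snp_weights=dict(zip(snp_ids, snp_lnor)),
        residue_weights=_residue_weights_from_haplotypes(
            hap_freqs, {h: config.hla_haplotype_lnor[h] for h in haplotypes}
        ),
        haplotype_weights={h: config.hla_haplotype_lnor[h] for h in haplotypes},
    )

    visits = _generate_visits(config, cohort, weights, panel_lnor, panel_dosages)

    truth = {
        "mafs": mafs,
        "panel_mafs": panel_mafs,
        "snp_lnor": snp_lnor,
        "panel_lnor": panel_lnor,
        "disease_intercept": alpha,
        "haplotypes": haplotypes,
        "haplotype_probs": hap_probs,
    }
    return SimulatedStudy(cohort=cohort, visits=visits, weights=weights, config=config, truth=truth)


def _generate_visits(
    config: SimulationConfig,
    cohort: Cohort,
    weights: WeightSet,
    panel_lnor: np.ndarray,
    panel_dosages: pd.DataFrame | None,
) -> pd.DataFrame:
    """Baseline + follow-up visit table for the treated sub-cohort (all cases)."""
    seed = config.seed
    cases = cohort.subjects.index[cohort.case_mask]
    n = len(cases)
    bm = config.baseline_model

    rng_clin = substream(seed, "clinical")
    base = {
        "tjc28": np.clip(
            np.round(rng_clin.gamma(bm.tjc_shape, bm.tjc_mean / bm.tjc_shape, n)), 0, 28
        ).astype(int),
        "sjc28": np.clip(
            np.round(rng_clin.gamma(bm.sjc_shape, bm.sjc_mean / bm.sjc_shape, n)), 0, 28
        ).astype(int),
        "esr": np.maximum(1, np.round(np.exp(rng_clin.normal(bm.ln_esr_mu, bm.esr_sigma, n)))).astype(int),
        "crp": np.maximum(0.0, np.round(np.exp(rng_clin.normal(bm.ln_crp_mu, bm.crp_sigma, n)), 1)),
        "vas_global": np.clip(np.round(rng_clin.normal(bm.vas_global_mean, bm.vas_global_sd, n)), 0, 100).astype(int),
        "vas_pain": np.clip(np.round(rng_clin.normal(bm.vas_pain_mean, bm.vas_pain_sd, n)), 0, 100).astype(int),
        "haq": _round_haq(rng_clin.normal(bm.haq_mean, bm.haq_sd, n)),
    }
    das28_base = outcomes.das28(base["tjc28"], base["sjc28"], base["esr"], base["vas_global"])

    rng_visit = substream(seed, "visits")
    baseline_day = rng_visit.integers(-3, 4, n)
    drug = np.array(DRUGS, dtype=object)[rng_visit.choice(len(DRUGS), p=DRUG_PROBS, size=n)]
    lo, hi = config.visit_day_distribution
    main_day = rng_visit.integers(lo, hi + 1, n)
    has_extra = rng_visit.random(n) < config.extra_visit_prob
    xlo, xhi = config.extra_visit_range
    extra_day = rng_visit.integers(xlo, xhi + 1, n)
    # avoid duplicate-day visits for the same subject
    extra_day = np.where(extra_day == main_day, extra_day + 1, extra_day)
    missing = rng_visit.random(n) < config.missing_followup_prob

    # which follow-up will be the evaluation visit downstream (nearest to
    # day 150 within the window, earlier visit on ties)
    target = 150

    def _dist(day: np.ndarray, ok: np.ndarray) -> np.ndarray:
        d = np.abs(day - target).astype(float)
        d[~ok] = np.inf
        return d

    main_ok = ~missing
    extra_ok = has_extra & ~missing & (extra_day >= lo) & (extra_day <= hi)
    dm, dx = _dist(main_day, main_ok), _dist(extra_day, extra_ok)
    eval_is_extra = (dx < dm) | ((dx == dm) & (extra_day < main_day))
    eval_day = np.where(eval_is_extra, extra_day, main_day)
    has_eval = main_ok | extra_ok

    means, cov = config.improvement_model.mvn_params(bm)
    chol = np.linalg.cholesky(cov)
    rng_delta = substream(seed, "deltas")

    def draw_deltas(m: int) -> np.ndarray:
        return means + rng_delta.standard_normal((m, len(means))) @ chol.T

    # evaluation-visit deltas, conditioned on the responder draw when a
    # genetic response effect is configured
    beta = config.response_lnor_per_sd
    eval_delta = draw_deltas(n)
    if beta != 0.0:
        z = _response_driver_score(config, cohort, weights, panel_lnor, panel_dosages, cases)
        rng_resp = substream(seed, "response")

        def rate_deficit(c: float) -> float:
            return float(expit(c + beta * z).mean() - config.response_rate)

        c0 = brentq(rate_deficit, -30.0, 30.0, xtol=1e-10)
        target_resp = rng_resp.random(n) < expit(c0 + beta * z)
        active = np.flatnonzero(has_eval)
        for _ in range(300):
            meas = _realize_followup({k_: v[active] for k_, v in base.items()}, eval_delta[active])
            d28 = outcomes.das28(meas["tjc28"], meas["sjc28"], meas["esr"], meas["vas_global"])
            resp = (
                np.asarray(outcomes.eular_response(das28_base[active], d28)) != "none"
            )
            bad = active[resp != target_resp[active]]
            if bad.size == 0:
                break
            eval_delta[bad] = draw_deltas(bad.size)
            active = bad

    rows = []

    def add_rows(subj_idx: np.ndarray, days: np.ndarray, measures: dict[str, np.ndarray]) -> None:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": np.asarray(cases)[subj_idx],
                    "days_since_treatment_start": days,
                    "drug": drug[subj_idx],
                    **{c: measures[c] for c in ("tjc28", "sjc28", "esr", "crp", "vas_global", "vas_pain", "haq")},
                }
            )
        )

    all_idx = np.arange(n)
    add_rows(all_idx, baseline_day, base)

    eval_meas = _realize_followup(base, eval_delta)
    keep = has_eval
    add_rows(all_idx[keep], eval_day[keep], {k_: v[keep] for k_, v in eval_meas.items()})

    # the non-evaluation follow-up (where a second visit exists) gets an
    # independent null draw from the improvement model
    other_mask = has_extra & ~missing
    other_day = np.where(eval_is_extra, main_day, extra_day)
    oi = all_idx[other_mask]
    if oi.size:
        od = draw_deltas(oi.size)
        om = _realize_followup({k_: v[oi] for k_, v in base.items()}, od)
        add_rows(oi, other_day[oi], om)

    visits = pd.concat(rows, ignore_index=True)
    visits = visits.sort_values(
        ["subject_id", "days_since_treatment_start"], kind="mergesort"
    ).reset_index(drop=True)
    return visits


def _response_driver_score(
    config: SimulationConfig,
    cohort: Cohort,
    weights: WeightSet,
    panel_lnor: np.ndarray,
    panel_dosages: pd.DataFrame | None,
    cases: pd.Index,
) -> np.ndarray:
    """Standardized score that the response effect acts on."""
    from .grs import score_snp_grs

    if config.response_driver == "snp_grs":
        score = score_snp_grs(cohort.snp_dosages.loc[cases], weights).to_numpy()
    else:
        if panel_dosages is None or not np.any(panel_lnor):
            raise ValueError("response_driver='panel' requires a panel with non-zero panel_lnor")
        score = panel_dosages.loc[cases].to_numpy(dtype=float) @ panel_lnor
    sd = score.std()
    if sd == 0:
        raise ValueError("response driver score has zero variance")
    return (score - score.mean()) / sd
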