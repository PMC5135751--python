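"""Generator invariants: determinism, genetic structure, clinical anchors."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from tnfigrs import hla, outcomes
from tnfigrs.config import SimulationConfig
from tnfigrs.synthetic_cohort import generate_cohort


def test_fixed_seed_reproduces_cohort_and_visits():
    cfg = dict(seed=1, n_cases=120, n_controls=150, n_panel_snps=40)
    a = generate_cohort(SimulationConfig(**cfg))
    b = generate_cohort(SimulationConfig(**cfg))
    assert_frame_equal(a.cohort.subjects, b.cohort.subjects)
    assert_frame_equal(a.cohort.snp_dosages, b.cohort.snp_dosages)
    assert_frame_equal(a.cohort.panel_dosages, b.cohort.panel_dosages)
    assert_frame_equal(a.visits, b.visits)


def test_residue_dosages_are_marginals_of_haplotype_pair(small_study):
    cohort = small_study.cohort
    res = cohort.residue_dosages()
    for pos in hla.POSITIONS:
        mat = res[pos]
        assert (mat.sum(axis=1) == 2).all()
        # spot-check a few subjects against direct string counting
        k = hla.POSITIONS.index(pos)
        for sid in cohort.subjects.index[:20]:
            h1 = cohort.subjects.loc[sid, "hap1"][k]
            h2 = cohort.subjects.loc[sid, "hap2"][k]
            expected = pd.Series(0, index=mat.columns)
            expected[h1] += 1
            expected[h2] += 1
            assert (mat.loc[sid] == expected).all()


def test_control_allele_frequencies_match_configured_maf(small_study):
    cohort = small_study.cohort
    ctrl = cohort.snp_dosages[~cohort.case_mask]
    emp = ctrl.mean().to_numpy() / 2
    maf = small_study.truth["mafs"]
    mc_sd = np.sqrt(maf * (1 - maf) / (2 * len(ctrl)))
    assert np.all(np.abs(emp - maf) < 3.5 * mc_sd + 0.01)


def test_null_effects_give_no_case_control_dosage_difference():
    """With zero SNP and haplotype weights, per-SNP case-control mean dosage
    t-tests are significant at the nominal 5% rate (Monte-Carlo pooled)."""
    from scipy.stats import ttest_ind

    n_sig = n_tot = 0
    for seed in range(30):
        cfg = SimulationConfig(
            seed=seed,
            n_cases=150,
            n_controls=150,
            n_snps=76,
            n_panel_snps=0,
            snp_lnor=np.zeros(76),
            hla_haplotype_lnor={h: 0.0 for h in hla.HAPLOTYPE_PREVALENCE_PCT},
        )
        study = generate_cohort(cfg)
        g = study.cohort.snp_dosages.to_numpy(dtype=float)
        mask = study.cohort.case_mask
        t, p = ttest_ind(g[mask], g[~mask], axis=0)
        n_sig += int((p < 0.05).sum())
        n_tot += p.size
    rate = n_sig / n_tot
    assert 0.03 < rate < 0.07


def test_mean_das28_change_matches_cohort_anchor():
    """At the study scale the cohort mean DAS28 change is −1.5 ± 0.1."""
    study = generate_cohort(SimulationConfig(seed=5, n_controls=50, n_panel_snps=0))
    out = outcomes.derive_outcomes(study.visits)
    assert len(out) == 867
    assert abs(out["d_DAS28"].mean() - (-1.5)) < 0.1
    assert abs(out["d_HAQ"].mean() - (-0.3)) < 0.15


def test_visit_table_structure(small_study):
    visits = small_study.visits
    cohort = small_study.cohort
    # only cases are treated
    assert set(visits["subject_id"]) <= set(cohort.subjects.index[cohort.case_mask])
    day = visits["days_since_treatment_start"]
    base = visits[day.abs() <= 7]
    assert (base.groupby("subject_id").size() == 1).all()
    follow = visits[day > 7]
    assert set(base["subject_id"]) == set(visits["subject_id"])
    assert (follow.groupby("subject_id").size() >= 1).all()
    for col in ("tjc28", "sjc28"):
        assert visits[col].between(0, 28).all()
    assert (visits["esr"] > 0).all()
    assert (visits["crp"] >= 0).all()
    assert visits["vas_global"].between(0, 100).all()
    assert visits["haq"].between(0, 3).all()


def test_controls_have_missing_acpa(small_study):
    subj = small_study.cohort.subjects
    assert subj.loc[~subj["is_case"], "acpa_positive"].isna().all()
    assert subj.loc[subj["is_case"], "acpa_positive"].notna().all()


@pytest.mark.parametrize(
    "bad",
    [
        dict(n_cases=0),
        dict(maf_range=(0.0, 0.5)),
        dict(maf_range=(0.6, 0.7)),
        dict(acpa_pos_fraction=0.0),
        dict(snp_lnor=np.zeros(5)),  # wrong length for default n_snps
        dict(hla_haplotype_freqs={"VHKA": -1.0}),
        dict(hla_haplotype_freqs={}),
    ],
)
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        SimulationConfig(**bad)


def test_unknown_config_keys_rejected():
    with pytest.raises(ValueError, match="unknown"):
        SimulationConfig.from_dict({"n_cases": 10, "typo_key": 1})


def test_response_effect_changes_only_response_distribution():
    """The injected response effect shifts responder status with the GRS but
    leaves genotypes untouched (same substream draws)."""
    base = dict(seed=3, n_cases=200, n_controls=50, n_panel_snps=0)
    null = generate_cohort(SimulationConfig(**base))
    eff = generate_cohort(SimulationConfig(**base, response_lnor_per_sd=np.log(2.0)))
    assert_frame_equal(null.cohort.snp_dosages, eff.cohort.snp_dosages)
    assert_frame_equal(null.cohort.subjects, eff.cohort.subjects)
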