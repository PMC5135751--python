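"""Risk-score arithmetic, shared-epitope rules and control quartiles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnfigrs import hla
from tnfigrs.grs import (
    WeightSet,
    apply_quartiles,
    classify_shared_epitope,
    fit_quartiles,
    score_haplotype_grs,
    score_position_grs,
    score_snp_grs,
)


def _random_weightset(rng, snp_ids):
    return WeightSet(
        snp_weights={s: rng.normal(0, 0.2) for s in snp_ids},
        residue_weights={
            (p, r): rng.normal(0, 0.3) for p in hla.POSITIONS for r in hla.RESIDUE_ALPHABET[p]
        },
        haplotype_weights={h: rng.normal(0, 0.4) for h in hla.HAPLOTYPE_PREVALENCE_PCT},
    )


class TestSnpScore:
    def test_zero_weights_give_zero(self, rng):
        ids = [f"rs{i}" for i in range(10)]
        dos = pd.DataFrame(rng.integers(0, 3, (5, 10)), columns=ids)
        w = WeightSet(snp_weights={s: 0.0 for s in ids})
        assert (score_snp_grs(dos, w) == 0).all()

    def test_hand_arithmetic(self):
        dos = pd.DataFrame({"a": [2], "b": [1]})
        w = WeightSet(snp_weights={"a": math.log(1.5), "b": math.log(1.5)})
        assert score_snp_grs(dos, w)[0] == pytest.approx(3 * math.log(1.5), abs=1e-12)

    def test_matches_per_element_loop_oracle(self, rng):
        ids = [f"rs{i}" for i in range(76)]
        dos = pd.DataFrame(rng.integers(0, 3, (50, 76)), columns=ids)
        w = _random_weightset(rng, ids)
        fast = score_snp_grs(dos, w)
        for sid in dos.index:
            slow = sum(w.snp_weights[c] * dos.loc[sid, c] for c in ids)
            assert abs(fast[sid] - slow) < 1e-12

    def test_missing_weight_refused(self):
        dos = pd.DataFrame({"a": [1], "zzz": [1]})
        with pytest.raises(KeyError, match="zzz"):
            score_snp_grs(dos, WeightSet(snp_weights={"a": 0.1}))

    def test_out_of_range_dosage_refused(self):
        dos = pd.DataFrame({"a": [2.5]})
        with pytest.raises(ValueError, match=r"\[0, 2\]"):
            score_snp_grs(dos, WeightSet(snp_weights={"a": 0.1}))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-0.5, 0.5), min_size=3, max_size=3), st.permutations(range(3)))
    def test_snp_permutation_invariance(self, weights, perm):
        ids = ["r1", "r2", "r3"]
        dos = pd.DataFrame([[0, 1, 2]], columns=ids)
        w = WeightSet(snp_weights=dict(zip(ids, weights)))
        permuted = dos[[ids[i] for i in perm]]
        assert score_snp_grs(dos, w)[0] == pytest.approx(score_snp_grs(permuted, w)[0], abs=1e-12)


class TestPositionAndHaplotypeScores:
    def test_homozygote_doubles_weight(self, rng):
        w = _random_weightset(rng, [])
        df = pd.DataFrame({r: [0] for r in hla.RESIDUE_ALPHABET[11]})
        df["V"] = 2
        assert score_position_grs(df, 11, w)[0] == pytest.approx(2 * w.residue_weights[(11, "V")])

    def test_heterozygote_adds_weights(self, rng):
        w = _random_weightset(rng, [])
        df = pd.DataFrame({r: [0] for r in hla.RESIDUE_ALPHABET[71]})
        df["K"], df["R"] = 1, 1
        expected = w.residue_weights[(71, "K")] + w.residue_weights[(71, "R")]
        assert score_position_grs(df, 71, w)[0] == pytest.approx(expected)

    def test_dosages_must_sum_to_two(self, rng):
        w = _random_weightset(rng, [])
        df = pd.DataFrame({r: [1] for r in hla.RESIDUE_ALPHABET[11]})
        with pytest.raises(ValueError, match="sum to 2"):
            score_position_grs(df, 11, w)

    def test_position_loop_oracle(self, rng):
        haps = list(hla.HAPLOTYPE_PREVALENCE_PCT)
        h1 = rng.choice(haps, 50)
        h2 = rng.choice(haps, 50)
        res = hla.residue_dosages(h1, h2)
        w = _random_weightset(rng, [])
        for pos in hla.POSITIONS:
            fast = score_position_grs(res[pos], pos, w)
            for i in range(50):
                slow = sum(
                    w.residue_weights[(pos, r)] * res[pos].iloc[i][r] for r in res[pos].columns
                )
                assert abs(fast.iloc[i] - slow) < 1e-12

    def test_haplotype_pairs(self, rng):
        w = _random_weightset(rng, [])
        hw = w.haplotype_weights
        assert score_haplotype_grs(["VHKA"], ["VHKA"], w)[0] == pytest.approx(2 * hw["VHKA"])
        assert score_haplotype_grs(["VHKA"], ["PRAA"], w)[0] == pytest.approx(
            hw["VHKA"] + hw["PRAA"]
        )

    def test_haplotype_score_equals_copy_count_formulation(self, rng):
        """Pair-sum equals Σ over distinct haplotypes of weight × copies,
        for every haplotype in the default table."""
        w = _random_weightset(rng, [])
        haps = list(hla.HAPLOTYPE_PREVALENCE_PCT)
        for a in haps:
            for b in haps:
                pair_sum = score_haplotype_grs([a], [b], w)[0]
                copies = {h: (h == a) + (h == b) for h in haps}
                by_copies = sum(w.haplotype_weights[h] * c for h, c in copies.items())
                assert abs(pair_sum - by_copies) < 1e-12

    def test_unweighted_haplotype_names_the_string(self):
        with pytest.raises(KeyError, match="VHKA"):
            score_haplotype_grs(["VHKA"], ["VHKA"], WeightSet(haplotype_weights={"PRAA": 0.0}))


class TestSharedEpitope:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            (("DRB1*0401", "DRB1*0404"), 2),
            (("DRB1*0103", "DRB1*15"), 0),
            (("DRB1*10", "DRB1*07"), 1),
            (("DRB1*01", "DRB1*0408"), 2),
            (("DRB1*0402", "DRB1*13"), 0),
        ],
    )
    def test_classical_allele_rules(self, alleles, expected):
        assert classify_shared_epitope(alleles=alleles) == expected

    def test_ambiguous_two_digit_04_refused(self):
        with pytest.raises(ValueError, match="04"):
            classify_shared_epitope(alleles=("DRB1*04", "DRB1*07"))

    def test_haplotype_lookup(self):
        assert classify_shared_epitope(haplotype_pair=("VHKA", "VHRA")) == 2
        assert classify_shared_epitope(haplotype_pair=("VHKA", "PRAA")) == 1
        assert classify_shared_epitope(haplotype_pair=("SSEA", "GYRQ")) == 0


class TestQuartiles:
    def test_interpolated_cutpoints_and_assignment(self):
        cuts = fit_quartiles(np.arange(1, 101))
        assert cuts == pytest.approx([25.75, 50.5, 75.25])
        assert apply_quartiles([60.0], cuts)[0] == "Q3"
        assert apply_quartiles([25.75], cuts)[0] == "Q1"  # right-closed: on cutpoint -> lower

    def test_degenerate_controls_give_q1_ties(self):
        cuts = fit_quartiles(np.full(10, 3.0))
        assert apply_quartiles([3.0, 3.0], cuts).tolist() == ["Q1", "Q1"]

    def test_uniform_controls_balanced(self, rng):
        x = rng.uniform(0, 1, 10_000)
        cuts = fit_quartiles(x)
        frac = apply_quartiles(x, cuts).value_counts(normalize=True)
        assert np.all(np.abs(frac - 0.25) < 0.01)

    def test_too_few_or_nan_controls_refused(self):
        with pytest.raises(ValueError):
            fit_quartiles([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_quartiles([1.0, 2.0, np.nan, 4.0])


@settings(derandomize=True, max_examples=25)
@given(st.floats(0.1, 1.0))
def test_score_linearity_in_dosages(alpha):
    """score(α·d) = α·score(d) for dosage scaling within [0, 2]."""
    ids = ["a", "b", "c"]
    w = WeightSet(snp_weights={"a": 0.1, "b": -0.2, "c": 0.3})
    d = pd.DataFrame([[2.0, 1.0, 0.5]], columns=ids)
    assert score_snp_grs(d * alpha, w)[0] == pytest.approx(alpha * score_snp_grs(d, w)[0])
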