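"""Weighted genetic risk scores, shared-epitope status, and control quartiles.

Three scores are computed from published log odds ratios (lnOR):

* SNP score:       GRS = Σ_i lnOR_i · dosage_i  over the candidate SNPs
* position score:  per HLA-DRB1 amino-acid position, Σ over residues of
                   lnOR(residue) · residue dosage (each person carries two
                   residues per position)
* haplotype score: sum of the lnOR of the two carried 4-position haplotypes

Continuous scores are categorized into quartiles using cutpoints estimated
among controls only, then applied to cases and controls alike.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import hla

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WeightSet:
    """Published-weight lookup for SNPs, residues, and haplotypes."""

    snp_weights: Mapping[str, float] = field(default_factory=dict)
    residue_weights: Mapping[tuple[int, str], float] = field(default_factory=dict)
    haplotype_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (
            ("snp", self.snp_weights),
            ("residue", self.residue_weights),
            ("haplotype", self.haplotype_weights),
        ):
            bad = [k for k, v in table.items() if not np.isfinite(v)]
            if bad:
                raise ValueError(f"non-finite {name} weights for: {bad}")


def _check_dosage_range(values: np.ndarray, what: str) -> None:
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{what} contains missing or non-finite dosages")
    if np.any((values < 0) | (values > 2)):
        raise ValueError(f"{what} contains dosages outside [0, 2]")


def score_snp_grs(dosages: pd.DataFrame, weights: WeightSet) -> pd.Series:
    """Weighted SNP risk score, one value per subject (row).

    `dosages` columns are SNP ids; every column must have a weight in
    `weights.snp_weights`. Dosages must lie in [0, 2]; missing dosages are
    refused (impute upstream if desired, see `mean_impute`).
    """
    missing = [c for c in dosages.columns if c not in weights.snp_weights]
    if missing:
        raise KeyError(f"no published weight for SNPs: {missing[:10]}")
    x = dosages.to_numpy(dtype=float)
    _check_dosage_range(x, "SNP dosage matrix")
    w = np.array([weights.snp_weights[c] for c in dosages.columns], dtype=float)
    return pd.Series(x @ w, index=dosages.index, name="grs_snp")


def mean_impute(dosages: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Optional missing-dosage imputation with the per-SNP mean of `reference`
    (default: the matrix itself, typically the control sample). Logged."""
    ref = dosages if reference is None else reference
    n_missing = int(dosages.isna().to_numpy().sum())
    if n_missing:
        log.info("mean-imputing %d missing dosages", n_missing)
    return dosages.fillna(ref.mean())


def score_position_grs(
    residue_dosages: pd.DataFrame, position: int, weights: WeightSet
) -> pd.Series:
    """Amino-acid position score: Σ over residues of lnOR · dosage.

    `residue_dosages` has one column per residue observed at `position`;
    per-subject dosages must sum to 2 (two chromosomes) within 1e-6.
    """
    x = residue_dosages.to_numpy(dtype=float)
    _check_dosage_range(x, f"residue dosages at position {position}")
    sums = x.sum(axis=1)
    if np.any(np.abs(sums - 2.0) > 1e-6):
        bad = residue_dosages.index[np.abs(sums - 2.0) > 1e-6][:5].tolist()
        raise ValueError(f"residue dosages at position {position} do not sum to 2 for: {bad}")
    w = []
    for res in residue_dosages.columns:
        key = (position, res)
        if key not in weights.residue_weights:
            raise KeyError(f"no published weight for residue {res!r} at position {position}")
        w.append(weights.residue_weights[key])
    return pd.Series(x @ np.array(w), index=residue_dosages.index, name=f"grs_pos{position}")


def score_haplotype_grs(
    hap1: Sequence[str] | pd.Series, hap2: Sequence[str] | pd.Series, weights: WeightSet
) -> pd.Series:
    """Haplotype score: sum of the lnOR of the two carried haplotypes."""
    h1 = pd.Series(list(hap1), dtype=object)
    h2 = pd.Series(list(hap2), dtype=object).set_axis(h1.index)
    unknown = sorted((set(h1) | set(h2)) - set(weights.haplotype_weights))
    if unknown:
        raise KeyError(f"no published weight for haplotypes: {unknown}")
    w = weights.haplotype_weights
    vals = h1.map(w).astype(float) + h2.map(w).astype(float)
    vals.name = "grs_haplotype"
    return vals


# --- shared epitope ---------------------------------------------------------

_ALLELE_RE = re.compile(r"(?:HLA-)?(?:DRB1)?\*?(\d{2})(?::?(\d{2,3}))?$", re.IGNORECASE)


def _parse_allele(allele: str) -> tuple[str, str | None]:
    m = _ALLELE_RE.match(allele.strip())
    if not m:
        raise ValueError(f"unrecognized HLA-DRB1 allele: {allele!r}")
    return m.group(1), m.group(2)


def _is_se_allele(allele: str) -> bool:
    """Shared-epitope membership of a classical DRB1 allele.

    SE alleles: any *01 except *01:03; among *04 only *04:01, *04:04 and
    *04:08; and any *10. A bare two-digit *04 is ambiguous and refused.
    """
    group, four = _parse_allele(allele)
    if group == "01":
        return four != "03"
    if group == "04":
        if four is None:
            raise ValueError(f"ambiguous allele {allele!r}: *04 requires four-digit resolution")
        return four in {"01", "04", "08"}
    if group == "10":
        return True
    return False


def classify_shared_epitope(
    alleles: tuple[str, str] | None = None,
    haplotype_pair: tuple[str, str] | None = None,
    se_haplotypes: Iterable[str] = hla.DEFAULT_SE_HAPLOTYPES,
) -> int:
    """Count of shared-epitope alleles (0, 1 or 2) carried by one person.

    Either classical DRB1 alleles (e.g. ``("DRB1*0401", "DRB1*15")``) or a
    4-position amino-acid haplotype pair (e.g. ``("VHKA", "PRAA")``, scored
    against a configurable SE haplotype lookup) may be given. "Any SE"
    exposure is ``classify_shared_epitope(...) >= 1``.
    """
    if (alleles is None) == (haplotype_pair is None):
        raise ValueError("provide exactly one of alleles or haplotype_pair")
    if alleles is not None:
        return sum(_is_se_allele(a) for a in alleles)
    lookup = set(se_haplotypes)
    for h in haplotype_pair:
        hla.validate_haplotype(h)
    return sum(h in lookup for h in haplotype_pair)


def se_copies_from_pairs(
    hap1: Sequence[str], hap2: Sequence[str], se_haplotypes: Iterable[str] = hla.DEFAULT_SE_HAPLOTYPES
) -> pd.Series:
    """Vectorized haplotype-lookup SE copy count."""
    lookup = set(se_haplotypes)
    h1 = pd.Series(list(hap1), dtype=object)
    h2 = pd.Series(list(hap2), dtype=object).set_axis(h1.index)
    out = h1.isin(lookup).astype(int) + h2.isin(lookup).astype(int)
    out.name = "se_copies"
    return out


# --- quartiles --------------------------------------------------------------

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


def fit_quartiles(control_scores: Sequence[float] | pd.Series) -> np.ndarray:
    """25th/50th/75th percentile cutpoints estimated among controls.

    Uses the linear-interpolation percentile convention. Requires at least 4
    finite control scores; NaN scores are refused.
    """
    x = np.asarray(control_scores, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("control scores contain NaN")
    if x.size < 4:
        raise ValueError("need at least 4 control scores to fit quartiles")
    return np.percentile(x, [25, 50, 75], method="linear")


def apply_quartiles(scores: Sequence[float] | pd.Series, cutpoints: np.ndarray) -> pd.Series:
    """Assign Q1-Q4 given control cutpoints.

    Intervals are right-closed: a score equal to a cutpoint falls in the
    lower category (so with degenerate cutpoints every tied score is Q1).
    """
    c = np.asarray(cutpoints, dtype=float)
    if c.shape != (3,) or np.any(np.diff(c) < 0):
        raise ValueError("cutpoints must be 3 non-decreasing values")
    x = np.asarray(scores, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("scores contain NaN")
    idx = np.searchsorted(c, x, side="left")  # x <= c[k] -> category k
    labels = np.array(QUARTILE_LABELS, dtype=object)[idx]
    index = scores.index if isinstance(scores, pd.Series) else None
    return pd.Series(
        pd.Categorical(labels, categories=list(QUARTILE_LABELS), ordered=True), index=index
    )


def score_panel(
    snp_dosages: pd.DataFrame,
    hap1: Sequence[str],
    hap2: Sequence[str],
    weights: WeightSet,
    control_mask: Sequence[bool] | None = None,
    se_haplotypes: Iterable[str] = hla.DEFAULT_SE_HAPLOTYPES,
) -> pd.DataFrame:
    """Per-subject risk-score panel.

    Columns: grs_snp, grs_pos11/13/71/74, grs_haplotype, se_copies, and —
    when a control mask is given — control-referenced quartile categories
    q_grs_snp / q_grs_haplotype.
    """
    out = pd.DataFrame(index=snp_dosages.index)
    out["grs_snp"] = score_snp_grs(snp_dosages, weights)
    res = hla.residue_dosages(hap1, hap2)
    for pos in hla.POSITIONS:
        df = res[pos].set_axis(out.index)
        out[f"grs_pos{pos}"] = score_position_grs(df, pos, weights).to_numpy()
    out["grs_haplotype"] = score_haplotype_grs(hap1, hap2, weights).to_numpy()
    out["se_copies"] = se_copies_from_pairs(hap1, hap2, se_haplotypes).to_numpy()
    if control_mask is not None:
        mask = np.asarray(control_mask, dtype=bool)
        for col in ("grs_snp", "grs_haplotype"):
            cuts = fit_quartiles(out.loc[mask, col])
            out[f"q_{col}"] = apply_quartiles(out[col], cuts)
    return out
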