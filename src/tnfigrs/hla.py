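"""HLA-DRB1 amino-acid haplotypes at positions 11/13/71/74.

The four most strongly RA-associated polymorphic positions of HLA-DRB1 are
amino acids 11, 13, 71 and 74. A haplotype is written as a 4-letter string of
one-letter residue codes in position order, e.g. ``"VHKA"`` (Val11, His13,
Lys71, Ala74, corresponding to the classical shared-epitope allele *04:01).
Each person carries two such haplotypes; per-position residue dosages are the
marginal counts of the pair.

Default haplotype population frequencies follow the prevalence of the 18
haplotypes observed in Scandinavian RA case-control material. The default
per-haplotype and per-residue disease weights shipped here are *synthetic*
stand-ins on a realistic scale (shared-epitope-like haplotypes most at risk);
real analyses should supply published log odds ratios via a WeightSet.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Position order used everywhere in the package.
POSITIONS: tuple[int, ...] = (11, 13, 71, 74)

#: Residue alphabet per position.
RESIDUE_ALPHABET: dict[int, tuple[str, ...]] = {
    11: ("P", "D", "G", "L", "S", "V"),
    13: ("R", "F", "Y", "H", "G", "S"),
    71: ("A", "E", "K", "R"),
    74: ("A", "E", "Q", "L", "R"),
}

#: Population prevalence (%) of the default 4-position haplotypes.
HAPLOTYPE_PREVALENCE_PCT: dict[str, float] = {
    "PRAA": 10.2,
    "DFRE": 1.7,
    "GYRQ": 4.8,
    "LFEA": 0.4,
    "LFRA": 14.9,
    "PRRA": 0.8,
    "SGRA": 1.7,
    "SGRL": 2.9,
    "SSEA": 5.4,
    "SSKA": 0.7,
    "SSKR": 9.3,
    "SSRA": 3.6,
    "SSRE": 1.1,
    "VFRA": 2.1,
    "VHEA": 0.3,
    "VHKA": 27.0,
    "VHRA": 11.9,
    "VHRE": 1.3,
}

#: Synthetic per-haplotype log odds ratios for ACPA-positive RA risk,
#: relative to the most prevalent non-SE haplotype PRAA (weight 0).
#: Shared-epitope-like haplotypes (VHKA ~ *04:01, VHRA ~ *04:04/*04:08,
#: LFRA ~ *01:01) carry the largest risk; DERAA-like haplotypes are protective.
SYNTHETIC_HAPLOTYPE_LNOR: dict[str, float] = {
    "PRAA": 0.0,
    "DFRE": -0.45,
    "GYRQ": -0.60,
    "LFEA": -0.35,
    "LFRA": 0.30,
    "PRRA": 0.05,
    "SGRA": -0.20,
    "SGRL": -0.30,
    "SSEA": -0.50,
    "SSKA": 0.25,
    "SSKR": 0.40,
    "SSRA": 0.10,
    "SSRE": 0.05,
    "VFRA": 0.35,
    "VHEA": 0.10,
    "VHKA": 1.00,
    "VHRA": 0.60,
    "VHRE": 0.20,
}

#: Haplotypes counted as shared-epitope carriers in the default
#: haplotype→SE lookup (configurable; see grs.classify_shared_epitope).
DEFAULT_SE_HAPLOTYPES: frozenset[str] = frozenset({"VHKA", "VHRA", "LFRA"})


def normalized_haplotype_freqs(
    freqs: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Haplotype frequency table normalized to sum exactly to 1.

    Input values may be on a percent or proportion scale; only ratios matter.
    Raises ValueError if the table is empty, has non-positive mass, or lists a
    haplotype with residues outside the position alphabets.
    """
    raw = dict(HAPLOTYPE_PREVALENCE_PCT if freqs is None else freqs)
    if not raw:
        raise ValueError("haplotype frequency table is empty")
    total = float(sum(raw.values()))
    if not np.isfinite(total) or total <= 0 or any(v < 0 for v in raw.values()):
        raise ValueError("haplotype frequency table is not normalizable")
    for hap in raw:
        validate_haplotype(hap)
    return {h: v / total for h, v in raw.items()}


def validate_haplotype(hap: str) -> None:
    if len(hap) != len(POSITIONS):
        raise ValueError(f"haplotype {hap!r} must have {len(POSITIONS)} residues")
    for pos, res in zip(POSITIONS, hap):
        if res not in RESIDUE_ALPHABET[pos]:
            raise ValueError(f"residue {res!r} not in position {pos} alphabet for haplotype {hap!r}")


def residue_dosages(hap1: Iterable[str], hap2: Iterable[str]) -> dict[int, pd.DataFrame]:
    """Per-position residue dosage matrices implied by haplotype pairs.

    Returns {position: DataFrame} where each DataFrame has one column per
    residue in that position's alphabet and one row per subject; row sums are
    exactly 2 (two chromosomes).
    """
    h1 = pd.Series(list(hap1), dtype=object)
    h2 = pd.Series(list(hap2), dtype=object).set_axis(h1.index)
    out: dict[int, pd.DataFrame] = {}
    for k, pos in enumerate(POSITIONS):
        alpha = RESIDUE_ALPHABET[pos]
        mat = np.zeros((len(h1), len(alpha)), dtype=np.int64)
        lut = {r: j for j, r in enumerate(alpha)}
        for series in (h1, h2):
            codes = series.str[k].map(lut)
            if codes.isna().any():
                bad = series[codes.isna()].iloc[0]
                raise ValueError(f"haplotype {bad!r} has unknown residue at position {pos}")
            mat[np.arange(len(h1)), codes.to_numpy(dtype=np.int64)] += 1
        out[pos] = pd.DataFrame(mat, index=h1.index, columns=list(alpha))
    return out
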