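"""Reading and writing cohort artifacts.

Formats are deliberately plain text:

* ``subjects.csv``       demographics, case/control and ACPA labels
* ``snp_dosages.tsv``    tab-separated, header of SNP ids, one row/subject
* ``panel_dosages.tsv``  same layout for the genome-wide stand-in panel
* ``hla.csv``            hap1/hap2 strings plus per-residue dosage columns
* ``visits.csv``         longitudinal visit table, days relative to start
* ``weights.tsv``        (snp_id, effect_allele, lnOR)
* ``residue_weights.csv`` / ``haplotype_weights.csv``

Round trips are exact: `read_cohort(write_cohort(...))` reproduces every
field. An optional VCF reader converts GT/DS fields into dosages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import hla
from .grs import WeightSet
from .synthetic_cohort import Cohort


def _check_dosage_frame(df: pd.DataFrame, what: str) -> None:
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(~((arr >= 0) & (arr <= 2)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{what}: dosage {arr[i, j]!r} outside [0, 2] "
            f"for subject {df.index[i]!r}, marker {df.columns[j]!r}"
        )


def write_cohort(cohort: Cohort, visits: pd.DataFrame, directory: str | Path) -> Path:
    """Write a cohort + visit table as a plain-text file set."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    subj = cohort.subjects.copy()
    subj.to_csv(d / "subjects.csv")
    cohort.snp_dosages.to_csv(d / "snp_dosages.tsv", sep="\t")
    if cohort.panel_dosages is not None:
        cohort.panel_dosages.to_csv(d / "panel_dosages.tsv", sep="\t")
    hla_df = subj[["hap1", "hap2"]].copy()
    for pos, res in cohort.residue_dosages().items():
        for col in res.columns:
            hla_df[f"pos{pos}_{col}"] = res[col].to_numpy()
    hla_df.to_csv(d / "hla.csv")
    visits.to_csv(d / "visits.csv", index=False)
    meta = {
        "n_subjects": int(len(subj)),
        "n_snps": int(cohort.snp_dosages.shape[1]),
        "n_panel_snps": int(0 if cohort.panel_dosages is None else cohort.panel_dosages.shape[1]),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    return d


def read_cohort(directory: str | Path) -> tuple[Cohort, pd.DataFrame]:
    """Read a cohort written by `write_cohort`, validating schema and bounds."""
    d = Path(directory)
    subj = pd.read_csv(d / "subjects.csv", index_col="subject_id")
    required = {"is_case", "acpa_positive", "age", "sex", "hap1", "hap2"}
    missing = required - set(subj.columns)
    if missing:
        raise ValueError(f"subjects.csv missing required columns: {sorted(missing)}")
    subj["is_case"] = subj["is_case"].astype(bool)
    subj["acpa_positive"] = subj["acpa_positive"].astype("boolean")
    for h in pd.concat([subj["hap1"], subj["hap2"]]).unique():
        hla.validate_haplotype(h)

    snps = pd.read_csv(d / "snp_dosages.tsv", sep="\t", index_col="subject_id")
    _check_dosage_frame(snps, "snp_dosages.tsv")
    panel = None
    if (d / "panel_dosages.tsv").exists():
        panel = pd.read_csv(d / "panel_dosages.tsv", sep="\t", index_col="subject_id")
        _check_dosage_frame(panel, "panel_dosages.tsv")

    visits = pd.read_csv(d / "visits.csv")
    from .outcomes import VISIT_COLUMNS

    missing = set(VISIT_COLUMNS) - set(visits.columns)
    if missing:
        raise ValueError(f"visits.csv missing required columns: {sorted(missing)}")

    cohort = Cohort(subjects=subj, snp_dosages=snps, panel_dosages=panel)
    if (d / "hla.csv").exists():
        stored = pd.read_csv(d / "hla.csv", index_col="subject_id")
        res = cohort.residue_dosages()
        for pos, df in res.items():
            for col in df.columns:
                name = f"pos{pos}_{col}"
                if name in stored.columns and not np.array_equal(
                    stored[name].to_numpy(), df[col].to_numpy()
                ):
                    raise ValueError(
                        f"hla.csv residue column {name} inconsistent with haplotype pairs"
                    )
    return cohort, visits


def write_weights(weights: WeightSet, directory: str | Path, effect_alleles=None) -> Path:
    """Write the three weight tables (SNP weights as snp_id/effect_allele/lnOR)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    snp_ids = list(weights.snp_weights)
    ea = effect_alleles if effect_alleles is not None else ["A"] * len(snp_ids)
    pd.DataFrame(
        {"snp_id": snp_ids, "effect_allele": ea, "lnOR": [weights.snp_weights[s] for s in snp_ids]}
    ).to_csv(d / "weights.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(p, r, w) for (p, r), w in weights.residue_weights.items()],
        columns=["position", "residue", "lnOR"],
    ).to_csv(d / "residue_weights.csv", index=False)
    pd.DataFrame(
        sorted(weights.haplotype_weights.items()), columns=["haplotype", "lnOR"]
    ).to_csv(d / "haplotype_weights.csv", index=False)
    return d


def read_weights(directory: str | Path) -> WeightSet:
    d = Path(directory)
    snp = pd.read_csv(d / "weights.tsv", sep="\t")
    for col in ("snp_id", "lnOR"):
        if col not in snp.columns:
            raise ValueError(f"weights.tsv missing column {col!r}")
    res = pd.read_csv(d / "residue_weights.csv")
    haps = pd.read_csv(d / "haplotype_weights.csv")
    return WeightSet(
        snp_weights=dict(zip(snp["snp_id"], snp["lnOR"].astype(float))),
        residue_weights={
            (int(p), r): float(w)
            for p, r, w in zip(res["position"], res["residue"], res["lnOR"])
        },
        haplotype_weights=dict(zip(haps["haplotype"], haps["lnOR"].astype(float))),
    )


def read_vcf_dosages(path: str | Path) -> pd.DataFrame:
    """Dosage matrix (subjects x variants) from a VCF (v4.x).

    Uses the DS FORMAT field when present, otherwise the count of alternate
    alleles in GT. Missing genotypes become NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            vals = np.where((gt < 0).any(axis=1), np.nan, (gt > 0).sum(axis=1)).astype(float)
        cols[vid] = vals
    out = pd.DataFrame(cols, index=pd.Index(samples, name="subject_id"))
    with np.errstate(invalid="ignore"):
        if np.any((out.to_numpy() < 0) | (out.to_numpy() > 2)):
            raise ValueError("VCF dosages outside [0, 2]")
    return out
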