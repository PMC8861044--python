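"""Variant-effect classes and rare-variant burden statistics.

Effect classes: nondisrupting (ND) = exonic synonymous SNVs and exonic
non-frameshift indels; missense damaging (MD) = exonic nonsynonymous SNVs
meeting at least two of four damage-predictor thresholds (SIFT < 0.05,
PolyPhen-2 HumVar > 0.15, PROVEAN < -2.5, MutationAssessor > 2.26);
loss of function (LoF) = splice site variants and exonic stopgain,
stoploss or frameshift variants.  Burden contrasts compare variant rates
per 10^8 bp inside vs outside ROHs, the per-sample fraction of rare
homozygous variants falling inside ROHs against the genome fraction under
ROHs, and gnomAD-style constraint scores (pLI/pRec/pNull) between ROH and
non-ROH gene sets; group tests use Welch's unpaired t-test by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import VariantSite

EFFECT_CLASSES = ("ND", "MD", "LoF", "unclassified")

LOF_EFFECTS = ("splicing", "stopgain", "stoploss", "frameshift_indel")
ND_EFFECTS = ("synonymous_SNV", "nonframeshift_indel")

MD_THRESHOLDS = {
    "sift": ("<", 0.05),
    "polyphen2_hvar": (">", 0.15),
    "provean": ("<", -2.5),
    "mutation_assessor": (">", 2.26),
}

PER_BP_SCALE = 1e8


def md_criteria(
    sift: Optional[float],
    polyphen2_hvar: Optional[float],
    provean: Optional[float],
    mutation_assessor: Optional[float],
) -> dict[str, bool]:
    """The four damage-predictor criteria; a missing score fails its criterion."""

    def ok(value, op, thr):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return False
        return value < thr if op == "<" else value > thr

    scores = {
        "sift": sift,
        "polyphen2_hvar": polyphen2_hvar,
        "provean": provean,
        "mutation_assessor": mutation_assessor,
    }
    return {k: ok(scores[k], *MD_THRESHOLDS[k]) for k in MD_THRESHOLDS}


def classify_effect(site: VariantSite) -> str:
    """ND / MD / LoF / unclassified effect class of a variant."""
    eff = site.effect_annotation
    if eff in LOF_EFFECTS:
        return "LoF"
    if eff in ND_EFFECTS:
        return "ND"
    if eff == "nonsynonymous_SNV":
        n_met = sum(
            md_criteria(
                site.sift, site.polyphen2_hvar, site.provean, site.mutation_assessor
            ).values()
        )
        return "MD" if n_met >= 2 else "unclassified"
    return "unclassified"


def _welch(a: Sequence[float], b: Sequence[float], equal_var: bool = False):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return np.nan, np.nan
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 0.0, 1.0  # identical constant groups
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class BurdenResult:
    per_sample: pd.DataFrame  # sample, class, inside, outside counts and rates
    tests: pd.DataFrame  # contrast, class, t, p


def roh_burden_rates(
    variants: pd.DataFrame,
    roh_total_bp: Mapping[str, int],
    genome_length: int,
    classes: Sequence[str] = ("LoF/MD", "ND"),
    equal_var: bool = False,
) -> BurdenResult:
    """Rates per 10^8 bp inside and outside ROHs, per sample and class.

    ``variants`` needs columns sample, effect_class, in_roh (bool).  The
    inside denominator is each sample's total ROH length; the outside
    denominator is the remaining genome.  Classes group LoF and MD into
    the combined damaging class.  Inside-vs-outside rate contrasts use an
    unpaired t-test across individuals.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    df = variants.copy()
    df["grp"] = np.where(df["effect_class"].isin(["LoF", "MD"]), "LoF/MD", df["effect_class"])
    rows = []
    for sample, bp in roh_total_bp.items():
        if bp <= 0 or genome_length - bp <= 0:
            raise ValueError(f"zero-length denominator for {sample}")
        sub = df[df["sample"] == sample]
        for cls in classes:
            inside = int(((sub["grp"] == cls) & sub["in_roh"]).sum())
            outside = int(((sub["grp"] == cls) & ~sub["in_roh"]).sum())
            rows.append(
                {
                    "sample": sample,
                    "class": cls,
                    "inside_count": inside,
                    "outside_count": outside,
                    "total_count": inside + outside,
                    "inside_rate": inside / bp * PER_BP_SCALE,
                    "outside_rate": outside / (genome_length - bp) * PER_BP_SCALE,
                }
            )
    per_sample = pd.DataFrame(rows)
    tests = []
    for cls in classes:
        sub = per_sample[per_sample["class"] == cls]
        t, p = _welch(sub["inside_rate"], sub["outside_rate"], equal_var)
        tests.append({"contrast": "inside_vs_outside_rate", "class": cls, "t": t, "p": p})
    return BurdenResult(per_sample, pd.DataFrame(tests))


def hom_fraction_in_roh(
    rare_hom_variants: pd.DataFrame,
    genome_fraction: Mapping[str, float],
    equal_var: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample percentage of rare homozygous variants inside ROHs.

    Computed for the classes all / LoF/MD / ND and contrasted (unpaired
    t-test across samples) against the percentage of the genome under ROHs
    and between LoF/MD and ND.  Samples with zero variants in a class are
    excluded from that class with a note column.
    """
    df = rare_hom_variants.copy()
    df["grp"] = np.where(df["effect_class"].isin(["LoF", "MD"]), "LoF/MD", df["effect_class"])
    rows = []
    for sample in genome_fraction:
        sub = df[df["sample"] == sample]
        for cls in ("all", "LoF/MD", "ND"):
            s = sub if cls == "all" else sub[sub["grp"] == cls]
            n = len(s)
            rows.append(
                {
                    "sample": sample,
                    "class": cls,
                    "n_variants": n,
                    "pct_in_roh": 100.0 * s["in_roh"].mean() if n else np.nan,
                    "genome_pct": 100.0 * genome_fraction[sample],
                    "note": "" if n else "no variants; excluded",
                }
            )
    fr = pd.DataFrame(rows)
    tests = []
    for cls in ("all", "LoF/MD", "ND"):
        sub = fr[(fr["class"] == cls) & fr["pct_in_roh"].notna()]
        t, p = _welch(sub["pct_in_roh"], sub["genome_pct"], equal_var)
        tests.append({"contrast": "pct_in_roh_vs_genome_pct", "class": cls, "t": t, "p": p})
    a = fr[(fr["class"] == "LoF/MD") & fr["pct_in_roh"].notna()]["pct_in_roh"]
    b = fr[(fr["class"] == "ND") & fr["pct_in_roh"].notna()]["pct_in_roh"]
    t, p = _welch(a, b, equal_var)
    tests.append({"contrast": "LoF/MD_vs_ND_pct", "class": "LoF/MD|ND", "t": t, "p": p})
    return fr, pd.DataFrame(tests)


@dataclass(frozen=True)
class ConstraintSummary:
    gene_set: str  # ROH | non_ROH
    n_genes: int
    mean_pli: float
    mean_prec: float
    mean_pnull: float
    n_dropped: int  # genes absent from the constraint table


def constraint_comparison(
    genes_roh: Sequence[str],
    genes_non_roh: Sequence[str],
    constraint_table: pd.DataFrame,
    equal_var: bool = False,
) -> tuple[ConstraintSummary, ConstraintSummary, pd.DataFrame]:
    """Mean pLI/pRec/pNull of ROH vs non-ROH gene sets with t-tests.

    ``constraint_table`` maps gene -> pli, prec, pnull; genes absent from
    the table are dropped and counted.
    """
    tbl = constraint_table.set_index(constraint_table["gene"].str.upper())

    def subset(genes, tag):
        keys = [g.upper() for g in genes]
        present = [k for k in keys if k in tbl.index]
        if not present:
            raise ValueError(f"empty gene set for {tag} after table lookup")
        sub = tbl.loc[present]
        return sub, ConstraintSummary(
            tag,
            len(present),
            float(sub["pli"].mean()),
            float(sub["prec"].mean()),
            float(sub["pnull"].mean()),
            len(keys) - len(present),
        )

    sub_r, sum_r = subset(genes_roh, "ROH")
    sub_n, sum_n = subset(genes_non_roh, "non_ROH")
    tests = []
    for score in ("pli", "prec", "pnull"):
        t, p = _welch(sub_r[score], sub_n[score], equal_var)
        tests.append({"score": score, "t": t, "p": p})
    return sum_r, sum_n, pd.DataFrame(tests)


def group_burden(
    counts: pd.DataFrame,
    affection: Mapping[str, bool],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Affected-vs-unaffected per-class burden comparison.

    ``counts`` needs columns sample, effect_class, n.  Requires at least
    two individuals per group; returns group means and unpaired t-tests
    per class.
    """
    aff = [s for s, a in affection.items() if a]
    unaff = [s for s, a in affection.items() if not a]
    if len(aff) < 2 or len(unaff) < 2:
        raise ValueError("need >= 2 individuals per group")
    rows = []
    for cls in counts["effect_class"].unique():
        sub = counts[counts["effect_class"] == cls].set_index("sample")["n"]
        a = sub.reindex(aff).fillna(0).to_numpy(dtype=float)
        u = sub.reindex(unaff).fillna(0).to_numpy(dtype=float)
        t, p = _welch(a, u, equal_var)
        rows.append(
            {
                "class": cls,
                "mean_affected": float(a.mean()),
                "mean_unaffected": float(u.mean()),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
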