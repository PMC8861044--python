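"""Multi-criteria prioritization of candidate variants.

Candidate inheritance calls are filtered to potentially pathogenic effects
(frameshift, stopgain/stoploss, deleterious nonsynonymous, splice site,
unknown effect), deprioritized on subpopulation frequency evidence (coding
MAF >= 1%; noncoding MAF > 0.1% or any homozygote), cross-referenced
against ASD/NDD gene lists, OMIM phenotypes and brain-expression tables,
and assigned a high/medium/low/excluded tier from an editable, auditable
rule table: the tier is a pure function of the emitted rationale vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .burden import md_criteria
from .variants import VariantSite

TIERS = ("high", "medium", "low", "excluded")

PATHOGENIC_EFFECTS = (
    "frameshift_indel",
    "stopgain",
    "stoploss",
    "splicing",
    "unknown",
)


@dataclass(frozen=True)
class GeneEvidence:
    gene: str
    sfari_listed: bool = False
    sfari_score: Optional[str] = None
    ndd_listed: bool = False
    omim_phenotypes: tuple[str, ...] = ()
    brain_expressed: bool = False

    @property
    def known_gene(self) -> bool:
        return self.sfari_listed or self.ndd_listed


@dataclass
class PriorityCall:
    variant_ref: str
    sample: str
    inheritance_mode: str
    tier: str
    rationale: list[tuple[str, bool]]

    def rationale_dict(self) -> dict[str, bool]:
        return dict(self.rationale)


@dataclass(frozen=True)
class CnvCall:
    sample: str
    chromosome: str
    start: int
    end: int
    direction: str  # amplification | deletion

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must be > start")

    @property
    def length(self) -> int:
        return self.end - self.start


def is_deleterious_missense(site: VariantSite) -> tuple[bool, dict[str, bool]]:
    """>= 2 of the four damage-predictor thresholds, with the criteria vector."""
    crit = md_criteria(
        site.sift, site.polyphen2_hvar, site.provean, site.mutation_assessor
    )
    return sum(crit.values()) >= 2, crit


def candidate_filter(
    calls: pd.DataFrame, drop_log: Optional[list] = None
) -> pd.DataFrame:
    """Retain potentially pathogenic calls.

    ``calls`` needs columns effect and, for nonsynonymous SNVs, the four
    damage scores.  Retained: frameshift / stopgain / stoploss / splicing /
    unknown effect, plus nonsynonymous SNVs passing the >= 2-of-4
    deleteriousness rule; everything else is dropped with a reason.
    """
    keep = np.zeros(len(calls), dtype=bool)
    reasons = []
    for i, (_, r) in enumerate(calls.iterrows()):
        eff = r["effect"]
        if eff in PATHOGENIC_EFFECTS:
            keep[i] = True
        elif eff == "nonsynonymous_SNV":
            crit = md_criteria(
                r.get("sift"), r.get("polyphen2_hvar"),
                r.get("provean"), r.get("mutation_assessor"),
            )
            if sum(crit.values()) >= 2:
                keep[i] = True
            else:
                reasons.append((i, "nonsynonymous but not deleterious (<2 criteria)"))
        else:
            reasons.append((i, f"effect {eff} not potentially pathogenic"))
    if drop_log is not None:
        drop_log.extend(reasons)
    return calls[keep].reset_index(drop=True)


def subpop_deprioritize(
    subpop_afs: Mapping[str, tuple[float, int]],
    is_coding: bool,
    relevant_subpops: Sequence[str],
    coding_maf: float = 0.01,
    noncoding_maf: float = 0.001,
) -> bool:
    """True when subpopulation frequency evidence deprioritizes the variant.

    Coding: MAF >= 1% in any relevant subpopulation.  Noncoding: MAF >
    0.1% or any homozygote observed.  A subpopulation missing from the map
    contributes no evidence.
    """
    for name in relevant_subpops:
        if name not in subpop_afs:
            continue
        af, hom = subpop_afs[name]
        maf = min(af, 1 - af)
        if is_coding:
            if maf >= coding_maf:
                return True
        else:
            if maf > noncoding_maf or hom >= 1:
                return True
    return False


def cross_reference(
    gene: str,
    sfari_table: Optional[pd.DataFrame] = None,
    ndd_table: Optional[pd.DataFrame] = None,
    omim_table: Optional[pd.DataFrame] = None,
    expression_table: Optional[pd.DataFrame] = None,
    alias_map: Optional[Mapping[str, str]] = None,
) -> GeneEvidence:
    """Gene-list evidence by exact case-insensitive symbol match.

    Tables carry a ``gene`` column; the SFARI table may add ``score``, the
    OMIM table ``phenotype``, the expression table ``brain_expressed``.
    """
    key = gene.upper()
    if alias_map:
        key = {k.upper(): v.upper() for k, v in alias_map.items()}.get(key, key)

    def lookup(tbl):
        if tbl is None or len(tbl) == 0:
            return None
        m = tbl[tbl["gene"].str.upper() == key]
        return m if len(m) else None

    sfari = lookup(sfari_table)
    ndd = lookup(ndd_table)
    omim = lookup(omim_table)
    expr = lookup(expression_table)
    return GeneEvidence(
        gene=gene,
        sfari_listed=sfari is not None,
        sfari_score=str(sfari.iloc[0]["score"]) if sfari is not None and "score" in sfari else None,
        ndd_listed=ndd is not None,
        omim_phenotypes=tuple(omim["phenotype"]) if omim is not None and "phenotype" in omim else (),
        brain_expressed=bool(expr.iloc[0]["brain_expressed"]) if expr is not None else False,
    )


def cnv_overlap_filter(
    cnvs: Sequence[CnvCall], sfari_cnv_table: pd.DataFrame
) -> list[tuple[CnvCall, str]]:
    """Retain CNVs overlapping a known ASD CNV locus and larger than that
    locus's median size in ASD cases; each retained CNV is annotated with
    its matched locus."""
    required = {"chrom", "start", "end", "locus", "median_size_bp"}
    if not required.issubset(sfari_cnv_table.columns):
        raise ValueError(f"SFARI CNV table needs columns {sorted(required)}")
    out = []
    for cnv in cnvs:
        for _, r in sfari_cnv_table.iterrows():
            if (
                cnv.chromosome == r["chrom"]
                and cnv.start < int(r["end"])
                and int(r["start"]) < cnv.end
                and cnv.length > int(r["median_size_bp"])
            ):
                out.append((cnv, str(r["locus"])))
                break
    return out


#: rationale criteria, in emission order
RATIONALE_KEYS = (
    "deprioritized",
    "is_coding",
    "known_gene",
    "brain_expressed",
    "deleterious",
    "brain_specific_element",
    "interaction_validated",
)


def tier_from_rationale(r: Mapping[str, bool]) -> str:
    """Deterministic tier from a rationale vector (the shipped rule table).

    Excluded: deprioritized by subpopulation evidence.  High: known
    ASD/NDD gene, or (coding) brain-expressed and deleterious, or
    (noncoding) brain-specific element with a validated promoter/enhancer
    interaction.  Medium: one of those evidence legs.  Low: none.
    """
    if r["deprioritized"]:
        return "excluded"
    if r["is_coding"]:
        strong = r["known_gene"] or (r["brain_expressed"] and r["deleterious"])
        partial = r["brain_expressed"] or r["deleterious"]
    else:
        strong = r["known_gene"] or (
            r["brain_specific_element"] and r["interaction_validated"]
        )
        partial = r["brain_specific_element"] or r["interaction_validated"]
    if strong:
        return "high"
    if partial:
        return "medium"
    return "low"


def assign_tier(
    variant_ref: str,
    sample: str,
    inheritance_mode: str,
    gene_evidence: GeneEvidence,
    is_coding: bool,
    deleterious: bool,
    deprioritized: bool,
    brain_specific_element: bool = False,
    interaction_validated: bool = False,
) -> PriorityCall:
    """Build the rationale vector and derive the tier from it."""
    rationale = [
        ("deprioritized", deprioritized),
        ("is_coding", is_coding),
        ("known_gene", gene_evidence.known_gene),
        ("brain_expressed", gene_evidence.brain_expressed),
        ("deleterious", deleterious),
        ("brain_specific_element", brain_specific_element),
        ("interaction_validated", interaction_validated),
    ]
    return PriorityCall(
        variant_ref=variant_ref,
        sample=sample,
        inheritance_mode=inheritance_mode,
        tier=tier_from_rationale(dict(rationale)),
        rationale=rationale,
    )


def per_sample_report(calls: Sequence[PriorityCall]) -> pd.DataFrame:
    """Candidate report: high-priority calls per sample, falling back to
    medium-priority calls for samples with no high-priority variant."""
    rows = [
        {
            "sample": c.sample,
            "variant": c.variant_ref,
            "inheritance": c.inheritance_mode,
            "tier": c.tier,
            **{f"crit_{k}": v for k, v in c.rationale},
        }
        for c in calls
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    keep = []
    for sample, sub in df.groupby("sample"):
        if (sub["tier"] == "high").any():
            keep.append(sub[sub["tier"] == "high"])
        else:
            keep.append(sub[sub["tier"] == "medium"])
    return pd.concat(keep, ignore_index=True) if keep else df.iloc[:0]
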