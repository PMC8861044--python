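"""Inheritance-model variant calling for affected offspring.

Four candidate classes per affected child of a sequenced trio:

* de novo — allele in the child absent from both parents (and sibling when
  available), with allele-balance, call-quality, population-frequency,
  cohort-uniqueness, indel-size and repeat-region guards;
* compound heterozygous — two rare coding heterozygous variants in one
  gene, one transmitted from each parent;
* inherited homozygous — child homozygous, both parents heterozygous
  (parental homozygosity excluded under full penetrance);
* X-linked recessive — hemizygous in a male child, heterozygous in the
  mother, absent from the father, with pseudoautosomal exclusions.

Each call carries an evidence map (criterion -> pass/fail) so the decision
is auditable; a site with a missing required genotype is skipped with a
reason, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Chromosome
from .pedigree import MALE, Pedigree
from .variants import (
    CohortTable,
    GenotypeCall,
    VariantSite,
    classify_frequency,
    qc_pass,
)

MODES = ("de_novo", "compound_het", "hom_inherited", "x_linked")


@dataclass
class InheritanceCall:
    sample_id: str
    mode: str
    sites: list[VariantSite]
    evidence: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.evidence.values())


@dataclass(frozen=True)
class DeNovoParams:
    ab_range: tuple[float, float] = (0.3, 0.7)
    ab_min_male_xy: float = 0.7
    min_qd: float = 4.0
    min_rprs: float = -2.5
    max_af: float = 0.001
    max_indel_bp: int = 50


def _missing(*calls: Optional[GenotypeCall]) -> bool:
    return any(c is None or c.gt == "missing" for c in calls)


def call_de_novo(
    site: VariantSite,
    child: GenotypeCall,
    father: GenotypeCall,
    mother: GenotypeCall,
    child_is_male: bool,
    on_male_xy: bool,
    sibling: Optional[GenotypeCall] = None,
    other_rare_carriers: int = 0,
    params: DeNovoParams = DeNovoParams(),
) -> tuple[bool, dict[str, bool]]:
    """De novo test with the full criteria vector as evidence.

    ``on_male_xy`` selects the hemizygous allele-balance branch (>= 0.7 on
    X/Y in male probands; 0.3-0.7 otherwise).  ``other_rare_carriers`` is
    the number of cohort individuals outside the trio (and sibling) that
    carry the allele as a rare variant.
    """
    if _missing(child, father, mother):
        raise MissingGenotype("required trio genotype missing")
    ab = child.allele_balance
    if on_male_xy and child_is_male:
        ab_ok = bool(ab >= params.ab_min_male_xy)
    else:
        ab_ok = bool(params.ab_range[0] <= ab <= params.ab_range[1])
    afs = site.database_afs
    ev = {
        "child_carries_alt": child.carries_alt,
        "absent_in_parents": not father.carries_alt and not mother.carries_alt,
        "absent_in_sibling": sibling is None or not sibling.carries_alt,
        "allele_balance": ab_ok,
        "qd": bool(site.qd >= params.min_qd),
        "read_pos_rank_sum": bool(site.read_pos_rank_sum >= params.min_rprs),
        "no_other_rare_carrier": other_rare_carriers == 0,
        "rare_in_databases": all(a < params.max_af for a in afs),
        "indel_size": site.indel_length < params.max_indel_bp,
        "outside_repeats": not site.in_segdup and not site.in_simple_repeat,
    }
    return all(ev.values()), ev


class MissingGenotype(Exception):
    """A genotype required by an inheritance model is missing."""


def call_hom_inherited(
    site: VariantSite,
    child: GenotypeCall,
    father: GenotypeCall,
    mother: GenotypeCall,
    unaffected_sibling: Optional[GenotypeCall] = None,
) -> tuple[bool, dict[str, bool]]:
    """Inherited-homozygous test: child hom-alt, both parents het.

    Parental homozygosity disqualifies (full-penetrance assumption), as
    does homozygosity in an unaffected sibling.
    """
    if _missing(child, father, mother):
        raise MissingGenotype("required trio genotype missing")
    ev = {
        "child_hom_alt": child.gt == "hom_alt",
        "father_het": father.gt == "het",
        "mother_het": mother.gt == "het",
        "neither_parent_hom": father.gt != "hom_alt" and mother.gt != "hom_alt",
        "not_hom_in_unaffected_sibling": (
            unaffected_sibling is None or unaffected_sibling.gt != "hom_alt"
        ),
    }
    return all(ev.values()), ev


def call_x_linked(
    site: VariantSite,
    chromosome: Chromosome,
    child: GenotypeCall,
    father: GenotypeCall,
    mother: GenotypeCall,
    child_is_male: bool,
) -> tuple[bool, dict[str, bool]]:
    """X-linked recessive test for a male child.

    Non-PAR: child hemizygous alt, mother het, father non-carrier.
    Pseudoautosomal sites heterozygous in the male child are excluded.
    """
    if not chromosome.is_x:
        raise ValueError("call_x_linked requires an X-chromosome site")
    if _missing(child, father, mother):
        raise MissingGenotype("required trio genotype missing")
    in_par = chromosome.in_par(site.position)
    ev = {
        "male_child": child_is_male,
        "non_par": not in_par,
        "not_het_in_par": not (in_par and child.gt == "het"),
        "child_hemi_alt": child.gt == "hemi_alt",
        "mother_het": mother.gt == "het",
        "father_non_carrier": not father.carries_alt,
    }
    return all(ev.values()), ev


def call_compound_het(
    child_id: str,
    sites_and_calls: Sequence[tuple[VariantSite, GenotypeCall, GenotypeCall, GenotypeCall]],
) -> list[InheritanceCall]:
    """Pair rare coding heterozygous variants with opposite parental origin.

    Input tuples are (site, child, father, mother) restricted upstream to
    rare, exonic-or-splicing, QC-passing sites where the child is
    heterozygous.  Sites heterozygous in both parents are phase-ambiguous
    and excluded from pairing.  Returns one call per qualifying pair,
    grouped by gene.
    """
    by_gene: dict[str, dict[str, list[VariantSite]]] = {}
    for site, child, father, mother in sites_and_calls:
        if site.gene is None or child.gt != "het" or not site.is_coding:
            continue
        pa, ma = father.carries_alt, mother.carries_alt
        if pa and not ma:
            origin = "paternal"
        elif ma and not pa:
            origin = "maternal"
        else:
            continue  # untransmitted or ambiguous
        by_gene.setdefault(site.gene, {"paternal": [], "maternal": []})[origin].append(site)
    calls = []
    for gene, groups in sorted(by_gene.items()):
        for pat, mat in product(groups["paternal"], groups["maternal"]):
            calls.append(
                InheritanceCall(
                    sample_id=child_id,
                    mode="compound_het",
                    sites=[pat, mat],
                    evidence={
                        "same_gene": True,
                        "paternal_and_maternal": True,
                        "both_het_in_child": True,
                    },
                )
            )
    return calls


# -- cohort-level scan ---------------------------------------------------


@dataclass
class ScanResult:
    calls: list[InheritanceCall]
    skipped: pd.DataFrame  # sites skipped per mode with reasons

    def frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            for s in c.sites:
                rows.append(
                    {
                        "sample": c.sample_id,
                        "mode": c.mode,
                        "chrom": s.chromosome,
                        "pos": s.position,
                        "ref": s.ref,
                        "alt": s.alt,
                        "gene": s.gene,
                        "effect": s.effect_annotation,
                        **{f"ev_{k}": v for k, v in c.evidence.items()},
                    }
                )
        return pd.DataFrame(rows)


def scan_cohort(
    table: CohortTable,
    pedigree: Optional[Pedigree] = None,
    chromosomes: Optional[Sequence[Chromosome]] = None,
    maf_rare: float = 0.01,
    de_novo_params: DeNovoParams = DeNovoParams(),
) -> ScanResult:
    """Call all four inheritance modes for every affected non-founder.

    Applies per-genotype QC to the trio, restricts to rare variants
    (de novo uses its stricter 0.1% bound internally), and counts
    rare-variant carriers elsewhere in the cohort for the de novo
    uniqueness criterion.
    """
    ped = pedigree or table.pedigree
    if ped is None:
        raise ValueError("a pedigree is required")
    by_name = {c.name: c for c in (chromosomes or [])}
    qc = table.qc_mask()
    rare = table.rare_mask(maf_rare)
    carriers = np.isin(table.gt, (1, 2, 4))
    calls: list[InheritanceCall] = []
    skipped_rows: list[dict] = []

    for child in ped.affected:
        if child.is_founder:
            continue
        ci = table.sample_index(child.sample_id)
        fi = table.sample_index(child.father_id)
        mi = table.sample_index(child.mother_id)
        sibs = ped.siblings_of(child.sample_id)
        unaffected_sibs = [s for s in sibs if not s.affected]
        ch_sites: list[tuple[VariantSite, GenotypeCall, GenotypeCall, GenotypeCall]] = []
        family = {ci, fi, mi} | {table.sample_index(s.sample_id) for s in sibs}
        others = np.array([j for j in range(len(table.samples)) if j not in family], dtype=int)

        for i in np.where(rare)[0]:
            if not (qc[i, ci] and qc[i, fi] and qc[i, mi]):
                if table.gt[i, ci] != 0 and table.gt[i, ci] != 3:
                    skipped_rows.append(
                        {
                            "sample": child.sample_id,
                            "chrom": table.sites.at[i, "chrom"],
                            "pos": int(table.sites.at[i, "pos"]),
                            "reason": "trio genotype failed QC or missing",
                        }
                    )
                continue
            site = table.site(i)
            chrom = by_name.get(site.chromosome)
            is_x = chrom.is_x if chrom else site.chromosome in ("chrX", "X")
            c_call = table.call(i, child.sample_id)
            f_call = table.call(i, child.father_id)
            m_call = table.call(i, child.mother_id)
            sib_calls = [table.call(i, s.sample_id) for s in sibs]
            n_other = int(carriers[i, others].sum()) if len(others) else 0

            if c_call.carries_alt:
                sib = sib_calls[0] if sib_calls else None
                on_male_xy = is_x and not (chrom.in_par(site.position) if chrom else False)
                ok, ev = call_de_novo(
                    site, c_call, f_call, m_call,
                    child_is_male=child.sex == MALE,
                    on_male_xy=on_male_xy,
                    sibling=sib,
                    other_rare_carriers=n_other,
                    params=de_novo_params,
                )
                if ok:
                    calls.append(InheritanceCall(child.sample_id, "de_novo", [site], ev))

            if not is_x:
                usib = (
                    table.call(i, unaffected_sibs[0].sample_id)
                    if unaffected_sibs
                    else None
                )
                ok, ev = call_hom_inherited(site, c_call, f_call, m_call, usib)
                if ok:
                    calls.append(
                        InheritanceCall(child.sample_id, "hom_inherited", [site], ev)
                    )
                if c_call.gt == "het":
                    ch_sites.append((site, c_call, f_call, m_call))
            elif chrom is not None and child.sex == MALE:
                ok, ev = call_x_linked(
                    site, chrom, c_call, f_call, m_call, child_is_male=True
                )
                if ok:
                    calls.append(InheritanceCall(child.sample_id, "x_linked", [site], ev))

        calls.extend(call_compound_het(child.sample_id, ch_sites))

    skipped = pd.DataFrame(skipped_rows, columns=["sample", "chrom", "pos", "reason"])
    return ScanResult(calls, skipped)
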