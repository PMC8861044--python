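"""Variant and genotype model, VCF I/O, quality filtering, frequency classes.

The cohort lives in a :class:`CohortTable`: a site table (one row per
decomposed alternate allele, with population allele frequencies, damage
and conservation scores, and repeat-region flags) aligned with integer
genotype/GQ/allele-depth matrices across samples.  Single-site views are
exposed as :class:`VariantSite` / :class:`GenotypeCall` dataclasses.

Genotype codes: -1 missing, 0 hom-ref, 1 het, 2 hom-alt, 3 hemizygous-ref,
4 hemizygous-alt (hemizygous states only on the non-PAR X in males).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .pedigree import Pedigree

GT_MISSING = -1
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_HEMI_REF = 3
GT_HEMI_ALT = 4

ALT_CARRIER_CODES = (GT_HET, GT_HOM_ALT, GT_HEMI_ALT)

EFFECTS = (
    "synonymous_SNV",
    "nonsynonymous_SNV",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "splicing",
    "intronic",
    "intergenic",
    "UTR",
    "unknown",
)

CODING_EFFECTS = (
    "synonymous_SNV",
    "nonsynonymous_SNV",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "splicing",
)

#: columns of CohortTable.sites, in canonical order
SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "filter",
    "qd",
    "read_pos_rank_sum",
    "gene",
    "effect",
    "af_1000g",
    "af_gnomad",
    "af_gme",
    "sift",
    "polyphen2_hvar",
    "provean",
    "mutation_assessor",
    "cadd",
    "phastcons",
    "phylop",
    "gerp",
    "in_segdup",
    "in_simple_repeat",
    "subpop",
]


@dataclass
class VariantSite:
    chromosome: str
    position: int  # 1-based
    ref: str
    alt: str
    filter_status: str = "PASS"
    qd: float = np.nan
    read_pos_rank_sum: float = np.nan
    gene: Optional[str] = None
    effect_annotation: str = "unknown"
    af_1000g: Optional[float] = None  # None = absent from the database
    af_gnomad: Optional[float] = None
    af_gme: Optional[float] = None
    subpop_afs: dict[str, tuple[float, int]] = field(default_factory=dict)
    sift: Optional[float] = None
    polyphen2_hvar: Optional[float] = None
    provean: Optional[float] = None
    mutation_assessor: Optional[float] = None
    cadd: Optional[float] = None
    phastcons: Optional[float] = None
    phylop: Optional[float] = None
    gerp: Optional[float] = None
    in_segdup: bool = False
    in_simple_repeat: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.ref == self.alt:
            raise ValueError("alt must differ from ref")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def database_afs(self) -> tuple[float, float, float]:
        """AFs in the three population databases; absent is treated as 0."""
        return tuple(
            0.0 if v is None or (isinstance(v, float) and np.isnan(v)) else float(v)
            for v in (self.af_1000g, self.af_gnomad, self.af_gme)
        )

    @property
    def is_coding(self) -> bool:
        return self.effect_annotation in CODING_EFFECTS


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    gt: str  # hom_ref | het | hom_alt | hemi_ref | hemi_alt | missing
    gq: int
    allele_depths: tuple[int, int]  # (ref_reads, alt_reads)

    @property
    def carries_alt(self) -> bool:
        return self.gt in ("het", "hom_alt", "hemi_alt")

    @property
    def allele_balance(self) -> float:
        ref_r, alt_r = self.allele_depths
        total = ref_r + alt_r
        return alt_r / total if total else np.nan


_CODE_TO_GT = {
    GT_MISSING: "missing",
    GT_HOM_REF: "hom_ref",
    GT_HET: "het",
    GT_HOM_ALT: "hom_alt",
    GT_HEMI_REF: "hemi_ref",
    GT_HEMI_ALT: "hemi_alt",
}
GT_TO_CODE = {v: k for k, v in _CODE_TO_GT.items()}


@dataclass(frozen=True)
class FrequencyClass:
    value: str  # common | rare | ultra_rare
    private_flag: bool = False

    def __post_init__(self) -> None:
        if self.private_flag and self.value != "ultra_rare":
            raise ValueError("private implies ultra_rare")

    @property
    def is_rare(self) -> bool:
        return self.value in ("rare", "ultra_rare")


def classify_frequency(
    site: VariantSite, cohort_carriers: int = 0, maf_rare: float = 0.01
) -> FrequencyClass:
    """Population-frequency class of a variant.

    Rare: AF < ``maf_rare`` in all three databases.  Ultra-rare: AF = 0 (or
    absent) in all three.  Private: ultra-rare and carried by exactly one
    cohort individual.
    """
    afs = site.database_afs
    if all(a == 0.0 for a in afs):
        return FrequencyClass("ultra_rare", private_flag=cohort_carriers == 1)
    if all(a < maf_rare for a in afs):
        return FrequencyClass("rare")
    return FrequencyClass("common")


def qc_pass(
    site: VariantSite,
    call: GenotypeCall,
    min_gq: int = 99,
    min_ad: int = 10,
    pass_only: bool = True,
    ad_mode: str = "called_allele",
) -> bool:
    """Per-genotype quality filter: PASS, GQ >= 99, allelic depth >= 10.

    The depth requirement applies to the called allele(s): alt-supporting
    reads for alt-carrying genotypes, reference reads otherwise
    (``ad_mode="total"`` switches to ref+alt depth).
    """
    if pass_only and site.filter_status != "PASS":
        return False
    if call.gt == "missing" or call.gq < min_gq:
        return False
    ref_r, alt_r = call.allele_depths
    if ad_mode == "total":
        return ref_r + alt_r >= min_ad
    if call.carries_alt:
        return alt_r >= min_ad
    return ref_r >= min_ad


class CohortTable:
    """Site-by-sample genotype table for a cohort.

    ``sites`` is a DataFrame with :data:`SITE_COLUMNS`; ``gt``/``gq``/
    ``ad_ref``/``ad_alt`` are (n_sites, n_samples) arrays aligned with
    ``samples``.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        samples: list[str],
        gt: np.ndarray,
        gq: np.ndarray,
        ad_ref: np.ndarray,
        ad_alt: np.ndarray,
        pedigree: Optional[Pedigree] = None,
    ):
        n = len(sites)
        for name, arr in (("gt", gt), ("gq", gq), ("ad_ref", ad_ref), ("ad_alt", ad_alt)):
            if arr.shape != (n, len(samples)):
                raise ValueError(f"{name} shape {arr.shape} != ({n},{len(samples)})")
        self.sites = sites.reset_index(drop=True)
        self.samples = list(samples)
        self.gt = gt
        self.gq = gq
        self.ad_ref = ad_ref
        self.ad_alt = ad_alt
        self.pedigree = pedigree
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_idx[sample_id]

    def site(self, i: int) -> VariantSite:
        r = self.sites.iloc[i]
        subpop = _decode_subpop(r.get("subpop"))

        def opt(key):
            v = r.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        return VariantSite(
            chromosome=r["chrom"],
            position=int(r["pos"]),
            ref=r["ref"],
            alt=r["alt"],
            filter_status=r["filter"],
            qd=r["qd"],
            read_pos_rank_sum=r["read_pos_rank_sum"],
            gene=opt("gene"),
            effect_annotation=r["effect"],
            af_1000g=opt("af_1000g"),
            af_gnomad=opt("af_gnomad"),
            af_gme=opt("af_gme"),
            subpop_afs=subpop,
            sift=opt("sift"),
            polyphen2_hvar=opt("polyphen2_hvar"),
            provean=opt("provean"),
            mutation_assessor=opt("mutation_assessor"),
            cadd=opt("cadd"),
            phastcons=opt("phastcons"),
            phylop=opt("phylop"),
            gerp=opt("gerp"),
            in_segdup=bool(r["in_segdup"]),
            in_simple_repeat=bool(r["in_simple_repeat"]),
        )

    def call(self, i: int, sample_id: str) -> GenotypeCall:
        j = self._sample_idx[sample_id]
        return GenotypeCall(
            sample_id=sample_id,
            gt=_CODE_TO_GT[int(self.gt[i, j])],
            gq=int(self.gq[i, j]),
            allele_depths=(int(self.ad_ref[i, j]), int(self.ad_alt[i, j])),
        )

    # -- vectorised helpers ---------------------------------------------

    def qc_mask(
        self, min_gq: int = 99, min_ad: int = 10, pass_only: bool = True,
        ad_mode: str = "called_allele",
    ) -> np.ndarray:
        """(n_sites, n_samples) boolean matrix of per-genotype QC."""
        ok = self.gt != GT_MISSING
        ok &= self.gq >= min_gq
        if ad_mode == "total":
            ok &= (self.ad_ref + self.ad_alt) >= min_ad
        else:
            carries = np.isin(self.gt, ALT_CARRIER_CODES)
            ok &= np.where(carries, self.ad_alt >= min_ad, self.ad_ref >= min_ad)
        if pass_only:
            ok &= (self.sites["filter"].to_numpy() == "PASS")[:, None]
        return ok

    def carrier_counts(self) -> np.ndarray:
        return np.isin(self.gt, ALT_CARRIER_CODES).sum(axis=1)

    def rare_mask(self, maf_rare: float = 0.01) -> np.ndarray:
        """Sites rare (AF < maf_rare, absent treated as 0) in all three databases."""
        afs = self.sites[["af_1000g", "af_gnomad", "af_gme"]].to_numpy(dtype=float)
        afs = np.nan_to_num(afs, nan=0.0)
        return (afs < maf_rare).all(axis=1)

    def frequency_class(self, i: int) -> FrequencyClass:
        return classify_frequency(self.site(i), int(self.carrier_counts()[i]))


def _encode_subpop(subpop: dict[str, tuple[float, int]]) -> Optional[str]:
    if not subpop:
        return None
    return ",".join(f"{k}|{af:g}|{int(hom)}" for k, (af, hom) in sorted(subpop.items()))


def _decode_subpop(s) -> dict[str, tuple[float, int]]:
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return {}
    out = {}
    for item in str(s).split(","):
        name, af, hom = item.split("|")
        out[name] = (float(af), int(hom))
    return out


# -- VCF I/O -------------------------------------------------------------

_INFO_FIELDS = [
    ("QD", "1", "Float", "Quality by depth"),
    ("ReadPosRankSum", "1", "Float", "Read position rank-sum statistic"),
    ("GENE", "1", "String", "Gene symbol"),
    ("EFFECT", "1", "String", "Exonic/functional effect annotation"),
    ("AF1KG", "1", "Float", "1000 Genomes allele frequency"),
    ("AFGNOMAD", "1", "Float", "gnomAD allele frequency"),
    ("AFGME", "1", "Float", "GME Variome allele frequency"),
    ("SIFT", "1", "Float", "SIFT score"),
    ("PP2HVAR", "1", "Float", "PolyPhen-2 HumVar score"),
    ("PROVEAN", "1", "Float", "PROVEAN score"),
    ("MUTASSESS", "1", "Float", "MutationAssessor score"),
    ("CADD", "1", "Float", "CADD phred score"),
    ("PHASTCONS", "1", "Float", "phastCons score"),
    ("PHYLOP", "1", "Float", "phyloP score"),
    ("GERP", "1", "Float", "GERP++ RS score"),
    ("SEGDUP", "0", "Flag", "Overlaps a segmental duplication"),
    ("SIMPLEREP", "0", "Flag", "Overlaps a simple repeat"),
    ("SPOP", "1", "String", "Subpopulation AF/hom counts name|af|hom,..."),
]

_FLOAT_INFO = {
    "qd": "QD",
    "read_pos_rank_sum": "ReadPosRankSum",
    "af_1000g": "AF1KG",
    "af_gnomad": "AFGNOMAD",
    "af_gme": "AFGME",
    "sift": "SIFT",
    "polyphen2_hvar": "PP2HVAR",
    "provean": "PROVEAN",
    "mutation_assessor": "MUTASSESS",
    "cadd": "CADD",
    "phastcons": "PHASTCONS",
    "phylop": "PHYLOP",
    "gerp": "GERP",
}


def write_cohort_vcf(
    cohort: CohortTable, path: str | Path, contig_lengths: Optional[dict[str, int]] = None
) -> None:
    """Write the cohort as a VCF v4.2 with FORMAT GT:GQ:AD."""
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=LowQual,Description="Low quality call">')
    for cid, num, typ, desc in _INFO_FIELDS:
        header.add_line(f'##INFO=<ID={cid},Number={num},Type={typ},Description="{desc}">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    chroms = list(dict.fromkeys(cohort.sites["chrom"]))
    lengths = contig_lengths or {}
    for c in chroms:
        ln = lengths.get(c, int(cohort.sites.loc[cohort.sites["chrom"] == c, "pos"].max()) + 1000)
        header.add_line(f"##contig=<ID={c},length={ln}>")
    for s in cohort.samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(cohort.n_sites):
            r = cohort.sites.iloc[i]
            rec = out.new_record(
                contig=r["chrom"],
                start=int(r["pos"]) - 1,
                alleles=(r["ref"], r["alt"]),
            )
            rec.filter.add(r["filter"])
            for col, key in _FLOAT_INFO.items():
                v = r[col]
                if v is not None and not (isinstance(v, float) and np.isnan(v)):
                    rec.info[key] = float(v)
            if isinstance(r["gene"], str) and r["gene"]:
                rec.info["GENE"] = r["gene"]
            rec.info["EFFECT"] = r["effect"]
            if bool(r["in_segdup"]):
                rec.info["SEGDUP"] = True
            if bool(r["in_simple_repeat"]):
                rec.info["SIMPLEREP"] = True
            sp = r.get("subpop")
            if isinstance(sp, str) and sp:
                rec.info["SPOP"] = sp
            for j, s in enumerate(cohort.samples):
                code = int(cohort.gt[i, j])
                smp = rec.samples[s]
                if code == GT_MISSING:
                    smp["GT"] = (None, None)
                elif code == GT_HOM_REF:
                    smp["GT"] = (0, 0)
                elif code == GT_HET:
                    smp["GT"] = (0, 1)
                elif code == GT_HOM_ALT:
                    smp["GT"] = (1, 1)
                elif code == GT_HEMI_REF:
                    smp["GT"] = (0,)
                else:
                    smp["GT"] = (1,)
                smp["GQ"] = int(cohort.gq[i, j])
                smp["AD"] = (int(cohort.ad_ref[i, j]), int(cohort.ad_alt[i, j]))
            out.write(rec)


def read_cohort_vcf(path: str | Path, pedigree: Optional[Pedigree] = None) -> CohortTable:
    """Read a multi-sample VCF into a :class:`CohortTable`.

    Multi-allelic records are decomposed into one row per alternate allele;
    genotype codes and AD fields are re-projected per alt (other alternate
    alleles count as reference for the projected row).  Record order is
    preserved.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if pedigree is not None:
        missing = [s for s in pedigree.sample_ids if s not in samples]
        if missing:
            raise ValueError(f"VCF is missing pedigree samples: {missing}")
    rows, gts, gqs, adr, ada = [], [], [], [], []
    for lineno, rec in enumerate(vcf, start=1):
        try:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                info = rec.info

                def iget(key, default=None):
                    # pysam raises on keys absent from the header
                    try:
                        return info.get(key, default)
                    except (KeyError, ValueError):
                        return default

                def fget(key):
                    v = iget(key)
                    if v is None:
                        return np.nan
                    return float(v[ai] if isinstance(v, tuple) and len(v) > ai else v)

                filt = list(rec.filter.keys()) or ["PASS"]
                rows.append(
                    {
                        "chrom": rec.contig,
                        "pos": rec.pos,
                        "ref": rec.ref,
                        "alt": alt,
                        "filter": filt[0],
                        "qd": fget("QD"),
                        "read_pos_rank_sum": fget("ReadPosRankSum"),
                        "gene": iget("GENE"),
                        "effect": iget("EFFECT", "unknown"),
                        "af_1000g": fget("AF1KG"),
                        "af_gnomad": fget("AFGNOMAD"),
                        "af_gme": fget("AFGME"),
                        "sift": fget("SIFT"),
                        "polyphen2_hvar": fget("PP2HVAR"),
                        "provean": fget("PROVEAN"),
                        "mutation_assessor": fget("MUTASSESS"),
                        "cadd": fget("CADD"),
                        "phastcons": fget("PHASTCONS"),
                        "phylop": fget("PHYLOP"),
                        "gerp": fget("GERP"),
                        "in_segdup": bool(iget("SEGDUP", False)),
                        "in_simple_repeat": bool(iget("SIMPLEREP", False)),
                        "subpop": iget("SPOP"),
                    }
                )
                g_row = np.full(len(samples), GT_MISSING, dtype=np.int8)
                q_row = np.zeros(len(samples), dtype=np.int16)
                ar_row = np.zeros(len(samples), dtype=np.int32)
                aa_row = np.zeros(len(samples), dtype=np.int32)
                target = ai + 1
                for j, s in enumerate(samples):
                    smp = rec.samples[s]
                    alleles = smp.get("GT")
                    q_row[j] = smp.get("GQ") or 0
                    ad = smp.get("AD")
                    if ad is not None:
                        ar_row[j] = ad[0] if ad[0] is not None else 0
                        if len(ad) > target and ad[target] is not None:
                            aa_row[j] = ad[target]
                    if alleles is None or all(a is None for a in alleles):
                        continue
                    n_alt = sum(1 for a in alleles if a == target)
                    if len(alleles) == 1:
                        g_row[j] = GT_HEMI_ALT if n_alt else GT_HEMI_REF
                    elif n_alt == 2:
                        g_row[j] = GT_HOM_ALT
                    elif n_alt == 1:
                        g_row[j] = GT_HET
                    else:
                        g_row[j] = GT_HOM_REF
                gts.append(g_row)
                gqs.append(q_row)
                adr.append(ar_row)
                ada.append(aa_row)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record at line-record {lineno}: {exc}") from exc
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    n = len(sites)
    shape = (n, len(samples))
    return CohortTable(
        sites,
        samples,
        np.array(gts, dtype=np.int8).reshape(shape),
        np.array(gqs, dtype=np.int16).reshape(shape),
        np.array(adr, dtype=np.int32).reshape(shape),
        np.array(ada, dtype=np.int32).reshape(shape),
        pedigree=pedigree,
    )
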