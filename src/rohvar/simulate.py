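"""Synthetic consanguineous-cohort generator.

Gene-dropping simulator: founder chromosomes carry unique ancestry labels,
meioses place Poisson-distributed crossovers on a uniform genetic map, and
offspring genomes are recombinant mosaics of founder material.  Truth
autozygosity (both haplotypes descending from the same founder chromosome)
is tracked exactly, variant sites are synthesised on founder haplotypes at
configurable density and allele frequencies, and candidate variants of the
four inheritance classes (de novo, compound heterozygous, homozygous inside
an autozygous segment, X-linked) can be planted with their quality and
annotation attributes stamped inside passing ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import MB, Chromosome, GenomeModel
from .pedigree import MALE, Pedigree, PedigreeMember, build_pedigree
from .variants import (
    GT_HEMI_ALT,
    GT_HEMI_REF,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    SITE_COLUMNS,
    CohortTable,
)

PLANT_MODES = ("de_novo", "compound_het", "hom_in_roh", "x_linked")


# -- haplotype mosaics ---------------------------------------------------


@dataclass
class Mosaic:
    """Piecewise-constant ancestry labels along one chromosome.

    ``ends[i]`` is the 1-based inclusive end of segment i; the last end
    equals the chromosome length.  ``labels[i]`` is the founder-haplotype
    id of the segment.
    """

    ends: np.ndarray
    labels: np.ndarray

    @classmethod
    def uniform(cls, length: int, label: int) -> "Mosaic":
        return cls(np.array([length], dtype=np.int64), np.array([label], dtype=np.int32))

    def label_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.ends, positions, side="left")
        return self.labels[idx]

    @property
    def length(self) -> int:
        return int(self.ends[-1])


def _compress(ends: list[int], labels: list[int]) -> Mosaic:
    ce, cl = [], []
    for e, l in zip(ends, labels):
        if cl and cl[-1] == l:
            ce[-1] = e
        else:
            ce.append(e)
            cl.append(l)
    return Mosaic(np.array(ce, dtype=np.int64), np.array(cl, dtype=np.int32))


def meiosis(
    hap_a: Mosaic, hap_b: Mosaic, rate_cm_per_mb: float, rng: np.random.Generator
) -> tuple[Mosaic, int]:
    """One gamete from a parental haplotype pair.

    Crossover count is Poisson(length_Mb * rate / 100); no interference.
    Returns the recombinant mosaic and the crossover count.
    """
    length = hap_a.length
    mean_x = length / MB * rate_cm_per_mb / 100.0
    n_x = int(rng.poisson(mean_x))
    cur = int(rng.integers(0, 2))
    if n_x == 0:
        src = hap_a if cur == 0 else hap_b
        return Mosaic(src.ends.copy(), src.labels.copy()), 0
    xs = np.unique(rng.integers(1, length, size=n_x))
    ends: list[int] = []
    labels: list[int] = []
    prev = 0
    for bound in [*xs.tolist(), length]:
        src = hap_a if cur == 0 else hap_b
        i = int(np.searchsorted(src.ends, prev + 1, side="left"))
        while src.ends[i] < bound:
            ends.append(int(src.ends[i]))
            labels.append(int(src.labels[i]))
            i += 1
        ends.append(int(bound))
        labels.append(int(src.labels[i]))
        prev = bound
        cur ^= 1
    return _compress(ends, labels), len(xs)


def autozygous_intervals(h1: Mosaic, h2: Mosaic) -> list[tuple[int, int]]:
    """Maximal 1-based intervals where the two haplotype labels coincide."""
    bounds = np.union1d(h1.ends, h2.ends)
    out: list[tuple[int, int]] = []
    prev = 0
    for b in bounds.tolist():
        if int(h1.label_at(np.array([b]))[0]) == int(h2.label_at(np.array([b]))[0]):
            if out and out[-1][1] == prev:
                out[-1] = (out[-1][0], int(b))
            else:
                out.append((prev + 1, int(b)))
        prev = int(b)
    return out


# -- gene dropping -------------------------------------------------------


@dataclass
class ChromPair:
    """Per-sample haplotypes of one chromosome.

    Autosomes and female X: two full mosaics.  Male X: ``hap1`` is the
    maternally inherited X and ``hap2`` the father's X, carried only within
    the pseudoautosomal intervals (no X-Y crossover is simulated).
    """

    hap1: Mosaic
    hap2: Mosaic
    male_x: bool = False


@dataclass
class GeneDrop:
    pedigree: Pedigree
    model: GenomeModel
    haplotypes: dict[str, dict[str, ChromPair]]
    founder_hap_ids: dict[str, tuple[int, int]]
    crossover_counts: list[int] = field(default_factory=list)

    def autozygous_segments(self, sample_id: str) -> list[tuple[str, int, int]]:
        """Truth autozygous intervals (chrom, start, end); male X skipped."""
        out = []
        for chrom in self.model.chromosomes:
            pair = self.haplotypes[sample_id][chrom.name]
            if pair.male_x and chrom.is_x:
                continue
            for s, e in autozygous_intervals(pair.hap1, pair.hap2):
                out.append((chrom.name, s, e))
        return out

    def autozygous_fraction(self, sample_id: str, autosomal_only: bool = True) -> float:
        total = 0
        denom = 0
        auto_names = {c.name for c in self.model.autosomes}
        for chrom, s, e in self.autozygous_segments(sample_id):
            if autosomal_only and chrom not in auto_names:
                continue
            total += e - s + 1
        denom = self.model.autosomal_length if autosomal_only else sum(
            c.length_bp for c in self.model.chromosomes
        )
        return total / denom


def gene_drop(
    pedigree: Pedigree,
    model: GenomeModel,
    seed: int | np.random.Generator,
    label_offset: int = 0,
) -> GeneDrop:
    """Drop founder haplotypes through the pedigree with recombination.

    Each founder chromosome copy carries a unique integer label starting at
    ``label_offset``; non-founders inherit recombinant mosaics.  The X is
    transmitted hemizygously to males outside the pseudoautosomal regions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    founder_ids: dict[str, tuple[int, int]] = {}
    nxt = label_offset
    for m in pedigree.founders:
        founder_ids[m.sample_id] = (nxt, nxt + 1)
        nxt += 2
    haps: dict[str, dict[str, ChromPair]] = {}
    gd = GeneDrop(pedigree, model, haps, founder_ids)
    rate = model.recombination_rate

    order = sorted(pedigree.members, key=lambda m: pedigree.depth(m.sample_id))
    for m in order:
        haps[m.sample_id] = {}
        for chrom in model.chromosomes:
            L = chrom.length_bp
            if m.is_founder:
                l1, l2 = founder_ids[m.sample_id]
                if chrom.is_x and m.sex == MALE:
                    # hap1: his X; hap2: placeholder carried only in the PARs
                    pair = ChromPair(Mosaic.uniform(L, l1), Mosaic.uniform(L, l2), True)
                else:
                    pair = ChromPair(Mosaic.uniform(L, l1), Mosaic.uniform(L, l2))
            else:
                fa = haps[m.father_id][chrom.name]
                mo = haps[m.mother_id][chrom.name]
                mat, nx = meiosis(mo.hap1, mo.hap2, rate, rng)
                gd.crossover_counts.append(nx)
                if chrom.is_x:
                    # father's X passes whole (no X recombination in males)
                    if m.sex == MALE:
                        pair = ChromPair(mat, fa.hap1, True)
                    else:
                        pair = ChromPair(fa.hap1, mat)
                else:
                    pat, nx = meiosis(fa.hap1, fa.hap2, rate, rng)
                    gd.crossover_counts.append(nx)
                    pair = ChromPair(pat, mat)
            haps[m.sample_id][chrom.name] = pair
    return gd


def redraw_child(gd: GeneDrop, child_id: str, rng: np.random.Generator) -> None:
    """Re-draw the meioses producing one child (used to guarantee a planted
    autozygous segment exists; see docs)."""
    m = gd.pedigree[child_id]
    if m.is_founder:
        raise ValueError("cannot redraw a founder")
    for chrom in gd.model.chromosomes:
        fa = gd.haplotypes[m.father_id][chrom.name]
        mo = gd.haplotypes[m.mother_id][chrom.name]
        mat, _ = meiosis(mo.hap1, mo.hap2, gd.model.recombination_rate, rng)
        if chrom.is_x:
            if m.sex == MALE:
                pair = ChromPair(mat, fa.hap1, True)
            else:
                pair = ChromPair(fa.hap1, mat)
        else:
            pat, _ = meiosis(fa.hap1, fa.hap2, gd.model.recombination_rate, rng)
            pair = ChromPair(pat, mat)
        gd.haplotypes[child_id][chrom.name] = pair


# -- site synthesis ------------------------------------------------------


def gene_symbol(chrom: str, pos: int, bin_bp: int = 100_000) -> str:
    """Deterministic synthetic gene symbol from a genomic bin."""
    return f"G{chrom.removeprefix('chr')}_{pos // bin_bp}"


_EFFECT_CHOICES = (
    ("intergenic", 0.40),
    ("intronic", 0.42),
    ("UTR", 0.05),
    ("synonymous_SNV", 0.06),
    ("nonsynonymous_SNV", 0.07),
)


@dataclass
class SiteSet:
    """Synthesised variant sites plus founder haplotype alleles."""

    sites: pd.DataFrame  # SITE_COLUMNS, position-sorted within chromosome
    positions: dict[str, np.ndarray]  # chrom -> 1-based positions
    founder_alleles: dict[str, np.ndarray]  # chrom -> (n_sites, n_hap_labels) uint8


def synthesize_sites(
    model: GenomeModel, n_hap_labels: int, seed: int | np.random.Generator
) -> SiteSet:
    """Draw variant sites and founder allele carriage.

    Sites are position-sorted; founder haplotypes carry the alternate allele
    as Bernoulli draws at frequencies from the model's allele-frequency
    spec; the three population-database AF stamps are consistent with the
    simulated (common) frequency class.
    """
    if model.site_density <= 0:
        raise ValueError("site_density must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = model.af_spec
    if model.site_density < 100:
        warnings.warn(
            "site density below ~100/Mb makes 100-site ROH windows span >1 Mb; "
            "short ROHs may be undetectable",
            stacklevel=2,
        )
    rows = []
    positions: dict[str, np.ndarray] = {}
    alleles: dict[str, np.ndarray] = {}
    effects, probs = zip(*_EFFECT_CHOICES)
    for chrom in model.chromosomes:
        n = int(round(chrom.length_bp / MB * model.site_density))
        pos = np.sort(
            rng.choice(chrom.length_bp - 1, size=min(n, chrom.length_bp - 1), replace=False)
        ).astype(np.int64) + 1
        positions[chrom.name] = pos
        n = len(pos)
        af = spec.draw(n, rng)
        alleles[chrom.name] = (
            rng.random((n, n_hap_labels)) < af[:, None]
        ).astype(np.uint8)
        eff = rng.choice(effects, size=n, p=probs)
        db = np.empty((n, 3))
        for k in range(3):
            jitter = 1.0 + rng.uniform(-spec.db_noise, spec.db_noise, size=n)
            db[:, k] = np.clip(af * jitter, 0.02, 0.95)
            if spec.db_concordance < 1.0:
                db[rng.random(n) >= spec.db_concordance, k] = 0.0
        nonsyn = eff == "nonsynonymous_SNV"
        genic = eff != "intergenic"
        df = pd.DataFrame(
            {
                "chrom": chrom.name,
                "pos": pos,
                "ref": "A",
                "alt": "G",
                "filter": "PASS",
                "qd": rng.uniform(8, 20, size=n).round(2),
                "read_pos_rank_sum": rng.uniform(-1.5, 1.5, size=n).round(2),
                "gene": [
                    gene_symbol(chrom.name, int(p)) if g else None
                    for p, g in zip(pos, genic)
                ],
                "effect": eff,
                "af_1000g": db[:, 0].round(4),
                "af_gnomad": db[:, 1].round(4),
                "af_gme": db[:, 2].round(4),
                "sift": np.where(nonsyn, rng.uniform(0.2, 1.0, size=n).round(3), np.nan),
                "polyphen2_hvar": np.where(nonsyn, rng.uniform(0.0, 0.1, size=n).round(3), np.nan),
                "provean": np.where(nonsyn, rng.uniform(-1.0, 1.0, size=n).round(3), np.nan),
                "mutation_assessor": np.where(nonsyn, rng.uniform(0.0, 1.0, size=n).round(3), np.nan),
                "cadd": np.nan,
                "phastcons": np.nan,
                "phylop": np.nan,
                "gerp": np.nan,
                "in_segdup": False,
                "in_simple_repeat": False,
                "subpop": None,
            }
        )
        rows.append(df)
    sites = pd.concat(rows, ignore_index=True)[SITE_COLUMNS]
    return SiteSet(sites, positions, alleles)


def materialize_genotypes(
    model: GenomeModel, siteset: SiteSet, drops: Sequence[GeneDrop], samples: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Project founder alleles through sample mosaics into genotype codes.

    Returns (gt, gq, ad_ref, ad_alt) matrices in cohort site order with
    noise-free quality stamps (GQ 99, depth 30).
    """
    by_sample: dict[str, dict[str, ChromPair]] = {}
    for gd in drops:
        by_sample.update(gd.haplotypes)
    n_total = len(siteset.sites)
    gt = np.zeros((n_total, len(samples)), dtype=np.int8)
    offset = 0
    for chrom in model.chromosomes:
        pos = siteset.positions[chrom.name]
        A = siteset.founder_alleles[chrom.name]
        n = len(pos)
        sl = slice(offset, offset + n)
        for j, s in enumerate(samples):
            pair = by_sample[s][chrom.name]
            a1 = A[np.arange(n), pair.hap1.label_at(pos)]
            if pair.male_x and chrom.is_x:
                code = np.where(a1 > 0, GT_HEMI_ALT, GT_HEMI_REF).astype(np.int8)
                if chrom.par:
                    par_mask = np.zeros(n, dtype=bool)
                    for ps, pe in chrom.par:
                        par_mask |= (pos >= ps) & (pos <= pe)
                    a2 = A[np.arange(n), pair.hap2.label_at(pos)]
                    code[par_mask] = (a1 + a2)[par_mask].astype(np.int8)
                gt[sl, j] = code
            else:
                a2 = A[np.arange(n), pair.hap2.label_at(pos)]
                gt[sl, j] = (a1 + a2).astype(np.int8)
        offset += n
    gq = np.full(gt.shape, 99, dtype=np.int16)
    ad_ref = np.zeros(gt.shape, dtype=np.int32)
    ad_alt = np.zeros(gt.shape, dtype=np.int32)
    ad_ref[(gt == GT_HOM_REF) | (gt == GT_HEMI_REF)] = 30
    ad_alt[(gt == GT_HOM_ALT) | (gt == GT_HEMI_ALT)] = 30
    ad_ref[gt == GT_HET] = 15
    ad_alt[gt == GT_HET] = 15
    return gt, gq, ad_ref, ad_alt


# -- variant planting ----------------------------------------------------


@dataclass
class PlantSpec:
    """A candidate variant to plant, with the site attributes to stamp."""

    mode: str  # de_novo | compound_het | hom_in_roh | x_linked
    target_sample: str
    effect: str = "nonsynonymous_SNV"
    gene: Optional[str] = None
    damage: tuple[float, float, float, float] = (0.01, 0.90, -5.0, 3.5)
    afs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    regulatory_kind: Optional[str] = None  # None | promoter | enhancer
    known_gene: bool = False
    brain_expressed: bool = True
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in PLANT_MODES:
            raise ValueError(f"unknown plant mode {self.mode!r}")


LEDGER_COLUMNS = [
    "event_id",
    "mode",
    "sample",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "regulatory_kind",
    "known_gene",
    "brain_expressed",
]


@dataclass
class SyntheticCohort:
    """A fully materialised synthetic cohort with planted-event truth."""

    pedigree: Pedigree
    model: GenomeModel
    table: CohortTable
    drops: list[GeneDrop]
    ledger: pd.DataFrame

    def autozygous_segments(self, sample_id: str) -> list[tuple[str, int, int]]:
        for gd in self.drops:
            if sample_id in gd.haplotypes:
                return gd.autozygous_segments(sample_id)
        raise KeyError(sample_id)


def _trio_of(pedigree: Pedigree, child_id: str) -> tuple[PedigreeMember, PedigreeMember]:
    m = pedigree[child_id]
    if m.is_founder:
        raise ValueError(f"{child_id} has no parents to plant against")
    return pedigree[m.father_id], pedigree[m.mother_id]


def plant_variants(
    cohort: SyntheticCohort, specs: Sequence[PlantSpec], seed: int | np.random.Generator
) -> SyntheticCohort:
    """Insert planted candidate variants and return the updated cohort.

    Every planted event is recorded in the truth ledger; requested loci must
    not already carry a site.  Stamped QD/ReadPosRankSum/allele-balance
    values sit inside the de novo filter's passing ranges.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ped = cohort.pedigree
    model = cohort.model
    table = cohort.table
    occupied = set(zip(table.sites["chrom"], table.sites["pos"].astype(int)))
    samples = table.samples
    x = model.x_chromosome

    new_rows: list[dict] = []
    new_gt: list[np.ndarray] = []
    ledger_rows: list[dict] = list(cohort.ledger.to_dict("records"))
    next_event = len({r["event_id"] for r in ledger_rows}) if ledger_rows else 0

    def free_pos(chrom: Chromosome, lo: int = 1, hi: Optional[int] = None) -> int:
        hi = hi or chrom.length_bp
        for _ in range(1000):
            p = int(rng.integers(lo, hi + 1))
            if (chrom.name, p) not in occupied:
                return p
        raise RuntimeError("could not find a free locus")

    def add_site(
        spec: PlantSpec, chrom: str, pos: int, geno: dict[str, int],
        ref: str = "C", alt: str = "T", event_id: int = 0,
    ) -> None:
        occupied.add((chrom, pos))
        gene = spec.gene or gene_symbol(chrom, pos)
        sift, pp2, prov, ma = (
            spec.damage if spec.effect == "nonsynonymous_SNV" else (np.nan,) * 4
        )
        new_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "filter": "PASS",
                "qd": 12.0,
                "read_pos_rank_sum": 0.0,
                "gene": gene,
                "effect": spec.effect,
                "af_1000g": spec.afs[0],
                "af_gnomad": spec.afs[1],
                "af_gme": spec.afs[2],
                "sift": sift,
                "polyphen2_hvar": pp2,
                "provean": prov,
                "mutation_assessor": ma,
                "cadd": np.nan,
                "phastcons": np.nan,
                "phylop": np.nan,
                "gerp": np.nan,
                "in_segdup": False,
                "in_simple_repeat": False,
                "subpop": None,
            }
        )
        is_x = x is not None and chrom == x.name
        row = np.zeros(len(samples), dtype=np.int8)
        if is_x:
            for j, s in enumerate(samples):
                if ped[s].sex == MALE and not x.in_par(pos):
                    row[j] = GT_HEMI_REF
        for s, code in geno.items():
            row[samples.index(s)] = code
        new_gt.append(row)
        ledger_rows.append(
            {
                "event_id": event_id,
                "mode": spec.mode,
                "sample": spec.target_sample,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": gene,
                "effect": spec.effect,
                "regulatory_kind": spec.regulatory_kind,
                "known_gene": spec.known_gene,
                "brain_expressed": spec.brain_expressed,
            }
        )

    autosomes = model.autosomes
    for spec in specs:
        child = ped[spec.target_sample]
        fa, mo = _trio_of(ped, spec.target_sample)
        eid = next_event
        next_event += 1
        if spec.mode == "de_novo":
            chrom = autosomes[int(rng.integers(len(autosomes)))]
            pos = spec.pos or free_pos(chrom)
            add_site(
                spec, spec.chrom or chrom.name, pos,
                {spec.target_sample: GT_HET}, event_id=eid,
            )
        elif spec.mode == "compound_het":
            chrom = autosomes[int(rng.integers(len(autosomes)))]
            bin_start = int(rng.integers(0, chrom.length_bp // 100_000 - 1)) * 100_000
            p1 = free_pos(chrom, bin_start + 1, bin_start + 50_000)
            p2 = free_pos(chrom, bin_start + 50_001, bin_start + 100_000)
            g = spec.gene or gene_symbol(chrom.name, p1)
            s2 = replace(spec, gene=g)
            add_site(
                s2, chrom.name, p1,
                {spec.target_sample: GT_HET, fa.sample_id: GT_HET}, event_id=eid,
            )
            add_site(
                s2, chrom.name, p2,
                {spec.target_sample: GT_HET, mo.sample_id: GT_HET}, event_id=eid,
            )
        elif spec.mode == "hom_in_roh":
            segs = [
                (c, s, e)
                for c, s, e in cohort.autozygous_segments(spec.target_sample)
                if e - s + 1 >= MB and (x is None or c != x.name)
            ]
            if not segs:
                raise ValueError(
                    f"{spec.target_sample} has no autozygous segment >= 1 Mb to plant in"
                )
            c, s, e = segs[int(rng.integers(len(segs)))]
            chrom = model.chromosome(c)
            mid_lo = s + (e - s) // 4
            mid_hi = e - (e - s) // 4
            pos = spec.pos or free_pos(chrom, mid_lo, mid_hi)
            add_site(
                spec, c, pos,
                {
                    spec.target_sample: GT_HOM_ALT,
                    fa.sample_id: GT_HET,
                    mo.sample_id: GT_HET,
                },
                event_id=eid,
            )
        else:  # x_linked
            if x is None:
                raise ValueError("model has no X chromosome")
            if child.sex != MALE:
                raise ValueError("x_linked plant requires a male offspring")
            for _ in range(1000):
                pos = spec.pos or free_pos(x)
                if not x.in_par(pos):
                    break
            add_site(
                spec, x.name, pos,
                {
                    spec.target_sample: GT_HEMI_ALT,
                    mo.sample_id: GT_HET,
                    fa.sample_id: GT_HEMI_REF,
                },
                event_id=eid,
            )

    if not new_rows:
        return cohort

    sites = pd.concat([table.sites, pd.DataFrame(new_rows)], ignore_index=True)
    gt = np.vstack([table.gt, np.array(new_gt, dtype=np.int8)])
    nq = np.full((len(new_gt), len(samples)), 99, dtype=np.int16)
    gq = np.vstack([table.gq, nq])
    ar = np.zeros((len(new_gt), len(samples)), dtype=np.int32)
    aa = np.zeros((len(new_gt), len(samples)), dtype=np.int32)
    ng = np.array(new_gt)
    ar[(ng == GT_HOM_REF) | (ng == GT_HEMI_REF)] = 30
    aa[ng == GT_HOM_ALT] = 30
    # hemizygous-alt allele balance stamped >= 0.7 (male X/Y de novo branch)
    ar[ng == GT_HEMI_ALT] = 1
    aa[ng == GT_HEMI_ALT] = 29
    ar[ng == GT_HET] = 14
    aa[ng == GT_HET] = 16
    ad_ref = np.vstack([table.ad_ref, ar])
    ad_alt = np.vstack([table.ad_alt, aa])

    chrom_order = {c.name: i for i, c in enumerate(model.chromosomes)}
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].map(chrom_order).to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    new_table = CohortTable(
        sites, samples, gt[order], gq[order], ad_ref[order], ad_alt[order], pedigree=ped
    )
    ledger = pd.DataFrame(ledger_rows, columns=LEDGER_COLUMNS)
    return SyntheticCohort(ped, model, new_table, cohort.drops, ledger)


# -- cohort assembly -----------------------------------------------------


def merge_pedigrees(peds: Sequence[Pedigree]) -> Pedigree:
    members = [m for p in peds for m in p.members]
    loops = {p.loops for p in peds} - {"none"}
    return Pedigree(members, loops=loops.pop() if len(loops) == 1 else "none")


def simulate_cohort(
    families: Sequence[tuple[str, int]] | Sequence[tuple[str, int, Sequence[str]]],
    model: GenomeModel,
    seed: int,
    plants: Sequence[PlantSpec] = (),
    max_redraws: int = 50,
) -> SyntheticCohort:
    """Generate a multi-family cohort and optionally plant candidate variants.

    ``families`` is a sequence of (kind, n_children[, child_sexes]) tuples;
    family ids are F1, F2, ...  The single seed expands deterministically to
    per-stage substreams (pedigree drops, site synthesis, planting).  When a
    ``hom_in_roh`` plant targets a child with no autozygous segment >= 1 Mb,
    that child's meioses are redrawn (bounded retries) so the plant is
    satisfiable.
    """
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(len(families) + 3)
    peds = []
    drops: list[GeneDrop] = []
    offset = 0
    for i, fam in enumerate(families):
        kind, n_children = fam[0], fam[1]
        sexes = fam[2] if len(fam) > 2 else None
        ped = build_pedigree(kind, n_children, family_id=f"F{i + 1}", child_sexes=sexes)
        rng = np.random.default_rng(sub[i])
        gd = gene_drop(ped, model, rng, label_offset=offset)
        offset += 2 * len(ped.founders)
        # guarantee plantability of hom_in_roh targets in this family
        targets = {
            p.target_sample
            for p in plants
            if p.mode == "hom_in_roh" and p.target_sample in ped
        }
        for t in targets:
            tries = 0
            while not any(
                e - s + 1 >= MB
                for c, s, e in gd.autozygous_segments(t)
                if not model.chromosome(c).is_x
            ):
                if tries >= max_redraws:
                    raise RuntimeError(
                        f"no autozygous segment >= 1 Mb for {t} after {max_redraws} redraws"
                    )
                redraw_child(gd, t, rng)
                tries += 1
        peds.append(ped)
        drops.append(gd)
    pedigree = merge_pedigrees(peds)
    site_rng = np.random.default_rng(sub[len(families)])
    siteset = synthesize_sites(model, offset, site_rng)
    samples = pedigree.sample_ids
    gt, gq, ad_ref, ad_alt = materialize_genotypes(model, siteset, drops, samples)
    table = CohortTable(siteset.sites, samples, gt, gq, ad_ref, ad_alt, pedigree=pedigree)
    cohort = SyntheticCohort(
        pedigree, model, table, drops, pd.DataFrame(columns=LEDGER_COLUMNS)
    )
    if plants:
        cohort = plant_variants(cohort, plants, np.random.default_rng(sub[len(families) + 1]))
    return cohort


def mendelian_violations(cohort: SyntheticCohort) -> int:
    """Count child genotypes not derivable from parental genotypes.

    Autosomal diploid check on non-planted sites; used as a generator
    self-consistency property.
    """
    table = cohort.table
    ped = cohort.pedigree
    planted = set(zip(cohort.ledger["chrom"], cohort.ledger["pos"].astype(int))) if len(
        cohort.ledger
    ) else set()
    x = cohort.model.x_chromosome
    keep = np.ones(table.n_sites, dtype=bool)
    for i, (c, p) in enumerate(zip(table.sites["chrom"], table.sites["pos"].astype(int))):
        if (c, p) in planted or (x is not None and c == x.name):
            keep[i] = False
    violations = 0
    for m in ped.members:
        if m.is_founder:
            continue
        ci = table.sample_index(m.sample_id)
        fi = table.sample_index(m.father_id)
        mi = table.sample_index(m.mother_id)
        child, fa, mo = table.gt[keep, ci], table.gt[keep, fi], table.gt[keep, mi]

        def gametes(g):
            return {
                GT_HOM_REF: {0},
                GT_HET: {0, 1},
                GT_HOM_ALT: {1},
            }.get(int(g), {0, 1})

        for g_c, g_f, g_m in zip(child, fa, mo):
            need = {
                GT_HOM_REF: [(0, 0)],
                GT_HET: [(0, 1), (1, 0)],
                GT_HOM_ALT: [(1, 1)],
            }.get(int(g_c))
            if need is None:
                continue
            if not any(a in gametes(g_f) and b in gametes(g_m) for a, b in need):
                violations += 1
    return violations
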