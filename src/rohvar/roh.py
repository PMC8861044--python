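"""Runs-of-homozygosity detection and ROH set operations.

The detector follows the sliding-window homozygosity-mapping approach:
sites are pre-filtered on Hardy-Weinberg equilibrium (exact test,
P < 0.001), cohort MAF (> 5%) and missingness (<= 25%); windows of 100
retained sites tolerate up to 30 heterozygous and 30 missing calls; runs of
window-supported sites whose overall homozygous fraction (PHOM) reaches 75%
and whose span exceeds 1 Mb are emitted as ROH segments.  Per-genome
metrics use autosomal segments only.  Cross-sample utilities merge ROHs
shared by >= 2 affected individuals, subtract parental ROHs from a child's,
and partition variants by ROH membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variants import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, CohortTable

MB = 1_000_000


@dataclass(frozen=True)
class ROHSegment:
    sample_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    n_sites: int
    n_het: int
    n_missing: int
    phom: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "ROHSegment") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class ROHMetrics:
    n_segments: int
    mean_length: float
    max_length: int
    total_length: int
    genome_fraction: float

    @property
    def genome_percent(self) -> float:
        return 100.0 * self.genome_fraction


@dataclass(frozen=True)
class MergedROH:
    chromosome: str
    start: int
    end: int
    carrier_samples: frozenset[str]

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_samples)


@dataclass(frozen=True)
class ROHParams:
    window_sites: int = 100
    max_het: int = 30
    max_missing: int = 30
    phom: float = 0.75
    min_length_bp: int = MB
    # fraction of covering windows that must satisfy the het/missing limits
    # for a site to join a run (as in the referenced sliding-window method)
    window_hit_fraction: float = 0.05
    # ends of a candidate run are retracted until the outermost
    # end_refine_sites contain no heterozygote (see docs/methods.md)
    end_refine_sites: int = 15
    hwe_p: float = 0.001
    min_maf: float = 0.05
    max_missing_rate: float = 0.25


# -- Hardy-Weinberg exact test ------------------------------------------


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote configurations no more probable than the observed one
    (the standard exact formulation; computed with a log-gamma closed form
    per configuration for numerical stability).
    """
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_a = n_het + 2 * min(n_hom1, n_hom2)  # minor allele count
    parity = n_a % 2
    hets = np.arange(parity, min(n_a, 2 * n - n_a) + 1, 2)

    def logp(h: np.ndarray) -> np.ndarray:
        hom_minor = (n_a - h) // 2
        hom_major = n - h - hom_minor
        return (
            h * np.log(2.0)
            + lgamma(n + 1)
            - _lg(h + 1)
            - _lg(hom_minor + 1)
            - _lg(hom_major + 1)
            - lgamma(2 * n + 1)
            + _lg(n_a + 1)
            + _lg(2 * n - n_a + 1)
        )

    lp = logp(hets)
    lp -= lp.max()
    p = np.exp(lp)
    p /= p.sum()
    obs = p[np.where(hets == n_het)[0][0]]
    return float(p[p <= obs * (1 + 1e-12)].sum())


def _lg(x: np.ndarray) -> np.ndarray:
    return np.vectorize(lgamma)(x) if np.ndim(x) else lgamma(x)


# -- site filtering ------------------------------------------------------


def roh_site_filter(
    table: CohortTable, params: ROHParams = ROHParams()
) -> np.ndarray:
    """Boolean mask of sites retained for ROH detection.

    Retains sites with HWE exact P >= ``hwe_p``, cohort MAF > ``min_maf``
    and missing-genotype rate <= ``max_missing_rate``.  Counts use diploid
    autosomal genotypes (hemizygous calls are ignored).
    """
    gt = table.gt
    n_het = (gt == GT_HET).sum(axis=1)
    n_hom_ref = (gt == GT_HOM_REF).sum(axis=1)
    n_hom_alt = (gt == GT_HOM_ALT).sum(axis=1)
    n_missing = (gt == GT_MISSING).sum(axis=1)
    n_called = n_het + n_hom_ref + n_hom_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_count = n_het + 2 * n_hom_alt
        af = np.where(n_called > 0, alt_count / (2 * n_called), 0.0)
        maf = np.minimum(af, 1 - af)
        miss_rate = np.where(
            n_missing + n_called > 0, n_missing / (n_missing + n_called), 1.0
        )
    keep = (maf > params.min_maf) & (miss_rate <= params.max_missing_rate)
    for i in np.where(keep)[0]:
        p = hwe_exact_test(int(n_het[i]), int(n_hom_ref[i]), int(n_hom_alt[i]))
        if p < params.hwe_p:
            keep[i] = False
    if not keep.any():
        raise ValueError(
            "no sites retained by the ROH site filter; increase site density "
            "or relax the filter parameters"
        )
    return keep


# -- detection -----------------------------------------------------------


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.concatenate([[0], np.cumsum(x)])
    return c[w:] - c[:-w]


def detect_roh(
    positions: np.ndarray,
    codes: np.ndarray,
    chromosome: str,
    sample_id: str,
    params: ROHParams = ROHParams(),
) -> list[ROHSegment]:
    """Detect ROH segments for one sample on one chromosome.

    ``positions`` must be sorted 1-based coordinates of retained sites and
    ``codes`` the aligned genotype codes.  Windows of ``window_sites``
    variants are scored against the het/missing limits; a site joins a
    candidate run when at least ``window_hit_fraction`` of the windows
    covering it pass.  Candidate-run ends are retracted while the local homozygous
    fraction of the outermost ``end_refine_sites`` falls below ``phom``,
    then trimmed to their first/last homozygous site; the run must reach
    ``phom`` overall and span more than ``min_length_bp``.
    """
    n = len(positions)
    if n == 0:
        return []
    het = (codes == GT_HET).astype(np.int32)
    miss = (codes == GT_MISSING).astype(np.int32)
    hom = (codes == GT_HOM_REF) | (codes == GT_HOM_ALT)
    w = min(params.window_sites, n)
    good = (_sliding_sum(het, w) <= params.max_het) & (
        _sliding_sum(miss, w) <= params.max_missing
    )
    n_win = n - w + 1
    # per-site counts of covering windows and of good covering windows
    cg = np.concatenate([[0], np.cumsum(good)])
    starts = np.maximum(0, np.arange(n) - w + 1)
    stops = np.minimum(np.arange(n), n_win - 1)
    n_cover = stops - starts + 1
    n_good = cg[stops + 1] - cg[starts]
    eligible = n_good >= params.window_hit_fraction * n_cover

    segments: list[ROHSegment] = []
    i = 0
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1]:
            j += 1
        # end refinement: retract each end until its outermost K sites are
        # free of heterozygotes (missing calls allowed), so segment ends
        # anchor on locally clean homozygosity rather than chance runs in
        # the heterozygous flank
        a0, b0 = i, j
        k = min(params.end_refine_sites, b0 - a0 + 1)
        if k > 0:
            while b0 - a0 + 1 > k:
                w = het[a0 : a0 + k]
                if not w.any():
                    break
                a0 += int(np.where(w)[0][-1]) + 1
            while b0 - a0 + 1 > k:
                w = het[b0 - k + 1 : b0 + 1]
                if not w.any():
                    break
                b0 -= k - int(np.where(w)[0][0])
        hom_idx = np.where(hom[a0 : b0 + 1])[0]
        if hom_idx.size:
            a = a0 + int(hom_idx[0])
            b = a0 + int(hom_idx[-1])
            n_sites = b - a + 1
            nh = int(het[a : b + 1].sum())
            nm = int(miss[a : b + 1].sum())
            called = n_sites - nm
            phom = (called - nh) / called if called else 0.0
            length = int(positions[b] - positions[a] + 1)
            if phom >= params.phom and length > params.min_length_bp:
                segments.append(
                    ROHSegment(
                        sample_id=sample_id,
                        chromosome=chromosome,
                        start=int(positions[a]),
                        end=int(positions[b]),
                        n_sites=n_sites,
                        n_het=nh,
                        n_missing=nm,
                        phom=phom,
                    )
                )
        i = j + 1
    return segments


def detect_cohort_roh(
    table: CohortTable,
    params: ROHParams = ROHParams(),
    apply_site_filter: bool = True,
    samples: Optional[Sequence[str]] = None,
) -> dict[str, list[ROHSegment]]:
    """Run the site filter and per-sample detector over a cohort table."""
    keep = roh_site_filter(table, params) if apply_site_filter else np.ones(
        table.n_sites, dtype=bool
    )
    chroms = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy(dtype=np.int64)
    out: dict[str, list[ROHSegment]] = {}
    for s in samples or table.samples:
        j = table.sample_index(s)
        segs: list[ROHSegment] = []
        for chrom in dict.fromkeys(chroms):
            m = keep & (chroms == chrom)
            segs.extend(detect_roh(pos[m], table.gt[m, j], chrom, s, params))
        out[s] = segs
    return out


# -- metrics and set operations -----------------------------------------


def roh_metrics(
    segments: Iterable[ROHSegment], callable_bases: int, autosomes: Optional[set] = None
) -> ROHMetrics:
    """Per-genome ROH summary over autosomal segments.

    ``genome_fraction`` is total ROH length over ``callable_bases`` (total
    simulated genome length in the synthetic setting, or the bases covered
    at >= 1x for real data).
    """
    if callable_bases <= 0:
        raise ValueError("callable_bases must be positive")
    segs = [
        s
        for s in segments
        if autosomes is None or s.chromosome in autosomes
    ]
    if not segs:
        return ROHMetrics(0, 0.0, 0, 0, 0.0)
    lengths = [s.length for s in segs]
    total = int(sum(lengths))
    return ROHMetrics(
        n_segments=len(segs),
        mean_length=float(np.mean(lengths)),
        max_length=int(max(lengths)),
        total_length=total,
        genome_fraction=total / callable_bases,
    )


def merge_shared_roh(
    segments_by_affected: Mapping[str, Sequence[ROHSegment]],
) -> list[MergedROH]:
    """Union-merge ROHs found in >= 2 affected individuals.

    Overlapping segments are chained (single linkage) into merged
    intervals; a merged interval is emitted when segments from at least two
    distinct individuals contribute, with carrier count the number of
    individuals whose segment intersects it.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for sample, segs in segments_by_affected.items():
        for s in segs:
            by_chrom.setdefault(s.chromosome, []).append((s.start, s.end, sample))
    out: list[MergedROH] = []
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        cur_s, cur_e, samples = None, None, set()
        for s, e, smp in ivs:
            if cur_s is None:
                cur_s, cur_e, samples = s, e, {smp}
            elif s <= cur_e:
                cur_e = max(cur_e, e)
                samples.add(smp)
            else:
                if len(samples) >= 2:
                    out.append(MergedROH(chrom, cur_s, cur_e, frozenset(samples)))
                cur_s, cur_e, samples = s, e, {smp}
        if cur_s is not None and len(samples) >= 2:
            out.append(MergedROH(chrom, cur_s, cur_e, frozenset(samples)))
    out.sort(key=lambda m: (m.chromosome, m.start))
    return out


def subtract_parental_roh(
    child_segments: Sequence[ROHSegment], parent_segments: Sequence[ROHSegment]
) -> list[ROHSegment]:
    """Drop child ROHs that overlap any parental ROH (any-overlap rule)."""
    return [
        c
        for c in child_segments
        if not any(c.overlaps(p) for p in parent_segments)
    ]


def variants_in_roh(
    segments_by_sample: Mapping[str, Sequence[ROHSegment]],
    variant_calls: pd.DataFrame,
) -> np.ndarray:
    """Boolean "inside an ROH of the same sample" flag per variant call.

    ``variant_calls`` needs columns sample, chrom, pos (1-based).  Bounds
    are inclusive, so the partition inside/outside is exhaustive and
    exclusive.
    """
    inside = np.zeros(len(variant_calls), dtype=bool)
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for sample, segs in segments_by_sample.items():
        for s in segs:
            by_key.setdefault((sample, s.chromosome), []).append((s.start, s.end))
    for i, (sample, chrom, pos) in enumerate(
        zip(variant_calls["sample"], variant_calls["chrom"], variant_calls["pos"])
    ):
        for s, e in by_key.get((sample, chrom), ()):
            if s <= pos <= e:
                inside[i] = True
                break
    return inside


def segments_to_frame(segments_by_sample: Mapping[str, Sequence[ROHSegment]]) -> pd.DataFrame:
    rows = [
        {
            "sample": s.sample_id,
            "chrom": s.chromosome,
            "start": s.start,
            "end": s.end,
            "length": s.length,
            "n_sites": s.n_sites,
            "n_het": s.n_het,
            "n_missing": s.n_missing,
            "phom": s.phom,
        }
        for segs in segments_by_sample.values()
        for s in segs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "chrom", "start", "end", "length",
            "n_sites", "n_het", "n_missing", "phom",
        ],
    )
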