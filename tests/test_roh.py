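from math import factorial

import numpy as np
import pandas as pd
import pytest

from rohvar import (
    ROHParams,
    ROHSegment,
    detect_roh,
    hwe_exact_test,
    merge_shared_roh,
    roh_metrics,
    roh_site_filter,
    subtract_parental_roh,
    variants_in_roh,
)
from rohvar.variants import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING, CohortTable
from rohvar.variants import SITE_COLUMNS


def hwe_enumeration_oracle(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Independent exact-integer enumeration of the conditional
    heterozygote distribution (two-sided exact test)."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    na = n_het + 2 * min(n_hom1, n_hom2)

    def weight(h):
        hm = (na - h) // 2
        hM = n - h - hm
        return factorial(n) // (factorial(h) * factorial(hm) * factorial(hM)) * 2**h

    hs = range(na % 2, min(na, 2 * n - na) + 1, 2)
    ws = {h: weight(h) for h in hs}
    total = sum(ws.values())
    obs = ws[n_het]
    return sum(w for w in ws.values() if w <= obs) / total


class TestHweExact:
    def test_matches_enumeration_oracle_small_n(self):
        for n in range(1, 21):
            for het in range(n + 1):
                for hom1 in range(n - het + 1):
                    hom2 = n - het - hom1
                    assert hwe_exact_test(het, hom1, hom2) == pytest.approx(
                        hwe_enumeration_oracle(het, hom1, hom2), abs=1e-9
                    )

    def test_matches_enumeration_random_n_up_to_50(self, rng):
        for _ in range(300):
            n = int(rng.integers(21, 51))
            het = int(rng.integers(0, n + 1))
            hom1 = int(rng.integers(0, n - het + 1))
            hom2 = n - het - hom1
            assert hwe_exact_test(het, hom1, hom2) == pytest.approx(
                hwe_enumeration_oracle(het, hom1, hom2), abs=1e-9
            )

    def test_all_het_is_extreme(self):
        # every carrier heterozygous at n=68 is wildly out of equilibrium
        assert hwe_exact_test(68, 0, 0) < 1e-6

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 0, 0)


def _table_from_gt(gt: np.ndarray, positions=None, chrom="chr1") -> CohortTable:
    n, k = gt.shape
    pos = positions if positions is not None else np.arange(1, n + 1) * 1000
    sites = pd.DataFrame({c: [None] * n for c in SITE_COLUMNS})
    sites["chrom"] = chrom
    sites["pos"] = pos
    sites["ref"], sites["alt"], sites["filter"], sites["effect"] = "A", "G", "PASS", "intronic"
    sites["in_segdup"] = sites["in_simple_repeat"] = False
    samples = [f"s{i}" for i in range(k)]
    shape = (n, k)
    return CohortTable(
        sites, samples, gt.astype(np.int8), np.full(shape, 99, np.int16),
        np.full(shape, 15, np.int32), np.full(shape, 15, np.int32),
    )


class TestSiteFilter:
    def test_hwe_maf_missingness_rules(self, rng):
        n_samples = 68
        # site 0: perfect HWE at MAF 0.3; site 1: all carriers het;
        # site 2: MAF 0.04; site 3: 30% missing
        rows = []
        hwe_ok = np.array([GT_HOM_REF] * 34 + [GT_HET] * 28 + [GT_HOM_ALT] * 6)
        rows.append(hwe_ok)
        rows.append(np.array([GT_HET] * 40 + [GT_HOM_REF] * 28))
        rows.append(np.array([GT_HET] * 5 + [GT_HOM_REF] * 63))
        missing = np.array([GT_MISSING] * 21 + [GT_HET] * 20 + [GT_HOM_REF] * 27)
        rows.append(missing)
        gt = np.vstack(rows)
        keep = roh_site_filter(_table_from_gt(gt))
        assert keep.tolist() == [True, False, False, False]
        # the all-het removal is the exact-test oracle speaking
        assert hwe_enumeration_oracle(40, 0, 28) < 0.001

    def test_all_removed_raises(self):
        gt = np.array([[GT_HET] * 68])
        with pytest.raises(ValueError, match="no sites retained"):
            roh_site_filter(_table_from_gt(gt))


class TestDetectRoh:
    def test_fully_homozygous_stretch_called_exactly(self, rng):
        """2 Mb of homozygous calls flanked by dense heterozygosity gives
        exactly one segment covering the stretch."""
        pos = np.sort(rng.choice(5_000_000, size=5000, replace=False)) + 1
        codes = np.full(5000, GT_HET, dtype=np.int8)
        inside = (pos >= 1_500_000) & (pos <= 3_500_000)
        codes[inside] = GT_HOM_ALT
        segs = detect_roh(pos, codes, "chr1", "s")
        assert len(segs) == 1
        seg = segs[0]
        assert seg.start == pos[inside][0] and seg.end == pos[inside][-1]
        assert seg.phom >= 0.99 and seg.n_het == 0

    def test_short_homozygous_stretch_not_reported(self, rng):
        pos = np.sort(rng.choice(3_000_000, size=3000, replace=False)) + 1
        codes = np.where(rng.random(3000) < 0.4, GT_HET, GT_HOM_REF).astype(np.int8)
        inside = (pos >= 1_000_000) & (pos <= 1_500_000)  # 0.5 Mb only
        codes[inside] = GT_HOM_ALT
        codes[~inside] = np.where(
            rng.random((~inside).sum()) < 0.45, GT_HET, GT_HOM_REF
        )
        assert detect_roh(pos, codes, "chr1", "s") == []

    def test_forty_percent_heterozygous_stretch_rejected(self, rng):
        """A region with 40% heterozygous calls has PHOM < 0.75 and its
        windows exceed the het allowance: no segment."""
        pos = np.arange(1, 3001) * 1000
        codes = np.where(rng.random(3000) < 0.4, GT_HET, GT_HOM_REF).astype(np.int8)
        assert detect_roh(pos, codes, "chr1", "s") == []

    def test_boundaries_are_homozygous_sites(self, rng):
        pos = np.sort(rng.choice(6_000_000, size=6000, replace=False)) + 1
        codes = np.where(rng.random(6000) < 0.45, GT_HET, GT_HOM_REF).astype(np.int8)
        inside = (pos >= 2_000_000) & (pos <= 4_000_000)
        codes[inside] = GT_HOM_ALT
        for seg in detect_roh(pos, codes, "chr1", "s"):
            i0 = np.searchsorted(pos, seg.start)
            i1 = np.searchsorted(pos, seg.end)
            assert codes[i0] in (GT_HOM_REF, GT_HOM_ALT)
            assert codes[i1] in (GT_HOM_REF, GT_HOM_ALT)

    def test_empty_input(self):
        assert detect_roh(np.array([]), np.array([]), "chr1", "s") == []


class TestMetrics:
    def test_published_arithmetic_consistency(self):
        """278.7 Mb of ROH over a 2,888 Mb callable genome is 9.65%."""
        segs = [ROHSegment("s", "chr1", 1, 278_700_000, 1000, 0, 0, 1.0)]
        m = roh_metrics(segs, callable_bases=2_888_000_000)
        assert m.genome_percent == pytest.approx(9.65, abs=0.01)
        assert m.total_length == 278_700_000

    def test_degenerate_cases(self):
        assert roh_metrics([], 1000).genome_fraction == 0.0
        seg = ROHSegment("s", "chr1", 1, 1000, 10, 0, 0, 1.0)
        assert roh_metrics([seg], 1000).genome_fraction == 1.0
        with pytest.raises(ValueError):
            roh_metrics([], 0)


def _seg(sample, chrom, start, end):
    return ROHSegment(sample, chrom, start, end, 10, 0, 0, 1.0)


class TestMergeShared:
    def test_identical_segments_two_probands(self):
        merged = merge_shared_roh(
            {"a": [_seg("a", "chr1", 100, 200)], "b": [_seg("b", "chr1", 100, 200)]}
        )
        assert len(merged) == 1
        assert merged[0].n_carriers == 2 and (merged[0].start, merged[0].end) == (100, 200)

    def test_partial_overlap_three_probands_union(self):
        merged = merge_shared_roh(
            {
                "a": [_seg("a", "chr1", 100, 250)],
                "b": [_seg("b", "chr1", 200, 400)],
                "c": [_seg("c", "chr1", 350, 500)],
            }
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end, merged[0].n_carriers) == (100, 500, 3)

    def test_private_segment_not_emitted(self):
        assert merge_shared_roh({"a": [_seg("a", "chr1", 1, 10)]}) == []

    def test_matches_brute_force_union_oracle(self, rng):
        """Single-linkage merging equals a brute-force per-base union scan
        on random segment sets."""
        for _ in range(50):
            by_sample = {}
            for s in ("a", "b", "c", "d"):
                segs = []
                for _ in range(int(rng.integers(0, 5))):
                    # even coordinates so intervals can only meet by true
                    # overlap, matching the oracle's per-base scan
                    start = 2 * int(rng.integers(1, 450))
                    segs.append(_seg(s, "chr1", start, start + 2 * int(rng.integers(5, 100))))
                by_sample[s] = segs
            merged = merge_shared_roh(by_sample)
            # oracle: per-base coverage and carriers
            cov = np.zeros(1500, dtype=int)
            carriers = [set() for _ in range(1500)]
            for s, segs in by_sample.items():
                for seg in segs:
                    for b in range(seg.start, seg.end + 1):
                        cov[b] += 1
                        carriers[b].add(s)
            # chain maximal covered runs, keep those with >=2 distinct carriers
            expected = []
            b = 1
            while b < 1500:
                if cov[b]:
                    e = b
                    while e + 1 < 1500 and cov[e + 1]:
                        e += 1
                    who = set().union(*carriers[b : e + 1])
                    if len(who) >= 2:
                        expected.append((b, e, frozenset(who)))
                    b = e + 1
                else:
                    b += 1
            got = [(m.start, m.end, m.carrier_samples) for m in merged]
            assert got == expected


class TestSubtractParental:
    def test_any_overlap_removes(self):
        child = [_seg("c", "chr1", 100, 200), _seg("c", "chr2", 100, 200)]
        parents = [_seg("f", "chr1", 100, 200), _seg("m", "chr2", 300, 400)]
        kept = subtract_parental_roh(child, parents)
        assert [s.chromosome for s in kept] == ["chr2"]

    def test_one_bp_overlap_removes(self):
        child = [_seg("c", "chr1", 100, 200)]
        assert subtract_parental_roh(child, [_seg("m", "chr1", 200, 300)]) == []
        assert subtract_parental_roh(child, [_seg("m", "chr1", 201, 300)]) == child


class TestVariantsInRoh:
    def test_inclusive_bounds(self):
        segs = {"s": [_seg("s", "chr1", 100, 200)]}
        df = pd.DataFrame(
            {"sample": ["s"] * 3, "chrom": ["chr1"] * 3, "pos": [100, 200, 201]}
        )
        assert variants_in_roh(segs, df).tolist() == [True, True, False]

    def test_matches_brute_force_scan(self, rng):
        segs = {}
        for s in ("a", "b"):
            segs[s] = [
                _seg(s, f"chr{c}", int(st), int(st) + int(rng.integers(50, 500)))
                for c in (1, 2)
                for st in rng.integers(1, 5000, size=3)
            ]
        df = pd.DataFrame(
            {
                "sample": rng.choice(["a", "b"], size=1000),
                "chrom": rng.choice(["chr1", "chr2"], size=1000),
                "pos": rng.integers(1, 6000, size=1000),
            }
        )
        got = variants_in_roh(segs, df)
        for i, r in df.iterrows():
            expected = any(
                seg.chromosome == r["chrom"] and seg.start <= r["pos"] <= seg.end
                for seg in segs[r["sample"]]
            )
            assert got[i] == expected


def test_total_length_invariant_to_chromosome_order(planted_cohort):
    """Processing chromosomes in any order yields the same ROH set."""
    from rohvar import detect_cohort_roh

    table = planted_cohort.table
    segs = detect_cohort_roh(table, apply_site_filter=False)
    chroms = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    for sample, expected in segs.items():
        j = table.sample_index(sample)
        got = []
        for chrom in reversed(list(dict.fromkeys(chroms))):
            m = chroms == chrom
            got.extend(detect_roh(pos[m], table.gt[m, j], chrom, sample))
        assert sorted((s.chromosome, s.start, s.end) for s in got) == sorted(
            (s.chromosome, s.start, s.end) for s in expected
        )
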