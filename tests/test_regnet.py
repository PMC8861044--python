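import numpy as np
import pandas as pd
import pytest

from rohvar.regnet import (
    ACTIVE_PROMOTER_STATE,
    InteractionPair,
    RegulatoryElement,
    RegulatoryTracks,
    annotate_roh_noncoding,
    classify_enhancer,
    classify_promoter,
    link_to_genes,
    read_bed,
    write_bed,
)


def el(source, chrom, start, end, cell=None, label=None):
    return RegulatoryElement(source, chrom, start, end, cell_line=cell, state_label=label)


def tracks_with(peaks=(), pres=(), states=()):
    t = RegulatoryTracks()
    for s, e in peaks:
        t.h3k4me3.add(el("h3k4me3_peak", "chr1", s, e))
    for s, e in pres:
        t.pre.add(el("pre_enhancer", "chr1", s, e))
    for s, e, cell, label in states:
        t.chromatin.add(el("chromatin_state", "chr1", s, e, cell, label))
    return t


class TestPromoterClassification:
    def test_in_peak_without_active_promoter_state_is_specific(self):
        t = tracks_with(peaks=[(100, 200)])
        assert classify_promoter("chr1", 150, "A", t) == "brain_specific_promoter"

    def test_cell_line_active_promoter_downgrades(self):
        t = tracks_with(
            peaks=[(100, 200)],
            states=[(140, 160, "HepG2", ACTIVE_PROMOTER_STATE)],
        )
        assert classify_promoter("chr1", 150, "A", t) == "brain_promoter"

    def test_outside_peaks_is_none(self):
        t = tracks_with(peaks=[(100, 200)])
        assert classify_promoter("chr1", 201, "A", t) == "none"


class TestEnhancerClassification:
    def test_in_pre_without_strong_enhancer_is_specific(self):
        t = tracks_with(pres=[(100, 200)])
        assert classify_enhancer("chr1", 150, "A", t) == "brain_specific_enhancer"

    @pytest.mark.parametrize("state", ["4_Strong_Enhancer", "5_Strong_Enhancer"])
    def test_strong_enhancer_state_downgrades(self, state):
        t = tracks_with(pres=[(100, 200)], states=[(150, 150, "K562", state)])
        assert classify_enhancer("chr1", 150, "A", t) == "brain_enhancer"

    def test_weak_states_do_not_downgrade(self):
        t = tracks_with(
            pres=[(100, 200)], states=[(150, 150, "K562", "7_Weak_Enhancer")]
        )
        assert classify_enhancer("chr1", 150, "A", t) == "brain_specific_enhancer"


class TestLinking:
    PAIRS = [
        InteractionPair(("chr1", 100, 200), ("chr1", 5000, 5100), "G1"),
        InteractionPair(("chr1", 150, 250), ("chr1", 7000, 7100), "G2"),
    ]

    def test_variant_in_anchor_links_target_gene(self):
        assert link_to_genes("chr1", 120, "A", self.PAIRS[:1]) == {"G1"}

    def test_variant_in_no_anchor_links_nothing(self):
        assert link_to_genes("chr1", 3000, "A", self.PAIRS) == set()

    def test_two_pairs_link_both_genes(self):
        assert link_to_genes("chr1", 180, "A", self.PAIRS) == {"G1", "G2"}

    def test_promoter_map_gates_link(self):
        promoters = {"G1": [("chr1", 5000, 5100)], "G2": [("chr1", 9000, 9100)]}
        assert link_to_genes("chr1", 180, "A", self.PAIRS, promoters) == {"G1"}

    def test_matches_brute_force_pair_scan(self, rng):
        pairs = [
            InteractionPair(
                ("chr1", int(s1), int(s1) + 50),
                ("chr1", int(s2), int(s2) + 50),
                f"G{k}",
            )
            for k, (s1, s2) in enumerate(
                zip(rng.integers(1, 2000, 40), rng.integers(1, 2000, 40))
            )
        ]
        for pos in rng.integers(1, 2100, size=200):
            got = link_to_genes("chr1", int(pos), "A", pairs)
            expected = {
                p.target_gene
                for p in pairs
                if p.anchor1[1] <= pos <= p.anchor1[2]
                or p.anchor2[1] <= pos <= p.anchor2[2]
            }
            assert got == expected


class TestOracleEquivalence:
    def _random_tracks(self, rng, n=60):
        elements = []
        for _ in range(n):
            s = int(rng.integers(1, 5000))
            e = s + int(rng.integers(1, 100))
            kind = rng.choice(["peak", "pre", "state"])
            if kind == "peak":
                elements.append(el("h3k4me3_peak", "chr1", s, e))
            elif kind == "pre":
                elements.append(el("pre_enhancer", "chr1", s, e))
            else:
                elements.append(
                    el(
                        "chromatin_state", "chr1", s, e,
                        str(rng.choice(["HepG2", "K562", "NHEK"])),
                        str(
                            rng.choice(
                                [
                                    ACTIVE_PROMOTER_STATE,
                                    "4_Strong_Enhancer",
                                    "5_Strong_Enhancer",
                                    "11_Weak_Txn",
                                ]
                            )
                        ),
                    )
                )
        t = RegulatoryTracks()
        for e_ in elements:
            if e_.source == "h3k4me3_peak":
                t.h3k4me3.add(e_)
            elif e_.source == "pre_enhancer":
                t.pre.add(e_)
            else:
                t.chromatin.add(e_)
        return t, elements

    def test_classification_equals_point_overlap_oracle(self, rng):
        """Promoter/enhancer categories equal a brute-force per-element
        overlap scan, and brain-specific calls always satisfy the
        brain-level condition."""
        for _ in range(5):
            tracks, elements = self._random_tracks(rng)
            for pos in rng.integers(1, 5200, size=200):
                pos = int(pos)
                in_peak = any(
                    e.source == "h3k4me3_peak" and e.start <= pos <= e.end
                    for e in elements
                )
                in_pre = any(
                    e.source == "pre_enhancer" and e.start <= pos <= e.end
                    for e in elements
                )
                has_active = any(
                    e.source == "chromatin_state"
                    and e.state_label == ACTIVE_PROMOTER_STATE
                    and e.start <= pos <= e.end
                    for e in elements
                )
                has_strong = any(
                    e.source == "chromatin_state"
                    and e.state_label in ("4_Strong_Enhancer", "5_Strong_Enhancer")
                    and e.start <= pos <= e.end
                    for e in elements
                )
                p = classify_promoter("chr1", pos, "A", tracks)
                en = classify_enhancer("chr1", pos, "A", tracks)
                assert p == (
                    "none"
                    if not in_peak
                    else "brain_promoter" if has_active else "brain_specific_promoter"
                )
                assert en == (
                    "none"
                    if not in_pre
                    else "brain_enhancer" if has_strong else "brain_specific_enhancer"
                )
                # specific implies the brain-level condition
                if p == "brain_specific_promoter":
                    assert in_peak
                if en == "brain_specific_enhancer":
                    assert in_pre

    def test_invariant_to_element_order(self, rng):
        tracks, elements = self._random_tracks(rng)
        shuffled = list(elements)
        rng.shuffle(shuffled)
        t2 = RegulatoryTracks()
        for e_ in shuffled:
            {"h3k4me3_peak": t2.h3k4me3, "pre_enhancer": t2.pre}.get(
                e_.source, t2.chromatin
            ).add(e_)
        for pos in rng.integers(1, 5200, size=100):
            pos = int(pos)
            assert classify_promoter("chr1", pos, "A", tracks) == classify_promoter(
                "chr1", pos, "A", t2
            )
            assert classify_enhancer("chr1", pos, "A", tracks) == classify_enhancer(
                "chr1", pos, "A", t2
            )


class TestAnnotateTable:
    def test_empty_input_empty_output(self):
        t = tracks_with(peaks=[(1, 10)])
        assert annotate_roh_noncoding(pd.DataFrame(columns=["chrom", "pos", "ref"]), t) == []

    def test_dual_overlap_reports_both_categories(self):
        t = tracks_with(peaks=[(100, 200)], pres=[(150, 250)])
        t.n_cell_lines_expected = 0
        calls = annotate_roh_noncoding(
            pd.DataFrame({"chrom": ["chr1"], "pos": [160], "ref": ["A"]}), t
        )
        assert set(calls[0].categories) == {
            "brain_specific_promoter",
            "brain_specific_enhancer",
        }

    def test_indel_ref_footprint_overlap(self):
        t = tracks_with(pres=[(100, 200)])
        t.n_cell_lines_expected = 0
        # deletion starting at 95 with 10 bp REF footprint reaches into the pRE
        calls = annotate_roh_noncoding(
            pd.DataFrame({"chrom": ["chr1"], "pos": [95], "ref": ["ACGTACGTAC"]}), t
        )
        assert "brain_specific_enhancer" in calls[0].categories

    def test_fewer_cell_lines_warns(self):
        t = tracks_with(peaks=[(1, 10)], states=[(1, 5, "K562", "11_Weak_Txn")])
        with pytest.warns(UserWarning, match="cell lines"):
            annotate_roh_noncoding(
                pd.DataFrame({"chrom": ["chr1"], "pos": [5], "ref": ["A"]}), t
            )


def test_bed_round_trip_coordinates(tmp_path):
    """BED on disk is 0-based half-open; internal is 1-based inclusive."""
    path = tmp_path / "t.bed"
    write_bed([("chr1", 101, 200)], path)
    raw = path.read_text().split()
    assert raw[:3] == ["chr1", "100", "200"]
    els = read_bed(path, "pre_enhancer")
    assert (els[0].start, els[0].end) == (101, 200)
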