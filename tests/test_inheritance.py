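import numpy as np
import pytest

from rohvar import (
    VariantSite,
    call_compound_het,
    call_de_novo,
    call_hom_inherited,
    call_x_linked,
)
from rohvar.genome import Chromosome
from rohvar.inheritance import DeNovoParams, MissingGenotype
from rohvar.variants import GenotypeCall


def site(**kw):
    base = dict(
        chromosome="chr1", position=1000, ref="A", alt="G", qd=10.0,
        read_pos_rank_sum=0.0, af_1000g=0.0, af_gnomad=0.0, af_gme=0.0,
        effect_annotation="nonsynonymous_SNV", gene="G1",
    )
    base.update(kw)
    return VariantSite(**base)


def gc(sample, gt, ad=(15, 15), gq=99):
    return GenotypeCall(sample, gt, gq, ad)


HOM_REF = gc("x", "hom_ref", (30, 0))
HET = gc("x", "het", (15, 15))


class TestDeNovo:
    def test_clean_autosomal_de_novo_called(self):
        ok, ev = call_de_novo(
            site(), gc("c", "het", (15, 15)), HOM_REF, HOM_REF,
            child_is_male=True, on_male_xy=False,
        )
        assert ok and all(ev.values())

    def test_allele_balance_boundary(self):
        # AB = 0.29 fails criterion (i); 0.30 passes
        ok, ev = call_de_novo(
            site(), gc("c", "het", (71, 29)), HOM_REF, HOM_REF,
            child_is_male=False, on_male_xy=False,
        )
        assert not ok and not ev["allele_balance"]
        ok, _ = call_de_novo(
            site(), gc("c", "het", (70, 30)), HOM_REF, HOM_REF,
            child_is_male=False, on_male_xy=False,
        )
        assert ok

    def test_male_x_hemizygous_branch_requires_high_ab(self):
        s = site(chromosome="chrX")
        ok, ev = call_de_novo(
            s, gc("c", "hemi_alt", (1, 19)), gc("f", "hemi_ref", (20, 0)), HOM_REF,
            child_is_male=True, on_male_xy=True,
        )
        assert ok and ev["allele_balance"]  # AB 0.95 >= 0.7
        ok, ev = call_de_novo(
            s, gc("c", "hemi_alt", (8, 12)), gc("f", "hemi_ref", (20, 0)), HOM_REF,
            child_is_male=True, on_male_xy=True,
        )
        assert not ok  # AB 0.6 < 0.7 on male X

    @pytest.mark.parametrize(
        "kw,failing",
        [
            (dict(qd=3.9), "qd"),
            (dict(read_pos_rank_sum=-2.6), "read_pos_rank_sum"),
            (dict(af_gnomad=0.002), "rare_in_databases"),
            (dict(in_segdup=True), "outside_repeats"),
            (dict(in_simple_repeat=True), "outside_repeats"),
            (dict(ref="A" * 51, alt="A"), "indel_size"),
        ],
    )
    def test_each_criterion_gates(self, kw, failing):
        ok, ev = call_de_novo(
            site(**kw), gc("c", "het", (15, 15)), HOM_REF, HOM_REF,
            child_is_male=False, on_male_xy=False,
        )
        assert not ok and not ev[failing]

    def test_parent_or_sibling_carrier_blocks(self):
        ok, ev = call_de_novo(
            site(), gc("c", "het"), HET, HOM_REF,
            child_is_male=False, on_male_xy=False,
        )
        assert not ok and not ev["absent_in_parents"]
        ok, ev = call_de_novo(
            site(), gc("c", "het"), HOM_REF, HOM_REF,
            child_is_male=False, on_male_xy=False, sibling=HET,
        )
        assert not ok and not ev["absent_in_sibling"]

    def test_other_cohort_rare_carrier_blocks(self):
        ok, ev = call_de_novo(
            site(), gc("c", "het"), HOM_REF, HOM_REF,
            child_is_male=False, on_male_xy=False, other_rare_carriers=1,
        )
        assert not ok and not ev["no_other_rare_carrier"]

    def test_missing_parent_genotype_raises(self):
        with pytest.raises(MissingGenotype):
            call_de_novo(
                site(), gc("c", "het"), gc("f", "missing", (0, 0)), HOM_REF,
                child_is_male=False, on_male_xy=False,
            )

    def test_relaxing_thresholds_never_shrinks_call_set(self, rng):
        """Monotone filters: loosening any one de novo threshold can only
        add calls, never remove them."""
        sites_calls = []
        for _ in range(300):
            s = site(
                qd=float(rng.uniform(0, 10)),
                read_pos_rank_sum=float(rng.uniform(-5, 2)),
                af_gnomad=float(rng.uniform(0, 0.004)),
            )
            c = gc("c", "het", (int(rng.integers(0, 30)), int(rng.integers(1, 30))))
            sites_calls.append((s, c))

        def called(params):
            return {
                i
                for i, (s, c) in enumerate(sites_calls)
                if call_de_novo(
                    s, c, HOM_REF, HOM_REF,
                    child_is_male=False, on_male_xy=False, params=params,
                )[0]
            }

        base = called(DeNovoParams())
        for relaxed in (
            DeNovoParams(min_qd=2.0),
            DeNovoParams(min_rprs=-4.0),
            DeNovoParams(max_af=0.01),
            DeNovoParams(ab_range=(0.2, 0.8)),
        ):
            assert called(relaxed) >= base


class TestHomInherited:
    def test_child_hom_parents_het(self):
        ok, _ = call_hom_inherited(site(), gc("c", "hom_alt", (0, 30)), HET, HET)
        assert ok

    def test_parent_homozygosity_excluded(self):
        ok, ev = call_hom_inherited(
            site(), gc("c", "hom_alt", (0, 30)), gc("f", "hom_alt", (0, 30)), HET
        )
        assert not ok and not ev["neither_parent_hom"]

    def test_unaffected_sibling_homozygosity_excluded(self):
        ok, ev = call_hom_inherited(
            site(), gc("c", "hom_alt", (0, 30)), HET, HET,
            unaffected_sibling=gc("s", "hom_alt", (0, 30)),
        )
        assert not ok and not ev["not_hom_in_unaffected_sibling"]


X = Chromosome("chrX", 60_000_000, is_x=True, par=((1, 1_000_000), (59_000_000, 60_000_000)))


class TestXLinked:
    def test_non_par_hemizygous_called(self):
        s = site(chromosome="chrX", position=30_000_000)
        ok, _ = call_x_linked(
            s, X, gc("c", "hemi_alt", (0, 30)), gc("f", "hemi_ref", (30, 0)), HET,
            child_is_male=True,
        )
        assert ok

    def test_carrier_father_blocks(self):
        s = site(chromosome="chrX", position=30_000_000)
        ok, ev = call_x_linked(
            s, X, gc("c", "hemi_alt", (0, 30)), gc("f", "hemi_alt", (0, 30)), HET,
            child_is_male=True,
        )
        assert not ok and not ev["father_non_carrier"]

    def test_par_het_male_excluded(self):
        s = site(chromosome="chrX", position=500_000)
        ok, ev = call_x_linked(
            s, X, gc("c", "het", (15, 15)), gc("f", "hom_ref", (30, 0)), HET,
            child_is_male=True,
        )
        assert not ok and not ev["not_het_in_par"]

    def test_autosomal_site_rejected(self):
        with pytest.raises(ValueError):
            call_x_linked(
                site(), Chromosome("chr1", 1_000_000),
                gc("c", "hemi_alt", (0, 30)), HOM_REF, HET, child_is_male=True,
            )


class TestCompoundHet:
    def _tuples(self, spec):
        """spec: list of (gene, father_gt, mother_gt)."""
        out = []
        for i, (gene, fgt, mgt) in enumerate(spec):
            s = site(gene=gene, position=1000 + i)
            out.append(
                (s, gc("c", "het"), gc("f", fgt, (15, 15)), gc("m", mgt, (15, 15)))
            )
        return out

    def test_opposite_parents_pair_called(self):
        calls = call_compound_het(
            "c", self._tuples([("G", "het", "hom_ref"), ("G", "hom_ref", "het")])
        )
        assert len(calls) == 1
        assert {s.position for s in calls[0].sites} == {1000, 1001}

    def test_same_parent_no_call(self):
        assert call_compound_het(
            "c", self._tuples([("G", "hom_ref", "het"), ("G", "hom_ref", "het")])
        ) == []

    def test_single_site_no_call(self):
        assert call_compound_het("c", self._tuples([("G", "het", "hom_ref")])) == []

    def test_ambiguous_both_parent_carrier_excluded(self):
        calls = call_compound_het(
            "c", self._tuples([("G", "het", "het"), ("G", "hom_ref", "het")])
        )
        assert calls == []

    def test_noncoding_sites_excluded(self):
        tuples = self._tuples([("G", "het", "hom_ref"), ("G", "hom_ref", "het")])
        s0 = tuples[0][0]
        s0.effect_annotation = "intronic"
        assert call_compound_het("c", tuples) == []


def test_planted_recovery_and_mode_exclusivity(planted_cohort):
    """Every planted event is recovered by the cohort scan under its own
    mode and no two modes fire for the same (site, child)."""
    from rohvar.inheritance import scan_cohort

    res = scan_cohort(
        planted_cohort.table,
        planted_cohort.pedigree,
        chromosomes=planted_cohort.model.chromosomes,
    )
    seen = {}
    for c in res.calls:
        for s in c.sites:
            key = (c.sample_id, s.chromosome, s.position)
            assert key not in seen or seen[key] == c.mode
            seen[key] = c.mode
    mode_map = {
        "de_novo": "de_novo",
        "compound_het": "compound_het",
        "hom_in_roh": "hom_inherited",
        "x_linked": "x_linked",
    }
    for _, ev in planted_cohort.ledger.iterrows():
        key = (ev["sample"], ev["chrom"], ev["pos"])
        assert seen.get(key) == mode_map[ev["mode"]]
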