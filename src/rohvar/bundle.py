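"""Write and read a complete pipeline input bundle for a synthetic cohort.

The bundle mirrors the study's input shapes: a multi-sample VCF
(GT:GQ:AD, QD/ReadPosRankSum/annotation INFO keys), a pedigree TSV, BED
tracks (chromatin-state segmentations for nine cell lines, H3K4me3 peaks,
predicted regulatory elements, segmental duplications, simple repeats,
activating marks), a promoter-enhancer interaction-pair TSV, and gene
tables (SFARI/NDD lists, constraint scores, OMIM phenotypes, brain
expression, SFARI CNV loci with median ASD-case sizes).  Planted
regulatory-overlap variants are guaranteed an element (and interaction
pair) over their position; background intervals avoid planted loci so
brain-specificity is controlled by construction.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import read_pedigree_tsv, write_pedigree_tsv
from .regnet import RegulatoryTracks, load_tracks, write_bed
from .simulate import SyntheticCohort, gene_symbol
from .variants import CohortTable, read_cohort_vcf, write_cohort_vcf

CELL_LINES = (
    "GM12878", "H1hESC", "HepG2", "HMEC", "HSMM",
    "HUVEC", "K562", "NHEK", "NHLF",
)

BACKGROUND_STATES = (
    "1_Active_Promoter",
    "4_Strong_Enhancer",
    "5_Strong_Enhancer",
    "7_Weak_Enhancer",
    "9_Txn_Transition",
    "11_Weak_Txn",
    "13_Heterochrom_lo",
)

GENE_BIN_BP = 100_000


def gene_promoter_interval(gene: str) -> tuple[str, int, int]:
    """Promoter interval of a synthetic gene (first 2 kb of its bin)."""
    num, bin_idx = gene.removeprefix("G").split("_")
    start = int(bin_idx) * GENE_BIN_BP + 1
    return f"chr{num}", start, start + 1999


def write_fixture_bundle(
    cohort: SyntheticCohort, out_dir: str | Path, seed: int = 0
) -> dict[str, Path]:
    """Write all pipeline inputs; returns a name -> path map.

    Background track intervals are drawn at random but never overlap a
    planted locus (2 kb exclusion), so planted brain-specific elements
    stay specific and planted de novo sites stay outside repeat tracks.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    table = cohort.table
    ledger = cohort.ledger
    model = cohort.model

    paths: dict[str, Path] = {}
    paths["vcf"] = out / "cohort.vcf"
    write_cohort_vcf(
        table, paths["vcf"], {c.name: c.length_bp for c in model.chromosomes}
    )
    paths["pedigree"] = out / "pedigree.tsv"
    write_pedigree_tsv(cohort.pedigree, paths["pedigree"])

    planted = ledger if len(ledger) else pd.DataFrame(columns=["chrom", "pos", "regulatory_kind", "gene"])
    avoid: dict[str, list[int]] = {}
    for _, r in planted.iterrows():
        avoid.setdefault(r["chrom"], []).append(int(r["pos"]))

    def background(n_per_chrom: int, width: int) -> list[tuple[str, int, int]]:
        ivs = []
        for chrom in model.chromosomes:
            bad = avoid.get(chrom.name, [])
            made = 0
            while made < n_per_chrom:
                s = int(rng.integers(1, max(2, chrom.length_bp - width)))
                if any(abs(s - p) < width + 2000 for p in bad):
                    continue
                ivs.append((chrom.name, s, s + width - 1))
                made += 1
        return ivs

    prom = planted[planted["regulatory_kind"] == "promoter"]
    enh = planted[planted["regulatory_kind"] == "enhancer"]

    peaks = [(r["chrom"], int(r["pos"]) - 500, int(r["pos"]) + 500) for _, r in prom.iterrows()]
    peaks += background(3, 1000)
    paths["h3k4me3"] = out / "h3k4me3_peaks.bed"
    write_bed(peaks, paths["h3k4me3"])

    pres = [(r["chrom"], int(r["pos"]) - 400, int(r["pos"]) + 400) for _, r in enh.iterrows()]
    pres += background(3, 800)
    paths["pre"] = out / "pre_elements.bed"
    write_bed(pres, paths["pre"])

    chromatin_paths = {}
    for cell in CELL_LINES:
        ivs = []
        for chrom, s, e in background(4, 1200):
            label = str(rng.choice(BACKGROUND_STATES))
            ivs.append((chrom, s, e, label))
        p = out / f"chromstate_{cell}.bed"
        write_bed(ivs, p, with_label=True)
        chromatin_paths[cell] = p
    paths.update({f"chromstate_{c}": p for c, p in chromatin_paths.items()})

    marks = {}
    for mark in ("H3K4me1", "H3K27ac"):
        ivs = [
            (r["chrom"], int(r["pos"]) - 600, int(r["pos"]) + 600)
            for _, r in enh.iterrows()
        ] + background(2, 1200)
        p = out / f"{mark.lower()}.bed"
        write_bed(ivs, p)
        marks[mark] = p
        paths[mark] = p

    paths["segdup"] = out / "segdups.bed"
    write_bed(background(2, 5000), paths["segdup"])
    paths["simple_repeat"] = out / "simple_repeats.bed"
    write_bed(background(2, 300), paths["simple_repeat"])

    pair_rows = []
    for _, r in pd.concat([prom, enh]).iterrows():
        chrom, pos, gene = r["chrom"], int(r["pos"]), r["gene"]
        pc, ps, pe = gene_promoter_interval(gene)
        pair_rows.append([chrom, pos - 600, pos + 600, pc, ps - 1, pe, gene])
    paths["pairs"] = out / "interactions.tsv"
    pd.DataFrame(pair_rows).to_csv(paths["pairs"], sep="\t", header=False, index=False)

    # gene tables
    genes = sorted(set(planted["gene"].dropna()) | set(table.sites["gene"].dropna()))
    genes = genes[:500]
    known = sorted(set(planted.loc[planted.get("known_gene", False) == True, "gene"]))  # noqa: E712
    extra = [g for g in genes if g not in known][:5]
    paths["sfari_genes"] = out / "sfari_genes.tsv"
    pd.DataFrame(
        {"gene": known + extra, "score": ["S"] * len(known) + ["2"] * len(extra)}
    ).to_csv(paths["sfari_genes"], sep="\t", index=False)
    paths["ndd_genes"] = out / "ndd_genes.tsv"
    pd.DataFrame({"gene": extra[:3]}).to_csv(paths["ndd_genes"], sep="\t", index=False)
    paths["constraint"] = out / "constraint.tsv"
    pd.DataFrame(
        {
            "gene": genes,
            "pli": rng.random(len(genes)).round(3),
            "prec": rng.random(len(genes)).round(3),
            "pnull": rng.random(len(genes)).round(3),
        }
    ).to_csv(paths["constraint"], sep="\t", index=False)
    paths["omim"] = out / "omim.tsv"
    pd.DataFrame(
        {"gene": extra[:2], "phenotype": ["Intellectual disability", "Epilepsy"][: len(extra[:2])]}
    ).to_csv(paths["omim"], sep="\t", index=False)
    expressed = set(planted.loc[planted.get("brain_expressed", False) == True, "gene"])  # noqa: E712
    paths["expression"] = out / "expression.tsv"
    pd.DataFrame(
        {
            "gene": genes,
            "brain_expressed": [g in expressed or bool(rng.random() < 0.3) for g in genes],
        }
    ).to_csv(paths["expression"], sep="\t", index=False)
    first = model.chromosomes[0].name
    paths["sfari_cnv"] = out / "sfari_cnv.tsv"
    pd.DataFrame(
        {
            "chrom": [first] * 2,
            "start": [1_000_000, 10_000_000],
            "end": [3_000_000, 12_000_000],
            "locus": ["locus_A", "locus_B"],
            "median_size_bp": [500_000, 1_500_000],
        }
    ).to_csv(paths["sfari_cnv"], sep="\t", index=False)

    manifest = {
        "vcf": paths["vcf"].name,
        "pedigree": paths["pedigree"].name,
        "chromatin_states": {c: p.name for c, p in chromatin_paths.items()},
        "h3k4me3": paths["h3k4me3"].name,
        "pre": paths["pre"].name,
        "marks": {m: p.name for m, p in marks.items()},
        "pairs": paths["pairs"].name,
        "segdup": paths["segdup"].name,
        "simple_repeat": paths["simple_repeat"].name,
        "gene_tables": {
            k: paths[k].name
            for k in ("sfari_genes", "ndd_genes", "constraint", "omim", "expression", "sfari_cnv")
        },
    }
    paths["manifest"] = out / "tracks.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=1))
    return paths


def load_fixture_bundle(bundle_dir: str | Path):
    """Read a bundle back: (CohortTable, Pedigree, RegulatoryTracks, tables)."""
    d = Path(bundle_dir)
    manifest = json.loads((d / "tracks.json").read_text())
    pedigree = read_pedigree_tsv(d / manifest["pedigree"])
    table = read_cohort_vcf(d / manifest["vcf"], pedigree)
    tracks = load_tracks(
        {c: d / p for c, p in manifest["chromatin_states"].items()},
        h3k4me3_bed=d / manifest["h3k4me3"],
        pre_bed=d / manifest["pre"],
        mark_beds={m: d / p for m, p in manifest["marks"].items()},
        pairs_tsv=d / manifest["pairs"],
    )
    tracks.promoters_by_gene = {
        g: [gene_promoter_interval(g)]
        for g in {p.target_gene for p in tracks.pairs}
    }
    tables = {
        k: pd.read_csv(d / v, sep="\t")
        for k, v in manifest["gene_tables"].items()
    }
    return table, pedigree, tracks, tables
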