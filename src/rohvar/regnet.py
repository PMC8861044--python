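"""Brain regulatory-element annotation of noncoding variants.

Variants are intersected with three kinds of epigenomic interval tracks:
H3K4me3 peaks from human prefrontal cortex (promoter evidence), predicted
developmental brain enhancers (pREs), and chromatin-state segmentations
from nine non-neuronal cell lines.  A variant inside a peak is a predicted
brain-promoter variant; if no cell line calls an overlapping
``1_Active_Promoter`` state it is upgraded to brain-specific.  Enhancers
work the same way against ``4_Strong_Enhancer``/``5_Strong_Enhancer``
states.  Promoter-enhancer interaction pairs (PLAC-seq-style) link a
variant's element to its target gene's promoter.

Coordinates: BED intervals are 0-based half-open on disk and converted to
1-based inclusive internally; an SNV at position p overlaps [s, e) iff
s < p <= e.  Indels use their REF footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

ACTIVE_PROMOTER_STATE = "1_Active_Promoter"
STRONG_ENHANCER_STATES = ("4_Strong_Enhancer", "5_Strong_Enhancer")

CATEGORIES = (
    "brain_promoter",
    "brain_specific_promoter",
    "brain_enhancer",
    "brain_specific_enhancer",
    "none",
)


@dataclass(frozen=True)
class RegulatoryElement:
    source: str  # chromatin_state | h3k4me3_peak | pre_enhancer
    chromosome: str
    start: int  # 1-based inclusive (converted from BED)
    end: int
    cell_line: Optional[str] = None
    state_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")
        if self.source == "chromatin_state" and (
            self.cell_line is None or self.state_label is None
        ):
            raise ValueError("chromatin_state elements need cell_line and state_label")


@dataclass(frozen=True)
class InteractionPair:
    anchor1: tuple[str, int, int]  # (chrom, start, end) 1-based inclusive
    anchor2: tuple[str, int, int]
    target_gene: str

    def __post_init__(self) -> None:
        for c, s, e in (self.anchor1, self.anchor2):
            if s > e:
                raise ValueError("empty anchor")
        if not self.target_gene:
            raise ValueError("target gene required")


@dataclass
class RegulatoryCall:
    chrom: str
    pos: int
    sample: Optional[str]
    categories: list[str]
    linked_genes: set[str]
    supporting_marks: set[str]
    state_notes: list[str] = field(default_factory=list)


class IntervalIndex:
    """Per-chromosome interval lookup over 1-based inclusive intervals."""

    def __init__(self, elements: Iterable[RegulatoryElement] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for el in elements:
            self.add(el)

    def add(self, el: RegulatoryElement) -> None:
        # intervaltree is half-open; store [start, end+1)
        self._trees.setdefault(el.chromosome, IntervalTree()).addi(
            el.start, el.end + 1, el
        )

    def overlapping(self, chrom: str, start: int, end: int) -> list[RegulatoryElement]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end + 1)]

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def variant_footprint(pos: int, ref: str = "N") -> tuple[int, int]:
    """1-based inclusive REF footprint of a variant."""
    return pos, pos + max(len(ref), 1) - 1


@dataclass
class RegulatoryTracks:
    """All interval evidence used by the classifier."""

    h3k4me3: IntervalIndex = field(default_factory=IntervalIndex)
    pre: IntervalIndex = field(default_factory=IntervalIndex)
    chromatin: IntervalIndex = field(default_factory=IntervalIndex)
    marks: dict[str, IntervalIndex] = field(default_factory=dict)  # e.g. H3K4me1
    pairs: list[InteractionPair] = field(default_factory=list)
    promoters_by_gene: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    n_cell_lines_expected: int = 9

    def cell_lines(self) -> set[str]:
        return {
            el.cell_line
            for tree in self.chromatin._trees.values()
            for iv in tree
            for el in [iv.data]
        }

    def check_cell_lines(self) -> None:
        n = len(self.cell_lines())
        if n < self.n_cell_lines_expected:
            warnings.warn(
                f"chromatin-state tracks cover {n} cell lines; "
                f"{self.n_cell_lines_expected} expected",
                stacklevel=2,
            )


def classify_promoter(
    chrom: str, pos: int, ref: str, tracks: RegulatoryTracks
) -> str:
    """Promoter category of a variant position.

    ``brain_promoter`` iff inside any H3K4me3 peak; upgraded to
    ``brain_specific_promoter`` iff additionally no cell line has an
    overlapping ``1_Active_Promoter`` chromatin state.
    """
    s, e = variant_footprint(pos, ref)
    if not tracks.h3k4me3.overlapping(chrom, s, e):
        return "none"
    states = tracks.chromatin.overlapping(chrom, s, e)
    if any(el.state_label == ACTIVE_PROMOTER_STATE for el in states):
        return "brain_promoter"
    return "brain_specific_promoter"


def classify_enhancer(
    chrom: str, pos: int, ref: str, tracks: RegulatoryTracks
) -> str:
    """Enhancer category: pRE membership, with strong-enhancer specificity."""
    s, e = variant_footprint(pos, ref)
    if not tracks.pre.overlapping(chrom, s, e):
        return "none"
    states = tracks.chromatin.overlapping(chrom, s, e)
    if any(el.state_label in STRONG_ENHANCER_STATES for el in states):
        return "brain_enhancer"
    return "brain_specific_enhancer"


def _intervals_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]


def link_to_genes(
    chrom: str,
    pos: int,
    ref: str,
    pairs: Sequence[InteractionPair],
    promoters_by_gene: Optional[Mapping[str, Sequence[tuple[str, int, int]]]] = None,
) -> set[str]:
    """Genes whose promoters interact with the element containing the variant.

    For every pair with one anchor containing the variant, the target gene
    is linked when the other anchor overlaps that gene's promoter (or
    unconditionally when no promoter map is supplied).
    """
    s, e = variant_footprint(pos, ref)
    fp = (chrom, s, e)
    genes: set[str] = set()
    for pair in pairs:
        if _intervals_overlap(fp, pair.anchor1):
            other = pair.anchor2
        elif _intervals_overlap(fp, pair.anchor2):
            other = pair.anchor1
        else:
            continue
        if promoters_by_gene is None:
            genes.add(pair.target_gene)
            continue
        promos = promoters_by_gene.get(pair.target_gene)
        if promos is None or any(_intervals_overlap(other, p) for p in promos):
            genes.add(pair.target_gene)
    return genes


def annotate_roh_noncoding(
    variants: pd.DataFrame, tracks: RegulatoryTracks
) -> list[RegulatoryCall]:
    """Regulatory annotation for noncoding inherited-homozygous ROH variants.

    ``variants`` needs columns chrom, pos, ref and optionally sample.  A
    variant overlapping both promoter- and enhancer-defining tracks
    receives both categories.  Activating-mark support (H3K4me1/H3K27ac)
    and non-category chromatin-state labels are reported as annotations.
    """
    tracks.check_cell_lines()
    out: list[RegulatoryCall] = []
    for _, r in variants.iterrows():
        chrom, pos, ref = r["chrom"], int(r["pos"]), r.get("ref", "N")
        cats = []
        p = classify_promoter(chrom, pos, ref, tracks)
        en = classify_enhancer(chrom, pos, ref, tracks)
        if p != "none":
            cats.append(p)
        if en != "none":
            cats.append(en)
        s, e = variant_footprint(pos, ref)
        marks = {
            name for name, idx in tracks.marks.items() if idx.overlapping(chrom, s, e)
        }
        genes = (
            link_to_genes(chrom, pos, ref, tracks.pairs, tracks.promoters_by_gene or None)
            if cats
            else set()
        )
        notes = sorted(
            {
                f"{el.cell_line}:{el.state_label}"
                for el in tracks.chromatin.overlapping(chrom, s, e)
                if el.state_label != ACTIVE_PROMOTER_STATE
                and el.state_label not in STRONG_ENHANCER_STATES
            }
        )
        out.append(
            RegulatoryCall(
                chrom=chrom,
                pos=pos,
                sample=r.get("sample"),
                categories=cats or ["none"],
                linked_genes=genes,
                supporting_marks=marks,
                state_notes=notes,
            )
        )
    return out


# -- BED / track I/O -----------------------------------------------------


def read_bed(
    path: str | Path,
    source: str,
    cell_line: Optional[str] = None,
    label_column: bool = False,
) -> list[RegulatoryElement]:
    """Read a BED file (0-based half-open) into 1-based elements."""
    names = ["chrom", "start", "end"] + (["label"] if label_column else [])
    df = pd.read_csv(path, sep="\t", header=None, names=names, usecols=range(len(names)))
    out = []
    for _, r in df.iterrows():
        out.append(
            RegulatoryElement(
                source=source,
                chromosome=r["chrom"],
                start=int(r["start"]) + 1,
                end=int(r["end"]),
                cell_line=cell_line,
                state_label=r["label"] if label_column else None,
            )
        )
    return out


def write_bed(
    elements: Sequence[RegulatoryElement] | Sequence[tuple], path: str | Path,
    with_label: bool = False,
) -> None:
    rows = []
    for el in elements:
        if isinstance(el, RegulatoryElement):
            row = [el.chromosome, el.start - 1, el.end]
            if with_label:
                row.append(el.state_label)
        else:
            chrom, start, end, *rest = el
            row = [chrom, start - 1, end] + (list(rest) if with_label else [])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_interaction_pairs(path: str | Path) -> list[InteractionPair]:
    """Read a BEDPE-like TSV: chrom1 start1 end1 chrom2 start2 end2 gene."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "gene"],
    )
    return [
        InteractionPair(
            (r["chrom1"], int(r["start1"]) + 1, int(r["end1"])),
            (r["chrom2"], int(r["start2"]) + 1, int(r["end2"])),
            r["gene"],
        )
        for _, r in df.iterrows()
    ]


def load_tracks(
    chromatin_beds: Mapping[str, str | Path],
    h3k4me3_bed: Optional[str | Path] = None,
    pre_bed: Optional[str | Path] = None,
    mark_beds: Optional[Mapping[str, str | Path]] = None,
    pairs_tsv: Optional[str | Path] = None,
) -> RegulatoryTracks:
    """Assemble tracks from files; chromatin_beds maps cell line -> BED path."""
    tracks = RegulatoryTracks()
    for cell, path in chromatin_beds.items():
        for el in read_bed(path, "chromatin_state", cell_line=cell, label_column=True):
            tracks.chromatin.add(el)
    if h3k4me3_bed:
        for el in read_bed(h3k4me3_bed, "h3k4me3_peak"):
            tracks.h3k4me3.add(el)
    if pre_bed:
        for el in read_bed(pre_bed, "pre_enhancer"):
            tracks.pre.add(el)
    for name, path in (mark_beds or {}).items():
        idx = IntervalIndex()
        for el in read_bed(path, name, label_column=False):
            idx.add(el)
        tracks.marks[name] = idx
    if pairs_tsv:
        tracks.pairs = read_interaction_pairs(pairs_tsv)
    return tracks
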