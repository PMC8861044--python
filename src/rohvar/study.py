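"""Autozygosity recovery studies.

Drives the simulator and the ROH detector at cohort scale to estimate the
mean autozygous genome fraction of offspring of consanguineous unions and
compare it with the pedigree expectation (F = 1/16 for first cousins,
1/8 for double first cousins).  Replicate children come from independent
families so their autozygous fractions are i.i.d. and the Monte-Carlo
standard error across children is valid.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .genome import GenomeModel, full_scale_model
from .pedigree import build_pedigree
from .roh import ROHParams, detect_roh
from .simulate import gene_drop

EXPECTED_FRACTION = {"first_cousin": 1 / 16, "double_first_cousin": 1 / 8, "trio": 0.0}


def simulate_autozygosity_study(
    kind: str,
    n_children: int,
    model: Optional[GenomeModel] = None,
    seed: int = 1,
    run_detector: bool = True,
    roh_params: Optional[ROHParams] = None,
) -> pd.DataFrame:
    """Gene-drop ``n_children`` independent families of the given union kind.

    Returns one row per child with the truth autozygous genome fraction
    (both haplotypes descending from one founder chromosome) and, when
    ``run_detector`` is set, the fraction of the genome called as ROH by
    the sliding-window detector on genotypes synthesised at the model's
    site density.  Fractions are over the autosomal genome length.
    """
    model = model or full_scale_model(include_x=False)
    params = roh_params or ROHParams()
    ss = np.random.SeedSequence(seed)
    subs = ss.spawn(n_children + 1)
    site_rng = np.random.default_rng(subs[-1])

    autosomes = model.autosomes
    positions: dict[str, np.ndarray] = {}
    afs: dict[str, np.ndarray] = {}
    if run_detector:
        for chrom in autosomes:
            n = int(round(chrom.length_bp / 1e6 * model.site_density))
            positions[chrom.name] = (
                np.sort(site_rng.choice(chrom.length_bp - 1, size=n, replace=False)) + 1
            )
            afs[chrom.name] = model.af_spec.draw(n, site_rng)

    total_bp = model.autosomal_length
    rows = []
    for i in range(n_children):
        rng = np.random.default_rng(subs[i])
        ped = build_pedigree(kind, 1, family_id=f"R{i}", child_sexes=["female"])
        gd = gene_drop(ped, model, rng)
        child = f"R{i}_c1"
        truth = gd.autozygous_fraction(child)
        detected = np.nan
        if run_detector:
            n_labels = 2 * len(ped.founders)
            called_bp = 0
            pair_by_chrom = gd.haplotypes[child]
            for chrom in autosomes:
                pos = positions[chrom.name]
                p = afs[chrom.name]
                alleles = (rng.random((len(pos), n_labels)) < p[:, None]).astype(np.int8)
                pair = pair_by_chrom[chrom.name]
                idx = np.arange(len(pos))
                a1 = alleles[idx, pair.hap1.label_at(pos)]
                a2 = alleles[idx, pair.hap2.label_at(pos)]
                codes = (a1 + a2).astype(np.int8)
                for seg in detect_roh(pos, codes, chrom.name, child, params):
                    called_bp += seg.length
            detected = called_bp / total_bp
        rows.append({"child": child, "truth_fraction": truth, "detected_fraction": detected})
    return pd.DataFrame(rows)


def summarize_study(df: pd.DataFrame) -> dict:
    """Mean and standard error (across children) of both estimators, in %."""
    out = {}
    for col in ("truth_fraction", "detected_fraction"):
        v = df[col].dropna().to_numpy()
        if len(v) == 0:
            continue
        out[col] = {
            "mean_pct": 100.0 * float(v.mean()),
            "se_pct": 100.0 * float(v.std(ddof=1) / np.sqrt(len(v))),
            "n": int(len(v)),
        }
    return out
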