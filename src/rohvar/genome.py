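"""Genome model for the cohort simulator.

A :class:`GenomeModel` describes the chromosomes to simulate (autosomes and
optionally an X with pseudoautosomal intervals), a uniform genetic map in
cM/Mb, the variant site density, and the distribution of founder allele
frequencies.  Two stock profiles are provided: a desk-scale genome for fast
tests and a full-scale ~2,700 Mb / 22-autosome profile whose analytic
autozygosity expectations (6.25% for first-cousin offspring, 12.5% for
double-first-cousin offspring) drive the recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MB = 1_000_000


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    is_x: bool = False
    par: tuple[tuple[int, int], ...] = ()  # 1-based inclusive intervals

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("chromosome length must be positive")
        for s, e in self.par:
            if not (1 <= s <= e <= self.length_bp):
                raise ValueError(f"PAR interval ({s},{e}) outside {self.name}")

    def in_par(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.par)


@dataclass(frozen=True)
class AlleleFrequencySpec:
    """Distribution of founder alternate-allele frequencies.

    Background sites are drawn as "common" (uniform on ``common_af``) so that
    they survive the ROH site filters (cohort MAF > 5%) but are excluded from
    every rare-variant analysis; the matching population-database allele
    frequencies are stamped jointly with concordance ``db_concordance`` (the
    probability that each database reports a frequency consistent with the
    simulated class rather than 0).
    """

    common_af: tuple[float, float] = (0.10, 0.50)
    db_concordance: float = 1.0
    db_noise: float = 0.1  # relative jitter on stamped database AFs

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.common_af
        return rng.uniform(lo, hi, size=n)


@dataclass(frozen=True)
class GenomeModel:
    chromosomes: tuple[Chromosome, ...]
    recombination_rate: float = 1.0  # cM/Mb, uniform, no interference
    site_density: float = 100.0  # variant sites per Mb
    af_spec: AlleleFrequencySpec = field(default_factory=AlleleFrequencySpec)

    def __post_init__(self) -> None:
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")

    @property
    def autosomes(self) -> tuple[Chromosome, ...]:
        return tuple(c for c in self.chromosomes if not c.is_x)

    @property
    def x_chromosome(self) -> Chromosome | None:
        for c in self.chromosomes:
            if c.is_x:
                return c
        return None

    @property
    def autosomal_length(self) -> int:
        return sum(c.length_bp for c in self.autosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)


# GRCh37 autosome lengths (Mb), used only as relative proportions when
# scaling a model to a target genome size.
_GRCH37_AUTOSOME_MB = (
    249.3, 243.2, 198.0, 191.2, 180.9, 171.1, 159.1, 146.4, 141.2, 135.5,
    135.0, 133.9, 115.2, 107.3, 102.5, 90.4, 81.2, 78.1, 59.1, 63.0, 48.1, 51.3,
)

# GRCh37-convention X PARs, scaled into a model X when requested.
_GRCH37_X_MB = 155.3
_GRCH37_PAR = ((60_001, 2_699_520), (154_931_044, 155_260_560))


def full_scale_model(
    total_autosomal_mb: float = 2700.0,
    include_x: bool = True,
    recombination_rate: float = 1.0,
    site_density: float = 100.0,
    af_spec: AlleleFrequencySpec | None = None,
) -> GenomeModel:
    """22 autosomes in GRCh37 proportions totalling ``total_autosomal_mb``."""
    scale = total_autosomal_mb / sum(_GRCH37_AUTOSOME_MB)
    chroms = [
        Chromosome(f"chr{i + 1}", int(round(mb * scale * MB)))
        for i, mb in enumerate(_GRCH37_AUTOSOME_MB)
    ]
    if include_x:
        xlen = int(round(_GRCH37_X_MB * scale * MB))
        xscale = xlen / (_GRCH37_X_MB * MB)
        par = tuple(
            (max(1, int(s * xscale)), min(xlen, int(e * xscale)))
            for s, e in _GRCH37_PAR
        )
        chroms.append(Chromosome("chrX", xlen, is_x=True, par=par))
    return GenomeModel(
        tuple(chroms),
        recombination_rate=recombination_rate,
        site_density=site_density,
        af_spec=af_spec or AlleleFrequencySpec(),
    )


def test_scale_model(
    n_autosomes: int = 4,
    autosome_mb: float = 75.0,
    include_x: bool = True,
    x_mb: float = 60.0,
    recombination_rate: float = 1.0,
    site_density: float = 100.0,
    af_spec: AlleleFrequencySpec | None = None,
) -> GenomeModel:
    """Small genome (default 4 x 75 Mb autosomes + 60 Mb X) for fast runs.

    Few long chromosomes, rather than many short ones, so that autozygous
    segments (mean ~17 Mb for first-cousin offspring at 1 cM/Mb) are not
    dominated by chromosome-end truncation.
    """
    chroms = [
        Chromosome(f"chr{i + 1}", int(autosome_mb * MB)) for i in range(n_autosomes)
    ]
    if include_x:
        xlen = int(x_mb * MB)
        par = ((1, int(0.02 * xlen)), (int(0.98 * xlen), xlen))
        chroms.append(Chromosome("chrX", xlen, is_x=True, par=par))
    return GenomeModel(
        tuple(chroms),
        recombination_rate=recombination_rate,
        site_density=site_density,
        af_spec=af_spec or AlleleFrequencySpec(),
    )
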