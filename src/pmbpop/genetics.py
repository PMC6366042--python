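"""Transgene inheritance and paternal sex-ratio distortion.

The construct modelled here is a single autosomal dominant-marker transgene
whose carriers can be hemizygous (one copy) or homozygous (two copies).
Inheritance is Mendelian: each parent independently transmits 0 or 1 copies.
The phenotype is paternal: broods sired by a transgenic father (hemi- or
homozygous) are strongly male-biased (default 95% male), while the mother's
genotype never affects the brood sex ratio.

Genotype and sex of each egg are drawn independently — a multinomial over
genotypes and a per-egg Bernoulli for sex — which is the only consistent
joint model for an autosomal construct whose sex effect acts through sperm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Genotype",
    "Sex",
    "GENOTYPES",
    "DEFAULT_MALE_BIAS",
    "CrossDistribution",
    "BroodCounts",
    "offspring_genotype_distribution",
    "sample_brood",
]

DEFAULT_MALE_BIAS = 0.95
"""Probability an egg is male when the father carries the transgene."""


class Genotype(str, enum.Enum):
    """Transgene state of an individual: 0, 1 or 2 copies of the construct."""

    WT = "WT"
    HEMI = "HEMI"
    HOMO = "HOMO"

    @property
    def index(self) -> int:
        return _GENOTYPE_INDEX[self]

    @property
    def n_copies(self) -> int:
        return _GENOTYPE_INDEX[self]

    @property
    def is_transgenic(self) -> bool:
        return self is not Genotype.WT


class Sex(str, enum.Enum):
    FEMALE = "F"
    MALE = "M"

    @property
    def index(self) -> int:
        return 0 if self is Sex.FEMALE else 1


GENOTYPES = (Genotype.WT, Genotype.HEMI, Genotype.HOMO)
_GENOTYPE_INDEX = {Genotype.WT: 0, Genotype.HEMI: 1, Genotype.HOMO: 2}

# P(transmit 0 copies), P(transmit 1 copy) for each parental genotype.
_TRANSMISSION = {
    Genotype.WT: (1.0, 0.0),
    Genotype.HEMI: (0.5, 0.5),
    Genotype.HOMO: (0.0, 1.0),
}


@dataclass(frozen=True)
class CrossDistribution:
    """Offspring genotype probabilities and brood sex ratio for a mating pair.

    ``probs`` is ordered (WT, HEMI, HOMO).  Probabilities are exact binary
    fractions (multiples of 1/4), so the sum-to-one invariant holds exactly.
    """

    probs: tuple[float, float, float]
    male_prob: float

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > 1e-12:
            raise ValueError(f"genotype probabilities sum to {sum(self.probs)}, not 1")
        if any(p < 0.0 or p > 1.0 for p in self.probs):
            raise ValueError("genotype probabilities must lie in [0, 1]")
        if not 0.0 <= self.male_prob <= 1.0:
            raise ValueError("male_prob must lie in [0, 1]")

    def prob(self, genotype: Genotype) -> float:
        return self.probs[genotype.index]


def offspring_genotype_distribution(
    father: Genotype,
    mother: Genotype,
    male_bias: float = DEFAULT_MALE_BIAS,
) -> CrossDistribution:
    """Exact single-locus Mendelian cross for the autosomal transgene.

    Each parent transmits one chromosome of the pair, so the offspring copy
    number is the convolution of the two per-parent transmission laws.  The
    brood male probability is ``male_bias`` if and only if the father carries
    the transgene; the mother never distorts the sex ratio.
    """
    father = Genotype(father)
    mother = Genotype(mother)
    pf = _TRANSMISSION[father]
    pm = _TRANSMISSION[mother]
    probs = (
        pf[0] * pm[0],              # 0 copies -> WT
        pf[0] * pm[1] + pf[1] * pm[0],  # 1 copy  -> HEMI
        pf[1] * pm[1],              # 2 copies -> HOMO
    )
    male_prob = male_bias if father.is_transgenic else 0.5
    return CrossDistribution(probs=probs, male_prob=male_prob)


@dataclass
class BroodCounts:
    """Counts of eggs by (genotype, sex).

    ``counts`` has shape (3, 2): rows ordered (WT, HEMI, HOMO), columns
    ordered (female, male).
    """

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((3, 2), dtype=np.int64)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 2):
            raise ValueError("counts must have shape (3, 2)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def zero(cls) -> "BroodCounts":
        return cls()

    def __getitem__(self, key: tuple[Genotype, Sex]) -> int:
        genotype, sex = key
        return int(self.counts[Genotype(genotype).index, Sex(sex).index])

    def __add__(self, other: "BroodCounts") -> "BroodCounts":
        return BroodCounts(self.counts + other.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BroodCounts):
            return NotImplemented
        return bool(np.array_equal(self.counts, other.counts))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_female(self) -> int:
        return int(self.counts[:, 0].sum())

    @property
    def n_male(self) -> int:
        return int(self.counts[:, 1].sum())

    @property
    def n_transgenic(self) -> int:
        return int(self.counts[1:, :].sum())

    def by_genotype(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def sample_brood(
    n_eggs: int,
    father: Genotype,
    mother: Genotype,
    rng: np.random.Generator,
    male_bias: float = DEFAULT_MALE_BIAS,
) -> BroodCounts:
    """Randomise the composition of a brood of ``n_eggs`` viable eggs.

    Genotype counts are multinomial with the Mendelian probabilities of the
    pair; each egg's sex is then an independent Bernoulli draw with the
    pair's male probability.
    """
    if n_eggs < 0:
        raise ValueError("n_eggs must be non-negative")
    dist = offspring_genotype_distribution(father, mother, male_bias=male_bias)
    by_genotype = rng.multinomial(n_eggs, dist.probs)
    males = rng.binomial(by_genotype, dist.male_prob)
    counts = np.stack([by_genotype - males, males], axis=1)
    return BroodCounts(counts)
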