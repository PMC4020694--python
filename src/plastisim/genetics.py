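"""Genotypes, phenotype determination, mutation, and inheritance.

A genotype carries up to three classes of additive diploid loci (5 loci,
hence 10 allelic values, per class):

* **nonplastic** alleles ``N`` — environment-independent contributions; their
  sum is the intercept of the reaction norm;
* **plastic** alleles ``P`` — contributions multiplied by the developmental
  cue ``E``; the sum ``sum(P)`` times the cue slope across demes is the slope
  of the reaction norm;
* **instability** alleles ``D`` — nonnegative values whose sum is the
  standard deviation of a single Gaussian developmental-noise draw.

The phenotype, fixed once at development, is::

    T = sum(N) + E * sum(P) + R,    R ~ Normal(0, sd)

with ``sd = sum(D)`` when instability has its own loci (independent mode) or
``sd = (S/10) * |sum(P)|`` in the pleiotropic variant, where ``S`` is the
pleiotropy strength expressed as the noise sd realized by a genotype at the
optimal reaction norm (``sum(P) = 10``).

All operations work element-wise over a trailing allele axis, so they apply
unchanged to a single :class:`Genotype` (1-D allele arrays) and to whole
populations stored as ``(n, 2 * n_loci)`` matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LocusConfig",
    "Genotype",
    "genotypic_plasticity",
    "genotypic_instability",
    "pleiotropic_sd",
    "develop",
    "mutate",
    "mutate_genotype",
    "segregate",
    "inherit",
]

#: loci per class; 2 alleles each
N_LOCI = 5
N_ALLELES = 2 * N_LOCI


@dataclass(frozen=True)
class LocusConfig:
    """Which locus classes a genotype carries.

    ``pleiotropic=True`` removes the instability class entirely: noise is a
    side effect of plasticity with strength ``pleiotropy_strength`` (the
    noise sd at the optimal reaction norm, explored over 0-4).
    """

    has_plastic: bool = True
    has_instability: bool = True
    pleiotropic: bool = False
    pleiotropy_strength: float = 0.0
    n_loci: int = N_LOCI

    def __post_init__(self) -> None:
        if self.pleiotropic:
            if self.has_instability:
                raise ValueError(
                    "pleiotropic mode has no instability loci; "
                    "set has_instability=False"
                )
            if not self.has_plastic:
                raise ValueError("pleiotropic mode requires plastic loci")
            if self.pleiotropy_strength < 0:
                raise ValueError("pleiotropy_strength must be >= 0")


@dataclass
class Genotype:
    """Allelic values of one individual; arrays of length ``2 * n_loci``.

    ``plastic`` / ``instability`` are ``None`` when the class is absent
    (instability is always absent in the pleiotropic variant).
    """

    nonplastic: np.ndarray
    plastic: np.ndarray | None = None
    instability: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nonplastic = np.asarray(self.nonplastic, dtype=float)
        if self.plastic is not None:
            self.plastic = np.asarray(self.plastic, dtype=float)
        if self.instability is not None:
            self.instability = np.asarray(self.instability, dtype=float)
            if np.any(self.instability < 0):
                raise ValueError("instability alleles must be >= 0")


def genotypic_plasticity(g: Genotype | np.ndarray) -> float | np.ndarray:
    """Sum of plastic allelic values, ``sum(P)`` (0 if the class is absent).

    Multiplied by the cue slope across demes this is the slope of the
    genotype's reaction norm; a value of 10 is the optimal slope under the
    default gradient.
    """
    if isinstance(g, Genotype):
        if g.plastic is None:
            return 0.0
        return float(np.sum(g.plastic))
    return np.asarray(g, dtype=float).sum(axis=-1)


def genotypic_instability(g: Genotype | np.ndarray) -> float | np.ndarray:
    """Sum of instability allelic values, ``sum(D)`` — the developmental
    noise sd of the genotype in independent-loci mode.

    Raises ``ValueError`` on a genotype without instability loci (the
    pleiotropic variant), where this quantity does not exist.
    """
    if isinstance(g, Genotype):
        if g.instability is None:
            raise ValueError(
                "genotype has no instability loci (pleiotropic mode?)"
            )
        return float(np.sum(g.instability))
    return np.asarray(g, dtype=float).sum(axis=-1)


def pleiotropic_sd(
    g: Genotype | np.ndarray | float, pleiotropy_strength: float
) -> float | np.ndarray:
    """Developmental-noise sd in the pleiotropic variant.

    ``sd = (strength / 10) * |sum(P)|`` so that a genotype at the optimal
    reaction norm (``sum(P) = 10``) realizes a noise sd equal to the quoted
    strength.  Symmetric in the sign of ``sum(P)``: equal plasticity of
    opposite slope yields identical instability.

    ``g`` may be a Genotype, a plastic-allele array, or ``sum(P)`` directly.
    """
    if pleiotropy_strength < 0:
        raise ValueError("pleiotropy_strength must be >= 0")
    if isinstance(g, Genotype):
        sum_p = genotypic_plasticity(g)
    elif np.ndim(g) == 0:
        sum_p = float(g)
    else:
        sum_p = np.asarray(g, dtype=float).sum(axis=-1)
    return (pleiotropy_strength / 10.0) * np.abs(sum_p)


def develop(
    g: Genotype,
    cue: float,
    rng: np.random.Generator,
    *,
    pleiotropy_strength: float | None = None,
) -> float:
    """Realize the phenotype of one genotype developing under ``cue``.

    ``T = sum(N) + cue * sum(P) + R`` with a single Gaussian noise draw whose
    sd is ``sum(D)`` (independent mode) or the pleiotropic sd when
    ``pleiotropy_strength`` is given.  A zero sd yields ``R = 0`` exactly.
    The phenotype is fixed for the individual's lifetime.
    """
    sum_n = float(np.sum(g.nonplastic))
    sum_p = genotypic_plasticity(g)
    if pleiotropy_strength is not None:
        sd = pleiotropic_sd(sum_p, pleiotropy_strength)
    elif g.instability is not None:
        sd = genotypic_instability(g)
    else:
        sd = 0.0
    noise = float(rng.standard_normal()) * sd if sd > 0 else 0.0
    return sum_n + cue * sum_p + noise


def mutate(
    alleles: np.ndarray,
    rate: float,
    sd: float,
    rng: np.random.Generator,
    *,
    nonnegative: bool = False,
) -> np.ndarray:
    """Return a mutated copy of an allele array (any shape).

    Each allele independently mutates with probability ``rate``; a mutation
    adds a ``Normal(0, sd)`` deviate (infinite-alleles model).  With
    ``nonnegative=True`` (instability alleles) values are clamped at zero
    from below after mutation.
    """
    alleles = np.asarray(alleles, dtype=float)
    if rate < 0 or rate > 1:
        raise ValueError("mutation rate must lie in [0, 1]")
    if rate == 0:
        return alleles.copy()
    hit = rng.random(alleles.shape) < rate
    out = alleles + hit * rng.normal(0.0, sd, size=alleles.shape)
    if nonnegative:
        np.maximum(out, 0.0, out=out)
    return out


def mutate_genotype(
    g: Genotype, rate: float, sd: float, rng: np.random.Generator
) -> Genotype:
    """Apply :func:`mutate` to every locus class of one genotype."""
    return Genotype(
        nonplastic=mutate(g.nonplastic, rate, sd, rng),
        plastic=None
        if g.plastic is None
        else mutate(g.plastic, rate, sd, rng),
        instability=None
        if g.instability is None
        else mutate(g.instability, rate, sd, rng, nonnegative=True),
    )


def segregate(
    alleles: np.ndarray, parents: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one gamete per requested parent from an allele matrix.

    ``alleles`` has shape ``(n_adults, 2 * L)`` with columns ``(2l, 2l+1)``
    holding the two homologous copies at locus ``l``; ``parents`` indexes
    rows (with repetition allowed).  At every locus one of the parent's two
    copies is chosen uniformly and independently — free recombination across
    unlinked loci.  Returns gametes of shape ``(len(parents), L)``.
    """
    alleles = np.asarray(alleles, dtype=float)
    n_loci = alleles.shape[-1] // 2
    paired = alleles.reshape(alleles.shape[0], n_loci, 2)
    choice = rng.integers(0, 2, size=(len(parents), n_loci))
    return paired[parents[:, None], np.arange(n_loci)[None, :], choice]


def _cross(
    mother_alleles: np.ndarray,
    father_alleles: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Single-pair Mendelian cross of two ``(2L,)`` allele arrays."""
    idx = np.array([0])
    gm = segregate(mother_alleles[None, :], idx, rng)[0]
    gf = segregate(father_alleles[None, :], idx, rng)[0]
    out = np.empty(mother_alleles.shape, dtype=float)
    out[0::2] = gm
    out[1::2] = gf
    return out


def inherit(
    mother: Genotype, father: Genotype, rng: np.random.Generator
) -> Genotype:
    """Mendelian offspring genotype: at every diploid locus the offspring
    receives one allele drawn uniformly from the mother's two copies and one
    from the father's, independently across loci (free recombination).

    Parents must share the same locus structure.  Mutation is applied
    separately (see :func:`mutate_genotype`).
    """
    if (mother.plastic is None) != (father.plastic is None) or (
        mother.instability is None
    ) != (father.instability is None):
        raise ValueError("parents must have the same locus structure")
    return Genotype(
        nonplastic=_cross(mother.nonplastic, father.nonplastic, rng),
        plastic=None
        if mother.plastic is None
        else _cross(mother.plastic, father.plastic, rng),
        instability=None
        if mother.instability is None
        else _cross(mother.instability, father.instability, rng),
    )
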