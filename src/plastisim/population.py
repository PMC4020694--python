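"""Struct-of-arrays container for a whole population.

Individuals are rows of per-class allele matrices plus phenotype and deme
vectors; this keeps the generation loop fully vectorized.  A single
individual can be extracted as a :class:`~plastisim.genetics.Genotype` view
for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import Genotype

__all__ = ["Population"]


@dataclass
class Population:
    """All individuals alive at one stage of the life cycle.

    ``nonplastic``/``plastic``/``instability`` are ``(n, 2 * n_loci)``
    allele matrices (``None`` when the class is absent); ``phenotype`` is
    NaN before development and fixed afterwards; ``deme`` and ``natal_deme``
    are 0-based deme indices.  Phenotypes are never recomputed after
    dispersal — the cue of the natal deme is the one that counts.
    """

    nonplastic: np.ndarray
    plastic: np.ndarray | None
    instability: np.ndarray | None
    phenotype: np.ndarray
    deme: np.ndarray
    natal_deme: np.ndarray

    @property
    def size(self) -> int:
        return self.nonplastic.shape[0]

    def __len__(self) -> int:
        return self.size

    def subset(self, index: np.ndarray) -> "Population":
        """Rows selected by a boolean mask or integer index array."""
        return Population(
            nonplastic=self.nonplastic[index],
            plastic=None if self.plastic is None else self.plastic[index],
            instability=None
            if self.instability is None
            else self.instability[index],
            phenotype=self.phenotype[index],
            deme=self.deme[index],
            natal_deme=self.natal_deme[index],
        )

    def genotype(self, i: int) -> Genotype:
        """Copy of individual ``i``'s genotype."""
        return Genotype(
            nonplastic=self.nonplastic[i].copy(),
            plastic=None if self.plastic is None else self.plastic[i].copy(),
            instability=None
            if self.instability is None
            else self.instability[i].copy(),
        )
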