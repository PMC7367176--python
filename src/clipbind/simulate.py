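"""Synthetic CLIP-like fixtures: planted-motif positives, matched random
negatives, and a toy genome with gene and peak annotations.

The generator emulates the shape of a CLIP training set — short bound
sequences carrying a degenerate motif, and unbound sequences of matched
length and base composition — without any of the protocol biases of real
CLIP data (cross-link-induced truncations, U-enrichment, coverage
non-uniformity).  Positives carry exactly one motif instance, sampled
column-wise from the planted PFM at a uniformly random offset, overwriting
the background bases so all sequences keep the same length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from clipbind.seq_io import VOCABULARY, GenomicInterval, NamedSequence

_DNA = ("A", "C", "G", "T")


def point_mass_pfm(consensus: str) -> np.ndarray:
    """A 4 x m PFM putting probability 1 on each consensus base."""
    pfm = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus):
        pfm[VOCABULARY.index(base), j] = 1.0
    return pfm


@dataclass
class PlantedMotifSpec:
    """Study conditions for a synthetic planted-motif dataset."""

    pfm: np.ndarray
    seq_length: int = 40
    n_pos: int = 1000
    n_neg: int = 1000
    occurrence_rate: float = 1.0
    background_composition: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4 or np.any(
            np.abs(self.pfm.sum(axis=0) - 1.0) > 1e-9
        ):
            raise ValueError("pfm must be 4 x m with columns summing to 1")
        if not (0.0 < self.occurrence_rate <= 1.0):
            raise ValueError("occurrence_rate must be in (0, 1]")
        if self.pfm.shape[1] > self.seq_length:
            raise ValueError("motif longer than seq_length")

    @property
    def motif_length(self) -> int:
        return self.pfm.shape[1]


def default_spec(seed: int = 0) -> PlantedMotifSpec:
    """The default fixture: a 7-mer point-mass UG-repeat motif planted in
    every positive, 1000 + 1000 sequences of length 40, uniform background."""
    return PlantedMotifSpec(pfm=point_mass_pfm("UGUGUGU"), seed=seed)


def _random_sequence(
    rng: np.random.Generator, length: int, composition: Sequence[float]
) -> list[str]:
    idx = rng.choice(4, size=length, p=np.asarray(composition, dtype=float))
    return [VOCABULARY[i] for i in idx]


def generate_dataset(
    spec: PlantedMotifSpec,
) -> tuple[list[NamedSequence], list[NamedSequence], list[dict]]:
    """Generate (positives, negatives, truth).

    Positives (label 1) carry one motif instance at a uniformly random
    offset with probability ``occurrence_rate``; negatives (label 0) are
    composition-matched random sequences.  The truth table records, per
    positive, the planted offset (or None) and the planted motif instance.
    Fully deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.motif_length
    positives, truth = [], []
    for i in range(spec.n_pos):
        bases = _random_sequence(rng, spec.seq_length, spec.background_composition)
        offset = None
        instance = None
        if rng.random() < spec.occurrence_rate:
            offset = int(rng.integers(0, spec.seq_length - m + 1))
            cols = [
                VOCABULARY[rng.choice(4, p=spec.pfm[:, j])] for j in range(m)
            ]
            bases[offset : offset + m] = cols
            instance = "".join(cols)
        positives.append(
            NamedSequence(id=f"pos_{i}", residues="".join(bases), label=1)
        )
        truth.append({"id": f"pos_{i}", "offset": offset, "motif": instance})
    negatives = [
        NamedSequence(
            id=f"neg_{i}",
            residues="".join(
                _random_sequence(rng, spec.seq_length, spec.background_composition)
            ),
            label=0,
        )
        for i in range(spec.n_neg)
    ]
    return positives, negatives, truth


def generate_toy_genome(
    n_genes: int,
    gene_length: int,
    peaks_per_gene: int,
    peak_width: int,
    seed: int,
    intergenic: int = 50,
) -> tuple[dict[str, str], list[GenomicInterval], list[GenomicInterval]]:
    """A single-chromosome toy genome with tiled genes and planted peaks.

    Genes are laid head-to-tail on ``chr1`` separated by ``intergenic``
    bases; within each gene, ``peaks_per_gene`` non-overlapping peaks of
    ``peak_width`` are placed uniformly at random.  Raises when the
    requested peaks cannot fit.
    """
    if peaks_per_gene * peak_width > gene_length:
        raise ValueError(
            f"{peaks_per_gene} peaks of width {peak_width} cannot fit in a "
            f"gene of length {gene_length}"
        )
    rng = np.random.default_rng(seed)
    chrom_len = n_genes * (gene_length + intergenic) + intergenic
    sequence = "".join(_DNA[i] for i in rng.integers(0, 4, size=chrom_len))
    genes, peaks = [], []
    for g in range(n_genes):
        g_start = intergenic + g * (gene_length + intergenic)
        gene = GenomicInterval(
            "chr1", g_start, g_start + gene_length, strand="+", name=f"gene_{g}"
        )
        genes.append(gene)
        placed: list[int] = []
        for p in range(peaks_per_gene):
            for _ in range(10000):
                start = int(rng.integers(gene.start, gene.end - peak_width + 1))
                if all(
                    start + peak_width <= q or q + peak_width <= start
                    for q in placed
                ):
                    placed.append(start)
                    peaks.append(
                        GenomicInterval(
                            "chr1", start, start + peak_width,
                            strand="+", name=f"peak_{g}_{p}",
                        )
                    )
                    break
            else:
                raise ValueError("could not place peaks without overlap")
    return {"chr1": sequence}, genes, peaks
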