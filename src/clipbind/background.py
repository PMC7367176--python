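"""Class-0 (unbound) sequence construction.

The default background strategy places, for every positive peak, one
random interval of identical width inside the peak's host gene such that
no background interval overlaps any positive peak or any other background
interval.  The alternative strategy scrambles the positive sequences
(mononucleotide permutation, composition preserved exactly).  Peaks can be
expanded by a fixed flank and/or recentred to a fixed width beforehand.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from clipbind.seq_io import GenomicInterval, NamedSequence

logger = logging.getLogger(__name__)


@dataclass
class BackgroundPlan:
    """Matched (peak, background) interval pairs plus skipped peaks.

    Invariants (audited by the test suite): each background has its peak's
    width, lies within the peak's host gene, and overlaps neither any
    positive peak nor any other background.
    """

    pairs: list[tuple[GenomicInterval, GenomicInterval]]
    seed: int
    skipped: list[GenomicInterval]

    @property
    def backgrounds(self) -> list[GenomicInterval]:
        return [bg for _, bg in self.pairs]


def adjust_peaks(
    peaks: Sequence[GenomicInterval],
    expand_by: int = 0,
    fixed_width: Optional[int] = None,
) -> list[GenomicInterval]:
    """Expand peaks on each side and/or recentre them to a fixed width.

    Expansion is applied first, then recentring on the (left-biased)
    midpoint.  Starts that would become negative are clipped at 0 with a
    warning.
    """
    if expand_by < 0:
        raise ValueError("expand_by must be >= 0")
    out = []
    for iv in peaks:
        start, end = iv.start - expand_by, iv.end + expand_by
        if fixed_width is not None:
            if fixed_width <= 0:
                raise ValueError("fixed_width must be positive")
            mid = (start + end) // 2
            start = mid - fixed_width // 2
            end = start + fixed_width
        if start < 0:
            warnings.warn(
                f"peak {iv.chrom}:{iv.start}-{iv.end} clipped at chromosome start"
            )
            start = 0
        out.append(replace(iv, start=start, end=end))
    return out


def _assign_host_gene(
    peak: GenomicInterval, genes: Sequence[GenomicInterval]
) -> Optional[GenomicInterval]:
    """Gene with the largest overlap; ties go to the first in annotation
    order.  None if no gene overlaps."""
    best, best_ov = None, 0
    for gene in genes:
        ov = peak.overlap_width(gene)
        if ov > best_ov:
            best, best_ov = gene, ov
    return best


def sample_genomic_background(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    seed: int,
    max_tries: int = 1000,
) -> BackgroundPlan:
    """Rejection-sample one same-gene background interval per peak.

    Peaks are processed in input order (feasibility is order-dependent);
    a peak with no legal placement after ``max_tries`` draws is skipped
    with a warning, never silently dropped.  Placement ignores strand; the
    background inherits its peak's strand so sequence extraction matches.
    """
    rng = np.random.default_rng(seed)
    placed: list[GenomicInterval] = []
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    skipped: list[GenomicInterval] = []
    peaks = list(peaks)
    for peak in peaks:
        gene = _assign_host_gene(peak, genes)
        width = peak.width
        if gene is None or gene.width < width:
            warnings.warn(
                f"peak {peak.chrom}:{peak.start}-{peak.end}: no host gene "
                "can accommodate a background of its width; skipped"
            )
            skipped.append(peak)
            continue
        lo, hi = gene.start, gene.end - width  # inclusive start range
        placement = None
        for _ in range(max_tries):
            start = int(rng.integers(lo, hi + 1))
            cand = GenomicInterval(
                peak.chrom, start, start + width, strand=peak.strand,
                name=f"bg_{peak.name or peak.start}",
            )
            if any(cand.overlaps(p) for p in peaks):
                continue
            if any(cand.overlaps(b) for b in placed):
                continue
            placement = cand
            break
        if placement is None:
            warnings.warn(
                f"peak {peak.chrom}:{peak.start}-{peak.end}: no non-"
                f"overlapping placement found in {max_tries} tries; skipped"
            )
            skipped.append(peak)
            continue
        placed.append(placement)
        pairs.append((peak, placement))
    return BackgroundPlan(pairs=pairs, seed=seed, skipped=skipped)


def scramble_sequences(
    seqs: Sequence[NamedSequence], seed: int, method: str = "mono"
) -> list[NamedSequence]:
    """Per-sequence shuffle preserving composition.

    ``method="mono"`` (default) permutes residues uniformly, preserving the
    mononucleotide composition exactly.  ``method="dinucleotide"`` preserves
    the dinucleotide composition as well (Eulerian-walk shuffle); it is off
    by default.  Deterministic given ``seed``.
    """
    if not seqs:
        raise ValueError("no sequences to scramble")
    if method not in ("mono", "dinucleotide"):
        raise ValueError(f"unknown scramble method {method!r}")
    rng = np.random.default_rng(seed)
    out = []
    for s in seqs:
        if method == "mono":
            perm = rng.permutation(len(s.residues))
            shuffled = "".join(s.residues[i] for i in perm)
        else:
            shuffled = _dinucleotide_shuffle(s.residues, rng)
        out.append(NamedSequence(id=f"{s.id}_scrambled", residues=shuffled, label=0))
    return out


def _dinucleotide_shuffle(
    residues: str, rng: np.random.Generator, max_tries: int = 200
) -> str:
    """Shuffle preserving dinucleotide counts.

    The sequence is viewed as an Eulerian walk on the base-transition
    multigraph; each vertex's outgoing edge list is shuffled and the walk
    re-traced from the original first base.  Draws that strand part of the
    graph are rejected and retried; the input order is the fall-back when
    no complete walk is found (degenerate very short inputs).
    """
    if len(residues) < 3:
        return residues
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for a, b in zip(residues, residues[1:]):
            edges.setdefault(a, []).append(b)
        for a in edges:
            order = rng.permutation(len(edges[a]))
            edges[a] = [edges[a][i] for i in order]
        walk = [residues[0]]
        node = residues[0]
        ok = True
        for _ in range(len(residues) - 1):
            if not edges.get(node):
                ok = False
                break
            node = edges[node].pop()
            walk.append(node)
        if ok:
            return "".join(walk)
    return residues
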