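"""Pseudo position frequency matrices from trained models.

For each convolution filter, high-scoring sequences contribute the k-mers
under filter placements with positive convolution score, weighted by the
*squared* raw convolution score of the placement.  A placement only
contributes when every base it covers has a positive binding-profile value
(i.e. is associated with the bound class); placements touching padding or
profile-nonpositive bases are zeroed out.  The resulting matrices are
"pseudo" PFMs: weighted counts rather than raw occurrence counts.  PFMs
are ranked by mean per-column information content (uniform background,
bits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from clipbind.encoding import encode_batch
from clipbind.network import (
    ModelBundle,
    conv_scan,
    forward_encoded,
    predict_scores,
)
from clipbind.seq_io import VOCABULARY, NamedSequence

logger = logging.getLogger(__name__)


@dataclass
class PseudoPFM:
    """Weighted 4 x m count matrix for one filter, rows in (A, C, G, U)."""

    filter_size: int
    counts: np.ndarray          # (4, m) non-negative weights
    n_contributing: int         # number of contributing placements

    @property
    def empty(self) -> bool:
        return self.n_contributing == 0

    @property
    def frequencies(self) -> np.ndarray:
        """Column-normalized counts; all-zero columns stay zero."""
        sums = self.counts.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(sums > 0, self.counts / np.where(sums > 0, sums, 1), 0.0)
        return freq

    @property
    def mean_ic(self) -> float:
        if self.empty:
            return 0.0
        per_col, mean = information_content(self.frequencies)
        return mean


def information_content(frequencies: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-column information content in bits plus the mean.

    IC_col = 2 + sum_b f_b log2 f_b with 0*log(0) = 0, i.e. relative to a
    uniform background over the 4 bases; 0 <= IC <= 2.
    """
    freq = np.asarray(frequencies, dtype=float)
    if freq.ndim != 2 or freq.shape[0] != 4:
        raise ValueError("frequencies must be a 4 x m matrix")
    col_sums = freq.sum(axis=0)
    if np.any(np.abs(col_sums - 1.0) > 1e-9):
        raise ValueError("every frequency column must sum to 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(np.where(freq > 0, freq, 1)), 0.0)
    per_col = 2.0 + plogp.sum(axis=0)
    return per_col, float(per_col.mean())


def _accumulate_pfm(
    onehot: np.ndarray,
    profile_positive: np.ndarray,
    scores: np.ndarray,
    m: int,
    left_pad: int,
    length: int,
) -> tuple[np.ndarray, int]:
    """Accumulate one sequence's contributions for one filter.

    ``profile_positive`` marks padded positions whose profile value is > 0;
    a placement contributes its covered columns weighted by score**2 only
    when its score is positive and it lies entirely inside the real region
    with every covered base profile-positive.
    """
    counts = np.zeros((4, m))
    n = 0
    for p in range(left_pad, left_pad + length - m + 1):
        s = scores[p]
        if s <= 0:
            continue
        if not profile_positive[p : p + m].all():
            continue
        counts += (s * s) * onehot[p : p + m, :].T
        n += 1
    return counts, n


def extract_pseudo_pfms(
    bundle: ModelBundle,
    seqs: Sequence[NamedSequence],
    top_n: Optional[int] = 1000,
    score_threshold: Optional[float] = None,
    weighting: str = "placement",
) -> list[PseudoPFM]:
    """Build one pseudo-PFM per filter from high-scoring sequences.

    Selection: the ``top_n`` sequences by classification score (descending,
    ties by input order), or — when ``score_threshold`` is given instead —
    every sequence scoring above the threshold.

    Weighting: ``"placement"`` (default) weights each contributing k-mer by
    the squared raw convolution score of its own placement; ``"seq_max"``
    weights every contribution of a sequence/filter pair by that pair's
    squared maximum placement score (the alternative reading).
    """
    if not seqs:
        raise ValueError("no sequences supplied")
    if weighting not in ("placement", "seq_max"):
        raise ValueError(f"unknown weighting {weighting!r}")
    scores = predict_scores(seqs, bundle)
    if score_threshold is not None:
        chosen = [i for i, sc in enumerate(scores) if sc > score_threshold]
    else:
        n = min(top_n, len(seqs))
        order = np.argsort(-scores, kind="stable")
        chosen = list(order[:n])

    sizes = bundle.params.filter_sizes
    counts = [np.zeros((4, m)) for m in sizes]
    n_contrib = [0] * len(sizes)
    encoded = encode_batch(
        [seqs[i] for i in chosen], sizes, max_length=bundle.max_length
    )
    for enc in encoded:
        profile = forward_encoded(enc, bundle.params)
        positive = np.zeros(enc.padded_length, dtype=bool)
        real = np.where(enc.mask > 0)[0]
        positive[real] = profile.values > 0
        conv = conv_scan(enc, bundle.params.conv)
        for k, m in enumerate(sizes):
            sc = conv[k]
            if weighting == "seq_max":
                sc = np.where(sc > 0, sc.max(), 0.0)
            c, n = _accumulate_pfm(
                enc.onehot, positive, sc, m, enc.left_pad, enc.length
            )
            counts[k] += c
            n_contrib[k] += n
    pfms = []
    for k, m in enumerate(sizes):
        pfm = PseudoPFM(filter_size=m, counts=counts[k], n_contributing=n_contrib[k])
        if pfm.empty:
            logger.warning("filter of size %d has no contributing placements", m)
        pfms.append(pfm)
    return pfms


def export_pfms(
    pfms: Sequence[PseudoPFM],
    meme_path: str,
    counts_path: Optional[str] = None,
    name_prefix: str = "filter",
) -> None:
    """Write PFMs as MEME minimal motif format plus a counts TSV.

    Motifs are ordered by descending mean information content; empty PFMs
    are omitted with a logged notice.
    """
    usable = [p for p in pfms if not p.empty]
    for p in pfms:
        if p.empty:
            logger.info("omitting empty PFM (filter size %d)", p.filter_size)
    if not usable:
        raise ValueError("no non-empty PFMs to export")
    ranked = sorted(usable, key=lambda p: -p.mean_ic)
    with open(meme_path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for p in ranked:
            fh.write(f"MOTIF {name_prefix}_{p.filter_size}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.filter_size} "
                f"nsites= {p.n_contributing} E= 0\n"
            )
            for col in p.frequencies.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")
    if counts_path is not None:
        with open(counts_path, "w") as fh:
            fh.write("motif\tposition\t" + "\t".join(VOCABULARY) + "\n")
            for p in ranked:
                for j in range(p.filter_size):
                    row = "\t".join(repr(float(v)) for v in p.counts[:, j])
                    fh.write(f"{name_prefix}_{p.filter_size}\t{j + 1}\t{row}\n")


def read_pfm_counts(counts_path: str) -> dict[str, np.ndarray]:
    """Read back a counts TSV written by :func:`export_pfms`."""
    out: dict[str, list[list[float]]] = {}
    with open(counts_path) as fh:
        header = fh.readline()
        if not header.startswith("motif\t"):
            raise ValueError("not a PFM counts table")
        for line in fh:
            name, _pos, *vals = line.rstrip("\n").split("\t")
            out.setdefault(name, []).append([float(v) for v in vals])
    return {name: np.array(cols).T for name, cols in out.items()}


def best_offset_pearson(pfm: np.ndarray, reference: np.ndarray) -> float:
    """Best Pearson correlation between two 4 x m frequency matrices over
    all alignments (offsets), computed on the flattened overlap columns.

    Used to compare a learned PFM with a planted ground-truth PFM; the
    overlap must span at least two columns.
    """
    m1, m2 = pfm.shape[1], reference.shape[1]
    best = -1.0
    for offset in range(-(m1 - 2), m2 - 1):
        lo1 = max(0, -offset)
        lo2 = max(0, offset)
        width = min(m1 - lo1, m2 - lo2)
        if width < 2:
            continue
        a = pfm[:, lo1 : lo1 + width].ravel()
        b = reference[:, lo2 : lo2 + width].ravel()
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        best = max(best, r)
    return best
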