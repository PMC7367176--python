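"""One-hot encoding with zero padding and validity masks.

Every sequence in a batch is padded to a common length: the longest real
sequence length (or a configured maximum) plus a symmetric margin of
``m_max - 1`` zero columns on each flank, where ``m_max`` is the largest
convolution filter size.  The margin lets the largest filter run in "full
convolution" mode; because the network has no bias parameters, all-zero
columns can never score above zero on their own.

Conventions (fixed here, relied on downstream):

* vocabulary order is ``(A, C, G, U)``;
* intra-batch length equalization pads on the RIGHT of the real region;
* ambiguity codes (``N`` etc.) become all-zero columns but keep mask 1 —
  they are real bases with no information, distinct from padding (mask 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from clipbind.seq_io import VOCABULARY, NamedSequence

_BASE_INDEX = {b: i for i, b in enumerate(VOCABULARY)}


@dataclass
class EncodedSequence:
    """Zero-padded one-hot matrix with a validity mask.

    ``onehot`` has shape (padded_length, 4); ``mask`` is 1 at real bases and
    0 at padding; ``left_pad`` is the offset of the first real base.
    """

    onehot: np.ndarray
    mask: np.ndarray
    left_pad: int
    source: NamedSequence

    @property
    def padded_length(self) -> int:
        return self.onehot.shape[0]

    @property
    def length(self) -> int:
        return len(self.source)

    def linearized(self) -> np.ndarray:
        """Row-major flattening (position-major, base-minor): the layout on
        which a stride of ``|v|`` walks whole one-hot bases."""
        return self.onehot.reshape(-1)


def encode_sequence(
    seq: NamedSequence,
    filter_sizes: Sequence[int],
    batch_length: Optional[int] = None,
) -> EncodedSequence:
    """Encode a single sequence (see :func:`encode_batch`)."""
    return encode_batch([seq], filter_sizes, max_length=batch_length)[0]


def encode_batch(
    seqs: Sequence[NamedSequence],
    filter_sizes: Sequence[int],
    max_length: Optional[int] = None,
) -> list[EncodedSequence]:
    """Encode a batch of sequences to a shared padded length.

    Parameters
    ----------
    seqs:
        Normalized sequences (RNA alphabet; ambiguity codes allowed).
    filter_sizes:
        Convolution filter sizes; the largest determines the flank margin.
    max_length:
        Optional configured maximum real length.  Sequences longer than this
        raise; shorter batches are still padded up to it so that encodings
        are comparable across batches (e.g. train vs. predict).
    """
    if not seqs:
        raise ValueError("cannot encode an empty batch")
    if not filter_sizes:
        raise ValueError("filter_sizes must be non-empty")
    m_max = max(filter_sizes)
    longest = max(len(s) for s in seqs)
    if max_length is not None:
        for s in seqs:
            if len(s) > max_length:
                raise ValueError(
                    f"sequence {s.id!r} has length {len(s)} > configured "
                    f"maximum {max_length}"
                )
        longest = max_length
    margin = m_max - 1
    padded_length = longest + 2 * margin
    out = []
    for s in seqs:
        onehot = np.zeros((padded_length, 4), dtype=np.float64)
        mask = np.zeros(padded_length, dtype=np.float64)
        for j, base in enumerate(s.residues):
            pos = margin + j
            mask[pos] = 1.0
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                onehot[pos, idx] = 1.0
            # ambiguity codes: all-zero column, mask stays 1
        out.append(EncodedSequence(onehot=onehot, mask=mask, left_pad=margin, source=s))
    return out


def stack_batch(encoded: Sequence[EncodedSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack encodings into (B, L, 4) one-hot and (B, L) mask arrays."""
    X = np.stack([e.onehot for e in encoded])
    M = np.stack([e.mask for e in encoded])
    return X, M
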