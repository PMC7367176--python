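"""Applied prediction modes built on the forward pass.

* wt/mutant variant scoring (score delta and per-base profile delta);
* sliding-window profiling of sequences longer than the model maximum,
  stitching the central-nucleotide value of each window;
* binding-site calling on a profile (9-nt windows with mean > 0.3,
  overlapping windows merged);
* grouped aggregation of profiles around anchored regions (exon starts
  and ends with intronic flanks) with normal-approximation 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from clipbind.network import ModelBundle, forward
from clipbind.seq_io import NamedSequence


@dataclass
class VariantResult:
    """Scores and profiles of a reference/variant sequence pair.

    ``delta = mut_score - wt_score``; a positive delta means the variant is
    predicted to bind better.  ``profile_delta`` (per-base mut - wt) is
    only defined for length-matched pairs.
    """

    wt_score: float
    mut_score: float
    wt_profile: np.ndarray
    mut_profile: np.ndarray

    @property
    def delta(self) -> float:
        return self.mut_score - self.wt_score

    @property
    def profile_delta(self) -> Optional[np.ndarray]:
        if len(self.wt_profile) != len(self.mut_profile):
            return None
        return self.mut_profile - self.wt_profile


@dataclass
class CalledSite:
    """A merged run of qualifying sliding windows on a query sequence.

    Coordinates are 0-based half-open on the query; ``mean_profile`` is the
    mean over the merged interval.
    """

    start: int
    end: int
    mean_profile: float

    @property
    def width(self) -> int:
        return self.end - self.start


def score_variant(
    bundle: ModelBundle, wt: NamedSequence, mut: NamedSequence
) -> VariantResult:
    """Score a reference/variant pair under a trained model.

    Warns when a substitution sits within the largest filter size of either
    sequence end: edge positions lack full sequence context and their
    profile values are unreliable.
    """
    wt_prof = forward(wt, bundle.params, max_length=bundle.max_length)
    mut_prof = forward(mut, bundle.params, max_length=bundle.max_length)
    if len(wt.residues) == len(mut.residues):
        diffs = [
            j for j, (a, b) in enumerate(zip(wt.residues, mut.residues)) if a != b
        ]
        m_max = bundle.params.conv.max_size
        L = len(wt.residues)
        if any(j < m_max or j >= L - m_max for j in diffs):
            warnings.warn(
                "variant position within one filter width of a sequence "
                "edge; edge profiles lack context and the delta is unreliable"
            )
    return VariantResult(
        wt_score=wt_prof.score,
        mut_score=mut_prof.score,
        wt_profile=wt_prof.values,
        mut_profile=mut_prof.values,
    )


def long_predict(
    bundle: ModelBundle,
    seq: NamedSequence,
    window: Optional[int] = None,
    step: int = 1,
) -> np.ndarray:
    """Full-length binding profile of an arbitrarily long sequence.

    A window of ``window`` nucleotides (default: the model's training
    maximum, forced odd) slides along the sequence with step 1; position p
    takes the central-nucleotide profile value of the window centred on p.
    The first and last half-window positions copy their values from the
    first and last full windows.  Sequences shorter than the window get a
    single direct forward pass.
    """
    if step != 1:
        raise ValueError("only step=1 is supported")
    if window is None:
        window = bundle.max_length
    if window > bundle.max_length:
        raise ValueError(
            f"window {window} exceeds model maximum {bundle.max_length}"
        )
    if window % 2 == 0:
        window -= 1
    L = len(seq.residues)
    if L <= window:
        return forward(seq, bundle.params, max_length=bundle.max_length).values
    half = window // 2
    out = np.empty(L)
    n_windows = L - window + 1
    for w in range(n_windows):
        sub = NamedSequence(
            id=f"{seq.id}|w{w}", residues=seq.residues[w : w + window]
        )
        values = forward(sub, bundle.params, max_length=bundle.max_length).values
        if w == 0:
            out[:half] = values[:half]
        out[w + half] = values[half]
        if w == n_windows - 1:
            out[L - half :] = values[window - half :]
    return out


def call_sites(
    profile: Sequence[float], window: int = 9, threshold: float = 0.3
) -> list[CalledSite]:
    """Find maximal runs of sliding windows whose mean exceeds ``threshold``.

    Every length-``window`` window with mean strictly greater than the
    threshold qualifies; overlapping qualifying windows are merged into
    maximal intervals, and each merged site's mean is recomputed over the
    whole merged interval.
    """
    values = np.asarray(profile, dtype=float)
    if len(values) < window:
        warnings.warn(
            f"profile length {len(values)} is shorter than the window "
            f"({window}); no sites can be called"
        )
        return []
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    starts = np.where(means > threshold)[0]
    sites: list[CalledSite] = []
    if len(starts) == 0:
        return sites
    run_start = prev = starts[0]
    for s in list(starts[1:]) + [None]:
        if s is not None and s < prev + window:  # windows overlap
            prev = s
            continue
        lo, hi = int(run_start), int(prev + window)
        sites.append(
            CalledSite(start=lo, end=hi, mean_profile=float(values[lo:hi].mean()))
        )
        if s is not None:
            run_start = prev = s
    return sites


def aggregate_region_profiles(
    profiles: Sequence[Sequence[float]],
    exons: Sequence[tuple[int, int]],
    exon_flank: int = 25,
    intron_flank: int = 50,
) -> dict[str, dict[str, np.ndarray]]:
    """Aggregate profiles around exon boundaries across many inputs.

    For each profile (covering an exon plus intronic context) and its exon
    coordinates (0-based half-open within the profile), four anchored
    regions are extracted: the last ``intron_flank`` nt of the upstream
    intron, the first and last ``exon_flank`` nt of the exon, and the first
    ``intron_flank`` nt of the downstream intron.  Returns, per region, the
    per-offset mean and the half-width of the normal-approximation 95% CI
    (1.96 * sd / sqrt(n)).  Profiles too short for any region are skipped
    with a warning.
    """
    if len(profiles) != len(exons):
        raise ValueError("profiles and exon coordinates must pair up")
    regions = {
        "intron_upstream": [],
        "exon_start": [],
        "exon_end": [],
        "intron_downstream": [],
    }
    for idx, (prof, (ex_start, ex_end)) in enumerate(zip(profiles, exons)):
        prof = np.asarray(prof, dtype=float)
        ok = (
            ex_start - intron_flank >= 0
            and ex_end + intron_flank <= len(prof)
            and ex_end - ex_start >= exon_flank
        )
        if not ok:
            warnings.warn(f"profile {idx}: requested regions out of range; skipped")
            continue
        regions["intron_upstream"].append(prof[ex_start - intron_flank : ex_start])
        regions["exon_start"].append(prof[ex_start : ex_start + exon_flank])
        regions["exon_end"].append(prof[ex_end - exon_flank : ex_end])
        regions["intron_downstream"].append(prof[ex_end : ex_end + intron_flank])
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, rows in regions.items():
        if not rows:
            raise ValueError("no profile covered the requested regions")
        arr = np.stack(rows)
        n = arr.shape[0]
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1) if n > 1 else np.zeros(arr.shape[1])
        out[name] = {
            "mean": mean,
            "ci_half_width": 1.96 * sd / np.sqrt(n),
            "n": np.full(arr.shape[1], n),
        }
    return out
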