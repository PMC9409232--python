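"""Transmembrane segment screening via Kyte–Doolittle hydropathy.

A trained topology HMM is deliberately not reproduced here; for a binary
"does this ORF product contain a membrane-spanning stretch" screen, a
centered sliding-window mean of the Kyte–Doolittle scale with the standard
transmembrane conventions (window 19, cutoff 1.6) is deterministic,
dependency-free and adequate.  All three constants are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

# Kyte & Doolittle hydropathy scale
KD_SCALE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class TmSegment:
    """A predicted membrane-spanning stretch, 1-based residue coordinates."""

    start: int
    end: int
    peak_score: float

    def __len__(self) -> int:
        return self.end - self.start + 1


def hydropathy_profile(protein: str, window: int = 19) -> np.ndarray:
    """Centered sliding-window mean Kyte–Doolittle score per residue.

    Returns an array of length ``len(protein)``; edge residues without a
    full window hold NaN.  Unknown residues (X, *) score 0.
    """
    n = len(protein)
    profile = np.full(n, np.nan)
    if n < window:
        warnings.warn(f"protein shorter than window ({n} < {window}); empty profile")
        return profile
    values = np.array([KD_SCALE.get(aa, 0.0) for aa in protein])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    half = window // 2
    profile[half : half + len(means)] = means
    return profile


def predict_tm(protein: str, window: int = 19, threshold: float = 1.6,
               min_tm_len: int = 19, merge_gap: int = 5) -> list[TmSegment]:
    """Maximal runs of window scores >= threshold, expanded to window extent.

    Runs whose expanded segments are separated by fewer than ``merge_gap``
    residues are merged; segments shorter than ``min_tm_len`` are dropped.
    """
    profile = hydropathy_profile(protein, window)
    above = np.flatnonzero(np.nan_to_num(profile, nan=-np.inf) >= threshold)
    if above.size == 0:
        return []
    half = window // 2
    runs = []
    run_s = prev = above[0]
    for i in above[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((run_s, prev))
            run_s = prev = i
    runs.append((run_s, prev))

    # expand each run of window centers to the full window extent (0-based)
    segs = [[max(0, a - half), min(len(protein) - 1, b + half)] for a, b in runs]
    merged = [segs[0]]
    for s, e in segs[1:]:
        if s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out = []
    for s, e in merged:
        if e - s + 1 >= min_tm_len:
            peak = float(np.nanmax(profile[s : e + 1]))
            out.append(TmSegment(int(s) + 1, int(e) + 1, peak))
    return out
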