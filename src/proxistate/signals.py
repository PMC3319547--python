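"""Per-fragment epigenetic signal statistics.

A chromatin property (histone mark, methylation, DNAse sensitivity,
expression, CTCF density, ...) is represented as a list of peaks with
heights.  The per-fragment signal strength S is the peak-height-weighted
coverage of the fragment:

    S_f = sum_p h_p * overlap(f, p) / len(f)

Pairwise statistics compare two fragments' signals on a log scale:

    D(i, j) = |ln(1 + S_i) - ln(1 + S_j)|      (difference)
    A(i, j) = (ln(1 + S_i) + ln(1 + S_j)) / 2  (average)

Signals are non-negative, so the +1 pseudocount keeps the logarithm
well-defined; an epsilon-ratio variant ``|ln((S_i+eps)/(S_j+eps))|`` is
available through ``log_mode="epsilon"``.

Chromatin-state annotations are summarized per fragment as a composition
vector v (v_k = fraction of the fragment in state k) and compared with
the generalized Jaccard coefficient  J = sum_k min(v_k, u_k) / sum_k
max(v_k, u_k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeBinning

PEAK_COLUMNS = ["chrom", "start", "end", "height"]


@dataclass
class SignalTrack:
    """Peak list for one chromatin property."""

    property_name: str
    peaks: pd.DataFrame  # columns chrom, start, end, height

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.peaks.columns]
        if missing:
            raise ValueError(f"peak table missing columns {missing}")
        if len(self.peaks) and (self.peaks["height"] < 0).any():
            raise ValueError("peak heights must be nonnegative")

    def __len__(self) -> int:
        return len(self.peaks)


def signal_strength(track: SignalTrack, binning: GenomeBinning) -> np.ndarray:
    """Per-fragment signal strength S (length-F array, 0 where no peaks).

    Peaks spanning a bin boundary contribute to each overlapped fragment in
    proportion to the overlapped length; the divisor is the fragment's true
    length, so chromosome-tail bins are weighted correctly.
    """
    S = np.zeros(binning.n_fragments, dtype=float)
    if not len(track.peaks):
        return S
    lengths = binning.fragment_lengths.astype(float)
    bs = binning.bin_size
    for chrom, sub in track.peaks.groupby("chrom", sort=False):
        if chrom not in binning.chromosome_lengths:
            continue
        first = binning.locate(chrom, 0)
        chrom_len = binning.chromosome_lengths[chrom]
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        heights = sub["height"].to_numpy(dtype=float)
        starts = np.clip(starts, 0, chrom_len)
        ends = np.clip(ends, 0, chrom_len)
        for s, e, h in zip(starts, ends, heights):
            if e <= s:
                continue
            b0, b1 = s // bs, (e - 1) // bs
            for b in range(b0, b1 + 1):
                lo = max(s, b * bs)
                hi = min(e, (b + 1) * bs)
                gi = first + b
                S[gi] += h * (hi - lo) / lengths[gi]
    return S


def _log_transform(S: np.ndarray | float, log_mode: str, epsilon: float) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("signal values must be nonnegative")
    if log_mode == "log1p":
        return np.log1p(S)
    if log_mode == "epsilon":
        return np.log(S + epsilon)
    raise ValueError(f"unknown log_mode {log_mode!r}")


def signal_difference(S_i, S_j, log_mode: str = "log1p",
                      epsilon: float = 1e-3) -> np.ndarray:
    """Order-independent log-scale signal difference D >= 0 (elementwise)."""
    return np.abs(_log_transform(S_i, log_mode, epsilon)
                  - _log_transform(S_j, log_mode, epsilon))


def signal_average(S_i, S_j, log_mode: str = "log1p",
                   epsilon: float = 1e-3) -> np.ndarray:
    """Log-scale signal average A (elementwise, exchange-symmetric)."""
    return 0.5 * (_log_transform(S_i, log_mode, epsilon)
                  + _log_transform(S_j, log_mode, epsilon))


def state_vectors(segments: pd.DataFrame, binning: GenomeBinning,
                  n_states: int) -> np.ndarray:
    """F x K matrix of chromatin-state composition vectors.

    ``segments`` columns: chrom, start, end, state (integer in [0, K)).
    Segments must not overlap within a chromosome; uncovered bases leave
    row sums below 1.
    """
    required = {"chrom", "start", "end", "state"}
    if not required.issubset(segments.columns):
        raise ValueError(f"segment table requires columns {sorted(required)}")
    V = np.zeros((binning.n_fragments, n_states), dtype=float)
    lengths = binning.fragment_lengths.astype(float)
    bs = binning.bin_size
    for chrom, sub in segments.groupby("chrom", sort=False):
        if chrom not in binning.chromosome_lengths:
            continue
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping state segments on {chrom}")
        first = binning.locate(chrom, 0)
        chrom_len = binning.chromosome_lengths[chrom]
        for s, e, k in zip(sub["start"], sub["end"], sub["state"]):
            k = int(k)
            if not 0 <= k < n_states:
                raise ValueError(f"state index {k} outside [0, {n_states})")
            s, e = max(0, int(s)), min(chrom_len, int(e))
            if e <= s:
                continue
            b0, b1 = s // bs, (e - 1) // bs
            for b in range(b0, b1 + 1):
                lo, hi = max(s, b * bs), min(e, (b + 1) * bs)
                gi = first + b
                V[gi, k] += (hi - lo) / lengths[gi]
    return V


def jaccard_similarity(v: np.ndarray, u: np.ndarray) -> float:
    """Generalized Jaccard similarity of two nonnegative vectors.

    Returns NaN (masked) when both vectors are all-zero: two unannotated
    fragments carry no information about similarity.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    if v.shape != u.shape:
        raise ValueError("state vectors differ in length")
    if np.any(v < 0) or np.any(u < 0):
        raise ValueError("state vectors must be nonnegative")
    denom = np.maximum(v, u).sum()
    if denom == 0:
        return float("nan")
    return float(np.minimum(v, u).sum() / denom)


def jaccard_matrix_pairs(V: np.ndarray, idx_i: np.ndarray,
                         idx_j: np.ndarray) -> np.ndarray:
    """Vectorized generalized Jaccard for many (i, j) row pairs of ``V``."""
    A, B = V[idx_i], V[idx_j]
    num = np.minimum(A, B).sum(axis=1)
    den = np.maximum(A, B).sum(axis=1)
    out = np.full(len(num), np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def gene_density(genes: pd.DataFrame, binning: GenomeBinning) -> np.ndarray:
    """Per-fragment gene count; genes are assigned by the start of the
    coding region (half-open bin rule)."""
    counts = np.zeros(binning.n_fragments, dtype=np.int64)
    for chrom, start in zip(genes["chrom"], genes["start"]):
        if chrom not in binning.chromosome_lengths:
            continue
        if not 0 <= start < binning.chromosome_lengths[chrom]:
            continue
        counts[binning.locate(chrom, int(start))] += 1
    return counts


def pair_gene_content(counts: np.ndarray, idx_i, idx_j) -> np.ndarray:
    """Mean gene count of a fragment pair (vectorized)."""
    counts = np.asarray(counts, dtype=float)
    return 0.5 * (counts[idx_i] + counts[idx_j])
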