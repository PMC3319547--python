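"""Hi-C contact normalization and proximity binning.

Raw interchromosomal contact counts O(i, j) are normalized in two stages:

* enrichment  C*(i, j) = O(i, j) / (f_i * f_j * T), where T is the total
  interchromosomal count and f_i the fraction of read pairs containing
  fragment i — observed over expected under independent coverage;
* correlation C(i, j) = Pearson correlation between the masked enrichment
  profiles of fragments i and j (computed over fragments k usable in both
  rows, excluding i and j themselves).

C(i, j) is the "spatial proximity" value used by every downstream analysis.
Only interchromosomal entries are ever usable, which removes the need to
normalize for linear genomic distance.

A sequence-identity QC guards against mapping/template-switching artifacts:
pairs of highly homologous fragments can masquerade as spatially proximal.
The identity level I(i, j) sums homology-hit lengths (merged per fragment)
over the pair and is profiled across proximity intervals; intervals with
inflated identity are flagged and excluded from downstream statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeBinning

logger = logging.getLogger(__name__)

STAGES = ("raw", "enrichment", "correlation", "external")

DEFAULT_N_BINS = 29
DEFAULT_N_KEPT = 18
DEFAULT_IDENTITY_THRESHOLD = 92.0


@dataclass
class ProximityMatrix:
    """Square fragment-by-fragment matrix with a usability mask.

    ``mask`` is True where the entry is usable: interchromosomal, both
    fragments covered, and (for the correlation stage) estimable.
    """

    stage: str
    values: np.ndarray
    mask: np.ndarray
    binning: GenomeBinning

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        F = self.binning.n_fragments
        if self.values.shape != (F, F) or self.mask.shape != (F, F):
            raise ValueError("matrix shape does not match fragment universe")

    @property
    def n_fragments(self) -> int:
        return self.binning.n_fragments

    def masked_values(self) -> np.ndarray:
        out = np.where(self.mask, self.values, np.nan)
        return out

    def pair_series(self) -> pd.DataFrame:
        """Upper-triangle usable entries as a (i, j, value) frame, i < j,
        lexicographic order."""
        iu, ju = np.triu_indices(self.n_fragments, k=1)
        keep = self.mask[iu, ju]
        return pd.DataFrame({
            "i": iu[keep], "j": ju[keep],
            "value": self.values[iu[keep], ju[keep]],
        })


def raw_matrix(counts: np.ndarray, binning: GenomeBinning) -> ProximityMatrix:
    """Wrap a symmetric nonnegative count matrix as the raw stage."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("raw counts must be nonnegative")
    if not np.allclose(counts, counts.T):
        raise ValueError("raw count matrix must be symmetric")
    mask = binning.interchromosomal_mask()
    return ProximityMatrix("raw", counts, mask, binning)


def coverage_fractions(O: ProximityMatrix) -> np.ndarray:
    """Fraction of interchromosomal read pairs containing each fragment.

    f_i = (sum over usable j of O(i, j)) / T with T the total
    interchromosomal pair count; sums to 2 because every pair is counted
    once for each of its two fragments.
    """
    if O.stage != "raw":
        raise ValueError("coverage fractions are defined on raw counts")
    contact = np.where(O.mask, O.values, 0.0)
    row = contact.sum(axis=1)
    T = row.sum() / 2.0
    if T <= 0:
        raise ValueError("no interchromosomal read pairs")
    return row / T


def enrichment_matrix(O: ProximityMatrix) -> ProximityMatrix:
    """Observed-over-expected enrichment C*; entries with zero expected
    count are masked out.  Invariant under uniform scaling of O."""
    f = coverage_fractions(O)
    contact = np.where(O.mask, O.values, 0.0)
    T = contact.sum() / 2.0
    expected = np.outer(f, f) * T
    mask = O.mask & (expected > 0)
    values = np.zeros_like(contact)
    np.divide(contact, expected, out=values, where=mask)
    n_dropped = int(O.mask.sum() - mask.sum())
    if n_dropped:
        logger.info("enrichment: masked %d entries with zero expected count",
                    n_dropped)
    return ProximityMatrix("enrichment", values, mask, O.binning)


def correlation_matrix(Cstar: ProximityMatrix,
                       min_common: int = 3) -> ProximityMatrix:
    """Pearson correlation of enrichment profiles for every usable pair.

    For the (i, j) entry the correlation runs over fragments k usable in
    both row i and row j with k not in {i, j}.  Pairs with fewer than
    ``min_common`` shared entries, or a zero-variance profile, are masked.
    """
    if Cstar.stage not in ("enrichment", "external"):
        raise ValueError("correlation is computed from the enrichment stage")
    F = Cstar.n_fragments
    V = Cstar.values
    M = Cstar.mask
    out = np.zeros((F, F))
    ok = np.zeros((F, F), dtype=bool)
    n_masked = 0
    for i in range(F):
        for j in range(i + 1, F):
            if not M[i, j]:
                continue
            common = M[i] & M[j]
            common[i] = common[j] = False
            n = int(common.sum())
            if n < min_common:
                n_masked += 1
                continue
            x = V[i, common]
            y = V[j, common]
            xc = x - x.mean()
            yc = y - y.mean()
            den = np.sqrt((xc @ xc) * (yc @ yc))
            if den == 0:
                n_masked += 1
                continue
            r = float(np.clip((xc @ yc) / den, -1.0, 1.0))
            out[i, j] = out[j, i] = r
            ok[i, j] = ok[j, i] = True
    if n_masked:
        logger.info("correlation: %d pairs masked (few common entries or "
                    "zero variance)", n_masked)
    return ProximityMatrix("correlation", out, ok, Cstar.binning)


def external_matrix(values: np.ndarray, binning: GenomeBinning,
                    mask: np.ndarray | None = None) -> ProximityMatrix:
    """Wrap a proximity matrix normalized elsewhere; skips normalization."""
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = binning.interchromosomal_mask() & np.isfinite(values)
    return ProximityMatrix("external", values, mask, binning)


# ---------------------------------------------------------------------------
# sequence-identity QC


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge_intervals(intervals))


def identity_level(i: int, j: int, hits: pd.DataFrame,
                   binning: GenomeBinning,
                   identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                   denominator: str = "pair_sum",
                   merge_hits: bool = True) -> float:
    """Sequence identity level I(i, j) in [0, 1] for one fragment pair.

    ``hits`` columns: frag_i, frag_j, start_i, end_i, start_j, end_j,
    percent_identity (hit coordinates in bp on each fragment's chromosome).
    Hits below ``identity_threshold`` are ignored; hit intervals on each
    fragment are merged (union) before summing unless ``merge_hits`` is
    False.  ``denominator``: "pair_sum" divides by len_i + len_j (keeps
    I <= 1); "per_fragment" divides each side by its own length and
    averages.
    """
    fi, fj = binning.fragments[i], binning.fragments[j]
    sel = hits[(hits["percent_identity"] >= identity_threshold)
               & (((hits["frag_i"] == i) & (hits["frag_j"] == j))
                  | ((hits["frag_i"] == j) & (hits["frag_j"] == i)))]
    if not len(sel):
        return 0.0
    ints_i: list[tuple[int, int]] = []
    ints_j: list[tuple[int, int]] = []
    for row in sel.itertuples():
        if row.frag_i == i:
            a = (int(row.start_i), int(row.end_i))
            b = (int(row.start_j), int(row.end_j))
        else:
            a = (int(row.start_j), int(row.end_j))
            b = (int(row.start_i), int(row.end_i))
        ca = (max(a[0], fi.start), min(a[1], fi.end))
        cb = (max(b[0], fj.start), min(b[1], fj.end))
        if ca != a or cb != b:
            warnings.warn("homology hit clipped to fragment bounds")
        if ca[1] > ca[0]:
            ints_i.append(ca)
        if cb[1] > cb[0]:
            ints_j.append(cb)
    if merge_hits:
        len_i, len_j = _merged_length(ints_i), _merged_length(ints_j)
    else:
        len_i = sum(e - s for s, e in ints_i)
        len_j = sum(e - s for s, e in ints_j)
    if denominator == "pair_sum":
        return (len_i + len_j) / (fi.length + fj.length)
    if denominator == "per_fragment":
        return 0.5 * (len_i / fi.length + len_j / fj.length)
    raise ValueError(f"unknown denominator mode {denominator!r}")


# ---------------------------------------------------------------------------
# proximity interval binning


@dataclass
class ProximityBinning:
    """Equal-width partition of proximity values into intervals, with a
    contiguous kept range (extreme intervals are sparsely populated and,
    at the high end, identity-artifact-prone)."""

    edges: np.ndarray                 # length n_bins + 1, strictly increasing
    kept_range: tuple[int, int]       # inclusive (first, last) kept bin

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def kept_bins(self) -> np.ndarray:
        return np.arange(self.kept_range[0], self.kept_range[1] + 1)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index per value; the last bin is closed on the right.
        Values outside [edges[0], edges[-1]] get -1."""
        values = np.asarray(values, dtype=float)
        idx = np.searchsorted(self.edges, values, side="right") - 1
        idx = np.where(values == self.edges[-1], self.n_bins - 1, idx)
        idx = np.where((values < self.edges[0]) | (values > self.edges[-1]),
                       -1, idx)
        return idx.astype(np.int64)

    def is_kept(self, bin_idx: np.ndarray) -> np.ndarray:
        lo, hi = self.kept_range
        return (bin_idx >= lo) & (bin_idx <= hi)


def make_proximity_bins(values: np.ndarray, n_bins: int = DEFAULT_N_BINS,
                        n_kept: int | None = None,
                        kept_range: tuple[int, int] | None = None) -> ProximityBinning:
    """Equal-width intervals spanning the observed value range.

    By default the ``n_kept`` central intervals are retained, dropping
    ``floor((n_bins - n_kept)/2)`` intervals at the low end and the
    remainder at the high end (the high tail is where homology artifacts
    concentrate).  With 29 bins and 18 kept this keeps bins 5..22.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(np.unique(values)) < n_bins:
        raise ValueError("fewer distinct values than requested intervals")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ValueError("degenerate value range")
    edges = np.linspace(lo, hi, n_bins + 1)
    if kept_range is None:
        if n_kept is None:
            n_kept = min(DEFAULT_N_KEPT, n_bins)
        if not 1 <= n_kept <= n_bins:
            raise ValueError("n_kept outside [1, n_bins]")
        drop_low = (n_bins - n_kept) // 2
        kept_range = (drop_low, drop_low + n_kept - 1)
    return ProximityBinning(edges, kept_range)


def identity_qc_profile(C: ProximityMatrix, hits: pd.DataFrame,
                        prox_bins: ProximityBinning,
                        identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                        flag_factor: float = 3.0) -> pd.DataFrame:
    """Distribution of identity levels I(i, j) per proximity interval.

    Returns one row per interval with count, quartiles, median, min, max
    and a ``flagged`` column marking intervals whose median identity
    exceeds ``flag_factor`` times the global median (or is positive when
    the global median is 0) — candidates for exclusion.
    """
    pairs = C.pair_series()
    ident = np.array([
        identity_level(int(r.i), int(r.j), hits, C.binning,
                       identity_threshold=identity_threshold)
        for r in pairs.itertuples()
    ]) if len(hits) else np.zeros(len(pairs))
    bins = prox_bins.assign(pairs["value"].to_numpy())
    global_median = float(np.median(ident)) if len(ident) else 0.0
    rows = []
    for b in range(prox_bins.n_bins):
        vals = ident[bins == b]
        if len(vals) == 0:
            rows.append({"bin": b, "count": 0, "q1": np.nan, "median": np.nan,
                         "q3": np.nan, "min": np.nan, "max": np.nan,
                         "flagged": False})
            continue
        med = float(np.median(vals))
        q3 = float(np.percentile(vals, 75))
        if global_median > 0:
            flagged = med > flag_factor * global_median
        else:
            # identity is zero almost everywhere: any consistently
            # elevated bin (upper quartile above zero) is suspect
            flagged = q3 > 0
        rows.append({"bin": b, "count": int(len(vals)),
                     "q1": float(np.percentile(vals, 25)), "median": med,
                     "q3": q3,
                     "min": float(vals.min()), "max": float(vals.max()),
                     "flagged": bool(flagged)})
    return pd.DataFrame(rows)
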