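"""Ward clustering of fragments by their spatial-proximity profiles.

Fragments are clustered by Ward's minimum-variance method on their rows
of the proximity correlation matrix (masked entries imputed by the row
mean over usable entries); a mode treating 1 - C directly as the
dissimilarity is also available.  Cluster summaries reproduce the
compact-vs-loose contrast: within-cluster proximity, within-vs-outside
proximity, per-property signal levels and differences, and linear
proximity (1 / distance-in-Mb for same-chromosome pairs, 0 across
chromosomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import GenomeBinning
from .hic import ProximityMatrix
from .signals import SignalTrack, signal_strength, signal_difference

logger = logging.getLogger(__name__)

DEFAULT_GROUP_COUNTS = (4, 8, 16, 32, 64)


@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray            # -1 for fragments dropped before clustering
    clustered: np.ndarray         # fragment indices actually clustered
    linkage_matrix: np.ndarray

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.labels == c)


def ward_cluster(C: ProximityMatrix, k: int,
                 mode: str = "profile",
                 min_usable: int = 3) -> ClusterAssignment:
    """Cut a Ward dendrogram of the proximity matrix at ``k`` clusters.

    ``mode`` "profile": Euclidean distances between fragments' masked
    correlation rows (row-mean imputation); "dissimilarity": 1 - C used
    directly as the pairwise distance.  Fragments with fewer than
    ``min_usable`` usable entries are dropped (label -1).  Deterministic
    given the input order.
    """
    usable = C.mask.sum(axis=1)
    keep = np.flatnonzero(usable >= min_usable)
    dropped = C.n_fragments - len(keep)
    if dropped:
        logger.info("ward_cluster: dropped %d fragments with < %d usable "
                    "entries", dropped, min_usable)
    if k > len(keep):
        raise ValueError(f"k={k} exceeds {len(keep)} clusterable fragments")
    if mode == "profile":
        X = np.where(C.mask, C.values, np.nan)[np.ix_(keep, keep)]
        row_mean = np.nanmean(X, axis=1, keepdims=True)
        X = np.where(np.isnan(X), row_mean, X)
        Z = linkage(X, method="ward")
    elif mode == "dissimilarity":
        D = 1.0 - np.where(C.mask, C.values, 0.0)[np.ix_(keep, keep)]
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method="ward")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sub_labels = fcluster(Z, t=k, criterion="maxclust") - 1
    labels = np.full(C.n_fragments, -1, dtype=np.int64)
    labels[keep] = sub_labels
    return ClusterAssignment(k, labels, keep, Z)


def linear_proximity(frag_i, frag_j) -> float:
    """1 / (center distance in Mb) on the same chromosome, 0 across
    chromosomes, NaN for an identical fragment."""
    if frag_i.chrom != frag_j.chrom:
        return 0.0
    d_mb = abs(frag_i.center - frag_j.center) / 1e6
    if d_mb == 0:
        return float("nan")
    return 1.0 / d_mb


@dataclass
class ClusterSummary:
    cluster: int
    size: int
    within_proximity: np.ndarray        # interchromosomal same-cluster pairs
    outside_proximity: np.ndarray       # cluster x non-cluster pairs
    within_linear: np.ndarray           # linear proximity of within pairs
    level_medians: dict[str, float]     # per-property median S in cluster
    difference_medians: dict[str, float]  # per-property median D within

    @property
    def median_within(self) -> float:
        return float(np.median(self.within_proximity)) \
            if len(self.within_proximity) else float("nan")

    @property
    def median_outside(self) -> float:
        return float(np.median(self.outside_proximity)) \
            if len(self.outside_proximity) else float("nan")

    @property
    def median_within_linear(self) -> float:
        vals = self.within_linear[np.isfinite(self.within_linear)]
        return float(np.median(vals)) if len(vals) else float("nan")

    @property
    def mean_within_linear(self) -> float:
        """Mean linear proximity over within-cluster pairs.  The mean is
        the summary of choice here: cross-chromosome pairs contribute
        exact zeros, so the median is degenerate for mixed clusters."""
        vals = self.within_linear[np.isfinite(self.within_linear)]
        return float(np.mean(vals)) if len(vals) else float("nan")


def cluster_summaries(assignment: ClusterAssignment, C: ProximityMatrix,
                      tracks: dict[str, SignalTrack] | None = None,
                      log_mode: str = "log1p") -> list[ClusterSummary]:
    """Per-cluster proximity and signal summaries.

    Within-cluster proximity runs over usable (interchromosomal)
    same-cluster pairs only; "outside" pairs one cluster member with each
    non-member.  Linear proximity covers all distinct within-cluster
    pairs (same-chromosome pairs included, that being its point).
    """
    binning = C.binning
    signals = {}
    if tracks:
        signals = {name: signal_strength(t, binning)
                   for name, t in tracks.items()}
    V, M = C.values, C.mask
    out = []
    for c in range(assignment.k):
        members = assignment.members(c)
        non_members = np.setdiff1d(assignment.clustered, members)
        within, lin = [], []
        for a_pos, a in enumerate(members):
            for b in members[a_pos + 1:]:
                if M[a, b]:
                    within.append(V[a, b])
                lin.append(linear_proximity(binning.fragments[a],
                                            binning.fragments[b]))
        if len(members) and len(non_members):
            block_mask = M[np.ix_(members, non_members)]
            outside = V[np.ix_(members, non_members)][block_mask]
        else:
            outside = np.array([])
        level_med = {name: float(np.median(S[members])) if len(members)
                     else float("nan") for name, S in signals.items()}
        diff_med = {}
        for name, S in signals.items():
            if len(within):
                ds = [signal_difference(S[a], S[b], log_mode=log_mode)
                      for a_pos, a in enumerate(members)
                      for b in members[a_pos + 1:] if M[a, b]]
                diff_med[name] = float(np.median(ds))
            else:
                diff_med[name] = float("nan")
        out.append(ClusterSummary(
            cluster=c, size=int(len(members)),
            within_proximity=np.asarray(within, dtype=float),
            outside_proximity=np.asarray(outside, dtype=float),
            within_linear=np.asarray(lin, dtype=float),
            level_medians=level_med, difference_medians=diff_med))
    return out


def summary_table(summaries: list[ClusterSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"cluster": s.cluster, "size": s.size,
               "median_within": s.median_within,
               "median_outside": s.median_outside,
               "median_within_linear": s.median_within_linear}
        for name, v in s.level_medians.items():
            row[f"level_{name}"] = v
        for name, v in s.difference_medians.items():
            row[f"difference_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def compactness_correlation(summaries: list[ClusterSummary]) -> dict[str, float]:
    """Pearson correlations across clusters: median within-cluster vs
    within-vs-outside proximity (expected negative: compact clusters
    stand apart), and within-cluster spatial vs linear proximity."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 clusters")
    within = np.array([s.median_within for s in summaries])
    outside = np.array([s.median_outside for s in summaries])
    lin = np.array([s.mean_within_linear for s in summaries])
    out: dict[str, float] = {}
    ok = np.isfinite(within) & np.isfinite(outside)
    if ok.sum() >= 3 and np.std(within[ok]) > 0 and np.std(outside[ok]) > 0:
        r, p = stats.pearsonr(within[ok], outside[ok])
        out["r_within_vs_outside"], out["p_within_vs_outside"] = float(r), float(p)
    else:
        out["r_within_vs_outside"] = out["p_within_vs_outside"] = float("nan")
    ok = np.isfinite(within) & np.isfinite(lin)
    if ok.sum() >= 3 and np.std(within[ok]) > 0 and np.std(lin[ok]) > 0:
        r, p = stats.pearsonr(within[ok], lin[ok])
        out["r_within_vs_linear"], out["p_within_vs_linear"] = float(r), float(p)
    else:
        out["r_within_vs_linear"] = out["p_within_vs_linear"] = float("nan")
    return out
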