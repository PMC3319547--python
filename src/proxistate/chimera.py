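"""Chimeric RNA read pairs versus spatial proximity.

Cross-chromosome read pairs (candidate chimeric transcripts) are mapped
to the fragment pair containing their two coordinates.  For each kept
proximity interval the profile reports the fraction of fragment pairs in
which at least one chimeric read pair was observed, divided by the total
number of chimeric pairs in the sample so that samples of different
depth are comparable; Spearman correlation of the normalized fraction
with the interval midpoints is the headline statistic.

The null control re-pairs reads: read pairs mapping to the SAME
chromosome are unpaired and the pooled reads are randomly re-paired
subject to landing on different chromosomes, preserving each
chromosome's read-position multiset (local coverage) while destroying
any proximity dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeBinning
from .hic import ProximityMatrix, ProximityBinning

logger = logging.getLogger(__name__)


def assign_to_fragments(reads: pd.DataFrame,
                        binning: GenomeBinning) -> pd.DataFrame:
    """Map read pairs (chrom1, pos1, chrom2, pos2[, sample_id]) to
    unordered fragment pairs.  Same-chromosome pairs are excluded and
    counted; positions beyond a chromosome reject the record (logged)."""
    rows = []
    n_same = n_bad = 0
    for r in reads.itertuples():
        try:
            fi = binning.locate(r.chrom1, int(r.pos1))
            fj = binning.locate(r.chrom2, int(r.pos2))
        except (KeyError, ValueError):
            n_bad += 1
            continue
        if r.chrom1 == r.chrom2:
            n_same += 1
            continue
        i, j = (fi, fj) if fi < fj else (fj, fi)
        rows.append((i, j, getattr(r, "sample_id", "sample")))
    if n_same:
        logger.info("assign_to_fragments: excluded %d same-chromosome pairs",
                    n_same)
    if n_bad:
        logger.warning("assign_to_fragments: rejected %d invalid records",
                       n_bad)
    return pd.DataFrame(rows, columns=["i", "j", "sample_id"])


@dataclass
class ChimeraProfile:
    table: pd.DataFrame       # per-interval counts and fractions
    total_chimeras: int
    rho: float
    p_value: float


def chimera_profile(pairs: pd.DataFrame, C: ProximityMatrix,
                    prox_bins: ProximityBinning,
                    weighting: str = "presence") -> ChimeraProfile:
    """Chimera-fraction profile over kept proximity intervals.

    ``weighting`` "presence" counts a fragment pair once however many
    chimeric read pairs it produced; "count" sums read pairs.  The
    fraction per interval is divided by the sample's total chimeric pair
    count (normalized_fraction).  Empty intervals are masked.
    """
    if weighting not in ("presence", "count"):
        raise ValueError(f"unknown weighting {weighting!r}")
    grid = C.pair_series()
    bins = prox_bins.assign(grid["value"].to_numpy())
    total = int(len(pairs))
    chim_per_pair = pairs.groupby(["i", "j"]).size() if total else pd.Series(dtype=int)
    key = pd.MultiIndex.from_arrays([grid["i"], grid["j"]])
    counts = chim_per_pair.reindex(key, fill_value=0).to_numpy()
    hit = counts if weighting == "count" else (counts > 0).astype(int)
    rows = []
    for b in prox_bins.kept_bins:
        sel = bins == b
        n_pairs = int(sel.sum())
        if n_pairs == 0:
            rows.append({"bin": b, "n_fragment_pairs": 0,
                         "n_pairs_with_chimera": 0, "fraction": np.nan,
                         "normalized_fraction": np.nan})
            continue
        n_hit = int(hit[sel].sum())
        frac = n_hit / n_pairs
        rows.append({"bin": b, "n_fragment_pairs": n_pairs,
                     "n_pairs_with_chimera": n_hit, "fraction": frac,
                     "normalized_fraction": frac / total if total else np.nan})
    tab = pd.DataFrame(rows)
    ok = tab["normalized_fraction"].notna()
    if ok.sum() >= 3 and tab.loc[ok, "normalized_fraction"].nunique() > 1:
        rho, p = stats.spearmanr(prox_bins.midpoints[tab.loc[ok, "bin"]],
                                 tab.loc[ok, "normalized_fraction"])
    else:
        rho, p = float("nan"), float("nan")
    return ChimeraProfile(tab, total, float(rho), float(p))


def repair_control(reads: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, int]:
    """Re-pairing null: unpair same-chromosome read pairs and randomly
    re-pair the pooled reads across chromosomes.

    Returns (control read-pair table, number of leftover reads dropped).
    Each read is used at most once; per-chromosome read-position multisets
    of the used reads are preserved.  At every step one read is drawn from
    the currently largest chromosome pool and matched with a uniform
    random read from the other pools, which maximizes the number of
    matched reads.
    """
    same = reads[reads["chrom1"] == reads["chrom2"]]
    if not len(same):
        raise ValueError("no same-chromosome read pairs to re-pair")
    pool: dict[str, list[int]] = {}
    for r in same.itertuples():
        pool.setdefault(r.chrom1, []).extend([int(r.pos1), int(r.pos2)])
    if len(pool) < 2:
        raise ValueError("all reads on one chromosome: cannot re-pair")
    rng = np.random.default_rng(seed)
    for positions in pool.values():
        rng.shuffle(positions)
    chroms = sorted(pool)
    out = []
    while True:
        sizes = {c: len(pool[c]) for c in chroms if pool[c]}
        if len(sizes) < 2:
            break
        big = max(sorted(sizes), key=lambda c: sizes[c])
        others = [c for c in sizes if c != big]
        weights = np.array([sizes[c] for c in others], dtype=float)
        mate_chrom = others[rng.choice(len(others), p=weights / weights.sum())]
        p1 = pool[big].pop()
        p2 = pool[mate_chrom].pop()
        c1, c2 = (big, mate_chrom) if big < mate_chrom else (mate_chrom, big)
        if c1 != big:
            p1, p2 = p2, p1
        out.append((c1, p1, c2, p2))
    leftover = sum(len(v) for v in pool.values())
    if leftover:
        logger.info("repair_control: dropped %d unmatched leftover reads",
                    leftover)
    table = pd.DataFrame(out, columns=["chrom1", "pos1", "chrom2", "pos2"])
    table["sample_id"] = "control"
    return table, leftover
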