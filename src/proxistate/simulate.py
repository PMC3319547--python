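"""Synthetic input generation with planted, parameterized structure.

The generator emulates the statistical structure the analysis assumes:

* a multi-chromosome genome tiled into 1-Mb bins with a planted
  two-compartment block structure (A open/active, B closed/inactive);
* a latent per-fragment activity a_i = mu(compartment) + Gaussian noise
  that drives every functional readout;
* Hi-C contact counts O(i, j) ~ Poisson with rate proportional to
  coverage propensities u_i * u_j times
  exp(kappa_compartment * 1[same compartment]
      + kappa_coactivity * s_i * s_j
      + kappa_factory * hub(i, j)
      - kappa_activity * |a_i - a_j|),
  where s = sigmoid(centered activity) and hub(i, j) marks transcription
  -factory co-membership among open-compartment fragments; similar and
  jointly active loci contact more often, and factory hubs plant the
  compact-active / loose-inactive cluster contrast ("exclusive" hubs:
  hard dichotomy; default "shared" hubs: graded level effects);
* peak tracks whose per-fragment signal strength follows the activity
  (positively for active marks, negatively for methylation and
  repressive marks), the expression track being built from gene bodies;
* chromatin-state segments drawn from activity-dependent state
  distributions (similar activity => similar composition vectors);
* genes (denser in A) carrying expression, compartment-biased GO terms
  from a generated three-namespace DAG, and co-expression links whose r
  decays with the activity difference of the linked loci;
* chimeric read pairs sampled per fragment pair at a rate proportional
  to exp(theta * c(i, j)) where c is the generated correlation-stage
  proximity, plus same-chromosome read pairs feeding the re-pairing
  control;
* optional high-homology hits attached to the top-proximity pairs to
  exercise the sequence-identity QC.

Ground truth (compartments, activities, the config) is returned with the
bundle for recovery tests.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import GenomeBinning, make_binning, COMPARTMENT_OPEN, COMPARTMENT_CLOSED
from .gosim import GOGraph, NAMESPACES
from .hic import ProximityMatrix, raw_matrix, enrichment_matrix, correlation_matrix
from .signals import SignalTrack

ACTIVE_PROPERTIES = (
    "expression", "DNAse", "CTCF", "H3K4me1", "H3K4me2", "H3K4me3",
    "H3K9ac", "H3K27ac", "H3K36me3", "H4K20me1",
)
REPRESSIVE_PROPERTIES = ("methylation", "H3K27me3")
ALL_PROPERTIES = ACTIVE_PROPERTIES + REPRESSIVE_PROPERTIES

PROPERTY_DIRECTION = {p: (1.0 if p in ACTIVE_PROPERTIES else -1.0)
                      for p in ALL_PROPERTIES}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle (defaults documented in
    docs/methods.md)."""

    chromosome_lengths: dict[str, int] = field(default_factory=lambda: {
        f"chr{k}": 20_000_000 for k in range(1, 7)})
    bin_size: int = 1_000_000
    compartment_block_bins: int = 5
    # latent activity
    mu_activity: dict[str, float] = field(default_factory=lambda: {
        "A": 1.3, "B": 0.7})
    sigma_activity: dict[str, float] = field(default_factory=lambda: {
        "A": 0.25, "B": 0.55})
    # contact model
    total_reads: int = 100_000
    kappa_compartment: float = 0.1
    kappa_coactivity: float = 1.2
    kappa_activity: float = 1.2
    n_factories: int = 4
    kappa_factory: float = 1.2
    factory_membership_p: float = 0.5
    factory_assignment: str = "shared"   # "shared" or "exclusive"
    specificity_slope: float = 0.0
    coverage_cv: float = 0.15
    coverage_activity: float = 0.0
    # signal tracks
    signal_coupling: float = 0.9
    signal_scale: float = 3.0
    signal_noise: float = 0.25
    peaks_per_fragment: float = 6.0
    # chromatin states
    n_states: int = 8
    state_segment_bp: int = 50_000
    state_sharpness: float = 2.5
    # genes
    genes_per_mb: dict[str, float] = field(default_factory=lambda: {
        "A": 6.0, "B": 4.0})
    expression_coupling: float = 1.3
    expression_noise: float = 0.3
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    # GO
    go_terms_per_gene: tuple[int, int] = (1, 3)
    go_crossover: float = 0.15
    # co-expression
    n_links: int = 20_000
    link_r_base: float = 0.7
    link_r_activity_slope: float = 0.35
    link_r_noise: float = 0.1
    # chimeras
    n_chimeras: int = 3_000
    chimera_theta: float = 2.5
    n_intra_read_pairs: int = 3_000
    # homology artifact injection
    n_artifact_pairs: int = 0
    artifact_identity: float = 95.0
    artifact_hit_bp: int = 50_000

    def validate(self) -> None:
        if self.bin_size <= 0 or self.total_reads <= 0:
            raise ValueError("bin_size and total_reads must be positive")
        for name, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"nonpositive length for {name}")
            if self.compartment_block_bins * self.bin_size > length:
                raise ValueError(
                    f"compartment block longer than chromosome {name}")
        if len(self.chromosome_lengths) < 2:
            raise ValueError("need at least two chromosomes")


@dataclass
class SimulationBundle:
    """Everything the pipeline consumes, plus ground truth."""

    config: SimulationConfig
    seed: int
    binning: GenomeBinning
    counts: ProximityMatrix              # raw stage
    enrichment: ProximityMatrix          # C*
    proximity: ProximityMatrix           # C
    tracks: dict[str, SignalTrack]
    states: pd.DataFrame
    genes: pd.DataFrame
    go_graphs: dict[str, GOGraph]
    go_pools: dict[str, dict[str, list[str]]]
    links: pd.DataFrame
    chimeras: pd.DataFrame               # interchromosomal read pairs
    intra_read_pairs: pd.DataFrame       # same-chromosome pairs (control pool)
    hits: pd.DataFrame
    truth: pd.DataFrame                  # fragment, compartment, activity


def _make_compartments(binning: GenomeBinning, block_bins: int) -> list[str]:
    """Alternating A/B blocks; the starting label alternates per
    chromosome so both compartments span chromosomes."""
    labels = []
    for ci, chrom in enumerate(binning.chromosome_names):
        n = binning.n_bins_of(chrom)
        start_open = ci % 2 == 0
        for b in range(n):
            block = b // block_bins
            open_block = (block % 2 == 0) == start_open
            labels.append(COMPARTMENT_OPEN if open_block else COMPARTMENT_CLOSED)
    return labels


def _simulate_counts(binning: GenomeBinning, a: np.ndarray, cfg: SimulationConfig,
                     rng: np.random.Generator) -> np.ndarray:
    F = binning.n_fragments
    comp = np.array(binning.compartments)
    u = rng.gamma(1.0 / cfg.coverage_cv ** 2,
                  cfg.coverage_cv ** 2, size=F) if cfg.coverage_cv > 0 \
        else np.ones(F)
    s = 1.0 / (1.0 + np.exp(-(a - a.mean())))  # "locus is active" propensity
    # open chromatin is better covered (accessibility/mappability bias);
    # separable in the rate, so it cancels from the enrichment mean but
    # leaves inactive rows with fewer counts, hence noisier profiles
    u = u * np.exp(cfg.coverage_activity * (a - a.mean()))
    mask = binning.interchromosomal_mask()
    same = comp[:, None] == comp[None, :]
    bonus = cfg.kappa_compartment * same \
        + cfg.kappa_coactivity * np.outer(s, s)
    # transcription factories: open-compartment fragments are grouped into
    # cross-chromosome hubs with strongly elevated within-hub contacts;
    # closed chromatin forms no hubs
    if cfg.n_factories > 0 and cfg.kappa_factory != 0.0:
        open_idx = np.flatnonzero(comp == COMPARTMENT_OPEN)
        if cfg.factory_assignment == "exclusive":
            # each active fragment belongs to exactly one hub: plants a
            # hard compact/loose dichotomy (hub clusters vs closed bulk)
            factory = np.full(F, -1, dtype=np.int64)
            factory[open_idx] = rng.integers(0, cfg.n_factories,
                                             size=len(open_idx))
            hub = (factory[:, None] == factory[None, :]) \
                & (factory[:, None] >= 0)
            bonus = bonus + cfg.kappa_factory * hub
        elif cfg.factory_assignment == "shared":
            # fragments share machinery across several hubs: plants a
            # graded activity-level proximity effect while the open
            # compartment stays broadly coherent
            membership = np.zeros((F, cfg.n_factories))
            membership[open_idx] = rng.random(
                (len(open_idx), cfg.n_factories)) < cfg.factory_membership_p
            none = open_idx[membership[open_idx].sum(axis=1) == 0]
            if len(none):
                membership[none, rng.integers(0, cfg.n_factories,
                                              size=len(none))] = 1.0
            shared = membership @ membership.T
            bonus = bonus + cfg.kappa_factory * np.minimum(shared, 2.0) / 2.0
        else:
            raise ValueError(
                f"unknown factory_assignment {cfg.factory_assignment!r}")
    dact = np.abs(a[:, None] - a[None, :])
    # active loci contact specifically (sharp activity-similarity kernel),
    # inactive chromatin contacts nonspecifically (flat kernel)
    spec = 1.0 + cfg.specificity_slope * (s - s.mean())
    kappa_pair = cfg.kappa_activity * 0.5 * (spec[:, None] + spec[None, :])
    w = u[:, None] * u[None, :] * np.exp(bonus - kappa_pair * dact)
    w = np.where(mask, w, 0.0)
    iu, ju = np.triu_indices(F, k=1)
    wk = w[iu, ju]
    lam = cfg.total_reads * wk / wk.sum()
    counts = rng.poisson(lam)
    O = np.zeros((F, F))
    O[iu, ju] = counts
    O += O.T
    return O


def _go_dag(ns: str) -> tuple[GOGraph, dict[str, list[str]]]:
    """A single-rooted DAG of depth 3 per namespace with leaf pools split
    between compartments (plus one part_of cross edge)."""
    root = f"{ns}:R"
    edges = []
    leaves: list[str] = []
    mids = []
    for b in range(3):
        mid = f"{ns}:M{b}"
        mids.append(mid)
        edges.append((mid, root, "is_a"))
        for s in range(2):
            lo = f"{ns}:L{b}{s}"
            edges.append((lo, mid, "is_a"))
            for t in range(2):
                leaf = f"{ns}:T{b}{s}{t}"
                edges.append((leaf, lo, "is_a"))
                leaves.append(leaf)
    # one part_of edge to exercise the second relation type
    edges.append((f"{ns}:L00", mids[1], "part_of"))
    graph = GOGraph(ns, edges=edges)
    half = len(leaves) // 2
    pools = {"A": leaves[:half], "B": leaves[half:]}
    return graph, pools


def _simulate_genes(binning: GenomeBinning, a: np.ndarray,
                    cfg: SimulationConfig, pools: dict[str, dict[str, list[str]]],
                    rng: np.random.Generator) -> pd.DataFrame:
    a_center = a.mean()
    rows = []
    gid = 0
    lo, hi = cfg.gene_length_range
    for frag in binning.fragments:
        dens = cfg.genes_per_mb["A" if frag.compartment == COMPARTMENT_OPEN
                                else "B"]
        n = rng.poisson(dens * frag.length / 1e6)
        for _ in range(n):
            length = int(rng.integers(lo, hi))
            start = int(rng.integers(frag.start,
                                     max(frag.start + 1, frag.end - length)))
            end = min(start + length, binning.chromosome_lengths[frag.chrom])
            expr = float(np.exp(cfg.expression_coupling * (a[frag.index] - a_center)
                                + rng.normal(0, cfg.expression_noise)))
            comp_key = "A" if frag.compartment == COMPARTMENT_OPEN else "B"
            terms = {}
            for ns in NAMESPACES:
                k = int(rng.integers(cfg.go_terms_per_gene[0],
                                     cfg.go_terms_per_gene[1] + 1))
                pool_key = comp_key
                chosen = []
                for _ in range(k):
                    key = ("B" if pool_key == "A" else "A") \
                        if rng.random() < cfg.go_crossover else pool_key
                    chosen.append(str(rng.choice(pools[ns][key])))
                terms[ns] = chosen
            rows.append({
                "gene_id": f"g{gid:05d}", "chrom": frag.chrom,
                "start": start, "end": end, "expression": expr,
                "go_MF": terms["MF"], "go_BP": terms["BP"],
                "go_CC": terms["CC"], "compartment": comp_key,
            })
            gid += 1
    return pd.DataFrame(rows)


def _simulate_tracks(binning: GenomeBinning, a: np.ndarray, genes: pd.DataFrame,
                     cfg: SimulationConfig,
                     rng: np.random.Generator) -> dict[str, SignalTrack]:
    a_center = a.mean()
    tracks: dict[str, SignalTrack] = {}
    # expression: peaks are gene bodies, heights are expression values
    tracks["expression"] = SignalTrack(
        "expression",
        genes[["chrom", "start", "end", "expression"]]
        .rename(columns={"expression": "height"}).reset_index(drop=True))
    for prop in ALL_PROPERTIES:
        if prop == "expression":
            continue
        direction = PROPERTY_DIRECTION[prop]
        rows = []
        for frag in binning.fragments:
            target = cfg.signal_scale * np.exp(
                direction * cfg.signal_coupling * (a[frag.index] - a_center)
                + rng.normal(0, cfg.signal_noise))
            n_peaks = 1 + rng.poisson(max(cfg.peaks_per_fragment - 1, 0))
            widths = rng.integers(5_000, 30_000, size=n_peaks)
            starts = np.array([
                int(rng.integers(frag.start, max(frag.start + 1,
                                                 frag.end - w)))
                for w in widths])
            ends = np.minimum(starts + widths,
                              binning.chromosome_lengths[frag.chrom])
            raw_h = rng.gamma(2.0, 1.0, size=n_peaks)
            weight = ((ends - starts) / frag.length * raw_h).sum()
            scale = target / weight if weight > 0 else 0.0
            for s, e, h in zip(starts, ends, raw_h):
                if e > s:
                    rows.append((frag.chrom, int(s), int(e),
                                 float(h * scale)))
        peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "height"])
        peaks = peaks.sort_values(["chrom", "start"], ignore_index=True)
        tracks[prop] = SignalTrack(prop, peaks)
    return tracks


def _simulate_states(binning: GenomeBinning, a: np.ndarray,
                     cfg: SimulationConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    K = cfg.n_states
    half = K // 2
    a_center = a.mean()
    rows = []
    for frag in binning.fragments:
        p_active = 1.0 / (1.0 + np.exp(-cfg.state_sharpness
                                       * (a[frag.index] - a_center)))
        weights = np.concatenate([
            np.full(half, p_active / half),
            np.full(K - half, (1 - p_active) / (K - half))])
        pos = frag.start
        while pos < frag.end:
            end = min(pos + cfg.state_segment_bp, frag.end)
            state = int(rng.choice(K, p=weights))
            rows.append((frag.chrom, pos, end, state))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])


def _simulate_links(genes: pd.DataFrame, binning: GenomeBinning,
                    a: np.ndarray, cfg: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    n_genes = len(genes)
    if n_genes < 2:
        return pd.DataFrame(columns=["gene1", "gene2", "r"])
    frag_of = np.array([binning.locate(c, s) for c, s
                        in zip(genes["chrom"], genes["start"])])
    seen = set()
    rows = []
    ids = genes["gene_id"].to_numpy()
    attempts = 0
    while len(rows) < cfg.n_links and attempts < 20 * cfg.n_links:
        attempts += 1
        g1, g2 = rng.integers(0, n_genes, size=2)
        if g1 == g2:
            continue
        key = (min(g1, g2), max(g1, g2))
        if key in seen:
            continue
        seen.add(key)
        dact = abs(a[frag_of[g1]] - a[frag_of[g2]])
        r = float(np.clip(cfg.link_r_base - cfg.link_r_activity_slope * dact
                          + rng.normal(0, cfg.link_r_noise), -1, 1))
        rows.append({"gene1": ids[key[0]], "gene2": ids[key[1]], "r": r})
    return pd.DataFrame(rows)


def _simulate_chimeras(binning: GenomeBinning, C: ProximityMatrix,
                       cfg: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    pairs = C.pair_series()
    w = np.exp(cfg.chimera_theta * pairs["value"].to_numpy())
    lam = cfg.n_chimeras * w / w.sum()
    counts = rng.poisson(lam)
    rows = []
    for (i, j), n in zip(zip(pairs["i"], pairs["j"]), counts):
        if n == 0:
            continue
        fi, fj = binning.fragments[int(i)], binning.fragments[int(j)]
        for _ in range(int(n)):
            rows.append((fi.chrom, int(rng.integers(fi.start, fi.end)),
                         fj.chrom, int(rng.integers(fj.start, fj.end))))
    df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
    df["sample_id"] = "synthetic"
    return df


def _simulate_intra_pairs(binning: GenomeBinning, cfg: SimulationConfig,
                          rng: np.random.Generator) -> pd.DataFrame:
    chroms = binning.chromosome_names
    lengths = np.array([binning.chromosome_lengths[c] for c in chroms],
                       dtype=float)
    p = lengths / lengths.sum()
    rows = []
    for _ in range(cfg.n_intra_read_pairs):
        c = chroms[rng.choice(len(chroms), p=p)]
        L = binning.chromosome_lengths[c]
        rows.append((c, int(rng.integers(0, L)), c, int(rng.integers(0, L))))
    df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
    df["sample_id"] = "synthetic"
    return df


def _inject_hits(binning: GenomeBinning, C: ProximityMatrix,
                 cfg: SimulationConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    cols = ["frag_i", "frag_j", "start_i", "end_i", "start_j", "end_j",
            "percent_identity"]
    if cfg.n_artifact_pairs <= 0:
        return pd.DataFrame(columns=cols)
    pairs = C.pair_series().sort_values("value", ascending=False)
    rows = []
    for r in pairs.head(cfg.n_artifact_pairs).itertuples():
        fi, fj = binning.fragments[int(r.i)], binning.fragments[int(r.j)]
        si = int(rng.integers(fi.start, fi.end - cfg.artifact_hit_bp))
        sj = int(rng.integers(fj.start, fj.end - cfg.artifact_hit_bp))
        rows.append((fi.index, fj.index, si, si + cfg.artifact_hit_bp,
                     sj, sj + cfg.artifact_hit_bp, cfg.artifact_identity))
    return pd.DataFrame(rows, columns=cols)


def default_config() -> SimulationConfig:
    """The default study conditions: a 6 x 20 Mb genome, compartment-
    correlated activity (open compartment more active and more coherent),
    shared transcription-factory hubs.  Plants monotone interval-median
    associations: negative for every D feature, positive for active-mark
    averages and state-vector Jaccard, negative for methylation averages."""
    return SimulationConfig()


def compartment_decoupled_config() -> SimulationConfig:
    """Conditions for validating the compartment-constrained shuffle:
    the activity continuum (and hence every payload distribution) is
    identical in both compartments, the compartment structure entering
    contacts only through the checkerboard term.  The planted proximity-
    payload coupling is then purely positional within compartments, so
    the gene-name shuffle must null it out."""
    return SimulationConfig(
        mu_activity={"A": 1.0, "B": 1.0},
        sigma_activity={"A": 0.5, "B": 0.5},
        genes_per_mb={"A": 5.0, "B": 5.0},
        kappa_compartment=0.25,
        kappa_activity=1.6,
        n_factories=0,
    )


def exclusive_factory_config() -> SimulationConfig:
    """Conditions planting a hard compact/loose cluster dichotomy: each
    open-compartment fragment belongs to exactly one transcription-
    factory hub, so Ward clusters split into compact active hubs and the
    loose closed-chromatin bulk."""
    return SimulationConfig(
        factory_assignment="exclusive", n_factories=6, kappa_factory=1.5)


def two_block_config() -> SimulationConfig:
    """Conditions planting two clean compartment blocks (no activity
    kernel, no hubs, strong checkerboard) for exact clustering recovery."""
    return SimulationConfig(
        kappa_compartment=2.0, kappa_coactivity=0.0, kappa_activity=0.0,
        n_factories=0, total_reads=200_000)


def simulate(config: SimulationConfig | None = None,
             seed: int = 0) -> SimulationBundle:
    """Generate a full input bundle; deterministic given ``seed``."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    binning = make_binning(cfg.chromosome_lengths, cfg.bin_size)
    binning.set_compartments(
        _make_compartments(binning, cfg.compartment_block_bins))
    comp = np.array(binning.compartments)
    mu = np.where(comp == COMPARTMENT_OPEN, cfg.mu_activity["A"],
                  cfg.mu_activity["B"])
    sigma = cfg.sigma_activity
    if not isinstance(sigma, dict):
        sigma = {"A": sigma, "B": sigma}
    sd = np.where(comp == COMPARTMENT_OPEN, sigma["A"], sigma["B"])
    a = mu + rng.normal(0, 1.0, size=binning.n_fragments) * sd

    O = raw_matrix(_simulate_counts(binning, a, cfg, rng), binning)
    Cstar = enrichment_matrix(O)
    C = correlation_matrix(Cstar)

    go_graphs: dict[str, GOGraph] = {}
    go_pools: dict[str, dict[str, list[str]]] = {}
    for ns in NAMESPACES:
        go_graphs[ns], go_pools[ns] = _go_dag(ns)

    genes = _simulate_genes(binning, a, cfg, go_pools, rng)
    tracks = _simulate_tracks(binning, a, genes, cfg, rng)
    states = _simulate_states(binning, a, cfg, rng)
    links = _simulate_links(genes, binning, a, cfg, rng)
    chimeras = _simulate_chimeras(binning, C, cfg, rng)
    intra = _simulate_intra_pairs(binning, cfg, rng)
    hits = _inject_hits(binning, C, cfg, rng)

    truth = pd.DataFrame({
        "fragment": np.arange(binning.n_fragments),
        "chrom": [f.chrom for f in binning.fragments],
        "compartment": comp,
        "activity": a,
    })
    return SimulationBundle(
        config=cfg, seed=seed, binning=binning, counts=O, enrichment=Cstar,
        proximity=C, tracks=tracks, states=states, genes=genes,
        go_graphs=go_graphs, go_pools=go_pools, links=links,
        chimeras=chimeras, intra_read_pairs=intra, hits=hits, truth=truth)


def plant_linear_proximity(table: pd.DataFrame, betas: dict[str, float],
                           noise_sd: float, seed: int,
                           standardize: bool = True) -> pd.DataFrame:
    """Replace the proximity column of a pair table with a planted linear
    function of the named features plus Gaussian noise (for parameter
    recovery tests of the regression protocol).  With ``standardize``
    the betas apply to z-scored features, so they are effect sizes in
    SD units regardless of the features' native scales."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    y = np.zeros(len(out))
    for feat, beta in betas.items():
        x = out[feat].to_numpy(dtype=float)
        if standardize:
            x = (x - np.nanmean(x)) / np.nanstd(x)
        y = y + beta * x
    out["proximity"] = y + rng.normal(0, noise_sd, size=len(out))
    return out


def toy_fixture() -> SimulationBundle:
    """A minimal hand-checkable bundle: 3 chromosomes of 3 x 1-Mb bins,
    deterministic contact counts with a planted two-group structure
    (even- vs odd-indexed fragments), a handful of peaks, 6 genes, a
    5-term GO DAG, 3 links, 4 chimeric read pairs and one homology hit."""
    cfg = SimulationConfig(
        chromosome_lengths={"c1": 3_000_000, "c2": 3_000_000,
                            "c3": 3_000_000},
        compartment_block_bins=1, n_links=3, n_chimeras=4,
        n_intra_read_pairs=2)
    binning = make_binning(cfg.chromosome_lengths, cfg.bin_size)
    binning.set_compartments(["A", "B", "A", "B", "A", "B", "A", "B", "A"])
    F = 9
    O = np.zeros((F, F))
    for i in range(F):
        for j in range(i + 1, F):
            if binning.fragments[i].chrom == binning.fragments[j].chrom:
                continue
            if i % 2 == j % 2:
                O[i, j] = 30 - (i + j) % 3     # within planted group
            else:
                O[i, j] = 5 + (i * j) % 3      # across groups
            O[j, i] = O[i, j]
    counts = raw_matrix(O, binning)
    Cstar = enrichment_matrix(counts)
    C = correlation_matrix(Cstar)

    edges = [("T:A", "T:R", "is_a"), ("T:B", "T:R", "is_a"),
             ("T:C", "T:A", "is_a"), ("T:D", "T:B", "part_of")]
    graphs = {ns: GOGraph(ns, edges=[(f"{ns}:{c[2:]}", f"{ns}:{p[2:]}", rel)
                                     for c, p, rel in edges])
              for ns in NAMESPACES}
    pools = {ns: {"A": [f"{ns}:C"], "B": [f"{ns}:D"]} for ns in NAMESPACES}

    genes = pd.DataFrame([
        {"gene_id": "g1", "chrom": "c1", "start": 100_000, "end": 110_000,
         "expression": 5.0, "go_MF": ["MF:A"], "go_BP": ["BP:A"],
         "go_CC": ["CC:C"], "compartment": "A"},
        {"gene_id": "g2", "chrom": "c1", "start": 1_200_000, "end": 1_240_000,
         "expression": 1.0, "go_MF": ["MF:B"], "go_BP": ["BP:B"],
         "go_CC": ["CC:D"], "compartment": "B"},
        {"gene_id": "g3", "chrom": "c2", "start": 50_000, "end": 60_000,
         "expression": 4.0, "go_MF": ["MF:A", "MF:C"], "go_BP": ["BP:A"],
         "go_CC": ["CC:C"], "compartment": "A"},
        {"gene_id": "g4", "chrom": "c2", "start": 1_500_000, "end": 1_520_000,
         "expression": 0.5, "go_MF": ["MF:B"], "go_BP": ["BP:D"],
         "go_CC": ["CC:D"], "compartment": "B"},
        {"gene_id": "g5", "chrom": "c3", "start": 300_000, "end": 330_000,
         "expression": 3.0, "go_MF": ["MF:C"], "go_BP": ["BP:A"],
         "go_CC": ["CC:C"], "compartment": "A"},
        {"gene_id": "g6", "chrom": "c3", "start": 700_000, "end": 705_000,
         "expression": 2.0, "go_MF": ["MF:A"], "go_BP": ["BP:C"],
         "go_CC": ["CC:A"], "compartment": "A"},
    ])
    tracks = {
        "expression": SignalTrack("expression", genes[
            ["chrom", "start", "end", "expression"]].rename(
                columns={"expression": "height"}).reset_index(drop=True)),
        "DNAse": SignalTrack("DNAse", pd.DataFrame([
            ("c1", 0, 250_000, 4.0), ("c1", 500_000, 1_000_000, 2.0),
            ("c2", 100_000, 200_000, 3.0), ("c3", 0, 1_000_000, 1.0)],
            columns=["chrom", "start", "end", "height"])),
        "methylation": SignalTrack("methylation", pd.DataFrame([
            ("c1", 1_100_000, 1_900_000, 5.0), ("c2", 1_000_000, 2_000_000, 4.0)],
            columns=["chrom", "start", "end", "height"])),
    }
    states = pd.DataFrame([
        ("c1", 0, 500_000, 0), ("c1", 500_000, 1_000_000, 1),
        ("c1", 1_000_000, 2_000_000, 2), ("c2", 0, 1_000_000, 0),
        ("c2", 1_000_000, 2_000_000, 2), ("c3", 0, 500_000, 0),
        ("c3", 500_000, 1_000_000, 1)],
        columns=["chrom", "start", "end", "state"])
    links = pd.DataFrame([
        {"gene1": "g1", "gene2": "g3", "r": 0.8},
        {"gene1": "g2", "gene2": "g4", "r": 0.6},
        {"gene1": "g1", "gene2": "g4", "r": -0.2}])
    chimeras = pd.DataFrame([
        ("c1", 500_000, "c2", 100_000), ("c1", 600_000, "c2", 200_000),
        ("c1", 100_000, "c3", 900_000), ("c2", 1_100_000, "c3", 100_000)],
        columns=["chrom1", "pos1", "chrom2", "pos2"])
    chimeras["sample_id"] = "toy"
    intra = pd.DataFrame([
        ("c1", 100_000, "c1", 1_700_000), ("c2", 200_000, "c2", 1_800_000)],
        columns=["chrom1", "pos1", "chrom2", "pos2"])
    intra["sample_id"] = "toy"
    hits = pd.DataFrame([
        {"frag_i": 0, "frag_j": 3, "start_i": 10_000, "end_i": 60_000,
         "start_j": 500_000, "end_j": 550_000, "percent_identity": 95.0}])
    truth = pd.DataFrame({
        "fragment": np.arange(F),
        "chrom": [f.chrom for f in binning.fragments],
        "compartment": binning.compartments,
        "activity": [1.5, 0.5, 1.4, 0.4, 1.6, 0.6, 1.3, 0.7, 1.2],
    })
    return SimulationBundle(
        config=cfg, seed=0, binning=binning, counts=counts, enrichment=Cstar,
        proximity=C, tracks=tracks, states=states, genes=genes,
        go_graphs=graphs, go_pools=pools, links=links, chimeras=chimeras,
        intra_read_pairs=intra, hits=hits, truth=truth)
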