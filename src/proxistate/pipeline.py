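"""End-to-end orchestration: simulate -> normalize -> features ->
associate -> cluster -> regress -> chimera, from one config, with a run
manifest recording seeds, per-stage outputs, checksums and timings."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .association import (build_pair_table, compartment_split,
                          interval_profile, shuffle_gene_signals)
from .chimera import assign_to_fragments, chimera_profile, repair_control
from .clustering import (cluster_summaries, compactness_correlation,
                         summary_table, ward_cluster)
from .hic import make_proximity_bins
from .regression import ProximityRegression, make_splits
from .simulate import SimulationConfig, simulate

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, str],
               elapsed: float, **info) -> None:
        checksums = {}
        for name, path in outputs.items():
            p = Path(path)
            if p.exists():
                checksums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
        self.stages[stage] = {"outputs": outputs, "sha256": checksums,
                              "seconds": round(elapsed, 3), **info}

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def load_run_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    return cfg or {}


def run_pipeline(config: dict | None = None, outdir: str | Path = "run",
                 seed: int = 0) -> RunManifest:
    """Execute all stages on a synthetic bundle and write TSV outputs.

    ``config`` keys (all optional): ``simulation`` (SimulationConfig
    fields), ``n_bins``, ``n_kept``, ``cluster_k``, ``regression``
    (n_splits, features), ``features`` (list profiled against proximity).
    """
    config = config or {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seed=seed)

    sim_kwargs = dict(config.get("simulation", {}))
    if "chromosome_lengths" in sim_kwargs:
        sim_kwargs["chromosome_lengths"] = {
            str(k): int(v) for k, v in sim_kwargs["chromosome_lengths"].items()}
    sim_cfg = SimulationConfig(**sim_kwargs)

    t0 = time.time()
    bundle = simulate(sim_cfg, seed=seed)
    paths = {
        "fragments": str(outdir / "fragments.tsv"),
        "counts": str(outdir / "counts.tsv"),
        "genes": str(outdir / "genes.tsv"),
        "links": str(outdir / "links.tsv"),
        "states": str(outdir / "states.tsv"),
        "chimeras": str(outdir / "chimeras.tsv"),
        "ontology": str(outdir / "ontology.obo"),
    }
    pio.write_fragment_table(bundle.binning, paths["fragments"])
    pio.write_contact_matrix(bundle.counts, paths["counts"])
    pio.write_gene_table(bundle.genes, paths["genes"])
    pio.write_links(bundle.links, paths["links"])
    pio.write_states(bundle.states, paths["states"])
    pio.write_chimeric_pairs(bundle.chimeras, paths["chimeras"])
    pio.write_ontology(bundle.go_graphs, paths["ontology"])
    manifest.record("simulate", paths, time.time() - t0,
                    n_fragments=bundle.binning.n_fragments)

    t0 = time.time()
    C = bundle.proximity
    cpath = {"proximity": str(outdir / "proximity.tsv")}
    pio.write_contact_matrix(C, cpath["proximity"])
    manifest.record("normalize", cpath, time.time() - t0,
                    usable_pairs=int(C.mask.sum() // 2))

    t0 = time.time()
    table = build_pair_table(
        C, tracks=bundle.tracks, states=bundle.states,
        n_states=bundle.config.n_states, genes=bundle.genes,
        go_graphs=bundle.go_graphs, links=bundle.links, hits=bundle.hits)
    tpath = {"pair_table": str(outdir / "pair_table.tsv")}
    table.to_csv(tpath["pair_table"], sep="\t", index=False)
    manifest.record("features", tpath, time.time() - t0, n_pairs=len(table))

    t0 = time.time()
    n_bins = int(config.get("n_bins", 29))
    n_kept = int(config.get("n_kept", 18))
    prox_bins = make_proximity_bins(table["proximity"].to_numpy(),
                                    n_bins=n_bins, n_kept=n_kept)
    features = config.get("features") or [
        c for c in table.columns
        if c.startswith(("D_", "A_")) or c in ("jaccard", "coexpression",
                                               "gene_content", "go_CC")]
    assoc_rows = []
    for feat in features:
        prof = interval_profile(table, feat, prox_bins)
        assoc_rows.append({"feature": feat, "rho_medians": prof.rho_medians,
                           "p_medians": prof.p_medians,
                           "rho_pairs": prof.rho_pairs,
                           "p_pairs": prof.p_pairs})
    apath = {"associations": str(outdir / "associations.tsv")}
    pd.DataFrame(assoc_rows).to_csv(apath["associations"], sep="\t",
                                    index=False)
    manifest.record("associate", apath, time.time() - t0,
                    n_features=len(features))

    t0 = time.time()
    k = int(config.get("cluster_k", 8))
    assignment = ward_cluster(C, k)
    summaries = cluster_summaries(assignment, C, tracks=bundle.tracks)
    cpaths = {"labels": str(outdir / "cluster_labels.tsv"),
              "cluster_summary": str(outdir / "cluster_summary.tsv")}
    pd.DataFrame({"fragment": np.arange(bundle.binning.n_fragments),
                  "k": k, "cluster": assignment.labels}).to_csv(
        cpaths["labels"], sep="\t", index=False)
    summary_table(summaries).to_csv(cpaths["cluster_summary"], sep="\t",
                                    index=False)
    manifest.record("cluster", cpaths, time.time() - t0, k=k,
                    **{k_: v for k_, v in
                       compactness_correlation(summaries).items()})

    t0 = time.time()
    reg_cfg = config.get("regression", {})
    n_splits = int(reg_cfg.get("n_splits", 20))
    model = ProximityRegression.from_pair_table(
        table, features=reg_cfg.get("features"),
        alpha_policy=reg_cfg.get("alpha", 1.0))
    splits = make_splits(model.fragments, n_splits=n_splits, seed=seed + 1)
    results = model.fit(splits=splits)
    rpaths = {"regression": str(outdir / "regression.txt"),
              "screen": str(outdir / "feature_screen.tsv")}
    Path(rpaths["regression"]).write_text(results.summary() + "\n")
    model.screen_features(splits).to_csv(rpaths["screen"], sep="\t",
                                         index=False)
    manifest.record("regress", rpaths, time.time() - t0,
                    rmse=results.rmse_mean, baseline=results.baseline_mean)

    t0 = time.time()
    assigned = assign_to_fragments(bundle.chimeras, bundle.binning)
    prof = chimera_profile(assigned, C, prox_bins)
    control, _ = repair_control(bundle.intra_read_pairs, seed=seed + 2)
    control_prof = chimera_profile(
        assign_to_fragments(control, bundle.binning), C, prox_bins)
    hpath = {"chimera_profile": str(outdir / "chimera_profile.tsv")}
    prof.table.assign(dataset="real").pipe(
        lambda d: pd.concat([d, control_prof.table.assign(dataset="control")])
    ).to_csv(hpath["chimera_profile"], sep="\t", index=False)
    manifest.record("chimera", hpath, time.time() - t0,
                    rho=prof.rho, rho_control=control_prof.rho)

    manifest.write(outdir / "manifest.json")
    return manifest
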