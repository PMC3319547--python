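"""Readers and writers for the external tables and tracks the pipeline
consumes: peak tracks (bedGraph / broadPeak / BED3+score), contact
matrices (dense or triplet TSV), chrom.sizes, gene / co-expression-link /
chromatin-state / chimeric-read / homology-hit tables, and an OBO-subset
ontology.  All writers emit plain TSV; in-memory containers are pandas
DataFrames plus the package's own matrix and track types.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomeBinning, make_binning
from .gosim import GOGraph, NAMESPACES
from .hic import ProximityMatrix, raw_matrix, external_matrix
from .signals import SignalTrack

logger = logging.getLogger(__name__)

_OBO_NAMESPACE_ALIASES = {
    "molecular_function": "MF", "biological_process": "BP",
    "cellular_component": "CC", "MF": "MF", "BP": "BP", "CC": "CC",
}

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "expression",
                "go_MF", "go_BP", "go_CC", "compartment"]


# ---------------------------------------------------------------------------
# chrom.sizes and fragment tables


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'name length'")
        sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{l}\n" for c, l in sizes.items()))


def read_binning(path, bin_size: int = 1_000_000) -> GenomeBinning:
    return make_binning(read_chrom_sizes(path), bin_size)


def write_fragment_table(binning: GenomeBinning, path) -> None:
    df = pd.DataFrame(
        [(f.index, f.chrom, f.start, f.end, f.compartment)
         for f in binning.fragments],
        columns=["index", "chrom", "start", "end", "compartment"])
    df.to_csv(path, sep="\t", index=False)


def read_fragment_table(path, binning: GenomeBinning) -> GenomeBinning:
    """Load compartment labels from a fragment TSV onto ``binning``."""
    df = pd.read_csv(path, sep="\t")
    labels = [None] * binning.n_fragments
    for row in df.itertuples():
        labels[int(row.index)] = str(row.compartment)
    if any(l is None for l in labels):
        raise ValueError("fragment table does not cover the universe")
    binning.set_compartments(labels)
    return binning


# ---------------------------------------------------------------------------
# peak tracks


def read_peaks(path, dialect: str = "bedGraph",
               property_name: str | None = None) -> SignalTrack:
    """Read a peak track.  Dialects: bedGraph (chrom start end value),
    broadPeak (9 columns, signalValue is column 7, 0-based 6), bed3+score
    (chrom start end score).  Records with negative heights are rejected
    with a logged count; malformed lines raise with a line number.
    """
    height_col = {"bedGraph": 3, "bed3+score": 3, "broadPeak": 6}
    if dialect not in height_col:
        raise ValueError(f"unknown dialect {dialect!r}")
    col = height_col[dialect]
    rows = []
    n_rejected = 0
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            height = float(fields[col])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed {dialect} line") from exc
        if height < 0:
            n_rejected += 1
            continue
        rows.append((chrom, start, end, height))
    if n_rejected:
        logger.warning("%s: rejected %d records with negative height",
                       path, n_rejected)
    if not rows:
        logger.warning("%s: empty peak track", path)
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "height"])
    peaks = peaks.sort_values(["chrom", "start"], kind="stable",
                              ignore_index=True)
    name = property_name or Path(path).stem
    return SignalTrack(name, peaks)


def write_peaks(track: SignalTrack, path) -> None:
    track.peaks.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# contact matrices


def read_contact_matrix(path, binning: GenomeBinning, form: str = "triplet",
                        stage: str = "raw",
                        symmetrize: bool = False) -> ProximityMatrix:
    """Read a contact matrix.  ``form``: "triplet" (i j value, duplicates
    summed, (i, j) mirrored) or "dense" (F x F TSV).  ``stage`` "raw"
    validates nonnegative symmetric counts; any other stage is wrapped as
    an externally normalized matrix.
    """
    F = binning.n_fragments
    if form == "triplet":
        M = np.zeros((F, F))
        tri = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                          names=["i", "j", "value"])
        for row in tri.itertuples():
            i, j = int(row.i), int(row.j)
            if not (0 <= i < F and 0 <= j < F):
                raise ValueError(f"fragment index ({i}, {j}) out of range")
            M[i, j] += row.value
            if i != j:
                M[j, i] += row.value
    elif form == "dense":
        M = pd.read_csv(path, sep="\t", header=None, comment="#").to_numpy(dtype=float)
        if M.shape != (F, F):
            raise ValueError(f"dense matrix shape {M.shape} != ({F}, {F})")
        if not np.allclose(M, M.T):
            if not symmetrize:
                raise ValueError("asymmetric dense matrix (set symmetrize=True "
                                 "to average)")
            logger.warning("%s: asymmetric dense matrix symmetrized by "
                           "averaging", path)
            M = 0.5 * (M + M.T)
    else:
        raise ValueError(f"unknown matrix form {form!r}")
    if stage == "raw":
        return raw_matrix(M, binning)
    return external_matrix(M, binning)


def write_contact_matrix(matrix: ProximityMatrix, path,
                         form: str = "triplet") -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={matrix.stage}\n")
        if form == "triplet":
            iu, ju = np.triu_indices(matrix.n_fragments)
            for i, j in zip(iu, ju):
                v = matrix.values[i, j]
                if v != 0:
                    fh.write(f"{i}\t{j}\t{v:.10g}\n")
        elif form == "dense":
            for row in matrix.values:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
        else:
            raise ValueError(f"unknown matrix form {form!r}")


# ---------------------------------------------------------------------------
# gene / link / state / chimera / hit tables


def _split_terms(cell) -> list[str]:
    if isinstance(cell, list):
        return cell
    if pd.isna(cell) or cell in ("", "."):
        return []
    return str(cell).split(",")


def read_gene_table(path) -> pd.DataFrame:
    """Gene table TSV: gene_id, chrom, start, end, expression, go_MF,
    go_BP, go_CC (comma-separated term lists, '.' = none), compartment."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for ns in NAMESPACES:
        df[f"go_{ns}"] = df[f"go_{ns}"].map(_split_terms)
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in gene table")
    if (df["expression"] < 0).any():
        raise ValueError("negative expression values")
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    out = genes.copy()
    for ns in NAMESPACES:
        out[f"go_{ns}"] = out[f"go_{ns}"].map(
            lambda ts: ",".join(ts) if ts else ".")
    out.to_csv(path, sep="\t", index=False)


def read_links(path, genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Co-expression links TSV: gene1, gene2, r.  Self links rejected;
    links naming unknown genes (when ``genes`` given) dropped and counted."""
    df = pd.read_csv(path, sep="\t", dtype={"gene1": str, "gene2": str})
    if ((df["r"] < -1) | (df["r"] > 1)).any():
        raise ValueError("correlation r outside [-1, 1]")
    if (df["gene1"] == df["gene2"]).any():
        raise ValueError("self co-expression link")
    if genes is not None:
        known = set(genes["gene_id"])
        ok = df["gene1"].isin(known) & df["gene2"].isin(known)
        if (~ok).any():
            logger.warning("dropped %d links referencing unknown genes",
                           int((~ok).sum()))
        df = df[ok].reset_index(drop=True)
    return df


def write_links(links: pd.DataFrame, path) -> None:
    links.to_csv(path, sep="\t", index=False)


def read_states(path) -> pd.DataFrame:
    """Chromatin-state segments TSV: chrom, start, end, state (int)."""
    df = pd.read_csv(path, sep="\t")
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping state segments on {chrom}")
    return df


def write_states(states: pd.DataFrame, path) -> None:
    states.to_csv(path, sep="\t", index=False)


def read_chimeric_pairs(path) -> pd.DataFrame:
    """Chimeric read-pair table TSV: chrom1, pos1, chrom2, pos2[, sample_id]."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        df["sample_id"] = "sample"
    return df


def write_chimeric_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_homology_hits(path) -> pd.DataFrame:
    """Homology hits TSV: frag_i, frag_j, start_i, end_i, start_j, end_j,
    percent_identity (blast-tabular style, coordinates in bp)."""
    df = pd.read_csv(path, sep="\t")
    if ((df["percent_identity"] < 0) | (df["percent_identity"] > 100)).any():
        raise ValueError("percent_identity outside [0, 100]")
    return df


def write_homology_hits(hits: pd.DataFrame, path) -> None:
    hits.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ontology


def read_ontology(path) -> dict[str, GOGraph]:
    """Read an OBO subset (id, namespace, is_a, relationship: part_of)
    into one DAG per namespace.  Unknown relationship types are dropped
    with a warning; a cyclic graph is an error."""
    import obonet

    multigraph = obonet.read_obo(path)
    namespaces: dict[str, list] = {ns: [] for ns in NAMESPACES}
    terms: dict[str, list[str]] = {ns: [] for ns in NAMESPACES}
    node_ns: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        ns = _OBO_NAMESPACE_ALIASES.get(data.get("namespace", ""), None)
        if ns is None:
            logger.warning("term %s has unknown namespace; skipped", node)
            continue
        node_ns[node] = ns
        terms[ns].append(node)
    n_dropped = 0
    for child, parent, key in multigraph.edges(keys=True):
        rel = "is_a" if key == "is_a" else ("part_of" if key == "part_of" else None)
        if rel is None:
            n_dropped += 1
            continue
        ns = node_ns.get(child)
        if ns is None or node_ns.get(parent) != ns:
            continue
        namespaces[ns].append((child, parent, rel))
    if n_dropped:
        logger.warning("dropped %d ontology edges with unknown relation",
                       n_dropped)
    return {ns: GOGraph(ns, edges=namespaces[ns], terms=terms[ns])
            for ns in NAMESPACES if terms[ns]}


def write_ontology(graphs: dict[str, GOGraph], path) -> None:
    """Write the minimal OBO subset the reader understands."""
    long_ns = {v: k for k, v in _OBO_NAMESPACE_ALIASES.items()
               if k not in NAMESPACES}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for ns, g in graphs.items():
            for term in g.terms:
                fh.write(f"\n[Term]\nid: {term}\nname: {term}\n"
                         f"namespace: {long_ns[ns]}\n")
                for _, parent, data in g.graph.out_edges(term, data=True):
                    if data["relation"] == "is_a":
                        fh.write(f"is_a: {parent}\n")
                    else:
                        fh.write(f"relationship: part_of {parent}\n")
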