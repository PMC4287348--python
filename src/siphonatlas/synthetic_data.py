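"""Synthetic pseudo-organ atlas generator with planted ground truth.

Emulates the sampling design of an intracellular expression atlas of a
siphonous alga: six pseudo-organs (apex, pinnule, rachis, frond base,
stolon, holdfast) with (5, 5, 5, 5, 5, 4) replicate libraries of
negative-binomial counts.  A configurable fraction of transcripts is
unstructured (flat across organs); the rest follow one of six hand-authored
prototype profiles arranged along the apical-basal axis, scaled by a
planted fold.  Companion generators produce a "tomato-like" foreign atlas
plus a best-hit homolog table with tunable node association, and a GO
annotation with planted per-node enriched terms together with log-normal
contig lengths and a FASTA.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    DEFAULT_ORGANS,
    CountMatrix,
    write_count_matrix,
    write_go_annotation,
    write_node_table,
)

__all__ = [
    "DEFAULT_PROTOTYPES",
    "SyntheticTruth",
    "generate_atlas",
    "generate_foreign_atlas_and_homologs",
    "generate_go_and_lengths",
    "write_simulated_inputs",
]

#: Six apical-basal prototype profiles (rows: planted node; columns:
#: apex, pinnule, rachis, frond_base, stolon, holdfast).  Entries are
#: relative expression multipliers before the planted fold is applied:
#: a 1 stays at baseline, the marked organs are ``fold`` times higher.
DEFAULT_PROTOTYPES = np.array([
    [1, 0, 0, 0, 0, 0],   # apex-high
    [0, 1, 1, 0, 0, 0],   # pinnule + rachis
    [0, 0, 1, 1, 0, 0],   # rachis + frond base
    [0, 0, 0, 1, 1, 0],   # frond base + stolon
    [0, 0, 0, 0, 1, 1],   # stolon + holdfast
    [0, 0, 0, 0, 0, 1],   # holdfast-high
], dtype=float)

DEFAULT_REPLICATES = (5, 5, 5, 5, 5, 4)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic atlas."""

    node_labels: pd.Series           # transcript -> planted node (-1 = null)
    prototypes: np.ndarray           # node × organ expression multipliers
    organ_labels: tuple[str, ...]
    fold: float
    dispersion: float
    mean_depth: float
    seed: int
    planted_go: dict[int, str] = field(default_factory=dict)
    association: np.ndarray | None = None   # source node × foreign node

    @property
    def structured_ids(self) -> pd.Index:
        return self.node_labels.index[self.node_labels >= 0]


def _profile_matrix(prototypes: np.ndarray, fold: float) -> np.ndarray:
    """Turn 0/1 prototype masks into expression multipliers (1 or fold)."""
    return 1.0 + (fold - 1.0) * prototypes


def generate_atlas(
    n_transcripts: int = 2000,
    frac_null: float = 0.5,
    organs: tuple[str, ...] = DEFAULT_ORGANS,
    replicates: Sequence[int] = DEFAULT_REPLICATES,
    prototypes: np.ndarray | None = None,
    fold: float = 4.0,
    dispersion: float = 0.1,
    mean_depth: float = 5e5,
    baseline_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Simulate a pseudo-organ count atlas with planted node structure.

    Structured transcripts (``1 - frac_null`` of the total) are assigned
    planted nodes in round-robin order and express at ``fold`` times
    baseline in their prototype's marked organs.  Counts are negative
    binomial with variance mu + dispersion * mu**2 around per-sample means
    proportional to each transcript's share of its organ's transcriptome,
    at an expected library size of ``mean_depth``.
    """
    if len(replicates) != len(organs):
        raise ValueError("one replicate count per organ required")
    if any(r < 1 for r in replicates):
        raise ValueError("every organ needs >= 1 replicate")
    if prototypes is None:
        prototypes = DEFAULT_PROTOTYPES
    prototypes = np.asarray(prototypes, dtype=float)
    if prototypes.shape[1] != len(organs):
        raise ValueError("prototype columns must match organ count")

    rng = np.random.default_rng(seed)
    n_nodes = prototypes.shape[0]
    n_struct = int(round(n_transcripts * (1.0 - frac_null)))

    labels = np.full(n_transcripts, -1, dtype=int)
    labels[:n_struct] = np.arange(n_struct) % n_nodes
    rng.shuffle(labels)
    tids = [f"synthetic_contig_{i:05d}" for i in range(n_transcripts)]

    baseline = rng.lognormal(mean=0.0, sigma=baseline_sigma, size=n_transcripts)
    profiles = _profile_matrix(prototypes, fold)
    rel = np.tile(baseline[:, None], (1, len(organs)))
    structured = labels >= 0
    rel[structured] = baseline[structured, None] * profiles[labels[structured]]

    sample_ids, organ_of = [], []
    cols = []
    for o_idx, (organ, n_rep) in enumerate(zip(organs, replicates)):
        organ_share = rel[:, o_idx] / rel[:, o_idx].sum()
        mu = mean_depth * organ_share
        for rep in range(n_rep):
            if dispersion > 0:
                r = 1.0 / dispersion
                lam = rng.gamma(shape=r, scale=mu / r)
                col = rng.poisson(lam)
            else:
                col = rng.poisson(mu)
            cols.append(col)
            sample_ids.append(f"{organ}_rep{rep + 1}")
            organ_of.append(organ)

    counts = pd.DataFrame(np.column_stack(cols).astype(np.int64),
                          index=tids, columns=sample_ids)
    sheet = pd.Series(organ_of, index=sample_ids, name="organ")
    truth = SyntheticTruth(
        node_labels=pd.Series(labels, index=tids, name="planted_node"),
        prototypes=prototypes, organ_labels=tuple(organs), fold=fold,
        dispersion=dispersion, mean_depth=mean_depth, seed=seed,
    )
    return CountMatrix(counts, sheet, tuple(organs)), truth


def generate_foreign_atlas_and_homologs(
    truth: SyntheticTruth,
    n_foreign_nodes: int = 9,
    n_foreign_transcripts: int = 3000,
    association_strength: float = 0.6,
    association: np.ndarray | None = None,
    hit_rate: float = 0.8,
    seed: int = 1,
) -> tuple[pd.Series, pd.DataFrame, np.ndarray]:
    """Simulate a foreign expression atlas and a best-hit homolog table.

    Foreign transcripts are spread over ``n_foreign_nodes`` nodes with
    equal expected proportions (a 1/n null).  Each source transcript gains a best hit
    with probability ``hit_rate``; its subject is drawn from a foreign node
    chosen from the source node's row of the association matrix.  The
    default association gives each planted source node probability
    ``association_strength`` of its partner node (source node i -> foreign
    node i mod n_foreign_nodes) and spreads the rest uniformly; null
    (unstructured) source transcripts follow the foreign null distribution.
    Hit e-values are log-uniform below 1e-5 so none are filtered.

    Returns (foreign membership Series, best-hit DataFrame, association).
    """
    rng = np.random.default_rng(seed)
    n_source_nodes = truth.prototypes.shape[0]
    if association is None:
        rest = (1.0 - association_strength) / (n_foreign_nodes - 1)
        association = np.full((n_source_nodes, n_foreign_nodes), rest)
        for i in range(n_source_nodes):
            association[i, i % n_foreign_nodes] = association_strength
    association = np.asarray(association, dtype=float)
    if not np.allclose(association.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("association rows must sum to 1")

    foreign_nodes = rng.choice(n_foreign_nodes, size=n_foreign_transcripts)
    foreign_ids = [f"foreign_gene_{i:05d}" for i in range(n_foreign_transcripts)]
    membership = pd.Series(foreign_nodes + 1, index=foreign_ids,
                           name="node")  # foreign nodes labeled 1..n

    by_node = {node + 1: np.array([fid for fid, fn in membership.items()
                                   if fn == node + 1])
               for node in range(n_foreign_nodes)}
    null_props = membership.value_counts(normalize=True).sort_index().to_numpy()

    rows = []
    for tid, src_node in truth.node_labels.items():
        if rng.random() > hit_rate:
            continue
        probs = association[src_node] if src_node >= 0 else null_props
        fnode = int(rng.choice(n_foreign_nodes, p=probs)) + 1
        pool = by_node[fnode]
        if len(pool) == 0:
            continue
        subject = str(rng.choice(pool))
        evalue = 10.0 ** rng.uniform(-180.0, np.log10(1e-5))
        rows.append({
            "query_id": tid, "subject_id": subject,
            "percent_identity": float(np.round(rng.uniform(30.0, 95.0), 2)),
            "e_value": evalue,
            "bit_score": float(np.round(rng.uniform(60.0, 400.0), 1)),
        })
    hits = pd.DataFrame(rows, columns=["query_id", "subject_id",
                                       "percent_identity", "e_value",
                                       "bit_score"])
    truth.association = association
    return membership, hits, association


def generate_go_and_lengths(
    truth: SyntheticTruth,
    planted_odds: float = 8.0,
    base_rate: float = 0.05,
    n_background_terms: int = 40,
    background_rate: float = 0.03,
    length_meanlog: float = 5.94,
    length_sdlog: float = 1.0,
    min_length: int = 200,
    seed: int = 2,
) -> tuple[dict[str, set[str]], dict[str, int], dict[int, str]]:
    """Simulate GO annotation with one planted term per node, plus lengths.

    Each planted node gets a dedicated term carried by its members with
    probability ``planted_odds * base_rate`` (capped at 0.95) and by other
    transcripts with probability ``base_rate``.  Background terms are
    independent of node.  Contig lengths are log-normal (defaults chosen to
    resemble a de novo transcriptome assembly: median ≈ 380 bp, mean ≈
    630 bp), floored at ``min_length``.

    Returns (annotation, lengths, planted term per node).
    """
    rng = np.random.default_rng(seed)
    tids = list(truth.node_labels.index)
    n_nodes = truth.prototypes.shape[0]
    planted = {node: f"GO:{7000001 + node:07d}" for node in range(n_nodes)}
    truth.planted_go = planted
    p_in = min(planted_odds * base_rate, 0.95)

    ann: dict[str, set[str]] = {t: set() for t in tids}
    labels = truth.node_labels.to_numpy()
    for node, term in planted.items():
        members = labels == node
        carry = np.where(members, rng.random(len(tids)) < p_in,
                         rng.random(len(tids)) < base_rate)
        for t, c in zip(tids, carry):
            if c:
                ann[t].add(term)
    for b in range(n_background_terms):
        term = f"GO:{1000001 + b:07d}"
        carry = rng.random(len(tids)) < background_rate
        for t, c in zip(tids, carry):
            if c:
                ann[t].add(term)

    lengths = {
        t: int(max(min_length,
                   round(rng.lognormal(length_meanlog, length_sdlog))))
        for t in tids
    }
    return {t: s for t, s in ann.items() if s}, lengths, planted


def write_fasta(lengths: Mapping[str, int], path: str | Path,
                seed: int = 3) -> None:
    """Write random-sequence contigs realizing the given lengths."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    with open(path, "w", encoding="utf-8") as fh:
        for tid in lengths:
            seq = "".join(rng.choice(bases, size=lengths[tid]))
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_simulated_inputs(outdir: str | Path, seed: int = 0,
                           **atlas_kwargs) -> dict:
    """Simulate a full input set and write it to ``outdir``.

    Emits counts.tsv, sheet.tsv, go.tsv, contigs.fasta, foreign_nodes.tsv,
    blast.tsv and truth.json.  Sub-generator seeds derive from ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = generate_atlas(seed=seed, **atlas_kwargs)
    membership, hits, association = generate_foreign_atlas_and_homologs(
        truth, seed=seed + 1)
    ann, lengths, planted = generate_go_and_lengths(truth, seed=seed + 2)

    write_count_matrix(cm, outdir / "counts.tsv", outdir / "sheet.tsv")
    write_go_annotation(ann, outdir / "go.tsv")
    write_fasta(lengths, outdir / "contigs.fasta", seed=seed + 3)
    write_node_table(membership, outdir / "foreign_nodes.tsv")
    hits_out = hits.copy()
    # pad to 12-column BLAST tabular for the outfmt-6 reader
    blast = pd.DataFrame({
        "qseqid": hits_out["query_id"], "sseqid": hits_out["subject_id"],
        "pident": hits_out["percent_identity"], "length": 100,
        "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": 100,
        "sstart": 1, "send": 100, "evalue": hits_out["e_value"],
        "bitscore": hits_out["bit_score"],
    })
    blast.to_csv(outdir / "blast.tsv", sep="\t", index=False, header=False)

    truth_json = {
        "seed": seed,
        "fold": truth.fold,
        "dispersion": truth.dispersion,
        "mean_depth": truth.mean_depth,
        "organ_labels": list(truth.organ_labels),
        "node_labels": {t: int(v) for t, v in truth.node_labels.items()},
        "prototypes": truth.prototypes.tolist(),
        "planted_go": {str(k): v for k, v in planted.items()},
        "association": association.tolist(),
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_json, fh, indent=1)
    return truth_json
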