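"""Assignment of RNA 3' parts to transcriptional units.

Three namespaces are populated: annotated genes (density-weighted,
antisense-overlap assignment), X-RNAs (clusters of unassigned parts that
behave like unannotated transcripts) and eRNAs (parts falling into
enhancer-class chromatin states 4-7, counted independently of any gene
assignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .contacts import dna_anchor, parse_blocks
from .tracks import ChromatinStateTrack, ENHANCER_STATES

XRNA_MIN_PARTS = 100
XRNA_MAX_GAP = 100
XRNA_MERGE_DISTANCE = 1000
XRNA_GENE_FLANK = 100
ERNA_MIN_CONTACTS = 100


def rna3_intersection_interval(row: pd.Series) -> Tuple[int, int]:
    """Interval of the RNA 3' part used for gene intersection.

    For spliced parts only the fragment running from the bridge to the
    first break in alignment is used: the terminal block holding the
    part's first sequenced base.
    """
    blocks = parse_blocks(row.get("rna3_blocks", ""), row["rna3_start"], row["rna3_end"])
    if len(blocks) == 1:
        return blocks[0]
    return blocks[0] if row["rna3_strand"] == "+" else blocks[-1]


def _gene_trees(genes: pd.DataFrame) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for i, g in genes.iterrows():
        trees.setdefault(g["chrom"], IntervalTree()).addi(g["start"], g["end"], i)
    return trees


def assign_rna3_to_genes(contacts: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Two-pass density assignment of each RNA 3' part to at most one gene.

    A part may be assigned to a gene it intersects by >= 1 nt on the
    strand opposite to the gene.  Pass 1 counts, per gene, every
    strand-compatible intersecting part (parts overlapping several genes
    count once per gene) and derives a coverage density count / length;
    pass 2 assigns each part to its maximal-density candidate, breaking
    exact ties by smaller gene length then lexicographic gene_id.

    Returns a Series indexed like ``contacts`` holding gene_id or None.
    """
    trees = _gene_trees(genes)
    lengths = (genes["end"] - genes["start"]).to_numpy()
    candidates: list[list[int]] = []
    counts = np.zeros(len(genes), dtype=np.int64)
    ivals = [rna3_intersection_interval(row) for _, row in contacts.iterrows()]
    for (_, row), (a, b) in zip(contacts.iterrows(), ivals):
        tree = trees.get(row["rna_chrom"])
        cand = []
        if tree is not None:
            for hit in tree.overlap(a, b):
                gi = hit.data
                if genes.iloc[gi]["strand"] != row["rna3_strand"]:
                    cand.append(gi)
        candidates.append(cand)
        for gi in cand:
            counts[gi] += 1
    density = counts / lengths
    gene_ids = genes["gene_id"].to_numpy()
    out = []
    for cand in candidates:
        if not cand:
            out.append(None)
            continue
        best = min(cand, key=lambda gi: (-density[gi], lengths[gi], gene_ids[gi]))
        out.append(gene_ids[best])
    return pd.Series(out, index=contacts.index, dtype=object)


def gene_part_counts(assignment: pd.Series) -> Dict[str, int]:
    """Number of RNA 3' parts assigned to each gene."""
    return assignment.dropna().value_counts().to_dict()


@dataclass
class XRnaCluster:
    chrom: str
    strand: str
    start: int
    end: int
    n_parts: int


def detect_xrna_clusters(
    unassigned: pd.DataFrame,
    genes: pd.DataFrame,
    gene_counts: Dict[str, int],
    min_parts: int = XRNA_MIN_PARTS,
    max_gap: int = XRNA_MAX_GAP,
    merge_distance: int = XRNA_MERGE_DISTANCE,
    gene_flank: int = XRNA_GENE_FLANK,
) -> pd.DataFrame:
    """Greedy strand-wise chaining of unassigned RNA 3' parts into X-RNAs.

    Parts are chained while the gap between the end of one part and the
    start of the next is <= ``max_gap`` (0 when overlapping).  Chains
    with fewer than ``min_parts`` parts are dropped; a chain is discarded
    when a gene lying within ``gene_flank`` bp of either boundary carries
    more assigned parts than the chain holds (a likely transcriptional
    tail); surviving same-strand chains closer than ``merge_distance``
    are aggregated with summed counts.
    """
    frames = []
    for _, row in unassigned.iterrows():
        a, b = rna3_intersection_interval(row)
        frames.append((row["rna_chrom"], row["rna3_strand"], a, b))
    parts = pd.DataFrame(frames, columns=["chrom", "strand", "start", "end"])
    clusters: list[XRnaCluster] = []
    for (chrom, strand), sub in parts.groupby(["chrom", "strand"]):
        sub = sub.sort_values(["start", "end"])
        cur_start = cur_end = None
        n = 0
        for a, b in zip(sub["start"], sub["end"]):
            if cur_end is None or a - cur_end > max_gap:
                if cur_end is not None:
                    clusters.append(XRnaCluster(chrom, strand, cur_start, cur_end, n))
                cur_start, cur_end, n = a, b, 1
            else:
                cur_end = max(cur_end, b)
                n += 1
        if cur_end is not None:
            clusters.append(XRnaCluster(chrom, strand, cur_start, cur_end, n))

    clusters = [c for c in clusters if c.n_parts >= min_parts]
    clusters = [c for c in clusters
                if not _is_gene_tail(c, genes, gene_counts, gene_flank)]

    merged: list[XRnaCluster] = []
    for c in sorted(clusters, key=lambda c: (c.chrom, c.strand, c.start)):
        last = merged[-1] if merged else None
        if (last is not None and last.chrom == c.chrom and last.strand == c.strand
                and c.start - last.end < merge_distance):
            last.end = max(last.end, c.end)
            last.n_parts += c.n_parts
        else:
            merged.append(c)
    merged.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return pd.DataFrame(
        [(c.chrom, c.start, c.end, c.strand, c.n_parts) for c in merged],
        columns=["chrom", "start", "end", "strand", "n_parts"],
    )


def _is_gene_tail(
    cluster: XRnaCluster, genes: pd.DataFrame, gene_counts: Dict[str, int], flank: int
) -> bool:
    near = genes[genes["chrom"] == cluster.chrom]
    for _, g in near.iterrows():
        gap = max(g["start"] - cluster.end, cluster.start - g["end"], 0)
        if gap < flank and gene_counts.get(g["gene_id"], 0) > cluster.n_parts:
            return True
    return False


def enhancer_units(states: ChromatinStateTrack) -> pd.DataFrame:
    """Every state-4..7 interval is an individual enhancer."""
    df = states.to_frame()
    df = df[df["state"].isin(ENHANCER_STATES)].reset_index(drop=True)
    df["enhancer_id"] = [
        f"enh_{c}_{s}_{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
    return df


def assign_enhancer_rnas(
    contacts: pd.DataFrame, states: ChromatinStateTrack
) -> pd.Series:
    """Assign each RNA 3' part intersecting an enhancer to that enhancer.

    Either strand qualifies and the assignment is independent of any gene
    assignment (parts may be counted twice).  A part touching two
    adjacent enhancers goes to the one with the larger overlap (lower
    coordinate on ties).
    """
    units = enhancer_units(states)
    trees: Dict[str, IntervalTree] = {}
    for i, u in units.iterrows():
        trees.setdefault(u["chrom"], IntervalTree()).addi(u["start"], u["end"], i)
    out = []
    for _, row in contacts.iterrows():
        a, b = rna3_intersection_interval(row)
        tree = trees.get(row["rna_chrom"])
        best, best_ov = None, 0
        if tree is not None:
            for hit in sorted(tree.overlap(a, b), key=lambda h: h.begin):
                ov = min(b, hit.end) - max(a, hit.begin)
                if ov > best_ov:
                    best, best_ov = units.iloc[hit.data]["enhancer_id"], ov
        out.append(best)
    return pd.Series(out, index=contacts.index, dtype=object)


def erna_set(
    enh_assignment: pd.Series, states: ChromatinStateTrack,
    min_contacts: int = ERNA_MIN_CONTACTS,
) -> pd.DataFrame:
    """Enhancers with at least ``min_contacts`` assigned parts."""
    units = enhancer_units(states).set_index("enhancer_id")
    counts = enh_assignment.dropna().value_counts()
    keep = counts[counts >= min_contacts]
    out = units.loc[keep.index]
    out.index = pd.Index(keep.index, name="enhancer_id")
    out = out.reset_index()
    out["n_contacts"] = keep.to_numpy()
    return out[["enhancer_id", "state", "chrom", "start", "end", "n_contacts"]]


def group_contacts_by_rna(
    contacts: pd.DataFrame,
    gene_assignment: Optional[pd.Series] = None,
    xrna_clusters: Optional[pd.DataFrame] = None,
    enh_assignment: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Long table (rna_id, dna_chrom, anchor, weight, read_id) of profiles.

    Contacts assigned to both a gene and an enhancer appear twice; X-RNA
    membership is resolved by the RNA part falling inside a cluster on
    the matching strand.  Unassigned contacts appear in no profile.
    """
    anchors = dna_anchor(contacts)
    pieces = []

    def _piece(mask: np.ndarray, ids: pd.Series) -> None:
        sub = contacts.loc[mask]
        pieces.append(pd.DataFrame({
            "rna_id": ids[mask].to_numpy(),
            "read_id": sub["read_id"].to_numpy(),
            "dna_chrom": sub["dna_chrom"].to_numpy(),
            "anchor": anchors[np.asarray(mask)],
            "weight": sub["weight"].to_numpy(),
        }))

    if gene_assignment is not None:
        _piece(gene_assignment.notna().to_numpy(), gene_assignment)
    if enh_assignment is not None:
        _piece(enh_assignment.notna().to_numpy(), enh_assignment)
    if xrna_clusters is not None and len(xrna_clusters):
        unassigned_mask = (gene_assignment.isna().to_numpy()
                           if gene_assignment is not None
                           else np.ones(len(contacts), dtype=bool))
        ids = pd.Series([None] * len(contacts), index=contacts.index, dtype=object)
        for ci, c in xrna_clusters.iterrows():
            m = unassigned_mask & (
                (contacts["rna_chrom"] == c["chrom"])
                & (contacts["rna3_strand"] == c["strand"])
                & (contacts["rna3_start"] < c["end"])
                & (contacts["rna3_end"] > c["start"])
            ).to_numpy()
            ids[m] = f"xrna_{c['chrom']}_{c['start']}_{c['end']}_{c['strand']}"
        _piece(ids.notna().to_numpy(), ids)
    if not pieces:
        return pd.DataFrame(columns=["rna_id", "read_id", "dna_chrom", "anchor", "weight"])
    return pd.concat(pieces, ignore_index=True)
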