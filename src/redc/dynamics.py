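"""mRNA transcription dynamics: part classes, metagene profiles,
directional asymmetry and contact-probability scaling.

RNA parts of mRNAs are classified from the genomic positions of their
two ends — the 5' end (adjoining the template-switch GGG) and the 3' end
(adjoining the bridge) — into exon, intron, exon-intron junction and
exon-exon junction classes.  Contacts of each class are then profiled
along a 24-bin metagene (6 flank + 12 body + 6 flank bins, all of length
gene_length/12), split by the direction of the DNA anchor relative to
the transcription site, or folded into a contact-probability-vs-distance
scaling curve over 100-kb bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contacts import dna_anchor, parse_blocks
from .genes import elements_in_transcription_order

PART_CLASSES = ("exon", "intron", "exon_intron", "exon_exon")

DEFAULT_BANDS = ((0, 10_000), (10_000, 50_000), (50_000, 100_000), (100_000, 500_000))

N_BODY_BINS = 12
N_FLANK_BINS = 6


@dataclass
class RnaPartClass:
    """Classification of one RNA part against its gene model."""

    part_class: Optional[str]  # None when unclassifiable
    gene_id: str
    element_index: Optional[int]  # 1-based index of the exon/intron (class-dependent)
    gene_body_bin: Optional[int]  # 1..12 from the RNA 3' end, transcription-oriented


def _element_at(elements, pos: int) -> Optional[Tuple[str, int]]:
    for kind, idx, a, b in elements:
        if a <= pos < b:
            return kind, idx
    return None


def gene_body_bin(gene: Mapping, pos: int, n_bins: int = N_BODY_BINS) -> Optional[int]:
    """1-based body bin of a position, counted in transcription direction."""
    start, end = int(gene["start"]), int(gene["end"])
    if not (start <= pos < end):
        return None
    frac = (pos - start) / (end - start)
    if gene["strand"] == "-":
        frac = 1.0 - frac - 1e-12
    return min(int(frac * n_bins), n_bins - 1) + 1


def classify_part(
    rna5_end: int,
    rna3_end: int,
    n_blocks: int,
    gene: Mapping,
) -> RnaPartClass:
    """Classify an RNA part by the elements containing its two ends.

    Same exon -> ``exon``; same intron -> ``intron``; ends in an exon and
    the adjacent intron (either order along transcription) ->
    ``exon_intron``; ends in consecutive exons with a splice junction
    reported (> 1 alignment block) -> ``exon_exon``.  Anything else,
    including ends outside the gene span, is unclassified.
    """
    elements = elements_in_transcription_order(gene)
    e5 = _element_at(elements, rna5_end)
    e3 = _element_at(elements, rna3_end)
    bin3 = gene_body_bin(gene, rna3_end)
    if e5 is None or e3 is None:
        return RnaPartClass(None, gene["gene_id"], None, bin3)
    (k5, i5), (k3, i3) = e5, e3
    if k5 == k3 and i5 == i3:
        return RnaPartClass(k5, gene["gene_id"], i5, bin3)
    if k5 == "exon" and k3 == "intron" and i3 == i5:
        return RnaPartClass("exon_intron", gene["gene_id"], i5, bin3)
    if k5 == "intron" and k3 == "exon" and i3 == i5 + 1:
        return RnaPartClass("exon_intron", gene["gene_id"], i3, bin3)
    if k5 == "exon" and k3 == "exon" and i3 == i5 + 1 and n_blocks > 1:
        return RnaPartClass("exon_exon", gene["gene_id"], i5, bin3)
    return RnaPartClass(None, gene["gene_id"], None, bin3)


def classify_contacts(
    contacts: pd.DataFrame,
    gene_assignment: pd.Series,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Classification columns for every gene-assigned contact.

    Adds part_class, element_index and gene_body_bin (None / NaN where
    unclassifiable); unassigned contacts are dropped.
    """
    gene_index = genes.set_index("gene_id")
    rows = []
    for idx, row in contacts.iterrows():
        gid = gene_assignment.get(idx)
        if gid is None or gid not in gene_index.index:
            continue
        gene = gene_index.loc[gid]
        gene = {**gene.to_dict(), "gene_id": gid}
        blocks = parse_blocks(row.get("rna3_blocks", ""), row["rna3_start"], row["rna3_end"])
        cls = classify_part(int(row["rna5_end_coord"]), int(row["rna3_end_coord"]),
                            len(blocks), gene)
        rows.append({
            "index": idx,
            "gene_id": gid,
            "part_class": cls.part_class,
            "element_index": cls.element_index,
            "gene_body_bin": cls.gene_body_bin,
        })
    return pd.DataFrame(rows).set_index("index") if rows else pd.DataFrame(
        columns=["gene_id", "part_class", "element_index", "gene_body_bin"])


# ---------------------------------------------------------------------------
# Metagene profile


def metagene_profile(
    contacts: pd.DataFrame,
    classified: pd.DataFrame,
    genes: pd.DataFrame,
    selector=None,
    n_body_bins: int = N_BODY_BINS,
    n_flank_bins: int = N_FLANK_BINS,
) -> np.ndarray:
    """24-bin average contact profile over gene bodies and half-gene flanks.

    For every protein-coding gene with >= 1 contact inside the gene or
    its half-gene-length flanks, the weights of contacts whose RNA part
    passes ``selector`` (a boolean function of the classified rows) are
    summed into 24 equal bins of length gene_length/12 — 6 upstream
    flank, 12 body, 6 downstream, oriented by transcription — then
    averaged position-wise across genes and scaled to a maximum of 1.
    """
    n_bins = n_body_bins + 2 * n_flank_bins
    gene_index = genes.set_index("gene_id")
    anchors = dna_anchor(contacts)
    profiles = []
    for gid, sub in classified.groupby("gene_id"):
        gene = gene_index.loc[gid]
        if gene["biotype"] != "protein_coding":
            continue
        length = int(gene["end"] - gene["start"])
        bin_len = length / n_body_bins
        lo = gene["start"] - n_flank_bins * bin_len
        rows = contacts.loc[sub.index]
        pos = anchors[contacts.index.get_indexer(sub.index)]
        local = rows["dna_chrom"].to_numpy() == gene["chrom"]
        within = local & (pos >= lo) & (pos < lo + n_bins * bin_len)
        if not within.any():
            continue
        if selector is not None:
            chosen = sub.apply(selector, axis=1).to_numpy(dtype=bool)
        else:
            chosen = np.ones(len(sub), dtype=bool)
        use = within & chosen
        vec = np.zeros(n_bins)
        if use.any():
            idx = ((pos[use] - lo) / bin_len).astype(int)
            np.add.at(vec, np.clip(idx, 0, n_bins - 1), rows["weight"].to_numpy()[use])
        if gene["strand"] == "-":
            vec = vec[::-1]
        profiles.append(vec)
    if not profiles:
        return np.zeros(n_bins)
    mean = np.mean(profiles, axis=0)
    top = mean.max()
    return mean / top if top > 0 else mean


# ---------------------------------------------------------------------------
# Directional asymmetry


def directional_asymmetry(
    contacts: pd.DataFrame,
    bands: Sequence[Tuple[int, int]] = DEFAULT_BANDS,
    oriented: bool = True,
) -> pd.DataFrame:
    """Downstream/upstream contact-frequency ratio per distance band.

    The transcription site of an RNA part is taken as the genomic
    position of its 3' end; the DNA anchor's signed offset from it is
    folded by the transcript strand when ``oriented``.  Only cis
    contacts contribute.  Ratios are NaN for empty bands.
    """
    cis = contacts["dna_chrom"] == contacts["rna_chrom"]
    sub = contacts.loc[cis]
    delta = dna_anchor(sub) - sub["rna3_end_coord"].to_numpy()
    if oriented:
        delta = np.where(sub["transcript_strand"].to_numpy() == "-", -delta, delta)
    w = sub["weight"].to_numpy(dtype=float)
    rows = []
    for lo, hi in bands:
        down = w[(delta >= lo) & (delta < hi)].sum()
        up = w[(delta <= -lo) & (delta > -hi)].sum()
        rows.append({
            "band_start": lo, "band_end": hi,
            "downstream": down, "upstream": up,
            "ratio": down / up if up > 0 else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contact-probability scaling


@dataclass
class ScalingCurve:
    """Mean contact probability against genomic separation."""

    bin_size: int
    distances: np.ndarray  # separation in bp (bin midpoint convention: d * bin_size)
    probability: np.ndarray
    n_bin_pairs: np.ndarray
    total_contacts: int

    def fit_exponent(self, min_sep: int, max_sep: int) -> float:
        """Log-log slope of the curve over a separation range (bp)."""
        m = (self.distances >= min_sep) & (self.distances <= max_sep) & (self.probability > 0)
        x = np.log(self.distances[m].astype(float))
        y = np.log(self.probability[m])
        slope, _ = np.polyfit(x, y, 1)
        return float(slope)


def scaling_curve(
    pairs: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 100_000,
) -> ScalingCurve:
    """Distance scaling of contact probability over 100-kb bins.

    ``pairs`` holds columns chrom1/pos1 (source; the RNA part 3' end or
    one side of a DNA-DNA ligation) and chrom2/pos2 (target).  Source
    bins are restricted to bins receiving >= 1 source; per source bin the
    target counts over every genomic bin (zeros included) are recorded,
    averaged among bin pairs of equal cis separation, and normalized to
    the total number of contacts including trans.
    """
    n_bins = {c: int(np.ceil(s / bin_size)) for c, s in chrom_sizes.items()}
    b1 = pairs["pos1"].to_numpy(dtype=np.int64) // bin_size
    b2 = pairs["pos2"].to_numpy(dtype=np.int64) // bin_size
    total = len(pairs)
    src = pd.DataFrame({"chrom": pairs["chrom1"], "bin": b1})
    source_bins = src.drop_duplicates()
    max_d = max(n_bins.values())
    contact_sum = np.zeros(max_d, dtype=float)
    pair_count = np.zeros(max_d, dtype=np.int64)

    # pairs at each separation available from the occupied source bins
    for chrom, sub in source_bins.groupby("chrom"):
        n = n_bins.get(chrom, 0)
        if n == 0:
            continue
        for b in sub["bin"].to_numpy():
            d = np.arange(max_d)
            pair_count += ((b - d) >= 0).astype(np.int64) + ((b + d) < n).astype(np.int64) \
                - (d == 0).astype(np.int64)

    cis = (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    sep = np.abs(b1[cis] - b2[cis])
    np.add.at(contact_sum, sep, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        prob = np.where(pair_count > 0, contact_sum / pair_count / max(total, 1), 0.0)
    return ScalingCurve(
        bin_size=bin_size,
        distances=np.arange(max_d) * bin_size,
        probability=prob,
        n_bin_pairs=pair_count,
        total_contacts=total,
    )


# ---------------------------------------------------------------------------
# Cis/trans summaries


def cis_trans_summary(
    contacts: pd.DataFrame,
    classified: pd.DataFrame,
) -> pd.DataFrame:
    """Cis/trans anchor fractions per RNA part class, averaged over chromosomes."""
    sub = contacts.loc[classified.index]
    is_cis = (sub["dna_chrom"] == sub["rna_chrom"]).to_numpy()
    rows = []
    for cls in PART_CLASSES:
        m = (classified["part_class"] == cls).to_numpy()
        if not m.any():
            continue
        per_chrom = []
        for chrom, idx in sub.loc[m].groupby("rna_chrom").groups.items():
            loc = sub.index.get_indexer(idx)
            per_chrom.append(is_cis[loc].mean())
        rows.append({
            "part_class": cls,
            "n": int(m.sum()),
            "cis_fraction": float(np.mean(per_chrom)),
            "trans_fraction": 1.0 - float(np.mean(per_chrom)),
        })
    return pd.DataFrame(rows)


def per_gene_cis_trans(
    contacts: pd.DataFrame,
    classified: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene cis/trans contact ratio alongside gene length."""
    gene_index = genes.set_index("gene_id")
    sub = contacts.loc[classified.index]
    is_cis = (sub["dna_chrom"] == sub["rna_chrom"]).to_numpy()
    rows = []
    for gid, idx in classified.groupby("gene_id").groups.items():
        loc = classified.index.get_indexer(idx)
        n_cis = int(is_cis[loc].sum())
        n_trans = int(len(loc) - n_cis)
        gene = gene_index.loc[gid]
        rows.append({
            "gene_id": gid,
            "gene_length": int(gene["end"] - gene["start"]),
            "n_cis": n_cis,
            "n_trans": n_trans,
            "cis_trans_ratio": n_cis / n_trans if n_trans else np.inf,
        })
    return pd.DataFrame(rows)


def contacts_per_nt(
    classified: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Contact counts per nucleotide of exonic vs intronic gene sequence."""
    gene_index = genes.set_index("gene_id")
    totals = {"exon": 0, "intron": 0}
    lengths = {"exon": 0, "intron": 0}
    for gid, sub in classified.groupby("gene_id"):
        gene = gene_index.loc[gid]
        exon_len = sum(b - a for a, b in gene["exons"])
        lengths["exon"] += exon_len
        lengths["intron"] += int(gene["end"] - gene["start"]) - exon_len
        counts = sub["part_class"].value_counts()
        totals["exon"] += int(counts.get("exon", 0))
        totals["intron"] += int(counts.get("intron", 0))
    rows = [
        {"part_class": k, "n_contacts": totals[k], "total_nt": lengths[k],
         "contacts_per_nt": totals[k] / lengths[k] if lengths[k] else np.nan}
        for k in ("exon", "intron")
    ]
    return pd.DataFrame(rows)
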