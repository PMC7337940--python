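"""Coordinate-level simulation scenarios with planted ground truth.

Each builder returns ready-made contact/anchor tables (no sequences)
that emulate one analysis situation: genomic-distribution archetypes,
unannotated-transcript clusters, enrichment peaks, co-transcriptional
mRNA dynamics, directional drag and contact-probability scaling.  The
default parameters define the study conditions under which the
downstream statistics are validated.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .genes import gene_frame

Region = Tuple[int, int]


def _sample_union(rng: np.random.Generator, regions: List[Region], n: int) -> np.ndarray:
    """Uniform positions over a union of [start, end) intervals."""
    regions = [(a, b) for a, b in regions if b > a]
    if not regions or n == 0:
        return np.zeros(0, dtype=np.int64)
    lengths = np.array([b - a for a, b in regions], dtype=float)
    pick = rng.choice(len(regions), size=n, p=lengths / lengths.sum())
    offs = rng.random(n)
    starts = np.array([regions[i][0] for i in pick])
    spans = np.array([regions[i][1] - regions[i][0] for i in pick])
    return (starts + offs * spans).astype(np.int64)


def contact_frame(chroms, anchors, **extra) -> pd.DataFrame:
    """Minimal contact-like frame (anchor encoded as [pos, pos+1))."""
    anchors = np.asarray(anchors, dtype=np.int64)
    df = pd.DataFrame({
        "dna_chrom": chroms,
        "dna_start": anchors,
        "dna_end": anchors + 1,
        "weight": 1.0,
    })
    for k, v in extra.items():
        df[k] = v
    return df


# ---------------------------------------------------------------------------
# Genomic-distribution archetypes (groups A / B / C)

ARCHETYPE_MASSES = {
    # plateau over gene +/- 5 Mb with a sharp cutoff; modest chromosome-wide
    # and genome-wide leakage sets R/T well above the decay fillers
    "proximal_plateau": {"plateau": 0.895, "parental": 0.060, "genome": 0.045},
    # XIST-like: essentially the whole parental chromosome
    "chromosome_wide": {"parental": 0.970, "genome": 0.030},
    # spread uniformly over all chromosomes
    "genome_wide": {"genome": 1.0},
}

#: mRNA-like steep proximal decay; these RNAs dominate real libraries and
#: populate the upper quantiles of every ratio
FILLER_MASSES = {"G": 0.05, "SM": 0.72, "L": 0.12, "R": 0.04, "T": 0.07}


def archetype_cohort(
    seed: int,
    n_per_archetype: int = 100,
    n_filler: int = 1200,
    chrom_sizes: Optional[Dict[str, int]] = None,
    contacts_range: Tuple[int, int] = (700, 1400),
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, int], pd.DataFrame]:
    """Cohort of RNAs with planted genomic-distribution archetypes.

    Returns (profiles, genes, chrom_sizes, truth) where profiles is the
    long (rna_id, dna_chrom, anchor, weight) table and truth maps rna_id
    to its planted archetype ('filler' for the decay background RNAs).
    """
    rng = np.random.default_rng(seed)
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 25_000_000, "chr2": 25_000_000, "chr3": 25_000_000}
    chroms = list(chrom_sizes)
    gene_rows, truth_rows, pieces = [], [], []
    plan = [(a, i) for a in ARCHETYPE_MASSES for i in range(n_per_archetype)]
    plan += [("filler", i) for i in range(n_filler)]
    for archetype, i in plan:
        rna_id = f"{archetype}_{i:04d}"
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = chrom_sizes[chrom]
        length = int(rng.integers(50_000, 150_000))
        start = int(rng.integers(7_000_000, size - 7_000_000 - length))
        end = start + length
        gene_rows.append({
            "gene_id": rna_id, "name": rna_id,
            "biotype": "protein_coding" if archetype == "filler" else "lincRNA",
            "chrom": chrom, "strand": "+" if rng.random() < 0.5 else "-",
            "start": start, "end": end, "exons": [(start, end)],
        })
        truth_rows.append({"rna_id": rna_id, "archetype": archetype})
        n = int(rng.integers(*contacts_range))
        others = [c for c in chroms if c != chrom]
        comp_regions: Dict[str, List[Tuple[str, Region]]] = {
            "plateau": [(chrom, (max(0, start - 5_000_000), min(size, end + 5_000_000)))],
            "parental": [(chrom, (0, size))],
            "genome": [(c, (0, chrom_sizes[c])) for c in chroms],
            "G": [(chrom, (start, end))],
            "SM": [(chrom, (max(0, start - 500_000), start)),
                   (chrom, (end, min(size, end + 500_000)))],
            "L": [(chrom, (max(0, start - 5_000_000), start - 500_000)),
                  (chrom, (end + 500_000, min(size, end + 5_000_000)))],
            "R": [(chrom, (0, start - 5_000_000)),
                  (chrom, (end + 5_000_000, size))],
            "T": [(c, (0, chrom_sizes[c])) for c in others],
        }
        masses = FILLER_MASSES if archetype == "filler" else ARCHETYPE_MASSES[archetype]
        counts = rng.multinomial(n, list(np.array(list(masses.values()))
                                         / sum(masses.values())))
        for (comp, _), k in zip(masses.items(), counts):
            placements = comp_regions[comp]
            lengths = np.array([max(b - a, 0) for _, (a, b) in placements], dtype=float)
            if lengths.sum() == 0 or k == 0:
                continue
            pick = rng.choice(len(placements), size=k, p=lengths / lengths.sum())
            for j, cnt in zip(*np.unique(pick, return_counts=True)):
                c, (a, b) = placements[j]
                pos = _sample_union(rng, [(a, b)], int(cnt))
                pieces.append(pd.DataFrame({
                    "rna_id": rna_id, "dna_chrom": c, "anchor": pos, "weight": 1.0,
                }))
    profiles = pd.concat(pieces, ignore_index=True)
    return profiles, gene_frame(gene_rows), dict(chrom_sizes), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# X-RNA discovery scenario


def _part_rows(chrom, strand, starts, part_len) -> List[dict]:
    rows = []
    for s in starts:
        rows.append({
            "read_id": None, "rna_chrom": chrom,
            "rna3_start": int(s), "rna3_end": int(s + part_len),
            "rna3_strand": strand, "rna3_blocks": f"{int(s)}-{int(s + part_len)}",
            "weight": 1.0,
        })
    return rows


def xrna_library(
    seed: int,
    n_transcripts: int = 20,
    n_tail_decoys: int = 5,
    chrom: str = "chr1",
    chrom_size: int = 12_000_000,
    part_len: int = 25,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Unannotated transcripts, gene-tail decoys and one 99-part decoy.

    Returns (parts, genes, truth): parts is a contact-like frame of RNA
    3' parts (assigned gene parts and unassigned cluster parts), truth
    lists each planted feature with kind in {transcript, tail_decoy,
    small_decoy} and its part span.
    """
    rng = np.random.default_rng(seed)
    gene_rows, rows, truth = [], [], []
    slot = 150_000  # feature spacing; keeps planted clusters > 1 kb apart
    cursor = 100_000

    def _cluster(start: int, n_parts: int, strand: str) -> Tuple[int, int]:
        gaps = rng.integers(0, 71, size=n_parts - 1)
        starts = start + np.concatenate([[0], np.cumsum(gaps + part_len)])
        rows.extend(_part_rows(chrom, strand, starts, part_len))
        return int(starts[0]), int(starts[-1] + part_len)

    for i in range(n_transcripts):
        strand = "+" if i % 2 == 0 else "-"
        span = _cluster(cursor, int(rng.integers(110, 150)), strand)
        truth.append({"kind": "transcript", "start": span[0], "end": span[1],
                      "strand": strand})
        cursor += slot

    for i in range(n_tail_decoys):
        gid = f"host{i:02d}"
        gstart, gend = cursor, cursor + 30_000
        gstrand = "+" if i % 2 == 0 else "-"
        gene_rows.append({
            "gene_id": gid, "name": gid, "biotype": "protein_coding",
            "chrom": chrom, "strand": gstrand, "start": gstart, "end": gend,
            "exons": [(gstart, gend)],
        })
        part_strand = "-" if gstrand == "+" else "+"
        # 400 antisense parts inside the gene keep it better covered than the tail
        starts = rng.integers(gstart, gend - part_len, size=400)
        rows.extend(_part_rows(chrom, part_strand, starts, part_len))
        span = _cluster(gend + 50, 150, part_strand)
        truth.append({"kind": "tail_decoy", "start": span[0], "end": span[1],
                      "strand": part_strand})
        cursor += slot

    span = _cluster(cursor, 99, "+")
    truth.append({"kind": "small_decoy", "start": span[0], "end": span[1], "strand": "+"})

    parts = pd.DataFrame(rows)
    parts["read_id"] = [f"p{i:06d}" for i in range(len(parts))]
    return parts, gene_frame(gene_rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Enrichment-peak scenario


def enrichment_library(
    seed: int,
    chrom_sizes: Optional[Dict[str, int]] = None,
    n_background: int = 120_000,
    n_rna: int = 10_000,
    block: Tuple[str, int, int] = ("chr2", 5_000_000, 6_000_000),
    block_fold: float = 4.0,
    bin_size: int = 100_000,
):
    """Trans background plus three RNAs: block peak, single spike, flat.

    The block RNA carries a planted ``block_fold`` density excess over a
    10-bin window; the spike RNA a single enriched bin; the flat RNA is
    background-identical.  Returns (bg_contacts, genes, chrom_sizes,
    rna_anchors dict, truth dict).
    """
    rng = np.random.default_rng(seed)
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000}
    chroms = list(chrom_sizes)
    total = sum(chrom_sizes.values())

    gene_rows = []
    for i in range(30):
        chrom = chroms[i % len(chroms)]
        start = 200_000 + (i // len(chroms)) * 600_000
        gene_rows.append({
            "gene_id": f"src{i:02d}", "name": f"src{i:02d}",
            "biotype": "protein_coding", "chrom": chrom, "strand": "+",
            "start": start, "end": start + 10_000,
            "exons": [(start, start + 10_000)],
        })
    genes = gene_frame(gene_rows)

    src = rng.integers(0, len(genes), size=n_background)
    bg_chroms, bg_pos = [], []
    for i in src:
        parental = genes.iloc[i]["chrom"]
        others = [c for c in chroms if c != parental]
        c = others[int(rng.integers(len(others)))]
        bg_chroms.append(c)
        bg_pos.append(int(rng.integers(chrom_sizes[c])))
    bg = contact_frame(bg_chroms, bg_pos,
                       gene_id=[genes.iloc[i]["gene_id"] for i in src])

    def _uniform_genome(n):
        c = rng.choice(chroms, size=n, p=np.array(list(chrom_sizes.values())) / total)
        pos = (rng.random(n) * np.array([chrom_sizes[x] for x in c])).astype(np.int64)
        return pd.DataFrame({"chrom": c, "anchor": pos, "weight": 1.0})

    def _with_hotspot(n, region, fold):
        c, a, b = region
        extra_mass = (fold - 1) * (b - a)
        p_hot = extra_mass / (total + extra_mass)
        n_hot = int(rng.binomial(n, p_hot))
        flat = _uniform_genome(n - n_hot)
        hot = pd.DataFrame({
            "chrom": c,
            "anchor": rng.integers(a, b, size=n_hot),
            "weight": 1.0,
        })
        return pd.concat([flat, hot], ignore_index=True)

    rna_anchors = {
        "rna_block": _with_hotspot(n_rna, block, block_fold),
        "rna_spike": _with_hotspot(
            n_rna, (block[0], 12_000_000, 12_000_000 + bin_size), 5.0),
        "rna_flat": _uniform_genome(n_rna),
    }
    truth = {"block": block, "block_fold": block_fold, "bin_size": bin_size}
    return bg, genes, dict(chrom_sizes), rna_anchors, truth


# ---------------------------------------------------------------------------
# mRNA dynamics scenarios


def _full_contact_row(read_id, chrom, strand, rna5_end, rna3_end, anchor_chrom,
                      anchor) -> dict:
    lo, hi = sorted((rna5_end, rna3_end))
    return {
        "read_id": read_id, "rna_chrom": chrom,
        "rna3_start": lo, "rna3_end": hi + 1,
        "rna3_strand": "-" if strand == "+" else "+",
        "rna3_blocks": f"{lo}-{hi + 1}",
        "rna5_chrom": chrom, "rna5_start": lo, "rna5_end": hi + 1,
        "rna5_strand": strand, "transcript_strand": strand,
        "rna3_end_coord": rna3_end, "rna5_end_coord": rna5_end,
        "dna_chrom": anchor_chrom, "dna_start": int(anchor),
        "dna_end": int(anchor) + 1, "dna_strand": "+",
        "gene_id": None, "weight": 1.0,
    }


def metagene_library(
    seed: int,
    n_genes: int = 30,
    contacts_per_class: int = 300,
    chrom: str = "chr1",
    chrom_size: int = 60_000_000,
) -> Tuple[pd.DataFrame, pd.Series, pd.DataFrame, Dict[str, int]]:
    """Co-transcriptional contact geometry for metagene profiling.

    First-exon RNA parts anchor uniformly from their source down to the
    transcription end site (the nascent transcript travels with the
    polymerase); first-intron parts anchor tightly around their source
    (introns are removed co-transcriptionally and stay near their locus).
    Genes alternate strands.  Returns (contacts, gene_assignment, genes,
    chrom_sizes).
    """
    rng = np.random.default_rng(seed)
    gene_rows, rows, assign = [], [], []
    cursor = 2_000_000
    for i in range(n_genes):
        gid = f"mg{i:03d}"
        strand = "+" if i % 2 == 0 else "-"
        length = int(rng.integers(30_000, 60_000))
        start, end = cursor, cursor + length
        cursor += length + 2 * length  # leave room for half-gene flanks
        # first exon and first intron both sit inside body bin 1 (length/12)
        # so intron-sourced contacts stay in their transcription bin
        exon_len, intron_len = length // 40, length // 24
        if strand == "+":
            exons = [(start, start + exon_len),
                     (start + exon_len + intron_len, end)]
            e1, i1 = exons[0], (start + exon_len, start + exon_len + intron_len)
            tes = end
        else:
            exons = [(start, end - exon_len - intron_len),
                     (end - exon_len, end)]
            e1, i1 = exons[1], (end - exon_len - intron_len, end - exon_len)
            tes = start
        gene_rows.append({
            "gene_id": gid, "name": gid, "biotype": "protein_coding",
            "chrom": chrom, "strand": strand, "start": start, "end": end,
            "exons": exons,
        })
        for j in range(contacts_per_class):
            a = int(rng.integers(e1[0], e1[1] - 20))
            r5, r3 = (a, a + 19) if strand == "+" else (a + 19, a)
            src = r3
            anchor = int(rng.integers(min(src, tes), max(src, tes)))
            rows.append(_full_contact_row(f"{gid}_e{j}", chrom, strand, r5, r3,
                                          chrom, anchor))
            assign.append(gid)
        for j in range(contacts_per_class):
            a = int(rng.integers(i1[0], i1[1] - 20))
            r5, r3 = (a, a + 19) if strand == "+" else (a + 19, a)
            anchor = int(np.clip(r3 + rng.integers(-500, 501), start, end - 1))
            rows.append(_full_contact_row(f"{gid}_i{j}", chrom, strand, r5, r3,
                                          chrom, anchor))
            assign.append(gid)
    contacts = pd.DataFrame(rows)
    assignment = pd.Series(assign, index=contacts.index, dtype=object)
    return contacts, assignment, gene_frame(gene_rows), {chrom: chrom_size}


def asymmetry_library(
    seed: int,
    n_contacts: int = 30_000,
    drag: float = 1.5,
    drag_range: int = 100_000,
    bands=((0, 10_000), (10_000, 50_000), (50_000, 100_000), (100_000, 500_000)),
    chrom: str = "chr1",
    chrom_size: int = 10_000_000,
) -> pd.DataFrame:
    """Contacts with a downstream drag factor inside ``drag_range``.

    Distances are drawn uniformly within each band (bands equally
    likely); within ``drag_range`` the anchor falls downstream of the
    transcription site with probability drag/(drag+1), otherwise 50/50.
    Transcript strands alternate so unoriented analysis cancels.
    """
    rng = np.random.default_rng(seed)
    rows = []
    margin = max(hi for _, hi in bands)
    for i in range(n_contacts):
        strand = "+" if i % 2 == 0 else "-"
        src = int(rng.integers(margin, chrom_size - margin))
        lo, hi = bands[int(rng.integers(len(bands)))]
        d = int(rng.integers(max(lo, 1), hi))
        p_down = drag / (drag + 1.0) if d < drag_range else 0.5
        downstream = rng.random() < p_down
        sign = 1 if downstream else -1
        if strand == "-":
            sign = -sign
        rows.append(_full_contact_row(f"a{i:06d}", chrom, strand, src, src,
                                      chrom, src + sign * d))
    return pd.DataFrame(rows)


def scaling_library(
    seed: int,
    n_pairs: int = 200_000,
    exponent: float = -1.0,
    min_sep: int = 200_000,
    max_sep: int = 10_000_000,
    chrom_sizes: Optional[Dict[str, int]] = None,
    trans_fraction: float = 0.05,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Position pairs with a planted power-law cis decay.

    Cis separations follow density proportional to s**exponent between
    ``min_sep`` and ``max_sep``; sources sit in the chromosome interior
    so both directions stay in bounds and the bin-pair count is constant
    over the planted range.
    """
    rng = np.random.default_rng(seed)
    if chrom_sizes is None:
        chrom_sizes = {"chrA": 30_000_000, "chrB": 20_000_000}
    n_trans = int(n_pairs * trans_fraction)
    n_cis = n_pairs - n_trans
    src = rng.integers(max_sep + 500_000, chrom_sizes["chrA"] - max_sep - 500_000,
                       size=n_cis)
    u = rng.random(n_cis)
    if exponent == -1.0:
        sep = (min_sep * np.exp(u * np.log(max_sep / min_sep))).astype(np.int64)
    else:
        a = exponent + 1.0
        sep = ((min_sep ** a + u * (max_sep ** a - min_sep ** a)) ** (1 / a)).astype(np.int64)
    sign = rng.choice([-1, 1], size=n_cis)
    cis = pd.DataFrame({
        "chrom1": "chrA", "pos1": src,
        "chrom2": "chrA", "pos2": src + sign * sep,
    })
    # trans sources stay in the same interior band so every occupied source
    # bin sees both directions over the whole planted range (flat bin-pair
    # counts; no edge correction enters the fitted slope)
    trans = pd.DataFrame({
        "chrom1": "chrA",
        "pos1": rng.integers(max_sep + 500_000,
                             chrom_sizes["chrA"] - max_sep - 500_000, size=n_trans),
        "chrom2": "chrB",
        "pos2": rng.integers(0, chrom_sizes["chrB"], size=n_trans),
    })
    return pd.concat([cis, trans], ignore_index=True), dict(chrom_sizes)
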