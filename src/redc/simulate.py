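"""Synthetic proximity-ligation libraries with known ground truth.

Generates toy genomes, gene annotations, chromatin-state tracks and raw
chimeric read pairs whose true DNA/RNA parts, source genes and contact
anchors are recorded, so the whole pipeline is testable without any
external data.  The defaults encode the experimental geometry: DNA parts
of 18-20 nt (the type-IIS trimming enzyme cuts predominantly 20 and 21 bp
from its site at roughly a 60/40 ratio, shifted by 1 bp by the bridge
position, with a few percent at 19), a 37-nt bridge, GGG template-switch
prefix, and read-through into adapter sequence on both mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .chimera import ReadPair
from .genes import elements_in_transcription_order, gene_frame
from .oligos import DEFAULT_CATALOG, STO_READTHROUGH, OligoCatalog, revcomp
from .tracks import (
    ChromatinStateTrack,
    GenomeSequence,
    find_motif,
    mmei_zones,
    nlaiii_zones,
    positions_in_zones,
)

DEFAULT_CHROM_SIZES = {"chr1": 1_500_000, "chr2": 1_200_000, "chr3": 1_000_000}


@dataclass
class TruthModel:
    """Parameters and ground truth of one simulated library."""

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_SIZES))
    n_genes: int = 20
    n_contacts: int = 1000
    read_length: int = 100
    # cut-length pattern of the DNA part after the 1-bp bridge shift
    dna_length_weights: Dict[int, float] = field(
        default_factory=lambda: {18: 0.05, 19: 0.40, 20: 0.55})
    rna_frag_len: Tuple[int, int] = (20, 40)
    spliced_fraction: float = 0.1
    template_switch_fraction: float = 0.0
    duplicate_rate: float = 0.0
    error_rate: float = 0.0
    rnase_mode: bool = False
    ligase_minus: bool = False

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_genome(seed: int, sizes: Mapping[str, int]) -> GenomeSequence:
    """I.i.d. uniform ACGT sequence per chromosome, deterministic under seed."""
    rng = np.random.default_rng(seed)
    seqs = {}
    for chrom, size in sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome size must be positive ({chrom})")
        codes = rng.integers(0, 4, size=size, dtype=np.uint8)
        seqs[chrom] = codes.tobytes().translate(bytes.maketrans(
            bytes([0, 1, 2, 3]), b"ACGT")).decode()
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome.keys():
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def simulate_annotation(
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
    n_genes: int = 20,
    exon_count_range: Tuple[int, int] = (2, 6),
    exon_len_range: Tuple[int, int] = (200, 1500),
    intron_len_range: Tuple[int, int] = (500, 4000),
    noncoding_fraction: float = 0.2,
    state_repeat_fraction: float = 0.05,
    state_gap_fraction: float = 0.02,
    state_segment_range: Tuple[int, int] = (2_000, 20_000),
) -> Tuple[pd.DataFrame, ChromatinStateTrack]:
    """Non-overlapping multi-exon genes plus a 15-state chromatin tiling.

    States 1-13 tile most of each chromosome; ``state_repeat_fraction``
    goes to repetitive/CNV states 14-15 and ``state_gap_fraction`` stays
    unannotated, so masked-denominator logic is exercised.
    """
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    attempts = 0
    while len(rows) < n_genes and attempts < n_genes * 200:
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=sizes / sizes.sum())]
        m = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        exon_lens = rng.integers(*exon_len_range, size=m)
        intron_lens = rng.integers(*intron_len_range, size=m - 1)
        length = int(exon_lens.sum() + intron_lens.sum())
        margin = 1000
        if chrom_sizes[chrom] < length + 2 * margin:
            continue
        start = int(rng.integers(margin, chrom_sizes[chrom] - length - margin))
        end = start + length
        if any(a < end + 500 and start < b + 500 for a, b in placed[chrom]):
            continue
        exons = []
        pos = start
        for i in range(m):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < m - 1:
                pos += int(intron_lens[i])
        placed[chrom].append((start, end))
        i = len(rows)
        coding = rng.random() >= noncoding_fraction
        rows.append({
            "gene_id": f"gene{i:03d}",
            "name": f"G{i:03d}",
            "biotype": "protein_coding" if coding else "lincRNA",
            "chrom": chrom,
            "strand": "+" if rng.random() < 0.5 else "-",
            "start": start,
            "end": end,
            "exons": exons,
        })
    if len(rows) < n_genes:
        raise RuntimeError("could not place requested genes (infeasible packing)")
    genes = gene_frame(rows)

    state_weights = np.ones(15)
    state_weights[13:] = 15 * state_repeat_fraction / 2 / (1 - state_repeat_fraction)
    state_weights /= state_weights.sum()
    srows = []
    for chrom, size in chrom_sizes.items():
        pos = 0
        while pos < size:
            seg = int(rng.integers(*state_segment_range))
            end = min(pos + seg, size)
            if rng.random() < state_gap_fraction:
                pos = end  # unannotated gap
                continue
            state = int(rng.choice(15, p=state_weights)) + 1
            srows.append((chrom, pos, end, state))
            pos = end
    states = ChromatinStateTrack.from_frame(
        pd.DataFrame(srows, columns=["chrom", "start", "end", "state"]))
    return genes, states


# ---------------------------------------------------------------------------
# Sequence-level contact simulation

CONTACT_TRUTH_COLUMNS = [
    "read_id", "rna_id", "rna_chrom", "transcript_strand",
    "rna5_end", "rna3_end", "rna_blocks", "rna3_frag", "rna5_frag",
    "dna_chrom", "dna_start", "dna_end", "dna_strand", "dna_seq",
    "template_switch", "duplicate_of",
]


def _sample_dna_anchor(truth, genome, states, catg, rng):
    """Random 18-20 nt DNA part ending at a genomic CATG, in states 1-13."""
    chroms = list(truth.chrom_sizes)
    lengths = np.array(list(truth.dna_length_weights))
    probs = np.array(list(truth.dna_length_weights.values()))
    probs = probs / probs.sum()
    for _ in range(200):
        chrom = chroms[int(rng.integers(len(chroms)))]
        sites = catg[chrom]
        if sites.size == 0:
            continue
        c = int(sites[int(rng.integers(sites.size))])
        L = int(rng.choice(lengths, p=probs))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[chrom]
        if strand == "+":
            s, e = c - L, c + 4  # supplemented interval; read part is [c-L, c)
            part = seq[c - L:c]
        else:
            s, e = c, c + 4 + L
            part = revcomp(seq[c + 4:c + 4 + L])
        if s < 0 or e > len(seq) or "N" in part:
            continue
        if states is not None:
            st = states.state_at(chrom, np.array([(s + e) // 2]))[0]
            if not (1 <= st <= 13):
                continue
        return chrom, s, e, strand, part
    raise RuntimeError("failed to sample a DNA anchor")


def _sample_rna_fragment(truth, genome, genes, nla, mme, rng, spliced: bool):
    """A contiguous or junction-spanning RNA fragment with clean ends.

    Ends are resampled until neither falls in an NlaIII CATG +/- 1 zone
    and the 5' end avoids MmeI digestion zones, mirroring the population
    of fragments that survive the restriction-site filter.
    """
    for _ in range(300):
        gene = genes.iloc[int(rng.integers(len(genes)))]
        chrom = gene["chrom"]
        if spliced:
            elements = elements_in_transcription_order(gene)
            exons = [(k, i, a, b) for k, i, a, b in elements if k == "exon"]
            if len(exons) < 2:
                continue
            j = int(rng.integers(len(exons) - 1))
            _, _, a1, b1 = exons[j]
            _, _, a2, b2 = exons[j + 1]
            x = int(rng.integers(8, min(20, b1 - a1) + 1))
            y = int(rng.integers(8, min(20, b2 - a2) + 1))
            if gene["strand"] == "+":
                blocks = [(b1 - x, b1), (a2, a2 + y)]
                frag = genome[chrom][b1 - x:b1] + genome[chrom][a2:a2 + y]
                rna5_end, rna3_end = b1 - x, a2 + y - 1
            else:
                # transcription-order exon j sits at higher genomic coords
                frag = revcomp(genome[chrom][a1:a1 + x]) + revcomp(genome[chrom][b2 - y:b2])
                rna5_end, rna3_end = a1 + x - 1, b2 - y
                blocks = sorted([(a1, a1 + x), (b2 - y, b2)])
        else:
            L = int(rng.integers(truth.rna_frag_len[0], truth.rna_frag_len[1] + 1))
            span = int(gene["end"] - gene["start"])
            if span <= L:
                continue
            a = int(gene["start"]) + int(rng.integers(span - L))
            blocks = [(a, a + L)]
            raw = genome[chrom][a:a + L]
            if gene["strand"] == "+":
                frag = raw
                rna5_end, rna3_end = a, a + L - 1
            else:
                frag = revcomp(raw)
                rna5_end, rna3_end = a + L - 1, a
        if "N" in frag:
            continue
        ends = np.array([rna3_end, rna5_end])
        if positions_in_zones(ends, nla[chrom]).any():
            continue
        if positions_in_zones(np.array([rna5_end]), mme[chrom])[0]:
            continue
        return {
            "rna_id": gene["gene_id"], "rna_chrom": chrom,
            "transcript_strand": gene["strand"],
            "rna5_end": rna5_end, "rna3_end": rna3_end,
            "rna_blocks": ",".join(f"{a}-{b}" for a, b in blocks),
            "frag": frag,
        }
    raise RuntimeError("failed to sample an RNA fragment")


def simulate_contacts(
    truth: TruthModel,
    genome: GenomeSequence,
    genes: pd.DataFrame,
    states: Optional[ChromatinStateTrack] = None,
) -> pd.DataFrame:
    """Ground-truth contact table for sequence-level simulation."""
    rng = truth.rng()
    catg = {c: find_motif(genome[c], "CATG") for c in truth.chrom_sizes}
    nla = {c: nlaiii_zones(genome[c]) for c in truth.chrom_sizes}
    mme = {c: mmei_zones(genome[c], "cutsite") for c in truth.chrom_sizes}
    rows = []
    for i in range(truth.n_contacts):
        read_id = f"read{i:06d}"
        if truth.ligase_minus:
            L = 0 if rng.random() < 0.6 else 1
            chrom = list(truth.chrom_sizes)[0]
            pos = int(rng.integers(0, truth.chrom_sizes[chrom] - 2))
            dna = (chrom, pos, pos + L, "+", genome[chrom][pos:pos + L])
        else:
            dna = _sample_dna_anchor(truth, genome, states, catg, rng)
        if truth.rnase_mode:
            L = int(rng.integers(1, 4))
            frag = "".join(rng.choice(["A", "G"], size=L))
            info = {"rna_id": None, "rna_chrom": None, "transcript_strand": "+",
                    "rna5_end": -1, "rna3_end": -1, "rna_blocks": "", "frag": frag}
            frag3 = frag5 = frag
            ts = False
        else:
            ts = rng.random() < truth.template_switch_fraction
            spliced = (not ts) and rng.random() < truth.spliced_fraction
            info = _sample_rna_fragment(truth, genome, genes, nla, mme, rng, spliced)
            frag3 = frag5 = info["frag"]
            if ts:
                # 3' and 5' fragments from unrelated loci (template switching)
                other = _sample_rna_fragment(truth, genome, genes, nla, mme, rng, False)
                tries = 0
                while other["rna_chrom"] == info["rna_chrom"] and tries < 50:
                    other = _sample_rna_fragment(truth, genome, genes, nla, mme, rng, False)
                    tries += 1
                # keep fragments short enough that adapter probes stay visible
                frag3 = info["frag"][:28]
                frag5 = other["frag"][:28]
        rows.append({
            "read_id": read_id, "rna_id": info["rna_id"],
            "rna_chrom": info["rna_chrom"],
            "transcript_strand": info["transcript_strand"],
            "rna5_end": info["rna5_end"], "rna3_end": info["rna3_end"],
            "rna_blocks": info["rna_blocks"],
            "rna3_frag": frag3, "rna5_frag": frag5,
            "dna_chrom": dna[0], "dna_start": dna[1], "dna_end": dna[2],
            "dna_strand": dna[3], "dna_seq": dna[4],
            "template_switch": ts, "duplicate_of": None,
        })
    return pd.DataFrame(rows, columns=CONTACT_TRUTH_COLUMNS)


def render_fastq(
    contacts: pd.DataFrame,
    truth: TruthModel,
    catalog: OligoCatalog = DEFAULT_CATALOG,
) -> Tuple[List[ReadPair], pd.DataFrame]:
    """Raw read pairs plus the expected parser output for each pair.

    R1 = DNA part + bridge + reverse-complemented RNA 3' fragment +
    switch-oligo read-through; R2 = GGG + sense RNA 5' fragment + bridge
    read-through + reverse-complemented DNA part.  Reads are constant
    length at Q37; substitution errors and exact PCR duplicates are
    injected at the configured rates.
    """
    rng = np.random.default_rng(truth.seed + 1)
    rl = truth.read_length
    min_payload = len(catalog.bridge_r1) + 1
    if rl < min_payload:
        raise ValueError("read length shorter than bridge + minimal parts")
    pairs: List[ReadPair] = []
    expected_rows = []
    bases = np.array(list("ACGT"))
    for _, c in contacts.iterrows():
        r1 = c["dna_seq"] + catalog.bridge_r1 + revcomp(c["rna3_frag"]) + STO_READTHROUGH
        r1 = (r1 + "A" * rl)[:rl]
        r2 = (catalog.r2_prefix + c["rna5_frag"] + revcomp(catalog.bridge_r1)
              + revcomp(c["dna_seq"]))
        r2 = (r2 + "A" * rl)[:rl]
        if truth.error_rate > 0:
            r1 = _inject_errors(r1, truth.error_rate, rng, bases)
            r2 = _inject_errors(r2, truth.error_rate, rng, bases)
        pairs.append(ReadPair(c["read_id"], r1, r2, [37] * rl, [37] * rl))
        avail3 = rl - len(c["dna_seq"]) - len(catalog.bridge_r1)
        avail5 = rl - len(catalog.r2_prefix)
        expected_rows.append({
            "read_id": c["read_id"],
            "dna": c["dna_seq"],
            "rna3": revcomp(c["rna3_frag"])[:max(avail3, 0)],
            "rna5": c["rna5_frag"][:avail5],
        })
    if truth.duplicate_rate > 0 and pairs:
        n_dup = int(round(truth.duplicate_rate * len(pairs) / (1 - truth.duplicate_rate)))
        src = rng.integers(0, len(pairs), size=n_dup)
        for j, s in enumerate(src):
            orig = pairs[s]
            pairs.append(ReadPair(f"dup{j:06d}", orig.r1_seq, orig.r2_seq,
                                  orig.r1_qual, orig.r2_qual))
    order = rng.permutation(len(pairs))
    # originals must precede their duplicates for first-seen dedup truth
    order = np.concatenate([order[order < len(contacts)], order[order >= len(contacts)]])
    pairs = [pairs[i] for i in order]
    return pairs, pd.DataFrame(expected_rows).set_index("read_id")


def _inject_errors(seq: str, rate: float, rng: np.random.Generator, bases) -> str:
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        arr[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(arr)


def write_paired_fastq(pairs: List[ReadPair], r1_path: str, r2_path: str) -> None:
    import gzip

    def _open(p):
        return gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "w")

    with _open(r1_path) as f1, _open(r2_path) as f2:
        for p in pairs:
            q1 = "".join(chr(q + 33) for q in p.r1_qual)
            q2 = "".join(chr(q + 33) for q in p.r2_qual)
            f1.write(f"@{p.id}\n{p.r1_seq}\n+\n{q1}\n")
            f2.write(f"@{p.id}\n{p.r2_seq}\n+\n{q2}\n")
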