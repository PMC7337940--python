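"""Assembly and filtering of RNA-DNA contacts from mapped read parts.

A contact is a read whose DNA, RNA-3' and RNA-5' parts all mapped
uniquely to canonical chromosomes and passed, in any order, three pure
per-contact predicates: the RNA-pairing rule (same chromosome, opposite
strands, lower coordinates within 10 kb), the restriction-site rule
(RNA ends away from NlaIII CATG +/- 1 and, for the 5' end, away from
MmeI digestion sites) and the chromatin-retention rule (DNA anchor in
states 1-13).

Coordinates are 0-based half-open throughout.  The single-bp genomic
positions of the RNA molecule's 3' end (bridge-adjoining) and 5' end
(GGG-adjoining) are derived from the mapping strand: each part's first
sequenced base is its relevant end, which sits at the lower coordinate
of the first block for a plus-strand alignment and at ``end - 1`` of the
last block for a minus-strand alignment.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .tracks import (
    ChromatinStateTrack,
    GenomeSequence,
    RETAINED_STATES,
    mmei_zones,
    nlaiii_zones,
    positions_in_zones,
)

PART_COLUMNS = [
    "read_id", "chrom", "start", "end", "strand",
    "n_mismatches", "is_unique", "blocks", "original_length",
]

CONTACT_COLUMNS = [
    "read_id", "rna_chrom", "rna3_start", "rna3_end", "rna3_strand", "rna3_blocks",
    "rna5_chrom", "rna5_start", "rna5_end", "rna5_strand",
    "transcript_strand", "rna3_end_coord", "rna5_end_coord",
    "dna_chrom", "dna_start", "dna_end", "dna_strand", "gene_id", "weight",
]

MAX_PAIR_DISTANCE = 10_000


def parse_blocks(blocks: str, start: int, end: int) -> list[Tuple[int, int]]:
    """Blocks string 's-e,s-e' -> sorted interval list ([start,end) fallback)."""
    if not blocks or blocks in (".", "nan"):
        return [(int(start), int(end))]
    out = []
    for token in str(blocks).split(","):
        a, b = token.split("-")
        out.append((int(a), int(b)))
    return sorted(out)


def format_blocks(blocks: Iterable[Tuple[int, int]]) -> str:
    return ",".join(f"{a}-{b}" for a, b in sorted(blocks))


def sequenced_end_coord(blocks: list[Tuple[int, int]], strand: str) -> int:
    """Genomic position of the part's first sequenced base (splice-aware)."""
    if strand == "+":
        return blocks[0][0]
    return blocks[-1][1] - 1


def filter_mapped_parts(
    parts: pd.DataFrame,
    part_class: str,
    canonical_chroms: Iterable[str],
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """Keep unique, low-mismatch parts of admissible length.

    DNA parts must be 18-20 nt (pre-supplementation length), RNA parts
    >= 14 nt; every part must map uniquely with at most two mismatches to
    a canonical chromosome.
    """
    canonical = set(canonical_chroms)
    keep = (
        parts["is_unique"].astype(bool)
        & (parts["n_mismatches"] <= max_mismatches)
        & parts["chrom"].isin(canonical)
    )
    length = parts["original_length"].astype(int)
    if part_class == "dna":
        keep &= (length >= 18) & (length <= 20)
    elif part_class in ("rna3", "rna5"):
        keep &= length >= 14
    else:
        raise ValueError(f"unknown part class {part_class!r}")
    return parts.loc[keep].reset_index(drop=True)


def assemble_triples(
    dna: pd.DataFrame, rna3: pd.DataFrame, rna5: pd.DataFrame
) -> pd.DataFrame:
    """One candidate contact per read possessing exactly one part of each class.

    Reads with a missing class or with multiple surviving parts of one
    class are discarded.
    """
    frames = {}
    for name, df in (("dna", dna), ("rna3", rna3), ("rna5", rna5)):
        df = df[~df["read_id"].duplicated(keep=False)]
        frames[name] = df.set_index("read_id")
    common = frames["dna"].index.intersection(frames["rna3"].index)
    common = common.intersection(frames["rna5"].index)
    rows = []
    for read_id in common:
        d = frames["dna"].loc[read_id]
        r3 = frames["rna3"].loc[read_id]
        r5 = frames["rna5"].loc[read_id]
        b3 = parse_blocks(r3.get("blocks", ""), r3["start"], r3["end"])
        b5 = parse_blocks(r5.get("blocks", ""), r5["start"], r5["end"])
        rows.append({
            "read_id": read_id,
            "rna_chrom": r3["chrom"],
            "rna3_start": int(r3["start"]), "rna3_end": int(r3["end"]),
            "rna3_strand": r3["strand"], "rna3_blocks": format_blocks(b3),
            "rna5_chrom": r5["chrom"],
            "rna5_start": int(r5["start"]), "rna5_end": int(r5["end"]),
            "rna5_strand": r5["strand"],
            "transcript_strand": r5["strand"],
            "rna3_end_coord": sequenced_end_coord(b3, r3["strand"]),
            "rna5_end_coord": sequenced_end_coord(b5, r5["strand"]),
            "dna_chrom": d["chrom"],
            "dna_start": int(d["start"]), "dna_end": int(d["end"]),
            "dna_strand": d["strand"],
            "gene_id": None,
            "weight": 1.0,
        })
    return pd.DataFrame(rows, columns=CONTACT_COLUMNS)


def pairing_filter(contacts: pd.DataFrame, max_distance: int = MAX_PAIR_DISTANCE) -> pd.DataFrame:
    """Same chromosome, opposite strands, lower coordinates within 10 kb.

    Guards against intermolecular template-switch chimeras; distance is
    measured between the lower mapping coordinates of the two RNA parts.
    """
    if not len(contacts):
        return contacts
    keep = (
        (contacts["rna_chrom"] == contacts["rna5_chrom"])
        & (contacts["rna3_strand"] != contacts["rna5_strand"])
        & ((contacts["rna3_start"] - contacts["rna5_start"]).abs() <= max_distance)
    )
    return contacts.loc[keep].reset_index(drop=True)


def site_filter(
    contacts: pd.DataFrame,
    genome: GenomeSequence,
    mmei_mode: str = "cutsite",
) -> pd.DataFrame:
    """Drop contacts whose RNA ends betray DNA-DNA ligation traces.

    A contact is removed if either RNA end falls within a genomic CATG
    occurrence extended by 1 bp, or if the RNA 5' end falls within an
    MmeI digestion site (see :func:`redc.tracks.mmei_zones`).
    """
    if not len(contacts):
        return contacts
    keep = np.ones(len(contacts), dtype=bool)
    for chrom, idx in contacts.groupby("rna_chrom").groups.items():
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} absent from genome")
        seq = genome[chrom]
        nla = nlaiii_zones(seq)
        mme = mmei_zones(seq, mmei_mode)
        sub = contacts.loc[idx]
        bad = positions_in_zones(sub["rna3_end_coord"].to_numpy(), nla)
        bad |= positions_in_zones(sub["rna5_end_coord"].to_numpy(), nla)
        bad |= positions_in_zones(sub["rna5_end_coord"].to_numpy(), mme)
        keep[contacts.index.get_indexer(idx)] = ~bad
    return contacts.loc[keep].reset_index(drop=True)


def dna_anchor(contacts: pd.DataFrame) -> np.ndarray:
    """Single-bp DNA anchor used for background and state lookups (midpoint)."""
    return ((contacts["dna_start"] + contacts["dna_end"]) // 2).to_numpy(dtype=np.int64)


def chromatin_retention_filter(
    contacts: pd.DataFrame, states: ChromatinStateTrack
) -> pd.DataFrame:
    """Keep contacts whose DNA anchor lies in chromatin states 1-13."""
    if not len(contacts):
        return contacts
    anchors = dna_anchor(contacts)
    keep = np.zeros(len(contacts), dtype=bool)
    for chrom, idx in contacts.groupby("dna_chrom").groups.items():
        loc = contacts.index.get_indexer(idx)
        st = states.state_at(chrom, anchors[loc])
        keep[loc] = np.isin(st, list(RETAINED_STATES))
    return contacts.loc[keep].reset_index(drop=True)


def build_contacts(
    dna: pd.DataFrame,
    rna3: pd.DataFrame,
    rna5: pd.DataFrame,
    genome: Optional[GenomeSequence],
    states: Optional[ChromatinStateTrack],
    canonical_chroms: Optional[Iterable[str]] = None,
    mmei_mode: str = "cutsite",
    max_distance: int = MAX_PAIR_DISTANCE,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Full post-mapping pipeline; returns contacts plus per-step counts."""
    if canonical_chroms is None:
        canonical_chroms = genome.chrom_sizes().keys() if genome is not None else (
            set(dna["chrom"]) | set(rna3["chrom"]) | set(rna5["chrom"]))
    counts: Dict[str, int] = {}
    dna_f = filter_mapped_parts(dna, "dna", canonical_chroms)
    rna3_f = filter_mapped_parts(rna3, "rna3", canonical_chroms)
    rna5_f = filter_mapped_parts(rna5, "rna5", canonical_chroms)
    counts["parts_dna"], counts["parts_rna3"], counts["parts_rna5"] = (
        len(dna_f), len(rna3_f), len(rna5_f))
    contacts = assemble_triples(dna_f, rna3_f, rna5_f)
    counts["triples"] = len(contacts)
    contacts = pairing_filter(contacts, max_distance)
    counts["paired"] = len(contacts)
    if genome is not None:
        contacts = site_filter(contacts, genome, mmei_mode)
    counts["site_clean"] = len(contacts)
    if states is not None:
        contacts = chromatin_retention_filter(contacts, states)
    counts["retained"] = len(contacts)
    return contacts, counts


def read_parts_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"blocks": str}, keep_default_na=False,
                     na_values=[])
    missing = [c for c in PART_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["is_unique"] = df["is_unique"].astype(bool) if df["is_unique"].dtype == bool else (
        df["is_unique"].astype(str).str.lower().isin(["true", "1"]))
    return df


def write_contacts_tsv(contacts: pd.DataFrame, path: str) -> None:
    contacts.to_csv(path, sep="\t", index=False)


def read_contacts_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    df["gene_id"] = df["gene_id"].where(df["gene_id"].notna() & (df["gene_id"] != ""), None)
    return df
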