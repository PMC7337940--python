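"""Demultiplexing of bridge-adapter chimeric read pairs.

Each proximity-ligation read pair encodes three molecules:

* forward read (R1): DNA fragment + 37-nt bridge + reverse-complemented
  RNA 3' fragment (+ switch-oligo read-through when the RNA is short);
* reverse read (R2): GGG + sense RNA 5' fragment (+ bridge read-through
  and reverse-complemented DNA when the RNA is short).

This module turns raw pairs into DNA / RNA-3' / RNA-5' part sequences by
applying, in order: 50-nt-key deduplication, a sliding-window quality
rule, bridge/GGG requirements, adapter read-through trimming, and part
extraction.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .oligos import DEFAULT_CATALOG, OligoCatalog, revcomp

REJECTION_REASONS = ("none", "no_bridge", "no_ggg", "duplicate", "all_low_quality")


@dataclass
class ReadPair:
    """A raw paired-end read with per-base Phred scores."""

    id: str
    r1_seq: str
    r2_seq: str
    r1_qual: Sequence[int]
    r2_qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        if not self.r1_seq or not self.r2_seq:
            raise ValueError(f"read {self.id}: empty mate")


@dataclass
class ChimeraParts:
    """Extracted part sequences of one read pair (lengths may be 0)."""

    read_id: str
    dna_seq: str = ""
    dna_qual: Sequence[int] = ()
    rna3_seq: str = ""
    rna3_qual: Sequence[int] = ()
    rna5_seq: str = ""
    rna5_qual: Sequence[int] = ()
    bridge_pos_r1: Optional[int] = None
    rejection_reason: str = "none"


def deduplicate_pairs(pairs: Iterable[ReadPair], key_len: int = 50) -> Iterator[ReadPair]:
    """Keep the first pair of every group sharing both 50-nt mate prefixes.

    Reads shorter than ``key_len`` contribute their full sequence to the
    key.  Output order follows input order (first-seen wins), which makes
    the operation deterministic and idempotent.
    """
    seen: set[str] = set()
    for pair in pairs:
        key = pair.r1_seq[:key_len] + "\x00" + pair.r2_seq[:key_len]
        if key in seen:
            continue
        seen.add(key)
        yield pair


def first_low_quality_position(
    qual: Sequence[int], window: int = 5, threshold: int = 26
) -> Optional[int]:
    """Start index of the leftmost window with mean quality < threshold.

    Scans left to right with a length-``window`` sliding window; windows
    shorter than ``window`` at the read end are not evaluated, except that
    a read shorter than the window is judged by its full-length mean.
    Returns ``None`` when every window passes.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    q = np.asarray(qual, dtype=float)
    if q.size == 0:
        return 0
    if q.size < window:
        return 0 if q.mean() < threshold else None
    means = np.convolve(q, np.ones(window) / window, mode="valid")
    below = np.nonzero(means < threshold)[0]
    return int(below[0]) if below.size else None


def scan_oligo(
    seq: str,
    pattern: str,
    max_mismatch: int,
    protected_suffix_len: int = 0,
) -> list[tuple[int, int]]:
    """All substitution-only alignments of ``pattern`` within ``seq``.

    Returns ``(start, mismatch_count)`` for every offset where the Hamming
    distance is <= ``max_mismatch`` and the rightmost
    ``protected_suffix_len`` pattern positions match exactly.  N bases
    count as mismatches.  Hits are ordered by start.
    """
    m, n = len(pattern), len(seq)
    if m == 0 or m > n:
        return []
    hits: list[tuple[int, int]] = []
    if max_mismatch == 0:
        start = seq.find(pattern)
        while start != -1:
            hits.append((start, 0))
            start = seq.find(pattern, start + 1)
        return hits
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mismatches = (windows != p).sum(axis=1)
    ok = np.nonzero(mismatches <= max_mismatch)[0]
    if protected_suffix_len > 0:
        suffix = p[m - protected_suffix_len :]
        ok = [i for i in ok if np.array_equal(windows[i, m - protected_suffix_len :], suffix)]
    return [(int(i), int(mismatches[i])) for i in ok]


def rightmost_complementarity_trim(seq: str, source14: str) -> Optional[int]:
    """Cut position removing read-through right of mate complementarity.

    ``source14`` is the 14 nt adjoining the relevant landmark in the mate
    read; its reverse complement marks, inside ``seq``, the end of the
    genuine RNA-derived region.  The rightmost exact occurrence of that
    reverse complement is located and the cut position is the end of the
    occurrence, so the complementary region itself is kept and only the
    residual adapter stub to its right is removed.  ``None`` means no
    occurrence (nothing to trim).
    """
    probe = revcomp(source14)
    pos = seq.rfind(probe)
    if pos == -1:
        return None
    cut = pos + len(probe)
    return cut if cut < len(seq) else None


def _truncate(seq: str, qual: Sequence[int], region_start: int, low_q: Optional[int]) -> tuple[str, Sequence[int]]:
    """Right-truncate an extracted part at the read-level low-quality position."""
    if low_q is None:
        return seq, qual
    keep = max(0, low_q - region_start)
    return seq[:keep], qual[:keep]


def split_read_pair(
    pair: ReadPair,
    catalog: OligoCatalog = DEFAULT_CATALOG,
    max_mismatch: int = 1,
    window: int = 5,
    quality_threshold: int = 26,
) -> ChimeraParts:
    """Extract DNA / RNA-3' / RNA-5' parts from one read pair.

    Order of rules: (0) both mates must have at least one base passing the
    quality window rule; (1) R1 must contain a complete bridge (leftmost
    hit, <= 1 mismatch outside the protected GA); (2) R2 must start with
    GGG; (3) the R1 region right of the bridge is trimmed in front of a
    switch-oligo hit and then by mate complementarity; (4) the R2 region
    after GGG is trimmed in front of a bridge-probe hit and then by mate
    complementarity; (5) parts are emitted with read-level quality
    truncation applied inside each part.  Oligo scanning always runs on
    full-length reads; the quality position only truncates output parts.
    """
    out = ChimeraParts(read_id=pair.id)
    low_q1 = first_low_quality_position(pair.r1_qual, window, quality_threshold)
    low_q2 = first_low_quality_position(pair.r2_qual, window, quality_threshold)
    if low_q1 == 0 or low_q2 == 0:
        out.rejection_reason = "all_low_quality"
        return out

    hits = scan_oligo(
        pair.r1_seq,
        catalog.bridge_r1,
        max_mismatch,
        protected_suffix_len=len(catalog.bridge_r1_protected_suffix),
    )
    if not hits:
        out.rejection_reason = "no_bridge"
        return out
    bpos = hits[0][0]
    out.bridge_pos_r1 = bpos

    if not pair.r2_seq.startswith(catalog.r2_prefix):
        out.rejection_reason = "no_ggg"
        return out

    g = len(catalog.r2_prefix)
    rna3_start = bpos + len(catalog.bridge_r1)
    rna3 = pair.r1_seq[rna3_start:]
    rna3_q = pair.r1_qual[rna3_start:]

    sto_hits = scan_oligo(rna3, catalog.sto_probe, max_mismatch)
    if sto_hits:
        cut = sto_hits[0][0]
        rna3, rna3_q = rna3[:cut], rna3_q[:cut]
    source_r2 = pair.r2_seq[g : g + catalog.probe_len]
    if len(source_r2) == catalog.probe_len:
        cut = rightmost_complementarity_trim(rna3, source_r2)
        if cut is not None:
            rna3, rna3_q = rna3[:cut], rna3_q[:cut]

    rna5 = pair.r2_seq[g:]
    rna5_q = pair.r2_qual[g:]
    probe_hits = scan_oligo(rna5, catalog.bridge_r2_probe, max_mismatch)
    if probe_hits:
        cut = probe_hits[0][0]
        rna5, rna5_q = rna5[:cut], rna5_q[:cut]
    source_r1 = pair.r1_seq[rna3_start : rna3_start + catalog.probe_len]
    if len(source_r1) == catalog.probe_len:
        cut = rightmost_complementarity_trim(rna5, source_r1)
        if cut is not None:
            rna5, rna5_q = rna5[:cut], rna5_q[:cut]

    dna, dna_q = _truncate(pair.r1_seq[:bpos], pair.r1_qual[:bpos], 0, low_q1)
    rna3, rna3_q = _truncate(rna3, rna3_q, rna3_start, low_q1)
    rna5, rna5_q = _truncate(rna5, rna5_q, g, low_q2)

    out.dna_seq, out.dna_qual = dna, dna_q
    out.rna3_seq, out.rna3_qual = rna3, rna3_q
    out.rna5_seq, out.rna5_qual = rna5, rna5_q
    return out


def prepare_dna_for_mapping(dna_seq: str) -> Optional[str]:
    """Supplement the bridge-adjoining end of a DNA part with CATG.

    The restriction overhang removed during end repair is restored
    computationally to lengthen the mapped sequence.  Returns ``None``
    for empty input (such records are never written).
    """
    if not dna_seq:
        return None
    return dna_seq + "CATG"


# ---------------------------------------------------------------------------
# FASTQ plumbing


def read_pairs_from_fastq(r1_path: str, r2_path: str) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    import pysam

    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for rec1, rec2 in zip(f1, f2):
            if rec1.name != rec2.name:
                raise ValueError(f"mate name mismatch at record {rec1.name} / {rec2.name}")
            if rec1.quality is None or rec2.quality is None:
                raise ValueError(f"record {rec1.name}: missing quality string")
            yield ReadPair(
                id=rec1.name,
                r1_seq=rec1.sequence.upper(),
                r2_seq=rec2.sequence.upper(),
                r1_qual=rec1.get_quality_array(),
                r2_qual=rec2.get_quality_array(),
            )


def _open_out(path: str):
    return gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")


def write_part_fastqs(
    parts: Iterable[ChimeraParts],
    dna_path: str,
    rna3_path: str,
    rna5_path: str,
    rejection_log: Optional[str] = None,
    supplement_dna: bool = True,
) -> dict:
    """Write part FASTQ files plus a TSV rejection log.

    A read contributes a record to a part file only when that part has
    non-zero length; the DNA part is CATG-supplemented on output (the
    appended bases receive the part's maximum quality, or Q37 for reads
    without bases).  Returns summary counts.
    """
    counts = {"pairs": 0, "accepted": 0}
    rejected: list[tuple[str, str]] = []
    with _open_out(dna_path) as fd, _open_out(rna3_path) as f3, _open_out(rna5_path) as f5:
        for part in parts:
            counts["pairs"] += 1
            if part.rejection_reason != "none":
                rejected.append((part.read_id, part.rejection_reason))
                continue
            counts["accepted"] += 1
            if part.dna_seq:
                seq = prepare_dna_for_mapping(part.dna_seq) if supplement_dna else part.dna_seq
                qual = list(part.dna_qual)
                if supplement_dna:
                    qual = qual + [max(qual) if qual else 37] * 4
                _write_fastq_record(fd, part.read_id, seq, qual)
            if part.rna3_seq:
                _write_fastq_record(f3, part.read_id, part.rna3_seq, part.rna3_qual)
            if part.rna5_seq:
                _write_fastq_record(f5, part.read_id, part.rna5_seq, part.rna5_qual)
    if rejection_log is not None:
        with open(rejection_log, "w") as fh:
            fh.write("read_id\treason\n")
            for read_id, reason in rejected:
                fh.write(f"{read_id}\t{reason}\n")
    counts["rejected"] = len(rejected)
    return counts


def _write_fastq_record(fh, name: str, seq: str, qual: Sequence[int]) -> None:
    fh.write(f"@{name}\n{seq}\n+\n{''.join(chr(q + 33) for q in qual)}\n")


def parse_library(
    pairs: Iterable[ReadPair],
    catalog: OligoCatalog = DEFAULT_CATALOG,
    max_mismatch: int = 1,
    window: int = 5,
    quality_threshold: int = 26,
) -> Iterator[ChimeraParts]:
    """Deduplicate and split a whole library (duplicates are not emitted)."""
    for pair in deduplicate_pairs(pairs):
        yield split_read_pair(
            pair,
            catalog,
            max_mismatch=max_mismatch,
            window=window,
            quality_threshold=quality_threshold,
        )
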