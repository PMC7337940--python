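"""Genome-anchored annotation tracks: chromatin states and genome sequence.

Chromatin states follow the 15-state segmentation vocabulary: promoters
(1-3), enhancers (4-7), insulator (8), transcribed (9-11), repressed
(12-13) and repetitive/CNV (14-15).  States 14/15 and unannotated gaps
are excluded from all frequency denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

ACTIVE_STATES = frozenset({1, 2, 4, 5, 6, 7, 9, 10, 11})
POLYCOMB_STATES = frozenset({3, 12})
REPRESSED_STATES = frozenset({3, 12, 13})
ENHANCER_STATES = frozenset({4, 5, 6, 7})
RETAINED_STATES = frozenset(range(1, 14))
STATE_COMBOS: Dict[str, frozenset] = {
    "active": ACTIVE_STATES,
    "polycomb": POLYCOMB_STATES,
    "repressed": REPRESSED_STATES,
}


@dataclass
class ChromatinStateTrack:
    """Sorted, non-overlapping state intervals per chromosome."""

    starts: Dict[str, np.ndarray] = field(default_factory=dict)
    ends: Dict[str, np.ndarray] = field(default_factory=dict)
    states: Dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChromatinStateTrack":
        """Build from a BED-like frame with columns chrom/start/end/state."""
        track = cls()
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping state intervals on {chrom}")
            states = sub["state"].to_numpy(dtype=np.int64)
            if states.min() < 1 or states.max() > 15:
                raise ValueError("states must be in 1..15")
            track.starts[chrom] = starts
            track.ends[chrom] = ends
            track.states[chrom] = states
        return track

    @classmethod
    def read_bed(cls, path: str) -> "ChromatinStateTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "state"], comment="#",
        )
        return cls.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.starts):
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "start": self.starts[chrom],
                "end": self.ends[chrom],
                "state": self.states[chrom],
            }))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "start", "end", "state"])

    def state_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """State covering each position; 0 for unannotated or unknown chrom."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(positions.shape, dtype=np.int64)
        if chrom not in self.starts:
            return out
        starts, ends, states = self.starts[chrom], self.ends[chrom], self.states[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = idx >= 0
        inside = np.zeros_like(valid)
        inside[valid] = positions[valid] < ends[idx[valid]]
        out[inside] = states[idx[inside]]
        return out

    def intervals_of(
        self, chrom: str, wanted: Iterable[int], start: int = 0, end: Optional[int] = None
    ) -> list[Tuple[int, int, int]]:
        """(start, end, state) intervals of the wanted states clipped to a window."""
        if chrom not in self.starts:
            return []
        wanted = set(wanted)
        s, e, st = self.starts[chrom], self.ends[chrom], self.states[chrom]
        out = []
        for a, b, x in zip(s, e, st):
            if end is not None and a >= end:
                break
            if b <= start or int(x) not in wanted:
                continue
            out.append((max(int(a), start), min(int(b), end) if end is not None else int(b), int(x)))
        return out

    def masked_length(self, chrom: str, start: int, end: int) -> int:
        """Length of [start, end) covered by states 14/15 or unannotated."""
        retained = sum(b - a for a, b, _ in self.intervals_of(chrom, RETAINED_STATES, start, end))
        return (end - start) - retained

    def effective_length(self, chrom: str, start: int, end: int) -> int:
        """Length of [start, end) covered by analysable states (1-13)."""
        return (end - start) - self.masked_length(chrom, start, end)


def effective_region_length(
    states: Optional[ChromatinStateTrack], regions: Sequence[Tuple[str, int, int]]
) -> int:
    """Total analysable length of a set of regions (full length if no track)."""
    total = 0
    for chrom, start, end in regions:
        if end <= start:
            continue
        if states is None:
            total += end - start
        else:
            total += states.effective_length(chrom, start, end)
    return total


# ---------------------------------------------------------------------------
# Genome sequence and restriction-site zones


class GenomeSequence:
    """Chromosome name -> upper-case nucleotide string.

    Wraps either an in-memory dict (as produced by the simulator) or a
    FASTA file opened through pyfaidx.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {c: s.upper() for c, s in seqs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeSequence":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __getitem__(self, chrom: str) -> str:
        return self._seqs[chrom]

    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def keys(self):
        return self._seqs.keys()


def find_motif(seq: str, motif: str) -> np.ndarray:
    """Start positions of all (possibly overlapping) motif occurrences.

    IUPAC code R (A/G) is supported; other letters match literally.
    """
    expansions = [""]
    for base in motif:
        alts = "AG" if base == "R" else base
        expansions = [p + a for p in expansions for a in alts]
    hits: list[int] = []
    for pat in expansions:
        start = seq.find(pat)
        while start != -1:
            hits.append(start)
            start = seq.find(pat, start + 1)
    return np.array(sorted(set(hits)), dtype=np.int64)


def merge_zones(zones: np.ndarray) -> np.ndarray:
    """Merge an (n, 2) array of [start, end) zones into disjoint zones."""
    if zones.size == 0:
        return zones.reshape(0, 2)
    zones = zones[np.argsort(zones[:, 0])]
    merged = [list(zones[0])]
    for a, b in zones[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.array(merged, dtype=np.int64)


def positions_in_zones(positions: np.ndarray, zones: np.ndarray) -> np.ndarray:
    """Boolean mask: does each position fall inside any [start, end) zone?"""
    positions = np.asarray(positions, dtype=np.int64)
    if zones.size == 0:
        return np.zeros(positions.shape, dtype=bool)
    idx = np.searchsorted(zones[:, 0], positions, side="right") - 1
    ok = idx >= 0
    out = np.zeros(positions.shape, dtype=bool)
    out[ok] = positions[ok] < zones[idx[ok], 1]
    return out


def nlaiii_zones(seq: str) -> np.ndarray:
    """Forbidden zones around NlaIII sites: every CATG extended by 1 bp."""
    starts = find_motif(seq, "CATG")
    if starts.size == 0:
        return np.zeros((0, 2), dtype=np.int64)
    zones = np.stack([np.maximum(starts - 1, 0), starts + 5], axis=1)
    return merge_zones(zones)


def mmei_zones(seq: str, mode: str = "cutsite") -> np.ndarray:
    """Forbidden zones around MmeI sites (recognition TCCRAC).

    ``cutsite`` marks positions 17-22 bp downstream of the recognition
    sequence in the enzyme's cutting direction (both strands);
    ``recognition`` marks the recognition sequence itself +/- 1 bp.
    """
    n = len(seq)
    fwd = find_motif(seq, "TCCRAC")
    # reverse-strand recognition: revcomp(TCCRAC) = GTYGGA with Y = C/T
    rev_hits: list[int] = []
    for pat in ("GTCGGA", "GTTGGA"):
        start = seq.find(pat)
        while start != -1:
            rev_hits.append(start)
            start = seq.find(pat, start + 1)
    rev = np.array(sorted(set(rev_hits)), dtype=np.int64)
    zones = []
    if mode == "cutsite":
        for s in fwd:
            zones.append((s + 6 + 17, s + 6 + 23))
        for s in rev:
            zones.append((s - 23, s - 17))
    elif mode == "recognition":
        for s in np.concatenate([fwd, rev]) if (fwd.size or rev.size) else []:
            zones.append((s - 1, s + 7))
    else:
        raise ValueError(f"unknown MmeI mode {mode!r}")
    if not zones:
        return np.zeros((0, 2), dtype=np.int64)
    arr = np.array(zones, dtype=np.int64)
    arr[:, 0] = np.clip(arr[:, 0], 0, n)
    arr[:, 1] = np.clip(arr[:, 1], 0, n)
    return merge_zones(arr[arr[:, 1] > arr[:, 0]])


def read_chrom_sizes(path: str) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))
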