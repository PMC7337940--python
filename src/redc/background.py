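"""Trans-chromosomal ligation background, normalization and enrichment.

The background of non-specific ligation at a locus is estimated from the
contacts that protein-coding mRNAs encoded on *other* chromosomes make
with that locus.  Raw per-contact counts are divided by the smoothed
background value at the DNA anchor and rescaled so the library's total
normalized weight equals its raw contact count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .contacts import dna_anchor
from .tracks import ChromatinStateTrack, STATE_COMBOS, effective_region_length

DEFAULT_BIN_SIZE = 500
DEFAULT_SIGMA_BINS = 10.0


def _bin_counts(
    chroms: Sequence[str],
    positions: np.ndarray,
    weights: Optional[np.ndarray],
    chrom_sizes: Mapping[str, int],
    bin_size: int,
) -> Dict[str, np.ndarray]:
    values = {
        c: np.zeros(int(np.ceil(size / bin_size)), dtype=float)
        for c, size in chrom_sizes.items()
    }
    df = pd.DataFrame({"chrom": chroms, "bin": np.asarray(positions) // bin_size})
    df["w"] = 1.0 if weights is None else np.asarray(weights, dtype=float)
    for chrom, sub in df.groupby("chrom"):
        if chrom not in values:
            continue
        arr = values[chrom]
        binned = sub.groupby("bin")["w"].sum()
        idx = binned.index.to_numpy(dtype=np.int64)
        ok = (idx >= 0) & (idx < arr.size)
        arr[idx[ok]] += binned.to_numpy()[ok]
    return values


@dataclass
class BackgroundTrack:
    """Smoothed per-bin trans-mRNA contact density."""

    bin_size: int
    values: Dict[str, np.ndarray]
    sigma: float

    def value_at(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(len(positions), dtype=float)
        bins = positions // self.bin_size
        for i, (c, b) in enumerate(zip(chroms, bins)):
            vec = self.values.get(c)
            if vec is not None and 0 <= b < vec.size:
                out[i] = vec[b]
        return out

    def min_nonzero(self) -> float:
        vals = np.concatenate([v[v > 0] for v in self.values.values() if np.any(v > 0)]
                              or [np.array([])])
        if vals.size == 0:
            raise ValueError("background is identically zero")
        return float(vals.min())

    def to_bedgraph(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                vec = self.values[chrom]
                for i, v in enumerate(vec):
                    if v != 0:
                        fh.write(f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{v:.6g}\n")


def trans_protein_coding_mask(contacts: pd.DataFrame, genes: pd.DataFrame) -> np.ndarray:
    """Contacts of protein-coding RNAs whose source gene lies on another chromosome."""
    info = genes.set_index("gene_id")
    gene_ids = contacts["gene_id"]
    assigned = gene_ids.notna().to_numpy()
    biotype = np.array([
        info.at[g, "biotype"] if a else "" for g, a in zip(gene_ids, assigned)
    ])
    src_chrom = np.array([
        info.at[g, "chrom"] if a else "" for g, a in zip(gene_ids, assigned)
    ])
    return assigned & (biotype == "protein_coding") & (
        src_chrom != contacts["dna_chrom"].to_numpy())


def build_background(
    contacts: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
    sigma: float = DEFAULT_SIGMA_BINS,
) -> BackgroundTrack:
    """Per-bin counts of trans protein-coding contacts, Gaussian-smoothed.

    ``sigma`` is expressed in bins.  Smoothing is applied per chromosome
    with reflecting boundaries and rescaled to preserve total mass.
    """
    mask = trans_protein_coding_mask(contacts, genes)
    sub = contacts.loc[mask]
    values = _bin_counts(
        sub["dna_chrom"].to_numpy(), dna_anchor(sub), None, chrom_sizes, bin_size)
    for chrom, vec in values.items():
        total = vec.sum()
        if total > 0 and sigma > 0:
            sm = gaussian_filter1d(vec, sigma, mode="reflect")
            sm *= total / sm.sum()
            values[chrom] = sm
    return BackgroundTrack(bin_size=bin_size, values=values, sigma=sigma)


def normalize_contacts(contacts: pd.DataFrame, bg: BackgroundTrack) -> pd.DataFrame:
    """Background-normalize contact weights, conserving the raw total.

    weight_i = 1 / (background(anchor_i) + p) with pseudocount p = 10% of
    the minimal non-zero background value, then rescaled so the weights
    sum to the raw contact count.
    """
    out = contacts.copy()
    if not len(out):
        return out
    p = 0.1 * bg.min_nonzero()
    denom = bg.value_at(out["dna_chrom"].tolist(), dna_anchor(out)) + p
    w = 1.0 / denom
    w *= len(out) / w.sum()
    out["weight"] = w
    return out


def contact_frequency(
    anchors: pd.DataFrame,
    region: Tuple[str, int, int] | Sequence[Tuple[str, int, int]],
    states: Optional[ChromatinStateTrack] = None,
    type_filter: Optional[frozenset | set | str] = None,
) -> float:
    """Weighted contacts per analysable bp of a region.

    ``anchors`` is a frame with columns dna_chrom (or chrom), anchor and
    weight.  With ``type_filter`` (a state set or a named combination:
    active / polycomb / repressed) both the numerator and the length are
    restricted to intervals of those states; otherwise the denominator is
    the region length minus masked (state-14/15 or unannotated) segments.
    """
    regions = [region] if isinstance(region, tuple) else list(region)
    chrom_col = "dna_chrom" if "dna_chrom" in anchors.columns else "chrom"
    if isinstance(type_filter, str):
        type_filter = STATE_COMBOS[type_filter]
    total_w = 0.0
    if type_filter is not None:
        if states is None:
            raise ValueError("type_filter requires a chromatin-state track")
        sel_regions = []
        for chrom, start, end in regions:
            sel_regions += [(chrom, a, b) for a, b, _ in
                            states.intervals_of(chrom, type_filter, start, end)]
        length = sum(b - a for _, a, b in sel_regions)
        if length == 0:
            raise ValueError("chromatin type absent from region")
        for chrom, a, b in sel_regions:
            m = (anchors[chrom_col] == chrom) & (anchors["anchor"] >= a) & (anchors["anchor"] < b)
            total_w += anchors.loc[m, "weight"].sum()
        return total_w / length
    length = effective_region_length(states, regions)
    if length == 0:
        raise ValueError("region has zero analysable length")
    for chrom, start, end in regions:
        m = (anchors[chrom_col] == chrom) & (anchors["anchor"] >= start) & (anchors["anchor"] < end)
        sub = anchors.loc[m]
        if states is not None and len(sub):
            st = states.state_at(chrom, sub["anchor"].to_numpy())
            total_w += sub["weight"].to_numpy()[(st >= 1) & (st <= 13)].sum()
        else:
            total_w += sub["weight"].sum()
    return total_w / length


def chromatin_type_enrichment(
    anchors: pd.DataFrame,
    type_combo: frozenset | set | str,
    region: Tuple[str, int, int] | Sequence[Tuple[str, int, int]],
    states: ChromatinStateTrack,
) -> float:
    """Contact frequency at a chromatin type over the region-wide frequency."""
    num = contact_frequency(anchors, region, states, type_filter=type_combo)
    den = contact_frequency(anchors, region, states)
    return num / den


# ---------------------------------------------------------------------------
# Fold-enrichment profiles


@dataclass
class EnrichmentProfile:
    """Per-bin fold enrichment of one RNA over the ligation background.

    ``fold`` holds the masked enrichment values (0 where filtered out);
    ``smoothed`` the final sliding-window smoothed signal; ``retained``
    the surviving-bin mask.
    """

    rna_id: str
    bin_size: int
    fold: Dict[str, np.ndarray] = field(default_factory=dict)
    smoothed: Dict[str, np.ndarray] = field(default_factory=dict)
    retained: Dict[str, np.ndarray] = field(default_factory=dict)

    def to_bedgraph(self, path: str, which: str = "smoothed") -> None:
        data = getattr(self, which)
        with open(path, "w") as fh:
            for chrom in sorted(data):
                for i, v in enumerate(data[chrom]):
                    if v != 0:
                        fh.write(f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{v:.6g}\n")


def _moving_average(vec: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average (left-biased window, truncated at ends)."""
    out = np.empty_like(vec, dtype=float)
    half_l = width // 2
    half_r = width - half_l - 1
    cums = np.concatenate([[0.0], np.cumsum(vec)])
    n = vec.size
    for i in range(n):
        a = max(0, i - half_l)
        b = min(n, i + half_r + 1)
        out[i] = (cums[b] - cums[a]) / (b - a)
    return out


def fold_enrichment_profile(
    rna_anchors: pd.DataFrame,
    contacts: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    bin_size: int = 100_000,
    rna_id: str = "rna",
    min_fold: float = 2.0,
    support_window: int = 11,
    support_min: int = 3,
    smooth_width: int = 10,
) -> EnrichmentProfile:
    """Robust per-bin enrichment of one RNA over the trans-mRNA background.

    Background: raw trans protein-coding contact counts per bin, divided
    by their genome-wide mean and smoothed with a 10-bin moving average.
    Signal: the RNA's raw counts per bin divided by their genome-wide
    mean.  The per-bin ratio is masked below ``min_fold``; a bin must
    additionally have >= ``support_min`` bins with ratio >= ``min_fold``
    inside the centered ``support_window``; the surviving signal is
    finally smoothed with a ``smooth_width``-bin sliding mean.
    """
    profile = EnrichmentProfile(rna_id=rna_id, bin_size=bin_size)
    if not len(rna_anchors):
        return profile
    mask = trans_protein_coding_mask(contacts, genes)
    bg_sub = contacts.loc[mask]
    bg = _bin_counts(bg_sub["dna_chrom"].to_numpy(), dna_anchor(bg_sub), None,
                     chrom_sizes, bin_size)
    chrom_col = "dna_chrom" if "dna_chrom" in rna_anchors.columns else "chrom"
    sig = _bin_counts(rna_anchors[chrom_col].to_numpy(),
                      rna_anchors["anchor"].to_numpy(),
                      None, chrom_sizes, bin_size)
    bg_mean = np.concatenate(list(bg.values())).mean()
    sig_mean = np.concatenate(list(sig.values())).mean()
    if bg_mean == 0 or sig_mean == 0:
        return profile
    for chrom in chrom_sizes:
        bg_norm = _moving_average(bg[chrom] / bg_mean, smooth_width)
        sig_norm = sig[chrom] / sig_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(bg_norm > 0, sig_norm / bg_norm, 0.0)
        enriched = ratio >= min_fold
        support = np.convolve(enriched.astype(float), np.ones(support_window), mode="same")
        retained = enriched & (support >= support_min)
        fold = np.where(retained, ratio, 0.0)
        profile.fold[chrom] = fold
        profile.retained[chrom] = retained
        profile.smoothed[chrom] = _moving_average(fold, smooth_width)
    return profile
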