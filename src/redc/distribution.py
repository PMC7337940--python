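"""Ranking of RNAs by preference for short- versus long-range contacts.

For every RNA the parental chromosome is partitioned, relative to its
gene, into gene body (G), 0-50 kb flanks (S), 50-500 kb (M), their union
SM, 500 kb-5 Mb (L) and >5 Mb (R); all other chromosomes form T.  The
ratios SM/L, L/R and R/T of average contact frequencies, z-transformed
within contact-count strata and split into five equal-count quantiles,
define three canonical distribution groups:

* A - enriched within +/-5 Mb of the gene (SM/L in Q1, L/R and R/T in Q5);
* B - spread over the parental chromosome, XIST-like (SM/L, L/R in Q1,
  R/T in Q5);
* C - distributed throughout the genome (all three ratios in Q1).

Quantile 1 holds the lowest ratio values: a ratio near 1 means the two
intervals are contacted equally densely, so the more genome-uniform an
RNA is, the lower it ranks on each ratio.
"""

from __future__ import annotations

import warnings
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .tracks import ChromatinStateTrack, effective_region_length

S_FLANK = 50_000
M_FLANK = 500_000
L_FLANK = 5_000_000

STRATA = ((500, 1500), (1500, 10_000), (10_000, np.inf))

Region = Tuple[str, int, int]


def partition_gene_intervals(
    gene: Mapping, chrom_sizes: Mapping[str, int]
) -> Dict[str, list[Region]]:
    """Disjoint distance-banded regions around one gene, clipped to bounds."""
    chrom, start, end = gene["chrom"], int(gene["start"]), int(gene["end"])
    size = chrom_sizes[chrom]

    def clip(a: int, b: int) -> Optional[Region]:
        a, b = max(a, 0), min(b, size)
        return (chrom, a, b) if b > a else None

    def band(inner: int, outer: int) -> list[Region]:
        parts = [clip(start - outer, start - inner), clip(end + inner, end + outer)]
        return [p for p in parts if p]

    schema: Dict[str, list[Region]] = {
        "G": [r for r in [clip(start, end)] if r],
        "S": band(0, S_FLANK),
        "M": band(S_FLANK, M_FLANK),
        "L": band(M_FLANK, L_FLANK),
        "R": [r for r in [clip(0, start - L_FLANK), clip(end + L_FLANK, size)] if r],
        "T": [(c, 0, s) for c, s in chrom_sizes.items() if c != chrom],
    }
    schema["SM"] = schema["S"] + schema["M"]
    return schema


def interval_frequencies(
    anchors: pd.DataFrame,
    schema: Dict[str, list[Region]],
    states: Optional[ChromatinStateTrack] = None,
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Average contact frequency and raw contact count per schema interval.

    Frequency = sum of weights of anchors inside the interval divided by
    its analysable length (masked chromatin subtracted).  Intervals with
    zero analysable length get frequency NaN, which excludes the RNA
    downstream.
    """
    chrom_col = "dna_chrom" if "dna_chrom" in anchors.columns else "chrom"
    freqs: Dict[str, float] = {}
    sums: Dict[str, float] = {}
    chroms = anchors[chrom_col].to_numpy()
    pos = anchors["anchor"].to_numpy()
    w = anchors["weight"].to_numpy(dtype=float)
    counts: Dict[str, float] = {}
    for label, regions in schema.items():
        total = 0.0
        n_raw = 0
        for chrom, a, b in regions:
            m = (chroms == chrom) & (pos >= a) & (pos < b)
            total += w[m].sum()
            n_raw += int(m.sum())
        length = effective_region_length(states, regions)
        sums[label] = total
        counts[label] = n_raw
        freqs[label] = total / length if length > 0 else np.nan
    return freqs, counts


def _safe_ratio(num: float, den: float, floor: float) -> float:
    num = num if num > 0 else floor
    den = den if den > 0 else floor
    return num / den


def distribution_table(
    profiles: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    states: Optional[ChromatinStateTrack] = None,
) -> pd.DataFrame:
    """Per-RNA interval frequencies and ratios for all gene-encoded RNAs.

    ``profiles`` is the long (rna_id, dna_chrom, anchor, weight) table;
    only rna_ids present in ``genes`` are processed.
    """
    rows = []
    gene_index = genes.set_index("gene_id")
    for rna_id, sub in profiles.groupby("rna_id"):
        if rna_id not in gene_index.index:
            continue
        gene = gene_index.loc[rna_id]
        schema = partition_gene_intervals(gene, chrom_sizes)
        freqs, counts = interval_frequencies(sub, schema, states)
        rows.append({
            "rna_id": rna_id,
            "biotype": gene["biotype"],
            "n_contacts": len(sub),
            **{f"f_{k}": freqs[k] for k in ("G", "S", "M", "SM", "L", "R", "T")},
            **{f"n_{k}": counts[k] for k in ("SM", "L", "R", "T")},
        })
    return pd.DataFrame(rows)


def classify_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Select, stratify, z-transform, quantile and group a ratio table.

    Eligibility: >= 500 contacts in total and >= 1 contact in each of L,
    R and T, with finite frequencies.  Each ratio is log-transformed and
    z-scored within contact-count strata (500-1500, 1500-10000, >10000),
    the strata pooled, and the pooled scores split into five equal-count
    quantiles (1 = lowest).  Strata with fewer than 5 RNAs are refused
    with a warning.  Zero frequencies surviving eligibility are replaced
    by half the RNA's minimal positive frequency.
    """
    df = table.copy()
    eligible = (
        (df["n_contacts"] >= 500)
        & (df["n_L"] >= 1) & (df["n_R"] >= 1) & (df["n_T"] >= 1)
        & df[["f_SM", "f_L", "f_R", "f_T"]].notna().all(axis=1)
    )
    df = df.loc[eligible].reset_index(drop=True)
    if not len(df):
        df["group"] = pd.Series(dtype=object)
        return df

    floors = df[["f_SM", "f_L", "f_R", "f_T"]].replace(0, np.nan).min(axis=1) * 0.5
    df["SM/L"] = [_safe_ratio(a, b, f) for a, b, f in zip(df["f_SM"], df["f_L"], floors)]
    df["L/R"] = [_safe_ratio(a, b, f) for a, b, f in zip(df["f_L"], df["f_R"], floors)]
    df["R/T"] = [_safe_ratio(a, b, f) for a, b, f in zip(df["f_R"], df["f_T"], floors)]

    df["stratum"] = pd.cut(
        df["n_contacts"],
        bins=[STRATA[0][0] - 0.5, STRATA[0][1], STRATA[1][1], np.inf],
        labels=["low", "medium", "high"],
    )
    keep = np.ones(len(df), dtype=bool)
    for name, sub in df.groupby("stratum", observed=True):
        if 0 < len(sub) < 5:
            warnings.warn(f"stratum {name}: fewer than 5 RNAs, classification refused")
            keep[df["stratum"] == name] = False
    df = df.loc[keep].reset_index(drop=True)

    for ratio in ("SM/L", "L/R", "R/T"):
        z = np.full(len(df), np.nan)
        logr = np.log(df[ratio].to_numpy(dtype=float))
        for _, idx in df.groupby("stratum", observed=True).groups.items():
            loc = df.index.get_indexer(idx)
            vals = logr[loc]
            sd = vals.std()
            z[loc] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        # pooled equal-count quintiles, ties broken by stable rna_id order
        order = np.lexsort((df["rna_id"].to_numpy(), z))
        ranks = np.empty(len(df), dtype=np.int64)
        ranks[order] = np.arange(len(df))
        df[f"q_{ratio}"] = (ranks * 5 // len(df)) + 1

    q1, q5 = df["q_SM/L"], df["q_L/R"]
    qa = df["q_R/T"]
    group = np.full(len(df), "none", dtype=object)
    group[(q1 == 1) & (q5 == 5) & (qa == 5)] = "A"
    group[(q1 == 1) & (q5 == 1) & (qa == 5)] = "B"
    group[(q1 == 1) & (q5 == 1) & (qa == 1)] = "C"
    df["group"] = group
    return df
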