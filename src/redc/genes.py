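"""Gene models: a flat table of transcriptional units with exon structure.

Genes are held in a pandas DataFrame with one row per gene and columns
``gene_id, name, biotype, chrom, strand, start, end, exons`` where
``exons`` is a coordinate-sorted list of (start, end) half-open tuples
within the gene span.  vlinc and repeat-derived RNA tracks are ordinary
rows with their own biotypes.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

import pandas as pd

BIOTYPES = (
    "protein_coding", "lincRNA", "vlincRNA", "snRNA", "snoRNA",
    "miRNA", "piRNA", "antisense", "other",
)

GENE_COLUMNS = ["gene_id", "name", "biotype", "chrom", "strand", "start", "end", "exons"]


def gene_frame(rows: Iterable[dict]) -> pd.DataFrame:
    """Validate and assemble a gene table."""
    df = pd.DataFrame(list(rows), columns=GENE_COLUMNS)
    if len(df):
        if (df["start"] >= df["end"]).any():
            raise ValueError("gene start must be < end")
        bad = ~df["biotype"].isin(BIOTYPES)
        if bad.any():
            raise ValueError(f"unknown biotypes: {sorted(df.loc[bad, 'biotype'].unique())}")
        for _, g in df.iterrows():
            for (a, b) in g["exons"]:
                if not (g["start"] <= a < b <= g["end"]):
                    raise ValueError(f"exon outside gene span for {g['gene_id']}")
    return df


def introns_of(gene: pd.Series) -> List[Tuple[int, int]]:
    """Intervals between consecutive exons, in genomic order."""
    exons = sorted(gene["exons"])
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]]


def elements_in_transcription_order(gene: pd.Series) -> list[tuple[str, int, int, int]]:
    """Alternating (kind, index, start, end) list: exon 1, intron 1, exon 2, ...

    Index is 1-based in transcription direction (strand-aware).
    """
    exons = sorted(gene["exons"])
    introns = introns_of(gene)
    merged: list[tuple[str, int, int]] = []
    for i, (a, b) in enumerate(exons):
        merged.append(("exon", a, b))
        if i < len(introns):
            merged.append(("intron", introns[i][0], introns[i][1]))
    if gene["strand"] == "-":
        merged = merged[::-1]
    out = []
    counters = {"exon": 0, "intron": 0}
    for kind, a, b in merged:
        counters[kind] += 1
        out.append((kind, counters[kind], a, b))
    return out


def write_gtf(genes: pd.DataFrame, path: str, source: str = "redc_sim") -> None:
    """Write gene/exon features in GTF (1-based, closed) format."""
    with open(path, "w") as fh:
        for _, g in genes.iterrows():
            attrs = (
                f'gene_id "{g["gene_id"]}"; gene_name "{g["name"]}"; '
                f'gene_type "{g["biotype"]}";'
            )
            fh.write(
                f'{g["chrom"]}\t{source}\tgene\t{g["start"] + 1}\t{g["end"]}\t.\t'
                f'{g["strand"]}\t.\t{attrs}\n'
            )
            for a, b in sorted(g["exons"]):
                fh.write(
                    f'{g["chrom"]}\t{source}\texon\t{a + 1}\t{b}\t.\t'
                    f'{g["strand"]}\t.\t{attrs}\n'
                )


def read_gtf(path: str) -> pd.DataFrame:
    """Load gene models from a GTF file via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes.get("gene_id", [None])[0]
        exons_by_gene.setdefault(gid, []).append((exon.start - 1, exon.end))
    rows = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        exons = exons_by_gene.get(gene_id, [])
        biotype = gene.attributes.get("gene_type", ["other"])[0]
        if biotype not in BIOTYPES:
            biotype = "other"
        rows.append({
            "gene_id": gene_id,
            "name": gene.attributes.get("gene_name", [gene_id])[0],
            "biotype": biotype,
            "chrom": gene.seqid,
            "strand": gene.strand,
            "start": gene.start - 1,
            "end": gene.end,
            "exons": sorted(exons) or [(gene.start - 1, gene.end)],
        })
    return gene_frame(rows)
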