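"""Readers for real-genome inputs.

Two entry paths produce :class:`~reggrammar.synth.GeneRecord` lists:
pre-split per-region FASTA files (one file per region, record id = gene
id), or a genome FASTA plus a gene-structure annotation (GFF3, treated
as 1-based closed coordinates, or a TSV of TSS/ORF/TTS boundaries).
All sequences are returned 5'->3' on the coding strand: minus-strand
genes are reverse-complemented and their regions re-ordered
accordingly. Internal coordinates are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .synth import GeneRecord

ALL_REGIONS = ("promoter", "utr5", "cds", "utr3", "terminator")


def read_region_fastas(paths: dict[str, str | Path]) -> list[GeneRecord]:
    """Assemble GeneRecords from per-region FASTA files.

    ``paths`` maps region name (promoter/utr5/cds/utr3/terminator) to a
    FASTA whose record ids are gene ids; only genes present in every
    provided file are returned, in the order of the first file.
    """
    per_region: dict[str, dict[str, str]] = {}
    for region, path in paths.items():
        if region not in ALL_REGIONS:
            raise ValueError(f"unknown region {region!r}")
        per_region[region] = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")
        }
    first = next(iter(per_region.values()))
    shared = [g for g in first
              if all(g in seqs for seqs in per_region.values())]
    return [
        GeneRecord(g, {r: per_region[r][g] for r in per_region}, {})
        for g in shared
    ]


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """TSV gene-structure table.

    Required columns: gene_id, chrom, strand, tss, cds_start, cds_end,
    tts (1-based closed genomic coordinates, as in GFF3).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "strand", "tss", "cds_start",
                "cds_end", "tts"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Minimal GFF3 reader: gene + CDS (or mRNA/five_prime_UTR bounds).

    Returns the same layout as :func:`read_gene_table`, with the TSS/TTS
    taken from the gene feature bounds and the CDS span from the
    outermost CDS features sharing the gene's ID/Parent.
    """
    genes: dict[str, dict] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
        fields = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        if ftype == "gene":
            gid = fields.get("ID", "").split(":")[-1]
            genes[gid] = {"chrom": chrom, "strand": strand,
                          "start": int(start), "end": int(end)}
        elif ftype == "CDS":
            parent = fields.get("Parent", fields.get("ID", "")).split(":")[-1]
            # strip transcript suffixes like _mRNA or .1
            for gid in (parent, parent.rsplit("_", 1)[0],
                        parent.rsplit(".", 1)[0]):
                if gid in genes or not cds:
                    break
            cds.setdefault(gid, []).append((int(start), int(end)))
    rows = []
    for gid, info in genes.items():
        spans = cds.get(gid)
        if not spans:
            continue
        lo = min(s for s, _ in spans)
        hi = max(e for _, e in spans)
        plus = info["strand"] == "+"
        rows.append({
            "gene_id": gid, "chrom": info["chrom"], "strand": info["strand"],
            "tss": info["start"] if plus else info["end"],
            "cds_start": lo, "cds_end": hi,
            "tts": info["end"] if plus else info["start"],
        })
    return pd.DataFrame(rows)


def extract_regions(
    genome_fasta: str | Path,
    annotation: pd.DataFrame,
    promoter_bp: int = 1000,
    terminator_bp: int = 500,
) -> list[GeneRecord]:
    """Slice the five regions for each annotated gene.

    The promoter is the ``promoter_bp`` upstream of the TSS, the 5'UTR
    the TSS-to-CDS interval, the 3'UTR the CDS-to-TTS interval, and the
    terminator ``terminator_bp`` downstream of the TTS. Minus-strand
    genes are reverse-complemented so every region reads 5'->3' on the
    coding strand. Annotation coordinates are 1-based closed.
    """
    chroms = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    out = []
    for row in annotation.itertuples():
        seq = chroms.get(row.chrom)
        if seq is None:
            continue
        L = len(seq)
        plus = row.strand == "+"
        tss, tts = int(row.tss), int(row.tts)
        cs, ce = int(row.cds_start), int(row.cds_end)
        if plus:
            regions = {
                "promoter": seq[max(0, tss - 1 - promoter_bp): tss - 1],
                "utr5": seq[tss - 1: cs - 1],
                "cds": seq[cs - 1: ce],
                "utr3": seq[ce: tts],
                "terminator": seq[tts: min(L, tts + terminator_bp)],
            }
        else:
            rc = lambda s: str(Seq(s).reverse_complement())  # noqa: E731
            regions = {
                "promoter": rc(seq[tss: min(L, tss + promoter_bp)]),
                "utr5": rc(seq[ce: tss]),
                "cds": rc(seq[cs - 1: ce]),
                "utr3": rc(seq[tts - 1: cs - 1]),
                "terminator": rc(seq[max(0, tts - 1 - terminator_bp): tts - 1]),
            }
        out.append(GeneRecord(row.gene_id, regions, {},
                              strand=row.strand))
    return out
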