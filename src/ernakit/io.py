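"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED6 for intervals and contigs, FASTA for sequences, and headered
TSVs for gene models, enhancer–target pairs, expression tables, seed
families and ncRNA family hits.  All coordinates are BED-native (0-based
half-open); read→write round-trips coordinates bit-exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import RnaContig
from .core import Enhancer, GeneModel, GenomicInterval, UNSTRANDED
from .correlation import BpkmTable

__all__ = [
    "read_bed", "write_bed", "read_contigs", "write_contigs",
    "read_fasta", "write_fasta",
    "read_gene_models", "write_gene_models",
    "read_enhancers", "write_enhancers",
    "read_bpkm_table", "write_bpkm_table",
    "read_seed_families", "write_seed_families",
    "read_hits", "read_chrom_sizes",
]


class BedParseError(ValueError):
    """Raised with the offending line number for malformed BED input."""


def _parse_bed_line(line: str, lineno: int, stranded: bool) -> tuple[GenomicInterval, list[str]]:
    fields = line.split()
    if len(fields) < 3:
        raise BedParseError(f"line {lineno}: expected >= 3 columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
    strand = UNSTRANDED
    if stranded:
        if len(fields) < 6:
            raise BedParseError(f"line {lineno}: stranded BED needs >= 6 columns")
        strand = fields[5]
        if strand not in ("+", "-"):
            raise BedParseError(f"line {lineno}: invalid strand {strand!r}")
    try:
        return GenomicInterval(chrom, start, end, strand), fields
    except ValueError as exc:
        raise BedParseError(f"line {lineno}: {exc}") from exc


def read_bed(path: str | Path, stranded: bool = False) -> list[GenomicInterval]:
    """Read BED3 (or BED6 when ``stranded``) into intervals.

    Malformed lines raise :class:`BedParseError` naming the line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            iv, _ = _parse_bed_line(line, lineno, stranded)
            out.append(iv)
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.strand == UNSTRANDED:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_contigs(path: str | Path) -> list[RnaContig]:
    """Read stranded RNA contigs from BED6; column 5 carries the BPKM."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            iv, fields = _parse_bed_line(line, lineno, stranded=True)
            try:
                bpkm = float(fields[4])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-numeric BPKM column") from exc
            out.append(RnaContig(iv, bpkm=bpkm))
    return out


def write_contigs(path: str | Path, contigs: Iterable[RnaContig]) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            iv = c.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tcontig\t{c.bpkm:.6g}\t{iv.strand}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sorted(seqs.items())]
    SeqIO.write(records, str(path), "fasta")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """TSV with header: gene_id, chrom, strand, tx_start, tx_end, cds_end.

    ``cds_end`` empty or ``NA`` marks a noncoding gene.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    genes = []
    for row in df.itertuples(index=False):
        coding_end = None
        if "cds_end" in df.columns and pd.notna(row.cds_end):
            coding_end = int(row.cds_end)
        genes.append(
            GeneModel(
                row.gene_id,
                GenomicInterval(row.chrom, int(row.tx_start), int(row.tx_end), row.strand),
                coding_end,
            )
        )
    return genes


def write_gene_models(path: str | Path, genes: Sequence[GeneModel]) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.interval.start,
                "tx_end": g.interval.end,
                "cds_end": g.coding_end if g.coding_end is not None else "NA",
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_enhancers(path: str | Path) -> list[Enhancer]:
    """TSV with header: enhancer_id, chrom, start, end, tissue, gene_id.

    One row per (enhancer, target gene); rows sharing (enhancer_id, tissue)
    are merged into one enhancer with the union of target genes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    grouped: dict[tuple[str, str], dict] = {}
    for row in df.itertuples(index=False):
        key = (row.tissue, row.enhancer_id)
        entry = grouped.setdefault(
            key,
            {"chrom": row.chrom, "start": int(row.start), "end": int(row.end), "genes": set()},
        )
        entry["genes"].add(row.gene_id)
    return [
        Enhancer(
            enhancer_id,
            GenomicInterval(e["chrom"], e["start"], e["end"]),
            tissue,
            frozenset(e["genes"]),
        )
        for (tissue, enhancer_id), e in sorted(grouped.items())
    ]


def write_enhancers(path: str | Path, enhancers: Sequence[Enhancer]) -> None:
    rows = []
    for e in sorted(enhancers, key=lambda e: (e.tissue, e.enhancer_id)):
        for gid in sorted(e.target_gene_ids):
            rows.append(
                {
                    "enhancer_id": e.enhancer_id,
                    "chrom": e.interval.chrom,
                    "start": e.interval.start,
                    "end": e.interval.end,
                    "tissue": e.tissue,
                    "gene_id": gid,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bpkm_table(path: str | Path) -> BpkmTable:
    """Headered TSV: region_id, tissue, bpkm; library sizes in leading
    ``#total_mapped_bases <tissue> <bases>`` comment lines."""
    totals: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#total_mapped_bases"):
            _, tissue, value = line.rstrip("\n").split("\t")
            totals[tissue] = float(value)
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                     dtype={"region_id": str, "tissue": str})
    return BpkmTable(df, totals)


def write_bpkm_table(path: str | Path, table: BpkmTable) -> None:
    with open(path, "w") as fh:
        for tissue, total in sorted(table.total_mapped_bases.items()):
            fh.write(f"#total_mapped_bases\t{tissue}\t{total:.10g}\n")
        table.frame.to_csv(fh, sep="\t", index=False)


def read_seed_families(path: str | Path):
    """TSV with header: family_id, family_class, seed7, mature_seqs
    (mature sequences comma-separated).  Returns (families, classes)."""
    from .mirtargets import SeedFamily

    df = pd.read_csv(path, sep="\t", dtype=str)
    families, classes = [], {}
    for row in df.itertuples(index=False):
        mats = tuple(m for m in str(row.mature_seqs).split(",") if m and m != "nan")
        families.append(SeedFamily(row.family_id, row.seed7, mats))
        classes[row.family_id] = row.family_class
    return families, classes


def write_seed_families(path: str | Path, families, classes: Mapping[str, str]) -> None:
    pd.DataFrame(
        [
            {
                "family_id": f.family_id,
                "family_class": classes.get(f.family_id, "other"),
                "seed7": f.seed7,
                "mature_seqs": ",".join(f.mature_seqs),
            }
            for f in families
        ]
    ).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> pd.DataFrame:
    """ncRNA family hit table: query_id, family_id, family_class, score."""
    return pd.read_csv(path, sep="\t", dtype={"query_id": str, "family_id": str,
                                              "family_class": str})


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                out[chrom] = int(size)
    return out
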