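"""Readers and writers for the text genomics formats the pipeline touches.

Coordinate conventions: BED and bedGraph are kept in their native 0-based
half-open form; GTF (1-based, closed) is converted on read by shifting
starts down by one. Chromosome name matching is exact string equality
throughout — a mismatch is an error, never a silent drop.
"""
from __future__ import annotations

import re
from typing import Dict, List, Optional

from Bio import SeqIO

from .core import (
    ChromSizes,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    ValidationError,
    sort_intervals,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


IUPAC = set("ACGTN")


def read_bed(path: str) -> List[GenomicInterval]:
    """Read BED3/BED6 into intervals, coordinates preserved verbatim."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else ""
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand, name, score))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: List[GenomicInterval], path: str) -> None:
    """Write sorted BED (chrom lexicographic, then start); BED6 when any
    interval carries a name, score or strand, else BED3."""
    ivs = sort_intervals(intervals)
    bed6 = any(iv.name or iv.score is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if bed6:
                score = "." if iv.score is None else repr(iv.score)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                    f"{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_genes(path: str) -> List[GeneModel]:
    """Read gene models from an ensembl-dialect GTF (gene/exon features).

    1-based closed GTF coordinates become 0-based half-open (start - 1, end).
    Genes lacking an explicit ``gene`` feature are inferred from the union of
    their exons. Book-ended exons are merged.
    """
    spans: Dict[str, List] = {}
    exons: Dict[str, List] = {}
    order: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("gene", "exon", "transcript"):
                continue
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            attr = dict(_ATTR_RE.findall(attrs))
            gid = attr.get("gene_id")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            if gid not in spans and gid not in exons:
                order.append(gid)
            if feature == "gene":
                spans[gid] = [chrom, strand, start, end]
            elif feature == "exon":
                exons.setdefault(gid, []).append((chrom, strand, start, end))
    genes: List[GeneModel] = []
    for gid in order:
        ex = sorted((s, e) for _c, _s, s, e in exons.get(gid, []))
        if gid in spans:
            chrom, strand, g_start, g_end = spans[gid]
        else:
            chrom, strand = exons[gid][0][0], exons[gid][0][1]
            g_start, g_end = ex[0][0], max(e for _s, e in ex)
        for c, s, es, ee in exons.get(gid, []):
            if c != chrom:
                raise ValidationError(f"gene {gid}: exon on {c}, gene on {chrom}")
            if es < g_start or ee > g_end:
                raise ValidationError(
                    f"gene {gid}: exon {es}-{ee} outside gene span {g_start}-{g_end}"
                )
        merged: List[List[int]] = []
        for s, e in ex:
            if merged and s <= merged[-1][1]:
                if s < merged[-1][1]:
                    raise ValidationError(f"gene {gid}: overlapping exons at {s}")
                merged[-1][1] = e  # book-ended
            else:
                merged.append([s, e])
        genes.append(
            GeneModel(gid, chrom, strand, g_start, g_end,
                      tuple((s, e) for s, e in merged))
        )
    return genes


def write_gtf_genes(genes: List[GeneModel], path: str, source: str = "rloopscape") -> None:
    """Write gene and exon features, converting back to 1-based closed."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
            attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons or ((g.tx_start, g.tx_end),):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def read_bedgraph(path: str) -> CoverageTrack:
    """Read a bedGraph into a CoverageTrack; overlapping records are an error."""
    runs: Dict[str, List] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed record") from exc
            if value < 0:
                raise ValidationError(f"{path}:{lineno}: negative value {value}")
            runs.setdefault(fields[0], []).append((start, end, value))
    track = CoverageTrack()
    for chrom, r in runs.items():
        try:
            track.set_chrom(chrom, r)
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return track


def write_bedgraph(track: CoverageTrack, path: str, omit_zero: bool = True) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs(chrom)
            for s, e, v in zip(starts, ends, values):
                if omit_zero and v == 0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_fasta(path: str, chrom_sizes: Optional[ChromSizes] = None) -> Dict[str, str]:
    """Read FASTA into {name: uppercased sequence}; optionally check lengths
    against bound chromosome sizes."""
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC
        if bad:
            raise ValidationError(
                f"{path}: sequence {rec.id} contains non-IUPAC characters {sorted(bad)}"
            )
        seqs[rec.id] = seq
    if chrom_sizes is not None:
        for name, seq in seqs.items():
            if name in chrom_sizes and chrom_sizes[name] != len(seq):
                raise ValidationError(
                    f"{path}: {name} length {len(seq)} != chrom.sizes "
                    f"{chrom_sizes[name]}"
                )
    return seqs


def write_fasta(seqs: Dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_chrom_sizes(path: str) -> ChromSizes:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected name<TAB>length")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer length") from exc
            if name in sizes:
                raise ValidationError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    return ChromSizes(sizes)


def write_chrom_sizes(sizes: ChromSizes, path: str) -> None:
    with open(path, "w") as fh:
        for name in sizes:
            fh.write(f"{name}\t{sizes[name]}\n")
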