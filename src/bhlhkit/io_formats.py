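"""Readers and writers for the standard file formats the pipeline touches.

All internal coordinates are 1-based inclusive (GFF convention); conversion
to 0-based half-open happens only at BED boundaries.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
DNA_ALPHABET = frozenset("ACGTN")

UPSTREAM_LENGTH = 1500  # promoter window, bp 5' of the gene start


@dataclass
class SequenceRecord:
    """A single FASTA entry (protein or DNA depending on context)."""

    id: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneAnnotation:
    """One gene model: the longest-CDS transcript of a GFF3 gene feature."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds_segments)


@dataclass
class SyntenyBlock:
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    block_id: str = ""


class DuplicateIdError(ValueError):
    pass


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Parse a FASTA file; sequences are uppercased and unwrapped.

    Raises :class:`DuplicateIdError` if two records share an id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, rec.description, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id, description=r.description if r.description != r.id else "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def _segments(feature_list) -> list[tuple[int, int]]:
    return sorted((f.start, f.end) for f in feature_list)


def read_gff3(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Read gene models from GFF3, keeping the longest-CDS transcript per gene.

    Coordinates stay 1-based inclusive. CDS/exon features whose Parent chain
    does not reach a gene are skipped with a warning. Output is sorted by
    (chromosome, start).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    gene_ids = {g.id for g in db.features_of_type("gene")}
    mrna_parent: dict[str, str] = {}
    for m in db.features_of_type("mRNA"):
        parents = m.attributes.get("Parent", [])
        if parents and parents[0] in gene_ids:
            mrna_parent[m.id] = parents[0]
        else:
            warnings.warn(f"mRNA {m.id} has no parent gene; skipped")

    genes: list[GeneAnnotation] = []
    for g in db.features_of_type("gene"):
        best: tuple[int, str, list, list] | None = None
        for m in db.children(g, featuretype="mRNA"):
            exons = list(db.children(m, featuretype="exon"))
            cds = list(db.children(m, featuretype="CDS"))
            cds_len = sum(c.end - c.start + 1 for c in cds)
            # deterministic: longest CDS, ties by mRNA id
            key = (cds_len, m.id)
            if best is None or key > (best[0], best[1]):
                best = (cds_len, m.id, exons, cds)
        if best is None:
            exon_list = [(g.start, g.end)]
            cds_list: list[tuple[int, int, int]] = []
        else:
            exon_list = _segments(best[2]) or [(g.start, g.end)]
            cds_list = sorted(
                (c.start, c.end, int(c.frame) if c.frame not in (None, ".") else 0)
                for c in best[3]
            )
        genes.append(
            GeneAnnotation(
                gene_id=g.id,
                chromosome=g.seqid,
                start=g.start,
                end=g.end,
                strand=g.strand or "+",
                exons=exon_list,
                cds_segments=cds_list,
            )
        )

    # orphan CDS check (no route to a gene)
    for c in db.features_of_type("CDS"):
        parents = c.attributes.get("Parent", [])
        if not parents or (parents[0] not in mrna_parent and parents[0] not in gene_ids):
            warnings.warn(f"CDS at {c.seqid}:{c.start}-{c.end} has no parent gene; skipped")

    genes.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return genes


def read_synteny_table(path: str | os.PathLike) -> list[SyntenyBlock]:
    """Tab-delimited block table: chrom_a start_a end_a chrom_b start_b end_b [id].

    Lines starting with '#' are skipped; malformed rows raise with the line
    number.
    """
    blocks: list[SyntenyBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"line {lineno}: expected >=6 tab-separated columns")
            try:
                sa, ea, sb, eb = int(parts[1]), int(parts[2]), int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if sa > ea or sb > eb:
                raise ValueError(f"line {lineno}: start > end")
            blocks.append(
                SyntenyBlock(parts[0], sa, ea, parts[3], sb, eb, parts[6] if len(parts) > 6 else "")
            )
    return blocks


# ---------------------------------------------------------------------------
# coordinate conversion


def gff_to_bed_interval(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def cds_position_to_genomic(gene: GeneAnnotation, cds_pos: int) -> int:
    """Map a 1-based CDS base position to its genomic coordinate.

    Walks CDS segments (falling back to exons) in transcription order.
    """
    segs = [(s, e) for s, e, *_ in gene.cds_segments] or list(gene.exons)
    if gene.strand == "-":
        segs = segs[::-1]
    remaining = cds_pos
    for s, e in segs:
        seg_len = e - s + 1
        if remaining <= seg_len:
            return s + remaining - 1 if gene.strand == "+" else e - remaining + 1
        remaining -= seg_len
    raise ValueError(f"CDS position {cds_pos} beyond CDS of {gene.gene_id}")


def protein_span_to_bed(gene: GeneAnnotation, prot_start: int, prot_end: int) -> tuple[str, int, int]:
    """Genomic BED span (0-based half-open) of protein residues prot_start..prot_end."""
    cds_first = 3 * (prot_start - 1) + 1
    cds_last = 3 * prot_end
    g1 = cds_position_to_genomic(gene, cds_first)
    g2 = cds_position_to_genomic(gene, cds_last)
    lo, hi = min(g1, g2), max(g1, g2)
    return gene.chromosome, lo - 1, hi


def extract_upstream(
    chromosomes: Mapping[str, str], gene: GeneAnnotation, length: int = UPSTREAM_LENGTH
) -> str:
    """Promoter window: `length` bp 5' of the gene start on the coding strand.

    Minus-strand genes are reverse-complemented; the window is truncated at
    the chromosome edge.
    """
    seq = chromosomes[gene.chromosome]
    if gene.strand == "+":
        lo = max(0, gene.start - 1 - length)
        return seq[lo : gene.start - 1]
    hi = min(len(seq), gene.end + length)
    return str(Seq(seq[gene.end : hi]).reverse_complement())


# ---------------------------------------------------------------------------
# result tables


def write_tsv(rows: Sequence[Mapping], columns: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def write_results_tables(results: Mapping[str, Sequence[Mapping]], out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write one TSV per result stage; 'bed' entries are written as BED6.

    `results` maps stage name -> list of row dicts. Column order is taken
    from the first row; empty stages produce header-only files only when a
    'columns' key is present in the stage via a leading row.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for stage, rows in results.items():
        if stage == "bed":
            path = out / "domains.bed"
            with open(path, "w") as fh:
                for row in rows:
                    fh.write(
                        f"{row['chrom']}\t{row['bed_start']}\t{row['bed_end']}\t"
                        f"{row.get('name', '.')}\t{row.get('score', 0)}\t{row.get('strand', '+')}\n"
                    )
        else:
            path = out / f"{stage}.tsv"
            columns = list(rows[0].keys()) if rows else _DEFAULT_COLUMNS.get(stage, ["empty"])
            write_tsv(rows, columns, path)
        written[stage] = path
    return written


_DEFAULT_COLUMNS = {
    "hits": ["protein_id", "start", "end", "mismatch_count", "accepted"],
    "calls": [
        "protein_id", "category", "basic_count", "has_his_lys9", "has_glu13",
        "has_arg16", "has_arg17", "has_leu27", "has_leu54", "tetramer_ready",
    ],
    "pairs": ["gene_a", "gene_b", "dup_type", "ka", "ks", "ratio", "t_mya", "selection"],
    "patterns": ["gene_id", "pattern_id", "events"],
    "properties": ["protein_id", "length", "mw", "pi", "gravy", "n_negative", "n_positive"],
}
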