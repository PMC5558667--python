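"""Exon–intron structure inference, domain intron-pattern typing, IUPAC
promoter scanning and expression arithmetic (log2 matrices, 2^-ddCt)."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .domain_scan import ConsensusProfile, DomainHit

MIN_INTRON = 4  # GT..AG is the shortest representable intron


class StructureError(ValueError):
    pass


def _chain_exons(cds: str, genomic: str) -> list[tuple[int, int]] | None:
    """Greedy longest-exact-match chaining of the CDS against one strand,
    requiring GT..AG intron boundaries. Returns 1-based inclusive exon
    coordinates or None."""
    failed: set[tuple[int, int]] = set()

    def search(ci: int, gi: int) -> list[tuple[int, int]] | None:
        if (ci, gi) in failed:
            return None
        # maximal exact extension
        m = 0
        while ci + m < len(cds) and gi + m < len(genomic) and cds[ci + m] == genomic[gi + m]:
            m += 1
        if ci + m == len(cds):
            return [(gi + 1, gi + m)]
        for exon_len in range(m, 0, -1):
            donor = gi + exon_len
            if genomic[donor : donor + 2] != "GT":
                continue
            rest = cds[ci + exon_len :]
            # candidate acceptor positions: every AG followed by the next CDS base
            j = donor + MIN_INTRON
            while True:
                j = genomic.find("AG" + rest[0], j - 2)
                if j == -1:
                    break
                acceptor = j + 2  # genomic index where the next exon starts
                if acceptor - donor >= MIN_INTRON:
                    tail = search(ci + exon_len, acceptor)
                    if tail is not None:
                        return [(gi + 1, gi + exon_len)] + tail
                j = j + 3
        failed.add((ci, gi))
        return None

    start = 0
    while True:
        g0 = genomic.find(cds[0], start)
        if g0 == -1:
            return None
        result = search(0, g0)
        if result is not None:
            return result
        start = g0 + 1


def infer_gene_structure(cds: str, genomic: str) -> tuple[str, list[tuple[int, int]]]:
    """Reconstruct exon coordinates by spliced exact matching of the CDS
    against the genomic sequence, preferring GT..AG intron boundaries.

    Tries the plus strand first, then the reverse complement; minus-strand
    exons are reported in ascending order on the forward genomic sequence.
    Returns (strand, exons) with 1-based inclusive coordinates.
    """
    cds = cds.upper()
    genomic = genomic.upper()
    exons = _chain_exons(cds, genomic)
    if exons is not None:
        return "+", exons
    rc = str(Seq(genomic).reverse_complement())
    exons = _chain_exons(cds, rc)
    if exons is not None:
        glen = len(genomic)
        mapped = sorted((glen - e + 1, glen - s + 1) for s, e in exons)
        return "-", mapped
    raise StructureError("CDS cannot be derived from the genomic sequence")


@dataclass
class IntronAssignment:
    gene_id: str
    intron_events: list[tuple[int, int]]  # (domain profile index, phase 0/1/2)
    pattern_id: str = ""

    @property
    def intronless(self) -> bool:
        return not self.intron_events


def cds_introns(exons: Sequence[tuple[int, int]], strand: str = "+") -> list[tuple[int, int]]:
    """Introns in CDS coordinates: (cds bases before the intron, phase)."""
    ordered = sorted(exons)
    if strand == "-":
        ordered = ordered[::-1]
    events = []
    cum = 0
    for s, e in ordered[:-1]:
        cum += e - s + 1
        events.append((cum, cum % 3))
    return events


def map_introns_to_domain(
    exons: Sequence[tuple[int, int]],
    hit: DomainHit,
    strand: str = "+",
    gene_id: str | None = None,
) -> IntronAssignment:
    """Map each intron inside the domain's codon span to the profile index of
    the codon it interrupts (phase 1/2) or immediately precedes (phase 0).

    Introns falling on loop-insertion residues that carry no profile index
    are ignored for pattern typing.
    """
    residue_of = {v: k for k, v in hit.protein_position.items()}
    events: list[tuple[int, int]] = []
    for cum, phase in cds_introns(exons, strand):
        codon_idx = cum // 3 + 1
        if not (hit.start <= codon_idx <= hit.end):
            continue
        profile_idx = residue_of.get(codon_idx)
        if profile_idx is not None:
            events.append((profile_idx, phase))
    events.sort()
    return IntronAssignment(gene_id or hit.protein_id, events)


@dataclass
class PatternCatalog:
    patterns: dict[str, frozenset[int]]

    @classmethod
    def load(cls, profile: ConsensusProfile, path: str | Path | None = None) -> "PatternCatalog":
        """Catalog TSV: pattern_id <tab> comma-separated position labels or indices."""
        if path is None:
            path = resources.files("bhlhkit.data") / "intron_patterns.tsv"
        patterns: dict[str, frozenset[int]] = {}
        with open(str(path)) as fh:
            fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or not parts[0]:
                    continue
                if parts[0] in patterns:
                    raise ValueError(f"duplicate pattern id {parts[0]!r}")
                idxs = frozenset(
                    profile.index_for_label(tok.strip()) if not tok.strip().isdigit() else int(tok)
                    for tok in parts[1].split(",")
                )
                patterns[parts[0]] = idxs
        return cls(patterns)


def assign_pattern(assignment: IntronAssignment, catalog: PatternCatalog) -> str:
    """Pattern label whose position set equals the event positions; 'intronless'
    for no events, 'novel' otherwise. Phases are recorded but not compared."""
    if assignment.intronless:
        assignment.pattern_id = "intronless"
        return assignment.pattern_id
    positions = frozenset(p for p, _ in assignment.intron_events)
    for label, posset in catalog.patterns.items():
        if posset == positions:
            assignment.pattern_id = label
            return label
    assignment.pattern_id = "novel"
    return "novel"


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII",
          "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX"]


def discover_patterns(assignments: Sequence[IntronAssignment]) -> PatternCatalog:
    """Cluster identical position sets and label them by frequency rank
    (ties by position set) with roman numerals."""
    counts: dict[frozenset[int], int] = {}
    for a in assignments:
        if a.intronless:
            continue
        key = frozenset(p for p, _ in a.intron_events)
        counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts, key=lambda k: (-counts[k], sorted(k)))
    labels = {}
    for i, key in enumerate(ranked):
        labels[_ROMAN[i] if i < len(_ROMAN) else f"P{i + 1}"] = key
    return PatternCatalog(labels)


# ---------------------------------------------------------------------------
# promoter motif scanning

_IUPAC = {k.upper(): v.upper() for k, v in ambiguous_dna_values.items()}


@dataclass
class MotifHit:
    gene_id: str
    motif_name: str
    strand: str
    offset: int  # 0-based within the upstream window, forward coordinates
    matched: str


def iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for sym in pattern.upper():
        if sym not in _IUPAC:
            raise ValueError(f"invalid IUPAC symbol {sym!r}")
        opts = _IUPAC[sym]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def load_motif_dict(path: str | Path | None = None) -> dict[str, str]:
    if path is None:
        path = resources.files("bhlhkit.data") / "motifs.tsv"
    motifs: dict[str, str] = {}
    with open(str(path)) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                motifs[parts[0]] = parts[1]
    return motifs


def scan_promoter(
    upstream: str, motif_dict: Mapping[str, str], gene_id: str = ""
) -> list[MotifHit]:
    """All (possibly overlapping) IUPAC matches on both strands.

    Minus-strand offsets are the forward-strand start of the matched span.
    """
    seq = upstream.upper()
    rc = str(Seq(seq).reverse_complement())
    hits: list[MotifHit] = []
    for name, pattern in motif_dict.items():
        rx = iupac_regex(pattern)
        for m in rx.finditer(seq):
            hits.append(MotifHit(gene_id, name, "+", m.start(), m.group(1)))
        for m in rx.finditer(rc):
            fwd_start = len(seq) - m.start() - len(m.group(1))
            hits.append(MotifHit(gene_id, name, "-", fwd_start, m.group(1)))
    hits.sort(key=lambda h: (h.motif_name, h.offset, h.strand))
    return hits


def motif_counts(hits: Sequence[MotifHit]) -> pd.DataFrame:
    rows = [(h.gene_id, h.motif_name) for h in hits]
    if not rows:
        return pd.DataFrame(columns=["gene_id", "motif_name", "count"])
    df = pd.DataFrame(rows, columns=["gene_id", "motif_name"])
    return df.value_counts().reset_index(name="count").sort_values(
        ["gene_id", "motif_name"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# expression arithmetic


def log2_matrix(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(value + pseudocount); negative input is an error."""
    values = expr.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression values must be non-negative")
    return pd.DataFrame(np.log2(values + pseudocount), index=expr.index, columns=expr.columns)


def ddct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression 2^-[(Ct_t,treat - Ct_ref,treat) - (Ct_t,ctrl - Ct_ref,ctrl)]."""
    delta_delta = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-delta_delta))


@dataclass
class QpcrSample:
    gene_id: str
    condition: str
    ct_target: float
    ct_reference: float
    relative_expression: float = field(default=1.0)


def qpcr_fold_changes(table: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Fold changes per gene/condition from a Ct table with columns
    gene_id, condition, ct_target, ct_reference (triplicate means)."""
    required = {"gene_id", "condition", "ct_target", "ct_reference"}
    if not required <= set(table.columns):
        raise ValueError(f"Ct table must contain columns {sorted(required)}")
    rows = []
    for gene, sub in table.groupby("gene_id"):
        ctrl = sub[sub["condition"] == control_condition]
        if ctrl.empty:
            raise ValueError(f"{gene}: no control condition {control_condition!r}")
        ct_t_ctrl = float(ctrl["ct_target"].mean())
        ct_r_ctrl = float(ctrl["ct_reference"].mean())
        for cond, grp in sub.groupby("condition"):
            fold = ddct(
                float(grp["ct_target"].mean()),
                float(grp["ct_reference"].mean()),
                ct_t_ctrl,
                ct_r_ctrl,
            )
            rows.append({"gene_id": gene, "condition": cond, "fold_change": fold})
    return pd.DataFrame(rows).sort_values(["gene_id", "condition"], ignore_index=True)
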