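"""Ground-truthed input generators for every pipeline stage.

Each generator is seed-deterministic and returns the generated objects plus
a :class:`SimTruth` ledger with one entry per generated entity; when an
output directory is given, the standard-format files and a truth JSON are
written as well.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domain_scan import (
    AMINO_ACIDS,
    ConsensusProfile,
    align_to_profile,
    load_profile,
)
from .duplication_evolution import BASES, CODON_TO_AA, STOP_CODONS
from .io_formats import GeneAnnotation, SequenceRecord, SyntenyBlock, write_fasta


@dataclass
class SimTruth:
    kind: str
    seed: int
    entries: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


# ---------------------------------------------------------------------------
# proteome with planted domains


def mutate_domain(
    domain: str,
    profile: ConsensusProfile,
    k: int,
    rng: np.random.Generator,
    loop_len: int,
) -> str:
    """Mutate exactly k conserved positions to residues outside their allowed
    sets. The domain must be profile-canonical with the given loop length."""
    conserved = profile.conserved_indices
    chosen = rng.choice(conserved, size=k, replace=False)
    lo, hi = profile.loop_span if profile.loop_span else (None, None)
    extra = loop_len - (hi - lo + 1) if lo is not None else 0
    chars = list(domain)
    for idx in sorted(int(c) for c in chosen):
        pos0 = idx - 1 if (hi is None or idx <= hi) else idx - 1 + extra
        banned = profile.position(idx).allowed_residues
        options = [a for a in AMINO_ACIDS if a not in banned]
        chars[pos0] = str(rng.choice(options))
    return "".join(chars)


def gen_proteome(
    n_proteins: int,
    n_planted: int,
    mismatch_distribution: Sequence[int],
    seed: int,
    profile: ConsensusProfile | None = None,
    out_dir: str | Path | None = None,
    flank: tuple[int, int] = (20, 120),
    loop_len: int = 8,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Proteome of `n_proteins`; the first `n_planted` carry a consensus
    domain mutated at exactly k conserved positions (k cycled from
    `mismatch_distribution`); decoys are verified non-matching at <=9.
    """
    if n_planted > n_proteins:
        raise ValueError("n_planted cannot exceed n_proteins")
    profile = profile or load_profile()
    rng = _rng(seed)
    truth = SimTruth("proteome", seed)
    records: list[SequenceRecord] = []
    consensus = profile.consensus_sequence(loop_len)

    for i in range(n_planted):
        k = int(mismatch_distribution[i % len(mismatch_distribution)])
        while True:
            domain = mutate_domain(consensus, profile, k, rng, loop_len)
            left = _random_protein(rng, int(rng.integers(flank[0], flank[1])))
            right = _random_protein(rng, int(rng.integers(flank[0], flank[1])))
            seq = left + domain + right
            rec = SequenceRecord(f"SYN{i + 1:04d}", "planted", seq)
            hit = align_to_profile(rec, profile)
            # accept the draw only if the planted window is the optimum
            if hit.mismatch_count == k and hit.start == len(left) + 1:
                break
        records.append(rec)
        truth.entries.append(
            {
                "id": rec.id,
                "planted": True,
                "domain_start": len(left) + 1,
                "domain_end": len(left) + len(domain),
                "true_mismatches": k,
                "loop_length": loop_len,
            }
        )

    for i in range(n_planted, n_proteins):
        while True:
            seq = _random_protein(rng, int(rng.integers(150, 400)))
            rec = SequenceRecord(f"SYN{i + 1:04d}", "decoy", seq)
            hit = align_to_profile(rec, profile)
            if not hit.found or hit.mismatch_count > 9:
                break
        records.append(rec)
        truth.entries.append({"id": rec.id, "planted": False, "true_mismatches": None})

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "proteome.fasta")
        truth.to_json(out / "proteome.truth.json")
    return records, truth


# ---------------------------------------------------------------------------
# codon pair evolution at chosen omega


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = [c for c in CODON_TO_AA if c not in STOP_CODONS]
    codons.sort()
    return "".join(rng.choice(codons, size=n_codons))


def _evolve(cds: str, n_proposals: int, omega: float, rng: np.random.Generator) -> tuple[str, int, int]:
    """Per-site nucleotide proposals: synonymous accepted with probability 1,
    nonsynonymous with probability omega; stop-creating changes rejected."""
    seq = list(cds)
    syn_events = nonsyn_events = 0
    n_sites = len(seq)
    for _ in range(n_proposals):
        # redraw stop-creating proposals so every proposal is a viable change
        while True:
            site = int(rng.integers(0, n_sites))
            old = seq[site]
            alternatives = [b for b in BASES if b != old]
            new = alternatives[int(rng.integers(0, 3))]
            codon_i = site // 3
            codon = "".join(seq[3 * codon_i : 3 * codon_i + 3])
            mutant = codon[: site % 3] + new + codon[site % 3 + 1 :]
            if mutant not in STOP_CODONS:
                break
        if CODON_TO_AA[mutant] == CODON_TO_AA[codon]:
            seq[site] = new
            syn_events += 1
        elif rng.random() < omega:
            seq[site] = new
            nonsyn_events += 1
    return "".join(seq), syn_events, nonsyn_events


def gen_codon_pairs(
    n_codons: int,
    omega: float,
    expected_ks: float,
    n_pairs: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Pairs of CDS evolved from a common ancestor along two branches so the
    expected synonymous divergence is `expected_ks`."""
    if omega < 0:
        raise ValueError("omega must be non-negative")
    if expected_ks >= 1.0:
        raise ValueError("expected_ks implies ps >= 3/4 (saturation); refuse")
    rng = _rng(seed)
    truth = SimTruth("codon_pairs", seed)
    # proposals per branch: T * P(syn) = (ks/2) * S with P(syn)=S/(3n) => T = 3n*ks/2
    proposals = int(round(3 * n_codons * expected_ks / 2))
    pairs: list[tuple[str, str]] = []
    for i in range(n_pairs):
        ancestor = _random_cds(rng, n_codons)
        a, syn_a, non_a = _evolve(ancestor, proposals, omega, rng)
        b, syn_b, non_b = _evolve(ancestor, proposals, omega, rng)
        pairs.append((a, b))
        truth.entries.append(
            {
                "pair": i + 1,
                "true_omega": omega,
                "expected_ks": expected_ks,
                "syn_events": syn_a + syn_b,
                "nonsyn_events": non_a + non_b,
            }
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records = []
        for i, (a, b) in enumerate(pairs, start=1):
            records.append(SequenceRecord(f"PAIR{i:03d}_A", "", a))
            records.append(SequenceRecord(f"PAIR{i:03d}_B", "", b))
        write_fasta(records, out / "codon_pairs.fasta")
        truth.to_json(out / "codon_pairs.truth.json")
    return pairs, truth


# ---------------------------------------------------------------------------
# gene models with planted introns

_PREFERRED_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACA", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def reverse_translate(protein: str) -> str:
    return "".join(_PREFERRED_CODON[a] for a in protein)


def _reverse_complement(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


@dataclass
class GeneModelPlan:
    gene_id: str
    introns: list[tuple[int, int]]  # (domain profile index, phase)
    strand: str = "+"


def gen_gene_models(
    intron_plans: Sequence[GeneModelPlan],
    seed: int,
    profile: ConsensusProfile | None = None,
    out_dir: str | Path | None = None,
    loop_len: int = 5,
    flank_codons: int = 10,
    genomic_flank: int = 60,
) -> tuple[dict, SimTruth]:
    """Genes whose CDS encodes a consensus domain, with GT..AG introns planted
    at the requested domain positions/phases.

    Returns a bundle dict with per-gene 'cds', 'genomic' (forward strand),
    'strand', 'exons' (1-based on the forward genomic) and 'annotation'.
    """
    profile = profile or load_profile()
    rng = _rng(seed)
    truth = SimTruth("gene_models", seed)
    consensus = profile.consensus_sequence(loop_len)
    domain_offset = flank_codons  # residues before the domain

    bundle: dict[str, dict] = {}
    for plan in intron_plans:
        protein = _random_protein(rng, flank_codons) + consensus + _random_protein(rng, flank_codons)
        cds = reverse_translate(protein)
        extra = loop_len - (profile.loop_span[1] - profile.loop_span[0] + 1) if profile.loop_span else 0
        cuts: list[int] = []
        for idx, phase in plan.introns:
            if idx not in {p.index for p in profile.positions}:
                raise ValueError(f"intron position {idx} outside the domain profile")
            pos0 = idx - 1 if (profile.loop_span is None or idx <= profile.loop_span[1]) else idx - 1 + extra
            residue = domain_offset + pos0 + 1  # 1-based protein residue
            cut = 3 * (residue - 1) + phase  # CDS bases before the intron
            cuts.append(cut)
        cuts = sorted(set(cuts))
        if any(c <= 0 or c >= len(cds) for c in cuts):
            raise ValueError("intron cut outside CDS")

        pieces = []
        prev = 0
        for c in cuts:
            pieces.append(cds[prev:c])
            prev = c
        pieces.append(cds[prev:])
        introns = [
            "GT" + "".join(rng.choice(list("ACT"), size=int(rng.integers(8, 30)))) + "AG"
            for _ in cuts
        ]
        left = "".join(rng.choice(list("ACGT"), size=genomic_flank))
        right = "".join(rng.choice(list("ACGT"), size=genomic_flank))
        body = pieces[0]
        exon_bounds = [(len(left) + 1, len(left) + len(pieces[0]))]
        for intron, piece in zip(introns, pieces[1:]):
            start = len(left) + len(body) + len(intron) + 1
            body += intron + piece
            exon_bounds.append((start, start + len(piece) - 1))
        forward = left + body + right

        if plan.strand == "-":
            glen = len(forward)
            forward = _reverse_complement(forward)
            exon_bounds = sorted((glen - e + 1, glen - s + 1) for s, e in exon_bounds)

        ann = GeneAnnotation(
            gene_id=plan.gene_id,
            chromosome=f"chr_{plan.gene_id}",
            start=min(s for s, _ in exon_bounds),
            end=max(e for _, e in exon_bounds),
            strand=plan.strand,
            exons=list(exon_bounds),
            cds_segments=[(s, e, 0) for s, e in exon_bounds],
        )
        bundle[plan.gene_id] = {
            "cds": cds,
            "protein": protein,
            "genomic": forward,
            "strand": plan.strand,
            "exons": exon_bounds,
            "annotation": ann,
        }
        truth.entries.append(
            {
                "id": plan.gene_id,
                "strand": plan.strand,
                "exons": exon_bounds,
                "intron_positions": sorted(plan.introns),
                "domain_start_residue": domain_offset + 1,
            }
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [SequenceRecord(g, "", b["cds"]) for g, b in bundle.items()], out / "cds.fasta"
        )
        write_fasta(
            [SequenceRecord(f"chr_{g}", "", b["genomic"]) for g, b in bundle.items()],
            out / "genomic.fasta",
        )
        _write_gff3([b["annotation"] for b in bundle.values()], out / "genes.gff3")
        truth.to_json(out / "gene_models.truth.json")
    return bundle, truth


def _write_gff3(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\t.\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chromosome}\t.\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(f"{g.chromosome}\t.\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n")
            for s, e, phase in g.cds_segments:
                fh.write(
                    f"{g.chromosome}\t.\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\tParent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# duplication layout


def gen_duplication_layout(
    n_chromosomes: int,
    tandem_pairs: int,
    segmental_pairs: int,
    seed: int,
    out_dir: str | Path | None = None,
    fillers_per_chromosome: int = 12,
) -> tuple[dict, SimTruth]:
    """Gene order with planted tandem pairs (adjacent, near-identical
    proteins) and segmental pairs (placed in paired synteny blocks)."""
    rng = _rng(seed)
    profile = load_profile()
    truth = SimTruth("duplication_layout", seed)
    consensus = profile.consensus_sequence(8)

    genes: list[GeneAnnotation] = []
    proteins: dict[str, str] = {}
    family: list[str] = []
    blocks: list[SyntenyBlock] = []
    positions = {c: 1000 for c in range(1, n_chromosomes + 1)}
    counter = 0

    def place(chrom: int, fam: bool, protein: str | None = None) -> GeneAnnotation:
        nonlocal counter
        counter += 1
        gid = f"G{counter:04d}"
        start = positions[chrom]
        length = int(rng.integers(900, 2400))
        positions[chrom] = start + length + int(rng.integers(500, 3000))
        g = GeneAnnotation(gid, f"chr{chrom}", start, start + length, "+",
                          exons=[(start, start + length)])
        genes.append(g)
        if protein is None:
            protein = _random_protein(rng, 120)
        proteins[gid] = protein
        if fam:
            family.append(gid)
        return g

    def family_protein() -> str:
        flank_l = _random_protein(rng, 15)
        flank_r = _random_protein(rng, 15)
        return flank_l + consensus + flank_r

    # fillers interleaved with planted tandem pairs on chromosome 1..n
    tandem_truth: list[tuple[str, str]] = []
    for t in range(tandem_pairs):
        chrom = (t % n_chromosomes) + 1
        for _ in range(int(rng.integers(1, 4))):
            place(chrom, fam=False)
        base = family_protein()
        a = place(chrom, fam=True, protein=base)
        b = place(chrom, fam=True, protein=base)  # adjacent: no intervening gene
        tandem_truth.append((a.gene_id, b.gene_id))

    segmental_truth: list[tuple[str, str]] = []
    for s in range(segmental_pairs):
        ca = (s % n_chromosomes) + 1
        cb = ((s + 1) % n_chromosomes) + 1
        place(ca, fam=False)
        base = family_protein()
        ga = place(ca, fam=True, protein=base)
        place(cb, fam=False)
        gb = place(cb, fam=True, protein=base)
        blocks.append(
            SyntenyBlock(
                ga.chromosome, ga.start - 200, ga.end + 200,
                gb.chromosome, gb.start - 200, gb.end + 200,
                block_id=f"blk{s + 1}",
            )
        )
        segmental_truth.append((ga.gene_id, gb.gene_id))

    for c in range(1, n_chromosomes + 1):
        for _ in range(fillers_per_chromosome):
            place(c, fam=False)

    genes.sort(key=lambda g: (g.chromosome, g.start))
    truth.entries.append(
        {
            "tandem": sorted(tuple(sorted(p)) for p in tandem_truth),
            "segmental": sorted(tuple(sorted(p)) for p in segmental_truth),
            "family": sorted(family),
        }
    )
    bundle = {"genes": genes, "proteins": proteins, "family": sorted(family), "blocks": blocks}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_gff3(genes, out / "layout.gff3")
        with open(out / "blocks.tsv", "w") as fh:
            fh.write("#chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\tblock_id\n")
            for b in blocks:
                fh.write(
                    f"{b.chrom_a}\t{b.start_a}\t{b.end_a}\t{b.chrom_b}\t{b.start_b}\t{b.end_b}\t{b.block_id}\n"
                )
        write_fasta(
            [SequenceRecord(g, "", p) for g, p in sorted(proteins.items())],
            out / "layout_proteins.fasta",
        )
        truth.to_json(out / "layout.truth.json")
    return bundle, truth


# ---------------------------------------------------------------------------
# expression matrices and qPCR tables


def gen_expression(
    groups: Mapping[str, Sequence[str]],
    tissues: Sequence[str],
    effect_size: float,
    noise_sd: float,
    seed: int,
    out_dir: str | Path | None = None,
    baseline: float = 50.0,
    fold_changes: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Group-structured expression matrix plus a qPCR Ct table whose fold
    changes are back-computed from `fold_changes` (default: 2 conditions
    per gene at folds 4 and 0.25) with triplicate jitter `noise_sd`."""
    rng = _rng(seed)
    truth = SimTruth("expression", seed)
    tissues = list(tissues)
    rows = []
    index = []
    group_names = sorted(groups)
    for gi, gname in enumerate(group_names):
        preferred = tissues[gi % len(tissues)]
        for gene in groups[gname]:
            mean = np.full(len(tissues), baseline)
            mean[tissues.index(preferred)] += effect_size
            values = np.clip(mean + rng.normal(0.0, noise_sd, size=len(tissues)), 0.0, None)
            rows.append(values)
            index.append(gene)
            truth.entries.append(
                {"id": gene, "group": gname, "preferred_tissue": preferred,
                 "effect_size": effect_size}
            )
    matrix = pd.DataFrame(rows, index=index, columns=tissues)
    matrix.index.name = "gene_id"

    if fold_changes is None:
        fold_changes = {
            gene: {"treatA": 4.0, "treatB": 0.25}
            for gname in group_names
            for gene in groups[gname]
        }
    ct_rows = []
    ct_ref, ct_target_ctrl = 20.0, 25.0
    for gene in sorted(fold_changes):
        for rep in range(3):
            ct_rows.append(
                {"gene_id": gene, "condition": "control", "replicate": rep + 1,
                 "ct_target": ct_target_ctrl + float(rng.normal(0, noise_sd)),
                 "ct_reference": ct_ref + float(rng.normal(0, noise_sd))}
            )
        for cond, fold in sorted(fold_changes[gene].items()):
            ct_treat = ct_target_ctrl - float(np.log2(fold))
            for rep in range(3):
                ct_rows.append(
                    {"gene_id": gene, "condition": cond, "replicate": rep + 1,
                     "ct_target": ct_treat + float(rng.normal(0, noise_sd)),
                     "ct_reference": ct_ref + float(rng.normal(0, noise_sd))}
                )
            truth.entries.append({"id": gene, "condition": cond, "true_fold": fold})
    qpcr = pd.DataFrame(ct_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        matrix.to_csv(out / "expression.tsv", sep="\t")
        qpcr.to_csv(out / "qpcr.tsv", sep="\t", index=False)
        truth.to_json(out / "expression.truth.json")
    return matrix, qpcr, truth
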