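"""Gene-duplication detection, NG86 Ka/Ks estimation, selection classes and
synonymous molecular-clock dating.

The Ka/Ks estimator is the Nei–Gojobori (1986) counting method: fractional
synonymous site counts from the universal code (mutations to stop codons
count as nonsynonymous, so per codon syn + nonsyn sites = 3), pathway
averaging of multi-position codon differences with stop-passing pathways
excluded, and the Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io_formats import GeneAnnotation, SyntenyBlock

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)
BASES = "ACGT"

DEFAULT_LAMBDA_SYN = 6.5e-9  # synonymous substitutions / site / year (grass clock)
DEFAULT_IDENTITY_MIN = 0.4


@dataclass
class ClockParams:
    lambda_syn: float = DEFAULT_LAMBDA_SYN

    def __post_init__(self) -> None:
        if self.lambda_syn <= 0:
            raise ValueError("lambda_syn must be positive")


@dataclass
class KaKsResult:
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    ratio: float | None


@dataclass
class DuplicationPair:
    gene_a: str
    gene_b: str
    dup_type: str  # tandem | segmental | orthologous
    kaks: KaKsResult | None = None
    t_mya: float | None = None
    selection: str = "undefined"


def translate(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            raise ValueError(f"unrecognized codon {codon!r} at position {i + 1}")
        if aa == "*":
            if i == len(cds) - 3:
                break  # terminal stop tolerated
            raise ValueError(f"internal stop codon {codon!r} at position {i + 1}")
        aas.append(aa)
    return "".join(aas)


def codon_align(
    cds_a: str, cds_b: str, protein_alignment: tuple[str, str]
) -> list[tuple[str, str]]:
    """Expand a protein alignment to paired codons, dropping gapped columns.

    Each CDS must translate to its ungapped aligned protein (a terminal stop
    codon is tolerated).
    """
    aln_a, aln_b = protein_alignment
    if len(aln_a) != len(aln_b):
        raise ValueError("protein alignment rows differ in length")
    for cds, aln, name in ((cds_a, aln_a, "first"), (cds_b, aln_b, "second")):
        prot = translate(cds)
        if prot != aln.replace("-", ""):
            # locate the first disagreeing codon for the error message
            stripped = aln.replace("-", "")
            for k, (x, y) in enumerate(zip(prot, stripped)):
                if x != y:
                    raise ValueError(
                        f"{name} CDS codon {k + 1} translates to {x!r}, alignment has {y!r}"
                    )
            raise ValueError(f"{name} CDS and aligned protein differ in length")
    pairs: list[tuple[str, str]] = []
    ia = ib = 0
    for ca, cb in zip(aln_a, aln_b):
        codon_a = cds_a[3 * ia : 3 * ia + 3] if ca != "-" else None
        codon_b = cds_b[3 * ib : 3 * ib + 3] if cb != "-" else None
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if codon_a and codon_b:
            pairs.append((codon_a, codon_b))
    return pairs


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """Fractional number of synonymous sites in a codon (0..3).

    Each position contributes (synonymous changes) / (viable changes), where
    nonsense mutations are disregarded: changes creating a stop codon are
    excluded from both numerator and denominator. Every position still
    contributes exactly one site, so syn + nonsyn sites = 3 per codon.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = viable = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            viable += 1
            if CODON_TO_AA[mutant] == aa:
                syn += 1
        if viable:
            s += syn / viable
    return s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) step counts over all minimal
    mutational pathways, excluding pathways through stop codons."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        current = codon_a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if CODON_TO_AA[nxt] == CODON_TO_AA[current] and nxt not in STOP_CODONS and current not in STOP_CODONS:
                sd += 1
            else:
                nd += 1
            current = nxt
        (fallback if blocked else valid).append((sd, nd))
    paths = valid or fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """d = -(3/4) ln(1 - 4p/3); None when saturated (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(codon_pairs: Sequence[tuple[str, str]]) -> KaKsResult:
    """Nei–Gojobori (1986) Ka/Ks for a list of paired codons."""
    if not codon_pairs:
        raise ValueError("ng86_kaks requires at least one codon pair")
    s_sites = n_sites = sd = nd = 0.0
    for ca, cb in codon_pairs:
        s_a, s_b = syn_site_fraction(ca), syn_site_fraction(cb)
        s_sites += (s_a + s_b) / 2.0
        n_sites += 3.0 - (s_a + s_b) / 2.0
        d_s, d_n = _pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    ratio = None
    if ks is not None and ka is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(s_sites, n_sites, sd, nd, ps, pn, ks, ka, ratio)


def classify_selection(result: KaKsResult) -> str:
    if result.ratio is None:
        return "undefined"
    if result.ratio < 1.0:
        return "purifying"
    if result.ratio > 1.0:
        return "positive"
    return "neutral"


def divergence_time(ks: float | None, clock: ClockParams | None = None) -> float | None:
    """T = Ks / (2 lambda), in millions of years; None for saturated Ks."""
    if ks is None:
        return None
    if ks < 0:
        raise ValueError("ks must be non-negative")
    clock = clock or ClockParams()
    return ks / (2.0 * clock.lambda_syn) / 1e6


# ---------------------------------------------------------------------------
# duplication detection


def global_identity(seq_a: str, seq_b: str) -> float:
    """Identity fraction of the best global alignment (matches / columns)."""
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a) if a else 0.0


def find_tandem_pairs(
    family_ids: Sequence[str],
    all_genes: Sequence[GeneAnnotation],
    proteins: Mapping[str, str] | None = None,
    identity_min: float = DEFAULT_IDENTITY_MIN,
) -> list[DuplicationPair]:
    """Family members adjacent in the full gene order of one chromosome
    (no intervening gene), with protein identity >= identity_min when
    sequences are supplied."""
    family = set(family_ids)
    ordered = sorted(all_genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    pairs: list[DuplicationPair] = []
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.chromosome != cur.chromosome:
            continue
        if prev.gene_id not in family or cur.gene_id not in family:
            continue
        if proteins is not None:
            pa, pb = proteins.get(prev.gene_id), proteins.get(cur.gene_id)
            if pa is None or pb is None or global_identity(pa, pb) < identity_min:
                continue
        a, b = sorted((prev.gene_id, cur.gene_id))
        pairs.append(DuplicationPair(a, b, "tandem"))
    return pairs


def assign_segmental(
    family_genes: Sequence[GeneAnnotation],
    blocks: Sequence[SyntenyBlock],
    exclude: set[tuple[str, str]] | None = None,
) -> list[DuplicationPair]:
    """Pairs (a, b) where a lies in a block's A-region and b in the paired
    B-region (or vice versa). Containment uses the gene start coordinate.
    Pairs in `exclude` (e.g. already tandem) are not re-flagged."""
    exclude = exclude or set()

    def inside(gene: GeneAnnotation, chrom: str, lo: int, hi: int) -> bool:
        return gene.chromosome == chrom and lo <= gene.start <= hi

    pairs: dict[tuple[str, str], DuplicationPair] = {}
    for blk in blocks:
        in_a = [g for g in family_genes if inside(g, blk.chrom_a, blk.start_a, blk.end_a)]
        in_b = [g for g in family_genes if inside(g, blk.chrom_b, blk.start_b, blk.end_b)]
        for ga in in_a:
            for gb in in_b:
                if ga.gene_id == gb.gene_id:
                    continue
                key = tuple(sorted((ga.gene_id, gb.gene_id)))
                if key in exclude or key in pairs:
                    continue
                pairs[key] = DuplicationPair(key[0], key[1], "segmental")
    return [pairs[k] for k in sorted(pairs)]


def evaluate_pair(
    pair: DuplicationPair,
    cds: Mapping[str, str],
    protein_alignment: tuple[str, str] | None = None,
    clock: ClockParams | None = None,
) -> DuplicationPair:
    """Fill in Ka/Ks, selection class and clock age for a duplication pair.

    When no protein alignment is given, one is computed by global alignment
    of the translated CDS.
    """
    cds_a, cds_b = cds[pair.gene_a], cds[pair.gene_b]
    if protein_alignment is None:
        prot_a, prot_b = translate(cds_a), translate(cds_b)
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -0.5
        aln = aligner.align(prot_a, prot_b)[0]
        protein_alignment = (str(aln[0]), str(aln[1]))
    pairs = codon_align(cds_a, cds_b, protein_alignment)
    result = ng86_kaks(pairs)
    pair.kaks = result
    pair.selection = classify_selection(result)
    pair.t_mya = divergence_time(result.ks, clock)
    return pair
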