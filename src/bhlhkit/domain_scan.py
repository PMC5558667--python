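"""Consensus-profile domain scanning and protein physicochemistry.

The bHLH domain is modeled as a per-position allowed-residue profile with a
variable-length loop. A protein is scanned exhaustively over all start
positions and loop lengths; mismatches are counted only at conserved
positions, and a domain is accepted when the count does not exceed the
mismatch budget (default 9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
REGIONS = ("basic", "helix1", "loop", "helix2")

DEFAULT_MAX_MISMATCH = 9
DEFAULT_LOOP_MIN = 5
DEFAULT_LOOP_MAX = 25

#: profile labels the binding classifier depends on
CLASSIFIER_LABELS = (
    "His/Lys-9", "Glu-13", "Arg-14", "Gln-15", "Arg-16", "Arg-17",
    "Gln-22", "Leu-27", "Leu-54",
)

GAP = "-"


@dataclass
class ProfilePosition:
    index: int
    region: str
    allowed_residues: frozenset[str]
    is_conserved: bool
    label: str = ""
    canonical: str = ""


@dataclass
class ConsensusProfile:
    positions: list[ProfilePosition]
    loop_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self._by_index = {p.index: p for p in self.positions}
        self._by_label = {p.label: p.index for p in self.positions if p.label}

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def conserved_indices(self) -> list[int]:
        return [p.index for p in self.positions if p.is_conserved]

    def position(self, index: int) -> ProfilePosition:
        return self._by_index[index]

    def region_indices(self, region: str) -> list[int]:
        return [p.index for p in self.positions if p.region == region]

    def index_for_label(self, label: str) -> int:
        """Resolve a position label ('Glu-13', or any '<aa>-<n>' alias) to its index."""
        if label in self._by_label:
            return self._by_label[label]
        if "-" in label:
            try:
                idx = int(label.rsplit("-", 1)[1])
            except ValueError:
                raise KeyError(label) from None
            if idx in self._by_index:
                return idx
        raise KeyError(label)

    def consensus_sequence(self, loop_len: int | None = None) -> str:
        """Canonical domain sequence; extra loop residues are padded with 'G'."""
        if self.loop_span is None:
            return "".join(p.canonical or sorted(p.allowed_residues)[0] for p in self.positions)
        lo, hi = self.loop_span
        out = []
        for p in self.positions:
            out.append(p.canonical or sorted(p.allowed_residues)[0])
            if p.index == hi and loop_len is not None:
                out.append("G" * (loop_len - (hi - lo + 1)))
        return "".join(out)


def load_profile(path: str | Path | None = None) -> ConsensusProfile:
    """Load a consensus profile TSV (columns: index, region, allowed_residues,
    conserved, label[, canonical]); None loads the shipped default.

    A profile that declares a loop region is treated as a full classification
    profile and must carry every label the binding classifier needs.
    """
    if path is None:
        path = resources.files("bhlhkit.data") / "bhlh_profile.tsv"
    positions: list[ProfilePosition] = []
    with open(str(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            idx = int(parts[col["index"]])
            region = parts[col["region"]]
            raw = parts[col["allowed_residues"]]
            allowed = frozenset(AMINO_ACIDS) if raw == "*" else frozenset(raw)
            conserved = parts[col["conserved"]] in ("1", "true", "True")
            label = parts[col["label"]] if "label" in col and len(parts) > col["label"] else ""
            canonical = parts[col["canonical"]] if "canonical" in col and len(parts) > col["canonical"] else ""
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r} at index {idx}")
            if not allowed or not allowed <= frozenset(AMINO_ACIDS):
                raise ValueError(f"invalid allowed-residue set at index {idx}")
            positions.append(ProfilePosition(idx, region, allowed, conserved, label, canonical))

    indices = [p.index for p in positions]
    if indices != sorted(set(indices)) or (indices and indices[0] != 1):
        raise ValueError("profile indices must be strictly increasing from 1")
    loop = [p.index for p in positions if p.region == "loop"]
    loop_span = (min(loop), max(loop)) if loop else None
    profile = ConsensusProfile(positions, loop_span)
    if loop_span is not None:
        labels = {p.label for p in positions}
        missing = [l for l in CLASSIFIER_LABELS if l not in labels]
        if missing:
            raise ValueError(f"profile missing classifier label(s): {', '.join(missing)}")
    return profile


@dataclass
class DomainHit:
    protein_id: str
    start: int  # 1-based inclusive protein coordinates
    end: int
    residue_at: dict[int, str]  # profile index -> residue or '-'
    mismatch_count: int
    accepted: bool = False
    loop_length: int | None = None
    protein_position: dict[int, int] = field(default_factory=dict)  # profile index -> residue no.

    @property
    def found(self) -> bool:
        return self.start > 0


def _no_hit(protein_id: str) -> DomainHit:
    return DomainHit(protein_id, 0, 0, {}, mismatch_count=10**9, accepted=False)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_to_profile(
    protein: SequenceRecord,
    profile: ConsensusProfile,
    loop_min: int = DEFAULT_LOOP_MIN,
    loop_max: int = DEFAULT_LOOP_MAX,
) -> DomainHit:
    """Best-scoring placement of the profile in the protein.

    The profile is split at the loop: indices up to the loop end map to a
    contiguous prefix; helix2 indices map after loop_len residues, where
    loop_len ranges over [loop_min, loop_max]. Only full windows are scored.
    Ties are broken by smallest start, then shortest loop. Returns a no-hit
    sentinel (start=0) when the protein is shorter than the minimal window.
    """
    seq = protein.sequence
    plen = len(seq)
    if profile.loop_span is None:
        loop_lengths = [0]
        n_a = len(profile)
        offsets_a = {p.index: i for i, p in enumerate(profile.positions)}
        offsets_b: dict[int, int] = {}
        n_b = 0
        base_loop = 0
    else:
        loop_end = profile.loop_span[1]
        a_positions = [p for p in profile.positions if p.index <= loop_end]
        b_positions = [p for p in profile.positions if p.index > loop_end]
        n_a, n_b = len(a_positions), len(b_positions)
        offsets_a = {p.index: i for i, p in enumerate(a_positions)}
        offsets_b = {p.index: i for i, p in enumerate(b_positions)}
        base_loop = profile.loop_span[1] - profile.loop_span[0] + 1
        loop_lengths = list(range(max(loop_min, base_loop), loop_max + 1))

    min_window = n_a + n_b + (min(loop_lengths) - base_loop if profile.loop_span else 0)
    if plen < min_window:
        return _no_hit(protein.id)

    enc = _encode(seq)
    # per conserved position: 1 where the protein residue is NOT allowed
    def bad_vector(pos: ProfilePosition) -> np.ndarray:
        allowed = _encode("".join(sorted(pos.allowed_residues)))
        return (~np.isin(enc, allowed)).astype(np.int32)

    cons_a = [(offsets_a[p.index], bad_vector(p)) for p in profile.positions
              if p.is_conserved and p.index in offsets_a]
    cons_b = [(offsets_b[p.index], bad_vector(p)) for p in profile.positions
              if p.is_conserved and p.index in offsets_b]

    def segment_scores(cons: list[tuple[int, np.ndarray]], seg_len: int) -> np.ndarray:
        n_starts = plen - seg_len + 1
        if n_starts <= 0:
            return np.zeros(0, dtype=np.int32)
        total = np.zeros(n_starts, dtype=np.int32)
        for off, bad in cons:
            total += bad[off : off + n_starts]
        return total

    mism_a = segment_scores(cons_a, n_a)

    best: tuple[int, int, int] | None = None  # (mismatch, start0, loop_len)
    for L in loop_lengths:
        extra = L - base_loop
        window = n_a + extra + n_b
        n_starts = plen - window + 1
        if n_starts <= 0:
            continue
        if n_b:
            mism_b = segment_scores(cons_b, n_b)
            total = mism_a[:n_starts] + mism_b[n_a + extra : n_a + extra + n_starts]
        else:
            total = mism_a[:n_starts]
        s = int(np.argmin(total))
        cand = (int(total[s]), s, L)
        if best is None or cand < (best[0], best[1], best[2]):
            best = cand
    if best is None:
        return _no_hit(protein.id)

    mismatch, s0, L = best
    extra = L - base_loop
    residue_at: dict[int, str] = {}
    protein_position: dict[int, int] = {}
    for p in profile.positions:
        if p.index in offsets_a:
            pos0 = s0 + offsets_a[p.index]
        else:
            pos0 = s0 + n_a + extra + offsets_b[p.index]
        residue_at[p.index] = seq[pos0]
        protein_position[p.index] = pos0 + 1
    end = s0 + n_a + extra + n_b
    return DomainHit(
        protein_id=protein.id,
        start=s0 + 1,
        end=end,
        residue_at=residue_at,
        mismatch_count=mismatch,
        loop_length=L if profile.loop_span else None,
        protein_position=protein_position,
    )


def scan_proteome(
    proteins: Sequence[SequenceRecord],
    profile: ConsensusProfile,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    loop_min: int = DEFAULT_LOOP_MIN,
    loop_max: int = DEFAULT_LOOP_MAX,
) -> list[DomainHit]:
    """One best hit per protein, filtered to mismatch_count <= max_mismatch,
    ordered by protein id."""
    hits = []
    for rec in sorted(proteins, key=lambda r: r.id):
        hit = align_to_profile(rec, profile, loop_min, loop_max)
        if hit.found and hit.mismatch_count <= max_mismatch:
            hit.accepted = True
            hits.append(hit)
    return hits


@dataclass
class ConservationEntry:
    index: int
    modal_residue: str
    frequency: float
    conserved_in_dataset: bool


def position_conservation(
    hits: Sequence[DomainHit], threshold: float = 0.5
) -> list[ConservationEntry]:
    """Per profile index: frequency of the modal residue among non-gap entries;
    flagged when frequency strictly exceeds `threshold`."""
    if not hits:
        raise ValueError("position_conservation requires at least one hit")
    indices = sorted(hits[0].residue_at)
    report = []
    for idx in indices:
        residues = [h.residue_at.get(idx, GAP) for h in hits]
        residues = [r for r in residues if r != GAP]
        if not residues:
            report.append(ConservationEntry(idx, GAP, 0.0, False))
            continue
        values, counts = np.unique(residues, return_counts=True)
        top = int(np.argmax(counts))
        freq = counts[top] / len(residues)
        report.append(ConservationEntry(idx, str(values[top]), float(freq), freq > threshold))
    return report


# ---------------------------------------------------------------------------
# physicochemical properties


def _load_table(name: str, value_col: str) -> dict[str, float]:
    path = resources.files("bhlhkit.data") / name
    table: dict[str, float] = {}
    with open(str(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts and parts[0]:
                table[parts[0]] = float(parts[header.index(value_col)])
    return table


def _load_pka() -> dict[str, tuple[float, int]]:
    path = resources.files("bhlhkit.data") / "pka.tsv"
    table: dict[str, tuple[float, int]] = {}
    with open(str(path)) as fh:
        fh.readline()
        for line in fh:
            group, pka, sign = line.rstrip("\n").split("\t")
            table[group] = (float(pka), 1 if sign == "+" else -1)
    return table


@dataclass
class ProteinProperties:
    protein_id: str
    length: int
    mw: float
    pi: float
    gravy: float
    n_negative: int
    n_positive: int


def net_charge(sequence: str, ph: float, pka: Mapping[str, tuple[float, int]] | None = None) -> float:
    """Henderson–Hasselbalch net charge at a given pH (X residues ignored)."""
    pka = pka or _load_pka()

    def positive(pk: float) -> float:
        return 1.0 / (1.0 + 10 ** (ph - pk))

    def negative(pk: float) -> float:
        return -1.0 / (1.0 + 10 ** (pk - ph))

    charge = positive(pka["n_term"][0]) + negative(pka["c_term"][0])
    for aa in sequence:
        if aa in pka:
            pk, sign = pka[aa]
            charge += positive(pk) if sign > 0 else negative(pk)
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH of zero net charge by bisection on [0, 14].

    net_charge is strictly decreasing in pH, so the root is unique.
    """
    pka = _load_pka()
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        c = net_charge(sequence, mid, pka)
        if abs(c) < tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def protein_properties(protein: SequenceRecord) -> ProteinProperties:
    seq = protein.sequence
    if "X" in seq:
        warnings.warn(f"{protein.id}: X residues excluded from GRAVY/pI")
    clean = seq.replace("X", "")
    kd = _load_table("kyte_doolittle.tsv", "hydropathy")
    masses = _load_table("residue_masses.tsv", "average_mass")
    gravy = sum(kd[a] for a in clean) / len(clean) if clean else 0.0
    mw = sum(masses.get(a, 110.0) for a in seq) + masses["water"]
    return ProteinProperties(
        protein_id=protein.id,
        length=len(seq),
        mw=mw,
        pi=isoelectric_point(clean),
        gravy=gravy,
        n_negative=seq.count("D") + seq.count("E"),
        n_positive=seq.count("R") + seq.count("K"),
    )
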