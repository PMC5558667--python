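"""Residue-rule DNA-binding classification of accepted domains.

Categories:
  * NON_DNA_BINDING  — fewer than six basic residues (R/K/H) in the basic region
  * G_BOX            — Glu-13 and Arg-16 plus the G-box triple (His/Lys-9, Arg-17)
  * E_BOX_NON_G      — Glu-13 and Arg-16 without the full G-box triple
  * NON_E_BOX_BINDER — basic region retained but Glu-13/Arg-16 pair missing

Dimerization is flagged from Leu-27/Leu-54; the tetramerization flag requires
Arg-14, Gln-15 and Gln-22 simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .domain_scan import GAP, ConsensusProfile, DomainHit

BASIC_RESIDUES = frozenset("RKH")
MIN_BASIC = 6


class Category(str, Enum):
    G_BOX = "G_BOX"
    E_BOX_NON_G = "E_BOX_NON_G"
    NON_E_BOX_BINDER = "NON_E_BOX_BINDER"
    NON_DNA_BINDING = "NON_DNA_BINDING"


@dataclass
class BindingCall:
    protein_id: str
    category: Category
    basic_count: int
    has_his_lys9: bool
    has_glu13: bool
    has_arg16: bool
    has_arg17: bool
    has_leu27: bool
    has_leu54: bool
    tetramer_ready: bool


def _residue(hit: DomainHit, profile: ConsensusProfile, label: str) -> str:
    try:
        idx = profile.index_for_label(label)
    except KeyError:
        raise ValueError(f"profile lacks labeled position {label!r}") from None
    return hit.residue_at.get(idx, GAP)


def count_basic_residues(
    hit: DomainHit, profile: ConsensusProfile, mode: str = "basic_residues"
) -> int:
    """Count residues at basic-region profile positions; gaps are excluded.

    mode='basic_residues' counts R/K/H only (default); mode='aligned_residues'
    counts every aligned residue (the literal reading).
    """
    residues = [hit.residue_at.get(i, GAP) for i in profile.region_indices("basic")]
    residues = [r for r in residues if r != GAP]
    if mode == "aligned_residues":
        return len(residues)
    return sum(1 for r in residues if r in BASIC_RESIDUES)


def dimer_tetramer_flags(hit: DomainHit, profile: ConsensusProfile) -> dict[str, bool]:
    return {
        "has_leu27": _residue(hit, profile, "Leu-27") == "L",
        "has_leu54": _residue(hit, profile, "Leu-54") == "L",
        "tetramer_ready": (
            _residue(hit, profile, "Arg-14") == "R"
            and _residue(hit, profile, "Gln-15") == "Q"
            and _residue(hit, profile, "Gln-22") == "Q"
        ),
    }


def classify_binding(
    hit: DomainHit, profile: ConsensusProfile, basic_count_mode: str = "basic_residues"
) -> BindingCall:
    """Apply the four-way residue rule to one accepted hit.

    Decision order: basic deficit first, then the Glu-13/Arg-16 E-box pair,
    then the G-box triple.
    """
    basic_count = count_basic_residues(hit, profile, mode=basic_count_mode)
    has_his_lys9 = _residue(hit, profile, "His/Lys-9") in ("H", "K")
    has_glu13 = _residue(hit, profile, "Glu-13") == "E"
    has_arg16 = _residue(hit, profile, "Arg-16") == "R"
    has_arg17 = _residue(hit, profile, "Arg-17") == "R"

    if basic_count < MIN_BASIC:
        category = Category.NON_DNA_BINDING
    elif has_glu13 and has_arg16:
        category = Category.G_BOX if (has_his_lys9 and has_arg17) else Category.E_BOX_NON_G
    else:
        category = Category.NON_E_BOX_BINDER

    flags = dimer_tetramer_flags(hit, profile)
    return BindingCall(
        protein_id=hit.protein_id,
        category=category,
        basic_count=basic_count,
        has_his_lys9=has_his_lys9,
        has_glu13=has_glu13,
        has_arg16=has_arg16,
        has_arg17=has_arg17,
        **flags,
    )


def classify_all(
    hits: Sequence[DomainHit], profile: ConsensusProfile, basic_count_mode: str = "basic_residues"
) -> list[BindingCall]:
    return [classify_binding(h, profile, basic_count_mode) for h in hits]
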