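"""Wild-type sequence and single-position substitution panels.

The study system is a 15-residue mitochondrial localization peptide (MLP),
MEVQLGLGRVYPRPP, scanned by substituting the residue at one position (the
glutamate at position 2) with each of the other 19 standard amino acids,
giving a 20-member panel (wild type + 19 variants).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "PeptideSequence",
    "VariantPanel",
    "make_variant_panel",
    "panel_to_fasta",
    "panel_manifest",
    "write_panel_manifest",
]

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The wild-type mitochondrial localization peptide studied here.
WILD_TYPE_MLP = "MEVQLGLGRVYPRPP"


@dataclass(frozen=True)
class PeptideSequence:
    """An immutable one-letter peptide sequence with a text label.

    Input is case-insensitive; residues are stored upper-case. Sequences
    must contain only standard amino acids and be at least 3 residues long
    so that interior residues (with complete phi/psi pairs) exist.
    """

    residues: str
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 3:
            raise ValueError(
                f"peptide must have >= 3 residues, got {len(self.residues)}"
            )
        bad = set(self.residues) - set(STANDARD_AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"non-standard residue code(s) {sorted(bad)} in {self.residues!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class VariantPanel:
    """A complete single-position substitution panel.

    ``members`` holds the wild type first, then the 19 substitutions in
    alphabetical order of the substituted residue, labelled
    ``<prefix>_<wtAA><pos><newAA>`` (e.g. ``MLP_E2A``).
    """

    wild_type: PeptideSequence
    position: int  # 1-based
    members: tuple[PeptideSequence, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seqs = [m.residues for m in self.members]
        if len(seqs) != 20:
            raise ValueError(f"panel must contain 20 members, got {len(seqs)}")
        if len(set(seqs)) != len(seqs):
            raise ValueError("panel contains duplicate sequences")
        lengths = {len(s) for s in seqs}
        if lengths != {len(self.wild_type)}:
            raise ValueError("all panel members must share the wild-type length")
        p = self.position - 1
        for m in self.members:
            diffs = [j for j, (a, b) in enumerate(zip(m.residues, self.wild_type.residues)) if a != b]
            if diffs not in ([], [p]):
                raise ValueError(
                    f"member {m.label} differs from wild type at {diffs}, "
                    f"expected only position {self.position}"
                )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[PeptideSequence]:
        return iter(self.members)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.members]


def make_variant_panel(
    wild_type: PeptideSequence | str,
    position: int,
    prefix: str = "MLP",
) -> VariantPanel:
    """Build the full 20-member panel substituting ``position`` (1-based).

    The wild type comes first (label ``<prefix>_wt``), then the 19
    substitutions alphabetically by new residue.
    """
    if isinstance(wild_type, str):
        wild_type = PeptideSequence(wild_type, label=f"{prefix}_wt")
    else:
        wild_type = PeptideSequence(wild_type.residues, label=f"{prefix}_wt")
    if not 1 <= position <= len(wild_type):
        raise IndexError(
            f"position {position} out of range for length {len(wild_type)}"
        )
    wt_aa = wild_type[position - 1]
    members = [wild_type]
    for aa in STANDARD_AMINO_ACIDS:
        if aa == wt_aa:
            continue
        residues = (
            wild_type.residues[: position - 1] + aa + wild_type.residues[position:]
        )
        members.append(
            PeptideSequence(residues, label=f"{prefix}_{wt_aa}{position}{aa}")
        )
    return VariantPanel(wild_type=wild_type, position=position, members=tuple(members))


def panel_to_fasta(panel: VariantPanel, path: str | Path) -> None:
    """Write the panel as FASTA, one record per member (ID = label)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(m.residues), id=m.label, description="") for m in panel
    ]
    seqio_write(records, str(path), "fasta")


def panel_manifest(panel: VariantPanel) -> list[dict]:
    """JSON-serializable manifest: label, sequence, position, substitution."""
    wt_aa = panel.wild_type[panel.position - 1]
    out = []
    for m in panel:
        new_aa = m[panel.position - 1]
        out.append(
            {
                "label": m.label,
                "sequence": m.residues,
                "position": panel.position,
                "substitution": None if new_aa == wt_aa else f"{wt_aa}{panel.position}{new_aa}",
            }
        )
    return out


def write_panel_manifest(panel: VariantPanel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(panel_manifest(panel), indent=2) + "\n")
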