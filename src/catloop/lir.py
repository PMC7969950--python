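"""LC3-interacting region (LIR) core-consensus scanner.

Atg8/LC3/GABARAP-binding proteins carry a short linear LIR motif with core
consensus ``[WFY]xx[ILV]`` — an aromatic residue, two arbitrary residues,
then a large hydrophobic residue.  Hits are reported in the field's
hexamer convention: the 4-residue core plus its two upstream flanking
residues, with 1-based inclusive coordinates (so a hit reported as
``146 DVYKLL 151`` has its aromatic Y at 148 and hydrophobic L at 151).

Only the core consensus is scanned; no position-specific scoring or
disorder filtering is applied, so scanning a full-length protein typically
yields more raw hits than a curated candidate list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "ProteinSequence",
    "LirHit",
    "AlphabetError",
    "CORE_PATTERN",
    "scan",
    "check_candidates",
    "scan_fasta",
    "hits_to_tsv",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

#: the LIR core consensus (WFY)xx(ILV); lookahead so overlapping cores all match
CORE_PATTERN = re.compile(r"(?=([WFY]..[ILV]))")

AROMATIC = set("WFY")
HYDROPHOBIC = set("ILV")


class AlphabetError(ValueError):
    """Sequence contains characters outside the amino-acid alphabet."""


@dataclass(frozen=True)
class ProteinSequence:
    identifier: str
    residues: str

    def __post_init__(self) -> None:
        res = self.residues.upper()
        bad = set(res) - AMINO_ACIDS
        if bad:
            raise AlphabetError(
                f"{self.identifier}: invalid residue(s) {''.join(sorted(bad))!r}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LirHit:
    """One consensus match, reported as a flanked hexamer.

    ``start``/``end`` are 1-based inclusive coordinates of the hexamer
    (``end = start + 5`` for full hexamers); ``core`` is positions 3–6 of
    the hexamer, the consensus-matching tetramer.  Hits within two residues
    of the N-terminus report a truncated flank (shorter hexamer, same core
    coordinates).
    """

    seq_id: str
    start: int
    end: int
    hexamer: str
    core: str

    @property
    def aromatic_position(self) -> int:
        """1-based sequence position of the core aromatic residue."""
        return self.end - 3

    @property
    def hydrophobic_position(self) -> int:
        return self.end


def scan(seq: ProteinSequence) -> list[LirHit]:
    """Return every LIR core-consensus match in the sequence, in start order.

    Overlapping matches are all reported.  An empty sequence yields an
    empty list.
    """
    hits: list[LirHit] = []
    res = seq.residues
    for m in CORE_PATTERN.finditer(res):
        core_start = m.start()          # 0-based index of the aromatic residue
        flank_start = max(0, core_start - 2)
        hexamer = res[flank_start : core_start + 4]
        hits.append(
            LirHit(
                seq_id=seq.identifier,
                start=flank_start + 1,
                end=core_start + 4,
                hexamer=hexamer,
                core=m.group(1),
            )
        )
    return hits


def matches_core(hexamer: str) -> bool:
    """Whether positions 3–6 of a hexamer match the core consensus."""
    if len(hexamer) != 6:
        raise ValueError(f"candidate must be exactly 6 residues, got {hexamer!r}")
    core = hexamer.upper()[2:]
    return core[0] in AROMATIC and core[3] in HYDROPHOBIC


def check_candidates(hexamers: Iterable[str]) -> dict[str, bool]:
    """Per-hexamer report of whether the core consensus is satisfied."""
    return {h: matches_core(h) for h in hexamers}


def scan_fasta(path: str | Path) -> list[LirHit]:
    """Scan every record of a (multi-)FASTA file."""
    hits: list[LirHit] = []
    for record in SeqIO.parse(str(path), "fasta"):
        hits.extend(scan(ProteinSequence(record.id, str(record.seq))))
    return hits


def hits_to_tsv(hits: Iterable[LirHit], path: str | Path) -> Path:
    path = Path(path)
    lines = ["seq_id\tstart\tend\thexamer\tcore"]
    for h in hits:
        lines.append(f"{h.seq_id}\t{h.start}\t{h.end}\t{h.hexamer}\t{h.core}")
    path.write_text("\n".join(lines) + "\n")
    return path
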