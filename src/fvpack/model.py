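"""Core data model for Kabat–Chothia-numbered antibody Fv domains.

Antibody variable domains are compared position-by-position using a
normalised residue numbering (Kabat–Chothia) in which equivalent framework
positions carry the same label across antibodies, with single-letter
insertion codes (e.g. ``H100B``) absorbing loop-length variation.  This
module defines the position algebra, numbered sequences, the per-structure
container used throughout the pipeline, and the canonical 20-position
VH–VL interface selection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

#: The 20 interface positions used for clustering, in canonical order.
INTERFACE_POSITIONS: tuple["PositionId", ...]


class FvError(ValueError):
    """Structured error for domain-model violations."""


@total_ordering
@dataclass(frozen=True)
class PositionId:
    """A chain-qualified Kabat–Chothia position such as L44 or H100B.

    Ordering is total within a chain: first by residue number, then by
    insertion code, with the uninserted position sorting before ``A``.
    Cross-chain comparisons order L before H (light chain first), which
    gives numbered sequences over both chains a stable ordering.
    """

    chain: str
    number: int
    insertion: Optional[str] = None

    _RE = re.compile(r"^([LH])(\d+)([A-Z]?)$")

    def __post_init__(self) -> None:
        if self.chain not in ("L", "H"):
            raise FvError(f"chain must be 'L' or 'H', got {self.chain!r}")
        if self.number <= 0:
            raise FvError(f"position number must be positive, got {self.number}")
        ins = self.insertion
        if ins is not None and not (len(ins) == 1 and "A" <= ins <= "Z"):
            raise FvError(f"insertion code must be a single uppercase letter, got {ins!r}")

    @classmethod
    def parse(cls, text: str) -> "PositionId":
        m = cls._RE.match(text.strip())
        if not m:
            raise FvError(f"cannot parse position {text!r}")
        chain, num, ins = m.groups()
        return cls(chain, int(num), ins or None)

    def render(self) -> str:
        return f"{self.chain}{self.number}{self.insertion or ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def _key(self) -> tuple:
        # chain L sorts before H; '' sorts before 'A'
        return (0 if self.chain == "L" else 1, self.number, self.insertion or "")

    def __lt__(self, other: "PositionId") -> bool:
        if not isinstance(other, PositionId):
            return NotImplemented
        return self._key() < other._key()


def _pp(text: str) -> PositionId:
    return PositionId.parse(text)


INTERFACE_POSITIONS = tuple(
    _pp(p)
    for p in (
        "L34 L36 L38 L43 L44 L46 L87 L89 L98 L100 "
        "H35 H37 H39 H44 H45 H47 H91 H93 H103 H105"
    ).split()
)


class NumberedSequence:
    """An ordered map from :class:`PositionId` to a one-letter residue.

    Keys must be strictly increasing under the position ordering; residues
    are one of the 20 amino-acid letters or the gap symbol ``-``.
    """

    def __init__(self, items: Mapping[PositionId, str] | Iterable[tuple[PositionId, str]]):
        pairs = list(items.items()) if isinstance(items, Mapping) else list(items)
        pairs.sort(key=lambda kv: kv[0])
        for i in range(1, len(pairs)):
            if not pairs[i - 1][0] < pairs[i][0]:
                raise FvError(f"duplicate position {pairs[i][0]}")
        for pos, res in pairs:
            if res != GAP and res not in AA_ALPHABET:
                raise FvError(f"invalid residue {res!r} at {pos}")
        self._positions = tuple(p for p, _ in pairs)
        self._map = dict(pairs)

    @classmethod
    def from_strings(cls, items: Mapping[str, str]) -> "NumberedSequence":
        return cls({PositionId.parse(k): v for k, v in items.items()})

    @property
    def positions(self) -> tuple[PositionId, ...]:
        return self._positions

    def get(self, pos: PositionId, default: Optional[str] = None) -> Optional[str]:
        return self._map.get(pos, default)

    def __getitem__(self, pos: PositionId) -> str:
        return self._map[pos]

    def __contains__(self, pos: PositionId) -> bool:
        return pos in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self):
        return iter(self._positions)

    def items(self):
        return ((p, self._map[p]) for p in self._positions)

    def __eq__(self, other) -> bool:
        return isinstance(other, NumberedSequence) and dict(self.items()) == dict(other.items())


@dataclass
class FvStructure:
    """One antibody Fv: numbered sequences, Cα coordinates and metadata.

    ``ca_coords`` maps positions to 3-vectors in Å.  ``backbone`` optionally
    carries extra backbone atoms (atom name -> 3-vector) for the positions
    where the peptide-bond omega dihedral is analysed.  ``antigen`` is a
    list of ``(element, xyz, vdw_radius)`` for bound-antigen atoms.
    """

    id: str
    light_type: str = "unknown"  # kappa | lambda | unknown
    species: str = ""
    resolution: Optional[float] = None
    sequences: dict[str, NumberedSequence] = field(default_factory=dict)
    ca_coords: dict[PositionId, np.ndarray] = field(default_factory=dict)
    antigen: list[tuple[str, np.ndarray, float]] = field(default_factory=list)
    backbone: dict[PositionId, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.light_type not in ("kappa", "lambda", "unknown"):
            raise FvError(f"light_type must be kappa/lambda/unknown, got {self.light_type!r}")
        for pos, xyz in self.ca_coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise FvError(f"bad coordinate for {pos}")
            self.ca_coords[pos] = xyz
            seq = self.sequences.get(pos.chain)
            if seq is None or pos not in seq:
                raise FvError(f"coordinate key {pos} has no residue in chain {pos.chain}")

    @property
    def bound(self) -> bool:
        """True iff a non-empty antigen atom set is attached."""
        return len(self.antigen) > 0

    def residue(self, pos: PositionId) -> Optional[str]:
        seq = self.sequences.get(pos.chain)
        return None if seq is None else seq.get(pos)


@dataclass
class InterfaceSelection:
    """The canonical 20-position interface extracted from one structure.

    ``residues`` and ``coords`` follow the canonical tuple order; positions
    absent from the structure are flagged in ``mask`` (True = missing) and
    carry a gap residue and NaN coordinates — never silently dropped.
    """

    structure_id: str
    residues: tuple[str, ...]
    coords: np.ndarray  # (20, 3), NaN rows where masked
    mask: np.ndarray  # (20,) bool, True = missing

    @property
    def positions(self) -> tuple[PositionId, ...]:
        return INTERFACE_POSITIONS

    def n_missing(self) -> int:
        return int(self.mask.sum())


def resolve_H100X(heavy: NumberedSequence) -> PositionId:
    """Return the last heavy-chain position strictly before H101.

    The heavy-chain CDR3 varies in length, so the residue packing against
    light-chain position 36 carries a structure-specific label (H100, H100A,
    H100B, ...).  It is identified as the greatest occupied position that
    precedes H101; with no insertion codes this degenerates to H100.
    """
    h101 = PositionId("H", 101)
    before = [p for p in heavy.positions if p.chain == "H" and p < h101]
    if not before:
        raise FvError("H3 loop absent")
    return max(before)


def extract_interface(s: FvStructure, max_missing: int = 2) -> InterfaceSelection:
    """Extract the canonical 20 interface positions from a structure.

    Positions without a residue or Cα coordinate are masked.  More than
    ``max_missing`` masked positions raises, since pairwise scores over a
    heavily incomplete interface are not comparable.
    """
    residues = []
    coords = np.full((len(INTERFACE_POSITIONS), 3), np.nan)
    mask = np.zeros(len(INTERFACE_POSITIONS), dtype=bool)
    for i, pos in enumerate(INTERFACE_POSITIONS):
        res = s.residue(pos)
        xyz = s.ca_coords.get(pos)
        if res is None or res == GAP or xyz is None:
            mask[i] = True
            residues.append(GAP)
        else:
            residues.append(res)
            coords[i] = xyz
    if int(mask.sum()) > max_missing:
        raise FvError(
            f"interface incomplete: {int(mask.sum())} of {len(INTERFACE_POSITIONS)} "
            f"positions missing in {s.id} (max {max_missing})"
        )
    return InterfaceSelection(s.id, tuple(residues), coords, mask)


def interface_identity(a: InterfaceSelection, b: InterfaceSelection) -> float:
    """Fraction of identical residues over mutually unmasked positions."""
    shared = ~(a.mask | b.mask)
    n = int(shared.sum())
    if n == 0:
        raise FvError("no mutually unmasked interface positions")
    same = sum(
        1 for i in np.nonzero(shared)[0] if a.residues[i] == b.residues[i]
    )
    return same / n
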