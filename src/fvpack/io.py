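"""Reading and writing Fv coordinate files.

Input structures are standard PDB or mmCIF files accompanied by a
numbering map (TSV: chain, author_resid, kabat_chothia_position) that
assigns Kabat–Chothia positions to author residue numbers; for
"Chothia-numbered PDB" files, where the author numbering already is the
Kabat–Chothia numbering, the map may be omitted.  Fixtures are written in
the fixed-column PDB dialect so external viewers open them.

Parsing goes through gemmi; only Cα atoms (plus the L43/L44 backbone
atoms used for the omega dihedral) and antigen heavy atoms are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .antigens import vdw_radius
from .model import FvError, FvStructure, NumberedSequence, PositionId

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class AtomRecord:
    """One coordinate-file atom (plumbing carrier, not a domain object)."""

    element: str
    name: str
    chain: str
    author_resid: str  # number plus optional insertion code, e.g. "100B"
    coord: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coord)):
            raise FvError("non-finite atom coordinate")
        if not 0.0 <= self.occupancy <= 1.0:
            raise FvError(f"occupancy {self.occupancy} outside [0,1]")


@dataclass
class ChainSpec:
    """Names the light/heavy chains and optional antigen chains in a file."""

    light: str
    heavy: str
    antigen: Sequence[str] = field(default_factory=tuple)


NumberingMap = dict[tuple[str, str], PositionId]


def read_numbering_map(path) -> NumberingMap:
    """Load a chain/author-residue -> Kabat–Chothia position map (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chain", "author_resid", "kabat_chothia_position"}
    if not required.issubset(df.columns):
        raise FvError(f"numbering map must have columns {sorted(required)}")
    return {
        (row.chain, str(row.author_resid)): PositionId.parse(row.kabat_chothia_position)
        for row in df.itertuples()
    }


def _residue_key(res: gemmi.Residue) -> str:
    icode = res.seqid.icode.strip()
    return f"{res.seqid.num}{icode}"


def _best_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # max occupancy, ties resolved by file order
    best = atoms[0]
    for a in atoms[1:]:
        if a.occ > best.occ:
            best = a
    return best


def read_structure(
    path,
    numbering_map: Optional[NumberingMap] = None,
    chain_spec: Optional[ChainSpec] = None,
    structure_id: Optional[str] = None,
) -> FvStructure:
    """Read one Fv from a PDB/mmCIF file.

    With ``numbering_map=None`` the author numbering is taken to be the
    Kabat–Chothia numbering already (Chothia-numbered PDB).  Altlocs
    resolve to the highest-occupancy conformer (ties: first in file).
    Mapped positions without a Cα keep their residue but get no
    coordinate, so they are masked downstream rather than dropped.
    """
    chain_spec = chain_spec or ChainSpec("L", "H", ("X",))
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = {ch.name: ch for ch in model}
    for required in (chain_spec.light, chain_spec.heavy):
        if required not in chains:
            raise FvError(f"chain {required!r} not found in {path}")

    sequences: dict[str, dict[PositionId, str]] = {"L": {}, "H": {}}
    ca_coords: dict[PositionId, np.ndarray] = {}
    backbone: dict[PositionId, dict[str, np.ndarray]] = {}

    for fv_chain, chain_name in (("L", chain_spec.light), ("H", chain_spec.heavy)):
        for res in chains[chain_name]:
            key = _residue_key(res)
            if numbering_map is not None:
                pos = numbering_map.get((chain_name, key))
                if pos is None:
                    continue
            else:
                try:
                    pos = PositionId.parse(f"{fv_chain}{key}")
                except FvError:
                    continue
            one = THREE_TO_ONE.get(res.name.upper())
            if one is None:
                continue
            sequences[fv_chain][pos] = one
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            if "CA" in by_name:
                a = _best_altloc(by_name["CA"])
                ca_coords[pos] = np.array([a.pos.x, a.pos.y, a.pos.z])
            else:
                warnings.warn(f"{path}: no CA for {pos}; position masked", stacklevel=2)
            extra = {}
            for name in ("N", "C"):
                if name in by_name:
                    a = _best_altloc(by_name[name])
                    extra[name] = np.array([a.pos.x, a.pos.y, a.pos.z])
            if extra and pos in ca_coords:
                extra["CA"] = ca_coords[pos]
                backbone[pos] = extra

    antigen = []
    for name in chain_spec.antigen:
        if name not in chains:
            continue
        for res in chains[name]:
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                el = atom.element.name.upper()
                antigen.append(
                    (el, np.array([atom.pos.x, atom.pos.y, atom.pos.z]), vdw_radius(el))
                )

    return FvStructure(
        id=structure_id or Path(str(path)).stem,
        sequences={c: NumberedSequence(s) for c, s in sequences.items()},
        ca_coords=ca_coords,
        antigen=antigen,
        backbone=backbone,
    )


def write_fixture(s: FvStructure, path) -> None:
    """Write a Chothia-numbered PDB fixture for one structure.

    Chains L and H carry the Cα trace (plus any stored backbone N/C
    atoms); antigen atoms go to HETATM chain X.  Round-trips through
    :func:`read_structure` to PDB precision (1e-3 Å).
    """
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")

    for chain_id in ("L", "H"):
        chain = gemmi.Chain(chain_id)
        seq = s.sequences.get(chain_id)
        if seq is None:
            continue
        for pos in seq.positions:
            resname = ONE_TO_THREE.get(seq[pos])
            if resname is None:
                continue
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(pos.number, pos.insertion or " ")
            atoms = {}
            if pos in s.ca_coords:
                atoms["CA"] = s.ca_coords[pos]
            for name, xyz in s.backbone.get(pos, {}).items():
                atoms[name] = xyz
            for name in ("N", "CA", "C"):
                if name not in atoms:
                    continue
                a = gemmi.Atom()
                a.name = name
                a.element = gemmi.Element("N" if name == "N" else "C")
                x, y, z = atoms[name]
                a.pos = gemmi.Position(x, y, z)
                a.occ = 1.0
                res.add_atom(a)
            if len(res) > 0:
                chain.add_residue(res)
        model.add_chain(chain)

    if s.antigen:
        chain = gemmi.Chain("X")
        for i, (el, xyz, _r) in enumerate(s.antigen, start=1):
            res = gemmi.Residue()
            res.name = "LIG"
            res.seqid = gemmi.SeqId(i, " ")
            res.het_flag = "H"
            a = gemmi.Atom()
            a.name = el
            a.element = gemmi.Element(el.capitalize())
            a.pos = gemmi.Position(*xyz)
            a.occ = 1.0
            res.add_atom(a)
            chain.add_residue(res)
        model.add_chain(chain)

    st.add_model(model)
    st.setup_entities()
    doc_path = Path(str(path))
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


METADATA_COLUMNS = ["id", "light_type", "species", "resolution", "bound"]


def write_metadata(structures: Sequence[FvStructure], path) -> None:
    rows = [
        {
            "id": s.id,
            "light_type": s.light_type,
            "species": s.species,
            "resolution": s.resolution if s.resolution is not None else "",
            "bound": s.bound,
        }
        for s in structures
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise FvError(f"metadata missing columns {sorted(missing)}")
    return df


def write_dataset(structures: Sequence[FvStructure], truth: pd.DataFrame, out_dir) -> None:
    """Write PDB fixtures, metadata TSV and the ground-truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in structures:
        write_fixture(s, out / f"{s.id}.pdb")
    write_metadata(structures, out / "metadata.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def read_dataset(in_dir, metadata: Optional[pd.DataFrame] = None) -> list[FvStructure]:
    """Read every ``*.pdb`` fixture in a directory, applying metadata."""
    in_dir = Path(in_dir)
    if metadata is None:
        meta_path = in_dir / "metadata.tsv"
        metadata = read_metadata(meta_path) if meta_path.exists() else None
    meta_by_id = {} if metadata is None else {str(r["id"]): r for _, r in metadata.iterrows()}
    structures = []
    for p in sorted(in_dir.glob("*.pdb")):
        s = read_structure(p)
        row = meta_by_id.get(s.id)
        if row is not None:
            s.light_type = str(row["light_type"])
            s.species = str(row["species"])
            res = row["resolution"]
            s.resolution = None if pd.isna(res) or res == "" else float(res)
        structures.append(s)
    return structures
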