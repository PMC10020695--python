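"""Protein backbone extraction from PDB text and exact 3-D geometry primitives.

The package works on a deliberately minimal representation of a protein
chain: the four backbone atoms N, CA, C, O of each residue, in angstroms.
That is all the geometry that beta-turn detection and classification needs
(torsions of the two central residues, the CA(i)-CA(i+3) span and the
turn-closing hydrogen bond), so side chains, hydrogens from the input file,
and heteroatoms are discarded at parse time.

Parsing and serialisation of the fixed-column PDB format are delegated to
``gemmi``; this module only maps between gemmi structures and the package's
:class:`BackboneChain` containers and implements the distance/dihedral
primitives used throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "BackboneResidue",
    "BackboneChain",
    "EmptyStructureError",
    "read_backbone",
    "write_backbone",
    "distance",
    "dihedral",
    "STANDARD_RESIDUES",
]

logger = logging.getLogger(__name__)

#: C(i)-N(i+1) distances above this many angstroms mark a chain break.
PEPTIDE_BOND_CUTOFF = 2.0

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class EmptyStructureError(ValueError):
    """Raised when PDB input contains no usable ATOM records."""


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is requested for collinear/coincident points."""


@dataclass
class BackboneResidue:
    """Backbone atoms of one residue.

    ``residue_number`` keeps the author numbering of the source file;
    ``insertion_code`` (if any) disambiguates inserted residues. ``o_xyz``
    may be absent (e.g. truncated C-terminal residues).
    """

    chain_id: str
    residue_number: int
    residue_name: str
    n_xyz: np.ndarray | None
    ca_xyz: np.ndarray
    c_xyz: np.ndarray | None
    o_xyz: np.ndarray | None = None
    insertion_code: str = ""

    def __post_init__(self) -> None:
        for name in ("n_xyz", "ca_xyz", "c_xyz", "o_xyz"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (3,) or not np.all(np.isfinite(v)):
                    raise ValueError(f"{name} must be a finite 3-vector, got {v!r}")
                setattr(self, name, v)
        if self.ca_xyz is None:
            raise ValueError("CA coordinates are required")

    @property
    def is_standard(self) -> bool:
        return self.residue_name in STANDARD_RESIDUES

    @property
    def label(self) -> str:
        """Residue number with insertion-code suffix, e.g. ``'52A'``."""
        return f"{self.residue_number}{self.insertion_code}"


@dataclass
class BackboneChain:
    """Ordered backbone residues of one chain, in file order."""

    chain_id: str
    residues: list[BackboneResidue] = field(default_factory=list)
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)

    def bonded_mask(self) -> np.ndarray:
        """Boolean array: entry j is True when residues j and j+1 share a
        peptide bond (C(j)-N(j+1) within :data:`PEPTIDE_BOND_CUTOFF`)."""
        out = np.zeros(max(len(self.residues) - 1, 0), dtype=bool)
        for j in range(len(out)):
            c = self.residues[j].c_xyz
            n = self.residues[j + 1].n_xyz
            if c is not None and n is not None:
                out[j] = distance(c, n) <= PEPTIDE_BOND_CUTOFF
        return out

    def find(self, residue_number: int, insertion_code: str = "") -> BackboneResidue:
        for r in self.residues:
            if r.residue_number == residue_number and r.insertion_code == insertion_code:
                return r
        raise KeyError(f"residue {residue_number}{insertion_code} not in chain {self.chain_id}")


def distance(p, q) -> float:
    """Euclidean distance between two points, in angstroms."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.linalg.norm(p - q))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC convention: an eclipsed (cis) arrangement is 0 deg and trans is
    180 deg; the sign flips under mirror reflection, and the value is
    unchanged when the four points are taken in reverse order.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-10 or np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("degenerate dihedral: collinear or coincident points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:  # map to (-180, 180]
        ang += 360.0
    return ang


_BACKBONE_NAMES = ("N", "CA", "C", "O")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by alphabetically first altloc code
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_backbone(
    pdb_text: str,
    model_index: int = 0,
    altloc_policy: str = "occupancy",
) -> list[BackboneChain]:
    """Parse PDB-format text into one :class:`BackboneChain` per chain.

    Only ATOM records contribute; HETATM (waters, ligands) are dropped, as
    are all atoms other than N, CA, C, O. Residues with no CA are skipped
    with a warning. ``model_index`` selects the model of a multi-model file
    (0 = first, matching single-model crystal structures). ``altloc_policy``
    currently supports ``"occupancy"`` (keep the highest-occupancy
    alternate, ties to the alphabetically first code) and ``"first"``.
    """
    if altloc_policy not in ("occupancy", "first"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise EmptyStructureError("empty structure: no ATOM records found")
    try:
        model = st[model_index]
    except IndexError:
        raise IndexError(
            f"model_index {model_index} out of range for {len(st)} model(s)"
        ) from None

    chains: list[BackboneChain] = []
    n_atoms = 0
    for ch in model:
        out = BackboneChain(
            chain_id=ch.name,
            source_label=f"{st.name or 'structure'}/model{model_index}",
        )
        for res in ch:
            if res.het_flag == "H":
                continue  # HETATM: waters, ligands, modified hetero groups
            coords: dict[str, np.ndarray] = {}
            for name in _BACKBONE_NAMES:
                cands = [a for a in res if a.name == name]
                if not cands:
                    continue
                if altloc_policy == "occupancy":
                    atom = _pick_altloc(cands)
                else:
                    atom = cands[0]
                coords[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                n_atoms += 1
            if "CA" not in coords:
                logger.warning(
                    "skipping residue %s %s%s in chain %s: no CA atom",
                    res.name, res.seqid.num, res.seqid.icode.strip(), ch.name,
                )
                continue
            out.residues.append(
                BackboneResidue(
                    chain_id=ch.name,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    n_xyz=coords.get("N"),
                    ca_xyz=coords["CA"],
                    c_xyz=coords.get("C"),
                    o_xyz=coords.get("O"),
                    insertion_code=res.seqid.icode.strip(),
                )
            )
        if out.residues:
            chains.append(out)
    if not chains or n_atoms == 0:
        raise EmptyStructureError("empty structure: no ATOM records found")
    return chains


_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def write_backbone(chains: list[BackboneChain]) -> str:
    """Serialise chains as fixed-column PDB ATOM records (3-decimal coords)."""
    if not chains:
        raise ValueError("no chains to write")
    st = gemmi.Structure()
    st.name = "backbone"
    model = gemmi.Model(1)
    serial = 0
    for chain in chains:
        ch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            r = gemmi.Residue()
            r.name = res.residue_name
            r.seqid = gemmi.SeqId(res.residue_number, res.insertion_code or " ")
            r.het_flag = "A"
            for name in _BACKBONE_NAMES:
                xyz = getattr(res, f"{name.lower()}_xyz")
                if xyz is None:
                    continue
                a = gemmi.Atom()
                a.name = name
                a.element = gemmi.Element(_ELEMENTS[name])
                a.pos = gemmi.Position(*map(float, xyz))
                a.occ = 1.0
                a.b_iso = 0.0
                serial += 1
                a.serial = serial
                r.add_atom(a)
            ch.add_residue(r)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))
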