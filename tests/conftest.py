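import numpy as np
import pytest
from hypothesis import settings

from lexatools import build_peptide, ideal_type_ii_turn_spec, synthetic_csr_spec

settings.register_profile("repeatable", deadline=None, derandomize=True)
settings.load_profile("repeatable")


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    altloc: str = " ",
    icode: str = " ",
    element: str | None = None,
    record: str = "ATOM",
) -> str:
    """One fixed-column PDB ATOM/HETATM record (for hand-built fixtures)."""
    if element is None:
        element = name.strip()[0]
    name_fmt = f" {name:<3}" if len(name) < 4 else name
    return (
        f"{record:<6}{serial:>5} {name_fmt}{altloc}{resname:>3} {chain}"
        f"{resnum:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2}"
    )


def backbone_lines(serial0, resname, chain, resnum, origin, **kwargs):
    """Four roughly-placed backbone atoms for one residue."""
    x, y, z = origin
    return [
        atom_line(serial0, "N", resname, chain, resnum, x, y, z, **kwargs),
        atom_line(serial0 + 1, "CA", resname, chain, resnum, x + 1.46, y, z, **kwargs),
        atom_line(serial0 + 2, "C", resname, chain, resnum, x + 2.0, y + 1.42, z, **kwargs),
        atom_line(serial0 + 3, "O", resname, chain, resnum, x + 1.75, y + 2.2, z - 0.9, **kwargs),
    ]


@pytest.fixture
def four_residue_pdb() -> str:
    """One chain, 4 residues, plus HETATM waters that must be ignored."""
    lines = []
    serial = 1
    for i in range(4):
        lines += backbone_lines(serial, "ALA", "A", i + 1, (3.5 * i, 0.0, 0.0))
        serial += 4
    lines.append(atom_line(serial, "O", "HOH", "A", 101, 20.0, 20.0, 20.0, record="HETATM"))
    lines.append(atom_line(serial + 1, "O", "HOH", "A", 102, 22.0, 20.0, 20.0, record="HETATM"))
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_chain_pdb() -> str:
    lines = []
    serial = 1
    for chain in ("A", "B"):
        for i in range(3):
            lines += backbone_lines(serial, "GLY", chain, i + 1, (3.5 * i, 0.0, 0.0))
            serial += 4
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def type_ii_chain():
    """Built peptide with one ideal type II turn at positions 3-6."""
    return build_peptide(ideal_type_ii_turn_spec(n_flank=2))


@pytest.fixture
def csr_chain():
    """Synthetic rebuild of the LexA cleavage-site-region turn (83-86)."""
    return build_peptide(synthetic_csr_spec())


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
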