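"""Beta-turn detection, classification and hydrogen-bond geometry.

A beta-turn is a four-residue chain reversal (positions i..i+3) whose
CA(i)-CA(i+3) distance is below ~7 A and which is not part of a regular
helix. Turns are classified into the standard types I, I', II, II', VIII,
VIa1, VIa2, VIb (plus the catch-all IV) from the phi/psi torsions of the
two central residues, residues i+1 and i+2. The classic assignment rule is
used: all four angles within +/-30 deg of a type's canonical values, with
at most one angle allowed out to +/-45 deg; the VI types additionally
require a cis peptide bond into residue i+2.

The motivating application is the cleavage-site region (CSR) of the
bacterial SOS repressor LexA, a tight type II turn whose geometry
beta-turn-mimetic inhibitors try to reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import BackboneChain, DegenerateGeometryError, dihedral, distance

__all__ = [
    "TorsionRecord",
    "TurnAssignment",
    "TurnType",
    "TurnTypeTable",
    "DEFAULT_TURN_TABLE",
    "compute_torsions",
    "classify_turn",
    "detect_turns",
    "turn_hbond",
    "place_amide_hydrogen",
]

#: Amide N-H bond length used when constructing the i+3 hydrogen, in A.
NH_BOND_LENGTH = 1.01

#: |omega| below this many degrees from 0 counts as a cis peptide bond.
CIS_OMEGA_TOLERANCE = 30.0


@dataclass
class TorsionRecord:
    """Backbone torsions of one residue; None where undefined (chain
    termini and either side of a chain break)."""

    residue_number: int
    residue_name: str
    phi: float | None
    psi: float | None
    omega: float | None  # peptide bond preceding this residue
    insertion_code: str = ""


@dataclass(frozen=True)
class TurnType:
    label: str
    phi1: float
    psi1: float
    phi2: float
    psi2: float
    requires_cis_at_i2: bool = False

    @property
    def angles(self) -> tuple[float, float, float, float]:
        return (self.phi1, self.psi1, self.phi2, self.psi2)


@dataclass(frozen=True)
class TurnTypeTable:
    """Canonical (phi1, psi1, phi2, psi2) per named turn type.

    ``strict_tolerance`` applies to all four angles; a single angle may
    instead match at ``relaxed_tolerance``. ``types`` are tried in order,
    strict matches before relaxed ones; anything unmatched is type IV.
    Users may extend the table (e.g. with newer clustering-derived turn
    labels) by passing extra entries.
    """

    types: tuple[TurnType, ...]
    strict_tolerance: float = 30.0
    relaxed_tolerance: float = 45.0
    catch_all: str = "IV"

    def __post_init__(self):
        if self.strict_tolerance <= 0 or self.relaxed_tolerance < self.strict_tolerance:
            raise ValueError("require 0 < strict_tolerance <= relaxed_tolerance")

    def extended(self, extra: list[TurnType]) -> "TurnTypeTable":
        return TurnTypeTable(
            types=self.types + tuple(extra),
            strict_tolerance=self.strict_tolerance,
            relaxed_tolerance=self.relaxed_tolerance,
            catch_all=self.catch_all,
        )


DEFAULT_TURN_TABLE = TurnTypeTable(
    types=(
        TurnType("I", -60.0, -30.0, -90.0, 0.0),
        TurnType("I'", 60.0, 30.0, 90.0, 0.0),
        TurnType("II", -60.0, 120.0, 80.0, 0.0),
        TurnType("II'", 60.0, -120.0, -80.0, 0.0),
        TurnType("VIII", -60.0, -30.0, -120.0, 120.0),
        TurnType("VIa1", -60.0, 120.0, -90.0, 0.0, requires_cis_at_i2=True),
        TurnType("VIa2", -120.0, 120.0, -60.0, 0.0, requires_cis_at_i2=True),
        TurnType("VIb", -135.0, 135.0, -75.0, 160.0, requires_cis_at_i2=True),
    )
)


@dataclass
class TurnAssignment:
    """One classified four-residue turn window starting at position i."""

    chain_id: str
    i_residue_number: int
    residue_names: tuple[str, str, str, str]
    phi1: float
    psi1: float
    phi2: float
    psi2: float
    omega2_cis: bool
    ca_distance_i_i3: float
    turn_type: str
    relaxed_match: bool
    o_n_distance: float | None = None
    o_h_distance: float | None = None
    i_index: int = field(default=-1, repr=False)  # index into chain.residues

    @property
    def sequence(self) -> str:
        return "-".join(self.residue_names)


def compute_torsions(chain: BackboneChain) -> list[TorsionRecord]:
    """Backbone phi/psi/omega for every residue of a chain.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i). Angles are left undefined at
    termini, across chain breaks (C-N > 2 A), and where a needed atom is
    missing.
    """
    res = chain.residues
    if len(res) < 2:
        raise ValueError("no torsions: chain must have at least 2 residues")
    bonded = chain.bonded_mask()
    if not bonded.any():
        raise ValueError("no torsions: no consecutively bonded residues")

    def _safe(*pts):
        if any(p is None for p in pts):
            return None
        try:
            return dihedral(*pts)
        except DegenerateGeometryError:
            return None

    out: list[TorsionRecord] = []
    for i, r in enumerate(res):
        phi = psi = omega = None
        if i > 0 and bonded[i - 1]:
            prev = res[i - 1]
            phi = _safe(prev.c_xyz, r.n_xyz, r.ca_xyz, r.c_xyz)
            omega = _safe(prev.ca_xyz, prev.c_xyz, r.n_xyz, r.ca_xyz)
        if i < len(res) - 1 and bonded[i]:
            nxt = res[i + 1]
            psi = _safe(r.n_xyz, r.ca_xyz, r.c_xyz, nxt.n_xyz)
        out.append(
            TorsionRecord(
                residue_number=r.residue_number,
                residue_name=r.residue_name,
                phi=phi,
                psi=psi,
                omega=omega,
                insertion_code=r.insertion_code,
            )
        )
    return out


def angular_difference(a: float, b: float) -> float:
    """Magnitude of the difference between two angles on the circle, deg."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def classify_turn(
    phi1: float,
    psi1: float,
    phi2: float,
    psi2: float,
    omega2_cis: bool = False,
    table: TurnTypeTable = DEFAULT_TURN_TABLE,
) -> tuple[str, bool]:
    """Assign a turn-type label from the central residues' torsions.

    Returns ``(label, relaxed_match)``. Strict matches (all four angles
    within the strict tolerance) are preferred over relaxed ones (exactly
    one angle between the strict and relaxed tolerance); among equal
    match quality the first type in table order wins. Cis-proline turn
    types (VIa1/VIa2/VIb) are only eligible when ``omega2_cis``.
    """
    for ang in (phi1, psi1, phi2, psi2):
        if ang is None:
            raise ValueError(
                "undefined torsion angle: exclude terminal/broken windows before classifying"
            )
    observed = (phi1, psi1, phi2, psi2)
    relaxed_hit: str | None = None
    for t in table.types:
        if t.requires_cis_at_i2 and not omega2_cis:
            continue
        diffs = [angular_difference(o, c) for o, c in zip(observed, t.angles)]
        n_strict = sum(d <= table.strict_tolerance for d in diffs)
        n_relaxed_ok = sum(d <= table.relaxed_tolerance for d in diffs)
        if n_strict == 4:
            return t.label, False
        if n_strict == 3 and n_relaxed_ok == 4 and relaxed_hit is None:
            relaxed_hit = t.label
    if relaxed_hit is not None:
        return relaxed_hit, True
    return table.catch_all, False


def _is_helical(phi: float, psi: float) -> bool:
    return -100.0 <= phi <= -30.0 and -80.0 <= psi <= -5.0


def detect_turns(
    chain: BackboneChain,
    ca_cutoff: float = 7.0,
    exclude_helical: bool = False,
    table: TurnTypeTable = DEFAULT_TURN_TABLE,
    with_hbond: bool = True,
    place_hydrogen: bool = True,
) -> list[TurnAssignment]:
    """Find and classify every beta-turn window of a chain.

    A window qualifies when residues i..i+3 are consecutively bonded,
    CA(i)-CA(i+3) <= ``ca_cutoff`` (A), and the four central torsions are
    defined. Overlapping windows are all reported. ``exclude_helical``
    drops windows whose two central residues both lie in the alpha-helical
    phi/psi region.
    """
    res = chain.residues
    if len(res) < 4:
        return []
    torsions = compute_torsions(chain)
    bonded = chain.bonded_mask()
    out: list[TurnAssignment] = []
    for i in range(len(res) - 3):
        if not bonded[i : i + 3].all():
            continue
        ca_d = distance(res[i].ca_xyz, res[i + 3].ca_xyz)
        if ca_d > ca_cutoff:
            continue
        t1, t2 = torsions[i + 1], torsions[i + 2]
        if None in (t1.phi, t1.psi, t2.phi, t2.psi):
            continue
        if exclude_helical and _is_helical(t1.phi, t1.psi) and _is_helical(t2.phi, t2.psi):
            continue
        omega2_cis = t2.omega is not None and angular_difference(t2.omega, 0.0) <= CIS_OMEGA_TOLERANCE
        label, relaxed = classify_turn(t1.phi, t1.psi, t2.phi, t2.psi, omega2_cis, table)
        turn = TurnAssignment(
            chain_id=chain.chain_id,
            i_residue_number=res[i].residue_number,
            residue_names=tuple(r.residue_name for r in res[i : i + 4]),
            phi1=t1.phi,
            psi1=t1.psi,
            phi2=t2.phi,
            psi2=t2.psi,
            omega2_cis=omega2_cis,
            ca_distance_i_i3=ca_d,
            turn_type=label,
            relaxed_match=relaxed,
            i_index=i,
        )
        if with_hbond and res[i].o_xyz is not None:
            turn.o_n_distance, turn.o_h_distance = turn_hbond(
                chain, turn, place_hydrogen=place_hydrogen
            )
        out.append(turn)
    return out


def place_amide_hydrogen(c_prev, n, ca) -> np.ndarray:
    """Construct the backbone amide hydrogen on nitrogen ``n``.

    The H lies in the peptide plane, 1.01 A from N, along the reverse of
    the bisector of the C(prev)->N and CA->N directions — i.e. trans to
    both heavy-atom substituents, the standard idealised sp2 placement.
    """
    c_prev, n, ca = (np.asarray(p, dtype=float) for p in (c_prev, n, ca))
    u = n - c_prev
    u /= np.linalg.norm(u)
    v = n - ca
    v /= np.linalg.norm(v)
    h_dir = u + v
    norm = np.linalg.norm(h_dir)
    if norm < 1e-8:
        raise DegenerateGeometryError("cannot place amide H: C, N, CA collinear")
    return n + NH_BOND_LENGTH * h_dir / norm


def turn_hbond(
    chain: BackboneChain,
    turn: TurnAssignment,
    place_hydrogen: bool = True,
) -> tuple[float, float | None]:
    """Hydrogen-bond geometry closing a turn: O(i)...N(i+3) and, with an
    idealised amide hydrogen, O(i)...H(i+3).

    Returns ``(o_n_distance, o_h_distance)``; the O-H distance is None for
    proline at i+3 (no amide hydrogen) or when not requested.
    """
    i = turn.i_index
    if i < 0:
        i = next(
            j
            for j, r in enumerate(chain.residues)
            if r.residue_number == turn.i_residue_number
        )
    res_i = chain.residues[i]
    res_i2 = chain.residues[i + 2]
    res_i3 = chain.residues[i + 3]
    if res_i.o_xyz is None:
        raise ValueError(f"missing atom: residue {res_i.label} has no carbonyl O")
    if res_i3.n_xyz is None:
        raise ValueError(f"missing atom: residue {res_i3.label} has no N")
    o_n = distance(res_i.o_xyz, res_i3.n_xyz)
    o_h: float | None = None
    if place_hydrogen and res_i3.residue_name != "PRO":
        if res_i2.c_xyz is not None and res_i3.ca_xyz is not None:
            h = place_amide_hydrogen(res_i2.c_xyz, res_i3.n_xyz, res_i3.ca_xyz)
            o_h = distance(res_i.o_xyz, h)
    return o_n, o_h
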