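"""Synthetic inputs: simulated cleavage timecourses, built peptide
backbones, and toy screening tables.

Everything the analysis pipeline consumes can be generated here without
any external files. The timecourse simulator draws band-intensity decay
curves from the same first-order model the kinetics module fits, so
parameter-recovery tests are exact in the noiseless limit. The peptide
builder converts prescribed backbone torsions (phi/psi/omega) into
Cartesian coordinates with ideal bond lengths and angles, which makes
turn detection testable against a known construction — including a
synthetic stand-in for the LexA cleavage-site region built from its
published torsions.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import Timecourse, effectiveness_curve
from .structure import BackboneChain, BackboneResidue

__all__ = [
    "SimulationConfig",
    "simulate_cleavage_series",
    "ResidueSpec",
    "TorsionSpec",
    "build_peptide",
    "extended_spec",
    "ideal_type_ii_turn_spec",
    "synthetic_csr_spec",
    "CSR_TURN_TORSIONS",
    "make_toy_screen_table",
    "default_screen_table",
]


# ---------------------------------------------------------------------------
# Cleavage timecourse simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Design of a simulated inhibitor titration experiment.

    Defaults reproduce the study conditions the package targets: an
    uninhibited control plus a two-fold dilution series from 1 mM down to
    62.5 uM inhibitor against ~6.7 uM LexA, sampled every 5 minutes for
    25 minutes, with additive Gaussian noise (sd 0.03) on the fraction
    scale.
    """

    k0: float = 0.1  # per minute, uninhibited cleavage rate
    phi: float = 43.422  # effectiveness (ratio at half-rate)
    lexa0: float = 6.7  # uM protein
    inhibitor_concs: tuple = (1000.0, 500.0, 250.0, 125.0, 62.5, 0.0)  # uM
    times: tuple = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)  # minutes
    noise_sd: float = 0.03  # additive sd on the fraction scale
    intensity0: float = 10_000.0  # densitometry units of the t=0 band
    noise_model: str = "gaussian"  # or "lognormal" (multiplicative)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 < 0 or self.phi <= 0 or self.lexa0 <= 0:
            raise ValueError("require k0 >= 0, phi > 0, lexa0 > 0")
        if self.noise_sd < 0 or self.intensity0 <= 0:
            raise ValueError("require noise_sd >= 0 and intensity0 > 0")
        if 0.0 not in self.times:
            raise ValueError("times must include 0 (the normalisation anchor)")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def simulate_cleavage_series(config: SimulationConfig) -> list[Timecourse]:
    """Simulate one normalised timecourse per inhibitor concentration.

    The true fraction remaining is exp(-k_i t) with k_i from the
    effectiveness curve at ratio [I]/[LexA]0. Noise is added to every
    point except t = 0, which stays exactly 1: experimentally the
    initial aliquot is the normalisation reference, so its error is
    shared by all points rather than scattering the anchor. Gaussian
    noise is additive on the fraction scale (clipped at 0); the
    lognormal option multiplies by exp(N(0, sd)) instead.
    """
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.times, dtype=float)
    out: list[Timecourse] = []
    for conc in config.inhibitor_concs:
        ratio = conc / config.lexa0
        k_i = float(effectiveness_curve(ratio, config.k0, config.phi))
        true = np.exp(-k_i * times)
        observed = true.copy()
        mask = times > 0
        if config.noise_sd > 0:
            if config.noise_model == "gaussian":
                observed[mask] = np.clip(
                    true[mask] + rng.normal(0.0, config.noise_sd, mask.sum()), 0.0, None
                )
            else:
                observed[mask] = true[mask] * np.exp(
                    rng.normal(0.0, config.noise_sd, mask.sum())
                )
        out.append(
            Timecourse(
                times=times,
                fractions=observed,
                label=f"[I]={conc:g}uM",
                inhibitor_conc=float(conc),
                lexa0_conc=config.lexa0,
                intensities=observed * config.intensity0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Peptide backbone construction from internal coordinates
# ---------------------------------------------------------------------------


@dataclass
class ResidueSpec:
    """Prescribed backbone torsions of one residue (degrees).

    ``phi`` of the first residue and ``omega`` of the first residue are
    not used (no preceding peptide bond); ``psi`` of the last residue
    only orients its carbonyl oxygen.
    """

    residue_name: str = "ALA"
    phi: float = -120.0
    psi: float = 120.0
    omega: float = 180.0


@dataclass
class TorsionSpec:
    """A peptide defined by per-residue torsions plus ideal geometry.

    Bond lengths (A) and angles (deg) are the standard trans-peptide
    values; they matter only for internal consistency of built fixtures,
    not as a model of any particular crystal structure.
    """

    residues: list[ResidueSpec] = field(default_factory=list)
    chain_id: str = "A"
    start_residue_number: int = 1
    # bond lengths, A
    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    # bond angles, deg
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.8


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (natural-extension reference frame)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise ValueError("degenerate torsion placement: reference atoms collinear")
    n /= n_norm
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_peptide(spec: TorsionSpec) -> BackboneChain:
    """Sequential internal-to-Cartesian construction of a backbone chain.

    Each N, CA, C is placed from the previous three backbone atoms via
    (bond, angle, torsion); carbonyl oxygens are placed in the peptide
    plane anti to the next amide nitrogen. ``compute_torsions`` on the
    result reproduces the prescribed phi/psi/omega to numerical
    precision, which is the builder's contract.
    """
    res_specs = spec.residues
    if len(res_specs) < 2:
        raise ValueError("need at least 2 residues to build a peptide")

    n_xyz: list[np.ndarray] = []
    ca_xyz: list[np.ndarray] = []
    c_xyz: list[np.ndarray] = []

    # seed the first residue in the xy-plane
    n_xyz.append(np.zeros(3))
    ca_xyz.append(np.array([spec.bond_n_ca, 0.0, 0.0]))
    ang = math.radians(spec.angle_n_ca_c)
    c_xyz.append(
        ca_xyz[0] + spec.bond_ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])
    )

    for i in range(1, len(res_specs)):
        r = res_specs[i]
        psi_prev = res_specs[i - 1].psi
        n_new = _place_atom(
            n_xyz[-1], ca_xyz[-1], c_xyz[-1], spec.bond_c_n, spec.angle_ca_c_n, psi_prev
        )
        ca_new = _place_atom(
            ca_xyz[-1], c_xyz[-1], n_new, spec.bond_n_ca, spec.angle_c_n_ca, r.omega
        )
        c_new = _place_atom(
            c_xyz[-1], n_new, ca_new, spec.bond_ca_c, spec.angle_n_ca_c, r.phi
        )
        n_xyz.append(n_new)
        ca_xyz.append(ca_new)
        c_xyz.append(c_new)

    chain = BackboneChain(chain_id=spec.chain_id, source_label="built")
    for i, r in enumerate(res_specs):
        # carbonyl O: in the peptide plane, anti (psi + 180) to the next N
        o = _place_atom(
            n_xyz[i], ca_xyz[i], c_xyz[i], spec.bond_c_o, spec.angle_ca_c_o, r.psi + 180.0
        )
        chain.residues.append(
            BackboneResidue(
                chain_id=spec.chain_id,
                residue_number=spec.start_residue_number + i,
                residue_name=r.residue_name,
                n_xyz=n_xyz[i],
                ca_xyz=ca_xyz[i],
                c_xyz=c_xyz[i],
                o_xyz=o,
            )
        )
    return chain


def extended_spec(n_residues: int, residue_name: str = "ALA") -> TorsionSpec:
    """An all-trans extended strand (phi = -120, psi = 120, omega = 180)."""
    return TorsionSpec(residues=[ResidueSpec(residue_name) for _ in range(n_residues)])


def ideal_type_ii_turn_spec(n_flank: int = 2) -> TorsionSpec:
    """A peptide carrying one ideal type II beta-turn.

    The two central residues take the canonical type II torsions
    (phi,psi) = (-60, 120) and (80, 0); ``n_flank`` extended residues pad
    each side. The turn's i residue is at position ``n_flank + 1``
    (1-based). Glycine is used at i+2, where type II turns strongly
    prefer it.
    """
    flank = [ResidueSpec("ALA") for _ in range(n_flank)]
    turn = [
        ResidueSpec("ALA"),  # i
        ResidueSpec("ALA", phi=-60.0, psi=120.0),  # i+1
        ResidueSpec("GLY", phi=80.0, psi=0.0),  # i+2
        ResidueSpec("ALA"),  # i+3
    ]
    return TorsionSpec(residues=flank + turn + [ResidueSpec("ALA") for _ in range(n_flank)])


#: Published backbone torsions (phi, psi) of the LexA cleavage-site-region
#: beta-turn, residues 83-86 (Glu-Gly-Ala-Ala, author numbering).
CSR_TURN_TORSIONS: dict[int, tuple[str, float, float]] = {
    83: ("GLU", -62.5, 145.65),
    84: ("GLY", -58.86, 126.78),
    85: ("ALA", 79.02, -24.45),
    86: ("ALA", -68.97, 136.73),
}


def synthetic_csr_spec(n_flank: int = 3) -> TorsionSpec:
    """SYNTHETIC stand-in for the LexA cleavage-site region (not deposited
    coordinates).

    The four turn residues 83-86 carry the published phi/psi torsions of
    the CSR beta-turn (:data:`CSR_TURN_TORSIONS`); flanking residues are
    synthetic extended alanines, and all geometry is ideal (trans peptide
    bonds, standard bond lengths/angles). Useful wherever the real
    crystal structure is unavailable: torsion-level analyses reproduce
    the published values exactly, while absolute distances are only as
    close as an ideal-geometry rebuild can be.
    """
    flank = lambda: ResidueSpec("ALA")  # noqa: E731
    residues = [flank() for _ in range(n_flank)]
    for num in sorted(CSR_TURN_TORSIONS):
        name, phi, psi = CSR_TURN_TORSIONS[num]
        residues.append(ResidueSpec(name, phi=phi, psi=psi))
    residues += [flank() for _ in range(n_flank)]
    return TorsionSpec(residues=residues, start_residue_number=83 - n_flank)


# ---------------------------------------------------------------------------
# Toy screening tables
# ---------------------------------------------------------------------------


def make_toy_screen_table(
    n_per_library: dict[str, int],
    n_selected: dict[str, int] | None = None,
    active_ids: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Deterministic toy compound table for screen bookkeeping tests.

    One row per docked compound with columns ``id``, ``library``,
    ``docking_score`` (seeded uniform, lower = better), ``selected``
    (the ``n_selected[library]`` best-scoring compounds) and ``active``
    (membership of ``active_ids``, which must be generated ids).
    """
    n_selected = n_selected or {}
    active_ids = list(active_ids or [])
    rng = np.random.default_rng(seed)
    frames = []
    for lib, n in n_per_library.items():
        if n < 0:
            raise ValueError(f"negative compound count for {lib!r}")
        if n == 0:
            continue
        ids = [f"{lib}-{i:06d}" for i in range(1, n + 1)]
        scores = rng.uniform(-10.0, 0.0, n)
        k = n_selected.get(lib, 0)
        if not 0 <= k <= n:
            raise ValueError(f"n_selected for {lib!r} must be in [0, {n}]")
        order = np.argsort(scores, kind="stable")
        selected = np.zeros(n, dtype=bool)
        selected[order[:k]] = True
        frames.append(
            pd.DataFrame(
                {"id": ids, "library": lib, "docking_score": scores, "selected": selected}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["id", "library", "docking_score", "selected", "active"])
    table = pd.concat(frames, ignore_index=True)
    unknown = set(active_ids) - set(table["id"])
    if unknown:
        raise ValueError(f"active_ids not in the generated table: {sorted(unknown)}")
    table["active"] = table["id"].isin(active_ids)
    return table


def default_screen_table(seed: int = 0) -> pd.DataFrame:
    """The two-library screening funnel at the studied sizes: 2276
    beta-turn mimetics (53 purchased, 0 active) and 8607 covalent
    candidates (80 purchased, 1 active)."""
    table = make_toy_screen_table(
        {"beta_turn_mimetics": 2276, "covalent": 8607},
        n_selected={"beta_turn_mimetics": 53, "covalent": 80},
        seed=seed,
    )
    first_selected = table.loc[table["selected"] & (table["library"] == "covalent"), "id"].iloc[0]
    table["active"] = table["id"] == first_selected
    return table
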