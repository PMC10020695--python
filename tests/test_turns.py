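"""Torsion computation, beta-turn detection/classification and the
turn-closing hydrogen bond."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lexatools import (
    DEFAULT_TURN_TABLE,
    ResidueSpec,
    TorsionSpec,
    TurnType,
    TurnTypeTable,
    build_peptide,
    classify_turn,
    compute_torsions,
    detect_turns,
    extended_spec,
    ideal_type_ii_turn_spec,
    turn_hbond,
)
from lexatools.turns import angular_difference

angles = st.floats(min_value=-180.0, max_value=180.0, allow_nan=False)


def brute_force_classify(phi1, psi1, phi2, psi2, omega2_cis, table=DEFAULT_TURN_TABLE):
    """Independent matcher: enumerate every (type, angle-subset) pairing
    and apply the tolerance rule by exhaustive subset check."""
    obs = (phi1, psi1, phi2, psi2)

    def wrap_diff(a, b):
        d = (a - b) % 360.0
        return min(d, 360.0 - d)

    strict_matches, relaxed_matches = [], []
    for t in table.types:
        if t.requires_cis_at_i2 and not omega2_cis:
            continue
        diffs = [wrap_diff(o, c) for o, c in zip(obs, t.angles)]
        if all(d <= table.strict_tolerance for d in diffs):
            strict_matches.append(t.label)
        else:
            # exactly one angle may relax out to the wider tolerance
            for relax_idx in range(4):
                ok = all(
                    d <= (table.relaxed_tolerance if j == relax_idx else table.strict_tolerance)
                    for j, d in enumerate(diffs)
                )
                if ok and diffs[relax_idx] > table.strict_tolerance:
                    relaxed_matches.append(t.label)
                    break
    if strict_matches:
        return strict_matches[0], False
    if relaxed_matches:
        return relaxed_matches[0], True
    return table.catch_all, False


class TestComputeTorsions:
    def test_builder_round_trip_exact(self):
        spec = extended_spec(6)
        tors = compute_torsions(build_peptide(spec))
        for i, t in enumerate(tors):
            if t.phi is not None:
                assert t.phi == pytest.approx(-120.0, abs=1e-6)
            if t.psi is not None:
                assert t.psi == pytest.approx(120.0, abs=1e-6)
            if t.omega is not None:
                assert abs(t.omega) == pytest.approx(180.0, abs=1e-6)

    def test_termini_are_undefined(self):
        spec = TorsionSpec(residues=[ResidueSpec("ALA"), ResidueSpec("GLY")])
        tors = compute_torsions(build_peptide(spec))
        assert tors[0].phi is None and tors[0].omega is None
        assert tors[-1].psi is None
        assert tors[1].phi is not None

    def test_single_residue_raises(self):
        chain = build_peptide(extended_spec(4))
        chain.residues = chain.residues[:1]
        with pytest.raises(ValueError, match="no torsions"):
            compute_torsions(chain)

    def test_no_torsions_across_chain_break(self):
        chain = build_peptide(extended_spec(6))
        # translate the last three residues far away: break between 3 and 4
        for r in chain.residues[3:]:
            for atom in ("n_xyz", "ca_xyz", "c_xyz", "o_xyz"):
                setattr(r, atom, getattr(r, atom) + np.array([50.0, 0, 0]))
        tors = compute_torsions(chain)
        assert tors[2].psi is None  # break ahead
        assert tors[3].phi is None and tors[3].omega is None  # break behind
        assert tors[4].phi is not None


class TestClassifyTurn:
    def test_csr_torsions_are_type_ii(self):
        # the LexA cleavage-site-region turn's central torsions
        label, relaxed = classify_turn(-58.86, 126.78, 79.02, -24.45, omega2_cis=False)
        assert label == "II"
        assert relaxed is False

    def test_exact_canonical_type_i(self):
        assert classify_turn(-60, -30, -90, 0, False) == ("I", False)

    def test_unmatchable_quadruple_is_type_iv(self):
        assert classify_turn(0, 0, 0, 0, False) == ("IV", False)
        assert brute_force_classify(0, 0, 0, 0, False) == ("IV", False)

    @pytest.mark.parametrize("turn_type", DEFAULT_TURN_TABLE.types, ids=lambda t: t.label)
    def test_canonical_angles_classify_as_themselves(self, turn_type):
        label, relaxed = classify_turn(
            *turn_type.angles, omega2_cis=turn_type.requires_cis_at_i2
        )
        assert label == turn_type.label
        assert relaxed is False

    def test_cis_types_need_cis_omega(self):
        # canonical VIa1 angles without a cis bond must not be VIa1
        t = next(t for t in DEFAULT_TURN_TABLE.types if t.label == "VIa1")
        label, _ = classify_turn(*t.angles, omega2_cis=False)
        assert label != "VIa1"

    def test_relaxed_match_flagged(self):
        # type II with psi2 pushed 40 deg off canonical: relaxed-only match
        label, relaxed = classify_turn(-60, 120, 80, 40, False)
        assert label == "II"
        assert relaxed is True

    def test_undefined_angle_raises(self):
        with pytest.raises(ValueError, match="terminal"):
            classify_turn(None, 120, 80, 0, False)

    @given(angles, angles, angles, angles, st.booleans())
    def test_agrees_with_brute_force_matcher(self, phi1, psi1, phi2, psi2, cis):
        assert classify_turn(phi1, psi1, phi2, psi2, cis) == brute_force_classify(
            phi1, psi1, phi2, psi2, cis
        )

    @given(angles, angles, angles, angles, st.integers(-2, 2), st.integers(-2, 2))
    def test_invariant_to_full_turns(self, phi1, psi1, phi2, psi2, m, n):
        base = classify_turn(phi1, psi1, phi2, psi2, False)
        shifted = classify_turn(phi1 + 360 * m, psi1 + 360 * n, phi2, psi2, False)
        assert shifted == base

    def test_user_extension_table(self):
        table = DEFAULT_TURN_TABLE.extended([TurnType("SC2-SC10", -60, 130, 75, -30)])
        label, _ = classify_turn(-60, 130, 75, -30, False, table=table)
        # the built-in II also matches these angles and sits earlier in the table
        assert label == "II"
        table_first = TurnTypeTable(
            types=(TurnType("SC2-SC10", -60, 130, 75, -30),) + DEFAULT_TURN_TABLE.types
        )
        assert classify_turn(-60, 130, 75, -30, False, table=table_first)[0] == "SC2-SC10"


class TestDetectTurns:
    def test_ideal_type_ii_found_once(self, type_ii_chain):
        turns = detect_turns(type_ii_chain)
        assert len(turns) == 1
        t = turns[0]
        assert t.i_residue_number == 3
        assert t.turn_type == "II"
        assert t.relaxed_match is False
        assert t.ca_distance_i_i3 < 7.0

    def test_extended_chain_has_no_turns(self):
        chain = build_peptide(extended_spec(8))
        assert detect_turns(chain) == []

    def test_cutoff_excludes_wide_windows(self, type_ii_chain):
        turns = detect_turns(type_ii_chain)
        tight = turns[0].ca_distance_i_i3
        assert detect_turns(type_ii_chain, ca_cutoff=tight - 0.01) == []

    def test_helical_windows_droppable(self):
        helix = TorsionSpec(
            residues=[ResidueSpec("ALA", phi=-60.0, psi=-45.0) for _ in range(8)]
        )
        chain = build_peptide(helix)
        with_helix = detect_turns(chain, exclude_helical=False)
        without = detect_turns(chain, exclude_helical=True)
        assert len(with_helix) > 0
        assert without == []

    def test_builder_analyzer_consistency(self, rng):
        """Turns detected in a built chain carry exactly the prescribed
        central torsions."""
        phi1, psi1, phi2, psi2 = -65.0, 115.0, 85.0, 5.0
        spec = TorsionSpec(
            residues=[
                ResidueSpec("ALA"),
                ResidueSpec("ALA"),
                ResidueSpec("ALA", phi=phi1, psi=psi1),
                ResidueSpec("GLY", phi=phi2, psi=psi2),
                ResidueSpec("ALA"),
                ResidueSpec("ALA"),
            ]
        )
        turns = detect_turns(build_peptide(spec))
        assert len(turns) == 1
        t = turns[0]
        assert (t.phi1, t.psi1, t.phi2, t.psi2) == pytest.approx(
            (phi1, psi1, phi2, psi2), abs=1e-6
        )


class TestTurnHbond:
    def test_ideal_turn_has_short_o_n_contact(self, type_ii_chain):
        turn = detect_turns(type_ii_chain)[0]
        o_n, o_h = turn_hbond(type_ii_chain, turn)
        assert o_n < 3.5
        assert o_h is not None and o_h < o_n  # H sits between N and O

    def test_proline_at_i3_has_no_amide_h(self):
        spec = ideal_type_ii_turn_spec(n_flank=2)
        spec.residues[5].residue_name = "PRO"  # i+3 of the turn at 3..6
        chain = build_peptide(spec)
        turn = detect_turns(chain)[0]
        o_n, o_h = turn_hbond(chain, turn)
        assert o_h is None
        assert o_n > 0

    def test_missing_carbonyl_o_raises(self, type_ii_chain):
        turn = detect_turns(type_ii_chain)[0]
        type_ii_chain.residues[turn.i_index].o_xyz = None
        with pytest.raises(ValueError, match="missing atom"):
            turn_hbond(type_ii_chain, turn)


@given(angles, angles)
def test_angular_difference_is_circle_metric(a, b):
    d = angular_difference(a, b)
    assert 0 <= d <= 180
    assert d == pytest.approx(angular_difference(b, a), abs=1e-9)
    assert angular_difference(a + 360, b) == pytest.approx(d, abs=1e-6)
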