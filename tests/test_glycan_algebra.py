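"""Composition arithmetic, the bounded mass-delta solver, enzyme transforms."""

import itertools

import pytest
from hypothesis import given, strategies as st

from glyproform.glycan_algebra import (
    EMPTY,
    MONOMER_CLASSES,
    TEMPLATES,
    GlycanComposition,
    SolverConfig,
    apply_enzyme,
    composition_mass,
    parse_composition,
    solve_delta,
)
from glyproform.mass_core import DEFAULT_TABLE

counts = st.integers(min_value=0, max_value=12)
compositions = st.builds(
    GlycanComposition, HexNAc=counts, Hex=counts, NeuAc=counts, dHex=counts
)


@pytest.mark.parametrize(
    "comp, expected, tol",
    [
        (EMPTY, 0.0, 1e-12),
        (TEMPLATES["A2G2S2"], 2206.01, 0.005),
        (TEMPLATES["ST"], 656.5953, 1e-9),  # 203.1950 + 162.1424 + 291.2579
    ],
)
def test_composition_mass_examples(comp, expected, tol):
    assert composition_mass(comp) == pytest.approx(expected, abs=tol)


def test_composition_mass_rejects_unknown_class():
    with pytest.raises(ValueError, match="unknown"):
        composition_mass({"Pent": 1})


@given(a=compositions, b=compositions)
def test_composition_mass_is_linear(a, b):
    assert composition_mass(a) + composition_mass(b) == pytest.approx(
        composition_mass(a + b), abs=1e-9
    )


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        GlycanComposition(Hex=-1)


@given(comp=compositions)
def test_composition_string_round_trip(comp):
    assert parse_composition(str(comp)) == comp


@pytest.mark.parametrize("text", ["hexnac1", "Hex", "Hex1Hex2", "Hex1Pent2"])
def test_parse_rejects_malformed_strings(text):
    with pytest.raises(ValueError):
        parse_composition(text)


def test_templates_are_self_consistent():
    assert TEMPLATES["A2G2S2"] == GlycanComposition(HexNAc=4, Hex=5, NeuAc=2)
    assert TEMPLATES["Man5"] == GlycanComposition(HexNAc=2, Hex=5)
    assert TEMPLATES["C-Man"] == GlycanComposition(Hex=1)


# --- solver ---------------------------------------------------------------


def brute_force_solve(delta, tol, bounds, rule="none"):
    """Independent nested-loop oracle over the same search space."""
    table = DEFAULT_TABLE.glycan_monomer_masses
    out = []
    for hn in range(bounds.get("HexNAc", 0) + 1):
        for hx in range(bounds.get("Hex", 0) + 1):
            for na in range(bounds.get("NeuAc", 0) + 1):
                for dh in range(bounds.get("dHex", 0) + 1):
                    m = (
                        hn * table["HexNAc"]
                        + hx * table["Hex"]
                        + na * table["NeuAc"]
                        + dh * table["dHex"]
                    )
                    if abs(m - delta) <= tol:
                        comp = GlycanComposition(hn, hx, na, dh)
                        if rule == "n_glycan_core" and comp != EMPTY and not (
                            hn >= 2 and hx >= 3
                        ):
                            continue
                        out.append((comp, m - delta))
    out.sort(key=lambda ce: (abs(ce[1]), ce[0].as_tuple()))
    return out


def test_solve_delta_zero_returns_empty_composition():
    assert solve_delta(0.0, SolverConfig(0.5, {"Hex": 3, "HexNAc": 3})) == [
        (EMPTY, 0.0)
    ]


def test_solve_delta_single_hexose():
    config = SolverConfig(0.05, {m: 4 for m in MONOMER_CLASSES})
    result = solve_delta(162.14, config)
    assert [c for c, _ in result] == [GlycanComposition(Hex=1)]
    assert result[0][1] == pytest.approx(0.0024, abs=1e-6)


def test_solve_delta_whole_protein_ptm_shift():
    config = SolverConfig(
        1.0, {"HexNAc": 10, "Hex": 20, "NeuAc": 6, "dHex": 2}, "aggregate"
    )
    result = solve_delta(5547.97, config)
    by_comp = {c: e for c, e in result}
    target = GlycanComposition(HexNAc=8, Hex=17, NeuAc=4)
    assert target in by_comp
    assert by_comp[target] == pytest.approx(-0.96, abs=0.005)
    # identical to the aggregate of 2 disialylated biantennary glycans + 7 Hex
    assert target == 2 * TEMPLATES["A2G2S2"] + 7 * TEMPLATES["C-Man"]


@pytest.mark.parametrize("delta", [100.0, 365.34, 656.60, 1216.9, 2206.01])
@pytest.mark.parametrize("rule", ["none", "n_glycan_core"])
def test_solve_delta_matches_nested_loop_oracle(delta, rule):
    bounds = {m: 5 for m in MONOMER_CLASSES}
    config = SolverConfig(2.0, bounds, rule)
    assert solve_delta(delta, config) == brute_force_solve(delta, 2.0, bounds, rule)


@given(delta=st.floats(min_value=0.0, max_value=3000.0))
def test_solve_delta_errors_within_tolerance(delta):
    config = SolverConfig(1.5, {m: 4 for m in MONOMER_CLASSES})
    for _comp, err in solve_delta(delta, config):
        assert abs(err) <= 1.5


def test_solve_delta_rejects_candidate_explosion():
    with pytest.raises(ValueError, match="tighten"):
        solve_delta(500.0, SolverConfig(1.0, {m: 200 for m in MONOMER_CLASSES}))


def test_solve_delta_rejects_negative_delta():
    with pytest.raises(ValueError):
        solve_delta(-1.0)


# --- enzymes --------------------------------------------------------------


def _two_site_assignment():
    s1 = ("alpha", 437, "N")
    s2 = ("beta", 243, "N")
    return {s1: TEMPLATES["A2G2S2"], s2: TEMPLATES["A2G2S2"]}, {s1: "N", s2: "N"}


def test_sialidase_removes_all_neuac():
    assignment, kinds = _two_site_assignment()
    new, removed = apply_enzyme(assignment, "sialidase", kinds)
    assert removed == GlycanComposition(NeuAc=4)
    assert composition_mass(removed) == pytest.approx(1165.03, abs=0.005)
    assert all(c.NeuAc == 0 for c in new.values())


def test_sialidase_on_sialic_free_assignment_removes_nothing():
    assignment = {("a", 1, "N"): TEMPLATES["Man5"]}
    new, removed = apply_enzyme(assignment, "sialidase")
    assert removed == EMPTY
    assert new == assignment


def test_pngasef_removes_whole_glycan_at_flagged_sites_only():
    assignment, kinds = _two_site_assignment()
    flagged = [("alpha", 437, "N")]
    new, removed = apply_enzyme(assignment, "pngasef", kinds, flagged)
    assert removed == TEMPLATES["A2G2S2"]
    assert composition_mass(removed) == pytest.approx(2206.01, abs=0.005)
    assert new[("alpha", 437, "N")] == EMPTY
    assert new[("beta", 243, "N")] == TEMPLATES["A2G2S2"]


def test_pngasef_rejects_non_n_sites():
    assignment = {("gamma", 35, "O"): TEMPLATES["ST"]}
    kinds = {("gamma", 35, "O"): "O"}
    with pytest.raises(ValueError, match="PNGase"):
        apply_enzyme(assignment, "pngasef", kinds, [("gamma", 35, "O")])


def test_pngasef_requires_susceptibility_flags():
    assignment, kinds = _two_site_assignment()
    with pytest.raises(ValueError, match="susceptibility"):
        apply_enzyme(assignment, "pngasef", kinds)


@pytest.mark.parametrize("enzyme", ["sialidase", "pngasef"])
def test_enzymes_conserve_mass(enzyme):
    assignment, kinds = _two_site_assignment()
    flagged = list(assignment) if enzyme == "pngasef" else None
    new, removed = apply_enzyme(assignment, enzyme, kinds, flagged)
    old_total = sum(composition_mass(c) for c in assignment.values())
    new_total = sum(composition_mass(c) for c in new.values())
    assert old_total == pytest.approx(new_total + composition_mass(removed), abs=1e-9)
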