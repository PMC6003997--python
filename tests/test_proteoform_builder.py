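"""Site-profile convolution, modal species, count statistics, cutoff."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glyproform.glycan_algebra import EMPTY, TEMPLATES, GlycanComposition, composition_mass
from glyproform.proteoform_builder import (
    BuilderConfig,
    ProteoformProfile,
    Species,
    apply_cutoff,
    convolve,
    count_distribution,
    modal_proteoform,
)
from glyproform.site_profiles import SiteId, SiteProfile

EXACT = BuilderConfig(abundance_prune=0.0, merge_bin_da=0.0)

H1 = GlycanComposition(Hex=1)
H2 = GlycanComposition(Hex=2)
N1 = GlycanComposition(HexNAc=1)
N2 = GlycanComposition(HexNAc=2)


def _site(i, abundances):
    return SiteProfile.from_abundances(SiteId("a", i, "N"), abundances)


def brute_force_convolve(backbone, profiles):
    """Cartesian-product oracle: enumerate every per-site glycoform choice."""
    acc = {}
    for choice in itertools.product(*[p.entries for p in profiles]):
        agg = EMPTY
        ab = 1.0
        for comp, p in choice:
            agg += comp
            ab *= p
        acc[agg] = acc.get(agg, 0.0) + ab
    return {
        comp: (backbone + composition_mass(comp), ab) for comp, ab in acc.items()
    }


def test_two_site_product_rule():
    profile = convolve(
        0.0, [_site(1, {H1: 0.6, H2: 0.4}), _site(2, {N1: 0.7, N2: 0.3})], EXACT
    )
    by_comp = {s.composition: s.abundance for s in profile.species}
    assert by_comp[H1 + N1] == pytest.approx(0.42)
    assert by_comp[H1 + N2] == pytest.approx(0.18)
    assert by_comp[H2 + N1] == pytest.approx(0.28)
    assert by_comp[H2 + N2] == pytest.approx(0.12)


def test_single_site_shifts_by_backbone():
    profile = convolve(1000.0, [_site(1, {H1: 0.6, H2: 0.4})], EXACT)
    by_comp = {s.composition: s for s in profile.species}
    assert by_comp[H1].abundance == pytest.approx(0.6)
    assert by_comp[H1].mass == pytest.approx(1000.0 + 162.1424)


@settings(max_examples=30, deadline=None)
@given(
    data=st.data(),
    n_sites=st.integers(min_value=1, max_value=6),
)
def test_convolve_equals_cartesian_brute_force(data, n_sites):
    menus = [TEMPLATES["A2G2S2"], TEMPLATES["Man5"], H1, N1, EMPTY]
    profiles = []
    for i in range(n_sites):
        k = data.draw(st.integers(min_value=1, max_value=4))
        weights = data.draw(
            st.lists(
                st.floats(min_value=0.01, max_value=1.0), min_size=k, max_size=k
            )
        )
        profiles.append(_site(i + 1, dict(zip(menus[:k], weights))))
    result = convolve(500.0, profiles, EXACT)
    oracle = brute_force_convolve(500.0, profiles)
    assert len(result.species) == len(oracle)
    for s in result.species:
        mass, ab = oracle[s.composition]
        assert s.mass == pytest.approx(mass, abs=1e-9)
        assert s.abundance == pytest.approx(ab, abs=1e-12)


def test_convolve_total_abundance_and_expected_mass(c8):
    assert c8.profile.total_abundance == pytest.approx(1.0, abs=1e-9)
    # linearity of expectation over independent sites (exact convolution:
    # pruning during convolution discards tail mass, so it is disabled here)
    exact = convolve(c8.backbone_mass, c8.site_profiles, EXACT)
    expected = c8.backbone_mass + sum(
        sum(p * composition_mass(comp) for comp, p in sp.entries)
        for sp in c8.site_profiles
    )
    assert exact.expected_mass() == pytest.approx(expected, abs=1e-6)


def test_convolve_rejects_unnormalized_profile():
    bad = SiteProfile.from_abundances(SiteId("a", 1, "N"), {H1: 1.0})
    object.__setattr__(bad, "entries", ((H1, 0.5),))
    with pytest.raises(ValueError, match="normalized"):
        convolve(0.0, [bad])


def test_c8_modal_proteoform(c8):
    modal = modal_proteoform(c8.profile)
    assert modal.composition == GlycanComposition(HexNAc=8, Hex=17, NeuAc=4)
    assert modal.composition == 2 * TEMPLATES["A2G2S2"] + 7 * TEMPLATES["C-Man"]
    assert modal.mass == pytest.approx(148_622.6, abs=0.1)


def test_modal_tie_breaks_to_lower_mass():
    profile = ProteoformProfile(
        (Species(H2, 324.3, 0.5), Species(N1, 203.2, 0.5)), 0.0
    )
    assert modal_proteoform(profile).composition == N1


def test_modal_single_species_and_empty():
    single = ProteoformProfile((Species(H1, 162.1, 1.0),), 0.0)
    assert modal_proteoform(single).composition == H1
    with pytest.raises(ValueError):
        modal_proteoform(ProteoformProfile((), 0.0))


# --- Poisson-binomial count distribution ----------------------------------


def test_count_distribution_degenerate_cases():
    assert count_distribution([1.0, 1.0])[2] == pytest.approx(1.0)
    np.testing.assert_allclose(
        count_distribution([0.5, 0.5]), [0.25, 0.5, 0.25], atol=1e-12
    )


def enumerate_counts(ps):
    """2^n enumeration oracle for the occupied-site count distribution."""
    n = len(ps)
    dist = np.zeros(n + 1)
    for bits in itertools.product([0, 1], repeat=n):
        prob = 1.0
        for b, p in zip(bits, ps):
            prob *= p if b else 1.0 - p
        dist[sum(bits)] += prob
    return dist


def test_cman_count_mode_is_seven():
    # five fully occupied Trp sites plus five partial ones
    ps = [1, 1, 1, 1, 1, 0.27, 0.354, 0.74, 0.571, 0.425]
    dist = count_distribution(ps)
    oracle_partial = enumerate_counts([0.27, 0.354, 0.74, 0.571, 0.425])
    oracle = np.concatenate([np.zeros(5), oracle_partial])
    np.testing.assert_allclose(dist, oracle, atol=1e-12)
    assert int(np.argmax(dist)) == 7
    assert dist[7] > dist[8] > 0


@given(
    ps=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=8)
)
def test_count_distribution_matches_enumeration(ps):
    np.testing.assert_allclose(
        count_distribution(ps), enumerate_counts(ps), atol=1e-9
    )


def test_count_distribution_rejects_bad_probability():
    with pytest.raises(ValueError):
        count_distribution([0.5, 1.2])


# --- cutoff ----------------------------------------------------------------


def _uniform_profile(abundances):
    species = tuple(
        Species(GlycanComposition(Hex=i), 162.1424 * i, a)
        for i, a in enumerate(abundances, start=1)
    )
    return ProteoformProfile(species, 0.0)


def test_cutoff_one_keeps_only_modal():
    cut = apply_cutoff(_uniform_profile([0.5, 0.3, 0.2]), 1.0)
    assert len(cut.species) == 1
    assert cut.species[0].abundance == pytest.approx(0.5)


def test_cutoff_drops_below_threshold_without_renormalizing():
    cut = apply_cutoff(_uniform_profile([0.5, 0.3, 0.004]), 0.01)
    assert [s.abundance for s in cut.species] == [0.5, 0.3]
    assert cut.total_abundance == pytest.approx(0.8)


def test_cutoff_is_idempotent(c8):
    once = apply_cutoff(c8.profile, 0.01)
    twice = apply_cutoff(once, 0.01)
    assert once.species == twice.species


def test_cutoff_validation():
    with pytest.raises(ValueError):
        apply_cutoff(_uniform_profile([1.0]), 0.0)
    with pytest.raises(ValueError):
        apply_cutoff(_uniform_profile([1.0]), 1.5)


def test_c8_species_count_at_one_percent(c8):
    # reported for comparison with the ~20 co-occurring intact-MS signals;
    # the exact count depends on merge binning, so only sanity-bounded here
    retained = apply_cutoff(c8.profile, 0.01)
    assert 5 <= len(retained.species) <= 40
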