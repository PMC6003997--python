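"""Seeded generators for every input the pipeline consumes.

The packaged fixture emulates the complement C8 alpha-beta-gamma assembly:
two dominant complex biantennary N-glycosylation sites, one low-occupancy
high-mannose N-site, low-abundance mucin-type O-glycosylation on the gamma
chain, and ten thrombospondin-domain C-mannosylation sites with the
occupancy pattern that makes partial C-mannosylation the main source of
intact-mass heterogeneity.

The fixture backbone mass defaults to the assembly's known average backbone
value (143,075.63 Da for mature C8 with 22 disulfides and the gamma-chain
pyroglutamate correction) so the synthetic pipeline needs no sequence
download; computing the backbone from user-supplied mature sequences is the
separate path in :mod:`glyproform.mass_core`.

All generators draw from ``numpy.random.default_rng(seed)``: identical
configuration implies identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .glycan_algebra import EMPTY, GlycanComposition, TEMPLATES
from .proteoform_builder import BuilderConfig, ProteoformProfile, convolve
from .site_profiles import GlycoformRecord, SiteId, SiteProfile
from .spectrum_tools import (
    AdductModel,
    ChargeEnvelope,
    PeakShapeConfig,
    Spectrum,
    simulate_spectrum,
)

__all__ = [
    "C8_BACKBONE_MASS_DA",
    "C8_CMAN_OCCUPANCIES",
    "ScenarioConfig",
    "C8Fixture",
    "make_c8_fixture",
    "c8_scenario",
    "generate_xic_tables",
    "generate_experimental_spectrum",
]

#: Average backbone mass (Da) of mature C8 alpha+beta+gamma with 22
#: disulfide bonds and the gamma N-terminal pyroglutamate correction.
C8_BACKBONE_MASS_DA = 143_075.63

#: Per-site C-mannosylation occupancies of the fixture. Sites reported as
#: fully (or almost fully, alpha W545) occupied carry 1.0.
C8_CMAN_OCCUPANCIES: dict[SiteId, float] = {
    SiteId("alpha", 44, "C-Man"): 1.0,
    SiteId("alpha", 47, "C-Man"): 0.27,
    SiteId("alpha", 542, "C-Man"): 1.0,
    SiteId("alpha", 545, "C-Man"): 1.0,
    SiteId("alpha", 548, "C-Man"): 0.354,
    SiteId("beta", 70, "C-Man"): 1.0,
    SiteId("beta", 73, "C-Man"): 0.74,
    SiteId("beta", 548, "C-Man"): 0.571,
    SiteId("beta", 551, "C-Man"): 1.0,
    SiteId("beta", 554, "C-Man"): 0.425,
}

_CMAN = GlycanComposition(Hex=1)


@dataclass(frozen=True)
class ScenarioConfig:
    """One synthetic study: truth, noise levels, instrument settings.

    ``minor_fraction`` is the point value standing in for glycoforms whose
    abundance is only bounded ("< 1%" / "< 0.5%") at the peptide level.
    ``xic_sigma`` is the log-scale standard deviation of the multiplicative
    log-normal noise on XIC areas; ``spectrum_noise_fraction`` is the
    amplitude (relative to the base-peak intensity) of additive uniform
    noise on the simulated spectrum.
    """

    seed: int = 0
    backbone_mass: float = C8_BACKBONE_MASS_DA
    minor_fraction: float = 0.005
    n_runs: int = 4
    xic_sigma: float = 0.2
    xic_base_area: float = 1e6
    spectrum_noise_fraction: float = 0.0
    adducts: AdductModel = field(default_factory=AdductModel)
    envelope: ChargeEnvelope = field(
        default_factory=lambda: ChargeEnvelope(21, 26, 24.0, 1.5)
    )
    peak_shape: PeakShapeConfig = field(default_factory=PeakShapeConfig)
    grid_step: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.minor_fraction < 0.02):
            raise ValueError("minor_fraction should be a small point value")
        if self.xic_sigma < 0 or self.spectrum_noise_fraction < 0:
            raise ValueError("noise levels must be non-negative")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def c8_scenario(seed: int = 0, noisy: bool = False) -> ScenarioConfig:
    """The packaged C8 scenario.

    ``noisy=False`` is the clean self-consistency setting (no spectrum
    noise, no adducts). ``noisy=True`` is the calibrated realistic setting —
    Na/K adduct satellites plus additive noise at levels chosen so the
    constructed-vs-synthetic-experimental correlation lands between the
    clean limit and the noise floor.
    """
    if not noisy:
        return ScenarioConfig(seed=seed)
    return ScenarioConfig(
        seed=seed,
        spectrum_noise_fraction=0.03,
        adducts=AdductModel(na_probability=0.18, k_probability=0.09),
    )


@dataclass(frozen=True)
class C8Fixture:
    """The C8 ground truth: site profiles and the convolved proteoform
    distribution over a configurable backbone mass."""

    backbone_mass: float
    site_profiles: tuple[SiteProfile, ...]
    profile: ProteoformProfile

    def profile_for(self, site_id: SiteId) -> SiteProfile:
        for p in self.site_profiles:
            if p.site_id == site_id:
                return p
        raise KeyError(site_id)


def make_c8_fixture(
    backbone_mass: float = C8_BACKBONE_MASS_DA,
    minor_fraction: float = 0.005,
    builder: BuilderConfig = BuilderConfig(),
) -> C8Fixture:
    """Build the C8 ground-truth occupancy scenario.

    Site glycoform menus and occupancies:

    * alpha N437 — complex biantennary, sialylation split 59.5 / 38.7 / 0.3 %
      (2 / 1 / 0 NeuAc), plus core-fucosylated minor forms;
    * beta N243 — fully occupied by the disialylated biantennary glycan;
    * beta N101 — mostly unoccupied; high-mannose Man5/Man8 minors;
    * gamma T35 — mostly unmodified; Tn / TF / sialyl-T core minors;
    * ten C-Man sites with :data:`C8_CMAN_OCCUPANCIES`.

    Glycoforms whose abundance is only known to be below a bound enter at
    ``minor_fraction`` each; every site is renormalized to 1.
    """
    m = minor_fraction
    fucosylated_s2 = TEMPLATES["A2G2S2"] + GlycanComposition(dHex=1)
    fucosylated_s1 = TEMPLATES["A2G2S1"] + GlycanComposition(dHex=1)
    profiles = [
        SiteProfile.from_abundances(
            SiteId("alpha", 437, "N"),
            {
                TEMPLATES["A2G2S2"]: 0.595,
                TEMPLATES["A2G2S1"]: 0.387,
                TEMPLATES["A2G2"]: 0.003,
                fucosylated_s2: m,
                fucosylated_s1: m,
            },
        ),
        SiteProfile.from_abundances(
            SiteId("beta", 243, "N"), {TEMPLATES["A2G2S2"]: 1.0}
        ),
        SiteProfile.from_abundances(
            SiteId("beta", 101, "N"),
            {EMPTY: 1.0 - 2 * m, TEMPLATES["Man5"]: m, TEMPLATES["Man8"]: m},
        ),
        SiteProfile.from_abundances(
            SiteId("gamma", 35, "O"),
            {
                EMPTY: 1.0 - 3 * m,
                TEMPLATES["Tn"]: m,
                TEMPLATES["TF"]: m,
                TEMPLATES["ST"]: m,
            },
        ),
    ]
    for site, p in C8_CMAN_OCCUPANCIES.items():
        if p >= 1.0:
            profiles.append(SiteProfile.from_abundances(site, {_CMAN: 1.0}))
        else:
            profiles.append(
                SiteProfile.from_abundances(site, {_CMAN: p, EMPTY: 1.0 - p})
            )
    profile = convolve(backbone_mass, profiles, builder)
    return C8Fixture(backbone_mass, tuple(profiles), profile)


def generate_xic_tables(
    scenario: ScenarioConfig,
    fixture: C8Fixture | None = None,
) -> list[GlycoformRecord]:
    """Multi-run glycopeptide XIC tables with multiplicative noise.

    Per run and glycoform, ``area = base * p * LogNormal(0, xic_sigma)``;
    the site-profile recovery from these tables is the test surface for the
    normalization/averaging stage.
    """
    if fixture is None:
        fixture = make_c8_fixture(scenario.backbone_mass, scenario.minor_fraction)
    rng = np.random.default_rng(scenario.seed)
    records: list[GlycoformRecord] = []
    for run in range(1, scenario.n_runs + 1):
        run_id = f"run{run}"
        for sp in fixture.site_profiles:
            for comp, p in sp.entries:
                noise = (
                    float(rng.lognormal(0.0, scenario.xic_sigma))
                    if scenario.xic_sigma > 0
                    else 1.0
                )
                records.append(
                    GlycoformRecord(
                        sp.site_id, comp, run_id, scenario.xic_base_area * p * noise
                    )
                )
    return records


def generate_experimental_spectrum(
    profile: ProteoformProfile,
    scenario: ScenarioConfig,
) -> Spectrum:
    """A synthetic "experimental" native spectrum of ``profile``.

    The deterministic simulation (with the scenario's adduct satellites) is
    degraded by seeded additive uniform noise at
    ``spectrum_noise_fraction x base-peak intensity``. With zero noise and
    zero adduct probability the output equals the clean simulation exactly.
    """
    adducts = scenario.adducts
    if adducts.na_probability == 0 and adducts.k_probability == 0:
        adducts = None
    clean = simulate_spectrum(
        profile,
        scenario.envelope,
        scenario.peak_shape,
        adducts=adducts,
        grid_step=scenario.grid_step,
    )
    if scenario.spectrum_noise_fraction <= 0:
        return clean
    rng = np.random.default_rng(scenario.seed + 1)
    noise = (
        scenario.spectrum_noise_fraction
        * clean.intensity.max()
        * rng.uniform(0.0, 1.0, size=clean.intensity.size)
    )
    return Spectrum(clean.axis, clean.intensity + noise, clean.axis_kind)
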