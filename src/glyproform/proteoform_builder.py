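"""Convolve site glycoform profiles into an intact-proteoform distribution.

The model: modification sites are occupied independently, so the abundance
of an intact proteoform is the product of its per-site glycoform
abundances and its mass is the backbone mass plus the summed glycan masses.
Co-occurrence constraints within one peptide (e.g. mutually exclusive
C-mannosylation positional isomers) are honored by convolving an
isomer-level joint distribution as a single pseudo-site instead of the
individual site marginals.

The resulting distribution mirrors a zero-charge deconvoluted native-MS
spectrum and is filtered the same way real spectra are read: a relative
intensity cutoff against the most abundant species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .glycan_algebra import EMPTY, GlycanComposition, composition_mass
from .mass_core import DEFAULT_TABLE, ResidueMassTable
from .site_profiles import SiteProfile

__all__ = [
    "Species",
    "ProteoformProfile",
    "BuilderConfig",
    "convolve",
    "modal_proteoform",
    "count_distribution",
    "apply_cutoff",
]


@dataclass(frozen=True)
class Species:
    """One intact proteoform: aggregate glycan composition, mass, abundance."""

    composition: GlycanComposition
    mass: float
    abundance: float


@dataclass(frozen=True)
class ProteoformProfile:
    """A (composition, mass, abundance) distribution over intact proteoforms.

    Abundances sum to 1 for a freshly convolved profile; after
    :func:`apply_cutoff` the retained species keep their original scale, so
    the sum may be < 1.
    """

    species: tuple[Species, ...]
    backbone_mass: float

    def __post_init__(self) -> None:
        for s in self.species:
            if s.abundance < 0:
                raise ValueError("species abundance must be >= 0")

    @property
    def total_abundance(self) -> float:
        return sum(s.abundance for s in self.species)

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.species])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([s.abundance for s in self.species])

    def expected_mass(self) -> float:
        """Abundance-weighted mean mass."""
        total = self.total_abundance
        if total <= 0:
            raise ValueError("empty profile")
        return float(sum(s.mass * s.abundance for s in self.species) / total)


@dataclass(frozen=True)
class BuilderConfig:
    """Convolution bookkeeping thresholds.

    ``abundance_prune`` drops vanishing species *during* convolution (keeps
    the species count polynomial); ``merge_bin_da`` merges species closer in
    mass than the native-MS peak spacing could ever resolve, replacing them
    by an abundance-weighted mean mass under the dominant composition;
    ``cutoff_fraction`` is the post-hoc relative-intensity cutoff used when
    reading the profile as a spectrum.
    """

    abundance_prune: float = 1e-6
    merge_bin_da: float = 0.1
    cutoff_fraction: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.abundance_prune < self.cutoff_fraction <= 1):
            raise ValueError(
                "require 0 <= abundance_prune < cutoff_fraction <= 1, got "
                f"prune={self.abundance_prune}, cutoff={self.cutoff_fraction}"
            )
        if self.merge_bin_da < 0:
            raise ValueError("merge_bin_da must be >= 0")


def convolve(
    backbone: float,
    profiles: Sequence[SiteProfile],
    config: BuilderConfig = BuilderConfig(),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> ProteoformProfile:
    """Product-convolve independent site profiles over the backbone mass.

    Species sharing an aggregate composition are summed exactly; species
    within ``merge_bin_da`` of each other are then merged (merge first, then
    prune, then renormalize — fixed order for determinism).
    """
    for p in profiles:
        total = sum(a for _, a in p.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"profile for site {p.site_id} is not normalized")

    acc: dict[GlycanComposition, float] = {EMPTY: 1.0}
    for p in profiles:
        nxt: dict[GlycanComposition, float] = {}
        for agg, ab in acc.items():
            for comp, pr in p.entries:
                key = agg + comp
                nxt[key] = nxt.get(key, 0.0) + ab * pr
        if config.abundance_prune > 0:
            nxt = {c: a for c, a in nxt.items() if a >= config.abundance_prune}
        acc = nxt

    species = [
        Species(comp, backbone + composition_mass(comp, table), ab)
        for comp, ab in acc.items()
    ]
    species.sort(key=lambda s: (s.mass, s.composition.as_tuple()))

    if config.merge_bin_da > 0 and len(species) > 1:
        merged: list[list[Species]] = [[species[0]]]
        for s in species[1:]:
            if s.mass - merged[-1][-1].mass <= config.merge_bin_da:
                merged[-1].append(s)
            else:
                merged.append([s])
        species = []
        for group in merged:
            ab = sum(s.abundance for s in group)
            mass = sum(s.mass * s.abundance for s in group) / ab
            dominant = max(group, key=lambda s: (s.abundance, -s.mass))
            species.append(Species(dominant.composition, mass, ab))

    total = sum(s.abundance for s in species)
    if total <= 0:
        raise ValueError("all species pruned; lower abundance_prune")
    species = [Species(s.composition, s.mass, s.abundance / total) for s in species]
    return ProteoformProfile(tuple(species), backbone)


def modal_proteoform(profile: ProteoformProfile) -> Species:
    """The most abundant species; ties broken by lower mass."""
    if not profile.species:
        raise ValueError("empty profile")
    return max(profile.species, key=lambda s: (s.abundance, -s.mass))


def count_distribution(occupancies: Sequence[float]) -> np.ndarray:
    """Poisson-binomial distribution of the number of occupied sites.

    Exact dynamic-programming convolution of independent Bernoulli sites:
    returns ``P(count = k)`` for ``k = 0..n``. This is the distribution of
    e.g. the total C-mannose count over partially occupied Trp sites.
    """
    dist = np.array([1.0])
    for p in occupancies:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"occupancy {p} outside [0, 1]")
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


def apply_cutoff(
    profile: ProteoformProfile, cutoff_fraction: float = 0.01
) -> ProteoformProfile:
    """Retain species with abundance >= cutoff x the modal abundance.

    The cutoff is relative to the most intense species (how peak-intensity
    cutoffs are read off a spectrum), and the retained abundances are NOT
    renormalized, so they keep their scale relative to the original profile.
    Idempotent.
    """
    if not (0 < cutoff_fraction <= 1):
        raise ValueError("cutoff_fraction must be in (0, 1]")
    if not profile.species:
        raise ValueError("empty profile")
    peak = max(s.abundance for s in profile.species)
    kept = tuple(
        s for s in profile.species if s.abundance >= cutoff_fraction * peak
    )
    return ProteoformProfile(kept, profile.backbone_mass)
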