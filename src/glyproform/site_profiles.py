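"""Site-specific glycoform occupancy profiles from glycopeptide XIC areas.

Relative quantification at the peptide level: each modification site's
glycoforms (including the unmodified form) are quantified by extracted-ion-
chromatogram (XIC) areas, normalized within the site so the proteoform areas
of one peptide sum to 100%, then averaged over LC-MS/MS runs.

C-mannosylation positional isomers (the WXXWXXW motif can carry two mannoses
on either the first+second or second+third Trp) are handled by
:func:`isomers_to_marginals`, which converts isomer-level abundances into
per-site marginal occupancies.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .glycan_algebra import EMPTY, GlycanComposition

__all__ = [
    "SiteId",
    "GlycoformRecord",
    "SiteProfile",
    "IsomerRecord",
    "normalize_site",
    "average_runs",
    "isomers_to_marginals",
]

_KINDS = ("N", "O", "C-Man")


class SiteId(NamedTuple):
    """(chain, mature-chain residue number, site kind)."""

    chain: str
    residue: int
    kind: str


def _check_site(site: SiteId) -> SiteId:
    site = SiteId(*site)
    if site.kind not in _KINDS:
        raise ValueError(f"site kind must be one of {_KINDS}, got {site.kind!r}")
    if site.residue < 1:
        raise ValueError(f"residue number must be >= 1, got {site.residue}")
    return site


@dataclass(frozen=True)
class GlycoformRecord:
    """One glycoform of one site in one run, with its XIC area."""

    site_id: SiteId
    composition: GlycanComposition  # EMPTY means unmodified
    run_id: str
    xic_area: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_id", _check_site(self.site_id))
        if self.xic_area < 0:
            raise ValueError(f"xic_area must be >= 0, got {self.xic_area}")


@dataclass(frozen=True)
class IsomerRecord:
    """One positional isomer of a multi-sequon peptide: the set of C-Man
    positions modified together, with its XIC area."""

    peptide_id: str
    site_set: frozenset[SiteId]
    run_id: str
    xic_area: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "site_set", frozenset(_check_site(s) for s in self.site_set)
        )
        if self.xic_area < 0:
            raise ValueError(f"xic_area must be >= 0, got {self.xic_area}")


@dataclass(frozen=True)
class SiteProfile:
    """A site's normalized glycoform distribution.

    ``entries`` maps composition -> relative abundance; abundances sum to 1.
    """

    site_id: SiteId
    entries: tuple[tuple[GlycanComposition, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "site_id", _check_site(self.site_id))
        comps = [c for c, _ in self.entries]
        if len(set(comps)) != len(comps):
            raise ValueError(f"site {self.site_id}: duplicate compositions")
        total = sum(a for _, a in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"site {self.site_id}: abundances sum to {total}, expected 1"
            )

    @classmethod
    def from_abundances(
        cls, site_id: SiteId, abundances: dict[GlycanComposition, float]
    ) -> "SiteProfile":
        """Build from raw non-negative weights, normalizing to 1."""
        total = sum(abundances.values())
        if total <= 0:
            raise ValueError(f"site {site_id}: all abundances zero")
        return cls(
            site_id,
            tuple((c, a / total) for c, a in abundances.items() if a > 0),
        )

    def abundance(self, comp: GlycanComposition) -> float:
        for c, a in self.entries:
            if c == comp:
                return a
        return 0.0

    def as_dict(self) -> dict[GlycanComposition, float]:
        return dict(self.entries)


def normalize_site(records: Sequence[GlycoformRecord]) -> SiteProfile:
    """Normalize one site's XIC areas of one run to relative abundances.

    Records must all belong to one site and one run; duplicate compositions
    have their areas summed. All-zero areas are rejected.
    """
    if not records:
        raise ValueError("no records to normalize")
    sites = {r.site_id for r in records}
    if len(sites) != 1:
        raise ValueError(f"records mix sites: {sorted(sites)}")
    runs = {r.run_id for r in records}
    if len(runs) != 1:
        raise ValueError(f"records mix runs: {sorted(runs)}")
    areas: dict[GlycanComposition, float] = defaultdict(float)
    for r in records:
        areas[r.composition] += r.xic_area
    return SiteProfile.from_abundances(records[0].site_id, dict(areas))


def average_runs(profiles: Sequence[SiteProfile]) -> SiteProfile:
    """Unweighted mean of per-run profiles for one site, renormalized.

    A composition missing from a run contributes abundance 0 in that run.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    sites = {p.site_id for p in profiles}
    if len(sites) != 1:
        raise ValueError(f"profiles mix sites: {sorted(sites)}")
    n = len(profiles)
    acc: dict[GlycanComposition, float] = defaultdict(float)
    for p in profiles:
        for comp, a in p.entries:
            acc[comp] += a / n
    return SiteProfile.from_abundances(profiles[0].site_id, dict(acc))


def isomers_to_marginals(
    isomer_records: Iterable[IsomerRecord],
) -> dict[SiteId, float]:
    """Per-site marginal occupancies from positional-isomer abundances.

    Isomer areas (for one peptide) are normalized to 1; the marginal of a
    site is the summed abundance of all isomers containing it. A site present
    in every isomer therefore has marginal 1.
    """
    records = list(isomer_records)
    if not records:
        raise ValueError("no isomer records")
    peptides = {r.peptide_id for r in records}
    if len(peptides) != 1:
        raise ValueError(f"isomer records mix peptides: {sorted(peptides)}")
    # Same isomer observed in several runs: sum its areas first.
    by_set: dict[frozenset[SiteId], float] = defaultdict(float)
    for r in records:
        by_set[r.site_set] += r.xic_area
    total = sum(by_set.values())
    if total <= 0:
        raise ValueError("all isomer areas zero")
    marginals: dict[SiteId, float] = defaultdict(float)
    for site_set, area in by_set.items():
        for site in site_set:
            marginals[site] += area / total
    return dict(marginals)
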