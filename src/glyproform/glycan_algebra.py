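"""Glycan monomer-composition arithmetic and mass-delta assignment.

A :class:`GlycanComposition` is an integer count vector over the four monomer
classes relevant to plasma glycoprotein work — HexNAc, Hex, NeuAc and dHex
(fucose). Linkage and branching are never inferred; only compositions are
tracked, which is all an intact-mass delta can support.

:func:`solve_delta` systematizes the manual step of reading a glycan
composition off an intact-mass difference: it enumerates every bounded
composition whose average mass falls within an absolute tolerance of the
delta, optionally filtered by a biosynthetic plausibility rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .mass_core import DEFAULT_TABLE, ResidueMassTable

__all__ = [
    "MONOMER_CLASSES",
    "GlycanComposition",
    "SolverConfig",
    "TEMPLATES",
    "composition_mass",
    "parse_composition",
    "solve_delta",
    "apply_enzyme",
]

#: Canonical monomer order; also the parser/formatter order and the
#: lexicographic tie-break order of the solver.
MONOMER_CLASSES: tuple[str, ...] = ("HexNAc", "Hex", "NeuAc", "dHex")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Integer monomer counts (HexNAc, Hex, NeuAc, dHex)."""

    HexNAc: int = 0
    Hex: int = 0
    NeuAc: int = 0
    dHex: int = 0

    def __post_init__(self) -> None:
        for mono in MONOMER_CLASSES:
            n = getattr(self, mono)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"{mono} count must be a non-negative integer, got {n!r}")

    def counts(self) -> dict[str, int]:
        return {m: getattr(self, m) for m in MONOMER_CLASSES}

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, m) for m in MONOMER_CLASSES)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            **{m: getattr(self, m) + getattr(other, m) for m in MONOMER_CLASSES}
        )

    def __sub__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            **{m: getattr(self, m) - getattr(other, m) for m in MONOMER_CLASSES}
        )

    def __mul__(self, k: int) -> "GlycanComposition":
        return GlycanComposition(**{m: getattr(self, m) * k for m in MONOMER_CLASSES})

    __rmul__ = __mul__

    def mass(self, table: ResidueMassTable = DEFAULT_TABLE) -> float:
        return composition_mass(self, table)

    def __str__(self) -> str:
        # "HexNAc4Hex5NeuAc2"; the empty composition prints as "unmodified".
        parts = [f"{m}{getattr(self, m)}" for m in MONOMER_CLASSES if getattr(self, m)]
        return "".join(parts) or "unmodified"


EMPTY = GlycanComposition()


def composition_mass(
    comp: GlycanComposition | Mapping[str, int],
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """Average mass (Da) of a composition: sum of count x monomer mass.

    Attachment to the protein is mass-additive — the condensation water is
    already accounted for in the residue-mass convention.
    """
    counts = comp.counts() if isinstance(comp, GlycanComposition) else comp
    total = 0.0
    for mono, n in counts.items():
        try:
            total += n * table.glycan_monomer_masses[mono]
        except KeyError:
            raise ValueError(f"unknown glycan monomer class {mono!r}") from None
    return total


def parse_composition(text: str) -> GlycanComposition:
    """Parse a concatenated class-count string like ``"HexNAc4Hex5NeuAc2"``.

    Case-sensitive; ``"unmodified"`` and ``""`` parse to the empty
    composition. Classes may appear in any order but not twice.
    """
    if text in ("", "unmodified"):
        return EMPTY
    counts: dict[str, int] = {}
    i = 0
    # Longest-first so "HexNAc" is not consumed as "Hex".
    classes = sorted(MONOMER_CLASSES, key=len, reverse=True)
    while i < len(text):
        for mono in classes:
            if text.startswith(mono, i):
                i += len(mono)
                j = i
                while j < len(text) and text[j].isdigit():
                    j += 1
                if j == i:
                    raise ValueError(f"missing count after {mono!r} in {text!r}")
                if mono in counts:
                    raise ValueError(f"duplicate class {mono!r} in {text!r}")
                counts[mono] = int(text[i:j])
                i = j
                break
        else:
            raise ValueError(f"cannot parse composition {text!r} at offset {i}")
    return GlycanComposition(**counts)


#: Named glycan templates: biantennary complex N-glycans at 0-2 sialic acids,
#: high-mannose N-glycans, mucin-type O-glycan cores and the single C-mannose.
TEMPLATES: dict[str, GlycanComposition] = {
    "A2G2S2": GlycanComposition(HexNAc=4, Hex=5, NeuAc=2),
    "A2G2S1": GlycanComposition(HexNAc=4, Hex=5, NeuAc=1),
    "A2G2": GlycanComposition(HexNAc=4, Hex=5),
    "Man5": GlycanComposition(HexNAc=2, Hex=5),
    "Man8": GlycanComposition(HexNAc=2, Hex=8),
    "Tn": GlycanComposition(HexNAc=1),
    "TF": GlycanComposition(HexNAc=1, Hex=1),
    "ST": GlycanComposition(HexNAc=1, Hex=1, NeuAc=1),
    "C-Man": GlycanComposition(Hex=1),
}

PlausibilityRule = Literal["none", "n_glycan_core", "aggregate"]

_MAX_CANDIDATES = 10**8


@dataclass(frozen=True)
class SolverConfig:
    """Bounded search settings for mapping a mass delta to compositions.

    ``tolerance_da`` is absolute (Da), not ppm of the delta: intact-mass
    accuracy is set by the ~150 kDa precursor, so a whole-protein PTM delta
    carries about +/-1 Da of absolute uncertainty regardless of its own size.

    ``plausibility_rule``:

    * ``"none"`` — no filter.
    * ``"n_glycan_core"`` — the delta is a single N-glycan, so it must
      contain the chitobiose/trimannosyl core (HexNAc >= 2 and Hex >= 3).
    * ``"aggregate"`` — the delta is a whole-protein PTM sum (several glycans
      plus C-mannoses); no per-glycan core constraint applies.
    """

    tolerance_da: float = 1.0
    per_class_bounds: Mapping[str, int] = field(
        default_factory=lambda: {"HexNAc": 10, "Hex": 20, "NeuAc": 6, "dHex": 2}
    )
    plausibility_rule: PlausibilityRule = "none"

    def __post_init__(self) -> None:
        if self.tolerance_da <= 0:
            raise ValueError("tolerance_da must be positive")
        for mono, b in self.per_class_bounds.items():
            if mono not in MONOMER_CLASSES:
                raise ValueError(f"unknown monomer class in bounds: {mono!r}")
            if b < 0:
                raise ValueError(f"bound for {mono} must be >= 0")


def _plausible(comp: GlycanComposition, rule: PlausibilityRule) -> bool:
    if rule == "n_glycan_core":
        return comp == EMPTY or (comp.HexNAc >= 2 and comp.Hex >= 3)
    return True


def solve_delta(
    delta: float,
    config: SolverConfig = SolverConfig(),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[tuple[GlycanComposition, float]]:
    """All bounded compositions whose mass matches ``delta`` within tolerance.

    Returns ``(composition, signed_error)`` pairs with
    ``error = composition_mass - delta``, sorted by absolute error then by
    lexicographic count vector — fully deterministic.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    bounds = [config.per_class_bounds.get(m, 0) for m in MONOMER_CLASSES]
    n_candidates = 1
    for b in bounds:
        n_candidates *= b + 1
    if n_candidates > _MAX_CANDIDATES:
        raise ValueError(
            f"bounds produce {n_candidates:.2e} candidates (> {_MAX_CANDIDATES:.0e}); "
            "tighten per_class_bounds"
        )
    masses = [table.glycan_monomer_masses[m] for m in MONOMER_CLASSES]
    out: list[tuple[GlycanComposition, float]] = []
    for counts in itertools.product(*(range(b + 1) for b in bounds)):
        err = sum(n * m for n, m in zip(counts, masses)) - delta
        if abs(err) <= config.tolerance_da:
            comp = GlycanComposition(**dict(zip(MONOMER_CLASSES, counts)))
            if _plausible(comp, config.plausibility_rule):
                out.append((comp, err))
    out.sort(key=lambda ce: (abs(ce[1]), ce[0].as_tuple()))
    return out


def apply_enzyme(
    assignment: Mapping[tuple, GlycanComposition],
    enzyme: Literal["sialidase", "pngasef"],
    site_kinds: Mapping[tuple, str] | None = None,
    pngasef_susceptible: Iterable[tuple] | None = None,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> tuple[dict[tuple, GlycanComposition], GlycanComposition]:
    """Transform a per-site composition assignment by an enzymatic treatment.

    * ``sialidase`` removes every NeuAc at every site.
    * ``pngasef`` removes the entire glycan, but only at the N-sites listed
      in ``pngasef_susceptible`` — under native conditions PNGase F action is
      typically incomplete, so susceptibility is an explicit per-site flag.
      ``site_kinds`` (site -> "N"/"O"/"C-Man") is required and any flagged
      non-N site is rejected: PNGase F cannot release O-glycans or C-mannose.

    Returns ``(new_assignment, removed_composition)``; mass is conserved
    (old total = new total + removed mass).
    """
    new: dict[tuple, GlycanComposition] = dict(assignment)
    removed = EMPTY
    if enzyme == "sialidase":
        for site, comp in assignment.items():
            if comp.NeuAc:
                removed += GlycanComposition(NeuAc=comp.NeuAc)
                new[site] = comp - GlycanComposition(NeuAc=comp.NeuAc)
    elif enzyme == "pngasef":
        if pngasef_susceptible is None:
            raise ValueError("pngasef requires a per-site susceptibility flag set")
        if site_kinds is None:
            raise ValueError("pngasef requires site_kinds to verify N-linkage")
        for site in pngasef_susceptible:
            kind = site_kinds.get(site)
            if kind != "N":
                raise ValueError(
                    f"PNGase F cannot act on site {site!r} of kind {kind!r}"
                )
            comp = assignment.get(site, EMPTY)
            removed += comp
            new[site] = EMPTY
    else:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    return new, removed
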