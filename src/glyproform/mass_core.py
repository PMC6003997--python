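"""Average-mass arithmetic for mature, disulfide-bonded multi-chain assemblies.

Everything here works in *average* masses (Da), the convention used when
assigning PTM compositions to intact-protein native-MS peaks: at ~150 kDa the
isotope envelope is unresolved and the centroid tracks the average mass.
Monoisotopic bookkeeping is deliberately out of scope.

The backbone mass of an assembly such as complement C8 (alpha-beta-gamma) is

    sum over chains of (residue masses + water)
      - 2 * n_disulfide * m(H)
      + sum of terminal corrections (e.g. N-terminal pyroglutamate)

Each disulfide bridge removes two hydrogens; terminal corrections are signed
deltas applied per chain (the C8 gamma chain carries a pyroglutamate
correction on its N-terminal Gln).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "ResidueMassTable",
    "ChainSpec",
    "AssemblySpec",
    "residue_sum",
    "backbone_mass",
    "mz_from_mass",
    "mass_from_mz",
    "ppm_error",
    "PYROGLU_CORRECTION_DA",
]

# Standard average amino-acid residue masses (Da), 4 decimals.
_AVERAGE_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

# Glycan monomer average masses (Da). Hex/HexNAc/NeuAc are the values used
# throughout intact-glycoprotein assignment; dHex (fucose) completes the set
# for core-fucosylated minor forms.
_GLYCAN_MONOMER_MASSES: dict[str, float] = {
    "Hex": 162.1424,
    "HexNAc": 203.1950,
    "NeuAc": 291.2579,
    "dHex": 146.1412,
}

#: Mass shift applied for N-terminal Gln -> pyroglutamate as reported for the
#: C8 gamma chain. Chemically an NH3 loss is -17.03 Da; the reported intact
#: backbone arithmetic uses -18.01 Da, so that is the packaged default and it
#: stays configurable per chain.
PYROGLU_CORRECTION_DA: float = -18.01


@dataclass(frozen=True)
class ResidueMassTable:
    """Average masses used for all backbone and glycan arithmetic."""

    amino_acid_residue_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(_AVERAGE_RESIDUE_MASSES)
    )
    water_mass: float = 18.0153
    proton_mass: float = 1.00728
    hydrogen_mass: float = 1.00794
    glycan_monomer_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(_GLYCAN_MONOMER_MASSES)
    )

    def __post_init__(self) -> None:
        for name, m in (
            ("water_mass", self.water_mass),
            ("proton_mass", self.proton_mass),
            ("hydrogen_mass", self.hydrogen_mass),
        ):
            if m <= 0:
                raise ValueError(f"{name} must be positive, got {m}")
        for code, m in self.amino_acid_residue_masses.items():
            if m <= 0:
                raise ValueError(f"residue mass for {code!r} must be positive")
        for mono, m in self.glycan_monomer_masses.items():
            if m <= 0:
                raise ValueError(f"glycan monomer mass for {mono!r} must be positive")


#: Module-wide default table.
DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class ChainSpec:
    """One polypeptide chain of an assembly.

    ``mature_range`` lists 1-based inclusive intervals of ``full_sequence``
    retained in the secreted protein (i.e. after removal of the signal
    peptide and any propeptide). ``terminal_mass_corrections`` are signed
    (label, delta-Da) pairs, e.g. ``("pyroGlu", -18.01)``.
    """

    chain_id: str
    full_sequence: str
    mature_range: tuple[tuple[int, int], ...] = ()
    terminal_mass_corrections: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.full_sequence)
        ranges = self.mature_range or ((1, n),)
        prev_end = 0
        for start, end in sorted(ranges):
            if not (1 <= start <= end <= n):
                raise ValueError(
                    f"chain {self.chain_id!r}: mature range {start}-{end} outside "
                    f"sequence of length {n}"
                )
            if start <= prev_end:
                raise ValueError(
                    f"chain {self.chain_id!r}: overlapping mature ranges"
                )
            prev_end = end
        if not self.mature_sequence:
            raise ValueError(f"chain {self.chain_id!r}: empty mature sequence")

    @property
    def mature_sequence(self) -> str:
        ranges = self.mature_range or ((1, len(self.full_sequence)),)
        return "".join(
            self.full_sequence[start - 1 : end] for start, end in sorted(ranges)
        )


@dataclass(frozen=True)
class AssemblySpec:
    """A multi-chain, disulfide-bonded assembly."""

    chains: tuple[ChainSpec, ...]
    n_disulfide_bonds: int = 0

    def __post_init__(self) -> None:
        if self.n_disulfide_bonds < 0:
            raise ValueError("n_disulfide_bonds must be non-negative")
        n_cys = sum(c.mature_sequence.count("C") for c in self.chains)
        if self.n_disulfide_bonds > n_cys // 2:
            raise ValueError(
                f"{self.n_disulfide_bonds} disulfide bonds exceed capacity of "
                f"{n_cys} mature cysteines"
            )


def residue_sum(sequence: str, table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Average mass (Da) of a peptide: sum of residue masses plus one water.

    The empty sequence returns the water mass.
    """
    total = table.water_mass
    masses = table.amino_acid_residue_masses
    for pos, code in enumerate(sequence, start=1):
        try:
            total += masses[code]
        except KeyError:
            raise ValueError(
                f"unknown residue code {code!r} at position {pos}"
            ) from None
    return total


def backbone_mass(
    assembly: AssemblySpec, table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """Average backbone mass (Da) of a disulfide-bonded assembly.

    Sums the mature chain masses, subtracts two hydrogens per disulfide bond
    and applies every chain's terminal corrections.
    """
    total = sum(residue_sum(c.mature_sequence, table) for c in assembly.chains)
    total -= assembly.n_disulfide_bonds * 2.0 * table.hydrogen_mass
    total += sum(
        delta for c in assembly.chains for _, delta in c.terminal_mass_corrections
    )
    return total


def mz_from_mass(
    mass: float, z: int, table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """m/z of the [M + zH]^z+ ion."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (mass + z * table.proton_mass) / z


def mass_from_mz(mz: float, z: int, table: ResidueMassTable = DEFAULT_TABLE) -> float:
    """Neutral (zero-charge) mass from an [M + zH]^z+ m/z. Exact inverse of
    :func:`mz_from_mass`."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    if mz < table.proton_mass:
        raise ValueError(f"m/z {mz} below a bare proton is nonphysical")
    return z * mz - z * table.proton_mass


def ppm_error(predicted: float, observed: float) -> float:
    """Signed relative error of ``observed`` vs ``predicted`` in ppm."""
    if predicted <= 0:
        raise ValueError("predicted mass must be positive")
    if observed <= 0:
        raise ValueError("observed mass must be positive")
    return (observed - predicted) / predicted * 1e6
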