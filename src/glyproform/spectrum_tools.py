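"""Native ESI-MS spectrum simulation and zero-charge deconvolution.

Simulation: each proteoform species spreads its abundance over a discrete
Gaussian charge envelope; every (species, charge) pair contributes a Gaussian
peak at ``(M + z*p)/z`` whose width follows an Orbitrap-like resolution decay
``R_eff(mz) = R200 * sqrt(200/mz)``. Optional Na/K adduct satellites model
the unresolved +21.98 / +37.96 Da shoulders common in native ESI.

Deconvolution: peak picking with parabolic interpolation, integer charge
assignment by minimizing the variance of implied neutral masses over a
candidate base charge, and a remap-and-sum transform of the full m/z trace
onto a zero-charge mass axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .glycan_algebra import SolverConfig, solve_delta
from .mass_core import DEFAULT_TABLE, ResidueMassTable, mass_from_mz, mz_from_mass
from .proteoform_builder import ProteoformProfile

__all__ = [
    "Spectrum",
    "ChargeEnvelope",
    "PeakShapeConfig",
    "AdductModel",
    "simulate_spectrum",
    "pick_peaks",
    "assign_charges",
    "deconvolute_spectrum",
    "annotate_differences",
]

_GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

NA_MINUS_H_DA = 21.9818
K_MINUS_H_DA = 37.9559


@dataclass(frozen=True)
class Spectrum:
    """Sampled intensity over a strictly increasing m/z or mass axis."""

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: str = "mz"  # "mz" | "zero_charge"

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if axis.ndim != 1 or axis.shape != intensity.shape:
            raise ValueError("axis and intensity must be 1-D and equal length")
        if axis.size and np.any(np.diff(axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if np.any(intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.axis_kind not in ("mz", "zero_charge"):
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")


@dataclass(frozen=True)
class ChargeEnvelope:
    """Discrete Gaussian intensity weights over integer charge states."""

    z_min: int
    z_max: int
    center_z: float
    width_z: float

    def __post_init__(self) -> None:
        if not (1 <= self.z_min <= self.z_max):
            raise ValueError("require 1 <= z_min <= z_max")
        if self.width_z <= 0:
            raise ValueError("width_z must be positive")

    @property
    def charges(self) -> np.ndarray:
        return np.arange(self.z_min, self.z_max + 1)

    @property
    def weights(self) -> np.ndarray:
        z = self.charges.astype(float)
        w = np.exp(-0.5 * ((z - self.center_z) / self.width_z) ** 2)
        return w / w.sum()


@dataclass(frozen=True)
class PeakShapeConfig:
    """Gaussian peak shape under an Orbitrap-like resolution decay.

    ``FWHM(mz) = mz / R_eff(mz)`` with
    ``R_eff(mz) = resolution_at_200 * sqrt(200 / mz)``.
    """

    resolution_at_200: float = 30000.0

    def __post_init__(self) -> None:
        if self.resolution_at_200 <= 0:
            raise ValueError("resolution must be positive")

    def fwhm(self, mz: float) -> float:
        r_eff = self.resolution_at_200 * np.sqrt(200.0 / mz)
        return mz / r_eff


@dataclass(frozen=True)
class AdductModel:
    """Na+/K+ satellite model: each species sheds the stated intensity
    fraction into +Na-H and +K-H satellites (mass conserved)."""

    na_probability: float = 0.0
    k_probability: float = 0.0
    na_minus_h_mass: float = NA_MINUS_H_DA
    k_minus_h_mass: float = K_MINUS_H_DA

    def __post_init__(self) -> None:
        for p in (self.na_probability, self.k_probability):
            if not (0.0 <= p <= 1.0):
                raise ValueError("adduct probabilities must lie in [0, 1]")
        if self.na_probability + self.k_probability > 1.0:
            raise ValueError("adduct probabilities sum above 1")

    def split(self, mass: float, abundance: float) -> list[tuple[float, float]]:
        """(mass, weight) components: bare species plus satellites."""
        p_main = 1.0 - self.na_probability - self.k_probability
        out = [(mass, abundance * p_main)]
        if self.na_probability:
            out.append((mass + self.na_minus_h_mass, abundance * self.na_probability))
        if self.k_probability:
            out.append((mass + self.k_minus_h_mass, abundance * self.k_probability))
        return out


def simulate_spectrum(
    profile: ProteoformProfile,
    envelope: ChargeEnvelope,
    shape: PeakShapeConfig = PeakShapeConfig(),
    adducts: AdductModel | None = None,
    grid: np.ndarray | None = None,
    grid_step: float = 0.05,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> Spectrum:
    """Deterministic m/z spectrum of a proteoform profile.

    ``intensity(x) = sum over species, charges of
    abundance * weight(z) * Gaussian(x; mz(M, z), FWHM(mz))``.
    If ``grid`` is None a default grid with step ``grid_step`` spanning the
    envelope plus 5 FWHM margins is built.
    """
    if not profile.species:
        raise ValueError("empty profile")
    components: list[tuple[float, float]] = []  # (neutral mass, weight)
    for s in profile.species:
        if adducts is None:
            components.append((s.mass, s.abundance))
        else:
            components.extend(adducts.split(s.mass, s.abundance))

    zs = envelope.charges
    ws = envelope.weights
    if grid is None:
        masses = [m for m, _ in components]
        lo = mz_from_mass(min(masses), int(zs[-1]), table)
        hi = mz_from_mass(max(masses), int(zs[0]), table)
        margin = 5.0 * shape.fwhm(hi)
        grid = np.arange(lo - margin, hi + margin + grid_step, grid_step)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty m/z grid")

    intensity = np.zeros_like(grid)
    for mass, weight in components:
        if weight <= 0:
            continue
        for z, w in zip(zs, ws):
            center = mz_from_mass(mass, int(z), table)
            sigma = shape.fwhm(center) * _GAUSS_FWHM_TO_SIGMA
            lo_i, hi_i = np.searchsorted(
                grid, [center - 6 * sigma, center + 6 * sigma]
            )
            if hi_i > lo_i:
                x = grid[lo_i:hi_i]
                intensity[lo_i:hi_i] += (
                    weight * w * np.exp(-0.5 * ((x - center) / sigma) ** 2)
                )
    return Spectrum(grid, intensity, "mz")


def pick_peaks(
    spectrum: Spectrum, min_rel_intensity: float = 0.01
) -> list[tuple[float, float]]:
    """Local maxima above ``min_rel_intensity x global max``.

    Maxima must also be *prominent* at the same relative level, so noise
    wiggles riding on a peak flank or a baseline are not reported as peaks.
    Positions are refined by 3-point parabolic interpolation; returns
    ``(position, apex_intensity)`` pairs in axis order. A flat spectrum
    yields no peaks.
    """
    from scipy.signal import find_peaks

    y = spectrum.intensity
    x = spectrum.axis
    if y.size < 3 or y.max() <= 0:
        return []
    threshold = min_rel_intensity * y.max()
    indices, _ = find_peaks(y, height=threshold, prominence=threshold)
    out: list[tuple[float, float]] = []
    for i in indices:
        if 1 <= i <= y.size - 2:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom < 0:
                delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
            else:
                delta = 0.0
            step_l = x[i] - x[i - 1]
            step_r = x[i + 1] - x[i]
            step = step_r if delta >= 0 else step_l
            pos = x[i] + delta * step
            apex = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
            out.append((float(pos), float(apex)))
    return out


def cluster_apexes(
    peaks: Sequence[tuple[float, float]], min_gap: float = 50.0
) -> list[tuple[float, float]]:
    """The most intense peak of each charge-state cluster.

    Peaks are grouped wherever consecutive positions are separated by more
    than ``min_gap`` (charge-state clusters of a ~150 kDa species sit
    hundreds of m/z apart while proteoform peaks within a cluster are a few
    m/z apart). Tracking one species — its apex — across charge states is
    what makes the series consumable by :func:`assign_charges`.
    """
    ordered = sorted(peaks)
    if not ordered:
        return []
    clusters: list[list[tuple[float, float]]] = [[ordered[0]]]
    for p in ordered[1:]:
        if p[0] - clusters[-1][-1][0] > min_gap:
            clusters.append([p])
        else:
            clusters[-1].append(p)
    return [max(c, key=lambda pi: pi[1]) for c in clusters]


def assign_charges(
    peaks: Sequence[float],
    z_search: tuple[int, int] = (1, 100),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> tuple[list[int], np.ndarray, float]:
    """Infer integer charges of one species' consecutive charge-state series.

    ``peaks`` are the m/z positions (any order) of >= 2 consecutive charge
    states. Ascending m/z maps to consecutive descending charges
    ``z0+n-1 .. z0``; the base charge ``z0`` is chosen to minimize the
    variance of the implied neutral masses. Returns
    ``(charges_per_ascending_peak, implied_masses, mean_mass)``.
    """
    mz = np.sort(np.asarray(peaks, dtype=float))
    n = mz.size
    if n < 2:
        raise ValueError("need >= 2 peaks; charge is underdetermined")
    best: tuple[float, int] | None = None
    for z0 in range(z_search[0], z_search[1] + 1):
        zs = np.arange(z0 + n - 1, z0 - 1, -1)  # descending with ascending m/z
        masses = zs * (mz - table.proton_mass)
        # coefficient of variation, so large-z0 candidates are not favored by
        # their larger absolute mass scale
        var = float(np.var(masses) / np.mean(masses) ** 2)
        if best is None or var < best[0]:
            best = (var, z0)
    z0 = best[1]
    zs = np.arange(z0 + n - 1, z0 - 1, -1)
    masses = zs * (mz - table.proton_mass)
    return list(int(z) for z in zs), masses, float(masses.mean())


def deconvolute_spectrum(
    spectrum: Spectrum,
    charges: Sequence[int],
    mass_grid: np.ndarray,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> Spectrum:
    """Zero-charge transform: remap each charge state's trace onto a neutral
    mass axis and sum.

    ``I_zero(M) = sum over z of I_mz((M + z*p)/z)`` — each candidate neutral
    mass collects the intensity of all its charge-state images. Peaks
    supported by the whole charge series reinforce; noise does not.
    """
    if spectrum.axis_kind != "mz":
        raise ValueError("deconvolute_spectrum expects an m/z spectrum")
    mass_grid = np.asarray(mass_grid, dtype=float)
    if mass_grid.size == 0:
        raise ValueError("empty mass grid")
    out = np.zeros_like(mass_grid)
    for z in charges:
        mz_images = (mass_grid + z * table.proton_mass) / z
        out += np.interp(
            mz_images, spectrum.axis, spectrum.intensity, left=0.0, right=0.0
        )
    return Spectrum(mass_grid, out, "zero_charge")


def annotate_differences(
    masses: Sequence[float],
    solver: SolverConfig | None = None,
    pairwise: bool = False,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[tuple[float, float, float, str]]:
    """Label mass differences with their best glycan composition.

    Consecutive (or, with ``pairwise=True``, all pairwise) deltas of the
    sorted masses are run through :func:`solve_delta`; a delta with no
    composition within tolerance is labeled
    ``"unassigned (possible Na/K adduct)"``. Returns
    ``(mass_low, mass_high, delta, label)`` rows.
    """
    if len(masses) < 2:
        raise ValueError("need >= 2 masses to take differences")
    if solver is None:
        solver = SolverConfig(
            tolerance_da=1.0,
            per_class_bounds={"HexNAc": 4, "Hex": 10, "NeuAc": 4, "dHex": 2},
        )
    ms = sorted(float(m) for m in masses)
    if pairwise:
        pairs = [(a, b) for i, a in enumerate(ms) for b in ms[i + 1 :]]
    else:
        pairs = list(zip(ms, ms[1:]))
    out = []
    for lo, hi in pairs:
        delta = hi - lo
        solutions = solve_delta(delta, solver, table)
        solutions = [(c, e) for c, e in solutions if c.total > 0]
        if solutions:
            label = str(solutions[0][0])
        else:
            label = "unassigned (possible Na/K adduct)"
        out.append((lo, hi, delta, label))
    return out
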