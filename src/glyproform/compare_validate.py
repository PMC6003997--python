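"""Compare a constructed (in-silico) spectrum against an experimental one.

The constructed spectrum encodes what the peptide-centric site profiles
predict the intact protein should look like; the experimental spectrum is
what native MS measured. Agreement is quantified by the Pearson correlation
of the two traces on a common grid, and peak-by-peak by greedy
nearest-neighbor matching with glycan annotation of the leftovers
(unmatched experimental signals are typically Na+/K+ adducts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .glycan_algebra import SolverConfig
from .spectrum_tools import Spectrum, annotate_differences

__all__ = [
    "ComparisonResult",
    "resample_to_grid",
    "pearson_r",
    "match_peaks",
    "compare_spectra",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of an experimental-vs-constructed comparison."""

    pearson_r: float | None
    matched: tuple[tuple[float, float, float], ...]  # (exp, con, delta)
    unmatched_experimental: tuple[tuple[float, str], ...]  # (position, note)
    grid_step: float | None = None

    def __post_init__(self) -> None:
        if self.pearson_r is not None and abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")


def resample_to_grid(
    a: Spectrum, b: Spectrum, step: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate both spectra onto a shared grid over their
    overlapping axis range. Returns ``(grid, ya, yb)``."""
    if a.axis_kind != b.axis_kind:
        raise ValueError("spectra are on different axis kinds")
    if step <= 0:
        raise ValueError("step must be positive")
    lo = max(a.axis[0], b.axis[0])
    hi = min(a.axis[-1], b.axis[-1])
    if hi <= lo:
        raise ValueError("spectra axes do not overlap")
    grid = np.arange(lo, hi + step / 2, step)
    ya = np.interp(grid, a.axis, a.intensity)
    yb = np.interp(grid, b.axis, b.intensity)
    return grid, ya, yb


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Standard Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def match_peaks(
    experimental: Sequence[tuple[float, float]],
    constructed: Sequence[tuple[float, float]],
    tol_mass: float = 3.0,
    solver: SolverConfig | None = None,
) -> ComparisonResult:
    """Greedy nearest-neighbor peak matching within ``tol_mass``.

    Candidate pairs are taken closest-first, each peak used at most once.
    Unmatched experimental peaks are annotated by solving the mass gap to
    the nearest constructed peak for a glycan composition; gaps that no
    composition explains are flagged as possible Na/K adducts.
    """
    exp_pos = [p for p, _ in experimental]
    con_pos = [p for p, _ in constructed]
    pairs = sorted(
        ((abs(e - c), i, j) for i, e in enumerate(exp_pos) for j, c in enumerate(con_pos)),
        key=lambda t: t[0],
    )
    used_e: set[int] = set()
    used_c: set[int] = set()
    matched: list[tuple[float, float, float]] = []
    for d, i, j in pairs:
        if d > tol_mass:
            break
        if i in used_e or j in used_c:
            continue
        used_e.add(i)
        used_c.add(j)
        matched.append((exp_pos[i], con_pos[j], exp_pos[i] - con_pos[j]))
    unmatched: list[tuple[float, str]] = []
    for i, e in enumerate(exp_pos):
        if i in used_e:
            continue
        if con_pos:
            nearest = min(con_pos, key=lambda c: abs(e - c))
            lo, hi = sorted((e, nearest))
            if hi > lo:
                _, _, _, label = annotate_differences([lo, hi], solver)[0]
            else:
                label = "unassigned (possible Na/K adduct)"
            note = f"delta {e - nearest:+.2f} to nearest constructed: {label}"
        else:
            note = "no constructed peaks"
        unmatched.append((e, note))
    matched.sort()
    return ComparisonResult(None, tuple(matched), tuple(unmatched))


def compare_spectra(
    experimental: Spectrum,
    constructed: Spectrum,
    grid_step: float | None = None,
    tol_mass: float = 3.0,
    min_rel_intensity: float = 0.01,
    baseline_subtract: bool = False,
    solver: SolverConfig | None = None,
) -> ComparisonResult:
    """Full comparison: correlation on a common grid plus peak matching.

    The default grid step is 1 Da on a zero-charge axis and 0.05 on m/z.
    ``baseline_subtract`` subtracts each trace's minimum before correlating
    (off by default).
    """
    from .spectrum_tools import pick_peaks

    if grid_step is None:
        grid_step = 1.0 if experimental.axis_kind == "zero_charge" else 0.05
    _, ye, yc = resample_to_grid(experimental, constructed, grid_step)
    if baseline_subtract:
        ye = ye - ye.min()
        yc = yc - yc.min()
    r = pearson_r(ye, yc)
    exp_peaks = pick_peaks(experimental, min_rel_intensity)
    con_peaks = pick_peaks(constructed, min_rel_intensity)
    base = match_peaks(exp_peaks, con_peaks, tol_mass, solver)
    return ComparisonResult(r, base.matched, base.unmatched_experimental, grid_step)
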