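"""File formats: FASTA chains, assembly config, XIC/profile TSVs, spectra CSVs.

All tabular formats are TSV with a header row; spectra are two-column CSV.
Composition strings use the concatenated class-count notation
(``HexNAc4Hex5NeuAc2``), parsed case-sensitively; site labels are
``chain:residue`` with the site kind in its own column. Structured configs
are YAML (a JSON superset here) parsed strictly: unknown keys are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .glycan_algebra import GlycanComposition, parse_composition
from .mass_core import AssemblySpec, ChainSpec
from .proteoform_builder import ProteoformProfile, Species
from .site_profiles import GlycoformRecord, SiteId, SiteProfile
from .compare_validate import ComparisonResult
from .spectrum_tools import Spectrum

__all__ = [
    "read_fasta_sequences",
    "read_assembly_config",
    "read_xic_table",
    "write_xic_table",
    "read_site_profiles",
    "write_site_profiles",
    "write_proteoform_table",
    "read_proteoform_table",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_comparison_json",
]


def _format_site(site: SiteId) -> str:
    return f"{site.chain}:{site.residue}"


def _parse_site(label: str, kind: str) -> SiteId:
    chain, _, residue = str(label).partition(":")
    if not residue:
        raise ValueError(f"site label {label!r} is not 'chain:residue'")
    return SiteId(chain, int(residue), kind)


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def _reject_unknown(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def read_assembly_config(path: str | Path) -> AssemblySpec:
    """Read an assembly description (YAML/JSON).

    Schema::

        n_disulfide_bonds: 22
        chains:
          - chain_id: alpha
            fasta: chains.fasta        # or  sequence: "MA..."
            fasta_record: P07357       # optional; default: record == chain_id
            mature_range: [[31, 584]]  # 1-based inclusive; optional
            terminal_corrections: [["pyroGlu", -18.01]]  # optional

    FASTA paths are resolved relative to the config file.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: assembly config must be a mapping")
    _reject_unknown(doc, {"chains", "n_disulfide_bonds"}, str(path))
    chains = []
    for entry in doc.get("chains", []):
        _reject_unknown(
            entry,
            {
                "chain_id",
                "fasta",
                "fasta_record",
                "sequence",
                "mature_range",
                "terminal_corrections",
            },
            f"{path} chain entry",
        )
        chain_id = entry["chain_id"]
        if "sequence" in entry:
            seq = str(entry["sequence"]).upper()
        elif "fasta" in entry:
            fasta = path.parent / entry["fasta"]
            if not fasta.exists():
                raise FileNotFoundError(f"FASTA not found: {fasta}")
            records = read_fasta_sequences(fasta)
            rec_id = entry.get("fasta_record", chain_id)
            if rec_id not in records:
                raise ValueError(
                    f"record {rec_id!r} not in {fasta} (has {sorted(records)})"
                )
            seq = records[rec_id]
        else:
            raise ValueError(f"chain {chain_id!r}: need 'sequence' or 'fasta'")
        mature = tuple(
            (int(s), int(e)) for s, e in entry.get("mature_range", [])
        )
        corrections = tuple(
            (str(label), float(delta))
            for label, delta in entry.get("terminal_corrections", [])
        )
        chains.append(ChainSpec(chain_id, seq, mature, corrections))
    return AssemblySpec(tuple(chains), int(doc.get("n_disulfide_bonds", 0)))


_XIC_COLUMNS = ["site", "kind", "composition", "run", "area"]


def write_xic_table(records: Iterable[GlycoformRecord], path: str | Path) -> None:
    rows = [
        {
            "site": _format_site(r.site_id),
            "kind": r.site_id.kind,
            "composition": str(r.composition),
            "run": r.run_id,
            "area": r.xic_area,
        }
        for r in records
    ]
    # %.17g round-trips float64 exactly
    pd.DataFrame(rows, columns=_XIC_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_xic_table(path: str | Path) -> list[GlycoformRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_XIC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing XIC columns {sorted(missing)}")
    return [
        GlycoformRecord(
            _parse_site(row["site"], row["kind"]),
            parse_composition(str(row["composition"])),
            str(row["run"]),
            float(row["area"]),
        )
        for _, row in df.iterrows()
    ]


def write_site_profiles(profiles: Iterable[SiteProfile], path: str | Path) -> None:
    rows = [
        {
            "site": _format_site(p.site_id),
            "kind": p.site_id.kind,
            "composition": str(comp),
            "abundance": ab,
        }
        for p in profiles
        for comp, ab in p.entries
    ]
    pd.DataFrame(
        rows, columns=["site", "kind", "composition", "abundance"]
    ).to_csv(path, sep="\t", index=False)


def read_site_profiles(path: str | Path) -> list[SiteProfile]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    profiles = []
    for (site, kind), group in df.groupby(["site", "kind"], sort=False):
        site_id = _parse_site(site, kind)
        abundances = {
            parse_composition(str(row["composition"])): float(row["abundance"])
            for _, row in group.iterrows()
        }
        profiles.append(SiteProfile.from_abundances(site_id, abundances))
    return profiles


def write_proteoform_table(profile: ProteoformProfile, path: str | Path) -> None:
    rows = [
        {"composition": str(s.composition), "mass": s.mass, "abundance": s.abundance}
        for s in profile.species
    ]
    pd.DataFrame(rows, columns=["composition", "mass", "abundance"]).to_csv(
        path, sep="\t", index=False
    )


def read_proteoform_table(
    path: str | Path, backbone_mass: float | None = None
) -> ProteoformProfile:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    species = tuple(
        Species(
            parse_composition(str(row["composition"])),
            float(row["mass"]),
            float(row["abundance"]),
        )
        for _, row in df.iterrows()
    )
    if backbone_mass is None:
        # recover backbone from the least-glycosylated species' own mass
        from .glycan_algebra import composition_mass

        ref = min(species, key=lambda s: s.composition.total)
        backbone_mass = ref.mass - composition_mass(ref.composition)
    return ProteoformProfile(species, backbone_mass)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    label = "mz" if spectrum.axis_kind == "mz" else "mass"
    pd.DataFrame({label: spectrum.axis, "intensity": spectrum.intensity}).to_csv(
        path, index=False
    )


def read_spectrum_csv(path: str | Path, axis_kind: str | None = None) -> Spectrum:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: spectrum CSV needs two columns")
    if axis_kind is None:
        axis_kind = "zero_charge" if df.columns[0].lower() == "mass" else "mz"
    axis = df.iloc[:, 0].to_numpy(dtype=float)
    intensity = df.iloc[:, 1].to_numpy(dtype=float)
    order = np.argsort(axis)
    return Spectrum(axis[order], intensity[order], axis_kind)


def write_comparison_json(result: ComparisonResult, path: str | Path) -> None:
    doc = {
        "pearson_r": result.pearson_r,
        "grid_step": result.grid_step,
        "n_matched": len(result.matched),
        "n_unmatched_experimental": len(result.unmatched_experimental),
        "matched": [
            {"experimental": e, "constructed": c, "delta": d}
            for e, c, d in result.matched
        ],
        "unmatched_experimental": [
            {"position": p, "note": note}
            for p, note in result.unmatched_experimental
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))
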