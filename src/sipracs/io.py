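"""Readers and writers for the pipeline's plain-text artifact formats.

All files are UTF-8 with a header row and '.' decimal separator:

* ASV table — TSV, rows are ASVs, columns ``<treatment>_<fraction>`` holding
  relative abundances (optional ``taxonomy`` column);
* fraction metadata — CSV with treatment, fraction_number,
  buoyant_density_g_ml, copies_16S;
* spectra — long CSV with cell_id, treatment, wavenumber_cm1, intensity and
  an optional true_labelled ground-truth column (fixtures only);
* windows, medium, ratios, manifests, reports — JSON.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consortium import AnnotationSet, MediumRecipe, RatioDesign
from .enrichment import AsvFractionTable, RefRecord
from .gradient import Fraction, FractionWindows, GradientRun
from .raman import LabelCall, Spectrum

__all__ = [
    "read_asv_table",
    "write_asv_table",
    "read_fractions_csv",
    "write_fractions_csv",
    "read_spectra",
    "write_spectra",
    "read_windows_json",
    "write_windows_json",
    "write_ref_calls",
    "read_ref_calls",
    "write_label_calls",
    "write_sorting_manifest",
    "read_annotations",
    "write_medium_json",
    "write_ratios_json",
]

logger = logging.getLogger(__name__)

_COLUMN_RE = re.compile(r"^(12C|13C)_(\d+)$")
MIN_SPECTRUM_POINTS = 50


def _parse_asv_columns(columns: Iterable[str]) -> dict[str, tuple[str, int]]:
    parsed = {}
    for col in columns:
        m = _COLUMN_RE.match(col)
        if m:
            parsed[col] = (m.group(1), int(m.group(2)))
    return parsed


def read_asv_table(path: str | Path) -> AsvFractionTable:
    """Read a TSV ASV relative-abundance table.

    Rejects missing abundance columns, non-numeric cells and negative values,
    naming the offending row/column; warns when a fraction's column sum is off
    1 by more than 1e-4.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "asv_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'asv_id'")
    df = df.set_index("asv_id")
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df.pop("taxonomy").fillna("").to_dict()
    parsed = _parse_asv_columns(df.columns)
    if not parsed:
        raise ValueError(
            f"{path}: no abundance columns of the form <treatment>_<fraction> found"
        )
    unknown = [c for c in df.columns if c not in parsed]
    if unknown:
        raise ValueError(f"{path}: unrecognised columns {unknown}")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = df.index[converted.isna()][0]
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        if (converted < 0).any():
            row = df.index[converted < 0][0]
            raise ValueError(f"{path}: negative abundance at row {row!r}, column {col!r}")
        numeric[col] = converted
    numeric.columns = pd.MultiIndex.from_tuples(
        [parsed[c] for c in numeric.columns], names=["treatment", "fraction_number"]
    )
    sums = numeric.sum(axis=0)
    off = sums[(sums - 1.0).abs() > 1e-4]
    if not off.empty:
        logger.warning("%s: %d fraction columns deviate from sum 1 by > 1e-4", path, len(off))
    return AsvFractionTable(numeric, taxonomy=taxonomy, check=False)


def write_asv_table(table: AsvFractionTable, path: str | Path) -> None:
    flat = table.data.copy()
    flat.columns = [f"{t}_{k}" for t, k in flat.columns]
    if table.taxonomy:
        flat.insert(0, "taxonomy", [table.taxonomy.get(a, "") for a in flat.index])
    flat.index.name = "asv_id"
    flat.to_csv(path, sep="\t", float_format="%.10g")


def read_fractions_csv(path: str | Path) -> dict[str, GradientRun]:
    """Read fraction metadata CSV into one GradientRun per treatment."""
    df = pd.read_csv(path)
    required = {"treatment", "fraction_number", "buoyant_density_g_ml", "copies_16S"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    runs = {}
    for treatment, grp in df.groupby("treatment"):
        runs[str(treatment)] = GradientRun(
            treatment=str(treatment),
            fractions=[
                Fraction(
                    treatment=str(treatment),
                    fraction_number=int(r.fraction_number),
                    buoyant_density=float(r.buoyant_density_g_ml),
                    copies_16s=float(r.copies_16S),
                )
                for r in grp.itertuples()
            ],
        )
    return runs


def write_fractions_csv(runs: Sequence[GradientRun], path: str | Path) -> None:
    rows = [
        {
            "treatment": f.treatment,
            "fraction_number": f.fraction_number,
            "buoyant_density_g_ml": f.buoyant_density,
            "copies_16S": f.copies_16s,
        }
        for run in runs
        for f in run.fractions
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_spectra(path: str | Path) -> list[Spectrum]:
    """Read a long-format spectra CSV into per-cell spectra.

    Rows may arrive in any order; each cell's grid is sorted ascending.
    Duplicate (cell_id, wavenumber) pairs and cells with fewer than 50 points
    are rejected.
    """
    df = pd.read_csv(path)
    required = {"cell_id", "treatment", "wavenumber_cm1", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    spectra = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("wavenumber_cm1")
        if grp["wavenumber_cm1"].duplicated().any():
            raise ValueError(f"{path}: duplicated (cell_id, wavenumber) for cell {cell_id!r}")
        if len(grp) < MIN_SPECTRUM_POINTS:
            raise ValueError(
                f"{path}: cell {cell_id!r} has {len(grp)} points (< {MIN_SPECTRUM_POINTS})"
            )
        meta = {}
        if "true_labelled" in grp.columns:
            meta["true_labelled"] = bool(grp["true_labelled"].iloc[0])
        spectra.append(
            Spectrum(
                cell_id=str(cell_id),
                treatment=str(grp["treatment"].iloc[0]),
                wavenumbers=grp["wavenumber_cm1"].to_numpy(float),
                intensities=grp["intensity"].to_numpy(float),
                meta=meta,
            )
        )
    return spectra


def write_spectra(spectra: Sequence[Spectrum], path: str | Path) -> None:
    frames = []
    for s in spectra:
        frame = pd.DataFrame(
            {
                "cell_id": s.cell_id,
                "treatment": s.treatment,
                "wavenumber_cm1": s.wavenumbers,
                "intensity": s.intensities,
            }
        )
        if "true_labelled" in s.meta:
            frame["true_labelled"] = bool(s.meta["true_labelled"])
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def write_windows_json(windows: FractionWindows, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(windows.to_dict(), fh, indent=2)


def read_windows_json(path: str | Path) -> FractionWindows:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return FractionWindows(
        light_lo=d["light"][0],
        light_hi=d["light"][1],
        heavy_lo=d["heavy"][0],
        heavy_hi=d["heavy"][1],
        fallback=bool(d.get("fallback", False)),
    )


REF_COLUMNS = [
    "asv_id", "taxonomy", "A13_heavy", "A13_light", "A12_heavy", "A12_light",
    "REF", "rank", "active",
]


def write_ref_calls(records: Sequence[RefRecord], path: str | Path) -> None:
    rows = [
        {
            "asv_id": r.asv_id,
            "taxonomy": r.taxonomy,
            "A13_heavy": r.a13_heavy,
            "A13_light": r.a13_light,
            "A12_heavy": r.a12_heavy,
            "A12_light": r.a12_light,
            "REF": r.ref,
            "rank": r.rank,
            "active": r.active,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=REF_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_ref_calls(path: str | Path) -> list[RefRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        RefRecord(
            asv_id=str(r.asv_id),
            taxonomy="" if pd.isna(r.taxonomy) else str(r.taxonomy),
            a13_heavy=float(r.A13_heavy),
            a13_light=float(r.A13_light),
            a12_heavy=float(r.A12_heavy),
            a12_light=float(r.A12_light),
            ref=float(r.REF),
            rank=int(r.rank),
            active=bool(r.active),
        )
        for r in df.itertuples()
    ]


def write_label_calls(calls: Sequence[LabelCall], path: str | Path) -> None:
    rows = [
        {
            "cell_id": c.cell_id,
            "labelled": c.labelled,
            "band_position": "" if c.band_position is None else c.band_position,
            "intensity_968": c.intensity_968,
            "intensity_1001": c.intensity_1001,
            "shift_cm1": "" if c.shift_cm1 is None else c.shift_cm1,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_sorting_manifest(manifest: dict, path: str | Path) -> None:
    lines = [f"# sorted labelled cells: {manifest['n_labelled']}"]
    for cell in manifest["cells"]:
        lines.append(f"{cell['cell_id']}\t{cell['band_position']}\t{cell['shift_cm1']}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotations(path: str | Path, bin_id: str | None = None) -> AnnotationSet:
    """Read one gene label per line (free text or KO-style ids); '#' comments."""
    path = Path(path)
    labels = [
        line.strip()
        for line in path.read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return AnnotationSet(bin_id=bin_id or path.stem, labels=labels)


def write_medium_json(recipe: MediumRecipe, path: str | Path) -> None:
    payload = {
        "base": recipe.base,
        "supplements": [
            {
                "component": s.component,
                "amount": s.amount,
                "unit": s.unit,
                "rule": s.rule,
                "matched_labels": list(s.matched_labels),
            }
            for s in recipe.supplements
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def write_ratios_json(design: RatioDesign, path: str | Path) -> None:
    payload = {
        "strain_a": design.strain_a,
        "strain_b": design.strain_b,
        "abundance_a": design.abundance_a,
        "abundance_b": design.abundance_b,
        "log_ratio": design.log_ratio,
        "recommended_ratio": design.recommended_ratio,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
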