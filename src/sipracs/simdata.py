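"""Synthetic SIP gradients and single-cell Raman spectra.

The gradient simulator spreads each taxon's DNA over a buoyant-density (BD)
grid as a Gaussian whose centre moves with the taxon's ¹³C atom fraction:
fully labelled DNA is ~0.031 g/ml denser than unlabelled DNA (the separation
of the study's light and heavy window midpoints, 1.70655 and 1.73765 g/ml).
Discretised taxon masses give per-fraction relative-abundance tables and 16S
copy totals with the structure the downstream window/REF analysis assumes.

The spectra simulator emulates single-cell Raman acquisition: pseudo-Voigt
bands (phenylalanine at 1001 cm⁻¹, redshifted to 968 cm⁻¹ in labelled cells,
plus accessory cell bands), a smooth polynomial baseline, per-cell gain
variation and additive Gaussian noise.  Ground-truth labels are carried in
spectrum metadata only — classifiers never see them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .gradient import Fraction, GradientRun
from .enrichment import AsvFractionTable
from .raman import Spectrum

__all__ = [
    "SimGradientConfig",
    "SimSpectraConfig",
    "simulate_gradient_experiment",
    "simulate_spectra",
    "write_fixture",
    "soil_gradient_config",
    "screening_census_config",
]

import pandas as pd

#: Light/heavy window midpoints are 1.70655 and 1.73765 g/ml; their difference
#: is the default BD shift of fully ¹³C-labelled DNA.
BD_UNLABELLED_MEAN = 1.7066
BD_FULL_LABEL_SHIFT = 0.0311


def _default_bd_grid(n_fractions: int = 14) -> np.ndarray:
    """Descending BD grid (fraction 1 densest), 1.755 → 1.690 g/ml."""
    return np.linspace(1.755, 1.690, n_fractions)


@dataclass
class SimGradientConfig:
    """Configuration of one two-treatment (¹²C/¹³C) SIP gradient experiment."""

    seed: int
    taxon_ids: list[str]
    base_abundances: np.ndarray  # per-taxon, sums to 1
    labelled_taxa: dict[str, float] = field(default_factory=dict)  # taxon -> atom fraction ¹³C
    n_fractions: int = 14
    bd_unlabelled_mean: float = BD_UNLABELLED_MEAN
    bd_full_label_shift: float = BD_FULL_LABEL_SHIFT
    bd_within_taxon_sd: float = 0.006
    bd_grid: np.ndarray | None = None
    copies_total: float = 1e9
    abundance_noise_cv: float = 0.10  # lognormal CV of per-taxon per-fraction mass

    def __post_init__(self) -> None:
        self.base_abundances = np.asarray(self.base_abundances, dtype=float)
        if self.bd_grid is None:
            self.bd_grid = _default_bd_grid(self.n_fractions)
        self.bd_grid = np.asarray(self.bd_grid, dtype=float)
        if len(self.taxon_ids) != self.base_abundances.size:
            raise ValueError("taxon_ids and base_abundances must have equal length")
        if abs(self.base_abundances.sum() - 1.0) > 1e-9:
            raise ValueError("base_abundances must sum to 1 (±1e-9)")
        if (self.base_abundances < 0).any():
            raise ValueError("base_abundances must be non-negative")
        for taxon, af in self.labelled_taxa.items():
            if taxon not in self.taxon_ids:
                raise ValueError(f"labelled taxon {taxon!r} not in taxon_ids")
            if not (0.0 <= af <= 1.0):
                raise ValueError(f"atom fraction for {taxon!r} must be in [0, 1]")
        diffs = np.diff(self.bd_grid)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("bd_grid must be strictly monotone")
        if self.n_fractions != self.bd_grid.size:
            raise ValueError("n_fractions must equal len(bd_grid)")
        if self.abundance_noise_cv < 0:
            raise ValueError("abundance_noise_cv must be >= 0")


@dataclass
class SimSpectraConfig:
    """Configuration of a simulated single-cell Raman screen."""

    seed: int
    n_cells: int
    n_labelled: int
    treatment: str = "13C"
    wavenumber_lo: float = 600.0
    wavenumber_hi: float = 1800.0
    wavenumber_step: float = 1.0
    band_unlabelled: float = 1001.0
    band_labelled: float = 968.0
    band_fwhm: float = 8.0
    band_amplitude: float = 1.0
    #: accessory cell bands (position cm⁻¹, relative amplitude); defaults keep
    #: the 1500–1700 cm⁻¹ noise-estimation region band-free
    accessory_bands: tuple[tuple[float, float], ...] = (
        (785.0, 0.45),
        (1095.0, 0.35),
        (1245.0, 0.40),
        (1450.0, 0.55),
    )
    baseline_coefficients: tuple[float, ...] = (0.6, 1.2, -0.8)  # polynomial in scaled wn
    noise_sd: float = 0.02
    amplitude_cv: float = 0.2  # per-cell lognormal gain variation

    def __post_init__(self) -> None:
        if self.n_labelled > self.n_cells:
            raise ValueError("n_labelled must not exceed n_cells")
        if self.wavenumber_step <= 0:
            raise ValueError("wavenumber_step must be > 0")
        lo, hi = self.wavenumber_lo, self.wavenumber_hi
        for pos in (self.band_unlabelled, self.band_labelled):
            if not (lo <= pos <= hi):
                raise ValueError(f"band position {pos} outside wavenumber range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")

    @property
    def wavenumbers(self) -> np.ndarray:
        n = int(round((self.wavenumber_hi - self.wavenumber_lo) / self.wavenumber_step)) + 1
        return self.wavenumber_lo + self.wavenumber_step * np.arange(n)


def simulate_gradient_experiment(
    config: SimGradientConfig,
) -> tuple[GradientRun, GradientRun, AsvFractionTable]:
    """Simulate the ¹²C control and ¹³C treatment gradients of one experiment.

    Each taxon's DNA mass is a Gaussian over BD centred at
    ``bd_unlabelled_mean + atom_fraction * bd_full_label_shift`` (atom fraction
    0 for every taxon in the ¹²C run), evaluated on the fraction BD grid,
    perturbed by lognormal noise, and renormalised so the taxon's total mass
    equals its base abundance exactly.  Per-fraction relative abundances and
    16S copy totals follow by column normalisation.

    Both treatments consume an identically seeded noise stream, so with zero
    labelling the two runs are identical.
    """
    bd = config.bd_grid
    n_taxa, n_frac = len(config.taxon_ids), config.n_fractions
    atom = np.array([config.labelled_taxa.get(t, 0.0) for t in config.taxon_ids])

    runs: dict[str, GradientRun] = {}
    tables: dict[str, np.ndarray] = {}
    for treatment in ("12C", "13C"):
        rng = np.random.default_rng(config.seed)  # shared stream: symmetry at zero labelling
        atom_eff = atom if treatment == "13C" else np.zeros_like(atom)
        means = config.bd_unlabelled_mean + atom_eff * config.bd_full_label_shift
        z = (bd[None, :] - means[:, None]) / config.bd_within_taxon_sd
        weights = np.exp(-0.5 * z**2)
        if config.abundance_noise_cv > 0:
            sigma = np.sqrt(np.log1p(config.abundance_noise_cv**2))
            weights = weights * rng.lognormal(mean=0.0, sigma=sigma, size=weights.shape)
        row_sums = weights.sum(axis=1)
        if np.any(row_sums == 0):
            raise ValueError("a taxon's density profile vanished on the BD grid")
        mass = config.base_abundances[:, None] * weights / row_sums[:, None]

        col_mass = mass.sum(axis=0)
        rel = mass / col_mass[None, :]
        copies = config.copies_total * col_mass / col_mass.sum()
        runs[treatment] = GradientRun(
            treatment=treatment,
            fractions=[
                Fraction(
                    treatment=treatment,
                    fraction_number=i + 1,
                    buoyant_density=float(bd[i]),
                    copies_16s=float(copies[i]),
                )
                for i in range(n_frac)
            ],
        )
        tables[treatment] = rel

    columns = pd.MultiIndex.from_tuples(
        [(t, i + 1) for t in ("12C", "13C") for i in range(n_frac)],
        names=["treatment", "fraction_number"],
    )
    data = pd.DataFrame(
        np.hstack([tables["12C"], tables["13C"]]),
        index=pd.Index(config.taxon_ids, name="asv_id"),
        columns=columns,
    )
    return runs["12C"], runs["13C"], AsvFractionTable(data)


def _pseudo_voigt(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Height-normalised 50/50 Gaussian/Lorentzian line."""
    gauss = np.exp(-4.0 * np.log(2.0) * (x - center) ** 2 / fwhm**2)
    lorentz = 1.0 / (1.0 + 4.0 * (x - center) ** 2 / fwhm**2)
    return 0.5 * gauss + 0.5 * lorentz


def simulate_spectra(config: SimSpectraConfig) -> list[Spectrum]:
    """Simulate ``n_cells`` single-cell spectra, the first ``n_labelled`` with
    the phenylalanine band at the labelled position.

    Trace = gain · (phenylalanine band + accessory bands) + polynomial
    baseline + Gaussian noise; the ground-truth label is stored only in
    ``Spectrum.meta['true_labelled']``.
    """
    rng = np.random.default_rng(config.seed)
    wn = config.wavenumbers
    scaled = (wn - config.wavenumber_lo) / (config.wavenumber_hi - config.wavenumber_lo)
    baseline = (
        np.polynomial.polynomial.polyval(scaled, np.asarray(config.baseline_coefficients))
        if config.baseline_coefficients
        else np.zeros_like(wn)
    )
    accessory = np.zeros_like(wn)
    for pos, amp in config.accessory_bands:
        accessory += amp * _pseudo_voigt(wn, pos, config.band_fwhm)

    sigma_gain = np.sqrt(np.log1p(config.amplitude_cv**2)) if config.amplitude_cv else 0.0
    width = len(str(max(config.n_cells, 1)))
    spectra = []
    for i in range(config.n_cells):
        labelled = i < config.n_labelled
        phe_pos = config.band_labelled if labelled else config.band_unlabelled
        signal = config.band_amplitude * _pseudo_voigt(wn, phe_pos, config.band_fwhm)
        gain = float(rng.lognormal(0.0, sigma_gain)) if sigma_gain else 1.0
        trace = gain * (signal + config.band_amplitude * accessory) + baseline
        if config.noise_sd > 0:
            trace = trace + rng.normal(0.0, config.noise_sd, size=wn.size)
        spectra.append(
            Spectrum(
                cell_id=f"cell_{i + 1:0{width}d}",
                treatment=config.treatment,
                wavenumbers=wn.copy(),
                intensities=trace,
                meta={"true_labelled": labelled},
            )
        )
    return spectra


def soil_gradient_config(
    seed: int,
    n_taxa: int = 100,
    labelled: Mapping[str, float] | None = None,
    **overrides,
) -> SimGradientConfig:
    """Study-condition gradient config: 100 taxa, two fully labelled degraders.

    Base abundances follow a geometric rank-abundance curve; the two labelled
    taxa sit at moderate abundance with a ~2:1 ratio, matching the structure
    of a soil community in which two degrader populations respond to the
    labelled substrate.
    """
    taxon_ids = [f"ASV_{i + 1}" for i in range(n_taxa)]
    ranks = np.arange(n_taxa)
    base = 0.96**ranks
    base /= base.sum()
    if labelled is None:
        # 17 ranks apart on the 0.96-geometric curve -> 0.96**-17 ≈ 2.0,
        # i.e. a ~2:1 abundance ratio between the two degraders
        labelled = {"ASV_3": 1.0, "ASV_20": 1.0}
    return SimGradientConfig(
        seed=seed,
        taxon_ids=taxon_ids,
        base_abundances=base,
        labelled_taxa=dict(labelled),
        **overrides,
    )


def screening_census_config(seed: int, **overrides) -> SimSpectraConfig:
    """Study-condition Raman screen: 800 cells of which 60 are ¹³C-labelled."""
    params: dict = {"n_cells": 800, "n_labelled": 60}
    params.update(overrides)
    return SimSpectraConfig(seed=seed, **params)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_fixture(
    gradient_config: SimGradientConfig,
    spectra_config: SimSpectraConfig,
    directory: str | Path,
) -> dict:
    """Simulate both experiments and write the on-disk fixture set.

    Writes ``asv_table.tsv``, ``fractions.csv``, ``spectra.csv`` and a
    ``manifest.json`` recording every file plus the full configs, so all
    downstream analyses can run offline from disk.  Returns the manifest.
    """
    from . import io as sio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    run12, run13, table = simulate_gradient_experiment(gradient_config)
    spectra = simulate_spectra(spectra_config)

    files = {
        "asv_table": "asv_table.tsv",
        "fractions": "fractions.csv",
        "spectra": "spectra.csv",
    }
    sio.write_asv_table(table, directory / files["asv_table"])
    sio.write_fractions_csv([run12, run13], directory / files["fractions"])
    sio.write_spectra(spectra, directory / files["spectra"])

    manifest = {
        "files": files,
        "gradient_config": _jsonable(dataclasses.asdict(gradient_config)),
        "spectra_config": _jsonable(dataclasses.asdict(spectra_config)),
        "n_taxa": len(gradient_config.taxon_ids),
        "n_cells": spectra_config.n_cells,
        "n_labelled": spectra_config.n_labelled,
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["directory"] = str(directory)
    return manifest
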