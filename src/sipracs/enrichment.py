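"""Relative enrichment factor (REF) calling of active substrate degraders.

For each ASV the REF is a ratio of ratios,

    REF = (A13_heavy / A13_light) / (A12_heavy / A12_light),

where A13_* are the ASV's mean relative abundances over the heavy/light
gradient fractions of the ¹³C treatment and A12_* the same for the ¹²C
control.  ASVs with REF > 2.0 among the top 100 most abundant ASVs are called
active degraders.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gradient import FractionWindows, GradientRun, classify_fraction

__all__ = [
    "AsvFractionTable",
    "RefRecord",
    "CallingParams",
    "WindowAggregates",
    "aggregate_window_abundance",
    "compute_ref",
    "call_active_degraders",
]

logger = logging.getLogger(__name__)


class AsvFractionTable:
    """Per-ASV relative abundance indexed by (treatment, fraction_number).

    Wraps a DataFrame whose rows are ASV ids and whose columns are a
    two-level (treatment, fraction_number) MultiIndex; each column is a
    compositional profile summing to 1.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        taxonomy: Mapping[str, str] | None = None,
        check: bool = True,
    ) -> None:
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 2:
            raise ValueError("columns must be a (treatment, fraction_number) MultiIndex")
        self.data = data.astype(float)
        self.taxonomy = dict(taxonomy) if taxonomy else {}
        if check:
            self.validate()

    def validate(self) -> None:
        if (self.data.values < 0).any():
            bad = self.data.columns[(self.data.values < 0).any(axis=0)][0]
            raise ValueError(f"negative abundance in column {bad}")
        sums = self.data.sum(axis=0)
        off = sums[(sums - 1.0).abs() > 1e-6]
        if not off.empty:
            raise ValueError(
                f"per-fraction abundances must sum to 1; offending columns: {list(off.index)[:5]}"
            )

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.index)

    def column(self, treatment: str, fraction_number: int) -> pd.Series:
        return self.data[(treatment, fraction_number)]


@dataclass(frozen=True)
class RefRecord:
    """The four aggregate abundances and resulting REF for one ASV."""

    asv_id: str
    a13_heavy: float
    a13_light: float
    a12_heavy: float
    a12_light: float
    ref: float
    rank: int
    active: bool
    taxonomy: str = ""


@dataclass(frozen=True)
class CallingParams:
    """REF calling rule: REF strictly greater than ``threshold`` among the
    ``top_n`` ASVs ranked by mean windowed abundance."""

    top_n: int = 100
    threshold: float = 2.0
    pseudocount: float = 1e-6

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class WindowAggregates:
    """Per-ASV window means plus the abundance basis used for ranking."""

    frame: pd.DataFrame  # columns: a13_heavy, a13_light, a12_heavy, a12_light
    rank_basis: pd.Series  # mean relative abundance over all windowed fractions
    window_fractions: dict  # {(treatment, window): [fraction_number, ...]}


def aggregate_window_abundance(
    table: AsvFractionTable,
    windows: FractionWindows,
    runs: Mapping[str, GradientRun],
) -> WindowAggregates:
    """Mean relative abundance of each ASV over each (treatment, window).

    A fraction belongs to a window when its buoyant density falls inside the
    closed window interval.  Every (treatment, window) pair must contain at
    least one fraction present in the table.
    """
    window_fractions: dict = {}
    for treatment in ("13C", "12C"):
        if treatment not in runs:
            raise ValueError(f"missing gradient run for treatment {treatment}")
        for window in ("heavy", "light"):
            members = [
                f.fraction_number
                for f in runs[treatment].fractions
                if classify_fraction(f.buoyant_density, windows) == window
                and (treatment, f.fraction_number) in table.data.columns
            ]
            if not members:
                raise ValueError(
                    f"no fractions classified into the {window} window for {treatment}"
                )
            window_fractions[(treatment, window)] = members

    def mean_over(treatment: str, window: str) -> pd.Series:
        cols = [(treatment, k) for k in window_fractions[(treatment, window)]]
        return table.data[cols].mean(axis=1)

    frame = pd.DataFrame(
        {
            "a13_heavy": mean_over("13C", "heavy"),
            "a13_light": mean_over("13C", "light"),
            "a12_heavy": mean_over("12C", "heavy"),
            "a12_light": mean_over("12C", "light"),
        }
    )
    all_cols = [(t, k) for (t, _w), ks in window_fractions.items() for k in ks]
    rank_basis = table.data[all_cols].mean(axis=1)
    return WindowAggregates(frame=frame, rank_basis=rank_basis, window_fractions=window_fractions)


def compute_ref(
    a13_heavy: float,
    a13_light: float,
    a12_heavy: float,
    a12_light: float,
    pseudocount: float = 1e-6,
) -> float:
    """REF = (A13_heavy/A13_light) / (A12_heavy/A12_light).

    The pseudocount is added to all four terms only when at least one of them
    is zero, so exact inputs give exact ratios while zero denominators stay
    finite.
    """
    terms = (a13_heavy, a13_light, a12_heavy, a12_light)
    if any(t < 0 for t in terms):
        raise ValueError("abundances must be non-negative")
    if any(t == 0.0 for t in terms):
        if pseudocount == 0.0:
            raise ValueError("REF undefined: zero abundance with zero pseudocount")
        a13_heavy, a13_light, a12_heavy, a12_light = (t + pseudocount for t in terms)
    return (a13_heavy / a13_light) / (a12_heavy / a12_light)


def call_active_degraders(
    table: AsvFractionTable,
    aggregates: WindowAggregates,
    params: CallingParams = CallingParams(),
) -> list[RefRecord]:
    """Rank ASVs, compute REF, and call actives (rank ≤ top_n and REF > threshold).

    Ranking is by mean relative abundance across all windowed fractions of both
    treatments, descending; ties break lexicographically by ASV id.  Records
    are returned sorted by REF descending.
    """
    order = sorted(
        table.asv_ids, key=lambda a: (-aggregates.rank_basis[a], a)
    )
    if len(order) < params.top_n:
        warnings.warn(
            f"table has {len(order)} ASVs, fewer than top_n={params.top_n}; using all",
            stacklevel=2,
        )
    rank = {asv: i + 1 for i, asv in enumerate(order)}

    records = []
    for asv in table.asv_ids:
        row = aggregates.frame.loc[asv]
        ref = compute_ref(
            row["a13_heavy"],
            row["a13_light"],
            row["a12_heavy"],
            row["a12_light"],
            pseudocount=params.pseudocount,
        )
        records.append(
            RefRecord(
                asv_id=asv,
                a13_heavy=float(row["a13_heavy"]),
                a13_light=float(row["a13_light"]),
                a12_heavy=float(row["a12_heavy"]),
                a12_light=float(row["a12_light"]),
                ref=float(ref),
                rank=rank[asv],
                active=rank[asv] <= params.top_n and ref > params.threshold,
                taxonomy=table.taxonomy.get(asv, ""),
            )
        )
    records.sort(key=lambda r: (-r.ref, r.asv_id))
    n_active = sum(r.active for r in records)
    logger.info("REF calling: %d/%d ASVs active (top_n=%d, threshold=%s)",
                n_active, len(records), params.top_n, params.threshold)
    return records
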