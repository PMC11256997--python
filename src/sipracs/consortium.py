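"""Genome-directed cultivation and consortium design.

Single-cell genome annotations of the sorted degraders drive three desk-side
decisions: (i) which supplements to add to the minimal medium (vitamin and
mineral stock solutions, streptomycin when an aminoglycoside-resistance gene
is present, L-lactate when a lactate dehydrogenase is present); (ii) at what
ratio to co-inoculate the two strains, snapped to the tested candidate set
{2:1, 1:1, 1:2} from their observed abundance ratio; and (iii) accounting of
substrate degradation efficiency from concentration time points.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AnnotationSet",
    "MediumRule",
    "Supplement",
    "MediumRecipe",
    "RatioDesign",
    "DegradationMeasurement",
    "DEFAULT_RULES",
    "recommend_medium",
    "design_ratios",
    "degradation_efficiency",
    "control_corrected_efficiency",
]

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """Free-text / KO-style gene labels for one genome bin."""

    bin_id: str
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for raw in self.labels:
            if not isinstance(raw, str) or not raw.strip():
                logger.warning("skipping unparseable annotation line in %s: %r", self.bin_id, raw)
                continue
            cleaned.append(raw.strip())
        self.labels = cleaned


@dataclass(frozen=True)
class MediumRule:
    """Keyword rule mapping annotated gene functions to one supplement.

    The rule fires when any label contains one of ``any_keywords`` and, if
    ``context_keywords`` is non-empty, that same label also contains one of
    those (e.g. a metal name plus 'transport').  Matching is case-insensitive
    substring matching, suited to the free-text annotations emitted by
    standard prokaryotic annotation pipelines.
    """

    name: str
    component: str
    amount: float
    unit: str
    any_keywords: tuple[str, ...]
    context_keywords: tuple[str, ...] = ()

    def matches(self, label: str) -> bool:
        low = label.lower()
        if not any(k in low for k in self.any_keywords):
            return False
        if self.context_keywords and not any(k in low for k in self.context_keywords):
            return False
        return True


DEFAULT_RULES: tuple[MediumRule, ...] = (
    MediumRule(
        name="vitamin_metabolism",
        component="vitamin stock solution",
        amount=10.0,
        unit="ml/L",
        any_keywords=(
            "vitamin", "thiamin", "riboflavin", "niacin", "nicotinate",
            "pyridox", "biotin", "cobalamin", "lipoic", "lipoate",
            "pantothen", "folate", "retinol",
        ),
    ),
    MediumRule(
        name="trace_metal_transport",
        component="mineral stock solution",
        amount=10.0,
        unit="ml/L",
        any_keywords=(
            "calcium", "copper", "zinc", "cobalt", "sodium", "molybdenum",
            "molybdate", "nickel",
        ),
        context_keywords=("transport", "transporter", "uptake", "exchanger", "efflux"),
    ),
    MediumRule(
        name="aminoglycoside_resistance",
        component="streptomycin",
        amount=5.0,
        unit="mg/L",
        any_keywords=("aminoglycoside", "streptomycin resistance", "aph(", "aac("),
    ),
    MediumRule(
        name="l_lactate_utilisation",
        component="L-lactate",
        amount=50.0,
        unit="mM",
        any_keywords=("lactate dehydrogenase", "l-lactate dehydrogenase", "lldd", "ldh"),
    ),
)


@dataclass(frozen=True)
class Supplement:
    component: str
    amount: float
    unit: str
    rule: str
    matched_labels: tuple[str, ...]


@dataclass
class MediumRecipe:
    """A base medium plus the supplements whose genomic triggers fired."""

    base: str
    supplements: list[Supplement] = field(default_factory=list)

    def component_amounts(self) -> dict[str, tuple[float, str]]:
        return {s.component: (s.amount, s.unit) for s in self.supplements}


def recommend_medium(
    ann: AnnotationSet,
    rules: Sequence[MediumRule] = DEFAULT_RULES,
    base: str = "minimal medium (MM)",
) -> MediumRecipe:
    """Apply the genome→supplement rule table to one bin's annotations.

    Each rule fires at most once; every emitted supplement records the rule
    and the annotation labels that triggered it.  Order-insensitive in the
    annotation list and idempotent.
    """
    supplements = []
    for rule in rules:
        matched = tuple(sorted({lab for lab in ann.labels if rule.matches(lab)}))
        if matched:
            supplements.append(
                Supplement(
                    component=rule.component,
                    amount=rule.amount,
                    unit=rule.unit,
                    rule=rule.name,
                    matched_labels=matched,
                )
            )
    return MediumRecipe(base=base, supplements=supplements)


RATIO_CANDIDATES = {1: "2:1", 0: "1:1", -1: "1:2"}


@dataclass(frozen=True)
class RatioDesign:
    strain_a: str
    strain_b: str
    abundance_a: float
    abundance_b: float
    log_ratio: float  # log2(abundance_a / abundance_b)
    recommended_ratio: str


def design_ratios(
    abundance_a: float,
    abundance_b: float,
    strain_a: str = "JB-1",
    strain_b: str = "JB-2",
) -> RatioDesign:
    """Snap the observed abundance ratio to the nearest tested CFU mix.

    log2(a/b) is rounded to the nearest of {1, 0, −1} → {2:1, 1:1, 1:2};
    exact midpoints (|log2 ratio| = 0.5) snap toward 1:1.
    """
    if abundance_a <= 0 or abundance_b <= 0:
        raise ValueError("abundances must be > 0")
    lr = math.log2(abundance_a / abundance_b)
    # tolerance so the true midpoint (a/b = √2, not float-representable)
    # snaps toward 1:1 as intended
    if abs(lr) <= 0.5 + 1e-9:
        snapped = 0
    elif lr > 0:
        snapped = 1
    else:
        snapped = -1
    return RatioDesign(
        strain_a=strain_a,
        strain_b=strain_b,
        abundance_a=abundance_a,
        abundance_b=abundance_b,
        log_ratio=lr,
        recommended_ratio=RATIO_CANDIDATES[snapped],
    )


def degradation_efficiency(c0: float, ct: float) -> float:
    """Percent substrate removed between two time points: 100·(c0−ct)/c0.

    Clipped at 0 from below (apparent increases report 0% removal); values
    above 100 are impossible for non-negative ct.
    """
    if c0 <= 0:
        raise ValueError("initial concentration must be > 0")
    if ct < 0:
        raise ValueError("final concentration must be >= 0")
    return max(0.0, 100.0 * (c0 - ct) / c0)


def control_corrected_efficiency(
    c0: float, ct: float, control_c0: float, control_ct: float
) -> float:
    """Removal percentage minus the sterile-control (abiotic) loss percentage.

    Off by default in reporting; provided because published efficiencies
    sometimes subtract abiotic losses and sometimes do not.
    """
    biotic = degradation_efficiency(c0, ct)
    abiotic = degradation_efficiency(control_c0, control_ct)
    return max(0.0, biotic - abiotic)


@dataclass
class DegradationMeasurement:
    """Substrate concentrations (mg/L) over the incubation for one treatment."""

    treatment: str
    concentrations: dict[int, float]  # day -> mg/L

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")

    def efficiency(self, day0: int = 0, day_t: int | None = None) -> float:
        """Efficiency from day0 to day_t (default: the last sampled day)."""
        days = sorted(self.concentrations)
        if day_t is None:
            day_t = days[-1]
        return degradation_efficiency(self.concentrations[day0], self.concentrations[day_t])
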