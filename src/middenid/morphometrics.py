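"""Rule-based classification of ungulate fecal pellets.

Isolated pellets of large-bodied taxa (wapiti, shrub-ox, Harrington's
mountain goat and kin) are readily separated from *Ovis*, *Antilocapra*
and *Oreamnos americanus* by weight: above 0.5 g the pellet belongs to a
large ungulate.  Among the small taxa, pronghorn pellets tend to a
width:length ratio above 1.1 while *Ovis* pellets are more cuboid, with
ratios between 0.5 and 0.9.  Pellets falling in neither region (e.g. a
ratio in the 0.9-1.1 gap, or missing weight in the 0.3-0.5 g overlap
zone) are flagged rather than forced into a class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .config import PipelineConfig


class PelletClass(str, Enum):
    LARGE_UNGULATE = "LARGE_UNGULATE"
    PRONGHORN_LIKE = "PRONGHORN_LIKE"
    OVIS_LIKE = "OVIS_LIKE"
    AMBIGUOUS = "AMBIGUOUS"


#: classification caveat flags
WEIGHT_MISSING = "WEIGHT_MISSING"
WEIGHT_OVERLAP_ZONE = "WEIGHT_OVERLAP_ZONE"
RATIO_GAP_ZONE = "RATIO_GAP_ZONE"


@dataclass(frozen=True)
class PelletMeasurement:
    """One pellet: long axis, short axis (mm) and optional weight (g)."""

    id: str
    length_mm: float
    width_mm: float
    weight_g: float | None = None

    def __post_init__(self) -> None:
        if not self.length_mm > 0:
            raise ValueError(f"pellet {self.id}: length_mm must be > 0")
        if not self.width_mm > 0:
            raise ValueError(f"pellet {self.id}: width_mm must be > 0")
        if self.weight_g is not None and self.weight_g < 0:
            raise ValueError(f"pellet {self.id}: weight_g must be >= 0")


@dataclass(frozen=True)
class PelletClassification:
    id: str
    label: PelletClass
    ratio: float
    flags: frozenset[str] = frozenset()


@dataclass
class SampleSummary:
    n: int
    counts: dict[PelletClass, int]
    modal_class: PelletClass
    mean_length_mm: float
    mean_width_mm: float
    per_pellet: list[PelletClassification] = field(default_factory=list)


def pellet_ratio(p: PelletMeasurement) -> float:
    """Width:length ratio (short axis over long axis, both in mm)."""
    return p.width_mm / p.length_mm


def classify_pellet(
    p: PelletMeasurement, cfg: PipelineConfig | None = None
) -> PelletClassification:
    """Apply the fixed discrimination rules to one pellet.

    Decision order: weight above the large-ungulate cutoff dominates;
    then the pronghorn ratio rule; then the closed Ovis ratio interval;
    anything else is AMBIGUOUS.
    """
    cfg = cfg or PipelineConfig()
    ratio = pellet_ratio(p)
    flags: set[str] = set()

    if p.weight_g is None:
        flags.add(WEIGHT_MISSING)
    elif cfg.weight_small_typical_g < p.weight_g <= cfg.weight_large_g:
        flags.add(WEIGHT_OVERLAP_ZONE)
    if cfg.ratio_ovis_high < ratio <= cfg.ratio_pronghorn_min:
        flags.add(RATIO_GAP_ZONE)

    if p.weight_g is not None and p.weight_g > cfg.weight_large_g:
        label = PelletClass.LARGE_UNGULATE
    elif ratio > cfg.ratio_pronghorn_min:
        label = PelletClass.PRONGHORN_LIKE
    elif cfg.ratio_ovis_low <= ratio <= cfg.ratio_ovis_high:
        label = PelletClass.OVIS_LIKE
    else:
        label = PelletClass.AMBIGUOUS

    return PelletClassification(p.id, label, ratio, frozenset(flags))


def classify_sample(
    pellets: list[PelletMeasurement], cfg: PipelineConfig | None = None
) -> SampleSummary:
    """Classify every pellet and summarize the sample.

    The modal class is the most frequent non-AMBIGUOUS label; a tie for
    the mode is reported as AMBIGUOUS.
    """
    if not pellets:
        raise ValueError("classify_sample requires at least one pellet")
    results = [classify_pellet(p, cfg) for p in pellets]
    counts = Counter(r.label for r in results)
    decisive = {k: v for k, v in counts.items() if k is not PelletClass.AMBIGUOUS}
    if not decisive:
        modal = PelletClass.AMBIGUOUS
    else:
        top = max(decisive.values())
        winners = [k for k, v in decisive.items() if v == top]
        modal = winners[0] if len(winners) == 1 else PelletClass.AMBIGUOUS
    full_counts = {c: counts.get(c, 0) for c in PelletClass}
    return SampleSummary(
        n=len(pellets),
        counts=full_counts,
        modal_class=modal,
        mean_length_mm=sum(p.length_mm for p in pellets) / len(pellets),
        mean_width_mm=sum(p.width_mm for p in pellets) / len(pellets),
        per_pellet=results,
    )
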