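"""Engine configuration and typed annotations attached to switch suggestions.

The knobs collected in :class:`EngineConfig` are exactly the places where the
underlying switching procedure is under-determined and a site must choose a
policy: how much strength difference still counts as "the same strength"
(``rel_tol``), how much total-daily-dose deviation is clinically acceptable
after regimen recomputation (``max_dose_deviation``), and how complex a
combination product may be before it is left to a human
(``max_combination_components``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction

from ._util import as_fraction


@dataclass(frozen=True)
class EngineConfig:
    """Policy knobs for the switch engine.

    Parameters
    ----------
    rel_tol:
        Relative strength tolerance for pharmaceutical equivalence. The
        default 0 demands exact strength match (the historical behaviour that
        famously fails on 78.09 mg vs 77.82 mg metoprolol salt-rounding
        differences); 0.01 is the documented opt-in that absorbs those.
    max_dose_deviation:
        Largest tolerated relative deviation |achieved − target| / target of
        the recomputed total daily dose. Conversions that cannot meet it are
        demoted to manual handling rather than silently emitting a bad dose.
    max_combination_components:
        Combination products with more active ingredients than this are never
        split automatically.
    allow_split_combinations:
        Master switch for splitting combination products into single agents.
    max_units_per_slot:
        Search-space bound for regimen redistribution: at most this many dose
        units per administration time. Four units per slot covers realistic
        oral regimens and keeps exhaustive verification trivial.
    """

    rel_tol: Fraction = Fraction(0)
    max_dose_deviation: Fraction = Fraction(1, 10)
    max_combination_components: int = 3
    allow_split_combinations: bool = True
    max_units_per_slot: int = 4

    def __post_init__(self):
        object.__setattr__(self, "rel_tol", as_fraction(self.rel_tol))
        object.__setattr__(self, "max_dose_deviation", as_fraction(self.max_dose_deviation))
        if self.rel_tol < 0:
            raise ValueError("rel_tol must be >= 0")
        if self.max_dose_deviation < 0:
            raise ValueError("max_dose_deviation must be >= 0")
        if self.max_combination_components < 1:
            raise ValueError("max_combination_components must be >= 1")
        if self.max_units_per_slot < 1:
            raise ValueError("max_units_per_slot must be >= 1")


class AnnotationKind(str, enum.Enum):
    """Typed warning categories a switch suggestion can carry."""

    INDICATION_DIFFERENCE = "indication-difference"
    TABLET_SPLITTING = "tablet-splitting"
    SALT_DIFFERENCE = "salt-difference"
    DOSE_DEVIATION = "dose-deviation"
    INCOMPLETE = "incomplete-prescription"
    EXCLUDED_CLASS = "excluded-class"
    NOT_ORAL_SOLID = "not-oral-solid"
    COMBINATION_SPLIT = "combination-split"


@dataclass(frozen=True)
class Annotation:
    """One structured warning (typed so tests and UIs can assert on it)."""

    kind: AnnotationKind
    message: str = ""

    def to_dict(self) -> dict:
        return {"kind": self.kind.value, "message": self.message}


DEFAULT_CONFIG = EngineConfig()
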