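"""Evaluation bookkeeping: compare engine output to reference switches and
assemble the performance accounting.

The evaluation design this mirrors: a batch of documented consultations is
run through the engine; prescriptions with missing essential information are
excluded up front; the rest are tallied per outcome group (1–5), with the
automatic-switch total being the sum of the group 1–4 shares. Where manual
reference switches exist, each engine suggestion is classified *identical*
(exact product + scheme multiset match) or *different*; whether a different
suggestion is equivalent, better or worse is an expert judgement supplied as
an external label file, never inferred by code.

Percentages are rounded half-up to one decimal per cell, and the Σ row is
the sum of the rounded cells (so a column may legitimately sum to 100.1) —
the unrounded value is reported alongside.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import pct_half_up
from .engine import Group, SwitchResult
from .regimen import Prescription, scheme_to_text

__all__ = [
    "Verdict",
    "ExpertLabel",
    "SubLabel",
    "ComparisonRecord",
    "PerformanceReport",
    "classify",
    "performance_table",
    "comparison_summary",
]


class Verdict(str, enum.Enum):
    IDENTICAL = "identical"
    DIFFERENT = "different"


class ExpertLabel(str, enum.Enum):
    EQUIVALENT = "equivalent"
    CDSS_BETTER = "cdss_better"
    REFERENCE_BETTER = "reference_better"


class SubLabel(str, enum.Enum):
    CDSS_OK = "cdss_ok"  # correct but inferior to the reference
    CDSS_NOT_OK = "cdss_not_ok"  # inadequate / wrong


@dataclass(frozen=True)
class ComparisonRecord:
    """Engine vs reference for one prescription."""

    source: Prescription
    reference: tuple[Prescription, ...]
    engine: tuple[Prescription, ...]
    verdict: Verdict
    expert_label: ExpertLabel | None = None
    sub_label: SubLabel | None = None

    def __post_init__(self):
        if self.expert_label is not None and self.verdict != Verdict.DIFFERENT:
            raise ValueError("expert_label applies only to 'different' verdicts")
        if self.sub_label is not None and self.expert_label != ExpertLabel.REFERENCE_BETTER:
            raise ValueError("sub_label applies only when the reference was better")


def _suggestion_multiset(suggestions: Iterable[Prescription]) -> Counter:
    return Counter(
        (s.product.product_id, scheme_to_text(s.regimen)) for s in suggestions
    )


def classify(
    engine_result: SwitchResult,
    reference: Sequence[Prescription],
    expert_label: ExpertLabel | None = None,
    sub_label: SubLabel | None = None,
) -> ComparisonRecord:
    """Classify one engine result against the manual reference switch.

    The verdict is *identical* iff the multiset of suggested
    (product_id, scheme) pairs matches exactly — suggestion order never
    matters, but a changed dosage scheme on the same product does. Expert
    labels come from external adjudication and are attached verbatim.
    """
    identical = _suggestion_multiset(engine_result.suggestions) == _suggestion_multiset(
        reference
    )
    verdict = Verdict.IDENTICAL if identical else Verdict.DIFFERENT
    return ComparisonRecord(
        source=engine_result.source,
        reference=tuple(reference),
        engine=tuple(engine_result.suggestions),
        verdict=verdict,
        expert_label=expert_label if verdict == Verdict.DIFFERENT else None,
        sub_label=sub_label if verdict == Verdict.DIFFERENT else None,
    )


@dataclass(frozen=True)
class PerformanceReport:
    """Per-group performance accounting for one evaluation batch."""

    n_documented: int
    n_excluded_incomplete: int
    n_assessable: int
    group_counts: dict[int, int]
    group_pct: dict[int, float]
    cdss_switch_count: int
    cdss_switch_pct: float  # sum of the rounded group 1-4 cells, as displayed
    cdss_switch_pct_exact: float
    assessable_pct: float
    comparison: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "n_documented": self.n_documented,
            "n_excluded_incomplete": self.n_excluded_incomplete,
            "n_assessable": self.n_assessable,
            "assessable_pct": self.assessable_pct,
            "group_counts": {str(k): v for k, v in sorted(self.group_counts.items())},
            "group_pct": {str(k): v for k, v in sorted(self.group_pct.items())},
            "cdss_switch_count": self.cdss_switch_count,
            "cdss_switch_pct": self.cdss_switch_pct,
            "cdss_switch_pct_exact": self.cdss_switch_pct_exact,
        }
        if self.comparison is not None:
            d["comparison"] = self.comparison
        return d

    _GROUP_LABELS = {
        1: "Group 1: HDF drug",
        2: "Group 2: Pharmaceutical equivalent",
        3: "Group 3: Pharmaceutical alternative",
        4: "Group 4: Therapeutic equivalent",
        5: "Group 5: No automatic switch",
    }

    def to_table(self) -> str:
        """Human-readable performance table."""
        width = max(len(v) for v in self._GROUP_LABELS.values())
        lines = [
            f"Documented prescriptions: {self.n_documented}",
            f"Excluded (incomplete):    {self.n_excluded_incomplete}"
            f"  (assessable {self.assessable_pct}%)",
            f"Assessable:               {self.n_assessable}",
            "",
        ]
        for g in range(1, 5):
            lines.append(
                f"{self._GROUP_LABELS[g]:<{width}}  "
                f"{self.group_counts[g]:>5}  {self.group_pct[g]:>5.1f}%"
            )
        lines.append(
            f"{'Σ: automatic switch':<{width}}  "
            f"{self.cdss_switch_count:>5}  {self.cdss_switch_pct:>5.1f}%"
        )
        lines.append(
            f"{self._GROUP_LABELS[5]:<{width}}  "
            f"{self.group_counts[5]:>5}  {self.group_pct[5]:>5.1f}%"
        )
        return "\n".join(lines)

    def to_tsv(self) -> str:
        rows = [("row", "count", "percent")]
        for g in range(1, 5):
            rows.append((self._GROUP_LABELS[g], str(self.group_counts[g]), str(self.group_pct[g])))
        rows.append(("Sum: automatic switch", str(self.cdss_switch_count), str(self.cdss_switch_pct)))
        rows.append((self._GROUP_LABELS[5], str(self.group_counts[5]), str(self.group_pct[5])))
        return "\n".join("\t".join(r) for r in rows)


def performance_table(
    results: Sequence[SwitchResult] | Sequence[Group] | Sequence[int],
    n_documented: int,
    n_excluded: int,
    comparisons: Sequence[ComparisonRecord] | None = None,
) -> PerformanceReport:
    """Build the per-group performance accounting.

    ``results`` may be switch results, groups or plain group numbers for the
    assessable prescriptions; ``n_documented − n_excluded`` must equal their
    count. Percentages are per-cell rounded half-up to one decimal; the
    automatic-switch total is the sum of the rounded group 1–4 cells (the
    exact value is also carried).
    """
    groups = [
        int(r.group) if isinstance(r, SwitchResult) else int(r) for r in results
    ]
    n_assessable = len(groups)
    if n_documented - n_excluded != n_assessable:
        raise ValueError(
            f"inconsistent accounting: {n_documented} documented - {n_excluded} "
            f"excluded != {n_assessable} assessable results"
        )
    counts = {g: 0 for g in range(1, 6)}
    for g in groups:
        counts[g] += 1
    group_pct = {g: pct_half_up(c, n_assessable) for g, c in counts.items()}
    switch_count = sum(counts[g] for g in range(1, 5))
    report = PerformanceReport(
        n_documented=n_documented,
        n_excluded_incomplete=n_excluded,
        n_assessable=n_assessable,
        group_counts=counts,
        group_pct=group_pct,
        cdss_switch_count=switch_count,
        cdss_switch_pct=round(sum(group_pct[g] for g in range(1, 5)), 1),
        cdss_switch_pct_exact=pct_half_up(switch_count, n_assessable, digits=4),
        assessable_pct=pct_half_up(n_assessable, n_documented),
        comparison=None if comparisons is None else comparison_summary(comparisons),
    )
    return report


def comparison_summary(records: Sequence[ComparisonRecord]) -> dict:
    """Identical/different breakdown with expert-label percentages.

    Expert-label percentages are over the *different* cases; the sub-label
    percentages over the *reference-better* cases, matching how blinded
    review results are reported.
    """
    n = len(records)
    n_identical = sum(1 for r in records if r.verdict == Verdict.IDENTICAL)
    different = [r for r in records if r.verdict == Verdict.DIFFERENT]
    out = {
        "n": n,
        "n_identical": n_identical,
        "identical_pct": pct_half_up(n_identical, n) if n else None,
        "n_different": len(different),
        "different_pct": pct_half_up(len(different), n) if n else None,
    }
    labelled = [r for r in different if r.expert_label is not None]
    if labelled:
        for label in ExpertLabel:
            k = sum(1 for r in labelled if r.expert_label == label)
            out[f"{label.value}_pct"] = pct_half_up(k, len(labelled))
        worse = [r for r in labelled if r.expert_label == ExpertLabel.REFERENCE_BETTER]
        sub = [r for r in worse if r.sub_label is not None]
        if sub:
            for label in SubLabel:
                k = sum(1 for r in sub if r.sub_label == label)
                out[f"{label.value}_pct"] = pct_half_up(k, len(sub))
    return out
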