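"""Confusion tallies, protectiveness/utility metrics and the platform ablation.

Protectiveness is the fraction of benchmark high-risk scenarios the decision
model does **not** conclude low-risk, HU/(HU+HL); utility is the fraction of
benchmark low-risk scenarios correctly concluded low-risk, LL/(LL+LU).
Percentages are rendered to integer percent with banker's rounding
(round-half-even), which reproduces the printed benchmark tables from their
underlying counts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .benchmark_model import BenchmarkSet
from .ber_engine import (
    DEFAULT_THRESHOLDS,
    FULL_MASK,
    LOW_RISK,
    BERRecord,
    PlatformMask,
    ThresholdTable,
    classify_benchmark,
    select_min_pod,
)
from .errors import DataError, UndefinedMetricError

logger = logging.getLogger("toxtoolbox")


@dataclass(frozen=True)
class ConfusionCounts:
    """Decision-vs-benchmark tallies.

    HU: high-risk decided uncertain, HL: high-risk decided low-risk,
    LL: low-risk decided low-risk, LU: low-risk decided uncertain.
    """

    HU: int = 0
    HL: int = 0
    LL: int = 0
    LU: int = 0

    @property
    def n_high(self) -> int:
        return self.HU + self.HL

    @property
    def n_low(self) -> int:
        return self.LL + self.LU

    @property
    def total(self) -> int:
        return self.n_high + self.n_low


@dataclass(frozen=True)
class PerformanceResult:
    counts: ConfusionCounts
    protectiveness: Optional[float]
    utility: Optional[float]

    @property
    def n_high(self) -> int:
        return self.counts.n_high

    @property
    def n_low(self) -> int:
        return self.counts.n_low


def tally_confusion(
    records: Iterable[BERRecord],
    labels: Mapping[str, str],
) -> ConfusionCounts:
    """Exact confusion tallies of decisions against benchmark risk labels.

    Scenarios without a record (excluded/absent classifications) are simply
    not counted; a record whose scenario has no label raises DataError.
    """
    hu = hl = ll = lu = 0
    for rec in records:
        if rec.scenario_id not in labels:
            raise DataError(f"no benchmark label for scenario {rec.scenario_id!r}")
        label = labels[rec.scenario_id]
        if label not in ("high", "low"):
            raise DataError(f"invalid label {label!r} for {rec.scenario_id!r}")
        low_decision = rec.decision == LOW_RISK
        if label == "high":
            hl += low_decision
            hu += not low_decision
        else:
            ll += low_decision
            lu += not low_decision
    return ConfusionCounts(HU=hu, HL=hl, LL=ll, LU=lu)


def render_percent(fraction: float) -> str:
    """Integer-percent rendering with round-half-even, e.g. 0.625 -> "62%"."""
    return f"{round(fraction * 100):d}%"


def protectiveness(counts: ConfusionCounts) -> float:
    """HU/(HU+HL): the fraction of high-risk scenarios not concluded low-risk."""
    if counts.n_high == 0:
        raise UndefinedMetricError("protectiveness undefined: no high-risk scenarios")
    return counts.HU / counts.n_high


def utility(counts: ConfusionCounts) -> float:
    """LL/(LL+LU): the fraction of low-risk scenarios concluded low-risk."""
    if counts.n_low == 0:
        raise UndefinedMetricError("utility undefined: no low-risk scenarios")
    return counts.LL / counts.n_low


def performance(counts: ConfusionCounts) -> PerformanceResult:
    """Bundle counts with both metrics, leaving a metric absent when undefined."""
    prot = protectiveness(counts) if counts.n_high else None
    util = utility(counts) if counts.n_low else None
    return PerformanceResult(counts=counts, protectiveness=prot, utility=util)


def evaluate_benchmark(
    bset: BenchmarkSet,
    mask: PlatformMask = FULL_MASK,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    level_policy: str = "highest",
    strict: bool = True,
) -> PerformanceResult:
    """Classify a benchmark set and compute its performance metrics."""
    records = classify_benchmark(bset, mask, thresholds, level_policy, strict)
    return performance(tally_confusion(records, bset.labels()))


def evaluate_levels(
    bset: BenchmarkSet,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    mask: PlatformMask = FULL_MASK,
    strict: bool = True,
) -> dict[str, PerformanceResult]:
    """Per-PBK-level performance (fixed L1, L2, L3, and the highest policy)."""
    return {
        policy: evaluate_benchmark(bset, mask, thresholds, policy, strict)
        for policy in ("L1", "L2", "L3", "highest")
    }


_SOURCES = ("ipp", "csp", "httr_global", "httr_pathway")


def all_masks() -> list[PlatformMask]:
    """The 15 non-empty subsets of the four PoD sources, IPP-first order."""
    masks = []
    for r in range(1, len(_SOURCES) + 1):
        for combo in itertools.combinations(_SOURCES, r):
            masks.append(PlatformMask.from_names(combo))
    return masks


def run_ablation(
    bset: BenchmarkSet,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    level_policy: str = "highest",
    strict: bool = True,
) -> dict[PlatformMask, PerformanceResult]:
    """Performance for every non-empty platform combination (15 rows).

    Scenarios whose chemical has no PoD under a mask are excluded from that
    row's denominators, which is why single-platform rows can have fewer
    benchmark scenarios than the full toolbox.
    """
    return {
        mask: evaluate_benchmark(bset, mask, thresholds, level_policy, strict)
        for mask in all_masks()
    }


#: tie-break priority when several sources supply the same minimum PoD
_ATTRIBUTION_PRIORITY = [
    "ipp",
    "csp",
    "httr_global:HepG2",
    "httr_global:HepaRG",
    "httr_global:MCF7",
    "httr_pathway:HepG2",
    "httr_pathway:HepaRG",
    "httr_pathway:MCF7",
]


def attribute_leading_platform(bset: BenchmarkSet) -> dict[str, int]:
    """Count, per PoD source, the chemicals for which it supplies the minimum.

    Ties are broken by a fixed priority (IPP > CSP > transcriptomics global >
    transcriptomics pathway; within transcriptomics HepG2 > HepaRG > MCF7) and
    logged.  Counts sum to the number of chemicals.
    """
    counts = {src: 0 for src in _ATTRIBUTION_PRIORITY}
    for chem in bset.chemicals:
        values = chem.pods.all_values()
        if not values:
            raise DataError(f"chemical {chem.chem_id!r} has no PoD from any platform")
        vmin = min(values.values())
        leaders = [src for src in _ATTRIBUTION_PRIORITY if values.get(src) == vmin]
        if len(leaders) > 1:
            logger.info(
                "chemical %s: tied minimum PoD among %s; attributed to %s",
                chem.chem_id, leaders, leaders[0],
            )
        counts[leaders[0]] += 1
    return counts


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _result_row(result: PerformanceResult) -> dict:
    c = result.counts
    return {
        "hu": c.HU,
        "hl": c.HL,
        "ll": c.LL,
        "lu": c.LU,
        "n_high": c.n_high,
        "n_low": c.n_low,
        "protectiveness": result.protectiveness,
        "utility": result.utility,
        "protectiveness_pct": (
            render_percent(result.protectiveness) if result.protectiveness is not None else None
        ),
        "utility_pct": render_percent(result.utility) if result.utility is not None else None,
    }


def render_report(
    level_results: Mapping[str, PerformanceResult] | None = None,
    ablation_results: Mapping[PlatformMask, PerformanceResult] | None = None,
) -> dict:
    """Deterministic JSON-serializable report mirroring the benchmark tables.

    The per-level block has one row per level policy; the ablation block one
    row per platform combination with Y/blank source flags.
    """
    report: dict = {}
    if level_results is not None:
        report["levels"] = [
            {"level": policy, **_result_row(res)} for policy, res in level_results.items()
        ]
    if ablation_results is not None:
        rows = []
        for mask, res in ablation_results.items():
            srcs = set(mask.sources())
            rows.append(
                {
                    **{s: ("Y" if s in srcs else "") for s in _SOURCES},
                    **_result_row(res),
                }
            )
        report["ablation"] = rows
    return report


def render_report_text(report: dict) -> str:
    """Plain-text tables for terminal display; byte-identical for equal input."""
    lines: list[str] = []
    if "levels" in report:
        lines.append("Per-PBK-level performance")
        lines.append(f"{'level':<9}{'protectiveness':<22}{'utility':<20}")
        for row in report["levels"]:
            prot = (
                f"{row['protectiveness_pct']} ({row['hu']} out of {row['n_high']})"
                if row["protectiveness_pct"] is not None else "-"
            )
            util = (
                f"{row['utility_pct']} ({row['ll']} out of {row['n_low']})"
                if row["utility_pct"] is not None else "-"
            )
            lines.append(f"{row['level']:<9}{prot:<22}{util:<20}")
    if "ablation" in report:
        if lines:
            lines.append("")
        lines.append("Platform ablation (highest available PBK level)")
        header = "".join(f"{s:<14}" for s in _SOURCES) + f"{'protectiveness':<22}{'utility':<20}"
        lines.append(header)
        for row in report["ablation"]:
            flags = "".join(f"{row[s]:<14}" for s in _SOURCES)
            prot = (
                f"{row['protectiveness_pct']} ({row['hu']} out of {row['n_high']})"
                if row["protectiveness_pct"] is not None else "-"
            )
            util = (
                f"{row['utility_pct']} ({row['ll']} out of {row['n_low']})"
                if row["utility_pct"] is not None else "-"
            )
            lines.append(f"{flags}{prot:<22}{util:<20}")
    return "\n".join(lines) + ("\n" if lines else "")
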