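"""Reverse dosimetry, margin-of-safety decisions and PoD correlation.

To compare in vitro PoDs (µM plasma concentrations) with traditional in vivo
PoDs (external doses in mg/kg bw/d), the NAM PoD is converted to an external
dose equivalent by dose-linear scaling against the most refined available
Cmax estimate: a scenario dosed at D mg/kg bw/d that reaches Cmax of C µM is
assumed to scale linearly, so a bioactive concentration P µM corresponds to
an external dose of P·D/C.  The margin of safety (MoS) is the traditional
PoD divided by the external exposure, with MoS > 100 conventionally read as
low-risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .benchmark_model import BenchmarkSet, ScenarioExposure
from .ber_engine import FULL_MASK, LOW_RISK, UNCERTAIN, PlatformMask, best_available_level, select_min_pod
from .errors import DataError, DomainError, InsufficientDataError
from .evaluation import ConfusionCounts, PerformanceResult, performance

DEFAULT_MOS_THRESHOLD = 100.0


@dataclass(frozen=True)
class DoseEquivalent:
    scenario_id: str
    pod_nam_uM: float
    external_dose_equiv: float  # mg/kg bw/d
    cmax_level_used: str


@dataclass(frozen=True)
class MoSRecord:
    scenario_id: str
    mos: float
    decision: str
    threshold: float = DEFAULT_MOS_THRESHOLD


def pod_to_external_dose(
    pod_nam: float,
    exposure: ScenarioExposure,
) -> DoseEquivalent:
    """Convert a NAM PoD (µM) to its external-dose equivalent (mg/kg bw/d).

    Uses dose-linear kinetics against the highest available Cmax level:
    external equivalent = pod_nam × applied_dose / Cmax.  Both PoD and Cmax
    are µM, so no molecular weight enters.  The level used is recorded.
    """
    if pod_nam is None or pod_nam <= 0:
        raise DomainError(f"pod_nam must be > 0 (got {pod_nam})")
    if exposure.applied_dose is None:
        raise DataError(
            f"scenario {exposure.scenario_id!r} has no applied dose; "
            "reverse dosimetry needs one"
        )
    if exposure.applied_dose <= 0:
        raise DomainError("applied_dose must be > 0")
    level = best_available_level(exposure)
    cmax = exposure.cmax[level]
    if cmax <= 0:
        raise DomainError("cmax must be > 0")
    return DoseEquivalent(
        scenario_id=exposure.scenario_id,
        pod_nam_uM=pod_nam,
        external_dose_equiv=pod_nam * exposure.applied_dose / cmax,
        cmax_level_used=level,
    )


def margin_of_safety(
    pod_traditional: float,
    external_exposure: float,
    threshold: float = DEFAULT_MOS_THRESHOLD,
    scenario_id: str = "",
) -> MoSRecord:
    """MoS = traditional PoD / external exposure; low-risk iff strictly > threshold."""
    if pod_traditional <= 0 or external_exposure <= 0:
        raise DomainError(
            f"pod_traditional and external_exposure must be > 0 "
            f"(got {pod_traditional}, {external_exposure})"
        )
    mos = pod_traditional / external_exposure
    return MoSRecord(
        scenario_id=scenario_id,
        mos=mos,
        decision=LOW_RISK if mos > threshold else UNCERTAIN,
        threshold=threshold,
    )


def pod_correlation(
    nam_pods: Sequence[float],
    traditional_pods: Sequence[float],
    scale: str = "log10",
) -> float:
    """Pearson correlation of paired NAM and traditional PoDs.

    ``scale="log10"`` (default, appropriate for PoDs spanning orders of
    magnitude) correlates the log-transformed values; ``"linear"`` the raw
    values.
    """
    if scale not in ("log10", "linear"):
        raise DomainError(f"unknown scale {scale!r}")
    if len(nam_pods) != len(traditional_pods):
        raise DataError(
            f"paired lists differ in length ({len(nam_pods)} vs {len(traditional_pods)})"
        )
    if len(nam_pods) < 3:
        raise InsufficientDataError("need at least 3 pairs for a correlation")
    x = np.asarray(nam_pods, dtype=float)
    y = np.asarray(traditional_pods, dtype=float)
    if scale == "log10":
        if np.any(x <= 0) or np.any(y <= 0):
            raise DomainError("log10 scale requires strictly positive PoDs")
        x, y = np.log10(x), np.log10(y)
    return float(stats.pearsonr(x, y).statistic)


def external_exposure_for(exposure: ScenarioExposure) -> float:
    """The scenario's external exposure in mg/kg bw/d (its applied dose)."""
    if exposure.applied_dose is None:
        raise DataError(f"scenario {exposure.scenario_id!r} has no applied dose")
    return exposure.applied_dose


def mos_records(
    bset: BenchmarkSet,
    threshold: float = DEFAULT_MOS_THRESHOLD,
) -> list[MoSRecord]:
    """MoS decisions for every scenario whose chemical has a traditional PoD."""
    trad = {t.chem_id: t.pod_traditional for t in bset.traditional_pods}
    records = []
    for s in bset.scenarios:
        if s.chem_id not in trad or s.applied_dose is None:
            continue
        records.append(
            margin_of_safety(trad[s.chem_id], external_exposure_for(s), threshold,
                             scenario_id=s.scenario_id)
        )
    return records


def mos_benchmark_evaluation(
    bset: BenchmarkSet,
    threshold: float = DEFAULT_MOS_THRESHOLD,
) -> PerformanceResult:
    """Protectiveness/utility of MoS-based decisions on the traditional-PoD subset.

    Uses the same confusion machinery as the BER decisions; scenarios whose
    chemical has no traditional PoD (or no applied dose) are excluded.
    """
    records = mos_records(bset, threshold)
    if not records:
        raise InsufficientDataError(
            "no scenario has both a traditional PoD and an applied dose"
        )
    labels = bset.labels()
    hu = hl = ll = lu = 0
    for rec in records:
        label = labels.get(rec.scenario_id)
        if label is None:
            raise DataError(f"no benchmark label for scenario {rec.scenario_id!r}")
        low = rec.decision == LOW_RISK
        if label == "high":
            hl += low
            hu += not low
        else:
            ll += low
            lu += not low
    return performance(ConfusionCounts(HU=hu, HL=hl, LL=ll, LU=lu))


def dose_equivalents(
    bset: BenchmarkSet,
    mask: PlatformMask = FULL_MASK,
) -> list[DoseEquivalent]:
    """Reverse-dosimetry table: the minimum masked PoD of each scenario's
    chemical converted to an external-dose equivalent."""
    out = []
    for s in bset.scenarios:
        pod = select_min_pod(bset.pods_for(s), mask)
        if pod is None or s.applied_dose is None:
            continue
        out.append(pod_to_external_dose(pod, s))
    return out
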