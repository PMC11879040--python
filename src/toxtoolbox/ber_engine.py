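"""PoD aggregation, BER computation and the thresholded low-risk decision model.

The bioactivity:exposure ratio (BER) for a chemical-exposure scenario is the
minimum point of departure across the selected bioactivity platforms divided
by the predicted plasma Cmax.  A scenario is concluded *low risk* when its
BER strictly exceeds the threshold attached to the PBK parameterization level
of the Cmax estimate used (defaults 110 at L1, 11 at L2, 2.5 at L3 — less
refined exposure models demand a larger margin); otherwise the conclusion is
*uncertain risk* and the scenario needs higher-tier assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .benchmark_model import LEVELS, BenchmarkSet, PoDSet, ScenarioExposure
from .errors import (
    ConsistencyError,
    DataError,
    DomainError,
    ParameterError,
)

LOW_RISK = "low_risk"
UNCERTAIN = "uncertain"

#: level policies accepted by classify_scenario
LEVEL_POLICIES = ("L1", "L2", "L3", "highest")


@dataclass(frozen=True)
class PlatformMask:
    """Which of the four PoD sources participate in the minimum-PoD selection."""

    include_ipp: bool = True
    include_csp: bool = True
    include_httr_global: bool = True
    include_httr_pathway: bool = True

    def __post_init__(self):
        if not any(
            (
                self.include_ipp,
                self.include_csp,
                self.include_httr_global,
                self.include_httr_pathway,
            )
        ):
            raise ParameterError("platform mask must include at least one source")

    def sources(self) -> tuple[str, ...]:
        out = []
        if self.include_ipp:
            out.append("ipp")
        if self.include_csp:
            out.append("csp")
        if self.include_httr_global:
            out.append("httr_global")
        if self.include_httr_pathway:
            out.append("httr_pathway")
        return tuple(out)

    def issubset(self, other: "PlatformMask") -> bool:
        return set(self.sources()) <= set(other.sources())

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "PlatformMask":
        names = {n.strip().lower() for n in names}
        known = {"ipp", "csp", "httr_global", "httr_pathway"}
        unknown = names - known
        if unknown:
            raise ParameterError(f"unknown platform source(s): {sorted(unknown)}")
        return cls(
            include_ipp="ipp" in names,
            include_csp="csp" in names,
            include_httr_global="httr_global" in names,
            include_httr_pathway="httr_pathway" in names,
        )

FULL_MASK = PlatformMask()


@dataclass(frozen=True)
class ThresholdTable:
    """Per-PBK-level BER thresholds for a low-risk conclusion."""

    l1: float = 110.0
    l2: float = 11.0
    l3: float = 2.5

    def __post_init__(self):
        if not (self.l1 > self.l2 > self.l3 > 0):
            raise ParameterError(
                "thresholds must be strictly decreasing L1 > L2 > L3 and positive"
            )

    def threshold(self, level: str) -> float:
        return {"L1": self.l1, "L2": self.l2, "L3": self.l3}[level]


DEFAULT_THRESHOLDS = ThresholdTable()


@dataclass(frozen=True)
class BERRecord:
    scenario_id: str
    level: str
    pod_min: float
    cmax: float
    ber: float
    decision: str


def select_min_pod(pods: PoDSet, mask: PlatformMask = FULL_MASK) -> Optional[float]:
    """Minimum PoD over the masked sources, or ``None`` if none has a value.

    The transcriptomics global and minimum-pathway sources each contribute all
    of their cell-line values to the candidate list.
    """
    candidates: list[float] = []
    if mask.include_ipp and pods.ipp_min is not None:
        candidates.append(pods.ipp_min)
    if mask.include_csp and pods.csp_global is not None:
        candidates.append(pods.csp_global)
    if mask.include_httr_global:
        candidates.extend(pods.httr_global.values())
    if mask.include_httr_pathway:
        candidates.extend(pods.httr_min_pathway_bmdl.values())
    return min(candidates) if candidates else None


def pathway_pod_from_probes(
    probe_bmdls: Mapping[str, Iterable[float]],
    enriched: Iterable[str],
) -> Optional[float]:
    """Minimum mean pathway BMDL across significantly enriched pathways.

    For each enriched pathway the pathway BMDL is the arithmetic mean of its
    significant probe-level BMDLs; the returned PoD is the minimum of these
    means, or ``None`` when no pathway is enriched.
    """
    enriched = list(enriched)
    if not enriched:
        return None
    means = []
    for pw in enriched:
        if pw not in probe_bmdls:
            raise KeyError(f"enriched pathway {pw!r} has no probe BMDLs")
        vals = list(probe_bmdls[pw])
        if not vals:
            raise DataError(f"pathway {pw!r} has an empty probe BMDL list")
        if any(v <= 0 for v in vals):
            raise DomainError(f"pathway {pw!r} has non-positive probe BMDLs")
        means.append(sum(vals) / len(vals))
    return min(means)


def ipp_pod_from_panel(
    screen_results: Mapping[str, float],
    dose_response: Mapping[str, float],
    screen_threshold: float = 50.0,
) -> Optional[float]:
    """Two-stage pharmacological-profiling PoD.

    Stage one screens every target at a fixed concentration; targets whose
    absolute percent effect (inhibition or stimulation) strictly exceeds
    ``screen_threshold`` are followed up with concentration-response assays.
    The PoD is the minimum IC50/EC50 among followed-up targets, or ``None``
    when nothing exceeds the screen threshold.
    """
    followed_up = {t for t, eff in screen_results.items() if abs(eff) > screen_threshold}
    stray = set(dose_response) - followed_up
    if stray:
        raise ConsistencyError(
            f"dose-response value(s) for target(s) that failed the screen: {sorted(stray)}"
        )
    values = [dose_response[t] for t in dose_response]
    return min(values) if values else None


def compute_ber(pod_min: float, cmax: float) -> float:
    """BER = minimum PoD (µM) / maximum plasma concentration (µM)."""
    if pod_min is None or cmax is None or pod_min <= 0 or cmax <= 0:
        raise DomainError(f"pod_min and cmax must be > 0 (got {pod_min}, {cmax})")
    return pod_min / cmax


def best_available_level(exposure: ScenarioExposure) -> str:
    """Most refined PBK level with a Cmax estimate: L3, else L2, else L1."""
    for level in ("L3", "L2", "L1"):
        if level in exposure.cmax:
            return level
    raise DataError(f"scenario {exposure.scenario_id!r} has no Cmax at any level")


def classify_scenario(
    exposure: ScenarioExposure,
    pods: PoDSet,
    mask: PlatformMask = FULL_MASK,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    level_policy: str = "highest",
    strict: bool = True,
) -> Optional[BERRecord]:
    """Classify one scenario as low-risk or uncertain-risk.

    ``level_policy`` is a fixed level ("L1"/"L2"/"L3") or "highest", which
    uses the most refined available Cmax with its matching threshold.  Returns
    ``None`` when the masked PoD set is empty or (under a fixed-level policy)
    the scenario lacks a Cmax at that level.  With ``strict`` (the default) a
    low-risk conclusion requires BER strictly greater than the threshold;
    ``strict=False`` accepts equality.
    """
    if level_policy not in LEVEL_POLICIES:
        raise ParameterError(f"unknown level policy {level_policy!r}")
    pod_min = select_min_pod(pods, mask)
    if pod_min is None:
        return None
    if level_policy == "highest":
        level = best_available_level(exposure)
    else:
        level = level_policy
        if level not in exposure.cmax:
            return None
    cmax = exposure.cmax[level]
    ber = compute_ber(pod_min, cmax)
    thr = thresholds.threshold(level)
    is_low = ber > thr if strict else ber >= thr
    return BERRecord(
        scenario_id=exposure.scenario_id,
        level=level,
        pod_min=pod_min,
        cmax=cmax,
        ber=ber,
        decision=LOW_RISK if is_low else UNCERTAIN,
    )


def classify_benchmark(
    bset: BenchmarkSet,
    mask: PlatformMask = FULL_MASK,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    level_policy: str = "highest",
    strict: bool = True,
    absent_policy: str = "exclude",
) -> list[BERRecord]:
    """Classify every scenario in a benchmark set.

    ``absent_policy`` controls scenarios that cannot be classified under the
    mask/level (no masked PoD or missing Cmax level): ``"exclude"`` (default,
    matching the reduced denominators of platform-subset analyses) drops them;
    ``"uncertain"`` records them as uncertain risk with NaN BER.
    """
    if absent_policy not in ("exclude", "uncertain"):
        raise ParameterError(f"unknown absent policy {absent_policy!r}")
    records: list[BERRecord] = []
    for s in bset.scenarios:
        rec = classify_scenario(s, bset.pods_for(s), mask, thresholds, level_policy, strict)
        if rec is None:
            if absent_policy == "uncertain":
                records.append(
                    BERRecord(s.scenario_id, level_policy, float("nan"), float("nan"),
                              float("nan"), UNCERTAIN)
                )
            continue
        records.append(rec)
    return records
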