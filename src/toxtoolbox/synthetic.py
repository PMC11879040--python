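"""Synthetic benchmark generator with known ground truth.

Emulates the statistical structure the decision model assumes: chemicals
with a true bioactive potency (log-uniform over a configurable µM range),
platform PoDs observed through multiplicative lognormal assay noise, an
IPP source present only for chemicals with a specific pharmacological target
(gated through the fixed-concentration screen), and exposure scenarios whose
plasma Cmax is observed through level-specific lognormal PBK error that
shrinks from L1 to L3.  Benchmark labels are margin-based: a scenario is
high-risk when its true bioactivity margin (minimum platform PoD over true
Cmax) falls below a configurable threshold, which makes protectiveness and
utility recoverable quantities with a known answer.

All randomness flows from one integer seed; per-chemical substreams are
derived from (seed, chemical index) so adding chemicals does not perturb
existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .benchmark_model import (
    CELL_LINES,
    BenchmarkSet,
    Chemical,
    PoDSet,
    ScenarioExposure,
)
from .errors import ParameterError

DEFAULT_ROUTE_WEIGHTS = {"oral": 0.70, "dermal": 0.19, "iv": 0.08, "inhalation": 0.03}
DEFAULT_CMAX_ERROR_SD = {"L1": 0.60, "L2": 0.35, "L3": 0.15}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for the synthetic benchmark.

    Defaults echo the benchmark composition: 38 chemicals with 1–3 exposure
    scenarios each, roughly two-thirds high-risk, route mix dominated by oral
    exposure, near-complete L2 availability and sparser L3, and PBK error
    (lognormal sd in log10 units) decreasing with parameterization level.
    """

    n_chemicals: int = 38
    scenarios_min: int = 1
    scenarios_max: int = 3
    potency_log10_range: tuple[float, float] = (-2.0, 2.0)
    platform_noise_sd_log10: float = 0.3
    ipp_specific_fraction: float = 0.3
    ipp_specific_potency_shift_log10: float = -1.5
    cmax_error_sd_log10: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CMAX_ERROR_SD)
    )
    l2_availability: float = 0.95
    l3_availability: float = 0.60
    true_margin_threshold: float = 1.0
    high_risk_fraction: float = 46 / 70
    margin_log10_spread: float = 2.0
    route_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROUTE_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_chemicals < 1:
            raise ParameterError("n_chemicals must be >= 1")
        if not (1 <= self.scenarios_min <= self.scenarios_max):
            raise ParameterError("need 1 <= scenarios_min <= scenarios_max")
        if any(sd < 0 for sd in self.cmax_error_sd_log10.values()):
            raise ParameterError("cmax error sds must be >= 0")
        if self.platform_noise_sd_log10 < 0:
            raise ParameterError("platform noise sd must be >= 0")
        for frac_name in ("ipp_specific_fraction", "l2_availability",
                          "l3_availability", "high_risk_fraction"):
            frac = getattr(self, frac_name)
            if not (0 <= frac <= 1):
                raise ParameterError(f"{frac_name} must lie in [0, 1]")
        total = sum(self.route_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ParameterError(f"route weights must sum to 1 (got {total})")
        if self.true_margin_threshold <= 0:
            raise ParameterError("true_margin_threshold must be > 0")


@dataclass
class GroundTruth:
    """Latent quantities behind a generated benchmark."""

    true_potency: dict[str, float] = field(default_factory=dict)      # per chemical, µM
    true_cmax: dict[str, float] = field(default_factory=dict)         # per scenario, µM
    true_margin: dict[str, float] = field(default_factory=dict)       # per scenario
    true_label: dict[str, str] = field(default_factory=dict)          # per scenario
    ipp_specific: dict[str, bool] = field(default_factory=dict)       # per chemical


def simulate_ipp_screen(
    true_ic50s: Mapping[str, float],
    screen_conc: float = 10.0,
    hill: float = 1.0,
    screen_threshold: float = 50.0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Fixed-concentration screen followed by concentration-response follow-up.

    Percent effect at the screen concentration follows a Hill curve,
    effect = 100·cʰ/(cʰ + IC50ʰ); targets whose effect strictly exceeds the
    screen threshold are followed up and their IC50 reported.  Returns
    (percent effects, followed-up IC50s).
    """
    if screen_conc <= 0:
        raise ParameterError("screen concentration must be > 0")
    effects: dict[str, float] = {}
    followed: dict[str, float] = {}
    for target, ic50 in true_ic50s.items():
        if ic50 <= 0:
            raise ParameterError(f"IC50 for {target!r} must be > 0")
        c_h = screen_conc ** hill
        effect = 100.0 * c_h / (c_h + ic50 ** hill)
        effects[target] = effect
        if effect > screen_threshold:
            followed[target] = ic50
    return effects, followed


def _chem_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([seed, index])


def generate_benchmark(cfg: GeneratorConfig) -> tuple[BenchmarkSet, GroundTruth]:
    """Generate a benchmark set plus its ground truth, deterministically."""
    truth = GroundTruth()
    chemicals: list[Chemical] = []
    scenarios: list[ScenarioExposure] = []

    lo, hi = cfg.potency_log10_range
    routes = sorted(cfg.route_weights)
    route_p = np.array([cfg.route_weights[r] for r in routes])

    for i in range(cfg.n_chemicals):
        rng = _chem_rng(cfg.seed, i)
        chem_id = f"syn{i:03d}"
        potency = 10.0 ** rng.uniform(lo, hi)
        truth.true_potency[chem_id] = potency

        noise = cfg.platform_noise_sd_log10

        def observed(base: float) -> float:
            return base * 10.0 ** rng.normal(0.0, noise)

        csp = observed(potency)
        httr_global = {line: observed(potency) for line in CELL_LINES}
        # pathway PoDs rely on multi-gene responses, so they sit at or above
        # the gene-level global PoD of the same cell line
        httr_pathway = {
            line: g * 10.0 ** abs(rng.normal(0.0, noise))
            for line, g in httr_global.items()
        }

        specific = bool(rng.random() < cfg.ipp_specific_fraction)
        truth.ipp_specific[chem_id] = specific
        ipp_min: Optional[float] = None
        if specific:
            ic50 = potency * 10.0 ** (
                cfg.ipp_specific_potency_shift_log10 + rng.normal(0.0, noise)
            )
            screen_conc = float(rng.choice([10.0, 100.0]))
            _, followed = simulate_ipp_screen({"target0": ic50}, screen_conc)
            if followed:
                ipp_min = followed["target0"]

        pods = PoDSet(
            ipp_min=ipp_min,
            csp_global=csp,
            httr_global=httr_global,
            httr_min_pathway_bmdl=httr_pathway,
        )
        chemicals.append(
            Chemical(chem_id=chem_id, name=f"synthetic chemical {i}", pods=pods)
        )
        pod_min = min(pods.all_values().values())

        n_scen = int(rng.integers(cfg.scenarios_min, cfg.scenarios_max + 1))
        for k in range(n_scen):
            sid = f"{chem_id}_s{k}"
            high = bool(rng.random() < cfg.high_risk_fraction)
            # place the true margin on the correct side of the threshold,
            # log-uniform up to margin_log10_spread decades away
            offset = rng.uniform(0.02, cfg.margin_log10_spread)
            margin = cfg.true_margin_threshold * 10.0 ** (-offset if high else offset)
            true_cmax = pod_min / margin

            cmax: dict[str, float] = {}
            have_l2 = rng.random() < cfg.l2_availability
            p_l3 = cfg.l3_availability / cfg.l2_availability if cfg.l2_availability else 0.0
            have_l3 = have_l2 and rng.random() < min(p_l3, 1.0)
            for level, have in (("L1", True), ("L2", have_l2), ("L3", have_l3)):
                if have:
                    sd = cfg.cmax_error_sd_log10.get(level, 0.0)
                    cmax[level] = true_cmax * 10.0 ** rng.normal(0.0, sd)

            truth.true_cmax[sid] = true_cmax
            truth.true_margin[sid] = margin
            truth.true_label[sid] = "high" if high else "low"
            scenarios.append(
                ScenarioExposure(
                    scenario_id=sid,
                    chem_id=chem_id,
                    route=routes[int(rng.choice(len(routes), p=route_p))],
                    applied_dose=10.0 ** rng.uniform(-2.0, 2.0),
                    cmax=cmax,
                    risk_label="high" if high else "low",
                )
            )

    return BenchmarkSet(chemicals=chemicals, scenarios=scenarios), truth


def generate_descriptor_fixture(
    n_items: int,
    n_informative: int,
    n_redundant: int,
    n_constant: int,
    seed: int = 0,
):
    """Descriptor matrix with known pruning outcome and a planted coverage gap.

    Informative columns are i.i.d. standard normal (shifted by a two-cluster
    structure), redundant columns are affine copies of informative ones
    (r² = 1), constant columns are constant.  Items are labelled test /
    initial / cosmetic, with the second cluster absent from the test label so
    set-coverage comparisons have a real gap to find.
    """
    from .chemspace import DescriptorMatrix

    if min(n_items, n_informative) < 0 or n_redundant < 0 or n_constant < 0:
        raise ParameterError("counts must be >= 0")
    if n_redundant > 0 and n_informative == 0:
        raise ParameterError("redundant columns need at least one informative column")
    rng = np.random.default_rng(seed)
    cluster = rng.random(n_items) < 0.5
    X_inf = rng.standard_normal((n_items, n_informative))
    if n_informative:
        X_inf[cluster, 0] += 6.0  # separated second cluster along the first axis
    cols = [X_inf]
    names = [f"inf{j}" for j in range(n_informative)]
    if n_redundant:
        idx = [j % n_informative for j in range(n_redundant)]
        cols.append(2.0 * X_inf[:, idx] + 3.0)
        names += [f"red{j}" for j in range(n_redundant)]
    if n_constant:
        cols.append(np.full((n_items, n_constant), 7.0))
        names += [f"const{j}" for j in range(n_constant)]
    values = np.hstack(cols) if cols else np.empty((n_items, 0))

    items = [f"item{i}" for i in range(n_items)]
    labels = {}
    for i, it in enumerate(items):
        if cluster[i]:
            labels[it] = "initial" if rng.random() < 0.5 else "cosmetic"
        else:
            labels[it] = ("test", "initial", "cosmetic")[int(rng.choice(3))]
    return DescriptorMatrix(items=items, descriptors=names, values=values, set_label=labels)
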