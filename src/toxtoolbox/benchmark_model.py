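"""Domain types, CSV I/O and validation for benchmark decision datasets.

A benchmark dataset couples per-chemical points of departure (PoDs, µM) from
up to eight bioactivity sources with per-scenario internal-exposure estimates
(plasma Cmax, µM) at up to three PBK parameterization levels, each scenario
carrying a high/low benchmark risk label.  All concentrations are in µM and
applied doses in mg/kg bw/d throughout; missing values are encoded as empty
CSV cells, never zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .errors import ReferentialError, SchemaError

logger = logging.getLogger("toxtoolbox")

ROUTES = ("oral", "dermal", "iv", "inhalation")
LEVELS = ("L1", "L2", "L3")
CELL_LINES = ("HepG2", "HepaRG", "MCF7")
USE_CATEGORIES = (
    "Agricultural",
    "Drug",
    "Homecare",
    "Food",
    "Cosmetic",
    "Occupational",
    "Other",
)

#: CSV schemas (mandatory column -> None means required, no default)
POD_COLUMNS = [
    "chem_id",
    "name",
    "smiles",
    "mol_weight",
    "use_category",
    "ipp_min_uM",
    "csp_global_uM",
    "httr_global_hepg2_uM",
    "httr_global_heparg_uM",
    "httr_global_mcf7_uM",
    "httr_pathway_hepg2_uM",
    "httr_pathway_heparg_uM",
    "httr_pathway_mcf7_uM",
]
SCENARIO_COLUMNS = [
    "scenario_id",
    "chem_id",
    "route",
    "applied_dose_mgkgd",
    "cmax_l1_uM",
    "cmax_l2_uM",
    "cmax_l3_uM",
    "risk_label",
]
TRADITIONAL_COLUMNS = ["chem_id", "pod_traditional_mgkgd", "descriptor"]

_POD_MANDATORY = {"chem_id", "name", "use_category"}
_SCENARIO_MANDATORY = {"scenario_id", "chem_id", "route", "cmax_l1_uM", "risk_label"}
_TRADITIONAL_MANDATORY = set(TRADITIONAL_COLUMNS)

_HTTR_COLMAP = {
    "HepG2": ("httr_global_hepg2_uM", "httr_pathway_hepg2_uM"),
    "HepaRG": ("httr_global_heparg_uM", "httr_pathway_heparg_uM"),
    "MCF7": ("httr_global_mcf7_uM", "httr_pathway_mcf7_uM"),
}


@dataclass(frozen=True)
class PoDSet:
    """The up-to-8 per-chemical platform PoDs (all µM).

    ``httr_global`` holds the per-cell-line gene-level global PoDs and
    ``httr_min_pathway_bmdl`` the per-cell-line minimum pathway BMDLs; for any
    cell line where both are present the pathway PoD is expected to sit at or
    above the gene-level PoD.
    """

    ipp_min: Optional[float] = None
    csp_global: Optional[float] = None
    httr_global: Mapping[str, float] = field(default_factory=dict)
    httr_min_pathway_bmdl: Mapping[str, float] = field(default_factory=dict)

    def all_values(self) -> dict[str, float]:
        """Flat mapping source-name -> value for every present PoD."""
        out: dict[str, float] = {}
        if self.ipp_min is not None:
            out["ipp"] = self.ipp_min
        if self.csp_global is not None:
            out["csp"] = self.csp_global
        for line, v in self.httr_global.items():
            out[f"httr_global:{line}"] = v
        for line, v in self.httr_min_pathway_bmdl.items():
            out[f"httr_pathway:{line}"] = v
        return out

    @property
    def is_empty(self) -> bool:
        return not self.all_values()


@dataclass(frozen=True)
class Chemical:
    chem_id: str
    name: str
    smiles: Optional[str] = None
    mol_weight: Optional[float] = None
    use_category: str = "Other"
    pods: PoDSet = field(default_factory=PoDSet)


@dataclass(frozen=True)
class ScenarioExposure:
    """One benchmark exposure scenario.

    ``cmax`` maps PBK level (L1 mandatory, L2/L3 optional) to the predicted
    total plasma Cmax in µM.  ``risk_label`` is the benchmark classification
    ("high" or "low") the decision model is evaluated against.
    """

    scenario_id: str
    chem_id: str
    route: str
    cmax: Mapping[str, float]
    applied_dose: Optional[float] = None
    risk_label: Optional[str] = None


@dataclass(frozen=True)
class TraditionalPoD:
    """Minimum NOAEL/NOEL/BMDL from repeat-dose in vivo studies, mg/kg bw/d."""

    chem_id: str
    pod_traditional: float
    descriptor: str = "NOAEL"


@dataclass
class BenchmarkSet:
    chemicals: list[Chemical] = field(default_factory=list)
    scenarios: list[ScenarioExposure] = field(default_factory=list)
    traditional_pods: list[TraditionalPoD] = field(default_factory=list)

    def chemical(self, chem_id: str) -> Chemical:
        for c in self.chemicals:
            if c.chem_id == chem_id:
                return c
        raise ReferentialError(f"unknown chem_id: {chem_id!r}")

    def pods_for(self, scenario: ScenarioExposure) -> PoDSet:
        return self.chemical(scenario.chem_id).pods

    def labels(self) -> dict[str, str]:
        return {
            s.scenario_id: s.risk_label
            for s in self.scenarios
            if s.risk_label is not None
        }


@dataclass
class ValidationReport:
    counts: dict[str, int] = field(default_factory=dict)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_dict(self) -> dict:
        return {"counts": dict(self.counts), "violations": list(self.violations)}


# ---------------------------------------------------------------------------
# CSV parsing helpers
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, mandatory: set[str], known: list[str], table: str) -> None:
    missing = mandatory - set(df.columns)
    if missing:
        raise SchemaError(
            f"{table}: missing mandatory column(s): {', '.join(sorted(missing))}"
        )
    unknown = set(df.columns) - set(known)
    if unknown:
        logger.warning("%s: ignoring unknown column(s): %s", table, ", ".join(sorted(unknown)))


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if not value:
            return None
    return float(value)


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def _parse_pod_row(row: pd.Series) -> Chemical:
    httr_global, httr_pathway = {}, {}
    for line, (gcol, pcol) in _HTTR_COLMAP.items():
        g = _opt_float(row.get(gcol))
        p = _opt_float(row.get(pcol))
        if g is not None:
            httr_global[line] = g
        if p is not None:
            httr_pathway[line] = p
    pods = PoDSet(
        ipp_min=_opt_float(row.get("ipp_min_uM")),
        csp_global=_opt_float(row.get("csp_global_uM")),
        httr_global=httr_global,
        httr_min_pathway_bmdl=httr_pathway,
    )
    return Chemical(
        chem_id=str(row["chem_id"]).strip(),
        name=str(row["name"]).strip(),
        smiles=_opt_str(row.get("smiles")),
        mol_weight=_opt_float(row.get("mol_weight")),
        use_category=_opt_str(row.get("use_category")) or "Other",
        pods=pods,
    )


def _parse_scenario_row(row: pd.Series) -> ScenarioExposure:
    cmax = {}
    for level, col in zip(LEVELS, ("cmax_l1_uM", "cmax_l2_uM", "cmax_l3_uM")):
        v = _opt_float(row.get(col))
        if v is not None:
            cmax[level] = v
    return ScenarioExposure(
        scenario_id=str(row["scenario_id"]).strip(),
        chem_id=str(row["chem_id"]).strip(),
        route=str(row["route"]).strip(),
        applied_dose=_opt_float(row.get("applied_dose_mgkgd")),
        cmax=cmax,
        risk_label=_opt_str(row.get("risk_label")),
    )


def load_benchmark(
    pod_table_path,
    scenario_table_path,
    traditional_table_path=None,
) -> BenchmarkSet:
    """Load a benchmark dataset from its CSV tables and cross-reference it.

    Unknown columns are ignored with a logged warning; a missing mandatory
    column raises :class:`SchemaError` naming the column, and a scenario
    referencing an unknown chemical raises :class:`ReferentialError`.
    """
    pods_df = pd.read_csv(pod_table_path, dtype={"chem_id": str})
    _check_columns(pods_df, _POD_MANDATORY, POD_COLUMNS, "pods table")
    chemicals = [_parse_pod_row(r) for _, r in pods_df.iterrows()]

    scen_df = pd.read_csv(scenario_table_path, dtype={"scenario_id": str, "chem_id": str})
    if scen_df.empty and not scen_df.columns.size:
        scenarios: list[ScenarioExposure] = []
        logger.warning("scenario table is empty")
    else:
        _check_columns(scen_df, _SCENARIO_MANDATORY, SCENARIO_COLUMNS, "scenario table")
        scenarios = [_parse_scenario_row(r) for _, r in scen_df.iterrows()]
        if not scenarios:
            logger.warning("scenario table has no data rows")

    known_ids = {c.chem_id for c in chemicals}
    for s in scenarios:
        if s.chem_id not in known_ids:
            raise ReferentialError(
                f"scenario {s.scenario_id!r} references unknown chem_id {s.chem_id!r}"
            )

    traditional: list[TraditionalPoD] = []
    if traditional_table_path is not None and Path(traditional_table_path).exists():
        trad_df = pd.read_csv(traditional_table_path, dtype={"chem_id": str})
        _check_columns(trad_df, _TRADITIONAL_MANDATORY, TRADITIONAL_COLUMNS, "traditional table")
        for _, r in trad_df.iterrows():
            traditional.append(
                TraditionalPoD(
                    chem_id=str(r["chem_id"]).strip(),
                    pod_traditional=float(r["pod_traditional_mgkgd"]),
                    descriptor=str(r["descriptor"]).strip(),
                )
            )
    return BenchmarkSet(chemicals=chemicals, scenarios=scenarios, traditional_pods=traditional)


def load_benchmark_dir(directory) -> BenchmarkSet:
    """Load ``pods.csv``/``scenarios.csv`` (and ``traditional.csv`` if present)."""
    d = Path(directory)
    return load_benchmark(d / "pods.csv", d / "scenarios.csv", d / "traditional.csv")


def write_benchmark(bset: BenchmarkSet, out_dir) -> list[Path]:
    """Write a benchmark set to CSV with deterministic row order.

    Rows are sorted by chem_id / scenario_id; the traditional table is only
    written when traditional PoDs are present.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pod_rows = []
    for c in sorted(bset.chemicals, key=lambda c: c.chem_id):
        row = {
            "chem_id": c.chem_id,
            "name": c.name,
            "smiles": c.smiles,
            "mol_weight": c.mol_weight,
            "use_category": c.use_category,
            "ipp_min_uM": c.pods.ipp_min,
            "csp_global_uM": c.pods.csp_global,
        }
        for line, (gcol, pcol) in _HTTR_COLMAP.items():
            row[gcol] = c.pods.httr_global.get(line)
            row[pcol] = c.pods.httr_min_pathway_bmdl.get(line)
        pod_rows.append(row)
    pods_path = out / "pods.csv"
    pd.DataFrame(pod_rows, columns=POD_COLUMNS).to_csv(pods_path, index=False)

    scen_rows = []
    for s in sorted(bset.scenarios, key=lambda s: s.scenario_id):
        scen_rows.append(
            {
                "scenario_id": s.scenario_id,
                "chem_id": s.chem_id,
                "route": s.route,
                "applied_dose_mgkgd": s.applied_dose,
                "cmax_l1_uM": s.cmax.get("L1"),
                "cmax_l2_uM": s.cmax.get("L2"),
                "cmax_l3_uM": s.cmax.get("L3"),
                "risk_label": s.risk_label,
            }
        )
    scen_path = out / "scenarios.csv"
    pd.DataFrame(scen_rows, columns=SCENARIO_COLUMNS).to_csv(scen_path, index=False)

    paths = [pods_path, scen_path]
    if bset.traditional_pods:
        trad_rows = [
            {
                "chem_id": t.chem_id,
                "pod_traditional_mgkgd": t.pod_traditional,
                "descriptor": t.descriptor,
            }
            for t in sorted(bset.traditional_pods, key=lambda t: t.chem_id)
        ]
        trad_path = out / "traditional.csv"
        pd.DataFrame(trad_rows, columns=TRADITIONAL_COLUMNS).to_csv(trad_path, index=False)
        paths.append(trad_path)
    return paths


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_benchmark(bset: BenchmarkSet) -> ValidationReport:
    """Pure validation pass: summary counts plus a list of invariant violations."""
    report = ValidationReport()
    v = report.violations

    seen_chem: set[str] = set()
    for c in bset.chemicals:
        if c.chem_id in seen_chem:
            v.append(f"duplicate chem_id: {c.chem_id}")
        seen_chem.add(c.chem_id)
        if c.mol_weight is not None and c.mol_weight <= 0:
            v.append(f"{c.chem_id}: mol_weight must be > 0")
        if c.use_category not in USE_CATEGORIES:
            v.append(f"{c.chem_id}: unknown use_category {c.use_category!r}")
        for src, val in c.pods.all_values().items():
            if val <= 0:
                v.append(f"{c.chem_id}: PoD {src} must be > 0 (got {val})")
        for line in CELL_LINES:
            g = c.pods.httr_global.get(line)
            p = c.pods.httr_min_pathway_bmdl.get(line)
            if g is not None and p is not None and p < g:
                v.append(
                    f"{c.chem_id}: pathway BMDL below gene-level global PoD in {line}"
                )
        if c.pods.is_empty:
            v.append(f"{c.chem_id}: no PoD from any platform")

    seen_scen: set[str] = set()
    route_counts = {r: 0 for r in ROUTES}
    level_counts = {lv: 0 for lv in LEVELS}
    n_high = n_low = 0
    for s in bset.scenarios:
        if s.scenario_id in seen_scen:
            v.append(f"duplicate scenario_id: {s.scenario_id}")
        seen_scen.add(s.scenario_id)
        if s.chem_id not in seen_chem:
            v.append(f"{s.scenario_id}: references unknown chem_id {s.chem_id}")
        if s.route in route_counts:
            route_counts[s.route] += 1
        else:
            v.append(f"{s.scenario_id}: unknown route {s.route!r}")
        if "L1" not in s.cmax:
            v.append(f"{s.scenario_id}: missing mandatory L1 Cmax")
        if "L3" in s.cmax and "L2" not in s.cmax:
            v.append(f"{s.scenario_id}: L3 Cmax present without L2 (non-monotone availability)")
        for lv, val in s.cmax.items():
            if val <= 0:
                v.append(f"{s.scenario_id}: Cmax at {lv} must be > 0 (got {val})")
            else:
                level_counts[lv] += 1
        if s.risk_label == "high":
            n_high += 1
        elif s.risk_label == "low":
            n_low += 1
        elif s.risk_label is not None:
            v.append(f"{s.scenario_id}: unknown risk_label {s.risk_label!r}")
        else:
            v.append(f"{s.scenario_id}: benchmark scenario lacks a risk label")

    for t in bset.traditional_pods:
        if t.pod_traditional <= 0:
            v.append(f"traditional PoD for {t.chem_id} must be > 0")
        if t.chem_id not in seen_chem:
            v.append(f"traditional PoD references unknown chem_id {t.chem_id}")

    report.counts = {
        "chemicals": len(bset.chemicals),
        "scenarios": len(bset.scenarios),
        "high": n_high,
        "low": n_low,
        **route_counts,
        **{f"cmax_{lv}": n for lv, n in level_counts.items()},
    }
    return report


def load_paper_fixture() -> BenchmarkSet:
    """Load the packaged 38-chemical / 70-scenario benchmark decision fixture.

    The fixture encodes, scenario by scenario, the decision structure of the
    published benchmark evaluation: per-level Cmax availability, benchmark
    risk labels, and platform PoDs arranged so that every per-level and
    per-platform-combination confusion tally of the study is reproduced.
    """
    data = resources.files("toxtoolbox") / "data"
    with resources.as_file(data / "pods.csv") as p, resources.as_file(
        data / "scenarios.csv"
    ) as s:
        return load_benchmark(p, s)
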