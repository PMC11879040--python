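"""BER engine: PoD aggregation, ratio, level selection and decisions."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from toxtoolbox import (
    PlatformMask,
    PoDSet,
    ScenarioExposure,
    ThresholdTable,
    best_available_level,
    classify_scenario,
    compute_ber,
    ipp_pod_from_panel,
    pathway_pod_from_probes,
    select_min_pod,
)
from toxtoolbox.errors import (
    ConsistencyError,
    DataError,
    DomainError,
    ParameterError,
)

FULL = PlatformMask()


def _scenario(cmax, scenario_id="s", applied_dose=None, label="high"):
    return ScenarioExposure(scenario_id, "c", "oral", cmax, applied_dose, label)


# ---------------------------------------------------------------------------
# select_min_pod
# ---------------------------------------------------------------------------

def test_min_pod_prefers_potent_specific_target():
    """A potent pharmacological-profiling IC50 leads the PoD set; excluding
    that platform falls back to the next-lowest transcriptomics PoD."""
    pods = PoDSet(ipp_min=0.046, httr_global={"HepG2": 16.0})
    assert select_min_pod(pods, FULL) == 0.046
    no_ipp = PlatformMask(include_ipp=False)
    assert select_min_pod(pods, no_ipp) == 16.0


def test_min_pod_absent_when_masked_sources_empty():
    pods = PoDSet(csp_global=3.0)
    httr_only = PlatformMask(include_ipp=False, include_csp=False,
                             include_httr_pathway=False)
    assert select_min_pod(pods, httr_only) is None


def test_empty_mask_rejected():
    with pytest.raises(ParameterError):
        PlatformMask(False, False, False, False)


@given(
    ipp=st.one_of(st.none(), st.floats(0.001, 1e3)),
    csp=st.one_of(st.none(), st.floats(0.001, 1e3)),
    glines=st.dictionaries(st.sampled_from(["HepG2", "HepaRG", "MCF7"]),
                           st.floats(0.001, 1e3), max_size=3),
    plines=st.dictionaries(st.sampled_from(["HepG2", "HepaRG", "MCF7"]),
                           st.floats(0.001, 1e3), max_size=3),
    flags=st.tuples(*[st.booleans()] * 4),
)
def test_min_pod_matches_bruteforce_enumeration(ipp, csp, glines, plines, flags):
    """select_min_pod equals the minimum of an explicitly enumerated list."""
    if not any(flags):
        return
    pods = PoDSet(ipp_min=ipp, csp_global=csp, httr_global=glines,
                  httr_min_pathway_bmdl=plines)
    mask = PlatformMask(*flags)
    candidates = []
    if flags[0] and ipp is not None:
        candidates.append(ipp)
    if flags[1] and csp is not None:
        candidates.append(csp)
    if flags[2]:
        candidates += list(glines.values())
    if flags[3]:
        candidates += list(plines.values())
    expected = min(candidates) if candidates else None
    assert select_min_pod(pods, mask) == expected


# ---------------------------------------------------------------------------
# pathway / IPP PoD derivation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "probes, enriched, expected",
    [
        ({"pw1": [1.0, 3.0]}, {"pw1"}, 2.0),
        ({"pw1": [1.0, 3.0], "pw2": [5.0]}, {"pw1", "pw2"}, 2.0),
        ({"pw1": [1.0]}, set(), None),
    ],
)
def test_pathway_pod_min_of_pathway_means(probes, enriched, expected):
    assert pathway_pod_from_probes(probes, enriched) == expected


def test_pathway_pod_missing_pathway_raises():
    with pytest.raises(KeyError):
        pathway_pod_from_probes({"pw1": [1.0]}, {"pw2"})


def test_pathway_pod_never_below_global_probe_minimum():
    """The min pathway mean is bounded below by the global minimum probe BMDL."""
    probes = {"a": [0.2, 5.0, 9.0], "b": [1.0, 1.5], "c": [4.0]}
    pod = pathway_pod_from_probes(probes, set(probes))
    global_min = min(v for vals in probes.values() for v in vals)
    assert pod >= global_min


@pytest.mark.parametrize(
    "screen, dose_response, expected",
    [
        ({"A": 80.0, "B": 20.0}, {"A": 0.5}, 0.5),
        ({"A": 40.0, "B": 50.0}, {}, None),       # nothing exceeds 50% strictly
        ({"A": 80.0, "B": 60.0}, {"A": 2.0, "B": 0.3}, 0.3),
        ({"A": -75.0}, {"A": 1.2}, 1.2),          # stimulation or inhibition
    ],
)
def test_ipp_pod_two_stage_screen(screen, dose_response, expected):
    assert ipp_pod_from_panel(screen, dose_response) == expected


def test_ipp_pod_follow_up_of_failed_screen_rejected():
    with pytest.raises(ConsistencyError):
        ipp_pod_from_panel({"A": 30.0}, {"A": 1.0})


# ---------------------------------------------------------------------------
# BER and decisions
# ---------------------------------------------------------------------------

def test_ber_is_pod_over_cmax():
    """Warfarin-like: minimum PoD 13.6 µM over Cmax 0.6 µM gives BER ~22.67."""
    assert compute_ber(13.6, 0.6) == pytest.approx(22.67, abs=0.01)
    assert compute_ber(5.0, 5.0) == 1.0


@pytest.mark.parametrize("pod,cmax", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
def test_ber_domain_errors(pod, cmax):
    with pytest.raises(DomainError):
        compute_ber(pod, cmax)


def test_best_available_level_prefers_refined_models():
    assert best_available_level(_scenario({"L1": 1, "L2": 1, "L3": 1})) == "L3"
    assert best_available_level(_scenario({"L1": 1, "L2": 1})) == "L2"
    assert best_available_level(_scenario({"L1": 1})) == "L1"
    with pytest.raises(DataError):
        best_available_level(_scenario({}))


def test_decision_threshold_is_strict_by_default():
    """A BER exactly at the threshold concludes uncertain under the strict
    tie rule; the lenient switch accepts equality."""
    pods = PoDSet(csp_global=110.0)
    scen = _scenario({"L1": 1.0})
    rec = classify_scenario(scen, pods, level_policy="L1")
    assert rec.ber == 110.0 and rec.decision == "uncertain"
    rec = classify_scenario(scen, pods, level_policy="L1", strict=False)
    assert rec.decision == "low_risk"


def test_low_risk_above_l2_threshold():
    pods = PoDSet(httr_global={"HepaRG": 13.6})
    rec = classify_scenario(_scenario({"L1": 0.1, "L2": 0.6}), pods, level_policy="L2")
    assert rec.ber == pytest.approx(22.67, abs=0.01)
    assert rec.decision == "low_risk"
    rec = classify_scenario(_scenario({"L1": 0.1, "L2": 6.0}), pods, level_policy="L2")
    assert rec.ber == pytest.approx(2.27, abs=0.01)
    assert rec.decision == "uncertain"


def test_classification_absent_cases():
    pods = PoDSet(csp_global=3.0)
    # fixed level without a Cmax at that level
    assert classify_scenario(_scenario({"L1": 1.0}), pods, level_policy="L3") is None
    # no PoD under the mask
    httr_only = PlatformMask(include_ipp=False, include_csp=False,
                             include_httr_pathway=False)
    assert classify_scenario(_scenario({"L1": 1.0}), pods, mask=httr_only) is None


@given(
    pod=st.floats(0.01, 1e4),
    cmax=st.floats(0.01, 1e4),
    t_low=st.floats(1.0, 100.0),
    bump=st.floats(0.1, 100.0),
)
def test_raising_thresholds_never_creates_low_risk(pod, cmax, t_low, bump):
    """Threshold monotonicity: raising a threshold can only turn low_risk
    into uncertain, never the reverse."""
    pods = PoDSet(csp_global=pod)
    scen = _scenario({"L3": cmax})
    lo = ThresholdTable(l1=1000.0, l2=500.0, l3=t_low)
    hi = ThresholdTable(l1=2000.0, l2=1000.0, l3=t_low + bump)
    d_lo = classify_scenario(scen, pods, thresholds=lo, level_policy="L3").decision
    d_hi = classify_scenario(scen, pods, thresholds=hi, level_policy="L3").decision
    assert not (d_lo == "uncertain" and d_hi == "low_risk")


@given(
    values=st.lists(st.floats(0.01, 1e3), min_size=4, max_size=4),
    cmax=st.floats(0.01, 100.0),
    sub=st.tuples(*[st.booleans()] * 4),
    extra=st.integers(0, 3),
)
def test_platform_subset_monotonicity(values, cmax, sub, extra):
    """For masks A ⊆ B, the B-minimum PoD is no larger, so BER(B) ≤ BER(A)
    and a low-risk decision under B implies one under A."""
    if not any(sub):
        return
    a_flags = list(sub)
    b_flags = list(sub)
    b_flags[extra] = True
    pods = PoDSet(ipp_min=values[0], csp_global=values[1],
                  httr_global={"HepG2": values[2]},
                  httr_min_pathway_bmdl={"HepG2": max(values[2], values[3])})
    scen = _scenario({"L2": cmax})
    rec_a = classify_scenario(scen, pods, mask=PlatformMask(*a_flags), level_policy="L2")
    rec_b = classify_scenario(scen, pods, mask=PlatformMask(*b_flags), level_policy="L2")
    assert rec_b.ber <= rec_a.ber
    if rec_b.decision == "low_risk":
        assert rec_a.decision == "low_risk"


def test_thresholds_must_decrease_with_refinement():
    with pytest.raises(ParameterError):
        ThresholdTable(l1=10.0, l2=11.0, l3=2.5)
    with pytest.raises(ParameterError):
        ThresholdTable(l1=110.0, l2=11.0, l3=-1.0)
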