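import numpy as np
import pandas as pd
import pytest

from mibci.erders import (
    ERDERSResult,
    analyze_session,
    compute_baseline,
    erd_ers_percent,
    max_excursions,
    render_reports,
    results_to_frame,
)
from mibci.errors import MibciError, ReportError
from mibci.protocol import ProtocolSpec
from mibci.synth import (
    BandPowerTable,
    ERDSpec,
    compute_band_powers,
    default_erd_template,
    generate_recording,
    make_session_fixture,
)
from mibci.protocol import build_protocol_timeline
from mibci.labels import EpochLabel


def test_baseline_is_arithmetic_mean():
    assert compute_baseline([1.0, 2.0, 3.0]) == 2.0
    assert compute_baseline(np.full(10, 4.2)) == pytest.approx(4.2)
    rng = np.random.default_rng(0)
    x = rng.normal(size=1000)
    assert compute_baseline(x) == pytest.approx(sum(x) / len(x), abs=1e-12)
    with pytest.raises(MibciError):
        compute_baseline([])


def test_max_excursions_by_hand():
    assert max_excursions([2.0, 5.0, 1.0], 2.0) == (3.0, 1.0)
    assert max_excursions([3.0, 3.0], 3.0) == (0.0, 0.0)
    # affine shift of series and baseline leaves excursions unchanged
    inc, dec = max_excursions(np.array([2.0, 5.0, 1.0]) + 7.0, 9.0)
    assert (inc, dec) == (3.0, 1.0)


def test_percent_change_convention():
    assert erd_ers_percent(7.0, 10.0) == pytest.approx(-30.0)
    assert erd_ers_percent(10.0, 10.0) == 0.0
    assert erd_ers_percent(12.0, 10.0) == pytest.approx(20.0)
    assert erd_ers_percent(5.0, 0.0) is None


def _session_table(depth=0.5, reps=3, seed=0, template=None):
    tl = build_protocol_timeline(ProtocolSpec(repetitions=reps))
    specs = template if template is not None else default_erd_template(depth)
    rec = generate_recording(tl, specs, seed=seed)
    return compute_band_powers(rec, step_s=0.04)


def test_session_analysis_populates_valid_cells():
    table = _session_table(reps=3)
    results = analyze_session(table, repetitions=3)
    # full cross for 3 cycles: 2 arms x 2 movements x 2 hemispheres x 2 bands x 3
    assert len(results) == 48
    for key, r in results.items():
        assert r.max_increase >= 0
        assert r.max_decrease >= 0
        assert r.baseline > 0
        assert 1 <= key.cycle <= 3
        if r.ratio is not None:
            assert r.ratio == pytest.approx(r.max_increase / r.max_decrease)


def test_contralateral_alpha_erd_recovered():
    """Injected 30% alpha suppression shows up in the matching cells."""
    table = _session_table(depth=0.3, reps=10, seed=21)
    results = analyze_session(table, repetitions=10)
    pcts = [
        r.percent_change
        for k, r in results.items()
        if k.arm == "right" and k.movement == "flexion" and k.hemisphere == "left" and k.band == "alpha"
    ]
    assert len(pcts) == 10
    assert np.mean(pcts) == pytest.approx(-30.0, abs=10.0)


def test_injected_ers_yields_positive_percent():
    template = [ERDSpec("alpha", -0.5, {0, 1, 2, 3}, {EpochLabel.RIGHT_FLEX})]
    table = _session_table(reps=5, template=template, seed=8)
    results = analyze_session(table, repetitions=5)
    pcts = [
        r.percent_change
        for k, r in results.items()
        if k.arm == "right" and k.movement == "flexion" and k.hemisphere == "left" and k.band == "alpha"
    ]
    assert np.mean(pcts) > 0


def test_scale_equivariance():
    table = _session_table(reps=2, seed=4)
    k = 3.5
    scaled_frame = table.frame.copy()
    feats = table.feature_columns
    scaled_frame[feats] = scaled_frame[feats] * k
    scaled = BandPowerTable(scaled_frame)
    base = analyze_session(table, repetitions=2)
    big = analyze_session(scaled, repetitions=2)
    for key in base:
        a, b = base[key], big[key]
        assert b.baseline == pytest.approx(k * a.baseline, rel=1e-9)
        assert b.max_increase == pytest.approx(k * a.max_increase, rel=1e-9)
        assert b.percent_change == pytest.approx(a.percent_change, rel=1e-9)
        if a.ratio is not None:
            assert b.ratio == pytest.approx(a.ratio, rel=1e-9)


def test_single_arm_session_leaves_other_arm_absent():
    table = _session_table(reps=2, seed=5)
    keep = table.frame["label"].isin(["left_flex", "left_ext", "rest"])
    left_only = BandPowerTable(table.frame[keep].reset_index(drop=True))
    results = analyze_session(left_only, repetitions=2)
    assert results
    assert all(k.arm == "left" for k in results)


def test_excess_runs_vs_stated_repetitions_rejected():
    table = _session_table(reps=3)
    with pytest.raises(MibciError, match="repetitions"):
        analyze_session(table, repetitions=1)


def test_report_frame_matches_group_by_oracle(tmp_path):
    table = _session_table(reps=2, seed=6)
    results = analyze_session(table, repetitions=2)
    frame = results_to_frame(results)
    assert len(frame) == len(results)
    # brute-force group mean equals pandas aggregation used by the report
    sel = frame[(frame.band == "alpha") & (frame.hemisphere == "left")]
    manual = np.mean([r.percent_change for k, r in results.items()
                      if k.band == "alpha" and k.hemisphere == "left"])
    assert sel["percent_change"].mean() == pytest.approx(manual)
    paths = render_reports(results, tmp_path, make_plots=False)
    written = pd.read_csv(paths["cells"])
    assert len(written) == len(results)


def test_empty_results_rejected():
    with pytest.raises(ReportError):
        results_to_frame({})
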