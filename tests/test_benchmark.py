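"""Thresholding, TP/FP classification, method comparison, outlier scan."""

import numpy as np
import pandas as pd
import pytest

from splinewin import (
    SimConfig,
    classify,
    compare_methods,
    merge_outliers,
    null_threshold,
    run_benchmark,
    scan,
)
from splinewin.benchmark import method_windows


def test_null_threshold_quantile_rule():
    assert null_threshold([5.0, 5.0, 5.0]).threshold == 5.0
    assert null_threshold(np.arange(1, 21), 0.95).threshold == pytest.approx(19.05)
    assert null_threshold([3.0, 1.0, 2.0], 1.0).threshold == 3.0
    spec = null_threshold(np.arange(1, 21), 0.95)
    assert spec.maxima.min() <= spec.threshold <= spec.maxima.max()
    with pytest.raises(ValueError):
        null_threshold([])
    with pytest.raises(ValueError):
        null_threshold([1.0])


def windows_df(rows):
    return pd.DataFrame(rows, columns=["CHROM", "WindowStart", "WindowStop"])


CM_PER_BP = 2e-6  # 2 cM/Mb


def test_classify_window_spanning_qtl_is_tp():
    qtl = pd.DataFrame({"CHROM": ["1"], "POS": [5_000_000]})
    wins = windows_df([("1", 4_900_000, 5_100_000)])
    assert classify(wins, qtl, 5.0, CM_PER_BP) == (1, 0)


def test_classify_distant_window_is_fp():
    qtl = pd.DataFrame({"CHROM": ["1"], "POS": [5_000_000]})
    wins = windows_df([("1", 10_100_000, 10_200_000)])  # 10.2 cM from QTL
    assert classify(wins, qtl, 5.0, CM_PER_BP) == (0, 1)


def test_classify_edge_within_radius_is_tp():
    qtl = pd.DataFrame({"CHROM": ["1"], "POS": [5_000_000]})
    wins = windows_df([("1", 6_000_000, 7_000_000)])  # nearest edge 2 cM away
    assert classify(wins, qtl, 5.0, CM_PER_BP) == (1, 0)


def test_classify_qtl_counted_once_per_replicate():
    qtl = pd.DataFrame({"CHROM": ["1"], "POS": [5_000_000]})
    wins = windows_df(
        [("1", 4_000_000, 4_500_000), ("1", 5_500_000, 6_000_000)]
    )
    assert classify(wins, qtl, 5.0, CM_PER_BP) == (1, 0)


def test_classify_mixed_counts_and_attribution_identity():
    qtl = pd.DataFrame({"CHROM": ["1", "2"], "POS": [5_000_000, 5_000_000]})
    wins = windows_df(
        [
            ("1", 4_900_000, 5_100_000),   # TP for QTL 1
            ("1", 40_000_000, 40_100_000), # FP
            ("2", 4_000_000, 4_100_000),   # TP for QTL 2
            ("2", 5_900_000, 6_000_000),   # same QTL again
            ("3", 1_000_000, 1_100_000),   # chromosome with no QTL: FP
        ]
    )
    det, fp = classify(wins, qtl, 5.0, CM_PER_BP)
    assert (det, fp) == (2, 2)
    # attributed windows + FPs account for every significant window
    assert fp + (len(wins) - fp) == len(wins)


def test_classify_requires_map():
    with pytest.raises(ValueError, match="genetic map"):
        classify(windows_df([]), pd.DataFrame({"CHROM": [], "POS": []}), 5.0, None)


def tiny_benchmark_inputs():
    """Deterministic synthetic FST tables with one hot region per chrom."""
    rng = np.random.default_rng(0)
    qtl = pd.DataFrame({"CHROM": ["1"], "POS": [5_000_000], "EFFECT": [1.0]})

    def fst_df(hot, seed):
        r = np.random.default_rng(seed)
        pos = np.sort(r.choice(np.arange(1, 10_000_001), 400, replace=False))
        y = r.gamma(2.0, 0.02, 400)
        if hot:
            y = y + 0.5 * np.exp(-0.5 * ((pos - 5_000_000) / 400_000.0) ** 2)
        return pd.DataFrame({"CHROM": "1", "POS": pos, "FST": y})

    selected = [(fst_df(True, s), qtl) for s in range(3)]
    null = [fst_df(False, 100 + s) for s in range(5)]
    return selected, null


def test_compare_methods_finds_planted_signal_and_recomputes_ratio():
    selected, null = tiny_benchmark_inputs()
    res = compare_methods(
        selected, null, ["spline", "distinct-25"], cm_per_bp=CM_PER_BP
    )
    by = {r.method: r for r in res}
    for r in res:
        if r.mean_false_positives > 0:
            assert r.ratio == pytest.approx(
                r.mean_detected / r.mean_false_positives
            )
    assert by["spline"].mean_detected == pytest.approx(1.0)  # planted QTL found


def test_nulls_fed_as_selected_detect_nothing():
    selected, null = tiny_benchmark_inputs()
    qtl = selected[0][1]
    null_as_selected = [(f, qtl) for f in null[:2]]
    res = compare_methods(
        null_as_selected, null[2:], ["distinct-25"], cm_per_bp=CM_PER_BP
    )
    assert res[0].mean_detected <= 1.0
    assert res[0].mean_false_positives <= 2.0


def test_uncalibrated_method_rejected():
    selected, _ = tiny_benchmark_inputs()
    with pytest.raises(ValueError, match="uncalibrated"):
        compare_methods(selected, [], ["spline"], cm_per_bp=CM_PER_BP)
    with pytest.raises(ValueError, match="unknown method"):
        method_windows("window-25", selected[0][0])


def test_scan_flags_exactly_one_of_1000():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {
            "CHROM": "1",
            "WindowStart": np.arange(1000) * 10_000 + 1,
            "WindowStop": np.arange(1000) * 10_000 + 10_001,
            "Wstat": rng.normal(size=1000),
        }
    )
    regions = scan(df, outlier_q=0.999)
    assert len(regions) == 1
    assert regions[0].windows["Wstat"].iloc[0] == df["Wstat"].max()


def test_scan_merge_rule_5mb():
    def flagged(gap_bp):
        return pd.DataFrame(
            {
                "CHROM": ["1", "1"],
                "WindowStart": [1_000_000, 1_000_000 + gap_bp],
                "WindowStop": [1_100_000, 1_100_000 + gap_bp],
                "Wstat": [9.0, 8.0],
            }
        )

    close = merge_outliers(flagged(3_000_000))  # windows 2.9 Mb apart
    assert len(close) == 1
    assert (close[0].start, close[0].stop) == (1_000_000, 4_100_000)
    assert close[0].max_w == 9.0
    far = merge_outliers(flagged(9_000_000))
    assert len(far) == 2


def test_merge_is_idempotent():
    rng = np.random.default_rng(2)
    starts = np.sort(rng.choice(np.arange(0, 200), 40, replace=False)) * 1_000_000
    df = pd.DataFrame(
        {
            "CHROM": "1",
            "WindowStart": starts,
            "WindowStop": starts + 500_000,
            "Wstat": rng.normal(size=40),
        }
    )
    once = merge_outliers(df)
    again = merge_outliers(
        pd.concat([r.windows for r in once], ignore_index=True)
    )
    assert [(r.chrom, r.start, r.stop) for r in once] == [
        (r.chrom, r.start, r.stop) for r in again
    ]


def test_run_benchmark_smoke_tiny():
    cfg = SimConfig(
        n_chrom=1,
        chrom_cm=100.0,
        chrom_bp=10_000_000,
        n_markers_per_chrom=300,
        n_qtl_per_chrom=2,
        qtl_positions_cm=(30.0, 70.0),
        n_sires=10,
        n_dams=10,
        litter_size=30,
        n_generations=8,
        burnin_popsize=80,
        burnin_generations=10,
        seed=0,
    )
    res = run_benchmark(cfg, n_selected=2, n_null=2, roster=["distinct-10"], base_seed=5)
    (r,) = res
    assert r.n_qtl_total == 2
    assert r.mean_detected <= 2
    assert r.mean_detected >= 0 and r.mean_false_positives >= 0
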