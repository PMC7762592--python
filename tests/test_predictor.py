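"""Genome-length classification, KDE density estimation, candidate reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsidkit.allometry import predict_mean
from capsidkit.predictor import (
    GenomeRecord,
    assign_t,
    candidate_report,
    classify_batch,
    default_t_grid,
    estimate_density,
    find_peaks,
)
from capsidkit.simulate import gen_genome_mixture, mixture_spec


@pytest.mark.parametrize(
    "length_bp,expected_t",
    [
        (11600, 3.0),  # smallest isolate predicted T = 3
        (11700, 3.0),
        (14300, 3.0),
        (14500, 3.0),
        (7400, 7.0 / 3.0),  # smallest MCP-encoding gut contig
        (102000, 13.0),  # crAssphage-sized genome
        (4500, 4.0 / 3.0),  # smallest gut contig
        (5400, 4.0 / 3.0),
        (497500, 39.0),  # isolate maximum on the T < 40 grid
        (294500, 27.0),  # gut-metagenome maximum
    ],
)
def test_worked_classification_examples(genome_fit, t_series, length_bp, expected_t):
    result = assign_t(length_bp, genome_fit, t_series)
    assert result.assigned_t == pytest.approx(expected_t, rel=1e-9)


def test_assignment_reports_nearest_mean_and_distance(genome_fit, t_series):
    a = assign_t(11600, genome_fit, t_series)
    assert a.nearest_mean_kbp == pytest.approx(predict_mean(genome_fit, 3.0))
    assert a.abs_distance_kbp == pytest.approx(abs(11.6 - a.nearest_mean_kbp))
    assert a.continuous_t == pytest.approx(3.0, abs=0.05)
    assert a.is_small_candidate


def test_midpoint_tie_breaks_to_smaller_t(genome_fit, t_series):
    m1 = predict_mean(genome_fit, t_series[3])
    m2 = predict_mean(genome_fit, t_series[4])
    tie = (m1 + m2) / 2.0 * 1000.0
    assert assign_t(tie, genome_fit, t_series).assigned_t == t_series[3]


def test_assignment_monotone_in_genome_length(genome_fit, t_series):
    previous = 0.0
    for bp in range(1000, 600001, 997):
        t = assign_t(bp, genome_fit, t_series).assigned_t
        assert t >= previous
        previous = t


def test_assignment_matches_midpoint_boundary_oracle(genome_fit, t_series):
    # classification regions are exactly the arithmetic-midpoint intervals of
    # consecutive model means
    means = [predict_mean(genome_fit, t) for t in t_series]

    def midpoint_oracle(kbp):
        for i in range(len(t_series) - 1):
            if kbp <= (means[i] + means[i + 1]) / 2.0:
                return t_series[i]
        return t_series[-1]

    for bp in range(500, 600001, 463):
        assert assign_t(bp, genome_fit, t_series).assigned_t == pytest.approx(
            midpoint_oracle(bp / 1000.0)
        )


@given(bp=st.integers(min_value=1, max_value=600000))
@settings(derandomize=True, max_examples=100)
def test_assignment_total_on_positive_lengths(genome_fit, t_series, bp):
    a = assign_t(bp, genome_fit, t_series)
    assert a.assigned_t in t_series
    assert a.is_small_candidate == (a.assigned_t <= 4.0 + 1e-9)


def test_assignment_input_validation(genome_fit):
    with pytest.raises(ValueError):
        assign_t(0, genome_fit)
    with pytest.raises(ValueError):
        assign_t(1000, genome_fit, [])


def test_batch_classification_and_frequency_table(genome_fit, t_series):
    records = [
        GenomeRecord("astrithr", 11600),
        GenomeRecord("P1", 11700),
        GenomeRecord("RRH1", 14300),
        GenomeRecord("bIL311", 14500),
    ]
    assignments, freq = classify_batch(records, genome_fit, t_series)
    assert all(a.assigned_t == 3.0 for a in assignments)
    assert len(freq) == 1
    assert freq.iloc[0]["t"] == 3.0
    assert freq.iloc[0]["percent"] == 100.0


def test_uniform_42kbp_batch_lands_on_t7(genome_fit, t_series):
    records = [GenomeRecord(f"g{i}", 42000) for i in range(10)]
    _, freq = classify_batch(records, genome_fit, t_series)
    assert len(freq) == 1 and freq.iloc[0]["t"] == 7.0


def test_no_small_candidates_above_30_kbp(genome_fit, t_series):
    records = [GenomeRecord(f"g{i}", bp) for i, bp in enumerate(range(31000, 300000, 9000))]
    assignments, _ = classify_batch(records, genome_fit, t_series)
    report = candidate_report(assignments)
    assert len(report.candidates) == 0


def test_candidate_report_groups_printed_small_contigs(genome_fit, t_series):
    # the reported T < 3 metagenome groups: 4.5/5.4 kbp -> 4/3 and the nine
    # 7.3-8.5 kbp genomes -> 7/3
    lengths = [4500, 5400] + [7300, 7400, 7600, 7800, 8000, 8100, 8200, 8400, 8500]
    records = [GenomeRecord(f"c{i}", bp, source="metagenome") for i, bp in enumerate(lengths)]
    assignments, _ = classify_batch(records, genome_fit, t_series)
    report = candidate_report(assignments, threshold_t=3.0)
    counts = {round(r.t, 4): r.count for r in report.counts.itertuples(index=False)}
    assert counts == {round(4.0 / 3.0, 4): 2, round(7.0 / 3.0, 4): 9}
    # sorted by t then length
    assert list(report.candidates["length_bp"][:2]) == [4500, 5400]


def test_candidate_report_threshold_extremes(genome_fit, t_series):
    records = [GenomeRecord(f"g{i}", bp) for i, bp in enumerate((5000, 42000, 160000))]
    assignments, _ = classify_batch(records, genome_fit, t_series)
    assert len(candidate_report(assignments, threshold_t=0.0).candidates) == 0
    assert len(candidate_report(assignments, threshold_t=float("inf")).candidates) == 3


def test_log_space_matching_available(genome_fit, t_series):
    linear = assign_t(10370, genome_fit, t_series)
    logged = assign_t(10370, genome_fit, t_series, log_space=True)
    assert linear.assigned_t in t_series and logged.assigned_t in t_series


# ---------------------------------------------------------------------------
# density estimation


def test_density_integrates_to_one():
    recs = gen_genome_mixture(mixture_spec("isolates", n=500, seed=3))
    est = estimate_density(recs)
    assert np.trapezoid(est.density, est.grid) == pytest.approx(1.0, abs=0.01)
    assert len(est.grid) == 512


def test_two_separated_clusters_give_two_peaks():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(20.0, 1.0, 200), rng.normal(80.0, 1.0, 200)])
    est = estimate_density(x)
    assert len(est.peaks) == 2
    locs = sorted(l for l, _ in est.peaks)
    assert abs(locs[0] - 20.0) <= est.bandwidth
    assert abs(locs[1] - 80.0) <= est.bandwidth


def test_single_cluster_gives_single_peak():
    # with a bandwidth on the order of the cluster spread the estimate is
    # unimodal (the rule-of-thumb bandwidth can leave tail-sampling wiggles)
    rng = np.random.default_rng(1)
    est = estimate_density(rng.normal(42.0, 2.0, 400), bandwidth=2.0)
    assert len(est.peaks) == 1
    assert abs(est.peaks[0][0] - 42.0) <= est.bandwidth


def test_density_rejects_degenerate_input():
    with pytest.raises(ValueError):
        estimate_density(np.array([42.0]))
    with pytest.raises(ValueError):
        estimate_density(np.array([42.0] * 10))


def test_flat_density_has_no_interior_peaks():
    est = estimate_density(np.array([10.0, 20.0]), bandwidth=50.0)
    assert find_peaks(est) == [] or len(find_peaks(est)) == 1  # single smooth bump


def test_preset_mixture_recovers_component_peaks():
    # mixture presets anchored at the reported peak locations: every
    # component mean is within one bandwidth of a KDE peak
    for preset, targets in [
        ("isolates", (18.3, 42.0, 158.9)),
        ("gut", (12.6, 42.9, 98.2, 160.8)),
    ]:
        recs = gen_genome_mixture(mixture_spec(preset, seed=0))
        est = estimate_density(recs)
        locs = [l for l, _ in est.peaks]
        for target in targets:
            assert any(abs(l - target) <= est.bandwidth for l in locs), (preset, target)
        # dominant peak is the ~42 kbp mode in both collections
        assert abs(est.peaks[0][0] - targets[1]) <= est.bandwidth
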