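import numpy as np
import pandas as pd
import pytest

from cutac.coverage import SignalMatrix
from cutac.outcome import (arm_dosage, biomarker_report, direction_check,
                           histone_vs_aneuploidy, km_logrank,
                           per_arm_null_correlation, rnaseq_arm_matrix,
                           threshold_scan, top_k_groups)

from conftest import make_tiny_genome
from cutac.genome import GeneAnnotation, build_gene_spans


def records(times, events, ids=None):
    ids = ids or [f"p{i}" for i in range(len(times))]
    return pd.DataFrame({"recurrence_months": times, "event": events},
                        index=ids)


class TestKMLogrank:
    def test_identical_groups_p_near_one(self):
        rec = records([5, 10, 15, 20] * 2, [1, 0, 1, 0] * 2)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=rec.index)
        res = km_logrank(rec, groups)
        assert res.p_value > 0.9

    def test_textbook_observed_minus_expected(self):
        # A: events at 1, 2; B: events at 3, 4. Hand O-E computation:
        # t=1: E_A=1/2; t=2: E_A=1/3; O_A=2, E_A=5/6, V=17/36
        # chi2 = (2 - 5/6)^2 / (17/36) = 2.882; p ~ 0.0895 < 0.5
        rec = records([1, 2, 3, 4], [1, 1, 1, 1])
        groups = pd.Series(["A", "A", "B", "B"], index=rec.index)
        res = km_logrank(rec, groups)
        assert res.statistic == pytest.approx(2.8824, abs=1e-3)
        assert res.p_value < 0.5

    def test_no_event_group_warns(self):
        rec = records([5, 6, 7, 8], [1, 1, 0, 0])
        groups = pd.Series(["a", "a", "b", "b"], index=rec.index)
        with pytest.warns(UserWarning):
            km_logrank(rec, groups)

    def test_km_reduces_to_empirical_survivor_without_censoring(self):
        rec = records([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        groups = pd.Series(["a", "a", "b", "b"], index=rec.index)
        res = km_logrank(rec, groups)
        curve = res.curves["a"].set_index("time")["survival"]
        assert curve.loc[1.0] == pytest.approx(0.5)
        assert curve.loc[2.0] == pytest.approx(0.0)

    def test_logrank_permutation_superuniform(self):
        rng = np.random.default_rng(0)
        rec = records(rng.exponential(20, 24).round(2),
                      (rng.random(24) < 0.7).astype(int))
        hits = 0
        for _ in range(200):
            labels = np.array(["a"] * 12 + ["b"] * 12)
            rng.shuffle(labels)
            res = km_logrank(rec, pd.Series(labels, index=rec.index))
            hits += res.p_value < 0.05
        assert hits <= 0.10 * 200  # 5% nominal, generous bound


class TestThresholdScan:
    def test_top_k_group_sizes_and_tiebreak(self):
        vals = pd.Series([3.0, 1.0, 2.0, 2.0], index=list("dcba"))
        groups = top_k_groups(vals, 2, "high")
        assert (groups == "malignant").sum() == 2
        # tie at value 2.0 between 'a' and 'b': deterministic by id
        assert groups["d"] == "malignant"
        assert groups["a"] == "malignant" and groups["b"] == "benign"

    def test_scan_shape(self):
        rng = np.random.default_rng(1)
        rec = records(rng.exponential(20, 6).round(1), [1] * 6)
        vals = pd.Series(rng.random(6), index=rec.index)
        scan = threshold_scan(rec, vals, "high", range(2, 5))
        assert list(scan["k"]) == [2, 3, 4]

    def test_constant_biomarker_flat_p(self):
        rng = np.random.default_rng(2)
        rec = records(rng.exponential(20, 10).round(1), [1] * 10)
        vals = pd.Series(np.ones(10), index=rec.index)
        scan = threshold_scan(rec, vals, "high", [5])
        # constant biomarker: grouping is arbitrary (id order); no signal
        assert scan["p"][0] > 0.05

    def test_direction_flags(self):
        rec = records([1, 2, 3, 100, 110, 120], [1, 1, 1, 0, 0, 0])
        vals = pd.Series([10, 9, 8, 1, 2, 3], index=rec.index)
        scan = threshold_scan(rec, vals, "high", [3])
        out = direction_check(rec, vals, scan, "high")
        assert bool(out["direction_ok"][0]) is True
        flipped = direction_check(rec, -vals, threshold_scan(
            rec, -vals, "high", [3]), "high")
        assert bool(flipped["direction_ok"][0]) is False


def arm_matrix(per_arm_values, genome, n_per_arm=12):
    """Matrix with n intervals per arm at the given per-sample values."""
    rows, ids = [], []
    for arm, (a_start, a_end) in {"p": (0, 6000), "q": (6000, 10_000)}.items():
        step = (a_end - a_start) // n_per_arm
        for i in range(n_per_arm):
            s = a_start + i * step
            rows.append(("chr1", s, s + 10, f"{arm}{i}", "cCRE"))
            ids.append(f"{arm}{i}")
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "id",
                                            "category"])
    data = {}
    for sample, (vp, vq) in per_arm_values.items():
        data[sample] = [vp] * n_per_arm + [vq] * n_per_arm
    values = pd.DataFrame(data).T
    values.columns = ids
    return SignalMatrix(values=values, intervals=intervals,
                        interval_kind="ccre")


class TestArmDosage:
    def test_equal_arms_neutral(self, tiny_genome):
        m = arm_matrix({"s": (2.0, 2.0)}, tiny_genome)
        dt = arm_dosage(m, tiny_genome)
        assert set(dt["call"]) == {"neutral"}
        np.testing.assert_allclose(dt["dosage"], 1.0)

    def test_half_dosage_called_loss(self, tiny_genome):
        m = arm_matrix({"s": (1.0, 2.0)}, tiny_genome)
        dt = arm_dosage(m, tiny_genome, loss_delta=0.2).set_index("arm")
        assert dt.loc["chr1p", "call"] == "loss"

    def test_scale_invariance(self, tiny_genome):
        m1 = arm_matrix({"s": (1.0, 2.0)}, tiny_genome)
        m2 = arm_matrix({"s": (10.0, 20.0)}, tiny_genome)
        d1 = arm_dosage(m1, tiny_genome)
        d2 = arm_dosage(m2, tiny_genome)
        np.testing.assert_allclose(d1["dosage"], d2["dosage"])

    def test_sparse_arm_withheld(self, tiny_genome):
        m = arm_matrix({"s": (1.0, 2.0)}, tiny_genome, n_per_arm=5)
        dt = arm_dosage(m, tiny_genome).set_index("arm")
        assert dt.loc["chr1p", "call"] is None

    def test_rnaseq_path_shares_dosage_code(self):
        genes = ([GeneAnnotation(f"p{i}", "chr1", "+", [i * 500],
                                 [i * 500 + 400]) for i in range(11)]
                 + [GeneAnnotation(f"q{i}", "chr1", "+", [6000 + i * 300],
                                   [6000 + i * 300 + 200])
                    for i in range(11)])
        g = make_tiny_genome(genes=genes, ccres=[("chr1", 10, 20, "c", "PLS")])
        build_gene_spans(g)
        counts = pd.DataFrame(
            {"s1": [100] * 11 + [50] * 11},
            index=[f"p{i}" for i in range(11)] + [f"q{i}" for i in range(11)])
        m = rnaseq_arm_matrix(counts, g)
        dt = arm_dosage(m, g, loss_delta=0.25).set_index("arm")
        assert dt.loc["chr1q", "call"] == "loss"


class TestAneuploidyCorrelations:
    def test_loss_counts_track_scores(self, tiny_genome):
        vals = {f"s{i}": ((1.0, 2.0) if i >= 5 else (2.0, 2.0))
                for i in range(8)}
        m = arm_matrix(vals, tiny_genome)
        dt = arm_dosage(m, tiny_genome)
        scores = pd.Series(np.arange(8, dtype=float),
                           index=[f"s{i}" for i in range(8)])
        out = histone_vs_aneuploidy(scores, dt)
        assert out["r_losses"] > 0.7

    def test_all_neutral_reports_nan(self, tiny_genome):
        m = arm_matrix({f"s{i}": (2.0, 2.0) for i in range(6)}, tiny_genome)
        dt = arm_dosage(m, tiny_genome)
        scores = pd.Series(np.arange(6, dtype=float),
                           index=[f"s{i}" for i in range(6)])
        out = histone_vs_aneuploidy(scores, dt)
        assert np.isnan(out["r_losses"]) and np.isnan(out["r_gains"])

    def test_per_arm_null_correlation_extremes(self, tiny_genome):
        m = arm_matrix({f"s{i}": (2.0, 2.0) for i in range(6)}, tiny_genome)
        dt = arm_dosage(m, tiny_genome)
        # chr1p null fraction increases with score; chr1q constant
        dt = dt.set_index(["sample", "arm"])
        for i in range(6):
            dt.loc[(f"s{i}", "chr1p"), "null_fraction"] = i / 10
            dt.loc[(f"s{i}", "chr1q"), "null_fraction"] = 0.2
        dt = dt.reset_index()
        scores = pd.Series(np.arange(6, dtype=float),
                           index=[f"s{i}" for i in range(6)])
        out = per_arm_null_correlation(scores, dt, n_bootstrap=100,
                                       seed=0).set_index("arm")
        assert out.loc["chr1p", "rho"] == pytest.approx(1.0)
        assert out.loc["chr1p", "sd"] >= 0.0
        assert np.isnan(out.loc["chr1q", "rho"])
        assert out.attrs["n_positive"] == 1


class TestBiomarkerReport:
    def test_side_by_side_table(self):
        rng = np.random.default_rng(3)
        rec = records(rng.exponential(30, 12).round(1),
                      (rng.random(12) < 0.8).astype(int))
        good = pd.Series(-rec["recurrence_months"].to_numpy(),
                         index=rec.index)
        noise = pd.Series(rng.random(12), index=rec.index)
        rep = biomarker_report({"signal": (good, "high"),
                                "noise": (noise, "high")}, rec, [4, 6])
        assert set(rep["biomarker"]) == {"signal", "noise"}
        assert len(rep) == 4
        p_signal = rep[(rep.biomarker == "signal") & (rep.k == 6)]["p"].iloc[0]
        p_noise = rep[(rep.biomarker == "noise") & (rep.k == 6)]["p"].iloc[0]
        assert p_signal < p_noise
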