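import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mgmin import (MethylMatrix, QcParams, SimulationSpec, count_true_positives,
                   detect_dmps, deviation_summary, distribution_distance,
                   mean_abs_diff, moderated_t, ppv, probe_sd,
                   qc_filter_samples, simulate_array)


def _matrix(values, types, scale="beta"):
    df = pd.DataFrame(values)
    df.index = [f"cg{i:02d}" for i in range(len(df))]
    pt = pd.Series(types, index=df.index)
    return MethylMatrix(values=df, probe_type=pt, scale=scale)


class TestProbeSd:
    def test_identical_columns_zero_sd(self):
        m = _matrix({"a": [0.1, 0.4], "b": [0.1, 0.4], "c": [0.1, 0.4]},
                    ["I", "II"])
        assert np.allclose(probe_sd(m, ["a", "b", "c"]), 0.0)

    def test_closed_form(self):
        m = _matrix({"a": [0.1], "b": [0.2], "c": [0.3]}, ["II"])
        assert probe_sd(m, ["a", "b", "c"]).iloc[0] == pytest.approx(0.1)

    def test_requires_two_samples(self):
        m = _matrix({"a": [0.1]}, ["II"])
        with pytest.raises(ValueError):
            probe_sd(m, ["a"])
        with pytest.raises(ValueError):
            probe_sd(m, ["a", "nope"])


class TestMeanAbsDiff:
    def test_identical_samples_zero(self):
        m = _matrix({"a": [0.1, 0.5], "b": [0.1, 0.5]}, ["II", "II"])
        assert mean_abs_diff(m, "a", "b") == 0.0

    def test_hand_value_and_type_restriction(self):
        m = _matrix({"a": [0.9, 0.5, 0.1], "b": [0.2, 0.6, 0.4]},
                    ["I", "II", "II"])
        # only the two type II probes count: diffs 0.1 and 0.3
        assert mean_abs_diff(m, "a", "b") == pytest.approx(0.2)

    def test_missing_sample_rejected(self):
        m = _matrix({"a": [0.1]}, ["II"])
        with pytest.raises(ValueError):
            mean_abs_diff(m, "a", "zz")

    def test_m_scale_converts_to_beta(self):
        m = _matrix({"a": [0.0], "b": [2.0]}, ["II"], scale="m")
        # beta(0)=0.5, beta(2)=0.8
        assert mean_abs_diff(m, "a", "b") == pytest.approx(0.3)


class TestDistributionDistance:
    def test_identical_samples(self):
        x = np.random.default_rng(0).normal(size=200)
        assert distribution_distance(x, x) == 0.0

    def test_disjoint_supports(self):
        assert distribution_distance([0.0, 1.0], [5.0, 6.0]) == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distribution_distance([], [1.0])


class TestDeviationSummary:
    def test_zero_when_equal(self):
        assert deviation_summary([0.2, 0.4], [0.2, 0.4]) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        mx, mean, rmse = deviation_summary([0.5, 0.6], [0.2, 0.2])
        assert mx == pytest.approx(0.4)
        assert mean == pytest.approx(0.35)
        assert rmse == pytest.approx(np.sqrt((0.09 + 0.16) / 2))

    def test_single_element_collapses(self):
        mx, mean, rmse = deviation_summary([0.7], [0.4])
        assert mx == mean == pytest.approx(rmse) == pytest.approx(0.3)

    def test_mean_le_rmse_le_max(self):
        rng = np.random.default_rng(1)
        v, r = rng.uniform(size=50), rng.uniform(size=50)
        mx, mean, rmse = deviation_summary(v, r)
        assert mean <= rmse <= mx

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            deviation_summary([0.1], [0.1, 0.2])


class TestModeratedT:
    def test_matches_limma_reference(self, tmp_path):
        """The in-package moderated t reproduces Bioconductor limma."""
        rng = np.random.default_rng(42)
        vals = rng.normal(0, 1, (150, 6)) * rng.uniform(0.5, 2, 150)[:, None]
        vals[:15, 3:] += 1.5
        labels = np.array([0, 0, 0, 1, 1, 1])
        stat, p, _, d0, s0_sq = moderated_t(vals, labels)

        mat = tmp_path / "m.tsv"
        pd.DataFrame(vals).to_csv(mat, sep="\t")
        rscript = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{mat}", row.names=1))
            design <- model.matrix(~ factor(c(0,0,0,1,1,1)))
            fit <- eBayes(lmFit(x, design))
            write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2],
                                   d0=fit$df.prior, s0=fit$s2.prior),
                        "{tmp_path / 'out.tsv'}", sep="\\t", quote=FALSE)
        """)
        (tmp_path / "check.R").write_text(rscript)
        subprocess.run(["Rscript", str(tmp_path / "check.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert np.allclose(stat, ref["t"], atol=1e-8)
        assert np.allclose(p, ref["p"], atol=1e-10)
        assert d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-6)

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            moderated_t(np.zeros((5, 3)), np.array([0, 0, 1]))


@pytest.fixture(scope="module")
def spiked_sim():
    spec = SimulationSpec(n_typeI=1_000, n_typeII=4_000, n_samples=10,
                          replicate_noise_sd=0.5, n_spiked=200,
                          effect_size=2.0,
                          group_labels=(0,) * 5 + (1,) * 5, seed=13)
    return simulate_array(spec)


class TestDetectDmps:
    def test_recovers_spiked_probes(self, spiked_sim):
        matrix, truth = spiked_sim
        res = detect_dmps(matrix, truth["group_labels"], fdr=0.35)
        spiked = pd.Index(truth["spiked_probes"])
        recovered = spiked.intersection(res.dmp_ids)
        assert len(recovered) / len(spiked) >= 0.9

    def test_invariant_to_column_order_within_groups(self, spiked_sim):
        matrix, truth = spiked_sim
        res1 = detect_dmps(matrix, truth["group_labels"], fdr=0.35)
        perm = [1, 0, 2, 4, 3, 9, 8, 7, 6, 5]
        shuffled = matrix.copy_with(matrix.values.iloc[:, perm])
        res2 = detect_dmps(shuffled, np.array(truth["group_labels"])[perm],
                           fdr=0.35)
        assert np.allclose(res1.table["stat"], res2.table["stat"], atol=1e-9)

    def test_constant_probe_is_na_and_never_dmp(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, (50, 6))
        vals[7] = 3.14
        m = _matrix({f"s{j}": vals[:, j] for j in range(6)},
                    ["II"] * 50, scale="m")
        res = detect_dmps(m, [0, 0, 0, 1, 1, 1])
        row = res.table.iloc[7]
        assert np.isnan(row["p"]) and not row["is_dmp"]

    def test_q_values_monotone_in_p(self, spiked_sim):
        matrix, truth = spiked_sim
        res = detect_dmps(matrix, truth["group_labels"])
        t = res.table.dropna().sort_values("p")
        assert np.all(np.diff(t["q"]) >= -1e-12)

    def test_count_true_positives_requires_concordant_sign(self, spiked_sim):
        matrix, truth = spiked_sim
        res = detect_dmps(matrix, truth["group_labels"], fdr=0.35)
        n_tp = count_true_positives(res, res)
        assert n_tp == res.n_dmp  # self-validation is perfect
        flipped = res.table.copy()
        flipped["stat"] = -flipped["stat"]
        import dataclasses
        res_flip = dataclasses.replace(res, table=flipped)
        assert count_true_positives(res, res_flip) == 0
        assert count_true_positives(res, res_flip, require_sign=False) == res.n_dmp


class TestPpv:
    @pytest.mark.parametrize("n_tp, n_dmp, expected",
                             [(16, 51, 0.31), (37, 220, 0.17), (0, 7, 0.0)])
    def test_rounded_values(self, n_tp, n_dmp, expected):
        value, rounded = ppv(n_tp, n_dmp)
        assert rounded == expected
        assert value == pytest.approx(n_tp / n_dmp)

    def test_product_identity(self):
        value, _ = ppv(37, 220)
        assert value * 220 == pytest.approx(37)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            ppv(1, 0)
        with pytest.raises(ValueError):
            ppv(5, 3)


class TestQcFilter:
    def _det(self, fracs, n_probes=100):
        """Detection-p table where sample j has fracs[j] bad probes at p=1."""
        cols = {}
        for j, f in enumerate(fracs):
            n_bad = int(round(f * n_probes))
            cols[f"s{j}"] = np.r_[np.ones(n_bad), np.zeros(n_probes - n_bad)]
        return pd.DataFrame(cols)

    def test_all_good_all_kept(self):
        kept, r = qc_filter_samples(self._det([0.0, 0.0]),
                                    QcParams(tau_p=0.01, tau_r=0.3))
        assert kept == ["s0", "s1"] and r == 1.0

    def test_over_threshold_dropped(self):
        kept, r = qc_filter_samples(self._det([0.31, 0.05]),
                                    QcParams(tau_p=0.01, tau_r=0.3))
        assert kept == ["s1"] and r == 0.5

    def test_boundary_fraction_kept(self):
        # exactly tau_r bad probes: "more than" is strict, sample stays
        kept, _ = qc_filter_samples(self._det([0.30]),
                                    QcParams(tau_p=0.01, tau_r=0.3))
        assert kept == ["s0"]

    def test_monotone_in_thresholds(self):
        det = pd.DataFrame(np.random.default_rng(3).uniform(size=(200, 6)))
        det.columns = [f"s{j}" for j in range(6)]
        kept_loose, _ = qc_filter_samples(det, QcParams(0.9, 0.3))
        kept_tight, _ = qc_filter_samples(det, QcParams(0.5, 0.3))
        assert set(kept_tight) <= set(kept_loose)
        kept_tight_r, _ = qc_filter_samples(det, QcParams(0.9, 0.1))
        assert set(kept_tight_r) <= set(kept_loose)

    def test_p_out_of_range_rejected(self):
        det = pd.DataFrame({"s0": [0.5, 1.2]})
        with pytest.raises(ValueError):
            qc_filter_samples(det, QcParams(0.01, 0.3))

    def test_params_validated(self):
        with pytest.raises(ValueError):
            QcParams(tau_p=0.0, tau_r=0.3)
        with pytest.raises(ValueError):
            QcParams(tau_p=0.01, tau_r=0.4)
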