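import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pepkit.epochs import EpochSet, Epoch
from pepkit.simulate import SubjectProfile
from pepkit.stats import (
    cohens_d,
    compute_peak_magnitude,
    compute_rms,
    split_plot_anova,
    summarize_rms,
    tukey_hsd,
)


class TestRms:
    @pytest.mark.parametrize(
        "samples,expected",
        [
            (np.zeros(10), 0.0),
            (np.full(7, -3.0), 3.0),
            (np.array([3.0, -4.0, 3.0, -4.0]), np.sqrt(12.5)),
        ],
    )
    def test_closed_forms(self, samples, expected):
        assert compute_rms(samples) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1, max_size=64,
        )
    )
    def test_matches_loop_oracle(self, values):
        acc = 0.0
        for v in values:
            acc += v * v
        expected = (acc / len(values)) ** 0.5
        assert compute_rms(np.array(values)) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_rms(np.array([]))


class TestPeakMagnitude:
    def test_positive_peak(self):
        pm = compute_peak_magnitude(np.array([0.1, 2.7, -5.0]))
        assert pm.value == 2.7 and pm.positive_peak

    def test_all_negative_flags_missing_positive_peak(self):
        pm = compute_peak_magnitude(np.array([-3.0, -0.5, -2.0]))
        assert pm.value == -0.5 and not pm.positive_peak

    def test_injected_amplitude_recovered_noise_free(self):
        from pepkit.simulate import simulate_pep_waveform

        w = simulate_pep_waveform(100.0, 4.2, 130.0)
        epoch = np.zeros(300)
        epoch[: len(w)] = w[:300]
        assert compute_peak_magnitude(epoch).value == pytest.approx(4.2, abs=1e-12)


def _normalized_epoch(subject, channel, trial, label, samples):
    return Epoch(
        subject_id=subject, trial_index=trial, channel_name=channel,
        analysis_label=label, samples=np.asarray(samples, dtype=float),
        baseline_mean=0.0, baseline_sd=1.0, state="normalized",
    )


class TestSummarizeRms:
    def test_row_structure_and_epoch_counts(self):
        es = EpochSet()
        profiles = {"S01": SubjectProfile("S01", "young", "male", 1.0)}
        for trial in (1, 16):
            es.add(_normalized_epoch("S01", "Cz", trial, "unpredictable", np.full(300, 2.0)))
        for trial in (6, 7, 8):
            es.add(_normalized_epoch("S01", "Cz", trial, "predictable", np.full(300, 1.0)))
        table = summarize_rms(es, profiles)
        assert len(table) == 2
        u = table[table.condition == "unpredictable"].iloc[0]
        p = table[table.condition == "predictable"].iloc[0]
        assert u.n_epochs == 2 and p.n_epochs == 3
        assert u.mean_rms == pytest.approx(2.0)
        assert p.mean_rms == pytest.approx(1.0)
        assert u.mean_peak == pytest.approx(2.0)

    def test_identical_epochs_mean_rms_is_their_rms(self):
        es = EpochSet()
        profiles = {"S01": SubjectProfile("S01", "young", "male", 1.0)}
        samples = np.array([3.0, -4.0] * 150)
        for trial, label in ((1, "unpredictable"), (6, "predictable")):
            es.add(_normalized_epoch("S01", "mastoid", trial, label, samples))
        table = summarize_rms(es, profiles)
        assert np.allclose(table.mean_rms, np.sqrt(12.5))

    def test_invalid_and_unnormalized_epochs_rejected_or_skipped(self):
        es = EpochSet()
        profiles = {"S01": SubjectProfile("S01", "young", "male", 1.0)}
        bad = _normalized_epoch("S01", "Cz", 1, "unpredictable", np.ones(300))
        object.__setattr__(bad, "state", "corrected")
        es.add(bad)
        with pytest.raises(ValueError, match="normalized"):
            summarize_rms(es, profiles)


def _rms_table(rng, n_per_cell=3, cond_shift=0.3, channel="Cz"):
    rows = []
    i = 0
    for age in ("young", "elder"):
        for sex in ("male", "female"):
            for _ in range(n_per_cell):
                i += 1
                base = rng.normal(1.0, 0.3)
                for cond, shift in (("unpredictable", cond_shift), ("predictable", 0.0)):
                    rows.append(
                        dict(
                            subject_id=f"S{i:02d}", age_group=age, sex=sex,
                            channel=channel, condition=cond,
                            mean_rms=base + shift + rng.normal(0, 0.2),
                            n_epochs=5, mean_peak=1.0,
                        )
                    )
    return pd.DataFrame(rows)


def _brute_force_split_plot(table, channel):
    """Independent oracle: textbook balanced split-plot sums of squares."""
    wide = table[table.channel == channel].pivot_table(
        index=["subject_id", "age_group", "sex"], columns="condition",
        values="mean_rms",
    ).reset_index()
    y = wide[["unpredictable", "predictable"]].to_numpy()  # subjects x cond
    n_subj, n_cond = y.shape
    grand = y.mean()
    cells = wide.groupby(["age_group", "sex"])
    n_cell = cells.size().iloc[0]

    subj_mean = y.mean(axis=1)
    # between stratum
    ss_cells, ss_age, ss_sex = 0.0, 0.0, 0.0
    cell_means = cells.apply(
        lambda g: y[g.index].mean(), include_groups=False
    )
    age_means = {
        a: subj_mean[wide.age_group == a].mean() for a in ("young", "elder")
    }
    sex_means = {s: subj_mean[wide.sex == s].mean() for s in ("male", "female")}
    ss_age = n_cond * n_cell * 2 * sum(
        (m - grand) ** 2 for m in age_means.values()
    )
    ss_sex = n_cond * n_cell * 2 * sum(
        (m - grand) ** 2 for m in sex_means.values()
    )
    ss_cells = n_cond * n_cell * sum(
        (m - grand) ** 2 for m in cell_means
    )
    ss_agesex = ss_cells - ss_age - ss_sex
    ss_subj_within = n_cond * sum(
        (subj_mean[i] - cell_means[(wide.age_group[i], wide.sex[i])]) ** 2
        for i in range(n_subj)
    )
    df_between_err = n_subj - 4

    # within stratum, built from difference scores (2-level within factor)
    d = y[:, 0] - y[:, 1]
    dg = d.mean()
    cell_d = {k: d[g.index].mean() for k, g in cells}
    age_d = {a: d[wide.age_group == a].mean() for a in ("young", "elder")}
    sex_d = {s: d[wide.sex == s].mean() for s in ("male", "female")}
    ss_cond = n_subj * dg**2 / 2  # sum over cond of n*(m_c - grand)^2 == n*d^2/2
    ss_cond_age = 2 * n_cell * sum((v - dg) ** 2 for v in age_d.values()) / 2
    ss_cond_sex = 2 * n_cell * sum((v - dg) ** 2 for v in sex_d.values()) / 2
    ss_cond_cells = n_cell * sum((v - dg) ** 2 for v in cell_d.values()) / 2
    ss_cond_agesex = ss_cond_cells - ss_cond_age - ss_cond_sex
    ss_within_err = sum(
        (d[i] - cell_d[(wide.age_group[i], wide.sex[i])]) ** 2
        for i in range(n_subj)
    ) / 2
    df_within_err = n_subj - 4

    out = {}
    ms_b = ss_subj_within / df_between_err
    ms_w = ss_within_err / df_within_err
    for name, ss, ms_err, dfe in (
        ("age", ss_age, ms_b, df_between_err),
        ("sex", ss_sex, ms_b, df_between_err),
        ("age:sex", ss_agesex, ms_b, df_between_err),
        ("condition", ss_cond, ms_w, df_within_err),
        ("condition:age", ss_cond_age, ms_w, df_within_err),
        ("condition:sex", ss_cond_sex, ms_w, df_within_err),
        ("condition:age:sex", ss_cond_agesex, ms_w, df_within_err),
    ):
        F = ss / ms_err
        out[name] = (F, float(sps.f.sf(F, 1, dfe)))
    return out


class TestSplitPlotAnova:
    def test_balanced_df_pattern(self):
        table = _rms_table(np.random.default_rng(0), n_per_cell=10)
        aov = split_plot_anova(table, "Cz")
        assert set(aov.df_den) == {36}  # 40 subjects - 4 cells
        assert set(aov.df_num) == {1}
        assert len(aov) == 7
        assert set(aov.loc[aov.stratum == "between", "effect"]) == {
            "age", "sex", "age:sex",
        }

    def test_zero_condition_effect_gives_zero_f(self):
        rows = []
        i = 0
        for age in ("young", "elder"):
            for sex in ("male", "female"):
                for k in range(3):
                    i += 1
                    base = 1.0 + 0.1 * i
                    for cond in ("unpredictable", "predictable"):
                        rows.append(
                            dict(subject_id=f"S{i}", age_group=age, sex=sex,
                                 channel="Cz", condition=cond, mean_rms=base,
                                 n_epochs=3, mean_peak=1.0)
                        )
        aov = split_plot_anova(pd.DataFrame(rows), "Cz")
        cond = aov[aov.effect == "condition"].iloc[0]
        assert cond.F == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_oracle(self):
        table = _rms_table(np.random.default_rng(7), n_per_cell=3)
        aov = split_plot_anova(table, "Cz").set_index("effect")
        oracle = _brute_force_split_plot(table, "Cz")
        for effect, (F, p) in oracle.items():
            assert aov.loc[effect, "F"] == pytest.approx(F, rel=1e-8), effect
            assert aov.loc[effect, "p"] == pytest.approx(p, rel=1e-8), effect

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R is part of the analysis environment")
    def test_matches_r_aov_oracle(self, tmp_path):
        """Independent cross-check against base-R aov with Error(subject/cond)."""
        table = _rms_table(np.random.default_rng(42), n_per_cell=3)
        csv = tmp_path / "d.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            f'd <- read.csv("{csv}")\n'
            'd$age <- factor(d$age_group); d$sex <- factor(d$sex)\n'
            'd$cond <- factor(d$condition); d$subject <- factor(d$subject_id)\n'
            'a <- aov(mean_rms ~ age*sex*cond + Error(subject/cond), data=d)\n'
            's <- summary(a)\n'
            'for (nm in names(s)) { t <- s[[nm]][[1]]\n'
            '  for (r in rownames(t)) cat(trimws(r), t[r,"F value"], "\\n") }\n'
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        r_f = {}
        names = {
            "age": "age", "sex": "sex", "age:sex": "age:sex",
            "cond": "condition", "age:cond": "condition:age",
            "sex:cond": "condition:sex", "age:sex:cond": "condition:age:sex",
        }
        for line in res.stdout.splitlines():
            parts = line.split()
            if len(parts) == 2 and parts[0] in names and parts[1] != "NA":
                r_f[names[parts[0]]] = float(parts[1])
        assert len(r_f) == 7
        aov = split_plot_anova(table, "Cz").set_index("effect")
        for effect, F in r_f.items():
            assert aov.loc[effect, "F"] == pytest.approx(F, rel=1e-5), effect

    def test_listwise_drop_reduces_df(self):
        table = _rms_table(np.random.default_rng(1), n_per_cell=4)
        # remove one condition row: that subject drops listwise
        table = table.drop(table.index[0])
        aov = split_plot_anova(table, "Cz")
        assert set(aov.df_den) == {16 - 1 - 4}

    def test_sparse_cells_rejected(self):
        table = _rms_table(np.random.default_rng(2), n_per_cell=1)
        with pytest.raises(ValueError, match=">= 2 subjects"):
            split_plot_anova(table, "Cz")


class TestTukeyHsd:
    def test_identical_means_give_q_zero_p_one(self):
        res = tukey_hsd({"a": 1.0, "b": 1.0}, mse=0.5, df=10,
                        n_per_cell={"a": 5, "b": 5})
        assert res[0].q == 0.0
        assert res[0].p_adjusted == pytest.approx(1.0)
        assert not res[0].significant

    def test_two_groups_equal_pooled_t_test(self):
        """With k=2 the studentized range is sqrt(2)|t|, so Tukey-adjusted p
        equals the two-sided pooled t-test p."""
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 8), rng.normal(0.9, 1, 8)
        mse = ((a.var(ddof=1) + b.var(ddof=1)) / 2)
        res = tukey_hsd(
            {"a": a.mean(), "b": b.mean()}, mse=mse, df=14,
            n_per_cell={"a": 8, "b": 8},
        )
        t_p = sps.ttest_ind(a, b).pvalue
        assert res[0].p_adjusted == pytest.approx(t_p, rel=1e-10)

    def test_matches_pingouin_pairwise_tukey(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "y": np.concatenate(
                    [rng.normal(m, 1.0, 6) for m in (0.0, 0.8, 1.5)]
                ),
                "g": np.repeat(["a", "b", "c"], 6),
            }
        )
        ref = pingouin.pairwise_tukey(data=df, dv="y", between="g")
        cells = df.groupby("g")["y"]
        means = cells.mean().to_dict()
        ns = cells.size().to_dict()
        mse = df.groupby("g")["y"].apply(lambda g: ((g - g.mean()) ** 2).sum()).sum() / (18 - 3)
        mine = {
            frozenset(r.pair): r.p_adjusted
            for r in tukey_hsd(means, mse, 15, ns)
        }
        for _, row in ref.iterrows():
            key = frozenset((row["A"], row["B"]))
            assert mine[key] == pytest.approx(row["p_tukey"], abs=1e-8)

    def test_degenerate_mse_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            tukey_hsd({"a": 1.0, "b": 2.0}, mse=0.0, df=5,
                      n_per_cell={"a": 3, "b": 3})


class TestCohensD:
    def test_identical_groups_give_zero(self):
        rows = []
        for i, age in enumerate(("young", "elder")):
            for j in range(3):
                for cond in ("unpredictable", "predictable"):
                    rows.append(
                        dict(subject_id=f"{age}{j}", age_group=age,
                             sex="male" if j else "female", channel="Cz",
                             condition=cond, mean_rms=float(j), n_epochs=2,
                             mean_peak=1.0)
                    )
        d = cohens_d(pd.DataFrame(rows), "age", "Cz")
        assert d.cohens_d == pytest.approx(0.0, abs=1e-12)
        assert d.definition == "between-pooled"

    def test_unit_difference_unit_sd_gives_one(self):
        x = 1.0 / np.sqrt(2.0)
        rows = []
        for sid, age, vals in (
            ("a1", "elder", [1 + x, 1 - x]),
            ("a2", "young", [x, -x]),
        ):
            for j, v in enumerate(vals):
                for cond in ("unpredictable", "predictable"):
                    rows.append(
                        dict(subject_id=f"{sid}_{j}", age_group=age,
                             sex="male" if j else "female", channel="Cz",
                             condition=cond, mean_rms=v, n_epochs=2,
                             mean_peak=1.0)
                    )
        d = cohens_d(pd.DataFrame(rows), "age", "Cz")
        assert d.cohens_d == pytest.approx(1.0, rel=1e-12)

    def test_condition_d_uses_pooled_column_sd(self):
        table = _rms_table(np.random.default_rng(11), n_per_cell=5)
        d = cohens_d(table, "condition", "Cz")
        wide = table.pivot_table(
            index="subject_id", columns="condition", values="mean_rms"
        )
        u, p = wide["unpredictable"], wide["predictable"]
        expected = (u - p).mean() / np.sqrt((u.var(ddof=1) + p.var(ddof=1)) / 2)
        assert d.cohens_d == pytest.approx(expected, rel=1e-12)
        assert d.definition == "within-subject"
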