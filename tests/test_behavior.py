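import numpy as np
import pandas as pd
import pytest

from abastream.behavior import (DIALECT_COLUMNS, ExclusionResult,
                                analyze_glp2, apply_exclusions,
                                read_durations, rm_anova_oneway,
                                rm_anova_twoway, subject_normalize,
                                write_durations)
from abastream.synth_behavior import EffectSpec, generate_cohort


def trial_frame(durations, subject="S01", rep=1, delta_f=5.0,
                first_percept="integrated"):
    rows, t = [], 0.0
    percepts = ["integrated", "segregated"]
    if first_percept != "integrated":
        percepts = percepts[::-1]
    for i, d in enumerate(durations):
        rows.append({"subject": subject, "repetition": rep,
                     "delta_f": delta_f, "onset_s": t, "duration_s": d,
                     "percept": percepts[i % 2], "is_first": i == 0,
                     "is_incomplete": i == len(durations) - 1})
        t += d
    return pd.DataFrame(rows, columns=list(DIALECT_COLUMNS))


class TestIO:
    def test_hand_written_csv_loads_with_flags(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text(
            "subject,repetition,delta_f,onset_s,duration_s,percept,"
            "is_first,is_incomplete\n"
            "S01,1,5,0.0,8.0,integrated,True,False\n"
            "S01,1,5,8.0,4.0,segregated,False,False\n"
            "S01,1,5,12.0,5.0,integrated,False,True\n")
        frame = read_durations(path)
        assert frame["duration_s"].tolist() == [8.0, 4.0, 5.0]
        assert frame["is_first"].tolist() == [True, False, False]
        assert frame["is_incomplete"].tolist() == [False, False, True]

    def test_csv_and_mat_round_trips_agree(self, tmp_path, cohort):
        write_durations(cohort, tmp_path / "c.csv")
        write_durations(cohort, tmp_path / "c.mat", dialect="mat")
        a = read_durations(tmp_path / "c.csv")
        b = read_durations(tmp_path / "c.mat", dialect="mat")
        for col in ("duration_s", "delta_f", "onset_s"):
            assert np.allclose(a[col], b[col])
            assert np.allclose(a[col], cohort[col])
        assert (a["percept"].to_numpy() == b["percept"].to_numpy()).all()

    def test_distinct_diagnostics(self, tmp_path):
        bad1 = trial_frame([3.0, 2.0, 1.0]).drop(columns=["percept"])
        bad1.to_csv(tmp_path / "m.csv", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_durations(tmp_path / "m.csv")

        bad2 = trial_frame([3.0, 2.0, 1.0], delta_f=4.0)
        bad2.to_csv(tmp_path / "df.csv", index=False)
        with pytest.raises(ValueError, match="unknown delta_f"):
            read_durations(tmp_path / "df.csv")

        bad3 = trial_frame([3.0, -2.0, 1.0])
        bad3.to_csv(tmp_path / "neg.csv", index=False)
        with pytest.raises(ValueError, match="non-positive durations"):
            read_durations(tmp_path / "neg.csv")


class TestExclusions:
    def test_rule_application(self):
        frame = trial_frame([8.0, 0.3, 4.0, 5.0, 7.0])
        out = apply_exclusions(frame)
        assert sorted(out.frame["duration_s"]) == [4.0, 5.0]
        rules = out.report["rule"].value_counts().to_dict()
        assert rules["final-incomplete"] == 1
        assert rules["first-duration"] == 1
        assert rules["shorter-than-0.5s"] == 1

    def test_constant_long_switcher_flagged_as_outlier(self, cohort):
        slow = pd.concat([trial_frame([50.0] * 6, subject="SLOW", rep=r,
                                      delta_f=df)
                          for r in (1, 2, 3) for df in (1, 2, 3, 5, 7, 9, 11, 15)],
                         ignore_index=True)
        out = apply_exclusions(pd.concat([cohort, slow], ignore_index=True))
        assert "SLOW" in out.outlier_subjects
        # flagged, not dropped
        assert "SLOW" in set(out.frame["subject"])
        out2 = apply_exclusions(pd.concat([cohort, slow], ignore_index=True),
                                drop_outliers=True)
        assert "SLOW" not in set(out2.frame["subject"])

    def test_empty_trial_reported_not_fatal(self):
        frame = trial_frame([5.0])         # single incomplete duration
        out = apply_exclusions(frame)
        assert out.frame.empty
        assert len(out.report) == 1


class TestNormalization:
    def test_single_duration_identity(self):
        frame = trial_frame([2.0, 6.0, 1.0])   # keeps only the 6.0
        summary = subject_normalize(apply_exclusions(frame))
        assert summary.t_glob["S01"] == 6.0
        row = summary.per_subject.iloc[0]
        assert row["nbar_seg"] == pytest.approx(1.0)
        assert np.isnan(row["nbar_int"])

    def test_scale_invariance(self, cohort):
        sub = cohort[cohort["subject"].isin(["S01", "S02", "S03"])]
        scaled = sub.assign(duration_s=sub["duration_s"] * 3.0,
                            onset_s=sub["onset_s"] * 3.0)
        a = subject_normalize(apply_exclusions(sub, min_duration=0.0))
        b = subject_normalize(apply_exclusions(scaled, min_duration=0.0))
        pd.testing.assert_frame_equal(a.per_subject, b.per_subject)

    def test_group_mean_matches_brute_force_sum(self):
        trials = []
        for s, scale in zip(("S01", "S02", "S03"), (1.0, 2.0, 0.5)):
            trials.append(trial_frame(
                [x * scale for x in (9.0, 4.0, 6.0, 2.0, 5.0)], subject=s))
        frame = pd.concat(trials, ignore_index=True)
        excl = apply_exclusions(frame)
        summary = subject_normalize(excl)
        # brute force: per subject retained durations are (4, 6, 2)*scale
        # with percepts (seg, int, seg); t_glob = 4*scale
        expected_int = np.mean([6.0 / 4.0] * 3)
        expected_seg = np.mean([3.0 / 4.0] * 3)
        grp = summary.group.iloc[0]
        assert grp["nbar_int_mean"] == pytest.approx(expected_int)
        assert grp["nbar_seg_mean"] == pytest.approx(expected_seg)

    def test_idempotence(self, cohort):
        excl = apply_exclusions(cohort)
        once = subject_normalize(excl)
        renorm = excl.frame.merge(excl.t_glob, on="subject")
        renorm["duration_s"] = renorm["duration_s"] / renorm["t_glob"]
        twice = subject_normalize(
            ExclusionResult(frame=renorm, report=pd.DataFrame(),
                            t_glob=renorm.groupby("subject")["duration_s"].mean(),
                            outlier_subjects=[]))
        assert np.allclose(twice.t_glob, 1.0)
        pd.testing.assert_frame_equal(
            once.per_subject, twice.per_subject, atol=1e-12)


class TestGLP2:
    def test_null_cohort_has_zero_eta(self):
        coh = generate_cohort(n_subjects=6, effect=EffectSpec(branch_slope=0.0),
                              seed=3)
        summary = subject_normalize(apply_exclusions(coh))
        out = analyze_glp2(summary)
        assert np.all(np.abs(out["eta_group"]["mean"]) < 0.25)

    def test_crossover_cohort_positive_eta_away_from_crossover(self):
        coh = generate_cohort(n_subjects=10, effect=EffectSpec(branch_slope=0.8),
                              seed=4)
        summary = subject_normalize(apply_exclusions(coh))
        out = analyze_glp2(summary)
        g = out["eta_group"].set_index("delta_f")["mean"]
        assert g[1.0] > 0 and g[15.0] > 0
        assert abs(g[5.0]) < abs(g[1.0])

    def test_missing_equidominance_condition(self, cohort):
        summary = subject_normalize(apply_exclusions(cohort))
        with pytest.raises(ValueError):
            analyze_glp2(summary, eq_df=4.0)


def textbook_oneway_ss(wide: np.ndarray):
    """Brute-force within-subject sums of squares from the defining formulas."""
    n, c = wide.shape
    grand = wide.mean()
    ss_cond = n * ((wide.mean(axis=0) - grand) ** 2).sum()
    ss_subj = c * ((wide.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((wide - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    ms_cond = ss_cond / (c - 1)
    ms_err = ss_err / ((c - 1) * (n - 1))
    return ss_cond, ss_err, ms_cond / ms_err


class TestOneWayANOVA:
    def test_no_condition_effect_gives_zero_F(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(6, 4))
        scores -= scores.mean(axis=0, keepdims=True)   # kill condition effect
        res = rm_anova_oneway(pd.DataFrame(scores))
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p == 1.0

    def test_matches_brute_force_sums_of_squares(self):
        table = np.array([[3.0, 5.0, 4.0],
                          [4.0, 7.0, 6.0],
                          [2.0, 4.0, 5.0],
                          [5.0, 8.0, 6.0]])
        res = rm_anova_oneway(pd.DataFrame(table))
        ss_cond, ss_err, F = textbook_oneway_ss(table)
        assert res.ss == pytest.approx(ss_cond, abs=1e-8)
        assert res.ss_error == pytest.approx(ss_err, abs=1e-8)
        assert res.F == pytest.approx(F, abs=1e-8)
        assert (res.df1, res.df2) == (2, 6)

    def test_gg_epsilon_is_one_under_exact_sphericity(self):
        """Data built so the sample covariance is compound symmetric."""
        rng = np.random.default_rng(1)
        n, c = 30, 4
        target = 0.5 * np.eye(c) + 0.5            # CS covariance
        x = rng.normal(size=(n, c))
        x -= x.mean(axis=0)
        cov = x.T @ x / (n - 1)
        whiten = np.linalg.inv(np.linalg.cholesky(cov))
        color = np.linalg.cholesky(target)
        y = x @ whiten.T @ color.T + rng.normal(size=(n, 1))
        res = rm_anova_oneway(pd.DataFrame(y))
        assert res.gg_epsilon == pytest.approx(1.0, abs=1e-10)
        assert res.mauchly_p == pytest.approx(1.0, abs=1e-6)

    def test_incomplete_cases_rejected(self):
        wide = pd.DataFrame([[1.0, 2.0], [3.0, np.nan]])
        with pytest.raises(ValueError, match="incomplete"):
            rm_anova_oneway(wide)
        with pytest.raises(ValueError, match="2 subjects"):
            rm_anova_oneway(pd.DataFrame([[1.0, 2.0]]))


def make_twoway_long(values):
    """values[subject, percept, condition] -> tidy long frame."""
    n, p, c = values.shape
    rows = []
    for i in range(n):
        for j, percept in enumerate(["integrated", "segregated"][:p]):
            for k in range(c):
                rows.append({"subject": f"S{i}", "percept": percept,
                             "delta_f": k, "value": values[i, j, k]})
    return pd.DataFrame(rows)


class TestTwoWayANOVA:
    def test_percept_symmetric_fixture_kills_percept_and_interaction(self):
        rng = np.random.default_rng(2)
        base = np.exp(rng.normal(size=(8, 1, 5)))
        vals = np.repeat(base, 2, axis=1)          # integrated == segregated
        table = rm_anova_twoway(make_twoway_long(vals))
        by = table.set_index("source")
        assert by.loc["percept", "F"] == 0.0
        assert by.loc["percept * delta_f", "F"] == 0.0

    def test_crossover_fixture_dominated_by_interaction(self):
        rng = np.random.default_rng(3)
        n, c = 10, 6
        grid = np.linspace(-1, 1, c)
        vals = np.empty((n, 2, c))
        for i in range(n):
            noise = rng.normal(0, 0.05, (2, c))
            vals[i, 0] = np.exp(-grid + noise[0])   # integrated falls
            vals[i, 1] = np.exp(+grid + noise[1])   # segregated rises
        table = rm_anova_twoway(make_twoway_long(vals)).set_index("source")
        assert table.loc["percept * delta_f", "F"] > 10 * max(
            table.loc["percept", "F"], table.loc["delta_f", "F"])

    def test_log_base_cannot_change_F(self):
        rng = np.random.default_rng(4)
        vals = np.exp(rng.normal(size=(6, 2, 4)))
        long = make_twoway_long(vals)
        a = rm_anova_twoway(long.assign(value=np.log(long["value"])),
                            log_transform=False)
        b = rm_anova_twoway(long.assign(value=np.log2(long["value"])),
                            log_transform=False)
        assert np.allclose(a["F"], b["F"], rtol=1e-9, equal_nan=True)

    def test_missing_cells_rejected(self):
        rng = np.random.default_rng(5)
        vals = np.exp(rng.normal(size=(5, 2, 3)))
        long = make_twoway_long(vals).iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            rm_anova_twoway(long)
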