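import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from infantmmr.simulate import simulate_measures_table
from infantmmr.stats import (LmeResult, analyze_log_bf, fit_factorial_lme,
                             partial_eta_squared, summarize_descriptives)


class TestPartialEtaSquared:
    @pytest.mark.parametrize("F,df1,df2,expected", [
        (3.12, 2, 244.6, 0.025),
        (18.08, 2, 287.3, 0.112),
        (0.41, 2, 271.8, 0.003),
        (100.76, 2, 254.0, 0.442),
    ])
    def test_reported_study_cells(self, F, df1, df2, expected):
        assert partial_eta_squared(F, df1, df2, ndigits=3) == expected

    def test_zero_f_gives_zero(self):
        assert partial_eta_squared(0.0, 3, 100.0) == 0.0

    def test_monotone_in_f(self):
        vals = [partial_eta_squared(f, 2, 200.0) for f in (0.5, 1, 5, 50)]
        assert vals == sorted(vals)

    def test_result_consistency_enforced(self):
        with pytest.raises(ValueError):
            LmeResult("Session", 3.0, 2, 100.0, 0.05, 0.5)


@pytest.fixture(scope="module")
def unbalanced_table():
    t = simulate_measures_table(30, seed=42, grand_mean=100.0,
                                session_effect={"T2": -8.0, "T3": -15.0},
                                language_effect=3.0,
                                interaction={("T2", "nonnative"): 5.0},
                                subject_sd=12.0, resid_sd=10.0)
    rng = np.random.default_rng(1)
    drop = rng.choice(t.index, size=25, replace=False)
    return t.drop(index=drop).reset_index(drop=True)


class TestFactorialLme:
    def test_matches_lmer_satterthwaite_oracle(self, tmp_path, unbalanced_table):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        csv = tmp_path / "d.csv"
        unbalanced_table.to_csv(csv, index=False)
        rcode = f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        d$session <- factor(d$session); d$language <- factor(d$language)
        contrasts(d$session) <- contr.sum(3)
        contrasts(d$language) <- contr.sum(2)
        m <- lmer(value ~ session * language + (1|subject), data=d)
        a <- anova(m, type=3, ddf="Satterthwaite")
        write.csv(data.frame(F=a$`F value`, df2=a$DenDF), "{tmp_path}/ref.csv",
                  row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv")
        ours = fit_factorial_lme(unbalanced_table, "value")
        for r, (_, refrow) in zip(ours, ref.iterrows()):
            assert r.F == pytest.approx(refrow["F"], rel=1e-3)
            assert r.df2 == pytest.approx(refrow["df2"], rel=1e-3)

    def test_degenerate_limit_matches_fixed_effects_anova(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm
        # balanced, complete, essentially no subject variance
        t = simulate_measures_table(24, seed=9, session_effect={"T2": -5.0},
                                    language_effect=2.0, subject_sd=1e-6,
                                    resid_sd=10.0)
        ours = fit_factorial_lme(t, "value")
        ols = smf.ols("value ~ C(session, Sum) * C(language, Sum)", data=t).fit()
        ref = sm.stats.anova_lm(ols, typ=3)
        ref_f = {"Session": ref.loc["C(session, Sum)", "F"],
                 "Language": ref.loc["C(language, Sum)", "F"],
                 "Session:Language": ref.loc["C(session, Sum):C(language, Sum)", "F"]}
        for r in ours:
            assert r.F == pytest.approx(ref_f[r.term], rel=0.01)

    def test_shuffling_sessions_destroys_session_effect(self):
        t = simulate_measures_table(40, seed=3, grand_mean=200.0,
                                    session_effect={"T2": -40.0, "T3": -80.0},
                                    subject_sd=10.0, resid_sd=10.0)
        strong = fit_factorial_lme(t, "value")
        f_session = next(r for r in strong if r.term == "Session").F
        rng = np.random.default_rng(0)
        shuffled = t.copy()
        shuffled["session"] = rng.permutation(shuffled["session"].to_numpy())
        shuffled = shuffled.drop_duplicates(["subject", "session", "language"])
        weak = fit_factorial_lme(shuffled, "value")
        f_shuffled = next(r for r in weak if r.term == "Session").F
        assert f_session > 50 and f_shuffled < f_session / 10

    def test_preconditions(self, unbalanced_table):
        with pytest.raises(ValueError, match="10 subjects"):
            fit_factorial_lme(unbalanced_table[unbalanced_table.subject
                                               .isin(["S001", "S002"])], "value")
        one_lang = unbalanced_table[unbalanced_table.language == "native"]
        with pytest.raises(ValueError, match="both languages"):
            fit_factorial_lme(one_lang, "value")
        dup = pd.concat([unbalanced_table, unbalanced_table.iloc[[0]]])
        with pytest.raises(ValueError, match="one row per"):
            fit_factorial_lme(dup, "value")

    def test_eta_p2_identity_and_scale_invariance(self, unbalanced_table):
        base = fit_factorial_lme(unbalanced_table, "value")
        scaled = unbalanced_table.assign(value=unbalanced_table.value * 7.3)
        other = fit_factorial_lme(scaled, "value")
        for a, b in zip(base, other):
            assert a.eta_p2 == pytest.approx(
                a.F * a.df1 / (a.F * a.df1 + a.df2), abs=1e-9)
            assert a.eta_p2 == pytest.approx(b.eta_p2, rel=1e-4)


class TestDescriptives:
    def test_known_cell_means_recovered(self):
        t = simulate_measures_table(200, seed=5, grand_mean=10.0,
                                    session_effect={"T2": 4.0},
                                    subject_sd=1.0, resid_sd=1.0)
        desc = summarize_descriptives(t, "value")
        t2n = desc[(desc.session == "T2") & (desc.language == "native")].iloc[0]
        t1n = desc[(desc.session == "T1") & (desc.language == "native")].iloc[0]
        assert t2n["mean"] - t1n["mean"] == pytest.approx(4.0, abs=0.5)
        assert t2n["n"] == 200
        grand = (desc["mean"] * desc["n"]).sum() / desc["n"].sum()
        assert grand == pytest.approx(t["value"].mean())

    def test_degenerate_single_value_cell(self):
        t = pd.DataFrame({"subject": ["S1"], "session": ["T1"],
                          "language": ["native"], "value": [5.0]})
        desc = summarize_descriptives(t, "value")
        row = desc[(desc.session == "T1") & (desc.language == "native")].iloc[0]
        assert row["n"] == 1 and np.isnan(row["sd"])
        assert desc[desc.session == "T3"]["n"].sum() == 0


class TestLogBfAnalysis:
    def test_unit_bayes_factors_give_null_f(self):
        rows = [{"subject": f"S{i:03d}", "session": s, "language": l,
                 "bf_max": 1.0}
                for i in range(12) for s in ("T1", "T2", "T3")
                for l in ("native", "nonnative")]
        results, props = analyze_log_bf(pd.DataFrame(rows))
        for r in results:
            assert r.F == pytest.approx(0.0, abs=1e-6)
        assert (props["prop_strong"] == 0.0).all()

    def test_strict_strong_threshold_and_positivity(self):
        # BF exactly 10 must not count as strong; only subject S000 exceeds it
        rows = [{"subject": f"S{i:03d}", "session": s, "language": l,
                 "bf_max": 10.5 if i == 0 else 10.0}
                for i in range(12) for s in ("T1", "T2", "T3")
                for l in ("native", "nonnative")]
        df = pd.DataFrame(rows)
        _, props = analyze_log_bf(df)
        assert np.allclose(props["prop_strong"], 1 / 12)
        df.loc[0, "bf_max"] = -1.0
        with pytest.raises(ValueError, match="positive"):
            analyze_log_bf(df)
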