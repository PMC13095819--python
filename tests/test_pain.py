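"""Pain volume, period summaries, reference-table parity and mixed models."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mibci
from mibci.pain import (BASELINE, DayRecord, Episode, PainDiary,
                        percent_variation, round_half_up)
from mibci.synth import PainSimConfig


def day(episodes=(), period="m-1", **nrs):
    import datetime
    kw = {"nrs_min": 2.0, "nrs_avg": 4.0, "nrs_max": 6.0}
    kw.update(nrs)
    return DayRecord(date=datetime.date(2020, 1, 1), period=period,
                     episodes=tuple(episodes), **kw)


class TestPainVolume:
    def test_no_episodes_zero(self):
        assert mibci.pain_volume(day()) == 0.0

    def test_hand_computed_sum(self):
        d = day([Episode(3.0, 0.5), Episode(7.0, 1.0)])
        assert mibci.pain_volume(d) == pytest.approx(8.5)

    def test_single_episode_product(self):
        assert mibci.pain_volume(day([Episode(5.0, 2.0)])) == pytest.approx(10.0)

    @given(st.lists(st.tuples(st.floats(0.5, 10.0), st.floats(0.1, 12.0)),
                    max_size=6),
           st.lists(st.tuples(st.floats(0.5, 10.0), st.floats(0.1, 12.0)),
                    max_size=6))
    def test_additive_over_episode_sets(self, eps_a, eps_b):
        a = [Episode(i, d) for i, d in eps_a]
        b = [Episode(i, d) for i, d in eps_b]
        total = mibci.pain_volume(day(a + b))
        assert total == pytest.approx(
            mibci.pain_volume(day(a)) + mibci.pain_volume(day(b)))

    def test_invalid_episode_rejected(self):
        with pytest.raises(ValueError):
            Episode(intensity=-1.0, duration_h=1.0)
        with pytest.raises(ValueError):
            Episode(intensity=5.0, duration_h=0.0)

    def test_nrs_ordering_enforced(self):
        with pytest.raises(ValueError, match="min <= avg"):
            day(nrs_min=5.0, nrs_avg=4.0)


class TestSummaries:
    def test_quartiles_ordered(self):
        diaries = mibci.generate_pain_diaries(PainSimConfig(seed=3))
        table = mibci.summarize_periods(diaries, "volume", "both")
        assert (table["q25"] <= table["median"] + 1e-12).all()
        assert (table["median"] <= table["q75"] + 1e-12).all()
        assert "All" in set(table["patient"])

    def test_identical_medians_zero_variation(self):
        assert percent_variation(5.0, 5.0) == 0.0

    def test_zero_baseline_flagged_na(self):
        assert percent_variation(5.0, 0.0) is None

    def test_half_up_rounding(self):
        assert round_half_up(-86.1194) == -86.12
        assert round_half_up(0.005) == 0.01
        assert round_half_up(-92.6216) == -92.62


@pytest.fixture(scope="module")
def tables():
    return mibci.load_reference_tables()


class TestReferenceTableParity:
    """The percent-variation rule reproduces the printed variation cells
    from the printed medians on every unambiguous row."""


    @staticmethod
    def check_table(df):
        checked = 0
        for patient, sub in df.groupby("patient"):
            base = float(sub.loc[sub["period"] == BASELINE, "median"].iloc[0])
            for _, row in sub.iterrows():
                if row["period"] == BASELINE or pd.isna(row["variation_pct"]):
                    continue
                got = percent_variation(float(row["median"]), base)
                assert got == pytest.approx(float(row["variation_pct"]),
                                            abs=0.011), \
                    f"{patient}/{row['period']}"
                checked += 1
        return checked

    def test_volume_table_unambiguous_rows(self, tables):
        df = tables["volume"]
        df = df[~df["ambiguous"]]
        assert self.check_table(df) >= 20

    def test_nrs_table_all_measures(self, tables):
        df = tables["nrs"]
        n = 0
        for measure, sub in df.groupby("measure"):
            n += self.check_table(sub)
        assert n >= 60

    def test_flagged_rows_present_but_excluded(self, tables):
        amb = tables["volume"]["ambiguous"]
        assert amb.sum() == 5  # one patient's rows are number-format ambiguous


class TestMixedModels:
    @staticmethod
    def balanced_frame(effect=-4.0, offsets=(10.0, 20.0), noise_sd=0.0,
                       n_days=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s, off in enumerate(offsets):
            for phase, eff in (("m-1", 0.0), ("w1w2", effect)):
                for _ in range(n_days):
                    rows.append({"subject_id": f"s{s}", "period": phase,
                                 "phase": phase,
                                 "value": off + eff +
                                 (rng.normal(0, noise_sd) if noise_sd else 0.0)})
        return pd.DataFrame(rows)

    def test_noiseless_recovery_exact(self):
        from mibci.pain import _fit_mixed
        res = _fit_mixed(self.balanced_frame(), "phase", ("m-1", "w1w2"))
        est = res.coefficients.loc["m-1 vs w1w2", "estimate"]
        assert est == pytest.approx(-4.0, abs=1e-6)

    def test_subject_variance_matches_reml_closed_form(self):
        """REML between-subject variance -> ddof=1 variance of the
        intercepts (= 50 for offsets {10, 20}) as residual noise -> 0."""
        from mibci.pain import _fit_mixed
        res = _fit_mixed(self.balanced_frame(noise_sd=0.1), "phase",
                         ("m-1", "w1w2"))
        assert res.re_variance == pytest.approx(50.0, rel=0.05)

    def test_constant_data_null_model(self):
        from mibci.pain import _fit_mixed
        df = self.balanced_frame(effect=0.0, offsets=(7.0, 7.0))
        res = _fit_mixed(df, "phase", ("m-1", "w1w2"))
        assert res.coefficients["estimate"].abs().max() < 1e-6
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-6)
        assert res.lrt_p > 0.99

    def test_weekly_pure_w4_effect(self):
        rows = []
        for s, off in enumerate((3.0, 9.0)):
            for week in ("m-1", "w1", "w2", "w3", "w4"):
                for _ in range(5):
                    rows.append({"subject_id": f"s{s}", "period": week,
                                 "value": off - (100.0 if week == "w4" else 0.0)})
        res = mibci.fit_weekly_lmm(pd.DataFrame(rows))
        coefs = res.coefficients["estimate"]
        assert coefs["m-1 vs w4"] == pytest.approx(-100.0, abs=1e-6)
        for other in ("w1", "w2", "w3"):
            assert coefs[f"m-1 vs {other}"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_subject_sd_matches_pooled_ols(self):
        """With no between-subject heterogeneity (raw-volume response) the
        random-intercept variance collapses and fixed effects equal pooled
        OLS."""
        import statsmodels.formula.api as smf
        cfg = PainSimConfig(subject_sd=0.0, seed=9)
        diaries = mibci.generate_pain_diaries(cfg)
        res = mibci.fit_phase_lmm(diaries, response="volume")
        from mibci.pain import _phase_frame, _response_frame
        df = _phase_frame(_response_frame(diaries, "volume"))
        ols = smf.ols("value ~ C(phase, Treatment('m-1'))", df).fit()
        assert res.re_variance < 0.01 * df["value"].var()
        assert res.coefficients.loc["m-1 vs w1w2", "estimate"] == \
            pytest.approx(float(ols.params.iloc[1]), rel=1e-6)

    def test_volume_scale_invariance_of_variation_response(self):
        """Scaling all volumes leaves percent-variation coefficients
        unchanged; raw-volume coefficients scale with the data."""
        cfg = PainSimConfig(seed=12, n_subjects=4)
        diaries = mibci.generate_pain_diaries(cfg)
        scaled = []
        for d in diaries:
            days = [DayRecord(date=x.date, period=x.period, nrs_min=x.nrs_min,
                              nrs_avg=x.nrs_avg, nrs_max=x.nrs_max,
                              episodes=tuple(Episode(e.intensity,
                                                     3.0 * e.duration_h)
                                             for e in x.episodes))
                    for x in d.days]
            scaled.append(PainDiary(subject_id=d.subject_id, days=days))
        a = mibci.fit_phase_lmm(diaries, response="volume_variation")
        b = mibci.fit_phase_lmm(scaled, response="volume_variation")
        assert b.coefficients["estimate"].values == pytest.approx(
            a.coefficients["estimate"].values, rel=1e-6)
        av = mibci.fit_phase_lmm(diaries, response="volume")
        bv = mibci.fit_phase_lmm(scaled, response="volume")
        assert bv.coefficients["estimate"].values == pytest.approx(
            3.0 * av.coefficients["estimate"].values, rel=1e-4)

    def test_single_subject_redirected(self):
        cfg = PainSimConfig(n_subjects=1, seed=2)
        diaries = mibci.generate_pain_diaries(cfg)
        with pytest.warns(UserWarning, match="per-patient"):
            out = mibci.fit_phase_lmm(diaries)
        assert isinstance(out, pd.DataFrame)
        assert set(out["contrast"]) == {"m-1 vs w1w2", "m-1 vs w3w4"}

    def test_per_patient_table_shape(self):
        diaries = mibci.generate_pain_diaries(PainSimConfig(n_subjects=3,
                                                            seed=4))
        out = mibci.fit_weekly_lmm(diaries, per_patient=True)
        assert len(out) == 3 * 4  # subjects x week contrasts
        assert {"patient", "contrast", "coef", "p"} <= set(out.columns)

    def test_followup_period_never_modelled(self):
        cfg = PainSimConfig(days_per_period={"m-1": 10, "w1": 5, "w2": 5,
                                             "w3": 5, "w4": 5, "w12-w23": 5},
                            seed=6)
        diaries = mibci.generate_pain_diaries(cfg)
        res = mibci.fit_weekly_lmm(diaries)
        assert not any("w12" in c for c in res.coefficients.index)


class TestDiaryIO:
    def test_csv_round_trip(self, tmp_path):
        diaries = mibci.generate_pain_diaries(PainSimConfig(n_subjects=2,
                                                            seed=8))
        path = tmp_path / "diary.csv"
        mibci.diaries_to_csv(diaries, path)
        back = mibci.diaries_from_csv(path)
        assert [d.subject_id for d in back] == [d.subject_id for d in diaries]
        for a, b in zip(diaries, back):
            va = [mibci.pain_volume(x) for x in a.days]
            vb = [mibci.pain_volume(x) for x in b.days]
            assert va == pytest.approx(vb)
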