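"""Factor coding and random-intercept mixed-model estimation."""

import numpy as np
import pandas as pd
import pytest

import oabayes as oa
from oabayes.errors import InputError
from oabayes.lmem import (
    SEQUENCE_CODES,
    STIMULUS_CODES,
    TIMING_CODES,
    sequence_view,
    t3_view,
)
from oabayes.pipeline import SEQUENCE_TERMS, STIMULUS_TERMS


def balanced_table(n_participants=10, intercept_sd=0.0, noise_sd=0.0,
                   effects=(0.0, 0.0, 0.0), seed=0, base=40.0):
    """Balanced R1-R3 design with known generating coefficients."""
    rng = np.random.default_rng(seed)
    rows = []
    t_eff, s_eff, ts_eff = effects
    for part in range(1, n_participants + 1):
        b = rng.normal(0, intercept_sd)
        for trial, cond in enumerate(
            ["conventional"] * 4 + ["noise_seq1"] * 2 + ["noise_seq2"] * 2, 1
        ):
            for timing in ("R1", "R2", "R3"):
                t = TIMING_CODES[timing]
                s = STIMULUS_CODES[cond]
                vas = base + t_eff * t + s_eff * s + ts_eff * t * s
                vas += b + rng.normal(0, noise_sd)
                rows.append((part, trial, cond, timing, vas))
    return pd.DataFrame(
        rows, columns=["participant", "trial", "condition", "timing", "vas"]
    )


class TestCoding:
    def test_paper_codings(self):
        raw = pd.DataFrame(
            {
                "participant": [1, 1, 1],
                "trial": [3, 4, 5],
                "condition": ["conventional", "noise_seq2", "noise_seq1"],
                "timing": ["R2", "R3", "R1"],
                "vas": [40.0, 45.0, 30.0],
            }
        )
        coded = oa.code_factors(raw)
        assert coded.loc[0, "timing_code"] == 0.0
        assert coded.loc[0, "stimulus_code"] == -0.5
        assert coded.loc[1, "timing_code"] == 0.5
        assert coded.loc[1, "stimulus_code"] == 0.5
        assert coded.loc[1, "sequence_code"] == 0.5
        assert coded.loc[2, "sequence_code"] == -0.5
        assert np.isnan(coded.loc[0, "sequence_code"])

    def test_r0_and_constant_excluded_from_t3_view(self):
        raw = pd.DataFrame(
            {
                "participant": [1, 1, 1],
                "trial": [1, 3, 3],
                "condition": ["constant", "conventional", "conventional"],
                "timing": ["R1", "R0", "R2"],
                "vas": [50.0, 60.0, 40.0],
            }
        )
        view = t3_view(oa.code_factors(raw))
        assert len(view) == 1
        assert view.loc[0, "timing"] == "R2"

    def test_sequence_view_noise_only(self):
        table = oa.code_factors(balanced_table(n_participants=2))
        view = sequence_view(table)
        assert set(view["condition"]) == {"noise_seq1", "noise_seq2"}

    def test_unknown_labels_rejected(self):
        raw = balanced_table(n_participants=2)
        bad = raw.copy()
        bad.loc[0, "condition"] = "mystery"
        with pytest.raises(InputError):
            oa.code_factors(bad)
        bad = raw.copy()
        bad.loc[0, "timing"] = "R9"
        with pytest.raises(InputError):
            oa.code_factors(bad)

    def test_timing_codes_sum_to_zero_per_trial(self):
        coded = oa.code_factors(balanced_table(n_participants=3))
        sums = coded.groupby(["participant", "trial"])["timing_code"].sum()
        assert np.allclose(sums, 0.0)

    def test_stimulus_codes_balance(self):
        assert STIMULUS_CODES["conventional"] + STIMULUS_CODES["noise_seq1"] == 0.0
        assert SEQUENCE_CODES["noise_seq1"] + SEQUENCE_CODES["noise_seq2"] == 0.0


class TestFit:
    def test_noiseless_generative_identity(self):
        """Zero residual noise: estimates equal the generating effects."""
        table = oa.code_factors(
            balanced_table(intercept_sd=5.0, effects=(4.0, 3.5, 11.0), seed=3)
        )
        fit = oa.fit_random_intercept(t3_view(table), STIMULUS_TERMS)
        assert fit["timing_code"]["estimate"] == pytest.approx(4.0, abs=1e-6)
        assert fit["stimulus_code"]["estimate"] == pytest.approx(3.5, abs=1e-6)
        assert fit["timing_code:stimulus_code"]["estimate"] == pytest.approx(
            11.0, abs=1e-6
        )

    def test_estimates_converge_as_noise_shrinks(self):
        errs = []
        for noise_sd in (4.0, 0.4, 0.004):
            table = oa.code_factors(
                balanced_table(
                    intercept_sd=3.0, noise_sd=noise_sd,
                    effects=(4.0, 3.5, 11.0), seed=8,
                )
            )
            fit = oa.fit_random_intercept(t3_view(table), STIMULUS_TERMS)
            errs.append(abs(fit["timing_code"]["estimate"] - 4.0))
        assert errs[0] > errs[2]
        assert errs[2] < 1e-2

    def test_ols_equivalence_without_grouping_variance(self):
        """No between-participant variance: the ML fit collapses to OLS."""
        import statsmodels.api as sm

        table = oa.code_factors(
            balanced_table(intercept_sd=0.0, noise_sd=6.0,
                           effects=(2.0, 1.0, 3.0), seed=11)
        )
        view = t3_view(table)
        fit = oa.fit_random_intercept(view, STIMULUS_TERMS)
        X = sm.add_constant(
            np.column_stack(
                [
                    view["timing_code"],
                    view["stimulus_code"],
                    view["timing_code"] * view["stimulus_code"],
                ]
            )
        )
        ols = sm.OLS(view["vas"].to_numpy(), X).fit()
        assert np.allclose(fit.estimates, ols.params, atol=1e-4)
        assert fit.sigma_b2 < 1e-6

    def test_matches_statsmodels_mixedlm(self):
        """Independent ML implementation agrees with statsmodels MixedLM."""
        import statsmodels.formula.api as smf

        table = oa.code_factors(
            balanced_table(intercept_sd=7.0, noise_sd=9.0,
                           effects=(4.0, 3.5, 11.0), seed=5)
        )
        view = t3_view(table).rename(
            columns={"timing_code": "t", "stimulus_code": "s"}
        )
        fit = oa.fit_random_intercept(
            view, ["t", "s", "t:s"], response="vas", group="participant"
        )
        sm_fit = smf.mixedlm(
            "vas ~ t * s", view, groups=view["participant"]
        ).fit(reml=False)
        assert fit.estimates[0] == pytest.approx(sm_fit.params["Intercept"], abs=1e-4)
        assert fit.estimates[1] == pytest.approx(sm_fit.params["t"], abs=1e-4)
        assert fit.estimates[2] == pytest.approx(sm_fit.params["s"], abs=1e-4)
        assert fit.estimates[3] == pytest.approx(sm_fit.params["t:s"], abs=1e-4)
        assert fit.sigma_b2 == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=0.02, abs=1e-3
        )

    def test_residual_style_df(self):
        table = oa.code_factors(balanced_table(n_participants=22, noise_sd=5.0))
        view = t3_view(table)
        fit = oa.fit_random_intercept(view, STIMULUS_TERMS)
        assert fit.n_obs == 528
        assert fit.df == 528 - 4 - 21  # n - fixed effects - (groups - 1)

    def test_single_participant_rejected(self):
        table = oa.code_factors(balanced_table(n_participants=1, noise_sd=1.0))
        with pytest.raises(InputError):
            oa.fit_random_intercept(t3_view(table), STIMULUS_TERMS)

    def test_sequence_terms_fit(self):
        table = oa.code_factors(
            balanced_table(intercept_sd=4.0, noise_sd=6.0, seed=9)
        )
        fit = oa.fit_random_intercept(sequence_view(table), SEQUENCE_TERMS)
        assert fit.n_obs == 120  # 10 participants x 4 noise trials x 3 timings
        assert np.isfinite(fit.loglik)


class TestCohensD:
    def test_zero_t(self):
        assert oa.cohens_d(0.0, 100.0) == 0.0

    @pytest.mark.parametrize(
        "t, df, expected",
        [(3.30, 504, 0.294), (4.33, 506, 0.385), (3.07, 506, 0.273)],
    )
    def test_two_t_over_sqrt_df(self, t, df, expected):
        assert oa.cohens_d(t, df) == pytest.approx(expected, abs=5e-4)

    def test_invalid_df(self):
        with pytest.raises(InputError):
            oa.cohens_d(1.0, 0.0)
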