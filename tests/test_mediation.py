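"""Product-of-coefficients mediation and mediated proportions.

The reference rows come from the bundled PM2.5 -> mediator -> longevity
coefficient table (``mrkit.datasets``); recomputed products are compared to
the values reported alongside those inputs.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrkit.datasets import longevity_mediation_coefficients
from mrkit.errors import MRKitError, ScaleError
from mrkit.estimators import MREstimate, ivw, with_scale
from mrkit.instruments import select_instruments
from mrkit.mediation import indirect_effect, mediated_proportion, two_step_mediation
from mrkit.simulate import StudyConfig, simulate_study
from mrkit.summary_io import harmonize

TABLE = longevity_mediation_coefficients().set_index(["mediator", "percentile"])

# rows whose printed product agrees with the printed mediation effect at the
# printed two-decimal precision
EXACT_ROWS = [
    ("DBP", "90th"),
    ("hypertension", "90th"),
    ("hypertension", "99th"),
    ("hypercholesterolaemia", "90th"),
    ("AD", "90th"),
    ("AD", "99th"),
    ("hypothyroidism", "90th"),
    ("hypothyroidism", "99th"),
]
# rows reported from unrounded upstream estimates: products of the printed
# inputs agree only to about one unit in the second decimal
LOOSE_ROWS = [
    ("DBP", "99th"),
    ("hypercholesterolaemia", "99th"),
    ("angina", "90th"),
    ("angina", "99th"),
]


def _est(beta, se, n=8):
    return MREstimate("ivw_mre", beta, se, beta - 1.96 * se, beta + 1.96 * se,
                      0.05, n)


class TestIndirectEffect:
    @pytest.mark.parametrize("row", EXACT_ROWS, ids=lambda r: f"{r[0]}-{r[1]}")
    def test_reference_products_at_printed_precision(self, row):
        r = TABLE.loc[row]
        res = indirect_effect(r["a"], r["a_se"], r["b"], r["b_se"])
        assert round(res.beta, 2) == pytest.approx(r["mediation_ref"])

    @pytest.mark.parametrize("row", LOOSE_ROWS, ids=lambda r: f"{r[0]}-{r[1]}")
    def test_reference_products_within_rounding_slack(self, row):
        r = TABLE.loc[row]
        res = indirect_effect(r["a"], r["a_se"], r["b"], r["b_se"])
        assert res.beta == pytest.approx(r["mediation_ref"], abs=0.01)

    def test_delta_se_consistent_with_reference_ci(self):
        # DBP / 90th: recomputed delta SE must reproduce the reported CI width
        r = TABLE.loc[("DBP", "90th")]
        res = indirect_effect(r["a"], r["a_se"], r["b"], r["b_se"])
        ref_se = (r["mediation_ref_hi"] - r["mediation_ref_lo"]) / (2 * 1.96)
        assert res.se == pytest.approx(ref_se, rel=0.05)

    def test_null_factor_gives_null_symmetric_ci(self):
        res = indirect_effect(0.0, 0.1, 0.5, 0.1)
        assert res.beta == 0.0
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(MRKitError):
            indirect_effect(0.1, 0.0, 0.2, 0.1)

    def test_delta_se_matches_monte_carlo_oracle(self):
        a, sa, b, sb = -2.65, 0.676, -0.068, 0.00714
        res = indirect_effect(a, sa, b, sb)
        rng = np.random.default_rng(123)
        draws = rng.normal(a, sa, 200_000) * rng.normal(b, sb, 200_000)
        assert abs(res.se - draws.std()) / draws.std() < 0.10

    @given(
        a=st.floats(-3, 3, allow_nan=False),
        sa=st.floats(1e-3, 1),
        b=st.floats(-3, 3, allow_nan=False),
        sb=st.floats(1e-3, 1),
    )
    def test_symmetric_in_arguments_and_exact_product(self, a, sa, b, sb):
        r1 = indirect_effect(a, sa, b, sb)
        r2 = indirect_effect(b, sb, a, sa)
        assert r1.beta == a * b
        assert r1 == r2


class TestMediatedProportion:
    def test_reference_proportion_dbp(self):
        prop, _ = mediated_proportion(0.18, -0.57, 0.0503)
        assert prop == pytest.approx(31.48, abs=1.5)

    def test_reference_proportion_angina(self):
        prop, _ = mediated_proportion(-0.014, -0.57, 0.006)
        assert prop == pytest.approx(2.45, abs=1.5)

    def test_overshoot_clips_to_100(self):
        prop, _ = mediated_proportion(-0.69, -0.57, 0.34)
        assert prop == 100.0

    def test_null_indirect_is_zero_percent(self):
        prop, _ = mediated_proportion(0.0, -0.57, 0.01)
        assert prop == 0.0

    def test_ci_propagation_matches_reference_bounds(self):
        # hypertension / 90th: indirect CI does not span zero
        prop, (lo, hi) = mediated_proportion(-0.41, -0.57, (0.74 - 0.070) / (2 * 1.96))
        assert (lo, hi) == (pytest.approx(12.23, abs=1.5), 100.0)

    def test_ci_spanning_zero_has_zero_lower_bound(self):
        # hypothyroidism / 90th: indirect CI (-0.69, 0.011) crosses zero
        prop, (lo, hi) = mediated_proportion(-0.34, -0.57, (0.69 + 0.011) / (2 * 1.96))
        assert lo == 0.0
        assert hi == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(MRKitError):
            mediated_proportion(0.1, 0.0, 0.05)

    @given(
        ind=st.floats(-2, 2, allow_nan=False),
        tot=st.floats(0.05, 2, allow_nan=False),
        se=st.floats(1e-3, 0.5),
    )
    def test_bounds_always_in_unit_interval(self, ind, tot, se):
        prop, (lo, hi) = mediated_proportion(ind, tot, se)
        assert 0 <= lo <= hi <= 100
        assert 0 <= prop <= 100


class TestTwoStepMediation:
    def test_assembles_reference_row(self):
        r = TABLE.loc[("hypertension", "90th")]
        res = two_step_mediation(
            _est(r["a"], r["a_se"]), _est(r["b"], r["b_se"]),
            _est(r["total"], r["total_se"]),
        )
        assert round(res.indirect_beta, 2) == pytest.approx(-0.41)
        assert res.proportion == pytest.approx(70.86, abs=1.5)
        assert not res.inconsistent

    def test_sign_discordant_mediation_flagged(self):
        # DBP: positive indirect effect against a negative total
        r = TABLE.loc[("DBP", "90th")]
        with pytest.warns(UserWarning, match="inconsistent"):
            res = two_step_mediation(
                _est(r["a"], r["a_se"]), _est(r["b"], r["b_se"]),
                _est(r["total"], r["total_se"]),
            )
        assert res.inconsistent
        assert res.proportion == pytest.approx(31.48, abs=1.5)

    def test_null_second_step(self):
        res = two_step_mediation(_est(0.5, 0.1), _est(0.0, 0.1), _est(0.3, 0.1))
        assert res.indirect_beta == 0.0
        assert res.proportion == 0.0

    def test_odds_ratio_scale_rejected(self):
        bad = with_scale(_est(1.08, 0.03), "or")
        with pytest.raises(ScaleError):
            two_step_mediation(bad, _est(0.2, 0.05), _est(0.3, 0.1))

    def test_recovers_simulated_chain_proportion(self):
        # step 2 must use the mediator's own instruments: exposure
        # instruments reach the outcome through both paths
        study = simulate_study(
            StudyConfig(seed=21, a=(0.5,), b=((0.4,),), c_prime=(0.1,),
                        j_exposure=40, j_mediator=40)
        )
        exp = study.traits["exposure"]
        med = study.traits[study.mediator_labels[0]]
        out = study.traits[study.outcome_labels[0]]
        exp_iv = select_instruments(exp).records
        med_iv = select_instruments(med).records
        res = two_step_mediation(
            ivw(harmonize(exp_iv, med)),
            ivw(harmonize(med_iv, out)),
            ivw(harmonize(exp_iv, out)),
        )
        true_prop = 100 * 0.2 / 0.3
        se_prop = 100 * res.indirect_se / abs(res.total_beta)
        assert abs(res.proportion - true_prop) < 2 * se_prop
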