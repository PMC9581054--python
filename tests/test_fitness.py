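"""Bayesian fitness-effect arithmetic, confidence intervals, merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from edgotype import fitness as ft
from edgotype.errors import EmptyClassError, UndefinedPosteriorError
from edgotype.labels import (
    ASSUMPTION_I,
    ASSUMPTION_II,
    EDGETIC,
    EDGOTYPES,
    FITNESS_CLASSES,
    MILD,
    NEUTRAL,
    NONPATHOGENIC,
    PATHOGENIC,
    QUASI_NULL,
    QUASI_WILDTYPE,
    STRONG,
)

PRIORS = ft.DEFAULT_PRIORS

Y2H_FRACTIONS = {
    QUASI_WILDTYPE: (0.97, 0.74),
    EDGETIC: (0.015, 0.13),
    QUASI_NULL: (0.015, 0.13),
}


def y2h_conditionals(assumption=ASSUMPTION_I, n_n=1072, n_m=318):
    return ft.conditional_probs_from_fractions(
        Y2H_FRACTIONS, n_n, n_m, assumption
    )


def counts_frame(non, path):
    return pd.DataFrame(
        [non, path], index=[NONPATHOGENIC, PATHOGENIC], columns=list(EDGOTYPES)
    )


class TestConditionalProbs:
    def test_row_fractions(self):
        cond = ft.conditional_probs(
            counts_frame((1040, 16, 16), (235, 41, 42))
        )
        assert cond.given_n[QUASI_WILDTYPE].p == pytest.approx(1040 / 1072)
        assert cond.given_m[QUASI_WILDTYPE].p == pytest.approx(235 / 318)

    def test_uniform_counts(self):
        cond = ft.conditional_probs(counts_frame((5, 5, 5), (7, 7, 7)))
        for t in EDGOTYPES:
            assert cond.given_n[t].p == pytest.approx(1 / 3)
            assert cond.given_m[t].p == pytest.approx(1 / 3)

    def test_zero_row_total(self):
        with pytest.raises(EmptyClassError):
            ft.conditional_probs(counts_frame((0, 0, 0), (1, 1, 1)))

    def test_assumption_fixes_p_t_given_s(self):
        cond1 = y2h_conditionals(ASSUMPTION_I)
        assert cond1.p_t_given_s(QUASI_NULL) == 1.0
        assert cond1.p_t_given_s(QUASI_WILDTYPE) == 0.0
        assert cond1.p_t_given_s(EDGETIC) == 0.0
        cond2 = y2h_conditionals(ASSUMPTION_II)
        for t in EDGOTYPES:
            assert cond2.p_t_given_s(t) == cond2.given_m[t].p


class TestFitnessPosterior:
    def test_published_quasi_wildtype_chain(self):
        """P(QW) = 0.97*0.27 + 0.74*0.53 = 0.6541; Bayes gives ~40% neutral,
        ~60% mildly deleterious, 0 strongly detrimental."""
        post = ft.fitness_posterior(y2h_conditionals())[QUASI_WILDTYPE]
        assert post.p_t == pytest.approx(0.6541, abs=1e-12)
        assert post.posteriors[NEUTRAL] == pytest.approx(0.400, abs=5e-4)
        assert post.posteriors[MILD] == pytest.approx(0.600, abs=5e-4)
        assert post.posteriors[STRONG] == 0.0

    def test_uninformative_edgotype_returns_priors(self):
        cond = ft.conditional_probs_from_fractions(
            {QUASI_WILDTYPE: (1 / 3, 1 / 3), EDGETIC: (1 / 3, 1 / 3),
             QUASI_NULL: (1 / 3, 1 / 3)},
            assumption=ASSUMPTION_II,  # P(T|S) = P(T|M) = 1/3 too
        )
        post = ft.fitness_posterior(cond)[EDGETIC]
        assert post.posteriors[NEUTRAL] == pytest.approx(PRIORS.p_n)
        assert post.posteriors[MILD] == pytest.approx(PRIORS.p_m)
        assert post.posteriors[STRONG] == pytest.approx(PRIORS.p_s)

    def test_quasi_null_assumption_ii_worked_example(self):
        post = ft.fitness_posterior(
            y2h_conditionals(ASSUMPTION_II))[QUASI_NULL]
        assert post.p_t == pytest.approx(0.09895, abs=1e-12)
        assert post.posteriors[MILD] == pytest.approx(0.696, abs=5e-4)
        assert post.posteriors[STRONG] == pytest.approx(0.263, abs=5e-4)

    def test_undefined_posterior(self):
        cond = ft.conditional_probs_from_fractions(
            {QUASI_WILDTYPE: (1.0, 1.0), EDGETIC: (0.0, 0.0),
             QUASI_NULL: (0.0, 0.0)},
            assumption=ASSUMPTION_II,
        )
        with pytest.raises(UndefinedPosteriorError):
            ft.fitness_posterior(cond, edgotype=EDGETIC)


@st.composite
def random_conditionals(draw):
    def simplex():
        a = draw(st.floats(0.01, 1)); b = draw(st.floats(0.01, 1))
        c = draw(st.floats(0.01, 1))
        s = a + b + c
        return (a / s, b / s, c / s)

    pn, pm = simplex(), simplex()
    assumption = draw(st.sampled_from([ASSUMPTION_I, ASSUMPTION_II]))
    return ft.conditional_probs_from_fractions(
        {t: (pn[i], pm[i]) for i, t in enumerate(EDGOTYPES)},
        1000, 500, assumption,
    )


class TestInvariants:
    @given(random_conditionals())
    def test_law_of_total_probability(self, cond):
        posts = ft.fitness_posterior(cond, PRIORS)
        assert sum(p.p_t for p in posts.values()) == pytest.approx(1.0)
        for p in posts.values():
            assert sum(p.posteriors.values()) == pytest.approx(1.0)

    @given(random_conditionals())
    def test_bayes_consistency(self, cond):
        posts = ft.fitness_posterior(cond, PRIORS)
        for t, post in posts.items():
            assert post.posteriors[NEUTRAL] * post.p_t == pytest.approx(
                cond.given_n[t].p * PRIORS.p_n, abs=1e-15
            )
            assert post.posteriors[MILD] * post.p_t == pytest.approx(
                cond.given_m[t].p * PRIORS.p_m, abs=1e-15
            )

    def test_assumption_identities(self):
        posts1 = ft.fitness_posterior(y2h_conditionals(ASSUMPTION_I))
        assert posts1[QUASI_WILDTYPE].posteriors[STRONG] == 0.0
        assert posts1[EDGETIC].posteriors[STRONG] == 0.0
        posts2 = ft.fitness_posterior(y2h_conditionals(ASSUMPTION_II))
        for t in EDGOTYPES:
            ratio = posts2[t].posteriors[STRONG] / posts2[t].posteriors[MILD]
            assert ratio == pytest.approx(PRIORS.p_s / PRIORS.p_m)


class TestBlandCi:
    def test_published_quasi_wildtype_interval(self):
        """Counts 1040/1072 vs 235/318 give a ~38.5-41.7% interval for the
        neutral posterior, matching the published ~38-42%."""
        cond = ft.conditional_probs(counts_frame((1040, 16, 16), (235, 41, 42)))
        lo, hi = ft.bland_ci(cond, PRIORS)[QUASI_WILDTYPE][NEUTRAL]
        assert lo == pytest.approx(0.385, abs=2e-3)
        assert hi == pytest.approx(0.417, abs=2e-3)

    def test_interval_width_vanishes_with_n(self):
        widths = []
        for n in (10**3, 10**5, 10**7):
            cond = y2h_conditionals(n_n=n, n_m=n)
            lo, hi = ft.bland_ci(cond, PRIORS)[QUASI_WILDTYPE][NEUTRAL]
            post = ft.fitness_posterior(cond)[QUASI_WILDTYPE]
            assert lo <= post.posteriors[NEUTRAL] <= hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] < 1e-3

    def test_zero_count_gets_continuity_correction(self):
        cond = ft.conditional_probs(counts_frame((100, 0, 5), (50, 10, 10)))
        with pytest.warns(UserWarning, match="continuity"):
            ci = ft.bland_ci(cond, PRIORS)
        lo, hi = ci[EDGETIC][MILD]
        assert 0.0 <= lo <= hi <= 1.0

    @given(random_conditionals())
    def test_intervals_bracket_estimates(self, cond):
        posts = ft.fitness_posterior(cond, PRIORS)
        cis = ft.bland_ci(cond, PRIORS)
        for t in EDGOTYPES:
            for f in FITNESS_CLASSES:
                lo, hi = cis[t][f]
                assert 0.0 <= lo <= posts[t].posteriors[f] <= hi <= 1.0

    def test_bootstrap_oracle_agreement(self):
        """Analytic intervals agree with a parametric bootstrap within
        half a percentage point at the published sample sizes."""
        rng = np.random.default_rng(17)
        cond = y2h_conditionals()
        lo, hi = ft.bland_ci(cond, PRIORS)[QUASI_WILDTYPE][NEUTRAL]
        blo, bhi = ft.parametric_bootstrap_ci(
            cond, PRIORS, QUASI_WILDTYPE, NEUTRAL, n_draws=200_000, rng=rng
        )
        assert abs(lo - blo) < 0.005 and abs(hi - bhi) < 0.005


class TestMergeAssumptions:
    def _merged(self):
        p1 = ft.fitness_posterior(y2h_conditionals(ASSUMPTION_I))
        p2 = ft.fitness_posterior(y2h_conditionals(ASSUMPTION_II))
        return p1, p2, ft.merge_assumptions(p1, p2).set_index(
            ["edgotype", "fitness_class"]
        )

    def test_identical_posteriors_degenerate(self):
        p1 = ft.fitness_posterior(y2h_conditionals(ASSUMPTION_I))
        merged = ft.merge_assumptions(p1, p1)
        assert (merged.merged_low == merged.merged_high).all()

    def test_quasi_null_strong_worked_example(self):
        """Assumption I gives ~0.733, Assumption II ~0.263; the merged range
        is [mean, AI] = [~0.498, ~0.733]."""
        _, _, merged = self._merged()
        row = merged.loc[(QUASI_NULL, STRONG)]
        assert row.merged_low == pytest.approx(0.498, abs=1e-3)
        assert row.merged_high == pytest.approx(0.733, abs=1e-3)

    def test_merged_interval_between_inputs(self):
        p1, p2, merged = self._merged()
        for t in EDGOTYPES:
            for f in FITNESS_CLASSES:
                lo = min(p1[t].posteriors[f], p2[t].posteriors[f])
                hi = max(p1[t].posteriors[f], p2[t].posteriors[f])
                row = merged.loc[(t, f)]
                assert lo - 1e-12 <= row.merged_low <= row.merged_high \
                    <= hi + 1e-12


def test_priors_must_form_simplex():
    with pytest.raises(ValueError):
        ft.FitnessPriors(0.5, 0.5, 0.5)


def test_parameter_recovery_from_multinomial_counts():
    """Posteriors from counts drawn at n = 1e5 per class match posteriors
    from the true conditionals within 3 delta-method standard errors."""
    from edgotype import synthetic

    n = 10**5
    probs = {NONPATHOGENIC: (0.97, 0.015, 0.015),
             PATHOGENIC: (0.74, 0.13, 0.13)}
    counts = synthetic.generate_edgotype_counts(n, n, probs, seed=23)
    cond_hat = ft.conditional_probs(counts, ASSUMPTION_I)
    cond_true = ft.conditional_probs_from_fractions(
        {t: (probs[NONPATHOGENIC][i], probs[PATHOGENIC][i])
         for i, t in enumerate(EDGOTYPES)},
        n, n, ASSUMPTION_I,
    )
    posts_hat = ft.fitness_posterior(cond_hat, PRIORS)
    posts_true = ft.fitness_posterior(cond_true, PRIORS)
    cis = ft.bland_ci(cond_hat, PRIORS)
    for t in EDGOTYPES:
        for f in FITNESS_CLASSES:
            lo, hi = cis[t][f]
            se = (hi - lo) / (2 * ft.Z_95)
            diff = abs(posts_hat[t].posteriors[f] - posts_true[t].posteriors[f])
            assert diff <= max(3 * se, 1e-9)
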