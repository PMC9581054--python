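"""Bayesian estimation of edgotype fitness effects.

New missense mutations fall into three fitness classes with genome-wide
prior probabilities P(N) = 27% (effectively neutral), P(M) = 53% (mildly
deleterious) and P(S) = 20% (strongly detrimental).  Observed mutation sets
provide the conditional edgotype probabilities P(T|N) (common, non-pathogenic
mutations, treated as neutral) and P(T|M) (pathogenic mutations, treated as
mildly deleterious) for each edgotype T in {quasi-wild-type, edgetic,
quasi-null}.  No genome-wide data exist for strongly detrimental mutations,
so P(T|S) is fixed by assumption:

* **Assumption I** — strongly detrimental mutations are all quasi-null:
  P(QN|S) = 1, P(QW|S) = P(E|S) = 0.
* **Assumption II** — strongly detrimental mutations are distributed like
  mildly deleterious ones: P(T|S) = P(T|M) for every T.

The marginal edgotype probability is

    P(T) = P(T|N) P(N) + P(T|M) P(M) + P(T|S) P(S)

and Bayes' theorem yields the fitness-effect posteriors P(N|T), P(M|T),
P(S|T).  Each posterior can be rewritten as 1/P(F|T) = 1 + Q where Q is a
ratio (or sum) of the two estimated conditionals; 95% confidence intervals
follow Bland's log-scale interval for a ratio of proportions whenever Q is
an affine function of the single ratio P(T|M)/P(T|N), and first-order
(delta-method) propagation of the binomial variances otherwise.

The final reported estimate for each (edgotype, fitness class) merges the
two assumptions: the interval spans from the Assumption-I value to the mean
of the Assumption-I and Assumption-II values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyClassError, UndefinedPosteriorError
from .labels import (
    ASSUMPTION_I,
    ASSUMPTION_II,
    ASSUMPTIONS,
    EDGOTYPES,
    FITNESS_CLASSES,
    MILD,
    NEUTRAL,
    NONPATHOGENIC,
    PATHOGENIC,
    QUASI_NULL,
    STRONG,
)

Z_95 = 1.959964  # fixed 95% normal quantile, for determinism


@dataclass(frozen=True)
class FitnessPriors:
    """Prior probabilities for the three fitness classes of a new mutation."""

    p_n: float = 0.27
    p_m: float = 0.53
    p_s: float = 0.20

    def __post_init__(self):
        total = self.p_n + self.p_m + self.p_s
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"priors must sum to 1, got {total!r}")
        if min(self.p_n, self.p_m, self.p_s) < 0:
            raise ValueError("priors must be nonnegative")


DEFAULT_PRIORS = FitnessPriors()


@dataclass(frozen=True)
class BinomialEstimate:
    """A proportion with its count basis (x successes out of n)."""

    p: float
    x: float | None = None
    n: float | None = None

    @classmethod
    def from_counts(cls, x: float, n: float) -> "BinomialEstimate":
        if n <= 0:
            raise EmptyClassError("zero row total")
        return cls(p=x / n, x=float(x), n=float(n))

    @classmethod
    def from_fraction(cls, p: float, n: float | None = None) -> "BinomialEstimate":
        return cls(p=p, x=(p * n if n is not None else None),
                   n=(float(n) if n is not None else None))

    def has_counts(self) -> bool:
        return self.x is not None and self.n is not None


@dataclass(frozen=True)
class ConditionalEdgotypeProbs:
    """Conditional edgotype probabilities P(T|N) and P(T|M) with count bases.

    ``assumption`` fixes P(T|S): under I, 1 for quasi-null and 0 otherwise;
    under II, equal to P(T|M) (same estimate, hence perfectly dependent for
    variance purposes).
    """

    given_n: dict[str, BinomialEstimate]  # edgotype -> P(T|N)
    given_m: dict[str, BinomialEstimate]  # edgotype -> P(T|M)
    assumption: str = ASSUMPTION_I

    def __post_init__(self):
        if self.assumption not in ASSUMPTIONS:
            raise ValueError(f"unknown assumption {self.assumption!r}")
        for name, d in (("P(T|N)", self.given_n), ("P(T|M)", self.given_m)):
            total = sum(est.p for est in d.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total!r}")

    def p_t_given_s(self, edgotype: str) -> float:
        if self.assumption == ASSUMPTION_I:
            return 1.0 if edgotype == QUASI_NULL else 0.0
        return self.given_m[edgotype].p


def conditional_probs(
    counts: pd.DataFrame, assumption: str = ASSUMPTION_I
) -> ConditionalEdgotypeProbs:
    """Estimate P(T|N) and P(T|M) from a 2x3 edgotype count table.

    ``counts`` is indexed by phenotype class (rows ``nonpathogenic`` and
    ``pathogenic``) with one column per edgotype.  Row fractions estimate
    the conditionals; the count bases are retained for interval estimation.
    """
    for row in (NONPATHOGENIC, PATHOGENIC):
        if row not in counts.index:
            raise EmptyClassError(f"missing phenotype row {row!r}")
        if counts.loc[row].sum() <= 0:
            raise EmptyClassError(f"zero total for phenotype row {row!r}")
        if (counts.loc[row] < 0).any():
            raise ValueError("counts must be nonnegative")
    n_n = float(counts.loc[NONPATHOGENIC].sum())
    n_m = float(counts.loc[PATHOGENIC].sum())
    given_n = {
        t: BinomialEstimate.from_counts(float(counts.loc[NONPATHOGENIC, t]), n_n)
        for t in EDGOTYPES
    }
    given_m = {
        t: BinomialEstimate.from_counts(float(counts.loc[PATHOGENIC, t]), n_m)
        for t in EDGOTYPES
    }
    return ConditionalEdgotypeProbs(given_n=given_n, given_m=given_m,
                                    assumption=assumption)


def conditional_probs_from_fractions(
    fractions: dict[str, tuple[float, float]],
    n_nonpathogenic: float | None = None,
    n_pathogenic: float | None = None,
    assumption: str = ASSUMPTION_I,
) -> ConditionalEdgotypeProbs:
    """Build conditionals from printed fractions (P(T|N), P(T|M)) per edgotype.

    Count bases are optional; interval estimation requires them.
    """
    given_n = {
        t: BinomialEstimate.from_fraction(pn, n_nonpathogenic)
        for t, (pn, _) in fractions.items()
    }
    given_m = {
        t: BinomialEstimate.from_fraction(pm, n_pathogenic)
        for t, (_, pm) in fractions.items()
    }
    return ConditionalEdgotypeProbs(given_n=given_n, given_m=given_m,
                                    assumption=assumption)


@dataclass
class FitnessPosterior:
    """Posterior fitness-class probabilities for one edgotype."""

    edgotype: str
    assumption: str
    p_t: float
    posteriors: dict[str, float]  # fitness class -> P(F|T)
    # (a, b) coefficients of the transformed forms 1/P(F|T) = 1 + Q:
    #   F=N: Q = (a*P(T|M) + b) / P(T|N)
    #   F=M: Q = (a*P(T|N) + b) / P(T|M)
    #   F=S: Q = a*P(T|N) + b*P(T|M)
    coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)


def fitness_posterior(
    conditionals: ConditionalEdgotypeProbs,
    priors: FitnessPriors = DEFAULT_PRIORS,
    edgotype: str | None = None,
) -> dict[str, FitnessPosterior]:
    """Exact posteriors P(N|T), P(M|T), P(S|T) for each edgotype.

    Implements the marginal (law of total probability over the three
    fitness classes) followed by Bayes' theorem.
    """
    targets = EDGOTYPES if edgotype is None else (edgotype,)
    out: dict[str, FitnessPosterior] = {}
    for t in targets:
        p_n_t = conditionals.given_n[t].p
        p_m_t = conditionals.given_m[t].p
        p_s_t = conditionals.p_t_given_s(t)
        p_t = p_n_t * priors.p_n + p_m_t * priors.p_m + p_s_t * priors.p_s
        if p_t == 0:
            raise UndefinedPosteriorError(
                f"P(T)=0 for edgotype {t!r}; posteriors undefined"
            )
        posts = {
            NEUTRAL: p_n_t * priors.p_n / p_t,
            MILD: p_m_t * priors.p_m / p_t,
            STRONG: p_s_t * priors.p_s / p_t,
        }
        coeffs = {
            NEUTRAL: (priors.p_m / priors.p_n, p_s_t * priors.p_s / priors.p_n),
            MILD: (priors.p_n / priors.p_m, p_s_t * priors.p_s / priors.p_m),
            STRONG: (
                (priors.p_n / (p_s_t * priors.p_s),
                 priors.p_m / (p_s_t * priors.p_s))
                if p_s_t * priors.p_s > 0
                else (math.inf, math.inf)
            ),
        }
        out[t] = FitnessPosterior(
            edgotype=t,
            assumption=conditionals.assumption,
            p_t=p_t,
            posteriors=posts,
            coefficients=coeffs,
        )
    return out


def _z(level: float) -> float:
    if abs(level - 0.95) < 1e-12:
        return Z_95
    return float(stats.norm.ppf(0.5 + level / 2.0))


def _continuity(est: BinomialEstimate) -> tuple[float, float]:
    """Counts for variance formulas; add 1/2 to a zero success count."""
    x, n = est.x, est.n
    if x is None or n is None:
        raise ValueError("interval estimation requires count bases (x, n)")
    if x == 0 or x == n:
        warnings.warn(
            "zero cell in count basis; applying 1/2 continuity correction",
            stacklevel=3,
        )
        x = min(max(x, 0.5), n - 0.5)
    return x, n


def _ratio_log_ci(
    num: BinomialEstimate, den: BinomialEstimate, z: float
) -> tuple[float, float]:
    """Bland log-scale CI for the ratio of two independent proportions.

    SE(log r) = sqrt((1/x_num - 1/n_num) + (1/x_den - 1/n_den)).
    """
    x2, n2 = _continuity(num)
    x1, n1 = _continuity(den)
    r = (x2 / n2) / (x1 / n1)
    se = math.sqrt(max(1 / x2 - 1 / n2, 0.0) + max(1 / x1 - 1 / n1, 0.0))
    return r * math.exp(-z * se), r * math.exp(z * se)


def _q_interval_to_posterior(q_lo: float, q_hi: float) -> tuple[float, float]:
    """Map an interval for Q = 1/P - 1 to an interval for P, clipped to [0,1]."""
    q_lo = max(q_lo, 0.0)
    q_hi = max(q_hi, q_lo)
    lo = 1.0 / (1.0 + q_hi)
    hi = 1.0 / (1.0 + q_lo)
    return max(lo, 0.0), min(hi, 1.0)


def bland_ci(
    conditionals: ConditionalEdgotypeProbs,
    priors: FitnessPriors = DEFAULT_PRIORS,
    edgotype: str | None = None,
    level: float = 0.95,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Confidence intervals for the fitness posteriors of each edgotype.

    Writing 1/P(F|T) = 1 + Q, the interval for Q is computed as follows and
    transformed through the (monotone) equation:

    * whenever Q is an affine function k0 + k1 * r of the single ratio
      r of the two estimated conditionals (all cases except the
      Assumption-I quasi-null forms), the exact Bland log-scale interval
      for r is used;
    * otherwise (Assumption I, T = quasi-null, where the constant P(S)
      term enters through P(QN|S) = 1), a first-order delta-method
      propagation of the binomial variances is used.

    Intervals are truncated to [0, 1].  Returns
    ``{edgotype: {fitness class: (lo, hi)}}``.
    """
    z = _z(level)
    targets = EDGOTYPES if edgotype is None else (edgotype,)
    posts = fitness_posterior(conditionals, priors, edgotype=None)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for t in targets:
        est_n = conditionals.given_n[t]
        est_m = conditionals.given_m[t]
        a_ii = conditionals.assumption == ASSUMPTION_II
        const_s = (
            conditionals.assumption == ASSUMPTION_I and t == QUASI_NULL
        )  # P(T|S) = 1 enters as a genuine additive constant
        ci: dict[str, tuple[float, float]] = {}

        # --- F = N: Q = (P(M) p_m + P(S) p_s) / (P(N) p_n)
        if const_s:
            ci[NEUTRAL] = _delta_ci_ratio_form(
                a=priors.p_m / priors.p_n,
                b=priors.p_s / priors.p_n,
                num=est_m, den=est_n, z=z,
            )
        else:
            k1 = (priors.p_m + (priors.p_s if a_ii else 0.0)) / priors.p_n
            r_lo, r_hi = _ratio_log_ci(est_m, est_n, z)
            ci[NEUTRAL] = _q_interval_to_posterior(k1 * r_lo, k1 * r_hi)

        # --- F = M: Q = (P(N) p_n + P(S) p_s) / (P(M) p_m)
        if const_s:
            ci[MILD] = _delta_ci_ratio_form(
                a=priors.p_n / priors.p_m,
                b=priors.p_s / priors.p_m,
                num=est_n, den=est_m, z=z,
            )
        else:
            k0 = priors.p_s / priors.p_m if a_ii else 0.0
            k1 = priors.p_n / priors.p_m
            r_lo, r_hi = _ratio_log_ci(est_n, est_m, z)
            ci[MILD] = _q_interval_to_posterior(k0 + k1 * r_lo, k0 + k1 * r_hi)

        # --- F = S: Q = (P(N) p_n + P(M) p_m) / (P(S) p_s)
        if conditionals.assumption == ASSUMPTION_I and t != QUASI_NULL:
            ci[STRONG] = (0.0, 0.0)  # P(T|S) = 0 identically
        elif const_s:
            ci[STRONG] = _delta_ci_sum_form(
                a=priors.p_n / priors.p_s,
                b=priors.p_m / priors.p_s,
                first=est_n, second=est_m, z=z,
            )
        else:  # Assumption II: Q = (P(N)/P(S)) r + P(M)/P(S), r = p_n/p_m
            k0 = priors.p_m / priors.p_s
            k1 = priors.p_n / priors.p_s
            r_lo, r_hi = _ratio_log_ci(est_n, est_m, z)
            ci[STRONG] = _q_interval_to_posterior(k0 + k1 * r_lo, k0 + k1 * r_hi)

        # keep point estimates inside intervals against rounding jitter
        for f in FITNESS_CLASSES:
            lo, hi = ci[f]
            p = posts[t].posteriors[f]
            ci[f] = (min(lo, p), max(hi, p))
        out[t] = ci
    return out


def _delta_ci_ratio_form(
    a: float, b: float, num: BinomialEstimate, den: BinomialEstimate, z: float
) -> tuple[float, float]:
    """Delta-method CI for Q = (a*p2 + b)/p1 with independent binomials."""
    x2, n2 = _continuity(num)
    x1, n1 = _continuity(den)
    p2, p1 = x2 / n2, x1 / n1
    q = (a * p2 + b) / p1
    v2 = p2 * (1 - p2) / n2
    v1 = p1 * (1 - p1) / n1
    var = (a / p1) ** 2 * v2 + (q / p1) ** 2 * v1
    half = z * math.sqrt(var)
    return _q_interval_to_posterior(q - half, q + half)


def _delta_ci_sum_form(
    a: float, b: float, first: BinomialEstimate, second: BinomialEstimate, z: float
) -> tuple[float, float]:
    """Delta-method CI for Q = a*p1 + b*p2 with independent binomials."""
    x1, n1 = _continuity(first)
    x2, n2 = _continuity(second)
    p1, p2 = x1 / n1, x2 / n2
    q = a * p1 + b * p2
    var = a**2 * p1 * (1 - p1) / n1 + b**2 * p2 * (1 - p2) / n2
    half = z * math.sqrt(var)
    return _q_interval_to_posterior(q - half, q + half)


def parametric_bootstrap_ci(
    conditionals: ConditionalEdgotypeProbs,
    priors: FitnessPriors,
    edgotype: str,
    fitness_class: str,
    n_draws: int = 1_000_000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Simulation-based CI for one posterior, by parametric bootstrap.

    Resamples the two success counts from independent binomials at their
    point estimates and recomputes the posterior for each draw; returns
    the central ``level`` percentile interval.  Serves as an independent
    check on the analytic intervals.
    """
    rng = rng if rng is not None else np.random.default_rng()
    est_n = conditionals.given_n[edgotype]
    est_m = conditionals.given_m[edgotype]
    if not (est_n.has_counts() and est_m.has_counts()):
        raise ValueError("bootstrap requires count bases")
    n_n, n_m = int(round(est_n.n)), int(round(est_m.n))
    p_n = est_n.x / est_n.n
    p_m = est_m.x / est_m.n
    xs_n = rng.binomial(n_n, p_n, size=n_draws) / n_n
    xs_m = rng.binomial(n_m, p_m, size=n_draws) / n_m
    if conditionals.assumption == ASSUMPTION_I:
        xs_s = np.full(n_draws, 1.0 if edgotype == QUASI_NULL else 0.0)
    else:
        xs_s = xs_m
    p_t = xs_n * priors.p_n + xs_m * priors.p_m + xs_s * priors.p_s
    num = {
        NEUTRAL: xs_n * priors.p_n,
        MILD: xs_m * priors.p_m,
        STRONG: xs_s * priors.p_s,
    }[fitness_class]
    ok = p_t > 0
    post = num[ok] / p_t[ok]
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(post, alpha)),
        float(np.quantile(post, 1.0 - alpha)),
    )


def merge_assumptions(
    posterior_a1: dict[str, FitnessPosterior],
    posterior_a2: dict[str, FitnessPosterior],
) -> pd.DataFrame:
    """Merged interval per (edgotype, fitness class).

    The reported range runs from the Assumption-I estimate to the mean of
    the Assumption-I and Assumption-II estimates (endpoints ordered), the
    two bracketing scenarios for the unknown edgotype distribution of
    strongly detrimental mutations.
    """
    rows = []
    for t in EDGOTYPES:
        p1 = posterior_a1[t].posteriors
        p2 = posterior_a2[t].posteriors
        for f in FITNESS_CLASSES:
            v1 = p1[f]
            mid = (p1[f] + p2[f]) / 2.0
            lo, hi = sorted((v1, mid))
            rows.append(
                {"edgotype": t, "fitness_class": f,
                 "estimate_a1": v1, "estimate_a2": p2[f],
                 "merged_low": lo, "merged_high": hi}
            )
    return pd.DataFrame(rows)
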