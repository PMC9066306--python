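"""Inferential toolkit: rank-based group comparisons, Bayes factors,
rank ANCOVA, age-partialled correlations, power analysis and the
catch-trial criterion.

Conventions
-----------
* The reported W defaults to U of the first sample (configurable, since
  rank-sum conventions differ between packages).
* Rank-biserial correlation is ``2*U1/(n1*n2) - 1`` with U1 counting x > y
  pairs: positive when the *first* group tends larger.  Pass the typically
  developing group first to reproduce the sign pattern of the study reports.
* "Cauchy prior with a distribution of (0, 1)" is read as location 0,
  scale 1; the scale is exposed everywhere (0.707 is the other common
  default).
* Bayes factors are BF10 (alternative over null); values between 1/3 and 3
  are labelled inconclusive.
* Ties take mid-ranks everywhere; the exact Mann-Whitney distribution is
  only used for tie-free samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy import stats as sps

from .errors import IncompleteInputError, ParameterDomainError

__all__ = [
    "GroupComparison",
    "AncovaResult",
    "PowerSpec",
    "BayesRankResult",
    "NormalityGate",
    "mann_whitney",
    "jzs_bf10",
    "jzs_bf10_gauss_quadrature",
    "bayes_rank_bf10",
    "quade_ancova",
    "partial_rank_correlation",
    "required_n_two_sample",
    "catch_exclusion_threshold",
    "normality_gate",
    "bf_label",
    "hypothesis_table",
    "age_controlled_table",
    "HYPOTHESIS_MEASURES",
]


def bf_label(bf10: float) -> str:
    """Evidence band: BF10 in (1/3, 3) is inconclusive."""
    if bf10 < 1.0 / 3.0:
        return "supports null"
    if bf10 > 3.0:
        return "supports alternative"
    return "inconclusive"


@dataclass
class GroupComparison:
    """Mann-Whitney W, p, rank-biserial and (optionally) BF10."""

    w_stat: float
    p_two_sided: float
    rank_biserial: float
    bf10: Optional[float] = None
    method: str = "exact"

    @property
    def bf_band(self) -> Optional[str]:
        return None if self.bf10 is None else bf_label(self.bf10)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    w_convention: str = "u1",
) -> GroupComparison:
    """Two-sided Mann-Whitney test with rank-biserial effect size.

    Uses the exact permutation distribution when ``n1*n2 <= 400`` and there
    are no ties, otherwise the tie-corrected normal approximation with
    continuity correction.  ``w_convention`` selects the reported W: ``"u1"``
    (U of the first sample, default), ``"u2"``, or ``"rank_sum"`` (rank sum
    of the first sample).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise IncompleteInputError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    exact = (n1 * n2 <= 400) and not ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u1 = float(res.statistic)
    u2 = n1 * n2 - u1
    rank_biserial = 2.0 * u1 / (n1 * n2) - 1.0
    if w_convention == "u1":
        w = u1
    elif w_convention == "u2":
        w = u2
    elif w_convention == "rank_sum":
        w = u1 + n1 * (n1 + 1) / 2.0
    else:
        raise ParameterDomainError(f"unknown w_convention {w_convention!r}")
    return GroupComparison(
        w_stat=w,
        p_two_sided=float(min(res.pvalue, 1.0)),
        rank_biserial=rank_biserial,
        method="exact" if exact else "approximate",
    )


def jzs_bf10(t_stat: float, n1: int, n2: int, cauchy_scale: float = 1.0) -> float:
    """Two-sample JZS Bayes factor for a t statistic.

    Integrates the noncentral-t likelihood over a Cauchy(0, scale) prior on
    the standardized effect size delta and divides by the central-t
    likelihood at delta = 0.  The substitution delta = scale*tan(theta) maps
    the integral onto a finite interval evaluated by Gauss-Legendre
    quadrature.
    """
    if not math.isfinite(t_stat):
        raise ParameterDomainError("t statistic must be finite")
    if n1 < 2 or n2 < 2:
        raise ParameterDomainError("need at least two observations per group")
    if cauchy_scale <= 0:
        raise ParameterDomainError("cauchy_scale must be positive")
    df = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    nodes, weights = np.polynomial.legendre.leggauss(400)
    theta = nodes * (np.pi / 2.0)
    delta = cauchy_scale * np.tan(theta)
    # cauchy pdf * ddelta/dtheta = 1/pi  (the substitution absorbs the prior)
    like = sps.nct.pdf(t_stat, df, delta * math.sqrt(n_eff))
    numerator = float(np.sum(weights * (np.pi / 2.0) * like) / np.pi)
    denominator = float(sps.t.pdf(t_stat, df))
    return numerator / denominator


def jzs_bf10_gauss_quadrature(
    t_stat: float, n1: int, n2: int, cauchy_scale: float = 1.0
) -> float:
    """Independent JZS route: marginalize over g with g ~ InvGamma(1/2, r^2/2).

    Serves as a numerical cross-check on :func:`jzs_bf10`; both must agree.
    """
    df = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    r = cauchy_scale
    t2 = t_stat**2

    def integrand(g):
        return (
            (1.0 + n_eff * g) ** -0.5
            * (1.0 + t2 / (df * (1.0 + n_eff * g))) ** (-(df + 1) / 2.0)
            * (r**2 / 2.0) ** 0.5
            / special.gamma(0.5)
            * g ** (-1.5)
            * np.exp(-(r**2) / (2.0 * g))
        )

    numerator, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    denominator = (1.0 + t2 / df) ** (-(df + 1) / 2.0)
    return float(numerator / denominator)


class BayesRankResult(NamedTuple):
    bf10: float
    mc_se: float
    per_chain: tuple[float, ...]


def _truncnorm_draw(rng, mean, lower, upper):
    """Vectorized truncated-normal sampling via inverse-CDF (unit variance)."""
    a = special.ndtr(lower - mean)
    b = special.ndtr(upper - mean)
    u = a + (b - a) * rng.random(mean.shape)
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    return mean + special.ndtri(u)


def bayes_rank_bf10(
    x: Sequence[float],
    y: Sequence[float],
    cauchy_scale: float = 1.0,
    iterations: int = 10000,
    chains: int = 5,
    seed: Optional[int] = None,
    burn_frac: float = 0.1,
) -> BayesRankResult:
    """Bayesian rank-based two-sample test (latent-normal data augmentation).

    Only the rank order of the pooled data enters.  Latent normal values
    v_i ~ N(+/- delta/2, 1) are Gibbs-sampled subject to the rank-order
    constraints (odd/even positions alternately, which is a valid chromatic
    scheme since each value is truncated only by its immediate neighbours),
    with a Cauchy(0, scale) prior on the standardized location shift delta
    via the usual normal/inverse-gamma mixture.  BF10 comes from the
    Savage-Dickey ratio with a Rao-Blackwellised estimate of the posterior
    density at delta = 0; the Monte-Carlo SE is the spread of the per-chain
    Bayes factors.

    Ties in the pooled sample are broken by stable sort order (documented
    approximation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise IncompleteInputError("both samples must be non-empty")
    if iterations < 1000:
        warnings.warn("fewer than 1000 iterations: Bayes factor may be unstable")
    pooled = np.concatenate([x, y])
    signs = np.concatenate([-np.ones(len(x)), np.ones(len(y))])  # x: -d/2, y: +d/2
    order = np.argsort(pooled, kind="stable")
    s_sorted = signs[order]
    n = len(pooled)
    r = cauchy_scale
    burn = max(int(burn_frac * iterations), 1)
    prior_at_zero = 1.0 / (math.pi * r)
    ss = np.random.SeedSequence(seed)
    chain_bfs = []
    odd = np.arange(0, n, 2)
    even = np.arange(1, n, 2)
    for chain_seq in ss.spawn(chains):
        rng = np.random.default_rng(chain_seq)
        v = special.ndtri((np.arange(1, n + 1)) / (n + 1.0))  # normal scores init
        delta, g = 0.0, r**2
        dens_at_zero = []
        for it in range(iterations):
            mu = s_sorted * (delta / 2.0)
            for idx in (odd, even):
                lower = np.where(idx == 0, -np.inf, v[np.maximum(idx - 1, 0)])
                upper = np.where(idx == n - 1, np.inf, v[np.minimum(idx + 1, n - 1)])
                v[idx] = _truncnorm_draw(rng, mu[idx], lower, upper)
            prec = n / 4.0 + 1.0 / g
            mean = (np.dot(s_sorted, v) / 2.0) / prec
            delta = mean + rng.normal() / math.sqrt(prec)
            g = (delta**2 + r**2) / (2.0 * rng.gamma(1.0))
            if it >= burn:
                sd = 1.0 / math.sqrt(prec)
                dens_at_zero.append(math.exp(-0.5 * (mean / sd) ** 2) / (sd * math.sqrt(2 * math.pi)))
        post_at_zero = float(np.mean(dens_at_zero))
        chain_bfs.append(prior_at_zero / post_at_zero)
    chain_bfs = np.asarray(chain_bfs)
    bf10 = float(np.exp(np.mean(np.log(chain_bfs))))
    mc_se = float(np.std(np.log(chain_bfs), ddof=1) / math.sqrt(chains)) if chains > 1 else float("nan")
    return BayesRankResult(bf10=bf10, mc_se=mc_se, per_chain=tuple(float(b) for b in chain_bfs))


@dataclass
class AncovaResult:
    """Rank ANCOVA (Quade) output: group test on residual deviation ranks."""

    statistic: float
    p_two_sided: float
    slope: float
    residuals: np.ndarray


def quade_ancova(dv: Sequence[float], covariate: Sequence[float], group) -> AncovaResult:
    """Quade's rank ANCOVA for a two-group comparison controlling a covariate.

    Ranks the dependent variable and covariate (mid-ranks for ties), centres
    both to deviation scores, regresses the DV deviations on the covariate
    deviations by least squares, and runs a two-sample t-test on the residual
    deviation ranks between the groups.
    """
    dv = np.asarray(dv, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    group = np.asarray(group)
    if not (len(dv) == len(cov) == len(group)):
        raise IncompleteInputError("dv, covariate and group must have equal lengths")
    labels = np.unique(group)
    if len(labels) != 2:
        raise ParameterDomainError(f"exactly two groups required, got {len(labels)}")
    dd = sps.rankdata(dv) - (len(dv) + 1) / 2.0
    cd = sps.rankdata(cov) - (len(cov) + 1) / 2.0
    denom = float(np.dot(cd, cd))
    if denom == 0.0:
        warnings.warn("constant covariate: falling back to a plain rank test")
        slope = 0.0
    else:
        slope = float(np.dot(cd, dd) / denom)
    resid = dd - slope * cd
    a = resid[group == labels[0]]
    b = resid[group == labels[1]]
    t, p = sps.ttest_ind(a, b)
    return AncovaResult(statistic=float(t), p_two_sided=float(p), slope=slope, residuals=resid)


def partial_rank_correlation(a, b, covariate) -> tuple[float, float]:
    """Partial correlation of rank-transformed a and b, controlling a ranked
    covariate; two-sided t-based p-value with n - 3 degrees of freedom."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = len(a)
    if not (len(b) == len(c) == n):
        raise IncompleteInputError("all inputs must have equal lengths")
    if n < 4:
        raise IncompleteInputError("need at least 4 observations")
    ra, rb, rc = sps.rankdata(a), sps.rankdata(b), sps.rankdata(c)
    r_ab = float(np.corrcoef(ra, rb)[0, 1])
    r_ac = float(np.corrcoef(ra, rc)[0, 1])
    r_bc = float(np.corrcoef(rb, rc)[0, 1])
    denom = math.sqrt((1.0 - r_ac**2) * (1.0 - r_bc**2))
    r = (r_ab - r_ac * r_bc) / denom if denom > 0 else 0.0
    r = max(min(r, 1.0), -1.0)
    df = n - 3
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(p)


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of an a-priori two-sample power analysis."""

    effect_size_d: float
    alpha: float = 0.05
    power: float = 0.95
    tails: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ParameterDomainError("alpha and power must be in (0, 1)")
        if self.effect_size_d <= 0:
            raise ParameterDomainError("effect size d must be positive")
        if self.tails not in (1, 2):
            raise ParameterDomainError("tails must be 1 or 2")


def _two_sample_power(d: float, n: int, alpha: float, tails: int) -> float:
    df = 2 * n - 2
    ncp = d * math.sqrt(n / 2.0)
    if tails == 2:
        tc = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp))
    tc = sps.t.ppf(1.0 - alpha, df)
    return float(sps.nct.sf(tc, df, ncp))


def required_n_two_sample(spec: PowerSpec, n_max: int = 10**6) -> int:
    """Smallest per-group n for which a two-sample t-test reaches the
    requested power (noncentral-t, equal group sizes)."""
    for n in range(2, n_max + 1):
        if _two_sample_power(spec.effect_size_d, n, spec.alpha, spec.tails) >= spec.power:
            return n
    raise ParameterDomainError(f"requested power unreachable within n <= {n_max}")


def catch_exclusion_threshold(n_catch: int, p_chance: float = 0.5, alpha: float = 0.05) -> int:
    """Smallest error count whose catch performance is *not* significantly
    above chance.

    With e errors the one-sided binomial p-value is P(X >= n - e | p_chance);
    returns the smallest e for which that p-value is >= alpha.  (With e = n
    the p-value is 1, so the search always terminates.)
    """
    if n_catch < 1:
        raise ParameterDomainError("n_catch must be >= 1")
    if not (0.0 < p_chance < 1.0 and 0.0 < alpha <= 1.0):
        raise ParameterDomainError("p_chance and alpha must be in (0, 1)")
    for e in range(1, n_catch + 1):
        p_val = float(sps.binom.sf(n_catch - e - 1, n_catch, p_chance))
        if p_val >= alpha:
            return e
    return n_catch


class NormalityGate(NamedTuple):
    w_stat: float
    p: float
    use_nonparametric: bool


def normality_gate(x, alpha: float = 0.05) -> NormalityGate:
    """Shapiro-Wilk gate: switch to nonparametric tests when p < alpha."""
    x = np.asarray(x, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise IncompleteInputError("Shapiro-Wilk requires 3 <= n <= 5000")
    w, p = sps.shapiro(x)
    return NormalityGate(w_stat=float(w), p=float(p), use_nonparametric=bool(p < alpha))


# ---------------------------------------------------------------------------
# Hypothesis-level reporting

#: the six pre-registered group comparisons, in order
HYPOTHESIS_MEASURES = (
    ("H1", "motion", "coherence_threshold"),
    ("H2", "motion", "n_samp"),
    ("H3", "motion", "sigma_int"),
    ("H4", "orientation", "coherence_threshold"),
    ("H5", "orientation", "n_samp"),
    ("H6", "orientation", "sigma_int"),
)

_COLUMN_FOR_MEASURE = {
    "coherence_threshold": "coherence_threshold",
    "n_samp": "n_samp",
    "sigma_int": "sigma_int_deg",
}


def _measure_samples(df: pd.DataFrame, modality: str, measure: str,
                     reference_group: str) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    col = _COLUMN_FOR_MEASURE[measure]
    sub = df[(df["modality"] == modality)].dropna(subset=[col])
    ref = sub[sub["group"] == reference_group][col].to_numpy()
    other = sub[sub["group"] != reference_group][col].to_numpy()
    return ref, other, sub


def hypothesis_table(
    en_df: pd.DataFrame,
    reference_group: str = "typical",
    cauchy_scale: float = 1.0,
    iterations: int = 10000,
    chains: int = 5,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Six-row results table: one Mann-Whitney + Bayesian comparison per
    pre-registered measure.

    ``en_df`` must carry columns group, modality, coherence_threshold,
    n_samp, sigma_int_deg (one row per participant and modality).  The
    reference group is passed first to every test, so a positive
    rank-biserial means the reference group tends larger.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for (hyp, modality, measure), sub_seed in zip(
        HYPOTHESIS_MEASURES, ss.spawn(len(HYPOTHESIS_MEASURES))
    ):
        ref, other, _ = _measure_samples(en_df, modality, measure, reference_group)
        if len(ref) == 0 or len(other) == 0:
            raise IncompleteInputError(f"no data for {modality}/{measure}")
        gate_ref = normality_gate(ref)
        gate_other = normality_gate(other)
        comp = mann_whitney(ref, other)
        bf = bayes_rank_bf10(
            ref, other, cauchy_scale=cauchy_scale, iterations=iterations,
            chains=chains, seed=int(np.random.default_rng(sub_seed).integers(2**31)),
        )
        rows.append(
            {
                "hypothesis": hyp,
                "modality": modality,
                "measure": measure,
                "median_reference": float(np.median(ref)),
                "median_comparison": float(np.median(other)),
                "w": comp.w_stat,
                "p": comp.p_two_sided,
                "rank_biserial": comp.rank_biserial,
                "bf10": bf.bf10,
                "bf_label": bf_label(bf.bf10),
                "shapiro_p_reference": gate_ref.p,
                "shapiro_p_comparison": gate_other.p,
                "use_nonparametric": gate_ref.use_nonparametric or gate_other.use_nonparametric,
            }
        )
    return pd.DataFrame(rows)


def age_controlled_table(
    en_df: pd.DataFrame,
    reference_group: str = "typical",
    cauchy_scale: float = 1.0,
) -> pd.DataFrame:
    """Age-controlled re-analysis: Quade rank ANCOVA per measure plus a JZS
    Bayes factor computed from the t statistic on the residual deviation
    ranks.  ``en_df`` needs an ``age_years`` column in addition to the
    hypothesis-table columns."""
    rows = []
    for hyp, modality, measure in HYPOTHESIS_MEASURES:
        col = _COLUMN_FOR_MEASURE[measure]
        sub = en_df[en_df["modality"] == modality].dropna(subset=[col, "age_years"])
        is_ref = (sub["group"] == reference_group).to_numpy()
        res = quade_ancova(sub[col].to_numpy(), sub["age_years"].to_numpy(), is_ref)
        n_ref, n_other = int(is_ref.sum()), int((~is_ref).sum())
        bf = jzs_bf10(res.statistic, n_ref, n_other, cauchy_scale=cauchy_scale)
        rows.append(
            {
                "hypothesis": hyp,
                "modality": modality,
                "measure": measure,
                "ancova_t": res.statistic,
                "ancova_p": res.p_two_sided,
                "slope": res.slope,
                "bf10": bf,
                "bf_label": bf_label(bf),
            }
        )
    return pd.DataFrame(rows)
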