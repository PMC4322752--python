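"""Complete-data likelihood ratio tests for X-linked case-parent triads.

Four nested analyses of the same multinomial cell counts:

* :func:`exchangeability_test` -- 2-df check that, conditional on the
  parental allele sum, variant alleles are placed at random across the
  parents' three X chromosomes (mother 2/3 vs father 1/3 within each
  informative mating-sum stratum).
* :func:`ssx_lrt` -- the sex-stratified transmission LRT: conditions on
  the full parental mating type and sex, so only heterozygous-mother
  transmissions inform it.
* :func:`parent_only_lrt` -- uses only the parental genotypes, via the
  exchangeability-based distribution of (M, F) given M+F; an independent
  replication of the transmission signal.
* :func:`pix_lrt` -- the parent-informed LRT: conditions only on the
  mating sum and sex, capturing transmission and parental enrichment in
  one likelihood.  :func:`combine_z` merges per-sex 1-df statistics into
  a single signed Z weighted by informative-family counts.

All maximum-likelihood fits are low-dimensional numeric maximizations on
the log-relative-risk scale, bracketed to R in [1e-6, 1e6]; tests verify
them against brute-force grid search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import xlogy

from .risk import (
    NULL_RR,
    RelativeRiskModel,
    matingsum_cell_probs,
    parent_pair_probs,
    transmission_prob,
)
from .triad_model import CellCounts

__all__ = [
    "LOG_RISK_CAP",
    "ExchangeabilityResult",
    "SexTestResult",
    "CombinedResult",
    "JointFit",
    "exchangeability_test",
    "ssx_lrt",
    "parent_only_lrt",
    "pix_lrt",
    "combine_z",
    "fit_joint_model",
]

#: relative risks are constrained to [1e-6, 1e6] during maximization
LOG_RISK_CAP = math.log(1e6)


@dataclass
class ExchangeabilityResult:
    alpha1_hat: float
    alpha2_hat: float
    lrt: float
    df: int
    p_value: float
    flags: tuple[str, ...] = ()


@dataclass
class SexTestResult:
    """A per-sex LRT: statistic, sign of the fitted effect, and weights."""

    method: str
    sex: str
    statistic: float
    df: int
    sign: int
    n_informative: float
    rr: RelativeRiskModel
    p_value: float
    loglik_full: float
    loglik_null: float
    flags: tuple[str, ...] = ()


@dataclass
class CombinedResult:
    z: float
    p_value: float
    flags: tuple[str, ...] = ()


@dataclass
class JointFit:
    rr: RelativeRiskModel
    lrt: float
    df: int
    p_value: float
    loglik_full: float
    loglik_null: float


# ---------------------------------------------------------------------------
# exchangeability
# ---------------------------------------------------------------------------

def _binom_lrt_vs(n_success: float, n_failure: float, p0: float) -> float:
    """2 * log-LR of a binomial against fixed null probability p0."""
    n = n_success + n_failure
    if n == 0:
        return 0.0
    phat = n_success / n
    ll_hat = xlogy(n_success, phat) + xlogy(n_failure, 1.0 - phat)
    ll_0 = xlogy(n_success, p0) + xlogy(n_failure, 1.0 - p0)
    return max(0.0, 2.0 * (ll_hat - ll_0))


def exchangeability_test(parent_counts) -> ExchangeabilityResult:
    """Test parental allelic exchangeability from mating-type counts.

    Within mating-sum stratum 1 the mother carries the single variant
    with probability 2/3 under exchangeability; within stratum 2 the
    heterozygous-mother configuration likewise has probability 2/3.  The
    statistic is the sum of the two binomial LRTs; empty strata reduce
    the degrees of freedom and are flagged.
    """
    if isinstance(parent_counts, CellCounts):
        margins = parent_counts.parent_margins()
    else:
        margins = dict(parent_counts)
    n10 = margins.get((1, 0), 0.0)
    n01 = margins.get((0, 1), 0.0)
    n11 = margins.get((1, 1), 0.0)
    n20 = margins.get((2, 0), 0.0)

    flags: list[str] = []

    def alpha_hat(a: float, b: float) -> float:
        if a > 0 and b > 0:
            return math.log(a / b / 2.0)
        flags.append("boundary_alpha")
        if a == 0 and b == 0:
            return math.nan
        return math.inf if b == 0 else -math.inf

    lrt = 0.0
    df = 0
    if n10 + n01 > 0:
        lrt += _binom_lrt_vs(n10, n01, 2.0 / 3.0)
        df += 1
        if n10 + n01 < 10:
            flags.append("small_stratum_1")
    else:
        flags.append("empty_stratum_1")
    if n11 + n20 > 0:
        lrt += _binom_lrt_vs(n11, n20, 2.0 / 3.0)
        df += 1
        if n11 + n20 < 10:
            flags.append("small_stratum_2")
    else:
        flags.append("empty_stratum_2")
    p = stats.chi2.sf(lrt, df) if df > 0 else math.nan
    return ExchangeabilityResult(
        alpha1_hat=alpha_hat(n10, n01),
        alpha2_hat=alpha_hat(n11, n20),
        lrt=lrt, df=df, p_value=p, flags=tuple(flags))


# ---------------------------------------------------------------------------
# per-sex LRT machinery
# ---------------------------------------------------------------------------

def theta_to_rr(theta, sex: str, mode: str) -> RelativeRiskModel:
    """Map free log-RR parameters to a :class:`RelativeRiskModel`."""
    theta = np.clip(np.atleast_1d(np.asarray(theta, dtype=float)),
                    -LOG_RISK_CAP, LOG_RISK_CAP)
    if sex == "boy":
        return RelativeRiskModel(r_boy=math.exp(theta[0]))
    if mode == "logadditive_girls":
        r1 = math.exp(theta[0])
        return RelativeRiskModel(r_girl_het=r1, r_girl_hom=r1 * r1,
                                 mode="logadditive_girls")
    if mode == "codominant":
        return RelativeRiskModel(r_girl_het=math.exp(theta[0]),
                                 r_girl_hom=math.exp(theta[1]))
    raise ValueError(f"mode {mode!r} not supported for a single-sex fit")


def n_free_params(sex: str, mode: str) -> int:
    if sex == "boy":
        return 1
    return 1 if mode == "logadditive_girls" else 2


def _maximize(loglik, k: int) -> tuple[np.ndarray, float]:
    """Maximize a k-parameter log-likelihood on the log-RR scale."""
    if k == 1:
        res = optimize.minimize_scalar(
            lambda t: -loglik([t]),
            bounds=(-LOG_RISK_CAP, LOG_RISK_CAP), method="bounded",
            options={"xatol": 1e-12})
        return np.array([res.x]), -res.fun
    res = optimize.minimize(
        lambda t: -loglik(t), x0=np.zeros(k), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return np.asarray(res.x), -res.fun


def _sign_of(rr: RelativeRiskModel, sex: str) -> int:
    primary = rr.r_boy if sex == "boy" else rr.r_girl_het
    return -1 if primary < 1.0 else 1


def _lrt_result(method: str, counts, sex: str, mode: str,
                cell_logprob, n_informative: float) -> SexTestResult:
    """Generic 1- or 2-parameter conditional LRT over cell counts.

    ``cell_logprob(rr)`` returns the log-likelihood of the counts under a
    relative-risk model; the null fixes all risks at 1.
    """
    flags: list[str] = []
    k = n_free_params(sex, mode)
    df = k

    def loglik(theta):
        return cell_logprob(theta_to_rr(theta, sex, mode))

    ll_null = cell_logprob(NULL_RR)
    if n_informative <= 0:
        flags.append("no_informative_families")
        return SexTestResult(method, sex, math.nan, df, 1, 0.0, NULL_RR,
                             math.nan, ll_null, ll_null, tuple(flags))
    theta_hat, ll_full = _maximize(loglik, k)
    if np.any(np.abs(theta_hat) >= LOG_RISK_CAP - 1e-6):
        flags.append("boundary")
    x = max(0.0, 2.0 * (ll_full - ll_null))
    rr_hat = theta_to_rr(theta_hat, sex, mode)
    # S = +1 by convention at a (numerically) zero statistic
    sign = 1 if x < 1e-10 else _sign_of(rr_hat, sex)
    return SexTestResult(
        method=method, sex=sex, statistic=x, df=df,
        sign=sign, n_informative=n_informative,
        rr=rr_hat, p_value=stats.chi2.sf(x, df),
        loglik_full=ll_full, loglik_null=ll_null, flags=tuple(flags))


def _sex_counts(cells: CellCounts, sex: str) -> dict[tuple[int, int, int], float]:
    return cells.sex_cells(sex)


def ssx_lrt(cells: CellCounts, sex: str,
            mode: str = "logadditive_girls") -> SexTestResult:
    """Sex-stratified transmission LRT (conditional on mating type and sex).

    For sons this is the binomial LRT on transmissions from heterozygous
    mothers; for daughters under the girls-log-additive constraint both
    heterozygous-mother strata pool into one binomial.  ``n_informative``
    counts triads with a heterozygous mother.
    """
    counts = _sex_counts(cells, sex)

    def ll(rr: RelativeRiskModel) -> float:
        return sum(xlogy(n, transmission_prob(m, f, c, sex, rr))
                   for (m, f, c), n in counts.items() if n > 0)

    n_inf = sum(n for (m, f, c), n in counts.items() if m == 1)
    return _lrt_result("ssx", counts, sex, mode, ll, n_inf)


def pix_lrt(cells: CellCounts, sex: str,
            mode: str = "logadditive_girls") -> SexTestResult:
    """Parent-informed LRT (conditional on the mating sum and sex).

    Uses the full triad distribution given M+F, so mating types
    (M=0, F=1) and (M=2, F=0) become informative in addition to the
    heterozygous-mother strata.  ``n_informative`` counts families whose
    parental sum is 1 or 2.
    """
    counts = _sex_counts(cells, sex)

    def ll(rr: RelativeRiskModel) -> float:
        probs = matingsum_cell_probs(sex, rr)
        return sum(xlogy(n, probs[cell]) for cell, n in counts.items() if n > 0)

    n_inf = sum(n for (m, f, c), n in counts.items() if m + f in (1, 2))
    return _lrt_result("pix", counts, sex, mode, ll, n_inf)


def parent_only_lrt(parent_counts, sex: str,
                    mode: str = "logadditive_girls") -> SexTestResult:
    """Parent-only LRT on mating-type margins N_{M,F} for one sex.

    The child genotype is ignored by design; the likelihood is the
    exchangeability-based distribution of (M, F) given the mating sum,
    tilted by the offspring risk.  Accepts a :class:`CellCounts` or a
    mapping (M, F) -> count.
    """
    if isinstance(parent_counts, CellCounts):
        margins = parent_counts.parent_margins(sex)
    else:
        margins = dict(parent_counts)

    def ll(rr: RelativeRiskModel) -> float:
        probs = parent_pair_probs(sex, rr)
        return sum(xlogy(n, probs[pair]) for pair, n in margins.items() if n > 0)

    n_inf = sum(n for (m, f), n in margins.items() if m + f in (1, 2))
    return _lrt_result("parent_only", margins, sex, mode, ll, n_inf)


# ---------------------------------------------------------------------------
# combining the sexes
# ---------------------------------------------------------------------------

def combine_z(boy: SexTestResult | None, girl: SexTestResult | None) -> CombinedResult:
    """Weighted combined Z over the two offspring sexes.

    z = (S_B sqrt(N_B X_B) + S_G sqrt(N_G X_G)) / sqrt(N_B + N_G); the
    squared convex weights sum to 1, so z is standard normal under the
    null and z**2 is chi-squared on 1 df.  Requires 1-df inputs from the
    same method family.
    """
    flags: list[str] = []
    parts = []
    for res in (boy, girl):
        if res is None:
            continue
        if res.df != 1:
            raise ValueError("combine_z requires 1-df per-sex statistics")
        if math.isnan(res.statistic) or res.n_informative <= 0:
            flags.append(f"no_information_{res.sex}")
            continue
        parts.append((res.sign, res.n_informative, res.statistic))
    n_tot = sum(n for _, n, _ in parts)
    if n_tot <= 0:
        return CombinedResult(math.nan, math.nan, tuple(flags) + ("undefined",))
    z = sum(s * math.sqrt(n * x) for s, n, x in parts) / math.sqrt(n_tot)
    return CombinedResult(z, stats.chi2.sf(z * z, 1), tuple(flags))


# ---------------------------------------------------------------------------
# pooled constrained fits
# ---------------------------------------------------------------------------

_JOINT_HYPOTHESES = ("xinactivation", "joint_logadditive", "xinactivation_null")


def fit_joint_model(cells: CellCounts, hypothesis: str) -> JointFit:
    """Pooled two-sex transmission model under a cross-sex risk constraint.

    ``xinactivation``: alternative R_G2 = R_B with R_G1 free, tested
    against all risks 1 (2 df).  ``joint_logadditive``: alternative
    R_G1**2 = R_G2 = R_B, against all risks 1 (1 df).
    ``xinactivation_null``: tests the constraint R_G2 = R_B itself
    against the free codominant model (1 df).
    """
    if hypothesis not in _JOINT_HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}; "
                         f"choose from {_JOINT_HYPOTHESES}")
    boy_counts = cells.sex_cells("boy")
    girl_counts = cells.sex_cells("girl")

    def ll(rr: RelativeRiskModel) -> float:
        out = 0.0
        for (m, f, c), n in boy_counts.items():
            if n > 0:
                out += n * math.log(transmission_prob(m, f, c, "boy", rr))
        for (m, f, c), n in girl_counts.items():
            if n > 0:
                out += n * math.log(transmission_prob(m, f, c, "girl", rr))
        return out

    def rr_xinact(theta):  # (log R_G1, log R_B), R_G2 = R_B
        t = np.clip(theta, -LOG_RISK_CAP, LOG_RISK_CAP)
        return RelativeRiskModel(r_boy=math.exp(t[1]), r_girl_het=math.exp(t[0]),
                                 r_girl_hom=math.exp(t[1]), mode="xinactivation")

    def rr_jla(theta):  # (log R_B,), R_G1 = sqrt(R_B), R_G2 = R_B
        t = np.clip(theta, -LOG_RISK_CAP, LOG_RISK_CAP)
        return RelativeRiskModel(r_boy=math.exp(t[0]),
                                 r_girl_het=math.exp(t[0] / 2.0),
                                 r_girl_hom=math.exp(t[0]),
                                 mode="joint_logadditive")

    def rr_codom(theta):  # (log R_G1, log R_G2, log R_B)
        t = np.clip(theta, -LOG_RISK_CAP, LOG_RISK_CAP)
        return RelativeRiskModel(r_boy=math.exp(t[2]), r_girl_het=math.exp(t[0]),
                                 r_girl_hom=math.exp(t[1]))

    if hypothesis == "xinactivation":
        full_map, k_full = rr_xinact, 2
        null_map, k_null = None, 0
        df = 2
    elif hypothesis == "joint_logadditive":
        full_map, k_full = rr_jla, 1
        null_map, k_null = None, 0
        df = 1
    else:  # xinactivation_null
        full_map, k_full = rr_codom, 3
        null_map, k_null = rr_xinact, 2
        df = 1

    theta_f, ll_full = _maximize(lambda t: ll(full_map(t)), k_full)
    if null_map is None:
        ll_null = ll(NULL_RR)
    else:
        _, ll_null = _maximize(lambda t: ll(null_map(t)), k_null)
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    return JointFit(rr=full_map(theta_f), lrt=lrt, df=df,
                    p_value=stats.chi2.sf(lrt, df),
                    loglik_full=ll_full, loglik_null=ll_null)
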