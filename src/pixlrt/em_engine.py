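"""Observed-data maximum likelihood for triads with missing members.

Families missing one genotyped member still carry information about the
relative risks.  The observed-data likelihood sums, per family, over all
Mendelian-consistent completions of the missing genotypes, weighting each
completion by a nuisance mass for its stratum times the method's
conditional cell probability:

* ``pix``  -- stratum = mating sum M+F (4 masses per subpopulation),
  cell term Pr(M, F, C | M+F, affected, sex);
* ``ssx``  -- stratum = mating type (M, F) (6 masses per subpopulation),
  cell term Pr(C | M, F, affected, sex).

The EM alternates distributing each incomplete family over its
completions (E) with re-maximizing the relative risk and the stratum
masses (M).  Under ``strata_mode='by_stratum'`` the nuisance masses are
fitted separately per subpopulation label while the risk parameters are
shared, which removes the bias that informative missingness across
subpopulations with different allele frequencies would otherwise induce.
Missingness is assumed MAR given subpopulation and child sex, so no
missingness parameters are needed.

Everything operates on *weighted observation patterns* (distinct observed
(M, F, C) triples with real-valued weights), so finite samples and
expected counts share one code path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exact_tests import _maximize, _sign_of, n_free_params, theta_to_rr, SexTestResult
from .risk import NULL_RR, RelativeRiskModel, admissible_cells, matingsum_cell_probs, transmission_prob
from .triad_model import TriadRecord, consistent_completions, validate_mendelian

__all__ = ["EmConfig", "EmFit", "em_fit", "em_lrt", "count_informative",
           "em_lrt_patterns", "records_to_patterns"]

#: observation pattern: (M, F, C, subpopulation label), None = unobserved
Pattern = tuple[int | None, int | None, int | None, object]


@dataclass
class EmConfig:
    tol: float = 1e-8
    max_iter: int = 500
    strata_mode: str = "pooled"

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.strata_mode not in ("pooled", "by_stratum"):
            raise ValueError("strata_mode must be 'pooled' or 'by_stratum'")


@dataclass
class EmFit:
    rr: RelativeRiskModel
    nuisance: dict
    loglik: float
    loglik_trace: list[float]
    converged: bool
    n_informative: float
    flags: tuple[str, ...] = ()


def _group(cell: tuple[int, int, int], method: str):
    m, f, _ = cell
    return m + f if method == "pix" else (m, f)


def _cell_logcond(method: str, sex: str, rr: RelativeRiskModel) -> dict:
    if method == "pix":
        probs = matingsum_cell_probs(sex, rr)
    else:
        probs = {cell: transmission_prob(*cell, sex, rr)
                 for cell in admissible_cells(sex)}
    return probs


def records_to_patterns(records: list[TriadRecord], sex: str,
                        strata_mode: str = "pooled") -> dict[Pattern, float]:
    """Aggregate one sex's records into weighted observation patterns."""
    patterns: dict[Pattern, float] = {}
    for rec in records:
        if rec.sex != sex:
            continue
        if rec.M is None and rec.F is None and rec.C is None:
            raise ValueError(f"family {rec.family_id}: no genotyped member")
        if validate_mendelian(rec) == "inconsistent":
            raise ValueError(
                f"family {rec.family_id}: no Mendelian-consistent completion")
        label = rec.stratum if strata_mode == "by_stratum" else None
        key = (rec.M, rec.F, rec.C, label)
        patterns[key] = patterns.get(key, 0.0) + 1.0
    return patterns


def _pattern_completions(pat: Pattern, sex: str) -> list[tuple[int, int, int]]:
    m, f, c, _ = pat
    cells = []
    for cell in admissible_cells(sex):
        if m is not None and cell[0] != m:
            continue
        if f is not None and cell[1] != f:
            continue
        if c is not None and cell[2] != c:
            continue
        cells.append(cell)
    if not cells:
        raise ValueError(f"pattern {pat} has no consistent completion")
    return cells


def _em(patterns: dict[Pattern, float], method: str, sex: str, mode: str,
        config: EmConfig, fix_null: bool) -> EmFit:
    groups = sorted({_group(cell, method) for cell in admissible_cells(sex)},
                    key=str)
    comp = {pat: _pattern_completions(pat, sex) for pat in patterns}
    labels = sorted({pat[3] for pat in patterns}, key=str)

    # initial stratum masses from families whose group is determined
    pi: dict = {}
    for lab in labels:
        tall = {g: 1.0 for g in groups}  # add-one smoothing
        for pat, w in patterns.items():
            if pat[3] != lab:
                continue
            gset = {_group(cell, method) for cell in comp[pat]}
            if len(gset) == 1:
                tall[next(iter(gset))] += w
        tot = sum(tall.values())
        pi[lab] = {g: v / tot for g, v in tall.items()}

    k = n_free_params(sex, mode)
    theta = np.zeros(k)
    rr = NULL_RR if fix_null else theta_to_rr(theta, sex, mode)

    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        probs = _cell_logcond(method, sex, rr)
        # E-step: fractional cell counts per label, and observed loglik
        frac = {lab: {cell: 0.0 for cell in admissible_cells(sex)} for lab in labels}
        ll = 0.0
        for pat, w in patterns.items():
            lab = pat[3]
            ws = [pi[lab][_group(cell, method)] * probs[cell] for cell in comp[pat]]
            tot = sum(ws)
            if tot <= 0.0:
                raise ValueError(f"pattern {pat}: zero likelihood mass")
            ll += w * math.log(tot)
            for cell, wi in zip(comp[pat], ws):
                frac[lab][cell] += w * wi / tot
        trace.append(ll)
        if len(trace) > 1:
            rel = (trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-300)
            if abs(rel) < config.tol:
                converged = True
                break
        # M-step: stratum masses ...
        for lab in labels:
            gtot = {g: 0.0 for g in groups}
            for cell, v in frac[lab].items():
                gtot[_group(cell, method)] += v
            tot = sum(gtot.values())
            pi[lab] = {g: v / tot for g, v in gtot.items()}
        # ... and risk parameters (pooled across labels)
        if not fix_null:
            pooled = {cell: sum(frac[lab][cell] for lab in labels)
                      for cell in admissible_cells(sex)}

            def ecll(th):
                pr = _cell_logcond(method, sex, theta_to_rr(th, sex, mode))
                return sum(n * math.log(pr[cell])
                           for cell, n in pooled.items() if n > 0)

            theta, _ = _maximize(ecll, k)
            rr = theta_to_rr(theta, sex, mode)

    flags = () if converged else ("not_converged",)
    return EmFit(rr=rr, nuisance=pi, loglik=trace[-1], loglik_trace=trace,
                 converged=converged, n_informative=math.nan, flags=flags)


def em_fit(records: list[TriadRecord], method: str, sex: str,
           mode: str = "logadditive_girls",
           config: EmConfig | None = None) -> EmFit:
    """Full (alternative-model) EM fit on possibly incomplete triads."""
    config = config or EmConfig()
    patterns = records_to_patterns(records, sex, config.strata_mode)
    fit = _em(patterns, method, sex, mode, config, fix_null=False)
    fit.n_informative = count_informative(records, method, sex)
    return fit


def em_lrt_patterns(patterns: dict[Pattern, float], method: str, sex: str,
                    mode: str = "logadditive_girls",
                    config: EmConfig | None = None,
                    n_informative: float = math.nan) -> SexTestResult:
    """Observed-data LRT computed directly from weighted patterns."""
    config = config or EmConfig()
    if not patterns:
        return SexTestResult(method, sex, math.nan, n_free_params(sex, mode), 1,
                             0.0, NULL_RR, math.nan, math.nan, math.nan,
                             ("no_informative_families",))
    full = _em(patterns, method, sex, mode, config, fix_null=False)
    null = _em(patterns, method, sex, mode, config, fix_null=True)
    x = max(0.0, 2.0 * (full.loglik - null.loglik))
    df = n_free_params(sex, mode)
    flags = tuple(set(full.flags) | set(null.flags))
    return SexTestResult(
        method=method, sex=sex, statistic=x, df=df,
        sign=_sign_of(full.rr, sex), n_informative=n_informative,
        rr=full.rr, p_value=stats.chi2.sf(x, df),
        loglik_full=full.loglik, loglik_null=null.loglik, flags=flags)


def em_lrt(records: list[TriadRecord], method: str, sex: str,
           mode: str = "logadditive_girls",
           config: EmConfig | None = None) -> SexTestResult:
    """EM-based LRT: twice the observed-data log-likelihood gap between
    the full fit and the null fit (risks fixed at 1, nuisance re-maximized).

    On complete data this equals the corresponding exact test, because the
    stratum-mass estimates coincide under null and alternative and cancel.
    """
    config = config or EmConfig()
    patterns = records_to_patterns(records, sex, config.strata_mode)
    n_inf = count_informative(records, method, sex)
    return em_lrt_patterns(patterns, method, sex, mode, config, n_inf)


def count_informative(records: list[TriadRecord], method: str, sex: str) -> int:
    """Number of families contributing information to a method's statistic.

    ``ssx``: families with an *observed* heterozygous mother.  ``pix`` (and
    ``parent_only``): families whose observed members do not force the
    mating sum into the uninformative strata {0, 3}.
    """
    n = 0
    for rec in records:
        if rec.sex != sex:
            continue
        if method == "ssx":
            n += rec.M == 1
            continue
        sums = {m + f for (m, f, _) in consistent_completions(rec)}
        if sums and not sums <= {0, 3}:
            n += 1
    return n
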