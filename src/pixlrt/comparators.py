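"""Comparator tests: the XTDT and a reconstruction of the X-LRT.

The XTDT is the McNemar-type transmission test: among heterozygous
mothers of affected offspring, compare transmissions b against
non-transmissions c of the variant, (b - c)**2 / (b + c).  Fathers
contribute nothing, since a father's transmission to a daughter is
obligatory.  It is the score test of the same model whose likelihood
ratio test is the sex-stratified transmission LRT, so the two agree
closely in non-centrality.

The X-LRT is a pooled log-linear model that conditions on the parental
mating type but *shares* the six mating-type parameters between families
with affected sons and affected daughters, adjusting only by a single
sex-proportion offset.  When subpopulations differ both in allele
frequency and in the male:female ratio of baseline disease risk, that
sharing is misspecified and the test loses its nominal Type I error
rate -- the failure mode the sex-stratified tests are built to avoid.
The model here is fitted as a Poisson log-linear regression (statsmodels
GLM), which maximizes the equivalent multinomial likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .risk import admissible_cells
from .triad_model import CellCounts

__all__ = ["XlrtFit", "xtdt", "xlrt"]

_HYPOTHESES = ("all_null", "male_null", "female_null")


@dataclass
class XlrtFit:
    lrt: float
    df: int
    p_value: float
    params_full: dict[str, float]
    hypothesis: str
    girls_mode: str


def xtdt(cells: CellCounts, sex: str | None = None):
    """XTDT statistic, df=1.  ``sex`` restricts to one offspring sex;
    default pools transmissions across sexes.

    Returns ``(statistic, df, p_value)``; the statistic is ``nan`` (and
    the p-value 1) when no heterozygous-mother transmissions exist.
    """
    b = c = 0.0
    for (m, f, cc, s), n in cells.counts.items():
        if m != 1 or (sex is not None and s != sex):
            continue
        transmitted = cc if s == "boy" else cc - f
        if transmitted == 1:
            b += n
        else:
            c += n
    if b + c == 0:
        return math.nan, 1, math.nan
    stat = (b - c) ** 2 / (b + c)
    return stat, 1, stats.chi2.sf(stat, 1)


def _design(girls_mode: str, free: dict[str, bool]):
    """Column builders for the X-LRT Poisson design matrix."""
    mating_types = [(0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 1)]

    def row(m, f, c, s):
        cols = [1.0 if (m, f) == mt else 0.0 for mt in mating_types]
        cols.append(1.0 if s == "girl" else 0.0)  # sex offset
        if girls_mode == "codominant":
            if free["girls"]:
                cols.append(1.0 if (s == "girl" and c == 1) else 0.0)  # beta1
                cols.append(1.0 if (s == "girl" and c == 2) else 0.0)  # beta2
            if free["boys"]:
                cols.append(1.0 if (s == "boy" and c == 1) else 0.0)   # beta3
        else:  # girls log-additive dose
            if free["girls"]:
                cols.append(float(c) if s == "girl" else 0.0)          # beta1
            if free["boys"]:
                cols.append(1.0 if (s == "boy" and c == 1) else 0.0)   # beta3
        return cols

    return row


def _fit_poisson(cells: CellCounts, girls_mode: str, free: dict[str, bool]):
    rows = []
    y = []
    row = _design(girls_mode, free)
    for s in ("boy", "girl"):
        for (m, f, c) in admissible_cells(s):
            rows.append(row(m, f, c, s))
            y.append(cells.get(m, f, c, s))
    X = np.asarray(rows)
    y = np.asarray(y)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        # structural zeros (deterministic-transmission cells that are empty
        # under some scenarios) trigger a separation warning; the deviance,
        # which is all the LRT needs, is unaffected
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = model.fit(maxiter=200, tol=1e-12)
    return res


def xlrt(cells: CellCounts, hypothesis: str = "all_null",
         girls_mode: str = "codominant") -> XlrtFit:
    """Fit the X-LRT and test the requested null on its risk parameters.

    ``all_null`` tests every relative risk equal to 1 (3 df codominant,
    2 df girls-log-additive); ``male_null`` tests R_B = 1 with the girl
    risks free (1 df); ``female_null`` tests the girl risks equal to 1
    with R_B free (2 df codominant, 1 df log-additive).
    """
    if hypothesis not in _HYPOTHESES:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    sexes = cells.sexes()
    if "boy" not in sexes or "girl" not in sexes:
        raise ValueError("X-LRT needs both offspring sexes; "
                         "use the sex-stratified tests for single-sex data")

    full = _fit_poisson(cells, girls_mode, {"girls": True, "boys": True})
    null_free = {
        "all_null": {"girls": False, "boys": False},
        "male_null": {"girls": True, "boys": False},
        "female_null": {"girls": False, "boys": True},
    }[hypothesis]
    null = _fit_poisson(cells, girls_mode, null_free)

    n_girl_beta = 2 if girls_mode == "codominant" else 1
    df = {
        "all_null": n_girl_beta + 1,
        "male_null": 1,
        "female_null": n_girl_beta,
    }[hypothesis]

    lrt = max(0.0, null.deviance - full.deviance)
    names = ["g00", "g01", "g10", "g11", "g20", "g21", "sex_offset"]
    if girls_mode == "codominant":
        names += ["beta1", "beta2", "beta3"]
    else:
        names += ["beta1", "beta3"]
    params = dict(zip(names, full.params))
    return XlrtFit(lrt=lrt, df=df, p_value=stats.chi2.sf(lrt, df),
                   params_full=params, hypothesis=hypothesis,
                   girls_mode=girls_mode)
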