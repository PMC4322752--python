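"""Expected triad counts under population scenarios, and NCP/power.

A :class:`PopulationScenario` is a mixture of Hardy-Weinberg
subpopulations, each with its own variant frequency and sex-specific
baseline disease risks, plus a relative-risk model and a family count.
``expected_counts`` turns a scenario into real-valued triad cell counts
for the ascertained affected-offspring design; every implemented test
evaluated on those expected counts yields its chi-squared
*non-centrality parameter* (NCP), which maps to power through the
noncentral chi-squared distribution.  This is the engine behind all the
package's power and Type-I-error computations: no simulation is needed
for deterministic quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from . import comparators, exact_tests
from .em_engine import EmConfig, em_lrt_patterns
from .risk import RelativeRiskModel, admissible_cells
from .triad_model import CellCounts

__all__ = [
    "Subpopulation",
    "PopulationScenario",
    "MissingnessSpec",
    "expected_counts",
    "ncp",
    "power_from_ncp",
    "ncp_with_missingness",
    "scenario_from_dict",
    "scenario_to_dict",
]

SEX_DESIGNS = ("boys_only", "girls_only", "both_proportional")


@dataclass(frozen=True)
class Subpopulation:
    weight: float
    maf: float
    risk_male: float = 0.01
    risk_female: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 1.0:
            raise ValueError("maf must be in [0, 1]")
        for r in (self.risk_male, self.risk_female):
            if not 0.0 < r < 1.0:
                raise ValueError("baseline risks must be in (0, 1)")


@dataclass(frozen=True)
class PopulationScenario:
    """Subpopulation mixture + relative risks + ascertained family count."""

    subpops: tuple[Subpopulation, ...]
    rr: RelativeRiskModel
    n_families: float
    sex_design: str = "both_proportional"
    scenario_id: str = "scenario"

    def __post_init__(self) -> None:
        if abs(sum(s.weight for s in self.subpops) - 1.0) > 1e-9:
            raise ValueError("subpopulation weights must sum to 1")
        if self.sex_design not in SEX_DESIGNS:
            raise ValueError(f"sex_design must be one of {SEX_DESIGNS}")
        if not self.n_families > 0:
            raise ValueError("n_families must be positive")

    def sexes(self) -> tuple[str, ...]:
        return {"boys_only": ("boy",), "girls_only": ("girl",),
                "both_proportional": ("boy", "girl")}[self.sex_design]


@dataclass(frozen=True)
class MissingnessSpec:
    """Per-family parental missingness; at most one parent may be missing,
    so the two probabilities must sum to at most 1."""

    p_mother_missing: float = 0.0
    p_father_missing: float = 0.0

    def __post_init__(self) -> None:
        pm, pf = self.p_mother_missing, self.p_father_missing
        if not (0.0 <= pm <= 1.0 and 0.0 <= pf <= 1.0):
            raise ValueError("missingness probabilities must be in [0, 1]")
        if pm + pf > 1.0 + 1e-12:
            raise ValueError(
                "p_mother_missing + p_father_missing > 1 would imply families "
                "with both parents missing, which the design excludes")


def _hwe(maf: float) -> tuple[float, float, float]:
    q = maf
    return ((1 - q) ** 2, 2 * q * (1 - q), q * q)


def _mendel(m: int) -> float:
    return 0.5 if m == 1 else 1.0


def _raw_cell_mass(scenario: PopulationScenario, sex: str) -> dict:
    """Unnormalized joint mass of (M, F, C, affected) for one offspring sex,
    mixed over subpopulations (HWE within each)."""
    rr = scenario.rr
    mass = {cell: 0.0 for cell in admissible_cells(sex)}
    for sub in scenario.subpops:
        pm = _hwe(sub.maf)
        pf = (1 - sub.maf, sub.maf)
        base = sub.risk_male if sex == "boy" else sub.risk_female
        for (m, f, c) in admissible_cells(sex):
            w = sub.weight * pm[m] * pf[f] * _mendel(m) * base * rr.risk_factor(c, sex)
            mass[(m, f, c)] += w
    return mass


def expected_counts(scenario: PopulationScenario,
                    sex: str | None = None) -> CellCounts:
    """Expected triad cell counts for the ascertained design.

    For a single-sex design (or an explicit ``sex``), the masses are
    normalized over that sex's cells and scaled to ``n_families``.  For
    ``both_proportional``, a 1:1 sex ratio at birth is assumed and the
    total is split between boy and girl cells in proportion to each sex's
    marginal affection probability.
    """
    sexes = (sex,) if sex is not None else scenario.sexes()
    raw = {s: _raw_cell_mass(scenario, s) for s in sexes}
    if len(sexes) == 1:
        s = sexes[0]
        tot = sum(raw[s].values())
        if tot <= 0:
            raise ValueError("scenario has zero affection probability")
        scale = scenario.n_families / tot
        return CellCounts({(m, f, c, s): v * scale
                           for (m, f, c), v in raw[s].items()})
    # both sexes: joint normalization with a 1:1 sex ratio at birth
    tot = 0.5 * sum(sum(raw[s].values()) for s in sexes)
    if tot <= 0:
        raise ValueError("scenario has zero affection probability")
    counts: dict = {}
    for s in sexes:
        scale = 0.5 * scenario.n_families / tot
        for (m, f, c), v in raw[s].items():
            counts[(m, f, c, s)] = v * scale
    return CellCounts(counts)


_SINGLE_SEX_TESTS = {"pix", "ssx", "parent_only"}


def ncp(test: str, scenario: PopulationScenario, *,
        hypothesis: str = "all_null") -> float:
    """Non-centrality parameter: the test's statistic on expected counts.

    ``test`` is one of ``pix``, ``ssx``, ``parent_only``, ``xtdt``,
    ``xlrt``, or ``combined_pix`` / ``combined_ssx`` / ``combined_parent_only``
    (the signed-root combination across sexes, using sqrt(NCP_sex) as the
    expected signed root).  Girls are fitted under the scenario's
    relative-risk mode constraint (log-additive for 1-df tests).
    """
    cells = expected_counts(scenario)
    mode = scenario.rr.mode if scenario.rr.mode != "codominant" else "logadditive_girls"
    if test in _SINGLE_SEX_TESTS:
        sexes = scenario.sexes()
        if len(sexes) != 1:
            raise ValueError(f"{test} NCP needs a single-sex design; "
                             "use combined_* for both sexes")
        res = _sex_statistic(test, cells, sexes[0], mode)
        return res.statistic
    if test.startswith("combined_"):
        base = test.removeprefix("combined_")
        if base not in _SINGLE_SEX_TESTS:
            raise ValueError(f"unknown test {test!r}")
        parts = []
        for s in scenario.sexes():
            r = _sex_statistic(base, cells, s, mode)
            parts.append((r.sign, r.n_informative, r.statistic))
        n_tot = sum(n for _, n, _ in parts)
        if n_tot <= 0:
            return 0.0
        e_num = sum(s * math.sqrt(n * x) for s, n, x in parts)
        return e_num * e_num / n_tot
    if test == "xtdt":
        stat, _, _ = comparators.xtdt(cells)
        return 0.0 if math.isnan(stat) else stat
    if test == "xlrt":
        girls_mode = ("codominant" if scenario.rr.mode
                      in ("codominant", "xinactivation") else "logadditive")
        return comparators.xlrt(cells, hypothesis, girls_mode).lrt
    raise ValueError(f"unknown test {test!r}")


def _sex_statistic(test: str, cells: CellCounts, sex: str, mode: str):
    fn = {"pix": exact_tests.pix_lrt, "ssx": exact_tests.ssx_lrt,
          "parent_only": exact_tests.parent_only_lrt}[test]
    res = fn(cells, sex, mode)
    if math.isnan(res.statistic):
        res.statistic = 0.0
    return res


def power_from_ncp(ncp_value: float, df: int, alpha: float) -> float:
    """Power of a chi-squared(df) test at level alpha given an NCP.

    The upper-tail probability of a noncentral chi-squared(df, ncp)
    beyond the central 1-alpha critical value.  With ``ncp=0`` this is
    alpha itself; with ``alpha=0.05`` it doubles as the actual Type I
    error rate of a miscalibrated test whose null NCP is positive.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if ncp_value < 0:
        raise ValueError("ncp must be nonnegative")
    crit = stats.chi2.ppf(1.0 - alpha, df)
    if ncp_value == 0:
        return float(stats.chi2.sf(crit, df))
    return float(stats.ncx2.sf(crit, df, ncp_value))


def missingness_patterns(cells: CellCounts, sex: str,
                         miss: MissingnessSpec) -> dict:
    """Spread complete-cell expected counts over MAR observation patterns."""
    pm, pf = miss.p_mother_missing, miss.p_father_missing
    pc = 1.0 - pm - pf
    patterns: dict = {}

    def add(key, w):
        if w > 0:
            patterns[key] = patterns.get(key, 0.0) + w

    for (m, f, c), n in cells.sex_cells(sex).items():
        add((m, f, c, None), n * pc)
        add((None, f, c, None), n * pm)
        add((m, None, c, None), n * pf)
    return patterns


def ncp_with_missingness(test: str, scenario: PopulationScenario,
                         miss: MissingnessSpec,
                         config: EmConfig | None = None) -> float:
    """NCP of the EM-based observed-data LRT under MAR parental missingness.

    Expected complete counts are distributed over the observed-data
    patterns (complete / mother-missing / father-missing) and the EM
    likelihood ratio is evaluated on those expected pattern counts.
    """
    if test not in ("pix", "ssx"):
        raise ValueError("missingness NCPs are defined for 'pix' and 'ssx'")
    sexes = scenario.sexes()
    if len(sexes) != 1:
        raise ValueError("ncp_with_missingness needs a single-sex design")
    sex = sexes[0]
    mode = scenario.rr.mode if scenario.rr.mode != "codominant" else "logadditive_girls"
    cells = expected_counts(scenario)
    patterns = missingness_patterns(cells, sex, miss)
    config = config or EmConfig(tol=1e-10, max_iter=2000)
    res = em_lrt_patterns(patterns, test, sex, mode, config)
    return res.statistic


# ---------------------------------------------------------------------------
# scenario (de)serialization for config files
# ---------------------------------------------------------------------------

def scenario_from_dict(d: dict) -> PopulationScenario:
    """Build a scenario from a plain mapping (e.g. parsed YAML)."""
    rrd = d.get("rr", {})
    mode = rrd.get("mode", "codominant")
    rr = RelativeRiskModel(
        r_boy=float(rrd.get("r_boy", 1.0)),
        r_girl_het=float(rrd.get("r_girl_het", 1.0)),
        r_girl_hom=float(rrd.get("r_girl_hom", rrd.get("r_girl_het", 1.0) ** 2
                                 if mode == "logadditive_girls" else 1.0)),
        mode=mode,
    ).constrained()
    subs = tuple(Subpopulation(
        weight=float(s["weight"]), maf=float(s["maf"]),
        risk_male=float(s.get("risk_male", 0.01)),
        risk_female=float(s.get("risk_female", 0.01)))
        for s in d["subpops"])
    return PopulationScenario(
        subpops=subs, rr=rr, n_families=float(d["n_families"]),
        sex_design=d.get("sex_design", "both_proportional"),
        scenario_id=str(d.get("scenario_id", "scenario")))


def scenario_to_dict(s: PopulationScenario) -> dict:
    return {
        "scenario_id": s.scenario_id,
        "n_families": s.n_families,
        "sex_design": s.sex_design,
        "rr": {"r_boy": s.rr.r_boy, "r_girl_het": s.rr.r_girl_het,
               "r_girl_hom": s.rr.r_girl_hom, "mode": s.rr.mode},
        "subpops": [{"weight": p.weight, "maf": p.maf,
                     "risk_male": p.risk_male, "risk_female": p.risk_female}
                    for p in s.subpops],
    }
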