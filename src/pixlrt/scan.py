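"""Multi-SNP X-chromosome scan orchestration.

Filters markers (parent-based minor allele frequency, excluded
coordinate intervals), runs the per-sex test of choice -- with the EM
when incomplete triads should contribute -- combines the sexes into a
signed Z, flags exchangeability violations, and reports the Bonferroni
threshold computed from the number of markers actually tested.
``qq_data`` prepares quantile-quantile coordinates with pointwise
beta-order-statistic bands, and ``concordance_report`` contrasts the
offspring-based (transmission) and parent-only signed statistics on
complete triads, where the two are statistically independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import exact_tests
from .em_engine import EmConfig, em_lrt
from .triad_model import SnpDataset, parent_maf, tabulate, validate_mendelian

__all__ = ["ScanConfig", "run_scan", "qq_data", "concordance_report"]


@dataclass
class ScanConfig:
    method: str = "pix"
    girls_mode: str = "logadditive_girls"
    use_em: bool = False
    strata_mode: str = "pooled"
    maf_min: float = 0.0
    alpha_family: float = 0.05
    excluded_regions: tuple[tuple[int, int], ...] = ()
    exch_flag_p: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 < self.alpha_family < 1.0:
            raise ValueError("alpha_family must be in (0, 1)")
        if self.method not in ("pix", "ssx", "parent_only"):
            raise ValueError("method must be pix, ssx or parent_only")


def _in_excluded(pos: int, regions) -> bool:
    return any(lo <= pos <= hi for lo, hi in regions)


_EXACT = {"pix": exact_tests.pix_lrt, "ssx": exact_tests.ssx_lrt,
          "parent_only": exact_tests.parent_only_lrt}


def _sex_result(records, method, sex, mode, use_em, em_config):
    if use_em:
        usable = [r for r in records
                  if r.sex == sex and not (r.M is None and r.F is None and r.C is None)]
        if not usable:
            return None
        return em_lrt(usable, method, sex, mode, em_config)
    complete = [r for r in records if r.sex == sex and r.complete]
    if not complete:
        return None
    cells = tabulate(complete)
    return _EXACT[method](cells, sex, mode)


def run_scan(datasets: list[SnpDataset], config: ScanConfig) -> pd.DataFrame:
    """Per-SNP scan table; every input SNP appears as tested or skipped.

    The Bonferroni p-value threshold (family-wise ``alpha_family`` over
    the SNPs actually tested) is stored in ``result.attrs['bonferroni']``
    together with the test count.
    """
    em_config = EmConfig(strata_mode=config.strata_mode)
    rows = []
    for ds in datasets:
        row: dict = {"snp_id": ds.snp_id, "position": ds.position,
                     "n_families": len(ds.records), "status": "tested",
                     "reason": "", "flags": ""}
        flags = []
        if _in_excluded(ds.position, config.excluded_regions):
            row.update(status="skipped", reason="excluded_region")
            rows.append(row)
            continue
        consistent = [r for r in ds.records
                      if validate_mendelian(r) != "inconsistent"]
        n_bad = len(ds.records) - len(consistent)
        if n_bad:
            flags.append(f"mendel_errors={n_bad}")
        maf = parent_maf(consistent)
        row["parent_maf"] = maf
        if math.isnan(maf):
            row.update(status="skipped", reason="no_parent_data")
            rows.append(row)
            continue
        if maf < config.maf_min:
            row.update(status="skipped", reason="maf")
            rows.append(row)
            continue

        both_parents = {(m, f): 0.0 for m in (0, 1, 2) for f in (0, 1)}
        for r in consistent:
            if r.M is not None and r.F is not None:
                both_parents[(r.M, r.F)] += 1
        exch = exact_tests.exchangeability_test(both_parents)
        row["exch_lrt"] = exch.lrt
        row["exch_p"] = exch.p_value
        if not math.isnan(exch.p_value) and exch.p_value < config.exch_flag_p:
            flags.append("exchangeability")

        results = {}
        for sex in ("boy", "girl"):
            res = _sex_result(consistent, config.method, sex,
                              config.girls_mode, config.use_em, em_config)
            results[sex] = res
            tag = "boy" if sex == "boy" else "girl"
            if res is None:
                row[f"x_{tag}"] = math.nan
                row[f"n_inf_{tag}"] = 0
                continue
            row[f"x_{tag}"] = res.statistic
            row[f"p_{tag}"] = res.p_value
            row[f"sign_{tag}"] = res.sign
            row[f"n_inf_{tag}"] = res.n_informative
            if sex == "boy":
                row["rr_boy"] = res.rr.r_boy
            else:
                row["rr_girl_het"] = res.rr.r_girl_het
                row["rr_girl_hom"] = res.rr.r_girl_hom
            flags.extend(f"{tag}:{fl}" for fl in res.flags)

        combinable = {s: r for s, r in results.items()
                      if r is not None and r.df == 1}
        if combinable:
            comb = exact_tests.combine_z(combinable.get("boy"),
                                         combinable.get("girl"))
            row["z_combined"] = comb.z
            row["p_combined"] = comb.p_value
        row["flags"] = ";".join(flags)
        rows.append(row)

    out = pd.DataFrame(rows)
    n_tested = int((out["status"] == "tested").sum()) if len(out) else 0
    out.attrs["n_tested"] = n_tested
    out.attrs["bonferroni"] = (config.alpha_family / n_tested
                               if n_tested else math.nan)
    if n_tested == 0:
        import warnings
        warnings.warn("no SNPs survived the filters; empty scan result")
    return out


def qq_data(p_values) -> pd.DataFrame:
    """Observed vs expected -log10(p) with 95% pointwise beta bands.

    The i-th order statistic of n uniform p-values is Beta(i, n - i + 1);
    its 2.5% and 97.5% quantiles give the band.
    """
    p = np.sort(np.asarray(list(p_values), dtype=float))
    n = p.size
    if n == 0:
        return pd.DataFrame(columns=["expected", "observed", "lower", "upper"])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    i = np.arange(1, n + 1)
    expected = i / (n + 1.0)
    lower = stats.beta.ppf(0.025, i, n - i + 1)
    upper = stats.beta.ppf(0.975, i, n - i + 1)
    return pd.DataFrame({
        "expected": -np.log10(expected),
        "observed": -np.log10(p),
        "lower": -np.log10(upper),
        "upper": -np.log10(lower),
    })


def _quadrant(z1: float, z2: float) -> str:
    if z1 == 0 or z2 == 0:
        return "axis"
    ew = "east" if z1 > 0 else "west"
    ns = "north" if z2 > 0 else "south"
    return ns + ew


def concordance_report(datasets: list[SnpDataset],
                       snp_ids: list[str] | None = None,
                       girls_mode: str = "logadditive_girls") -> pd.DataFrame:
    """Independent offspring-based vs parent-only signed Z per SNP.

    Restricted to complete triads, where the transmission (SSX) and
    parent-only components are statistically independent; the quadrant
    column classifies sign agreement (x = SSX Z, y = parent-only Z).
    """
    wanted = set(snp_ids) if snp_ids is not None else None
    rows = []
    for ds in datasets:
        if wanted is not None and ds.snp_id not in wanted:
            continue
        complete = [r for r in ds.records
                    if r.complete and validate_mendelian(r) == "consistent"]
        if not complete:
            rows.append({"snp_id": ds.snp_id, "status": "excluded",
                         "reason": "no_complete_triads"})
            continue
        cells = tabulate(complete)

        def signed_z(method) -> tuple[float, dict]:
            per_sex = {}
            for sex in ("boy", "girl"):
                if cells.total(sex) > 0:
                    per_sex[sex] = _EXACT[method](cells, sex, girls_mode)
            comb = exact_tests.combine_z(per_sex.get("boy"), per_sex.get("girl"))
            return comb.z, per_sex

        z_ssx, ssx_res = signed_z("ssx")
        z_par, _ = signed_z("parent_only")
        z_pix, pix_res = signed_z("pix")
        row = {"snp_id": ds.snp_id, "status": "ok", "reason": "",
               "z_ssx": z_ssx, "z_parent_only": z_par, "z_pix": z_pix,
               "quadrant": (_quadrant(z_ssx, z_par)
                            if not (math.isnan(z_ssx) or math.isnan(z_par))
                            else "undefined")}
        for sex, res in pix_res.items():
            row[f"rr_boy" if sex == "boy" else "rr_girl_het"] = (
                res.rr.r_boy if sex == "boy" else res.rr.r_girl_het)
        rows.append(row)
    return pd.DataFrame(rows)
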