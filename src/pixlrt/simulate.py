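"""Sampling of finite case-parent triad datasets from population scenarios.

The sampler mirrors the ascertainment of the case-parent design: parental
genotypes are drawn under Hardy-Weinberg equilibrium within a randomly
chosen subpopulation, a child is produced by Mendelian transmission, and
the family enters the sample with probability equal to the child's
disease risk (sex-specific baseline times the genotype relative risk),
continuing until the design's family count is reached.  The conditional
law of the accepted triads therefore equals the expected-count
distribution of :mod:`pixlrt.design_power` exactly.

All randomness flows from a single integer seed through a
``numpy.random.SeedSequence``; per-marker child streams make replicate
markers independent and the output byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .design_power import MissingnessSpec, PopulationScenario
from .triad_model import SnpDataset, TriadRecord

__all__ = ["SimSpec", "sample_triads", "apply_missingness"]


@dataclass(frozen=True)
class SimSpec:
    scenario: PopulationScenario
    seed: int
    miss: MissingnessSpec | None = None
    n_snps: int = 1


def _sample_one_snp(scenario: PopulationScenario,
                    rng: np.random.Generator) -> list[TriadRecord]:
    subs = scenario.subpops
    weights = np.array([s.weight for s in subs])
    max_rr = max(scenario.rr.risk_factor(c, s)
                 for s in ("boy", "girl") for c in ((0, 1) if s == "boy" else (0, 1, 2)))
    for s in subs:
        for base in (s.risk_male, s.risk_female):
            if base * max_rr > 1.0:
                raise ValueError("baseline risk times relative risk exceeds 1; "
                                 "affection cannot be a probability")
    if all(s.risk_male <= 0 and s.risk_female <= 0 for s in subs):
        raise ValueError("zero acceptance probability")

    n_target = int(round(scenario.n_families))
    records: list[TriadRecord] = []
    fam = 0
    # vectorized rejection sampling in batches
    batch = max(1024, int(4 * n_target / max(1e-6, min(
        s.risk_male for s in subs) * 0.5)))
    batch = min(batch, 2_000_000)
    while len(records) < n_target:
        k = rng.choice(len(subs), size=batch, p=weights)
        maf = np.array([subs[i].maf for i in k])
        mother = (rng.random(batch) < maf).astype(int) + (rng.random(batch) < maf)
        father = (rng.random(batch) < maf).astype(int)
        if scenario.sex_design == "boys_only":
            is_boy = np.ones(batch, dtype=bool)
        elif scenario.sex_design == "girls_only":
            is_boy = np.zeros(batch, dtype=bool)
        else:
            is_boy = rng.random(batch) < 0.5
        transmit = np.where(mother == 1, rng.random(batch) < 0.5, mother // 2)
        child = np.where(is_boy, transmit, father + transmit)
        base = np.where(is_boy,
                        np.array([subs[i].risk_male for i in k]),
                        np.array([subs[i].risk_female for i in k]))
        rrv = np.empty(batch)
        for sex_flag, sex in ((True, "boy"), (False, "girl")):
            mask = is_boy == sex_flag
            for c in (0, 1, 2):
                rrv[mask & (child == c)] = scenario.rr.risk_factor(
                    min(c, 1) if sex == "boy" else c, sex)
        affected = rng.random(batch) < base * rrv
        for i in np.flatnonzero(affected):
            fam += 1
            records.append(TriadRecord(
                family_id=f"fam{fam}",
                M=int(mother[i]), F=int(father[i]), C=int(child[i]),
                sex="boy" if is_boy[i] else "girl",
                stratum=f"pop{k[i] + 1}" if len(subs) > 1 else None))
            if len(records) == n_target:
                break
    return records


def sample_triads(spec: SimSpec) -> list[SnpDataset]:
    """Draw ``n_snps`` independent replicate markers under the scenario."""
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_snps)
    out = []
    for j, child_seq in enumerate(children, start=1):
        rng = np.random.default_rng(child_seq)
        recs = _sample_one_snp(spec.scenario, rng)
        ds = SnpDataset(f"snp{j}", j, recs)
        if spec.miss is not None:
            ds = apply_missingness(ds, spec.miss, rng=rng)
        out.append(ds)
    return out


def apply_missingness(dataset: SnpDataset, miss: MissingnessSpec,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None) -> SnpDataset:
    """Mask parental genotypes at random, at most one parent per family.

    A single uniform draw per family is partitioned into mother-missing,
    father-missing, and complete, so the one-missing-parent constraint
    holds by construction.  Child genotypes are never masked here.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pm, pf = miss.p_mother_missing, miss.p_father_missing
    new = []
    for rec in dataset.records:
        u = rng.random()
        if u < pm:
            new.append(replace(rec, M=None))
        elif u < pm + pf:
            new.append(replace(rec, F=None))
        else:
            new.append(rec)
    return SnpDataset(dataset.snp_id, dataset.position, new)
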