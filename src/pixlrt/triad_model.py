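"""Domain types and genotype I/O for X-linked case-parent triads.

A :class:`TriadRecord` holds one family's minor-allele copy counts at a
single X SNP (mother M, hemizygous father F, affected child C) plus the
child's sex and an optional subpopulation label.  Records tabulate into
:class:`CellCounts`, the multinomial table over the 16 Mendelian-admissible
(M, F, C, sex) cells that every test in this package consumes.

Two on-disk dialects are supported: a long-format TSV (one row per
family per SNP, ``NA`` for missing) and a PLINK-style ped/map pair in
which fathers carry a single effective allele (second allele ``0`` or
duplicated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .risk import admissible_cells

__all__ = [
    "TriadRecord",
    "CellCounts",
    "SnpDataset",
    "ParseError",
    "consistent_completions",
    "validate_mendelian",
    "tabulate",
    "parent_maf",
    "read_triads",
    "write_triads",
]

MISSING = None
_SEX_CODES = {"boy": "boy", "girl": "girl", "m": "boy", "f": "girl",
              "male": "boy", "female": "girl", "b": "boy", "g": "girl",
              "1": "boy", "2": "girl"}


class ParseError(ValueError):
    """Raised for malformed input files; the message names the line."""


@dataclass(frozen=True)
class TriadRecord:
    """One family's genotypes at one X SNP; ``None`` marks a missing member."""

    family_id: str
    M: int | None
    F: int | None
    C: int | None
    sex: str
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("boy", "girl"):
            raise ValueError(f"family {self.family_id}: unknown sex {self.sex!r}")
        if self.M is not None and self.M not in (0, 1, 2):
            raise ValueError(f"family {self.family_id}: mother genotype {self.M} out of range")
        if self.F is not None and self.F not in (0, 1):
            raise ValueError(
                f"family {self.family_id}: father carries {self.F} copies; "
                "fathers are hemizygous on the non-PAR X")
        cmax = 1 if self.sex == "boy" else 2
        if self.C is not None and self.C not in range(cmax + 1):
            raise ValueError(f"family {self.family_id}: child genotype {self.C} out of range")

    @property
    def complete(self) -> bool:
        return self.M is not None and self.F is not None and self.C is not None


def consistent_completions(rec: TriadRecord) -> list[tuple[int, int, int]]:
    """All Mendelian-admissible (M, F, C) triples matching the observed members."""
    out = []
    for (m, f, c) in admissible_cells(rec.sex):
        if rec.M is not None and rec.M != m:
            continue
        if rec.F is not None and rec.F != f:
            continue
        if rec.C is not None and rec.C != c:
            continue
        out.append((m, f, c))
    return out


def validate_mendelian(rec: TriadRecord) -> str:
    """Classify a record as ``consistent``, ``inconsistent`` or ``incomplete``.

    Incomplete records are checked only on their observed members: e.g. a
    daughter with F=1, C=0 is inconsistent no matter the mother, because a
    father transmits his only X to his daughter.
    """
    ok = bool(consistent_completions(rec))
    if rec.complete:
        return "consistent" if ok else "inconsistent"
    return "incomplete" if ok else "inconsistent"


@dataclass
class CellCounts:
    """Counts (or expected counts) over the admissible (M, F, C, sex) cells."""

    counts: dict[tuple[int, int, int, str], float] = field(default_factory=dict)

    def get(self, m: int, f: int, c: int, sex: str) -> float:
        return self.counts.get((m, f, c, sex), 0.0)

    def add(self, m: int, f: int, c: int, sex: str, w: float = 1.0) -> None:
        if (m, f, c) not in admissible_cells(sex):
            raise ValueError(f"inadmissible cell {(m, f, c)} for {sex}")
        self.counts[(m, f, c, sex)] = self.counts.get((m, f, c, sex), 0.0) + w

    def sexes(self) -> list[str]:
        return sorted({k[3] for k in self.counts})

    def sex_cells(self, sex: str) -> dict[tuple[int, int, int], float]:
        """Counts over (M, F, C) for one offspring sex."""
        return {(m, f, c): v for (m, f, c, s), v in self.counts.items() if s == sex}

    def total(self, sex: str | None = None) -> float:
        if sex is None:
            return sum(self.counts.values())
        return sum(self.sex_cells(sex).values())

    def parent_margins(self, sex: str | None = None) -> dict[tuple[int, int], float]:
        """Mating-type margins N_{M,F} (one sex, or both pooled)."""
        out: dict[tuple[int, int], float] = {}
        for (m, f, c, s), v in self.counts.items():
            if sex is None or s == sex:
                out[(m, f)] = out.get((m, f), 0.0) + v
        return out

    def matingsum_margins(self, sex: str | None = None) -> dict[int, float]:
        """Mating-sum margins N_{M+F}."""
        out: dict[int, float] = {}
        for (m, f), v in self.parent_margins(sex).items():
            out[m + f] = out.get(m + f, 0.0) + v
        return out

    def __add__(self, other: "CellCounts") -> "CellCounts":
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0.0) + v
        return CellCounts(merged)


@dataclass
class SnpDataset:
    """All triad records for one SNP marker."""

    snp_id: str
    position: int
    records: list[TriadRecord]

    def __post_init__(self) -> None:
        ids = [r.family_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.snp_id}: duplicate family_ids")


def tabulate(records: list[TriadRecord]) -> CellCounts:
    """Tabulate complete, Mendelian-consistent triads into cell counts.

    Incomplete records belong to the EM machinery instead and raise here,
    as do Mendelian inconsistencies (reported by family id).
    """
    cc = CellCounts()
    bad = [r.family_id for r in records if validate_mendelian(r) == "inconsistent"]
    if bad:
        raise ValueError(f"Mendelian-inconsistent families: {', '.join(bad)}")
    incomplete = [r.family_id for r in records if not r.complete]
    if incomplete:
        raise ValueError(
            f"incomplete families (use the EM engine): {', '.join(incomplete)}")
    for r in records:
        cc.add(r.M, r.F, r.C, r.sex)
    return cc


def parent_maf(records: list[TriadRecord]) -> float:
    """Minor-allele frequency computed from the parents only.

    Mothers contribute two X chromosomes, fathers one.  Returns ``nan``
    when no parental genotype is observed.
    """
    copies = 0
    chroms = 0
    for r in records:
        if r.M is not None:
            copies += r.M
            chroms += 2
        if r.F is not None:
            copies += r.F
            chroms += 1
    if chroms == 0:
        return math.nan
    return copies / chroms


# ---------------------------------------------------------------------------
# I/O: long TSV and ped/map dialects
# ---------------------------------------------------------------------------

_LONG_COLS = ["snp_id", "family_id", "mother_gt", "father_gt", "child_gt", "child_sex"]


def _parse_gt(tok: str, line: int, who: str) -> int | None:
    if tok.upper() in ("NA", "", "."):
        return None
    try:
        return int(tok)
    except ValueError:
        raise ParseError(f"line {line}: non-integer {who} genotype {tok!r}") from None


def _flip_if_major(records: list[TriadRecord]) -> list[TriadRecord]:
    """Re-orient copy counts so they count the parent-based minor allele."""
    freq = parent_maf(records)
    if not math.isnan(freq) and freq > 0.5:
        flipped = []
        for r in records:
            flipped.append(replace(
                r,
                M=None if r.M is None else 2 - r.M,
                F=None if r.F is None else 1 - r.F,
                C=None if r.C is None else (1 - r.C if r.sex == "boy" else 2 - r.C),
            ))
        return flipped
    return records


def _dedupe(records: list[TriadRecord], rng: np.random.Generator | None) -> list[TriadRecord]:
    """Keep one record per family: first by file order, or random with a seed."""
    by_fam: dict[str, list[TriadRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.family_id not in by_fam:
            order.append(r.family_id)
        by_fam.setdefault(r.family_id, []).append(r)
    out = []
    for fam in order:
        group = by_fam[fam]
        if len(group) == 1 or rng is None:
            out.append(group[0])
        else:
            out.append(group[int(rng.integers(len(group)))])
    return out


def read_triads(path, format: str = "long-tsv", *,
                sibling_choice: str = "first",
                seed: int | None = None) -> list[SnpDataset]:
    """Read triad genotypes, one :class:`SnpDataset` per marker.

    Genotypes are returned as minor-allele copy counts, the minor allele
    being the one less frequent among the parents of the dataset (counts
    are flipped when the coded allele turns out to be the major one).
    ``sibling_choice`` governs duplicate family ids: ``first`` keeps the
    first row in file order, ``random`` draws one using ``seed``.
    """
    if sibling_choice not in ("first", "random"):
        raise ValueError("sibling_choice must be 'first' or 'random'")
    rng = np.random.default_rng(seed) if sibling_choice == "random" else None
    if format == "long-tsv":
        return _read_long_tsv(path, rng)
    if format == "ped-map":
        return _read_ped_map(path, rng)
    raise ValueError(f"unknown format {format!r}")


def _read_long_tsv(path, rng) -> list[SnpDataset]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ParseError("empty file")
    header = lines[0].split()
    for col in _LONG_COLS:
        if col not in header:
            raise ParseError(f"missing required column {col!r}")
    idx = {c: header.index(c) for c in header}
    has_stratum = "stratum" in idx
    by_snp: dict[str, list[TriadRecord]] = {}
    order: list[str] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        toks = ln.split()
        if len(toks) < len(_LONG_COLS):
            raise ParseError(f"line {lineno}: expected at least {len(_LONG_COLS)} fields")
        snp = toks[idx["snp_id"]]
        sex_tok = toks[idx["child_sex"]].lower()
        if sex_tok not in _SEX_CODES:
            raise ParseError(f"line {lineno}: unknown sex code {toks[idx['child_sex']]!r}")
        stratum = None
        if has_stratum and len(toks) > idx["stratum"]:
            tok = toks[idx["stratum"]]
            stratum = None if tok.upper() == "NA" else tok
        try:
            rec = TriadRecord(
                family_id=toks[idx["family_id"]],
                M=_parse_gt(toks[idx["mother_gt"]], lineno, "mother"),
                F=_parse_gt(toks[idx["father_gt"]], lineno, "father"),
                C=_parse_gt(toks[idx["child_gt"]], lineno, "child"),
                sex=_SEX_CODES[sex_tok],
                stratum=stratum,
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if snp not in by_snp:
            order.append(snp)
        by_snp.setdefault(snp, []).append(rec)
    return [SnpDataset(snp, pos, _flip_if_major(_dedupe(by_snp[snp], rng)))
            for pos, snp in enumerate(order, start=1)]


def write_triads(datasets: list[SnpDataset], path) -> None:
    """Write datasets in the long-TSV dialect (round-trips exactly)."""
    rows = []
    for ds in datasets:
        for r in ds.records:
            rows.append({
                "snp_id": ds.snp_id,
                "family_id": r.family_id,
                "mother_gt": "NA" if r.M is None else r.M,
                "father_gt": "NA" if r.F is None else r.F,
                "child_gt": "NA" if r.C is None else r.C,
                "child_sex": r.sex,
                "stratum": "NA" if r.stratum is None else r.stratum,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_ped_map(path, rng) -> list[SnpDataset]:
    """PLINK-style ped/map pair.

    ``path`` names the .ped file; the .map sits beside it.  Fathers must
    carry a single effective allele: second allele '0' or a duplicate of
    the first.  Sons are coded the same way.
    """
    import os

    ped_path = str(path)
    base = ped_path[:-4] if ped_path.endswith(".ped") else ped_path
    map_path = base + ".map"
    if not os.path.exists(map_path):
        raise ParseError(f"map file not found: {map_path}")
    snps: list[tuple[str, int]] = []
    with open(map_path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            toks = ln.split()
            if not toks:
                continue
            if len(toks) == 4:
                snp_id, pos = toks[1], toks[3]
            elif len(toks) == 3:
                snp_id, pos = toks[1], toks[2]
            else:
                raise ParseError(f"{map_path} line {lineno}: expected 3 or 4 fields")
            snps.append((snp_id, int(pos)))

    people: dict[tuple[str, str], dict] = {}
    with open(ped_path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            toks = ln.split()
            if not toks:
                continue
            if len(toks) != 6 + 2 * len(snps):
                raise ParseError(
                    f"{ped_path} line {lineno}: expected {6 + 2 * len(snps)} fields, "
                    f"got {len(toks)}")
            fam, ind, pat, mat, sex, pheno = toks[:6]
            alleles = [(toks[6 + 2 * i], toks[7 + 2 * i]) for i in range(len(snps))]
            people[(fam, ind)] = {
                "fam": fam, "ind": ind, "pat": pat, "mat": mat,
                "sex": sex, "pheno": pheno, "alleles": alleles, "line": lineno,
            }

    # identify affected children with both parental ids present in the file
    triads = []
    for key, p in people.items():
        if p["pheno"] != "2":
            continue
        fa = people.get((p["fam"], p["pat"]))
        mo = people.get((p["fam"], p["mat"]))
        if fa is None or mo is None:
            continue
        triads.append((p, mo, fa))

    def male_copies(pair: tuple[str, str], who: str, line: int) -> int | None:
        a, b = pair
        if a == "0" and b == "0":
            return None
        if a == "0" or b == "0":
            allele = a if a != "0" else b
        elif a == b:
            allele = a
        else:
            raise ParseError(
                f"{ped_path} line {line}: {who} carries two distinct alleles "
                f"({a}/{b}) at an X SNP; males are hemizygous")
        return allele

    datasets = []
    for i, (snp_id, pos) in enumerate(snps):
        # minor allele from parents: mothers twice, fathers once
        tally: dict[str, float] = {}

        def count(allele: str | None, w: float) -> None:
            if allele is not None:
                tally[allele] = tally.get(allele, 0.0) + w

        parsed = []
        for child, mo, fa in triads:
            ma, mb = mo["alleles"][i]
            f_allele = male_copies(fa["alleles"][i], "father", fa["line"])
            count(None if ma == "0" else ma, 1.0)
            count(None if mb == "0" else mb, 1.0)
            count(f_allele, 1.0)
            parsed.append((child, (ma, mb), f_allele))
        alleles_seen = sorted(tally)
        if len(alleles_seen) > 2:
            raise ParseError(f"{snp_id}: more than two alleles observed")
        if not alleles_seen:
            minor = None
        elif len(alleles_seen) == 1:
            minor = None  # monomorphic in parents: no copy ever minor
        else:
            a, b = alleles_seen
            # less frequent among parents is minor; ties break lexicographically
            minor = a if (tally[a], a) <= (tally[b], b) else b

        records = []
        for child, (ma, mb), f_allele in parsed:
            if ma == "0" or mb == "0":
                m_ct: int | None = None
            else:
                m_ct = (ma == minor) + (mb == minor) if minor else 0
            f_ct = None if f_allele is None else (1 if f_allele == minor else 0)
            sex = "boy" if child["sex"] == "1" else "girl"
            ca, cb = child["alleles"][i]
            if sex == "boy":
                c_allele = male_copies((ca, cb), "son", child["line"])
                c_ct = None if c_allele is None else (1 if c_allele == minor else 0)
            else:
                if ca == "0" or cb == "0":
                    c_ct = None
                else:
                    c_ct = (ca == minor) + (cb == minor) if minor else 0
            records.append(TriadRecord(
                family_id=child["fam"], M=m_ct, F=f_ct, C=c_ct, sex=sex))
        datasets.append(SnpDataset(snp_id, pos, _dedupe(records, rng)))
    return datasets
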