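"""Genotype relative-risk models and X-linked triad cell probabilities.

At a di-allelic non-PAR X locus, let M, F, C be the minor-allele copy
counts of the mother, father, and affected child.  Fathers are hemizygous
(F in {0,1}); sons inherit their single X from the mother (C in {0,1});
daughters receive the paternal X plus one maternal X (C in {0,1,2}).

Three nested conditional distributions drive every test in this package:

* ``transmission_prob`` -- Pr(C | M, F, affected, sex): the offspring
  transmission distribution within a parental mating type.  Only
  heterozygous-mother strata are informative.
* ``matingsum_cell_probs`` -- Pr(M, F, C | M+F, affected, sex): the joint
  distribution of the full triad conditional on the parental allele sum,
  valid under parental allelic exchangeability.  Strata M+F in {0, 3}
  are deterministic and carry no information.
* ``parent_pair_probs`` -- Pr(M, F | M+F, affected, sex): the parental
  margin of the previous distribution; uses no offspring genotype at all.

All three are parameterized by sex-specific genotype relative risks:
``r_boy`` (per-copy risk in hemizygous sons), ``r_girl_het`` and
``r_girl_hom`` (heterozygous / homozygous daughters relative to
non-carrier daughters).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "RelativeRiskModel",
    "BOY_CELLS",
    "GIRL_CELLS",
    "admissible_cells",
    "EXCHANGEABLE_PRIOR",
    "transmission_prob",
    "matingsum_cell_probs",
    "parent_pair_probs",
    "NULL_RR",
]

#: Mendelian-admissible (M, F, C) triples for an affected son.
BOY_CELLS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),
    (0, 1, 0),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, 0),
    (1, 1, 1),
    (2, 0, 1),
    (2, 1, 1),
)

#: Mendelian-admissible (M, F, C) triples for an affected daughter.
GIRL_CELLS: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),
    (0, 1, 1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, 1),
    (1, 1, 2),
    (2, 0, 1),
    (2, 1, 2),
)

#: Pr(M, F | M+F) under parental allelic exchangeability: conditional on
#: the mating sum, the variant alleles are placed at random on the three
#: parental X chromosomes (two maternal, one paternal).
EXCHANGEABLE_PRIOR: dict[tuple[int, int], float] = {
    (0, 0): 1.0,
    (1, 0): 2.0 / 3.0,
    (0, 1): 1.0 / 3.0,
    (1, 1): 2.0 / 3.0,
    (2, 0): 1.0 / 3.0,
    (2, 1): 1.0,
}

MODES = ("codominant", "logadditive_girls", "xinactivation", "joint_logadditive")


@dataclass(frozen=True)
class RelativeRiskModel:
    """Sex-specific genotype relative risks with an optional constraint mode.

    Parameters
    ----------
    r_boy
        Relative risk of disease for a son carrying the variant versus a
        non-carrier son.
    r_girl_het, r_girl_hom
        Relative risks for daughters with one / two copies versus
        non-carrier daughters.
    mode
        ``codominant`` leaves all three risks free;
        ``logadditive_girls`` constrains ``r_girl_hom == r_girl_het**2``;
        ``xinactivation`` constrains ``r_girl_hom == r_boy``;
        ``joint_logadditive`` constrains ``r_girl_het**2 == r_girl_hom == r_boy``.
    """

    r_boy: float = 1.0
    r_girl_het: float = 1.0
    r_girl_hom: float = 1.0
    mode: str = "codominant"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("r_boy", "r_girl_het", "r_girl_hom"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def logadditive(cls, r_girl_het: float, r_boy: float = 1.0) -> "RelativeRiskModel":
        """Girls log-additive in copy number: r_girl_hom = r_girl_het**2."""
        return cls(r_boy=r_boy, r_girl_het=r_girl_het,
                   r_girl_hom=r_girl_het ** 2, mode="logadditive_girls")

    def constrained(self) -> "RelativeRiskModel":
        """Return a copy with the mode's constraint re-imposed."""
        if self.mode == "logadditive_girls":
            return replace(self, r_girl_hom=self.r_girl_het ** 2)
        if self.mode == "xinactivation":
            return replace(self, r_girl_hom=self.r_boy)
        if self.mode == "joint_logadditive":
            return replace(self, r_girl_het=self.r_boy ** 0.5, r_girl_hom=self.r_boy)
        return self

    def risk_factor(self, c: int, sex: str) -> float:
        """Relative risk multiplier for an affected child with C = c copies."""
        if sex == "boy":
            return self.r_boy if c == 1 else 1.0
        return (1.0, self.r_girl_het, self.r_girl_hom)[c]


NULL_RR = RelativeRiskModel()


def admissible_cells(sex: str) -> tuple[tuple[int, int, int], ...]:
    if sex == "boy":
        return BOY_CELLS
    if sex == "girl":
        return GIRL_CELLS
    raise ValueError(f"unknown sex {sex!r}")


def _mendel_prob(m: int) -> float:
    # probability of the realized maternal transmission given the mother
    return 0.5 if m == 1 else 1.0


def transmission_prob(m: int, f: int, c: int, sex: str, rr: RelativeRiskModel) -> float:
    """Pr(C = c | M = m, F = f, affected, sex).

    Informative only when the mother is heterozygous; all other mating
    types determine the child genotype and return 1.
    """
    if (m, f, c) not in admissible_cells(sex):
        raise ValueError(f"inadmissible cell {(m, f, c)} for {sex}")
    if m != 1:
        return 1.0
    if sex == "boy":
        r = rr.r_boy
        return r / (1.0 + r) if c == 1 else 1.0 / (1.0 + r)
    # girl: child genotype is F plus the maternal transmission
    if f == 0:
        r = rr.r_girl_het
        return r / (1.0 + r) if c == 1 else 1.0 / (1.0 + r)
    r1, r2 = rr.r_girl_het, rr.r_girl_hom
    return r2 / (r1 + r2) if c == 2 else r1 / (r1 + r2)


def matingsum_cell_probs(sex: str, rr: RelativeRiskModel) -> dict[tuple[int, int, int], float]:
    """Pr(M, F, C | M+F, affected, sex) for every admissible cell.

    Built from the exchangeability prior over (M, F) given M+F, Mendelian
    transmission, and the affection weighting RR(C); normalized within
    each mating-sum stratum.
    """
    raw: dict[tuple[int, int, int], float] = {}
    strata: dict[int, float] = {}
    for (m, f, c) in admissible_cells(sex):
        w = EXCHANGEABLE_PRIOR[(m, f)] * _mendel_prob(m) * rr.risk_factor(c, sex)
        raw[(m, f, c)] = w
        strata[m + f] = strata.get(m + f, 0.0) + w
    return {cell: w / strata[cell[0] + cell[1]] for cell, w in raw.items()}


def parent_pair_probs(sex: str, rr: RelativeRiskModel) -> dict[tuple[int, int], float]:
    """Pr(M, F | M+F, affected, sex): the parental margin of
    :func:`matingsum_cell_probs`; ignores the offspring genotype."""
    out: dict[tuple[int, int], float] = {}
    for (m, f, c), p in matingsum_cell_probs(sex, rr).items():
        out[(m, f)] = out.get((m, f), 0.0) + p
    return out
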