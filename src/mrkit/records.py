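"""Core domain records for GWAS summary statistics.

A :class:`SumStatRecord` is one variant's association summary in one study:
alleles, effect-allele frequency, effect size (beta), standard error,
p-value and sample size. :class:`StudyMeta` describes the study the records
came from (trait name, continuous vs binary, case/control counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "SumStatRecord",
    "StudyMeta",
    "VALID_ALLELES",
    "COMPLEMENT",
    "complement_allele",
    "validate_record",
]

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele pairs whose strand cannot be inferred from the letters alone
_PALINDROMIC_SETS = (frozenset({"A", "T"}), frozenset({"G", "C"}))


def complement_allele(allele: str) -> str:
    """Watson-Crick complement of a single-base allele."""
    return COMPLEMENT[allele]


@dataclass(frozen=True)
class SumStatRecord:
    """One variant's summary association in one study.

    Parameters
    ----------
    variant_id:
        rsID or ``chr:pos:ref:alt`` string; the key used to match variants
        across studies.
    chrom, pos:
        1-based genomic coordinate; optional, but required for LD clumping.
    effect_allele, other_allele:
        Single-base alleles; ``beta`` is per copy of ``effect_allele``.
    eaf:
        Effect-allele frequency in (0, 1); optional, but required to resolve
        palindromic variants during harmonization.
    beta:
        Per-allele effect (SD units for continuous traits, log-odds for
        binary traits).
    se:
        Standard error of ``beta``; strictly positive.
    pval:
        Two-sided p-value in (0, 1].
    n:
        Study sample size; optional, but required for the F-statistic.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: Optional[str] = None
    pos: Optional[int] = None
    eaf: Optional[float] = None
    n: Optional[float] = None

    @property
    def is_palindromic(self) -> bool:
        """True iff the allele pair is A/T or G/C (strand-ambiguous)."""
        return frozenset({self.effect_allele, self.other_allele}) in _PALINDROMIC_SETS

    @property
    def allele_set(self) -> frozenset:
        return frozenset({self.effect_allele, self.other_allele})

    def with_swapped_alleles(self) -> "SumStatRecord":
        """Re-express the record on the other allele (flip beta sign, 1-eaf)."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def with_complemented_alleles(self) -> "SumStatRecord":
        """Re-express the record on the opposite strand (letters only)."""
        return replace(
            self,
            effect_allele=complement_allele(self.effect_allele),
            other_allele=complement_allele(self.other_allele),
        )


def validate_record(rec: SumStatRecord) -> list[str]:
    """Return the list of invariant violations for ``rec`` (empty if valid)."""
    problems: list[str] = []
    if not rec.variant_id:
        problems.append("missing variant_id")
    if rec.effect_allele not in VALID_ALLELES or rec.other_allele not in VALID_ALLELES:
        problems.append("invalid allele")
    elif rec.effect_allele == rec.other_allele:
        problems.append("effect and other allele identical")
    if not (rec.se > 0):
        problems.append("non-positive se")
    if not (0 < rec.pval <= 1):
        problems.append("p-value outside (0, 1]")
    if rec.eaf is not None and not (0 < rec.eaf < 1):
        problems.append("eaf outside (0, 1)")
    if rec.n is not None and not (rec.n > 0):
        problems.append("non-positive sample size")
    if rec.pos is not None and rec.pos < 1:
        problems.append("non-positive position")
    return problems


@dataclass(frozen=True)
class StudyMeta:
    """Metadata describing one GWAS summary-statistics study."""

    study_id: str
    trait_name: str = ""
    trait_type: str = "continuous"
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    ancestry_label: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous or binary, got {self.trait_type!r}")
        if self.trait_type == "binary" and (self.n_cases is None or self.n_controls is None):
            raise ValueError("binary trait requires n_cases and n_controls")

    @property
    def is_binary(self) -> bool:
        return self.trait_type == "binary"
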