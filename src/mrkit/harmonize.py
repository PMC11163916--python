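"""Harmonization of exposure/outcome effect pairs onto a common effect allele.

Two studies may report the same variant with swapped allele roles, on
opposite strands, or both. Non-palindromic pairs are resolved from the
letters alone; palindromic variants (A/T, G/C) are strand-ambiguous and are
oriented using effect-allele frequencies — or dropped when either frequency
is missing or both sit too close to 0.5 to be informative. Irreconcilable
allele pairs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .instruments import InstrumentSet
from .records import SumStatRecord, complement_allele

__all__ = [
    "HarmonizedPair",
    "harmonize_pair",
    "harmonize_set",
    "AMBIGUITY_WINDOW",
    "DROP_ACTIONS",
]

#: palindromes with both eafs within 0.5 +/- this window are dropped
AMBIGUITY_WINDOW = 0.08

DROP_ACTIONS = frozenset({"dropped_incompatible", "dropped_ambiguous_palindrome"})

_ACTION_FROM_FLIPS = {
    (False, False): "kept",
    (False, True): "sign_flipped",
    (True, False): "strand_flipped",
    (True, True): "strand_flipped_and_sign_flipped",
}


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one variant on a shared effect allele.

    ``action`` records what was done to the outcome record: ``kept``,
    ``sign_flipped``, ``strand_flipped``, ``strand_flipped_and_sign_flipped``,
    or one of the ``dropped_*`` actions (in which case the outcome fields
    hold the unharmonized values and the pair must not be analyzed).
    """

    variant_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action: str
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None

    @property
    def dropped(self) -> bool:
        return self.action in DROP_ACTIONS


def _pair(exp: SumStatRecord, out: SumStatRecord, action: str) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exp.variant_id,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=out.beta,
        se_out=out.se,
        action=action,
        eaf_exp=exp.eaf,
        eaf_out=out.eaf,
    )


def harmonize_pair(
    exp_rec: SumStatRecord,
    out_rec: SumStatRecord,
    ambiguity_window: float = AMBIGUITY_WINDOW,
) -> HarmonizedPair:
    """Align one outcome record to the exposure record's effect allele.

    Non-palindromic variants: match the allele letters directly, or after
    complementing the outcome's alleles (strand flip); if the outcome's
    effect allele then sits in the exposure's "other" slot, flip the sign of
    the outcome beta and take 1-eaf. Palindromic variants: the letters are
    uninformative about strand, so orientation is taken from the allele
    frequencies — both studies' effect-allele frequencies must fall on the
    same side of 0.5; a disagreement implies a hidden strand flip and the
    outcome beta changes sign. Palindromes with either frequency missing, or
    both frequencies within ``0.5 +/- ambiguity_window``, are dropped as
    ambiguous.
    """
    if exp_rec.variant_id != out_rec.variant_id:
        raise ValueError(
            f"variant_id mismatch: {exp_rec.variant_id} vs {out_rec.variant_id}"
        )

    if exp_rec.is_palindromic:
        if out_rec.allele_set != exp_rec.allele_set:
            return _pair(exp_rec, out_rec, "dropped_incompatible")
        e_lo = 0.5 - ambiguity_window
        e_hi = 0.5 + ambiguity_window
        if exp_rec.eaf is None or out_rec.eaf is None:
            return _pair(exp_rec, out_rec, "dropped_ambiguous_palindrome")
        if e_lo <= exp_rec.eaf <= e_hi and e_lo <= out_rec.eaf <= e_hi:
            return _pair(exp_rec, out_rec, "dropped_ambiguous_palindrome")
        # align letters first, then let the frequencies arbitrate strand
        aligned = out_rec
        sign_flips = 0
        if aligned.effect_allele != exp_rec.effect_allele:
            aligned = aligned.with_swapped_alleles()
            sign_flips += 1
        same_side = (exp_rec.eaf - 0.5) * (aligned.eaf - 0.5) >= 0
        strand_flipped = not same_side
        if strand_flipped:
            aligned = aligned.with_swapped_alleles().with_complemented_alleles()
            sign_flips += 1
        action = _ACTION_FROM_FLIPS[(strand_flipped, sign_flips % 2 == 1)]
        return _pair(exp_rec, aligned, action)

    # non-palindromic: letters identify the strand unambiguously
    aligned = out_rec
    strand_flipped = False
    if aligned.allele_set != exp_rec.allele_set:
        complemented = aligned.with_complemented_alleles()
        if complemented.allele_set != exp_rec.allele_set:
            return _pair(exp_rec, out_rec, "dropped_incompatible")
        aligned = complemented
        strand_flipped = True
    sign_flipped = aligned.effect_allele != exp_rec.effect_allele
    if sign_flipped:
        aligned = aligned.with_swapped_alleles()
    return _pair(exp_rec, aligned, _ACTION_FROM_FLIPS[(strand_flipped, sign_flipped)])


def harmonize_set(
    instrument_set: InstrumentSet | Sequence[SumStatRecord],
    outcome_records: Sequence[SumStatRecord],
    ambiguity_window: float = AMBIGUITY_WINDOW,
) -> tuple[list[HarmonizedPair], dict]:
    """Harmonize every instrument found in the outcome study.

    Returns ``(pairs, attrition)`` where ``pairs`` contains one entry per
    instrument present in the outcome (dropped ones included, flagged by
    their action) and ``attrition`` counts
    ``{missing_in_outcome, dropped_incompatible, dropped_ambiguous_palindrome,
    analyzed}`` — always summing to the instrument count.
    """
    records = (
        instrument_set.records
        if isinstance(instrument_set, InstrumentSet)
        else list(instrument_set)
    )
    by_id = {r.variant_id: r for r in outcome_records}
    pairs: list[HarmonizedPair] = []
    attrition = {
        "missing_in_outcome": 0,
        "dropped_incompatible": 0,
        "dropped_ambiguous_palindrome": 0,
        "analyzed": 0,
    }
    for rec in records:
        out = by_id.get(rec.variant_id)
        if out is None:
            attrition["missing_in_outcome"] += 1
            continue
        pair = harmonize_pair(rec, out, ambiguity_window)
        pairs.append(pair)
        if pair.dropped:
            attrition[pair.action] += 1
        else:
            attrition["analyzed"] += 1
    return pairs, attrition


def audit_table(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    """Harmonization audit: one row per pair with the action taken."""
    return pd.DataFrame(
        [(p.variant_id, p.action, p.eaf_exp, p.eaf_out) for p in pairs],
        columns=["variant_id", "action", "eaf_exp", "eaf_out"],
    )
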