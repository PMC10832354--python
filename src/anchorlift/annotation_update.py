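"""Updating allele-indexed annotations when allele order changes.

Liftover can reorder the alleles of a record — either the reference allele
swaps roles with an alternate that the destination assembly carries, or a
novel reference allele is inserted when the destination matches no existing
allele.  Annotation fields indexed by allele (Number=R), by alternate allele
(Number=A) or by genotype (Number=G) must then be permuted consistently, and
a few fields carry extra assumptions:

* AF-like fields: per-alt frequencies whose implicit reference frequency is
  ``1 - sum``; the full per-allele vector is permuted and re-emitted per-alt.
* AC-like fields: per-alt counts whose implicit reference count is
  ``AN - sum``.
* GWAS-VCF effect size (ES) and Z-score (EZ): sign is relative to the
  reference allele, so a ref/alt swap reverses it.
* INFO/END: recomputed from the final position and reference length.

Slots created for a novel reference allele are filled with the missing-value
sentinel (``None``): no data exists for an allele that was never observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .variant_model import Genotype, VariantRecord

logger = logging.getLogger(__name__)

#: default name sets for fields carrying AF/AC semantics (header Number=A)
AF_LIKE_NAMES = ("AF", "MAF")
AF_LIKE_SUFFIX = "_AF"
AC_LIKE_NAMES = ("AC",)
AC_LIKE_SUFFIX = "_AC"
ES_NAMES = ("ES",)
EZ_NAMES = ("EZ",)

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class AllelePermutation:
    """Bijection from old allele indices onto new ones.

    ``mapping[i]`` is the new index of old allele ``i`` (0 = reference).
    With ``novel_ref`` the new allele count is ``n_old + 1`` and new index 0
    corresponds to the inserted reference allele, which has no old source.
    """

    mapping: tuple[int, ...]
    novel_ref: bool = False

    def __post_init__(self) -> None:
        n_new = self.n_new
        targets = set(self.mapping)
        if len(targets) != len(self.mapping) or not targets <= set(range(n_new)):
            raise ValueError(f"mapping {self.mapping} is not injective into 0..{n_new - 1}")
        if self.novel_ref and 0 in targets:
            raise ValueError("novel_ref permutation may not map anything onto index 0")

    @property
    def n_old(self) -> int:
        return len(self.mapping)

    @property
    def n_new(self) -> int:
        return self.n_old + (1 if self.novel_ref else 0)

    def __call__(self, i: int) -> int:
        return self.mapping[i]

    def is_identity(self) -> bool:
        return not self.novel_ref and all(self.mapping[i] == i for i in range(self.n_old))

    def inverse(self) -> "AllelePermutation":
        if self.novel_ref:
            raise ValueError("a novel-ref permutation is not invertible")
        inv = [0] * self.n_old
        for i, j in enumerate(self.mapping):
            inv[j] = i
        return AllelePermutation(tuple(inv))

    @classmethod
    def identity(cls, n_alleles: int) -> "AllelePermutation":
        return cls(tuple(range(n_alleles)))

    @classmethod
    def swap_ref_with(cls, n_alleles: int, alt_allele_index: int) -> "AllelePermutation":
        """Transposition exchanging the reference with allele ``alt_allele_index``."""
        if not 1 <= alt_allele_index < n_alleles:
            raise ValueError("alt allele index out of range")
        mapping = list(range(n_alleles))
        mapping[0], mapping[alt_allele_index] = alt_allele_index, 0
        return cls(tuple(mapping))

    @classmethod
    def novel_reference(cls, n_alleles: int) -> "AllelePermutation":
        """Novel ref inserted at index 0; the old ref becomes the last alternate."""
        mapping = [n_alleles] + list(range(1, n_alleles))
        return cls(tuple(mapping), novel_ref=True)


def genotype_index(j: int, k: int) -> int:
    """Index of diploid genotype (j, k) in VCF Number=G ordering."""
    if j > k:
        j, k = k, j
    return k * (k + 1) // 2 + j


# ---------------------------------------------------------------------------
# Positional permutation of R / A / G vectors
# ---------------------------------------------------------------------------

def permute_R(values: Sequence, perm: AllelePermutation) -> Optional[tuple]:
    """Reorder a per-allele (Number=R) vector; novel-ref slot becomes missing.

    Returns ``None`` (leave the tag untouched) on length mismatch.
    """
    if values is None:
        return None
    if len(values) != perm.n_old:
        logger.warning("Number=R vector of length %d does not match %d alleles; left untouched",
                       len(values), perm.n_old)
        return None
    out: list = [None] * perm.n_new
    for i, v in enumerate(values):
        out[perm(i)] = v
    return tuple(out)


def permute_A(values: Sequence, perm: AllelePermutation) -> Optional[tuple]:
    """Positionally reorder a per-alt (Number=A) vector.

    Values follow their alleles for alt-to-alt movements.  A ref/alt swap
    has no slot for the promoted alt's value, so that value stays in the
    slot now occupied by the demoted reference — the value describes the
    ref/alt contrast, which still lives in that slot (ES/EZ additionally
    reverse its sign; see :func:`flip_signed_A`).  This keeps a double swap
    an exact involution.  Slots of a novel reference's appended old-ref
    allele get the missing sentinel.
    """
    if values is None:
        return None
    if len(values) != perm.n_old - 1:
        logger.warning("Number=A vector of length %d does not match %d alt alleles; left untouched",
                       len(values), perm.n_old - 1)
        return None
    out: list = [None] * (perm.n_new - 1)
    for i, v in enumerate(values, start=1):
        j = perm(i)
        if j >= 1:
            out[j - 1] = v
    if not perm.novel_ref and perm(0) >= 1:
        pivot_old = perm.inverse()(0)
        if pivot_old >= 1:
            out[perm(0) - 1] = values[pivot_old - 1]
    return tuple(out)


def permute_G(values: Sequence, perm: AllelePermutation, ploidy: int = 2) -> Optional[tuple]:
    """Reorder a per-genotype (Number=G) vector for haploid or diploid calls.

    Diploid: value for genotype (j, k) moves to the index of
    (perm(j), perm(k)); genotypes involving a novel reference get the
    missing sentinel.  Haploid: behaves like Number=R.
    """
    if values is None:
        return None
    n_old, n_new = perm.n_old, perm.n_new
    if ploidy == 1 or len(values) == n_old:
        return permute_R(values, perm)
    if len(values) != n_old * (n_old + 1) // 2:
        logger.warning("Number=G vector of length %d does not match %d alleles; left untouched",
                       len(values), n_old)
        return None
    out: list = [None] * (n_new * (n_new + 1) // 2)
    for k in range(n_old):
        for j in range(k + 1):
            out[genotype_index(perm(j), perm(k))] = values[genotype_index(j, k)]
    return tuple(out)


# ---------------------------------------------------------------------------
# AF-like / AC-like fields with an implicit reference slot
# ---------------------------------------------------------------------------

def update_AF_like(values: Sequence, perm: AllelePermutation) -> Optional[tuple]:
    """Permute per-alt frequencies assuming the per-allele sum is 1.

    The implicit reference frequency ``1 - sum(values)`` joins the vector,
    the full per-allele vector is permuted, and the new reference's slot is
    dropped on re-emission.  Left untouched (returns ``None``) when values
    are missing, mismatched in length, or sum above ``1 + 1e-6``.
    """
    if values is None or any(v is None for v in values):
        return None
    if len(values) != perm.n_old - 1:
        logger.warning("AF-like vector length %d does not match %d alt alleles; left untouched",
                       len(values), perm.n_old - 1)
        return None
    total = float(sum(values))
    if total > 1.0 + _SUM_TOL:
        logger.warning("AF-like values sum to %g > 1; left untouched", total)
        return None
    full = [1.0 - total] + [float(v) for v in values]
    out: list = [None] * perm.n_new
    for i, v in enumerate(full):
        out[perm(i)] = v
    if perm.novel_ref:
        # the novel reference allele was never observed: frequency 0
        out[0] = 0.0
    return tuple(out[1:])


def update_AC_like(values: Sequence, perm: AllelePermutation, an: Optional[int]) -> Optional[tuple]:
    """Permute per-alt counts assuming the per-allele sum equals AN."""
    if values is None or any(v is None for v in values):
        return None
    if an is None:
        logger.warning("AC-like field without AN; left untouched")
        return None
    if len(values) != perm.n_old - 1:
        logger.warning("AC-like vector length %d does not match %d alt alleles; left untouched",
                       len(values), perm.n_old - 1)
        return None
    total = int(sum(values))
    if an < total:
        logger.warning("AC-like values sum to %d > AN=%d; left untouched", total, an)
        return None
    full = [an - total] + [int(v) for v in values]
    out: list = [None] * perm.n_new
    for i, v in enumerate(full):
        out[perm(i)] = v
    if perm.novel_ref:
        out[0] = 0
    return tuple(out[1:])


# ---------------------------------------------------------------------------
# GWAS-VCF sign reversal, END, genotypes
# ---------------------------------------------------------------------------

def flip_signed_A(values: Sequence, perm: AllelePermutation) -> Optional[tuple]:
    """Permute a signed per-alt vector (ES/EZ), negating the swapped slot.

    On a ref/alt swap the value of the alt that became reference moves to
    the old reference's new slot with its sign reversed; other values are
    untouched.  With a novel reference no sign can be assigned to the old
    reference (the effect of an allele never measured), so its slot is
    missing.
    """
    if values is None:
        return None
    if len(values) != perm.n_old - 1:
        logger.warning("signed Number=A vector length %d does not match %d alt alleles; "
                       "left untouched", len(values), perm.n_old - 1)
        return None
    out = permute_A(values, perm)
    if out is None:
        return None
    ref_new = perm(0)
    if not perm.novel_ref and ref_new >= 1:
        swapped_old = perm.inverse()(0)  # the alt that became reference
        v = values[swapped_old - 1]
        out = tuple(
            (-v if v is not None else None) if slot == ref_new - 1 else x
            for slot, x in enumerate(out))
    return out


def update_end(record: VariantRecord) -> VariantRecord:
    """Recompute INFO/END from the final position and reference length.

    Records without a declared END are left without one.
    """
    if "END" in record.info:
        record.info["END"] = record.pos + len(record.ref) - 1
    return record


def recode_genotype(gt: Genotype, perm: AllelePermutation) -> Genotype:
    """Map genotype allele indices through the permutation.

    Missing indices stay missing; unphased genotypes are re-sorted
    ascending, phased genotypes keep their order.  Out-of-range indices are
    set missing with a warning.
    """
    new: list[Optional[int]] = []
    for idx in gt.indices:
        if idx is None:
            new.append(None)
        elif 0 <= idx < perm.n_old:
            new.append(perm(idx))
        else:
            logger.warning("genotype index %d out of range for %d alleles; set missing",
                           idx, perm.n_old)
            new.append(None)
    if not gt.phased:
        new.sort(key=lambda x: (x is None, -1 if x is None else x))
    return Genotype(tuple(new), phased=gt.phased)


# ---------------------------------------------------------------------------
# Tag classification and whole-record application
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TagRules:
    """Per-tag semantic classes resolved from header Numbers and tag names.

    ``numbers`` maps tag name to its declared Number ('A', 'R', 'G', 0, 1,
    '.', ...).  AF-like, AC-like, ES and EZ tags are recognized by name
    among Number=A tags; unknown A/R/G tags are still permuted positionally.
    """

    info_numbers: Mapping[str, object]
    format_numbers: Mapping[str, object]

    def classify(self, tag: str, number: object) -> str:
        if tag == "END":
            return "END"
        if number == "A":
            if tag in ES_NAMES:
                return "ES-sign"
            if tag in EZ_NAMES:
                return "EZ-sign"
            if tag in AF_LIKE_NAMES or tag.endswith(AF_LIKE_SUFFIX):
                return "AF-like"
            if tag in AC_LIKE_NAMES or tag.endswith(AC_LIKE_SUFFIX):
                return "AC-like"
            return "A-ordered"
        if number == "R":
            return "R-ordered"
        if number == "G":
            return "G-ordered"
        return "plain"


def apply_permutation(
    record: VariantRecord,
    perm: AllelePermutation,
    rules: TagRules,
) -> VariantRecord:
    """Apply an allele permutation to every annotation of ``record`` in place.

    The record's allele fields must already reflect the new order; this
    routine only rewrites INFO values, FORMAT values and genotypes.  Fields
    whose update rule cannot be applied (length mismatch, missing AN, AF sum
    above 1) are left untouched, mirroring a warn-and-carry-on policy.
    """
    if perm.is_identity():
        return record

    an = record.info.get("AN")

    def updated(tag: str, value, numbers: Mapping[str, object]):
        kind = rules.classify(tag, numbers.get(tag))
        if kind == "plain" or kind == "END" or value is None:
            return value
        vals = value if isinstance(value, (tuple, list)) else (value,)
        if kind == "R-ordered":
            new = permute_R(vals, perm)
        elif kind == "G-ordered":
            new = permute_G(vals, perm)
        elif kind == "AF-like":
            new = update_AF_like(vals, perm)
        elif kind == "AC-like":
            new = update_AC_like(vals, perm, an if isinstance(an, int) else None)
        elif kind == "ES-sign" or kind == "EZ-sign":
            new = flip_signed_A(vals, perm)
        else:  # A-ordered
            new = permute_A(vals, perm)
        return value if new is None else new

    for tag in list(record.info):
        record.info[tag] = updated(tag, record.info[tag], rules.info_numbers)
    for sample in record.samples:
        for tag in list(sample):
            if tag == "GT":
                gt = sample["GT"]
                if isinstance(gt, Genotype):
                    sample["GT"] = recode_genotype(gt, perm)
            else:
                sample[tag] = updated(tag, sample[tag], rules.format_numbers)
    update_end(record)
    return record
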