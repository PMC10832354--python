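"""Conversion of one variant record between assemblies.

The engine converts a record in five steps:

1. SNV records take a fast path: the single polymorphic base is mapped
   directly through the chain index; if it falls in a chain gap the record
   falls through to the anchor path.
2. Otherwise the record is maximally extended and the 5' and 3' anchor
   bases are mapped.  The destination anchor bases are *not* required to
   equal the source anchor bases — only their locations matter.
3. If exactly one anchor maps (the variant sits at the edge of a chain
   gap), the other anchor's position is inferred by local realignment of
   the surrounding windows with affine-gap Needleman-Wunsch.
4. The destination sequence spanned by the mapped anchors is compared with
   the alleles (reverse-complemented first on '-'-strand chains): a match
   with the reference leaves allele order unchanged; a match with an
   alternate swaps it into the reference slot; no match inserts the
   destination sequence as a novel reference allele, with the old reference
   appended as the last alternate.
5. The converted record is re-normalized (left-aligned) against the
   destination genome and its allele-indexed annotations are permuted.

Every failure mode becomes a DROPPED result with a machine-readable
reason — never an exception.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .affine_align import AlignmentParams, AlignmentRefusedError, infer_missing_anchor
from .annotation_update import AllelePermutation, TagRules, apply_permutation, update_end
from .chain_index import BaseMapping, ChainIndex, MapOutcome
from .variant_model import (
    ExtendedRecord,
    GenomeSource,
    UnanchorableAtEdgeError,
    VariantClass,
    VariantRecord,
    classify,
    is_allelic_primitive,
    maximally_extend,
    normalize,
    reverse_complement,
)

logger = logging.getLogger(__name__)

#: INFO tags recording the pre-liftover location and alleles
SRC_CONTIG_TAG = "SRC_CONTIG"
SRC_POS_TAG = "SRC_POS"
SRC_REF_ALT_TAG = "SRC_REF_ALT"

_EMPTY_RULES = TagRules(info_numbers={}, format_numbers={})


class LiftStatus(Enum):
    REF_UNCHANGED = "REF_UNCHANGED"
    REF_SWAPPED = "REF_SWAPPED"
    REF_ADDED = "REF_ADDED"
    DROPPED = "DROPPED"


class DropReason(Enum):
    UNMAPPED_BOTH_ANCHORS = "unmapped_both_anchors"
    ANCHORS_DISCORDANT = "anchors_discordant"
    AMBIGUOUS_MAPPING = "ambiguous_mapping"
    UNANCHORABLE_AT_EDGE = "unanchorable_at_edge"
    REALIGN_FAILED = "realign_failed"
    REGION_TOO_LONG = "region_too_long"
    SYMBOLIC_UNSUPPORTED = "symbolic_unsupported"
    SRC_REF_MISMATCH = "src_ref_mismatch"
    BECAME_NON_PRIMITIVE = "became_non_primitive"


@dataclass(frozen=True)
class LiftOptions:
    """Tunables of the conversion.

    ``realign_window_flank`` is the number of bases appended beyond the
    failed anchor when extracting realignment windows; ``max_region_len``
    caps the anchor span on either assembly so that anchors mapping across
    a huge chain gap do not trigger unbounded sequence fetches.
    """

    realign_window_flank: int = 100
    max_region_len: int = 10_000
    align_params: AlignmentParams = field(default_factory=AlignmentParams)
    drop_non_primitives: bool = False
    record_source: bool = False

    def __post_init__(self) -> None:
        if self.realign_window_flank < 1:
            raise ValueError("realign_window_flank must be >= 1")
        if self.max_region_len < 1:
            raise ValueError("max_region_len must be >= 1")


@dataclass
class LiftResult:
    status: LiftStatus
    record: Optional[VariantRecord] = None
    reason: Optional[DropReason] = None
    permutation: Optional[AllelePermutation] = None
    strand_flipped: bool = False
    became_non_primitive: bool = False

    @property
    def dropped(self) -> bool:
        return self.status is LiftStatus.DROPPED


def _dropped(reason: DropReason) -> LiftResult:
    return LiftResult(status=LiftStatus.DROPPED, reason=reason)


# ---------------------------------------------------------------------------
# Allele resolution against the destination sequence
# ---------------------------------------------------------------------------

def resolve_alleles(
    ext_alleles: tuple[str, ...],
    dst_seq: str,
    strand: str,
) -> tuple[Optional[int], tuple[str, ...], AllelePermutation]:
    """Decide which allele the destination assembly carries.

    ``dst_seq`` is the forward-strand destination sequence between the
    mapped anchors, inclusive.  Alleles are oriented to the destination
    forward strand first (reverse complement on '-' chains).  Returns the
    old allele index that matched (``None`` for a novel reference), the new
    allele tuple in new order, and the permutation old index -> new index.
    Alleles are pairwise distinct, so at most one can match.
    """
    oriented = tuple(
        reverse_complement(a) if strand == "-" else a for a in ext_alleles)
    n = len(oriented)
    try:
        match = oriented.index(dst_seq)
    except ValueError:
        match = None
    if match is None:
        perm = AllelePermutation.novel_reference(n)
        new_alleles = (dst_seq,) + oriented[1:] + (oriented[0],)
        return None, new_alleles, perm
    if match == 0:
        return 0, oriented, AllelePermutation.identity(n)
    perm = AllelePermutation.swap_ref_with(n, match)
    new = list(oriented)
    new[0], new[match] = new[match], new[0]
    return match, tuple(new), perm


# ---------------------------------------------------------------------------
# Anchor mapping and recovery
# ---------------------------------------------------------------------------

@dataclass
class AnchorMappings:
    m5: Optional[BaseMapping]
    m3: Optional[BaseMapping]
    usable: bool
    reason: Optional[DropReason] = None
    ambiguous5: bool = False
    ambiguous3: bool = False


def _check_concordance(
    m5: BaseMapping, m3: BaseMapping, opts: LiftOptions
) -> Optional[DropReason]:
    if (m5.chain_id != m3.chain_id or m5.dst_contig != m3.dst_contig
            or m5.strand != m3.strand):
        return DropReason.ANCHORS_DISCORDANT
    if m5.strand == "+" and m5.dst_pos > m3.dst_pos:
        return DropReason.ANCHORS_DISCORDANT
    if m5.strand == "-" and m3.dst_pos > m5.dst_pos:
        return DropReason.ANCHORS_DISCORDANT
    if abs(m3.dst_pos - m5.dst_pos) + 1 > opts.max_region_len:
        return DropReason.REGION_TOO_LONG
    return None


def map_anchors(
    ext: ExtendedRecord, index: ChainIndex, opts: LiftOptions
) -> AnchorMappings:
    """Map the 5' and 3' anchor bases through the chain index.

    ``usable`` requires both anchors on the same chain, contig and strand,
    ordered consistently on the forward strand, within the region cap.
    Ambiguously covered anchors count as failed mappings (and are reported
    so the caller can distinguish the drop reason).
    """
    r5 = index.map_base(ext.contig, ext.anchor5)
    r3 = index.map_base(ext.contig, ext.anchor3)
    m5 = r5 if isinstance(r5, BaseMapping) else None
    m3 = r3 if isinstance(r3, BaseMapping) else None
    amb5 = r5 is MapOutcome.AMBIGUOUS
    amb3 = r3 is MapOutcome.AMBIGUOUS
    if m5 is None and m3 is None:
        reason = (DropReason.AMBIGUOUS_MAPPING if (amb5 or amb3)
                  else DropReason.UNMAPPED_BOTH_ANCHORS)
        return AnchorMappings(None, None, False, reason, amb5, amb3)
    if m5 is not None and m3 is not None:
        reason = _check_concordance(m5, m3, opts)
        return AnchorMappings(m5, m3, reason is None, reason, amb5, amb3)
    # exactly one mapped: not usable directly, recovery may follow
    return AnchorMappings(m5, m3, False, None, amb5, amb3)


def recover_anchor_by_realignment(
    ext: ExtendedRecord,
    mapped_side: str,
    m_known: BaseMapping,
    src_genome: GenomeSource,
    dst_genome: GenomeSource,
    opts: LiftOptions,
) -> Optional[BaseMapping]:
    """Infer the position of the anchor that the chain failed to map.

    ``mapped_side`` is ``"5"`` or ``"3"`` — the side that *did* map.  The
    source window spans the extended region plus a flank beyond the failed
    side; the destination window extends from the known anchor toward the
    failed side for the source window's length plus the flank (so that a
    net chain gap up to the flank size stays inside the window), reverse
    complemented on '-' chains so both windows share the source
    orientation.  Returns the recovered mapping or ``None`` when the
    alignment is refused or projects into a gap.
    """
    flank = opts.realign_window_flank
    src_len = src_genome.length(ext.contig)
    if mapped_side == "5":
        w_start = ext.anchor5
        w_end = min(ext.anchor3 + flank, src_len)
        failed_off = ext.anchor3 - w_start
    else:
        w_start = max(ext.anchor5 - flank, 1)
        w_end = ext.anchor3
        failed_off = ext.anchor5 - w_start
    src_window = src_genome.fetch(ext.contig, w_start, w_end)
    L = len(src_window) + flank

    pk = m_known.dst_pos
    strand = m_known.strand
    clen = dst_genome.length(m_known.dst_contig)
    # orient the destination window to the source orientation, with the
    # known anchor at the same end as in the source window
    toward_right = (mapped_side == "5") == (strand == "+")
    if toward_right:
        lo, hi = pk, min(pk + L - 1, clen)
    else:
        lo, hi = max(pk - L + 1, 1), pk
    if hi < lo:
        return None
    window_fwd = dst_genome.fetch(m_known.dst_contig, lo, hi)
    if strand == "+":
        dst_window = window_fwd

        def to_forward(off: int) -> int:
            return lo + off
    else:
        dst_window = reverse_complement(window_fwd)

        def to_forward(off: int) -> int:
            return hi - off

    try:
        off = infer_missing_anchor(
            src_window, dst_window, failed_off,
            params=opts.align_params, max_len=opts.max_region_len + 2 * flank)
    except AlignmentRefusedError:
        return None
    if off is None:
        return None
    pos = to_forward(off)
    if not 1 <= pos <= clen:
        return None
    return BaseMapping(dst_contig=m_known.dst_contig, dst_pos=pos,
                       strand=strand, chain_id=m_known.chain_id)


# ---------------------------------------------------------------------------
# Record assembly and finalization
# ---------------------------------------------------------------------------

def finalize(record: VariantRecord, dst_genome: GenomeSource) -> VariantRecord:
    """Left-align the converted record against the destination genome.

    Identifiers, quality and filters are preserved by normalization; END is
    recomputed from the final coordinates if declared.
    """
    out = normalize(record, dst_genome)
    return update_end(out)


def _build_converted(
    rec: VariantRecord,
    new_contig: str,
    new_pos: int,
    new_alleles: tuple[str, ...],
    perm: AllelePermutation,
    dst_genome: GenomeSource,
    opts: LiftOptions,
    rules: TagRules,
) -> VariantRecord:
    out = VariantRecord(
        contig=new_contig,
        pos=new_pos,
        ref=new_alleles[0],
        alts=tuple(new_alleles[1:]),
        ids=rec.ids,
        qual=rec.qual,
        filters=rec.filters,
        info=copy.deepcopy(rec.info),
        samples=copy.deepcopy(rec.samples),
    )
    out = apply_permutation(out, perm, rules)
    out = finalize(out, dst_genome)
    if opts.record_source:
        out.info[SRC_CONTIG_TAG] = rec.contig
        out.info[SRC_POS_TAG] = rec.pos
        out.info[SRC_REF_ALT_TAG] = rec.ref + "/" + ",".join(rec.alts)
    return out


# ---------------------------------------------------------------------------
# SNV fast path
# ---------------------------------------------------------------------------

_COMPLEMENT1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def lift_snv_fastpath(
    rec: VariantRecord,
    index: ChainIndex,
    dst_genome: GenomeSource,
    opts: LiftOptions,
    rules: TagRules,
) -> Optional[LiftResult]:
    """Convert a pure-SNV record by mapping its single polymorphic base.

    Returns ``None`` (fall through to the anchor path) when the base is not
    covered by the chain file.
    """
    r = index.map_base(rec.contig, rec.pos)
    if r is MapOutcome.UNMAPPED:
        return None
    if r is MapOutcome.AMBIGUOUS:
        return _dropped(DropReason.AMBIGUOUS_MAPPING)
    assert isinstance(r, BaseMapping)
    strand = r.strand
    try:
        dst_base = dst_genome.fetch(r.dst_contig, r.dst_pos, r.dst_pos)
    except (KeyError, IndexError):
        return _dropped(DropReason.UNMAPPED_BOTH_ANCHORS)
    match, new_alleles, perm = resolve_alleles(rec.alleles, dst_base, strand)
    if match == 0:
        status = LiftStatus.REF_UNCHANGED
    elif match is not None:
        status = LiftStatus.REF_SWAPPED
    else:
        status = LiftStatus.REF_ADDED
    out = _build_converted(
        rec, r.dst_contig, r.dst_pos, new_alleles, perm, dst_genome, opts, rules)
    assert out.ref == dst_base
    return LiftResult(status=status, record=out, permutation=perm,
                      strand_flipped=strand == "-",
                      became_non_primitive=not is_allelic_primitive(out))


# ---------------------------------------------------------------------------
# Full conversion
# ---------------------------------------------------------------------------

def lift_record(
    rec: VariantRecord,
    index: ChainIndex,
    src_genome: GenomeSource,
    dst_genome: GenomeSource,
    opts: LiftOptions = LiftOptions(),
    rules: TagRules = _EMPTY_RULES,
) -> LiftResult:
    """Convert one record to the destination assembly.

    Dispatches pure-SNV records to the fast path, everything else through
    maximal extension and anchor mapping.  On success the output record's
    reference allele matches the destination genome at its coordinates and
    the record is left-aligned against the destination.
    """
    if rec.is_symbolic():
        return _dropped(DropReason.SYMBOLIC_UNSUPPORTED)
    try:
        observed = src_genome.fetch(rec.contig, rec.pos, rec.end)
    except (KeyError, IndexError):
        return _dropped(DropReason.UNMAPPED_BOTH_ANCHORS)
    if observed != rec.ref:
        logger.warning("record %s:%d REF %s does not match source genome (%s)",
                       rec.contig, rec.pos, rec.ref, observed)
        return _dropped(DropReason.SRC_REF_MISMATCH)

    result: Optional[LiftResult] = None
    if classify(rec) is VariantClass.SNV:
        result = lift_snv_fastpath(rec, index, dst_genome, opts, rules)
    if result is None:
        result = _lift_by_anchors(rec, index, src_genome, dst_genome, opts, rules)
    if (opts.drop_non_primitives and not result.dropped
            and result.became_non_primitive):
        return _dropped(DropReason.BECAME_NON_PRIMITIVE)
    return result


def _lift_by_anchors(
    rec: VariantRecord,
    index: ChainIndex,
    src_genome: GenomeSource,
    dst_genome: GenomeSource,
    opts: LiftOptions,
    rules: TagRules,
) -> LiftResult:
    try:
        ext = maximally_extend(rec, src_genome)
    except UnanchorableAtEdgeError:
        return _dropped(DropReason.UNANCHORABLE_AT_EDGE)
    if ext.anchor3 - ext.anchor5 + 1 > opts.max_region_len:
        return _dropped(DropReason.REGION_TOO_LONG)

    anchors = map_anchors(ext, index, opts)
    m5, m3 = anchors.m5, anchors.m3
    if not anchors.usable:
        if anchors.reason is not None:
            return _dropped(anchors.reason)
        # exactly one anchor mapped: recover the other by realignment
        if m5 is not None:
            m3 = recover_anchor_by_realignment(
                ext, "5", m5, src_genome, dst_genome, opts)
        else:
            assert m3 is not None
            m5 = recover_anchor_by_realignment(
                ext, "3", m3, src_genome, dst_genome, opts)
        if m5 is None or m3 is None:
            return _dropped(DropReason.REALIGN_FAILED)
        reason = _check_concordance(m5, m3, opts)
        if reason is not None:
            return _dropped(reason)

    assert m5 is not None and m3 is not None
    strand = m5.strand
    p_lo, p_hi = sorted((m5.dst_pos, m3.dst_pos))
    try:
        dst_seq = dst_genome.fetch(m5.dst_contig, p_lo, p_hi)
    except (KeyError, IndexError):
        return _dropped(DropReason.ANCHORS_DISCORDANT)
    match, new_alleles, perm = resolve_alleles(ext.alleles, dst_seq, strand)
    if match == 0:
        status = LiftStatus.REF_UNCHANGED
    elif match is not None:
        status = LiftStatus.REF_SWAPPED
    else:
        status = LiftStatus.REF_ADDED

    out = _build_converted(
        rec, m5.dst_contig, p_lo, new_alleles, perm, dst_genome, opts, rules)
    was_primitive = is_allelic_primitive(rec)
    return LiftResult(
        status=status, record=out, permutation=perm,
        strand_flipped=strand == "-",
        became_non_primitive=was_primitive and not is_allelic_primitive(out),
    )
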