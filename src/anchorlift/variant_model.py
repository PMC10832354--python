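"""VCF record value model, normalization, and maximal extension.

A variant has many equivalent VCF representations.  Two canonical ones matter
here:

* the *normalized* record — left-aligned and parsimonious — which is the
  conventional representation for matching and deduplicating variants; and
* the *maximally extended* record, in which no allele is a prefix or suffix of
  another, all alleles share their first and last base, and no shorter
  representation does so.  The shared terminal bases are the 5' and 3'
  *anchors*: the only two positions that need to be located in a destination
  assembly in order to re-place the variant, which makes this representation
  the right substrate for liftover of indels and short tandem repeats.

Both representations are unique per variant.  This module also classifies
ref/alt pairs into allelic primitives (SNV, indel) versus MNV/complex, and
merges co-located bi-allelic records into multi-allelic ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Protocol, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Characters permitted in sequence alleles.  Anything else (symbolic
#: alleles, breakends, spanning deletions) is carried opaquely.
_SEQ_CHARS = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_sequence_allele(allele: str) -> bool:
    """True for plain nucleotide alleles; False for symbolic/breakend/'*'."""
    return bool(allele) and set(allele.upper()) <= _SEQ_CHARS


class GenomeSource(Protocol):
    """Random access to an assembly: 1-based inclusive coordinates."""

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return uppercase sequence of ``contig`` over ``[start, end]``."""
        ...

    def length(self, contig: str) -> int:
        ...

    def contigs(self) -> Sequence[str]:
        ...


class InMemoryGenome:
    """Dict-backed :class:`GenomeSource` used by tests and fixtures."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self._seqs[contig]
        if start < 1 or end > len(seq):
            raise IndexError(f"{contig}:{start}-{end} outside contig of length {len(seq)}")
        return seq[start - 1 : end]

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def contigs(self) -> Sequence[str]:
        return list(self._seqs)


@dataclass(frozen=True)
class Genotype:
    """Allele-index tuple of one sample call; ``None`` entries are missing."""

    indices: tuple[int | None, ...]
    phased: bool = False

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if i is None else str(i) for i in self.indices)


@dataclass
class VariantRecord:
    """One VCF data line.

    ``info`` values follow the header's Number declaration: scalars for
    Number=0/1, tuples for A/R/G and variable counts, with ``None`` entries
    for missing values.  ``samples`` holds one dict per sample in header
    order; the GT entry is a :class:`Genotype`.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    ids: tuple[str, ...] = ()
    qual: float | None = None
    filters: tuple[str, ...] = ()
    info: dict = field(default_factory=dict)
    samples: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alts = tuple(a.upper() if is_sequence_allele(a) else a for a in self.alts)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference allele span."""
        return self.pos + len(self.ref) - 1

    def is_symbolic(self) -> bool:
        return not all(is_sequence_allele(a) for a in self.alleles)


@dataclass(frozen=True)
class ExtendedRecord:
    """Maximally extended representation with its anchor coordinates.

    ``alleles[0]`` is the reference allele; ``anchor5 == pos`` and
    ``anchor3 == pos + len(alleles[0]) - 1`` are the shared first/last
    reference bases.
    """

    contig: str
    pos: int
    alleles: tuple[str, ...]
    anchor5: int
    anchor3: int


class VariantClass(Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    MNV = "MNV"
    COMPLEX = "COMPLEX"
    SYMBOLIC = "SYMBOLIC"


class UnanchorableAtEdgeError(Exception):
    """Maximal extension ran off the contig before its conditions were met."""


class MergeConflictError(Exception):
    """Co-located records carry genotypes that cannot coexist in one site."""


# ---------------------------------------------------------------------------
# Normalization (left-align + parsimony)
# ---------------------------------------------------------------------------

def normalize(rec: VariantRecord, genome: GenomeSource) -> VariantRecord:
    """Return the left-aligned, parsimonious representation of ``rec``.

    Iteratively right-trims shared terminal bases, extending left with the
    preceding reference base whenever an allele would become empty, then
    left-trims shared leading bases while every allele keeps length >= 1.
    Idempotent.  If left extension is required at the contig start the
    procedure stops there and the partially trimmed record is returned.
    """
    if rec.is_symbolic():
        return rec
    pos = rec.pos
    alleles = [a for a in rec.alleles]
    if len(set(alleles)) < 2:
        return rec
    contig = rec.contig
    while True:
        last = {a[-1] for a in alleles}
        if len(last) != 1:
            break
        if any(len(a) == 1 for a in alleles):
            if pos == 1:
                logger.warning(
                    "normalization stopped at start of contig %s for record at pos %d",
                    contig, rec.pos,
                )
                break
            base = genome.fetch(contig, pos - 1, pos - 1)
            alleles = [base + a[:-1] for a in alleles]
            pos -= 1
        else:
            alleles = [a[:-1] for a in alleles]
    while all(len(a) >= 2 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    return replace(rec, pos=pos, ref=alleles[0], alts=tuple(alleles[1:]))


# ---------------------------------------------------------------------------
# Maximal extension
# ---------------------------------------------------------------------------

def _has_prefix_suffix_pair(alleles: Sequence[str]) -> bool:
    n = len(alleles)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = alleles[i], alleles[j]
            if len(a) == len(b):
                continue
            short, long_ = (a, b) if len(a) < len(b) else (b, a)
            if long_.startswith(short) or long_.endswith(short):
                return True
    return False


def maximally_extend(rec: VariantRecord, genome: GenomeSource) -> ExtendedRecord:
    """Compute the unique maximally extended representation of ``rec``.

    Normalizes first, then extends one base left if the alleles do not share
    a first base, one base right if they do not share a last base, and keeps
    extending right while any allele is a prefix or suffix of a longer one.
    Extension always appends the same reference base to every allele, so the
    shared-first-base and shared-last-base conditions, once established, are
    preserved.

    Raises :class:`UnanchorableAtEdgeError` when a required extension would
    run past either end of the contig.
    """
    if rec.is_symbolic():
        raise ValueError("symbolic alleles cannot be maximally extended")
    nrec = normalize(rec, genome)
    contig = nrec.contig
    clen = genome.length(contig)
    pos = nrec.pos
    alleles = list(nrec.alleles)

    def extend_left() -> None:
        nonlocal pos, alleles
        if pos <= 1:
            raise UnanchorableAtEdgeError(
                f"cannot extend past start of contig {contig} at pos {pos}")
        base = genome.fetch(contig, pos - 1, pos - 1)
        alleles = [base + a for a in alleles]
        pos -= 1

    def extend_right() -> None:
        nonlocal alleles
        ref_end = pos + len(alleles[0]) - 1
        if ref_end >= clen:
            raise UnanchorableAtEdgeError(
                f"cannot extend past end of contig {contig} at pos {ref_end}")
        base = genome.fetch(contig, ref_end + 1, ref_end + 1)
        alleles = [a + base for a in alleles]

    if len({a[0] for a in alleles}) != 1:
        extend_left()
    if len({a[-1] for a in alleles}) != 1:
        extend_right()
    while _has_prefix_suffix_pair(alleles):
        extend_right()

    anchor3 = pos + len(alleles[0]) - 1
    return ExtendedRecord(
        contig=contig, pos=pos, alleles=tuple(alleles), anchor5=pos, anchor3=anchor3
    )


# ---------------------------------------------------------------------------
# Classification into allelic primitives
# ---------------------------------------------------------------------------

def classify_pair(ref: str, alt: str) -> VariantClass:
    """Classify one ref/alt pair after reducing it to its minimal form."""
    if not (is_sequence_allele(ref) and is_sequence_allele(alt)):
        return VariantClass.SYMBOLIC
    a, b = ref.upper(), alt.upper()
    # strip longest shared prefix, then longest shared suffix
    i = 0
    while i < len(a) and i < len(b) and a[i] == b[i]:
        i += 1
    a, b = a[i:], b[i:]
    j = 0
    while j < len(a) and j < len(b) and a[len(a) - 1 - j] == b[len(b) - 1 - j]:
        j += 1
    if j:
        a, b = a[:-j], b[:-j]
    if len(a) == 1 and len(b) == 1:
        return VariantClass.SNV
    if len(a) == 0 or len(b) == 0:
        return VariantClass.INDEL
    if len(a) == len(b):
        return VariantClass.MNV
    return VariantClass.COMPLEX


def classify(rec: VariantRecord) -> VariantClass:
    """Overall class of a record: primitive only if every ref/alt pair is.

    SNV if every pair is an SNV; INDEL if every pair is primitive and at
    least one is an indel; otherwise the record is complex (or symbolic).
    """
    classes = {classify_pair(rec.ref, alt) for alt in rec.alts}
    if VariantClass.SYMBOLIC in classes:
        return VariantClass.SYMBOLIC
    if VariantClass.COMPLEX in classes:
        return VariantClass.COMPLEX
    if VariantClass.MNV in classes:
        return VariantClass.MNV
    if classes == {VariantClass.SNV}:
        return VariantClass.SNV
    return VariantClass.INDEL


def is_allelic_primitive(rec: VariantRecord) -> bool:
    return classify(rec) in (VariantClass.SNV, VariantClass.INDEL)


# ---------------------------------------------------------------------------
# Bi-allelic -> multi-allelic merge
# ---------------------------------------------------------------------------

def _genotype_index(j: int, k: int) -> int:
    """VCF ordering of diploid genotype (j, k) with j <= k."""
    if j > k:
        j, k = k, j
    return k * (k + 1) // 2 + j


def merge_biallelic(
    records: Sequence[VariantRecord],
    numbers: Mapping[str, object] | None = None,
) -> VariantRecord:
    """Join co-located records into one multi-allelic record.

    All records must share contig and position; every ref must be a prefix of
    the longest ref so that shorter alleles can be padded with reference
    bases.  Number=A/R/G annotations (as declared in ``numbers``, a tag ->
    Number mapping for both INFO and FORMAT tags) are concatenated or
    expanded; genotypes are re-indexed.  Cross-allele genotype values that no
    input record observed (e.g. PL of a 1/2 genotype) become missing.

    Sample genotypes are combined by alternate-allele dosage; if the summed
    dosage at a sample exceeds its ploidy the merge is refused with
    :class:`MergeConflictError`.  Merged genotypes are emitted unphased.
    """
    if not records:
        raise ValueError("no records to merge")
    if len(records) == 1:
        return records[0]
    first = records[0]
    if any(r.contig != first.contig or r.pos != first.pos for r in records):
        raise ValueError("records to merge must share contig and position")
    numbers = dict(numbers or {})

    longest_ref = max((r.ref for r in records), key=len)
    for r in records:
        if not longest_ref.startswith(r.ref):
            raise ValueError(
                f"ref {r.ref} is not a prefix of {longest_ref}; cannot pad")

    # padded alt lists per record, then a deduplicated combined alt list
    padded: list[list[str]] = []
    for r in records:
        suffix = longest_ref[len(r.ref):]
        padded.append([alt + suffix for alt in r.alts])
    new_alts: list[str] = []
    # old (record index, local alt index 1-based) -> merged allele index
    remap: dict[tuple[int, int], int] = {}
    for ri, alts in enumerate(padded):
        for ai, alt in enumerate(alts, start=1):
            if alt == longest_ref:
                raise ValueError("padded alt equals reference allele")
            if alt in new_alts:
                remap[(ri, ai)] = new_alts.index(alt) + 1
            else:
                new_alts.append(alt)
                remap[(ri, ai)] = len(new_alts)
    n_new = len(new_alts) + 1

    # --- genotypes by dosage -------------------------------------------------
    n_samples = len(first.samples)
    if any(len(r.samples) != n_samples for r in records):
        raise ValueError("records to merge must have the same sample count")
    merged_samples: list[dict] = []
    for si in range(n_samples):
        fields: dict = {}
        gts = [r.samples[si].get("GT") for r in records]
        ploidies = {len(g.indices) for g in gts if g is not None}
        if len(ploidies) > 1:
            raise MergeConflictError(f"sample {si}: inconsistent ploidy across records")
        if ploidies:
            ploidy = ploidies.pop()
            if all(g is None or all(i is None for i in g.indices) for g in gts):
                fields["GT"] = Genotype((None,) * ploidy, phased=False)
            else:
                dosage: list[int] = []
                for ri, g in enumerate(gts):
                    if g is None:
                        continue
                    for idx in g.indices:
                        if idx is not None and idx >= 1:
                            dosage.append(remap[(ri, idx)])
                if len(dosage) > ploidy:
                    raise MergeConflictError(
                        f"sample {si}: {len(dosage)} non-reference alleles for ploidy {ploidy}")
                indices = sorted(dosage) + [0] * (ploidy - len(dosage))
                fields["GT"] = Genotype(tuple(sorted(indices)), phased=False)
        merged_samples.append(fields)

    def merge_vector(tag: str, values_per_record: list) -> object:
        number = numbers.get(tag)
        if number == "A":
            out: list = [None] * (n_new - 1)
            for ri, vals in enumerate(values_per_record):
                if vals is None:
                    continue
                for ai, v in enumerate(vals, start=1):
                    out[remap[(ri, ai)] - 1] = v
            return tuple(out)
        if number == "R":
            out = [None] * n_new
            for ri, vals in enumerate(values_per_record):
                if vals is None:
                    continue
                if out[0] is None:
                    out[0] = vals[0]
                for ai, v in enumerate(vals[1:], start=1):
                    out[remap[(ri, ai)]] = v
            return tuple(out)
        if number == "G":
            out = [None] * (n_new * (n_new + 1) // 2)
            for ri, vals in enumerate(values_per_record):
                if vals is None:
                    continue
                j = remap[(ri, 1)]
                if out[_genotype_index(0, 0)] is None:
                    out[_genotype_index(0, 0)] = vals[0]
                if len(vals) >= 3:
                    out[_genotype_index(0, j)] = vals[1]
                    out[_genotype_index(j, j)] = vals[2]
            return tuple(out)
        for vals in values_per_record:
            if vals is not None:
                return vals
        return None

    info: dict = {}
    for tag in {t for r in records for t in r.info}:
        info[tag] = merge_vector(tag, [r.info.get(tag) for r in records])
    for si in range(n_samples):
        for tag in {t for r in records for t in r.samples[si] if t != "GT"}:
            merged_samples[si][tag] = merge_vector(
                tag, [r.samples[si].get(tag) for r in records])

    ids = tuple(dict.fromkeys(i for r in records for i in r.ids))
    return VariantRecord(
        contig=first.contig,
        pos=first.pos,
        ref=longest_ref,
        alts=tuple(new_alts),
        ids=ids,
        qual=first.qual,
        filters=first.filters,
        info=info,
        samples=merged_samples,
    )


def split_multiallelic(
    rec: VariantRecord,
    numbers: Mapping[str, object] | None = None,
    genome: GenomeSource | None = None,
) -> list[VariantRecord]:
    """Split a multi-allelic record into one bi-allelic record per alt.

    The inverse of :func:`merge_biallelic` up to normalization: Number=A/R/G
    vectors are sliced per allele, genotype indices of other alternates map
    to the reference.  If ``genome`` is given each output is normalized.
    """
    if len(rec.alts) <= 1:
        return [rec]
    numbers = dict(numbers or {})
    out: list[VariantRecord] = []
    for ai, alt in enumerate(rec.alts, start=1):
        def slice_vector(tag: str, vals: object) -> object:
            number = numbers.get(tag)
            if vals is None or not isinstance(vals, tuple):
                return vals
            if number == "A":
                return (vals[ai - 1],)
            if number == "R":
                return (vals[0], vals[ai])
            if number == "G":
                return (
                    vals[_genotype_index(0, 0)],
                    vals[_genotype_index(0, ai)],
                    vals[_genotype_index(ai, ai)],
                )
            return vals

        samples = []
        for s in rec.samples:
            fields = {}
            for tag, v in s.items():
                if tag == "GT" and isinstance(v, Genotype):
                    idx = tuple(
                        None if i is None else (1 if i == ai else 0) for i in v.indices)
                    fields["GT"] = Genotype(idx, phased=v.phased)
                else:
                    fields[tag] = slice_vector(tag, v)
            samples.append(fields)
        sub = VariantRecord(
            contig=rec.contig,
            pos=rec.pos,
            ref=rec.ref,
            alts=(alt,),
            ids=rec.ids,
            qual=rec.qual,
            filters=rec.filters,
            info={t: slice_vector(t, v) for t, v in rec.info.items()},
            samples=samples,
        )
        out.append(normalize(sub, genome) if genome is not None else sub)
    return out
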