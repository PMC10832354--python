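"""Synthetic paired assemblies with exact chains and a lift truth table.

The generator plants a configurable mix of assembly differences into a
random source contig — substituted bases, short tandem repeat (STR) length
changes, insertions, deletions, inverted segments and regions absent from
the destination — applies them to produce the destination contig, and emits
the *exact* chain describing that alignment together with a VCF of planted
variants and the expected outcome of lifting each one.

Two chain dialects are produced on request, mirroring how real same-species
liftover chains are built:

* ``gap`` style: substituted bases are excluded from aligned blocks, giving
  one-base-pair double-sided gaps (BLAT-style), and single-sided indel gaps
  are widened by one aligned base so that one anchor of the planted indel
  falls inside the gap and must be recovered by realignment;
* ``tolerant`` style: substitutions stay inside aligned blocks and indel
  gaps are exact.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .chain_index import Chain, ChainBlock, write_chain_file
from .lift_engine import DropReason, LiftResult, LiftStatus
from .variant_model import Genotype, InMemoryGenome, VariantRecord, reverse_complement

_BASES = "ACGT"

#: header Number declarations for the planted annotations
FIXTURE_INFO_NUMBERS: Mapping[str, object] = {"AF": "A", "AC": "A", "AN": 1}
FIXTURE_FORMAT_NUMBERS: Mapping[str, object] = {"GT": 1, "AD": "R", "PL": "G"}

#: fraction of planted variants per scenario kind
KIND_FRACTIONS = {
    "snv_same": 0.15,        # destination carries the reference base
    "snv_alt": 0.20,         # destination carries the alternate -> swap
    "snv_third": 0.10,       # destination carries a third base -> novel ref
    "str_swap": 0.125,       # STR resized to the alternate's length
    "str_added": 0.125,      # STR resized to a third length -> novel ref
    "delete": 0.075,         # destination carries the deletion allele
    "insert": 0.075,         # destination carries the insertion allele
    "invert_ref": 0.05,      # SNV inside an inverted segment, ref retained
    "invert_alt": 0.05,      # SNV inside an inverted segment, alt in dst
    "transloc": 0.05,        # variant inside a region absent from dst
}


@dataclass(frozen=True)
class Segment:
    """Base-level correspondence: ``n`` source bases from ``t0`` align to
    ``n`` destination bases from ``q0`` (both 0-based, forward strand);
    on '-' the destination run is reversed and complemented."""

    t0: int
    q0: int
    n: int
    strand: str


@dataclass
class PlantedVariant:
    """One planted record and the outcome its construction implies."""

    record: VariantRecord
    kind: str
    expected_status: LiftStatus
    expected_reason: Optional[DropReason] = None
    strand_flipped: bool = False
    in_gap: bool = False

    @property
    def key(self) -> tuple:
        r = self.record
        return (r.contig, r.pos, r.ref, r.alts)


@dataclass
class TruthReport:
    n: int
    n_matched: int
    n_nongap: int
    n_nongap_matched: int
    confusion: dict

    @property
    def overall_fraction(self) -> float:
        return self.n_matched / self.n if self.n else 1.0

    @property
    def nongap_fraction(self) -> float:
        return self.n_nongap_matched / self.n_nongap if self.n_nongap else 1.0


@dataclass
class AssemblyPair:
    """Synthetic source/destination genomes plus their exact alignment."""

    src_name: str
    dst_name: str
    src_seq: str
    dst_seq: str
    segments: list[Segment]
    truth: list[PlantedVariant]
    chain_style: str
    info_numbers: Mapping[str, object] = field(default_factory=lambda: dict(FIXTURE_INFO_NUMBERS))
    format_numbers: Mapping[str, object] = field(default_factory=lambda: dict(FIXTURE_FORMAT_NUMBERS))
    sample_names: tuple[str, ...] = ("S1", "S2")

    @property
    def src_genome(self) -> InMemoryGenome:
        return InMemoryGenome({self.src_name: self.src_seq})

    @property
    def dst_genome(self) -> InMemoryGenome:
        return InMemoryGenome({self.dst_name: self.dst_seq})

    @property
    def records(self) -> list[VariantRecord]:
        return [t.record for t in self.truth]

    def chains(self) -> list[Chain]:
        return _segments_to_chains(
            self.segments, self.src_name, len(self.src_seq),
            self.dst_name, len(self.dst_seq))

    def inverse_chains(self) -> list[Chain]:
        inv = [Segment(t0=s.q0, q0=s.t0, n=s.n, strand=s.strand)
               for s in self.segments]
        inv.sort(key=lambda s: s.t0)
        return _segments_to_chains(
            inv, self.dst_name, len(self.dst_seq),
            self.src_name, len(self.src_seq))

    def map_src_base(self, pos: int) -> Optional[tuple[int, str]]:
        """Ground-truth destination (1-based forward pos, strand) of a source
        base, independent of the chain machinery."""
        p0 = pos - 1
        for seg in self.segments:
            if seg.t0 <= p0 < seg.t0 + seg.n:
                off = p0 - seg.t0
                if seg.strand == "+":
                    return seg.q0 + off + 1, "+"
                return seg.q0 + seg.n - off, "-"
        return None

    def mirror(self) -> "AssemblyPair":
        """The same pair with the destination contig reverse-complemented.

        Every '+' correspondence becomes '-' and vice versa; planted records
        and expected statuses are unchanged while strand flags invert.
        """
        dlen = len(self.dst_seq)
        segs = [
            Segment(t0=s.t0, q0=dlen - s.q0 - s.n, n=s.n,
                    strand="-" if s.strand == "+" else "+")
            for s in self.segments
        ]
        truth = [
            PlantedVariant(
                record=t.record, kind=t.kind,
                expected_status=t.expected_status,
                expected_reason=t.expected_reason,
                strand_flipped=(not t.strand_flipped
                                if t.expected_status is not LiftStatus.DROPPED
                                else t.strand_flipped),
                in_gap=t.in_gap)
            for t in self.truth
        ]
        return AssemblyPair(
            src_name=self.src_name, dst_name=self.dst_name + "_rc",
            src_seq=self.src_seq, dst_seq=reverse_complement(self.dst_seq),
            segments=segs, truth=truth, chain_style=self.chain_style,
            info_numbers=dict(self.info_numbers),
            format_numbers=dict(self.format_numbers),
            sample_names=self.sample_names)

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTA (+ .fai), chains, planted VCF and truth TSV."""
        from pyfaidx import Faidx

        from .io_cli import write_vcf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for label, name, seq in (("src_fasta", self.src_name, self.src_seq),
                                 ("dst_fasta", self.dst_name, self.dst_seq)):
            p = outdir / f"{name}.fa"
            with open(p, "w") as fh:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
            Faidx(str(p))
            paths[label] = p
        paths["chain"] = outdir / "src2dst.chain"
        write_chain_file(self.chains(), paths["chain"])
        paths["inverse_chain"] = outdir / "dst2src.chain"
        write_chain_file(self.inverse_chains(), paths["inverse_chain"])
        paths["vcf"] = outdir / "planted.vcf"
        write_vcf(paths["vcf"], self.records,
                  contigs={self.src_name: len(self.src_seq)},
                  info_numbers=self.info_numbers,
                  format_numbers=self.format_numbers,
                  sample_names=self.sample_names)
        paths["truth"] = outdir / "truth.tsv"
        with open(paths["truth"], "w") as fh:
            fh.write("contig\tpos\tref\talts\tkind\texpected_status\t"
                     "expected_reason\tstrand_flipped\tin_gap\n")
            for t in self.truth:
                r = t.record
                fh.write("\t".join([
                    r.contig, str(r.pos), r.ref, ",".join(r.alts), t.kind,
                    t.expected_status.value,
                    t.expected_reason.value if t.expected_reason else ".",
                    "1" if t.strand_flipped else "0",
                    "1" if t.in_gap else "0",
                ]) + "\n")
        return paths


# ---------------------------------------------------------------------------
# Chain emission from segments
# ---------------------------------------------------------------------------

def _segments_to_chains(
    segments: Sequence[Segment], t_name: str, t_size: int,
    q_name: str, q_size: int,
) -> list[Chain]:
    """Group colinear same-strand segments into chains with gaps.

    A run of segments joins one chain while both coordinates advance
    consistently (forward q for '+', reverse-complement q offsets for '-',
    per the UCSC convention); an inversion embedded in a forward alignment
    therefore becomes its own single-block chain, while a genome-wide
    reverse alignment becomes one gapped '-' chain.
    """
    chains: list[Chain] = []
    next_id = 1
    for strand in ("+", "-"):
        segs = sorted((s for s in segments if s.strand == strand),
                      key=lambda s: s.t0)
        group: list[Segment] = []

        def q_off(s: Segment) -> int:
            # block offset on the strand the chain header states
            return s.q0 if strand == "+" else q_size - (s.q0 + s.n)

        def flush() -> None:
            nonlocal next_id
            if not group:
                return
            blocks = tuple(ChainBlock(t_start=s.t0, t_end=s.t0 + s.n,
                                      q_start=q_off(s), size=s.n)
                           for s in group)
            chains.append(Chain(
                score=1000.0, t_name=t_name, t_size=t_size,
                t_start=blocks[0].t_start, t_end=blocks[-1].t_end,
                q_name=q_name, q_size=q_size, q_strand=strand,
                q_start=blocks[0].q_start,
                q_end=blocks[-1].q_start + blocks[-1].size,
                chain_id=next_id, blocks=blocks))
            next_id += 1
            group.clear()

        for s in segs:
            if group:
                prev = group[-1]
                if s.t0 < prev.t0 + prev.n or q_off(s) < q_off(prev) + prev.n:
                    flush()
            group.append(s)
        flush()
    return chains


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _other_base(rng: random.Random, *exclude: str) -> str:
    pool = [b for b in _BASES if b not in exclude]
    return rng.choice(pool)


def _make_genotype_fields(rng: random.Random, n_alts: int = 1) -> tuple[dict, list[dict]]:
    """INFO (AF/AC/AN) and two diploid samples (GT/AD/PL), mutually consistent."""
    an = 4
    ac = rng.choice([1, 2, 3])
    if ac == 1:
        gts = [(0, 1), (0, 0)]
    elif ac == 2:
        gts = rng.choice([[(0, 1), (0, 1)], [(1, 1), (0, 0)]])
    else:
        gts = [(1, 1), (0, 1)]
    info = {"AF": (ac / an,), "AC": (ac,), "AN": an}
    samples = []
    for gt in gts:
        dp_ref = rng.randrange(5, 30)
        dp_alt = rng.randrange(5, 30)
        pl = tuple(sorted(rng.sample(range(0, 200), 3)))
        samples.append({
            "GT": Genotype(tuple(sorted(gt))),
            "AD": (dp_ref, dp_alt),
            "PL": (pl[0] if 0 in gt else pl[2],
                   pl[0] if set(gt) == {0, 1} else pl[1],
                   pl[0] if gt == (1, 1) else pl[2]),
        })
    return info, samples


@dataclass
class _Edit:
    start: int                 # 0-based source offset where the edit's items begin
    src_end: int               # 0-based exclusive source end consumed by the items
    items: list
    variant: PlantedVariant


def generate_pair(
    seed: int,
    contig_length: int = 50_000,
    n_variants: int = 200,
    chain_style: str = "gap",
    str_units: Sequence[str] = ("AC", "CAG"),
    src_name: str = "srcA",
    dst_name: str = "dstA",
) -> AssemblyPair:
    """Build a deterministic :class:`AssemblyPair` under ``seed``.

    Scenario counts follow :data:`KIND_FRACTIONS`; loci are evenly spaced
    with jitter and kept clear of the contig ends.  ``chain_style`` selects
    the ``gap`` or ``tolerant`` chain dialect (see module docstring).
    """
    if chain_style not in ("gap", "tolerant"):
        raise ValueError("chain_style must be 'gap' or 'tolerant'")
    rng = random.Random(seed)
    margin = 300
    span = contig_length - 2 * margin
    step = span / n_variants
    if step < 180:
        raise ValueError(
            f"{n_variants} variants do not fit a {contig_length} bp contig "
            "with non-overlapping extended regions")

    kinds: list[str] = []
    for kind, frac in KIND_FRACTIONS.items():
        kinds.extend([kind] * int(frac * n_variants))
    while len(kinds) < n_variants:
        kinds.append("snv_same")
    kinds = kinds[:n_variants]
    rng.shuffle(kinds)

    src = list(_random_seq(rng, contig_length))
    loci = [margin + int(step * (i + 0.5)) + rng.randrange(-20, 21)
            for i in range(n_variants)]

    # pass 1: carve STR runs into the source so that records can read them
    str_layout: dict[int, tuple[str, int]] = {}
    for c, kind in zip(loci, kinds):
        if kind not in ("str_swap", "str_added"):
            continue
        unit = rng.choice(list(str_units))
        k = rng.randrange(5, 9)
        u = len(unit)
        s = c
        src[s:s + k * u] = list(unit * k)
        src[s - 1] = _other_base(rng, unit[-1], unit[0])
        src[s + k * u] = _other_base(rng, unit[0], unit[-1])
        str_layout[c] = (unit, k)

    gap_mode = chain_style == "gap"
    edits: list[_Edit] = []
    for c, kind in zip(loci, kinds):
        ref1 = src[c]

        def planted(pos1: int, ref: str, alt: str, status, reason=None,
                    flipped=False, in_gap=False) -> PlantedVariant:
            info, samples = _make_genotype_fields(rng)
            rec = VariantRecord(
                contig=src_name, pos=pos1, ref=ref, alts=(alt,),
                ids=(f"pv{pos1}",), qual=50.0, filters=("PASS",),
                info=info, samples=samples)
            return PlantedVariant(record=rec, kind=kind, expected_status=status,
                                  expected_reason=reason, strand_flipped=flipped,
                                  in_gap=in_gap)

        if kind == "snv_same":
            alt = _other_base(rng, ref1)
            edits.append(_Edit(c, c + 1, [("aln", 1)],
                               planted(c + 1, ref1, alt, LiftStatus.REF_UNCHANGED)))
        elif kind == "snv_alt":
            alt = _other_base(rng, ref1)
            edits.append(_Edit(c, c + 1, [("mismatch", alt)],
                               planted(c + 1, ref1, alt, LiftStatus.REF_SWAPPED,
                                       in_gap=gap_mode)))
        elif kind == "snv_third":
            alt = _other_base(rng, ref1)
            third = _other_base(rng, ref1, alt)
            edits.append(_Edit(c, c + 1, [("mismatch", third)],
                               planted(c + 1, ref1, alt, LiftStatus.REF_ADDED,
                                       in_gap=gap_mode)))
        elif kind in ("str_swap", "str_added"):
            unit, k = str_layout[c]
            u = len(unit)
            k2 = k - 1 if kind == "str_swap" else rng.choice([k + 1, k - 2])
            status = (LiftStatus.REF_SWAPPED if kind == "str_swap"
                      else LiftStatus.REF_ADDED)
            m = min(k, k2) * u
            items: list = [("aln", m)] if m else []
            if k2 < k:
                items.append(("del", (k - k2) * u))
            else:
                items.append(("ins", unit * (k2 - k)))
            fb = c - 1
            edits.append(_Edit(c, c + k * u, items,
                               planted(fb + 1, src[fb] + unit, src[fb], status,
                                       in_gap=True)))
        elif kind == "delete":
            d = rng.randrange(3, 9)
            ref = "".join(src[c:c + 1 + d])
            edits.append(_Edit(c + 1, c + 2 + d, [("del", d), ("pair", 1)],
                               planted(c + 1, ref, ref1, LiftStatus.REF_SWAPPED,
                                       in_gap=True)))
        elif kind == "insert":
            ins = _random_seq(rng, rng.randrange(3, 9))
            edits.append(_Edit(c + 1, c + 2, [("ins", ins), ("pair", 1)],
                               planted(c + 1, ref1, ref1 + ins, LiftStatus.REF_SWAPPED,
                                       in_gap=True)))
        elif kind in ("invert_ref", "invert_alt"):
            s, e = c - 30, c + 30
            seg = src[s:e]
            alt = _other_base(rng, ref1)
            if kind == "invert_alt":
                seg = seg.copy()
                seg[c - s] = alt
                status = LiftStatus.REF_SWAPPED
            else:
                status = LiftStatus.REF_UNCHANGED
            dst_seg = reverse_complement("".join(seg))
            edits.append(_Edit(s, e, [("inv", dst_seg)],
                               planted(c + 1, ref1, alt, status, flipped=True)))
        else:  # transloc
            s, e = c - 60, c + 60
            alt = _other_base(rng, ref1)
            edits.append(_Edit(s, e, [("del", e - s)],
                               planted(c + 1, ref1, alt, LiftStatus.DROPPED,
                                       DropReason.UNMAPPED_BOTH_ANCHORS,
                                       in_gap=True)))

    edits.sort(key=lambda e: e.start)
    src_str = "".join(src)

    # pass 2: walk the alignment script, building dst and the segment list
    dst_parts: list[str] = []
    segments: list[Segment] = []
    t = 0
    q = 0
    run: Optional[list[int]] = None  # [t0, q0, n] of the open '+' run

    def extend_run(n: int) -> None:
        nonlocal run
        if run is not None and run[0] + run[2] == t and run[1] + run[2] == q:
            run[2] += n
        else:
            if run is not None:
                segments.append(Segment(run[0], run[1], run[2], "+"))
            run = [t, q, n]

    def apply_items(items) -> None:
        nonlocal t, q, run
        for op, payload in items:
            if op == "aln" or op == "pair":
                n = payload
                if n == 0:
                    continue
                aligned = op == "aln" or not gap_mode
                if aligned:
                    extend_run(n)
                elif run is not None:
                    segments.append(Segment(run[0], run[1], run[2], "+"))
                    run = None
                dst_parts.append(src_str[t:t + n])
                t += n
                q += n
            elif op == "mismatch":
                if not gap_mode:
                    extend_run(1)
                elif run is not None:
                    segments.append(Segment(run[0], run[1], run[2], "+"))
                    run = None
                dst_parts.append(payload)
                t += 1
                q += 1
            elif op == "del":
                if run is not None:
                    segments.append(Segment(run[0], run[1], run[2], "+"))
                    run = None
                t += payload
            elif op == "ins":
                if run is not None:
                    segments.append(Segment(run[0], run[1], run[2], "+"))
                    run = None
                dst_parts.append(payload)
                q += len(payload)
            elif op == "inv":
                if run is not None:
                    segments.append(Segment(run[0], run[1], run[2], "+"))
                    run = None
                n = len(payload)
                segments.append(Segment(t, q, n, "-"))
                dst_parts.append(payload)
                t += n
                q += n
            else:
                raise AssertionError(f"unknown op {op}")

    cursor = 0
    for edit in edits:
        apply_items([("aln", edit.start - cursor)])
        apply_items(edit.items)
        cursor = edit.src_end
        t_expected = cursor
        assert t == t_expected, f"script cursor drift at {cursor}"
    apply_items([("aln", contig_length - cursor)])
    if run is not None:
        segments.append(Segment(run[0], run[1], run[2], "+"))

    dst_str = "".join(dst_parts)
    truth = [e.variant for e in edits]
    return AssemblyPair(
        src_name=src_name, dst_name=dst_name,
        src_seq=src_str, dst_seq=dst_str,
        segments=segments, truth=truth, chain_style=chain_style)


# ---------------------------------------------------------------------------
# Scoring engine output against the truth table
# ---------------------------------------------------------------------------

def truth_check(
    results: Mapping[tuple, LiftResult],
    truth: Sequence[PlantedVariant],
) -> TruthReport:
    """Confusion counts and exact-match fractions of engine output vs truth.

    A variant matches when the observed status equals the expected one and,
    for non-dropped outcomes, the strand flag agrees.  Category counts
    always sum to the number of planted variants.
    """
    confusion: dict = {}
    n_matched = 0
    n_nongap = 0
    n_nongap_matched = 0
    for t in truth:
        res = results.get(t.key)
        if res is None:
            observed = ("MISSING", None)
            ok = False
        else:
            observed = (res.status.value,
                        res.reason.value if res.reason else None)
            ok = res.status is t.expected_status
            if ok and not res.dropped:
                ok = res.strand_flipped == t.strand_flipped
        expected = (t.expected_status.value,
                    t.expected_reason.value if t.expected_reason else None)
        confusion[(expected, observed)] = confusion.get((expected, observed), 0) + 1
        n_matched += ok
        if not t.in_gap:
            n_nongap += 1
            n_nongap_matched += ok
    return TruthReport(n=len(truth), n_matched=n_matched,
                       n_nongap=n_nongap, n_nongap_matched=n_nongap_matched,
                       confusion=confusion)
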