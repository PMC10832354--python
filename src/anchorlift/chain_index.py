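"""UCSC chain file parsing and per-base source-to-destination mapping.

A chain is a gapped pairwise alignment between a source ("target" in UCSC
parlance, ``t``) and destination ("query", ``q``) sequence.  Chain files used
for liftover are filtered so that every source base maps to at most one
destination position; toy or unfiltered inputs may violate that, in which
case multiply-covered bases are surfaced as *ambiguous* rather than resolved
by guesswork.

Coordinate conventions: the chain format is 0-based half-open, with
``q`` coordinates of '-'-strand chains expressed on the reverse-complemented
destination sequence (UCSC convention).  Every public query here speaks
1-based inclusive forward-strand coordinates (VCF convention); the
conversion happens only inside this module.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Sequence

from intervaltree import IntervalTree


class ChainParseError(ValueError):
    """Malformed chain input; the message names the offending line number."""


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped alignment block.

    ``t_start``/``t_end`` are 0-based half-open source offsets; ``q_start``
    is the 0-based destination offset on the strand stated by the chain
    header.
    """

    t_start: int
    t_end: int
    q_start: int
    size: int


@dataclass(frozen=True)
class Chain:
    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    blocks: tuple[ChainBlock, ...]


class MapOutcome(Enum):
    UNMAPPED = "unmapped"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class BaseMapping:
    """Destination of one source base, on the forward strand, 1-based."""

    dst_contig: str
    dst_pos: int
    strand: str
    chain_id: int


@dataclass(frozen=True)
class CoverageOverlap:
    """A source interval (1-based inclusive) covered by more than one block."""

    contig: str
    start: int
    end: int
    chain_ids: tuple[int, ...]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _open_text(source) -> IO[str]:
    if hasattr(source, "read"):
        data = source.read()
        if isinstance(data, str):
            return io.StringIO(data)
        raw: bytes = data
    else:
        with open(source, "rb") as fh:
            raw = fh.read()
    if raw[:2] == b"\x1f\x8b":  # gzip magic
        raw = gzip.decompress(raw)
    return io.StringIO(raw.decode("ascii"))


def parse_chain_file(source) -> list[Chain]:
    """Parse a chain file from a path, text stream, or (gzipped) byte stream.

    Accepts ``size dt dq`` block lines with a terminal bare-``size`` line,
    tolerates blank lines and ``#`` comments, and validates that the block
    arithmetic reconstructs the header spans.
    """
    fh = _open_text(source)
    chains: list[Chain] = []
    header: list[str] | None = None
    header_lineno = 0
    blocks: list[ChainBlock] = []
    t_cur = q_cur = 0
    open_stanza = False

    def finish(lineno: int) -> None:
        nonlocal header, blocks, open_stanza
        if header is None:
            return
        (score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = header
        if t_cur != int(t_end) or q_cur != int(q_end):
            raise ChainParseError(
                f"line {lineno}: chain {chain_id} block arithmetic ends at "
                f"t={t_cur},q={q_cur} but header declares t_end={t_end},q_end={q_end}")
        chains.append(Chain(
            score=float(score), t_name=t_name, t_size=int(t_size),
            t_start=int(t_start), t_end=int(t_end),
            q_name=q_name, q_size=int(q_size), q_strand=q_strand,
            q_start=int(q_start), q_end=int(q_end),
            chain_id=int(chain_id), blocks=tuple(blocks),
        ))
        header = None
        blocks = []
        open_stanza = False

    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if line.startswith("#"):
            continue
        if not line:
            if open_stanza:
                raise ChainParseError(
                    f"line {lineno}: chain stanza not terminated by a bare size line")
            continue
        fields = line.split()
        if fields[0] == "chain":
            if open_stanza:
                raise ChainParseError(
                    f"line {lineno}: new chain header inside an unterminated stanza")
            if len(fields) != 13:
                raise ChainParseError(
                    f"line {lineno}: chain header has {len(fields)} fields, expected 13")
            header = fields[1:]
            header_lineno = lineno
            if header[3] != "+":
                raise ChainParseError(
                    f"line {lineno}: source strand must be '+', got {header[3]!r}")
            if header[8] not in "+-":
                raise ChainParseError(
                    f"line {lineno}: unknown strand symbol {header[8]!r}")
            try:
                t_cur = int(header[4])
                q_cur = int(header[9])
            except ValueError as exc:
                raise ChainParseError(f"line {lineno}: non-integer coordinate") from exc
            open_stanza = True
            continue
        if header is None:
            raise ChainParseError(f"line {lineno}: block line outside a chain stanza")
        try:
            nums = [int(x) for x in fields]
        except ValueError as exc:
            raise ChainParseError(f"line {lineno}: non-integer block field") from exc
        if len(nums) not in (1, 3):
            raise ChainParseError(
                f"line {lineno}: block line has {len(nums)} fields, expected 1 or 3")
        size = nums[0]
        if size < 1:
            raise ChainParseError(f"line {lineno}: block size {size} < 1")
        blocks.append(ChainBlock(t_start=t_cur, t_end=t_cur + size,
                                 q_start=q_cur, size=size))
        t_cur += size
        q_cur += size
        if len(nums) == 3:
            dt, dq = nums[1], nums[2]
            if dt < 0 or dq < 0:
                raise ChainParseError(f"line {lineno}: negative gap length")
            t_cur += dt
            q_cur += dq
        else:
            finish(lineno)
    if open_stanza:
        # stanza terminated by EOF after its bare size line is fine; an
        # unterminated block list is not
        raise ChainParseError(
            f"line {header_lineno}: chain stanza not terminated before end of file")
    return chains


def format_chain(chain: Chain) -> str:
    """Render one chain stanza in the UCSC dialect (inverse of the parser)."""
    lines = [
        f"chain {chain.score:g} {chain.t_name} {chain.t_size} + "
        f"{chain.t_start} {chain.t_end} {chain.q_name} {chain.q_size} "
        f"{chain.q_strand} {chain.q_start} {chain.q_end} {chain.chain_id}"
    ]
    for i, blk in enumerate(chain.blocks):
        if i + 1 < len(chain.blocks):
            nxt = chain.blocks[i + 1]
            dt = nxt.t_start - blk.t_end
            dq = nxt.q_start - (blk.q_start + blk.size)
            lines.append(f"{blk.size} {dt} {dq}")
        else:
            lines.append(f"{blk.size}")
    lines.append("")
    return "\n".join(lines) + "\n"


def write_chain_file(chains: Iterable[Chain], path) -> None:
    text = "".join(format_chain(c) for c in chains)
    if str(path).endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Index and point queries
# ---------------------------------------------------------------------------

class ChainIndex:
    """Interval index from source base ranges to chain blocks.

    Point queries run in O(log n + k); bases covered by more than one block
    are reported :data:`MapOutcome.AMBIGUOUS` — ambiguity is data, not an
    error, because liftover-grade chain files preclude it but toy inputs
    need not.
    """

    def __init__(self, chains: Sequence[Chain]):
        self.chains = list(chains)
        self._trees: dict[str, IntervalTree] = {}
        for chain in self.chains:
            tree = self._trees.setdefault(chain.t_name, IntervalTree())
            for blk in chain.blocks:
                tree.addi(blk.t_start, blk.t_end, (chain, blk))

    def map_base(self, contig: str, pos: int) -> BaseMapping | MapOutcome:
        """Map one source base (1-based) to its destination position.

        Returns :data:`MapOutcome.UNMAPPED` for bases in chain gaps, outside
        every chain, or on unknown contigs (so that contig-name
        reconciliation can retry), and :data:`MapOutcome.AMBIGUOUS` for bases
        covered by more than one block.
        """
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        tree = self._trees.get(contig)
        if tree is None:
            return MapOutcome.UNMAPPED
        hits = tree[pos - 1]
        if not hits:
            return MapOutcome.UNMAPPED
        if len(hits) > 1:
            return MapOutcome.AMBIGUOUS
        chain, blk = next(iter(hits)).data
        offset = (pos - 1) - blk.t_start
        q_off = blk.q_start + offset
        if chain.q_strand == "+":
            dst_pos = q_off + 1
        else:
            dst_pos = chain.q_size - q_off
        return BaseMapping(dst_contig=chain.q_name, dst_pos=dst_pos,
                           strand=chain.q_strand, chain_id=chain.chain_id)

    def source_contigs(self) -> list[str]:
        return list(self._trees)


def build_index(chains: Sequence[Chain]) -> ChainIndex:
    return ChainIndex(chains)


def validate_unique_coverage(chains: Sequence[Chain]) -> list[CoverageOverlap]:
    """Report every source interval covered by more than one block.

    Empty for UCSC-style liftover chains, which are filtered for unique
    source coverage.  Intervals are 1-based inclusive.
    """
    by_contig: dict[str, list[tuple[int, int, int]]] = {}
    for chain in chains:
        for blk in chain.blocks:
            by_contig.setdefault(chain.t_name, []).append(
                (blk.t_start, blk.t_end, chain.chain_id))
    overlaps: list[CoverageOverlap] = []
    for contig, intervals in sorted(by_contig.items()):
        events: list[tuple[int, int, int]] = []
        for start, end, cid in intervals:
            events.append((start, 1, cid))
            events.append((end, -1, cid))
        events.sort(key=lambda e: (e[0], -e[1]))
        active: Counter = Counter()
        prev = None
        i = 0
        while i < len(events):
            x = events[i][0]
            if prev is not None and sum(active.values()) > 1 and x > prev:
                ids = tuple(sorted(active))
                seg = CoverageOverlap(contig=contig, start=prev + 1, end=x, chain_ids=ids)
                if (overlaps and overlaps[-1].contig == contig
                        and overlaps[-1].end == seg.start - 1
                        and overlaps[-1].chain_ids == ids):
                    overlaps[-1] = CoverageOverlap(contig, overlaps[-1].start, seg.end, ids)
                else:
                    overlaps.append(seg)
            while i < len(events) and events[i][0] == x:
                _, delta, cid = events[i]
                active[cid] += delta
                if active[cid] == 0:
                    del active[cid]
                i += 1
            prev = x
    return overlaps
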