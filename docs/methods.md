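# Methods

## The conversion model

A VCF record is a redundant encoding: the same variant can be written at
many positions with many allele paddings. Two canonical forms anchor this
package. The *normalized* form (left-aligned and parsimonious) is obtained
by iteratively right-trimming shared terminal bases — extending left with
the preceding reference base whenever an allele would empty — and finally
left-trimming shared leading bases while every allele keeps length ≥ 1.
The *maximally extended* form grows the normalized record until (i) no
allele is a prefix or suffix of another, (ii) all alleles share their first
and last base, and (iii) no shorter representation satisfies both. Both
forms are unique per variant; uniqueness of the extension is what makes the
5'/3' anchors (the shared terminal reference bases) well-defined.

Extension is implemented as: normalize; extend one base left if the first
bases differ; one base right if the last bases differ; then, while any
allele pair (including alt–alt pairs in multi-allelic records) is in a
prefix/suffix relation, extend right. Because every extension appends the
*same* reference base to every allele, the shared-first/last-base
conditions, once established, are invariant, so no re-checking loop is
needed. `N` bases compare literally (`N == N`, `N != A`): deterministic,
and consistent with byte comparison of assembly sequence. Extension that
would run past a contig end raises, and the engine turns that into a
dropped record with reason `unanchorable_at_edge`.

Anchor mapping uses a per-contig interval index over chain blocks. Chains
are 0-based half-open with '-'-strand destination coordinates expressed on
the reverse-complemented sequence (the UCSC convention); all public queries
speak 1-based forward-strand coordinates, and the conversion happens in one
module only, to keep off-by-one reasoning in a single place. Source bases
covered by more than one block are answered as *ambiguous* rather than
resolved by score: liftover-grade chains preclude the case, and guessing
silently would be worse than refusing. Chain scores are parsed and carried
but never used.

Allele resolution compares the destination sequence between the mapped
anchors (reverse-complemented for '-' chains) with the extended alleles.
Alleles are pairwise distinct, so at most one can match: a REF match leaves
order unchanged, an ALT match swaps it into the reference slot (a
transposition), and no match inserts the destination sequence as a novel
reference. The old reference is appended as the *last* alternate in the
novel case so that existing per-alt value positions survive unchanged and
only one slot is appended — the cheapest choice for annotation churn; the
position of the appended allele is a free design choice, nothing upstream
constrains it. The emitted reference therefore always equals the
destination sequence at the record's coordinates, which the tests verify
exhaustively.

## Realignment at chain gaps

When exactly one anchor maps, the other is inferred by global affine-gap
alignment (three-state Gotoh DP) of a source window (the extended region
plus a flank beyond the failed side, default 100 bp) against a destination
window extracted from the known anchor toward the failed side, of the
source window's length plus the flank — so a net chain gap up to the flank
size stays inside the window. Windows are oriented to the source strand
before aligning. When *both* anchors fail, no realignment is attempted and
the record is dropped: with neither end pinned there is nothing to anchor
the alignment.

Scoring defaults are `match=1, mismatch=-1, gap_open=-2, gap_extend=-1`,
with a length-`L` gap costing `open + (L-1)·extend`; all four are CLI
flags. The defaults are conventional unit-cost values; anchor inference
depends on where the optimum sits, not on the absolute scale, so any
reasonable setting recovers the same anchor in the regimes the tool
targets (small gaps near indels). Traceback ties prefer match/mismatch,
then a gap in the destination, then a gap in the source, evaluated from the
terminal cell — a fixed order chosen for determinism, with the leftward
bias matching the left-alignment applied downstream. A projection that
lands inside a gap is treated as low confidence and the record is dropped
(`realign_failed`) rather than guessed. Alignment length is capped
(default window cap tracks `max_region_len`, 10 kb): anchors that map
across enormous gaps are pathological under the anchor model and produce
`region_too_long` instead of unbounded quadratic DP.

## Annotation updates

An allele permutation (old index → new index, with an optional novel-ref
extension) drives every update. Number=R and Number=G vectors and genotype
indices move with their alleles; genotype (j,k) moves to the canonical
index of (perm(j), perm(k)). Slots that exist only in the new record (the
novel reference, and genotypes involving it) receive the missing-value
sentinel: no data exists for an allele never observed in the cohort.
Unphased genotypes are re-sorted ascending after recoding; phased ones keep
order.

Number=A fields split by semantics, recognized by name among Number=A tags
(`AF`, `MAF`, `*_AF`; `AC`, `*_AC`; `ES`; `EZ` — the sets are module
constants). AF-like fields materialize the implicit reference frequency
`1 − Σ`, permute the full per-allele vector, and re-emit it per-alt;
AC-like fields do the same with `AN − Σ`. For a novel reference the new
allele takes frequency/count 0 (never observed). Generic Number=A tags are
permuted positionally, with one subtlety: a REF↔ALT swap has no slot for
the promoted alternate's value, so the value stays in the slot now occupied
by the demoted reference — it describes the same ref/alt contrast, which
still lives in that slot. This keeps a double swap an exact involution.
ES/EZ get exactly that treatment plus a sign reversal of the swapped slot,
matching their definition relative to the reference allele. Updates that
cannot be applied (length mismatch, missing AN, AF sum > 1 + 1e−6) leave
the field untouched with a logged warning — corrupting a field is worse
than carrying it stale.

Records with symbolic alleles (`<DEL>`, breakends, spanning `*`) are
dropped with `symbolic_unsupported`: the method is sequence-based and has
nothing to compare. Records with no ALT allele are likewise not converted.
Splitting complex records into primitives is out of scope (the
decomposition is not unique); the `--drop-non-primitives` option instead
drops records whose *output* is no longer an SNV/indel, since such records
cannot match calls made natively against the destination.

## The synthetic assembly pairs

`synthetic_fixtures.generate_pair` builds a random source contig, plants a
mix of differences, applies them to produce the destination contig, and
emits the *exact* chain of that alignment plus a truth table of expected
outcomes — so every engine path is testable without external downloads.
The scenario classes and their expected results: SNV sites where the
destination carries the reference (unchanged), the alternate (swap) or a
third base (novel ref); STR loci resized to the alternate's repeat count
(swap) or a third count (novel ref); insertions/deletions the destination
already carries (swap); inverted segments containing an SNV (unchanged or
swap, strand-flipped); and segments absent from the destination (dropped,
both anchors unmapped). Defaults are a 50 kb contig with 200 planted
variants (~250 bp spacing keeps extended regions and realignment windows
from colliding), STR units of 2–3 bp at 5–8 copies with flanks chosen to
break the repeat, indels of 3–8 bp, 60 bp inversions and 120 bp deleted
segments; planted records carry AF/AC/AN and two diploid samples with
GT/AD/PL so annotation updates are exercised end to end.

Two chain dialects mirror how real same-species chains behave: `gap` style
excludes substituted bases from blocks (the one-base-pair double-sided
gaps of BLAT-derived chains) and widens indel gaps by one aligned base so
that one anchor of the planted indel genuinely falls inside the gap and
must be recovered by realignment; `tolerant` style keeps substitutions
inside blocks and gaps exact. Colinear same-strand runs are grouped into
gapped chains, so a mirrored pair (destination reverse-complemented, used
by the strand-symmetry tests) yields one genome-wide '-' chain rather than
fragments.

What the generator does *not* emulate: realistic allele-frequency spectra,
overlapping variants, nested/repeated segmental structure, chain
misassemblies, or multi-contig genomes. Passing the truth-table tests
therefore shows the engine handles each difference class and their chain
encodings correctly; it does not bound error rates on real assemblies,
where gaps can be larger and repeat structure richer than planted here.

## Verification strategy

Every nontrivial computation is checked against an independent oracle:
normalization against exhaustive enumeration of equivalent representations
on a short contig; alignment scores against brute-force enumeration of all
global alignments (exhaustive for short pairs, seeded samples at lengths
4–6, three parameter sets); Number=G permutation against explicit genotype
re-enumeration for up to four alleles; chain queries against the
generator's own base-level correspondence, exhaustively over the contig.
End-to-end properties: identity lifts are byte-stable after normalization;
truth-table recovery is exact away from chain gaps; lifting converted
records back through the inverse chain reproduces the original normalized
records with inverse permutations; mirrored destinations give identical
outcomes up to reverse complement, compared through the unique maximally
extended form (a left-aligned indel is a *rotated* representation on the
other strand, so field-wise comparison would be wrong). The acceptance
script recomputes all of these from scratch under a caller-supplied seed
on the default 50 kb / 200-variant conditions.

## Known limitations

Ref-only (no-ALT) and symbolic records are not converted. Phase is
preserved per-genotype but merge of co-located bi-allelic records emits
unphased genotypes (dosage-based combination). The realignment window
bounds recoverable net gap size by the flank (default 100 bp); variants at
the edge of larger gaps drop with `realign_failed` or `region_too_long`.
QUAL, GQ and likelihood re-scaling beyond reordering are out of scope.
Conversion remains inherently lossy: regions absent from the destination
assembly cannot be recovered, and realigning raw reads will always beat
lifting calls when raw data exist.
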