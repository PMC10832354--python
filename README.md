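# anchorlift

Convert VCF variant records from one genome assembly to another through a
UCSC chain file — including the hard cases where the two assemblies carry
*different alleles* of the same variant.

Interval-based liftover works for SNVs, but indels and short tandem repeats
(STRs) break it: the destination assembly may represent the locus with the
alternate allele, with a different number of repeat units, or on the other
strand, and naive coordinate mapping then drops or silently corrupts the
record. `anchorlift` is aimed at people harmonizing legacy callsets and
GWAS summary statistics across assemblies (e.g. onto a
telomere-to-telomere assembly, where a large fraction of common variants
change reference allele) who need those records converted correctly, with
their annotations kept consistent.

## Method

Every variant has a unique **maximally extended** representation: the
record is grown until, for each pair of alleles, the shorter is neither a
prefix nor a suffix of the longer, all alleles share their first and last
base, and no shorter representation does so. Those shared terminal bases
are the **5' and 3' anchors** — the only two positions that must be located
in the destination assembly:

1. Pure-SNV records take a fast path: the polymorphic base is mapped
   directly; if it sits in a chain gap the record falls through to step 2.
2. The record is maximally extended and both anchors are mapped through the
   chain. The destination anchor *bases* are not required to match the
   source — only their locations matter.
3. If exactly one anchor maps (the variant abuts a chain gap), the other is
   recovered by global realignment of the flanking windows with affine gap
   costs (Needleman–Wunsch/Gotoh; score `gap_open + (L-1)·gap_extend` for a
   length-`L` gap).
4. The destination sequence between the anchors picks the new reference
   allele: equal to the old REF → unchanged; equal to an ALT → REF/ALT
   **swap**; equal to none → a **novel reference allele** is inserted and
   the old REF becomes the last alternate.
5. The converted record is left-aligned against the destination and its
   allele-indexed annotations are permuted: Number=R/G vectors and
   genotypes follow the allele permutation, AF-like fields keep
   `sum over all alleles (incl. the implicit reference) = 1`, AC-like
   fields keep `sum = AN`, GWAS-VCF effect sizes (ES) and Z-scores (EZ)
   reverse sign on a swap, and INFO/END is recomputed.

Records that cannot be converted are written to a reject VCF with a
machine-readable reason (`unmapped_both_anchors`, `anchors_discordant`,
`realign_failed`, `region_too_long`, `symbolic_unsupported`, ...), never
silently discarded.

## Command line

```sh
anchorlift --input in.vcf.gz \
    --src-fasta grch37.fa --dst-fasta grch38.fa \
    --chain hg19ToHg38.over.chain.gz \
    --output out.vcf.gz --reject rejected.vcf \
    --record-src --flexible-names
```

Output records keep input order (pipe through `bcftools sort` if you need
coordinate order). `--flexible-names` reconciles `chr`-prefix and
`MT`/`chrM` naming differences between the VCF, FASTAs and chain.
Realignment scoring is tunable with `--match/--mismatch/--gap-open/--gap-extend`.

## Worked example

The package ships a generator of paired synthetic assemblies with the exact
chain describing their alignment, so the whole pipeline can be exercised
without downloads:

```python
from anchorlift import generate_pair
from anchorlift.io_cli import RunConfig, run_liftover

pair = generate_pair(seed=42, contig_length=20_000, n_variants=60,
                     chain_style="gap")
paths = pair.write("demo")
summary = run_liftover(RunConfig(
    input_vcf=str(paths["vcf"]),
    src_fasta=str(paths["src_fasta"]), dst_fasta=str(paths["dst_fasta"]),
    chain=str(paths["chain"]),
    output="demo/lifted.vcf", reject="demo/rejected.vcf",
    record_source=True))
print("total:", summary.total)
for status, n in sorted(summary.by_status.items()):
    print(f"  {status:<14} {n}")
```

prints

```
total: 60
  DROPPED        3
  REF_ADDED      13
  REF_SWAPPED    30
  REF_UNCHANGED  14
```

The 60 planted variants include SNVs whose destination base is the
alternate or a third allele, STRs resized to the alternate's or a novel
length, indels the destination already carries, inverted segments and
regions absent from the destination; the 3 dropped records are the planted
variants inside deleted regions. A converted line where the destination
STR had a novel length looks like:

```
dstA  451  pv451  T  TAC,TACAC  50  PASS  AF=0.75,0.25;AC=3,1;AN=4;SRC_CONTIG=srcA;SRC_POS=451;SRC_REF_ALT=TAC/T
```

The destination sequence matched neither `TAC` (old REF) nor `T` (old ALT),
so it became the new reference; the old reference was appended as the last
alternate and the allele-frequency mass (including the implicit reference
frequency) was redistributed accordingly.

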