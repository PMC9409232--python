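# Methods

This note records the models, conventions and design choices behind
`mitocms`, in the order the pipeline runs.

## Coordinates and circularity

Plant mitogenomes assemble into circular molecules, so every stage is
wrap-aware. Internally all coordinates are 0-based half-open; a span
crossing the origin has `end > length` (up to `2 × length`) and slices as
the concatenation tail+head. Files keep their native conventions (GFF3 and
VCF 1-based). GFF3 cannot express origin-wrapping features natively, so
wrapped gene models are written as two features sharing an ID with
`part=1/2` attributes and rejoined on read. IUPAC ambiguity codes are
normalized to N with a warning rather than rejected; repeat and ORF
operations treat N as matching nothing.

## ORF discovery

ORFs are ATG-initiated and stop-terminated on both strands under the
standard genetic code (plant mitochondria use it), scanning the doubled
sequence of a circular molecule so frames crossing the origin are seen.
Each stop codon yields at most one ORF per frame — the longest, i.e. the
earliest in-frame ATG after the previous stop — which avoids the
combinatorial blowup of reporting every nested ATG. Because a scan of the
doubled sequence meets each stop twice, the first encounter may lack
upstream context; candidates are therefore deduplicated per stop position
modulo the length, keeping the longest (the fully contextual one). The
retention cutoff is ≥100 aa inclusive by default (a strict `>`
interpretation is available via `inclusive=False`). Names are
`orf<aa_length>` with `a/b/c…` suffixes in coordinate order for equal
lengths and a `-k` counter past the alphabet (`orf119a-2` style).

## Repeats

Direct repeats come from k-mer seeds (k = 21) of the genome against
itself, inverted repeats against its reverse complement. Co-diagonal seed
runs are extended to maximal exact matches; matches separated by small
gaps with bounded diagonal drift (both 100 bp) are chained and re-aligned
globally with edlib, so a long near-identical repeat interrupted by short
indels is reported as one pair with percent identity
(matches/columns × 100) and per-copy gap bp. Thresholds are inclusive:
`size ≥ min_len` (default 50) and `identity ≥ min_identity` (default 99).
Size classes use `>10 kb`, `>1 kb` (large) and `≤1 kb` (small); repeat
content is the interval union of all copies over the genome length.
Origin-crossing repeats are not specially searched; a multi-copy repeat
emits all pairwise maximal pairs. Repeats are computed natively rather
than by wrapping an external masker so the module is self-contained.

## Pairwise comparison and variants

Anchors are 31-mers unique in both genomes (in either orientation),
chained greedily along genome A into blocks (same orientation, gaps
≤5 kb). Classification uses a length-weighted longest increasing
subsequence of forward blocks as the collinear backbone: forward blocks
off the backbone are translocations; an inverted block is an in-place
inversion when its B span fits between its backbone neighbours, otherwise
translocation+inversion. Weighting by block length makes the smaller of
two swapped segments the one deemed moved.

Base-level calls are made between consecutive anchors within forward
blocks. Identical segments are skipped; differing segments are aligned
globally (match +1, mismatch −1, gap open −4, gap extend −1) — for
segments over 500 bp an edit-distance alignment stands in, since such
segments arise only around large insertions where the gap structure is
unambiguous. Adjacent anchor extents can overlap on one genome when a
flank base happens to match across an indel; the right anchor is trimmed
forward by the overlap rather than dropping the gap. InDel coordinates are
left-normalized (the VCF convention, rotating the allele as it shifts) so
calls are deterministic regardless of gap placement; segments below 70%
identity are flagged complex-InDel regions with no base calls. Adjacent
SNP columns are never merged into MNPs.

Location classes: genic = inside a protein-coding exon; intronic is kept
as its own label and folded into the intergenic side of the two-way
summary. Coding effects substitute the allele into the spliced CDS
(strand-aware) and compare the affected codon; an InDel of length not
divisible by 3 is a frameshift whose reported "affected amino acids" is
the number of residues differing from the original translation before the
first stop in the new frame. A change to a stop codon counts as
non-synonymous.

## Unique and chimeric ORFs

Two ORFs are counterparts when the best local alignment reaches ≥95%
identity over ≥90% of the shorter sequence *and* the two lengths are
within that same coverage factor of each other. The length condition stops
a long chimeric ORF from being "matched" by a short ORF nested in its
known segment; conversely, an ORF duplicated within one genome is shared
as long as any qualifying counterpart exists (a strict bijection would
mis-call the extra copy unique).

Decomposition aligns each ORF against every known CDS (Smith–Waterman,
match +1, mismatch −1, gap −2, both strands). A raw Smith–Waterman end can
drift past the true homology boundary whenever a low-identity tail keeps a
net-positive score, so each hit is trimmed to its shortest maximal-scoring
sub-path under a stricter column scoring (match +1, mismatch/gap −4),
which pins boundaries to sustained ~80%+ local identity; on planted
chimeras the recovered junction is within ±3 bp of truth. Hits ≥30 bp and
≥90% identity are selected greedily by score with overlap trimming;
uncovered stretches ≥30 bp become unknown segments, shorter gaps are
absorbed into the flanking segment. "Chimeric" requires a known and an
unknown segment of ≥30 bp each — the smallest published known segment in
this problem family is 35 bp, so 30 bp keeps it detectable. tRNA/rRNA
models are excluded from the library.

## Transmembrane screen

A trained topology HMM would bring opaque parameters for what is, in this
screen, a binary question. The package uses the standard Kyte–Doolittle
convention instead: centered 19-residue window means, segments = maximal
runs of window scores ≥1.6 expanded to window extent, merged when
separated by <5 residues, kept at ≥19 residues. All three constants are
configurable. Count monotonicity in the threshold holds for well-separated
hydrophobic stretches; two stretches closer than the merge distance can
split into two segments as the threshold rises.

## Expression evidence

Counts are normalized by median-of-ratios size factors (geometric-mean
pseudo-reference over genes with all-positive counts). Differential
expression is a Welch t-test on log2(normalized + 0.5) with
log2FC = log2((meanB+0.5)/(meanA+0.5)); significant means |log2FC| ≥ 1 and
p < 0.05. This is a deliberately transparent surrogate with the same
decision-rule shape as dedicated RNA-seq packages and no hidden shrinkage;
with fewer than two replicates per group only the fold-change is reported.
The 0.5 pseudocount keeps zeros finite everywhere. 2^−ΔΔCt follows the
Livak convention with per-replicate ΔCt averaging (not per-condition Ct
averaging); adding any constant to all Ct values cancels. Intron retention
is the fraction of intronic bases covered by a transcript's alignment
blocks, averaged over transcripts that touch both flanking exons;
gene-level classes operationalize the usual wording as spliced <0.2,
partial 0.2–0.8, retained >0.8.

## Candidate screen

Tier 1 = unique to the CMS line ∧ chimeric ∧ TM; tier 2 drops TM; tier 3
keeps only uniqueness. Expression evidence is advisory — it orders
candidates within a tier but never promotes a non-unique ORF, because the
structural criteria are what define the candidate class and expression
confirms it. Weakly expressed protein-coding genes with retained or
partially retained introns are reported in a separate splicing-defect
section rather than mixed into the ORF tiers.

## Synthetic data generator

The generator emulates the observables of a sterile-line/restorer-line
comparison at desk scale. Defaults: 100 kb circular genomes; 33
protein-coding genes named after the canonical plant mitochondrial
complement, CDSs of 300–1500 bp of uniform sense codons (ATG…stop, no
internal stops); background i.i.d. at GC 45%; one multi-intron gene
(*nad4*-like, 3 introns of 300–800 bp); repeats of 1200 bp DR, 400 bp IR
and 60 bp DR at 100% identity; 60 SNPs (6 genic with known
synonymous/non-synonymous status, transitions and transversions ~1:1);
12 intergenic InDels of 1–10 bp; one chimeric ORF = 1336 bp of the
*atp1*-like donor 5′ end + 485 bp of unknown sequence whose translation
carries a 25-residue hydrophobic stretch drawn from {L,I,V,F,A,M} codons,
inserted with a same-frame stop immediately 5′ so the ORF start is pinned;
negative-binomial counts (mean 500, dispersion 0.05, 3 replicates per
condition) with planted log2 fold-changes +3 on the chimera and −2 on the
intron gene; per-intron retention fractions 0.95/0.0/0.5, realized per
transcript as a Binomial(intron length, fraction) 5′ prefix so the mean
covered fraction equals the planted value.

Edits are chosen on genome A and applied in one pass to derive genome B;
truth coordinates are recorded on both final coordinate systems, with
indels left-normalized by the same routine the caller uses. The donor CDS
is drawn long enough (≥ known_bp/0.8) that the chimera's shared prefix
stays well below the counterpart-coverage threshold. Three placement
validations keep the planted truth unambiguous: the chimera junction is
redrawn if the unknown segment happens to continue the donor sequence;
the insertion site is redrawn if the insert (with flanking context) would
spawn secondary ≥100 aa ORFs absent from genome A; and every SNP/InDel
position is redrawn unless it leaves all ≥100 aa ORF extents within
±1.5 kb unchanged — otherwise an edit that creates or destroys a
start/stop in any frame would surface as a spurious "line-specific" ORF
that no screen could distinguish from the planted one. These constraints
are what make 100% precision/recall a meaningful target; they also mean
the generator does not model the background churn of ORF gain/loss that
real line comparisons show, so recovery rates on real genome pairs will be
lower than on synthetic ones. No read-level or sequencing-error
simulation is attempted, and repeats/ORFs crossing the origin are planted
only implicitly (the genome is circular but features are laid out away
from the origin).

Structural variants (inversion, translocation, both) can be planted in
gene-free windows for synteny-classification tests; they are off by
default and point edits are never placed inside them.

## Problem sizes

Default test and acceptance runs use 100 kb genome pairs; the screen
property is checked across 20 seeds; statistical properties use 200
simulated datasets at n = 3 replicates (power for a planted log2FC = 3
gene, type-I error at nominal 0.05 bounded by 0.07); oracle suites use
50 random 2 kb circular genomes (ORFs), ~3 kb sequences (repeats vs a
quadratic maximal-exact-match scan), and all 64×9 single-base codon
changes (coding effects). These sizes make the full suite complete in
about a minute while keeping every check exact.

## Known limitations

- Variant calls inside inverted or translocated blocks are not reported;
  the default comparison is collinear and the published totals it
  emulates are dominated by collinear regions.
- The TM screen is a hydropathy heuristic, not a topology model; it
  reports segments, never orientation.
- `match_orfs` decisions near the 90%/95% thresholds depend on alignment
  end trimming; ORFs whose true divergence sits exactly at a threshold
  may flip class between dialects of local alignment.
- The generator's negative-binomial counts share one dispersion across
  genes and conditions.
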