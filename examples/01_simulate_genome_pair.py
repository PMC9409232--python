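"""Generate a synthetic CMS-line / restorer-line mitogenome pair.

The pair shares a conserved 33-gene backbone on ~100 kb circular molecules;
the CMS-like genome differs by planted SNPs, short InDels, and one
line-specific chimeric ORF.  The truth set records every planted feature.
"""

from mitocms import GeneratorConfig, generate_genome_pair

genomeA, genomeB, annotations, truth = generate_genome_pair(GeneratorConfig(seed=1))

print(f"restorer-like genome: {genomeA.name}, {genomeA.length:,} bp, circular={genomeA.circular}")
print(f"CMS-like genome:      {genomeB.name}, {genomeB.length:,} bp")
print(f"planted: {len(truth.snps)} SNPs, {len(truth.indels)} InDels, "
      f"{len(truth.repeats)} repeat pairs")
print(f"planted chimeric ORF: {truth.chimera['orf_name']} "
      f"({truth.chimera['known_bp']} bp of {truth.chimera['donor_gene']} "
      f"+ {truth.chimera['unknown_bp']} bp unknown)")
# The genome pair is the input to every other example; the truth set is what
# lets each analysis stage be scored exactly.
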