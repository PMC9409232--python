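"""Unique-ORF screening, chimera decomposition and TM prediction.

ORFs present only in the CMS-like genome are decomposed against the known
gene CDS library into known/unknown segments, and their products screened
for membrane-spanning hydrophobic stretches — the two structural hallmarks
of CMS-associated ORFs.
"""

from mitocms import (GeneratorConfig, decompose, extract_spliced_cds, find_orfs,
                     generate_genome_pair, match_orfs, predict_tm)

genomeA, genomeB, annotations, truth = generate_genome_pair(GeneratorConfig(seed=1))
orfsA, orfsB = find_orfs(genomeA), find_orfs(genomeB)
matches = match_orfs(orfsA, orfsB)
print(f"shared ORFs: {len(matches['shared'])}, "
      f"unique to CMS line: {len(matches['uniqueB'])}")

library = [(m.gene_id, extract_spliced_cds(genomeA, m))
           for m in annotations[genomeA.name] if m.biotype == "protein_coding"]
for orf in matches["uniqueB"]:
    d = decompose(orf, library)
    tm = predict_tm(orf.protein)
    segs = ", ".join(f"{s.origin}[{s.start + 1}-{s.end}]" for s in d.segments)
    print(f"  {orf.orf_id}: {segs}; chimeric={d.is_chimeric}; TM segments={len(tm)}")
# The planted chimera decomposes into its donor-gene 5' segment plus an
# unknown segment whose translation carries one transmembrane stretch.
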