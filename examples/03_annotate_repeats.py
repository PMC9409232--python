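"""Direct and inverted repeat annotation.

Repeats >= 50 bp are found by seed-and-extend of the genome against itself
(direct) and its reverse complement (inverted), with percent identity and
size-class tallies — the quantities a mitogenome repeat table reports.
"""

from mitocms import (GeneratorConfig, classify_repeat_sizes, find_repeats,
                     generate_genome_pair, repeat_content)

genomeA, _, _, truth = generate_genome_pair(GeneratorConfig(seed=1))
repeats = find_repeats(genomeA, min_len=50, min_identity=99)

for r in repeats:
    print(f"{r.repeat_id}: {r.rtype} {r.size1} bp  "
          f"copy1 {r.copy1.start + 1:,}..{r.copy1.end:,}  "
          f"copy2 {r.copy2.start + 1:,}..{r.copy2.end:,}  identity {r.identity:.0f}%")
print("size classes:", classify_repeat_sizes(repeats))
print(f"repeat content: {repeat_content(genomeA, repeats):.2f}% of the genome")
# Large direct repeats are the recombination substrate that splits plant
# mitogenomes into sub-circles, which is why their tally matters for CMS.
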