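# paleomito

Molecular species identification for ancient remains from mitochondrial
capture data.

Fossil bones of closely related species — the motivating case is the
dhole (*Cuon alpinus*) versus the gray wolf — often cannot be told apart
morphologically. Given short, degraded sequencing reads from such a
specimen and a panel of candidate mitochondrial genomes, `paleomito`
weighs three lines of evidence to call the species:

1. **read counts** — how many reads map to each candidate reference,
   normalized to the best one;
2. **coverage evenness** — the ratio of mean coverage *C* = *S*/*L*
   (aligned bases over reference length) to mean read depth
   *D* = *S*/*B* over covered positions, which equals the covered
   fraction *B*/*L*: near 1 for a conspecific reference, lower when
   reads stick only to conserved stretches of a wrong reference;
3. **phylogenetic placement** — which clade a consensus sequence joins
   in a bootstrap-supported neighbor-joining tree rooted on an outgroup.

Around that core the package provides the full supporting toolchain:
a seed-and-extend mapper for circular references with a MAPQ-style
uniqueness score (filtered at ≥ 30), duplicate removal, mapDamage-style
terminal C→T / G→A deamination profiling with a geometric-decay model
fit, consensus calling (depth ≥ 3, 50 % plurality, ties → N),
reference-anchored multiple alignment with control-region and gap/N
column stripping, variable / parsimony-informative site counts,
within-group pairwise differences, median-joining haplotype networks,
and p / JC69 / K80 distances with neighbor joining. A synthetic
ancient-read generator (lognormal fragment lengths, geometrically
decaying terminal deamination, sequencing error, PCR duplicates,
contaminant reads, truth tags in read names) makes the entire analysis
testable offline.

## Worked example

`examples/02_identify_species.py` simulates 5,000 damaged reads from a
"dhole" reference in a five-member panel (~8 % pairwise divergence,
plus a distant human contaminant control), maps them against every
panel member, and prints:

```
reference   mapped   norm %  evenness
dhole         4740    100.0    1.0000
wolf          3038     64.1    0.9610
coyote        3093     65.3    0.9495
jackal        3117     65.8    0.9601
human            8      0.2    0.0067

verdict: dhole
```

The true source attracts the most reads and blankets its reference
completely (evenness 1.0), while ~8 %-divergent references lose about a
third of the reads and leave gaps where local divergence exceeds the
mismatch budget. Both mapping-based lines agree, so the verdict is the
concordant call `dhole`. The other examples walk through read
simulation, damage profiling (recovering d5 = 0.295, r = 0.519 from
reads simulated at 0.30/0.50), consensus + diversity statistics,
haplotype networks, and tree placement.

There is also a thin CLI for the tool-like operations:

```bash
paleomito simulate --out demo --n-refs 4 --n-reads 5000 --seed 1
paleomito identify --panel demo/panel.fa --annotations demo/panel.tsv \
    --reads demo/reads.fastq --out demo/report
```

`identify` writes per-reference SAM, the evidence table, consensus
FASTA, damage profile, newick tree, network files and a JSON report per
sample.

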