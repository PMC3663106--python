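# asmlik

Likelihood-based evaluation of genome assemblies from paired-end reads.

De novo assemblies are usually compared by contiguity summaries (N50,
contig counts) that say nothing about whether the assembled sequence
actually explains the sequencing data — gluing all reads end to end gives
a spectacular N50 and a terrible assembly.  `asmlik` scores an assembly by
the probability of the read set under a generative model of sequencing,
giving a single reference-free number that rewards coverage and accuracy
and penalises inflated or erroneous sequence.  It is aimed at anyone
choosing between assemblers or tuning assembler parameters (e.g. de Bruijn
k-mer length) on a genome without a trusted reference.

## The model

Each read pair is generated by drawing a fragment length `l ~ p_F`, a
start site `s` uniformly over all positions where the fragment fits
(either strand, any contig), and reading the fragment's two ends through a
position-specific error model `p_E` (substitution rates per machine cycle,
reference base and substituting base; insertion/deletion opening rates per
cycle; indel-length pmfs).  With placements supplied by a report-all
mapper, the assembly's score is

    L(A; R) = sum_i log sum_j p_F(l_ij) * p_S(s_ij) * 1/2 * p_E(r_i | a_ij, e_ij)

summed over each pair's mappings `j`.  All distributions — the empirical
insert-size pmf and every error rate — are learned from the uniquely
mapped reads themselves.  Pairs the mapper cannot place are handled by
Smith–Waterman-aligning a random subsample against the assembly and
imputing the mean log probability to the rest.  See `docs/methods.md` for
the full account.

## Worked example

Score a genome against reads simulated from it, and against the same
genome with a 3 kb deletion:

```python
import numpy as np
from asmlik import AssemblyIndex, Contig, evaluate_assembly
from asmlik.simulator import SimulationConfig, simulate_reads
from asmlik.mapper import SeedMapper

rng = np.random.default_rng(7)
genome = AssemblyIndex([Contig("chr", "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000)))])
cfg = SimulationConfig(n_pairs=5_000, read_length=35, fragment_mean=200, fragment_sd=20, seed=7)
pairs, _ = simulate_reads(genome, cfg)

broken = AssemblyIndex([Contig("chr", genome.contigs[0].sequence[:20_000]
                                      + genome.contigs[0].sequence[23_000:])])
for name, asm in [("true genome", genome), ("3 kb deletion", broken)]:
    routed = SeedMapper(asm).route_pairs(pairs, 35, 400, max_edits=5)
    result = evaluate_assembly(asm, routed, {p.id: p for p in pairs}, seed=7)
    r = result.report
    print(f"{name:14s} log likelihood {r.total_log_likelihood:14.1f}   "
          f"mapped {r.category_counts['mapped']}, rescued {r.category_counts['rescued_sampled']}")
```

prints

```
true genome    log likelihood      -105466.3   mapped 4980, rescued 20
3 kb deletion  log likelihood      -133918.0   mapped 4675, rescued 325
```

The intact genome explains the reads far better: the deletion strands the
~300 pairs drawn from the missing region (they fall to low-probability
rescue values), so its total log likelihood drops by ~28,000 nats.  Totals
are natural logs; only differences between assemblies evaluated on the
same read set are meaningful.

## Command line

The same pipeline is exposed as subcommands mirroring its three stages,
plus the simulator and a built-in mapper for self-contained runs:

```
asmlik simulate --genome genome.fa --out sim/ --n-pairs 50000 --seed 1
asmlik map      --assembly asm.fa --reads1 sim/reads_1.fastq --reads2 sim/reads_2.fastq --out aln.sam
asmlik convert  --sam aln.sam --assembly asm.fa --out routed/
asmlik align    --routed routed/ --assembly asm.fa --reads1 ... --reads2 ... --out rescue.json --seed 1
asmlik cgal     --routed routed/ --assembly asm.fa --align-json rescue.json --out report.json
```

Any external mapper that reports all alignments (with indels) can replace
`asmlik map`; `convert` consumes standard SAM.

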