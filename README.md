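# indelkit

Genome-wide InDel marker development for plant genetics, modeled on the
workflow used to build InDel marker sets for bitter gourd (*Momordica
charantia*): from a multi-sample population VCF to PIC-ranked candidate
loci, uniquely-mapping PCR primer pairs, in-silico polymorphism
prediction between two parental lines, and an F2 genetic linkage map.

It is aimed at researchers developing codominant PCR markers from
resequencing panels — the kind of project where a few thousand candidate
insertion/deletion sites are winnowed down to a gel-scorable marker set
and then validated on a mapping population.

## What it computes

**Marker informativeness.** Small InDels (≤ 50 bp) are read from a
multi-sample VCF; each locus's allele frequencies *P₁…Pₙ* are estimated
from the called diploid genotypes, and its polymorphism information
content is

```
PIC = 1 − Σᵢ Pᵢ² − Σᵢ<ⱼ 2 Pᵢ² Pⱼ²
```

Loci with PIC ≥ 0.6 become primer-design candidates. Under this
statistic a biallelic locus can reach at most 0.375 and a triallelic one
0.5926, so every selected candidate carries four or more observed
alleles.

**Primer design and screening.** Candidate primers flanking each InDel
are enumerated exhaustively under windowed constraints (size 18–27 bp,
optimum 20; Tm 57–63 °C, optimum 60, nearest-neighbor SantaLucia
thermodynamics; GC 40–60 %, optimum 50; product 100–500 bp, optimum 250)
and paired by a primer3-style weighted-deviation penalty. A pair is
*unique* when both primers align to exactly one place in the reference
genome (exact full-length matching, both strands). In-silico PCR then
predicts product lengths in each parental genome; a marker is called
polymorphic when the two single products differ by at least 3 bp
(roughly the band shift resolvable on a 6 % polyacrylamide gel).

**Linkage mapping.** From codominant F2 genotypes (`a`/`h`/`b`/`u`),
markers with > 20 % missing data are dropped, pairwise recombination
fractions r̂ and LOD scores are estimated by EM over the nine joint
genotype classes, linkage groups are connected components at a LOD
threshold (default 4.0, with a stability scan over 3.0–10.0), orders
come from LOD²-weighted least-squares seriation (greedy insertion +
2-opt), and positions from non-negative least squares on Kosambi
distances, *d* = 25 ln((1+2r)/(1−2r)) cM. Summaries report per-group
genetic length, marker density (cM/marker), physical span (Mb) and
recombination rate (cM/Mb).

A fully seeded synthetic-data module generates every input the pipeline
consumes (toy genome, population VCF with 2–7 alleles per locus, two
homozygous parents, an F2 cross with known crossovers), so the whole
toolkit is testable without any download.

## Worked example

```python
from indelkit import simulate as sim, catalog, primers, linkage

cfg = sim.SimConfig(seed=42, n_chromosomes=3, chrom_length_bp=60_000)
genome, truth, parent_a, parent_b, f2 = sim.simulate_all(cfg)
sim.write_population_vcf(truth, genome, "population.vcf")

loci, genotypes = catalog.read_population_vcf("population.vcf")
loci = catalog.length_filter(loci, max_len=50)
scored = catalog.score_loci(loci, genotypes, min_call_rate=0.8)
candidates = catalog.select_candidates(scored, min_pic=0.6)

pair = primers.design_primers(genome, candidates[0].locus)[0]
amp_a = primers.insilico_pcr(parent_a, pair, line_id="A")
amp_b = primers.insilico_pcr(parent_b, pair, line_id="B")
call = primers.call_polymorphism(pair.pair_id, amp_a, amp_b)

groups, pairs, dropped, _ = linkage.build_map(f2)
```

Run on the seed above, this prints:

```
223 InDel loci, 5 candidates with PIC >= 0.6
MC_g61ind0001: MC02:3353 n=5 PIC=0.719
F 5'-CGTCAGTCGCTCGCGTCAAA-3'  Tm=59.9C GC=60%
R 5'-ATCTACGCGCGACCTGACCA-3'  Tm=59.9C GC=60%
product 221 bp, unique: True
e-PCR: parent A 221 bp, parent B 218 bp -> polymorphic
```

Reading: of 223 simulated InDels only 5 are informative enough
(PIC ≥ 0.6, so ≥ 4 alleles); the top candidate gets a primer pair close
to all optima whose product is 221 bp on the reference and 218 bp in
parent B — a 3 bp shift, called polymorphic at gel resolution.

The same flow is available from the shell:

```sh
indelkit simulate --out run --seed 42
indelkit catalog  --vcf run/population.vcf --fasta run/reference.fasta --out run
indelkit select   --scored run/scored_loci.tsv --out run/candidates.tsv
indelkit design   --fasta run/reference.fasta --candidates run/candidates.tsv --out run/primers.tsv
indelkit screen   --genome run/reference.fasta --primers run/primers.tsv --out run/primers_screened.tsv
indelkit epcr     --primers run/primers_screened.tsv --genome-a run/parent_a.fasta --genome-b run/parent_b.fasta --out run/epcr.tsv
indelkit map      --genotypes run/f2_genotypes.tsv --physical run/physical_positions.tsv --out run
indelkit report   --run run --out run/summary.tsv
```

Outputs are TSV with a version/config-hash header; identical
config + seed gives byte-identical files.

## Layout

- `src/indelkit/catalog.py` — VCF ingestion, allele spectra, PIC, selection, density
- `src/indelkit/primers.py` — thermodynamics, enumeration/pairing, genome search, e-PCR
- `src/indelkit/linkage.py` — two-point EM, grouping, ordering, Kosambi spacing, summaries
- `src/indelkit/simulate.py` — seeded synthetic genomes, panels, parents, F2 crosses
- `src/indelkit/published.py` — published reference numbers used for arithmetic checks
- `src/indelkit/cli.py`, `src/indelkit/report.py` — orchestration and bit-stable I/O
- `docs/methods.md` — models, assumptions, parameter choices, limitations
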