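# Methods

This note documents the models implemented in indelkit, the parameter
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that matter for
reproducibility.

## InDel catalog and PIC

An InDel locus is a VCF record in which the reference allele and at
least one alternate allele differ in length; records whose alts are all
length-preserving substitutions are excluded, and at mixed records the
substitution alts are dropped (with a logged warning) while the calls
that carried them become missing. The length filter retains loci whose
every alternate differs from the reference by at most 50 bp (inclusive),
the conventional upper bound for "small" InDels scorable on a gel.

Allele frequencies are estimated by counting alleles over the
non-missing diploid calls: Pᵢ = cᵢ / (2·n_called). Two conservative
rules apply before scoring:

- loci with call rate below 0.8 are ineligible for ranking (a low call
  rate makes the spectrum, and hence PIC, unreliable); configurable;
- alleles declared in the VCF but never observed in the sample are
  pruned, so the locus's effective allele number n reflects the data.
  Pruning never changes the PIC value (unobserved alleles have Pᵢ = 0)
  but keeps n ∈ [2, 7] meaningful.

Polymorphism information content is computed exactly as

PIC = 1 − Σᵢ Pᵢ² − Σᵢ<ⱼ 2 Pᵢ² Pⱼ²,

evaluated through the power-sum identity
2 Σᵢ<ⱼ Pᵢ²Pⱼ² = (ΣPᵢ²)² − ΣPᵢ⁴ (O(n), agrees with the literal double
loop to ~1e-16). Note this statistic is *not* the Botstein expected
heterozygosity variant (which subtracts 2PᵢPⱼ(1−PᵢPⱼ) cross terms); the
formula above is implemented verbatim because it is the selection
criterion this workflow is defined by. Its consequences are worth
spelling out: the maximum at equal frequencies is 1 − 1/n − (n−1)/n³,
i.e. 0.375 (n=2), 0.5926 (n=3), 0.7031 (n=4). A PIC ≥ 0.6 cutoff
therefore admits only loci with ≥ 4 observed alleles, even though most
InDels in a real panel are biallelic. Selection is inclusive (≥, with a
1e-12 floating-point tolerance), sorts by (chromosome, position), and
assigns sequential candidate IDs.

Coordinates are 1-based in VCF and all reports, 0-based half-open
internally. Input VCFs are assumed left-normalized; REF is validated
against the FASTA when one is supplied, but no re-normalization is
attempted.

## Primer engine

**Melting temperature.** Nearest-neighbor thermodynamics with the
SantaLucia (1998) unified parameter set: duplex ΔH/ΔS summed over
dinucleotide steps plus terminal initiation terms, entropy-corrected for
monovalent salt by 0.368·(N−1)·ln[Na⁺], and converted to Tm with duplex
concentration k = [oligo] − [template]/2. Defaults are 50 mM Na⁺ and
50 nM oligo, the customary primer-design settings; all are arguments.
The implementation is cross-checked in the test suite against an
independent reference implementation (Biopython's `Tm_NN` with identical
settings) to within 0.5 °C — in practice they agree to round-off.

**Enumeration and pairing.** Every substring of length 18–27 bp lying
wholly 5′ (forward) or 3′ (reverse) of the InDel footprint is a
candidate if it contains no N and passes the GC (40–60 %) and Tm
(57–63 °C) windows; the InDel must be strictly flanked, never under a
primer. Candidate penalty is a weighted absolute deviation from the
optima, w_size·|size−20| + w_tm·|Tm−60| + w_gc·|GC−50| with weights
(1.0, 1.0, 0.2); pairing adds 0.05·|product−250| and keeps products in
[100, 500] bp. These weights are stated defaults in the primer3 style —
the design windows and optima are the substantive constraints, the
weights only rank admissible candidates. Enumeration uses prefix-sum
prefilters and re-scores survivors exactly, so results equal the literal
brute-force enumeration (asserted in tests). Tie-breaks are fully
deterministic: (penalty, product size, forward sequence, reverse
sequence). The default flank window of ±400 bp is the smallest that
guarantees any admissible ≤ 500 bp product fits.

**Uniqueness and e-PCR.** Genome search is exact full-length matching
of the primer and its reverse complement, via a sorted k-mer (k = 11)
seed index verified against naive scanning in tests. A pair is unique
iff each primer has exactly one hit with both strands pooled — the
strictest reproducible reading of "uniquely aligned"; mismatch-tolerant
mapping is out of scope. In-silico PCR reports every correctly oriented
same-chromosome hit combination with product length ≤ 750 bp (1.5× the
design maximum, to catch expanded alleles). Zero products predicts
amplification failure, two or more a multiband pattern. Polymorphism
between two lines requires a single product in each line differing by
≥ 3 bp, an approximation of 6 % polyacrylamide gel resolution; both
thresholds are arguments and recorded in output headers.

## Linkage mapping

**Two-point estimation.** For codominant F2 data the recombination
fraction is the MLE under the nine-class multinomial: classes other than
the double heterozygote have a known recombinant-gamete count (0, 1 or
2); the double heterozygote pools the coupling (0 recombinants) and
repulsion (2 recombinants) gamete pairs with probabilities proportional
to (1−r)² and r². EM iterates r ← (R_fixed + 2·n_hh·r²/((1−r)²+r²)) /
(2n) from r₀ = 0.25 to |Δr| < 1e-6 (max 1000 iterations), clamps to
[0, 0.5], and LOD = log₁₀ L(r̂) − log₁₀ L(0.5). Phase is assumed
coupling throughout, as in an F2 from two inbred parents with anchored
codes. Pairs with fewer than 10 joint calls are flagged (LOD 0). The EM
is validated against a grid-search MLE (step 1e-4) in the tests.

**Grouping.** Linkage groups are connected components of the graph with
edges LOD ≥ 4.0 and r̂ ≤ 0.4. Because published practice often quotes a
threshold *range* rather than a single value, a stability scan re-runs
grouping at every integer LOD in [3, 10] and reports the partition at
each threshold; raising the threshold can only split groups, never merge
them (tested). A chromosome may legitimately split into several groups
when marker coverage has gaps.

**Ordering.** Marker order minimizes the LOD²-weighted stress
Σ w_ij (d_ij^path − D_ij)², where D_ij is the mapping-function distance
of r̂_ij and d_ij^path the summed adjacent distances along the order.
The optimizer is greedy insertion from the highest-LOD pair followed by
2-opt segment reversals — a deterministic, desk-scale stand-in for
proprietary regression-mapping implementations. For groups of ≤ 7
markers the tests confirm it attains the exhaustive-permutation optimum;
orientation is normalized (lexicographically smaller endpoint first) and
flipped, if needed, against physical positions.

**Spacing.** Interval lengths along a fixed order solve a non-negative
least-squares problem on mapping-function distances, weighted by LOD.
By default only pairs at most 2 adjacency steps apart contribute. The
localization is deliberate: two-point distances of weakly linked pairs
are noisy, and no mapping function is exactly additive, so distant pairs
systematically compress the fitted map (with Kosambi on
interference-free data the all-pairs fit runs ~18 % short, the windowed
fit ~12 %). `window=None` restores the all-pairs fit. A degenerate
system falls back to adjacent-pair distances (logged).

**Mapping functions.** Kosambi d = 25·ln((1+2r)/(1−2r)) cM is the
reporting default; Haldane d = −50·ln(1−2r) is available and is the
natural choice for recovery checks against the simulator (below), since
the simulator generates crossovers without interference. Both inverses
round-trip to 1e-10.

**Summaries.** Per-group rows report marker count, genetic length
(last position), marker density = length / marker count, physical span =
max(bp) − min(bp) over mapped markers in Mb, and recombination rate =
genetic / physical. The totals row recomputes density and rate from the
summed columns (total density = total length / total markers — the
published convention, not length/(markers − groups)). Full precision is
kept internally; rounding to 2 decimals happens only in the report
layer. Two cells of the published reference table (LG1 and LG9 density)
disagree with their own printed inputs by one unit in the last decimal —
presumably rounded from unrounded lengths — so consistency checks use
the reconciling cells and the totals.

## Synthetic data

The generator emulates the study conditions end to end, at toy genome
scale so the full pipeline runs in seconds while every code path is
exercised:

- genome: 11 chromosomes × 100 kb of uniform random sequence
  (GC = 0.5); real genomes have repeats, so genome-uniqueness failure
  rates here are optimistic — uniqueness logic is instead tested with
  constructed duplications;
- population panel: 61 accessions; locus counts Poisson at 1298
  InDels/Mb; allele number per locus drawn from a biallelic-dominated
  class mix (77.53 % two-allele, descending to 0.3 % seven-allele);
  allele length offsets distinct, ≤ 50 bp; population frequencies
  symmetric Dirichlet(1), chosen so informative multi-allelic loci occur
  at testable rates; genotypes Hardy–Weinberg with no linkage
  disequilibrium, population structure or selection;
- parents: two fully homozygous genomes, alleles differing at 70 % of
  loci, spliced into the reference with exact coordinate bookkeeping;
- F2 cross: 113 individuals; 10 markers per chromosome at 8 cM spacing;
  crossovers per meiosis Poisson(length/100 Morgans) placed uniformly in
  cM — the Haldane, no-interference model — with 2 % missing genotypes.

Determinism: every stage draws from its own RNG stream derived from
(seed, stage index), so regeneration with the same configuration is
bit-for-bit identical regardless of which stages are invoked.

What passing tests on this generator do *not* show: performance on
repeat-rich genomes, on non-left-normalized or multi-caller VCFs, under
segregation distortion, or with interference-affected crossover data.
The Kosambi-vs-Haldane mismatch is quantified above; recovery tests use
Haldane mode for unbiasedness checks and allow 15 % total-length error
for Kosambi reporting.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the complete pipeline at
the default synthetic scale (11 × 100 kb genome, ~1400 loci, 61
accessions, 110 F2 markers × 113 individuals), 1000-query search-index
validation on a 100 kb genome, 1000-spectrum PIC oracle comparison, and
200 replicate crosses for order-recovery statistics — sizes chosen so a
full run completes in minutes on one core while keeping every estimate's
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- No hairpin/self-dimer/cross-dimer screening and no mismatch-tolerant
  primer mapping; "unique" means exact-match unique.
- Segregation-type support is codominant F2 only (no backcross or
  dominant markers); no multipoint HMM likelihood, no QTL analysis, no
  interference estimation.
- Variant normalization, read mapping and variant calling are upstream
  of this toolkit; it consumes a finished multi-sample VCF.
- The PIC formula is implemented as printed for this workflow; users
  wanting Botstein's expected-heterozygosity PIC should score spectra
  themselves from `allele_spectrum` output.
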