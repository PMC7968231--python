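"""Seeded synthetic fixtures for the whole pipeline, with exported truth.

The generator emulates every input the toolkit consumes: a toy
multi-chromosome reference genome, a multi-accession InDel panel written
as a valid VCF (2-7 alleles per locus, Dirichlet population frequencies,
Hardy-Weinberg genotypes), two fully homozygous parental genomes derived
from the panel, and a simulated F2 cross (Poisson crossovers placed
uniformly in cM; no interference) genotyped at codominant markers.  All
stages draw from per-stage RNG streams derived from the single seed, so
regenerating with the same configuration reproduces the truth exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from .linkage import F2GenotypeTable

_BASES = np.array(list("ACGT"))

DEFAULT_ALLELE_CLASS_MIX = {
    2: 0.7753, 3: 0.1447, 4: 0.05, 5: 0.02, 6: 0.007, 7: 0.003,
}


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic pipeline.

    The population mirrors a 61-accession resequencing panel at ~1298
    InDels/Mb with a biallelic-dominated allele-class mix (77.53% two
    alleles); the mapping population is a 113-individual F2.  Chromosome
    count follows the 11 pseudochromosomes, scaled to 100 kb each so the
    full pipeline stays desk-sized.
    """

    seed: int = 0
    n_chromosomes: int = 11
    chrom_length_bp: int = 100_000
    gc: float = 0.5
    n_accessions: int = 61
    indel_density_per_mb: float = 1298.0
    allele_class_mix: dict = field(default_factory=lambda: dict(DEFAULT_ALLELE_CLASS_MIX))
    max_indel_len: int = 50
    dirichlet_conc: float = 1.0
    min_locus_spacing_bp: int = 100
    parent_diff_fraction: float = 0.7
    f2_n: int = 113
    f2_markers_per_chrom: int = 10
    map_marker_spacing_cM: float = 8.0
    f2_missing_rate: float = 0.02

    def __post_init__(self):
        total = sum(self.allele_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele_class_mix sums to {total}, not 1")
        for name in ("n_chromosomes", "chrom_length_bp", "n_accessions", "f2_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def chrom_names(self) -> list[str]:
        return [f"MC{i + 1:02d}" for i in range(self.n_chromosomes)]


@dataclass
class TrueLocus:
    locus_id: str
    chrom: str
    pos: int                     # 1-based, left-anchored
    ref: str
    alts: list[str]
    frequencies: list[float]     # over ref + alts
    length_offsets: list[int]    # signed len(allele) - len(ref), index 0 = ref


@dataclass
class F2Marker:
    marker_id: str
    locus_index: int
    chrom: str
    bp: int
    cM: float


@dataclass
class SimTruth:
    """Ground truth accumulated across the simulation stages."""

    config: SimConfig
    loci: list[TrueLocus] = field(default_factory=list)
    genotypes: Optional[np.ndarray] = None     # (n_loci, n_accessions, 2)
    parent_alleles: Optional[np.ndarray] = None  # (n_loci, 2) allele indices
    f2_markers: list[F2Marker] = field(default_factory=list)
    f2_codes: Optional[np.ndarray] = None      # (n_markers, f2_n) 0/1/2/3
    crossovers: Optional[list] = None

    def marker_physical_positions(self) -> dict[str, tuple[str, int]]:
        return {m.marker_id: (m.chrom, m.bp) for m in self.f2_markers}

    def true_map(self) -> dict[str, list[tuple[str, float]]]:
        out: dict[str, list[tuple[str, float]]] = {}
        for m in self.f2_markers:
            out.setdefault(m.chrom, []).append((m.marker_id, m.cM))
        for v in out.values():
            v.sort(key=lambda t: t[1])
        return out


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


# --- genome ------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> dict[str, str]:
    """Random genome: uniform bases at the configured GC fraction."""
    rng = _rng(config, 1)
    p_gc = config.gc / 2.0
    p = np.array([0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc])  # A C G T
    return {
        name: "".join(rng.choice(_BASES, size=config.chrom_length_bp, p=p))
        for name in config.chrom_names()
    }


# --- population panel --------------------------------------------------------

def simulate_population_indels(genome: Mapping[str, str], config: SimConfig) -> SimTruth:
    """Place InDel loci and draw population frequencies and genotypes.

    Locus count per chromosome is Poisson at the configured density;
    positions are uniform, re-drawn (bounded retries) when closer than
    ``min_locus_spacing_bp`` to another locus.  Each locus draws its
    allele number from the class mix, distinct signed length offsets up to
    ``max_indel_len``, Dirichlet frequencies, and Hardy-Weinberg diploid
    genotypes for every accession.
    """
    rng = _rng(config, 2)
    truth = SimTruth(config=config)
    classes = sorted(config.allele_class_mix)
    class_p = np.array([config.allele_class_mix[c] for c in classes])
    edge = config.max_indel_len + 2  # keep REF footprints inside the chromosome
    all_geno = []
    for chrom in config.chrom_names():
        seq = genome[chrom]
        lam = config.indel_density_per_mb * len(seq) / 1e6
        n_loci = int(rng.poisson(lam))
        positions: list[int] = []
        taken: set[int] = set()
        for _ in range(n_loci):
            for _attempt in range(100):
                pos = int(rng.integers(edge, len(seq) - edge))
                if all(abs(pos - q) >= config.min_locus_spacing_bp
                       for q in taken):
                    positions.append(pos)
                    taken.add(pos)
                    break
        positions.sort()
        for pos in positions:
            n_alleles = int(rng.choice(classes, p=class_p))
            locus, geno = _simulate_locus(seq, chrom, pos, n_alleles, rng, config)
            truth.loci.append(locus)
            all_geno.append(geno)
    truth.genotypes = (np.stack(all_geno) if all_geno
                       else np.zeros((0, config.n_accessions, 2), dtype=np.int8))
    return truth


def _simulate_locus(seq: str, chrom: str, pos: int, n_alleles: int,
                    rng: np.random.Generator, config: SimConfig):
    # signed offsets for the alts: distinct, nonzero, |offset| <= max_indel_len
    offsets: list[int] = []
    while len(offsets) < n_alleles - 1:
        size = int(rng.integers(1, config.max_indel_len + 1))
        sign = -1 if rng.random() < 0.5 else 1
        off = sign * size
        if off not in offsets:
            offsets.append(off)
    max_del = max((-o for o in offsets if o < 0), default=0)
    ref = seq[pos - 1 : pos + max_del]  # anchor base + deletable bases
    alts = []
    for off in offsets:
        if off < 0:
            alts.append(ref[0] + ref[1 + (-off):])
        else:
            ins = "".join(rng.choice(_BASES, size=off))
            alts.append(ref[0] + ins + ref[1:])
    freqs = rng.dirichlet(np.full(n_alleles, config.dirichlet_conc))
    geno = rng.choice(n_alleles, size=(config.n_accessions, 2), p=freqs).astype(np.int8)
    geno.sort(axis=1)
    locus = TrueLocus(
        locus_id=f"{chrom}_{pos}", chrom=chrom, pos=pos, ref=ref,
        alts=alts, frequencies=[float(f) for f in freqs],
        length_offsets=[0] + offsets,
    )
    return locus, geno


# --- parental lines ----------------------------------------------------------

def derive_parental_lines(
    truth: SimTruth, config: SimConfig, genome: Mapping[str, str]
) -> tuple[dict[str, str], dict[str, str]]:
    """Two homozygous parental genomes with per-locus allele assignments.

    Parent A draws its allele from the population frequencies; parent B
    takes a different allele (uniform over the rest) with probability
    ``parent_diff_fraction``, otherwise the same one.  Each parent's
    genome is the reference with its alleles spliced in.
    """
    rng = _rng(config, 3)
    n = len(truth.loci)
    parent = np.zeros((n, 2), dtype=np.int8)
    for i, locus in enumerate(truth.loci):
        freqs = np.asarray(locus.frequencies)
        a = int(rng.choice(len(freqs), p=freqs))
        if len(freqs) > 1 and rng.random() < config.parent_diff_fraction:
            others = [k for k in range(len(freqs)) if k != a]
            b = int(others[rng.integers(len(others))])
        else:
            b = a
        parent[i] = (a, b)
    truth.parent_alleles = parent
    genome_a = _apply_alleles(genome, truth, parent[:, 0])
    genome_b = _apply_alleles(genome, truth, parent[:, 1])
    return genome_a, genome_b


def _apply_alleles(genome: Mapping[str, str], truth: SimTruth,
                   choice: np.ndarray) -> dict[str, str]:
    out = {}
    by_chrom: dict[str, list[int]] = {}
    for i, locus in enumerate(truth.loci):
        by_chrom.setdefault(locus.chrom, []).append(i)
    for chrom, seq in genome.items():
        pieces = []
        cursor = 0
        for i in sorted(by_chrom.get(chrom, []), key=lambda k: truth.loci[k].pos):
            locus = truth.loci[i]
            allele = ([locus.ref] + locus.alts)[int(choice[i])]
            start = locus.pos - 1
            pieces.append(seq[cursor:start])
            pieces.append(allele)
            cursor = start + len(locus.ref)
        pieces.append(seq[cursor:])
        out[chrom] = "".join(pieces)
    return out


# --- F2 cross ----------------------------------------------------------------

def select_f2_markers(truth: SimTruth, config: SimConfig) -> list[F2Marker]:
    """Pick codominant markers: loci where the parents carry alleles of
    different lengths, up to ``f2_markers_per_chrom`` per chromosome,
    evenly spread by physical position, at ``map_marker_spacing_cM``."""
    if truth.parent_alleles is None:
        raise ValueError("derive_parental_lines must run first")
    markers: list[F2Marker] = []
    per_chrom: dict[str, list[int]] = {}
    for i, locus in enumerate(truth.loci):
        a, b = truth.parent_alleles[i]
        if locus.length_offsets[a] != locus.length_offsets[b]:
            per_chrom.setdefault(locus.chrom, []).append(i)
    k = 0
    for chrom in sorted(per_chrom):
        idxs = sorted(per_chrom[chrom], key=lambda i: truth.loci[i].pos)
        take = min(config.f2_markers_per_chrom, len(idxs))
        sel = [idxs[int(round(j * (len(idxs) - 1) / max(take - 1, 1)))]
               for j in range(take)]
        sel = sorted(dict.fromkeys(sel))
        for rank, i in enumerate(sel):
            k += 1
            markers.append(F2Marker(
                marker_id=f"M{k:04d}", locus_index=i, chrom=chrom,
                bp=truth.loci[i].pos, cM=rank * config.map_marker_spacing_cM,
            ))
    truth.f2_markers = markers
    return markers


def _gamete(chrom_markers_cM: np.ndarray, length_cM: float,
            rng: np.random.Generator) -> np.ndarray:
    """One meiotic product: 0/1 parental origin per marker.

    Crossover count is Poisson(length in Morgans), positions uniform in
    cM (Haldane model, no interference); origin at a marker flips with
    each crossover to its left.
    """
    n_x = int(rng.poisson(length_cM / 100.0))
    xpos = np.sort(rng.uniform(0.0, length_cM, size=n_x)) if n_x else np.empty(0)
    start = int(rng.integers(2))
    flips = np.searchsorted(xpos, chrom_markers_cM, side="right")
    return (start + flips) % 2


def simulate_f2(truth: SimTruth, config: SimConfig) -> F2GenotypeTable:
    """Genotype the F2 cross at the selected markers (codes a/h/b, with a
    missing-data mask at the configured rate)."""
    if not truth.f2_markers:
        raise ValueError("select_f2_markers must run first")
    rng = _rng(config, 4)
    chrom_groups: dict[str, list[F2Marker]] = {}
    for m in truth.f2_markers:
        chrom_groups.setdefault(m.chrom, []).append(m)
    marker_ids = [m.marker_id for m in truth.f2_markers]
    idx_of = {m: i for i, m in enumerate(marker_ids)}
    codes = np.zeros((len(marker_ids), config.f2_n), dtype=np.int8)
    for chrom in sorted(chrom_groups):
        ms = sorted(chrom_groups[chrom], key=lambda m: m.cM)
        cm = np.array([m.cM for m in ms])
        length = float(cm[-1]) if len(cm) else 0.0
        rows = [idx_of[m.marker_id] for m in ms]
        for ind in range(config.f2_n):
            g1 = _gamete(cm, length, rng)
            g2 = _gamete(cm, length, rng)
            codes[rows, ind] = g1 + g2  # 0=a, 1=h, 2=b
    if config.f2_missing_rate > 0:
        mask = rng.random(codes.shape) < config.f2_missing_rate
        codes[mask] = 3
    truth.f2_codes = codes
    individual_ids = [f"F2_{i + 1:03d}" for i in range(config.f2_n)]
    return F2GenotypeTable(marker_ids, individual_ids, codes)


# --- writers / readers -------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    genome: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                genome[name] = []
            elif line and name is not None:
                genome[name].append(line.upper())
    return {k: "".join(v) for k, v in genome.items()}


def write_population_vcf(truth: SimTruth, genome: Mapping[str, str], path) -> None:
    """Valid multi-sample VCF 4.2 with unphased GT calls."""
    config = truth.config
    samples = [f"ACC{i + 1:03d}" for i in range(config.n_accessions)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=indelkit-simulate\n")
        for chrom in config.chrom_names():
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, locus in enumerate(truth.loci):
            gts = "\t".join(
                f"{a}/{b}" for a, b in truth.genotypes[i]
            )
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t{locus.locus_id}\t{locus.ref}\t"
                f"{','.join(locus.alts)}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_genotype_table(table: F2GenotypeTable, path) -> None:
    letters = np.array(["a", "h", "b", "u"])
    with open(path, "w") as fh:
        fh.write("marker_id\t" + "\t".join(table.individual_ids) + "\n")
        for i, m in enumerate(table.marker_ids):
            fh.write(m + "\t" + "\t".join(letters[table.codes[i]]) + "\n")


def write_physical_positions(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tchrom\tbp\n")
        for m in truth.f2_markers:
            fh.write(f"{m.marker_id}\t{m.chrom}\t{m.bp}\n")


def read_physical_positions(path) -> dict[str, tuple[str, int]]:
    out = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            marker, chrom, bp = line.rstrip("\n").split("\t")
            out[marker] = (chrom, int(bp))
    return out


def write_truth_json(truth: SimTruth, path) -> None:
    """Truth export (loci, frequencies, parent alleles, F2 map); the genome
    itself round-trips through its FASTA."""
    payload = {
        "config": asdict(truth.config),
        "loci": [asdict(l) for l in truth.loci],
        "parent_alleles": (truth.parent_alleles.tolist()
                           if truth.parent_alleles is not None else None),
        "f2_markers": [asdict(m) for m in truth.f2_markers],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path) -> SimTruth:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    cfg["allele_class_mix"] = {int(k): v for k, v in cfg["allele_class_mix"].items()}
    config = SimConfig(**cfg)
    truth = SimTruth(config=config)
    truth.loci = [TrueLocus(**l) for l in payload["loci"]]
    if payload["parent_alleles"] is not None:
        truth.parent_alleles = np.array(payload["parent_alleles"], dtype=np.int8)
    truth.f2_markers = [F2Marker(**m) for m in payload["f2_markers"]]
    return truth


def simulate_all(config: SimConfig):
    """Run every stage; returns (genome, truth, genome_a, genome_b, f2_table)."""
    genome = simulate_genome(config)
    truth = simulate_population_indels(genome, config)
    genome_a, genome_b = derive_parental_lines(truth, config, genome)
    select_f2_markers(truth, config)
    f2 = simulate_f2(truth, config)
    return genome, truth, genome_a, genome_b, f2
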