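"""Population InDel catalog: loci, allele spectra, PIC scoring and selection.

An InDel locus is a reference-anchored insertion/deletion site segregating in
a resequenced population.  The catalog layer parses a multi-sample VCF,
retains small (<= 50 bp) length polymorphisms, computes per-locus allele
frequency spectra from the diploid calls, and ranks loci by polymorphism
information content

    PIC = 1 - sum_i P_i^2 - sum_{i<j} 2 P_i^2 P_j^2

where P_i is the frequency of allele i and n the number of observed alleles.
Loci with PIC >= 0.6 become primer-design candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Call = Optional[tuple[int, int]]


class VcfParseError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class IndelLocus:
    """One insertion/deletion site with its allele set.

    ``pos`` is the 1-based reference coordinate of the VCF record (the
    left-anchored position).  Every alt allele differs from the reference
    allele in length; ``indel_lengths[k] = |len(alt_k) - len(ref)|``.
    """

    locus_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    indel_lengths: tuple[int, ...] = field(default=())

    def __post_init__(self):
        if not self.alt_alleles:
            raise ValueError(f"{self.locus_id}: at least one alt allele required")
        lengths = tuple(abs(len(a) - len(self.ref_allele)) for a in self.alt_alleles)
        if self.indel_lengths == ():
            object.__setattr__(self, "indel_lengths", lengths)
        if any(l == 0 for l in self.indel_lengths):
            raise ValueError(
                f"{self.locus_id}: alt equal in length to ref (pure substitution)"
            )

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt_alleles)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele,) + self.alt_alleles


@dataclass
class PopulationGenotypes:
    """Diploid genotype calls for every locus over a panel of accessions.

    ``calls[locus_id]`` is a list (one entry per accession, in
    ``accession_ids`` order) of unordered allele-index pairs, or ``None``
    for a missing call.
    """

    accession_ids: list[str]
    calls: dict[str, list[Call]]

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def call_rate(self, locus_id: str) -> float:
        calls = self.calls[locus_id]
        return sum(c is not None for c in calls) / len(calls)


@dataclass(frozen=True)
class AlleleSpectrum:
    """Observed allele frequencies at a locus.

    Alleles declared in the VCF but absent from the sample's calls are
    pruned, so ``len(frequencies)`` is the *effective* allele number n that
    enters PIC.  ``observed_alleles`` maps spectrum slots back to the
    locus's original allele indices.
    """

    frequencies: tuple[float, ...]
    n_called: int
    call_rate: float
    observed_alleles: tuple[int, ...] = ()
    eligible: bool = True

    @property
    def n(self) -> int:
        return len(self.frequencies)

    @property
    def is_monomorphic(self) -> bool:
        return self.n <= 1


@dataclass(frozen=True)
class ScoredLocus:
    locus: IndelLocus
    spectrum: AlleleSpectrum
    pic: float
    candidate_id: Optional[str] = None


def _length_variant_alt(ref: str, alt: str) -> bool:
    return len(alt) != len(ref) and set(alt) <= set("ACGTN")


def read_population_vcf(
    vcf_path, fasta_path=None
) -> tuple[list[IndelLocus], PopulationGenotypes]:
    """Read a multi-sample VCF, keeping only length-polymorphic records.

    Records whose alts are all the same length as REF (pure substitutions)
    are dropped.  At mixed records, substitution alts are removed from the
    allele list (logged) and calls carrying a removed allele become missing.
    When ``fasta_path`` is given, REF is validated against the reference.
    """
    import pysam

    fasta = None
    if fasta_path is not None:
        import pyfaidx

        fasta = pyfaidx.Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)

    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {vcf_path}: {exc}") from exc

    samples = list(vf.header.samples)
    loci: list[IndelLocus] = []
    calls: dict[str, list[Call]] = {}
    for rec in vf:
        if rec.alts is None:
            continue
        ref = rec.ref.upper()
        kept: list[str] = []
        index_map: dict[int, int] = {0: 0}  # old allele index -> new
        dropped = []
        for k, alt in enumerate(rec.alts, start=1):
            alt = alt.upper()
            if _length_variant_alt(ref, alt):
                kept.append(alt)
                index_map[k] = len(kept)
            else:
                dropped.append(alt)
        if not kept:
            continue
        if dropped:
            log.warning(
                "record %s:%d: dropped %d substitution alt(s) %s",
                rec.chrom, rec.pos, len(dropped), ",".join(dropped),
            )
        locus_id = f"{rec.chrom}_{rec.pos}"
        if fasta is not None:
            ref_slice = str(fasta[rec.chrom][rec.pos - 1 : rec.pos - 1 + len(ref)])
            if ref_slice != ref:
                raise ReferenceMismatchError(
                    f"locus {locus_id}: VCF REF {ref!r} != FASTA {ref_slice!r}"
                )
        locus = IndelLocus(
            locus_id=locus_id, chrom=rec.chrom, pos=rec.pos,
            ref_allele=ref, alt_alleles=tuple(kept),
        )
        locus_calls: list[Call] = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                locus_calls.append(None)
                continue
            if any(a not in index_map for a in gt):
                locus_calls.append(None)  # call used a dropped substitution alt
                continue
            a, b = sorted(index_map[x] for x in gt)
            locus_calls.append((a, b))
        loci.append(locus)
        calls[locus_id] = locus_calls
    return loci, PopulationGenotypes(accession_ids=samples, calls=calls)


def length_filter(loci: Sequence[IndelLocus], max_len: int = 50) -> list[IndelLocus]:
    """Keep loci whose every alt differs from REF by at most ``max_len`` bp."""
    return [l for l in loci if max(l.indel_lengths) <= max_len]


def allele_spectrum(
    locus: IndelLocus,
    genotypes: PopulationGenotypes,
    min_call_rate: float = 0.8,
) -> AlleleSpectrum:
    """Observed allele frequencies from the called diploid genotypes.

    Frequencies use only non-missing calls; alleles never observed in the
    sample are pruned before PIC.  A locus whose call rate falls below
    ``min_call_rate`` (or with zero calls) is flagged ineligible rather
    than raising.
    """
    calls = genotypes.calls[locus.locus_id]
    m = len(calls)
    counts = np.zeros(locus.n_alleles, dtype=np.int64)
    n_called = 0
    for c in calls:
        if c is None:
            continue
        n_called += 1
        counts[c[0]] += 1
        counts[c[1]] += 1
    call_rate = n_called / m if m else 0.0
    if n_called == 0:
        return AlleleSpectrum((), 0, call_rate, (), eligible=False)
    observed = tuple(int(i) for i in np.nonzero(counts)[0])
    freqs = tuple(float(counts[i]) / (2 * n_called) for i in observed)
    return AlleleSpectrum(
        frequencies=freqs, n_called=n_called, call_rate=call_rate,
        observed_alleles=observed, eligible=call_rate >= min_call_rate,
    )


def pic_score(spectrum) -> float:
    """Polymorphism information content of an allele-frequency spectrum.

    PIC = 1 - sum P_i^2 - sum_{i<j} 2 P_i^2 P_j^2, evaluated through the
    power-sum identity 2*sum_{i<j} P_i^2 P_j^2 = (sum P_i^2)^2 - sum P_i^4.
    Zero iff monomorphic.
    """
    freqs = spectrum.frequencies if isinstance(spectrum, AlleleSpectrum) else tuple(spectrum)
    if len(freqs) == 0:
        raise ValueError("empty allele spectrum")
    p = np.asarray(freqs, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"invalid spectrum (sum={p.sum()!r})")
    s2 = float(np.sum(p * p))
    s4 = float(np.sum(p ** 4))
    return 1.0 - s2 - (s2 * s2 - s4)


def score_loci(
    loci: Sequence[IndelLocus],
    genotypes: PopulationGenotypes,
    min_call_rate: float = 0.8,
) -> list[ScoredLocus]:
    """Spectrum + PIC for every eligible locus (call rate >= threshold)."""
    out = []
    for locus in loci:
        spec = allele_spectrum(locus, genotypes, min_call_rate)
        if not spec.eligible:
            log.info("locus %s ineligible (call rate %.3f)", locus.locus_id, spec.call_rate)
            continue
        out.append(ScoredLocus(locus=locus, spectrum=spec, pic=pic_score(spec)))
    return out


def select_candidates(
    scored: Sequence[ScoredLocus],
    min_pic: float = 0.6,
    id_prefix: str = "MC_g61ind",
    id_width: int = 4,
) -> list[ScoredLocus]:
    """Retain loci with PIC >= ``min_pic`` (inclusive, 1e-12 tolerance),
    sorted by (chrom, pos), with sequential candidate IDs."""
    kept = [s for s in scored if s.pic >= min_pic - 1e-12]
    kept.sort(key=lambda s: (s.locus.chrom, s.locus.pos))
    return [
        replace(s, candidate_id=f"{id_prefix}{i + 1:0{id_width}d}")
        for i, s in enumerate(kept)
    ]


def density_summary(
    loci: Sequence[IndelLocus],
    chrom_lengths: Mapping[str, int],
    window_bp: int,
) -> pd.DataFrame:
    """Locus counts and densities per window, per chromosome, and genome-wide.

    Windows are half-open ``[start, start + window_bp)`` in 0-based
    coordinates.  Densities are loci per Mb of window/chromosome/genome.
    """
    for l in loci:
        if l.chrom not in chrom_lengths:
            raise ValueError(f"locus {l.locus_id} on unknown chromosome {l.chrom}")
    rows = []
    total = 0
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        positions = np.array([l.pos - 1 for l in loci if l.chrom == chrom], dtype=int)
        n_windows = max(1, -(-length // window_bp))
        counts = np.bincount(positions // window_bp, minlength=n_windows) if positions.size else np.zeros(n_windows, dtype=int)
        for w in range(n_windows):
            start = w * window_bp
            end = min(start + window_bp, length)
            rows.append(("window", chrom, start, end, int(counts[w]),
                         counts[w] / ((end - start) / 1e6)))
        rows.append(("chromosome", chrom, 0, length, int(positions.size),
                     positions.size / (length / 1e6)))
        total += positions.size
    genome_bp = sum(chrom_lengths.values())
    rows.append(("genome", "*", 0, genome_bp, total, total / (genome_bp / 1e6)))
    return pd.DataFrame(
        rows, columns=["level", "chrom", "window_start", "window_end", "count", "density_per_mb"]
    )


def allele_class_table(scored: Sequence[ScoredLocus]) -> pd.DataFrame:
    """Counts and proportions of loci by observed allele number n."""
    ns = [s.spectrum.n for s in scored]
    if not ns:
        return pd.DataFrame(columns=["n_alleles", "count", "proportion"])
    vc = pd.Series(ns).value_counts().sort_index()
    return pd.DataFrame({
        "n_alleles": vc.index.to_numpy(),
        "count": vc.to_numpy(),
        "proportion": vc.to_numpy() / vc.sum(),
    })


def candidate_table(scored: Sequence[ScoredLocus]) -> pd.DataFrame:
    """Candidate export with fixed column order."""
    rows = []
    for s in scored:
        rows.append({
            "locus_id": s.candidate_id or s.locus.locus_id,
            "chrom": s.locus.chrom,
            "pos": s.locus.pos,
            "ref": s.locus.ref_allele,
            "alts": ",".join(s.locus.alt_alleles),
            "n_alleles": s.spectrum.n,
            "call_rate": s.spectrum.call_rate,
            "frequencies": ",".join(f"{p:.6f}" for p in s.spectrum.frequencies),
            "pic": s.pic,
        })
    return pd.DataFrame(
        rows,
        columns=["locus_id", "chrom", "pos", "ref", "alts", "n_alleles",
                 "call_rate", "frequencies", "pic"],
    )
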