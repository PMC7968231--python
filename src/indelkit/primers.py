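"""PCR primer design around InDel sites, genome uniqueness, in-silico PCR.

Candidate primers are enumerated exhaustively from the flanking sequence of
a locus under windowed constraints on size, melting temperature, and GC
content, scored with a primer3-style weighted deviation penalty, and paired
so the product spans the InDel.  Pairs are screened for genome uniqueness
by exact full-length matching (both strands), and amplification in a given
line's genome is predicted by locating primer binding sites (e-PCR).  A pair
is called polymorphic between two lines when each yields a single product
and the product lengths differ by at least the gel-resolvable minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerConstraints:
    """Windowed primer design constraints (min/opt/max per property)."""

    size_min: int = 18
    size_opt: int = 20
    size_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    product_min: int = 100
    product_opt: int = 250
    product_max: int = 500
    gc_min: float = 40.0
    gc_opt: float = 50.0
    gc_max: float = 60.0
    w_size: float = 1.0
    w_tm: float = 1.0
    w_gc: float = 0.2
    w_product: float = 0.05

    def __post_init__(self):
        for name in ("size", "tm", "product", "gc"):
            lo = getattr(self, f"{name}_min")
            opt = getattr(self, f"{name}_opt")
            hi = getattr(self, f"{name}_max")
            if not lo <= opt <= hi:
                raise ValueError(f"{name}: need min <= opt <= max, got {lo}/{opt}/{hi}")


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str            # 5'->3' (reverse candidates: revcomp of template slice)
    strand: str              # "forward" | "reverse"
    template_start: int      # 0-based start of the annealing site on the template
    tm: float
    gc: float
    penalty: float

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    pair_id: str
    locus_id: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    product_size: int        # on the reference (design) allele
    pair_penalty: float


@dataclass(frozen=True)
class UniquenessReport:
    pair_id: str
    forward_hits: int
    reverse_hits: int

    @property
    def is_unique(self) -> bool:
        return self.forward_hits == 1 and self.reverse_hits == 1


@dataclass(frozen=True)
class Amplicon:
    chrom: str
    start: int               # 0-based half-open reference coordinates
    end: int
    line_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PolymorphismCall:
    pair_id: str
    amplicon_a: Optional[Amplicon]
    amplicon_b: Optional[Amplicon]
    status: str              # polymorphic|monomorphic|failed_a|failed_b|failed_both|multiband


# --- sequence thermodynamics -------------------------------------------------

# SantaLucia (1998) unified nearest-neighbor parameters: (dH kcal/mol, dS e.u.)
# keyed by the top-strand dinucleotide; reverse-complement pairs share values.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# duplex initiation terms per terminal base pair
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
_R_GAS = 1.987  # cal/(K*mol)


def gc_content(seq: str) -> float:
    """GC percentage of a primer sequence (A/C/G/T only)."""
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT base in {seq!r}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(
    seq: str,
    na_mM: float = 50.0,
    dnac1_nM: float = 50.0,
    dnac2_nM: float = 0.0,
) -> float:
    """Nearest-neighbor duplex melting temperature in Celsius.

    Uses the SantaLucia 1998 unified parameter set with entropy-based
    monovalent salt correction (0.368 * (N-1) * ln[Na+]) and duplex
    concentration k = dnac1 - dnac2/2 (nM), the convention of standard
    thermodynamic oligo calculators.  Deterministic; defaults emulate
    primer-design tool settings (50 mM Na+, 50 nM oligo).
    """
    n = len(seq)
    if not 10 <= n <= 36:
        raise ValueError(f"primer length {n} outside [10, 36]")
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-ACGT base in {seq!r}")
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for i in range(n - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    ds += 0.368 * (n - 1) * math.log(na_mM / 1000.0)
    k = (dnac1_nM - dnac2_nM / 2.0) * 1e-9
    return 1000.0 * dh / (ds + _R_GAS * math.log(k)) - 273.15


# --- candidate enumeration and pairing ---------------------------------------

def extract_template(reference, locus, flank_bp: int = 400) -> tuple[str, tuple[int, int]]:
    """Reference slice around a locus plus the InDel's footprint on it.

    Returns ``(template, (target_start, target_end))`` with the target the
    ref-allele footprint in 0-based template coordinates.  The flank is
    clipped at chromosome ends.
    """
    seq = _chrom_seq(reference, locus.chrom)
    ref_len = len(locus.ref_allele)
    start = max(0, locus.pos - 1 - flank_bp)
    end = min(len(seq), locus.pos - 1 + ref_len + flank_bp)
    template = seq[start:end]
    t0 = locus.pos - 1 - start
    return template, (t0, t0 + ref_len)


def _chrom_seq(reference, chrom: str) -> str:
    if isinstance(reference, Mapping):
        if chrom not in reference:
            raise KeyError(f"chromosome {chrom} absent from reference")
        return reference[chrom]
    # pyfaidx.Fasta or similar
    if chrom not in reference:
        raise KeyError(f"chromosome {chrom} absent from reference")
    return str(reference[chrom][:]).upper()


def candidate_penalty(size: int, tm: float, gc: float, c: PrimerConstraints) -> float:
    """Weighted absolute deviation from the optima; 0 iff all optima met."""
    return (
        c.w_size * abs(size - c.size_opt)
        + c.w_tm * abs(tm - c.tm_opt)
        + c.w_gc * abs(gc - c.gc_opt)
    )


def enumerate_candidates(
    template: str,
    target: tuple[int, int],
    constraints: PrimerConstraints = PrimerConstraints(),
) -> tuple[list[PrimerCandidate], list[PrimerCandidate]]:
    """All window-passing primer candidates flanking the target.

    Forward candidates lie wholly 5' of the target; reverse candidates
    wholly 3' of it (stored as the reverse complement of the template
    slice).  Substrings containing N are rejected.  A vectorized
    prefilter over prefix sums narrows the windows; survivors are
    re-scored exactly with :func:`gc_content` / :func:`melting_temp`.
    """
    c = constraints
    t0, t1 = target
    n = len(template)
    codes = _encode(template)
    gc_pref = np.concatenate([[0], np.cumsum((codes == 1) | (codes == 2))])
    bad_pref = np.concatenate([[0], np.cumsum(codes >= 4)])
    # nearest-neighbor step prefix sums for O(1) Tm prefilter
    nn_dh = np.zeros(16)
    nn_ds = np.zeros(16)
    for dinuc, (h, s) in _NN.items():
        nn_dh[4 * _BASE_CODE[ord(dinuc[0])] + _BASE_CODE[ord(dinuc[1])]] = h
        nn_ds[4 * _BASE_CODE[ord(dinuc[0])] + _BASE_CODE[ord(dinuc[1])]] = s
    safe = np.minimum(codes, 3)
    steps = 4 * safe[:-1] + safe[1:] if n > 1 else np.empty(0, dtype=np.int64)
    dh_pref = np.concatenate([[0.0], np.cumsum(nn_dh[steps])])
    ds_pref = np.concatenate([[0.0], np.cumsum(nn_ds[steps])])
    init_dh = np.array([_INIT[b][0] for b in "ACGT"] + [0.0])
    init_ds = np.array([_INIT[b][1] for b in "ACGT"] + [0.0])
    log_k = math.log(50e-9)  # matches melting_temp defaults
    salt = 0.368 * math.log(50.0 / 1000.0)

    forwards: list[PrimerCandidate] = []
    reverses: list[PrimerCandidate] = []
    for size in range(c.size_min, c.size_max + 1):
        for strand, lo, hi in (("forward", 0, t0 - size + 1), ("reverse", t1, n - size + 1)):
            starts = np.arange(lo, max(lo, hi))
            if starts.size == 0:
                continue
            ends = starts + size
            ok = (bad_pref[ends] - bad_pref[starts]) == 0
            gc = 100.0 * (gc_pref[ends] - gc_pref[starts]) / size
            ok &= (gc >= c.gc_min) & (gc <= c.gc_max)
            dh = init_dh[codes[starts]] + init_dh[codes[ends - 1]] + dh_pref[ends - 1] - dh_pref[starts]
            ds = (init_ds[codes[starts]] + init_ds[codes[ends - 1]]
                  + ds_pref[ends - 1] - ds_pref[starts] + (size - 1) * salt)
            with np.errstate(divide="ignore", invalid="ignore"):
                tm = 1000.0 * dh / (ds + _R_GAS * log_k) - 273.15
            ok &= (tm >= c.tm_min - 1e-6) & (tm <= c.tm_max + 1e-6)
            for s in starts[ok]:
                sub = template[s : s + size]
                seq = sub if strand == "forward" else revcomp(sub)
                gc_exact = gc_content(seq)
                tm_exact = melting_temp(seq)
                if not (c.tm_min <= tm_exact <= c.tm_max):
                    continue
                pen = candidate_penalty(size, tm_exact, gc_exact, c)
                lst = forwards if strand == "forward" else reverses
                lst.append(PrimerCandidate(seq, strand, int(s), tm_exact, gc_exact, pen))
    key = lambda p: (p.penalty, p.sequence, p.template_start)
    forwards.sort(key=key)
    reverses.sort(key=key)
    return forwards, reverses


def pair_primers(
    forwards: Sequence[PrimerCandidate],
    reverses: Sequence[PrimerCandidate],
    target: tuple[int, int],
    constraints: PrimerConstraints = PrimerConstraints(),
    max_pairs: int = 1,
    locus_id: str = "",
) -> list[PrimerPair]:
    """Best product-window pairs spanning the target, by total penalty.

    pair_penalty = forward + reverse penalties + w_product * |product -
    product_opt|.  Ties broken by (penalty, product_size, forward sequence,
    reverse sequence) so the result is order-independent.
    """
    c = constraints
    if not forwards or not reverses:
        return []
    f_start = np.array([f.template_start for f in forwards])
    f_pen = np.array([f.penalty for f in forwards])
    r_end = np.array([r.template_start + r.length for r in reverses])
    r_pen = np.array([r.penalty for r in reverses])
    product = r_end[None, :] - f_start[:, None]
    pen = (f_pen[:, None] + r_pen[None, :]
           + c.w_product * np.abs(product - c.product_opt))
    fi, ri = np.nonzero((product >= c.product_min) & (product <= c.product_max))
    if fi.size == 0:
        return []
    if fi.size > max_pairs:
        # numeric pre-selection; exact ordering settled by the tie-break sort
        flat = pen[fi, ri]
        kth = np.partition(flat, max_pairs - 1)[max_pairs - 1]
        sel = flat <= kth + 1e-12
        fi, ri = fi[sel], ri[sel]
    scored = sorted(
        ((float(pen[a, b]), int(product[a, b]),
          forwards[a].sequence, reverses[b].sequence, forwards[a], reverses[b])
         for a, b in zip(fi, ri)),
        key=lambda t: t[:4],
    )
    pairs = []
    for i, (pp, prod, _, _, f, r) in enumerate(scored[:max_pairs]):
        pairs.append(PrimerPair(
            pair_id=f"{locus_id}_P{i + 1}" if locus_id else f"P{i + 1}",
            locus_id=locus_id, forward=f, reverse=r,
            product_size=prod, pair_penalty=pp,
        ))
    return pairs


def design_primers(
    reference,
    locus,
    constraints: PrimerConstraints = PrimerConstraints(),
    flank_bp: int = 400,
    max_pairs: int = 1,
) -> list[PrimerPair]:
    """Template extraction + enumeration + pairing for one locus."""
    template, target = extract_template(reference, locus, flank_bp)
    fwd, rev = enumerate_candidates(template, target, constraints)
    pairs = pair_primers(fwd, rev, target, constraints, max_pairs,
                         locus_id=getattr(locus, "candidate_id", None) or locus.locus_id)
    # lift template coordinates to reference coordinates
    offset = locus.pos - 1 - target[0]
    lifted = []
    for p in pairs:
        lifted.append(PrimerPair(
            p.pair_id, p.locus_id,
            PrimerCandidate(p.forward.sequence, "forward",
                            p.forward.template_start + offset,
                            p.forward.tm, p.forward.gc, p.forward.penalty),
            PrimerCandidate(p.reverse.sequence, "reverse",
                            p.reverse.template_start + offset,
                            p.reverse.tm, p.reverse.gc, p.reverse.penalty),
            p.product_size, p.pair_penalty,
        ))
    return lifted


# --- genome search, uniqueness, e-PCR ----------------------------------------

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes; windows containing non-ACGT get -1."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        out = out * 4 + np.where(window < 4, window, 0)
        bad |= window >= 4
    out[bad] = -1
    return out


class GenomeIndex:
    """Exact-match substring index over a genome (k-mer seed + verify).

    Each chromosome's rolling k-mer codes are sorted once; a query seeds
    on its first k bases by binary search and is verified full-length.
    Hits of the reverse complement on the + strand are reported as
    - strand hits.
    """

    def __init__(self, genome, k: int = 11):
        self.k = k
        if not isinstance(genome, Mapping):
            genome = {name: str(genome[name][:]).upper() for name in genome.keys()}
        self.chroms = sorted(genome)
        self.seqs = {c: genome[c].upper() for c in self.chroms}
        self._sorted: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in self.chroms:
            kcodes = _kmer_codes(_encode(self.seqs[c]), k)
            order = np.argsort(kcodes, kind="stable")
            self._sorted[c] = (kcodes[order], order)

    def _forward_hits(self, query: str) -> list[tuple[str, int]]:
        k = self.k
        if len(query) < k:
            raise ValueError(f"query shorter than index k={k}")
        code = 0
        for ch in query[:k]:
            code = code * 4 + int(_BASE_CODE[ord(ch)])
        hits = []
        for chrom in self.chroms:
            sorted_codes, order = self._sorted[chrom]
            lo = np.searchsorted(sorted_codes, code, side="left")
            hi = np.searchsorted(sorted_codes, code, side="right")
            seq = self.seqs[chrom]
            for pos in sorted(int(p) for p in order[lo:hi]):
                if seq.startswith(query, pos):
                    hits.append((chrom, pos))
        return hits

    def search(self, primer: str) -> list[tuple[str, int, str]]:
        """All exact occurrences as (chrom, 0-based start, strand)."""
        if set(primer) - set("ACGT"):
            raise ValueError(f"non-ACGT base in primer {primer!r}")
        hits = [(c, p, "+") for c, p in self._forward_hits(primer)]
        hits += [(c, p, "-") for c, p in self._forward_hits(revcomp(primer))]
        return sorted(hits)


def search_genome_exact(genome, primer: str) -> list[tuple[str, int, str]]:
    """Convenience wrapper: build an index and search one primer.

    For many queries against the same genome build a :class:`GenomeIndex`
    once and call ``.search``.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    return index.search(primer)


def naive_search(genome: Mapping[str, str], primer: str) -> list[tuple[str, int, str]]:
    """O(n*m) scan used as the validation oracle for GenomeIndex."""
    hits = []
    rc = revcomp(primer)
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for query, strand in ((primer, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                hits.append((chrom, start, strand))
                start = seq.find(query, start + 1)
    return sorted(hits)


def classify_uniqueness(pair: PrimerPair, genome) -> UniquenessReport:
    """Unique iff each primer has exactly one genome hit (strands pooled)."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    return UniquenessReport(
        pair_id=pair.pair_id,
        forward_hits=len(index.search(pair.forward.sequence)),
        reverse_hits=len(index.search(pair.reverse.sequence)),
    )


def insilico_pcr(
    line_genome,
    pair: PrimerPair,
    max_product: int = 750,
    line_id: str = "",
) -> list[Amplicon]:
    """Predicted PCR products of a primer pair in one line's genome.

    A product forms wherever one primer matches the + strand upstream of
    the other primer's - strand site on the same chromosome, with length
    at most ``max_product``.  Zero products predicts amplification
    failure; two or more predicts a multiband pattern.
    """
    index = line_genome if isinstance(line_genome, GenomeIndex) else GenomeIndex(line_genome)
    f_hits = index.search(pair.forward.sequence)
    r_hits = index.search(pair.reverse.sequence)
    amps = set()
    for left, right in ((f_hits, r_hits), (r_hits, f_hits)):
        plus = [(c, p) for c, p, s in left if s == "+"]
        minus = [(c, p) for c, p, s in right if s == "-"]
        for (cf, pf) in plus:
            for (cr, pr) in minus:
                if cf != cr:
                    continue
                # the - strand primer occupies [pr, pr + len) on the + strand
                rlen = pair.reverse.length if right is r_hits else pair.forward.length
                end = pr + rlen
                length = end - pf
                if length < 1 or length > max_product:
                    continue
                amps.add((cf, pf, end))
    return [Amplicon(c, s, e, line_id) for c, s, e in sorted(amps)]


def call_polymorphism(
    pair_id: str,
    amp_a: Sequence[Amplicon],
    amp_b: Sequence[Amplicon],
    min_diff_bp: int = 3,
) -> PolymorphismCall:
    """Classify a marker between two lines from its predicted products.

    Polymorphic iff both lines give exactly one product each and their
    lengths differ by at least ``min_diff_bp`` (the resolvable band shift
    on a 6% polyacrylamide gel at the default).
    """
    if len(amp_a) == 0 and len(amp_b) == 0:
        status = "failed_both"
    elif len(amp_a) == 0:
        status = "failed_a"
    elif len(amp_b) == 0:
        status = "failed_b"
    elif len(amp_a) > 1 or len(amp_b) > 1:
        status = "multiband"
    elif abs(amp_a[0].length - amp_b[0].length) >= min_diff_bp:
        status = "polymorphic"
    else:
        status = "monomorphic"
    return PolymorphismCall(
        pair_id=pair_id,
        amplicon_a=amp_a[0] if len(amp_a) == 1 else None,
        amplicon_b=amp_b[0] if len(amp_b) == 1 else None,
        status=status,
    )
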