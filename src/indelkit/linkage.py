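"""F2 linkage map construction from codominant marker genotypes.

The mapper takes an F2 genotype table (codes a = parent-A homozygote,
h = heterozygote, b = parent-B homozygote, u = missing), filters markers
with excessive missing data, estimates pairwise recombination fractions by
EM over the nine joint genotype classes, groups markers by LOD-thresholded
connected components, orders each group by LOD^2-weighted least-squares
stress (greedy insertion plus 2-opt polishing), spaces markers with
Kosambi's mapping function via non-negative least squares, and emits
per-group summaries (genetic length, marker density, physical span,
recombination rate in cM/Mb) and a genetic-vs-physical collinearity report.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

_CODE_TO_INT = {"a": 0, "h": 1, "b": 2, "u": 3, "-": 3}
_LN10 = math.log(10.0)


@dataclass
class F2GenotypeTable:
    """Markers x individuals matrix of codominant F2 genotype codes."""

    marker_ids: list[str]
    individual_ids: list[str]
    codes: np.ndarray  # int8, 0=a 1=h 2=b 3=missing

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.marker_ids), len(self.individual_ids)):
            raise ValueError("codes shape inconsistent with marker/individual ids")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def missing_rate(self, marker_id: str) -> float:
        row = self.codes[self.marker_ids.index(marker_id)]
        return float(np.mean(row == 3))

    def row(self, marker_id: str) -> np.ndarray:
        return self.codes[self.marker_ids.index(marker_id)]

    def to_frame(self) -> pd.DataFrame:
        letters = np.array(["a", "h", "b", "u"])
        return pd.DataFrame(
            letters[self.codes], index=self.marker_ids, columns=self.individual_ids
        )


@dataclass(frozen=True)
class PairwiseLinkage:
    marker_i: str
    marker_j: str
    r_hat: float
    lod: float
    n_informative: int


@dataclass
class LinkageGroupResult:
    lg_id: str
    marker_ids: list[str]
    positions_cM: np.ndarray
    chrom: Optional[str] = None

    @property
    def length_cM(self) -> float:
        return float(self.positions_cM[-1]) if len(self.positions_cM) else 0.0


# --- input -------------------------------------------------------------------

class GenotypeParseError(ValueError):
    pass


def read_genotype_table(path) -> F2GenotypeTable:
    """Read a genotype table (TSV markers x individuals, or .loc dialect).

    TSV: header row of individual ids, one row per marker.  The .loc
    dialect has ``key = value`` headers (nloc/nind) and per-marker records
    of whitespace-separated codes, possibly wrapped over lines.  Codes
    a/h/b/u; '-' is read as missing.
    """
    path = str(path)
    if path.endswith(".loc"):
        return _read_loc(path)
    rows = []
    marker_ids = []
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")
    individual_ids = header[1:]
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        marker_ids.append(parts[0])
        row = []
        for col, code in enumerate(parts[1:], start=1):
            code = code.strip().lower()
            if code not in _CODE_TO_INT:
                raise GenotypeParseError(
                    f"unknown genotype code {code!r} at row {lineno}, column {col + 1}"
                )
            row.append(_CODE_TO_INT[code])
        if len(row) != len(individual_ids):
            raise GenotypeParseError(f"row {lineno}: expected {len(individual_ids)} calls")
        rows.append(row)
    return F2GenotypeTable(marker_ids, individual_ids, np.array(rows, dtype=np.int8))


def _read_loc(path: str) -> F2GenotypeTable:
    nind = None
    tokens_by_marker: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.split(";")[0].strip()
            if not line:
                continue
            if "=" in line and current is None:
                key, _, value = (t.strip() for t in line.partition("="))
                if key.lower() == "nind":
                    nind = int(value)
                continue
            tokens = line.split()
            codes = [t for t in tokens if t.lower() in _CODE_TO_INT]
            if len(codes) == len(tokens) and current is not None:
                tokens_by_marker[current].extend(t.lower() for t in tokens)
            else:
                current = tokens[0]
                tokens_by_marker[current] = [
                    t.lower() for t in tokens[1:] if t.lower() in _CODE_TO_INT
                ]
    if nind is None:
        raise GenotypeParseError(f"{path}: missing 'nind =' header")
    marker_ids = list(tokens_by_marker)
    rows = []
    for m in marker_ids:
        codes = tokens_by_marker[m]
        if len(codes) != nind:
            raise GenotypeParseError(f"marker {m}: {len(codes)} calls, expected {nind}")
        rows.append([_CODE_TO_INT[c] for c in codes])
    individual_ids = [f"I{i + 1:03d}" for i in range(nind)]
    return F2GenotypeTable(marker_ids, individual_ids, np.array(rows, dtype=np.int8))


def filter_missing(
    table: F2GenotypeTable, max_missing: float = 0.2
) -> tuple[F2GenotypeTable, list[str]]:
    """Drop markers whose missing rate exceeds ``max_missing``."""
    miss = np.mean(table.codes == 3, axis=1)
    keep = miss <= max_missing
    dropped = [m for m, k in zip(table.marker_ids, keep) if not k]
    kept = F2GenotypeTable(
        [m for m, k in zip(table.marker_ids, keep) if k],
        table.individual_ids,
        table.codes[keep],
    )
    return kept, dropped


def segregation_chi2(row: np.ndarray, min_calls: int = 20):
    """Chi-square test of the observed (a, h, b) counts against 1:2:1.

    Returns ``(chi2, df, p)`` or ``None`` when fewer than ``min_calls``
    genotypes are available (flagged, not tested).
    """
    row = np.asarray(row)
    counts = np.array([(row == g).sum() for g in (0, 1, 2)], dtype=float)
    n = counts.sum()
    if n < min_calls:
        return None
    expected = n * np.array([0.25, 0.5, 0.25])
    chi2, p = stats.chisquare(counts, expected)
    return float(chi2), 2, float(p)


# --- two-point linkage -------------------------------------------------------

def _pair_counts(xi: np.ndarray, xj: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts (flattened, a/h/b x a/h/b) over informative
    individuals."""
    mask = (xi < 3) & (xj < 3)
    idx = 3 * xi[mask].astype(np.int64) + xj[mask]
    return np.bincount(idx, minlength=9)


def _class_probs(r: float) -> np.ndarray:
    """F2 joint genotype probabilities for recombination fraction r.

    Order aa, ah, ab, ha, hh, hb, ba, bh, bb.  Each parent transmits a
    recombinant gamete with probability r; the double heterozygote pools
    the 0-recombinant (coupling) and 2-recombinant (repulsion) gamete
    combinations.
    """
    p, q = 1.0 - r, r
    return np.array([
        p * p / 4, p * q / 2, q * q / 4,
        p * q / 2, (p * p + q * q) / 2, p * q / 2,
        q * q / 4, p * q / 2, p * p / 4,
    ])


def _loglik(counts: np.ndarray, r: float) -> float:
    probs = _class_probs(r)
    ll = 0.0
    for c, pr in zip(counts, probs):
        if c:
            if pr <= 0.0:
                return -math.inf
            ll += c * math.log(pr)
    return ll


def two_point_rf(
    xi: np.ndarray,
    xj: np.ndarray,
    marker_i: str = "i",
    marker_j: str = "j",
    min_informative: int = 10,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PairwiseLinkage:
    """Maximum-likelihood recombination fraction for a codominant F2 pair.

    EM over the nine joint genotype classes: classes with unambiguous
    recombinant-gamete counts contribute them directly; the double
    heterozygote distributes its two gametes between 0 and 2 recombinants
    with weights (1-r)^2 and r^2.  LOD compares the maximized likelihood
    with independence (r = 0.5).  Pairs with fewer than
    ``min_informative`` joint calls are flagged with lod 0.
    """
    counts = _pair_counts(np.asarray(xi), np.asarray(xj))
    n = int(counts.sum())
    if n < min_informative:
        return PairwiseLinkage(marker_i, marker_j, 0.5, 0.0, n)
    # recombinant gametes per class (aa ah ab ha hh hb ba bh bb); hh handled in EM
    fixed = float(counts @ np.array([0, 1, 2, 1, 0, 1, 2, 1, 0]))
    n_hh = counts[4]
    r = 0.25
    for _ in range(max_iter):
        w = r * r / ((1 - r) ** 2 + r * r) if (1 - r) ** 2 + r * r > 0 else 0.0
        r_new = (fixed + 2.0 * n_hh * w) / (2.0 * n)
        if abs(r_new - r) < tol:
            r = r_new
            break
        r = r_new
    r = min(max(r, 0.0), 0.5)
    lod = (_loglik(counts, r) - _loglik(counts, 0.5)) / _LN10
    return PairwiseLinkage(marker_i, marker_j, float(r), max(float(lod), 0.0), n)


def grid_search_rf(xi: np.ndarray, xj: np.ndarray, step: float = 1e-4) -> float:
    """Brute-force MLE of r over a grid; validation oracle for the EM."""
    counts = _pair_counts(np.asarray(xi), np.asarray(xj))
    grid = np.arange(0.0, 0.5 + step / 2, step)
    probs = np.stack([_class_probs(r) for r in grid])  # (G, 9)
    with np.errstate(divide="ignore"):
        logp = np.where(probs > 0, np.log(probs), -np.inf)
    observed = counts > 0
    ll = logp[:, observed] @ counts[observed]
    return float(grid[int(np.argmax(ll))])


def pairwise_linkage(table: F2GenotypeTable, **kwargs) -> dict[tuple[str, str], PairwiseLinkage]:
    """Two-point linkage for every marker pair (keys sorted id pairs)."""
    out = {}
    ids = table.marker_ids
    for i, j in itertools.combinations(range(len(ids)), 2):
        a, b = sorted((ids[i], ids[j]))
        if a == ids[j]:
            i, j = j, i
        out[(a, b)] = two_point_rf(table.codes[i], table.codes[j], a, b, **kwargs)
    return out


def get_linkage(pairs, i: str, j: str) -> Optional[PairwiseLinkage]:
    return pairs.get((i, j) if i < j else (j, i))


# --- grouping ----------------------------------------------------------------

def group_markers(
    pairs: Mapping[tuple[str, str], PairwiseLinkage],
    marker_ids: Sequence[str],
    lod_min: float = 4.0,
    r_max: float = 0.4,
) -> list[list[str]]:
    """Connected components of the linkage graph at one LOD threshold.

    Edges connect pairs with lod >= lod_min and r_hat <= r_max.  Groups
    are sorted by size (descending) then by their first marker id; markers
    within a group are in id order (ordering happens later).
    """
    g = nx.Graph()
    g.add_nodes_from(marker_ids)
    for (a, b), pl in pairs.items():
        if pl.lod >= lod_min and pl.r_hat <= r_max:
            g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def grouping_stability(
    pairs, marker_ids, lod_range: tuple[float, float] = (3.0, 10.0), r_max: float = 0.4
) -> dict[float, list[list[str]]]:
    """Partitions at each integer LOD threshold across the scan range."""
    lo, hi = lod_range
    return {
        float(t): group_markers(pairs, marker_ids, lod_min=float(t), r_max=r_max)
        for t in range(int(math.ceil(lo)), int(math.floor(hi)) + 1)
    }


# --- mapping functions -------------------------------------------------------

def kosambi_cM(r: float) -> float:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) cM, for 0 <= r < 0.5."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1 + 2 * r) / (1 - 2 * r))


def kosambi_inverse(d_cM: float) -> float:
    """Inverse Kosambi: r = (e^{4d/100} - 1) / (2 (e^{4d/100} + 1))."""
    if d_cM < 0:
        raise ValueError("negative map distance")
    e = math.exp(4.0 * d_cM / 100.0)
    return 0.5 * (e - 1) / (e + 1)


def haldane_cM(r: float) -> float:
    """Haldane map distance d = -50 ln(1-2r) cM (no interference)."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return -50.0 * math.log(1 - 2 * r)


def haldane_inverse(d_cM: float) -> float:
    if d_cM < 0:
        raise ValueError("negative map distance")
    return 0.5 * (1 - math.exp(-2.0 * d_cM / 100.0))


_MAPFN = {"kosambi": kosambi_cM, "haldane": haldane_cM}


# --- ordering and spacing ----------------------------------------------------

_R_CAP = 0.4999  # keeps map distances finite for unlinked-looking pairs


def _distance_weight_matrices(group, pairs, map_function="kosambi"):
    fn = _MAPFN[map_function]
    k = len(group)
    D = np.zeros((k, k))
    W = np.zeros((k, k))
    for a, b in itertools.combinations(range(k), 2):
        pl = get_linkage(pairs, group[a], group[b])
        r = min(pl.r_hat, _R_CAP) if pl is not None else _R_CAP
        lod = pl.lod if pl is not None else 0.0
        D[a, b] = D[b, a] = fn(r)
        W[a, b] = W[b, a] = lod * lod
    return D, W


def _stress(order: Sequence[int], D: np.ndarray, W: np.ndarray) -> float:
    """LOD^2-weighted squared error between path distances along the order
    and pairwise map distances."""
    order = np.asarray(order)
    adj = D[order[:-1], order[1:]]
    pos = np.concatenate([[0.0], np.cumsum(adj)])
    diff = np.abs(pos[:, None] - pos[None, :]) - D[np.ix_(order, order)]
    w = W[np.ix_(order, order)]
    return float(np.sum(np.triu(w * diff * diff, k=1)))


def order_group(
    group: Sequence[str],
    pairs: Mapping,
    seed: int = 0,
    map_function: str = "kosambi",
) -> list[str]:
    """Order markers in a group by weighted least-squares seriation.

    Starts from the highest-LOD pair, greedily inserts each remaining
    marker (taken by decreasing best LOD to the placed set, marker id as
    tie-break) at its stress-minimizing position, then polishes with 2-opt
    segment reversals until no improvement.  Deterministic; the returned
    orientation places the lexicographically smaller endpoint first.
    """
    group = sorted(group)
    if len(group) < 2:
        return list(group)
    if len(group) == 2:
        return group
    D, W = _distance_weight_matrices(group, pairs, map_function)
    if not _connected(W):
        raise ValueError("group is not linkage-connected; re-run grouping")
    k = len(group)
    # seed pair: maximum weight (= LOD^2), ties by marker ids
    best = max(
        itertools.combinations(range(k), 2),
        key=lambda ab: (W[ab], -ab[0], -ab[1]),
    )
    order = [best[0], best[1]]
    placed = set(order)
    while len(order) < k:
        remaining = [i for i in range(k) if i not in placed]
        nxt = max(remaining, key=lambda i: (max(W[i, j] for j in placed), -i))
        best_pos, best_val = 0, math.inf
        for pos in range(len(order) + 1):
            trial = order[:pos] + [nxt] + order[pos:]
            val = _stress(trial, D, W)
            if val < best_val - 1e-12:
                best_val, best_pos = val, pos
        order.insert(best_pos, nxt)
        placed.add(nxt)
    order = _two_opt(order, D, W)
    if order[0] > order[-1]:
        order = order[::-1]
    return [group[i] for i in order]


def _two_opt(order, D, W, max_rounds: int = 50):
    order = list(order)
    current = _stress(order, D, W)
    for _ in range(max_rounds):
        improved = False
        k = len(order)
        for i in range(k - 1):
            for j in range(i + 2, k + 1):
                trial = order[:i] + order[i:j][::-1] + order[j:]
                val = _stress(trial, D, W)
                if val < current - 1e-12:
                    order, current = trial, val
                    improved = True
        if not improved:
            break
    return order


def _connected(W: np.ndarray) -> bool:
    g = nx.from_numpy_array((W > 0).astype(int))
    return nx.is_connected(g)


def exhaustive_order(group: Sequence[str], pairs, map_function: str = "kosambi") -> list[str]:
    """Global stress minimum by full permutation search (small groups only)."""
    group = sorted(group)
    if len(group) > 9:
        raise ValueError("exhaustive search limited to groups of <= 9 markers")
    D, W = _distance_weight_matrices(group, pairs, map_function)
    k = len(group)
    best_order, best_val = None, math.inf
    for perm in itertools.permutations(range(k)):
        if perm[0] > perm[-1]:
            continue  # orientation symmetry
        val = _stress(perm, D, W)
        if val < best_val - 1e-12:
            best_val, best_order = val, perm
    return [group[i] for i in best_order]


def fit_positions(
    ordered: Sequence[str],
    pairs: Mapping,
    map_function: str = "kosambi",
    window: Optional[int] = 2,
) -> np.ndarray:
    """Weighted nonnegative least-squares interval lengths along an order.

    Solves min sum w_ij (sum of intervals between i and j - D_ij)^2 over
    pairs with positive LOD at most ``window`` adjacency steps apart,
    intervals >= 0, and returns cumulative positions starting at 0.  The
    local window keeps spacing on the near-additive part of the mapping
    function, where two-point estimates are precise; ``window=None`` uses
    every linked pair.  Falls back to adjacent-pair map distances if the
    system is degenerate.
    """
    k = len(ordered)
    if k < 2:
        return np.zeros(k)
    D, W = _distance_weight_matrices(list(ordered), pairs, map_function)
    rows, targets, weights = [], [], []
    for a, b in itertools.combinations(range(k), 2):
        if W[a, b] <= 0 or (window is not None and b - a > window):
            continue
        row = np.zeros(k - 1)
        row[a:b] = 1.0
        rows.append(row)
        targets.append(D[a, b])
        weights.append(math.sqrt(W[a, b]))
    adjacent = np.array([D[i, i + 1] for i in range(k - 1)])
    if not rows:
        log.warning("no informative pairs in ordered group; using adjacent distances")
        return np.concatenate([[0.0], np.cumsum(adjacent)])
    A = np.asarray(rows) * np.asarray(weights)[:, None]
    y = np.asarray(targets) * np.asarray(weights)
    try:
        intervals, _ = optimize.nnls(A, y)
    except Exception:
        log.warning("NNLS failed; falling back to adjacent-pair distances")
        intervals = adjacent
    return np.concatenate([[0.0], np.cumsum(intervals)])


def build_map(
    table: F2GenotypeTable,
    max_missing: float = 0.2,
    lod_min: float = 4.0,
    lod_range: tuple[float, float] = (3.0, 10.0),
    r_max: float = 0.4,
    seed: int = 0,
    map_function: str = "kosambi",
):
    """Full pipeline: filter -> pairwise -> group -> order -> positions.

    Returns ``(groups, pairs, dropped_markers, stability)`` where groups
    is a list of :class:`LinkageGroupResult` (singletons excluded, as
    unplaced markers).
    """
    kept, dropped = filter_missing(table, max_missing)
    pairs = pairwise_linkage(kept)
    raw_groups = group_markers(pairs, kept.marker_ids, lod_min, r_max)
    stability = grouping_stability(pairs, kept.marker_ids, lod_range, r_max)
    results = []
    lg = 0
    for comp in raw_groups:
        if len(comp) < 2:
            continue
        lg += 1
        ordered = order_group(comp, pairs, seed=seed, map_function=map_function)
        positions = fit_positions(ordered, pairs, map_function=map_function)
        results.append(LinkageGroupResult(f"LG{lg}", ordered, positions))
    return results, pairs, dropped, stability


# --- summaries ---------------------------------------------------------------

def summary_from_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-group map summary plus totals from (marker_no, genetic, physical).

    Input columns: lg_id, chrom, marker_no, genetic_cM, physical_Mb.
    Adds marker density (cM/marker) and recombination rate (cM/Mb); the
    totals row uses summed columns (total density = total length / total
    markers).  Full precision retained; round for display with
    :func:`round_summary`.
    """
    df = rows.copy()
    df["marker_density_cM"] = df["genetic_cM"] / df["marker_no"]
    df["recomb_rate_cM_per_Mb"] = df["genetic_cM"] / df["physical_Mb"]
    total = pd.DataFrame([{
        "lg_id": "Total",
        "chrom": "",
        "marker_no": df["marker_no"].sum(),
        "genetic_cM": df["genetic_cM"].sum(),
        "physical_Mb": df["physical_Mb"].sum(),
        "marker_density_cM": df["genetic_cM"].sum() / df["marker_no"].sum(),
        "recomb_rate_cM_per_Mb": df["genetic_cM"].sum() / df["physical_Mb"].sum(),
    }])
    out = pd.concat([df, total], ignore_index=True)
    return out[["lg_id", "chrom", "marker_no", "genetic_cM", "marker_density_cM",
                "physical_Mb", "recomb_rate_cM_per_Mb"]]


def round_summary(summary: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    out = summary.copy()
    for col in ("genetic_cM", "marker_density_cM", "physical_Mb", "recomb_rate_cM_per_Mb"):
        out[col] = out[col].round(decimals)
    return out


def summarize_map(
    groups: Sequence[LinkageGroupResult],
    physical_positions: Mapping[str, tuple[str, int]],
) -> pd.DataFrame:
    """Table-style summary of a built map given marker physical positions."""
    rows = []
    for g in groups:
        chroms = [physical_positions[m][0] for m in g.marker_ids if m in physical_positions]
        bps = [physical_positions[m][1] for m in g.marker_ids if m in physical_positions]
        chrom = max(sorted(set(chroms)), key=chroms.count) if chroms else None
        span_mb = (max(bps) - min(bps)) / 1e6 if len(bps) >= 2 else float("nan")
        rows.append({
            "lg_id": g.lg_id, "chrom": chrom or "NA",
            "marker_no": len(g.marker_ids),
            "genetic_cM": g.length_cM, "physical_Mb": span_mb,
        })
    return summary_from_rows(pd.DataFrame(rows))


def compare_physical(
    groups: Sequence[LinkageGroupResult],
    physical_positions: Mapping[str, tuple[str, int]],
) -> pd.DataFrame:
    """Collinearity of genetic vs physical order per linkage group.

    Assigns each group the chromosome holding most of its markers, flips
    the group orientation if the Spearman correlation between cM and bp is
    negative, and reports |rho|.
    """
    rows = []
    for g in groups:
        info = [(m, p) for m, p in zip(g.marker_ids, g.positions_cM)
                if m in physical_positions]
        chroms = [physical_positions[m][0] for m, _ in info]
        if not chroms:
            rows.append({"lg_id": g.lg_id, "chrom": "NA", "n_markers": 0,
                         "abs_spearman_rho": float("nan"), "flipped": False})
            continue
        chrom = max(sorted(set(chroms)), key=chroms.count)
        on = [(m, p) for m, p in info if physical_positions[m][0] == chrom]
        cm = np.array([p for _, p in on])
        bp = np.array([physical_positions[m][1] for m, _ in on])
        if len(on) >= 2 and np.ptp(cm) > 0 and np.ptp(bp) > 0:
            rho = stats.spearmanr(cm, bp).statistic
        else:
            rho = float("nan")
        flipped = bool(rho < 0) if not math.isnan(rho) else False
        if flipped:
            g.marker_ids = g.marker_ids[::-1]
            g.positions_cM = g.positions_cM[-1] - g.positions_cM[::-1]
        g.chrom = chrom
        rows.append({"lg_id": g.lg_id, "chrom": chrom, "n_markers": len(on),
                     "abs_spearman_rho": abs(rho) if not math.isnan(rho) else rho,
                     "flipped": flipped})
    return pd.DataFrame(rows, columns=["lg_id", "chrom", "n_markers",
                                       "abs_spearman_rho", "flipped"])


def map_table(groups: Sequence[LinkageGroupResult],
              physical_positions: Optional[Mapping[str, tuple[str, int]]] = None
              ) -> pd.DataFrame:
    rows = []
    for g in groups:
        for m, p in zip(g.marker_ids, g.positions_cM):
            chrom, bp = (physical_positions.get(m, ("NA", -1))
                         if physical_positions else ("NA", -1))
            rows.append({"lg_id": g.lg_id, "marker_id": m, "position_cM": float(p),
                         "chrom": chrom, "bp": bp})
    return pd.DataFrame(rows, columns=["lg_id", "marker_id", "position_cM", "chrom", "bp"])


def write_map_svg(groups: Sequence[LinkageGroupResult], path) -> None:
    """Minimal map drawing: one vertical bar per linkage group with marker
    ticks at their cM positions (cosmetic export only)."""
    x_step, scale, top = 90, 2.0, 30
    height = top + 20 + scale * max((g.length_cM for g in groups), default=0.0)
    width = x_step * (len(groups) + 1)
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
             f'height="{height + 40:.0f}">']
    for i, g in enumerate(groups):
        x = x_step * (i + 1)
        parts.append(f'<text x="{x}" y="{top - 12}" text-anchor="middle" '
                     f'font-size="11">{g.lg_id}</text>')
        parts.append(f'<line x1="{x}" y1="{top}" x2="{x}" '
                     f'y2="{top + scale * g.length_cM:.1f}" stroke="black"/>')
        for m, p in zip(g.marker_ids, g.positions_cM):
            y = top + scale * p
            parts.append(f'<line x1="{x - 5}" y1="{y:.1f}" x2="{x + 5}" y2="{y:.1f}" '
                         f'stroke="black"/>')
            parts.append(f'<text x="{x + 8}" y="{y + 3:.1f}" font-size="7">{m}</text>')
    parts.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(parts) + "\n")
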