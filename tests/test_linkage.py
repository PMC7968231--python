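"""Linkage mapper: two-point EM, grouping, ordering, Kosambi, summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from indelkit import linkage
from indelkit.linkage import (
    F2GenotypeTable,
    PairwiseLinkage,
    build_map,
    compare_physical,
    exhaustive_order,
    filter_missing,
    fit_positions,
    grid_search_rf,
    group_markers,
    grouping_stability,
    haldane_cM,
    haldane_inverse,
    kosambi_cM,
    kosambi_inverse,
    order_group,
    pairwise_linkage,
    read_genotype_table,
    segregation_chi2,
    summarize_map,
    summary_from_rows,
    round_summary,
    two_point_rf,
)
from indelkit.published import (
    FUNNEL_PUBLISHED,
    MAP_SUMMARY_PUBLISHED,
    MAP_TOTALS_PUBLISHED,
    map_summary_rows,
)


def simulate_pair(r, n, rng, missing=0.0):
    """Joint F2 genotypes at two loci with recombination fraction r."""
    g1 = (rng.random((n, 2)) < 0.5).astype(int)  # locus-1 gamete origins
    flip = rng.random((n, 2)) < r
    g2 = g1 ^ flip
    x, y = g1.sum(1), g2.sum(1)
    if missing:
        x[rng.random(n) < missing] = 3
        y[rng.random(n) < missing] = 3
    return x.astype(np.int8), y.astype(np.int8)


class TestReadTable:
    def test_tsv_roundtrip_and_bad_code(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("marker_id\tI1\tI2\tI3\tI4\nm1\ta\th\tb\tu\nm2\t-\ta\ta\tb\n")
        t = read_genotype_table(p)
        assert t.marker_ids == ["m1", "m2"] and t.n_individuals == 4
        assert t.codes.tolist() == [[0, 1, 2, 3], [3, 0, 0, 2]]
        bad = tmp_path / "bad.tsv"
        bad.write_text("marker_id\tI1\nm1\tx\n")
        with pytest.raises(linkage.GenotypeParseError, match="row 2"):
            read_genotype_table(bad)

    def test_loc_dialect_equivalent(self, tmp_path):
        loc = tmp_path / "pop.loc"
        loc.write_text(
            "name = toy\npopt = F2\nnloc = 2\nnind = 4\n"
            "m1\ta h b u\nm2\n- a a b\n"
        )
        t = read_genotype_table(loc)
        assert t.marker_ids == ["m1", "m2"]
        assert t.codes.tolist() == [[0, 1, 2, 3], [3, 0, 0, 2]]


class TestFilterMissing:
    def test_threshold(self):
        codes = np.zeros((2, 113), dtype=np.int8)
        codes[1, :30] = 3  # 30/113 ~ 0.265 missing
        t = F2GenotypeTable(["ok", "gappy"], [f"I{i}" for i in range(113)], codes)
        kept, dropped = filter_missing(t, 0.2)
        assert kept.marker_ids == ["ok"] and dropped == ["gappy"]
        kept_all, dropped_none = filter_missing(t, 1.0)
        assert dropped_none == [] and kept_all.n_markers == 2

    def test_constructed_missing_rates_recovered(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=(6, 113)).astype(np.int8)
        for k in (1, 4):
            codes[k, :29] = 3  # > 20%
        t = F2GenotypeTable([f"m{k}" for k in range(6)],
                            [f"I{i}" for i in range(113)], codes)
        _, dropped = filter_missing(t, 0.2)
        assert dropped == ["m1", "m4"]


class TestSegregation:
    def test_exact_expectation(self):
        row = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=np.int8)
        chi2, df, p = segregation_chi2(row)
        assert chi2 == 0.0 and df == 2 and p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        row = np.array([0] * 40 + [1] * 40 + [2] * 20, dtype=np.int8)
        chi2, _, _ = segregation_chi2(row)
        assert chi2 == pytest.approx(12.0)  # 15^2/25 + 10^2/50 + 5^2/25

    def test_too_few_calls_flagged(self):
        assert segregation_chi2(np.array([0, 1, 2] * 5, dtype=np.int8)) is None

    def test_rejection_rate_under_null(self):
        rng = np.random.default_rng(1)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            row = rng.choice([0, 1, 2], size=113, p=[0.25, 0.5, 0.25]).astype(np.int8)
            _, _, p = segregation_chi2(row)
            rejections += p < 0.01
        assert rejections / reps == pytest.approx(0.01, abs=0.01)


class TestTwoPoint:
    def test_perfect_cosegregation(self):
        row = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2, 1, 0] * 5, dtype=np.int8)
        pl = two_point_rf(row, row)
        assert pl.r_hat == pytest.approx(0.0, abs=1e-6) and pl.lod > 3

    def test_independent_markers(self):
        rng = np.random.default_rng(2)
        x, y = simulate_pair(0.5, 500, rng)
        pl = two_point_rf(x, y)
        assert abs(pl.r_hat - 0.5) < 0.05 and pl.lod < 2

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = simulate_pair(0.2, 113, rng, missing=0.05)
        a, b = two_point_rf(x, y), two_point_rf(y, x)
        assert a.r_hat == b.r_hat and a.lod == b.lod

    def test_insufficient_data_flagged(self):
        x = np.full(113, 3, dtype=np.int8)
        x[:5] = 0
        pl = two_point_rf(x, x)
        assert pl.lod == 0.0 and pl.n_informative == 5

    def test_em_matches_grid_search_mle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            r = float(rng.uniform(0.0, 0.5))
            n = int(rng.integers(30, 200))
            x, y = simulate_pair(r, n, rng, missing=float(rng.uniform(0, 0.15)))
            em = two_point_rf(x, y).r_hat
            grid = grid_search_rf(x, y)
            assert abs(em - grid) < 1e-3


def _pl(i, j, lod, r=0.1):
    return PairwiseLinkage(*sorted((i, j)), r_hat=r, lod=lod, n_informative=100)


def _pairs(*pls):
    return {(p.marker_i, p.marker_j): p for p in pls}


class TestGrouping:
    def test_separate_clusters(self):
        pairs = _pairs(_pl("A", "B", 10), _pl("C", "D", 10))
        for t in (3.0, 6.0, 9.0):
            groups = group_markers(pairs, "ABCD", lod_min=t)
            assert sorted(map(tuple, groups)) == [("A", "B"), ("C", "D")]

    def test_chain_splits_at_higher_threshold(self):
        pairs = _pairs(_pl("A", "B", 10), _pl("B", "C", 5))
        assert group_markers(pairs, "ABC", lod_min=4) == [["A", "B", "C"]]
        assert group_markers(pairs, "ABC", lod_min=6) == [["A", "B"], ["C"]]

    def test_r_max_gate(self):
        pairs = _pairs(_pl("A", "B", 10, r=0.45))
        assert group_markers(pairs, "AB", lod_min=3) == [["A"], ["B"]]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        ids = [f"m{i}" for i in range(12)]
        pairs = _pairs(*(
            _pl(a, b, float(rng.uniform(0, 12)), r=float(rng.uniform(0, 0.4)))
            for a, b in itertools.combinations(ids, 2)))
        stab = grouping_stability(pairs, ids, (3.0, 10.0))
        sizes = [len(stab[t]) for t in sorted(stab)]
        assert sizes == sorted(sizes)  # raising LOD never merges groups


class TestMappingFunctions:
    def test_closed_forms(self):
        assert kosambi_cM(0.0) == 0.0
        assert kosambi_cM(0.25) == pytest.approx(25 * math.log(3))
        assert haldane_cM(0.0) == 0.0
        assert haldane_cM(0.25) == pytest.approx(-50 * math.log(0.5))

    @pytest.mark.parametrize("r", np.arange(0.01, 0.50, 0.02).tolist())
    def test_roundtrip(self, r):
        assert kosambi_inverse(kosambi_cM(r)) == pytest.approx(r, abs=1e-10)
        assert haldane_inverse(haldane_cM(r)) == pytest.approx(r, abs=1e-10)

    def test_domain_errors(self):
        for fn in (kosambi_cM, haldane_cM):
            with pytest.raises(ValueError):
                fn(0.5)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)


def _simulated_chromosome(rng, n_markers=6, n=113, spacing_cM=10.0):
    """Markers along one chromosome; returns (table, true order)."""
    ids = [f"m{i:02d}" for i in range(n_markers)]
    r_adj = haldane_inverse(spacing_cM)
    codes = np.zeros((n_markers, n), dtype=np.int8)
    g = (rng.random((n, 2)) < 0.5).astype(int)
    codes[0] = g.sum(1)
    for k in range(1, n_markers):
        g = g ^ (rng.random((n, 2)) < r_adj)
        codes[k] = g.sum(1)
    perm = rng.permutation(n_markers)
    return (F2GenotypeTable([ids[i] for i in perm], [f"I{j}" for j in range(n)],
                            codes[perm]), ids)


class TestOrdering:
    def test_three_markers(self):
        rng = np.random.default_rng(6)
        table, true_ids = _simulated_chromosome(rng, n_markers=3)
        pairs = pairwise_linkage(table)
        got = order_group(table.marker_ids, pairs)
        assert got in (true_ids, true_ids[::-1])

    @pytest.mark.parametrize("n_markers", [5, 6, 7])
    def test_matches_exhaustive_optimum(self, n_markers):
        rng = np.random.default_rng(n_markers)
        table, _ = _simulated_chromosome(rng, n_markers=n_markers)
        pairs = pairwise_linkage(table)
        greedy = order_group(table.marker_ids, pairs)
        exact = exhaustive_order(table.marker_ids, pairs)
        D, W = linkage._distance_weight_matrices(sorted(table.marker_ids), pairs)
        idx = {m: i for i, m in enumerate(sorted(table.marker_ids))}
        s_greedy = linkage._stress([idx[m] for m in greedy], D, W)
        s_exact = linkage._stress([idx[m] for m in exact], D, W)
        assert s_greedy <= s_exact + 1e-9

    def test_length_invariant_under_reversal(self):
        rng = np.random.default_rng(9)
        table, _ = _simulated_chromosome(rng, n_markers=6)
        pairs = pairwise_linkage(table)
        order = order_group(table.marker_ids, pairs)
        fwd = fit_positions(order, pairs)
        rev = fit_positions(order[::-1], pairs)
        assert fwd[-1] == pytest.approx(rev[-1], rel=1e-9)


class TestFitPositions:
    def test_two_markers(self):
        pairs = _pairs(_pl("A", "B", 8, r=0.2))
        pos = fit_positions(["A", "B"], pairs)
        assert pos[1] == pytest.approx(kosambi_cM(0.2))

    def test_additive_input_recovered(self):
        # exact pairwise distances from a known additive map
        truth = [0.0, 7.0, 18.0, 26.0]
        ids = ["a", "b", "c", "d"]
        pls = []
        for (i, mi), (j, mj) in itertools.combinations(enumerate(ids), 2):
            r = kosambi_inverse(truth[j] - truth[i])
            pls.append(_pl(mi, mj, 10, r=r))
        pos = fit_positions(ids, _pairs(*pls))
        assert np.allclose(pos, truth, atol=1e-6)

    def test_no_worse_than_adjacent_only(self):
        rng = np.random.default_rng(10)
        table, _ = _simulated_chromosome(rng, n_markers=6)
        pairs = pairwise_linkage(table)
        order = order_group(table.marker_ids, pairs)
        D, W = linkage._distance_weight_matrices(order, pairs)
        window = 2
        pos = fit_positions(order, pairs, window=window)
        adj = np.concatenate([[0.0], np.cumsum([D[i, i + 1] for i in range(len(order) - 1)])])

        def objective(p):
            total = 0.0
            for a, b in itertools.combinations(range(len(order)), 2):
                if W[a, b] > 0 and b - a <= window:
                    total += W[a, b] * (p[b] - p[a] - D[a, b]) ** 2
            return total

        assert objective(pos) <= objective(adj) + 1e-9

    def test_parameter_recovery_on_simulated_cross(self):
        """Kosambi-reported total length within 15% of truth and mean
        per-interval error within 5 cM at n = 113 (crossovers simulated
        without interference, so Kosambi reporting is conservative)."""
        rng = np.random.default_rng(20)
        n_markers, spacing = 10, 8.0
        table, true_ids = _simulated_chromosome(rng, n_markers, 113, spacing)
        pairs = pairwise_linkage(table)
        order = order_group(table.marker_ids, pairs)
        if order[0] != true_ids[0]:
            order = order[::-1]
        pos = fit_positions(order, pairs)
        true_len = spacing * (n_markers - 1)
        assert abs(pos[-1] - true_len) / true_len < 0.15
        intervals = np.diff(pos)
        assert np.mean(np.abs(intervals - spacing)) < 5.0


class TestSummaries:
    def test_published_totals_row(self):
        s = round_summary(summary_from_rows(map_summary_rows()))
        total = s[s.lg_id == "Total"].iloc[0]
        n, cm, dens, mb, rate = MAP_TOTALS_PUBLISHED
        assert total.marker_no == n
        assert total.genetic_cM == cm
        assert total.marker_density_cM == dens
        assert total.physical_Mb == mb
        assert total.recomb_rate_cM_per_Mb == rate

    def test_published_reconciling_cells(self):
        s = round_summary(summary_from_rows(map_summary_rows())).set_index("lg_id")
        assert s.loc["LG8", "marker_density_cM"] == 8.10
        assert s.loc["LG8", "recomb_rate_cM_per_Mb"] == 8.00
        assert s.loc["LG12", "recomb_rate_cM_per_Mb"] == 7.22

    def test_toy_recombination_rate(self):
        rows = pd.DataFrame([{"lg_id": "LG1", "chrom": "c1", "marker_no": 2,
                              "genetic_cM": 10.0, "physical_Mb": 2.0}])
        s = round_summary(summary_from_rows(rows))
        assert s.iloc[0].recomb_rate_cM_per_Mb == 5.00

    def test_ratio_consistency_of_published_rows(self):
        # printed density/rate cells agree with marker_no/genetic/physical
        # arithmetic for all rows except the two known rounding artefacts
        s = round_summary(summary_from_rows(map_summary_rows())).set_index("lg_id")
        mismatches = []
        for lg, _, n, cm, dens, mb, rate in MAP_SUMMARY_PUBLISHED:
            if s.loc[lg, "marker_density_cM"] != dens:
                mismatches.append((lg, "density"))
            if s.loc[lg, "recomb_rate_cM_per_Mb"] != rate:
                mismatches.append((lg, "rate"))
        assert set(mismatches) <= {("LG1", "density"), ("LG9", "density")}


class TestComparePhysical:
    def _groups_and_positions(self, reverse=False):
        ids = [f"m{i}" for i in range(5)]
        pos = np.array([0.0, 5.0, 11.0, 18.0, 30.0])
        g = linkage.LinkageGroupResult("LG1", list(ids), pos.copy())
        bp = {m: ("MC01", 1000 * (i + 1)) for i, m in enumerate(ids)}
        if reverse:
            g.marker_ids = g.marker_ids[::-1]
            g.positions_cM = pos[-1] - pos[::-1]
        return [g], bp

    def test_collinear(self):
        groups, bp = self._groups_and_positions()
        rep = compare_physical(groups, bp)
        assert rep.iloc[0].abs_spearman_rho == pytest.approx(1.0)
        assert not rep.iloc[0].flipped and groups[0].chrom == "MC01"

    def test_reversed_group_is_flipped(self):
        groups, bp = self._groups_and_positions(reverse=True)
        rep = compare_physical(groups, bp)
        assert rep.iloc[0].flipped
        assert groups[0].marker_ids == [f"m{i}" for i in range(5)]
        assert rep.iloc[0].abs_spearman_rho == pytest.approx(1.0)


class TestBuildMapOnSimulation:
    def test_groups_match_chromosomes_and_collinearity(self, sim_bundle):
        b = sim_bundle
        groups, pairs, dropped, stability = build_map(b.f2)
        phys = b.truth.marker_physical_positions()
        rep = compare_physical(groups, phys)
        by_chrom = {}
        for g in groups:
            by_chrom.setdefault(g.chrom, []).append(g)
        # every chromosome is represented; splits allowed, no chimeras
        assert set(by_chrom) == set(b.genome)
        for g in groups:
            chroms = {phys[m][0] for m in g.marker_ids}
            assert chroms == {g.chrom}
        assert rep.abs_spearman_rho.mean() > 0.9

    def test_map_length_sane(self, sim_bundle):
        b = sim_bundle
        groups, *_ = build_map(b.f2)
        spacing = b.config.map_marker_spacing_cM
        for g in groups:
            true_len = spacing * (len(g.marker_ids) - 1)
            assert g.length_cM == pytest.approx(true_len, rel=0.5, abs=8.0)
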