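import math

import numpy as np
import pytest

import breathescan as bs
from breathescan.cmn import CMNetwork
from breathescan.fel import (find_basins, basin_free_energy, build_dendrogram,
                             cluster_macrostates, split_nonspecific,
                             free_energy_difference, macrostate_entropy,
                             promoter_report, Basin, Macrostate)


def net_from(weights, links):
    """Build a CMNetwork from {key: P} and undirected link pairs."""
    edges = {}
    for a, b in links:
        edges[(a, b)] = 1
        edges[(b, a)] = 1
    return CMNetwork(weights=dict(weights), edges=edges,
                     frame_total=max(1, len(weights)))


def oracle_partition(weights, links):
    """Exhaustive hill-climb, recomputed per node with no shared state."""
    adj = {k: set() for k in weights}
    for a, b in links:
        adj[a].add(b)
        adj[b].add(a)
    assign = {}
    for key in weights:
        cur = key
        while True:
            heavier = [n for n in adj[cur] if weights[n] > weights[cur]]
            if not heavier:
                break
            cur = sorted(heavier, key=lambda n: (-weights[n], n))[0]
        assign[key] = cur
    return assign


class TestFindBasins:
    def test_monotone_chain_single_basin(self):
        w = {(0,): 0.5, (1,): 0.3, (2,): 0.2}
        net = net_from(w, [((0,), (1,)), ((1,), (2,))])
        basins = find_basins(net)
        assert len(basins) == 1
        assert basins[0].attractor == (0,)
        assert basins[0].weight == pytest.approx(1.0)

    def test_isolated_node_own_basin(self):
        w = {(0,): 0.6, (1,): 0.4}
        net = net_from(w, [])
        basins = find_basins(net)
        assert len(basins) == 2

    def test_two_peaks(self):
        w = {(0,): 0.4, (1,): 0.05, (2,): 0.35, (3,): 0.2}
        net = net_from(w, [((0,), (1,)), ((1,), (2,)), ((2,), (3,))])
        basins = find_basins(net)
        assert {b.attractor for b in basins} == {(0,), (2,)}

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(2, 9))
        keys = [(i,) for i in range(n)]
        w = rng.random(n)
        if trial % 3 == 0:  # occasionally force ties
            w = np.round(w, 1) + 0.01
        weights = {k: float(v / w.sum()) for k, v in zip(keys, w)}
        links = [(keys[i], keys[j]) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.4]
        net = net_from(weights, links)
        basins = find_basins(net)
        got = {}
        for b in basins:
            for k in b.members:
                got[k] = b.attractor
        assert got == oracle_partition(weights, links)

    def test_partition_complete(self):
        rng = np.random.default_rng(99)
        keys = [(i,) for i in range(8)]
        weights = {k: float(v) for k, v in zip(keys, rng.dirichlet(np.ones(8)))}
        links = [(keys[i], keys[(i + 3) % 8]) for i in range(8)]
        basins = find_basins(net_from(weights, links))
        all_members = [k for b in basins for k in b.members]
        assert sorted(all_members) == sorted(keys)

    def test_stochastic_variant_valid_partition(self):
        w = {(0,): 0.4, (1,): 0.05, (2,): 0.35, (3,): 0.2}
        net = net_from(w, [((0,), (1,)), ((1,), (2,)), ((2,), (3,))])
        basins = find_basins(net, stochastic=True, seed=0)
        members = sorted(k for b in basins for k in b.members)
        assert members == sorted(w)


class TestBasinFreeEnergy:
    def test_values(self):
        F = basin_free_energy([0.5, 0.5 / math.e, 0.25])
        assert F[0] == 0.0
        assert F[1] == pytest.approx(1.0)
        assert F[2] == pytest.approx(math.log(2))

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            basin_free_energy([0.5, 0.0])


def basins_with(weights, attractors=None):
    out = []
    for i, w in enumerate(weights):
        key = (attractors[i],) if attractors else (i,)
        out.append(Basin(attractor=key, members=frozenset([key]), weight=w))
    return out


def ridge_landscape(depths, ridges):
    """Chain of single-node basins at the given free-energy depths,
    connected through light ridge nodes at the given ridge free energies.
    Returns (basins, net) with weights e^{-F} renormalized."""
    n = len(depths)
    keys = [(2 * i,) for i in range(n)]
    ridge_keys = [(2 * i + 1,) for i in range(n - 1)]
    raw = {k: math.exp(-f) for k, f in zip(keys, depths)}
    raw.update({k: math.exp(-f) for k, f in zip(ridge_keys, ridges)})
    total = sum(raw.values())
    weights = {k: v / total for k, v in raw.items()}
    links = []
    for i in range(n - 1):
        links.append((keys[i], ridge_keys[i]))
        links.append((ridge_keys[i], keys[i + 1]))
    return weights, links


class TestDendrogram:
    def test_single_basin_no_merges(self):
        b = basins_with([1.0])
        net = net_from({(0,): 1.0}, [])
        dend = build_dendrogram(b, net)
        assert dend.merges == []

    def test_two_linked_basins(self):
        # attractor-node F = {0, 1.2}: directly linked, one merge at 1.2
        w2 = math.exp(-1.2)
        total = 1 + w2
        b = basins_with([1 / total, w2 / total])
        net = net_from({(0,): 1 / total, (1,): w2 / total}, [((0,), (1,))])
        dend = build_dendrogram(b, net)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(1.2)

    def test_three_basins_in_line(self):
        ws = [1.0, math.exp(-0.4), math.exp(-2.0)]
        total = sum(ws)
        b = basins_with([w / total for w in ws])
        net = net_from({(i,): ws[i] / total for i in range(3)},
                       [((0,), (1,)), ((1,), (2,))])
        dend = build_dendrogram(b, net)
        barriers = [m[2] for m in dend.merges]
        assert barriers == pytest.approx([0.4, 2.0])

    def test_ridge_barriers(self):
        # two deep basins joined through a light ridge microstate
        weights, links = ridge_landscape([0.0, 0.5], [3.0])
        net = net_from(weights, links)
        basins = find_basins(net)
        dend = build_dendrogram(basins, net)
        assert len(dend.merges) == 1
        assert dend.merges[0][2] == pytest.approx(3.0)

    def test_barriers_nondecreasing(self):
        rng = np.random.default_rng(4)
        n = 10
        ws = rng.dirichlet(np.ones(n))
        weights = {(i,): float(ws[i]) for i in range(n)}
        links = [((i,), (j,)) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.3]
        net = net_from(weights, links)
        basins = find_basins(net)
        dend = build_dendrogram(basins, net)
        barriers = [m[2] for m in dend.merges]
        assert barriers == sorted(barriers)

    def test_newick_export(self):
        weights, links = ridge_landscape([0.0, 0.7], [2.0])
        net = net_from(weights, links)
        basins = find_basins(net)
        dend = build_dendrogram(basins, net)
        nwk = dend.to_newick()
        assert nwk.endswith(";") and "(" in nwk


class TestMacrostates:
    def _landscape(self, depths, ridges, cut):
        weights, links = ridge_landscape(depths, ridges)
        net = net_from(weights, links)
        basins = find_basins(net)
        dend = build_dendrogram(basins, net)
        return cluster_macrostates(dend, basins, barrier_cut=cut), basins

    def test_all_barriers_above_cut_keeps_basins(self):
        # ridges 2.5 and 3 over basins at 0, 0.3, 0.7: effective barriers
        # 2.2 and 2.3, all above 1 kBT
        macro, _ = self._landscape([0.0, 0.3, 0.7], [2.5, 3.0], cut=1.0)
        assert len(macro) == 3

    def test_all_barriers_below_cut_single_state(self):
        macro, _ = self._landscape([0.0, 0.3, 0.7], [2.5, 3.0], cut=5.0)
        assert len(macro) == 1
        assert macro[0].weight == pytest.approx(1.0)

    def test_four_basin_hand_clustering(self):
        # depths A=0, B=0.3, C=1.0, D=1.2; ridges A|B=2.0, B|C=3.0, C|D=1.6
        # effective barriers: A-B 2.0-0.3=1.7, B-C 3.0-1.0=2.0,
        # C-D 1.6-1.2=0.4 -> only C,D cluster at cut 1
        macro, basins = self._landscape([0.0, 0.3, 1.0, 1.2],
                                        [2.0, 3.0, 1.6], cut=1.0)
        parts = sorted(sorted(b.attractor[0] for b in m.basins) for m in macro)
        assert parts == [[0], [2], [4, 6]]

    def test_input_order_invariance(self):
        weights, links = ridge_landscape([0.0, 0.2, 1.5, 1.1], [1.8, 2.6, 1.4])
        net = net_from(weights, links)
        basins = find_basins(net)

        def partition(perm):
            b = [basins[i] for i in perm]
            dend = build_dendrogram(b, net)
            macro = cluster_macrostates(dend, b, barrier_cut=1.0)
            return sorted(sorted(x.attractor[0] for x in m.basins)
                          for m in macro)

        assert partition(range(len(basins))) == partition(
            list(reversed(range(len(basins)))))


class TestNonspecific:
    def test_zero_threshold(self):
        b = basins_with([0.7, 0.3])
        specific, p_ns = split_nonspecific(b, 0.0)
        assert p_ns == 0.0 and len(specific) == 2

    def test_threshold_above_max_errors(self):
        b = basins_with([0.7, 0.3])
        with pytest.raises(ValueError, match="unresolved|threshold"):
            split_nonspecific(b, 0.9)

    def test_hand_sum(self):
        b = basins_with([0.5, 0.3, 0.15, 0.05])
        specific, p_ns = split_nonspecific(b, 0.1)
        assert p_ns == pytest.approx(0.05)
        assert len(specific) == 3


class TestFreeEnergyDifference:
    def test_equal_occupancies_zero(self):
        assert free_energy_difference(0.3, 0.3) == 0.0

    def test_argC_row(self):
        assert free_energy_difference(0.220, 0.027) == pytest.approx(2.10, abs=0.05)

    def test_furA_row(self):
        assert free_energy_difference(0.449, 0.014) == pytest.approx(3.45, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            free_energy_difference(0.0, 0.1)
        with pytest.raises(ValueError):
            free_energy_difference(0.1, -0.2)


class TestEntropy:
    def test_single_basin_zero(self):
        assert macrostate_entropy([0.4]) == 0.0

    def test_equal_basins_ln_m(self):
        assert macrostate_entropy([0.1] * 5) == pytest.approx(math.log(5))

    def test_closed_form_two_basins(self):
        assert macrostate_entropy([0.9, 0.1]) == pytest.approx(0.3251, abs=1e-4)

    @pytest.mark.parametrize("m", [2, 4, 7])
    def test_bounds(self, m):
        rng = np.random.default_rng(m)
        w = rng.random(m) + 1e-3
        s = macrostate_entropy(w)
        assert 0 <= s <= math.log(m) + 1e-12


class TestReport:
    def _macro(self, weight, site, basins=1, label=None):
        bs_ = [Basin(attractor=(site, 0), members=frozenset([(site, 0)]),
                     weight=weight / basins) for _ in range(basins)]
        return Macrostate(basins=bs_, weight=weight,
                          entropy=macrostate_entropy([b.weight for b in bs_]),
                          particle_site=site, label=label)

    def test_rows_sorted_and_consistent(self):
        macro = [self._macro(0.2, 5, label=-50),
                 self._macro(0.45, 12, basins=2, label=-20)]
        rep = promoter_report(macro, p_ns=0.05, seq_id="toy")
        rows = rep.rows()
        assert [r["P"] for r in rows] == [0.45, 0.2]
        assert rows[0]["dF_kBT"] == pytest.approx(math.log(0.45 / 0.05), abs=1e-3)
        assert rows[1]["S"] == 0.0

    def test_empty_macrostates_ns_only(self):
        rep = promoter_report([], p_ns=0.3, seq_id="toy")
        assert rep.rows() == []
        assert "NS" in rep.to_tsv()

    def test_tss_annotation_window(self):
        rep = promoter_report(
            [self._macro(0.3, 4, label=-48)], p_ns=0.02,
            known_tss=[-50])
        assert rep.macrostates[0].tss_match == -50
        rep2 = promoter_report(
            [self._macro(0.3, 4, label=-70)], p_ns=0.02, known_tss=[-50])
        assert rep2.macrostates[0].tss_match is None

    def test_json_tsv_render(self):
        rep = promoter_report([self._macro(0.3, 4, label=-48)], p_ns=0.02,
                              seq_id="s")
        assert "dF_kBT" in rep.to_tsv()
        assert '"P_NS": 0.02' in rep.to_json()
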