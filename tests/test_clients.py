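import math

import numpy as np
import pytest

from conftest import make_pair, make_profile
from riboprox.clients import (
    call_clients,
    decile_threshold,
    filter_expression,
    filter_localization,
    identify_clients,
)


def profile_map(entries):
    """entries: (gene, sample, counts, total) -> keyed profile dict."""
    return {
        (g, s): make_profile(g, s, counts, total) for g, s, counts, total in entries
    }


class TestFilterExpression:
    def test_density_above_cutoff_passes(self):
        # 100 codons, 10 input reads, 1e6 total -> 0.1 reads/codon/million > 0.02
        pair = make_pair()
        counts = np.zeros(100)
        counts[::10] = 1
        profiles = profile_map([
            ("g1", pair.input_sample, counts, 1e6),
            ("g1", pair.pulldown_sample, counts, 1e6),
        ])
        assert filter_expression(profiles, [pair], half_width=50, cutoff=0.02) == {"g1"}

    def test_exact_cutoff_fails_strictly(self):
        # 100 codons, 2 input reads, 1e6 total -> exactly 0.02
        pair = make_pair()
        counts = np.zeros(100)
        counts[[0, 99]] = 1
        profiles = profile_map([
            ("g1", pair.input_sample, counts, 1e6),
            ("g1", pair.pulldown_sample, counts, 1e6),
        ])
        assert filter_expression(profiles, [pair], 50, 0.02) == set()

    def test_zero_window_fails(self):
        # dense gene with an internal run of >101 zero codons in the pulldown
        pair = make_pair()
        in_counts = np.ones(400)
        pd_counts = np.ones(400)
        pd_counts[100:250] = 0  # 150-codon hole: some 101-windows sum to zero
        profiles = profile_map([
            ("g1", pair.input_sample, in_counts, 1e4),
            ("g1", pair.pulldown_sample, pd_counts, 1e4),
        ])
        assert filter_expression(profiles, [pair], 50, 0.02) == set()
        # closing the hole below window size restores the gene
        pd_counts[170] = 1
        profiles = profile_map([
            ("g1", pair.input_sample, in_counts, 1e4),
            ("g1", pair.pulldown_sample, pd_counts, 1e4),
        ])
        assert filter_expression(profiles, [pair], 50, 0.02) == {"g1"}

    def test_requires_every_baits_input(self):
        pair_a, pair_b = make_pair("a"), make_pair("b")
        ok = np.ones(50)
        profiles = profile_map([
            ("g1", pair_a.input_sample, ok, 1e4),
            ("g1", pair_a.pulldown_sample, ok, 1e4),
            ("g1", pair_b.input_sample, np.zeros(50), 1e4),
            ("g1", pair_b.pulldown_sample, ok, 1e4),
        ])
        assert filter_expression(profiles, [pair_a, pair_b], 10, 0.02) == set()


class TestFilterLocalization:
    def test_equal_shares_fail_strictly(self):
        pair = make_pair()
        profiles = profile_map([
            ("g1", pair.pulldown_sample, [5, 5], 1e4),
            ("g1", pair.input_sample, [5, 5], 1e4),
        ])
        assert filter_localization(profiles, [pair]) == set()

    def test_double_share_passes(self):
        pair = make_pair()
        profiles = profile_map([
            ("g1", pair.pulldown_sample, [10, 10], 1e4),
            ("g1", pair.input_sample, [5, 5], 1e4),
        ])
        assert filter_localization(profiles, [pair]) == {"g1"}

    def test_membership_matches_per_pair_oracle(self, rng):
        pairs = [make_pair("a", "rep1"), make_pair("a", "rep2"), make_pair("b", "rep1")]
        genes = [f"g{i}" for i in range(25)]
        entries, ratios = [], {g: [] for g in genes}
        for pair in pairs:
            tp = float(rng.integers(5000, 20000))
            ti = float(rng.integers(5000, 20000))
            for g in genes:
                pd_counts = rng.integers(0, 20, size=10)
                in_counts = rng.integers(1, 20, size=10)
                entries.append((g, pair.pulldown_sample, pd_counts, tp))
                entries.append((g, pair.input_sample, in_counts, ti))
                ratios[g].append((pd_counts.sum() / tp) / (in_counts.sum() / ti))
        result = filter_localization(profile_map(entries), pairs)
        expected = {g for g in genes if any(r > 1 for r in ratios[g])}
        assert result == expected


class TestCallClients:
    def two_rep(self, values_by_gene):
        return {
            g: {"rep1": v1, "rep2": v2} for g, (v1, v2) in values_by_gene.items()
        }

    def test_top_decile_of_ten_is_top_one(self):
        maxima = self.two_rep(
            {f"g{i}": (float(i + 1), float(i + 1)) for i in range(10)}
        )
        calls = call_clients(maxima, percentile=90)
        clients = {c.gene_id for c in calls if c.is_client}
        assert clients == {"g9"}

    def test_client_requires_top_decile_in_every_replicate(self):
        maxima = self.two_rep(
            {f"g{i}": (float(i + 1), float(i + 1)) for i in range(9)}
        )
        maxima["g9"] = {"rep1": 10.0, "rep2": 5.0}  # top in rep1, median in rep2
        calls = call_clients(maxima, percentile=90)
        clients = {c.gene_id for c in calls if c.is_client}
        assert "g9" not in clients
        # the two per-replicate top deciles are disjoint here
        assert clients == set()

    def test_all_tied_all_clients(self):
        maxima = self.two_rep({f"g{i}": (2.5, 2.5) for i in range(10)})
        calls = call_clients(maxima, percentile=90)
        assert all(c.is_client for c in calls)

    def test_single_replicate_is_fatal(self):
        with pytest.raises(ValueError, match="2 replicates"):
            call_clients({"g1": {"rep1": 1.0}, "g2": {"rep1": 2.0}}, 90)

    def test_client_fraction_bounded_without_ties(self, rng):
        for n in (10, 20, 47, 100):
            vals = rng.permutation(np.arange(1.0, n + 1))
            maxima = {f"g{i}": {"rep1": float(vals[i]), "rep2": float(vals[i])}
                      for i in range(n)}
            calls = call_clients(maxima, percentile=90)
            n_clients = sum(c.is_client for c in calls)
            assert n_clients <= 0.1 * n
            assert n_clients == math.floor(n * 0.1)

    def test_percentile_rank_consistent_with_client_flag(self, rng):
        vals1, vals2 = rng.normal(size=30), rng.normal(size=30)
        maxima = {f"g{i}": {"rep1": float(np.exp(vals1[i])),
                            "rep2": float(np.exp(vals2[i]))} for i in range(30)}
        for c in call_clients(maxima, percentile=90):
            if c.is_client:
                assert all(v >= 90 for v in c.percentile_rank_by_replicate.values())

    def test_removing_nonclient_matches_oracle_recomputation(self, rng):
        vals = {f"g{i}": (float(rng.uniform(1, 5)), float(rng.uniform(1, 5)))
                for i in range(20)}
        maxima = self.two_rep(vals)
        before = {c.gene_id for c in call_clients(maxima, 90) if c.is_client}
        victim = sorted(set(maxima) - before)[0]
        reduced = {g: v for g, v in maxima.items() if g != victim}
        after = {c.gene_id for c in call_clients(reduced, 90) if c.is_client}

        def oracle(mr):
            genes = sorted(mr)
            out = set(genes)
            for rep in ("rep1", "rep2"):
                ranked = sorted(genes, key=lambda g: mr[g][rep], reverse=True)
                k = math.floor(len(genes) * 0.1)
                cut = mr[ranked[k - 1]][rep] if k >= 1 else math.inf
                out &= {g for g in genes if mr[g][rep] >= cut}
            return out

        assert before == oracle(maxima)
        assert after == oracle(reduced)


class TestDecileThreshold:
    def test_too_few_values_yields_no_slots(self):
        assert decile_threshold(np.array([1.0, 2.0, 3.0]), 90) == math.inf

    def test_threshold_is_kth_largest(self):
        vals = np.arange(1.0, 31.0)  # N=30 -> k=3 -> threshold 28
        assert decile_threshold(vals, 90) == 28.0


class TestIdentifyClients:
    def test_planted_clients_recovered_on_small_sim(self, small_sim):
        sim = small_sim
        calls, diagnostics = identify_clients(
            sim.transcriptome.genes, sim.profiles, sim.pairs,
            sim.test_bait, sim.reference_bait,
        )
        called = {c.gene_id for c in calls if c.is_client}
        truth = sim.transcriptome.client_ids
        assert called == truth
        assert diagnostics["n_eligible"] <= diagnostics["n_profiled"]
        for c in calls:
            if c.is_client:
                assert c.eligible
            if not c.eligible:
                assert c.filter_failures
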