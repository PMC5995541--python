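import numpy as np
import pytest

from riboprox.models import GeneModel, TMDomain, TMDSource
from riboprox.tmd import (
    PROPERTIES,
    classify_residue,
    merge_tmd_sources,
    positional_property_fractions,
    property_enrichment,
    property_fractions,
    tmd_count_histogram,
)


def pred(gene, start, end):
    return TMDomain(gene, start, end, TMDSource.PREDICTED)


def cur(gene, start, end):
    return TMDomain(gene, start, end, TMDSource.CURATED)


class TestClassifyResidue:
    @pytest.mark.parametrize(
        "aa,expected",
        [
            ("K", {"CHARGED"}),
            ("F", {"AROMATIC", "HYDROPHOBIC"}),
            ("L", {"ALIPHATIC", "HYDROPHOBIC"}),
            ("S", {"POLAR"}),
            ("G", set()),
            ("Y", {"AROMATIC", "POLAR"}),
        ],
    )
    def test_fixed_classification(self, aa, expected):
        assert classify_residue(aa) == expected

    def test_nonstandard_residue_is_fatal(self):
        with pytest.raises(ValueError, match="B"):
            classify_residue("B")


class TestMergeTmdSources:
    def test_overlapping_prediction_yields_to_curated(self):
        merged = merge_tmd_sources([pred("g1", 10, 30)], [cur("g1", 12, 32)])
        assert merged == [cur("g1", 12, 32)]

    def test_disjoint_spans_both_retained(self):
        merged = merge_tmd_sources([pred("g1", 10, 30)], [cur("g1", 50, 70)])
        assert set(merged) == {pred("g1", 10, 30), cur("g1", 50, 70)}

    def test_overlap_on_other_gene_is_irrelevant(self):
        merged = merge_tmd_sources([pred("g2", 10, 30)], [cur("g1", 10, 30)])
        assert len(merged) == 2

    def test_excluded_genes_dropped(self):
        genes = {
            "ok": GeneModel("ok", 100),
            "dubious": GeneModel("dubious", 100, excluded=True),
        }
        merged = merge_tmd_sources(
            [pred("dubious", 5, 25)], [cur("ok", 5, 25), cur("dubious", 40, 60)], genes
        )
        assert merged == [cur("ok", 5, 25)]

    def test_matches_interval_oracle_on_random_spans(self, rng):
        for _ in range(50):
            predicted, curated = [], []
            for _ in range(int(rng.integers(1, 12))):
                s = int(rng.integers(1, 80))
                predicted.append(pred(f"g{rng.integers(3)}", s, s + int(rng.integers(0, 25))))
            for _ in range(int(rng.integers(1, 12))):
                s = int(rng.integers(1, 80))
                curated.append(cur(f"g{rng.integers(3)}", s, s + int(rng.integers(0, 25))))
            merged = merge_tmd_sources(predicted, curated)
            expected = set(curated) | {
                p
                for p in predicted
                if not any(
                    p.gene_id == c.gene_id
                    and max(p.start_aa, c.start_aa) <= min(p.end_aa, c.end_aa)
                    for c in curated
                )
            }
            assert set(merged) == expected
            # invariant: no surviving prediction overlaps a curated span
            for m in merged:
                if m.source is TMDSource.PREDICTED:
                    assert not any(m.overlaps(c) for c in curated)


class TestTmdCountHistogram:
    def test_counting(self):
        tmds = [cur("a", 1, 10), cur("b", 1, 10), cur("c", 1, 10),
                *[cur("c", 20 * i, 20 * i + 5) for i in range(1, 7)]]
        hist = tmd_count_histogram(tmds, {"a", "b", "c"})
        assert hist.bins == {1: pytest.approx(2 / 3), 7: pytest.approx(1 / 3)}

    def test_gene_without_tmds_counts_at_zero(self):
        hist = tmd_count_histogram([cur("a", 1, 10)], {"a", "soluble"})
        assert hist.bins == {0: 0.5, 1: 0.5}

    def test_proportions_sum_to_one(self, rng):
        genes = {f"g{i}" for i in range(20)}
        tmds = [cur(f"g{int(rng.integers(20))}", 1 + 30 * j, 21 + 30 * j)
                for j in range(3) for _ in range(int(rng.integers(1, 10)))]
        hist = tmd_count_histogram(tmds, genes)
        assert sum(hist.bins.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_set_is_fatal(self):
        with pytest.raises(ValueError):
            tmd_count_histogram([], set())


@pytest.fixture
def span_pool(rng):
    """Random protein pool with one fixed-length span per protein."""
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    seqs, spans = {}, []
    for i in range(60):
        g = f"p{i}"
        seqs[g] = "".join(rng.choice(aas, size=60))
        start = int(rng.integers(1, 30))
        spans.append(cur(g, start, start + 20))
    return seqs, spans


class TestPropertyEnrichment:
    def test_client_set_equal_to_universe_gives_unit_ratios(self, span_pool):
        seqs, spans = span_pool
        for e in property_enrichment(spans, spans, seqs, n_bootstrap=50, rng=0):
            if e.fraction_all > 0:
                assert e.ratio == pytest.approx(1.0, rel=1e-12)
                assert e.ci_low == pytest.approx(1.0, rel=1e-12)
                assert e.ci_high == pytest.approx(1.0, rel=1e-12)

    def test_fractions_match_hand_pooling(self, span_pool):
        seqs, spans = span_pool
        fracs = property_fractions(spans[:5], seqs)
        residues = "".join(
            seqs[t.gene_id][t.start_aa - 1 : t.end_aa] for t in spans[:5]
        )
        for prop in PROPERTIES:
            expected = sum(prop in classify_residue(a) for a in residues) / len(residues)
            assert fracs[prop] == pytest.approx(expected, rel=1e-12)

    def test_longer_spans_weigh_more_than_genes(self, span_pool):
        seqs = {"a": "K" * 30, "b": "L" * 30}
        spans = [cur("a", 1, 10), cur("b", 1, 30)]  # 10 K residues, 30 L residues
        fracs = property_fractions(spans, seqs)
        assert fracs["CHARGED"] == pytest.approx(0.25)

    def test_same_seed_reproduces_cis_exactly(self, span_pool):
        seqs, spans = span_pool
        a = property_enrichment(spans[:10], spans, seqs, 200, rng=42)
        b = property_enrichment(spans[:10], spans, seqs, 200, rng=42)
        assert [(e.ci_low, e.ci_high) for e in a] == [(e.ci_low, e.ci_high) for e in b]

    def test_client_set_larger_than_universe_is_fatal(self, span_pool):
        seqs, spans = span_pool
        with pytest.raises(ValueError):
            property_enrichment(spans, spans[:5], seqs, 10, rng=0)

    def test_enriched_subset_exceeds_null_band(self, rng):
        # clients deliberately charged-rich: the observed ratio must sit
        # above the resampling band built from the full pool
        seqs = {}
        spans = []
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for i in range(40):
            g = f"p{i}"
            if i < 10:
                seqs[g] = "".join(rng.choice(list("KRDE"), size=21))
            else:
                seqs[g] = "".join(rng.choice(aas, size=21))
            spans.append(cur(g, 1, 21))
        enr = {e.property: e for e in
               property_enrichment(spans[:10], spans, seqs, 2000, rng=rng)}
        assert enr["CHARGED"].ratio > enr["CHARGED"].ci_high


class TestPositionalFractions:
    def test_shape_and_range(self, span_pool):
        seqs, spans = span_pool
        mat = positional_property_fractions(spans, seqs, n_bins=7)
        assert mat.shape == (7, len(PROPERTIES))
        assert np.all((mat >= 0) & (mat <= 1))

    def test_detects_edge_concentration(self):
        # charged residues only in the first third of each span
        seqs = {"a": "KKKKKKK" + "L" * 14}
        mat = positional_property_fractions([cur("a", 1, 21)], seqs, n_bins=3)
        charged = PROPERTIES.index("CHARGED")
        assert mat[0, charged] == pytest.approx(1.0)
        assert mat[2, charged] == pytest.approx(0.0)
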