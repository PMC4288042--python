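import numpy as np
import pytest

from sulfomics import abundance as ab
from sulfomics import io, synthetic
from sulfomics.abundance import HitRecord


def hit(evalue=1e-10, cov=0.9, bits=200.0, family="sqr", taxon="Epsilonproteobacteria",
        genus="Sulfurovum", query="q1", length=1200):
    return HitRecord(
        query_id=query, gene_family=family, subject_taxon_class=taxon,
        subject_taxon_genus=genus, evalue=evalue, bit_score=bits,
        query_coverage=cov, gene_length=length,
    )


# the worked six-record table: two fail coverage, one fails bit score
TOY_TABLE = [
    hit(query="q1", evalue=1e-10, cov=0.80, bits=150),  # kept
    hit(query="q2", evalue=1e-10, cov=0.70, bits=150),  # dropped: coverage not > 0.70
    hit(query="q3", evalue=1e-06, cov=0.50, bits=300),  # dropped: coverage
    hit(query="q4", evalue=1e-20, cov=0.95, bits=100),  # dropped: bit score not > 100
    hit(query="q5", evalue=1e-04, cov=0.71, bits=101),  # kept: e-value inclusive at 1e-4
    hit(query="q6", evalue=1e-30, cov=0.99, bits=500),  # kept
]


class TestFunctionalFilter:
    def test_toy_table_survivors(self):
        kept = ab.filter_hits_functional(TOY_TABLE)
        assert [r.query_id for r in kept] == ["q1", "q5", "q6"]

    def test_coverage_boundary_strict(self):
        assert ab.filter_hits_functional([hit(cov=0.70)]) == []
        assert len(ab.filter_hits_functional([hit(cov=0.701)])) == 1

    def test_bit_score_boundary_strict(self):
        assert ab.filter_hits_functional([hit(bits=100.0)]) == []

    def test_idempotent_and_order_invariant(self):
        once = ab.filter_hits_functional(TOY_TABLE)
        assert ab.filter_hits_functional(once) == once
        rev = ab.filter_hits_functional(TOY_TABLE[::-1])
        assert sorted(r.query_id for r in rev) == sorted(r.query_id for r in once)


class TestClassAssignment:
    def test_coverage_threshold_inclusive(self):
        assert ab.assign_taxonomy_class([hit(evalue=1e-5, cov=0.75)]) == ["Epsilonproteobacteria"]

    def test_evalue_threshold_strict(self):
        assert ab.assign_taxonomy_class([hit(evalue=1e-4, cov=0.90)]) == [ab.UNASSIGNED]

    def test_empty_input(self):
        assert ab.assign_taxonomy_class([]) == []

    def test_idempotence_of_labels(self):
        labels = ab.assign_taxonomy_class(TOY_TABLE)
        assert len(labels) == len(TOY_TABLE)
        assert set(labels) <= {"Epsilonproteobacteria", ab.UNASSIGNED}


class TestNormalization:
    def test_stated_formula(self):
        assert ab.normalize_abundance(10, 2000, 5_000_000) == pytest.approx(1.0)

    def test_zero_hits(self):
        assert ab.normalize_abundance(0, 1000, 1_000_000) == 0.0

    def test_homogeneity(self):
        base = ab.normalize_abundance(7, 1500, 2_000_000)
        assert ab.normalize_abundance(7, 3000, 2_000_000) == pytest.approx(base / 2)
        assert ab.normalize_abundance(7, 1500, 4_000_000) == pytest.approx(base / 2)
        assert ab.normalize_abundance(14, 1500, 2_000_000) == pytest.approx(base * 2)

    @pytest.mark.parametrize("length,reads", [(0, 1000), (1000, 0), (-5, 1000)])
    def test_degenerate_inputs_rejected(self, length, reads):
        with pytest.raises(ValueError):
            ab.normalize_abundance(1, length, reads)


class TestAbundanceFloor:
    def test_below_floor_removed(self):
        assert ab.abundance_floor_16s({"a": 0.5, "b": 0.00009}) == {"a": 0.5}

    def test_exactly_at_floor_retained(self):
        assert ab.abundance_floor_16s({"a": 0.0001}) == {"a": 0.0001}

    def test_empty_table(self):
        assert ab.abundance_floor_16s({}) == {}

    def test_no_renormalization_by_default(self):
        out = ab.abundance_floor_16s({"a": 0.3, "b": 0.2, "c": 1e-6})
        assert out == {"a": 0.3, "b": 0.2}
        renorm = ab.abundance_floor_16s({"a": 0.3, "b": 0.2, "c": 1e-6}, renormalize=True)
        assert sum(renorm.values()) == pytest.approx(1.0)


class TestBestHits:
    def test_top_bit_score_wins(self):
        records = [hit(query="q", bits=100.5), hit(query="q", bits=300), hit(query="q", bits=200)]
        assert ab.best_hits(records)[0].bit_score == 300

    def test_tie_broken_by_evalue_then_order(self):
        a = hit(query="q", bits=200, evalue=1e-10, family="first")
        b = hit(query="q", bits=200, evalue=1e-20, family="second")
        c = hit(query="q", bits=200, evalue=1e-20, family="third")
        assert ab.best_hits([a, b, c])[0].gene_family == "second"


class TestAbundanceTable:
    def test_scales_inversely_with_total_reads(self):
        records = [hit(query=f"q{i}") for i in range(10)]
        t1 = ab.abundance_table(records, 1_000_000)
        t2 = ab.abundance_table(records, 2_000_000)
        np.testing.assert_allclose(
            t1["normalized_abundance"], 2 * t2["normalized_abundance"]
        )
        assert (t1["raw_count"] == t2["raw_count"]).all()

    def test_recovers_true_proportions_within_mislabel_error(self):
        # class-level profile vs true genome proportions: total-variation
        # error bounded by the mislabel rate plus sampling noise
        models = synthetic.default_models()[:3]
        genes = []
        for m in models:
            _, g = synthetic.simulate_genome(
                synthetic.GenomeModel(
                    genome_id=m.genome_id, taxon_class=m.taxon_class,
                    taxon_genus=m.taxon_genus, gc_target=m.gc_target,
                    genome_length=200_000, abundance=m.abundance,
                ),
                seed=3,
            )
            genes.extend(g)
        rate = 0.1
        hits = synthetic.simulate_hit_table(genes, rate, seed=5)
        kept = ab.filter_hits_functional(hits)
        true_prop = {}
        for g in genes:
            true_prop[g.best_hit_taxon_class] = true_prop.get(g.best_hit_taxon_class, 0) + 1
        total = sum(true_prop.values())
        true_prop = {k: v / total for k, v in true_prop.items()}
        obs = {}
        for r in kept:
            obs[r.subject_taxon_class] = obs.get(r.subject_taxon_class, 0) + 1
        tot = sum(obs.values())
        obs = {k: v / tot for k, v in obs.items()}
        tv = 0.5 * sum(
            abs(true_prop.get(k, 0) - obs.get(k, 0)) for k in set(true_prop) | set(obs)
        )
        se = np.sqrt(0.25 / len(kept))
        assert tv <= rate + 3 * se


class TestHitTableIO:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "hits.tsv"
        io.write_hit_table(TOY_TABLE, path, seed=1)
        back = io.read_hit_table(path)
        assert len(back) == len(TOY_TABLE)
        for orig, rec in zip(TOY_TABLE, back):
            assert rec.query_id == orig.query_id
            assert rec.gene_family == orig.gene_family
            assert rec.subject_taxon_class == orig.subject_taxon_class
            assert rec.evalue == pytest.approx(orig.evalue)
            assert rec.bit_score == pytest.approx(orig.bit_score)
            assert rec.gene_length == orig.gene_length
            # coverage survives up to 1 bp of qend rounding
            assert rec.query_coverage == pytest.approx(orig.query_coverage, abs=1e-3)
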