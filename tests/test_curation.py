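import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sulfomics import curation
from sulfomics.curation import AssemblyStats, GeneCall


def gene(contig, taxon="Epsilonproteobacteria", genus="Sulfurovum", marker=None, i=[0]):
    i[0] += 1
    return GeneCall(
        gene_id=f"g{i[0]}",
        contig_id=contig,
        start=1,
        end=900,
        strand="+",
        function_label="hyp",
        best_hit_taxon_class=taxon,
        best_hit_taxon_genus=genus,
        is_marker=marker,
    )


class TestMajorityVote:
    def test_three_of_five_retained(self):
        genes = [gene("c1") for _ in range(3)]
        genes += [gene("c1", taxon="Gammaproteobacteria") for _ in range(2)]
        kept, report = curation.majority_vote_filter(["c1"], genes, "Epsilonproteobacteria")
        assert kept == {"c1"}  # 0.6 > 0.5
        assert report.iloc[0]["status"] == "retained"

    def test_exactly_half_dropped(self):
        genes = [gene("c1") for _ in range(2)] + [
            gene("c1", taxon="Gammaproteobacteria") for _ in range(2)
        ]
        kept, report = curation.majority_vote_filter(["c1"], genes, "Epsilonproteobacteria")
        assert kept == set()  # 0.5 is not > 0.5, strict inequality
        assert report.iloc[0]["status"] == "dropped"

    def test_no_genes_flagged_separately(self):
        kept, report = curation.majority_vote_filter(["bare"], [], "Epsilonproteobacteria")
        assert kept == set()
        assert report.iloc[0]["status"] == "no_genes"

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError):
            curation.majority_vote_filter(["c1"], [], "x", rank="phylum")

    @given(st.integers(0, 6), st.integers(0, 6))
    def test_monotone_in_matching_genes(self, n_match, n_other):
        genes = [gene("c1") for _ in range(n_match)]
        genes += [gene("c1", taxon="Other") for _ in range(n_other)]
        kept_before, _ = curation.majority_vote_filter(["c1"], genes, "Epsilonproteobacteria")
        kept_after, _ = curation.majority_vote_filter(
            ["c1"], genes + [gene("c1")], "Epsilonproteobacteria"
        )
        # adding a matching gene can only help
        assert kept_before <= kept_after


class TestGcCoverageFilter:
    def test_homogeneous_bin_untouched(self):
        ids = [f"c{i}" for i in range(5)]
        gc = {c: 0.4 for c in ids}
        depth = {c: 20.0 for c in ids}
        kept, _ = curation.gc_coverage_filter(ids, gc, depth)
        assert kept == set(ids)

    def test_constructed_gc_outlier_removed(self):
        ids = [f"c{i}" for i in range(6)]
        gc = {c: 0.35 for c in ids}
        gc["c5"] = 0.65
        depth = {c: 20.0 for c in ids}
        kept, report = curation.gc_coverage_filter(ids, gc, depth, gc_window=0.05)
        assert "c5" not in kept
        assert report.set_index("contig_id").loc["c5", "reason"] == "gc_outlier"

    def test_coverage_band_is_multiplicative(self):
        ids = [f"c{i}" for i in range(5)]
        gc = {c: 0.4 for c in ids}
        depth = {c: 20.0 for c in ids}
        depth["c4"] = 100.0  # > 3x the median
        kept, _ = curation.gc_coverage_filter(ids, gc, depth, cov_band=3.0)
        assert "c4" not in kept

    def test_tiny_bin_is_noop_with_warning(self):
        with pytest.warns(UserWarning):
            kept, _ = curation.gc_coverage_filter(
                ["a", "b"], {"a": 0.2, "b": 0.8}, {"a": 1.0, "b": 99.0}
            )
        assert kept == {"a", "b"}


def brute_force_n50(lengths):
    """Independent formulation: the largest L in the list such that contigs
    of length >= L hold at least half the assembly."""
    total = sum(lengths)
    return max(l for l in lengths if sum(x for x in lengths if x >= l) >= total / 2)


class TestAssemblyStats:
    def test_hand_example(self):
        stats = curation.assembly_stats(["A" * n for n in [10, 8, 6, 4, 2]])
        assert stats.total_bp == 30
        assert stats.n50 == 8  # cumulative 10, 18 >= 15
        assert stats.longest == 10
        assert stats.n_scaffolds == 5

    def test_singleton_identity(self):
        stats = curation.assembly_stats(["G" * 437_665])
        assert stats.total_bp == stats.longest == stats.n50 == 437_665
        assert stats.gc_percent == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            curation.assembly_stats([])

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=40))
    def test_n50_matches_independent_oracle(self, lengths):
        assert curation.n50(lengths) == brute_force_n50(lengths)

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=40))
    def test_ordering_invariant(self, lengths):
        v = curation.n50(lengths)
        assert v <= max(lengths) <= sum(lengths)


class TestCompleteness:
    def markers(self, present, dup=()):
        calls = [gene("c1", marker=m) for m in present]
        calls += [gene("c1", marker=m) for m in dup]
        return calls

    def test_full_set(self):
        ms = sorted(curation.DEFAULT_MARKER_SET)
        pct, dup = curation.completeness(self.markers(ms), ms)
        assert pct == 100.0
        assert dup == 0

    def test_eighteen_of_nineteen(self):
        ms = sorted(curation.DEFAULT_MARKER_SET)
        pct, _ = curation.completeness(self.markers(ms[:-1]), ms)
        assert round(pct, 1) == 94.7

    def test_duplicates_never_raise_completeness(self):
        ms = sorted(curation.DEFAULT_MARKER_SET)
        pct, dup = curation.completeness(self.markers(ms[:10], dup=ms[:5]), ms)
        assert round(pct, 1) == round(100 * 10 / 19, 1)
        assert dup == 5

    def test_invariant_under_order(self):
        ms = sorted(curation.DEFAULT_MARKER_SET)
        calls = self.markers(ms[:12])
        assert curation.completeness(calls, ms) == curation.completeness(calls[::-1], ms)

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError):
            curation.completeness([], set())


class TestSelectBestAssembly:
    def stats(self, longest, n50, n):
        return AssemblyStats(
            total_bp=longest * 2, n_scaffolds=n, longest=longest, n50=n50,
            gc_percent=40.0, n_genes=0,
        )

    def test_single_candidate(self):
        assert curation.select_best_assembly([self.stats(100, 50, 10)]) == 0

    def test_dominant_candidate_wins(self):
        a = self.stats(400_000, 70_000, 68)
        b = self.stats(300_000, 50_000, 120)
        assert curation.select_best_assembly([a, b]) == 0

    def test_rank_sum_two_of_three_wins(self):
        a = self.stats(400_000, 50_000, 120)  # wins longest only
        b = self.stats(300_000, 70_000, 68)  # wins n50 and scaffold count
        assert curation.select_best_assembly([a, b]) == 1  # rank-sum 4 beats 5

    def test_tie_broken_by_n50_then_order(self):
        a = self.stats(100, 50, 10)
        b = self.stats(100, 50, 10)
        assert curation.select_best_assembly([a, b]) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            curation.select_best_assembly([])


class TestFullChain:
    def test_chain_keeps_markers_and_stays_pure(self, default_sample, default_profile, default_grid):
        """ESOM bins -> majority vote -> GC/coverage filter: each curated bin
        stays essentially free of foreign bp and captures the large majority
        of the markers its genome placed on the contig set (mean >= 85%,
        every bin >= 80%); markers on ridge-node windows account for the rest."""
        import collections

        from sulfomics import esom, kmer

        sample = default_sample
        matrix, meta = default_profile
        assignment = esom.extract_bins(
            default_grid, esom.bmus(default_grid, matrix),
            meta["contig_id"], window_ids=list(meta["window_id"]),
        )
        genes_by_contig = collections.defaultdict(list)
        for g in sample.gene_calls:
            genes_by_contig[g.contig_id].append(g)
        by_contig = {c.contig_id: c for c in sample.contigs}
        available = collections.defaultdict(set)
        for g in sample.gene_calls:
            if g.is_marker:
                available[sample.truth[g.contig_id]].add(g.is_marker)

        capture_fracs = []
        for _bin_id, cids in sorted(assignment.bins.items()):
            bin_genes = [g for c in cids for g in genes_by_contig[c]]
            target = collections.Counter(
                g.best_hit_taxon_class for g in bin_genes
            ).most_common(1)[0][0]
            kept, _ = curation.majority_vote_filter(sorted(cids), sample.gene_calls, target)
            gc = {c: kmer.gc_content(by_contig[c].sequence) for c in kept}
            depth = {c: by_contig[c].depth for c in kept}
            kept2, _ = curation.gc_coverage_filter(sorted(kept), gc, depth)
            genome = collections.Counter(sample.truth[c] for c in kept2).most_common(1)[0][0]
            captured = {
                g.is_marker for c in kept2 for g in genes_by_contig[c] if g.is_marker
            }
            frac = len(captured & available[genome]) / len(available[genome])
            capture_fracs.append(frac)
            assert frac >= 0.80
            foreign_bp = sum(len(by_contig[c]) for c in kept2 if sample.truth[c] != genome)
            total_bp = sum(len(by_contig[c]) for c in kept2)
            assert foreign_bp / total_bp <= 0.05
        assert len(capture_fracs) == 5
        assert np.mean(capture_fracs) >= 0.85
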