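import numpy as np
import pandas as pd
import pytest
from oracles import (connected_components, exhaustive_rarefaction,
                     loglog_powerlaw_fit)

from pancyan.errors import DegenerateInputError
from pancyan.io_formats import GeneAnnotation
from pancyan.pairwise import align_global
from pancyan.pangenome import (FamilyTable, PanPartition,
                               PresenceAbsenceMatrix, RarefactionResult,
                               accessory_dendrogram, cluster_families,
                               fit_heaps, locate_strain_specific, partition,
                               percentage, rarefaction, shared_cluster_count)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _annot(gene, genome, protein, contig="c1", start=1, end=None):
    return GeneAnnotation(gene, genome, contig, start,
                          end or start + 3 * len(protein) - 1, "+", protein)


def _perturb(seq, n_sub, rng):
    pos = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([c for c in AA if c != out[p]])
    return "".join(out)


class TestClusterFamilies:
    def test_single_linkage_chain_transitivity(self):
        # A~B and B~C above 70%, A~C ~55%: one family via the chain
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list(AA), size=100))
        b = _perturb(a, 25, rng)
        c = _perturb(b, 25, rng)
        assert align_global(a, c, protein=True).identity < 70
        table = cluster_families(
            [_annot("ga", "g1", a), _annot("gb", "g2", b), _annot("gc", "g3", c)],
            0.70,
        )
        assert table.n_families == 1

    def test_three_identical_proteins_one_family(self):
        prot = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        table = cluster_families(
            [_annot(f"g{i}", f"gn{i}", prot) for i in range(3)], 0.70
        )
        assert table.n_families == 1
        assert table.carriers("FAM00001") == {"gn0", "gn1", "gn2"}

    def test_matches_brute_force_components(self):
        # random proteins plus perturbed copies straddling the threshold
        rng = np.random.default_rng(2)
        annots = []
        k = 0
        for fam in range(8):
            base = "".join(rng.choice(list(AA), size=int(rng.integers(40, 80))))
            for copy in range(int(rng.integers(1, 5))):
                n_sub = int(rng.integers(0, len(base) // 2))
                annots.append(_annot(f"p{k}", f"g{k % 5}", _perturb(base, n_sub, rng)))
                k += 1
        assert len(annots) <= 50

        def edge(u, v):
            return align_global(u.protein, v.protein, protein=True).identity >= 70.0

        want = connected_components(annots, edge)
        want = {frozenset(a.gene_id for a in comp) for comp in want}
        for prefilter in (True, False):
            table = cluster_families(annots, 0.70, prefilter=prefilter)
            got = {frozenset(g for _, g in m) for m in table.families.values()}
            assert got == want

    def test_recovers_planted_families_exactly(self, small_sim, small_families):
        _, _, truth = small_sim
        truth_sets = {}
        for gene, fam in truth.family_of_gene.items():
            truth_sets.setdefault(fam, set()).add(gene)
        got = {frozenset(g for _, g in m) for m in small_families.families.values()}
        assert got == {frozenset(v) for v in truth_sets.values()}

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        annots = []
        for fam in range(4):
            base = "".join(rng.choice(list(AA), size=50))
            annots += [_annot(f"p{fam}_{i}", f"g{i}", _perturb(base, 5, rng))
                       for i in range(3)]
        t1 = cluster_families(annots, 0.70)
        t2 = cluster_families(list(reversed(annots)), 0.70)
        assert t1.families == t2.families

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            cluster_families([], 0.70)


class TestPartition:
    def test_printed_count_arithmetic(self):
        pan = PanPartition.from_counts(2736, 4191, 2085)
        assert pan.n_total == 9012
        assert (pan.pct_core, pan.pct_dispensable, pan.pct_singleton) == \
            (30.4, 46.5, 23.1)

    def test_family_in_all_of_three_genomes_is_core(self):
        table = FamilyTable({"f": [("g1", "a"), ("g2", "b"), ("g3", "c")]})
        pan = partition(table, ["g1", "g2", "g3"])
        assert pan.labels["f"] == "core"

    def test_matches_planted_partition(self, small_sim, small_families):
        genomes, _, truth = small_sim
        pan = partition(small_families, [g.genome_id for g in genomes])
        # map recovered family ids onto truth ids through member genes
        for fid, members in small_families.families.items():
            truth_fid = truth.family_of_gene[members[0][1]]
            assert pan.labels[fid] == truth.partition_of_family[truth_fid]

    def test_counts_conserve_total_and_percentages_sum(self, small_sim, small_families):
        genomes, _, _ = small_sim
        pan = partition(small_families, [g.genome_id for g in genomes])
        assert pan.n_core + pan.n_dispensable + pan.n_singleton == \
            small_families.n_families
        assert pan.pct_core + pan.pct_dispensable + pan.pct_singleton == \
            pytest.approx(100.0, abs=0.1)

    def test_two_genomes_refused(self):
        table = FamilyTable({"f": [("g1", "a"), ("g2", "b")]})
        with pytest.raises(DegenerateInputError):
            partition(table, ["g1", "g2"])

    def test_rounding_is_half_up(self):
        assert percentage(1, 16) == 6.3  # 6.25 rounds up, not to even


class TestSharedClusterCount:
    def test_all_genomes_gives_core_count(self, small_sim, small_families, small_matrix):
        genomes, _, _ = small_sim
        gids = [g.genome_id for g in genomes]
        pan = partition(small_families, gids)
        assert shared_cluster_count(small_matrix, set(gids)) == pan.n_core

    def test_single_genome_gives_its_singletons(self, small_sim, small_families, small_matrix):
        genomes, _, _ = small_sim
        gids = [g.genome_id for g in genomes]
        pan = partition(small_families, gids)
        for gid in gids:
            mine = sum(
                1 for fid in small_families.families
                if pan.labels[fid] == "singleton"
                and small_families.carriers(fid) == {gid}
            )
            assert shared_cluster_count(small_matrix, {gid}) == mine

    def test_matches_exhaustive_column_scan(self):
        rng = np.random.default_rng(4)
        data = rng.random((10, 200)) < 0.4
        data[0] |= ~data.any(axis=0)
        gids = [f"g{i}" for i in range(10)]
        m = PresenceAbsenceMatrix(
            pd.DataFrame(data, index=gids, columns=[f"f{j}" for j in range(200)])
        )
        for _ in range(20):
            size = int(rng.integers(1, 11))
            subset = set(rng.choice(gids, size=size, replace=False))
            idx = [gids.index(g) for g in subset]
            rest = [i for i in range(10) if i not in idx]
            want = sum(
                1 for j in range(200)
                if data[idx, j].all() and (not rest or not data[rest, j].any())
            )
            assert shared_cluster_count(m, subset) == want

    def test_unknown_genome_rejected(self, small_matrix):
        with pytest.raises(KeyError):
            shared_cluster_count(small_matrix, {"nope"})


class TestRarefaction:
    def _matrix(self, data):
        gids = [f"g{i}" for i in range(data.shape[0])]
        return PresenceAbsenceMatrix(
            pd.DataFrame(data, index=gids, columns=[f"f{j}" for j in range(data.shape[1])])
        )

    def test_identical_genomes_only_discover_at_step_one(self):
        data = np.ones((4, 30), dtype=bool)
        rar = rarefaction(self._matrix(data), n_permutations=10, rng_seed=0)
        assert (rar.mean_new[0] == 30) and (rar.mean_new[1:] == 0).all()
        assert (rar.mean_pan == 30).all()

    def test_exhaustive_three_genomes_matches_enumeration(self):
        rng = np.random.default_rng(5)
        data = rng.random((3, 40)) < 0.5
        data[0] |= ~data.any(axis=0)
        rar = rarefaction(self._matrix(data), exhaustive=True)
        assert rar.pan_sizes.shape[0] == 6  # all 3! orderings
        mean_pan, mean_new = exhaustive_rarefaction(data)
        np.testing.assert_allclose(rar.mean_pan, mean_pan)
        np.testing.assert_allclose(rar.mean_new, mean_new)

    def test_pan_size_monotone_in_every_permutation(self, truth_matrix):
        rar = rarefaction(truth_matrix, n_permutations=50, rng_seed=1)
        assert (np.diff(rar.pan_sizes, axis=1) >= 0).all()


class TestFitHeaps:
    def test_noiseless_power_law_recovered(self):
        steps = np.arange(1, 21)
        counts = 1000.0 * steps ** -0.5
        rar = RarefactionResult(np.cumsum(counts)[None, :], counts[None, :])
        fit = fit_heaps(rar)
        assert abs(fit.alpha - 0.5) < 1e-9
        assert abs(fit.kappa - 1000.0) < 1e-6
        assert fit.open_pangenome

    def test_constant_counts_give_alpha_zero(self):
        counts = np.full(10, 37.0)
        rar = RarefactionResult(np.cumsum(counts)[None, :], counts[None, :])
        assert fit_heaps(rar).alpha == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_closed_form_regression(self):
        rng = np.random.default_rng(6)
        counts = np.r_[500.0, 300 * np.arange(2, 12) ** -0.8 * np.exp(rng.normal(0, 0.05, 10))]
        rar = RarefactionResult(np.cumsum(counts)[None, :], counts[None, :])
        fit = fit_heaps(rar)
        kappa, alpha = loglog_powerlaw_fit(np.arange(2, 12), counts[1:])
        assert fit.alpha == pytest.approx(alpha)
        assert fit.kappa == pytest.approx(kappa)

    def test_no_discovery_beyond_step_one_is_an_error(self):
        counts = np.r_[100.0, np.zeros(5)]
        rar = RarefactionResult(np.cumsum(counts)[None, :], counts[None, :])
        with pytest.raises(DegenerateInputError):
            fit_heaps(rar)


class TestAccessoryDendrogram:
    def test_identical_accessory_profiles_merge_first(self):
        df = pd.DataFrame(
            {"core": [1, 1, 1], "x": [1, 1, 0], "y": [0, 0, 1], "z": [1, 1, 1]},
            index=["a", "b", "c"], dtype=bool,
        )
        dg = accessory_dendrogram(PresenceAbsenceMatrix(df))
        assert sorted(dg.linkage[0, :2]) == [0, 1]
        assert dg.linkage[0, 2] == pytest.approx(0.0)

    def test_disjoint_profiles_distance_one(self):
        df = pd.DataFrame(
            {"x": [1, 0, 0], "y": [0, 1, 0], "w": [0, 1, 0], "v": [0, 0, 1]},
            index=["a", "b", "c"], dtype=bool,
        )
        dg = accessory_dendrogram(PresenceAbsenceMatrix(df))
        assert dg.linkage[:, 2].max() == pytest.approx(1.0)

    def test_planted_sharing_groups_monophyletic(self):
        from scipy.cluster.hierarchy import fcluster

        # two groups of genomes, each sharing a block of exclusive
        # accessory families, plus sparse singleton noise
        rng = np.random.default_rng(7)
        gids = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        cols = {}
        for j in range(10):
            cols[f"shA{j}"] = [1, 1, 1, 0, 0, 0]
            cols[f"shB{j}"] = [0, 0, 0, 1, 1, 1]
        for j in range(6):
            noise = [0] * 6
            noise[int(rng.integers(0, 6))] = 1
            cols[f"noise{j}"] = noise
        df = pd.DataFrame(cols, index=gids, dtype=bool)
        dg = accessory_dendrogram(PresenceAbsenceMatrix(df))
        cut = fcluster(dg.linkage, t=2, criterion="maxclust")
        groups = {}
        for label, cl in zip(dg.labels, cut):
            groups.setdefault(cl, set()).add(label)
        assert {frozenset(v) for v in groups.values()} == {
            frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"})
        }

    def test_empty_accessory_vector_refused(self):
        df = pd.DataFrame(
            {"core": [1, 1, 1], "x": [1, 0, 0]}, index=["a", "b", "c"], dtype=bool
        )
        # genome b and c carry nothing accessory except... b: core only
        with pytest.raises(DegenerateInputError):
            accessory_dendrogram(PresenceAbsenceMatrix(df))


class TestLocateStrainSpecific:
    def _setup(self, placement):
        from pancyan.synthetic_data import SimParams, generate_pangenome

        params = SimParams(
            n_genomes=4, n_core_families=10, n_dispensable_families=5,
            singleton_rate=6, gene_length_mean=80, gene_length_sd=8,
            anchor_subset_size=0, n_planted_cooccurring=0, adjacent_pairs=0,
            n_confounders=0, leak_count=0, singleton_placement=placement,
            rng_seed=21,
        )
        genomes, ann, truth = generate_pangenome(params)
        table = cluster_families(ann, 0.70)
        pan = partition(table, [g.genome_id for g in genomes])
        return genomes, ann, truth, table, pan

    def test_block_placement_yields_one_run(self):
        genomes, ann, truth, table, pan = self._setup("block")
        for g in genomes:
            n_single = sum(1 for f, c in truth.carriers.items()
                           if c == {g.genome_id} and f.startswith("SING"))
            runs = locate_strain_specific(table, pan, ann, g.genome_id, min_run=2)
            if n_single >= 2:
                assert len(runs) == 1
                assert runs[0].length == n_single
            else:
                assert runs == []

    def test_runs_are_disjoint_and_cover_their_genes_once(self):
        genomes, ann, truth, table, pan = self._setup("random")
        for g in genomes:
            runs = locate_strain_specific(table, pan, ann, g.genome_id, min_run=2)
            seen = [gid for r in runs for gid in r.gene_ids]
            assert len(seen) == len(set(seen))

    def test_unknown_genome_rejected(self, small_sim, small_families):
        genomes, ann, _ = small_sim
        pan = partition(small_families, [g.genome_id for g in genomes])
        with pytest.raises(KeyError):
            locate_strain_specific(small_families, pan, ann, "missing")
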