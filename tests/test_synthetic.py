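import numpy as np
import pytest

from baculonet.communities import Partition, modularity
from baculonet.expression import concatenate_replicates, shuffle_time_points
from baculonet.spatial import rot_membership
from baculonet.synthetic import (
    SyntheticSpec,
    _activation_times,
    generate_genome,
    generate_grn,
    simulate_expression,
)


class TestSpecValidation:
    def test_probabilities_bounded(self):
        with pytest.raises(ValueError, match="probabilities"):
            SyntheticSpec(p_in=1.5)

    def test_onsets_must_fit_time_grid(self):
        with pytest.raises(ValueError, match="onsets"):
            SyntheticSpec(onset_times=(0, 1, 2, 3, 100))

    def test_mutation_density_bounded(self):
        with pytest.raises(ValueError, match="density"):
            SyntheticSpec(mutation_density=0.9)


class TestGenerateGrn:
    def test_planted_partition_is_strongly_modular(self):
        spec = SyntheticSpec(seed=1)
        truth = generate_grn(spec)
        part = Partition(labels=truth.module_of, q=0.0)
        assert modularity(truth.network, part) > 0.5

    def test_equal_probabilities_give_no_structure(self):
        spec = SyntheticSpec(seed=1, p_in=0.03, p_out=0.03)
        truth = generate_grn(spec)
        part = Partition(labels=truth.module_of, q=0.0)
        assert abs(modularity(truth.network, part)) < 0.15

    def test_every_gene_reachable_from_early_seeds(self):
        import networkx as nx

        spec = SyntheticSpec(seed=4, p_in=0.08, p_out=0.001)
        truth = generate_grn(spec)
        g = truth.network.digraph()
        seeds = [n for n in g if truth.module_of[n] == 1]
        reachable = set(seeds)
        for s in seeds:
            reachable |= nx.descendants(g, s)
        assert reachable == set(g.nodes)

    def test_fixed_seed_reproducible(self):
        spec = SyntheticSpec(seed=7)
        a, b = generate_grn(spec), generate_grn(spec)
        assert a.network.edges == b.network.edges
        assert a.module_of == b.module_of


class TestSimulateExpression:
    def test_regulator_activation_precedes_target(self):
        spec = SyntheticSpec(seed=2)
        truth = generate_grn(spec)
        t_act = _activation_times(truth, spec)
        for reg, tgt, _ in truth.network.edges:
            assert t_act[reg] < t_act[tgt]

    def test_early_genes_reach_half_max_before_late_genes(self):
        spec = SyntheticSpec(seed=3, noise_sd=0.0)
        truth = generate_grn(spec)
        reps = simulate_expression(truth, spec)
        series = reps[0]
        times = series.sample_times
        half_max_hour = {}
        for i, gene in enumerate(series.gene_ids):
            row = series.values[i]
            if row.max() <= 0:
                continue
            k = int(np.argmax(row >= row.max() / 2))
            half_max_hour[gene] = times[k]
        early = [half_max_hour[g] for g in half_max_hour if truth.module_of[g] == 1]
        late = [half_max_hour[g] for g in half_max_hour if truth.module_of[g] == 5]
        pairs = [(e, l) for e in early for l in late]
        frac = np.mean([e < l for e, l in pairs])
        assert frac >= 0.95

    def test_replicates_differ_only_by_noise(self):
        spec = SyntheticSpec(seed=5, noise_sd=0.0)
        reps = simulate_expression(generate_grn(spec), spec)
        assert np.array_equal(reps[0].values, reps[1].values)
        noisy = simulate_expression(
            generate_grn(SyntheticSpec(seed=5)), SyntheticSpec(seed=5)
        )
        assert not np.array_equal(noisy[0].values, noisy[1].values)

    def test_values_respect_detection_floor(self):
        spec = SyntheticSpec(seed=6)
        reps = simulate_expression(generate_grn(spec), spec)
        for s in reps:
            assert s.values.min() >= spec.detection_floor

    def test_time_shuffling_destroys_regulator_target_lag_correlation(self):
        spec = SyntheticSpec(seed=8)
        truth = generate_grn(spec)
        series = concatenate_replicates(*simulate_expression(truth, spec))
        shuffled = shuffle_time_points(series, seed=99)

        def mean_lag_corr(s):
            idx = {g: i for i, g in enumerate(s.gene_ids)}
            cols_t, cols_t1 = [], []
            for rep in s.replicates:
                cols = np.flatnonzero(s.replicate_of == rep)
                cols_t.extend(cols[:-1])
                cols_t1.extend(cols[1:])
            corrs = []
            rng = np.random.default_rng(0)
            edges = truth.network.edges
            sample = [edges[i] for i in rng.choice(len(edges), 150, replace=False)]
            for reg, tgt, _ in sample:
                x = s.values[idx[reg], cols_t]
                y = s.values[idx[tgt], cols_t1]
                if x.std() == 0 or y.std() == 0:
                    continue
                corrs.append(np.corrcoef(x, y)[0, 1])
            return float(np.mean(corrs))

        assert mean_lag_corr(series) > 0.3
        assert mean_lag_corr(shuffled) < 0.1


class TestGenerateGenome:
    def test_strict_mode_recovers_planted_classes(self):
        from baculonet.promoters import classify_promoters

        genome, _, _, truth = generate_genome(SyntheticSpec(seed=11), strict=True)
        classes, _ = classify_promoters(genome)
        assert classes == truth["planted_class"]

    def test_rot_layout_flags_exactly_the_planted_members(self):
        spec = SyntheticSpec(seed=12, n_orfs=40, rot_runs=(4, 4, 4))
        genome, rots, _, truth = generate_genome(spec)
        flags, counts = rot_membership(rots, genome)
        assert counts["n_in_rot"] == 12
        assert {o for o, f in flags.items() if f} == set(truth["in_rot"])

    def test_rot_members_overlap_their_neighbors(self):
        from baculonet.spatial import intergenic_spacers

        spec = SyntheticSpec(seed=13, n_orfs=30, rot_runs=(5,))
        genome, rots, _, _ = generate_genome(spec)
        members = rots.rots[0]["members"]
        spacers = {s["pair"]: s for s in intergenic_spacers(genome)}
        for a, b in zip(members, members[1:]):
            assert spacers[(a, b)]["spacer_bp"] < 0

    def test_nonstrict_recovery_beats_background_false_positive_bound(self):
        from baculonet.promoters import classify_promoter_window, classify_promoters

        spec = SyntheticSpec(seed=14)
        genome, _, _, truth = generate_genome(spec, strict=False)
        classes, _ = classify_promoters(genome)
        recovered = np.mean(
            [classes[o] == truth["planted_class"][o] for o in genome.orf_ids]
        )
        # background flip rate estimated on independent random windows
        rng = np.random.default_rng(999)
        bases = np.array(list("ACGT"))
        flips = np.mean([
            classify_promoter_window(
                "".join(bases[rng.integers(0, 4, 200)])
            ) != "none"
            for _ in range(400)
        ])
        assert recovered >= 1.0 - flips - 0.1

    def test_fixed_seed_reproducible(self):
        spec = SyntheticSpec(seed=15, n_orfs=25, rot_runs=(3,))
        g1, r1, a1, t1 = generate_genome(spec)
        g2, r2, a2, t2 = generate_genome(spec)
        assert g1.sequence == g2.sequence
        assert g1.orfs == g2.orfs
        assert t1 == t2

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            generate_genome(SyntheticSpec(seed=16, n_orfs=6, rot_runs=(4, 4)))
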