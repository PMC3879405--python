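import numpy as np
import pytest

from baculonet.promoters import GenomeRecord
from baculonet.spatial import (
    GeneOrderAttributes,
    ROTTable,
    circular_map_distance,
    expression_vs_position,
    intergenic_spacers,
    mc_cooccurrence,
    rot_membership,
)
from conftest import make_series
from oracles import run_probability_exhaustive_value


def genome_with(orfs, length=2000):
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return GenomeRecord(sequence=seq, orfs=orfs)


class TestIntergenicSpacers:
    def test_overlap_is_negative(self):
        genome = genome_with([("a", 1, 100, "+"), ("b", 95, 200, "+")], length=500)
        spacers = {s["pair"]: s for s in intergenic_spacers(genome)}
        rec = spacers[("a", "b")]
        assert rec["spacer_bp"] == -6
        assert rec["overlap"]

    def test_plain_gap(self):
        genome = genome_with([("a", 1, 100, "+"), ("b", 151, 200, "+")], length=500)
        spacers = {s["pair"]: s for s in intergenic_spacers(genome)}
        assert spacers[("a", "b")]["spacer_bp"] == 50

    def test_wraparound_pair_measured_across_origin(self):
        genome = genome_with([("a", 10, 100, "+"), ("b", 401, 480, "+")], length=500)
        spacers = {s["pair"]: s for s in intergenic_spacers(genome)}
        # from end of b (480) across the origin to start of a (10): 20 + 9
        assert spacers[("b", "a")]["spacer_bp"] == 29

    def test_invariant_under_origin_rotation(self):
        orfs = [("a", 50, 200, "+"), ("b", 260, 400, "-"), ("c", 420, 470, "+")]
        genome = genome_with(orfs, length=500)
        shift = 20  # keeps every rotated interval off the origin
        rotated = genome_with(
            [(o, (s - 1 + shift) % 500 + 1, (e - 1 + shift) % 500 + 1, st)
             for o, s, e, st in orfs],
            length=500,
        )
        original = {s["pair"]: s["spacer_bp"] for s in intergenic_spacers(genome)}
        after = {s["pair"]: s["spacer_bp"] for s in intergenic_spacers(rotated)}
        assert original == after


class TestRotMembership:
    def test_two_rots_of_three_flag_six(self):
        orfs = [(f"o{i}", 100 * i + 1, 100 * i + 90, "+") for i in range(8)]
        genome = genome_with(orfs)
        rots = ROTTable(rots=[
            {"rot_id": "R1", "members": ["o0", "o1", "o2"], "start": 1, "end": 290,
             "orientation": "+"},
            {"rot_id": "R2", "members": ["o4", "o5", "o6"], "start": 401, "end": 690,
             "orientation": "+"},
        ])
        flags, counts = rot_membership(rots, genome)
        assert sum(flags.values()) == 6
        assert counts["n_in_rot"] == 6
        assert counts["n_rots"] == 2

    def test_empty_table_flags_none(self):
        orfs = [("a", 1, 90, "+"), ("b", 101, 190, "+")]
        flags, counts = rot_membership(ROTTable(rots=[]), genome_with(orfs))
        assert sum(flags.values()) == 0

    def test_unknown_member_rejected(self):
        genome = genome_with([("a", 1, 90, "+"), ("b", 101, 190, "+")])
        rots = ROTTable(rots=[{"rot_id": "R1", "members": ["zz"], "start": 1,
                               "end": 90, "orientation": "+"}])
        with pytest.raises(KeyError):
            rot_membership(rots, genome)

    def test_tsv_roundtrip(self, tmp_path):
        rots = ROTTable(rots=[
            {"rot_id": "R1", "members": ["a", "b"], "start": 5, "end": 300,
             "orientation": "-"},
        ])
        path = tmp_path / "rots.tsv"
        rots.write_tsv(path)
        back = ROTTable.read_tsv(path)
        assert back.rots[0]["members"] == ["a", "b"]
        assert back.rots[0]["start"] == 5


class TestMcCooccurrence:
    def attrs(self, values, strands=None):
        n = len(values)
        return GeneOrderAttributes(
            orf_ids=[f"o{i}" for i in range(n)],
            values=list(values),
            strands=list(strands) if strands else ["+"] * n,
        )

    def test_aabb_circular_run_of_two(self):
        out = mc_cooccurrence(self.attrs("AABB"), "A", 2, n_iter=30_000, seed=1)
        assert out["p"] == pytest.approx(2 / 3, abs=3 * out["se"])

    def test_aabb_linear_run_of_two(self):
        out = mc_cooccurrence(
            self.attrs("AABB"), "A", 2, n_iter=30_000, seed=1, circular=False
        )
        assert out["p"] == pytest.approx(1 / 2, abs=3 * out["se"])

    def test_run_length_one_is_certain(self):
        out = mc_cooccurrence(self.attrs("ABBB"), "A", 1, n_iter=100, seed=0)
        assert out["p"] == 1.0

    def test_matches_exhaustive_enumeration_on_small_lists(self, rng):
        cases = [
            ("AAABBB", "A", 3),
            ("AABBCC", "B", 2),
            ("AAAB", "A", 2),
            ("ABABAB", "A", 2),
        ]
        for values, value, k in cases:
            for circular in (True, False):
                exact = run_probability_exhaustive_value(
                    list(values), value, k, circular=circular
                )
                est = mc_cooccurrence(
                    self.attrs(values), value, k, n_iter=20_000,
                    seed=7, circular=circular,
                )
                assert est["p"] == pytest.approx(exact, abs=max(3 * est["se"], 1e-9))

    def test_strand_restriction_matches_enumeration(self):
        values = list("AABB")
        strands = list("++--")
        exact = run_probability_exhaustive_value(
            values, "A", 2, circular=True, strands=strands
        )
        est = mc_cooccurrence(
            self.attrs(values, strands), "A", 2, strand_restricted=True,
            n_iter=30_000, seed=3,
        )
        assert est["p"] == pytest.approx(exact, abs=max(3 * est["se"], 1e-9))

    def test_excessive_run_length_rejected(self):
        with pytest.raises(ValueError, match="run_length"):
            mc_cooccurrence(self.attrs("AABB"), "A", 3, n_iter=10, seed=0)

    def test_deterministic_under_fixed_seed(self):
        a = mc_cooccurrence(self.attrs("AABBAB"), "A", 2, n_iter=5000, seed=9)
        b = mc_cooccurrence(self.attrs("AABBAB"), "A", 2, n_iter=5000, seed=9)
        assert a == b


class TestCircularMapDistance:
    def test_symmetric_bounded_triangle(self):
        orfs = [("a", 1, 200, "+"), ("b", 501, 700, "+"), ("c", 1501, 1700, "-")]
        genome = genome_with(orfs)
        d = circular_map_distance(genome)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert arr.max() <= 50.0
        ids = list(d.index)
        for i in ids:
            for j in ids:
                for k in ids:
                    assert d.loc[i, j] <= d.loc[i, k] + d.loc[k, j] + 1e-9

    def test_shorter_arc_is_used(self):
        orfs = [("a", 1, 100, "+"), ("b", 1901, 2000, "+")]
        genome = genome_with(orfs, length=2000)
        d = circular_map_distance(genome)
        # midpoints 50.5 and 1950.5: arc through the origin is 100 bp = 5 units
        assert d.loc["a", "b"] == pytest.approx(5.0)


class TestExpressionVsPosition:
    def test_identical_profiles_flagged_degenerate(self):
        orfs = [(f"g{i}", 100 * i + 1, 100 * i + 90, "+") for i in range(5)]
        genome = genome_with(orfs)
        series = make_series(np.ones((5, 6)), genes=[o[0] for o in orfs])
        out = expression_vs_position(series, genome)
        assert out["degenerate"]

    def test_planted_positional_signal_detected(self, rng):
        n = 30
        orfs = [(f"g{i}", 60 * i + 1, 60 * i + 50, "+") for i in range(n)]
        genome = genome_with(orfs, length=60 * n + 100)
        # profile drifts smoothly around the circle: neighbors are similar
        angle = 2 * np.pi * np.arange(n) / n
        profiles = np.vstack(
            [np.cos(angle[i]) * np.linspace(0, 3, 8)
             + np.sin(angle[i]) * np.linspace(3, 0, 8)
             + rng.normal(0, 0.05, 8)
             for i in range(n)]
        )
        series = make_series(profiles, genes=[o[0] for o in orfs])
        out = expression_vs_position(series, genome, n_perm=199, seed=0)
        assert out["pearson_r"] > 0.5
        assert out["mantel_p"] < 0.05

    def test_position_independent_profiles_show_no_signal(self):
        n = 30
        orfs = [(f"g{i}", 60 * i + 1, 60 * i + 50, "+") for i in range(n)]
        genome = genome_with(orfs, length=60 * n + 100)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            series = make_series(
                rng.normal(size=(n, 8)), genes=[o[0] for o in orfs]
            )
            out = expression_vs_position(series, genome, n_perm=99, seed=seed)
            if abs(out["pearson_r"]) < 0.3 and out["mantel_p"] > 0.05:
                hits += 1
        assert hits > n_seeds / 2

    def test_no_shared_genes_rejected(self):
        genome = genome_with([("a", 1, 90, "+"), ("b", 101, 190, "+")])
        series = make_series(np.ones((3, 5)), genes=["x", "y", "z"])
        with pytest.raises(ValueError, match="shared"):
            expression_vs_position(series, genome)
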