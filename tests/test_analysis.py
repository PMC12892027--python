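"""Sample-size calculator, wave/homophily diagnostics, convergence
detection, RDS-II weighting and the chain-bootstrap design effect."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from webrds import (
    SampleSizeSpec,
    chain_bootstrap_deff,
    convergence_trace,
    rds2_estimate,
    recruitment_homophily,
    sample_size,
    wave_statistics,
)
from webrds.simulator import RecruitmentForest


def _forest(rows):
    df = pd.DataFrame(
        rows, columns=["person_id", "wave", "seed_id", "recruiter_id"]
    ).set_index("person_id")
    df["recruiter_id"] = df["recruiter_id"].astype("string")
    df["coupon_code"] = [f"C{i}" for i in range(len(df))]
    df["day"] = df["wave"]
    return RecruitmentForest(df)


class TestSampleSize:
    @pytest.mark.parametrize(
        "p, se, deff, loss, expected",
        [
            (0.5, 0.05, 2.5, 0.2, (100, 250, 300)),
            (0.5, 0.05, 1.0, 0.0, (100, 100, 100)),
            (0.3, 0.02, 2.0, 0.1, (525, 1050, 1155)),
        ],
    )
    def test_design_numbers(self, p, se, deff, loss, expected):
        spec = SampleSizeSpec(p=p, se=se, deff=deff, loss_rate=loss)
        assert sample_size(spec) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            SampleSizeSpec(p=0.5, se=0.0)
        with pytest.raises(ValidationError):
            SampleSizeSpec(p=1.2, se=0.05)
        with pytest.raises(ValidationError):
            SampleSizeSpec(p=0.5, se=0.05, deff=0.5)


class TestWaveStatistics:
    def test_linear_chain_depth(self):
        rows = [("S1", 0, "S1", None)]
        for i in range(1, 5):
            rows.append((f"R{i}", i, "S1", f"R{i-1}" if i > 1 else "S1"))
        ws = wave_statistics(_forest(rows))
        assert ws.max_depth == 4
        assert ws.per_wave == {0: 1, 1: 1, 2: 1, 3: 1, 4: 1}
        assert ws.n_unproductive_seeds == 0

    def test_matches_bfs_depth_oracle(self, sim_result):
        forest = sim_result.forest
        g = nx.DiGraph()
        g.add_nodes_from(forest.participants.index)
        for _, e in forest.edges.iterrows():
            g.add_edge(e["recruiter_id"], e["recruit_id"])
        depths = []
        for seed in forest.seed_ids():
            lengths = nx.single_source_shortest_path_length(g, seed)
            depths.extend(lengths.values())
        ws = wave_statistics(forest)
        assert ws.max_depth == max(depths)
        assert sum(ws.per_wave.values()) == ws.n_participants

    def test_unproductive_seed_counted(self):
        ws = wave_statistics(
            _forest(
                [("S1", 0, "S1", None), ("S2", 0, "S2", None), ("R1", 1, "S1", "S1")]
            )
        )
        assert ws.seeds_without_recruits == ["S2"]


class TestConvergence:
    def _roster(self, values):
        return pd.DataFrame(
            {"attempt_id": range(1, len(values) + 1), "v": values}
        )

    def test_constant_variable_converges_immediately(self):
        tr = convergence_trace(self._roster(["a"] * 50), "v", category="a")
        assert tr.converged
        assert np.allclose(tr.trace, 1.0)

    def test_alternating_sequence_matches_closed_form(self):
        """0/1 alternation: cumulative mean after k values is
        ceil(k/2)/k for the leading value; oscillates into 0.5."""
        values = [1, 0] * 50
        tr = convergence_trace(
            self._roster(values), "v", category="1", window_frac=0.25, tol=0.05
        )
        k = np.arange(1, 101)
        expected = np.ceil(k / 2) / k
        assert np.allclose(tr.trace, expected)
        assert tr.converged

    def test_two_cluster_bottleneck_flagged(self):
        """Two seed clusters with different trait mixes enrolled one after
        the other: the trace drifts through the final window."""
        values = ["a"] * 50 + ["b"] * 50
        tr = convergence_trace(
            self._roster(values), "v", category="a", window_frac=0.25, tol=0.02
        )
        assert not tr.converged

    def test_numeric_variable_uses_cumulative_mean(self):
        tr = convergence_trace(self._roster([2.0, 4.0, 6.0]), "v")
        assert np.allclose(tr.trace, [2.0, 3.0, 4.0])

    def test_missing_variable_rejected(self):
        with pytest.raises(KeyError):
            convergence_trace(self._roster([1]), "nope")


class TestRecruitmentHomophily:
    def test_perfect_assortativity_doubles_index(self):
        rows = [("S1", 0, "S1", None), ("S2", 0, "S2", None)]
        rows += [(f"A{i}", 1, "S1", "S1") for i in range(2)]
        rows += [(f"B{i}", 1, "S2", "S2") for i in range(2)]
        forest = _forest(rows)
        traits = pd.Series(
            {"S1": "x", "A0": "x", "A1": "x", "S2": "y", "B0": "y", "B1": "y"}
        )
        hom = recruitment_homophily(forest, traits)
        assert hom["x"] == pytest.approx(2.0)
        assert hom["y"] == pytest.approx(2.0)

    def test_zero_within_group_recruitment(self):
        forest = _forest([("S1", 0, "S1", None), ("R1", 1, "S1", "S1")])
        traits = pd.Series({"S1": "x", "R1": "y"})
        hom = recruitment_homophily(forest, traits)
        assert hom["x"] == 0.0

    def test_random_mixing_close_to_one(self, sim_result):
        """Labels assigned independently of the forest: indices ~ 1."""
        forest = sim_result.forest
        rng = np.random.default_rng(3)
        vals = {"x": [], "y": []}
        for _ in range(50):
            traits = pd.Series(
                rng.choice(["x", "y"], size=len(forest.participants)),
                index=forest.participants.index,
            )
            hom = recruitment_homophily(forest, traits)
            for c in vals:
                if hom.get(c) is not None:
                    vals[c].append(hom[c])
        for c, series in vals.items():
            assert abs(np.mean(series) - 1.0) < 0.05


class TestRDS2:
    def test_hand_example(self):
        traits = pd.Series({"A": "1", "B": "0", "C": "1"})
        degrees = pd.Series({"A": 1, "B": 2, "C": 2})
        est = rds2_estimate(traits, degrees)
        assert est.proportions["1"] == pytest.approx(0.75)
        assert est.proportions["0"] == pytest.approx(0.25)

    def test_equal_degrees_reduce_to_sample_proportions(self):
        traits = pd.Series(list("aabbb"), index=list("ABCDE"))
        degrees = pd.Series(4, index=list("ABCDE"))
        est = rds2_estimate(traits, degrees)
        assert est.proportions["a"] == pytest.approx(0.4)

    def test_proportions_sum_to_one(self, rng):
        n = 200
        traits = pd.Series(rng.choice(list("abc"), size=n))
        degrees = pd.Series(rng.integers(1, 30, size=n))
        est = rds2_estimate(traits, degrees)
        assert sum(est.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_degree_rejected(self):
        with pytest.raises(ValueError):
            rds2_estimate(pd.Series({"A": "x"}), pd.Series({"A": 0}))

    def test_seed_exclusion_flag(self):
        traits = pd.Series({"S": "a", "R": "b"})
        degrees = pd.Series({"S": 1, "R": 1})
        est = rds2_estimate(traits, degrees, include_seeds=False, seed_ids={"S"})
        assert est.proportions == {"b": 1.0}


class TestChainBootstrapDeff:
    def _star_forest(self, n_seeds, rng):
        rows = [(f"S{i}", 0, f"S{i}", None) for i in range(n_seeds)]
        forest = _forest(rows)
        traits = pd.Series(
            rng.choice(["a", "b"], size=n_seeds), index=forest.participants.index
        )
        degrees = pd.Series(5, index=forest.participants.index)
        return forest, traits, degrees

    def test_independent_chains_equal_degrees_deff_near_one(self, rng):
        """Single-member chains with equal weights are an SRS: deff ~ 1."""
        forest, traits, degrees = self._star_forest(300, rng)
        out = chain_bootstrap_deff(traits, degrees, forest, "a", n_boot=800, rng_seed=5)
        assert 0.7 < out["deff"] < 1.3

    def test_clustered_chains_inflate_deff(self):
        """Chains homogeneous in the trait: between-chain variance dominates
        and deff > 1 in (almost) every replicate."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            rows = []
            traits = {}
            for s in range(10):
                sid = f"S{s}"
                rows.append((sid, 0, sid, None))
                label = "a" if s % 2 == 0 else "b"
                traits[sid] = label
                prev = sid
                for j in range(int(rng.integers(3, 10))):
                    pid = f"P{s}_{j}"
                    rows.append((pid, j + 1, sid, prev))
                    traits[pid] = label
                    prev = pid
            forest = _forest(rows)
            tr = pd.Series(traits)
            deg = pd.Series(5, index=tr.index)
            out = chain_bootstrap_deff(tr, deg, forest, "a", n_boot=300, rng_seed=rep)
            hits += out["deff"] > 1.0
        assert hits >= 19

    def test_too_few_bootstrap_replicates_rejected(self, rng):
        forest, traits, degrees = self._star_forest(10, rng)
        with pytest.raises(ValueError):
            chain_bootstrap_deff(traits, degrees, forest, "a", n_boot=0)

    def test_single_seed_rejected(self, rng):
        forest, traits, degrees = self._star_forest(1, rng)
        with pytest.raises(ValueError):
            chain_bootstrap_deff(traits, degrees, forest, "a", n_boot=200)
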