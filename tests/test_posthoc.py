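import subprocess

import numpy as np
import pandas as pd
import pytest

from vgm.posthoc import (
    K_over_tree_set,
    blombergs_K,
    diel_sensitivity_comparison,
    welch_t_test,
)
from vgm.synthetic import gen_phylogeny_and_traits


class TestBlombergsK:
    def test_brownian_values_near_one(self):
        ks = []
        for seed in range(25):
            tree, values = gen_phylogeny_and_traits(40, "brownian", seed=seed)
            ks.append(blombergs_K(values, tree))
        assert 0.8 < np.mean(ks) < 1.2

    def test_white_noise_well_below_one(self):
        ks = []
        for seed in range(25):
            tree, values = gen_phylogeny_and_traits(40, "white_noise", seed=seed)
            ks.append(blombergs_K(values, tree))
        assert np.mean(ks) < 0.5

    def test_affine_invariance(self):
        tree, values = gen_phylogeny_and_traits(20, "brownian", seed=3)
        k1 = blombergs_K(values, tree)
        scaled = {k: 3.5 * v + 11.0 for k, v in values.items()}
        assert blombergs_K(scaled, tree) == pytest.approx(k1)

    def test_label_mismatch_reported(self):
        tree, values = gen_phylogeny_and_traits(10, "brownian", seed=4)
        values["EXTRA"] = 1.0
        del values["SP000"]
        with pytest.raises(ValueError, match="EXTRA|SP000"):
            blombergs_K(values, tree)

    def test_matches_picante_reference(self, tmp_path):
        """Independent cross-check against the standard R implementation."""
        tree, values = gen_phylogeny_and_traits(20, "brownian", seed=5)
        mine = blombergs_K(values, tree)
        tree.write(path=str(tmp_path / "t.nwk"), schema="newick", suppress_rooting=True)
        pd.Series(values).to_csv(tmp_path / "v.csv", header=["x"])
        script = (
            f'suppressMessages(library(picante));'
            f'tr <- read.tree("{tmp_path}/t.nwk");'
            f'v <- read.csv("{tmp_path}/v.csv", row.names=1);'
            f'cat(Kcalc(setNames(v$x, rownames(v))[tr$tip.label], tr))'
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        if proc.returncode != 0:
            pytest.fail(f"picante reference run failed: {proc.stderr[-500:]}")
        assert mine == pytest.approx(float(proc.stdout.strip().split()[-1]), rel=1e-4)


class TestKOverTreeSet:
    def test_identical_trees_identical_K(self):
        tree, values = gen_phylogeny_and_traits(12, "brownian", seed=6)
        out = K_over_tree_set(values, [tree, tree, tree])
        assert out["min"] == out["max"] == out["median"]

    def test_white_noise_median_well_below_one(self):
        # one set of signal-free values scored over many candidate topologies
        _, values = gen_phylogeny_and_traits(30, "white_noise", seed=100)
        trees = [gen_phylogeny_and_traits(30, "brownian", seed=s)[0] for s in range(20)]
        out = K_over_tree_set(values, trees)
        assert out["median"] < 0.5

    def test_empty_tree_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            K_over_tree_set({"a": 1.0}, [])


class TestWelch:
    def test_identical_groups(self):
        out = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["t"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        out = welch_t_test(a, b)
        se = np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        assert out["mean_difference"] == pytest.approx(-1.0)
        assert out["t"] == pytest.approx(-1.0 / se)

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 14)
        fwd, rev = welch_t_test(a, b), welch_t_test(b, a)
        assert fwd["t"] == pytest.approx(-rev["t"])
        assert fwd["mean_difference"] == pytest.approx(-rev["mean_difference"])
        assert fwd["p"] == pytest.approx(rev["p"])

    def test_matches_pooled_when_balanced(self):
        from scipy import stats

        rng = np.random.default_rng(8)
        a, b = rng.normal(size=12), rng.normal(size=12)
        out = welch_t_test(a, b)
        pooled = stats.ttest_ind(a, b, equal_var=True)
        # equal sizes: identical t statistic (df differs only through variances)
        assert out["t"] == pytest.approx(pooled.statistic)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="2"):
            welch_t_test([1.0], [2.0, 3.0])


def test_diel_comparison_excludes_both_and_unknown():
    df = pd.DataFrame(
        {
            "species_code": [f"S{i}" for i in range(8)],
            "sensitivity": [0.1, 0.2, 0.15, -0.3, -0.25, -0.2, 5.0, -5.0],
            "diel": ["nocturnal"] * 3 + ["diurnal"] * 3 + ["both", "unknown"],
        }
    )
    out = diel_sensitivity_comparison(df)
    assert out["n_nocturnal"] == 3 and out["n_diurnal"] == 3
    assert out["mean_difference"] == pytest.approx(0.15 - (-0.25))
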