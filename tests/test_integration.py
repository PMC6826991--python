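"""Expression↔sensitivity associations and UES/OES hit calling."""

import numpy as np
import pandas as pd
import pytest

from phenomiq.integration import (
    associate,
    call_hits,
    summarize_conservation,
)
from phenomiq.simulate import generate_pharmaco_dataset


def make_assoc(rows):
    """rows: (human_gene, drug, tissue, coef, p)."""
    return pd.DataFrame(
        rows, columns=["human_gene", "drug", "tissue", "standardized_coefficient", "p_value"]
    )


def make_yeast(rows):
    """rows: (yeast_gene, drug, class, z_K, z_L)."""
    return pd.DataFrame(rows, columns=["yeast_gene", "drug", "class", "z_K", "z_L"])


def make_hom(pairs):
    return pd.DataFrame(
        [(y, h, "one-to-one") for y, h in pairs],
        columns=["yeast_gene", "human_gene", "homology_class"],
    )


class TestAssociate:
    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        sens = pd.Series(rng.beta(2, 5, 50), index=[f"c{i}" for i in range(50)])
        expr = pd.DataFrame([-sens.to_numpy()], index=["g"], columns=sens.index)
        tissues = pd.Series("HaL", index=sens.index)
        out = associate(expr, sens, tissues)
        row = out.iloc[0]
        assert row["standardized_coefficient"] == pytest.approx(-1.0)
        assert row["p_value"] < 1e-20

    def test_null_genes_hit_at_alpha_rate(self):
        """Type-I calibration: ~5% of independent genes reach p < 0.05."""
        expr, sens, tissues = generate_pharmaco_dataset(
            200, [f"g{i}" for i in range(800)], ["HaL"], {}, seed=4
        )
        out = associate(expr, sens, tissues)
        frac = (out["p_value"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 800)

    def test_planted_ues_gene_recovered(self):
        expr, sens, tissues = generate_pharmaco_dataset(
            200, ["target", "noise"], ["HaL"], {"target": ("UES", 1.0)}, seed=1
        )
        out = associate(expr, sens, tissues).set_index("human_gene")
        assert out.loc["target", "standardized_coefficient"] < 0
        assert out.loc["target", "p_value"] < 0.05

    def test_stratum_filters_cell_lines(self):
        expr, sens, tissues = generate_pharmaco_dataset(
            60, ["g"], ["HaL", "lung"], {}, seed=2
        )
        out = associate(expr, sens, tissues, stratum="HaL")
        assert out["n_lines"].iloc[0] == int((tissues == "HaL").sum())
        with pytest.raises(ValueError):
            associate(expr, sens, tissues, stratum="HaL", min_lines=10_000)

    def test_constant_expression_skipped(self):
        sens = pd.Series(np.linspace(0, 1, 20), index=[f"c{i}" for i in range(20)])
        expr = pd.DataFrame(
            [np.ones(20), np.linspace(0, 1, 20)], index=["flat", "ok"], columns=sens.index
        )
        out = associate(expr, sens, pd.Series("t", index=sens.index))
        assert list(out["human_gene"]) == ["ok"]


class TestCallHits:
    def setup_method(self):
        self.yeast = make_yeast([
            ("PMR1", "gem", "enhancer", -3.8, 3.6),
            ("CPR3", "gem", "suppressor", 2.1, -4.1),
            ("NULL1", "gem", "none", 0.1, -0.2),
        ])
        self.hom = make_hom([("PMR1", "ATP2C1"), ("CPR3", "PPIA"), ("NULL1", "HX")])

    def test_ues_and_oes_called(self):
        assoc = make_assoc([
            ("ATP2C1", "gem", "HaL", -0.4, 0.001),
            ("PPIA", "gem", "HaL", 0.5, 0.004),
            ("HX", "gem", "HaL", -0.6, 0.0001),
        ])
        hits = call_hits(self.yeast, self.hom, assoc, alpha=0.05)
        d = hits.set_index("yeast_gene")["direction"]
        assert d["PMR1"] == "UES" and d["CPR3"] == "OES"
        assert "NULL1" not in d.index  # class none never hits

    def test_insignificant_association_never_hits(self):
        assoc = make_assoc([("ATP2C1", "gem", "HaL", -0.4, 0.5)])
        assert len(call_hits(self.yeast, self.hom, assoc)) == 0

    def test_wrong_sign_never_hits(self):
        assoc = make_assoc([("ATP2C1", "gem", "HaL", 0.4, 0.001)])  # enhancer but +
        assert len(call_hits(self.yeast, self.hom, assoc)) == 0

    def test_duplicate_homolog_rows_deduplicated(self):
        assoc = make_assoc([("ATP2C1", "gem", "HaL", -0.4, 0.001)])
        hom2 = pd.concat([self.hom, self.hom], ignore_index=True)
        assert len(call_hits(self.yeast, hom2, assoc)) == 1

    def test_unknown_yeast_gene_skipped(self):
        assoc = make_assoc([("ATP2C1", "gem", "HaL", -0.4, 0.001)])
        hom = pd.concat(
            [self.hom, make_hom([("GHOST", "ATP2C1")])], ignore_index=True
        )
        hits = call_hits(self.yeast, hom, assoc)
        assert set(hits["yeast_gene"]) == {"PMR1"}

    def test_alpha_shrinks_hits_monotonically(self):
        assoc = make_assoc([
            ("ATP2C1", "gem", "HaL", -0.4, 0.001),
            ("PPIA", "gem", "HaL", 0.5, 0.03),
        ])
        loose = call_hits(self.yeast, self.hom, assoc, alpha=0.05)
        tight = call_hits(self.yeast, self.hom, assoc, alpha=0.01)
        keys = lambda df: set(map(tuple, df[["yeast_gene", "human_gene"]].to_numpy()))
        assert keys(tight) <= keys(loose)
        assert len(tight) < len(loose)

    def test_sensitivity_sign_flip_swaps_directions(self):
        """Flipping the sensitivity vector flips every coefficient, turning
        each UES call into OES and vice versa — exactly."""
        rng = np.random.default_rng(3)
        lines = [f"c{i}" for i in range(80)]
        sens = pd.Series(rng.beta(2, 5, 80), index=lines)
        tissues = pd.Series("HaL", index=lines)
        expr, _, _ = generate_pharmaco_dataset(
            80, ["A", "B"], ["HaL"], {"A": ("UES", 1.5), "B": ("OES", 1.5)}, seed=3
        )
        # regenerate expression against this sens for a controlled flip test
        z = (sens - sens.mean()) / sens.std(ddof=1)
        expr = pd.DataFrame(
            {"A": -1.5 * z + rng.normal(0, 1, 80), "B": 1.5 * z + rng.normal(0, 1, 80)}
        ).T
        yeast = make_yeast([
            ("yA", "gem", "enhancer", -3.0, 3.0),
            ("yB", "gem", "suppressor", 3.0, -3.0),
        ])
        hom = make_hom([("yA", "A"), ("yB", "B")])

        def run(s):
            assoc = associate(expr, s, tissues)
            assoc.insert(1, "drug", "gem")
            return call_hits(yeast, hom, assoc)

        fwd = run(sens).set_index("yeast_gene")["direction"]
        swapped_yeast = make_yeast([
            ("yA", "gem", "suppressor", 3.0, -3.0),
            ("yB", "gem", "enhancer", -3.0, 3.0),
        ])
        assoc_flipped = associate(expr, -sens, tissues)
        assoc_flipped.insert(1, "drug", "gem")
        rev = call_hits(swapped_yeast, hom, assoc_flipped).set_index("yeast_gene")["direction"]
        assert fwd["yA"] == "UES" and fwd["yB"] == "OES"
        assert rev["yA"] == "OES" and rev["yB"] == "UES"


class TestConservation:
    def test_no_hits_gives_zero(self):
        yeast = make_yeast([("y1", "gem", "enhancer", -3, 3)])
        hits = pd.DataFrame(columns=["yeast_gene", "drug", "tissue", "direction"])
        out = summarize_conservation(hits, yeast)
        assert (out["fraction"] == 0.0).all()

    def test_full_coverage_gives_one(self):
        yeast = make_yeast([
            ("y1", "gem", "enhancer", -3, 3),
            ("y2", "gem", "enhancer", -4, 4),
        ])
        hits = pd.DataFrame(
            [("y1", "h1", "one-to-one", "gem", "all", "UES", -0.5, 0.01),
             ("y2", "h2", "one-to-one", "gem", "all", "UES", -0.4, 0.02)],
            columns=["yeast_gene", "human_gene", "homology_class", "drug",
                     "tissue", "direction", "standardized_coefficient", "p_value"],
        )
        out = summarize_conservation(hits, yeast)
        assert out.loc[0, "fraction"] == 1.0
        assert out.loc[0, "n_enhancers"] == 2
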