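"""Subtraction-screen rounds, BH adjustment and the correlation network."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taxolminer import syn_data
from taxolminer.coexpr_net import (
    CorrEdge,
    bh_adjust,
    build_network,
    pearson_pvalue,
    round1_tissue_filter,
    round2_hc_lc_de,
    round3_anchor_correlation,
)
from taxolminer.formats_io import ExpressionStudy

import oracles


def tissue_study(gene_rpkm: dict[str, tuple[float, float, float]]) -> ExpressionStudy:
    """Build a minimal study whose (root, bark, leaf) mean RPKM match the
    requested values (equal gene lengths and library sizes make RPKM
    proportional to counts)."""
    genes = list(gene_rpkm)
    records = []
    for tissue in ("root", "bark", "leaf"):
        for rep in (1, 2):
            records.append((f"{tissue}_{rep}", tissue, "none", "control", 0.0, rep))
    samples = pd.DataFrame(
        records, columns=["sample", "tissue", "line", "treatment", "time_h", "replicate"]
    ).set_index("sample")
    counts = {}
    for sample, row in samples.iterrows():
        idx = {"root": 0, "bark": 1, "leaf": 2}[row["tissue"]]
        counts[sample] = [int(1000 * gene_rpkm[g][idx]) for g in genes]
    counts_df = pd.DataFrame(counts, index=genes)
    # a constant high-count gene pins the library size near 1e7, making
    # RPKM of the 100 kb test genes ~ counts/1000 = the requested value
    counts_df.loc["filler"] = 10_000_000
    lengths = pd.Series(100_000, index=counts_df.index)
    lengths["filler"] = 1_000
    return ExpressionStudy(counts_df, lengths, samples)


class TestRound1:
    def test_or_semantics(self):
        study = tissue_study({"kept": (5.0, 1.0, 2.0), "dropped": (1.0, 1.0, 2.0)})
        kept = round1_tissue_filter(study)
        assert "kept" in kept
        assert "dropped" not in kept

    def test_expression_floor(self):
        study = tissue_study({"dim": (0.5, 0.2, 0.1)})
        assert "dim" not in round1_tissue_filter(study, floor=1.0)
        assert "dim" in round1_tissue_filter(study, floor=0.01)

    def test_missing_tissue_rejected(self, null_study):
        broken = ExpressionStudy(
            null_study.counts[null_study.columns_for(tissue="root")],
            null_study.gene_lengths,
            null_study.samples.loc[null_study.columns_for(tissue="root")],
        )
        with pytest.raises(ValueError, match="leaf|bark"):
            round1_tissue_filter(broken)


class TestBH:
    def test_hand_stepped_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04, 0.5])
        assert adj == pytest.approx([0.04, 0.04, 0.0533333, 0.5], rel=1e-5)

    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 11)))
            assert bh_adjust(p) == pytest.approx(oracles.bh_oracle(p))


class TestRound2:
    def test_identical_counts_no_survivors(self, null_study):
        de = round2_hc_lc_de(null_study)
        assert de["survivor"].sum() <= 2  # BH under the global null

    def test_planted_fourfold_genes_dominate_survivors(self, planted_study):
        de = round2_hc_lc_de(planted_study["study"])
        survivors = set(de.loc[de["survivor"], "gene_id"])
        planted = planted_study["hc_planted"]
        assert len(survivors & planted) >= 0.9 * len(planted)
        assert len(survivors - planted) <= 0.05 * len(planted) + 2

    def test_all_zero_gene_excluded(self, planted_study):
        study = planted_study["study"]
        counts = study.counts.copy()
        counts.loc["g00000"] = 0
        zeroed = ExpressionStudy(counts, study.gene_lengths, study.samples)
        de = round2_hc_lc_de(zeroed).set_index("gene_id")
        assert np.isnan(de.loc["g00000", "pvalue"])
        assert not de.loc["g00000", "survivor"]


class TestRound3:
    def test_self_correlation_kept(self):
        tc = pd.DataFrame(
            {"t0": [1, 1], "t2": [2, 2], "t4": [5, 5], "t8": [4, 4], "t24": [2, 2]},
            index=["anchor", "copy"],
        ).astype(float)
        edges = round3_anchor_correlation(tc, ["anchor"], ["copy"])
        assert len(edges) == 1
        assert edges[0].r == pytest.approx(1.0)

    def test_minimal_significant_r_at_five_points(self):
        """At n=5 and alpha=0.05 the survival boundary is |r| ~ 0.878."""
        t_crit = stats.t.ppf(0.975, df=3)
        r_min = t_crit / np.sqrt(t_crit**2 + 3)
        assert r_min == pytest.approx(0.8783, abs=5e-4)
        assert pearson_pvalue(r_min * 1.001, 5) < 0.05
        assert pearson_pvalue(r_min * 0.999, 5) > 0.05

    def test_pvalue_matches_permutation_oracle(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(scale=1.0, size=30)
        r = float(np.corrcoef(x, y)[0, 1])
        p_t = pearson_pvalue(r, 30)
        p_perm = oracles.permutation_pearson_pvalue(x, y, 10_000, rng)
        assert p_t == pytest.approx(p_perm, abs=0.02)

    def test_zero_variance_series_skipped(self):
        tc = pd.DataFrame(
            {"t0": [1, 3], "t2": [1, 4], "t4": [1, 6], "t8": [1, 5], "t24": [1, 2]},
            index=["flat", "anchor"],
        ).astype(float)
        assert round3_anchor_correlation(tc, ["anchor"], ["flat"]) == []

    def test_null_series_survive_at_nominal_rate(self, rng):
        tc = pd.DataFrame(
            rng.normal(size=(1001, 5)), index=[f"n{i}" for i in range(1001)]
        )
        edges = round3_anchor_correlation(tc, ["n0"], [f"n{i}" for i in range(1, 1001)])
        assert abs(len(edges) / 1000 - 0.05) < 0.025

    def test_planted_partner_recovery(self, planted_study):
        study = planted_study["study"]
        anchors = list(planted_study["anchors"])
        partners = set(planted_study["partners"])
        candidates = sorted(set(study.counts.index) - set(anchors))
        edges = round3_anchor_correlation(study, anchors, candidates)
        recovered = {e.candidate_id for e in edges} & partners
        assert len(recovered) >= 9


class TestNetwork:
    def test_no_anchors_empty(self):
        assert build_network([]).number_of_nodes() == 0

    def test_candidate_with_two_anchors_single_node(self):
        edges = [
            CorrEdge("a1", "c", 0.95, 0.01),
            CorrEdge("a2", "c", 0.91, 0.03),
        ]
        g = build_network(edges)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2

    def test_survivor_intersection_and_annotations(self):
        edges = [
            CorrEdge("a1", "kept", 0.95, 0.01),
            CorrEdge("a1", "dropped", 0.95, 0.01),
        ]
        g = build_network(
            edges,
            de_survivors=["kept"],
            annotations={"kept": {"family": "CYP725A", "tf": False}},
        )
        assert set(g.nodes) == {"a1", "kept"}
        assert g.nodes["kept"]["family"] == "CYP725A"

    def test_screen_is_a_filter_chain(self, planted_study):
        """Final network candidates are a subset of rounds 1 and 2 survivors."""
        study = planted_study["study"]
        r1 = round1_tissue_filter(study)
        de = round2_hc_lc_de(study)
        r2 = set(de.loc[de["survivor"], "gene_id"])
        candidates = sorted((r1 & r2) - set(planted_study["anchors"]))
        edges = round3_anchor_correlation(
            study, list(planted_study["anchors"]), candidates
        )
        g = build_network(edges, de_survivors=r2)
        non_anchor_nodes = {
            n for n, d in g.nodes(data=True) if d.get("role") != "anchor"
        }
        assert non_anchor_nodes <= (r1 & r2)
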