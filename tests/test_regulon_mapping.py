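import itertools
import math

import numpy as np
import pandas as pd
import pytest

from regulonmap.coverage_io import MINUS, PLUS
from regulonmap.datasets import (
    load_flhdc_sites,
    load_flia_sites,
    synthetic_gene_spans_for_flia_sites,
)
from regulonmap.regulon_mapping import (
    AnnotationConfig,
    associate_sites_with_genes,
    classify_network,
    classify_regulation,
    classify_site_location,
    compare_magnitude,
    fold_change,
    network_edge_list,
    significant_de,
)
from regulonmap.synthetic_data import (
    SimulationConfig,
    assign_gene_classes,
    generate_annotation,
    generate_chip_experiment,
    generate_expression_table,
)


class TestSignificantDe:
    def test_collapsed_flagellar_operon_is_significant(self):
        # the master regulator's flgAMN target: 319 in wild type, 3 in the
        # deletion, q far below the cutoff
        rec = dict(gene="flgA", WT=319, delta=3, q_value=0.001)
        assert significant_de(rec, "WT", "delta")

    def test_identical_expression_is_not_significant(self):
        rec = dict(gene="x", WT=150, delta=150, q_value=0.0)
        assert not significant_de(rec, "WT", "delta")

    def test_good_fold_with_bad_q_is_not_significant(self):
        rec = dict(gene="x", WT=100, delta=10, q_value=0.02)
        assert not significant_de(rec, "WT", "delta")

    def test_missing_strain_is_an_error(self):
        with pytest.raises(KeyError):
            significant_de(dict(gene="x", WT=1, q_value=0.5), "WT", "delta")

    def test_pseudocount_keeps_zero_expression_finite(self):
        # a fully collapsed target like ycgR (104 vs 0)
        assert fold_change(104, 0) == pytest.approx(105.0)
        rec = dict(gene="ycgR", WT=104, delta=0, q_value=0.001)
        assert significant_de(rec, "WT", "delta")


@pytest.fixture
def toy_genes():
    return pd.DataFrame(dict(
        gene=["gA", "gB", "gC", "gD"],
        start=[1_000, 3_000, 6_000, 10_000],
        end=[2_000, 4_500, 7_000, 11_000],
        strand=[PLUS, MINUS, PLUS, MINUS],
    ))


class TestSiteLocation:
    def test_center_inside_a_gene_is_intragenic(self, toy_genes):
        loc = classify_site_location(1_500, toy_genes, site_strand=PLUS)
        assert loc["location_class"] == "intragenic"
        assert loc["nearest_gene"] == "gA"
        assert loc["orientation"] == "sense"

    def test_antisense_host_orientation(self, toy_genes):
        loc = classify_site_location(3_500, toy_genes, site_strand=PLUS)
        assert (loc["location_class"], loc["orientation"]) == \
            ("intragenic", "antisense")

    def test_center_between_genes_is_intergenic(self, toy_genes):
        loc = classify_site_location(5_000, toy_genes)
        assert loc["location_class"] == "intergenic"

    def test_center_at_gene_start_is_intragenic_closed_interval(self, toy_genes):
        assert classify_site_location(3_000, toy_genes)["location_class"] \
            == "intragenic"

    def test_upstream_distance_to_appropriately_oriented_start(self, toy_genes):
        # 5,000 is 1,000 bp before gC's start (plus strand, pointing away)
        # and 500 bp beyond gB's end (minus strand, pointing away)
        loc = classify_site_location(5_000, toy_genes)
        assert loc["upstream_of_start"] == 500
        assert loc["nearest_gene"] == "gB"

    def test_empty_annotation_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            classify_site_location(100, pd.DataFrame())


class TestAssociation:
    def test_divergent_gene_pair_yields_two_links(self):
        # a site between divergent genes (the yciK/sohB arrangement)
        genes = pd.DataFrame(dict(
            gene=["yciK", "sohB"], start=[800, 1_200], end=[400, 1_900],
            strand=[MINUS, PLUS],
        ))
        genes.loc[0, ["start", "end"]] = [400, 800]  # minus gene span
        sites = pd.DataFrame(dict(site_id=["s1"], center=[1_000]))
        links = associate_sites_with_genes(sites, genes)
        assert set(links.gene) == {"yciK", "sohB"}

    def test_site_deep_inside_long_gene_links_host_only(self):
        genes = pd.DataFrame(dict(gene=["long", "far"],
                                  start=[1_000, 9_000], end=[5_000, 9_900],
                                  strand=[PLUS, PLUS]))
        sites = pd.DataFrame(dict(site_id=["s1"], center=[2_500]))
        links = associate_sites_with_genes(sites, genes)
        assert links.gene.tolist() == ["long"]
        assert links.link_type.tolist() == ["host_n/a"]

    def test_association_window_is_inclusive_at_the_boundary(self):
        genes = pd.DataFrame(dict(gene=["g"], start=[1_300], end=[2_000],
                                  strand=[PLUS]))
        cfg = AnnotationConfig(association_window=300)
        at = associate_sites_with_genes(
            pd.DataFrame(dict(site_id=["s"], center=[1_000])), genes, cfg)
        beyond = associate_sites_with_genes(
            pd.DataFrame(dict(site_id=["s"], center=[999])), genes, cfg)
        assert at.gene.tolist() == ["g"] and beyond.empty


class TestRegulationClasses:
    def test_bound_but_unchanged_gene_is_bound_unregulated(self):
        # the gntR pattern: a confident binding site, no expression change
        links = pd.DataFrame(dict(site_id=["s"], gene=["gntR"],
                                  link_type=["promoter"]))
        de = pd.DataFrame(dict(gene=["gntR"], WT=[160], delta=[140],
                               q_value=[0.9]))
        assignments, counts = classify_regulation(links, de, "WT", "delta")
        assert assignments.regulation.tolist() == ["bound_unregulated"]
        assert counts["bound_unregulated"] == 1

    def test_significant_unlinked_gene_is_indirect(self):
        de = pd.DataFrame(dict(gene=["x"], WT=[400], delta=[40],
                               q_value=[0.001]))
        assignments, _ = classify_regulation(pd.DataFrame(columns=["site_id",
                                                                   "gene"]),
                                             de, "WT", "delta")
        assert assignments.regulation.tolist() == ["indirect"]

    def test_partition_sums_to_universe(self, regulon_truth):
        cfg, exp, genes, truth, expression = regulon_truth
        sites = pd.DataFrame(dict(
            site_id=[f"s{i}" for i in range(len(exp.truth.site_centers))],
            center=exp.truth.site_centers,
        ))
        links = associate_sites_with_genes(sites, genes)
        assignments, counts = classify_regulation(links, expression,
                                                  "WT", "delta")
        assert sum(counts.values()) == len(expression)
        assert set(assignments.regulation) <= {
            "direct", "indirect", "bound_unregulated", "unaffected"}

    def test_noise_free_truth_classes_recovered(self, regulon_truth):
        cfg, exp, genes, truth, expression = regulon_truth
        sites = pd.DataFrame(dict(
            site_id=[f"s{i}" for i in range(len(exp.truth.site_centers))],
            center=exp.truth.site_centers,
        ))
        links = associate_sites_with_genes(sites, genes)
        assignments, _ = classify_regulation(links, expression, "WT", "delta")
        merged = assignments.merge(
            pd.Series(truth.gene_classes, name="truth").rename_axis("gene"),
            on="gene")
        direct_truth = merged.truth.isin(["direct_activated",
                                          "direct_repressed"])
        # every truly direct gene is recovered as direct
        assert (merged.loc[direct_truth, "regulation"] == "direct").all()
        # every truly indirect gene is recovered as indirect unless a site
        # happens to sit in its promoter window
        indirect = merged[merged.truth == "indirect"]
        assert (indirect.regulation.isin(["indirect", "direct"])).all()
        assert (merged.loc[merged.truth == "unregulated", "regulation"]
                .isin(["unaffected", "bound_unregulated"])).all()


def exact_mann_whitney_p(a, b):
    """Exhaustive-enumeration oracle: one-sided P(U >= u_obs) over all
    re-labelings of the pooled sample."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(xs, ys):
        return sum(x > y for x in xs for y in ys)

    observed = u_stat(a, b)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(xs, ys) >= observed:
            count += 1
    return count / total


class TestCompareMagnitude:
    def test_identical_groups_sit_at_the_null(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        stat, p = compare_magnitude(a, list(a))
        assert p > 0.9

    def test_fully_separated_groups_exact_p(self):
        direct = [6.0, 7.0, 8.0, 9.0, 10.0]
        indirect = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = compare_magnitude(direct, indirect, alternative="greater")
        assert p == pytest.approx(1 / 252)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agreement_with_enumeration_for_small_n(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1.0, 1.0, size=rng.integers(3, 8)).round(3)
        b = rng.normal(0.0, 1.0, size=rng.integers(3, 8)).round(3)
        _, p = compare_magnitude(a, b, alternative="greater")
        assert p == pytest.approx(exact_mann_whitney_p(a, b))

    def test_three_groups_use_kruskal_wallis(self):
        stat, p = compare_magnitude([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert p < 0.05

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            compare_magnitude([1.0], [])

    def test_direct_magnitudes_dominate_indirect_on_synthetic_regulon(
            self, regulon_truth):
        cfg, exp, genes, truth, expression = regulon_truth
        classes = pd.Series(truth.gene_classes, name="truth").rename_axis("gene")
        df = expression.merge(classes, on="gene")
        mag = np.abs(np.log2((df.WT + 1) / (df.delta + 1)))
        direct = mag[df.truth == "direct_activated"]
        indirect = mag[df.truth == "indirect"]
        _, p = compare_magnitude(direct, indirect, alternative="greater")
        assert p < 1e-4


class TestNetwork:
    def _assign(self, rows):
        return pd.DataFrame(rows, columns=["gene", "regulation", "direction"])

    def test_class_assignment_for_each_binding_pattern(self):
        master = self._assign([("fliA", "direct", "activation"),
                               ("flgB", "direct", "activation"),
                               ("fliD", "direct", "activation"),
                               ("gntR", "bound_unregulated", "potential"),
                               ("other", "unaffected", "n/a")])
        sigma = self._assign([("fliC", "direct", "activation"),
                              ("fliD", "direct", "activation"),
                              ("other", "indirect", "n/a")])
        net = classify_network(master, sigma).set_index("gene")
        assert net.loc["flgB", "network_class"] == "class2"
        assert net.loc["fliC", "network_class"] == "class3"
        assert net.loc["fliD", "network_class"] == "dual"
        assert net.loc["gntR", "network_class"] == "class2"
        assert net.loc["other", "network_class"] == "none"

    def test_three_dual_operons_give_exactly_three_dual_calls(self):
        dual_genes = ["fliD", "flgM", "flgK"]
        master = self._assign([(g, "direct", "activation")
                               for g in dual_genes + ["flgB"]])
        sigma = self._assign([(g, "direct", "activation")
                              for g in dual_genes + ["fliC"]])
        net = classify_network(master, sigma)
        assert (net.network_class == "dual").sum() == 3

    def test_edge_list_labels_follow_direction(self):
        master = self._assign([("a", "direct", "repression"),
                               ("b", "bound_unregulated", "potential")])
        sigma = self._assign([("a", "direct", "activation")])
        edges = network_edge_list(classify_network(master, sigma))
        labels = {(e.regulator, e.gene): e.label for e in edges.itertuples()}
        assert labels[("master", "a")] == "repression"
        assert labels[("master", "b")] == "potential"
        assert labels[("sigma", "a")] == "activation"


class TestPackagedFixtures:
    def test_master_regulator_significance_flags_match_de_rule(self):
        # the asterisked rows of the binding-site table all collapse by far
        # more than 2-fold; unflagged rows stay under the rule's radar
        df = load_flhdc_sites().dropna(subset=["peak_center"])
        fold = (df[["expr_wt", "expr_dflhd"]].max(axis=1) + 1) \
            / (df[["expr_wt", "expr_dflhd"]].min(axis=1) + 1)
        assert (fold[df.sig_dflhd == 1] >= 2).all()
        assert (fold[df.sig_dflhd == 0] < 2).all()

    def test_intragenic_labels_reproduced_site_for_site(self):
        df = load_flia_sites()
        genes = synthetic_gene_spans_for_flia_sites(df)
        for row in df.itertuples():
            loc = classify_site_location(row.peak_center, genes,
                                         site_strand=row.motif_strand)
            expected = "intragenic" if row.intragenic else "intergenic"
            assert loc["location_class"] == expected, row.locus
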