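import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from circkit.annotation import GeneModel
from circkit.catalog import CircRecord, annotate_catalog
from circkit.enrichment import (
    DETable,
    chi_squared_2x2,
    flag_significant,
    flag_upregulated,
    genomewide_average_ratio,
    load_de_table,
    load_gene_list,
    ratio_enrichment,
    recurrent_responders,
    target_site_overlap,
)
from circkit.errors import (
    DegenerateTableError,
    InsufficientDataError,
    ValidationError,
)

from conftest import make_record


def de_table(rows, condition="miR-test"):
    return DETable(
        condition=condition,
        frame=pd.DataFrame(rows, columns=["circ_id", "log2fc", "pvalue", "padj"]),
    )


class TestLoadDETable:
    def test_deseq2_style_header(self, tmp_path):
        p = tmp_path / "de.tsv"
        p.write_text(
            "circ_id\tlog2FoldChange\tpvalue\tpadj\n"
            "c1\t1.2\t0.001\t0.01\n"
            "c2\tNA\tNA\tNA\n"
        )
        de = load_de_table(p, condition="x")
        assert list(de.frame.columns) == ["circ_id", "log2fc", "pvalue", "padj"]
        assert math.isnan(de.frame.loc[1, "padj"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            de_table([("c1", 1, 0.1, 0.2), ("c1", 2, 0.1, 0.2)])


class TestFlagUpregulated:
    def test_included(self):
        de = de_table([("c1", 1.2, 0.005, 0.01)])
        assert flag_upregulated(de, alpha=0.05) == {"c1"}

    def test_downregulated_excluded(self):
        de = de_table([("c2", -2.0, 0.0005, 0.001)])
        assert flag_upregulated(de, alpha=0.05) == set()

    def test_nan_padj_excluded(self):
        de = de_table([("c1", 1.2, 0.005, float("nan"))])
        assert flag_upregulated(de) == set()

    def test_empty_table(self):
        assert flag_upregulated(de_table([])) == set()

    def test_infinite_lfc_min_empty(self):
        de = de_table([("c1", 100.0, 1e-10, 1e-9)])
        assert flag_upregulated(de, lfc_min=float("inf")) == set()

    def test_significant_either_direction(self):
        de = de_table([("c1", -2.0, 0.001, 0.01), ("c2", 2.0, 0.001, 0.01),
                       ("c3", 0.5, 0.5, 0.9)])
        assert flag_significant(de, alpha=0.05) == {"c1", "c2"}


class TestGenomewideAverage:
    def _gene(self, gid, length, k):
        exons = [(1 + 100 * i, 1 + 100 * i + 9) for i in range(k - 1)]
        exons.append((length - 9, length))
        return GeneModel(gene_id=gid, chromosome="chr1", start=1, end=length,
                         exons=exons)

    def test_mean_of_two(self):
        genes = [self._gene("A", 1000, 1), self._gene("B", 3000, 1)]
        assert genomewide_average_ratio(genes, scope="all_genes") == 2000.0

    def test_single_gene(self):
        genes = [self._gene("A", 4500, 1)]
        assert genomewide_average_ratio(genes, scope="all_genes") == 4500.0

    def test_host_scope_restricts(self):
        genes = [self._gene("A", 1000, 1), self._gene("B", 3000, 1)]
        rec = make_record(start=10, end=20)
        rec.host_gene_id = "A"
        avg = genomewide_average_ratio(genes, catalog=[rec], scope="host_genes")
        assert avg == 1000.0

    def test_empty_scope(self):
        genes = [self._gene("A", 1000, 1)]
        with pytest.raises(InsufficientDataError):
            genomewide_average_ratio(genes, catalog=[], scope="host_genes")

    def test_matches_truth_mean(self, default_dataset):
        ds = default_dataset
        records = annotate_catalog(
            [CircRecord(chrom=c, start=s, end=e, strand=st, read_count=n)
             for c, s, e, st, n in ds.circ_calls.itertuples(index=False)],
            ds.genes,
        )
        avg = genomewide_average_ratio(ds.genes, catalog=records)
        assert avg == pytest.approx(ds.truth.genomewide_avg_ratio)


class TestChiSquared:
    def test_proportional_table(self):
        stat, p, df = chi_squared_2x2([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == 1.0
        assert df == 1

    def test_hand_oracle(self):
        # E = 20 in every cell -> stat = 4 * (100/20) = 20.0
        stat, p, _ = chi_squared_2x2([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(20.0, 1))

    def test_zero_margin(self):
        with pytest.raises(DegenerateTableError, match="margin"):
            chi_squared_2x2([[0, 0], [10, 30]])
        with pytest.raises(DegenerateTableError):
            chi_squared_2x2([[0, 10], [0, 30]])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            chi_squared_2x2([[-1, 2], [3, 4]])

    def test_continuity_reduces_stat(self):
        s0, _, _ = chi_squared_2x2([[30, 10], [10, 30]], continuity=False)
        s1, _, _ = chi_squared_2x2([[30, 10], [10, 30]], continuity=True)
        assert s1 < s0

    @given(st.tuples(st.integers(1, 200), st.integers(1, 200),
                     st.integers(1, 200), st.integers(1, 200)))
    def test_shortcut_formula_identity(self, cells):
        a, b, c, d = cells
        stat, _, _ = chi_squared_2x2([[a, b], [c, d]])
        n = a + b + c + d
        shortcut = (a * d - b * c) ** 2 * n / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert stat == pytest.approx(shortcut, rel=1e-9)


def planted_fixture():
    """Small hand-built catalog: low-ratio hosts mostly up, high-ratio not."""
    genes, catalog, rows = [], [], []
    for i in range(12):
        low = i < 6
        length = 2_000 if low else 80_000
        start = 200_000 * (i + 1)
        k = 4
        exons = [(start + 300 * j, start + 300 * j + 49) for j in range(k - 1)]
        exons.append((start + length - 50, start + length - 1))
        g = GeneModel(gene_id=f"G{i:02d}", chromosome="chr1", start=start,
                      end=start + length - 1, strand="+",
                      biotype="protein_coding", exons=exons)
        genes.append(g)
        r = make_record(chrom="chr1", start=g.exons[0][0], end=g.exons[1][1],
                        strand="+", count=10)
        r.host_gene_id = g.gene_id
        catalog.append(r)
        up = low and i < 5  # 5 of 6 low up; 0 of 6 high up
        rows.append((r.circ_id, 2.0 if up else 0.0,
                     0.001 if up else 0.5, 0.01 if up else 0.8))
    return genes, catalog, de_table(rows)


class TestRatioEnrichment:
    def test_contingency_sums_to_assessable(self):
        genes, catalog, de = planted_fixture()
        res = ratio_enrichment(catalog, genes, de)
        assert sum(sum(row) for row in res.contingency) == res.n_assessable
        assert res.n_assessable == len(catalog)

    def test_planted_effect_detected(self):
        genes, catalog, de = planted_fixture()
        res = ratio_enrichment(catalog, genes, de)
        assert res.avg_ratio_overexpressed < res.avg_ratio_stable
        assert res.p_value < 0.05
        assert res.contingency[0][0] == 5  # low & up

    def test_order_invariant(self):
        genes, catalog, de = planted_fixture()
        res1 = ratio_enrichment(catalog, genes, de)
        shuffled_de = DETable(
            condition=de.condition,
            frame=de.frame.iloc[::-1].reset_index(drop=True),
        )
        res2 = ratio_enrichment(list(reversed(catalog)), genes, shuffled_de)
        assert res1.contingency == res2.contingency
        assert res1.chi2_stat == pytest.approx(res2.chi2_stat)

    def test_zero_upregulated_degenerate(self):
        genes, catalog, _ = planted_fixture()
        rows = [(r.circ_id, 0.0, 0.5, 0.9) for r in catalog]
        with pytest.raises(DegenerateTableError, match="upregulated"):
            ratio_enrichment(catalog, genes, de_table(rows))

    def test_empty_assessable_set(self):
        genes, catalog, _ = planted_fixture()
        with pytest.raises(InsufficientDataError):
            ratio_enrichment(catalog, genes, de_table([]))

    def test_permutation_p_agrees_roughly(self):
        genes, catalog, de = planted_fixture()
        res = ratio_enrichment(catalog, genes, de, n_permutations=2000, seed=0)
        assert res.permutation_p is not None
        assert res.permutation_p < 0.05


class TestTargetSiteOverlap:
    def test_basic(self):
        assert target_site_overlap({"A", "B", "C"}, {"B", "D"}) == (3, 1)

    def test_empty_targets(self):
        assert target_site_overlap({"A", "B"}, set()) == (2, 0)

    def test_planted_overlap_recovered(self, default_dataset):
        ds = default_dataset
        truth = ds.truth
        cond = truth.conditions[0]
        c = truth.circles
        de_hosts = {
            h for h, pa in zip(c["host_gene_id"], c[f"padj_{cond}"])
            if h and pa < 0.05
        }
        n_de, n_hit = target_site_overlap(de_hosts, ds.targets[cond])
        assert n_de == len(de_hosts)
        planted_hits = set(ds.targets[cond]) & de_hosts
        assert n_hit == len(planted_hits)

    def test_load_gene_list(self, tmp_path):
        p = tmp_path / "targets.txt"
        p.write_text("A\n\nB\nC\n")
        assert load_gene_list(p) == ["A", "B", "C"]


class TestRecurrentResponders:
    def _catalog(self, hosts):
        catalog = []
        for i, h in enumerate(hosts):
            r = make_record(start=100 * i + 1, end=100 * i + 50)
            r.host_gene_id = h
            catalog.append(r)
        return catalog

    def test_shared_singleton(self):
        catalog = self._catalog(["A", "B", "C"])
        ids = [r.circ_id for r in catalog]
        de1 = de_table([(ids[0], 1, 0.001, 0.01), (ids[1], 1, 0.001, 0.01)],
                       condition="c1")
        de2 = de_table([(ids[0], -1, 0.001, 0.01), (ids[2], 1, 0.001, 0.01)],
                       condition="c2")
        assert recurrent_responders([de1, de2], catalog) == {"A"}

    def test_disjoint_sets_empty(self):
        catalog = self._catalog(["A", "B"])
        ids = [r.circ_id for r in catalog]
        de1 = de_table([(ids[0], 1, 0.001, 0.01)], condition="c1")
        de2 = de_table([(ids[1], 1, 0.001, 0.01)], condition="c2")
        assert recurrent_responders([de1, de2], catalog) == set()

    def test_needs_two_conditions(self):
        with pytest.raises(ValidationError):
            recurrent_responders([de_table([])], [])

    def test_planted_responders_exact_with_null_background(self):
        # no background up-probability -> recovered == planted exactly
        from circkit.simulate import SynthConfig, simulate_dataset

        cfg = SynthConfig(seed=3, enrichment_effect=(0.0, 0.0), n_responders=4)
        ds = simulate_dataset(cfg)
        records = annotate_catalog(
            [CircRecord(chrom=c, start=s, end=e, strand=st, read_count=n)
             for c, s, e, st, n in ds.circ_calls.itertuples(index=False)],
            ds.genes,
        )
        tables = [
            DETable(condition=cond, frame=frame.rename(
                columns={"log2FoldChange": "log2fc"}))
            for cond, frame in ds.de_frames.items()
        ]
        found = recurrent_responders(tables, records)
        assert found == set(ds.truth.planted_responders)
        assert len(found) == 4
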