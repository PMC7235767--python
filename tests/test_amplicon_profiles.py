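import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from digestor import amplicon_profiles as ap

from conftest import make_table


def fastq_text(records):
    lines = []
    for rid, seq, quals in records:
        lines += [f"@{rid}", seq, "+", "".join(chr(q + 33) for q in quals)]
    return "\n".join(lines) + "\n"


def make_read(rid, length, mean_q):
    return ap.ReadRecord(id=rid, sequence="A" * length, qualities=(int(mean_q),) * length)


class TestFilterReads:
    def test_short_read_removed(self):
        kept, summary = ap.filter_reads([make_read("r", 399, 30)])
        assert kept == [] and summary.removed_length == 1

    def test_boundary_read_retained(self):
        kept, summary = ap.filter_reads([make_read("r", 400, 7)])
        assert len(kept) == 1 and summary.retained == 1

    def test_low_quality_removed(self):
        kept, summary = ap.filter_reads([make_read("r", 500, 6)])
        assert kept == [] and summary.removed_quality == 1

    def test_constructed_thousand_read_file(self, rng):
        # 300 reads pass by construction, 400 fail on length, 300 on quality
        reads = (
            [make_read(f"p{i}", 400 + int(rng.integers(0, 200)), 20) for i in range(300)]
            + [make_read(f"l{i}", int(rng.integers(50, 400)), 20) for i in range(400)]
            + [make_read(f"q{i}", 450, 6) for i in range(300)]
        )
        order = rng.permutation(len(reads))
        kept, summary = ap.filter_reads([reads[i] for i in order])
        assert summary.total == 1000
        assert summary.retained == len(kept) == 300
        assert summary.removed_length == 400
        assert summary.removed_quality == 300
        assert all(r.id.startswith("p") for r in kept)

    def test_fastq_round_trip(self):
        text = fastq_text([("a", "ACGT", [30, 30, 2, 40]), ("b", "GG", [7, 7])])
        records = list(ap.read_fastq(io.StringIO(text)))
        assert [r.id for r in records] == ["a", "b"]
        assert records[0].qualities == (30, 30, 2, 40)
        assert records[1].mean_quality == 7.0

    def test_malformed_fastq_reports_index(self):
        text = "@ok\nACGT\n+\nIIII\n@broken\nACGT\n+\nII\n"
        it = ap.read_fastq(io.StringIO(text))
        assert next(it).id == "ok"
        with pytest.raises(ap.FastqParseError) as err:
            list(it)
        assert err.value.index == 1

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ap.ReadRecord(id="x", sequence="ACGT", qualities=(1, 2))


class TestRelativeAbundance:
    def test_even_counts(self):
        t = make_table([[2, 2]], ["a", "b"], ["s1"])
        p = ap.relative_abundance(t)
        assert p.proportions.loc["s1"].tolist() == [0.5, 0.5]

    def test_zero_sample_flagged(self):
        t = make_table([[0, 0]], ["a", "b"], ["s1"])
        p = ap.relative_abundance(t)
        assert p.empty_samples == {"s1"}
        assert p.proportions.loc["s1"].isna().all()

    def test_rows_sum_to_one(self, rng):
        counts = rng.integers(1, 100, size=(20, 30))
        t = make_table(counts, [f"t{i}" for i in range(30)], [f"s{i}" for i in range(20)])
        p = ap.relative_abundance(t)
        assert np.allclose(p.proportions.sum(axis=1), 1.0, atol=1e-9)


class TestAggregateRank:
    def test_sums_within_phylum(self, small_table):
        agg = ap.aggregate_rank(small_table, "phylum")
        assert agg.counts.loc["s1", "Firmicutes"] == 3 + 5

    def test_unresolved_grouped_under_parent(self, small_table):
        agg = ap.aggregate_rank(small_table, "genus")
        assert "unclassified-Bacteroidetes" in agg.counts.columns

    def test_identity_at_same_rank(self):
        lineages = {"g1": ("B", "P", "C", "O", "F", "g1"), "g2": ("B", "P", "C", "O", "F", "g2")}
        t = make_table([[1, 2]], ["g1", "g2"], ["s1"], lineages=lineages)
        agg = ap.aggregate_rank(t, "genus")
        assert sorted(agg.counts.columns) == ["g1", "g2"]
        assert agg.counts.loc["s1"].sum() == 3

    def test_totals_conserved(self, rng):
        taxa = [f"t{i}" for i in range(12)]
        lineages = {
            t: ("B", f"P{i % 3}", f"C{i % 4}", "O", "F", f"G{i}") for i, t in enumerate(taxa)
        }
        counts = rng.integers(0, 50, size=(6, 12))
        t = make_table(counts, taxa, [f"s{i}" for i in range(6)], lineages=lineages)
        for rank in ("phylum", "class", "genus"):
            agg = ap.aggregate_rank(t, rank)
            assert (agg.counts.sum(axis=1) == t.counts.sum(axis=1)).all()

    def test_unknown_rank_rejected(self, small_table):
        with pytest.raises(ValueError):
            ap.aggregate_rank(small_table, "kingdomish")


class TestTopTaxa:
    def test_orders_by_total(self):
        # summed proportions: a = 9/14 + 1, b = 4/14, c = 1/14
        t = make_table([[9, 4, 1], [1, 0, 0]], ["a", "b", "c"], ["s1", "s2"])
        p = ap.relative_abundance(t)
        assert ap.top_taxa(p, 2) == ["a", "b"]

    def test_tie_breaks_lexicographically(self):
        t = make_table([[5, 5, 0]], ["zzz", "aaa", "mid"], ["s1"])
        p = ap.relative_abundance(t)
        assert ap.top_taxa(p, 2) == ["aaa", "zzz"]

    def test_n_larger_than_taxa_returns_all(self):
        t = make_table([[1, 2]], ["a", "b"], ["s1"])
        p = ap.relative_abundance(t)
        assert len(ap.top_taxa(p, 99)) == 2

    def test_matches_brute_force_oracle(self, rng):
        n_taxa = 50
        counts = rng.integers(0, 1000, size=(8, n_taxa))
        taxa = [f"t{i:03d}" for i in range(n_taxa)]
        t = make_table(counts, taxa, [f"s{i}" for i in range(8)])
        p = ap.relative_abundance(t)
        totals = p.proportions.sum(axis=0)
        oracle = sorted(taxa, key=lambda x: (-totals[x], x))[:10]
        assert ap.top_taxa(p, 10) == oracle


class TestIntersectTop:
    def _profile(self, counts, taxa):
        t = make_table(counts, taxa, [f"s{i}" for i in range(len(counts))])
        return ap.relative_abundance(t)

    def test_identical_profiles_keep_all(self):
        taxa = list("abcde")
        p = self._profile([[5, 4, 3, 2, 1]], taxa)
        assert ap.intersect_top({"c1": p, "c2": p}, 3) == ["a", "b", "c"]

    def test_disjoint_tops_empty(self):
        p1 = self._profile([[10, 1, 1, 0, 0, 0]], list("abcdef"))
        p2 = self._profile([[0, 0, 0, 10, 1, 1]], list("abcdef"))
        assert ap.intersect_top({"c1": p1, "c2": p2}, 3) == []

    def test_constructed_seven_taxon_intersection(self, rng):
        # 4 conditions; 7 shared dominant taxa plus 3 condition-specific ones
        shared = [f"core{i}" for i in range(7)]
        profiles = {}
        for c in range(4):
            uniq = [f"u{c}_{i}" for i in range(3)]
            taxa = shared + uniq
            base = np.concatenate([rng.uniform(50, 100, 7), rng.uniform(5, 10, 3)])
            profiles[f"cond{c}"] = ap.relative_abundance(
                make_table(base[None, :].astype(int) + 1, taxa, [f"s{c}"])
            )
        kept = ap.intersect_top(profiles, 10)
        assert sorted(kept) == sorted(shared)

    def test_requires_two_conditions(self):
        p = self._profile([[1, 2]], ["a", "b"])
        with pytest.raises(ValueError):
            ap.intersect_top({"only": p}, 5)


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        t = make_table([[3, 3], [3, 3]], ["a", "b"], ["s1", "s2"])
        d = ap.bray_curtis(ap.relative_abundance(t))
        assert d.loc["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        t = make_table([[5, 0], [0, 7]], ["a", "b"], ["s1", "s2"])
        d = ap.bray_curtis(ap.relative_abundance(t))
        assert d.loc["s1", "s2"] == pytest.approx(1.0)

    def test_hand_computed_half(self):
        t = make_table([[1, 1], [2, 0]], ["a", "b"], ["s1", "s2"])
        d = ap.bray_curtis(ap.relative_abundance(t))
        assert d.loc["s1", "s2"] == pytest.approx(0.5)

    def test_empty_sample_masked(self):
        t = make_table([[1, 1], [0, 0]], ["a", "b"], ["s1", "s2"])
        d = ap.bray_curtis(ap.relative_abundance(t))
        assert np.isnan(d.loc["s1", "s2"])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_metric_properties_on_random_fixtures(self, seed):
        r = np.random.default_rng(seed)
        counts = r.integers(1, 50, size=(5, 8))
        t = make_table(counts, [f"t{i}" for i in range(8)], [f"s{i}" for i in range(5)])
        d = ap.bray_curtis(ap.relative_abundance(t)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()

    def test_oracle_formula(self, rng):
        counts = rng.integers(1, 100, size=(3, 6))
        t = make_table(counts, [f"t{i}" for i in range(6)], ["s0", "s1", "s2"])
        p = ap.relative_abundance(t)
        d = ap.bray_curtis(p)
        x, y = p.proportions.loc["s0"].to_numpy(), p.proportions.loc["s1"].to_numpy()
        expect = np.abs(x - y).sum() / (x + y).sum()
        assert d.loc["s0", "s1"] == pytest.approx(expect, rel=1e-12)


class TestOrdinate:
    def test_two_samples(self):
        d = pd.DataFrame([[0.0, 0.6], [0.6, 0.0]], index=["a", "b"], columns=["a", "b"])
        res = ap.ordinate(d, k=2)
        coords = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        assert coords == pytest.approx([-0.3, 0.3])

    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)))
        res = ap.ordinate(d, k=2)
        rec = res.coordinates.to_numpy()
        # Procrustes: optimal rotation between centered configurations
        a = pts - pts.mean(axis=0)
        u, _, vt = np.linalg.svd(rec.T @ a)
        aligned = rec @ u @ vt
        assert np.max(np.abs(aligned - a)) < 1e-8

    def test_equilateral_configuration(self):
        d = pd.DataFrame(1 - np.eye(3))
        res = ap.ordinate(d, k=2)
        # all three pairwise embedding distances equal, two equal eigenvalues
        c = res.coordinates.to_numpy()
        dists = [np.linalg.norm(c[i] - c[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        assert np.allclose(dists, dists[0])
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)

    def test_negative_eigenvalues_reported(self):
        # non-Euclidean dissimilarity set
        m = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1.9], [1, 1, 1.9, 0]]
        )
        res = ap.ordinate(pd.DataFrame(m), k=2)
        assert res.eigenvalues.min() < 0

    def test_rejects_asymmetric(self):
        d = pd.DataFrame([[0, 1], [2, 0]])
        with pytest.raises(ValueError):
            ap.ordinate(d)


class TestTableIO:
    def test_tsv_round_trip(self, small_table, tmp_path):
        cp, mp = tmp_path / "counts.tsv", tmp_path / "meta.tsv"
        small_table.to_tsv(cp, mp)
        back = ap.AbundanceTable.from_tsv(cp, mp)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)
        assert back.lineages["otu1"] == small_table.lineages["otu1"]
        assert list(back.metadata["condition"]) == list(small_table.metadata["condition"])

    def test_biom_json_reader(self, tmp_path):
        import json

        doc = {
            "matrix_type": "sparse",
            "rows": [
                {"id": "t1", "metadata": {"taxonomy": "k__B;p__Firmicutes"}},
                {"id": "t2", "metadata": None},
            ],
            "columns": [{"id": "s1"}, {"id": "s2"}],
            "data": [[0, 0, 5], [1, 1, 3]],
        }
        path = tmp_path / "table.biom"
        path.write_text(json.dumps(doc))
        t = ap.AbundanceTable.from_biom_json(path)
        assert t.counts.loc["s1", "t1"] == 5
        assert t.counts.loc["s2", "t2"] == 3
        assert t.lineages["t1"] == ("B", "Firmicutes")

    def test_parse_lineage_prefixes(self):
        assert ap.parse_lineage("k__Bacteria;p__Firmicutes;c__") == ("Bacteria", "Firmicutes")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            make_table([[-1]], ["a"], ["s1"])
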