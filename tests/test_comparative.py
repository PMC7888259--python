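"""Set algebra, differential peptides, substrate abundance, outliers,
group statistics and rule-based protease attribution."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import woundpep as wp


def bitmask_venn_oracle(sets):
    """Independent region partition via per-element membership bitmasks."""
    labels = list(sets)
    material = {l: set(s) for l, s in sets.items()}
    regions = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            regions[frozenset(combo)] = 0
    for elem in set().union(*material.values()):
        members = frozenset(l for l in labels if elem in material[l])
        regions[members] += 1
    return regions


class TestVennCounts:
    def test_two_set_enumeration(self):
        vc = wp.venn_counts({"S1": {"A", "B"}, "S2": {"B", "C"}})
        assert vc.region_counts[frozenset({"S1"})] == 1
        assert vc.region_counts[frozenset({"S2"})] == 1
        assert vc.region_counts[frozenset({"S1", "S2"})] == 1

    def test_identical_sets_concentrate_in_full_intersection(self):
        vc = wp.venn_counts({"a": {"X", "Y"}, "b": {"X", "Y"}, "c": {"X", "Y"}})
        assert vc.region_counts[frozenset({"a", "b", "c"})] == 2
        assert vc.union_size() == 2

    def test_set_count_bounds(self):
        with pytest.raises(ValueError):
            wp.venn_counts({"only": {"A"}})

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_partition_matches_bitmask_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"PEP{i}" for i in range(60)]
        sets = {
            f"S{j}": set(rng.choice(universe, size=rng.integers(0, 40), replace=False))
            for j in range(5)
        }
        vc = wp.venn_counts(sets)
        assert vc.region_counts == bitmask_venn_oracle(sets)
        assert vc.union_size() == len(set().union(*sets.values()))


class TestIntersectionalPeptides:
    def test_intersection_definition(self):
        samples = [
            wp.SampleTable.from_counts("s1", {"AAAA": 1, "CCCC": 1}),
            wp.SampleTable.from_counts("s2", {"CCCC": 1, "DDDD": 1}),
            wp.SampleTable.from_counts("s3", {"CCCC": 1}),
        ]
        assert wp.intersectional_peptides(samples) == {"CCCC"}

    def test_single_sample_identity(self):
        t = wp.SampleTable.from_counts("s1", {"AAAA": 1, "CCCC": 2})
        assert wp.intersectional_peptides([t]) == t.sequences()

    def test_adding_samples_never_grows_intersection(self, study):
        tables = study.filtered.groups["infected"]
        inter_all = wp.intersectional_peptides(tables)
        for i in range(1, len(tables) + 1):
            assert inter_all <= wp.intersectional_peptides(tables[:i])

    def test_recovers_planted_cores_exactly(self, study):
        for g, tables in study.filtered.groups.items():
            assert wp.intersectional_peptides(tables) == study.truth.core_peptides[g]


class TestDifferentialPeptides:
    def _group(self, sid_counts, group):
        return [
            wp.SampleTable.from_counts(sid, counts, group)
            for sid, counts in sid_counts.items()
        ]

    def test_difference_arithmetic(self):
        a = self._group({"a1": {"AAKK": 10}}, "A")
        b = self._group({"b1": {"AAKK": 2}}, "B")
        (d,) = wp.differential_peptides(a, b, k=5)
        assert d.difference == 8
        assert d.rank == 1

    def test_absence_counts_as_zero(self):
        a = self._group({"a1": {"AAKK": 7}}, "A")
        b = self._group({"b1": {"CCDD": 1}}, "B")
        diffs = wp.differential_peptides(a, b, k=5)
        by_seq = {d.sequence: d for d in diffs}
        assert by_seq["AAKK"].difference == 7
        assert by_seq["CCDD"].difference == -1

    def test_ranking_permutation_invariant(self, study):
        a = study.filtered.groups["infected"]
        b = study.filtered.groups["non_infected"]
        d1 = wp.differential_peptides(a, b, k=20)
        d2 = wp.differential_peptides(list(reversed(a)), list(reversed(b)), k=20)
        assert [x.sequence for x in d1] == [x.sequence for x in d2]
        assert [x.difference for x in d1] == [x.difference for x in d2]

    def test_top_k_recovers_planted_enrichment(self, study):
        """Core peptides boosted in one group dominate the differential list."""
        a = [
            wp.SampleTable.from_counts(
                t.sample_id,
                {
                    s: c * (20 if s in sorted(study.truth.core_peptides["infected"])[:5] else 1)
                    for s, c in t.counts().items()
                },
                t.group_label,
            )
            for t in study.filtered.groups["infected"]
        ]
        b = study.filtered.groups["non_infected"]
        top = {d.sequence for d in wp.differential_peptides(a, b, k=5)}
        assert top == set(sorted(study.truth.core_peptides["infected"])[:5])


class TestSubstrateAbundance:
    def test_share_computation(self, toy_db):
        ds = wp.GroupedDataset(
            {
                "g": [
                    wp.SampleTable.from_counts(
                        "s1", {"EFTPPVQ": 6, "VHLTPEEK": 4}, "g"
                    )
                ]
            }
        )
        mapped = wp.map_dataset(ds, toy_db)
        sub = wp.protein_substrate_abundance(mapped)
        assert sub.totals["HBB_TOY"] == 6
        assert sub.totals["HBB_NTERM_TOY"] == 4
        assert sub.n_proteins == 2

    def test_exclusion_list(self, toy_db):
        ds = wp.GroupedDataset(
            {"g": [wp.SampleTable.from_counts("s1", {"EFTPPVQ": 6, "VHLTPEEK": 4}, "g")]}
        )
        mapped = wp.map_dataset(ds, toy_db)
        sub = wp.protein_substrate_abundance(mapped, exclude_accessions=["HBB_TOY"])
        assert sub.totals.index.tolist() == ["HBB_NTERM_TOY"]

    def test_recovers_planted_substrate_enrichment(self, study):
        """The hemoglobin toy's spectral share is far higher in the infected
        group, whose model plants both a substrate-weight and an abundance
        enrichment for it, than in the sterile acute group."""
        shares = {}
        for g in ("infected", "acute"):
            sub = wp.protein_substrate_abundance(study.mapped_filtered, group_label=g)
            shares[g] = sub.totals.get("HBB_CTERM_TOY", 0.0) / sub.totals.sum()
        assert shares["infected"] > 5 * shares["acute"]

    def test_pie_data_is_top_n_plus_other(self, study):
        sub = wp.protein_substrate_abundance(study.mapped_filtered,
                                             group_label="infected", top_n=10)
        assert len(sub.pie_data) <= 11
        assert sub.pie_data.sum() == pytest.approx(sub.totals.sum())


class TestOccurrenceOutliers:
    def test_high_count_singleton_flagged(self):
        group = [
            wp.SampleTable.from_counts("s1", {"AAKK": 500, "CCDD": 10}, "g"),
            wp.SampleTable.from_counts("s2", {"CCDD": 12}, "g"),
            wp.SampleTable.from_counts("s3", {"CCDD": 9}, "g"),
        ]
        df = wp.occurrence_outliers(group, count_quantile=0.5).set_index("sequence")
        assert bool(df.loc["AAKK", "flagged"])

    def test_ubiquitous_sequence_never_flagged(self):
        group = [
            wp.SampleTable.from_counts(f"s{i}", {"AAKK": 1000, "CCDD": 1}, "g")
            for i in range(3)
        ]
        df = wp.occurrence_outliers(group, count_quantile=0.1).set_index("sequence")
        assert not bool(df.loc["AAKK", "flagged"])

    def test_flags_match_brute_force(self, study):
        group = study.filtered.groups["acute"]
        df = wp.occurrence_outliers(group, count_quantile=0.9)
        threshold = df["total_count"].quantile(0.9)
        for _, row in df.iterrows():
            expected = row["total_count"] > threshold and row["n_samples"] == 1
            assert bool(row["flagged"]) == expected


def welch_oracle(a, b):
    """Closed-form Welch t and two-sided p via the t CDF."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


def paired_oracle(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    p = 2 * sps.t.sf(abs(t), len(d) - 1)
    return t, p


class TestCompareGroupMeans:
    def test_identical_vectors(self):
        res = wp.compare_group_means([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_paired_constant_shift_is_degenerate(self):
        res = wp.compare_group_means([1.0, 2.0, 4.0], [3.0, 4.0, 6.0], paired=True)
        assert res.degenerate
        assert math.isnan(res.t)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            wp.compare_group_means([1.0], [2.0, 3.0])

    def test_welch_matches_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 12)))
            res = wp.compare_group_means(a, b)
            t, p = welch_oracle(a, b)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_paired_matches_closed_form(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            a, b = rng.normal(size=n), rng.normal(size=n)
            res = wp.compare_group_means(a, b, paired=True)
            t, p = paired_oracle(a, b)
            assert res.t == pytest.approx(t, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_sd_uses_ddof_one(self):
        res = wp.compare_group_means([1.0, 3.0], [2.0, 2.0, 2.0])
        assert res.sd_a == pytest.approx(math.sqrt(2.0))


class TestAttributeProteases:
    TABLE = {
        "trypsin_like": wp.ProteaseSpecificity({"K": 1.0, "R": 1.0}),
        "glutamyl_like": wp.ProteaseSpecificity({"D": 1.0, "E": 1.0}),
    }

    def _mapped(self, counts, db):
        ds = wp.GroupedDataset({"g": [wp.SampleTable.from_counts("s1", counts, "g")]})
        return wp.map_dataset(ds, db)

    def test_n_side_event_uses_preceding_residue(self):
        db = wp.ProteinDatabase({"P": ("", "AAKGGGG")})
        attr = wp.attribute_proteases(self._mapped({"GGGG": 5}, db), self.TABLE)
        # preceding residue K -> trypsin-like N-side event; C-terminal end inherent
        assert attr["trypsin_like"] == 1
        assert attr["glutamyl_like"] == 0

    def test_c_side_event_uses_last_residue(self):
        db = wp.ProteinDatabase({"P": ("", "GGGGEAAA")})
        attr = wp.attribute_proteases(self._mapped({"GGGGE": 5}, db), self.TABLE)
        assert attr["glutamyl_like"] == 1

    def test_empty_table_rejected(self, study):
        with pytest.raises(ValueError):
            wp.attribute_proteases(study.mapped, {})

    def test_planted_single_protease_wins(self):
        db = wp.bundled_proteins(n_filler=8, filler_length=400)
        model = wp.DigestionModel(p1_weights={"K": 1.0, "R": 1.0}, exo_trim_prob=0.0)
        ds, _ = wp.simulate_dataset(db, {"d": model}, {"d": 2},
                                    peptides_per_sample=600, seed=7)
        mapped = wp.map_dataset(ds, db)
        table = dict(self.TABLE)
        table["chymotrypsin_like"] = wp.ProteaseSpecificity(
            {"F": 1.0, "Y": 1.0, "W": 1.0, "L": 1.0}
        )
        attr = wp.attribute_proteases(mapped, table)
        assert attr.index[0] == "trypsin_like"
        assert attr["trypsin_like"] > 10 * max(attr["glutamyl_like"],
                                               attr["chymotrypsin_like"])


def test_specificity_table_round_trip(tmp_path):
    (tmp_path / "spec.yaml").write_text(
        "trypsin_like:\n  p1: {K: 1.0, R: 1.0}\n"
        "glutamyl_like:\n  p1: {D: 0.5, E: 1.0}\n  p1_prime: {A: 1.0}\n"
    )
    table = wp.comparative.load_specificity_table(tmp_path / "spec.yaml")
    assert table["trypsin_like"].p1_weights == {"K": 1.0, "R": 1.0}
    assert table["glutamyl_like"].p1_prime_weights == {"A": 1.0}
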