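"""Tests for the family filter, the three classification approaches and the
content/enrichment analyses."""

import math

import numpy as np
import pandas as pd
import pytest

import te_longsel as tl
from te_longsel.abundance import LABEL_C, LABEL_NS, LABEL_S
from conftest import make_profile


class TestFilterFamilies:
    def _profile(self, values):
        """One family, two samples, per-position values from a list."""
        return make_profile(
            {"fam": {"a": values, "b": values}}, ["a", "b"])

    def test_all_positions_above_threshold_retained(self):
        assert tl.filter_families(self._profile([0.6] * 10)) == ["fam"]

    def test_seventy_percent_excluded(self):
        vals = [0.6] * 7 + [0.4] * 3
        assert tl.filter_families(self._profile(vals)) == []

    def test_exactly_eighty_percent_retained(self):
        """The >= 0.5 at >= 80% boundary counts as retained."""
        vals = [0.5] * 8 + [0.49] * 2
        assert tl.filter_families(self._profile(vals)) == ["fam"]

    def test_study_average_pools_populations(self):
        """0.4 and 0.6 in the two populations average to 0.5: retained."""
        profile = make_profile(
            {"fam": {"a": [0.4] * 5, "b": [0.6] * 5}}, ["a", "b"])
        assert tl.filter_families(profile) == ["fam"]


class TestEstimateAbundance:
    def test_constant_and_simple_means(self):
        profile = make_profile(
            {"f1": {"a": [2.0, 2.0], "b": [2.0, 2.0]},
             "f2": {"a": [1, 2, 3][:2], "b": [1.0, 3.0]}}, ["a", "b"])
        table = tl.estimate_abundance(profile, ["f1", "f2"])
        assert table.data.loc["f1", "a"] == 2.0
        assert table.data.loc["f2", "b"] == 2.0

    def test_matches_brute_force_on_random_profile(self):
        rng = np.random.default_rng(0)
        vals = {f"f{i}": {s: list(rng.uniform(0.5, 5, 7))
                          for s in ("a", "b", "c")} for i in range(4)}
        profile = make_profile(vals, ["a", "b", "c"])
        table = tl.estimate_abundance(profile, list(vals))
        for fam, by_sample in vals.items():
            for s, v in by_sample.items():
                assert table.data.loc[fam, s] == pytest.approx(np.mean(v))


class TestFoldChanges:
    def test_hand_values(self, basic_design):
        data = pd.DataFrame(
            {s.name: [2.0 if s.regime == "S" else 1.0]
             for s in basic_design.samples}, index=["fam"])
        fc = tl.fold_changes(tl.AbundanceTable(data), basic_design)
        assert fc.loc["fam", "log2fc"] == pytest.approx(1.0)
        assert fc.loc["fam", "delta_insertion"] == pytest.approx(1.0)

    def test_equal_means_zero(self, basic_design):
        data = pd.DataFrame({s.name: [3.0] for s in basic_design.samples},
                            index=["fam"])
        fc = tl.fold_changes(tl.AbundanceTable(data), basic_design)
        assert fc.loc["fam", "log2fc"] == 0.0
        assert fc.loc["fam", "delta_insertion"] == 0.0

    def test_antisymmetric_under_regime_swap(self):
        d1 = tl.make_design("X", 2, 2)
        data = pd.DataFrame(
            {s.name: [4.0 if s.regime == "S" else 1.5] for s in d1.samples},
            index=["fam"])
        fc = tl.fold_changes(tl.AbundanceTable(data), d1)
        swapped = pd.DataFrame(
            {s.name: [1.5 if s.regime == "S" else 4.0] for s in d1.samples},
            index=["fam"])
        fc_swapped = tl.fold_changes(tl.AbundanceTable(swapped), d1)
        assert fc_swapped.loc["fam", "log2fc"] == \
            pytest.approx(-fc.loc["fam", "log2fc"])
        assert fc_swapped.loc["fam", "delta_insertion"] == \
            pytest.approx(-fc.loc["fam", "delta_insertion"])


class TestApproach1:
    def test_planted_effect_recovered(self, basic_design):
        cfg = tl.SynthConfig(n_families=12, n_s_gt_c=2, n_c_gt_s=1,
                             delta=1.0, sigma=0.1, n_positions=60, seed=14)
        hier = tl.generate_hierarchy(cfg)
        truths = tl.sample_reference_families(cfg)
        profile = tl.generate_coverage_data(truths, hier, basic_design, cfg)
        labels = {c.family: c.label
                  for c in tl.classify_approach1(profile, basic_design)}
        for t in truths:
            if t.delta > 0:
                assert labels[t.name] == LABEL_S
            elif t.delta < 0:
                assert labels[t.name] == LABEL_C

    def test_identical_regimes_ns(self, basic_design):
        rng = np.random.default_rng(1)
        per_pop = {s.name: list(rng.uniform(1, 2, 30))
                   for s in basic_design.samples_for(regime="C")}
        vals = {"fam": {}}
        for s in basic_design.samples:
            # mirror control data into the selected populations
            source = list(per_pop.values())[int(s.replicate_id[1:]) - 1]
            vals["fam"][s.name] = source
        profile = make_profile(vals, basic_design.sample_names)
        (cls,) = tl.classify_approach1(profile, basic_design)
        assert cls.label == LABEL_NS

    def test_small_delta_fails_effect_filter(self, basic_design):
        """A regime shift of 0.25 insertions is highly significant at tiny
        noise but below the 0.3-insertion effect filter: NS."""
        cfg = tl.SynthConfig(n_families=6, n_s_gt_c=1, delta=0.25,
                             sigma=0.02, n_positions=80, seed=15)
        hier = tl.generate_hierarchy(cfg)
        truths = tl.sample_reference_families(cfg)
        profile = tl.generate_coverage_data(truths, hier, basic_design, cfg)
        cls = {c.family: c for c in tl.classify_approach1(profile, basic_design)}
        planted_name = next(t.name for t in truths if t.delta != 0)
        planted = cls[planted_name]
        assert planted.p_raw < 1e-6  # detected ...
        assert planted.label == LABEL_NS  # ... but filtered by |delta|

    def test_diet_design_uses_interaction_model(self, diet_design):
        cfg = tl.SynthConfig(n_families=8, n_s_gt_c=1, delta=1.0,
                             sigma=0.2, n_positions=40, seed=16)
        hier = tl.generate_hierarchy(cfg)
        truths = tl.sample_reference_families(cfg)
        profile = tl.generate_coverage_data(truths, hier, diet_design, cfg)
        labels = {c.family: c.label
                  for c in tl.classify_approach1(profile, diet_design)}
        planted = next(t.name for t in truths if t.delta > 0)
        assert labels[planted] == LABEL_S


class TestApproach2:
    def _tables(self, shift):
        designs, tables = {}, {}
        rng = np.random.default_rng(3)
        for study in ("A", "B"):
            design = tl.make_design(study, 3, 3)
            rows = {}
            for s in design.samples:
                base = np.array([5.0, 3.0, 2.0, 1.0]) + rng.normal(0, 0.05, 4)
                if s.regime == "S":
                    base[0] += shift
                rows[s.name] = base
            tables[study] = tl.AbundanceTable(
                pd.DataFrame(rows, index=[f"f{i}" for i in range(4)]))
            designs[study] = design
        return tables, designs

    def test_constant_proportions_ns(self):
        tables, designs = self._tables(shift=0.0)
        cls = tl.classify_approach2(tables, designs)
        assert all(c.label == LABEL_NS for c in cls)

    def test_planted_proportion_shift_recovered(self):
        tables, designs = self._tables(shift=1.5)
        cls = {c.family: c.label
               for c in tl.classify_approach2(tables, designs)}
        assert cls["f0"] == LABEL_S

    def test_operates_on_common_families_only(self):
        tables, designs = self._tables(shift=0.0)
        tables["B"] = tl.AbundanceTable(tables["B"].data.drop(index="f3"))
        cls = tl.classify_approach2(tables, designs)
        assert {c.family for c in cls} == {"f0", "f1", "f2"}


class TestApproach3:
    def _table(self, s_vals, c_vals, design):
        row = {}
        for s, v in zip(design.samples_for(regime="S"), s_vals):
            row[s.name] = [v]
        for s, v in zip(design.samples_for(regime="C"), c_vals):
            row[s.name] = [v]
        return tl.AbundanceTable(pd.DataFrame(row, index=["fam"]))

    def test_dominance_called(self):
        design = tl.make_design("X", 2, 2)
        (cls,) = tl.classify_approach3(
            self._table([3.1, 3.2], [2.8, 2.9], design), design)
        assert cls.label == LABEL_S

    def test_single_overlap_is_ns(self):
        design = tl.make_design("X", 2, 2)
        (cls,) = tl.classify_approach3(
            self._table([3.1, 2.85], [2.8, 2.9], design), design)
        assert cls.label == LABEL_NS

    def test_invariant_under_replicate_permutation_and_rescaling(self):
        design = tl.make_design("X", 3, 3)
        rng = np.random.default_rng(4)
        s_vals, c_vals = rng.uniform(1, 4, 3), rng.uniform(1, 4, 3)
        base = tl.classify_approach3(
            self._table(s_vals, c_vals, design), design)[0].label
        permuted = tl.classify_approach3(
            self._table(s_vals[::-1], c_vals[::-1], design), design)[0].label
        rescaled = tl.classify_approach3(
            self._table(10 * s_vals, 10 * c_vals, design), design)[0].label
        assert base == permuted == rescaled

    def test_per_diet_classification(self, diet_design):
        row = {}
        for s in diet_design.samples:
            if s.diet == "low":
                row[s.name] = [3.0 if s.regime == "S" else 2.0]
            else:
                row[s.name] = [2.5]
        table = tl.AbundanceTable(pd.DataFrame(row, index=["fam"]))
        by_diet = tl.classify_approach3_by_diet(table, diet_design)
        assert by_diet["low"][0].label == LABEL_S
        assert by_diet["medium"][0].label == LABEL_NS
        assert by_diet["high"][0].label == LABEL_NS


class TestMagnitudeComparisons:
    def _cls(self, study, fcs, labels):
        return [tl.RegimeClassification(
            family=f"{study}_f{i}", label=lab, p_raw=0.001, p_adjusted=0.01,
            log2fc=fc, delta_insertion=fc) for i, (fc, lab)
            in enumerate(zip(fcs, labels))]

    def test_planted_difference_detected(self):
        rng = np.random.default_rng(6)
        big = rng.normal(1.0, 0.1, 20)
        small = rng.normal(0.3, 0.1, 20)
        cls = {"A": self._cls("A", list(big) + list(small),
                              [LABEL_C] * 20 + [LABEL_S] * 20)}
        out = tl.magnitude_comparisons(cls)
        assert out["fc_magnitude_by_study"]["A"].p < 1e-6

    def test_identical_studies_flat_anova(self):
        fcs = [0.2, 0.5, 0.9, 1.4]
        cls = {s: self._cls(s, fcs, [LABEL_S] * 4) for s in ("A", "B")}
        out = tl.magnitude_comparisons(cls)
        assert out["anova_study"].term("Study").f == pytest.approx(0.0)
        assert len(out["pairwise_study"]) == 1


class TestContentAndEnrichment:
    def test_totals_sum_families(self, basic_design):
        data = pd.DataFrame({s.name: [2.0, 2.0] for s in basic_design.samples},
                            index=["f1", "f2"])
        tables = {"StudyA": tl.AbundanceTable(data)}
        hier = [tl.TEFamily("f1", "LTR", "RNA", 100),
                tl.TEFamily("f2", "TIR", "DNA", 100)]
        # a second study is needed for the Study term
        d2 = tl.make_design("StudyB", 3, 3)
        tables["StudyB"] = tl.AbundanceTable(
            pd.DataFrame({s.name: [2.0, 2.0] for s in d2.samples},
                         index=["f1", "f2"]))
        res = tl.content_tests(tables, hier,
                               {"StudyA": basic_design, "StudyB": d2})
        assert set(res) == {"total", "LTR", "TIR"}
        # identical everywhere: no regime signal
        assert math.isnan(res["total"]["model"].term("Regime").f)

    def test_planted_total_shift_significant(self):
        rng = np.random.default_rng(8)
        designs, tables = {}, {}
        for study in ("A", "B"):
            design = tl.make_design(study, 4, 4)
            rows = {}
            for s in design.samples:
                vals = np.array([5.0, 5.0]) + rng.normal(0, 0.1, 2)
                if s.regime == "S":
                    vals *= 1.1
                rows[s.name] = vals
            tables[study] = tl.AbundanceTable(
                pd.DataFrame(rows, index=["f1", "f2"]))
            designs[study] = design
        hier = [tl.TEFamily("f1", "LTR", "RNA", 100),
                tl.TEFamily("f2", "LTR", "RNA", 100)]
        res = tl.content_tests(tables, hier, designs)
        assert res["total"]["model"].term("Regime").p < 0.001

    def test_enrichment_shares_fisher_oracle(self):
        hier = ([tl.TEFamily(f"t{i}", "TIR", "DNA", 100) for i in range(4)]
                + [tl.TEFamily(f"r{i}", "LTR", "RNA", 100) for i in range(4)])
        # S>C group: 3 TIR + 1 RNA; rest of background: 1 TIR + 3 RNA
        cls = []
        for i, fam in enumerate([f.name for f in hier]):
            label = LABEL_S if fam in ("t0", "t1", "t2", "r0") else LABEL_NS
            cls.append(tl.RegimeClassification(fam, label, 0.5, 0.5,
                                               0.0, 0.0))
        res = tl.subclass_enrichment(cls, hier)
        assert res[(LABEL_S, "TIR")].p == pytest.approx(34 / 70)
        assert res[(LABEL_S, "DNA")].p == pytest.approx(34 / 70)

    def test_group_matching_background_is_flat(self):
        hier = [tl.TEFamily(f"f{i}", "TIR" if i % 2 else "LTR",
                            "DNA" if i % 2 else "RNA", 100) for i in range(8)]
        cls = [tl.RegimeClassification(
            f.name, LABEL_S if i < 4 else LABEL_NS, 0.5, 0.5, 0.0, 0.0)
            for i, f in enumerate(hier)]
        res = tl.subclass_enrichment(cls, hier)
        assert res[(LABEL_S, "TIR")].p == pytest.approx(1.0)


class TestCountCorrection:
    def test_division_and_single_copy_default(self, basic_design):
        table = tl.AbundanceTable(pd.DataFrame(
            {s.name: [4.0] for s in basic_design.samples}, index=["f1"]))
        counts = pd.DataFrame(
            {s.name: [100.0, 60.0] for s in basic_design.samples},
            index=["f1", "unfiltered"])
        out = tl.correct_counts_by_copies(counts, table)
        assert (out.loc["f1"] == 25.0).all()
        assert (out.loc["unfiltered"] == 60.0).all()

    def test_zero_copies_warns_and_divides_by_one(self, basic_design):
        table = tl.AbundanceTable(pd.DataFrame(
            {s.name: [0.0] for s in basic_design.samples}, index=["f1"]))
        counts = pd.DataFrame({s.name: [7.0] for s in basic_design.samples},
                              index=["f1"])
        with pytest.warns(UserWarning, match="zero copy"):
            out = tl.correct_counts_by_copies(counts, table)
        assert (out.loc["f1"] == 7.0).all()

    def test_unit_copies_identity(self, basic_design):
        table = tl.AbundanceTable(pd.DataFrame(
            {s.name: [1.0] for s in basic_design.samples}, index=["f1"]))
        counts = pd.DataFrame({s.name: [9.0] for s in basic_design.samples},
                              index=["f1"])
        out = tl.correct_counts_by_copies(counts, table)
        pd.testing.assert_frame_equal(out, counts)


class TestNullBehaviour:
    def test_null_study_rarely_labelled(self):
        """Under a fully null study approach #1 labels at most a small
        fraction of families and approach #3 is direction-balanced."""
        design = tl.make_design("N", 5, 5)
        cfg = tl.SynthConfig(n_families=60, sigma=0.3, n_positions=50,
                             seed=17)
        hier = tl.generate_hierarchy(cfg)
        truths = tl.sample_reference_families(cfg)
        profile = tl.generate_coverage_data(truths, hier, design, cfg)
        cls = tl.classify_approach1(profile, design)
        counts = tl.label_counts(cls)
        assert counts[LABEL_S] + counts[LABEL_C] <= 2
        table = tl.estimate_abundance(profile, [c.family for c in cls])
        c3 = tl.label_counts(tl.classify_approach3(table, design))
        assert abs(c3[LABEL_S] - c3[LABEL_C]) <= \
            4 * math.sqrt(max(1, c3[LABEL_S] + c3[LABEL_C]))
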