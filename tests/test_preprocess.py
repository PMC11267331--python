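import numpy as np
import pandas as pd
import pytest

from secretodiff import (GoccAnnotation, apply_qc_filters, median_center,
                         merge_batches, presence_filter, restrict_secreted)
from secretodiff.io import ProteinTable

from conftest import make_design, make_matrix


def _table(flags):
    """flags: list of None/'C'/'R'/'S' (a string may hold several)."""
    code = {"C": "flag_contaminant", "R": "flag_reverse", "S": "flag_site_only"}
    meta = pd.DataFrame({
        "protein_ids": [f"P{i}" for i in range(len(flags))],
        "protein_id": [f"P{i}" for i in range(len(flags))],
        "gene_names": "", "flag_reverse": False, "flag_contaminant": False,
        "flag_site_only": False, "gocc_terms": [frozenset()] * len(flags),
    })
    for i, f in enumerate(flags):
        for ch in (f or ""):
            meta.loc[i, code[ch]] = True
    inten = pd.DataFrame(np.full((len(flags), 2), 100.0), columns=["s1", "s2"])
    return ProteinTable(meta, inten)


class TestQCFilters:
    def test_one_of_each_flag_removed(self):
        out, report = apply_qc_filters(_table(["C", "R", "S", None, None]))
        assert len(out) == 2
        assert report == {"contaminant": 1, "reverse": 1, "site_only": 1,
                          "retained": 2}

    def test_multiply_flagged_row_counted_once_by_priority(self):
        out, report = apply_qc_filters(_table(["CR", "RS", None]))
        assert len(out) == 1
        assert report["contaminant"] == 1  # CR counts as contaminant
        assert report["reverse"] == 1      # RS counts as reverse
        assert report["site_only"] == 0

    def test_clean_table_is_identity(self):
        table = _table([None, None, None])
        out, report = apply_qc_filters(table)
        assert len(out) == 3
        assert report == {"contaminant": 0, "reverse": 0, "site_only": 0,
                          "retained": 3}


class TestPresenceFilter:
    @pytest.mark.parametrize("pattern, kept", [
        # measured in 2 of 4 UT, none elsewhere: 2/4 = 0.5 >= 0.5 -> kept
        ({"UT": [1, 1, 0, 0], "T": [0, 0, 0, 0]}, True),
        # 1 of 4 everywhere: 0.25 < 0.5 -> removed
        ({"UT": [1, 0, 0, 0], "T": [1, 0, 0, 0]}, False),
        # 3 of 5 in one condition only: 0.6 >= 0.5 -> kept
        ({"UT": [1, 1, 1, 0, 0], "T": [0, 0, 0, 0]}, True),
    ])
    def test_rule_examples(self, pattern, kept):
        design = make_design({c: len(v) for c, v in pattern.items()})
        row = [np.nan if x == 0 else 20.0 for c in pattern for x in pattern[c]]
        m = make_matrix({"A": row}, design)
        out = presence_filter(m, design, tau=0.5)
        assert ("A" in out.protein_ids) == kept

    def test_matches_brute_force_oracle_on_random_fixtures(self, rng):
        for _ in range(300):
            groups = {f"c{j}": int(rng.integers(2, 6)) for j in range(rng.integers(1, 4))}
            design = make_design(groups)
            n_samp = len(design.sample_ids)
            n_prot = int(rng.integers(1, 8))
            vals = rng.normal(20, 2, size=(n_prot, n_samp))
            vals[rng.random((n_prot, n_samp)) < 0.5] = np.nan
            tau = float(rng.choice([0.3, 0.5, 0.75, 1.0]))
            m = make_matrix({f"P{i}": vals[i] for i in range(n_prot)}, design)
            out = presence_filter(m, design, tau=tau)
            # oracle: enumerate groups, count measured, exact comparison
            expect = []
            for i in range(n_prot):
                keep = False
                for cond in groups:
                    samples = design.group_samples("b1", cond)
                    cols = [design.sample_ids.index(s) for s in samples]
                    frac = np.isfinite(vals[i, cols]).sum() / len(cols)
                    if frac >= tau - 1e-12:
                        keep = True
                if keep:
                    expect.append(f"P{i}")
            assert out.protein_ids == expect

    def test_exclusions_do_not_count_toward_presence(self):
        from secretodiff.containers import StudyDesign
        base = make_design({"UT": 4})
        design = StudyDesign(base.table, exclusions=(("3", "UT"), ("4", "UT")))
        # measured only in the two excluded samples -> 0/2 after exclusion
        m = make_matrix({"A": [np.nan, np.nan, 20.0, 20.0]}, base)
        out = presence_filter(m, design, tau=0.5)
        assert out.protein_ids == []

    def test_invalid_tau_rejected(self):
        design = make_design({"UT": 2})
        m = make_matrix({"A": [1.0, 2.0]}, design)
        with pytest.raises(ValueError, match="tau"):
            presence_filter(m, design, tau=1.5)


class TestRestrictSecreted:
    annot = GoccAnnotation.from_pairs([
        ("A", "Extracellular exosome"), ("B", "nucleus"),
    ])

    def test_secreted_term_kept_nucleus_and_unannotated_removed(self):
        design = make_design({"UT": 2})
        m = make_matrix({"A": [1, 2], "B": [1, 2], "C": [1, 2]}, design)
        out = restrict_secreted(m, self.annot)
        assert out.protein_ids == ["A"]

    def test_term_match_is_case_insensitive(self):
        design = make_design({"UT": 2})
        m = make_matrix({"A": [1, 2]}, design)
        out = restrict_secreted(m, self.annot, terms=("EXTRACELLULAR  EXOSOME",))
        assert out.protein_ids == ["A"]


class TestMergeBatches:
    def test_disjoint_proteins_yield_complementary_missing_blocks(self):
        d1 = make_design({"UT": 2}, batch="b1")
        d2 = make_design({"UT": 2}, batch="b2")
        m1 = make_matrix({f"A{i}": [1.0, 2.0] for i in range(3)}, d1, "filtered")
        m2 = make_matrix({f"B{i}": [3.0, 4.0] for i in range(4)}, d2, "filtered")
        merged = merge_batches(m1, m2)
        assert merged.shape == (7, 4)
        assert merged.mask.loc["A0", d2.sample_ids].all()
        assert merged.mask.loc["B0", d1.sample_ids].all()
        assert not merged.mask.loc["A0", d1.sample_ids].any()

    def test_shared_protein_gets_single_row_with_both_batches(self):
        d1 = make_design({"UT": 2}, batch="b1")
        d2 = make_design({"UT": 2}, batch="b2")
        m1 = make_matrix({"X": [1.0, 2.0]}, d1, "filtered")
        m2 = make_matrix({"X": [3.0, 4.0]}, d2, "filtered")
        merged = merge_batches(m1, m2)
        assert merged.shape == (1, 4)
        assert merged.values.loc["X"].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_merge_with_empty_batch_is_identity(self):
        from secretodiff import LogIntensityMatrix

        d1 = make_design({"UT": 2}, batch="b1")
        m1 = make_matrix({"X": [1.0, 2.0]}, d1, "filtered")
        m2 = LogIntensityMatrix(pd.DataFrame(dtype=float), stage="filtered")
        merged = merge_batches(m1, m2)
        pd.testing.assert_frame_equal(merged.values, m1.values)


class TestMedianCenter:
    def test_worked_columns(self):
        design = make_design({"UT": 3})
        m = make_matrix({"A": [10.0, 5.0, 1.0], "B": [12.0, np.nan, 2.0],
                         "C": [20.0, 7.0, 3.0]}, design, "filtered")
        out = median_center(m)
        # col1 median 12 -> (-2, 0, 8); col2 median of observed (5,7) = 6
        assert out.values["b1_UT_1"].tolist() == [-2.0, 0.0, 8.0]
        assert out.values.loc["A", "b1_UT_2"] == -1.0
        assert np.isnan(out.values.loc["B", "b1_UT_2"])
        assert out.values.loc["C", "b1_UT_2"] == 1.0

    def test_observed_median_zero_and_idempotent(self, rng):
        design = make_design({"UT": 4, "T": 4})
        vals = rng.normal(20, 3, size=(30, 8))
        vals[rng.random((30, 8)) < 0.2] = np.nan
        m = make_matrix({f"P{i}": vals[i] for i in range(30)}, design, "filtered")
        out = median_center(m)
        med = out.values.median(axis=0, skipna=True)
        assert np.abs(med.to_numpy()).max() < 1e-9
        twice = median_center(out)
        diff = (twice.values - out.values).abs().to_numpy()
        assert np.nanmax(diff) < 1e-12

    def test_all_missing_column_errors_with_sample_name(self):
        design = make_design({"UT": 2})
        m = make_matrix({"A": [1.0, np.nan], "B": [2.0, np.nan]}, design, "filtered")
        with pytest.raises(ValueError, match="b1_UT_2"):
            median_center(m)
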