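"""Gel-slice scheme, intensity tables and the cohort differential test."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pccelv.slice_quant import (
    COHORTS,
    DEFAULT_SCHEME,
    GelSliceScheme,
    IntensityTable,
    SchemeError,
    TableError,
    assign_expected_slice,
    differential_peptides,
    read_intensity_table,
    slice_consistency,
)


class TestScheme:
    def test_default_scheme_tiles_10_to_500(self):
        lo = [w[1] for w in DEFAULT_SCHEME.windows]
        hi = [w[2] for w in DEFAULT_SCHEME.windows]
        assert hi[0] == 500 and lo[-1] == 10
        # contiguous: each window's min equals the next window's max
        assert lo[:-1] == hi[1:]

    @pytest.mark.parametrize(
        "mass,label",
        [(145, "B"), (335, "A"), (500, "A"), (270, "A"), (140, "B"),
         (10, "J"), (5, "out_of_range"), (600, "out_of_range")],
    )
    def test_assignment_and_boundary_convention(self, mass, label):
        """A boundary mass belongs to the heavier window."""
        assert assign_expected_slice(mass) == label

    def test_every_mass_hits_exactly_one_window(self):
        rng = np.random.default_rng(0)
        for mass in rng.uniform(0, 600, size=1000):
            hits = [
                lab
                for i, (lab, lo, hi) in enumerate(DEFAULT_SCHEME.windows)
                if lo <= mass < hi or (i == 0 and mass == hi)
            ]
            assigned = DEFAULT_SCHEME.assign(mass)
            assert len(hits) <= 1
            assert assigned == (hits[0] if hits else "out_of_range")

    def test_overlapping_windows_rejected(self):
        with pytest.raises(SchemeError):
            GelSliceScheme(windows=(("A", 100, 500), ("B", 140, 270)))

    def test_slice_range(self):
        assert DEFAULT_SCHEME.slice_range("B", "D") == ("B", "C", "D")


def _rows(n=3, **over):
    base = dict(
        protein_id="P1", peptide_seq="AAK", start=1, stop=3, slice="A",
        sample="s", cohort="normal", intensity=1.0,
    )
    rows = []
    for i in range(n):
        r = {**base, "sample": f"s{i}"}
        r.update(over)
        rows.append(r)
    return rows


class TestIntensityTableIO:
    def test_read_valid_rows(self):
        df = pd.DataFrame(_rows(3))
        buf = io.StringIO(df.to_csv(sep="\t", index=False))
        table = read_intensity_table(buf)
        assert len(table) == 3
        assert table.cohort_sizes == {"normal": 3}

    def test_invalid_rows_rejected_and_logged(self, caplog):
        rows = _rows(2)
        rows.append({**rows[0], "sample": "neg", "intensity": -5.0})
        rows.append({**rows[0], "sample": "badslice", "slice": "Z"})
        buf = io.StringIO(pd.DataFrame(rows).to_csv(sep="\t", index=False))
        with caplog.at_level("WARNING"):
            table = read_intensity_table(buf)
        assert len(table) == 2
        assert "rejected 2/4" in caplog.text

    def test_missing_column_is_schema_error(self):
        buf = io.StringIO("protein_id\tstart\nP1\t1\n")
        with pytest.raises(TableError, match="missing columns"):
            read_intensity_table(buf)

    def test_duplicate_keys_rejected(self):
        df = pd.DataFrame(_rows(1) * 2)
        with pytest.raises(TableError, match="duplicate"):
            IntensityTable(data=df)

    def test_write_read_round_trip(self, tmp_path, pc1_table):
        table, _ = pc1_table
        p = tmp_path / "t.tsv"
        table.write(p)
        back = read_intensity_table(p)
        a = table.data.reset_index(drop=True)
        b = back.data.reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b, check_exact=False, rtol=1e-5)


def _cohort_table(rng, n_pkd=13, n_norm=18, fold=1.0, sd=0.1, n_pep=5):
    rows = []
    for pep in range(n_pep):
        start = 10 * pep + 1
        for cohort, n, mult in (("PKD1", n_pkd, fold), ("normal", n_norm, 1.0)):
            for s in range(n):
                rows.append(
                    dict(
                        protein_id="P1", peptide_seq="AAK", start=start,
                        stop=start + 2, slice="A", sample=f"{cohort}{s}",
                        cohort=cohort,
                        intensity=1000 * mult * 2 ** rng.normal(0, sd),
                    )
                )
    return IntensityTable(data=pd.DataFrame(rows))


class TestDifferential:
    def test_identical_cohorts_do_not_pass(self):
        rng = np.random.default_rng(1)
        res = differential_peptides(_cohort_table(rng, fold=1.0), alpha=0.01)
        assert not res["passes_threshold"].any()
        assert (res["p_value"] > 0.01).all()

    def test_twofold_decrease_recovered(self):
        rng = np.random.default_rng(2)
        res = differential_peptides(_cohort_table(rng, fold=0.5, sd=0.1), alpha=0.01)
        assert res["passes_threshold"].all()
        assert res["log2_ratio"].mean() == pytest.approx(-1.0, abs=0.1)

    def test_sign_convention_decrease_is_negative(self):
        rng = np.random.default_rng(3)
        down = differential_peptides(_cohort_table(rng, fold=0.25))
        up = differential_peptides(_cohort_table(rng, fold=4.0))
        assert (down["log2_ratio"] < 0).all()
        assert (up["log2_ratio"] > 0).all()

    def test_single_sample_cohort_flagged_undefined(self):
        rng = np.random.default_rng(4)
        table = _cohort_table(rng, n_pkd=1, n_pep=1)
        res = differential_peptides(table)
        assert len(res) == 1
        assert np.isnan(res.loc[0, "p_value"])
        assert not res.loc[0, "passes_threshold"]

    def test_zero_intensities_treated_as_censored(self):
        rng = np.random.default_rng(5)
        table = _cohort_table(rng, n_pep=1)
        df = table.data.copy()
        df.loc[df.index[:3], "intensity"] = 0.0
        res = differential_peptides(IntensityTable(data=df))
        assert res.loc[0, "n_PKD1"] + res.loc[0, "n_normal"] == len(df) - 3

    def test_empty_table_gives_empty_result(self):
        table = IntensityTable(
            data=pd.DataFrame(columns=[
                "protein_id", "peptide_seq", "start", "stop", "slice",
                "sample", "cohort", "intensity",
            ])
        )
        assert differential_peptides(table).empty

    def test_welch_matches_hand_formula_on_random_tables(self):
        """Oracle equivalence: Welch statistic + df written out by hand."""
        rng = np.random.default_rng(6)
        for _ in range(1000):
            na, nb = rng.integers(2, 12, size=2)
            a = rng.normal(0, 1 + rng.random(), size=na)
            b = rng.normal(rng.random(), 1, size=nb)
            va, vb = a.var(ddof=1), b.var(ddof=1)
            t = (a.mean() - b.mean()) / np.sqrt(va / na + vb / nb)
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
            p_hand = 2 * stats.t.sf(abs(t), df)
            _, p_impl = stats.ttest_ind(a, b, equal_var=False)
            assert abs(p_hand - p_impl) < 1e-10


class TestSliceConsistency:
    def test_generated_data_is_fully_consistent(self, pc1_table):
        table, truth = pc1_table
        detail, summary = slice_consistency(table, truth.proteins["PC1"].fragments)
        assert summary["PC1"] == 1.0
        assert detail["consistent"].all()

    def test_misplaced_peptide_is_flagged(self, pc1_table):
        table, truth = pc1_table
        df = table.data.copy()
        df.loc[df.index[0], "slice"] = "J"
        bad = IntensityTable(data=df)
        detail, summary = slice_consistency(bad, truth.proteins["PC1"].fragments)
        assert summary["PC1"] < 1.0

    def test_protein_without_model_is_skipped(self, pc1_table, caplog):
        table, _ = pc1_table
        with caplog.at_level("WARNING"):
            detail, summary = slice_consistency(table, [])
        assert summary == {}


def test_cohort_labels_are_closed_set():
    assert set(COHORTS) == {"PKD1", "normal"}
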