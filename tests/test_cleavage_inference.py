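"""Region ratios, tail depletion, change-point calls and band algebra."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pccelv.cleavage_inference import (
    BandConstraint,
    RegionSpec,
    contiguity_check,
    fragment_model,
    infer_cleavage_positions,
    localize_by_glycan_milestones,
    region_intensity_ratio,
    tail_depletion,
)
from pccelv.sequence_model import (
    CleavageSite,
    GlycanAnnotation,
    ProteinAnnotations,
    ProteinFeature,
    ProteinRecord,
)
from pccelv.slice_quant import DEFAULT_SCHEME, IntensityTable
from pccelv.synthetic_data import (
    Population,
    SyntheticConfig,
    SyntheticProtein,
    random_protein_sequence,
    simulate_dataset,
    simulate_preset,
)


def _uniform_table(n_pep=10, boundary=50):
    """Every peptide has intensity 1 in slice A (stop<boundary) or B."""
    rows = []
    for i in range(n_pep):
        start = 1 + 10 * i
        stop = start + 8
        lab = "A" if stop < boundary else "B"
        for s in range(3):
            rows.append(
                dict(protein_id="P1", peptide_seq="X", start=start, stop=stop,
                     slice=lab, sample=f"s{s}", cohort="normal", intensity=1.0)
            )
    return IntensityTable(data=pd.DataFrame(rows))


class TestRegionIntensityRatio:
    def test_uniform_intensities_give_ratio_one(self):
        table = _uniform_table()
        res = region_intensity_ratio(
            table, "P1",
            RegionSpec(slices=("A",), stop_lt=50),
            RegionSpec(slices=("B",), stop_gt=50),
        )
        assert res.ratio == pytest.approx(1.0)
        assert res.defined

    def test_empty_region_is_flagged_undefined(self):
        table = _uniform_table()
        res = region_intensity_ratio(
            table, "P1",
            RegionSpec(slices=("J",)),
            RegionSpec(slices=("B",)),
        )
        assert not res.defined and np.isnan(res.ratio)

    def test_slice_sum_precedes_peptide_average(self):
        # One peptide split across two slices must count once, at its sum.
        rows = []
        for lab, inten in (("A", 3.0), ("B", 1.0)):
            rows.append(
                dict(protein_id="P1", peptide_seq="X", start=1, stop=5,
                     slice=lab, sample="s0", cohort="normal", intensity=inten)
            )
        rows.append(
            dict(protein_id="P1", peptide_seq="Y", start=11, stop=15,
                 slice="C", sample="s0", cohort="normal", intensity=2.0)
        )
        table = IntensityTable(data=pd.DataFrame(rows))
        res = region_intensity_ratio(
            table, "P1",
            RegionSpec(slices=("A", "B")),
            RegionSpec(slices=("C",)),
        )
        assert res.ratio == pytest.approx(4.0 / 2.0)

    def test_pc1_preset_recovers_planted_ectodomain_excess(self, pc1_table):
        table, truth = pc1_table
        check = truth.checks[0]
        res = region_intensity_ratio(
            table, "PC1", check.numerator, check.denominator, boundary=3048
        )
        assert res.ratio == pytest.approx(1.4, rel=0.1)

    def test_fibrocystin_preset_recovers_post_ppc_deficit(self, fcys_table):
        table, truth = fcys_table
        check = next(c for c in truth.checks if c.kind == "region_ratio")
        res = region_intensity_ratio(
            table, "FCYS", check.numerator, check.denominator, boundary=3616
        )
        assert res.ratio == pytest.approx(0.58, rel=0.1)


class TestTailDepletion:
    def test_no_tail_peptides_returns_zero(self):
        table = _uniform_table(n_pep=4, boundary=100)
        res = tail_depletion(table, "P1", tail_start=500,
                             reference=RegionSpec(slices=("A",)))
        assert res.ratio == 0.0 and res.n_tail == 0

    def test_empty_reference_is_error(self):
        table = _uniform_table(n_pep=4, boundary=100)
        with pytest.raises(ValueError, match="reference region"):
            tail_depletion(table, "P1", tail_start=1,
                           reference=RegionSpec(slices=("J",)))

    def test_fibrocystin_tail_recovers_planted_level(self, fcys_table):
        table, truth = fcys_table
        check = next(c for c in truth.checks if c.kind == "tail_depletion")
        res = tail_depletion(table, "FCYS", check.tail_start, check.reference)
        assert res.ratio == pytest.approx(0.051, rel=0.15)
        assert res.n_tail == 1  # the single detectable C-tail peptide

    def test_pc2_tail_slice_ratio(self):
        table, truth = simulate_preset("pc2_tail", seed=3)
        check = truth.checks[0]
        res = region_intensity_ratio(
            table, "PC2", check.numerator, check.denominator, boundary=806
        )
        assert res.ratio == pytest.approx(0.13, rel=0.1)


class TestInferCleavage:
    def test_uncleaved_protein_yields_no_calls(self):
        rec = ProteinRecord(
            id="U1", sequence=random_protein_sequence(1383, seed=21)
        )
        cfg = SyntheticConfig(
            proteins=[SyntheticProtein(record=rec)], seed=5
        )
        table, _ = simulate_dataset(cfg)
        assert infer_cleavage_positions(table, "U1") == []

    def test_too_few_peptides_yields_empty(self, caplog):
        table = _uniform_table(n_pep=4)
        with caplog.at_level("WARNING"):
            assert infer_cleavage_positions(table, "P1") == []

    def test_gps_site_recovered_in_top_call(self, pc1_table):
        table, _ = pc1_table
        calls = infer_cleavage_positions(table, "PC1")
        assert calls and calls[0].contains(3048)

    def test_ppc_site_recovered_in_top_call(self, fcys_table):
        table, _ = fcys_table
        calls = infer_cleavage_positions(table, "FCYS")
        assert calls and calls[0].contains(3616)

    def test_interval_spans_gap_between_flanking_peptides(self, pc1_table):
        table, _ = pc1_table
        top = infer_cleavage_positions(table, "PC1")[0]
        df = table.for_protein("PC1")
        stops = df["stop"].unique()
        starts = df["start"].unique()
        assert top.position == max(s for s in stops if s <= 3048)
        assert top.interval_end == min(s for s in starts if s > top.position) - 1

    def test_noise_does_not_inflate_true_boundary_score(self):
        """Mean top-call score at high noise <= score at low noise."""
        def mean_score(sd):
            scores = []
            for seed in range(20):
                from pccelv.synthetic_data import preset
                cfg, _ = preset("pc1_fig1", seed=1000 + seed)
                cfg.noise_sd_log2 = sd
                table, _ = simulate_dataset(cfg)
                calls = infer_cleavage_positions(table, "PC1")
                scores.append(calls[0].score if calls else 0.0)
            return np.mean(scores)

        assert mean_score(1.2) <= mean_score(0.2) + 0.5


class TestFragmentModel:
    def _pc1(self):
        from pccelv.synthetic_data import _pc1_protein

        return _pc1_protein()

    def test_empty_cleavage_set_gives_whole_protein(self):
        rec = ProteinRecord(id="P", sequence="MKTRAGGG")
        frags = fragment_model(rec, [()])
        assert len(frags) == 1
        assert (frags[0].start, frags[0].stop) == (1, 8)

    def test_gps_split_gives_two_fragments_with_11_tms(self):
        rec, ann = self._pc1()
        frags = fragment_model(
            rec, [(CleavageSite(3048),)], glycans=ann.glycans,
            scheme=DEFAULT_SCHEME, annotations=ann,
        )
        assert [(f.start, f.stop) for f in frags] == [(1, 3048), (3049, 4302)]
        ecto, ctf = frags
        assert ctf.tm_count == 11 and ecto.tm_count == 0
        # 12 kDa of glycan on the C-terminal fragment
        assert ctf.mass_kDa["glyc"] - ctf.mass_kDa["pngaseF"] == pytest.approx(12.0)
        assert ctf.mass_kDa["glyc"] - ctf.mass_kDa["endoH"] == pytest.approx(2.0)
        assert ecto.expected_slice["glyc"] == "A"

    def test_fragments_tile_protein_and_masses_add(self):
        rec, ann = self._pc1()
        sites = tuple(CleavageSite(p) for p in (3048, 3475, 3760, 4202))
        frags = fragment_model(rec, [sites], annotations=ann)
        assert sum(f.length for f in frags) == rec.length
        assert frags[0].start == 1 and frags[-1].stop == rec.length
        for a, b in zip(frags, frags[1:]):
            assert b.start == a.stop + 1
        # mass additivity: adjacent deglycosylated masses sum to the
        # undivided fragment's mass minus one water per junction
        from pccelv.digestion_mass import WATER_AVG, fragment_mass

        whole = fragment_mass(rec, 3049, 4302)
        parts = [fragment_mass(rec, f.start, f.stop) for f in frags[1:]]
        assert sum(parts) - 3 * WATER_AVG / 1000 == pytest.approx(whole, abs=1e-9)

    def test_duplicate_sites_rejected(self):
        rec = ProteinRecord(id="P", sequence="MKTRAGGG")
        with pytest.raises(ValueError, match="duplicate"):
            fragment_model(rec, [(CleavageSite(3), CleavageSite(3))])

    def test_masses_decrease_under_stronger_deglycosylation(self, pc1_table):
        _, truth = pc1_table
        for f in truth.proteins["PC1"].fragments:
            assert f.mass_kDa["glyc"] >= f.mass_kDa["endoH"] >= f.mass_kDa["pngaseF"]


class TestContiguityCheck:
    BANDS = {"B": 81.0, "C": 70.0, "D": 52.0, "F": 29.0}

    def test_published_band_sums_pass(self):
        report = contiguity_check(
            self.BANDS,
            [
                BandConstraint(terms=(("D", 1), ("F", 1)), expected="B",
                               label="D+F=B"),
                BandConstraint(terms=(("B", 1), ("C", -1)), expected=11.0,
                               label="B-C=trim"),
            ],
        )
        assert report["passed"].all()
        assert report.loc[0, "residual_kDa"] == pytest.approx(0.0)

    def test_inconsistent_sum_fails_with_residual(self):
        report = contiguity_check(
            {"B": 81.0, "X": 50.0, "Y": 20.0},
            [BandConstraint(terms=(("X", 1), ("Y", 1)), expected="B")],
        )
        assert not report.loc[0, "passed"]
        assert report.loc[0, "residual_kDa"] == pytest.approx(-11.0)

    def test_unmatched_band_label_is_error(self):
        with pytest.raises(KeyError, match="Z"):
            contiguity_check(
                self.BANDS,
                [BandConstraint(terms=(("Z", 1),), expected="B")],
            )

    def test_tolerance_override(self):
        report = contiguity_check(
            {"B": 81.0, "X": 50.0, "Y": 20.0},
            [BandConstraint(terms=(("X", 1), ("Y", 1)), expected="B")],
            tolerance_kDa=15.0,
        )
        assert report.loc[0, "passed"]


class TestGlycanMilestones:
    GLYCANS = (
        GlycanAnnotation(sequon_position=3738, state="endoH_sensitive", mass_kDa=2.0),
        GlycanAnnotation(sequon_position=3790, state="mature", mass_kDa=5.0),
        GlycanAnnotation(sequon_position=3845, state="mature", mass_kDa=5.0),
    )

    def test_full_set_matches_full_shift(self):
        subsets = localize_by_glycan_milestones(12.0, self.GLYCANS, "pngaseF")
        assert (3738, 3790, 3845) in subsets

    def test_ten_kda_shift_implies_the_two_mature_chains(self):
        subsets = localize_by_glycan_milestones(10.0, self.GLYCANS, "pngaseF")
        assert subsets == [(3790, 3845)]

    def test_endoh_only_removes_sensitive_chain(self):
        subsets = localize_by_glycan_milestones(2.0, self.GLYCANS, "endoH")
        assert subsets == [(3738,)]

    def test_inconsistent_shift_yields_empty(self):
        assert localize_by_glycan_milestones(3.0, self.GLYCANS, "pngaseF") == []

    def test_matches_exhaustive_bitmask_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = rng.integers(1, 6)
            glycans = [
                GlycanAnnotation(
                    sequon_position=int(100 + 10 * i),
                    state="mature" if rng.random() < 0.5 else "endoH_sensitive",
                    mass_kDa=float(np.round(rng.uniform(0.5, 6.0), 1)),
                )
                for i in range(n)
            ]
            shift = float(np.round(rng.uniform(0, 15), 1))
            got = localize_by_glycan_milestones(shift, glycans, "pngaseF", 0.25)
            expected = set()
            for bits in itertools.product([0, 1], repeat=n):
                chosen = [g for g, b in zip(glycans, bits) if b]
                if abs(sum(g.mass_kDa for g in chosen) - shift) <= 0.25:
                    expected.add(tuple(sorted(g.sequon_position for g in chosen)))
            assert set(got) == expected
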