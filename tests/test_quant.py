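"""Unit and property tests for the SIP protein quantification chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syntrophyflux.quant import (
    SampleContext,
    biomass_yield,
    mag_c13_protein,
    metaproteome_fraction,
    quantify_all_samples,
    read_labels,
    read_proteins,
    relative_protein_abundance,
    total_protein_g_per_l,
    total_protein_nmol_per_l,
)


def _lfq(rows):
    return pd.DataFrame(rows, columns=["sample_id", "protein_id", "lfq_intensity"])


def _ctx(sample_id="s1", conc=1.0):
    return SampleContext(sample_id=sample_id, time_h=24.0, replicate=1,
                         total_protein_conc=conc)


class TestRelativeAbundance:
    def test_single_protein_normalizes_to_one(self):
        rel = relative_protein_abundance(_lfq([("s1", "p1", 7.0)]), "s1")
        assert rel["p1"] == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        rel = relative_protein_abundance(
            _lfq([("s1", "p1", 3.0), ("s1", "p2", 1.0)]), "s1"
        )
        assert rel["p1"] == pytest.approx(0.75)
        assert rel["p2"] == pytest.approx(0.25)

    def test_random_table_sums_to_one(self):
        rng = np.random.default_rng(0)
        rows = [("s1", f"p{i}", float(v)) for i, v in enumerate(rng.lognormal(size=50))]
        rel = relative_protein_abundance(_lfq(rows), "s1")
        assert abs(rel.sum() - 1.0) < 1e-9

    def test_all_zero_intensities_raise(self):
        with pytest.raises(ValueError, match="zero total"):
            relative_protein_abundance(_lfq([("s1", "p1", 0.0)]), "s1")

    def test_unknown_sample_raises(self):
        with pytest.raises(KeyError):
            relative_protein_abundance(_lfq([("s1", "p1", 1.0)]), "s2")


class TestAbsoluteQuantities:
    def test_mass_concentration_and_conservation(self):
        rel = pd.Series({"p1": 0.75, "p2": 0.25})
        out = total_protein_g_per_l(rel, _ctx(conc=1.0))
        assert out["p1"] == pytest.approx(0.75)
        assert out.sum() == pytest.approx(1.0)
        zero = total_protein_g_per_l(rel, _ctx(conc=0.0))
        assert (zero == 0).all()

    def test_negative_total_protein_rejected(self):
        with pytest.raises(ValueError):
            _ctx(conc=-0.1)

    def test_molar_conversion_and_roundtrip(self):
        gpl = pd.Series({"p1": 0.05, "p2": 0.0})
        proteins = pd.DataFrame(
            {"protein_id": ["p1", "p2"], "mag_id": ["m", "m"],
             "molecular_weight": [50_000.0, 20_000.0]}
        )
        nmol = total_protein_nmol_per_l(gpl, proteins)
        assert nmol["p1"] == pytest.approx(1000.0)
        assert nmol["p2"] == 0.0
        back = nmol * proteins.set_index("protein_id")["molecular_weight"] / 1e9
        assert np.allclose(back, gpl, rtol=1e-12)

    def test_missing_molecular_weight_names_protein(self):
        gpl = pd.Series({"p1": 0.05, "orphan": 0.01})
        proteins = pd.DataFrame(
            {"protein_id": ["p1"], "mag_id": ["m"], "molecular_weight": [50_000.0]}
        )
        with pytest.raises(KeyError, match="orphan"):
            total_protein_nmol_per_l(gpl, proteins)


class TestMagC13:
    PROTEINS = pd.DataFrame(
        {"protein_id": ["p1", "p2"], "mag_id": ["magA", "magA"],
         "molecular_weight": [5e4, 5e4]}
    )

    def _labels(self, ria, lr):
        return pd.DataFrame(
            {"sample_id": ["s1", "s1"], "protein_id": ["p1", "p2"],
             "ria": ria, "lr": lr}
        )

    def test_forced_arithmetic(self):
        # proteins at 10 and 6 mg/L, mean RIA 0.5, mean LR 0.5 -> 16 * 0.25
        gpl = pd.Series({"p1": 0.010, "p2": 0.006})
        out = mag_c13_protein(gpl, self._labels([0.4, 0.6], [0.3, 0.7]),
                              self.PROTEINS, "s1")
        assert out.loc["magA", "total_protein_mg_per_l"] == pytest.approx(16.0)
        assert out.loc["magA", "c13_protein_mg_per_l"] == pytest.approx(4.0)

    def test_zero_lr_zeroes_c13(self):
        gpl = pd.Series({"p1": 0.010, "p2": 0.006})
        out = mag_c13_protein(gpl, self._labels([0.9, 0.9], [0.0, 0.0]),
                              self.PROTEINS, "s1")
        assert out.loc["magA", "c13_protein_mg_per_l"] == 0.0

    def test_percent_scaled_labels_rejected(self):
        gpl = pd.Series({"p1": 0.010, "p2": 0.006})
        with pytest.raises(ValueError, match="percent"):
            mag_c13_protein(gpl, self._labels([40.0, 60.0], [0.5, 0.5]),
                            self.PROTEINS, "s1")

    def test_unlabeled_mag_gets_zero(self):
        proteins = pd.DataFrame(
            {"protein_id": ["p1", "q1"], "mag_id": ["magA", "magB"],
             "molecular_weight": [5e4, 5e4]}
        )
        gpl = pd.Series({"p1": 0.01, "q1": 0.02})
        labels = pd.DataFrame(
            {"sample_id": ["s1"], "protein_id": ["p1"], "ria": [0.5], "lr": [0.5]}
        )
        out = mag_c13_protein(gpl, labels, proteins, "s1")
        assert out.loc["magB", "c13_protein_mg_per_l"] == 0.0
        assert out.loc["magB", "total_protein_mg_per_l"] == pytest.approx(20.0)

    @given(scale=st.floats(min_value=0.01, max_value=1.0))
    @settings(max_examples=25, deadline=None)
    def test_lr_scaling_is_linear(self, scale):
        """Scaling every LR by c in (0,1] scales 13C-protein by exactly c."""
        gpl = pd.Series({"p1": 0.010, "p2": 0.006})
        base = mag_c13_protein(gpl, self._labels([0.4, 0.6], [0.3, 0.7]),
                               self.PROTEINS, "s1")
        scaled = mag_c13_protein(
            gpl, self._labels([0.4, 0.6], [0.3 * scale, 0.7 * scale]),
            self.PROTEINS, "s1",
        )
        assert scaled.loc["magA", "c13_protein_mg_per_l"] == pytest.approx(
            scale * base.loc["magA", "c13_protein_mg_per_l"]
        )

    def test_c13_bounded_by_total(self, small_tables):
        """RIA, LR in [0,1] force per-MAG 13C-protein <= total protein."""
        tabs = small_tables
        _, per_mag = quantify_all_samples(
            tabs["proteins"], tabs["lfq"], tabs["labels"], tabs["samples"]
        )
        assert (per_mag["c13_protein_mg_per_l"]
                <= per_mag["total_protein_mg_per_l"] + 1e-12).all()


class TestMetaproteomeFraction:
    def test_single_and_two_mag_split(self):
        proteins = pd.DataFrame(
            {"protein_id": ["p1", "p2", "p3"], "mag_id": ["A", "A", "B"],
             "molecular_weight": [1e4] * 3}
        )
        rel = pd.Series({"p1": 0.4, "p2": 0.2, "p3": 0.4})
        frac = metaproteome_fraction(rel, proteins)
        assert frac["A"] == pytest.approx(0.6)
        assert frac["B"] == pytest.approx(0.4)
        assert frac.sum() == pytest.approx(1.0)


class TestBiomassYield:
    def test_zero_c13_gives_zero_yield(self):
        y_vss, y_cod = biomass_yield(0.0, 3000.0)
        assert y_vss == 0.0 and y_cod == 0.0

    def test_cod_yield_with_acetate_cod_factor(self):
        _, y_cod = biomass_yield(15.0, 3000.0)
        assert y_cod == pytest.approx((30.0 * 1.42) / (3000.0 * 64.0 / 59.0), rel=1e-12)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            biomass_yield(15.0, 0.0)


class TestReaders:
    def test_ambiguous_protein_excluded(self, tmp_path):
        p = tmp_path / "proteins.tsv"
        p.write_text(
            "protein_id\tmag_id\tmolecular_weight\n"
            "p1\tA\t10000\np1\tB\t10000\np2\tA\t20000\n"
        )
        df = read_proteins(p)
        assert list(df["protein_id"]) == ["p2"]

    def test_percent_labels_converted(self, tmp_path):
        p = tmp_path / "labels.tsv"
        p.write_text(
            "sample_id\tprotein_id\tria\tlr\tunit\n"
            "s1\tp1\t50\t25\tpercent\n"
        )
        df = read_labels(p)
        assert df.loc[0, "ria"] == pytest.approx(0.5)
        assert df.loc[0, "lr"] == pytest.approx(0.25)
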