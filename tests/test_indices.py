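"""Registry tests, including the independent straight-line formula oracle.

The oracle below re-implements every index formula as flat hand-written
arithmetic over its own nearest-channel lookup, deliberately sharing no
code with the registry, so the two evaluation routes can be compared.
"""

import math

import numpy as np
import pytest

from leafspec import (
    SampleRecord,
    Spectrum,
    builtin_index_catalog,
    compute_all_indices,
    compute_index,
)
from leafspec.errors import OutOfRangeError
from leafspec.features import FeatureTable

from conftest import make_spectrum, random_reflectance


# ---------------------------------------------------------------------------
# independent oracle: flat formula transcriptions over a local band lookup
# ---------------------------------------------------------------------------

def V(s, nm):
    """Nearest-channel reflectance lookup, independent of the package's."""
    return float(s.values[np.abs(s.wavelengths - nm).argmin()])


def D(s, nm):
    """Central-difference derivative, independent implementation."""
    i = int(np.abs(s.wavelengths - nm).argmin())
    return float((s.values[i + 1] - s.values[i - 1])
                 / (s.wavelengths[i + 1] - s.wavelengths[i - 1]))


def _oracle_map():
    o = {}
    o["NDVI1"] = lambda s: (V(s, 800) - V(s, 670)) / (V(s, 800) + V(s, 670))
    o["NDVI2"] = lambda s: (V(s, 780) - V(s, 670)) / (V(s, 780) + V(s, 670))
    o["NDVI3"] = lambda s: (V(s, 573) - V(s, 440)) / (V(s, 573) + V(s, 440))
    o["NDVI4"] = lambda s: (V(s, 410) - V(s, 365)) / (V(s, 410) + V(s, 365))
    o["NDVI5"] = lambda s: (V(s, 503) - V(s, 483)) / (V(s, 503) + V(s, 483))
    o["NDVI6"] = lambda s: (V(s, 800) - V(s, 680)) / (V(s, 800) + V(s, 680))
    o["NDVI7"] = lambda s: (V(s, 1220) - V(s, 710)) / (V(s, 1220) + V(s, 710))
    o["NDVI8"] = lambda s: (V(s, 801) - V(s, 550)) / (V(s, 801) + V(s, 550))
    o["NDI1"] = lambda s: (V(s, 790) - V(s, 720)) / (V(s, 790) + V(s, 720))
    o["NDI2"] = lambda s: (V(s, 860) - V(s, 720)) / (V(s, 860) + V(s, 720))
    o["NDI3"] = lambda s: (V(s, 750) - V(s, 705)) / (V(s, 750) + V(s, 705))
    o["NDI4"] = lambda s: (V(s, 570) - V(s, 531)) / (V(s, 570) + V(s, 531))
    o["NDI5"] = lambda s: (V(s, 780) - V(s, 710)) / (V(s, 780) - V(s, 680))
    o["NDI6"] = lambda s: (V(s, 850) - V(s, 710)) / (V(s, 850) - V(s, 680))
    o["NDI7"] = lambda s: (V(s, 734) - V(s, 747)) / (V(s, 715) + V(s, 726))
    o["mNDI"] = lambda s: (V(s, 750) - V(s, 705)) / (V(s, 750) + V(s, 705)
                                                     - 2 * V(s, 445))
    o["SR1"] = lambda s: V(s, 700) / V(s, 670)
    o["SR2"] = lambda s: V(s, 750) / V(s, 550)
    o["SR3"] = lambda s: V(s, 750) / V(s, 700)
    o["SR4"] = lambda s: V(s, 780) / V(s, 670)
    o["SR5"] = lambda s: V(s, 787) / V(s, 765)
    o["SR6"] = lambda s: V(s, 553) / V(s, 537)
    o["SR7"] = lambda s: V(s, 545) / V(s, 538)
    o["SR8"] = lambda s: V(s, 554) / V(s, 677)
    o["SR9"] = lambda s: V(s, 801) / V(s, 670)
    o["SR10"] = lambda s: V(s, 800) / V(s, 550)
    o["SR11"] = lambda s: V(s, 740) / V(s, 720)
    o["SR12"] = lambda s: V(s, 670) / (V(s, 700) * V(s, 650))
    o["SR13"] = lambda s: V(s, 672) / (V(s, 708) * V(s, 550))
    o["SR14"] = lambda s: V(s, 860) / (V(s, 708) * V(s, 550))
    o["PSSRa"] = lambda s: V(s, 800) / V(s, 680)
    o["PSSRb"] = lambda s: V(s, 800) / V(s, 635)
    o["SR15"] = lambda s: V(s, 750) / V(s, 705)
    o["SR16"] = lambda s: V(s, 950) / V(s, 660)
    o["SR17"] = lambda s: V(s, 990) / V(s, 720)
    o["SR18"] = lambda s: V(s, 780) / V(s, 740)
    o["SR19"] = lambda s: D(s, 743) / D(s, 1316)
    o["SR20"] = lambda s: D(s, 730) / D(s, 705)
    o["ZTM"] = lambda s: V(s, 760) / V(s, 710)
    o["VIopt2"] = lambda s: V(s, 760) / V(s, 730)
    o["MSR1"] = lambda s: (V(s, 800) / V(s, 670) - 1) \
        / math.sqrt(V(s, 800) / V(s, 670) + 1)
    o["MSR2"] = lambda s: (V(s, 750) / V(s, 705) - 1) \
        / math.sqrt(V(s, 750) / V(s, 705) + 1)
    o["CARI"] = lambda s: (V(s, 700) - V(s, 670)) - 0.2 * (V(s, 700)
                                                           + V(s, 550))
    o["MCARI1"] = lambda s: ((V(s, 700) - V(s, 670))
                             - 0.2 * (V(s, 700) - V(s, 550))) \
        * (V(s, 700) / V(s, 670))
    o["MCARI2"] = lambda s: ((V(s, 750) - V(s, 705))
                             - 0.2 * (V(s, 750) - V(s, 550))) \
        * (V(s, 750) / V(s, 705))
    o["TCARI"] = lambda s: 3 * ((V(s, 700) - V(s, 670))
                                - 0.2 * (V(s, 700) - V(s, 550))
                                * (V(s, 700) / V(s, 670)))
    o["TVI"] = lambda s: 0.5 * (120 * (V(s, 750) - V(s, 550))
                                - 200 * (V(s, 670) - V(s, 550)))
    o["MTVI1"] = lambda s: 1.2 * (1.2 * (V(s, 800) - V(s, 550))
                                  - 2.5 * (V(s, 670) - V(s, 550)))
    o["MTVI2"] = lambda s: 1.5 * (1.2 * (V(s, 800) - V(s, 550))
                                  - 2.5 * (V(s, 670) - V(s, 550))) \
        / math.sqrt((2 * V(s, 800) + 1) ** 2
                    - (6 * V(s, 800) - 5 * math.sqrt(V(s, 670))) - 0.5)
    o["REP"] = lambda s: 710 + 50 * (0.5 * (V(s, 810) + V(s, 660))
                                     - V(s, 710)) / (V(s, 760) - V(s, 710))
    o["OSAVI1"] = lambda s: 1.16 * (V(s, 800) - V(s, 670)) \
        / (V(s, 700) + V(s, 670) + 0.16)
    o["OSAVI2"] = lambda s: 1.16 * (V(s, 750) - V(s, 705)) \
        / (V(s, 750) + V(s, 705) + 0.16)
    o["MSAVI"] = lambda s: 0.5 * (2 * V(s, 800) + 1
                                  - math.sqrt((2 * V(s, 800) + 1) ** 2
                                              - 8 * (V(s, 800) - V(s, 670))))
    o["TBI1"] = lambda s: V(s, 705) / (V(s, 717) + V(s, 491))
    o["TBI2"] = lambda s: V(s, 1310) / (V(s, 1720) + V(s, 730))
    o["TBI3"] = lambda s: (V(s, 924) - V(s, 703) + 2 * V(s, 423)) \
        / (V(s, 924) + V(s, 703) - 2 * V(s, 423))
    o["R_M"] = lambda s: V(s, 750) / V(s, 720) - 1
    o["G_M"] = lambda s: V(s, 750) / V(s, 550) - 1
    o["PNC"] = lambda s: math.exp(2.5 - 23.5 * (V(s, 503) - V(s, 483))
                                  / (V(s, 503) + V(s, 483)))
    for num in ("TCARI", "CARI", "MCARI1", "MCARI2"):
        for den in ("OSAVI1", "OSAVI2"):
            o[f"{num}_{den}"] = (lambda s, n=num, d=den:
                                 o[n](s) / o[d](s))
    return o


ORACLE = _oracle_map()


class TestCatalog:
    def test_exactly_67_indices(self):
        assert len(builtin_index_catalog()) == 67

    def test_contains_headline_indices(self):
        names = {d.name for d in builtin_index_catalog()}
        assert {"TVI", "MTVI1", "MTVI2", "MSAVI"} <= names

    def test_names_unique(self):
        names = [d.name for d in builtin_index_catalog()]
        assert len(names) == len(set(names))

    def test_family_expansion_members(self):
        names = {d.name for d in builtin_index_catalog()}
        expected = {"TCARI_OSAVI1", "TCARI_OSAVI2", "CARI_OSAVI1",
                    "CARI_OSAVI2", "MCARI1_OSAVI1", "MCARI1_OSAVI2",
                    "MCARI2_OSAVI1", "MCARI2_OSAVI2"}
        assert expected <= names

    def test_oracle_covers_catalog(self):
        assert {d.name for d in builtin_index_catalog()} == set(ORACLE)

    def test_every_expression_band_appears_in_bands(self):
        for d in builtin_index_catalog():
            assert len(d.bands) >= 1
            for key in d.band_keys():
                assert key[0] in "RD"


class TestComputeIndex:
    def _by_name(self, name):
        return next(d for d in builtin_index_catalog() if d.name == name)

    def test_ndvi1_zero_on_flat_spectrum(self):
        assert compute_index(make_spectrum(value=0.4),
                             self._by_name("NDVI1")) == 0.0

    def test_msavi_zero_when_bands_equal(self):
        assert np.isclose(
            compute_index(make_spectrum(value=0.37), self._by_name("MSAVI")),
            0.0)

    def test_ndvi1_worked_example(self):
        # oracle: hand evaluation (0.5-0.1)/(0.5+0.1)
        s = make_spectrum(value=0.1)
        v = s.values.copy()
        v[np.abs(s.wavelengths - 800).argmin()] = 0.5
        s2 = Spectrum(s.wavelengths, v, "reflectance")
        assert np.isclose(compute_index(s2, self._by_name("NDVI1")),
                          0.4 / 0.6)

    def test_tvi_worked_example(self):
        # oracle: 0.5*[120*(0.45-0.10) - 200*(0.05-0.10)] = 26.0
        s = make_spectrum(value=0.10)
        v = s.values.copy()
        wl = s.wavelengths
        v[np.abs(wl - 750).argmin()] = 0.45
        v[np.abs(wl - 670).argmin()] = 0.05
        s2 = Spectrum(wl, v, "reflectance")
        assert np.isclose(compute_index(s2, self._by_name("TVI")), 26.0)

    def test_zero_denominator_yields_sentinel(self, caplog):
        # NDI5 denominator R780 - R680 vanishes on a flat spectrum
        with caplog.at_level("WARNING"):
            v = compute_index(make_spectrum(value=0.3), self._by_name("NDI5"))
        assert np.isnan(v)

    def test_missing_coverage_raises_named_error(self):
        s = make_spectrum(stop=1200)
        with pytest.raises(OutOfRangeError, match="TBI2"):
            compute_index(s, self._by_name("TBI2"))

    def test_registry_matches_oracle_on_random_spectra(self):
        rng = np.random.default_rng(2024)
        catalog = builtin_index_catalog()
        for _ in range(25):
            s = random_reflectance(rng)
            for d in catalog:
                got = compute_index(s, d)
                want = ORACLE[d.name](s)
                assert np.isfinite(got), d.name
                denom = max(abs(want), 1e-30)
                assert abs(got - want) / denom < 1e-12, d.name

    def test_literal_modes_change_msr_and_rep(self):
        rng = np.random.default_rng(5)
        s = random_reflectance(rng)
        canon = {d.name: compute_index(s, d) for d in builtin_index_catalog()}
        lit = {d.name: compute_index(s, d)
               for d in builtin_index_catalog("literal", "literal")}
        for name in ("MSR1", "MSR2", "REP"):
            assert canon[name] != lit[name]
        r = V(s, 800) / V(s, 670)
        assert np.isclose(lit["MSR1"], (r - 1) / (r + 1))
        assert np.isclose(
            lit["REP"],
            710 + 50 * (0.5 * (V(s, 810) + V(s, 660)) - V(s, 710))
            / (V(s, 760) + V(s, 710)))


class TestIndexProperties:
    ND_NAMES = ["NDVI1", "NDVI2", "NDVI3", "NDVI4", "NDVI5", "NDVI6",
                "NDVI7", "NDVI8", "NDI1", "NDI2", "NDI3", "NDI4", "NDI7"]

    def test_normalized_differences_bounded(self):
        rng = np.random.default_rng(77)
        catalog = {d.name: d for d in builtin_index_catalog()}
        for _ in range(10):
            s = random_reflectance(rng)
            for name in self.ND_NAMES:
                v = compute_index(s, catalog[name])
                assert -1.0 <= v <= 1.0, name

    def test_rep_in_red_edge_interval_on_plant_like_spectra(
            self, noiseless_dataset):
        catalog = {d.name: d for d in builtin_index_catalog()}
        for rec in noiseless_dataset[:5]:
            v = compute_index(rec.reflectance_reps[0], catalog["REP"])
            assert 700.0 <= v <= 760.0


class TestComputeAllIndices:
    def test_shape_contract(self, noiseless_dataset):
        table = compute_all_indices(noiseless_dataset[:2])
        assert table.shape == (2, 67)
        assert np.isfinite(table.values).all()

    def test_truncated_spectrum_gives_partial_sentinels(self):
        short = make_spectrum(stop=1200, value=0.3)
        rec = SampleRecord("t", 0, 0.0, 2.0, [short], [])
        table = compute_all_indices([rec])
        assert np.isnan(table.column("TBI2")[0])
        assert np.isfinite(table.column("NDVI1")[0])

    def test_identical_samples_identical_rows(self, noiseless_dataset):
        rec = noiseless_dataset[0]
        twin = SampleRecord("twin", rec.year, rec.n_rate, rec.lnc,
                            rec.reflectance_reps, rec.fluorescence_reps)
        table = compute_all_indices([rec, twin])
        assert np.allclose(table.values[0], table.values[1], equal_nan=True)

    def test_sample_order_equivariance(self, noiseless_dataset):
        recs = noiseless_dataset[:4]
        fwd = compute_all_indices(recs)
        rev = compute_all_indices(recs[::-1])
        assert np.allclose(fwd.values, rev.values[::-1], equal_nan=True)

    def test_sample_without_reflectance_is_sentinel_row(self, caplog,
                                                        noiseless_dataset):
        rec = noiseless_dataset[0]
        empty = SampleRecord("none", 0, 0.0, 2.0, [],
                             rec.fluorescence_reps)
        with caplog.at_level("WARNING"):
            table = compute_all_indices([empty])
        assert np.isnan(table.values).all()


class TestFeatureTable:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            FeatureTable(["a"], ["x", "y"], np.zeros((1, 3)))

    def test_csv_roundtrip_with_sentinels(self, tmp_path):
        t = FeatureTable(["a", "b"], ["x", "y"],
                         np.array([[1.5, np.nan], [2.0, 3.0]]))
        p = tmp_path / "t.csv"
        t.write(p)
        assert ",," in p.read_text() or ",\n" in p.read_text()
        back = FeatureTable.read(p)
        assert back.feature_names == ["x", "y"]
        assert np.allclose(back.values, t.values, equal_nan=True)

    def test_select_and_hstack(self):
        t = FeatureTable(["a"], ["x", "y"], np.array([[1.0, 2.0]]))
        u = FeatureTable(["a"], ["z"], np.array([[3.0]]))
        combined = t.select(["y"]).hstack(u)
        assert combined.feature_names == ["y", "z"]
        assert np.array_equal(combined.values, [[2.0, 3.0]])
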