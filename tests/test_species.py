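"""TAG species arithmetic: partition numbers, molar masses, enumeration."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipolyzer import (
    FattyAcid,
    OilComposition,
    TAGSpecies,
    ValidationError,
    annotate_peaks,
    enumerate_plausible_species,
    fatty_acid,
    mean_oil_molar_mass,
    parse_tag_label,
    partition_number,
    tag_from_labels,
    tag_molar_mass,
)
from lipolyzer.constants import GLYCEROL, WATER, fatty_acid_mass
from lipolyzer.elsd import Peak, PeakTable

# Strategy: plausible acyl chains with valid unsaturation (d < c/2 always).
_acids = st.builds(
    lambda c, d: FattyAcid(f"C{c}:{d}", f"X{c}_{d}", c, d),
    st.integers(8, 24),
    st.integers(0, 3),
)


class TestPartitionNumber:
    @pytest.mark.parametrize(
        "labels, cn, nd, pn",
        [
            (("CLn", "CLn", "CLn"), 54, 9, 36),
            (("P", "P", "P"), 48, 0, 48),
            (("CLn", "CLn", "O"), 54, 7, 40),
            (("L", "L", "L"), 54, 6, 42),
            (("CLn", "CLn", "L"), 54, 8, 38),
        ],
    )
    def test_known_species(self, labels, cn, nd, pn):
        species = tag_from_labels(*labels)
        assert (species.cn, species.nd) == (cn, nd)
        assert partition_number(species) == pn

    def test_rejects_non_species(self):
        with pytest.raises(ValidationError):
            TAGSpecies((fatty_acid("L"), fatty_acid("L")))
        with pytest.raises(ValidationError):
            partition_number("L-L-L")

    @given(st.tuples(_acids, _acids, _acids), st.permutations([0, 1, 2]))
    def test_permutation_invariance_and_parity(self, acids, perm):
        base = TAGSpecies(acids)
        shuffled = TAGSpecies(tuple(acids[i] for i in perm))
        assert base.pn == shuffled.pn
        assert base.label == shuffled.label
        # PN = CN - 2 ND keeps the parity of CN
        assert base.pn % 2 == base.cn % 2


class TestMolarMass:
    def test_triundecanoin(self):
        # atomic-mass sum of C36H68O6
        assert tag_molar_mass(tag_from_labels("U", "U", "U")) == pytest.approx(
            596.9, abs=0.1
        )

    def test_trilinolein(self):
        # atomic-mass sum of C57H98O6
        assert tag_molar_mass(tag_from_labels("L", "L", "L")) == pytest.approx(
            879.4, abs=0.1
        )

    @given(st.tuples(_acids, _acids, _acids))
    def test_esterification_identity(self, acids):
        species = TAGSpecies(acids)
        expected = sum(fa.molar_mass for fa in acids) + GLYCEROL - 3 * WATER
        assert species.molar_mass == pytest.approx(expected, abs=1e-9)

    @given(st.integers(6, 22), st.integers(0, 2))
    def test_monotone_in_cn_and_nd(self, carbons, dbs):
        fa = FattyAcid("x", "x", carbons, dbs)
        longer = FattyAcid("y", "y", carbons + 1, dbs)
        rest = (fatty_acid("P"), fatty_acid("O"))
        assert (
            TAGSpecies((longer, *rest)).molar_mass
            > TAGSpecies((fa, *rest)).molar_mass
        )
        if dbs + 1 < carbons / 2:
            unsat = FattyAcid("z", "z", carbons, dbs + 1)
            assert (
                TAGSpecies((unsat, *rest)).molar_mass
                < TAGSpecies((fa, *rest)).molar_mass
            )

    def test_validates_stated_molar_mass(self):
        with pytest.raises(ValidationError):
            FattyAcid("C18:2", "L", 18, 2, molar_mass=282.0)  # 1.5 g/mol off


class TestMeanOilMolarMass:
    def test_single_acid_oil_equals_simple_tag(self):
        comp = OilComposition("pureL", ((fatty_acid("L"), 100.0),))
        assert mean_oil_molar_mass(comp) == pytest.approx(879.4, abs=0.1)

    def test_sbo_against_spreadsheet_oracle(self, sbo):
        # independent weighted sum straight from the published area table
        rows = {  # label: (area %, carbons, double bonds)
            "P": (13.1, 16, 0), "S": (3.8, 18, 0), "O": (22.1, 18, 1),
            "V": (2.8, 18, 1), "Lt": (0.5, 18, 2), "L": (49.5, 18, 2),
            "gLn": (0.6, 18, 3), "Ln": (5.5, 18, 3),
        }
        known = sum(pct for pct, *_ in rows.values())
        mean_ffa = sum(
            pct / known * fatty_acid_mass(c, d) for pct, c, d in rows.values()
        )
        oracle = 3 * mean_ffa + GLYCEROL - 3 * WATER
        assert mean_oil_molar_mass(sbo) == pytest.approx(oracle, abs=1e-9)

    def test_blend_linearity(self):
        blend = OilComposition(
            "LO", ((fatty_acid("L"), 50.0), (fatty_acid("O"), 50.0))
        )
        lll = tag_molar_mass(tag_from_labels("L", "L", "L"))
        ooo = tag_molar_mass(tag_from_labels("O", "O", "O"))
        assert mean_oil_molar_mass(blend) == pytest.approx((lll + ooo) / 2, abs=0.1)

    def test_low_coverage_names_unknown_fraction(self):
        comp = OilComposition(
            "murky", ((fatty_acid("L"), 80.0),), unknown_percent=20.0
        )
        with pytest.raises(ValidationError, match="unknown fraction 20.0"):
            mean_oil_molar_mass(comp)


class TestEnumeration:
    def test_pgo_top_group_is_pn36_tricln(self, pgo):
        cands = enumerate_plausible_species(pgo, min_abundance=0.05)
        assert cands[0].pn == min(c.pn for c in cands) == 36
        assert cands[0].species.label == "CLn-CLn-CLn"

    def test_single_acid_oil(self):
        comp = OilComposition("pureL", ((fatty_acid("L"), 100.0),))
        cands = enumerate_plausible_species(comp)
        assert len(cands) == 1
        assert cands[0].species.label == "L-L-L"

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_multiset_count(self, k):
        labels = ["P", "S", "O", "L"][:k]
        comp = OilComposition(
            "mix", tuple((fatty_acid(lb), 100.0 / k) for lb in labels)
        )
        cands = enumerate_plausible_species(comp, min_abundance=0.01)
        assert len(cands) == math.comb(k + 2, 3)

    def test_abundances_sum_to_one(self, sbo):
        cands = enumerate_plausible_species(sbo, min_abundance=1e-6)
        assert sum(c.abundance for c in cands) == pytest.approx(1.0, abs=1e-9)

    def test_empty_composition_rejected(self, pgo):
        with pytest.raises(ValidationError):
            enumerate_plausible_species(pgo, min_abundance=0.99)


class TestAnnotation:
    @staticmethod
    def _table(n_peaks):
        peaks = tuple(
            Peak(retention_min=10.0 + 3 * i, area=1000.0) for i in range(n_peaks)
        )
        return PeakTable(
            sample_id="x", time_point_min=0.0, is_area=1e4, peaks=peaks,
            m_lp_mg=150.0, m_a_mg=150.0,
        )

    def test_single_peak_single_species(self, pgo):
        comp = OilComposition("pureL", ((fatty_acid("L"), 100.0),))
        cands = enumerate_plausible_species(comp)
        table = annotate_peaks(self._table(1), cands)
        assert table.peaks[0].annotation == "L-L-L"

    def test_pgo_elution_order_recovers_pn_sequence(self, pgo):
        cands = enumerate_plausible_species(pgo, min_abundance=0.05)
        pns = sorted({c.pn for c in cands})
        table = annotate_peaks(self._table(len(pns)), cands)
        annotated = [parse_tag_label(p.annotation).pn for p in table.peaks]
        assert annotated == pns
        assert table.peaks[0].annotation == "CLn-CLn-CLn"

    def test_excess_peaks_labelled_unknown(self, pgo):
        cands = enumerate_plausible_species(pgo, min_abundance=0.5)  # CLn only
        table = annotate_peaks(self._table(3), cands)
        assert [p.annotation for p in table.peaks] == [
            "CLn-CLn-CLn", "Unknown", "Unknown",
        ]

    def test_excess_groups_warn_not_fail(self, pgo):
        cands = enumerate_plausible_species(pgo, min_abundance=0.05)
        with pytest.warns(UserWarning, match="PN group"):
            table = annotate_peaks(self._table(1), cands)
        assert table.peaks[0].annotation == "CLn-CLn-CLn"

    def test_unsorted_peaks_rejected(self, pgo):
        cands = enumerate_plausible_species(pgo, min_abundance=0.05)
        peaks = (Peak(20.0, 1.0), Peak(10.0, 1.0))
        table = PeakTable("x", 0.0, 1e4, peaks, 150.0, 150.0)
        with pytest.raises(ValidationError):
            annotate_peaks(table, cands)


def test_composition_total_outside_tolerance_rejected():
    with pytest.raises(ValidationError):
        OilComposition("bad", ((fatty_acid("L"), 50.0),))
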