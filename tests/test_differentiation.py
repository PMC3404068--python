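"""Differentiation rule engine: lineage truth table, tissue fronts,
calcification, resorption/maturation and the comparator stimulus model."""

from itertools import product

import numpy as np
import pytest

from callusim.differentiation import (
    Lineage,
    PrendergastBand,
    PrendergastParams,
    RuleParams,
    TissueState,
    advance_front,
    advance_fronts,
    calcify_cartilage,
    classify,
    classify_element,
    prendergast_classify,
    resorb_and_mature,
)
from callusim.fixtures import FixtureSpec, make_fixture
from callusim.materials import Phenotype

O2_HIGH = 74.1
O2_LOW = 10.0


@pytest.fixture()
def rules():
    return RuleParams()


def strip_state(n=8, length=1.0, substrate=Phenotype.IMMATURE_BONE):
    """Granulation strip with one substrate element at the z-min end."""
    fx = make_fixture(FixtureSpec(kind="strip_1d", size=n, length=length))
    mesh = fx.mesh
    order = np.argsort(mesh.centroid[:, 1])
    state = TissueState.initial(mesh)
    state.phenotype[:] = int(Phenotype.GRANULATION)
    state.phenotype[order[0]] = int(substrate)
    return mesh, state, order


class TestClassifyTruthTable:
    NEIGHBORS = {
        "bone": [(Phenotype.CORTICAL_BONE, 1.0)],
        "marrow": [(Phenotype.MARROW, 1.0)],
        "none": [],
    }

    @pytest.mark.parametrize(
        "hypoxic,supplied,neighbor",
        list(product([True, False], [True, False], ["bone", "marrow", "none"])),
    )
    def test_exhaustive_lineage_table(self, rules, hypoxic, supplied, neighbor):
        """Hypoxia -> chondrogenesis regardless of substrate or supply;
        osteogenesis and adipogenesis need both a supply and a completed
        stiff/soft substrate; everything else is fibrogenesis."""
        lineage = classify_element(
            Phenotype.GRANULATION,
            O2_LOW if hypoxic else O2_HIGH,
            supplied,
            self.NEIGHBORS[neighbor],
            rules,
        )
        if hypoxic:
            expected = Lineage.CHONDROGENIC
        elif supplied and neighbor == "bone":
            expected = Lineage.OSTEOGENIC
        elif supplied and neighbor == "marrow":
            expected = Lineage.ADIPOGENIC
        else:
            expected = Lineage.FIBROGENIC
        assert lineage == expected

    def test_incomplete_substrate_does_not_count(self, rules):
        lineage = classify_element(
            Phenotype.GRANULATION,
            O2_HIGH,
            True,
            [(Phenotype.IMMATURE_BONE, 0.7)],
            rules,
        )
        assert lineage == Lineage.FIBROGENIC

    def test_differentiated_tissue_returns_none(self, rules):
        for phen in (
            Phenotype.CORTICAL_BONE,
            Phenotype.MATURE_BONE,
            Phenotype.IMMATURE_BONE,
            Phenotype.MARROW,
            Phenotype.CARTILAGE,
        ):
            assert (
                classify_element(
                    phen, O2_HIGH, True, self.NEIGHBORS["bone"], rules
                )
                == Lineage.NONE
            )

    def test_calcified_cartilage_endochondral_entry(self, rules):
        assert (
            classify_element(
                Phenotype.CALCIFIED_CARTILAGE,
                O2_HIGH,
                True,
                self.NEIGHBORS["bone"],
                rules,
            )
            == Lineage.OSTEOGENIC
        )
        assert (
            classify_element(
                Phenotype.CALCIFIED_CARTILAGE,
                O2_HIGH,
                False,
                self.NEIGHBORS["bone"],
                rules,
            )
            == Lineage.NONE
        )

    def test_resorbed_flag_blocks_osteogenic_reentry(self, rules):
        assert (
            classify_element(
                Phenotype.GRANULATION,
                O2_HIGH,
                True,
                self.NEIGHBORS["bone"],
                rules,
                resorbed=True,
            )
            == Lineage.FIBROGENIC
        )

    def test_no_bone_or_marrow_without_supply_vectorised(self, rules):
        """Invariant: the vectorised classifier never emits an osteogenic or
        adipogenic lineage for an unsupplied element."""
        mesh, state, order = strip_state()
        state.phenotype[order[1]] = int(Phenotype.MARROW)
        supplied = np.zeros(mesh.n_elems, dtype=bool)
        lineage = classify(
            state, mesh, np.full(mesh.n_elems, O2_HIGH), supplied, rules
        )
        assert not np.isin(
            lineage, [int(Lineage.OSTEOGENIC), int(Lineage.ADIPOGENIC)]
        ).any()


class TestTissueFront:
    def test_unit_cube_fills_in_one_day(self, rules):
        assert advance_front(0.0, 1.0, 1.0, rules, 1.0) == 1.0

    def test_no_substrate_area_leaves_fill_unchanged(self, rules):
        assert advance_front(0.25, 0.0, 1.0, rules, 1.0) == 0.25

    def test_zero_volume_rejected(self, rules):
        with pytest.raises(ValueError):
            advance_front(0.0, 1.0, 0.0, rules, 1.0)

    @pytest.mark.parametrize("n_elems", [4, 8, 16])
    def test_front_crossing_time_element_size_independent(self, rules, n_elems):
        """The bone front crosses a 1 mm strip in 1/TFR days at any
        discretisation: larger elements take proportionally longer to fill,
        and a filled element unlocks its neighbour within the same day."""
        mesh, state, order = strip_state(n=n_elems, length=1.0)
        o2 = np.full(mesh.n_elems, O2_HIGH)
        supplied = np.ones(mesh.n_elems, dtype=bool)
        days = 0
        while days < 10:
            state.lineage = classify(state, mesh, o2, supplied, rules)
            advance_fronts(state, mesh, o2, supplied, rules, 1.0)
            days += 1
            if np.all(
                state.phenotype[order[1:]] == int(Phenotype.IMMATURE_BONE)
            ):
                break
        assert days == 1  # length/TFR = 1 day, independent of n_elems

    def test_front_blocked_until_neighbour_full(self, rules):
        """An element two steps from the substrate gains no fill while the
        intermediate element is still filling."""
        mesh, state, order = strip_state(n=4, length=4.0)  # 1 mm elements
        o2 = np.full(mesh.n_elems, O2_HIGH)
        supplied = np.ones(mesh.n_elems, dtype=bool)
        state.lineage = classify(state, mesh, o2, supplied, rules)
        advance_fronts(state, mesh, o2, supplied, rules, 0.5)  # half a day
        assert state.fill[order[1]] == pytest.approx(0.5)
        assert state.phenotype[order[2]] == int(Phenotype.GRANULATION)
        assert state.fill[order[2]] == 1.0  # untouched, still granulation

    def test_marrow_front_produces_marrow(self, rules):
        mesh, state, order = strip_state(substrate=Phenotype.MARROW)
        o2 = np.full(mesh.n_elems, O2_HIGH)
        supplied = np.ones(mesh.n_elems, dtype=bool)
        for _ in range(3):
            state.lineage = classify(state, mesh, o2, supplied, rules)
            advance_fronts(state, mesh, o2, supplied, rules, 1.0)
        assert np.any(state.phenotype[order[1:]] == int(Phenotype.MARROW))


class TestCalcification:
    def test_cartilage_next_to_bone_calcifies(self, rules):
        mesh, state, order = strip_state()
        state.phenotype[order[1:]] = int(Phenotype.CARTILAGE)
        n = calcify_cartilage(state, mesh)
        assert n == 1
        assert state.phenotype[order[1]] == int(Phenotype.CALCIFIED_CARTILAGE)
        assert np.all(state.phenotype[order[2:]] == int(Phenotype.CARTILAGE))

    def test_cartilage_without_bone_neighbors_unchanged(self, rules):
        mesh, state, order = strip_state(substrate=Phenotype.FIBROUS)
        state.phenotype[order[1:]] = int(Phenotype.CARTILAGE)
        assert calcify_cartilage(state, mesh) == 0


class TestResorptionAndMaturation:
    def make_bone_strip(self):
        mesh, state, order = strip_state()
        state.phenotype[:] = int(Phenotype.IMMATURE_BONE)
        return mesh, state, order

    def test_below_threshold_bone_resorbs(self, rules):
        mesh, state, _ = self.make_bone_strip()
        gamma = np.full(mesh.n_elems, 0.001)  # < 0.005 %
        resorbed, _ = resorb_and_mature(state, gamma, rules, mesh, r_endosteal=7.0)
        assert resorbed == mesh.n_elems
        assert not np.isin(
            state.phenotype, [int(Phenotype.IMMATURE_BONE)]
        ).any()
        assert np.all(state.resorbed)

    def test_endosteal_vs_periosteal_resorption_targets(self, rules):
        mesh, state, _ = self.make_bone_strip()
        gamma = np.zeros(mesh.n_elems)
        # strip sits at r ~ 1000 mm: periosteal side of any r_endosteal < 1000
        resorb_and_mature(state, gamma, rules, mesh, r_endosteal=7.0)
        assert np.all(state.phenotype == int(Phenotype.FIBROUS))
        mesh2, state2, _ = self.make_bone_strip()
        resorb_and_mature(state2, gamma, rules, mesh2, r_endosteal=2000.0)
        assert np.all(state2.phenotype == int(Phenotype.GRANULATION))

    def test_loaded_bone_persists_and_ages(self, rules):
        mesh, state, _ = self.make_bone_strip()
        gamma = np.full(mesh.n_elems, 0.5)
        resorbed, matured = resorb_and_mature(
            state, gamma, rules, mesh, r_endosteal=7.0
        )
        assert resorbed == 0 and matured == 0
        assert np.all(state.days_immature == 1)

    def test_ten_day_maturation(self, rules):
        mesh, state, _ = self.make_bone_strip()
        gamma = np.full(mesh.n_elems, 0.5)
        for _ in range(10):
            resorb_and_mature(state, gamma, rules, mesh, r_endosteal=7.0)
        assert np.all(state.phenotype == int(Phenotype.MATURE_BONE))


class TestPrendergastComparator:
    def test_zero_stimulus_is_resorption(self):
        assert prendergast_classify(0.0, 0.0, PrendergastParams()) == int(
            PrendergastBand.RESORPTION
        )

    @pytest.mark.parametrize(
        "gamma,v,expected",
        [
            (7.5, 0.0, PrendergastBand.CARTILAGE),   # S = 2 with a = 3.75
            (0.0, 12.0, PrendergastBand.FIBROUS),    # S = 4 with b = 3
            (0.1875, 0.0, PrendergastBand.BONE),     # S = 0.05
        ],
    )
    def test_band_assignment(self, gamma, v, expected):
        assert prendergast_classify(gamma, v, PrendergastParams()) == int(expected)

    @pytest.mark.parametrize(
        "S,expected",
        [
            (0.01, PrendergastBand.RESORPTION),  # edges belong to the
            (1.0, PrendergastBand.BONE),         # lower-stimulus band
            (3.0, PrendergastBand.CARTILAGE),
        ],
    )
    def test_band_edges_belong_to_lower_band(self, S, expected):
        p = PrendergastParams()
        assert prendergast_classify(S * p.a, 0.0, p) == int(expected)

    def test_rejects_nonpositive_normalisers(self):
        with pytest.raises(ValueError):
            PrendergastParams(a=0.0)
        with pytest.raises(ValueError):
            PrendergastParams(b=-1.0)

    def test_stimulus_monotone_in_both_inputs(self):
        p = PrendergastParams()
        gammas = np.linspace(0.0, 20.0, 40)
        bands = prendergast_classify(gammas, np.zeros_like(gammas), p)
        assert np.all(np.diff(bands) >= 0)
        vs = np.linspace(0.0, 15.0, 40)
        bands_v = prendergast_classify(np.zeros_like(vs), vs, p)
        assert np.all(np.diff(bands_v) >= 0)
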