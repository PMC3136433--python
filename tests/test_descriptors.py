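"""The 61-descriptor panel: compositions, charge, pI, masses, scales,
secondary structure and min-max normalization."""

import json
from importlib import resources

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cppscreen as cs
from cppscreen import descriptors as d
from cppscreen.errors import EmptyInput

valid_sequences = st.text(alphabet=cs.ALPHABET, min_size=1, max_size=40)


def pep(seq: str) -> cs.Peptide:
    return cs.parse_peptide(seq, "p")


def grid_scan_pi(seq: str, step: float = 1e-4) -> float:
    """Independent pI oracle: dense pH grid scan for the charge sign flip.

    Rebuilds the Henderson-Hasselbalch charge directly from the packaged
    pKa registry, vectorized over the grid; shares no code with the
    bisection under test.
    """
    pka = d._PKA
    phs = np.arange(0.0, 14.0 + step, step)
    charge = (1.0 / (1.0 + 10.0 ** (phs - pka["nterm"]))
              - 1.0 / (1.0 + 10.0 ** (pka["cterm"] - phs)))
    for res, k in pka["sidechain"].items():
        n = seq.count(res)
        if not n:
            continue
        if res in pka["basic"]:
            charge += n / (1.0 + 10.0 ** (phs - k))
        else:
            charge -= n / (1.0 + 10.0 ** (k - phs))
    i = int(np.argmax(charge <= 0))
    return 0.5 * (phs[i - 1] + phs[i])


class TestComposition:
    @pytest.mark.parametrize("seq, expect", [
        ("RRRRRRRRR", {"R": (9, 100.0)}),
        ("PMLKE", {a: (1, 20.0) for a in "PMLKE"}),
    ])
    def test_examples(self, seq, expect):
        counts, percents = d.aa_composition(pep(seq))
        for a, (c, p) in expect.items():
            assert counts[a] == c
            assert percents[a] == pytest.approx(p)
        others = set(cs.ALPHABET) - set(expect)
        assert all(counts[a] == 0 for a in others)

    @given(valid_sequences)
    @settings(max_examples=50, deadline=None)
    def test_counts_and_percents_conserve(self, seq):
        p = pep(seq)
        counts, percents = d.aa_composition(p)
        assert sum(counts.values()) == len(p)
        assert sum(percents.values()) == pytest.approx(100.0, abs=1e-9)


class TestCharge:
    @pytest.mark.parametrize("seq, expect", [
        ("RRRRRRRRR", (9, 0, 9)),
        ("PMLKE", (1, 1, 0)),
        ("TCSSNCQTCPCSSNNCQ", (0, 0, 0)),   # all-polar negative control
    ])
    def test_examples(self, seq, expect):
        assert d.charge_features(pep(seq)) == expect

    def test_histidine_counts_as_positive(self):
        assert d.charge_features(pep("HHH")) == (3, 0, 3)


class TestIsoelectricPoint:
    def test_polyglycine_matches_termini_only_root(self):
        assert d.isoelectric_point(pep("G" * 12)) == pytest.approx(
            grid_scan_pi("G" * 12), abs=1e-3)

    def test_polyarginine_strongly_basic(self):
        assert d.isoelectric_point(pep("RRRRRRRRR")) > 11

    def test_bisection_agrees_with_grid_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            seq = "".join(rng.choice(list(cs.ALPHABET),
                                     size=rng.integers(5, 30)))
            assert d.isoelectric_point(pep(seq)) == pytest.approx(
                grid_scan_pi(seq), abs=1e-3)

    @given(valid_sequences)
    @settings(max_examples=25, deadline=None)
    def test_appending_lysine_never_decreases_pi(self, seq):
        assert (d.isoelectric_point(pep(seq + "K"))
                >= d.isoelectric_point(pep(seq)) - 1e-3)


class TestMolecularWeight:
    def test_glycine(self):
        assert d.molecular_weight(pep("G")) == pytest.approx(75.07, abs=0.01)

    def test_diglycine(self):
        assert d.molecular_weight(pep("GG")) == pytest.approx(132.12, abs=0.01)

    @given(valid_sequences, valid_sequences)
    @settings(max_examples=25, deadline=None)
    def test_condensation_identity(self, s1, s2):
        lhs = d.molecular_weight(pep(s1 + s2))
        rhs = (d.molecular_weight(pep(s1)) + d.molecular_weight(pep(s2))
               - 18.0153)
        assert lhs == pytest.approx(rhs, abs=1e-6)


class TestScales:
    def test_gravy_homopolymers(self):
        assert d.gravy(pep("RRRRRRRRR")) == pytest.approx(-4.5)
        assert d.gravy(pep("IIIII")) == pytest.approx(4.5)

    @pytest.mark.parametrize("scale_name", [
        "hydropathicity", "hydrophobicity", "lipophilicity",
        "amphiphilicity", "water_octanol_partition", "steric_bulk",
        "side_chain_bulk"])
    def test_homopolymer_mean_equals_residue_value(self, scale_name):
        scale = cs.get_scale(scale_name)
        assert d.scale_mean(pep("WWWW"), scale) == pytest.approx(
            scale.values["W"])

    def test_registry_complete_and_finite(self):
        reg = json.loads(resources.files("cppscreen.data")
                         .joinpath("scales.json").read_text())
        for name, entry in reg["scales"].items():
            assert set(entry["values"]) == set(cs.ALPHABET), name
            assert all(np.isfinite(v) for v in entry["values"].values())


class TestHydrogenBonds:
    def test_glycine_neutral(self):
        assert d.net_donated_hbonds(pep("G" * 17)) == 0

    def test_arginine_additive(self):
        one = d.net_donated_hbonds(pep("R"))
        assert d.net_donated_hbonds(pep("RRRRRRRRR")) == pytest.approx(9 * one)

    @given(valid_sequences, valid_sequences)
    @settings(max_examples=25, deadline=None)
    def test_concatenation_additive(self, s1, s2):
        assert d.net_donated_hbonds(pep(s1 + s2)) == pytest.approx(
            d.net_donated_hbonds(pep(s1)) + d.net_donated_hbonds(pep(s2)))


class TestSecondaryStructure:
    @given(valid_sequences)
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_100(self, seq):
        helix, sheet, coil = d.secondary_structure_fractions(pep(seq))
        assert helix + sheet + coil == pytest.approx(100.0, abs=1e-9)

    def test_propensity_argmax_assignments(self):
        cf = d._CF
        # the packaged table makes helix the argmax state for A ...
        assert cf["helix"]["A"] == max(cf[s]["A"] for s in ("helix", "sheet", "coil"))
        helix, _, _ = d.secondary_structure_fractions(pep("AAAAAA"))
        assert helix == 100.0
        # ... and coil the argmax state for G
        assert cf["coil"]["G"] == max(cf[s]["G"] for s in ("helix", "sheet", "coil"))
        _, _, coil = d.secondary_structure_fractions(pep("GGGGGG"))
        assert coil == 100.0


class TestFeatureVector:
    def test_dimension_and_finiteness_on_fixtures(self, cpp111, noncpp34,
                                                  validation13):
        for coll in (cpp111, noncpp34, validation13):
            for p in coll:
                v = cs.compute_feature_vector(p)
                assert v.shape == (61,)
                assert np.isfinite(v).all()

    def test_entries_match_single_feature_operations(self):
        p = pep("GRKKRRQRRRPQ")
        v = cs.compute_feature_vector(p)
        names = list(cs.FEATURE_NAMES)
        pos, neg, net = d.charge_features(p)
        assert v[names.index("net_charge")] == net
        assert v[names.index("length")] == len(p)
        assert v[names.index("hydropathicity")] == pytest.approx(d.gravy(p))
        assert v[names.index("count_R")] == p.sequence.count("R")

    def test_group_percents_partition_the_alphabet(self):
        groups = d.RESIDUE_GROUPS
        union = set().union(*groups.values())
        assert union == set(cs.ALPHABET)
        total = sum(len(g) for g in groups.values())
        assert total == 20  # exclusive partition, every residue once

    @given(valid_sequences)
    @settings(max_examples=20, deadline=None)
    def test_purity(self, seq):
        a = cs.compute_feature_vector(pep(seq))
        b = cs.compute_feature_vector(pep(seq))
        assert np.array_equal(a, b)


class TestNormalization:
    def test_fit_apply_unit_range(self, cpp111):
        X = cs.feature_table(cpp111).to_numpy()
        params = cs.fit_normalizer(X)
        Z = cs.apply_normalizer(params, X)
        span = X.max(axis=0) - X.min(axis=0)
        nonconst = span > 0
        assert Z[:, nonconst].min(axis=0) == pytest.approx(0.0)
        assert Z[:, nonconst].max(axis=0) == pytest.approx(1.0)

    def test_constant_column_maps_to_zero(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        Z = cs.apply_normalizer(cs.fit_normalizer(X), X)
        assert np.all(Z[:, 1] == 0.0)

    def test_held_out_values_clamped(self):
        X = np.array([[0.0], [10.0]])
        params = cs.fit_normalizer(X)
        Z = cs.apply_normalizer(params, np.array([[-5.0], [15.0]]))
        assert Z.ravel().tolist() == [0.0, 1.0]

    def test_invertible_on_nonconstant_columns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5)) * 100
        params = cs.fit_normalizer(X)
        Z = cs.apply_normalizer(params, X)
        back = params.minimum + Z * (params.maximum - params.minimum)
        assert np.allclose(back, X, rtol=1e-12, atol=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyInput):
            cs.fit_normalizer(np.empty((0, 3)))
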