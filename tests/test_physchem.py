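"""Periodic and windowed physicochemical descriptors against literal oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from featureforge.chain import AA1TO3, CANONICAL1, Chain
from featureforge.physchem import (
    PeriodicDescriptorSpec,
    PropertyTable,
    WindowDescriptorSpec,
    categorical_features,
    disorder_descriptor,
    load_physchem_catalog,
    load_property_table,
    periodic_descriptor,
    periodic_profile,
    window_profile,
)
from featureforge.synthetic import gen_property_table


def oracle_periodic(H, T, A):
    """Literal term-by-term evaluation of the resonance amplitude."""
    n = len(H) // 2
    c = s = 0.0
    for idx, k in enumerate(range(-n, n + 1)):
        f = math.exp(-A * (k / n) ** 2)
        c += H[idx] * math.cos(2 * math.pi * k / T) * f
        s += H[idx] * math.sin(2 * math.pi * k / T) * f
    return math.sqrt(c * c + s * s)


def make_chain(seq1, labels=None):
    return Chain(chain_id="T", seq1=seq1, seq3=[AA1TO3[l] for l in seq1],
                 labels8=labels or ["C"] * len(seq1))


class TestPropertyTable:
    def test_constant_table_validates(self):
        t = PropertyTable("CONST", {c: 1.0 for c in AA1TO3.values()})
        assert t.value1("A") == 1.0

    def test_missing_canonical_residue_rejected(self):
        vals = {c: 1.0 for c in AA1TO3.values()}
        vals.pop("TRP")
        with pytest.raises(ValueError, match="missing canonical"):
            PropertyTable("BAD", vals)

    def test_standardization_zeroes_canonical_mean(self):
        t = gen_property_table(seed=3).standardized()
        canon = [t.values[AA1TO3[l]] for l in CANONICAL1]
        assert np.mean(canon) == pytest.approx(0.0, abs=1e-12)
        assert np.std(canon) == pytest.approx(1.0, abs=1e-12)

    def test_kyte_doolittle_loads_from_packaged_flat_file(self):
        t = load_property_table("KYTJ820101")
        assert t.values["ILE"] == pytest.approx(4.5)
        assert t.values["ARG"] == pytest.approx(-4.5)

    def test_ncaa_strict_keeps_extension_value_distinct_from_parent(self):
        t = load_property_table("KARS160108", ncaa_policy="strict",
                                ncaa_codes=["HYP"])
        assert "HYP" in t.values
        assert t.values["HYP"] != t.values["PRO"]

    def test_ncaa_fallback_inherits_parent_when_unlisted(self, tmp_path):
        # a scale with no extension entries: MSE must inherit MET's value
        scale = tmp_path / "scale.tsv"
        lines = ["code\tvalue"] + [f"{c}\t{i}.0" for i, c in enumerate(AA3TO1_ORDER)]
        scale.write_text("\n".join(lines) + "\n")
        empty_ext = tmp_path / "ext.tsv"
        empty_ext.write_text("code\taccession\tvalue\n")
        t = load_property_table(scale, ncaa_policy="fallback",
                                ncaa_extension=empty_ext, ncaa_codes=["MSE"])
        assert t.values["MSE"] == t.values["MET"]
        t2 = load_property_table(scale, ncaa_policy="strict",
                                 ncaa_extension=empty_ext, ncaa_codes=["MSE"])
        assert "MSE" not in t2.values


AA3TO1_ORDER = sorted(AA1TO3.values())


class TestPeriodicDescriptor:
    def test_zero_signal_gives_zero(self):
        assert periodic_descriptor(np.zeros(11), T=3.6, A=1.0) == 0.0

    def test_single_center_residue_gives_absolute_value(self):
        H = np.zeros(11)
        H[5] = -2.5
        assert periodic_descriptor(H, T=3.6, A=1.0) == pytest.approx(2.5)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 12))
            H = rng.normal(size=2 * n + 1)
            T = float(rng.uniform(1.2, 15.0))
            A = float(rng.choice([0.5, 1.0, 2.0, 3.0]))
            assert periodic_descriptor(H, T, A) == pytest.approx(
                oracle_periodic(H, T, A), abs=1e-12)

    def test_pure_cosine_peaks_at_its_own_period(self):
        T0 = 3.6
        n = 9
        k = np.arange(-n, n + 1)
        H = np.cos(2 * np.pi * k / T0)
        grid = np.arange(1.2, 15.01, 0.1)
        vals = [periodic_descriptor(H, T, A=1.0) for T in grid]
        assert grid[int(np.argmax(vals))] == pytest.approx(T0, abs=0.05)

    def test_homogeneous_in_signal_scale(self):
        rng = np.random.default_rng(1)
        H = rng.normal(size=13)
        base = periodic_descriptor(H, 3.0, 1.0)
        assert periodic_descriptor(-4.0 * H, 3.0, 1.0) == pytest.approx(4.0 * base)

    def test_phase_shift_of_pure_sinusoid_preserves_amplitude(self):
        # 21-residue window spans exactly 7 periods of T0=3, so with a
        # negligible taper the amplitude at T0 is phase-independent.
        n, T0 = 10, 3.0
        k = np.arange(-n, n + 1)
        vals = [periodic_descriptor(np.cos(2 * np.pi * k / T0 + ph), T0, 1e-12)
                for ph in (0.0, 0.7, 2.1)]
        assert np.ptp(vals) < 1e-9

    def test_half_window_rule(self):
        spec = PeriodicDescriptorSpec(accession="X", T=3.6, n_T=5)
        assert spec.half_window == round((3.6 * 5 - 1) / 2)

    def test_profile_matches_windowed_oracle(self):
        table = gen_property_table(seed=4)
        chain = make_chain("ACDEFGHIKLMNPQRSTVWY")
        spec = PeriodicDescriptorSpec(accession=table.accession, T=3.6, n_T=5, A=1.0)
        prof = periodic_profile(chain, spec, table)
        n = spec.half_window
        std = table.standardized()
        signal = np.array([std.value1(l) for l in chain.seq1])
        padded = np.zeros(len(chain) + 2 * n)
        padded[n:n + len(chain)] = signal
        for p in range(len(chain)):
            assert prof[p] == pytest.approx(
                oracle_periodic(padded[p:p + 2 * n + 1], 3.6, 1.0), abs=1e-12)


class TestWindowDescriptor:
    def test_constant_property_unweighted_sum(self):
        table = PropertyTable("CONST", {c: 1.0 for c in AA1TO3.values()})
        chain = make_chain("AAAAAAAAAA")
        spec = WindowDescriptorSpec(accession="CONST", left=-2, right=2, A=0.0)
        prof = window_profile(chain, spec, table, standardize=False)
        assert prof[5] == pytest.approx(5.0)

    def test_window_entirely_off_chain_gives_zero(self):
        table = gen_property_table(seed=5)
        chain = make_chain("ACDEFGHIKLMNPQRSTVWY")
        spec = WindowDescriptorSpec(accession=table.accession, left=-10, right=-3)
        prof = window_profile(chain, spec, table)
        assert prof[0] == 0.0

    def test_matches_direct_sum_oracle_table3_spec(self):
        # the [-5, 6] window used by the published strand-energy descriptor
        table = gen_property_table(seed=6)
        chain = make_chain("ACDEFGHIKLMNPQRSTVWYACDEF")
        spec = WindowDescriptorSpec(accession=table.accession, left=-5, right=6,
                                    A=0.5, power=1)
        prof = window_profile(chain, spec, table)
        std = table.standardized()
        signal = [std.value1(l) for l in chain.seq1]
        m = 6
        for p in range(len(chain)):
            total = 0.0
            for k in range(-5, 7):
                if 0 <= p + k < len(chain):
                    total += signal[p + k] * math.exp(-0.5 * (k / m) ** 2)
            assert prof[p] == pytest.approx(total, abs=1e-12)

    def test_linear_in_property_when_undecayed(self):
        chain = make_chain("ACDEFGHIKL")
        t1 = gen_property_table(seed=7)
        t2 = gen_property_table(seed=8)
        combo = PropertyTable("COMBO", {c: t1.values[c] + t2.values[c]
                                        for c in t1.values})
        spec = WindowDescriptorSpec(accession="X", left=-3, right=3, A=0.0)
        p1 = window_profile(chain, spec, t1, standardize=False)
        p2 = window_profile(chain, spec, t2, standardize=False)
        pc = window_profile(chain, spec, combo, standardize=False)
        assert np.allclose(pc, p1 + p2, atol=1e-12)

    def test_invalid_offsets_rejected(self):
        with pytest.raises(ValueError):
            WindowDescriptorSpec(accession="X", left=3, right=-3)


class TestCategoricalFeatures:
    def test_one_hot_rows_sum_to_one_on_canonical_chain(self):
        chain = make_chain("ACDEFGHIKL")
        X, names = categorical_features(chain)
        onehot_cols = [i for i, n in enumerate(names) if n.startswith("onehot_")]
        assert np.allclose(X[:, onehot_cols].sum(axis=1), 1.0)

    def test_ncaa_gets_its_own_bit_not_the_parent(self):
        chain = Chain(chain_id="T", seq1="AMA", seq3=["ALA", "MSE", "ALA"],
                      labels8=["C"] * 3)
        X, names = categorical_features(chain)
        mse_col = names.index("onehot_MSE")
        met_col = names.index("onehot_MET")
        assert X[1, mse_col] == 1.0 and X[1, met_col] == 0.0

    def test_n_terminal_flag_covers_first_three_residues(self):
        chain = make_chain("ACDEFGHIKL")
        X, names = categorical_features(chain)
        col = names.index("End_N_3")
        assert X[:, col].tolist() == [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]

    def test_unknown_residue_row_is_all_zero(self):
        chain = Chain(chain_id="T", seq1="AXA", seq3=["ALA", "ZZZ", "ALA"],
                      labels8=["C"] * 3)
        X, names = categorical_features(chain)
        onehot_cols = [i for i, n in enumerate(names) if n.startswith("onehot_")]
        assert X[1, onehot_cols].sum() == 0.0


class TestDisorderDescriptor:
    def test_power_and_gaps(self, tmp_path):
        f = tmp_path / "scores.tsv"
        f.write_text("position\tscore\n0\t0.0\n1\t0.5\n3\t1.5\n")
        col = disorder_descriptor(f, length=5, power=3)
        assert col[0] == 0.0
        assert col[1] == pytest.approx(0.125)
        assert col[3] == 1.0  # clamped to [0, 1] before powering
        assert np.isnan(col[2]) and np.isnan(col[4])


def test_canonical_chain_identical_with_and_without_ncaa_support():
    chain = make_chain("ACDEFGHIKLMNPQRSTVWY")
    strict = load_property_table("KYTJ820101", ncaa_policy="strict")
    fallback = load_property_table("KYTJ820101", ncaa_policy="fallback")
    spec = WindowDescriptorSpec(accession="KYTJ820101", left=-3, right=3, A=1.0)
    assert np.allclose(window_profile(chain, spec, strict),
                       window_profile(chain, spec, fallback))


def test_shipped_catalog_loads():
    cat = load_physchem_catalog()
    assert {s.T for s in cat["periodic"]} == {3.7, 10.0, 3.6, 3.0}
    assert any(s.left == -5 and s.right == 6 for s in cat["window"])
    assert any(s["kind"] == "disorder" for s in cat["special"])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(-10, 10), min_size=5, max_size=21).filter(
    lambda v: len(v) % 2 == 1),
    st.floats(1.2, 15.0), st.sampled_from([0.5, 1.0, 2.0, 3.0]))
def test_periodic_descriptor_nonnegative_and_homogeneous(H, T, A):
    H = np.array(H)
    val = periodic_descriptor(H, T, A)
    assert val >= 0.0
    assert periodic_descriptor(2.0 * H, T, A) == pytest.approx(2.0 * val, rel=1e-9, abs=1e-12)
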