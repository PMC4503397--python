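"""Feature families: formulas, normalisations, and window assembly."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nabind.constants import AA_INDEX, AA_ORDER, BLOSUM62_BACKGROUND, MAX_ASA
from nabind.dataset_builder import LabeledChain
from nabind.features import (ConservationConfig, FeatureConfig,
                             assemble_vectors, conservation_scores,
                             feature_layout, global_features,
                             interface_propensity, logistic_normalize,
                             sequential_position, structural_descriptors,
                             vector_length)
from nabind.io_formats import DataError, SequenceProfile


class TestLogisticNormalize:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.5),
        (2.0, 0.880797),   # 1 / (1 + e^-2)
        (-2.0, 0.119203),
    ])
    def test_values(self, x, expected):
        assert logistic_normalize(x) == pytest.approx(expected, abs=1e-6)

    @given(st.floats(-30, 30), st.floats(-30, 30))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_symmetric(self, x, y):
        fx, fy = logistic_normalize(x), logistic_normalize(y)
        if x < y:
            assert fx <= fy
        assert logistic_normalize(-x) == pytest.approx(1.0 - fx, abs=1e-12)


def entropy_oracle(p, q, lam=0.5, base=2.0):
    """Direct 20-term summations of SE, RE and JSD."""
    def xlog(v, w):
        return 0.0 if v == 0 else v * math.log(w, base)
    c = [lam * pi + (1 - lam) * qi for pi, qi in zip(p, q)]
    se = -math.fsum(xlog(pi, pi) for pi in p)
    re = math.fsum(xlog(pi, pi / qi) for pi, qi in zip(p, q))
    jsd = (lam * math.fsum(xlog(pi, pi / ci) for pi, ci in zip(p, c))
           + (1 - lam) * math.fsum(xlog(qi, qi / ci) for qi, ci in zip(q, c)))
    return se, re, jsd


def profile_from_wop(wop):
    wop = np.atleast_2d(np.asarray(wop, float))
    return SequenceProfile("A" * wop.shape[0], np.zeros_like(wop), wop)


class TestConservationScores:
    def test_uniform_distribution(self):
        cs = conservation_scores(profile_from_wop(np.full((1, 20), 5.0)))
        assert cs.se[0] == pytest.approx(math.log2(20), abs=1e-12)

    def test_p_equals_q_zeroes_divergences(self):
        wop = BLOSUM62_BACKGROUND * 100
        cs = conservation_scores(profile_from_wop(wop))
        assert cs.re[0] == pytest.approx(0.0, abs=1e-12)
        assert cs.jsd[0] == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_against_uniform_background(self):
        wop = np.zeros((1, 20))
        wop[0, 3] = 100.0
        cfg = ConservationConfig(background=np.full(20, 1 / 20))
        cs = conservation_scores(profile_from_wop(wop), cfg)
        assert cs.se[0] == pytest.approx(0.0, abs=1e-12)
        assert cs.re[0] == pytest.approx(math.log2(20), abs=1e-12)
        p = wop[0] / 100
        _, _, jsd = entropy_oracle(p, [1 / 20] * 20)
        assert cs.jsd[0] == pytest.approx(jsd, abs=1e-12)

    def test_matches_oracle_on_random_rows(self, rng):
        wop = rng.dirichlet(np.ones(20), size=50) * 100
        cs = conservation_scores(profile_from_wop(wop))
        q = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()
        for i in range(50):
            p = wop[i] / wop[i].sum()
            se, re, jsd = entropy_oracle(p, q)
            assert cs.se[i] == pytest.approx(se, abs=1e-10)
            assert cs.re[i] == pytest.approx(re, abs=1e-10)
            assert cs.jsd[i] == pytest.approx(jsd, abs=1e-10)

    def test_zero_wop_row_falls_back_to_background(self):
        cs = conservation_scores(profile_from_wop(np.zeros((1, 20))))
        q = BLOSUM62_BACKGROUND / BLOSUM62_BACKGROUND.sum()
        se_q = -math.fsum(v * math.log2(v) for v in q)
        assert cs.se[0] == pytest.approx(se_q, abs=1e-10)
        assert cs.re[0] == pytest.approx(0.0, abs=1e-12)
        assert cs.jsd[0] == pytest.approx(0.0, abs=1e-12)

    def test_negative_wop_rejected(self):
        prof = profile_from_wop(np.full((1, 20), 5.0))
        prof.wop[0, 0] = -1.0
        with pytest.raises(DataError):
            conservation_scores(prof)

    def test_jsd_symmetric_and_bounded(self, rng):
        # lambda = 0.5, base 2: JSD(p, q) == JSD(q, p) and JSD <= 1
        for _ in range(200):
            p = rng.dirichlet(np.ones(20) * rng.uniform(0.2, 5))
            q = rng.dirichlet(np.ones(20) * rng.uniform(0.2, 5))
            _, _, j_pq = entropy_oracle(p, q)
            _, _, j_qp = entropy_oracle(q, p)
            assert j_pq == pytest.approx(j_qp, abs=1e-10)
            assert -1e-12 <= j_pq <= 1.0 + 1e-12
            cfg = ConservationConfig(background=np.maximum(q, 1e-12))
            cs = conservation_scores(profile_from_wop(p[None, :] * 100), cfg)
            assert cs.jsd[0] == pytest.approx(j_pq, abs=1e-9)

    def test_entropy_maximal_at_uniform(self, rng):
        uniform_se = math.log2(20)
        for _ in range(100):
            p = rng.dirichlet(np.ones(20))
            se, _, _ = entropy_oracle(p, [1 / 20] * 20)
            assert se <= uniform_se + 1e-12


def make_struct_table(n, ss="C", rsa=10.0, phi=0.0, psi=0.0, disorder=0.1):
    return pd.DataFrame({
        "position": np.arange(1, n + 1),
        "ss": [ss] * n, "rsa_raw": [rsa] * n,
        "phi": [phi] * n, "psi": [psi] * n, "disorder": [disorder] * n,
    })


class TestStructuralDescriptors:
    def test_rsa_at_maximum_is_one(self):
        table = make_struct_table(1, rsa=MAX_ASA["A"])
        sd = structural_descriptors(table, "A")
        assert sd.rsa_norm[0] == pytest.approx(1.0)

    def test_phi_normalisation(self):
        sd = structural_descriptors(make_struct_table(1, phi=-180.0), "A")
        assert sd.phi_norm[0] == -1.0

    def test_rsa_overshoot_clamped(self):
        sd = structural_descriptors(
            make_struct_table(1, rsa=MAX_ASA["A"] + 5.0), "A")
        assert sd.rsa_norm[0] == 1.0

    def test_unknown_ss_symbol_rejected(self):
        with pytest.raises(DataError):
            structural_descriptors(make_struct_table(1, ss="G"), "A")

    def test_onehot_columns(self):
        table = pd.DataFrame({
            "position": [1, 2, 3], "ss": ["H", "E", "C"],
            "rsa_raw": [0.0] * 3, "phi": [0.0] * 3, "psi": [0.0] * 3,
            "disorder": [0.0] * 3,
        })
        sd = structural_descriptors(table, "AAA")
        np.testing.assert_array_equal(sd.ss_onehot, np.eye(3))


def propensity_oracle(chains):
    """Two-pass counting: frequencies overall and at interfaces."""
    from collections import Counter
    all_c, int_c = Counter(), Counter()
    for ch in chains:
        for aa, b in zip(ch.sequence, ch.labels):
            if aa not in AA_INDEX:
                continue
            all_c[aa] += 1
            if b:
                int_c[aa] += 1
    n_all = sum(all_c.values())
    n_int = sum(int_c.values())
    raw = {}
    for aa in AA_ORDER:
        if all_c[aa] == 0:
            raw[aa] = 0.0
        else:
            raw[aa] = (int_c[aa] / n_int) / (all_c[aa] / n_all)
    return raw


class TestInterfacePropensity:
    def test_hand_counted_ratio(self):
        # K is 10% of all residues but 20% of interface residues -> raw 2.0
        seq = "K" + "A" * 9
        labels = np.array([True, True, True, True, True] + [False] * 5)
        chain = LabeledChain("c", seq, labels, "DNA")
        table = interface_propensity([chain])
        assert table.raw[AA_INDEX["K"]] == pytest.approx(2.0)

    def test_normalisation_endpoints(self, small_dataset):
        table = interface_propensity(small_dataset.chains)
        assert table.normalized.max() == 1.0
        assert table.normalized.min() == 0.0
        assert np.all((table.normalized >= 0) & (table.normalized <= 1))

    def test_matches_counting_oracle(self, small_dataset):
        table = interface_propensity(small_dataset.chains)
        oracle = propensity_oracle(small_dataset.chains)
        for aa, idx in AA_INDEX.items():
            assert table.raw[idx] == pytest.approx(oracle[aa], abs=1e-12)

    def test_degenerate_labels_rejected(self):
        chain = LabeledChain("c", "ACDE", np.ones(4, bool), "DNA")
        with pytest.raises(DataError):
            interface_propensity([chain])


class TestSequentialPosition:
    def test_terminus_indicator(self):
        out = sequential_position("A" * 50, "C" * 50)
        assert out[1, 0] == 1.0       # position 2 (1-based) is terminal
        assert out[3, 0] == 0.0
        assert out[-2, 0] == 1.0

    def test_all_coil(self):
        out = sequential_position("A" * 20, "C" * 20)
        np.testing.assert_array_equal(out[:, 1:], np.tile([0, 0, 1], (20, 1)))

    def test_helix_segment_in_window(self):
        ss = "C" * 10 + "HHH" + "C" * 10
        out = sequential_position("A" * 23, ss)
        # residue 7 (0-based) has the HHH run inside its +-5 window
        assert out[7, 1] == 1.0 and out[7, 3] == 0.0
        # residue 1 is 9 away from the run: outside the window
        assert out[1, 1] == 0.0 and out[1, 3] == 1.0

    def test_short_runs_ignored(self):
        ss = "C" * 5 + "HH" + "C" * 5
        out = sequential_position("A" * 12, ss)
        assert np.all(out[:, 1] == 0)


class TestGlobalFeatures:
    def test_length_normalisation(self):
        assert global_features("A" * 1000)[0] == 1.0

    def test_poly_a_composition(self):
        vec = global_features("A" * 10)
        assert vec[1 + AA_INDEX["A"]] == 1.0
        assert vec[1:].sum() == pytest.approx(1.0)

    def test_x_excluded_from_composition(self):
        vec = global_features("ACDX")
        assert vec[1:].sum() == pytest.approx(1.0)
        assert vec[1 + AA_INDEX["A"]] == pytest.approx(1 / 3)


class TestAssembly:
    def featurize(self, ds, cid, cfg=None):
        chain = next(c for c in ds.chains if c.id == cid)
        prop = interface_propensity(ds.chains)
        return assemble_vectors(chain.sequence, ds.profiles[cid],
                                ds.struct_tables[cid], prop, cfg)

    def test_vector_length(self, small_dataset):
        cid = small_dataset.chains[0].id
        mat = self.featurize(small_dataset, cid)
        assert mat.shape[1] == 11 * 40 + 21
        assert mat.shape[1] == vector_length(FeatureConfig())

    def test_first_residue_left_padding_zero(self, small_dataset):
        cid = small_dataset.chains[0].id
        mat = self.featurize(small_dataset, cid)
        assert np.all(mat[0, : 5 * 40] == 0.0)
        assert np.any(mat[0, 5 * 40: 6 * 40] != 0.0)

    def test_deterministic(self, small_dataset):
        cid = small_dataset.chains[0].id
        a = self.featurize(small_dataset, cid)
        b = self.featurize(small_dataset, cid)
        np.testing.assert_array_equal(a, b)

    def test_all_finite(self, small_dataset):
        for c in small_dataset.chains:
            assert np.all(np.isfinite(self.featurize(small_dataset, c.id)))

    def test_ablation_shrinks_by_family_footprint(self, small_dataset):
        cid = small_dataset.chains[0].id
        full = self.featurize(small_dataset, cid)
        cfg = FeatureConfig(include_conservation=False)
        ablated = self.featurize(small_dataset, cid, cfg)
        assert full.shape[1] - ablated.shape[1] == 11 * 3
        cfg2 = FeatureConfig(include_global=False)
        assert full.shape[1] - self.featurize(small_dataset, cid, cfg2).shape[1] == 21

    def test_layout_names(self):
        names = [n for n, _ in feature_layout(FeatureConfig())]
        assert names == ["profile", "conservation", "structure", "physchem",
                         "propensity", "seqpos", "global"]
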