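"""Centroid-level scoring terms against brute-force counting oracles."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from rnadock.coarse import reduce
from rnadock.lowres import (
    ALL_TYPES,
    ENV_CLASSES,
    LowResParams,
    estimate_env_params,
    estimate_pair_params,
    load_params,
    save_params,
    score_bump,
    score_contact,
    score_env,
    score_lowres,
    score_pair,
)
from rnadock.structure import Complex, KIND_PROTEIN, KIND_RNA

from conftest import build_unit, make_pair_complex, rigid_transform_complex


def _single_unit_complex(separation):
    return make_pair_complex(
        prot_atoms=[("CA", (0, 0, 0)), ("CB", (0, 0, 0))],
        rna_atoms=[("P", (separation, 0, 2)), ("N1", (separation, 0, 0))],
    )


class TestContact:
    def test_pair_within_cutoff_counts_both_units(self):
        model = reduce(_single_unit_complex(5.0))
        assert score_contact(model, cutoff=6.0) == 2

    def test_pair_beyond_cutoff(self):
        model = reduce(_single_unit_complex(7.0))
        assert score_contact(model, cutoff=6.0) == 0

    def test_against_bruteforce_double_loop(self, small_complex):
        model = reduce(small_complex)
        got = score_contact(model, cutoff=6.0)
        P = model.centroids("protein")
        R = model.centroids("rna")
        expect = 0
        for p in P:
            if any(np.linalg.norm(p - r) < 6.0 for r in R):
                expect += 1
        for r in R:
            if any(np.linalg.norm(p - r) < 6.0 for p in P):
                expect += 1
        assert got == expect

    def test_invalid_cutoff(self, small_complex):
        with pytest.raises(ValueError):
            score_contact(reduce(small_complex), cutoff=0.0)


class TestBump:
    def test_no_clash_is_zero(self):
        model = reduce(_single_unit_complex(20.0))
        assert score_bump(model, clash_distance=3.0) == 0.0

    def test_single_pair_closed_form(self):
        cd = 3.0
        cx = make_pair_complex(
            prot_atoms=[("CA", (0, 0, 0))],
            rna_atoms=[("N1", (cd / 2, 0, 0))],
        )
        # one coarse pair at cd/2: centroid-centroid (backbone copies centroid
        # for units without backbone atoms, so the pair appears 4x)
        model = reduce(cx)
        got = score_bump(model, clash_distance=cd)
        P = model.coarse_coords("protein")
        R = model.coarse_coords("rna")
        expect = sum(
            (cd - np.linalg.norm(p - r)) ** 2
            for p in P
            for r in R
            if np.linalg.norm(p - r) < cd
        )
        assert got == pytest.approx(expect, abs=1e-12)
        assert got == pytest.approx(len(P) * len(R) * (cd / 2) ** 2)

    def test_against_bruteforce_sum(self, small_complex):
        model = reduce(small_complex)
        got = score_bump(model, clash_distance=4.0)
        P = model.coarse_coords("protein")
        R = model.coarse_coords("rna")
        expect = sum(
            (4.0 - np.linalg.norm(p - r)) ** 2
            for p in P
            for r in R
            if np.linalg.norm(p - r) < 4.0
        )
        assert got == pytest.approx(expect, rel=1e-12)
        assert got >= 0.0


class TestEnvTable:
    def test_uniform_reference_gives_uniform_table(self):
        # all units far from the partner and exposed: every type lands in the
        # same class, so within that class all seen types share one value
        units_p = [
            build_unit(
                KIND_PROTEIN, code, i + 1, "A",
                [("CA", (40 * i, 0, 0)), ("CB", (40 * i + 1, 0, 0))],
                start_serial=1 + 10 * i,
            )
            for i, code in enumerate(("ALA", "SER"))
        ]
        units_r = [
            build_unit(
                KIND_RNA, code, i + 1, "B",
                [("P", (40 * i, 500, 0)), ("N1", (40 * i, 501, 0))],
                start_serial=50 + 10 * i,
            )
            for i, code in enumerate(("A", "U"))
        ]
        table = estimate_env_params([Complex(units_p, units_r, "u")])
        cls = "non_interface|exposed"
        assert table["ALA"][cls] == pytest.approx(table["SER"][cls])
        assert table["A"][cls] == pytest.approx(table["U"][cls])

    def test_hand_counted_single_complex(self):
        cx = _single_unit_complex(5.0)  # both units interface, exposed
        table = estimate_env_params([cx])
        T = len(ALL_TYPES)
        # class interface|exposed saw 2 units: one ALA, one U
        assert table["ALA"]["interface|exposed"] == pytest.approx(-math.log(2 / (2 + T)))
        assert table["U"]["interface|exposed"] == pytest.approx(-math.log(2 / (2 + T)))
        # unseen type in that class: pseudocount floor, finite
        assert table["GLY"]["interface|exposed"] == pytest.approx(-math.log(1 / (2 + T)))
        # empty class: -log(1/T)
        assert table["ALA"]["non_interface|buried"] == pytest.approx(-math.log(1 / T))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            estimate_env_params([])

    def test_score_env_uniform_table_is_count_times_value(self, small_complex):
        params = LowResParams(
            env_logprob={t: {e: 0.7 for e in ENV_CLASSES} for t in ALL_TYPES}
        )
        model = reduce(small_complex)
        n_units = len(model.protein_units) + len(model.rna_units)
        assert score_env(model, params) == pytest.approx(0.7 * n_units)


class TestPairTable:
    def test_single_contact_equals_table_entry(self):
        cx = make_pair_complex(
            prot_atoms=[("CA", (0, 0, 0)), ("CB", (0.5, 0, 0))],
            rna_atoms=[("P", (4, 0, 3)), ("N9", (4, 0, 0))],
            prot_code="ARG",
            rna_code="G",
        )
        table = estimate_pair_params([cx])
        params = LowResParams(pair_logodds=table)
        model = reduce(cx)
        assert score_pair(model, params) == pytest.approx(table[("ARG", "G")])

    def test_score_against_enumeration_oracle(self, small_complex):
        params = LowResParams()
        params.pair_logodds = estimate_pair_params([small_complex], params)
        model = reduce(small_complex)
        got = score_pair(model, params)
        expect = 0.0
        for pu in model.protein_units:
            for ru in model.rna_units:
                if np.linalg.norm(pu.centroid - ru.centroid) < params.contact_cutoff:
                    expect += params.pair_logodds[(pu.code, ru.code)]
        assert got == pytest.approx(expect, rel=1e-12)

    def test_uniform_contacts_approach_zero_logodds(self):
        # one synthetic complex per (type, nucleotide) combination with equal
        # type frequencies: log-odds shrink toward -log of a constant ratio
        refs = []
        codes = ("ALA", "SER", "GLY", "LEU")
        nts = ("A", "C", "G", "U")
        for i, p in enumerate(codes):
            for j, n in enumerate(nts):
                refs.append(
                    make_pair_complex(
                        prot_atoms=[("CA", (0, 0, 0)), ("CB", (1, 0, 0))],
                        rna_atoms=[("P", (4, 0, 2)), ("N1", (4, 0, 0))],
                        prot_code=p,
                        rna_code=n,
                    )
                )
        table = estimate_pair_params(refs)
        vals = [table[(p, n)] for p in codes for n in nts]
        # P(a,b|contact) = 1/16 and P(a)P(b) = 1/16: log-odds ~ 0
        np.testing.assert_allclose(vals, 0.0, atol=1e-4)


class TestTotal:
    def test_zero_weights_zero_total(self, small_complex):
        params = LowResParams(weights=(0.0, 0.0, 0.0, 0.0))
        params.env_logprob = estimate_env_params([small_complex], params)
        params.pair_logodds = estimate_pair_params([small_complex], params)
        s = score_lowres(reduce(small_complex), params)
        assert s.total == 0.0

    def test_total_is_weighted_sum_of_term_oracles(self, small_complex):
        params = LowResParams(weights=(1.0, 2.0, 0.5, 1.5))
        params.env_logprob = estimate_env_params([small_complex], params)
        params.pair_logodds = estimate_pair_params([small_complex], params)
        model = reduce(small_complex)
        s = score_lowres(model, params)
        expect = (
            1.0 * (-score_contact(model, params.contact_cutoff))
            + 2.0 * score_bump(model, params.clash_distance)
            + 0.5 * score_env(model, params)
            + 1.5 * score_pair(model, params)
        )
        assert s.total == pytest.approx(expect, rel=1e-12)

    def test_more_contacts_lower_total(self):
        # same env/pair/bump contributions forced to zero weight: adding a
        # contact must strictly decrease the total
        params = LowResParams(weights=(1.0, 0.0, 0.0, 0.0))
        params.env_logprob = {t: {e: 0.0 for e in ENV_CLASSES} for t in ALL_TYPES}
        params.pair_logodds = {(p, n): 0.0 for p in ALL_TYPES[:20] for n in ("A", "C", "G", "U")}
        near = score_lowres(reduce(_single_unit_complex(5.0)), params)
        far = score_lowres(reduce(_single_unit_complex(7.0)), params)
        assert near.total < far.total

    def test_rigid_invariance(self, small_complex, random_rotation):
        params = LowResParams()
        params.env_logprob = estimate_env_params([small_complex], params)
        params.pair_logodds = estimate_pair_params([small_complex], params)
        R, t = random_rotation
        moved = rigid_transform_complex(small_complex, R, t)
        s1 = score_lowres(reduce(small_complex), params)
        s2 = score_lowres(reduce(moved), params)
        assert s1.contact == s2.contact
        assert s1.total == pytest.approx(s2.total, abs=1e-8)


def test_params_roundtrip(tmp_path, small_complex):
    params = LowResParams(clash_distance=2.5, weights=(1.0, 0.5, 1.0, 2.0))
    params.env_logprob = estimate_env_params([small_complex], params)
    params.pair_logodds = estimate_pair_params([small_complex], params)
    path = tmp_path / "params.tsv"
    save_params(params, path)
    loaded = load_params(path)
    loaded.validate_tables()
    assert loaded.clash_distance == 2.5
    assert loaded.weights == params.weights
    assert loaded.env_logprob == params.env_logprob
    assert loaded.pair_logodds == params.pair_logodds
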