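"""All-atom scoring terms against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from rnadock.atomtypes import assign_type, load_atom_types
from rnadock.highres import (
    COULOMB_K,
    TERM_KEYS,
    HighResConfig,
    HighResScorer,
    WeightVector,
    load_weights,
    save_weights,
)
from rnadock.lowres import estimate_pair_params
from rnadock.pose import Pose

from conftest import make_pair_complex, rigid_transform_complex

TYPES = load_atom_types()


def _pair_at(distance, prot_atom="CA", rna_atom="N1", rna_code="U"):
    return make_pair_complex(
        prot_atoms=[(prot_atom, (0.0, 0.0, 0.0))],
        rna_atoms=[(rna_atom, (distance, 0.0, 0.0))],
        rna_code=rna_code,
    )


class TestLennardJones:
    def test_minimum_closed_form(self):
        t1 = TYPES[assign_type("protein-residue", "ALA", "CA", "C")]
        t2 = TYPES[assign_type("rna-nucleotide", "U", "N1", "N")]
        rmin = t1.lj_radius + t2.lj_radius
        eps = math.sqrt(t1.lj_welldepth * t2.lj_welldepth)
        atr, rep = HighResScorer(_pair_at(rmin)).lj(None)
        assert atr == pytest.approx(-eps, rel=1e-12)
        assert rep == 0.0

    def test_beyond_cutoff_is_zero(self):
        atr, rep = HighResScorer(_pair_at(6.5)).lj(None)
        assert atr == 0.0 and rep == 0.0

    def test_signs(self, small_complex):
        atr, rep = HighResScorer(small_complex).lj(None)
        assert atr <= 0.0
        assert rep >= 0.0

    def test_against_bruteforce_double_loop(self, small_complex):
        cfg = HighResConfig()
        scorer = HighResScorer(small_complex)
        atr, rep = scorer.lj(None)
        e_atr = e_rep = 0.0
        for pu in small_complex.protein:
            for pa in pu.heavy_atoms:
                tp = TYPES[assign_type(pu.kind, pu.code, pa.name, pa.element)]
                for ru in small_complex.rna:
                    for ra in ru.heavy_atoms:
                        tr = TYPES[assign_type(ru.kind, ru.code, ra.name, ra.element)]
                        d = float(np.linalg.norm(pa.coords - ra.coords))
                        if d >= cfg.lj_cutoff:
                            continue
                        rmin = tp.lj_radius + tr.lj_radius
                        eps = math.sqrt(tp.lj_welldepth * tr.lj_welldepth)
                        d0 = cfg.rep_linearize_frac * rmin
                        dd = max(d, d0)
                        x6 = (rmin / dd) ** 6
                        e = eps * (x6 * x6 - 2 * x6)
                        if d < d0:
                            slope = eps * 12.0 * (-(rmin**12) / d0**13 + rmin**6 / d0**7)
                            e += (-slope) * (d0 - d)
                        if e <= 0:
                            e_atr += e
                        else:
                            e_rep += e
        assert atr == pytest.approx(e_atr, abs=1e-9)
        assert rep == pytest.approx(e_rep, abs=1e-9)


class TestElectrostatics:
    def test_unit_charges_closed_form(self):
        scorer = HighResScorer(_pair_at(2.0))
        scorer.prot.charge[:] = 1.0
        scorer.rna.charge[:] = -1.0
        # distance-dependent dielectric eps(d) = d: E = k q1 q2 / d^2
        assert scorer.elec(None) == pytest.approx(COULOMB_K * (-1.0) / 4.0, rel=1e-12)
        assert scorer.elec(None) == pytest.approx(-83.016, abs=1e-3)

    def test_neutral_pair_is_zero(self):
        scorer = HighResScorer(_pair_at(2.0))
        scorer.prot.charge[:] = 0.0
        assert scorer.elec(None) == 0.0

    def test_short_distance_clamped(self):
        s1 = HighResScorer(_pair_at(1.0))
        s2 = HighResScorer(_pair_at(1.45))
        assert s1.elec(None) == pytest.approx(s2.elec(None), rel=1e-12)

    def test_against_bruteforce_sum(self, small_complex):
        cfg = HighResConfig()
        got = HighResScorer(small_complex).elec(None)
        expect = 0.0
        for pu in small_complex.protein:
            for pa in pu.heavy_atoms:
                qp = TYPES[assign_type(pu.kind, pu.code, pa.name, pa.element)].charge
                for ru in small_complex.rna:
                    for ra in ru.heavy_atoms:
                        qr = TYPES[assign_type(ru.kind, ru.code, ra.name, ra.element)].charge
                        d = float(np.linalg.norm(pa.coords - ra.coords))
                        if d < cfg.elec_cutoff:
                            deff = max(d, cfg.elec_min_dist)
                            expect += COULOMB_K * qp * qr / deff**2
        assert got == pytest.approx(expect, abs=1e-9)


class TestSolvation:
    def test_single_pair_closed_form(self):
        d = 3.0
        cx = _pair_at(d)
        ti = TYPES[assign_type("protein-residue", "ALA", "CA", "C")]
        tj = TYPES[assign_type("rna-nucleotide", "U", "N1", "N")]
        pref = 2.0 * math.pi**1.5
        xi = (d - ti.lj_radius) / ti.lk_lambda
        xj = (d - tj.lj_radius) / tj.lk_lambda
        expect = (
            -ti.lk_dgfree / (pref * ti.lk_lambda * d**2) * math.exp(-xi**2) * tj.lk_volume
            + -tj.lk_dgfree / (pref * tj.lk_lambda * d**2) * math.exp(-xj**2) * ti.lk_volume
        )
        assert HighResScorer(cx).solv(None) == pytest.approx(expect, rel=1e-12)

    def test_beyond_cutoff_is_zero(self):
        assert HighResScorer(_pair_at(6.1)).solv(None) == 0.0

    def test_against_bruteforce_sum(self, small_complex):
        cfg = HighResConfig()
        got = HighResScorer(small_complex).solv(None)
        pref = 2.0 * math.pi**1.5
        expect = 0.0
        for pu in small_complex.protein:
            for pa in pu.heavy_atoms:
                ti = TYPES[assign_type(pu.kind, pu.code, pa.name, pa.element)]
                for ru in small_complex.rna:
                    for ra in ru.heavy_atoms:
                        tj = TYPES[assign_type(ru.kind, ru.code, ra.name, ra.element)]
                        d = float(np.linalg.norm(pa.coords - ra.coords))
                        if d >= cfg.solv_cutoff:
                            continue
                        xi = (d - ti.lj_radius) / ti.lk_lambda
                        xj = (d - tj.lj_radius) / tj.lk_lambda
                        expect += (
                            -ti.lk_dgfree / (pref * ti.lk_lambda * d**2)
                            * math.exp(-(xi**2)) * tj.lk_volume
                        )
                        expect += (
                            -tj.lk_dgfree / (pref * tj.lk_lambda * d**2)
                            * math.exp(-(xj**2)) * ti.lk_volume
                        )
        assert got == pytest.approx(expect, abs=1e-9)


class TestHydrogenBond:
    def test_backbone_pair_at_optimum(self):
        # protein backbone N (donor, no H present -> angular factor 1.0)
        # vs RNA phosphate OP1 (backbone acceptor) at r0
        cx = make_pair_complex(
            prot_atoms=[("N", (0, 0, 0))],
            rna_atoms=[("OP1", (2.9, 0, 0))],
        )
        lr_bb, sr_bb, lr_sc, sr_sc = HighResScorer(cx).hbond(None)
        assert lr_bb == pytest.approx(-2.0, rel=1e-12)
        assert (sr_bb, lr_sc, sr_sc) == (0.0, 0.0, 0.0)

    def test_sidechain_binning(self):
        # base carbonyl O2 of uracil is a side-chain acceptor
        cx = make_pair_complex(
            prot_atoms=[("N", (0, 0, 0))],
            rna_atoms=[("O2", (2.9, 0, 0))],
        )
        lr_bb, _, lr_sc, _ = HighResScorer(cx).hbond(None)
        assert lr_bb == 0.0
        assert lr_sc == pytest.approx(-2.0, rel=1e-12)

    def test_outside_window_is_zero(self):
        cx = make_pair_complex(
            prot_atoms=[("N", (0, 0, 0))],
            rna_atoms=[("OP1", (4.0, 0, 0))],
        )
        assert HighResScorer(cx).hbond(None) == (0.0, 0.0, 0.0, 0.0)

    def test_angular_factor_with_explicit_hydrogen(self):
        # linear D-H...A: full strength; bent geometry: cos^2 attenuation
        for angle_deg in (180.0, 140.0):
            a = math.radians(angle_deg)
            h = np.array([0.98, 0.0, 0.0])
            # acceptor placed so that the D-H...A angle at H equals angle_deg
            direction = np.array([-math.cos(a), math.sin(a), 0.0])
            acc = h + 2.0 * direction
            d_da = float(np.linalg.norm(acc))
            cx = make_pair_complex(
                prot_atoms=[("N", (0, 0, 0)), ("H", tuple(h))],
                rna_atoms=[("OP1", tuple(acc))],
            )
            lr_bb, _, _, _ = HighResScorer(cx).hbond(None)
            r0, ehb = 2.9, 2.0
            radial = ehb * (5 * (r0 / d_da) ** 12 - 6 * (r0 / d_da) ** 10)
            expect = radial * math.cos(a) ** 2
            assert lr_bb == pytest.approx(expect, rel=1e-9), angle_deg

    def test_multi_bond_enumeration(self):
        # two backbone bonds and one side-chain bond, summed per bin
        cx = make_pair_complex(
            prot_atoms=[("N", (0, 0, 0)), ("O", (0, 8, 0))],
            rna_atoms=[("OP1", (2.9, 0, 0)), ("OP2", (-3.1, 0, 0)), ("N3", (0, 8, 3.0))],
        )
        lr_bb, _, lr_sc, _ = HighResScorer(cx).hbond(None)
        r0, ehb = 2.9, 2.0

        def e(d):
            return ehb * (5 * (r0 / d) ** 12 - 6 * (r0 / d) ** 10)

        # N->OP1 at 2.9 and N->OP2 at 3.1 are backbone-backbone; the protein
        # O is an acceptor, not a donor, and N3 of uracil is a donor whose
        # acceptor partner O (backbone, protein) sits 3.0 A away
        assert lr_bb == pytest.approx(e(2.9) + e(3.1), rel=1e-9)
        assert lr_sc == pytest.approx(e(3.0), rel=1e-9)


class TestPairAtomic:
    def test_single_contact_is_one_lookup(self, small_complex):
        table = {(p, n): 1.0 for p in ["ALA"] for n in ["U"]}
        cx = make_pair_complex(
            prot_atoms=[("CA", (0, 0, 0))],
            rna_atoms=[("N1", (4.0, 0, 0))],
        )
        assert HighResScorer(cx, pair_table=table).pair(None) == pytest.approx(1.0)

    def test_no_contact_is_zero(self):
        table = {("ALA", "U"): 5.0}
        cx = _pair_at(8.0)
        assert HighResScorer(cx, pair_table=table).pair(None) == 0.0

    def test_against_enumeration_oracle(self, small_complex):
        table = estimate_pair_params([small_complex])
        got = HighResScorer(small_complex, pair_table=table).pair(None)
        cfg = HighResConfig()
        expect = 0.0
        for pu in small_complex.protein:
            for ru in small_complex.rna:
                dmin = min(
                    float(np.linalg.norm(pa.coords - ra.coords))
                    for pa in pu.heavy_atoms
                    for ra in ru.heavy_atoms
                )
                if dmin < cfg.pair_cutoff:
                    expect += table[(pu.code, ru.code)]
        assert got == pytest.approx(expect, rel=1e-12)


class TestCombined:
    def test_zero_weights_zero_total(self, small_complex):
        b = HighResScorer(small_complex).score(None, WeightVector.zeros())
        assert b.total == 0.0

    def test_total_is_weighted_sum_and_linear(self, small_complex):
        scorer = HighResScorer(small_complex, pair_table=estimate_pair_params([small_complex]))
        terms = scorer.terms(None)
        w = WeightVector.from_dict({k: 0.5 for k in TERM_KEYS})
        b = scorer.score(None, w)
        assert b.total == pytest.approx(sum(0.5 * terms[k] for k in TERM_KEYS), rel=1e-12)
        # doubling one weight moves the total by exactly that term
        w2 = WeightVector.from_dict({**w.as_dict(), "fa_atr": 1.0})
        b2 = scorer.score(None, w2)
        assert b2.total - b.total == pytest.approx(0.5 * terms["fa_atr"], rel=1e-9)

    def test_fa_dun_is_zero(self, small_complex):
        assert HighResScorer(small_complex).terms(None)["fa_dun"] == 0.0

    def test_total_vanishes_at_infinite_separation(self, small_complex):
        scorer = HighResScorer(small_complex, pair_table=estimate_pair_params([small_complex]))
        far = Pose(translation=(500.0, 0.0, 0.0))
        b = scorer.score(far, WeightVector.ones())
        assert b.total == 0.0

    def test_rigid_invariance_of_terms(self, small_complex, random_rotation):
        R, t = random_rotation
        moved = rigid_transform_complex(small_complex, R, t)
        t1 = HighResScorer(small_complex).terms(None)
        t2 = HighResScorer(moved).terms(None)
        for k in TERM_KEYS:
            assert t1[k] == pytest.approx(t2[k], abs=1e-8), k


class TestWeightVector:
    def test_box_enforced(self):
        with pytest.raises(ValueError):
            WeightVector(tuple([1.5] + [0.0] * 9))
        with pytest.raises(ValueError):
            WeightVector(tuple([-0.1] + [0.0] * 9))

    def test_roundtrip_file(self, tmp_path):
        w = WeightVector.from_dict({"fa_atr": 0.25, "hbond_lr_sc": 1.0})
        save_weights(w, tmp_path / "w.tsv", intercept=0.5)
        w2, b = load_weights(tmp_path / "w.tsv")
        assert w2 == w
        assert b == 0.5
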