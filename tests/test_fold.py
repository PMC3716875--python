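"""Folding engine vs exhaustive structure enumeration."""

from __future__ import annotations

import math

import numpy as np
import pytest

import conftest  # noqa: F401  (sys.path setup for oracles)
from oracles import boltzmann, enumerate_structures

from structscan.fold import (
    EnergyModel,
    InsideTables,
    constrained_fold,
    local_partition_fold,
    read_bpp,
    structure_probability,
    write_bpp,
)
from structscan.model import ParseError, parse_dotbracket


def random_seq(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, size=n))


class TestReadBpp:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "x.bpp"
        p.write_text("# comment\n1\t9\t0.8\n2\t8\t0.8\n3\t7\t0.8\n")
        bpp = read_bpp(p)
        assert len(bpp) == 3
        assert bpp.max_span == 8
        out = tmp_path / "y.bpp"
        write_bpp(out, bpp)
        bpp2 = read_bpp(out)
        assert bpp2.entries == bpp.entries

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bpp"
        p.write_text("")
        assert len(read_bpp(p)) == 0

    def test_rejects_bad_probability(self, tmp_path):
        p = tmp_path / "b.bpp"
        p.write_text("1\t5\t1.2\n")
        with pytest.raises(ParseError, match=":1:"):
            read_bpp(p)

    def test_rejects_duplicates(self, tmp_path):
        p = tmp_path / "d.bpp"
        p.write_text("1\t5\t0.5\n1\t5\t0.4\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_bpp(p)


class TestPartitionFunction:
    def test_inside_matches_enumeration(self):
        model = EnergyModel()
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(8, 15))
            seq = random_seq(rng, n)
            ins = InsideTables(seq, model, span=n, dmax=n - 1)
            z_oracle, _, _, _, _ = boltzmann(seq, model.pair_energy,
                                             rt=model.rt)
            assert float(ins.zval(0, n - 1)) == pytest.approx(z_oracle,
                                                              rel=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_pair_probs_match_enumeration(self, seed):
        model = EnergyModel()
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 15))
        seq = random_seq(rng, n)
        bpp = local_partition_fold(seq, window=n, span=n, model=model,
                                   floor=0.0)
        _, probs, _, _, _ = boltzmann(seq, model.pair_energy, rt=model.rt)
        for pair, p in probs.items():
            assert bpp.get(*pair) == pytest.approx(p, abs=1e-9)
        for pair in bpp.pairs():
            assert pair in probs

    def test_windowed_probs_average_single_window_case(self):
        model = EnergyModel()
        seq = "GGGGAAAACCCC"
        bpp = local_partition_fold(seq, window=len(seq), span=len(seq),
                                   model=model)
        _, probs, _, _, _ = boltzmann(seq, model.pair_energy)
        for pair in [(1, 12), (2, 11), (3, 10), (4, 9)]:
            assert bpp.get(*pair) == pytest.approx(probs[pair], abs=1e-9)

    def test_no_canonical_pairs_empty(self):
        bpp = local_partition_fold("AAAAAAA", window=7, span=7)
        assert len(bpp) == 0

    def test_substochastic(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 30)
        bpp = local_partition_fold(seq, window=30, span=30)
        bpp.validate_substochastic()

    def test_lonely_pairs_excluded_from_support(self):
        model = EnergyModel(no_lonely_pairs=True)
        rng = np.random.default_rng(13)
        for _ in range(10):
            seq = random_seq(rng, 12)
            sts = enumerate_structures(seq, model.pair_energy,
                                       no_lonely_pairs=True)
            support = {p for st in sts for p in st}
            bpp = local_partition_fold(seq, window=12, span=12, model=model)
            for pair in bpp.pairs():
                assert pair in support

    def test_windowed_vs_plain_model(self):
        # probabilities in (0,1], spans respected, under both grammars
        rng = np.random.default_rng(21)
        seq = random_seq(rng, 60)
        for nolp in (True, False):
            model = EnergyModel(no_lonely_pairs=nolp)
            bpp = local_partition_fold(seq, window=30, span=15, model=model)
            for (i, j), p in bpp.entries.items():
                assert 0 < p <= 1
                assert j - i <= 15

    def test_short_sequence_empty(self):
        assert len(local_partition_fold("ACG", window=10, span=5)) == 0

    def test_fast_kernel_matches_reference_windows(self):
        # jitted float64 windows vs the extended-precision reference path
        from structscan import _kernels
        from structscan.fold import InsideTables, _window_pair_probs

        if not _kernels.HAS_NUMBA:
            pytest.skip("numba unavailable")
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 120)
        for nolp, init in ((True, 0.0), (True, 2.0), (False, 0.0)):
            model = EnergyModel(no_lonely_pairs=nolp, helix_init=init)
            W, span = 40, 25
            import math as _m
            from structscan.fold import _codes, _weight_matrix
            Z, H, G = _kernels.inside_diag(
                _codes(seq), _weight_matrix(model),
                _m.exp(-init / model.rt), model.min_loop, span, W - 1, nolp)
            ins = InsideTables(seq, model, span=span, dmax=W - 1)
            for s in (0, 17, 80):
                Pf = _kernels.outside_window(
                    Z, H, G, _codes(seq), _weight_matrix(model),
                    _m.exp(-init / model.rt), s, W, model.min_loop, span, nolp)
                Pr = _window_pair_probs(ins, s, W)
                assert np.allclose(Pf, Pr.astype(float), atol=1e-12)

    def test_inside_log_monotone_on_appended_unpairable(self):
        model = EnergyModel()
        seq = "GGGAAACCC"
        z = []
        for extra in range(4):
            s = seq + "A" * extra
            ins = InsideTables(s, model, span=len(s), dmax=len(s) - 1)
            z.append(float(ins.zval(0, len(s) - 1)))
        assert all(b >= a for a, b in zip(z, z[1:]))


class TestStructureProbability:
    def test_two_state_closed_form(self):
        # GGGGAAAACCCC constrained to one helix vs open chain is not 2-state;
        # use a sequence with exactly one legal stack
        model = EnergyModel()
        seq = "GCAAAGC"
        sts = enumerate_structures(seq, model.pair_energy)
        z, probs, _, _, _ = boltzmann(seq, model.pair_energy)
        for st in sts:
            if st:
                db = ["."] * len(seq)
                for (i, j) in st:
                    db[i - 1], db[j - 1] = "(", ")"
                p = structure_probability(seq, "".join(db), model)
                e = sum(model.pair_energy[seq[i - 1] + seq[j - 1]]
                        for (i, j) in st)
                assert p == pytest.approx(math.exp(-e) / z, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_probabilities_normalize(self, seed):
        model = EnergyModel()
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 15))
        seq = random_seq(rng, n)
        sts = enumerate_structures(seq, model.pair_energy)
        total = 0.0
        for st in sts:
            db = ["."] * n
            for (i, j) in st:
                db[i - 1], db[j - 1] = "(", ")"
            total += structure_probability(seq, "".join(db), model)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_noncanonical_structure_probability_zero(self):
        assert structure_probability("AAAAAAAA", "((....))") == 0.0

    def test_example_hairpin(self):
        model = EnergyModel()
        seq = "GGGAAACCC"
        _, probs, _, _, _ = boltzmann(seq, model.pair_energy)
        p = structure_probability(seq, "(((...)))", model)
        # direct enumeration of the same structure's weight
        z, _, _, _, sts = boltzmann(seq, model.pair_energy)
        e = model.pair_energy["GC"] * 3
        assert p == pytest.approx(math.exp(-e) / z, rel=1e-10)


class TestConstrainedFold:
    def test_mfe_matches_enumeration(self):
        model = EnergyModel()
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(8, 15))
            seq = random_seq(rng, n)
            _, _, best_e, _, _ = boltzmann(seq, model.pair_energy)
            st = constrained_fold(seq, None, model)
            pairs = parse_dotbracket(st)
            e = sum(model.pair_energy[seq[i - 1] + seq[j - 1]]
                    for (i, j) in pairs)
            assert e == pytest.approx(best_e)

    def test_forced_hairpin(self):
        model = EnergyModel()
        seq = "GGGAAACCCAAA"
        constraint = "(((...)))..."
        st = constrained_fold(seq, constraint, model)
        assert st.startswith("(((...)))")

    def test_forced_unpaired_respected(self):
        model = EnergyModel()
        seq = "GGGAAACCC"
        st = constrained_fold(seq, "." * 9, model)
        assert st == "." * 9

    def test_infeasible_constraint_errors(self):
        with pytest.raises(ParseError, match="non-canonical"):
            constrained_fold("GAAAAAAAG", "(.......)", EnergyModel())

    def test_unconstrained_positions_free(self):
        model = EnergyModel()
        seq = "GGGAAACCC"
        st = constrained_fold(seq, "?" * 9, model)
        assert st == constrained_fold(seq, None, model)
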