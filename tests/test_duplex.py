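import numpy as np
import pytest

import mirsite.pair_features as pf
from conftest import aligned_complement, random_rna
from oracles import brute_force_optimal_weight
from mirsite.duplex import (backtrack, duplex_dg37_pairs, fill_tables,
                            parse_duplex_rendering, predict_duplex,
                            render_duplex)
from mirsite.pair_features import pad_sequence
from mirsite.preference import ScoreDict

PAD = "-"


def toy_sd(rules):
    """ScoreDict holding only the given single-pair rules (i, j, type): w."""
    w = np.zeros(pf.N_FEATURES)
    for (i, j, t), val in rules.items():
        w[pf.single_index(i, j, pf._TYPE_INDEX[t])] = val
    return ScoreDict(w)


def random_sd(rng, scale=1.0):
    return ScoreDict(rng.normal(scale=scale, size=pf.N_FEATURES))


class TestFillTables:
    def test_no_canonical_pairs_gives_zero_tables(self, turner, uniform_sd):
        t = fill_tables("A" * 25, "A" * 25, uniform_sd, turner)
        assert np.all(t.S1 == 0)
        assert backtrack(t).pairs == []

    def test_single_rule_hand_trace(self, turner):
        sd = toy_sd({(1, 1, "AU"): 0.2})
        t = fill_tables(pad_sequence("AA"), pad_sequence("AU"), sd, turner)
        assert t.S1[24, 24] == pytest.approx(0.2)
        assert backtrack(t).pairs == [(1, 1, "AU")]

    def test_zero_borders_and_monotone(self, turner, uniform_sd):
        rng = np.random.default_rng(0)
        mic, cts = random_rna(rng, 25), random_rna(rng, 25)
        t = fill_tables(mic, cts, uniform_sd, turner)
        assert np.all(t.S1[0, :] == 0) and np.all(t.S1[:, 0] == 0)
        assert np.all(np.diff(t.S1, axis=0) >= 0)
        assert np.all(np.diff(t.S1, axis=1) >= 0)

    def test_malformed_sequence_rejected(self, turner, uniform_sd):
        with pytest.raises(ValueError):
            fill_tables("A" * 24, "U" * 25, uniform_sd, turner)


class TestOracleAgreement:
    def test_dp_matches_brute_force_on_small_instances(self, turner):
        rng = np.random.default_rng(2024)
        for trial in range(50):
            n = int(rng.integers(2, 9))
            mic = pad_sequence(random_rna(rng, n))
            cts = pad_sequence(random_rna(rng, n))
            sd = random_sd(rng)
            t = fill_tables(mic, cts, sd, turner, compute_mfe=False)
            structure = backtrack(t)
            opt = brute_force_optimal_weight(mic, cts, sd.lookup)
            assert structure.total_weight == pytest.approx(opt, abs=1e-9), \
                f"trial {trial}: DP {structure.total_weight} vs oracle {opt}"

    def test_backtracked_weight_recomputes_from_runs(self, turner):
        # total_weight equals the sum of run scores of the chosen structure
        rng = np.random.default_rng(77)
        for _ in range(20):
            mic = pad_sequence(random_rna(rng, int(rng.integers(5, 26))))
            cts = pad_sequence(random_rna(rng, int(rng.integers(5, 26))))
            sd = random_sd(rng)
            t = fill_tables(mic, cts, sd, turner, compute_mfe=False)
            structure = backtrack(t)
            total = 0.0
            run = []
            for pair in structure.pairs + [None]:
                if run and (pair is None or pair[0] != run[-1][0] + 1
                            or pair[1] != run[-1][1] + 1):
                    # the DP may split a maximal run; its score must still be
                    # reachable, so compare against the best partition
                    m = len(run)
                    best = [0.0] * (m + 1)
                    for end in range(1, m + 1):
                        best[end] = max(
                            best[end - k] + sd.lookup(
                                run[end - 1][0], run[end - 1][1],
                                tuple(x[2] for x in run[end - k:end]))
                            for k in (1, 2, 3) if end - k >= 0)
                    total += best[m]
                    run = []
                if pair is not None:
                    run.append(pair)
            assert structure.total_weight == pytest.approx(total, abs=1e-9)


class TestStructureInvariants:
    def test_position_zero_never_pairs(self, turner, uniform_sd):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mic = random_rna(rng, 25)
            cts = random_rna(rng, 25)
            structure = predict_duplex(mic, cts, uniform_sd, turner)
            assert all(r >= 1 and c >= 1 for r, c, _ in structure.pairs)

    def test_pairs_strictly_increasing(self, turner, uniform_sd):
        rng = np.random.default_rng(6)
        for _ in range(20):
            structure = predict_duplex(random_rna(rng, 25), random_rna(rng, 25),
                                       uniform_sd, turner)
            rs = [r for r, _, _ in structure.pairs]
            cs = [c for _, c, _ in structure.pairs]
            assert rs == sorted(set(rs)) and cs == sorted(set(cs))

    def test_full_complement_pairs_everything_but_position_zero(
            self, turner, uniform_sd):
        mic = pad_sequence("ACGUACGU")
        cts = pad_sequence(aligned_complement("ACGUACGU"))
        structure = predict_duplex(mic, cts, uniform_sd, turner)
        assert [(r, c) for r, c, _ in structure.pairs] == \
            [(k, k) for k in range(1, 8)]

    def test_all_pad_input(self, turner, uniform_sd):
        structure = predict_duplex(PAD * 25, PAD * 25, uniform_sd, turner)
        assert structure.pairs == [] and structure.dg37 == 0.0

    def test_diag_k_pointer_contributes_k_pairs(self, turner):
        # a triple run recorded by one diag-3 pointer yields exactly the
        # three trailing aligned pairs
        w = np.zeros(pf.N_FEATURES)
        t = pf._TYPE_INDEX
        w[pf.triple_index(1, 0, t["CG"], t["CG"], t["CG"])] = 5.0
        sd = ScoreDict(w)
        mic = pad_sequence("ACCC")
        cts = pad_sequence("AGGG")
        structure = predict_duplex(mic, cts, sd, turner)
        assert structure.pairs == [(1, 1, "CG"), (2, 2, "CG"), (3, 3, "CG")]
        assert structure.total_weight == pytest.approx(5.0)


class TestFreeEnergy:
    def test_empty_structure_is_zero(self, turner):
        assert duplex_dg37_pairs([], "A" * 25, "A" * 25, turner) == 0.0

    def test_two_stacked_gc_pairs(self, turner):
        # initiation + one GC/GC stack; no weak ends
        mic = pad_sequence("AGG")
        cts = pad_sequence("ACC")
        pairs = [(1, 1, "GC"), (2, 2, "GC")]
        expected = 4.09 + turner.stack("GC", "GC")
        assert duplex_dg37_pairs(pairs, mic, cts, turner) == \
            pytest.approx(expected)

    def test_au_terminal_pairs_add_two_penalties(self, turner):
        # helix AU-UA: both termini are weak pairs
        mic = pad_sequence("AAU")
        cts = pad_sequence("AUA")
        pairs = [(1, 1, "AU"), (2, 2, "UA")]
        expected = 4.09 + turner.stack("AU", "UA") + 2 * 0.45
        assert duplex_dg37_pairs(pairs, mic, cts, turner) == \
            pytest.approx(expected)

    def test_bulge_and_internal_loops(self, turner):
        # GC pair, 2-nt bulge on the microRNA strand, GC pair,
        # then a 1+1 internal loop before a final GC pair
        mic = pad_sequence("AGAAGAG")
        cts = pad_sequence("ACCAC")
        pairs = [(1, 1, "GC"), (4, 2, "GC"), (6, 4, "GC")]
        expected = (4.09 + turner.loop("bulge", 2)
                    + turner.loop("internal", 2))
        assert duplex_dg37_pairs(pairs, mic, cts, turner) == \
            pytest.approx(expected)

    def test_inconsistent_pair_type_rejected(self, turner):
        with pytest.raises(ValueError, match="inconsistent"):
            duplex_dg37_pairs([(1, 1, "GC")], pad_sequence("AA"),
                              pad_sequence("AU"), turner)

    def test_mfe_table_consistent_with_backtrack(self, turner):
        # MFE1[i, j] re-derives from the substructure backtracked at (i, j)
        from mirsite.duplex import _trace_pairs

        rng = np.random.default_rng(9)
        mic, cts = random_rna(rng, 25), random_rna(rng, 25)
        sd = random_sd(rng)
        t = fill_tables(mic, cts, sd, turner)
        cells = {(int(rng.integers(1, 25)), int(rng.integers(1, 25)))
                 for _ in range(40)}
        for i, j in list(cells)[:20]:
            pairs = _trace_pairs(t, i, j)
            assert t.MFE1[i, j] == pytest.approx(
                duplex_dg37_pairs(pairs, mic, cts, turner))

    def test_pad_suffix_content_is_inert(self, turner, uniform_sd):
        mic_core, cts_core = "ACGUACG", "UGCAUGC"
        a = predict_duplex(pad_sequence(mic_core), pad_sequence(cts_core),
                           uniform_sd, turner)
        b = predict_duplex(pad_sequence(mic_core + ""),
                           pad_sequence(cts_core), uniform_sd, turner)
        assert a.pairs == b.pairs and a.dg37 == b.dg37


class TestRendering:
    @pytest.mark.parametrize("core_mic,core_cts", [
        ("ACGUACGU", "UGCAUGCA"),
        ("GGGGG", "CCCCC"),
        ("AAAA", "GGGG"),
    ])
    def test_render_parse_round_trip(self, turner, uniform_sd,
                                     core_mic, core_cts):
        mic, cts = pad_sequence(core_mic), pad_sequence(core_cts)
        structure = predict_duplex(mic, cts, uniform_sd, turner)
        text = render_duplex(structure, mic, cts)
        back = parse_duplex_rendering(text)
        assert back.pairs == structure.pairs
        assert back.total_weight == structure.total_weight
        assert back.dg37 == structure.dg37
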