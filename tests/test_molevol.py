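"""Distances and NG86 dN/dS against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from pangloss import synthetic as syn
from pangloss.io_core import CodonPair
from pangloss.molevol import (
    DistanceResult,
    gamma_distance,
    mean_ortholog_similarity,
    ng86_counts,
    ng86_dnds,
    p_distance,
    poisson_distance,
    selection_class,
)

# -- independent NG86 oracle -------------------------------------------------

_CODE = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, repeat=3)):
    _CODE[_a + _b + _c] = _AAS[_i]


def oracle_sites(codon):
    """Fractional synonymous sites, straight from the definition."""
    s = 0.0
    for pos in range(3):
        syn_n = tot = 0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if _CODE[mut] == "*":
                continue
            tot += 1
            if _CODE[mut] == _CODE[codon]:
                syn_n += 1
        s += syn_n / tot if tot else 0.0
    return 3.0 - s, s  # (N, S)


def oracle_diffs(ca, cb):
    """Average Nd/Sd over all shortest stop-free substitution pathways."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(pos):
        cur, nd, sd, ok = ca, 0, 0, True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if _CODE[nxt] == "*" and nxt != cb:
                ok = False
                break
            if _CODE[nxt] == _CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((nd, sd))
    if not paths:  # all pathways cross stops; admit them
        for order in itertools.permutations(pos):
            cur, nd, sd = ca, 0, 0
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                if _CODE[nxt] == _CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((nd, sd))
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def oracle_ng86(pair: CodonPair):
    N = S = Nd = Sd = 0.0
    for ca, cb in pair.codons():
        na, sa = oracle_sites(ca)
        nb, sb = oracle_sites(cb)
        N += (na + nb) / 2
        S += (sa + sb) / 2
        nd, sd = oracle_diffs(ca, cb)
        Nd += nd
        Sd += sd
    return N, S, Nd, Sd


# -- distance tests ----------------------------------------------------------

class TestDistances:
    def test_identical_sequences_zero(self):
        res = p_distance("MKVLT" * 20, "MKVLT" * 20)
        assert res.p == res.d_poisson == res.d_gamma == 0.0

    def test_ten_percent_mismatches(self):
        a = "A" * 100
        b = "A" * 90 + "K" * 10
        assert p_distance(a, b).p == pytest.approx(0.10)

    def test_gap_and_x_sites_removed(self):
        rng = np.random.default_rng(61)
        for _ in range(50):
            n = int(rng.integers(20, 80))
            a = rng.choice(list("ACDEF-X"), size=n)
            b = rng.choice(list("ACDEF-X"), size=n)
            keep = [
                i for i in range(n)
                if a[i] not in "-X" and b[i] not in "-X"
            ]
            if not keep:
                with pytest.raises(ValueError):
                    p_distance("".join(a), "".join(b))
                continue
            expected = sum(a[i] != b[i] for i in keep) / len(keep)
            res = p_distance("".join(a), "".join(b))
            assert res.p == pytest.approx(expected)
            assert res.n_sites == len(keep)

    def test_correction_ordering_on_grid(self):
        for p in np.arange(0.01, 0.71, 0.05):
            d_p = poisson_distance(p)
            d_g = gamma_distance(p, alpha=4)
            assert d_g >= d_p >= p

    def test_gamma_decreasing_in_alpha_and_poisson_limit(self):
        p = 0.3
        assert gamma_distance(p, 2) > gamma_distance(p, 8) > gamma_distance(p, 100)
        assert abs(gamma_distance(p, 1e6) - poisson_distance(p)) < 1e-4

    def test_monotone_in_p(self):
        grid = np.arange(0.01, 0.71, 0.01)
        dp = [poisson_distance(p) for p in grid]
        dg = [gamma_distance(p) for p in grid]
        assert all(x < y for x, y in zip(dp, dp[1:]))
        assert all(x < y for x, y in zip(dg, dg[1:]))

    def test_p_out_of_range_rejected(self):
        for fn in (poisson_distance, gamma_distance):
            with pytest.raises(ValueError):
                fn(1.0)


class TestSimilarityMatrix:
    def test_identical_proteomes_all_hundred(self, default_config):
        from pangloss.io_core import Proteome
        from pangloss.io_core import ClusterTable

        seqs = {"p1": "MKVLT" * 10, "p2": "AWYQG" * 10}
        prots = {t: Proteome(t, dict(seqs)) for t in ("A", "B")}
        table = ClusterTable.from_members(
            {"c1": [("A", "p1"), ("B", "p1")], "c2": [("A", "p2"), ("B", "p2")]}
        )
        m = mean_ortholog_similarity(prots, table, ["c1", "c2"])
        assert m.loc["A", "B"] == 100.0
        assert m.loc["A", "A"] == 100.0

    def test_decreases_with_divergence(self):
        vals = []
        for scale in (0.0, 0.0005, 0.002):
            cfg = syn.default_config(seed=2)
            cfg.divergence_scale = scale
            table, truth = syn.simulate_family_evolution(cfg)
            prots = syn.emit_proteomes(table, truth, cfg)
            core = sorted(truth.clusters_in_category("core"))
            m = mean_ortholog_similarity(prots, table, core)
            vals.append(m.loc["SL1", "OG1"])
        assert vals[0] == 100.0
        assert vals[0] > vals[1] > vals[2]


class TestNG86:
    def test_identical_sequences(self):
        pair = CodonPair("ATGGCTAAA", "ATGGCTAAA")
        res = ng86_dnds(pair)
        assert res.dN == res.dS == 0.0
        assert res.omega is None

    def test_forced_synonymous_change(self):
        _, _, nd, sd = ng86_counts(CodonPair("TTT", "TTC"))  # Phe -> Phe
        assert sd == 1.0 and nd == 0.0

    def test_forced_nonsynonymous_change(self):
        _, _, nd, sd = ng86_counts(CodonPair("AAA", "GAA"))  # Lys -> Glu
        assert nd == 1.0 and sd == 0.0

    def test_sites_sum_to_three_per_codon(self):
        rng = np.random.default_rng(71)
        for _ in range(30):
            codons = [syn.SENSE_CODONS[i] for i in rng.integers(61, size=20)]
            pair = CodonPair("".join(codons), "".join(codons))
            res = ng86_dnds(pair)
            assert res.N + res.S == pytest.approx(60.0)

    def test_symmetry(self):
        rng = np.random.default_rng(73)
        for seed in range(20):
            pair = syn.simulate_codon_pair(1.0, 0.3, length=90, seed=seed)
            a = ng86_dnds(pair)
            b = ng86_dnds(CodonPair(pair.seq_b, pair.seq_a))
            assert a.Nd == pytest.approx(b.Nd, abs=1e-12)
            assert a.Sd == pytest.approx(b.Sd, abs=1e-12)

    def test_matches_pathway_enumeration_oracle(self):
        for seed in range(100):
            pair = syn.simulate_codon_pair(
                omega=0.5 if seed % 2 else 1.5, t=0.4, length=90, seed=seed
            )
            res = ng86_dnds(pair)
            N, S, Nd, Sd = oracle_ng86(pair)
            assert res.N == pytest.approx(N, abs=1e-9)
            assert res.S == pytest.approx(S, abs=1e-9)
            assert res.Nd == pytest.approx(Nd, abs=1e-9)
            assert res.Sd == pytest.approx(Sd, abs=1e-9)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            ng86_dnds(CodonPair("TAAAAA", "TACAAA"))


class TestSelectionClass:
    @pytest.mark.parametrize(
        "omega,expected",
        [(0.2, "purifying"), (1.0, "neutral"), (0.95, "neutral"),
         (1.3, "diversifying"), (None, "undefined")],
    )
    def test_thresholds(self, omega, expected):
        assert selection_class(omega) == expected

    def test_recovery_of_generating_regime(self):
        hits = {"purifying": 0, "neutral": 0}
        n_rep = 20
        for rep in range(n_rep):
            res = ng86_dnds(
                syn.simulate_codon_pair(0.1, 0.3, length=3000, seed=1000 + rep)
            )
            if selection_class(res.omega) == "purifying":
                hits["purifying"] += 1
            res = ng86_dnds(
                syn.simulate_codon_pair(1.0, 0.3, length=30_000, seed=2000 + rep)
            )
            if selection_class(res.omega) == "neutral":
                hits["neutral"] += 1
        assert hits["purifying"] >= int(0.95 * n_rep)
        assert hits["neutral"] >= int(0.95 * n_rep)
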