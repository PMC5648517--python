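"""Seed-site scanning, duplex energies and composite target scoring."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirlink import targeting as tg

LET7A = "UGAGGUAGUAGGUUGUAUAGUU"

_COMP = str.maketrans("ACGU", "UGCA")


def oracle_scan(mirna: str, utr: str):
    """Independent windowed scanner used as the ground-truth oracle.

    Patterns are rebuilt with str.translate; each start position is tested
    against all four site classes most-specific-first; matches nested inside
    a longer, more specific overlapping match are dropped.
    """
    seed6 = mirna[1:7].translate(_COMP)[::-1]
    seed7 = mirna[1:8].translate(_COMP)[::-1]
    pats = [("8mer", seed7 + "A"), ("7mer-m8", seed7),
            ("7mer-A1", seed6 + "A"), ("6mer", seed6)]
    rank = {"8mer": 3, "7mer-m8": 2, "7mer-A1": 1, "6mer": 0}
    hits = []
    for pos in range(len(utr)):
        for name, pat in pats:
            if utr[pos:pos + len(pat)] == pat:
                hits.append((pos, name, pat))
                break
    out = []
    for pos, name, pat in hits:
        nested = False
        for pos2, name2, pat2 in hits:
            if (pos2, name2) == (pos, name):
                continue
            if rank[name2] > rank[name] and pos2 <= pos and \
                    pos + len(pat) <= pos2 + len(pat2):
                nested = True
        if not nested:
            out.append((pos, name, pat))
    return out


class TestFindSeedSites:
    def test_let7_8mer_site(self):
        sites = tg.find_seed_sites(LET7A, "AAACUACCUCAAAA")
        assert len(sites) == 1
        assert sites[0].site_type == "8mer"
        assert sites[0].site_sequence == "CUACCUCA"
        assert sites[0].utr_position == 3

    def test_no_complement_gives_empty_list(self):
        assert tg.find_seed_sites(LET7A, "GGGGGGGGGGGG") == []

    def test_site_sequence_matches_utr_substring(self):
        utr = "CCCUACCUCCCCUACCUCACC"
        for s in tg.find_seed_sites(LET7A, utr):
            assert utr[s.utr_position:s.utr_position + len(s.site_sequence)] \
                == s.site_sequence

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            tg.find_seed_sites(LET7A, "ACGT")

    def test_agreement_with_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGU"))
        for _ in range(300):
            mirna = "".join(rng.choice(bases, size=22))
            # AU-rich UTR with the seed complement salted in to force matches
            utr = "".join(rng.choice(bases, size=120,
                                     p=[0.3, 0.2, 0.2, 0.3]))
            core = mirna[1:7].translate(_COMP)[::-1]
            pos = int(rng.integers(0, 100))
            utr = utr[:pos] + core + utr[pos + len(core):]
            got = [(s.utr_position, s.site_type, s.site_sequence)
                   for s in tg.find_seed_sites(mirna, utr)]
            assert got == oracle_scan(mirna, utr)


class TestDuplexDeltaG:
    def test_single_pair_has_no_stack(self):
        assert tg.duplex_delta_g("G", "C") == 0.0

    def test_two_stacked_gc_pairs_match_table(self):
        # top 5'-GG-3' over bottom 3'-CC-5' (site read 5'->3' is CC)
        assert tg.duplex_delta_g("GG", "CC") == tg.NN_STACKS["GG/CC"]

    def test_hand_summed_lookup(self):
        # miRNA 5'-GAC-3' / site 5'-GUC-3': pairs G:C, A:U, C:G; the second
        # stack AC/UG is stored in the table as its rotation GU/CA
        manual = tg.NN_STACKS["GA/CU"] + tg.NN_STACKS["GU/CA"]
        assert tg.duplex_delta_g("GAC", "GUC") == pytest.approx(manual)

    def test_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tg.duplex_delta_g("GG", "CA")

    def test_gc_substitution_never_weakens_duplex(self):
        """Replacing any A:U pair by G:C in a 6-pair duplex lowers (or keeps)
        the stacking free energy, for every AU/GC composition."""
        for combo in itertools.product("AG", repeat=6):
            mir = "".join(combo)
            site = mir.translate(_COMP)[::-1]
            dg = tg.duplex_delta_g(mir, site)
            for i, b in enumerate(combo):
                if b == "A":
                    harder = mir[:i] + "G" + mir[i + 1:]
                    hsite = harder.translate(_COMP)[::-1]
                    assert tg.duplex_delta_g(harder, hsite) <= dg + 1e-12


class TestAUFlank:
    def _site(self, pos):
        return tg.SeedSite(pos, "6mer", "GGGGGG")

    def test_all_au_flanks(self):
        utr = "A" * 10 + "GGGGGG" + "U" * 10
        assert tg.au_flank_content(utr, self._site(10)) == 1.0

    def test_all_gc_flanks(self):
        utr = "C" * 10 + "GGGGGG" + "G" * 10
        assert tg.au_flank_content(utr, self._site(10)) == 0.0

    def test_site_at_utr_start_counts_existing_flank_only(self):
        utr = "GGGGGG" + "AU"       # no left flank, 2 nt right flank
        assert tg.au_flank_content(utr, self._site(0)) == 1.0


class TestPOver:
    def test_zero_observed_is_one(self):
        assert tg.p_over("ACGU" * 10, "ACGUACG", 0) == 1.0

    def test_short_utr_has_no_positions(self):
        assert tg.p_over("ACG", "ACGUACG", 1) == 0.0

    def test_uniform_seven_mer_closed_form(self):
        utr = "A" * 106
        uniform = {b: 0.25 for b in "ACGU"}
        got = tg.p_over(utr, "AAAAAAA", 1, base_freqs=uniform)
        expected = 1.0 - (1.0 - 0.25**7) ** 100
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(6.08e-3, rel=0.01)

    def test_exact_for_single_base_patterns_by_enumeration(self):
        """For 1-nt patterns occurrences are independent per position, so the
        binomial tail must match exhaustive alphabet-weighted enumeration."""
        freqs = {"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3}
        L = 6
        for k in (1, 2, 4):
            total = 0.0
            for seq in itertools.product("ACGU", repeat=L):
                w = math.prod(freqs[b] for b in seq)
                if sum(1 for b in seq if b == "A") >= k:
                    total += w
            got = tg.p_over("X" * L, "A", k, base_freqs=freqs)
            assert got == pytest.approx(total, abs=1e-12)


class TestCompositeAndSelection:
    BOUNDS = {k: (0.0, 1.0) for k in tg.DEFAULT_WEIGHTS}

    @given(st.lists(st.floats(0, 1), min_size=4, max_size=4),
           st.integers(0, 3), st.floats(0.001, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_score_monotone_in_each_feature(self, vals, which, bump):
        names = list(tg.DEFAULT_WEIGHTS)
        feats = dict(zip(names, vals))
        base = tg.composite_score(feats, self.BOUNDS)
        feats[names[which]] = min(1.0, feats[names[which]] + bump)
        assert tg.composite_score(feats, self.BOUNDS) >= base - 1e-12

    def _scored(self, n, mirna="mir-1"):
        import pandas as pd
        return pd.DataFrame({
            "mirna_id": [mirna] * n,
            "transcript_id": [f"t{i}" for i in range(n)],
            "gene_id": [f"g{i}" for i in range(n)],
            "score": np.linspace(1, 0, n),
        })

    def test_fraction_20_of_10_keeps_2(self):
        assert len(tg.select_top_fraction(self._scored(10), 0.20)) == 2

    def test_fraction_one_keeps_all(self):
        assert len(tg.select_top_fraction(self._scored(7), 1.0)) == 7

    def test_ceil_rule(self):
        # ceil(0.2 * 11) = 3
        assert len(tg.select_top_fraction(self._scored(11), 0.20)) == 3

    def test_empty_input_empty_output(self):
        import pandas as pd
        empty = pd.DataFrame(columns=["mirna_id", "transcript_id",
                                      "gene_id", "score"])
        assert tg.select_top_fraction(empty, 0.2).empty

    def test_tie_break_is_lexicographic_by_gene(self):
        import pandas as pd
        df = pd.DataFrame({
            "mirna_id": ["m"] * 3,
            "transcript_id": ["t3", "t1", "t2"],
            "gene_id": ["g3", "g1", "g2"],
            "score": [1.0, 1.0, 1.0],
        })
        kept = tg.select_top_fraction(df, 1 / 3)
        assert kept["gene_id"].tolist() == ["g1"]


def test_planted_sites_recovered_with_requested_or_better_type():
    from mirlink import simdata as sd
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGU"))
    for st_type in tg.SITE_TYPES:
        mirna = "".join(rng.choice(bases, size=22))
        utr = "".join(rng.choice(bases, size=200))
        planted = sd.plant_seed_sites(utr, mirna, 2, st_type, rng_seed=1)
        found = tg.find_seed_sites(mirna, planted)
        rank = tg.SITE_RANK[st_type]
        assert sum(1 for s in found if tg.SITE_RANK[s.site_type] >= rank) >= 2
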