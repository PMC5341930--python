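"""Seed-site scanner: oracle equivalence, classification, mutagenesis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arscreen.seed_scan import (
    Amplicon,
    MatureMiRNA,
    SeedSite,
    TranscriptRegion,
    assign_amplicons,
    mutate_site,
    scan_sites,
    site_census,
)
from arscreen.synthetic_data import emit_sequences

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def brute_force_sites(mirna: MatureMiRNA, region: TranscriptRegion):
    """Independent sliding-window enumeration of canonical seed sites.

    Builds each site pattern base-by-base from pairing rules, tests every
    window, keeps the strongest type per locus and greedily suppresses
    overlapping weaker sites — the published site contract.
    """
    seq = region.sequence
    mir = mirna.sequence
    # pattern on the mRNA sense strand, 5'->3': partners of miRNA positions
    # k..2 in decreasing order, optionally preceded by p8's partner / followed by A
    core = "".join(_COMP[mir[i]] for i in range(6, 0, -1))  # partners of p7..p2
    p8 = _COMP[mir[7]]
    patterns = {
        "8mer": p8 + core + "A",
        "7mer-m8": p8 + core,
        "7mer-A1": core + "A",
        "6mer": core,
    }
    candidates = []
    for stype in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
        pat = patterns[stype]
        for i in range(len(seq) - len(pat) + 1):
            if seq[i : i + len(pat)] == pat:
                candidates.append((stype, i + 1, i + len(pat)))
    order = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2, "6mer": 3}
    kept = []
    for stype, s, e in sorted(candidates, key=lambda c: (order[c[0]], c[1])):
        if all(e < ks or s > ke for _, ks, ke in kept):
            kept.append((stype, s, e))
    return sorted((s, e, t) for t, s, e in kept)


def _as_tuples(sites):
    return sorted((s.start, s.end, s.site_type) for s in sites)


class TestScanSites:
    def test_8mer_example(self):
        # seed (positions 2-8) GUAAACA pairs mRNA TGTTTAC; trailing A = A1
        mirna = MatureMiRNA("let-like", "UGUAAACAUCCUCGACUGGAAG")
        region = TranscriptRegion("r", "CCCCCTGTTTACACCCCC")
        sites = scan_sites(mirna, region)
        assert _as_tuples(sites) == [(6, 13, "8mer")]
        assert sites[0].match_seq == "TGTTTACA"

    def test_6mer_when_no_extensions(self):
        mirna = MatureMiRNA("m", "UGUAAACAUCCUCGACUGGAAG")
        # bare core GTTTAC: preceding base != T (p8 partner), following != A
        region = TranscriptRegion("r", "GGGGGGTTTACGGGGG")
        sites = scan_sites(mirna, region)
        assert [(s.site_type, s.start, s.end) for s in sites] == [("6mer", 6, 11)]

    def test_no_match_and_empty(self):
        mirna = MatureMiRNA("m", "UGUAAACAUCCUCGACUGGAAG")
        assert scan_sites(mirna, TranscriptRegion("r", "CCCCCCCCCC")) == []

    def test_invalid_alphabet_named(self):
        with pytest.raises(ValueError, match="X"):
            MatureMiRNA("m", "UGUAAACAUCCUCGACUGGAXG")
        with pytest.raises(ValueError, match="N"):
            TranscriptRegion("r", "ACGTN")

    def test_distinct_7mer_types_plantable(self):
        mirnas, region, truth = emit_sequences(
            n_mirnas=1,
            utr_length=400,
            planted_sites=[(0, "7mer-m8", 50), (0, "7mer-A1", 200)],
            seed=5,
        )
        got = _as_tuples(scan_sites(mirnas[0], region))
        assert [t for _, _, t in got] == ["7mer-m8", "7mer-A1"]

    @pytest.mark.parametrize("case", range(10))
    def test_matches_brute_force_on_random_inputs(self, case):
        rng = np.random.default_rng(900 + case)
        mirna = MatureMiRNA(
            "m", "".join(rng.choice(list("ACGU"), size=int(rng.integers(18, 27))))
        )
        region = TranscriptRegion(
            "r", "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 2001))))
        )
        assert _as_tuples(scan_sites(mirna, region)) == brute_force_sites(mirna, region)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.data())
    def test_reported_sites_never_overlap(self, data):
        mir = data.draw(st.text(alphabet="ACGU", min_size=18, max_size=26))
        seq = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=400))
        sites = scan_sites(MatureMiRNA("m", mir), TranscriptRegion("r", seq))
        spans = sorted((s.start, s.end) for s in sites)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))


class TestAmplicons:
    AMPS = [Amplicon("AR1", 1, 500), Amplicon("AR2", 400, 900)]

    @pytest.mark.parametrize(
        "start,end,expected",
        [(100, 107, ["AR1"]), (450, 457, ["AR1", "AR2"]), (950, 957, [])],
    )
    def test_containment_assignment(self, start, end, expected):
        site = SeedSite("m", "r", "8mer", start, end, "ACGTACGT")
        (assigned,) = assign_amplicons([site], self.AMPS)
        assert assigned.amplicon_names == expected


class TestMutateSite:
    def _fixture(self, seed=0):
        mirnas, region, truth = emit_sequences(
            n_mirnas=2,
            utr_length=600,
            planted_sites=[(0, "8mer", 100), (1, "7mer-m8", 300)],
            seed=seed,
        )
        return mirnas, region, truth

    def test_mutation_removes_exactly_the_site(self):
        mirnas, region, truth = self._fixture()
        site = [s for s in truth if s.mirna_id == mirnas[0].id][0]
        mutated = mutate_site(region, site)
        assert scan_sites(mirnas[0], mutated) == []
        # the other miRNA's non-overlapping site is untouched
        other = scan_sites(mirnas[1], mutated)
        assert _as_tuples(other) == [(300, 306, "7mer-m8")]

    def test_stale_coordinates_rejected(self):
        mirnas, region, truth = self._fixture(seed=1)
        site = truth[0]
        mutated = mutate_site(region, site)
        with pytest.raises(ValueError, match="stale"):
            mutate_site(mutated, site)

    def test_only_three_bases_change(self):
        mirnas, region, truth = self._fixture(seed=2)
        site = truth[0]
        mutated = mutate_site(region, site)
        diffs = [
            i
            for i, (a, b) in enumerate(zip(region.sequence, mutated.sequence))
            if a != b
        ]
        assert len(diffs) == 3
        assert all(site.start - 1 <= i <= site.end - 1 for i in diffs)


class TestMirsvrFilter:
    def test_pass_through_threshold(self):
        from arscreen.seed_scan import filter_by_mirsvr

        sites = [
            SeedSite("m1", "r", "8mer", 10, 17, "ACGTACGT"),
            SeedSite("m2", "r", "6mer", 50, 55, "ACGTAC"),
            SeedSite("m3", "r", "6mer", 70, 75, "ACGTAC"),
        ]
        scores = {("m1", "r"): -0.9, ("m2", "r"): -0.1}
        kept = filter_by_mirsvr(sites, scores, threshold=-0.5)
        assert [s.mirna_id for s in kept] == ["m1"]  # m2 weak, m3 unscored


class TestCensus:
    def test_empty_inputs(self):
        assert len(site_census([], [])) == 0

    def test_counts_match_direct_recount(self):
        mirnas, region, truth = emit_sequences(
            n_mirnas=3,
            utr_length=800,
            planted_sites=[(0, "8mer", 50), (0, "6mer", 400), (2, "7mer-A1", 600)],
            seed=9,
        )
        amps = [Amplicon("AR1", 1, 450), Amplicon("AR2", 350, 800)]
        census = site_census(mirnas, [region], amps)
        # independent recount from scan output
        for m in mirnas:
            sites = assign_amplicons(scan_sites(m, region), amps)
            row = census.loc[m.id]
            assert row["n_utr3"] == len(sites)
            for stype in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
                assert row[stype] == sum(s.site_type == stype for s in sites)
            for a in amps:
                assert row[f"in_{a.name}"] == sum(
                    a.name in s.amplicon_names for s in sites
                )
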