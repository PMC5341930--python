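"""Canonical miRNA seed-site scanning, amplicon assignment and site ablation.

Canonical sites follow the TargetScan taxonomy.  A target site is an exact
Watson-Crick match, on the mRNA sense strand, to the reverse complement of the
miRNA seed (miRNA positions 2-7), optionally extended:

========  ==============================================================
6mer      match to miRNA positions 2-7 (6 nt)
7mer-m8   match to positions 2-8 (7 nt)
7mer-A1   match to positions 2-7 plus an ``A`` in the mRNA immediately
          3' of the match (opposite miRNA position 1), 7 nt
8mer      match to positions 2-8 plus the A1 adenine, 8 nt
========  ==============================================================

Each match locus is reported once with the strongest applicable type
(8mer > 7mer-m8 > 7mer-A1 > 6mer) and overlapping weaker sites of the same
miRNA are suppressed, so reported sites for one miRNA never overlap.
Coordinates are 1-based inclusive on the region's sense strand; BED export
(see :mod:`arscreen.io`) converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Seq import Seq

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_PRECEDENCE = {t: i for i, t in enumerate(SITE_TYPES)}
_RNA = set("ACGU")
_DNA = set("ACGT")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _check_alphabet(seq: str, alphabet: set, what: str) -> None:
    for ch in seq:
        if ch not in alphabet:
            raise ValueError(f"invalid {what} symbol {ch!r} in sequence")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: id plus 5'->3' RNA sequence, 18-26 nt."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _check_alphabet(self.sequence, _RNA, "RNA")
        if not 18 <= len(self.sequence) <= 26:
            raise ValueError(
                f"miRNA {self.id}: length {len(self.sequence)} outside 18-26 nt"
            )

    @property
    def seed(self) -> str:
        """Seed region, miRNA positions 2-8 (0-based slice 1:8)."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class TranscriptRegion:
    """A transcript region (3'UTR or CDS fragment), DNA sense strand 5'->3'."""

    id: str
    sequence: str
    role: str = "UTR3"
    offset: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _check_alphabet(self.sequence, _DNA, "DNA")
        if not self.sequence:
            raise ValueError(f"region {self.id}: empty sequence")
        if self.role not in ("UTR3", "CDS"):
            raise ValueError(f"region {self.id}: role must be UTR3 or CDS")


@dataclass(frozen=True)
class Amplicon:
    """A reporter amplicon interval within the UTR, 1-based inclusive."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"amplicon {self.name}: start must be < end")

    def contains(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end


@dataclass
class SeedSite:
    """A classified seed-match site on a transcript region.

    ``start``/``end`` are 1-based inclusive positions of the matched span on
    the region's sense strand; ``match_seq`` is the region substring at
    discovery time (used to detect stale coordinates before mutagenesis).
    """

    mirna_id: str
    region_id: str
    site_type: str
    start: int
    end: int
    match_seq: str
    amplicon_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = {"6mer": 6, "7mer-m8": 7, "7mer-A1": 7, "8mer": 8}[self.site_type]
        if self.end - self.start + 1 != expected:
            raise ValueError(
                f"{self.site_type} site span {self.start}-{self.end} is not "
                f"{expected} nt"
            )


def seed_match_core(mirna: MatureMiRNA) -> str:
    """DNA reverse complement of the seed 6mer (miRNA positions 2-7)."""
    rna_as_dna = mirna.sequence[1:7].replace("U", "T")
    return str(Seq(rna_as_dna).reverse_complement())


def scan_sites(mirna: MatureMiRNA, region: TranscriptRegion) -> list[SeedSite]:
    """Find all canonical seed sites of ``mirna`` in ``region``.

    Returns sites sorted by start position; loci are classified with the
    strongest applicable type and overlapping weaker sites are suppressed.
    """
    seq = region.sequence
    core = seed_match_core(mirna)
    # base on the mRNA that would pair miRNA position 8 (immediately 5' of core)
    p8_partner = mirna.sequence[7].replace("U", "T").translate(_DNA_COMPLEMENT)

    candidates: list[SeedSite] = []
    i = seq.find(core)
    while i != -1:
        has_m8 = i > 0 and seq[i - 1] == p8_partner
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, s, e = "8mer", i - 1, i + 6
        elif has_m8:
            site_type, s, e = "7mer-m8", i - 1, i + 5
        elif has_a1:
            site_type, s, e = "7mer-A1", i, i + 6
        else:
            site_type, s, e = "6mer", i, i + 5
        candidates.append(
            SeedSite(
                mirna_id=mirna.id,
                region_id=region.id,
                site_type=site_type,
                start=s + 1,
                end=e + 1,
                match_seq=seq[s : e + 1],
            )
        )
        i = seq.find(core, i + 1)

    # precedence-ordered overlap suppression (stronger type wins, then leftmost)
    kept: list[SeedSite] = []
    for site in sorted(candidates, key=lambda x: (_PRECEDENCE[x.site_type], x.start)):
        if all(site.end < k.start or site.start > k.end for k in kept):
            kept.append(site)
    kept.sort(key=lambda x: (x.start, x.mirna_id))
    return kept


def assign_amplicons(
    sites: list[SeedSite], amplicons: list[Amplicon]
) -> list[SeedSite]:
    """Fill ``amplicon_names`` with every amplicon fully containing the span."""
    out = []
    for site in sites:
        names = [a.name for a in amplicons if a.contains(site.start, site.end)]
        out.append(replace(site, amplicon_names=names))
    return out


def mutate_site(region: TranscriptRegion, site: SeedSite) -> TranscriptRegion:
    """Ablate a seed site by complementing bases within the seed match.

    The primary substitution complements the 3 span positions opposite miRNA
    positions 3-5, destroying the core seed match without touching flanking
    sequence, so non-overlapping sites of any miRNA are preserved.  For
    repetitive (e.g. AT-rich) seeds this substitution can accidentally
    recreate a shifted copy of the seed match; additional core positions are
    then complemented, one at a time, until no seed-core occurrence overlaps
    the original span.  Raises if the region content at the site span no
    longer equals ``match_seq`` (stale coordinates, e.g. already mutated).
    """
    seq = region.sequence
    s0, e0 = site.start - 1, site.end - 1  # 0-based inclusive span
    current = seq[s0 : e0 + 1]
    if current != site.match_seq:
        raise ValueError(
            f"stale site coordinates: region {region.id}[{site.start}-{site.end}] "
            f"is {current!r}, expected {site.match_seq!r}"
        )
    anchored = site.site_type in ("8mer", "7mer-m8")
    core = site.match_seq[1:7] if anchored else site.match_seq[0:6]
    # span offsets ordered: partners of miRNA p3-p5 first, then p6, p7, p2
    offs = (5, 4, 3, 2, 1, 6) if anchored else (4, 3, 2, 1, 0, 5)

    def survives(chars: list[str]) -> bool:
        # any core occurrence whose widest site span [j-1, j+6] overlaps
        # [s0, e0] would leave a site on the original locus
        lo, hi = max(0, s0 - 6), min(len(chars) - 6, e0 + 1)
        s = "".join(chars)
        return any(s[j : j + 6] == core for j in range(lo, hi + 1))

    chars = list(seq)
    for k, off in enumerate(offs):
        pos = s0 + off
        chars[pos] = chars[pos].translate(_DNA_COMPLEMENT)
        if k >= 2 and not survives(chars):
            return replace(region, sequence="".join(chars))
    raise RuntimeError(
        f"could not ablate {site.site_type} site at {site.start}-{site.end}"
    )


def filter_by_mirsvr(sites: list[SeedSite], scores, threshold: float = -0.5):
    """Pass-through filter on user-supplied mirSVR scores.

    ``scores`` maps (mirna_id, region_id) -> score from an external scoring
    tool; no score is computed here.  Sites whose pair has a score below
    ``threshold`` are kept; unscored sites are dropped.
    """
    return [
        s
        for s in sites
        if (s.mirna_id, s.region_id) in scores
        and scores[(s.mirna_id, s.region_id)] < threshold
    ]


def site_census(
    mirnas: list[MatureMiRNA],
    regions: list[TranscriptRegion],
    amplicons: list[Amplicon] | None = None,
):
    """Aggregate site counts per miRNA: by type, by region role, by amplicon.

    Returns a pandas DataFrame indexed by mirna_id with one column per site
    type, ``n_utr3``/``n_cds`` totals, and one ``in_<amplicon>`` column per
    amplicon (UTR sites fully contained in it).
    """
    import pandas as pd

    amplicons = amplicons or []
    rows = []
    for mirna in mirnas:
        counts = {t: 0 for t in SITE_TYPES}
        counts.update({"n_utr3": 0, "n_cds": 0})
        counts.update({f"in_{a.name}": 0 for a in amplicons})
        for region in regions:
            sites = scan_sites(mirna, region)
            if region.role == "UTR3":
                sites = assign_amplicons(sites, amplicons)
            for s in sites:
                counts[s.site_type] += 1
                counts["n_utr3" if region.role == "UTR3" else "n_cds"] += 1
                for name in s.amplicon_names:
                    counts[f"in_{name}"] += 1
        rows.append(pd.Series(counts, name=mirna.id))
    cols = list(SITE_TYPES) + ["n_utr3", "n_cds"] + [f"in_{a.name}" for a in amplicons]
    table = pd.DataFrame(rows, columns=cols).rename_axis("mirna_id")
    return table.astype(int) if len(table) else table
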