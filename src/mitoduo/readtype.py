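"""Read-based mitotype assignment via diagnostic k-mers.

Instead of short-read alignment, reads are typed against canonical k-mer
sets that are unique to one mitotype within declared diagnostic regions:
every k-mer found anywhere in the other mitotype's genome is subtracted,
so with error-free reads cross-mitotype assignment is structurally
impossible. Counts are normalized to matching reads per 100 bases of
region length, and a sample is called homoplasmic or heteroplasmic from
the per-mitotype read support.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, revcomp
from .scan import GroupAlignment, fixed_difference_columns, sliding_window_profile
from .synth import LineagePair, ReadSet

DEFAULT_K = 31
DEFAULT_MIN_HITS = 2


@dataclass(frozen=True)
class Region:
    mitotype: str  # genome the coordinates refer to
    name: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def canonical_kmers(seq: str, k: int) -> list[str]:
    """Strand-collapsed k-mers (lexicographic min of k-mer and its
    reverse complement); windows containing non-ACGT characters are skipped."""
    out = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if set(kmer) - set("ACGT"):
            continue
        rc = revcomp(kmer)
        out.append(kmer if kmer <= rc else rc)
    return out


def genome_kmer_set(genome: AnnotatedGenome, k: int) -> set[str]:
    seq = genome.sequence
    if genome.topology == "circular":
        seq = seq + seq[:k - 1]  # k-mers across the origin
    return set(canonical_kmers(seq, k))


@dataclass
class DiagnosticIndex:
    """Per-mitotype unique canonical k-mer sets over declared regions."""

    k: int
    regions: list[Region]
    kmer_map: dict[str, tuple[str, str]]  # kmer -> (mitotype, region name)

    def kmers(self, mitotype: str) -> set[str]:
        return {km for km, (m, _) in self.kmer_map.items() if m == mitotype}

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


def select_diagnostic_regions(pair: LineagePair, window: int = 300,
                              n_regions: int = 3, k: int = DEFAULT_K,
                              ) -> list[Region]:
    """Pick the densest fixed-difference windows as diagnostic regions.

    Windows are ranked by fixed-difference count over the pair alignment,
    greedily made non-overlapping, and projected onto each genome's own
    coordinates (one F and one M region per window, named dr1, dr2, ...).
    """
    aln = GroupAlignment.from_pair(pair)
    positions = fixed_difference_columns(aln)
    prof = sliding_window_profile(positions, aln.length, window=window, step=1)
    order = np.argsort(prof.counts, kind="stable")[::-1]
    chosen: list[int] = []
    for s in order:
        s = int(s)
        if prof.counts[s] == 0:
            break
        if all(abs(s - c) >= window for c in chosen):
            chosen.append(s)
        if len(chosen) == n_regions:
            break
    f_pos = np.cumsum([c != "-" for c in pair.aligned_f])  # F bases up to column
    m_pos = np.cumsum([c != "-" for c in pair.aligned_m])
    regions = []
    for i, s in enumerate(sorted(chosen), 1):
        c0, c1 = s, s + window
        for mito, cum in (("F", f_pos), ("M", m_pos)):
            start = int(cum[c0 - 1]) if c0 > 0 else 0
            end = int(cum[c1 - 1])
            if end - start >= k:
                regions.append(Region(mito, f"dr{i}", start, end))
    return regions


def build_diagnostic_index(pair: LineagePair, regions: list[Region] | None = None,
                           k: int = DEFAULT_K) -> DiagnosticIndex:
    """Index the type-specific k-mers of the diagnostic regions.

    Region k-mers are canonical; any k-mer present anywhere in the other
    mitotype's genome (circularly) is removed, which also guarantees the
    F and M sets are disjoint. A k-mer maps to exactly one region (first
    declaration wins).
    """
    if regions is None:
        regions = select_diagnostic_regions(pair, k=k)
    genomes = {"F": pair.genome_f, "M": pair.genome_m}
    other_kmers = {"F": genome_kmer_set(genomes["M"], k),
                   "M": genome_kmer_set(genomes["F"], k)}
    kmer_map: dict[str, tuple[str, str]] = {}
    for r in regions:
        g = genomes[r.mitotype]
        if r.length < k:
            raise ValueError(f"region {r.name}/{r.mitotype} shorter than k={k}")
        if not (0 <= r.start < r.end <= len(g)):
            raise ValueError(f"region {r.name} outside genome {r.mitotype}")
        for km in canonical_kmers(g.sequence[r.start:r.end], k):
            if km in other_kmers[r.mitotype] or km in kmer_map:
                continue
            kmer_map[km] = (r.mitotype, r.name)
    if not kmer_map:
        warnings.warn("diagnostic index is empty after cross-mitotype subtraction")
    return DiagnosticIndex(k, list(regions), kmer_map)


@dataclass
class ReadTypingResult:
    counts: pd.DataFrame          # region, mitotype, matching_reads, per_100_bases
    assignments: list[tuple[str, str, str]]  # (read id, mitotype, region)
    n_ambiguous: int
    n_skipped_short: int


def assign_reads(reads: ReadSet, index: DiagnosticIndex,
                 min_hits: int = DEFAULT_MIN_HITS) -> ReadTypingResult:
    """Type each read against the diagnostic index.

    A read matches a region when at least ``min_hits`` of its canonical
    k-mers belong to that region's set; reads matching regions of both
    mitotypes are discarded as ambiguous; reads shorter than k are
    skipped and tallied. Matching reads are credited to their best region
    and normalized per 100 bases of region length.
    """
    k = index.k
    region_hits: Counter = Counter()
    assignments = []
    n_ambiguous = 0
    n_short = 0
    for read in reads.reads:
        if len(read.sequence) < k:
            n_short += 1
            continue
        hits: Counter = Counter()
        for km in canonical_kmers(read.sequence, k):
            entry = index.kmer_map.get(km)
            if entry:
                hits[entry] += 1
        matched = {key: n for key, n in hits.items() if n >= min_hits}
        if not matched:
            continue
        mitos = {m for m, _ in matched}
        if len(mitos) > 1:
            n_ambiguous += 1
            continue
        best = max(matched, key=matched.get)
        region_hits[best] += 1
        assignments.append((read.id, best[0], best[1]))
    rows = []
    for r in index.regions:
        n = region_hits.get((r.mitotype, r.name), 0)
        rows.append((r.name, r.mitotype, r.length, n, n * 100.0 / r.length))
    counts = pd.DataFrame(rows, columns=["region", "mitotype", "region_length",
                                         "matching_reads", "per_100_bases"])
    return ReadTypingResult(counts, assignments, n_ambiguous, n_short)


def call_homoplasmy(counts: pd.DataFrame, min_reads: int = 5) -> str:
    """Sample-level call from per-region read support.

    Heteroplasmic when both mitotypes reach ``min_reads`` matching reads,
    homoplasmic toward the only mitotype reaching it, insufficient when
    neither does.
    """
    totals = counts.groupby("mitotype")["matching_reads"].sum()
    f_n = int(totals.get("F", 0))
    m_n = int(totals.get("M", 0))
    if f_n >= min_reads and m_n >= min_reads:
        return "heteroplasmic"
    if f_n >= min_reads:
        return "homoplasmic_F"
    if m_n >= min_reads:
        return "homoplasmic_M"
    return "insufficient"
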