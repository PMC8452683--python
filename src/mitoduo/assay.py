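"""In-silico multiplex PCR and size-based mitotype classification.

Primer sites are searched on both strands across the circular junction
with a mismatch budget and an exact 3'-clamp; amplicons are the shortest
forward->reverse spans under a maximum product size; samples are called
F / M / HET / FAIL from the band sizes alone, mirroring the two-locus
(cytb + 16S) agarose-gel assay used to screen adductor muscle.

Real assay primers are not published in the main text; synthetic primers
are designed deterministically against the generator's genomes: shared
primers flanking the 16S insertion (the two mitotypes then differ by
exactly the insertion length) and allele-specific cytb forwards anchored
3' on fixed differences at two distinct offsets from a shared reverse.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .genome import AnnotatedGenome, revcomp
from .scan import GroupAlignment, fixed_difference_columns
from .synth import LineagePair

DEFAULT_MAX_MISMATCH = 2
DEFAULT_CLAMP = 3
DEFAULT_MAX_PRODUCT = 2000
DEFAULT_TOLERANCE = 5


@dataclass(frozen=True)
class PrimerPair:
    name: str
    locus: str  # cytb, 16S, other
    forward: str  # 5'->3' on the + strand
    reverse: str  # 5'->3' on the - strand
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    three_prime_clamp: int = DEFAULT_CLAMP

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if not 15 <= len(p) <= 35:
                raise ValueError(f"primer length must be 15-35 nt, got {len(p)}")
            if set(p) - set("ACGT"):
                raise ValueError("primers must be plain ACGT")
        if self.three_prime_clamp > min(len(self.forward), len(self.reverse)):
            raise ValueError("clamp longer than primer")


@dataclass(frozen=True)
class PrimerSite:
    position: int  # 0-based + strand coordinate of the leftmost matched base
    strand: str
    mismatches: int


@dataclass
class AmpliconResult:
    genome_id: str
    locus: str
    start: int  # forward primer 5' end, + strand
    end: int    # one past the reverse primer 5' end (may exceed genome length before wrap)
    length: int
    sequence: str
    ambiguous: bool = False


def _mismatch_scan(seq: str, probe: str, circular: bool) -> np.ndarray:
    """Mismatch count of ``probe`` at every offset of ``seq`` (wrapping)."""
    m = len(probe)
    ext = seq + (seq[: m - 1] if circular and len(seq) > 1 else "")
    if len(ext) < m:
        return np.zeros((0, m), dtype=bool)
    arr = np.frombuffer(ext.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, m)
    probe_arr = np.frombuffer(probe.encode(), dtype=np.uint8)
    return win != probe_arr  # boolean mismatch matrix, rows = offsets


def find_primer_sites(genome: AnnotatedGenome, primer: str,
                      max_mismatch: int = DEFAULT_MAX_MISMATCH,
                      clamp: int = DEFAULT_CLAMP) -> list[PrimerSite]:
    """All annealing sites of ``primer`` on either strand.

    A site qualifies when total mismatches <= ``max_mismatch`` and the
    3'-terminal ``clamp`` bases match exactly. On the + strand the 3' end
    is the rightmost matched base; on the - strand it is the leftmost.
    Positions are reported modulo the genome length (circular scan).
    """
    n = len(genome)
    circular = genome.topology == "circular"
    sites = []
    for strand, probe in (("+", primer), ("-", revcomp(primer))):
        mm = _mismatch_scan(genome.sequence, probe, circular)
        if mm.size == 0:
            continue
        total = mm.sum(axis=1)
        clamp_cols = mm[:, -clamp:] if strand == "+" else mm[:, :clamp]
        ok = (total <= max_mismatch) & ~clamp_cols.any(axis=1)
        for off in np.nonzero(ok)[0]:
            pos = int(off) % n
            if int(off) >= n:  # duplicate of a wrapped hit
                continue
            sites.append(PrimerSite(pos, strand, int(total[off])))
    return sites


def amplify(genome: AnnotatedGenome, pair: PrimerPair,
            max_product: int = DEFAULT_MAX_PRODUCT) -> list[AmpliconResult]:
    """Products of a primer pair on a (circular) genome.

    The amplicon spans from the forward primer's 5' end to the reverse
    primer's 5' end inclusive (gel-size convention). Products longer than
    ``max_product`` are suppressed. Multiple viable products are all
    returned and flagged ambiguous. Both template orientations are
    examined, so primer roles may be swapped relative to the + strand.
    """
    n = len(genome)
    fwd_len, rev_len = len(pair.forward), len(pair.reverse)
    products: list[AmpliconResult] = []
    seen: set[tuple[int, int]] = set()

    def orient(fwd_sites: Iterable[PrimerSite], rev_sites: Iterable[PrimerSite],
               f_len: int, r_len: int) -> None:
        for fs in fwd_sites:
            for rs in rev_sites:
                f5 = fs.position
                r5 = rs.position + r_len - 1  # reverse primer 5' end on + strand
                span = (r5 - f5) % n + 1
                if span < max(f_len, r_len) or span > max_product:
                    continue
                key = (f5, span)
                if key in seen:
                    continue
                seen.add(key)
                products.append(AmpliconResult(
                    genome.id, pair.locus, f5, f5 + span, span,
                    genome.fetch(f5, f5 + span)))

    f_sites = find_primer_sites(genome, pair.forward, pair.max_mismatch,
                                pair.three_prime_clamp)
    r_sites = find_primer_sites(genome, pair.reverse, pair.max_mismatch,
                                pair.three_prime_clamp)
    orient([s for s in f_sites if s.strand == "+"],
           [s for s in r_sites if s.strand == "-"], fwd_len, rev_len)
    orient([s for s in r_sites if s.strand == "+"],
           [s for s in f_sites if s.strand == "-"], rev_len, fwd_len)
    if len(products) > 1:
        for p in products:
            p.ambiguous = True
    return products


# ---------------------------------------------------------------------------
# Size-based classification
# ---------------------------------------------------------------------------

@dataclass
class MultiplexAssay:
    """Expected band sizes per locus per mitotype, with a size tolerance."""

    expected: dict[str, dict[str, int]]  # locus -> {"F": bp, "M": bp}
    tolerance: int = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        for locus, sizes in self.expected.items():
            if set(sizes) != {"F", "M"}:
                raise ValueError(f"locus {locus}: need F and M expected sizes")
            if abs(sizes["F"] - sizes["M"]) <= 2 * self.tolerance:
                raise ValueError(
                    f"locus {locus}: F/M size windows overlap at tolerance "
                    f"{self.tolerance} ({sizes['F']} vs {sizes['M']})")

    def band_mitotype(self, locus: str, size: int) -> str | None:
        sizes = self.expected.get(locus)
        if sizes is None:
            return None
        for mito, s in sizes.items():
            if abs(size - s) <= self.tolerance:
                return mito
        return None


@dataclass
class MultiplexCall:
    sample_id: str
    bands: list[tuple[str, int]]  # (locus, size bp)
    call: str  # F, M, HET, FAIL


def classify_multiplex(bands: list[tuple[str, int]], assay: MultiplexAssay,
                       sample_id: str = "") -> MultiplexCall:
    """Call the mitotype from gel band sizes alone.

    F when only female-size bands are interpretable (at >= 1 locus), M
    when only male-size bands, HET when both mitotypes' band sets appear
    (the assay detects both genomes whatever their ratio), FAIL when no
    band is interpretable.
    """
    evidence = {"F": False, "M": False}
    for locus, size in bands:
        mito = assay.band_mitotype(locus, int(size))
        if mito:
            evidence[mito] = True
    if evidence["F"] and evidence["M"]:
        call = "HET"
    elif evidence["F"]:
        call = "F"
    elif evidence["M"]:
        call = "M"
    else:
        call = "FAIL"
    return MultiplexCall(sample_id, list(bands), call)


def genotype_sample(genomes: list[AnnotatedGenome], primer_pairs: list[PrimerPair],
                    assay: MultiplexAssay, sample_id: str = "",
                    max_product: int = DEFAULT_MAX_PRODUCT) -> MultiplexCall:
    """Amplify every genome present in a sample and classify the bands."""
    bands = []
    for g in genomes:
        for pp in primer_pairs:
            for amp in amplify(g, pp, max_product=max_product):
                bands.append((pp.locus, amp.length))
    return classify_multiplex(sorted(set(bands)), assay, sample_id)


# ---------------------------------------------------------------------------
# Deterministic primer design against a synthetic pair
# ---------------------------------------------------------------------------

def _identical_runs(pair: LineagePair) -> np.ndarray:
    """Boolean per F-genome position: identical in both genomes (no gap)."""
    a = np.frombuffer(pair.aligned_f.encode(), dtype=np.uint8)
    b = np.frombuffer(pair.aligned_m.encode(), dtype=np.uint8)
    not_gap = a != ord("-")
    same = (a == b) & not_gap & (b != ord("-"))
    return same[not_gap]  # projected onto F coordinates


def _find_identical_window(same: np.ndarray, lo: int, hi: int, width: int,
                           from_right: bool = False) -> int | None:
    """Leftmost (or rightmost) start in [lo, hi) of a width-long identical run."""
    starts = range(hi - width, lo - 1, -1) if from_right else range(lo, hi - width + 1)
    for s in starts:
        if s < 0:
            continue
        if same[s:s + width].all():
            return s
    return None


def _f_to_m_coord(pair: LineagePair, f_pos: int) -> int:
    """Map an F-genome position to the M genome via the true alignment."""
    aln_f = pair.aligned_f
    col = -1
    count = -1
    for i, c in enumerate(aln_f):
        if c != "-":
            count += 1
            if count == f_pos:
                col = i
                break
    return sum(1 for c in pair.aligned_m[:col] if c != "-")


def design_multiplex_assay(pair: LineagePair, primer_length: int = 22,
                           tolerance: int = DEFAULT_TOLERANCE,
                           ) -> tuple[list[PrimerPair], MultiplexAssay]:
    """Design the two-locus multiplex against a synthetic lineage pair.

    16S: shared primers in conserved flanks of the insertion; the M
    product is longer than the F product by exactly the insertion length.
    cytb: two allele-specific forward primers whose 3' base sits on a
    fixed difference (clamp rejects the other mitotype), at different
    distances from a shared reverse primer, so F and M bands differ in
    size. Raises if the pair offers no suitable sites.
    """
    same = _identical_runs(pair)
    gf = pair.genome_f

    # --- 16S: conserved primers spanning the insertion ---
    ins = [e for e in pair.event_log if e[0] == "ins" and e[4] == "16S"]
    if not ins:
        raise ValueError("pair has no 16S insertion; cannot design the size assay")
    q = ins[0][1]  # F coordinate of the insertion point
    up = _find_identical_window(same, max(0, q - 400), q - 10, primer_length,
                                from_right=True)
    down = _find_identical_window(same, q + 10, min(len(gf), q + 400), primer_length)
    if up is None or down is None:
        raise ValueError("no conserved windows flanking the 16S insertion")
    fwd_16s = gf.sequence[up:up + primer_length]
    rev_16s = revcomp(gf.sequence[down:down + primer_length])
    pair_16s = PrimerPair("syn16S", "16S", fwd_16s, rev_16s)
    size_f_16s = down + primer_length - up
    size_m_16s = size_f_16s + ins[0][2]

    # --- cytb: allele-specific forwards at two offsets + shared reverse ---
    cytb = gf.feature("cytb")
    subs = sorted(e[1] for e in pair.event_log
                  if e[0] == "sub" and cytb.start <= e[1] < cytb.end)
    diffs = [s for s in subs if s - primer_length + 1 >= cytb.start]
    min_sep = 2 * tolerance + 30
    chosen = None
    for s1 in diffs:
        for s2 in diffs:
            if s2 < s1 + min_sep:
                continue
            rev_start = _find_identical_window(
                same, s2 + 10, min(len(gf), s1 + DEFAULT_MAX_PRODUCT - primer_length),
                primer_length)
            if rev_start is None:
                continue
            chosen = (s1, s2, rev_start)
            break
        if chosen:
            break
    if chosen is None:
        raise ValueError("no usable fixed differences in cytb for allele-specific primers")
    s1, s2, rev_start = chosen
    fwd_f = gf.sequence[s1 - primer_length + 1:s1 + 1]
    m2 = _f_to_m_coord(pair, s2)
    fwd_m = pair.genome_m.sequence[m2 - primer_length + 1:m2 + 1]
    rev_cytb = revcomp(gf.sequence[rev_start:rev_start + primer_length])
    pair_f = PrimerPair("syncytbF", "cytb", fwd_f, rev_cytb)
    pair_m = PrimerPair("syncytbM", "cytb", fwd_m, rev_cytb)

    # expected sizes measured by actually amplifying (no manual arithmetic)
    def single_len(genome: AnnotatedGenome, pp: PrimerPair) -> int:
        prods = amplify(genome, pp)
        if len(prods) != 1:
            raise ValueError(f"primer pair {pp.name} yields {len(prods)} products on {genome.id}")
        return prods[0].length

    size_f_cytb = single_len(pair.genome_f, pair_f)
    size_m_cytb = single_len(pair.genome_m, pair_m)
    if amplify(pair.genome_m, pair_f) or amplify(pair.genome_f, pair_m):
        raise ValueError("allele-specific cytb primer cross-amplifies")
    assert single_len(pair.genome_f, pair_16s) == size_f_16s
    assert single_len(pair.genome_m, pair_16s) == size_m_16s

    assay = MultiplexAssay(
        expected={"cytb": {"F": size_f_cytb, "M": size_m_cytb},
                  "16S": {"F": size_f_16s, "M": size_m_16s}},
        tolerance=tolerance)
    return [pair_16s, pair_f, pair_m], assay
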