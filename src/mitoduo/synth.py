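"""Synthetic data generators for the mitotype pipeline.

Everything the downstream modules consume is generated here: an annotated
female-type (F) reference mitogenome, a diverged male-type (M) lineage with
the two diagnostic structural events (a 127-bp insertion in 16S rRNA and a
10-residue cox1 3' extension), sequencing reads from homoplasmic or
heteroplasmic mixtures, qPCR plates with standard curves, per-individual
enzyme activities, and population screening tables.

Substitutions are placed site-wise at rate = baseline x class multiplier
(hotspot / conserved / baseline per feature), with the baseline solved in
closed form so the expected genome-wide p-distance equals the configured
target. Reading frames are protected: start/stop codons are never touched
and substitutions that would create an internal stop are redrawn.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _iterproduct

import numpy as np
import pandas as pd

from .config import SynthConfig
from .genome import AnnotatedGenome, Feature, BASES, STOP_CODONS, revcomp

# independent RNG streams per generator, all derived from the config seed
_STREAM_REF, _STREAM_DIV, _STREAM_READS, _STREAM_QPCR, _STREAM_PHENO, _STREAM_SCREEN = range(6)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


_NONSTOP_CODONS = tuple(
    "".join(c) for c in _iterproduct(BASES, repeat=3) if "".join(c) not in STOP_CODONS
)

# ---------------------------------------------------------------------------
# Reference genome layout
# ---------------------------------------------------------------------------

_CDS_LENGTHS = {
    "cox1": 1536, "cox2": 690, "cox3": 780, "cytb": 1140, "atp6": 711,
    "nad1": 927, "nad2": 981, "nad3": 354, "nad4": 1338, "nad4L": 297,
    "nad5": 1719, "nad6": 498,
}
_TRNA_LENGTH = 66
_SPACER = 2  # intergenic bases between adjacent features

_HOTSPOTS = {"atp6", "cytb", "cox3", "nad4", "nad4L", "nad6", "16S",
             "tRNA-Ile", "tRNA-Cys", "NCR1", "NCR2"}
_CONSERVED = {"12S", "cox2", "nad3", "nad5"}  # plus all tRNAs except Ile/Cys

# gene order: one plausible venerid-like arrangement, all "+" strand
_FEATURE_ORDER = [
    ("cox1", "CDS"), ("tRNA-Leu1", "tRNA"), ("NCR1", "NCR"), ("cox2", "CDS"),
    ("tRNA-Asp", "tRNA"), ("atp6", "CDS"), ("tRNA-Lys", "tRNA"),
    ("tRNA-Ile", "tRNA"), ("nad2", "CDS"), ("tRNA-Met", "tRNA"),
    ("tRNA-Val", "tRNA"), ("12S", "rRNA"), ("tRNA-Phe", "tRNA"),
    ("nad4", "CDS"), ("tRNA-His", "tRNA"), ("nad4L", "CDS"),
    ("tRNA-Ser1", "tRNA"), ("cytb", "CDS"), ("tRNA-Trp", "tRNA"),
    ("nad6", "CDS"), ("tRNA-Pro", "tRNA"), ("nad1", "CDS"),
    ("tRNA-Leu2", "tRNA"), ("16S", "rRNA"), ("tRNA-Cys", "tRNA"),
    ("nad3", "CDS"), ("tRNA-Gly", "tRNA"), ("cox3", "CDS"),
    ("tRNA-Ala", "tRNA"), ("tRNA-Arg", "tRNA"), ("tRNA-Asn", "tRNA"),
    ("nad5", "CDS"), ("tRNA-Glu", "tRNA"), ("tRNA-Gln", "tRNA"),
    ("tRNA-Thr", "tRNA"), ("tRNA-Tyr", "tRNA"), ("NCR2", "NCR"),
    ("tRNA-Ser2", "tRNA"),
]
_RRNA_LENGTHS = {"12S": 846, "16S": 1245}
_MIN_NCR = 100


def _rate_class(name: str, kind: str) -> str:
    if name in _HOTSPOTS:
        return "hotspot"
    if name in _CONSERVED or (kind == "tRNA" and name not in _HOTSPOTS):
        return "conserved"
    return "baseline"


def feature_plan(genome_length: int) -> list[tuple[str, str, int, str]]:
    """Resolve the fixed gene layout to concrete lengths.

    The two non-coding regions absorb whatever ``genome_length`` leaves
    after genes, RNAs and spacers; raises if the feature set does not fit.
    """
    fixed = sum(_CDS_LENGTHS.values()) + sum(_RRNA_LENGTHS.values())
    fixed += _TRNA_LENGTH * sum(1 for _, k in _FEATURE_ORDER if k == "tRNA")
    fixed += _SPACER * len(_FEATURE_ORDER)
    ncr_total = genome_length - fixed
    if ncr_total < 2 * _MIN_NCR:
        raise ValueError(
            f"feature set does not fit: genome_length={genome_length} leaves "
            f"{ncr_total} bp for the two non-coding regions (need >= {2 * _MIN_NCR})"
        )
    ncr1 = int(round(0.6 * ncr_total))
    ncr_len = {"NCR1": ncr1, "NCR2": ncr_total - ncr1}
    plan = []
    for name, kind in _FEATURE_ORDER:
        if kind == "CDS":
            length = _CDS_LENGTHS[name]
        elif kind == "rRNA":
            length = _RRNA_LENGTHS[name]
        elif kind == "NCR":
            length = ncr_len[name]
        else:
            length = _TRNA_LENGTH
        plan.append((name, kind, length, _rate_class(name, kind)))
    return plan


def _random_bases(rng: np.random.Generator, n: int, p=None) -> str:
    return "".join(rng.choice(list(BASES), size=n, p=p))


def _random_cds(rng: np.random.Generator, length: int) -> str:
    if length % 3:
        raise ValueError("CDS length must be divisible by 3")
    n_codons = length // 3 - 2
    body = "".join(rng.choice(_NONSTOP_CODONS, size=n_codons))
    stop = str(rng.choice(STOP_CODONS))
    return "ATG" + body + stop


def build_reference_genome(config: SynthConfig) -> AnnotatedGenome:
    """Generate the annotated F-type reference mitogenome.

    Deterministic for a seed: 12 protein-coding genes, 22 tRNAs, the two
    rRNAs and two non-coding regions on a circular molecule of exactly
    ``config.genome_length`` bases (default 17,428).
    """
    plan = feature_plan(config.genome_length)
    rng = _rng(config.seed, _STREAM_REF)
    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    for name, kind, length, rate in plan:
        seq = _random_cds(rng, length) if kind == "CDS" else _random_bases(rng, length)
        features.append(Feature(name, kind, pos, pos + length, "+", rate))
        parts.append(seq)
        pos += length
        parts.append(_random_bases(rng, _SPACER))
        pos += _SPACER
    genome = AnnotatedGenome("F", "".join(parts), features, "circular")
    assert len(genome) == config.genome_length
    return genome


# ---------------------------------------------------------------------------
# Lineage divergence
# ---------------------------------------------------------------------------

@dataclass
class LineagePair:
    """An F/M mitogenome pair with its true alignment and event log.

    ``aligned_f``/``aligned_m`` are equal-length gapped strings whose
    ungapped projections reproduce the two genome sequences exactly.
    ``event_log`` records every applied substitution
    ``("sub", ref_pos, ref_base, alt_base)`` and insertion
    ``("ins", ref_pos, length, carrier, feature_name)``.
    """

    genome_f: AnnotatedGenome
    genome_m: AnnotatedGenome
    aligned_f: str
    aligned_m: str
    event_log: list[tuple] = field(default_factory=list)

    @property
    def n_substitutions(self) -> int:
        return sum(1 for e in self.event_log if e[0] == "sub")

    @property
    def realized_divergence(self) -> float:
        """Substitutions per compared (ungapped) site."""
        return self.n_substitutions / len(self.genome_f)


def _multiplier_array(ref: AnnotatedGenome, config: SynthConfig) -> np.ndarray:
    mults = {"hotspot": config.hotspot_multiplier,
             "conserved": config.conserved_multiplier,
             "baseline": 1.0}
    m = np.ones(len(ref))
    for f in ref.features:
        m[f.start:f.end] = mults[f.rate_class]
    return m


def diverge_lineages(ref: AnnotatedGenome, config: SynthConfig) -> LineagePair:
    """Evolve the M-type genome from the F-type reference.

    Substitution probability per site is baseline x class multiplier, with
    the baseline chosen so the expected pairwise-deletion p-distance equals
    ``config.divergence_target``. With ``config.structural_events`` the M
    genome additionally carries the 16S insertion (default 127 bp, placed
    at the 16S midpoint) and the cox1 3' extension (default 10 codons,
    inserted before the stop codon so the reading frame is preserved).
    """
    rng = _rng(config.seed, _STREAM_DIV)
    L = len(ref)
    seq_f = ref.sequence

    # site eligibility: protect start and stop codons of every CDS
    eligible = np.ones(L, dtype=bool)
    cds_start_at = {}  # position -> CDS start (for codon lookups)
    for f in ref.features:
        if f.kind == "CDS":
            eligible[f.start:f.start + 3] = False
            eligible[f.end - 3:f.end] = False
            for i in range(f.start, f.end):
                cds_start_at[i] = f.start

    m_seq = list(seq_f)
    events: list[tuple] = []
    if config.divergence_target > 0:
        mult = _multiplier_array(ref, config)
        baseline = config.divergence_target * L / mult[eligible].sum()
        p = np.where(eligible, np.clip(baseline * mult, 0.0, 0.95), 0.0)
        hits = np.nonzero(rng.random(L) < p)[0]
        for i in hits:
            ref_base = seq_f[i]
            alts = [b for b in BASES if b != ref_base]
            for alt in rng.permutation(alts):
                if i in cds_start_at:
                    s = cds_start_at[i]
                    c0 = s + 3 * ((i - s) // 3)
                    codon = m_seq[c0:c0 + 3]
                    codon[i - c0] = alt
                    if "".join(codon) in STOP_CODONS:
                        continue  # would truncate the protein; try another base
                m_seq[i] = alt
                events.append(("sub", int(i), ref_base, alt))
                break

    aln_f = list(seq_f)
    aln_m = list(m_seq)
    m_features = list(ref.features)

    inserts: list[tuple[int, str, str]] = []
    if config.structural_events:
        if config.indel_16S_length > 0:
            f16 = ref.feature("16S")
            pos = f16.start + f16.length // 2
            # A/T-rich filler, as is typical of mitochondrial indels
            ins = _random_bases(rng, config.indel_16S_length,
                                p=[0.4, 0.1, 0.1, 0.4])
            inserts.append((pos, ins, "16S"))
        if config.cox1_extension_aa > 0:
            fc = ref.feature("cox1")
            pos = fc.end - 3  # immediately before the stop codon, in frame
            ext = "".join(rng.choice(_NONSTOP_CODONS, size=config.cox1_extension_aa))
            inserts.append((pos, ext, "cox1"))

    for pos, ins, feat_name in sorted(inserts, reverse=True):
        aln_f[pos:pos] = ["-"] * len(ins)
        aln_m[pos:pos] = list(ins)
        shifted = []
        for f in m_features:
            if f.end <= pos:
                shifted.append(f)
            elif f.start >= pos:
                shifted.append(f.shifted(len(ins)))
            else:  # insertion internal to the feature: it grows
                shifted.append(Feature(f.name, f.kind, f.start, f.end + len(ins),
                                       f.strand, f.rate_class))
        m_features = shifted
        events.append(("ins", pos, len(ins), "M", feat_name))

    genome_m = AnnotatedGenome("M", "".join(aln_m).replace("-", ""),
                               sorted(m_features, key=lambda f: f.start), "circular")
    return LineagePair(ref, genome_m, "".join(aln_f), "".join(aln_m), events)


def make_lineage_pair(config: SynthConfig | None = None, **overrides) -> LineagePair:
    """Convenience: build the reference and diverge it in one call."""
    if config is None:
        config = SynthConfig(**overrides)
    return diverge_lineages(build_reference_genome(config), config)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class Read:
    id: str
    sequence: str
    quality: str
    truth: str  # "F" or "M"


@dataclass
class ReadSet:
    reads: list[Read]
    read_length: int
    error_rate: float
    coverage: float

    def __len__(self) -> int:
        return len(self.reads)

    def truth_fraction_m(self) -> float:
        if not self.reads:
            return 0.0
        return sum(r.truth == "M" for r in self.reads) / len(self.reads)


def simulate_reads(pair: LineagePair, config: SynthConfig) -> ReadSet:
    """Draw uniform-coverage reads from a mixture of the two genomes.

    Read starts are uniform on the circular molecules (origin-spanning
    reads wrap), strands are random, errors are substitutions at
    ``config.error_rate`` per base. ``config.mixture`` is the fraction of
    reads drawn from the M genome; truth labels are retained. The label
    draw uses one uniform per read compared against the mixture fraction,
    so for a fixed seed the number of M reads is monotone in the mixture.
    """
    if config.read_length > min(len(pair.genome_f), len(pair.genome_m)):
        raise ValueError("read_length exceeds genome length")
    rng = _rng(config.seed, _STREAM_READS)
    n_reads = int(rng.poisson(config.coverage * len(pair.genome_f) / config.read_length))
    # All randomness is drawn in fixed-size blocks up front, so runs at the
    # same seed differing only in the mixture are perfectly coupled: the set
    # of M-labelled reads grows monotonically with the mixture fraction and
    # every read keeps its position, strand and errors.
    label_u = rng.random(n_reads)
    pos_u = rng.random(n_reads)
    strand_u = rng.random(n_reads)
    err_u = rng.random((n_reads, config.read_length))
    err_choice = rng.integers(1, 4, size=(n_reads, config.read_length))
    qual = chr(33 + 30) * config.read_length
    genomes = {"F": pair.genome_f, "M": pair.genome_m}
    reads = []
    for i in range(n_reads):
        truth = "M" if label_u[i] < config.mixture else "F"
        g = genomes[truth]
        start = int(pos_u[i] * len(g))
        seq = g.fetch(start, start + config.read_length)
        if strand_u[i] < 0.5:
            seq = revcomp(seq)
        if config.error_rate > 0:
            s = list(seq)
            for j in np.nonzero(err_u[i] < config.error_rate)[0]:
                # shift by 1-3 positions in base order: always a different base
                s[j] = BASES[(BASES.index(s[j]) + err_choice[i, j]) % 4]
            seq = "".join(s)
        reads.append(Read(f"read_{i:06d}/{truth}", seq, qual, truth))
    return ReadSet(reads, config.read_length, config.error_rate, config.coverage)


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------

def simulate_qpcr(truth: pd.DataFrame, config: SynthConfig,
                  targets: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Simulate a qPCR plate from known template amounts.

    ``truth`` has columns (sample, tissue, target, amount_ng); amount 0
    means no template (the well reports no amplification, Ct = NaN).
    The plate includes a standard dilution series per target and duplicate
    unknown wells, with Ct = Ct(1 ng) - log_E(amount) + Gaussian noise.
    """
    q = config.qpcr
    required = {"sample", "tissue", "target", "amount_ng"}
    if not required <= set(truth.columns):
        raise ValueError(f"truth table needs columns {sorted(required)}")
    if (truth["amount_ng"] < 0).any():
        raise ValueError("template amounts must be >= 0")
    rng = _rng(config.seed, _STREAM_QPCR)
    log_e = math.log(q.efficiency)
    if targets is None:
        targets = tuple(dict.fromkeys(truth["target"]))

    def ct_of(amount: float) -> float:
        return q.ct_at_1ng - math.log(amount) / log_e

    rows = []
    for target in targets:
        for amount in q.standard_amounts:
            for rep in range(q.replicates):
                ct = ct_of(amount) + (rng.normal(0, q.noise_sd) if q.noise_sd else 0.0)
                rows.append(("standard", f"std_{target}", "", target, amount, rep + 1, ct))
    for _, r in truth.iterrows():
        for rep in range(q.replicates):
            if r["amount_ng"] > 0:
                ct = ct_of(r["amount_ng"]) + (rng.normal(0, q.noise_sd) if q.noise_sd else 0.0)
            else:
                ct = np.nan  # no amplification
            rows.append(("unknown", r["sample"], r["tissue"], r["target"],
                         np.nan, rep + 1, ct))
    return pd.DataFrame(rows, columns=["role", "sample", "tissue", "target",
                                       "known_amount_ng", "replicate", "ct"])


def tissue_truth(n_samples: int, seed: int, tissue: str = "gills",
                 heteroplasmy_fraction: float = 0.0,
                 m_fraction: float = 0.5,
                 minor_log10_range: tuple[float, float] = (1.0, 2.0),
                 copy_number_fold: float = 1.0) -> pd.DataFrame:
    """Build a per-sample template-amount truth table for qPCR simulation.

    Homoplasmic samples carry one cytb form only; heteroplasmic samples
    carry the minor form one to two orders of magnitude lower (the range is
    configurable). Housekeeping targets 18S and 28S are always present.
    ``copy_number_fold`` scales mtDNA template in M-carriers, emulating
    their higher mitochondrial density.
    """
    rng = np.random.default_rng([int(seed), 97])
    rows = []
    for i in range(n_samples):
        sample = f"ind_{i:03d}"
        is_m = rng.random() < m_fraction
        het = rng.random() < heteroplasmy_fraction
        major = float(rng.lognormal(math.log(0.5), 0.4))
        if is_m:
            major *= copy_number_fold
        amounts = {"cytbF": 0.0, "cytbM": 0.0}
        amounts["cytbM" if is_m else "cytbF"] = major
        if het:
            drop = rng.uniform(*minor_log10_range)
            amounts["cytbM" if not is_m else "cytbF"] = major / 10 ** drop
        amounts["18S"] = float(rng.lognormal(math.log(2.0), 0.3))
        amounts["28S"] = float(rng.lognormal(math.log(1.0), 0.3))
        truth_label = ("heteroplasmic" if het else
                       ("homoplasmic_M" if is_m else "homoplasmic_F"))
        for target, amt in amounts.items():
            rows.append((sample, tissue, target, amt, truth_label))
    return pd.DataFrame(rows, columns=["sample", "tissue", "target", "amount_ng", "truth"])


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _lognormal_with_mean(rng: np.random.Generator, mean: float, sigma: float,
                         n: int) -> np.ndarray:
    """Lognormal draws with the requested *arithmetic* mean."""
    mu = math.log(mean) - sigma ** 2 / 2
    return rng.lognormal(mu, sigma, n)


def simulate_phenotypes(config: SynthConfig) -> pd.DataFrame:
    """Per-individual enzyme activities across the four sex x mitotype cells.

    ETS and COX means are reduced in M-mitotype carriers (both sexes); CS
    is reduced in females (both mitotypes); mtDNA copy number (normalized
    cytb abundance) is ``copy_number_fold`` higher in M-carriers. Values
    are lognormal around the configured means.
    """
    e = config.effects
    rng = _rng(config.seed, _STREAM_PHENO)
    rows = []
    idx = 0
    for sex in ("female", "male"):
        for mito in ("F", "M"):
            n = e.n_per_cell
            ets_mean = e.ets_base * (e.ets_mito_factor if mito == "M" else 1.0)
            cox_mean = e.cox_base * (e.cox_mito_factor if mito == "M" else 1.0)
            cs_mean = e.cs_base_male * (e.cs_sex_factor if sex == "female" else 1.0)
            copy_mean = 1.0 * (e.copy_number_fold if mito == "M" else 1.0)
            ets = _lognormal_with_mean(rng, ets_mean, e.sigma_log, n)
            cox = _lognormal_with_mean(rng, cox_mean, e.sigma_log, n)
            cs = _lognormal_with_mean(rng, cs_mean, e.sigma_log, n)
            copy = _lognormal_with_mean(rng, copy_mean, e.sigma_log, n)
            for j in range(n):
                rows.append((f"ind_{idx:05d}", sex, mito,
                             ets[j], cox[j], cs[j], copy[j]))
                idx += 1
    return pd.DataFrame(rows, columns=["individual", "sex", "mitotype",
                                       "ETS", "COX", "CS", "cytb_copy"])


# ---------------------------------------------------------------------------
# Population screen
# ---------------------------------------------------------------------------

# Published screening counts: population, location, n, F-carriers, M-carriers
TABLE1 = pd.DataFrame(
    [
        ("Norway", "69°39N, 18°57E", 33, 30, 3),
        ("Iceland", "66°01N, 14°51W", 60, 50, 10),
        ("Baltic Sea", "54°32N, 10°42E", 77, 77, 0),
        ("Helgoland", "54°09N, 07°47E", 47, 47, 0),
        ("US", "41°00N, 71°00W", 58, 56, 2),
        ("Kattegat", "56°10N, 11°48E", 17, 17, 0),
        ("White Sea", "66°18N, 33°38E", 23, 23, 0),
    ],
    columns=["population", "location", "n", "carriers_F", "carriers_M"],
)


def simulate_population_screen(pop_table: pd.DataFrame | None = None,
                               seed: int = 1,
                               fixture: bool = False) -> pd.DataFrame:
    """Binomial carrier counts per population.

    ``pop_table`` has columns (population, n, carrier_probability). With
    ``fixture=True`` sampling is bypassed and the published screening table
    is transcribed exactly (including its totals row).
    """
    if fixture:
        out = TABLE1.copy()
        total = pd.DataFrame([{
            "population": "total", "location": "",
            "n": int(out["n"].sum()),
            "carriers_F": int(out["carriers_F"].sum()),
            "carriers_M": int(out["carriers_M"].sum()),
        }])
        return pd.concat([out, total], ignore_index=True)
    if pop_table is None:
        raise ValueError("pop_table required unless fixture=True")
    required = {"population", "n", "carrier_probability"}
    if not required <= set(pop_table.columns):
        raise ValueError(f"pop_table needs columns {sorted(required)}")
    if (pop_table["n"] < 0).any():
        raise ValueError("population sizes must be >= 0")
    if ((pop_table["carrier_probability"] < 0) | (pop_table["carrier_probability"] > 1)).any():
        raise ValueError("carrier probabilities must be in [0, 1]")
    rng = _rng(seed, _STREAM_SCREEN)
    rows = []
    for _, r in pop_table.iterrows():
        m = int(rng.binomial(int(r.n), float(r.carrier_probability)))
        rows.append((r.population, int(r.n), int(r.n) - m, m))
    return pd.DataFrame(rows, columns=["population", "n", "carriers_F", "carriers_M"])
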