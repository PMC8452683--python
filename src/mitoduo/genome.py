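"""Annotated circular mitochondrial genomes.

Coordinates are 0-based half-open internally; human-readable reports
(feature TSVs, window tables) are 1-based inclusive. All genes sit on the
"+" strand by default, the usual arrangement in venerid bivalves with
doubly uniparental inheritance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from Bio.Seq import Seq

MITO_TABLE = 5  # invertebrate mitochondrial code
STOP_CODONS = ("TAA", "TAG")
BASES = "ACGT"

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "NCR")
RATE_CLASSES = ("hotspot", "conserved", "baseline")

_COMPLEMENT = str.maketrans("ACGTacgt-", "TGCAtgca-")


def revcomp(seq: str) -> str:
    """Reverse complement (gap characters pass through)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Feature:
    """A gene, RNA, or non-coding region on a mitogenome."""

    name: str
    kind: str
    start: int
    end: int  # half-open
    strand: str = "+"
    rate_class: str = "baseline"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.rate_class not in RATE_CLASSES:
            raise ValueError(f"unknown rate class {self.rate_class!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.name}: need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Feature":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass
class AnnotatedGenome:
    """A mitogenome sequence plus its feature table.

    ``topology`` is ``"circular"`` for intact mitogenomes; extraction
    (:meth:`fetch`) wraps across the origin on circular molecules.
    """

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        if not self.sequence:
            raise ValueError("empty genome sequence")
        if set(self.sequence) - set(BASES):
            bad = sorted(set(self.sequence) - set(BASES))
            raise ValueError(f"genome sequence contains non-ACGT characters: {bad}")
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(f"feature {f.name} extends past genome end ({f.end} > {n})")
        ordered = sorted(self.features, key=lambda f: f.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"features {a.name} and {b.name} overlap")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r} on genome {self.id}")

    def fetch(self, start: int, end: int) -> str:
        """Extract ``[start, end)``; wraps across the origin when circular."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise ValueError(f"[{start}, {end}) runs off a linear genome of length {n}")
        if end - start > n:
            raise ValueError("requested span longer than the genome")
        return self.sequence[start:] + self.sequence[: end - n]

    def rotated(self, offset: int) -> "AnnotatedGenome":
        """Move the origin to ``offset``. Features are remapped; a feature
        that would span the new origin is an error (rotate within an
        intergenic point or a feature boundary)."""
        n = len(self.sequence)
        if self.topology != "circular":
            raise ValueError("only circular genomes can be rotated")
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            s = (f.start - offset) % n
            e = s + f.length
            if e > n:
                raise ValueError(f"rotation by {offset} would split feature {f.name}")
            feats.append(replace(f, start=s, end=e))
        return AnnotatedGenome(self.id, seq, sorted(feats, key=lambda f: f.start), self.topology)

    def cds_sequence(self, name: str) -> str:
        f = self.feature(name)
        if f.kind != "CDS":
            raise ValueError(f"{name} is not a CDS")
        seq = self.fetch(f.start, f.end)
        return seq if f.strand == "+" else revcomp(seq)

    def protein(self, name: str) -> str:
        """Translate a CDS under the invertebrate mitochondrial code; the
        terminal stop is trimmed. Raises on internal stops."""
        aa = str(Seq(self.cds_sequence(name)).translate(table=MITO_TABLE))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            raise ValueError(f"CDS {name} on {self.id} contains an internal stop")
        return aa


def translate_cds(seq: str) -> str:
    """Translate an in-frame CDS (table 5), trimming a terminal stop."""
    aa = str(Seq(seq).translate(table=MITO_TABLE))
    return aa[:-1] if aa.endswith("*") else aa
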