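"""File formats: FASTA/FASTQ via Biopython, TSV/BED via pandas.

Feature and window tables are written 1-based inclusive for human
consumption; BED keeps its native 0-based half-open convention.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .assay import MultiplexAssay, PrimerPair
from .genome import AnnotatedGenome, Feature
from .scan import DivergenceProfile, GroupAlignment, IndelRecord
from .synth import LineagePair, Read, ReadSet


# -- FASTA / FASTQ ----------------------------------------------------------

def write_fasta(records: dict[str, str] | list[AnnotatedGenome], path) -> None:
    if isinstance(records, dict):
        recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    else:
        recs = [SeqRecord(Seq(g.sequence), id=g.id,
                          description=f"topology={g.topology}") for g in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for r in reads.reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path, truth_from_id: bool = False) -> ReadSet:
    """Load reads; with ``truth_from_id`` the trailing ``/F`` or ``/M`` of
    simulator read names is recovered as the truth label (else 'F')."""
    reads = []
    length = 0
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        truth = rec.id.rsplit("/", 1)[-1] if truth_from_id and "/" in rec.id else "F"
        reads.append(Read(rec.id, str(rec.seq).upper(), qual, truth))
        length = max(length, len(rec.seq))
    return ReadSet(reads, length, error_rate=float("nan"), coverage=float("nan"))


# -- feature tables ---------------------------------------------------------

def write_features_tsv(genome: AnnotatedGenome, path) -> None:
    rows = [(genome.id, f.kind, f.start + 1, f.end, f.strand, f.name, f.rate_class)
            for f in genome.features]  # 1-based inclusive
    pd.DataFrame(rows, columns=["seqid", "kind", "start", "end", "strand",
                                "name", "rate_class"]).to_csv(path, sep="\t", index=False)


def read_features_tsv(path) -> list[Feature]:
    df = pd.read_csv(path, sep="\t")
    return [Feature(r["name"], r.kind, int(r.start) - 1, int(r.end),
                    r.strand, r.rate_class) for _, r in df.iterrows()]


# -- alignments and groups --------------------------------------------------

def read_group_alignment(aln_fasta, groups_tsv) -> GroupAlignment:
    """Aligned FASTA plus a two-column (name, group) TSV without header."""
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(aln_fasta), "fasta")}
    groups = pd.read_csv(groups_tsv, sep="\t", header=None, names=["name", "group"])
    names, rows, labels = [], [], []
    for _, r in groups.iterrows():
        if r["name"] not in seqs:
            raise ValueError(f"group table names {r['name']!r} absent from the alignment")
        names.append(r["name"])
        rows.append(seqs[r["name"]])
        labels.append(str(r.group))
    return GroupAlignment(names, rows, labels)


def write_pair_alignment(pair: LineagePair, aln_fasta, groups_tsv) -> None:
    write_fasta({pair.genome_f.id: pair.aligned_f,
                 pair.genome_m.id: pair.aligned_m}, aln_fasta)
    pd.DataFrame([(pair.genome_f.id, "F"), (pair.genome_m.id, "M")]).to_csv(
        groups_tsv, sep="\t", header=False, index=False)


# -- scan outputs -----------------------------------------------------------

def write_profile_tsv(profile: DivergenceProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def write_sites_bed(positions, path, chrom: str = "alignment",
                    name: str = "fixed_difference") -> None:
    rows = [(chrom, int(p), int(p) + 1, name) for p in positions]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_indels_bed(records: list[IndelRecord], path, chrom: str = "alignment") -> None:
    rows = [(chrom, r.aln_start, r.aln_start + r.length,
             f"indel_carrier_{r.carrier}" + (f"_{r.feature}" if r.feature else ""))
            for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_regions_bed(path):
    """BED of diagnostic regions: chrom is the mitotype (F/M), name column 4."""
    from .readtype import Region
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    return [Region(str(r.chrom), str(r["name"]), int(r.start), int(r.end))
            for _, r in df.iterrows()]


def write_regions_bed(regions, path) -> None:
    rows = [(r.mitotype, r.start, r.end, r.name) for r in regions]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# -- assay tables -----------------------------------------------------------

def read_primers_tsv(path) -> tuple[list[PrimerPair], MultiplexAssay]:
    """Primer TSV: name, locus, forward, reverse, expected_F_size, expected_M_size."""
    df = pd.read_csv(path, sep="\t")
    pairs = [PrimerPair(r["name"], r.locus, r.forward, r.reverse)
             for _, r in df.iterrows()]
    expected = {}
    for _, r in df.iterrows():
        expected.setdefault(r.locus, {"F": int(r.expected_F_size),
                                      "M": int(r.expected_M_size)})
    return pairs, MultiplexAssay(expected=expected)


def write_primers_tsv(pairs: list[PrimerPair], assay: MultiplexAssay, path) -> None:
    rows = []
    for p in pairs:
        e = assay.expected[p.locus]
        rows.append((p.name, p.locus, p.forward, p.reverse, e["F"], e["M"]))
    pd.DataFrame(rows, columns=["name", "locus", "forward", "reverse",
                                "expected_F_size", "expected_M_size"]
                 ).to_csv(path, sep="\t", index=False)


# -- generic tables ---------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
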