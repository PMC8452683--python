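"""Divergence scanning between the two mitotype lineages.

Implements the diagnostic computations on gapped alignments of F- and
M-type sequences: fixed-difference columns (group state sets disjoint,
gap counted as a fifth state), the sliding-window divergence profile,
p-distance with column-resampling bootstrap (pairwise deletion of gapped
columns), maximal indel localization, and per-feature divergence tables.
"""
from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import LineagePair

_ALPHABET = "ACGT-"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
GROUPS = ("F", "M")


def _encode(rows: list[str]) -> np.ndarray:
    """Rows -> int matrix over {A,C,G,T,-}; rejects other characters."""
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(len(rows), -1)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for c, i in _CODE.items():
        out[arr == ord(c)] = i
    if (out < 0).any():
        bad = sorted({chr(b) for b in arr[out < 0]})
        raise ValueError(
            f"alignment contains characters outside A/C/G/T/-: {bad} "
            "(ambiguity codes are rejected; the divergence rule is undefined for them)"
        )
    return out


@dataclass
class GroupAlignment:
    """Equal-length gapped sequences, each labelled F or M."""

    names: list[str]
    rows: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.rows) == len(self.labels)):
            raise ValueError("names, rows and labels must have equal length")
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows differ in length")
        if set(self.labels) - set(GROUPS):
            raise ValueError(f"group labels must be in {GROUPS}")
        for g in GROUPS:
            if g not in self.labels:
                raise ValueError(f"group {g} has no rows")
        self._matrix = _encode(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def group_matrix(self, label: str) -> np.ndarray:
        idx = [i for i, l in enumerate(self.labels) if l == label]
        return self._matrix[idx]

    @classmethod
    def from_pair(cls, pair: LineagePair) -> "GroupAlignment":
        return cls(names=[pair.genome_f.id, pair.genome_m.id],
                   rows=[pair.aligned_f, pair.aligned_m],
                   labels=["F", "M"])


def fixed_difference_columns(aln: GroupAlignment) -> np.ndarray:
    """Columns where the F and M state sets are disjoint (gap = 5th state).

    A column is diagnostic only if *every* M sequence differs from *every*
    F sequence there; shared polymorphism (e.g. M={A,G}, F={A}) does not
    qualify.
    """
    f, m = aln.group_matrix("F"), aln.group_matrix("M")
    pres_f = np.stack([(f == s).any(axis=0) for s in range(len(_ALPHABET))])
    pres_m = np.stack([(m == s).any(axis=0) for s in range(len(_ALPHABET))])
    divergent = ~np.any(pres_f & pres_m, axis=0)
    return np.nonzero(divergent)[0]


@dataclass
class DivergenceProfile:
    """Sliding-window counts of divergent columns over an alignment."""

    window: int
    step: int
    counts: np.ndarray
    source_positions: np.ndarray
    aln_length: int

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(len(self.counts)) * self.step
        return pd.DataFrame({"window_start": starts + 1,  # 1-based in reports
                             "count": self.counts})


def sliding_window_profile(positions, aln_length: int, window: int = 500,
                           step: int = 1) -> DivergenceProfile:
    """Count divergent columns in each window of ``window`` columns,
    advancing ``step`` columns at a time (defaults 500 / 1)."""
    if window > aln_length:
        raise ValueError(f"window ({window}) exceeds alignment length ({aln_length})")
    if step < 1 or window < 1:
        raise ValueError("window and step must be >= 1")
    positions = np.asarray(sorted(positions), dtype=int)
    if positions.size and (positions.min() < 0 or positions.max() >= aln_length):
        raise ValueError("divergent positions outside the alignment")
    ind = np.zeros(aln_length + 1, dtype=np.int64)
    np.add.at(ind, positions + 1, 1)
    cum = np.cumsum(ind)
    starts = np.arange(0, aln_length - window + 1, step)
    counts = cum[starts + window] - cum[starts]
    return DivergenceProfile(window, step, counts, positions, aln_length)


PDistance = namedtuple("PDistance", ["distance", "se"])


def p_distance(seq_a: str, seq_b: str, bootstrap_reps: int = 1000,
               seed: int | None = None) -> PDistance:
    """Proportion of differing sites, gapped columns excluded pairwise.

    The bootstrap standard error resamples alignment columns with
    replacement (``bootstrap_reps`` replicates, default 1000) and applies
    pairwise deletion within each replicate.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal gapped length")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    gap = ord("-")
    valid = (a != gap) & (b != gap)
    n_comp = int(valid.sum())
    if n_comp == 0:
        raise ValueError("no comparable (ungapped) sites")
    mismatch = (a != b) & valid
    d = mismatch.sum() / n_comp
    if bootstrap_reps <= 0:
        return PDistance(float(d), float("nan"))
    rng = np.random.default_rng(seed)
    L = len(a)
    reps = np.empty(bootstrap_reps)
    for r in range(bootstrap_reps):
        idx = rng.integers(0, L, L)
        v = valid[idx]
        nv = v.sum()
        reps[r] = mismatch[idx].sum() / nv if nv else np.nan
    se = float(np.nanstd(reps, ddof=1)) if bootstrap_reps > 1 else float("nan")
    return PDistance(float(d), se)


@dataclass
class IndelRecord:
    """A maximal gap run in the pair alignment."""

    aln_start: int   # alignment column, 0-based
    length: int
    carrier: str     # the group carrying the extra bases
    feature: str | None = None


def locate_indels(aln: GroupAlignment,
                  feature_spans: dict[str, tuple[int, int]] | None = None
                  ) -> list[IndelRecord]:
    """Maximal runs of columns gapped in exactly one group.

    A column counts toward an indel when one group is entirely gap and the
    other entirely ungapped; the carrier is the group that has sequence
    there. With ``feature_spans`` (feature name -> alignment column span)
    each record is annotated with the feature that fully contains it.
    """
    f, m = aln.group_matrix("F"), aln.group_matrix("M")
    gap = _CODE["-"]
    f_allgap = (f == gap).all(axis=0)
    f_nogap = (f != gap).all(axis=0)
    m_allgap = (m == gap).all(axis=0)
    m_nogap = (m != gap).all(axis=0)
    carrier = np.full(aln.length, "", dtype="U1")
    carrier[f_allgap & m_nogap] = "M"  # F lacks these columns; M carries them
    carrier[m_allgap & f_nogap] = "F"
    records = []
    i = 0
    while i < aln.length:
        if carrier[i]:
            j = i
            while j < aln.length and carrier[j] == carrier[i]:
                j += 1
            records.append(IndelRecord(i, j - i, str(carrier[i])))
            i = j
        else:
            i += 1
    if feature_spans:
        for rec in records:
            for name, (c0, c1) in feature_spans.items():
                if c0 <= rec.aln_start and rec.aln_start + rec.length <= c1:
                    rec.feature = name
                    break
    return records


# ---------------------------------------------------------------------------
# Feature projection and per-feature divergence
# ---------------------------------------------------------------------------

def feature_column_spans(pair: LineagePair) -> dict[str, tuple[int, int]]:
    """Project the F-genome feature map into alignment columns.

    A feature's span runs from the column of its first base to just past
    the column of its last base, so insertions internal to the feature
    fall inside its span.
    """
    aln_f = np.frombuffer(pair.aligned_f.encode(), dtype=np.uint8)
    not_gap = aln_f != ord("-")
    # colmap[p] = alignment column of F position p
    colmap = np.nonzero(not_gap)[0]
    spans = {}
    for f in pair.genome_f.features:
        spans[f.name] = (int(colmap[f.start]), int(colmap[f.end - 1]) + 1)
    return spans


def per_feature_divergence(pair: LineagePair,
                           bootstrap_reps: int = 0,
                           seed: int | None = None) -> pd.DataFrame:
    """Per-feature p-distance and fixed-difference count, plus an
    ``intergenic`` row so feature counts partition the genome-wide total."""
    aln = GroupAlignment.from_pair(pair)
    divergent = fixed_difference_columns(aln)
    div_mask = np.zeros(aln.length, dtype=bool)
    div_mask[divergent] = True
    spans = feature_column_spans(pair)
    assigned = np.zeros(aln.length, dtype=bool)
    rows = []
    for f in pair.genome_f.features:
        c0, c1 = spans[f.name]
        assigned[c0:c1] = True
        sub_a = pair.aligned_f[c0:c1]
        sub_b = pair.aligned_m[c0:c1]
        try:
            d = p_distance(sub_a, sub_b, bootstrap_reps=bootstrap_reps, seed=seed)
            dist = d.distance
        except ValueError:
            dist = float("nan")
        rows.append((f.name, f.kind, f.rate_class, f.length, dist,
                     int(div_mask[c0:c1].sum())))
    inter = ~assigned
    n_inter_div = int(div_mask[inter].sum())
    ia = "".join(c for c, keep in zip(pair.aligned_f, inter) if keep)
    ib = "".join(c for c, keep in zip(pair.aligned_m, inter) if keep)
    inter_dist = float("nan")
    if ia:
        try:
            inter_dist = p_distance(ia, ib, bootstrap_reps=0).distance
        except ValueError:
            pass
    rows.append(("intergenic", "intergenic", "baseline", int(inter.sum()),
                 inter_dist, n_inter_div))
    return pd.DataFrame(rows, columns=["feature", "kind", "rate_class",
                                       "length", "p_distance", "fixed_differences"])
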