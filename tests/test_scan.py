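"""Divergence-scan tests: fixed differences vs a brute-force oracle,
window profiles, p-distance, indel localization, per-feature partition."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitoduo import (
    GroupAlignment,
    SynthConfig,
    diverge_lineages,
    fixed_difference_columns,
    locate_indels,
    p_distance,
    per_feature_divergence,
    sliding_window_profile,
)
from mitoduo.scan import feature_column_spans


def brute_force_fixed_differences(aln: GroupAlignment) -> list[int]:
    """Independent per-column set-disjointness check (gap = fifth state)."""
    f_rows = [r for r, l in zip(aln.rows, aln.labels) if l == "F"]
    m_rows = [r for r, l in zip(aln.rows, aln.labels) if l == "M"]
    out = []
    for i in range(aln.length):
        if not ({r[i] for r in f_rows} & {r[i] for r in m_rows}):
            out.append(i)
    return out


class TestFixedDifferenceColumns:
    @pytest.mark.parametrize("f_rows,m_rows,expected", [
        (["ACGTA", "ACGTA"], ["ATGTC", "AGGTC"], [1, 4]),
        (["ACGT"], ["ACGT"], []),
        (["A-GT"], ["AAGT"], [1]),          # gap vs A: disjoint fifth state
        (["ACGT", "ATGT"], ["ATGT"], []),   # shared polymorphism at col 1
    ])
    def test_examples(self, f_rows, m_rows, expected):
        aln = GroupAlignment(
            names=[f"f{i}" for i in range(len(f_rows))] + [f"m{i}" for i in range(len(m_rows))],
            rows=f_rows + m_rows,
            labels=["F"] * len(f_rows) + ["M"] * len(m_rows))
        assert fixed_difference_columns(aln).tolist() == expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_f = data.draw(st.integers(1, 5))
        n_m = data.draw(st.integers(1, 5))
        length = data.draw(st.integers(1, 120))
        rows = data.draw(st.lists(
            st.text(alphabet="ACGT-", min_size=length, max_size=length),
            min_size=n_f + n_m, max_size=n_f + n_m))
        aln = GroupAlignment(names=[str(i) for i in range(n_f + n_m)],
                             rows=rows, labels=["F"] * n_f + ["M"] * n_m)
        assert fixed_difference_columns(aln).tolist() == brute_force_fixed_differences(aln)

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError, match="outside A/C/G/T"):
            GroupAlignment(["a", "b"], ["ACNT", "ACGT"], ["F", "M"])

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="group M has no rows"):
            GroupAlignment(["a"], ["ACGT"], ["F"])


class TestSlidingWindowProfile:
    def test_enumerated_example(self):
        prof = sliding_window_profile([2, 7], 10, window=4, step=1)
        assert prof.counts.tolist() == [1, 1, 1, 0, 1, 1, 1]

    def test_no_positions_gives_zero_vector(self):
        prof = sliding_window_profile([], 50, window=10)
        assert prof.counts.tolist() == [0] * 41

    def test_saturated_alignment(self):
        prof = sliding_window_profile(list(range(20)), 20, window=6)
        assert prof.counts.tolist() == [6] * 15

    def test_window_larger_than_alignment_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sliding_window_profile([0], 10, window=11)

    def test_count_conservation_identity(self):
        rng = np.random.default_rng(42)
        L, window, step = 500, 37, 1
        positions = np.sort(rng.choice(L, size=60, replace=False))
        prof = sliding_window_profile(positions, L, window=window, step=step)
        starts = np.arange(0, L - window + 1, step)
        multiplicity = sum(
            int(np.sum((starts <= p) & (p < starts + window))) for p in positions)
        assert int(prof.counts.sum()) == multiplicity


class TestPDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGA", 0.25),
        ("ACGT", "ACGT", 0.0),
        ("AC-T", "ACGT", 0.0),  # gapped column excluded: 0 over 3 sites
    ])
    def test_examples(self, a, b, expected):
        assert p_distance(a, b, bootstrap_reps=0).distance == pytest.approx(expected)

    def test_identical_sequences_zero_se(self):
        d = p_distance("ACGTACGT", "ACGTACGT", bootstrap_reps=50, seed=0)
        assert d.distance == 0.0 and d.se == 0.0

    def test_no_comparable_sites_rejected(self):
        with pytest.raises(ValueError, match="no comparable"):
            p_distance("A---", "-AAA", bootstrap_reps=0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            p_distance("ACG", "ACGT", bootstrap_reps=0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(1, 80), st.data())
    def test_symmetry_and_range(self, length, data):
        a = data.draw(st.text(alphabet="ACGT-", min_size=length, max_size=length))
        b = data.draw(st.text(alphabet="ACGT-", min_size=length, max_size=length))
        try:
            dab = p_distance(a, b, bootstrap_reps=0).distance
        except ValueError:
            return  # no comparable sites
        dba = p_distance(b, a, bootstrap_reps=0).distance
        assert dab == dba
        assert 0.0 <= dab <= 1.0

    def test_bootstrap_se_shrinks_with_length(self):
        rng = np.random.default_rng(7)
        ses = []
        for L in (1000, 10000, 50000):
            a = rng.choice(list("ACGT"), L)
            b = a.copy()
            flip = rng.random(L) < 0.05
            b[flip] = [("ACGT".replace(x, ""))[rng.integers(3)] for x in b[flip]]
            d = p_distance("".join(a), "".join(b), bootstrap_reps=200, seed=1)
            ses.append(d.se)
        assert ses[0] > ses[1] > ses[2]


class TestLocateIndels:
    def test_canonical_pair_structural_events(self, pair):
        spans = feature_column_spans(pair)
        recs = locate_indels(GroupAlignment.from_pair(pair), spans)
        by_feature = {r.feature: r for r in recs}
        assert set(by_feature) == {"16S", "cox1"}
        assert by_feature["16S"].length == 127
        assert by_feature["16S"].carrier == "M"
        assert by_feature["cox1"].length == 30

    def test_gapless_alignment_empty(self):
        aln = GroupAlignment(["a", "b"], ["ACGT", "AGGT"], ["F", "M"])
        assert locate_indels(aln) == []

    def test_maximal_runs_not_decomposed(self):
        aln = GroupAlignment(["a", "b"], ["A--T", "AGGT"], ["F", "M"])
        recs = locate_indels(aln)
        assert len(recs) == 1
        assert (recs[0].length, recs[0].carrier, recs[0].aln_start) == (2, "M", 1)


class TestPerFeatureDivergence:
    def test_hotspots_exceed_conserved(self, pair):
        tab = per_feature_divergence(pair).set_index("feature")
        assert tab.loc["16S", "p_distance"] > tab.loc["12S", "p_distance"]
        assert tab.loc["cox2", "p_distance"] < tab.loc["cytb", "p_distance"]

    def test_partition_identity(self, pair):
        tab = per_feature_divergence(pair)
        aln = GroupAlignment.from_pair(pair)
        total = len(fixed_difference_columns(aln))
        assert int(tab.fixed_differences.sum()) == total

    def test_zero_divergence_all_zero(self, reference):
        cfg = SynthConfig(seed=1, divergence_target=0.0, structural_events=False)
        tab = per_feature_divergence(diverge_lineages(reference, cfg))
        assert (tab.fixed_differences == 0).all()
        assert (tab.p_distance.dropna() == 0).all()
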