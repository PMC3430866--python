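import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regonset.config import PipelineConfig
from regonset.genomic_io import Peak
from regonset.motif_analysis import (
    ANNOTATION_COLUMNS,
    build_annotation_matrix,
    cluster_annotation,
    extended_consensus_counts,
    extract_cores,
    motif_promoter_association,
    revcomp,
    scan_consensus,
)
from tests.oracles import naive_scan

SEQ = st.text(alphabet="ACGTN", min_size=0, max_size=120)
MOTIF = st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=10)


class TestScan:
    def test_degenerate_code_matches(self):
        assert scan_consensus("TGCGGT", "TGYGGT") == [(0, "+")]
        assert scan_consensus("TGTGGT", "TGYGGT") == [(0, "+")]

    def test_w_code_matches_both_letters(self):
        assert (0, "+") in scan_consensus("AGATAA", "WGATAA")
        assert (0, "+") in scan_consensus("TGATAA", "WGATAA")

    def test_reverse_strand_match(self):
        # ACCGCA reverse-complements to TGCGGT
        assert scan_consensus("ACCGCA", "TGYGGT") == [(0, "-")]

    def test_n_in_sequence_never_matches(self):
        assert scan_consensus("TGNGGT", "TGYGGT") == []

    def test_invalid_iupac_letter_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_consensus("ACGT", "AXGT")

    def test_overlapping_matches_all_reported(self):
        hits = scan_consensus("AAAA", "AA")
        assert [h for h in hits if h[1] == "+"] == [(0, "+"), (1, "+"), (2, "+")]

    @settings(max_examples=300, deadline=None)
    @given(SEQ, MOTIF)
    def test_agrees_with_naive_matcher(self, seq, motif):
        assert scan_consensus(seq, motif) == naive_scan(seq, motif)

    @settings(max_examples=200, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=80), MOTIF)
    def test_strand_symmetry(self, seq, motif):
        m = len(motif)
        if len(seq) < m:
            return
        mirrored = {
            (len(seq) - m - o, "-" if s == "+" else "+")
            for o, s in scan_consensus(revcomp(seq), motif)
        }
        assert set(scan_consensus(seq, motif)) == mirrored

    def test_hit_counts_invariant_to_peak_order(self):
        seqs = {"a": "TGCGGTTT", "b": "ACCGCAAA", "c": "GGGGGGGG"}
        counts = {k: len(scan_consensus(v, "TGYGGT")) for k, v in seqs.items()}
        rev = {k: len(scan_consensus(v, "TGYGGT")) for k, v in reversed(seqs.items())}
        assert counts == rev


def _peak(pid, width, start=1000, chrom="chr1"):
    return Peak(pid, chrom, start, start + width, start + width // 2,
                (1.0, 1.0, 1.0), (True, True, True))


class TestExtractCores:
    def test_centred_200bp_window(self, cfg):
        p = _peak("p", 300)
        seq = "A" * 50 + "C" * 200 + "A" * 50
        cores, excluded = extract_cores([p], {"p": seq}, [], cfg)
        assert cores["p"] == "C" * 200 and excluded == []

    def test_short_peak_kept_whole(self, cfg):
        p = _peak("p", 150)
        cores, _ = extract_cores([p], {"p": "A" * 150}, [], cfg)
        assert len(cores["p"]) == 150

    @pytest.mark.parametrize("masked,kept", [(121, False), (120, True)])
    def test_repeat_fraction_boundary_in_core(self, masked, kept, cfg):
        p = _peak("p", 200, start=1000)
        mask = [("chr1", 1000, 1000 + masked)]
        cores, excluded = extract_cores([p], {"p": "A" * 200}, mask, cfg)
        assert ("p" in cores) is kept

    def test_lowercase_counts_as_masked_without_mask(self, cfg):
        p = _peak("p", 200)
        seq = "a" * 121 + "C" * 79
        cores, excluded = extract_cores([p], {"p": seq}, None, cfg)
        assert cores == {} and excluded[0].masked_fraction == pytest.approx(0.605)

    def test_length_mismatch_names_peak(self, cfg):
        with pytest.raises(ValueError, match="pX"):
            extract_cores([_peak("pX", 300)], {"pX": "ACGT"}, [], cfg)


class TestExtendedCounts:
    def test_paper_scale_expectation(self):
        # 1138 planted core matches -> expected extended count 285
        seqs = ["CCC" + "AGATA" + "CCC"] * 1138
        ext = extended_consensus_counts(seqs, "WGATA", "A")
        assert ext.n_total == 1138 and ext.n_expected == 285

    def test_empty_input(self):
        ext = extended_consensus_counts([], "WGATA", "A")
        assert (ext.n_total, ext.n_extended, ext.n_expected) == (0, 0, 0)

    def test_extension_detected_on_both_strands(self):
        # forward: AGATA followed by A;  reverse: TTATCT = revcomp(AGATAA)
        ext_f = extended_consensus_counts(["CCAGATAACC"], "WGATA", "A")
        ext_r = extended_consensus_counts(["CCTTATCTCC"], "WGATA", "A")
        assert ext_f.n_extended == 1 and ext_r.n_extended == 1

    def test_edge_match_counts_but_not_eligible(self):
        ext = extended_consensus_counts(["CCCAGATA"], "WGATA", "A")
        assert ext.n_total == 1 and ext.n_eligible == 0 and ext.n_extended == 0

    def test_random_sequences_within_central_binomial_interval(self):
        from scipy.stats import binom

        rng = np.random.default_rng(13)
        seqs = ["".join("ACGT"[i] for i in rng.integers(0, 4, 400)) for _ in range(300)]
        ext = extended_consensus_counts(seqs, "WGATA", "A")
        lo, hi = binom.ppf([0.005, 0.995], ext.n_eligible, 0.25)
        assert lo <= ext.n_extended <= hi


class TestAnnotationMatrix:
    def _matrix(self):
        ids = ["p1", "p2", "p3"]
        labels = {"p1": "2,3,4", "p2": "4 only", "p3": "4 only"}
        hits = {"runx": ["p1"], "gata": ["p3"], "new": []}
        return build_annotation_matrix(ids, labels, ["p1"], hits)

    def test_declared_rows_and_columns(self):
        m = self._matrix()
        assert list(m.columns) == list(ANNOTATION_COLUMNS)
        assert list(m.loc["p1"]) == [1, 1, 0, 1, 0]
        assert list(m.loc["p2"]) == [0, 0, 0, 0, 0]

    def test_column_sums_match_per_feature_counts(self, sim, cfg):
        from regonset.peak_annotation import assign_peaks, peak_category
        from regonset.peak_processing import filter_repeat_peaks, partition_peaks

        retained, _ = filter_repeat_peaks(sim.peaks, sim.repeat_mask, cfg)
        cores, _ = extract_cores(retained, sim.sequences, sim.repeat_mask, cfg)
        shared, late, _ = partition_peaks(retained)
        labels = {pid: shared.label for pid in shared.peak_ids}
        labels.update({pid: late.label for pid in late.peak_ids})
        links = assign_peaks(retained, sim.genes, cfg)
        promoters = [pid for pid, c in peak_category(links).items() if c == "promoter"]
        hits = {
            name: [pid for pid, s in cores.items() if scan_consensus(s, motif)]
            for name, motif in (("runx", "TGYGGT"), ("gata", "WGATAA"), ("new", "TGTAGT"))
        }
        m = build_annotation_matrix(sorted(cores), labels, promoters, hits)
        assert m["has_runx_motif"].sum() == len(set(hits["runx"]) & set(cores))
        assert m["promoter"].sum() == len(set(promoters) & set(cores))
        assert m["shared_partition"].sum() == len(
            [p for p in cores if labels[p] == "2,3,4"]
        )


class TestClustering:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, size=(20, 5))
        rows[7] = rows[3]  # force a duplicate pair
        m = pd.DataFrame(rows, index=[f"p{i:02d}" for i in range(20)],
                         columns=list(ANNOTATION_COLUMNS))
        order, Z = cluster_annotation(m)
        # identical rows must end up contiguous in the leaf order
        groups = {}
        for pos, pid in enumerate(order):
            groups.setdefault(tuple(m.loc[pid]), []).append(pos)
        for positions in groups.values():
            assert positions == list(range(min(positions), max(positions) + 1))

    def test_opposite_rows_maximally_distant(self):
        m = pd.DataFrame([[0] * 5, [1] * 5], index=["a", "b"],
                         columns=list(ANNOTATION_COLUMNS))
        _, Z = cluster_annotation(m)
        assert Z[0, 2] == pytest.approx(1.0)

    def test_single_row_trivial(self):
        m = pd.DataFrame([[1, 0, 1, 0, 1]], index=["only"],
                         columns=list(ANNOTATION_COLUMNS))
        order, Z = cluster_annotation(m)
        assert order == ["only"] and Z is None

    def test_deterministic_under_row_permutation(self):
        rng = np.random.default_rng(8)
        rows = rng.integers(0, 2, size=(15, 5))
        ids = [f"p{i:02d}" for i in range(15)]
        m = pd.DataFrame(rows, index=ids, columns=list(ANNOTATION_COLUMNS))
        order1, _ = cluster_annotation(m)
        order2, _ = cluster_annotation(m.iloc[::-1])
        assert order1 == order2


class TestPromoterAssociation:
    def test_degenerate_table(self):
        m = pd.DataFrame(
            [[1, 1, 1, 0, 0]] * 4, index=list("abcd"), columns=list(ANNOTATION_COLUMNS)
        )
        table, p = motif_promoter_association(m)
        assert p == 1.0

    def test_fisher_matches_exhaustive_enumeration(self):
        # enumerate all tables with the observed margins and sum those at
        # least as extreme (two-sided by point probability)
        a, b, c, d = 7, 3, 2, 9
        m = pd.DataFrame(
            [[0, 1, 1, 0, 0]] * a + [[0, 1, 0, 0, 0]] * b
            + [[0, 0, 1, 0, 0]] * c + [[0, 0, 0, 0, 0]] * d,
            index=[f"p{i}" for i in range(a + b + c + d)],
            columns=list(ANNOTATION_COLUMNS),
        )
        _, p = motif_promoter_association(m)
        n, row1, col1 = a + b + c + d, a + b, a + c

        def point_prob(k):
            return comb(row1, k) * comb(n - row1, col1 - k) / comb(n, col1)

        observed = point_prob(a)
        total = sum(
            point_prob(k)
            for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1)
            if point_prob(k) <= observed * (1 + 1e-9)
        )
        assert p == pytest.approx(total, rel=1e-9)

    def test_planted_promoter_motif_is_detected(self, sim, cfg):
        from regonset.peak_annotation import assign_peaks, peak_category
        from regonset.peak_processing import filter_repeat_peaks, partition_peaks

        retained, _ = filter_repeat_peaks(sim.peaks, sim.repeat_mask, cfg)
        cores, _ = extract_cores(retained, sim.sequences, sim.repeat_mask, cfg)
        shared, late, _ = partition_peaks(retained)
        labels = {pid: shared.label for pid in shared.peak_ids}
        labels.update({pid: late.label for pid in late.peak_ids})
        links = assign_peaks(retained, sim.genes, cfg)
        promoters = [pid for pid, c in peak_category(links).items() if c == "promoter"]
        hits = {"new": [pid for pid, s in cores.items() if scan_consensus(s, "TGTAGT")]}
        m = build_annotation_matrix(sorted(cores), labels, promoters, hits)
        _, p = motif_promoter_association(m)
        assert p < 1e-3

    def test_power_with_promoter_only_motif_at_50_per_cell(self):
        ids = [f"p{i:03d}" for i in range(200)]
        promoters = ids[:100]
        # motif exclusively in promoters: 50/100 promoters vs 0/100 others
        hits = {"new": ids[:50]}
        m = build_annotation_matrix(ids, {}, promoters, hits)
        _, p = motif_promoter_association(m)
        assert p < 1e-6

    def test_independent_features_give_uniform_ish_p(self):
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            ids = [f"p{i}" for i in range(80)]
            promoters = [i for i in ids if rng.random() < 0.5]
            hits = {"new": [i for i in ids if rng.random() < 0.5]}
            m = build_annotation_matrix(ids, {}, promoters, hits)
            _, p = motif_promoter_association(m)
            ps.append(p)
        assert 0.3 < float(np.median(ps)) < 0.9  # discrete test, median near 0.5
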