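import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from cernaflow.diffexpr import DERecord
from cernaflow.errors import UndefinedCorrelationError
from cernaflow.model import ExpressionMatrix, SequenceRecord
from cernaflow.networks import (
    CoexpressionConfig,
    CorrelationEdge,
    build_cerna_network,
    build_cnc_network,
    build_mirna_target_network,
    network_summary,
    pearson_with_p,
)
from cernaflow.seeds import scan


def _vector_with_r(r, n=8, seed=0):
    """Construct (x, y) with sample correlation exactly r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean() - x * np.dot(z - z.mean(), x) / np.dot(x, x)
    z /= z.std()
    return x, r * x + np.sqrt(1 - r * r) * z


class TestPearson:
    def test_affine_fit_flags_exact(self):
        x = np.arange(8.0)
        res = pearson_with_p(x, 2 * x + 1)
        assert res.pcc == pytest.approx(1.0)
        assert res.p_value == 0.0 and res.exact_fit

    def test_perfect_anticorrelation(self):
        x = np.arange(8.0)
        res = pearson_with_p(x, -x)
        assert res.pcc == pytest.approx(-1.0) and res.exact_fit

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p(np.ones(8), np.arange(8.0))

    def test_p_agrees_with_scipy_pearsonr(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x, y = rng.normal(size=(2, 10))
            res = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert res.pcc == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_threshold_correlation_p_value(self):
        """r = 0.968 at n = 8: t ~ 9.45 on 6 df, two-sided p ~ 8e-5."""
        x, y = _vector_with_r(0.968)
        res = pearson_with_p(x, y)
        assert res.pcc == pytest.approx(0.968, abs=1e-12)
        t = 0.968 * np.sqrt(6) / np.sqrt(1 - 0.968 ** 2)
        # independent oracle: regularized incomplete beta tail
        p_oracle = special.betainc(3.0, 0.5, 6.0 / (6.0 + t * t))
        assert res.p_value == pytest.approx(p_oracle, rel=0.01)
        assert res.p_value == pytest.approx(8e-5, rel=0.15)


def _de(tid, direction, passes=True):
    fc = 4.0 if direction == "up" else 0.25
    return DERecord(transcript_id=tid, mean_case=1.0, mean_control=1.0,
                    fold_change=fc, log2fc=np.log2(fc), p_value=0.001,
                    fdr=0.01, direction=direction, passes_filter=passes)


def _two_row_matrix(vec_a, vec_b, ids, classes):
    samples = [f"case_{i}" for i in range(1, 5)] + \
        [f"ctrl_{i}" for i in range(1, 5)]
    groups = {s: ("case" if s.startswith("case") else "control")
              for s in samples}
    values = pd.DataFrame(np.power(2.0, np.array([vec_a, vec_b])),
                          index=ids, columns=samples)
    return ExpressionMatrix(values=values, group_of=groups,
                            transcript_class=dict(zip(ids, classes)))


ANTI = (np.array([9, 9.1, 8.9, 9.0, 7.0, 7.1, 6.9, 7.0]),
        np.array([5, 4.9, 5.1, 5.0, 7.0, 6.9, 7.1, 7.0]))  # r ~ -0.99

# a let-7-like miRNA and an mRNA carrying its 8mer site
MIR = SequenceRecord(id="MIR1", sequence="UGAGGUAGUAGGUUGUAUAGUU")
MRNA_WITH_SITE = SequenceRecord(id="MRNA1",
                                sequence="GGG" + "CUACCUCA" + "G" * 30)
MRNA_NO_SITE = SequenceRecord(id="MRNA1", sequence="G" * 41)


class TestTargetNetwork:
    def _sites(self, target):
        return scan(MIR, target)

    def test_site_negative_corr_antidirectional_included(self):
        matrix = _two_row_matrix(*ANTI, ["MIR1", "MRNA1"], ["miRNA", "mRNA"])
        edges = build_mirna_target_network(
            [_de("MIR1", "up")], [_de("MRNA1", "down")],
            self._sites(MRNA_WITH_SITE), matrix)
        assert len(edges) == 1
        assert edges[0].sign == "negative"
        assert edges[0].pcc < -0.968

    def test_positive_correlation_excluded(self):
        pos = (ANTI[0], 14.0 - ANTI[1])  # flip to a positive correlation
        matrix = _two_row_matrix(*pos, ["MIR1", "MRNA1"], ["miRNA", "mRNA"])
        edges = build_mirna_target_network(
            [_de("MIR1", "up")], [_de("MRNA1", "down")],
            self._sites(MRNA_WITH_SITE), matrix)
        assert edges == []

    def test_missing_site_excluded_despite_correlation(self):
        matrix = _two_row_matrix(*ANTI, ["MIR1", "MRNA1"], ["miRNA", "mRNA"])
        edges = build_mirna_target_network(
            [_de("MIR1", "up")], [_de("MRNA1", "down")],
            self._sites(MRNA_NO_SITE), matrix)
        assert edges == []

    def test_codirectional_pair_excluded(self):
        matrix = _two_row_matrix(*ANTI, ["MIR1", "MRNA1"], ["miRNA", "mRNA"])
        edges = build_mirna_target_network(
            [_de("MIR1", "up")], [_de("MRNA1", "up")],
            self._sites(MRNA_WITH_SITE), matrix)
        assert edges == []


class TestCncNetwork:
    def test_planted_pairs_recovered_with_correct_sign(self, study, de_records):
        matrix = ExpressionMatrix.combine([study.matrices["lncRNA"],
                                           study.matrices["mRNA"]])
        edges = build_cnc_network(de_records["mRNA"], de_records["lncRNA"],
                                  matrix)
        by_pair = {(e.node_a, e.node_b): e for e in edges}
        for lnc, mrna, sign in study.truth.coexpressed_pairs:
            assert (lnc, mrna) in by_pair
            assert by_pair[(lnc, mrna)].sign == sign

    def test_every_retained_edge_passes_thresholds(self, study, de_records):
        matrix = ExpressionMatrix.combine([study.matrices["lncRNA"],
                                           study.matrices["mRNA"]])
        cfg = CoexpressionConfig()
        edges = build_cnc_network(de_records["mRNA"], de_records["lncRNA"],
                                  matrix, cfg)
        assert edges
        for e in edges:
            assert abs(e.pcc) >= cfg.pcc_threshold
            assert e.p_value < cfg.p_threshold

    def test_empty_de_list_gives_empty_network(self, study, de_records):
        matrix = ExpressionMatrix.combine([study.matrices["lncRNA"],
                                           study.matrices["mRNA"]])
        assert build_cnc_network(de_records["mRNA"], [], matrix) == []


class TestCernaNetwork:
    def test_planted_triplets_recovered_exactly(self, study, de_records):
        matrix = ExpressionMatrix.combine(
            [study.matrices["circRNA"], study.matrices["miRNA"],
             study.matrices["mRNA"]])
        triplets, n_missing = build_cerna_network(
            de_records["circRNA"], de_records["miRNA"], de_records["mRNA"],
            study.sequences, matrix)
        assert n_missing == 0
        found = {(t.circ_id, t.mirna_id, t.mrna_id) for t in triplets}
        assert found == set(map(tuple, study.truth.cerna_triplets))
        for t in triplets:
            assert t.r_circ_mir < 0 and t.r_mir_mrna < 0
            assert t.sites_on_circ and t.sites_on_mrna
            assert t.de_signs[0] == t.de_signs[2] != t.de_signs[1]

    def test_permutation_null_collapses_target_edges(self, study, de_records):
        """Shuffling the miRNA sample labels destroys the planted negative
        correlations, so almost no target edge survives the PCC gate."""
        rng = np.random.default_rng(0)
        matrix = ExpressionMatrix.combine([study.matrices["miRNA"],
                                           study.matrices["mRNA"]])
        mir_ids = [r.transcript_id for r in de_records["miRNA"]
                   if r.passes_filter]
        mrna_ids = [r.transcript_id for r in de_records["mRNA"]
                    if r.passes_filter]
        sites = [s for m in mir_ids for t in mrna_ids
                 for s in scan(study.sequences[m], study.sequences[t])]
        baseline = build_mirna_target_network(
            de_records["miRNA"], de_records["mRNA"], sites, matrix)
        assert baseline  # the planted pairs are found before permutation
        permuted_counts = []
        for _ in range(5):
            values = matrix.values.copy()
            perm = rng.permutation(values.shape[1])
            mir_rows = values.index.str.startswith("MIR")
            values.loc[mir_rows] = values.loc[mir_rows].to_numpy()[:, perm]
            pm = ExpressionMatrix(values=values, group_of=matrix.group_of,
                                  transcript_class=matrix.transcript_class)
            permuted_counts.append(len(build_mirna_target_network(
                de_records["miRNA"], de_records["mRNA"], sites, pm)))
        assert np.mean(permuted_counts) <= 0.2 * len(baseline)


class TestNetworkSummary:
    def test_triangle(self):
        edges = [CorrelationEdge("a", "b", 0.99, 1e-5),
                 CorrelationEdge("b", "c", 0.99, 1e-5),
                 CorrelationEdge("a", "c", -0.99, 1e-5)]
        s = network_summary(edges)
        assert s["n_nodes"] == 3 and s["n_edges"] == 3
        assert all(deg == 2 for _, deg in s["degree_table"])
        assert s["sign_counts"] == {"positive": 2, "negative": 1}

    def test_empty(self):
        s = network_summary([])
        assert s["n_nodes"] == 0 and s["n_edges"] == 0

    def test_star_hub_degree(self):
        edges = [CorrelationEdge("hub", f"leaf{i}", 0.99, 1e-5)
                 for i in range(10)]
        s = network_summary(edges)
        assert s["degree_table"][0] == ("hub", 10)
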