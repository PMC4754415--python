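"""Co-expression matrices, QAP permutation test, state partitions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from sdmnstates import (
    CoexpressionMatrix,
    coexpression_matrices,
    coexpression_matrix,
    export_heatmaps,
    partition_states,
    qap_correlation,
    qap_exhaustive,
    significance_mark,
)


def _table_from_wide(wide, treatment="w", nucleus="Dm"):
    rows = []
    for fid, row in wide.iterrows():
        for gene, v in row.items():
            rows.append((fid, treatment, nucleus, gene, v))
    return pd.DataFrame(
        rows, columns=["fish_id", "treatment", "nucleus", "gene", "relative_expression"]
    )


def _cm(r, genes=None, treatment="t", nucleus="Dm"):
    r = np.asarray(r, dtype=float)
    g = r.shape[0]
    genes = tuple(genes or [f"g{i}" for i in range(g)])
    n = np.full((g, g), 12, dtype=int)
    p = np.full((g, g), 0.5)
    np.fill_diagonal(p, np.nan)
    return CoexpressionMatrix(treatment, nucleus, genes, r, n, p, p.copy())


# ----------------------------------------------------------------------
# matrix construction


def test_duplicated_gene_correlates_perfectly():
    rng = np.random.default_rng(0)
    x = rng.normal(size=15)
    wide = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=15)},
                        index=[f"f{i}" for i in range(15)])
    m = coexpression_matrix(_table_from_wide(wide), "w", "Dm", genes=("a", "b", "c"))
    assert m.r[0, 1] == pytest.approx(1.0)
    assert m.p[0, 1] < 1e-10
    assert np.allclose(m.r, m.r.T, equal_nan=True)
    assert np.allclose(np.diag(m.r), 1.0)


def test_matrix_converges_to_population_correlation():
    """n = 2000 draws from a known MVN: max entry error < 0.1."""
    rho = 0.55
    target = np.array([[1, rho, 0], [rho, 1, 0], [0, 0, 1.0]])
    rng = np.random.default_rng(1)
    draws = rng.multivariate_normal(np.zeros(3), target, size=2000)
    wide = pd.DataFrame(draws, columns=["a", "b", "c"],
                        index=[f"f{i}" for i in range(2000)])
    m = coexpression_matrix(_table_from_wide(wide), "w", "Dm", genes=("a", "b", "c"))
    assert np.max(np.abs(m.r - target)) < 0.1


def test_sparse_gene_marked_missing():
    rng = np.random.default_rng(2)
    wide = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)},
                        index=[f"f{i}" for i in range(10)])
    tbl = _table_from_wide(wide)
    # gene c observed on only 2 fish: below min_n=3
    extra = pd.DataFrame({
        "fish_id": ["f0", "f1"], "treatment": "w", "nucleus": "Dm",
        "gene": "c", "relative_expression": [1.0, 2.0],
    })
    m = coexpression_matrix(pd.concat([tbl, extra]), "w", "Dm", genes=("a", "b", "c"))
    assert np.isfinite(m.r[0, 1])
    assert not np.isfinite(m.r[0, 2]) and not np.isfinite(m.r[1, 2])
    assert m.n[0, 2] == 2


def test_padj_never_below_raw_p():
    rng = np.random.default_rng(3)
    wide = pd.DataFrame(rng.normal(size=(12, 5)),
                        columns=list("abcde"), index=[f"f{i}" for i in range(12)])
    m = coexpression_matrix(_table_from_wide(wide), "w", "Dm")
    iu = np.triu_indices(5, k=1)
    assert np.all(m.p_adj[iu] >= m.p[iu] - 1e-12)


def test_coexpression_matrices_full_grid(expression_from_truth, design):
    mats = coexpression_matrices(
        expression_from_truth, design.treatments, design.nuclei, genes=design.genes
    )
    assert len(mats) == 20
    assert mats[("winner", "Dm")].label == "winner:Dm"


# ----------------------------------------------------------------------
# QAP


def test_qap_self_comparison_r_is_one():
    rng = np.random.default_rng(4)
    a = np.corrcoef(rng.normal(size=(20, 6)), rowvar=False)
    res = qap_correlation(_cm(a), _cm(a), n_perm=719, seed=0, mode="monte_carlo")
    assert res.r_obs == pytest.approx(1.0)
    assert res.p <= 0.05


def test_qap_exhaustive_three_genes_hand_case():
    """With distinct cell values and matching order, exactly one of the
    six permutations attains r = 1, so the exact one-tailed p is 1/6."""
    a = _cm([[1, 0.9, 0.1], [0.9, 1, 0.5], [0.1, 0.5, 1.0]])
    b = _cm([[1, 0.8, 0.0], [0.8, 1, 0.4], [0.0, 0.4, 1.0]])
    res = qap_exhaustive(a, b)
    assert res.mode == "exhaustive"
    assert res.n_perm == 6
    assert res.r_obs == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 6)
    # oracle: enumerate by hand with plain numpy
    ua = np.array([0.9, 0.1, 0.5])
    bm = np.asarray(b.r)
    stats = []
    for perm in itertools.permutations(range(3)):
        pb = bm[np.ix_(perm, perm)]
        ub = pb[np.triu_indices(3, k=1)]
        stats.append(np.corrcoef(ua, ub)[0, 1])
    expected_p = np.mean(np.asarray(stats) >= res.r_obs - 1e-12)
    assert res.p == pytest.approx(expected_p)


def test_qap_auto_uses_exhaustive_for_six_genes():
    rng = np.random.default_rng(5)
    a = np.corrcoef(rng.normal(size=(30, 6)), rowvar=False)
    b = np.corrcoef(rng.normal(size=(30, 6)), rowvar=False)
    res = qap_correlation(_cm(a), _cm(b), n_perm=5000, seed=1)
    assert res.mode == "exhaustive"
    assert res.n_perm == math.factorial(6)


def test_qap_constant_offdiagonal_undefined():
    c = np.full((4, 4), 0.3)
    np.fill_diagonal(c, 1.0)
    res = qap_correlation(_cm(c), _cm(c), n_perm=100, seed=0, mode="monte_carlo")
    assert res.mode == "undefined"
    assert not res.defined
    assert math.isnan(res.p)


def test_qap_exhaustive_refused_above_eight_genes():
    rng = np.random.default_rng(6)
    a = np.corrcoef(rng.normal(size=(30, 9)), rowvar=False)
    with pytest.raises(ValueError, match="refused"):
        qap_exhaustive(_cm(a), _cm(a))


def test_qap_mc_p_never_below_add_one_floor():
    rng = np.random.default_rng(7)
    a = np.corrcoef(rng.normal(size=(40, 9)), rowvar=False)
    res = qap_correlation(_cm(a), _cm(a), n_perm=200, seed=2, mode="monte_carlo")
    assert res.p >= 1.0 / 201


def test_qap_missing_cells_rejected():
    a = np.eye(4)
    a[0, 1] = a[1, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        qap_correlation(_cm(np.eye(4) * 0 + np.eye(4)), _cm(a), n_perm=10)


def test_qap_relabel_invariance():
    """Applying the same relabelling to both matrices leaves r_obs and the
    exhaustive p unchanged."""
    rng = np.random.default_rng(8)
    a = np.corrcoef(rng.normal(size=(25, 5)), rowvar=False)
    b = np.corrcoef(rng.normal(size=(25, 5)), rowvar=False)
    base = qap_exhaustive(_cm(a), _cm(b))
    perm = rng.permutation(5)
    ap = a[np.ix_(perm, perm)]
    bp = b[np.ix_(perm, perm)]
    out = qap_exhaustive(_cm(ap), _cm(bp))
    assert out.p == pytest.approx(base.p)
    # r_obs changes with the cell ordering in general, but the permutation
    # distribution (hence p) does not.


def test_qap_mc_converges_to_exhaustive():
    rng = np.random.default_rng(9)
    a = np.corrcoef(rng.normal(size=(18, 5)), rowvar=False)
    b = 0.6 * a + 0.4 * np.corrcoef(rng.normal(size=(18, 5)), rowvar=False)
    np.fill_diagonal(b, 1.0)
    exact = qap_exhaustive(_cm(a), _cm(b))
    mc = qap_correlation(_cm(a), _cm(b), n_perm=20000, seed=3, mode="monte_carlo")
    assert abs(mc.p - exact.p) < 0.02
    assert mc.r_obs == pytest.approx(exact.r_obs)


def test_qap_two_sided_tail():
    rng = np.random.default_rng(10)
    a = np.corrcoef(rng.normal(size=(30, 5)), rowvar=False)
    b = -a + 2 * np.eye(5)  # perfectly anti-correlated off-diagonals
    one = qap_exhaustive(_cm(a), _cm(b), tail="greater")
    two = qap_exhaustive(_cm(a), _cm(b), tail="two-sided")
    assert one.r_obs == pytest.approx(-1.0)
    assert two.p <= one.p


# ----------------------------------------------------------------------
# partitioning


def _mats_for(axis_units, r_by_unit, axis="treatment"):
    mats = {}
    for u in axis_units:
        kwargs = {"treatment": u, "nucleus": "Dm"} if axis == "treatment" else {
            "treatment": "w", "nucleus": u}
        mats[u] = _cm(r_by_unit[u], **kwargs)
    return mats


def test_partition_all_similar_single_letter():
    rng = np.random.default_rng(11)
    base = np.corrcoef(rng.normal(size=(40, 6)), rowvar=False)
    mats = _mats_for(["w", "l", "m"], {u: base for u in ["w", "l", "m"]})
    part = partition_states(mats, axis="treatment", seed=0)
    assert set(part.labels.values()) == {"A"}
    assert part.intransitive == []


def test_partition_opposite_matrices_get_distinct_letters():
    rng = np.random.default_rng(12)
    a = np.corrcoef(rng.normal(size=(40, 6)), rowvar=False)
    b = -a + 2 * np.eye(6)
    mats = _mats_for(["w", "l"], {"w": a, "l": b})
    part = partition_states(mats, axis="treatment", seed=0)
    assert part.labels["w"] != part.labels["l"]
    assert set(part.labels.values()) == {"A", "B"}


def test_partition_letters_follow_unit_order():
    rng = np.random.default_rng(13)
    a = np.corrcoef(rng.normal(size=(40, 6)), rowvar=False)
    b = -a + 2 * np.eye(6)
    mats = _mats_for(["x", "y"], {"x": a, "y": b})
    part = partition_states(mats, axis="treatment", seed=0)
    assert part.labels["x"] == "A" and part.labels["y"] == "B"


def test_partition_undefined_unit_flagged():
    rng = np.random.default_rng(14)
    a = np.corrcoef(rng.normal(size=(40, 6)), rowvar=False)
    flat = np.full((6, 6), 0.2)
    np.fill_diagonal(flat, 1.0)
    mats = _mats_for(["w", "l", "m"], {"w": a, "l": a, "m": flat})
    part = partition_states(mats, axis="treatment", seed=0)
    assert part.labels["m"] == "?"
    assert part.flagged == ["m"]
    assert part.labels["w"] == part.labels["l"] == "A"


def test_partition_duplicate_units_rejected():
    rng = np.random.default_rng(15)
    a = np.corrcoef(rng.normal(size=(40, 6)), rowvar=False)
    mats = [_cm(a, treatment="w"), _cm(a, treatment="w")]
    with pytest.raises(ValueError, match="distinct"):
        partition_states(mats, axis="treatment")


def test_partition_deterministic_given_seed():
    rng = np.random.default_rng(16)
    mats = _mats_for(
        ["w", "l", "m", "c"],
        {u: np.corrcoef(rng.normal(size=(12, 6)), rowvar=False)
         for u in ["w", "l", "m", "c"]},
    )
    p1 = partition_states(mats, axis="treatment", seed=42)
    p2 = partition_states(mats, axis="treatment", seed=42)
    assert p1.labels == p2.labels
    pd.testing.assert_frame_equal(p1.edges, p2.edges)


# ----------------------------------------------------------------------
# marks and export


def test_significance_marks():
    assert significance_mark(0.0005) == "***"
    assert significance_mark(0.005) == "**"
    assert significance_mark(0.049) == "*"
    assert significance_mark(0.07) == "·"
    assert significance_mark(0.5) == ""
    assert significance_mark(float("nan")) == ""


def test_export_heatmaps_writes_png_and_csv(tmp_path):
    rng = np.random.default_rng(17)
    a = np.corrcoef(rng.normal(size=(30, 4)), rowvar=False)
    m = _cm(a, genes=("g0", "g1", "g2", "g3"), treatment="winner", nucleus="Dm")
    paths = export_heatmaps([m], tmp_path)
    assert len(paths) == 1
    assert paths[0].exists() and paths[0].suffix == ".png"
    csv = tmp_path / "coexpression_winner_Dm.csv"
    back = pd.read_csv(csv, index_col=0)
    assert np.allclose(back.to_numpy(), a)
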