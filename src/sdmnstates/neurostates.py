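"""Neurogenomic states: co-expression matrices and their QAP comparison.

A neurogenomic state is the pattern of pairwise Pearson correlations among
candidate-gene expression levels within one brain nucleus under one social
treatment. States are compared with the quadratic assignment procedure
(QAP) correlation test: the observed statistic is the Pearson correlation
between the two matrices' upper-off-diagonal cells, and the null
distribution is generated by applying one random permutation simultaneously
to the rows and columns of one matrix. A significant positive association
is read as "same state"; units are then grouped into letter classes as
connected components of the similarity graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

logger = logging.getLogger(__name__)

#: largest gene count for which exhaustive permutation is allowed (8! = 40320)
MAX_EXHAUSTIVE_GENES = 8


@dataclass
class CoexpressionMatrix:
    """Gene x gene Pearson matrix for one (treatment, nucleus) cell."""

    treatment: str
    nucleus: str
    genes: tuple[str, ...]
    r: np.ndarray               # symmetric, unit diagonal; NaN = missing
    n: np.ndarray               # per-pair complete-observation counts
    p: np.ndarray               # raw two-sided p per pair (NaN diagonal)
    p_adj: np.ndarray           # BH-adjusted within this matrix's pairs

    def __post_init__(self) -> None:
        g = len(self.genes)
        for name in ("r", "n", "p", "p_adj"):
            a = np.asarray(getattr(self, name))
            if a.shape != (g, g):
                raise ValueError(f"{name} must be {g}x{g}")
        ok = np.isfinite(self.r)
        if np.any(np.abs(self.r[ok]) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def label(self) -> str:
        return f"{self.treatment}:{self.nucleus}"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.genes), columns=list(self.genes))


@dataclass
class QapResult:
    """QAP matrix-correlation test outcome."""

    label_a: str
    label_b: str
    r_obs: float
    p: float
    n_perm: int
    mode: str                   # monte_carlo / exhaustive / undefined
    seed: int | None = None

    @property
    def defined(self) -> bool:
        return self.mode != "undefined"


@dataclass
class StatePartition:
    """Letter classes over units sharing an axis (Figure-style letters)."""

    axis: str
    labels: dict[str, str]
    edges: pd.DataFrame          # unit_a, unit_b, r_obs, p, similar
    intransitive: list[tuple[str, str, str]] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)


# ----------------------------------------------------------------------
# matrix construction


def coexpression_matrix(
    table: pd.DataFrame,
    treatment: str,
    nucleus: str,
    genes: Sequence[str] | None = None,
    min_n: int = 3,
    value_col: str = "relative_expression",
) -> CoexpressionMatrix:
    """Pairwise-complete Pearson matrix for one (treatment, nucleus).

    Per-pair two-sided p-values are BH-adjusted within this matrix's
    gene pairs. A gene with fewer than ``min_n`` observations has its row
    and column marked missing (NaN) and is logged.
    """
    sub = table.loc[(table["treatment"] == treatment) & (table["nucleus"] == nucleus)]
    if genes is None:
        genes = tuple(sorted(sub["gene"].unique()))
    else:
        genes = tuple(genes)
    wide = sub.pivot_table(index="fish_id", columns="gene", values=value_col, aggfunc="first")
    g = len(genes)
    r = np.full((g, g), np.nan)
    n = np.zeros((g, g), dtype=int)
    p = np.full((g, g), np.nan)
    np.fill_diagonal(r, 1.0)
    for i, gene in enumerate(genes):
        cnt = int(wide[gene].notna().sum()) if gene in wide.columns else 0
        n[i, i] = cnt
        if cnt < min_n:
            logger.warning(
                "gene %s has %d < %d observations in (%s, %s); row marked missing",
                gene, cnt, min_n, treatment, nucleus,
            )
    for i, j in combinations(range(g), 2):
        ga, gb = genes[i], genes[j]
        if ga not in wide.columns or gb not in wide.columns:
            continue
        pair = wide[[ga, gb]].dropna()
        n[i, j] = n[j, i] = len(pair)
        if len(pair) < min_n:
            continue
        if pair[ga].std() == 0 or pair[gb].std() == 0:
            continue
        rr, pp = sps.pearsonr(pair[ga], pair[gb])
        r[i, j] = r[j, i] = float(rr)
        p[i, j] = p[j, i] = float(pp)
    # BH within the matrix's upper-triangle pairs
    iu = np.triu_indices(g, k=1)
    raw = p[iu]
    adj_flat = np.full_like(raw, np.nan)
    ok = np.isfinite(raw)
    if ok.any():
        adj_flat[ok] = bh_adjust(raw[ok])
    p_adj = np.full((g, g), np.nan)
    p_adj[iu] = adj_flat
    p_adj.T[iu] = adj_flat
    return CoexpressionMatrix(
        treatment=treatment, nucleus=nucleus, genes=genes, r=r, n=n, p=p, p_adj=p_adj
    )


def coexpression_matrices(
    table: pd.DataFrame,
    treatments: Sequence[str],
    nuclei: Sequence[str],
    genes: Sequence[str] | None = None,
    min_n: int = 3,
) -> dict[tuple[str, str], CoexpressionMatrix]:
    """One matrix per (treatment, nucleus) cell."""
    return {
        (t, k): coexpression_matrix(table, t, k, genes=genes, min_n=min_n)
        for t in treatments
        for k in nuclei
    }


# ----------------------------------------------------------------------
# QAP


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], k=1)]


def _as_r(matrix) -> np.ndarray:
    if isinstance(matrix, CoexpressionMatrix):
        return np.asarray(matrix.r, dtype=float)
    return np.asarray(matrix, dtype=float)


def _label(matrix, default: str) -> str:
    return matrix.label if isinstance(matrix, CoexpressionMatrix) else default


def _check_pair(A, B) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_r(A), _as_r(B)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if isinstance(A, CoexpressionMatrix) and isinstance(B, CoexpressionMatrix):
        if A.genes != B.genes:
            raise ValueError("matrices must share an identical, ordered gene set")
    if np.any(~np.isfinite(_upper(a))) or np.any(~np.isfinite(_upper(b))):
        raise ValueError("missing cells among compared pairs; QAP undefined")
    return a, b


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.corrcoef(u, v)[0, 1])


def _perm_cell_values(b: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Upper-triangle cells of b after simultaneous row+column permutation.

    ``perms`` is (m, g); returns (m, g(g-1)/2). Because b is symmetric, the
    permuted cell (i, j) is b[perm[i], perm[j]].
    """
    g = b.shape[0]
    iu, ju = np.triu_indices(g, k=1)
    rows = perms[:, iu]
    cols = perms[:, ju]
    return b[rows, cols]


def _perm_correlations(ua: np.ndarray, vals: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of vals with ua (row SDs are
    permutation-invariant, so they never vanish unless ua's does)."""
    uc = ua - ua.mean()
    vc = vals - vals.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(uc) * np.linalg.norm(vc, axis=1)
    return (vc @ uc) / denom


_TIE_EPS = 1e-12


def qap_correlation(
    A,
    B,
    n_perm: int = 5000,
    seed: int | None = None,
    mode: str = "auto",
    tail: str = "greater",
) -> QapResult:
    """QAP correlation test between two symmetric matrices.

    ``r_obs`` is the Pearson correlation over the g(g-1)/2 upper
    off-diagonal cells. The null applies one random permutation to B's
    rows and columns simultaneously. In Monte-Carlo mode the add-one
    estimator ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)`` is used (the
    observed arrangement counts as one permutation), so p is never 0; when
    g! <= n_perm (mode="auto") all permutations are enumerated instead and
    p is the exact fraction. ``tail="greater"`` tests positive association
    (matrix similarity); ``tail="two-sided"`` compares |r|.
    """
    a, b = _check_pair(A, B)
    g = a.shape[0]
    ua = _upper(a)
    if np.ptp(ua) == 0 or np.ptp(_upper(b)) == 0:
        logger.warning("QAP undefined: zero off-diagonal variance")
        return QapResult(_label(A, "A"), _label(B, "B"), math.nan, math.nan,
                         0, "undefined", seed)
    if mode == "auto":
        mode = "exhaustive" if math.factorial(g) <= n_perm else "monte_carlo"
    if mode == "exhaustive":
        return qap_exhaustive(A, B, tail=tail)
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    ub = _upper(b)
    r_obs = _pearson(ua, ub)
    stat_obs = abs(r_obs) if tail == "two-sided" else r_obs
    perms = rng.permuted(
        np.broadcast_to(np.arange(g), (n_perm, g)).copy(), axis=1
    )
    r_perm = _perm_correlations(ua, _perm_cell_values(b, perms))
    stat = np.abs(r_perm) if tail == "two-sided" else r_perm
    count = int(np.sum(stat >= stat_obs - _TIE_EPS))
    p = (1.0 + count) / (1.0 + n_perm)
    return QapResult(_label(A, "A"), _label(B, "B"), r_obs, p, n_perm, "monte_carlo", seed)


def qap_exhaustive(A, B, tail: str = "greater") -> QapResult:
    """Exact QAP p by enumerating all g! simultaneous row+column
    permutations of B; refused above g = 8."""
    a, b = _check_pair(A, B)
    g = a.shape[0]
    if g > MAX_EXHAUSTIVE_GENES:
        raise ValueError(f"exhaustive QAP refused for g={g} > {MAX_EXHAUSTIVE_GENES}")
    ua, ub = _upper(a), _upper(b)
    if np.ptp(ua) == 0 or np.ptp(ub) == 0:
        logger.warning("QAP undefined: zero off-diagonal variance")
        return QapResult(_label(A, "A"), _label(B, "B"), math.nan, math.nan,
                         0, "undefined", None)
    r_obs = _pearson(ua, ub)
    stat_obs = abs(r_obs) if tail == "two-sided" else r_obs
    perms = np.array(list(permutations(range(g))), dtype=np.intp)
    r_perm = _perm_correlations(ua, _perm_cell_values(b, perms))
    stat = np.abs(r_perm) if tail == "two-sided" else r_perm
    count = int(np.sum(stat >= stat_obs - _TIE_EPS))
    total = len(perms)
    return QapResult(_label(A, "A"), _label(B, "B"), r_obs, count / total,
                     total, "exhaustive", None)


# ----------------------------------------------------------------------
# partitioning


def partition_states(
    matrices: Mapping[str, CoexpressionMatrix] | Sequence[CoexpressionMatrix],
    axis: str,
    alpha: float = 0.05,
    n_perm: int = 5000,
    seed: int | None = None,
    tail: str = "greater",
) -> StatePartition:
    """Group units into letter classes by pairwise QAP similarity.

    ``axis`` names the varying unit: ``"treatment"`` (matrices from one
    nucleus across treatments) or ``"nucleus"`` (one treatment across
    nuclei). A similarity edge joins two units when the QAP p-value is
    below ``alpha`` (significant positive association = same state, the
    decision rule of the source analysis; note that reading a
    NON-significant test as evidence of difference conflates absence of
    evidence with evidence of absence — callers should treat distinct
    letters accordingly). Letter classes are the connected components of
    the similarity graph; intransitive triads (a~b, b~c but not a~c) are
    logged and reported.

    A unit whose own matrix has zero off-diagonal variance (or any
    non-finite compared cell) cannot enter a QAP test; such units are
    flagged, excluded from components and labelled ``"?"``.
    """
    import networkx as nx

    if isinstance(matrices, Mapping):
        mats = list(matrices.values())
    else:
        mats = list(matrices)
    units = [getattr(m, axis) for m in mats]
    if len(set(units)) != len(units):
        raise ValueError(f"units along axis {axis!r} must be distinct, got {units}")
    by_unit = dict(zip(units, mats))
    flagged: set[str] = set()
    for u, m in by_unit.items():
        off = _upper(_as_r(m))
        if np.any(~np.isfinite(off)) or np.ptp(off) == 0:
            logger.warning("unit %s has a degenerate matrix; flagged '?'", u)
            flagged.add(u)
    edge_rows = []
    graph = nx.Graph()
    graph.add_nodes_from(units)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = iter(ss.generate_state(len(units) * (len(units) - 1) // 2))
    for ua, ub in combinations(units, 2):
        pair_seed = int(next(child_seeds)) % (2**31)
        if ua in flagged or ub in flagged:
            edge_rows.append((ua, ub, math.nan, math.nan, "undefined", False))
            continue
        res = qap_correlation(
            by_unit[ua], by_unit[ub], n_perm=n_perm, seed=pair_seed, tail=tail
        )
        similar = res.defined and res.p < alpha
        if similar:
            graph.add_edge(ua, ub)
        edge_rows.append((ua, ub, res.r_obs, res.p, res.mode, similar))
    for u in flagged:
        graph.remove_node(u)
    comps = sorted(
        (sorted(c, key=units.index) for c in nx.connected_components(graph)),
        key=lambda c: units.index(c[0]),
    )
    labels = {}
    for letter_i, comp in enumerate(comps):
        letter = chr(ord("A") + letter_i)
        for u in comp:
            labels[u] = letter
    for u in flagged:
        labels[u] = "?"
    edges = pd.DataFrame(
        edge_rows, columns=["unit_a", "unit_b", "r_obs", "p", "mode", "similar"]
    )
    sim = {(r.unit_a, r.unit_b) for r in edges.itertuples() if r.similar}
    sim |= {(b, a) for a, b in sim}
    intransitive = []
    for x, y, z in combinations([u for u in units if u not in flagged], 3):
        trio = [(x, y), (y, z), (x, z)]
        n_sim = sum(pair in sim for pair in trio)
        if n_sim == 2:
            intransitive.append((x, y, z))
            logger.warning("intransitive similarity triad along %s: %s", axis, (x, y, z))
    return StatePartition(
        axis=axis, labels=labels, edges=edges,
        intransitive=intransitive, flagged=sorted(flagged),
    )


# ----------------------------------------------------------------------
# export


def significance_mark(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "·"
    return ""


def export_heatmaps(
    matrices: Mapping[tuple[str, str], CoexpressionMatrix] | Iterable[CoexpressionMatrix],
    out_dir: str | Path,
    fmt: str = "png",
    write_csv: bool = True,
) -> list[Path]:
    """One heatmap per matrix: diverging blue(-1)-red(+1) scale, adjusted-p
    significance marks, missing cells in neutral grey. Also writes each
    matrix as CSV. Returns the written image paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    if isinstance(matrices, Mapping):
        mats = list(matrices.values())
    else:
        mats = list(matrices)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for m in mats:
        g = len(m.genes)
        annot = np.empty((g, g), dtype=object)
        for i in range(g):
            for j in range(g):
                if i == j:
                    annot[i, j] = ""
                elif not np.isfinite(m.r[i, j]):
                    annot[i, j] = "n/a"
                else:
                    annot[i, j] = f"{m.r[i, j]:.2f}{significance_mark(m.p_adj[i, j])}"
        fig, ax = plt.subplots(figsize=(5.2, 4.4))
        cmap = plt.get_cmap("RdBu_r").copy()
        cmap.set_bad("0.85")
        sns.heatmap(
            m.frame(), vmin=-1.0, vmax=1.0, cmap=cmap, annot=annot, fmt="",
            annot_kws={"fontsize": 7}, square=True, linewidths=0.5,
            cbar_kws={"label": "Pearson r"}, ax=ax,
        )
        ax.set_title(f"{m.treatment} / {m.nucleus}")
        stem = f"coexpression_{m.treatment}_{m.nucleus}"
        path = out_dir / f"{stem}.{fmt}"
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
        if write_csv:
            m.frame().to_csv(out_dir / f"{stem}.csv")
    return written
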