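"""Univariate inference for behavior, cortisol and gene expression.

Behavior variables (latency to first bite, fight resolution time, last-five-
minute display frequencies) are compared with pooled-variance t-tests.
Gene expression is analysed per gene with a linear mixed model — fixed
effects treatment, brain nucleus and their interaction; random intercepts
for subject (crossing nuclei within fish) and for real-opponent dyad — and
planned pairwise treatment contrasts within each nucleus reported as
``z = estimate/SE`` with normal-theory p-values (unadjusted) and Cohen's
effect sizes (d_z for the dyad-paired winner-loser contrast, d_s
otherwise). Cortisol is compared across treatments with a Welch ANOVA and
Tukey HSD. Correlation screens use Pearson's r with Benjamini-Hochberg
adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf

from .design import NUCLEI, TREATMENTS

logger = logging.getLogger(__name__)

AGGRESSIVE_ACTS = ("bite", "chase", "strike")
SUBMISSIVE_ACTS = ("freeze", "flee")

LAST_WINDOW_S = 300.0  # frequencies counted over the final five minutes


# ----------------------------------------------------------------------
# containers


@dataclass
class BehaviorSummary:
    fish_id: str
    latency_first_bite_s: float
    latency_censored: bool
    resolution_time_s: float | None
    aggressive_freq_last5: int
    submissive_freq_last5: int


@dataclass
class TestResult:
    """A t or F test: statistic, degrees of freedom, p, method tag."""

    statistic: float
    df: float | tuple[float, float]
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p out of range: {self.p}")


@dataclass
class CohensD:
    d: float
    d_type: str          # "d_s" (independent) or "d_z" (paired differences)
    magnitude: str       # negligible / small / medium / large
    n: int


def _magnitude(d: float) -> str:
    a = abs(d)
    if a > 0.8:
        return "large"
    if a > 0.5:
        return "medium"
    if a > 0.2:
        return "small"
    return "negligible"


# ----------------------------------------------------------------------
# behavior


def summarize_behavior(
    events: pd.DataFrame,
    session_length_s: float,
    resolution_time_s: float | None = None,
    fish_id: str | None = None,
) -> BehaviorSummary:
    """Summaries for one fish's event stream (columns time_s, behavior).

    Latency is the time of the first bite (censored at session length when
    no bite occurred); display frequencies are counted over the final five
    minutes of the session only.
    """
    t = events["time_s"].to_numpy(dtype=float)
    b = events["behavior"].to_numpy(dtype=object)
    if len(t) and (t.min() < 0 or t.max() > session_length_s):
        raise ValueError("event times outside [0, session length]")
    bites = t[b == "bite"]
    censored = len(bites) == 0
    latency = session_length_s if censored else float(bites.min())
    w0 = session_length_s - LAST_WINDOW_S
    in_win = t >= w0
    agg = int(np.isin(b[in_win], AGGRESSIVE_ACTS).sum())
    sub = int(np.isin(b[in_win], SUBMISSIVE_ACTS).sum())
    return BehaviorSummary(
        fish_id=fish_id or "",
        latency_first_bite_s=latency,
        latency_censored=censored,
        resolution_time_s=resolution_time_s,
        aggressive_freq_last5=agg,
        submissive_freq_last5=sub,
    )


def summarize_behavior_table(
    events: pd.DataFrame,
    fish: pd.DataFrame,
    resolution: pd.DataFrame,
    session_length_s: float,
) -> pd.DataFrame:
    """Per-fish behavior summaries for a whole study."""
    res_map = resolution.set_index("fish_id")["resolution_time_s"].to_dict()
    rows = []
    for r in fish.itertuples():
        ev = events.loc[events["fish_id"] == r.fish_id]
        rt = res_map.get(r.fish_id, np.nan)
        s = summarize_behavior(
            ev, session_length_s,
            None if (rt is None or (isinstance(rt, float) and math.isnan(rt))) else float(rt),
            fish_id=r.fish_id,
        )
        rows.append(
            (r.fish_id, r.treatment, s.latency_first_bite_s, s.latency_censored,
             np.nan if s.resolution_time_s is None else s.resolution_time_s,
             s.aggressive_freq_last5, s.submissive_freq_last5)
        )
    return pd.DataFrame(
        rows,
        columns=["fish_id", "treatment", "latency_first_bite_s", "latency_censored",
                 "resolution_time_s", "aggressive_freq_last5", "submissive_freq_last5"],
    )


# ----------------------------------------------------------------------
# elementary tests


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pooled-variance two-sample t-test (integer df = n_x + n_y - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0.0:
        raise ValueError("zero pooled variance: t-test undefined")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    df = nx + ny - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=df, p=float(p), method="student-t")


def cohens_d(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> CohensD:
    """Cohen's d_s (pooled SD) or d_z (SD of paired differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        diff = x - y
        diff = diff[np.isfinite(diff)]
        if len(diff) < 2:
            raise ValueError("paired d_z needs >= 2 complete pairs")
        sd = diff.std(ddof=1)
        if sd == 0.0:
            raise ValueError("zero SD of differences: d_z undefined")
        d = diff.mean() / sd
        return CohensD(float(d), "d_z", _magnitude(d), len(diff))
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("d_s needs n >= 2 per group")
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0.0:
        raise ValueError("zero pooled SD: d_s undefined")
    d = (x.mean() - y.mean()) / math.sqrt(sp2)
    return CohensD(float(d), "d_s", _magnitude(d), nx + ny)


def welch_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA with Welch's correction for heteroscedasticity."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    for g in gs:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
        if g.var(ddof=1) == 0.0:
            raise ValueError("zero-variance group: Welch ANOVA undefined")
    k = len(gs)
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    w = n / v
    wsum = w.sum()
    mw = (w * m).sum() / wsum
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    tail = ((1.0 - w / wsum) ** 2 / (n - 1.0)).sum()
    b = 1.0 + 2.0 * (k - 2.0) / (k * k - 1.0) * tail
    f = a / b
    df1 = k - 1.0
    df2 = (k * k - 1.0) / (3.0 * tail)
    p = sps.f.sf(f, df1, df2)
    return TestResult(statistic=float(f), df=(df1, float(df2)), p=float(p), method="welch-anova")


def tukey_hsd(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range p-values)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(gs))]
    res = sps.tukey_hsd(*gs)
    rows = []
    for i, j in combinations(range(len(gs)), 2):
        rows.append(
            (labels[i], labels[j], float(gs[i].mean() - gs[j].mean()),
             float(res.statistic[i, j]), float(res.pvalue[i, j]))
        )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "statistic", "p"])


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def corr_with_bh(
    data: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson correlations for the given column pairs, BH-adjusted.

    Pairs with fewer than ``min_n`` complete observations are omitted and
    logged. Returns columns (var_a, var_b, n, r, p, p_adj).
    """
    rows = []
    for a, b in pairs:
        sub = data[[a, b]].dropna()
        if len(sub) < min_n:
            logger.warning("correlation %s~%s omitted: only %d complete pairs", a, b, len(sub))
            continue
        r, p = sps.pearsonr(sub[a], sub[b])
        rows.append((a, b, len(sub), float(r), float(p)))
    out = pd.DataFrame(rows, columns=["var_a", "var_b", "n", "r", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


# ----------------------------------------------------------------------
# mixed-model planned contrasts


@dataclass
class ExpressionLMM:
    """Mixed model for one gene's expression across treatments and nuclei.

    ``value ~ treatment * nucleus`` with a random intercept per subject
    (shared by all five nuclei of a fish) and one per real-opponent dyad
    (shared by a winner and its loser; absent for mirror/control fish).
    Expression enters on the natural-log scale by default, since qPCR
    ratios are multiplicative.

    Build with :meth:`from_expression_table`, then call :meth:`fit`.
    """

    data: pd.DataFrame
    gene: str = ""
    treatments: tuple[str, ...] = TREATMENTS
    nuclei: tuple[str, ...] = NUCLEI

    @classmethod
    def from_expression_table(
        cls,
        table: pd.DataFrame,
        gene: str,
        log_scale: bool = True,
        treatments: tuple[str, ...] = TREATMENTS,
        nuclei: tuple[str, ...] = NUCLEI,
    ) -> "ExpressionLMM":
        sub = table.loc[table["gene"] == gene].copy()
        if sub.empty:
            raise ValueError(f"no rows for gene {gene!r}")
        if log_scale:
            if (sub["relative_expression"] <= 0).any():
                raise ValueError("relative_expression must be positive for log scale")
            sub["value"] = np.log(sub["relative_expression"].to_numpy())
        else:
            sub["value"] = sub["relative_expression"].to_numpy()
        return cls(data=sub.reset_index(drop=True), gene=gene,
                   treatments=treatments, nuclei=nuclei)

    # -- fitting -------------------------------------------------------
    def fit(self, reml: bool = True, method: str = "lbfgs") -> "ExpressionLMMResults":
        df = self.data.copy()
        real = sorted(
            df.loc[df["treatment"].isin(["winner", "loser"]), "dyad_id"].unique()
        )
        dyad_cols = []
        for j, d in enumerate(real):
            col = f"_dyad_{j}"
            df[col] = (df["dyad_id"] == d).astype(float)
            dyad_cols.append(col)
        vc = {"subject": "0 + C(fish_id)"}
        if dyad_cols:
            vc["dyad"] = "0 + " + " + ".join(dyad_cols)
        formula = (
            f"value ~ C(treatment, levels={list(self.treatments)!r}) "
            f"* C(nucleus, levels={list(self.nuclei)!r})"
        )
        res, dropped = self._fit_with_vc(formula, df, vc, reml, method)
        # containment df counts complete dyads (both roles still present)
        roles = df.loc[df["treatment"].isin(["winner", "loser"])].groupby("dyad_id")[
            "treatment"
        ].nunique()
        n_complete = int((roles == 2).sum())
        return ExpressionLMMResults(
            model=self, _res=res, n_real_dyads=n_complete, dropped_components=dropped
        )

    @staticmethod
    def _fit_with_vc(formula, df, vc, reml, method, tol=1e-8):
        """Fit; if a variance component collapses to ~0, refit without it."""
        import warnings

        dropped: list[str] = []
        while True:
            md = smf.mixedlm(formula, df, groups=np.ones(len(df)), vc_formula=dict(vc))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = md.fit(reml=reml, method=method)
            names = list(md.exog_vc.names)
            vcomp = np.asarray(res.vcomp, dtype=float)
            near_zero = [n for n, v in zip(names, vcomp) if v < tol * res.scale]
            if not near_zero or len(vc) <= 1:
                return res, dropped
            drop = near_zero[0]
            logger.info("variance component %r ~ 0; refitting without it", drop)
            dropped.append(drop)
            vc = {k: v for k, v in vc.items() if k != drop}
            if not vc:
                return res, dropped


@dataclass
class ExpressionLMMResults:
    """Fitted mixed model: omnibus tests, planned contrasts, summary."""

    model: ExpressionLMM
    _res: object
    n_real_dyads: int
    dropped_components: list[str] = field(default_factory=list)

    # -- internals -----------------------------------------------------
    @property
    def _fe(self) -> np.ndarray:
        return np.asarray(self._res.fe_params, dtype=float)

    @property
    def _cov_fe(self) -> np.ndarray:
        k = len(self._fe)
        return np.asarray(self._res.cov_params())[:k, :k]

    @property
    def _design_info(self):
        return self._res.model.data.design_info

    def _cell_row(self, treatment: str, nucleus: str) -> np.ndarray:
        (m,) = build_design_matrices(
            [self._design_info], {"treatment": [treatment], "nucleus": [nucleus]}
        )
        return np.asarray(m)[0]

    @property
    def variance_components(self) -> dict[str, float]:
        names = list(self._res.model.exog_vc.names)
        out = dict(zip(names, np.asarray(self._res.vcomp, dtype=float)))
        out["residual"] = float(self._res.scale)
        return out

    # -- omnibus -------------------------------------------------------
    def omnibus(self) -> pd.DataFrame:
        """Wald F tests for treatment, nucleus and their interaction.

        Denominator df follow a containment convention: the
        between-subject treatment factor is tested against the
        real-opponent dyad stratum (n_dyads - n_treatments); within-subject
        terms against n_obs - rank(X) - n_subjects.
        """
        di = self._design_info
        n_obs = len(self.model.data)
        n_subj = self.model.data["fish_id"].nunique()
        rank_x = len(self._fe)
        den_within = max(n_obs - rank_x - n_subj, 1)
        den_between = max(self.n_real_dyads - len(self.model.treatments), 1)
        rows = []
        term_map = {
            "treatment": den_between,
            "nucleus": den_within,
            "interaction": den_within,
        }
        slices = dict(di.term_name_slices)
        names = [n for n in slices if n != "Intercept"]
        for label, name in zip(["treatment", "nucleus", "interaction"], names):
            sl = slices[name]
            idx = np.arange(sl.start, sl.stop)
            L = np.zeros((len(idx), rank_x))
            L[np.arange(len(idx)), idx] = 1.0
            est = L @ self._fe
            cov = L @ self._cov_fe @ L.T
            chi2 = float(est @ np.linalg.solve(cov, est))
            df1 = len(idx)
            df2 = term_map[label]
            f = chi2 / df1
            p = float(sps.f.sf(f, df1, df2))
            rows.append((label, f, df1, df2, p))
        return pd.DataFrame(rows, columns=["term", "F", "df1", "df2", "p"])

    # -- planned contrasts ---------------------------------------------
    def contrasts(self) -> pd.DataFrame:
        """All pairwise treatment contrasts within each nucleus.

        z = estimate/SE with a normal reference (unadjusted p); Cohen's
        d_z (dyad-paired) for winner-loser, d_s otherwise, computed from
        the modelled (log-scale) cell data.
        """
        rows = []
        for nuc in self.model.nuclei:
            cell = {t: self._cell_row(t, nuc) for t in self.model.treatments}
            for t1, t2 in combinations(self.model.treatments, 2):
                L = cell[t1] - cell[t2]
                est = float(L @ self._fe)
                se = float(math.sqrt(L @ self._cov_fe @ L))
                z = est / se
                p = 2.0 * sps.norm.sf(abs(z))
                d = self._effect_size(t1, t2, nuc)
                rows.append(
                    (self.model.gene, nuc, f"{t1}-{t2}", est, se, z, float(p),
                     d.d if d else np.nan, d.d_type if d else "undefined",
                     d.magnitude if d else "undefined")
                )
        return pd.DataFrame(
            rows,
            columns=["gene", "nucleus", "pair", "estimate", "SE", "z", "p",
                     "d", "d_type", "magnitude"],
        )

    def _effect_size(self, t1: str, t2: str, nucleus: str) -> CohensD | None:
        df = self.model.data
        sub = df.loc[df["nucleus"] == nucleus]
        a = sub.loc[sub["treatment"] == t1]
        b = sub.loc[sub["treatment"] == t2]
        try:
            if {t1, t2} == {"winner", "loser"}:
                merged = a.set_index("dyad_id")["value"].to_frame("x").join(
                    b.set_index("dyad_id")["value"].to_frame("y"), how="inner"
                )
                return cohens_d(merged["x"], merged["y"], paired=True)
            return cohens_d(a["value"], b["value"], paired=False)
        except ValueError as exc:
            logger.warning("effect size %s-%s in %s undefined: %s", t1, t2, nucleus, exc)
            return None

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Expression mixed model - gene {self.model.gene!r}",
            f"  observations: {len(self.model.data)}, "
            f"subjects: {self.model.data['fish_id'].nunique()}, "
            f"real-opponent dyads: {self.n_real_dyads}",
            "  variance components: "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.variance_components.items()),
        ]
        if self.dropped_components:
            lines.append(f"  dropped near-zero components: {self.dropped_components}")
        lines.append("")
        lines.append(self.omnibus().to_string(index=False))
        lines.append("")
        con = self.contrasts()
        lines.append(con.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def fit_lmm_contrasts(
    table: pd.DataFrame,
    gene: str,
    log_scale: bool = True,
    reml: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: returns (contrasts, omnibus) for one gene."""
    res = ExpressionLMM.from_expression_table(table, gene, log_scale=log_scale).fit(reml=reml)
    return res.contrasts(), res.omnibus()
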