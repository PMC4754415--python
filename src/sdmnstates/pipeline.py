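"""Configuration, validation and the end-to-end pipeline driver.

Stages: simulate (or load) -> quantify amplification curves -> screen
outliers -> univariate statistics (behavior, contrasts, cortisol,
correlation screens) -> neurogenomic states (co-expression, QAP,
partitions, heatmaps). Every invocation writes into a fresh run directory
with a JSON manifest recording the configuration hash and seeds, and
reruns with the same configuration reproduce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _pkg_version
from .design import EffectSpec, StudyDesign, NUCLEI, TARGET_GENES, TREATMENTS
from .qpcr import normalize_expression, quantify_curves
from .screening import screen_dataset
from .neurostates import coexpression_matrices, export_heatmaps, partition_states
from .stats import (
    corr_with_bh,
    fit_lmm_contrasts,
    summarize_behavior_table,
    tukey_hsd,
    two_sample_t,
    welch_anova,
)
from .synthdata import simulate_study

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"  # stable text representation for reproducible tables


@dataclass
class PipelineConfig:
    """Everything one run needs; serialisable to/from YAML."""

    mode: str = "simulate"                  # "simulate" or "load"
    seed: int | None = 0
    alpha: float = 0.05
    n_perm: int = 5000
    qap_tail: str = "greater"               # or "two-sided"
    log_scale: bool = True
    max_outlier_frac: float = 0.2
    heatmaps: bool = True
    n_per_treatment: dict[str, int] = field(
        default_factory=lambda: {"control": 10, "mirror": 12, "winner": 12, "loser": 11}
    )
    interaction_minutes: float = 30.0
    paths: dict[str, str] = field(default_factory=dict)   # load mode inputs

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"mode must be simulate/load, got {self.mode!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.qap_tail not in ("greater", "two-sided"):
            raise ValueError(f"qap_tail must be greater/two-sided, got {self.qap_tail!r}")
        if not (0.0 < self.max_outlier_frac < 1.0):
            raise ValueError("max_outlier_frac must be in (0, 1)")
        if self.seed is None and self.mode == "simulate":
            raise ValueError("seed is mandatory in simulate mode")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def sha256(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()

    def design(self) -> StudyDesign:
        return StudyDesign(
            n_per_treatment=dict(self.n_per_treatment),
            interaction_minutes=self.interaction_minutes,
        )


# ----------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [f"ERROR: {e}" for e in self.errors]
        lines += [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "all checks passed"


_SCHEMAS: dict[str, list[str]] = {
    "fish": ["fish_id", "dyad_id", "treatment", "standard_length_cm", "body_mass_g"],
    "behavior": ["fish_id", "time_s", "behavior"],
    "cortisol": ["fish_id", "treatment", "cortisol_ng_ml"],
    "curves": ["reaction_id", "fish_id", "nucleus", "gene", "cycle", "fluorescence"],
    "expression": ["fish_id", "nucleus", "gene", "relative_expression"],
}


def validate_tables(paths: Mapping[str, str | Path]) -> ValidationReport:
    """Schema, range and referential checks over the declared input files."""
    rep = ValidationReport()
    tables: dict[str, pd.DataFrame] = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            rep.errors.append(f"{name}: file not found: {path}")
            continue
        df = pd.read_csv(path)
        tables[name] = df
        required = _SCHEMAS.get(name)
        if required:
            missing = [c for c in required if c not in df.columns]
            if missing:
                rep.errors.append(f"{name}: missing columns {missing} in {path}")
    fish = tables.get("fish")
    if fish is not None and "fish_id" in fish.columns:
        ids = set(fish["fish_id"])
        if fish["fish_id"].duplicated().any():
            rep.errors.append("fish: duplicated fish_id values")
        for name in ("behavior", "cortisol", "curves", "expression"):
            df = tables.get(name)
            if df is not None and "fish_id" in df.columns:
                orphans = sorted(set(df["fish_id"]) - ids)
                if orphans:
                    rep.errors.append(
                        f"{name}: fish_id values absent from fish.csv: {orphans[:5]}"
                    )
        if {"dyad_id", "treatment"}.issubset(fish.columns):
            real = fish.loc[fish["treatment"].isin(["winner", "loser"])]
            for dyad, grp in real.groupby("dyad_id"):
                roles = sorted(grp["treatment"])
                if roles not in (["loser", "winner"], ["winner"], ["loser"]):
                    rep.errors.append(
                        f"fish: dyad {dyad} has invalid composition {roles}"
                    )
                elif len(roles) == 1:
                    rep.warnings.append(
                        f"fish: dyad {dyad} incomplete ({roles[0]} only; dropout?)"
                    )
    cur = tables.get("curves")
    if cur is not None and "fluorescence" in cur.columns:
        if (cur["fluorescence"] < 0).any():
            rep.warnings.append("curves: negative fluorescence values")
    beh = tables.get("behavior")
    if beh is not None and "time_s" in beh.columns and (beh["time_s"] < 0).any():
        rep.errors.append("behavior: negative event times")
    expr = tables.get("expression")
    if expr is not None and "relative_expression" in expr.columns:
        if (expr["relative_expression"] <= 0).any():
            rep.errors.append("expression: non-positive relative_expression")
    return rep


# ----------------------------------------------------------------------
# driver


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> Path:
    """Execute all stages into a fresh run directory; returns its path."""
    run_dir = Path(run_dir)
    if run_dir.exists():
        raise FileExistsError(f"run directory already exists: {run_dir}")
    run_dir.mkdir(parents=True)
    (run_dir / "data").mkdir()
    design = config.design()
    outputs: list[str] = []

    # -- stage 1: simulate or load ------------------------------------
    if config.mode == "simulate":
        ds = simulate_study(design=design, seed=int(config.seed))
        ds.to_dir(run_dir / "data")
        fish, behavior, resolution = ds.fish, ds.behavior, ds.resolution
        cortisol, curves = ds.cortisol, ds.curves
        expression_pre = None
        outputs += ["data/fish.csv", "data/behavior.csv", "data/resolution.csv",
                    "data/cortisol.csv", "data/truth.csv", "data/curves.csv"]
    else:
        rep = validate_tables(config.paths)
        if not rep.ok:
            raise ValueError(f"input validation failed:\n{rep}")
        fish = pd.read_csv(config.paths["fish"])
        behavior = pd.read_csv(config.paths["behavior"]) if "behavior" in config.paths else None
        resolution = (
            pd.read_csv(config.paths["resolution"]) if "resolution" in config.paths else None
        )
        cortisol = pd.read_csv(config.paths["cortisol"]) if "cortisol" in config.paths else None
        curves = pd.read_csv(config.paths["curves"]) if "curves" in config.paths else None
        expression_pre = (
            pd.read_csv(config.paths["expression"]) if "expression" in config.paths else None
        )
        if curves is None and expression_pre is None:
            raise ValueError("load mode needs either 'curves' or 'expression' input")

    # -- stage 2: quantify --------------------------------------------
    if expression_pre is not None:
        expression = expression_pre
        if "treatment" not in expression.columns:
            expression = expression.merge(
                fish[["fish_id", "dyad_id", "treatment"]], on="fish_id", how="left"
            )
    else:
        measurements = quantify_curves(curves)
        _write(measurements, run_dir / "qc_report.csv")
        outputs.append("qc_report.csv")
        expression = normalize_expression(
            measurements, reference_gene=design.reference_gene, fish_meta=fish
        )
    _write(expression, run_dir / "expression.csv")
    outputs.append("expression.csv")

    # -- stage 3: screening -------------------------------------------
    screened, screen_log = screen_dataset(
        expression, alpha=config.alpha, max_frac=config.max_outlier_frac
    )
    _write(screened, run_dir / "expression_screened.csv")
    _write(screen_log, run_dir / "screening_log.csv")
    outputs += ["expression_screened.csv", "screening_log.csv"]
    if cortisol is not None:
        cort_screened, cort_log = screen_dataset(
            cortisol, alpha=config.alpha, max_frac=config.max_outlier_frac,
            value_col="cortisol_ng_ml", group_cols=["treatment"],
        )
        _write(cort_screened, run_dir / "cortisol_screened.csv")
        _write(cort_log, run_dir / "cortisol_screening_log.csv")
        outputs += ["cortisol_screened.csv", "cortisol_screening_log.csv"]
    else:
        cort_screened = None

    # -- stage 4: univariate statistics --------------------------------
    genes = [g for g in design.genes if g in set(screened["gene"])]
    con_frames, omni_frames = [], []
    for gene in genes:
        con, omni = fit_lmm_contrasts(screened, gene, log_scale=config.log_scale)
        con_frames.append(con)
        omni.insert(0, "gene", gene)
        omni_frames.append(omni)
    _write(pd.concat(con_frames, ignore_index=True), run_dir / "contrasts.csv")
    _write(pd.concat(omni_frames, ignore_index=True), run_dir / "omnibus.csv")
    outputs += ["contrasts.csv", "omnibus.csv"]

    summary = None
    if behavior is not None and resolution is not None:
        summary = summarize_behavior_table(
            behavior, fish, resolution, design.session_seconds
        )
        _write(summary, run_dir / "behavior_summary.csv")
        _write(
            behavior_tests(summary, fish, design.session_seconds),
            run_dir / "behavior_tests.csv",
        )
        outputs += ["behavior_summary.csv", "behavior_tests.csv"]

    if cort_screened is not None:
        _write(cortisol_tests(cort_screened), run_dir / "cortisol_tests.csv")
        outputs.append("cortisol_tests.csv")

    if summary is not None and cort_screened is not None:
        corr = association_screens(summary, cort_screened, screened)
        _write(corr, run_dir / "correlations.csv")
        outputs.append("correlations.csv")

    # -- stage 5: neurogenomic states ----------------------------------
    mats = coexpression_matrices(screened, design.treatments, design.nuclei,
                                 genes=design.genes)
    qap_rows, part_rows = [], []
    seed0 = int(config.seed or 0)
    for k in design.nuclei:
        part = partition_states(
            {t: mats[(t, k)] for t in design.treatments}, axis="treatment",
            alpha=config.alpha, n_perm=config.n_perm,
            seed=seed0 + hash_stable(("nuc", k)), tail=config.qap_tail,
        )
        e = part.edges.copy()
        e.insert(0, "within_nucleus", k)
        e.insert(0, "axis", "treatment")
        qap_rows.append(e)
        for unit, letter in part.labels.items():
            part_rows.append(("treatment", k, unit, letter))
    for t in design.treatments:
        part = partition_states(
            {k: mats[(t, k)] for k in design.nuclei}, axis="nucleus",
            alpha=config.alpha, n_perm=config.n_perm,
            seed=seed0 + hash_stable(("treat", t)), tail=config.qap_tail,
        )
        e = part.edges.copy()
        e.insert(0, "within_nucleus", t)
        e.insert(0, "axis", "nucleus")
        qap_rows.append(e)
        for unit, letter in part.labels.items():
            part_rows.append(("nucleus", t, unit, letter))
    _write(pd.concat(qap_rows, ignore_index=True), run_dir / "qap_results.csv")
    _write(
        pd.DataFrame(part_rows, columns=["axis", "within", "unit", "letter"]),
        run_dir / "partitions.csv",
    )
    outputs += ["qap_results.csv", "partitions.csv"]
    heat_dir = run_dir / "heatmaps"
    if config.heatmaps:
        export_heatmaps(mats, heat_dir)
        outputs.append("heatmaps/")
    else:
        heat_dir.mkdir()
        for (t, k), m in sorted(mats.items()):
            m.frame().to_csv(heat_dir / f"coexpression_{t}_{k}.csv")
        outputs.append("heatmaps/")

    # -- manifest -------------------------------------------------------
    manifest = {
        "package_version": _pkg_version,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "n_fish": int(fish["fish_id"].nunique()),
        "n_coexpression_matrices": len(mats),
        "outputs": outputs,
    }
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return run_dir


def hash_stable(key) -> int:
    """Deterministic small int from a tuple of strings (process-stable)."""
    h = hashlib.sha256(repr(key).encode()).digest()
    return int.from_bytes(h[:4], "big") % 1_000_000


# ----------------------------------------------------------------------
# stage helpers


def behavior_tests(
    summary: pd.DataFrame, fish: pd.DataFrame, session_length_s: float
) -> pd.DataFrame:
    """Real-opponent vs mirror comparisons of the behavior variables.

    Fight-level units: one latency/resolution per real dyad (earliest first
    bite; shared resolution), one per mirror fish (mirror fights never
    resolve, so their resolution is censored at the session length). Overt
    aggression compares last-five-minute aggressive acts of winners (the
    only real-opponent fish still attacking post-resolution) with
    mirror-fighters.
    """
    s = summary.merge(fish[["fish_id", "dyad_id"]], on="fish_id", how="left")
    real = s.loc[s["treatment"].isin(["winner", "loser"])]
    mirror = s.loc[s["treatment"] == "mirror"]
    lat_real = real.groupby("dyad_id")["latency_first_bite_s"].min()
    lat_mirror = mirror["latency_first_bite_s"]
    res_real = real.groupby("dyad_id")["resolution_time_s"].first().dropna()
    res_mirror = np.full(len(mirror), session_length_s)
    agg_real = s.loc[s["treatment"] == "winner", "aggressive_freq_last5"]
    agg_mirror = mirror["aggressive_freq_last5"]
    rows = []
    for name, x, y in [
        ("latency_first_bite_s", lat_real, lat_mirror),
        ("resolution_time_s", res_real, res_mirror),
        ("aggressive_freq_last5", agg_real, agg_mirror),
    ]:
        try:
            t = two_sample_t(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
            rows.append((name, "real-vs-mirror", t.statistic, t.df, t.p))
        except ValueError as exc:
            logger.warning("behavior test %s skipped: %s", name, exc)
            rows.append((name, "real-vs-mirror", np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["variable", "comparison", "t", "df", "p"])


def cortisol_tests(cortisol: pd.DataFrame) -> pd.DataFrame:
    """Welch ANOVA across treatments plus Tukey HSD pairwise p-values."""
    groups, labels = [], []
    for t, grp in cortisol.groupby("treatment", sort=True):
        groups.append(grp["cortisol_ng_ml"].to_numpy(dtype=float))
        labels.append(t)
    w = welch_anova(groups)
    rows = [("welch_anova", "all", "", w.statistic, w.df[0], w.df[1], w.p)]
    tk = tukey_hsd(groups, labels)
    for r in tk.itertuples():
        rows.append(("tukey_hsd", r.group_a, r.group_b, r.statistic, np.nan, np.nan, r.p))
    return pd.DataFrame(
        rows, columns=["test", "group_a", "group_b", "statistic", "df1", "df2", "p"]
    )


def association_screens(
    summary: pd.DataFrame, cortisol: pd.DataFrame, expression: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation screens (BH-adjusted within each family):
    behavior~expression, behavior~cortisol, cortisol~expression."""
    wide = summary.set_index("fish_id")[
        ["latency_first_bite_s", "aggressive_freq_last5", "submissive_freq_last5"]
    ].copy()
    wide = wide.join(cortisol.set_index("fish_id")["cortisol_ng_ml"], how="outer")
    expr_wide = expression.pivot_table(
        index="fish_id", columns=["gene", "nucleus"], values="relative_expression",
        aggfunc="first",
    )
    expr_wide.columns = [f"{g}_{k}" for g, k in expr_wide.columns]
    wide = wide.join(expr_wide, how="outer")
    behav_cols = ["latency_first_bite_s", "aggressive_freq_last5", "submissive_freq_last5"]
    expr_cols = list(expr_wide.columns)
    families = {
        "behavior~expression": [(b, e) for b in behav_cols for e in expr_cols],
        "behavior~cortisol": [(b, "cortisol_ng_ml") for b in behav_cols],
        "cortisol~expression": [("cortisol_ng_ml", e) for e in expr_cols],
    }
    frames = []
    for fam, pairs in families.items():
        out = corr_with_bh(wide, pairs)
        out.insert(0, "family", fam)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)
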