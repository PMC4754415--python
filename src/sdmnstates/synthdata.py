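"""Synthetic agonistic-interaction studies with known ground truth.

Generates everything the downstream analysis consumes — fish and dyad
metadata, behavioral event streams, plasma cortisol, latent log-expression
with subject/dyad random effects and per-(treatment, nucleus) residual
co-expression structure, and raw qPCR amplification curves — from a master
seed, so each stage of the pipeline can be tested against the truth tables.

Random-number streams are split per fish and per reaction from the master
seed (``SeedSequence((seed, stream, *indices))``), so removing fish from a
design does not shift the draws of the remaining fish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import EffectSpec, StudyDesign, check_correlation_matrix
from .qpcr import AmplificationCurve

AGGRESSIVE_ACTS = ("bite", "chase", "strike")
SUBMISSIVE_ACTS = ("freeze", "flee")

# stream codes for seed splitting
_S_MORPHO, _S_RANEF, _S_RESID, _S_REF, _S_BEHAV, _S_CORT, _S_CURVE = range(7)


def _rng(seed: int, stream: int, *idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), stream, *idx)))


# ----------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class AmplificationKinetics:
    """Forward model for one qPCR reaction.

    Pre-plateau fluorescence follows ``baseline + F0 * (1+E)^cycle`` with
    ``F0 = template_scale * true_quantity``, saturating smoothly to
    ``baseline + plateau`` (a logistic in cycle number with slope
    ``log(1+E)``). Gaussian read noise with SD ``noise_sd`` is added.
    """

    efficiency: float = 0.9          # per-cycle fractional gain, in (0, 1]
    plateau: float = 3.0             # saturation amplitude above baseline
    baseline: float = 0.5            # background fluorescence
    noise_sd: float = 0.01           # fluorescence read noise SD
    n_cycles: int = 45
    template_scale: float = 2e-5     # F0 per unit of true quantity

    def __post_init__(self) -> None:
        if not (0.0 < self.efficiency <= 1.0):
            raise ValueError(f"efficiency must be in (0, 1], got {self.efficiency}")
        if self.plateau <= 0:
            raise ValueError("plateau must be positive")
        if self.n_cycles < 40:
            raise ValueError("n_cycles must be >= 40")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class BehaviorParams:
    """Latency / resolution distributions and event rates (per minute).

    Real-opponent fights resolve on average after ``resolution_mean_s``
    seconds (about 7 minutes); mirror fights never resolve. After
    resolution only winners act aggressively and only losers act
    submissively.
    """

    latency_real_mean_s: float = 60.0
    latency_real_sd_s: float = 30.0
    latency_mirror_mean_s: float = 20.0
    latency_mirror_sd_s: float = 10.0
    resolution_mean_s: float = 420.0
    resolution_sd_s: float = 120.0
    rate_pre_per_min: float = 4.0       # aggressive rate, both real fighters
    rate_winner_post_per_min: float = 3.0
    rate_loser_post_per_min: float = 3.0
    rate_mirror_per_min: float = 3.5


@dataclass(frozen=True)
class CortisolParams:
    """Log-normal plasma cortisol (ng/ml); mirror ~ winner > loser ~ control."""

    median_ng_ml: Mapping[str, float] = field(
        default_factory=lambda: {"control": 4.0, "loser": 5.0, "winner": 10.0, "mirror": 11.0}
    )
    sigma_log: float = 0.35


# ----------------------------------------------------------------------
# dataset container


@dataclass
class StudyDataset:
    """One complete simulated study.

    Attributes
    ----------
    fish : per-fish metadata (fish_id, dyad_id, treatment, morphometrics).
    behavior : long event log (fish_id, time_s, behavior) plus a per-fish
        resolution-time table in ``resolution``.
    cortisol : fish_id, treatment, cortisol_ng_ml.
    truth : latent log-expression with its generative components
        (mu, delta, subject and dyad intercepts, residual) per
        fish x nucleus x gene, reference gene included.
    curves : long amplification-curve table
        (reaction_id, fish_id, nucleus, gene, cycle, fluorescence).
    """

    design: StudyDesign
    effects: EffectSpec
    seed: int
    fish: pd.DataFrame
    behavior: pd.DataFrame
    resolution: pd.DataFrame
    cortisol: pd.DataFrame
    truth: pd.DataFrame
    curves: pd.DataFrame | None = None

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.fish.to_csv(path / "fish.csv", index=False)
        self.behavior.to_csv(path / "behavior.csv", index=False)
        self.resolution.to_csv(path / "resolution.csv", index=False)
        self.cortisol.to_csv(path / "cortisol.csv", index=False)
        self.truth.to_csv(path / "truth.csv", index=False)
        if self.curves is not None:
            self.curves.to_csv(path / "curves.csv", index=False)


# ----------------------------------------------------------------------
# fish & dyads


def make_fish_table(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Fish records with size-matched dyad pairing.

    Winners and losers share real-opponent dyad ids ``dyadNN``; mirror and
    control fish are housed in tank pairs (``mtankNN`` / ``ctankNN``) that
    carry no shared random effect downstream.
    """
    rows = []
    fish_idx = 0
    n_staged = design.n_dyads_staged
    for treatment in design.treatments:
        n = design.n_per_treatment[treatment]
        for i in range(n):
            if treatment in ("winner", "loser"):
                dyad = f"dyad{i + 1:02d}" if i < n_staged else f"dyad{i + 1:02d}"
            elif treatment == "mirror":
                dyad = f"mtank{i // 2 + 1:02d}"
            else:
                dyad = f"ctank{i // 2 + 1:02d}"
            rows.append((fish_idx, f"fish{fish_idx + 1:02d}", dyad, treatment))
            fish_idx += 1
    df = pd.DataFrame(rows, columns=["fish_index", "fish_id", "dyad_id", "treatment"])
    # size-matched dyads: shared dyad size + small within-pair jitter
    sl, bm = [], []
    dyad_codes = {d: j for j, d in enumerate(sorted(df["dyad_id"].unique()))}
    for _, row in df.iterrows():
        g_d = _rng(seed, _S_MORPHO, dyad_codes[row["dyad_id"]])
        pair_sl = g_d.normal(3.78, 0.18)
        pair_bm = g_d.normal(0.40, 0.04)
        g_f = _rng(seed, _S_MORPHO, 1000 + int(row["fish_index"]))
        sl.append(max(2.5, pair_sl + g_f.normal(0.0, 0.05)))
        bm.append(max(0.2, pair_bm + g_f.normal(0.0, 0.01)))
    df["standard_length_cm"] = np.round(sl, 3)
    df["body_mass_g"] = np.round(bm, 3)
    return df


# ----------------------------------------------------------------------
# expression truth


def simulate_truth(
    design: StudyDesign, effects: EffectSpec, seed: int, fish: pd.DataFrame
) -> pd.DataFrame:
    """Latent log-expression per fish x nucleus x gene plus components."""
    genes = design.genes
    g = len(genes)
    # random intercepts: per fish and per real-opponent dyad
    b_fish = {
        int(r.fish_index): _rng(seed, _S_RANEF, int(r.fish_index)).normal(0.0, effects.sigma_subject)
        for r in fish.itertuples()
    }
    real_dyads = sorted(
        fish.loc[fish["treatment"].isin(["winner", "loser"]), "dyad_id"].unique()
    )
    b_dyad = {
        d: _rng(seed, _S_RANEF, 10_000 + j).normal(0.0, effects.sigma_dyad)
        for j, d in enumerate(real_dyads)
    }
    chol = {}
    for t in design.treatments:
        for k in design.nuclei:
            m = effects.corr(t, k, g)
            check_correlation_matrix(m, f"(treatment={t}, nucleus={k})")
            chol[(t, k)] = np.linalg.cholesky(m + 1e-12 * np.eye(g))
    rows = []
    for r in fish.itertuples():
        fi = int(r.fish_index)
        t = r.treatment
        bd = b_dyad.get(r.dyad_id, 0.0) if t in ("winner", "loser") else 0.0
        for ki, k in enumerate(design.nuclei):
            rng = _rng(seed, _S_RESID, fi, ki)
            eps = effects.sigma_resid * (chol[(t, k)] @ rng.standard_normal(g))
            ref_rng = _rng(seed, _S_REF, fi, ki)
            ref_latent = ref_rng.normal(0.0, 0.05)
            for gi, gene in enumerate(genes):
                mu = effects.mu.get((k, gene), 0.0)
                de = effects.delta.get((t, k, gene), 0.0)
                y = mu + de + b_fish[fi] + bd + eps[gi]
                rows.append(
                    (r.fish_id, r.dyad_id, t, k, gene, y, mu, de, b_fish[fi], bd, eps[gi])
                )
            rows.append(
                (r.fish_id, r.dyad_id, t, k, design.reference_gene,
                 ref_latent, 0.0, 0.0, 0.0, 0.0, ref_latent)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "fish_id", "dyad_id", "treatment", "nucleus", "gene",
            "log_expression", "mu", "delta", "b_subject", "b_dyad", "residual",
        ],
    )


# ----------------------------------------------------------------------
# amplification curves


def simulate_amplification_curves(
    true_quantity: Sequence[float] | float,
    kinetics: AmplificationKinetics | None = None,
    seed: int | None = None,
    reaction_ids: Sequence[str] | None = None,
) -> list[AmplificationCurve]:
    """Forward-simulate amplification curves for the given template amounts.

    Each reaction's noiseless signal is
    ``baseline + plateau / (1 + exp(-k (c - m)))`` with ``k = log(1+E)`` and
    midpoint ``m`` set so that the early-cycle signal equals
    ``F0 (1+E)^c`` with ``F0 = template_scale * quantity``. A zero quantity
    yields a flat baseline (plus noise).
    """
    kin = kinetics or AmplificationKinetics()
    q = np.atleast_1d(np.asarray(true_quantity, dtype=float))
    if np.any(q < 0):
        raise ValueError("true_quantity must be non-negative")
    if reaction_ids is None:
        reaction_ids = [f"rxn{i:04d}" for i in range(len(q))]
    if len(reaction_ids) != len(q):
        raise ValueError("reaction_ids length must match true_quantity")
    cycles = np.arange(1, kin.n_cycles + 1, dtype=float)
    k = math.log1p(kin.efficiency)
    out = []
    for i, (rid, qi) in enumerate(zip(reaction_ids, q)):
        if qi == 0.0:
            signal = np.zeros_like(cycles)
        else:
            f0 = kin.template_scale * qi
            m = math.log(kin.plateau / f0) / k
            signal = kin.plateau / (1.0 + np.exp(-k * (cycles - m)))
        fluor = kin.baseline + signal
        if kin.noise_sd > 0:
            rng = _rng(0 if seed is None else seed, _S_CURVE, i)
            fluor = fluor + rng.normal(0.0, kin.noise_sd, size=fluor.shape)
        out.append(AmplificationCurve(reaction_id=rid, cycles=cycles, fluorescence=fluor))
    return out


def _curves_frame(
    truth: pd.DataFrame, design: StudyDesign, kinetics: AmplificationKinetics, seed: int
) -> pd.DataFrame:
    """Long curves table for every fish x nucleus x gene reaction."""
    cycles = np.arange(1, kinetics.n_cycles + 1, dtype=float)
    k = math.log1p(kinetics.efficiency)
    nuc_idx = {k_: i for i, k_ in enumerate(design.nuclei)}
    gene_idx = {g: i for i, g in enumerate(design.all_genes)}
    frames = []
    for r in truth.itertuples():
        qi = math.exp(r.log_expression)
        f0 = kinetics.template_scale * qi
        m = math.log(kinetics.plateau / f0) / k
        signal = kinetics.plateau / (1.0 + np.exp(-k * (cycles - m)))
        fluor = kinetics.baseline + signal
        if kinetics.noise_sd > 0:
            fid = int(r.fish_id.replace("fish", "")) - 1
            rng = _rng(seed, _S_CURVE, fid, nuc_idx[r.nucleus], gene_idx[r.gene])
            fluor = fluor + rng.normal(0.0, kinetics.noise_sd, size=fluor.shape)
        frames.append(
            pd.DataFrame(
                {
                    "reaction_id": f"{r.fish_id}_{r.nucleus}_{r.gene}",
                    "fish_id": r.fish_id,
                    "nucleus": r.nucleus,
                    "gene": r.gene,
                    "cycle": cycles.astype(int),
                    "fluorescence": np.round(fluor, 6),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# behavior & cortisol


def simulate_behavior(
    design: StudyDesign,
    params: BehaviorParams | None = None,
    seed: int = 0,
    fish: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Event streams per fish and per-fish resolution times.

    Returns ``(events, resolution)``: events has columns fish_id, time_s,
    behavior; resolution has fish_id, resolution_time_s (NaN for
    mirror-fighters, which fight the whole session, and controls).
    """
    p = params or BehaviorParams()
    if fish is None:
        fish = make_fish_table(design, seed)
    session = design.session_seconds
    # one resolution time per real-opponent dyad
    real_dyads = sorted(
        fish.loc[fish["treatment"].isin(["winner", "loser"]), "dyad_id"].unique()
    )
    dyad_resolution = {}
    for j, d in enumerate(real_dyads):
        rng = _rng(seed, _S_BEHAV, 50_000 + j)
        r = rng.normal(p.resolution_mean_s, p.resolution_sd_s)
        dyad_resolution[d] = float(np.clip(r, 60.0, session - 60.0))

    ev_rows: list[tuple[str, float, str]] = []
    res_rows: list[tuple[str, float]] = []
    for r in fish.itertuples():
        rng = _rng(seed, _S_BEHAV, int(r.fish_index))
        t = r.treatment
        if t == "control":
            res_rows.append((r.fish_id, np.nan))
            continue
        if t == "mirror":
            latency = max(1.0, rng.normal(p.latency_mirror_mean_s, p.latency_mirror_sd_s))
            res_rows.append((r.fish_id, np.nan))
            ev_rows.append((r.fish_id, latency, "bite"))
            ev_rows += _poisson_events(
                rng, r.fish_id, latency, session, p.rate_mirror_per_min, AGGRESSIVE_ACTS
            )
            continue
        resolution = dyad_resolution[r.dyad_id]
        res_rows.append((r.fish_id, resolution))
        latency = max(1.0, rng.normal(p.latency_real_mean_s, p.latency_real_sd_s))
        latency = min(latency, resolution - 1.0)
        ev_rows.append((r.fish_id, latency, "bite"))
        ev_rows += _poisson_events(
            rng, r.fish_id, latency, resolution, p.rate_pre_per_min, AGGRESSIVE_ACTS
        )
        if t == "winner":
            ev_rows += _poisson_events(
                rng, r.fish_id, resolution, session, p.rate_winner_post_per_min, AGGRESSIVE_ACTS
            )
        else:
            ev_rows += _poisson_events(
                rng, r.fish_id, resolution, session, p.rate_loser_post_per_min, SUBMISSIVE_ACTS
            )
    events = pd.DataFrame(ev_rows, columns=["fish_id", "time_s", "behavior"])
    events = events.sort_values(["fish_id", "time_s"], kind="mergesort").reset_index(drop=True)
    events["time_s"] = events["time_s"].round(2)
    resolution = pd.DataFrame(res_rows, columns=["fish_id", "resolution_time_s"])
    return events, resolution


def _poisson_events(rng, fish_id, t0, t1, rate_per_min, acts):
    if t1 <= t0 or rate_per_min <= 0:
        return []
    n = rng.poisson(rate_per_min * (t1 - t0) / 60.0)
    times = np.sort(rng.uniform(t0, t1, size=n))
    kinds = rng.choice(acts, size=n)
    return [(fish_id, float(t), str(k)) for t, k in zip(times, kinds)]


def simulate_cortisol(
    design: StudyDesign,
    params: CortisolParams | None = None,
    seed: int = 0,
    fish: pd.DataFrame | None = None,
) -> pd.DataFrame:
    p = params or CortisolParams()
    if fish is None:
        fish = make_fish_table(design, seed)
    vals = []
    for r in fish.itertuples():
        rng = _rng(seed, _S_CORT, int(r.fish_index))
        med = p.median_ng_ml[r.treatment]
        vals.append(float(np.exp(np.log(med) + rng.normal(0.0, p.sigma_log))))
    return pd.DataFrame(
        {
            "fish_id": fish["fish_id"],
            "treatment": fish["treatment"],
            "cortisol_ng_ml": np.round(vals, 3),
        }
    )


# ----------------------------------------------------------------------
# full study


def simulate_study(
    design: StudyDesign | None = None,
    effects: EffectSpec | None = None,
    seed: int = 0,
    kinetics: AmplificationKinetics | None = None,
    behavior_params: BehaviorParams | None = None,
    cortisol_params: CortisolParams | None = None,
    with_curves: bool = True,
) -> StudyDataset:
    """Simulate one complete study; identical inputs give identical output."""
    design = design or StudyDesign()
    effects = effects or EffectSpec.default(design)
    effects.validate(design)
    kin = kinetics or AmplificationKinetics()
    fish = make_fish_table(design, seed)
    truth = simulate_truth(design, effects, seed, fish)
    events, resolution = simulate_behavior(design, behavior_params, seed, fish)
    cortisol = simulate_cortisol(design, cortisol_params, seed, fish)
    curves = _curves_frame(truth, design, kin, seed) if with_curves else None
    return StudyDataset(
        design=design,
        effects=effects,
        seed=seed,
        fish=fish.drop(columns=["fish_index"]),
        behavior=events,
        resolution=resolution,
        cortisol=cortisol,
        truth=truth,
        curves=curves,
    )
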