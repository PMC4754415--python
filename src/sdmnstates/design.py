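"""Study design and generative effect specification.

The experimental layout mirrors a dyadic agonistic-interaction study in male
zebrafish: four social treatments (non-interacting controls, mirror-fighters,
and winners/losers of real-opponent fights staged in dyads), five brain
nuclei of the social decision-making network sampled per fish (Dm, Dl, Vv,
Vs, POA), six candidate neuroplasticity genes plus one reference gene
measured by qPCR in every fish x nucleus sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

TREATMENTS: tuple[str, ...] = ("control", "mirror", "winner", "loser")
NUCLEI: tuple[str, ...] = ("Dm", "Dl", "Vv", "Vs", "POA")
TARGET_GENES: tuple[str, ...] = ("bdnf", "npas4", "nlgn1", "nlgn2", "wnt3", "neurod")
REFERENCE_GENE: str = "eef1a1l1"

#: group sizes of the emulated study: winners 12, losers 11 (one dyad's loser
#: lost to technical dropout), mirror-fighters 12, visual-isolation controls 10
DEFAULT_COUNTS: dict[str, int] = {"control": 10, "mirror": 12, "winner": 12, "loser": 11}


@dataclass(frozen=True)
class StudyDesign:
    """Layout of one study: group sizes, nuclei, genes, session length.

    Winners and losers come from real-opponent dyads; every winner has
    exactly one loser partner unless ``allow_dyad_dropout`` is set, in which
    case ``|n_winner - n_loser|`` fish are treated as members of incomplete
    dyads (their partner dropped out post hoc).
    """

    n_per_treatment: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )
    treatments: tuple[str, ...] = TREATMENTS
    nuclei: tuple[str, ...] = NUCLEI
    genes: tuple[str, ...] = TARGET_GENES
    reference_gene: str = REFERENCE_GENE
    interaction_minutes: float = 30.0
    allow_dyad_dropout: bool = True

    def __post_init__(self) -> None:
        missing = set(self.treatments) - set(self.n_per_treatment)
        if missing:
            raise ValueError(f"n_per_treatment missing treatments: {sorted(missing)}")
        for t, n in self.n_per_treatment.items():
            if n < 2:
                raise ValueError(f"treatment {t!r} needs n >= 2, got {n}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene names must be unique")
        if self.reference_gene in self.genes:
            raise ValueError("reference gene must be disjoint from target genes")
        nw, nl = self.n_per_treatment["winner"], self.n_per_treatment["loser"]
        if nw != nl and not self.allow_dyad_dropout:
            raise ValueError(
                "winner and loser counts differ; unequal counts require "
                "allow_dyad_dropout=True (explicit dropout)"
            )
        if self.interaction_minutes <= 0:
            raise ValueError("interaction_minutes must be positive")

    @property
    def n_fish(self) -> int:
        return sum(self.n_per_treatment[t] for t in self.treatments)

    @property
    def n_dyads_staged(self) -> int:
        """Number of real-opponent dyads staged (max of winner/loser counts)."""
        return max(self.n_per_treatment["winner"], self.n_per_treatment["loser"])

    @property
    def n_dyads_complete(self) -> int:
        """Dyads with both the winner and the loser still in the dataset."""
        return min(self.n_per_treatment["winner"], self.n_per_treatment["loser"])

    @property
    def session_seconds(self) -> float:
        return self.interaction_minutes * 60.0

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.genes + (self.reference_gene,)


def _as_matrix(value, g: int) -> np.ndarray:
    m = np.asarray(value, dtype=float)
    if m.shape != (g, g):
        raise ValueError(f"coexpression matrix must be {g}x{g}, got {m.shape}")
    return m


def check_correlation_matrix(m: np.ndarray, label: str, tol: float = 1e-8) -> None:
    """Validate symmetry, unit diagonal and positive semi-definiteness."""
    if not np.allclose(m, m.T, atol=tol):
        raise ValueError(f"coexpression matrix for {label} is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=tol):
        raise ValueError(f"coexpression matrix for {label} has non-unit diagonal")
    w = np.linalg.eigvalsh(m)
    if w.min() < -tol:
        raise ValueError(
            f"coexpression matrix for {label} is not positive semi-definite "
            f"(min eigenvalue {w.min():.3g})"
        )


@dataclass
class EffectSpec:
    """Generative ground truth for expression on the natural-log scale.

    log-expression of gene g in nucleus k of fish i (treatment t):

        y = mu[k, g] + delta[t, k, g] + b_fish(i) + b_dyad(d(i)) + eps

    with b_fish ~ N(0, sigma_subject^2) shared across all nuclei of a fish,
    b_dyad ~ N(0, sigma_dyad^2) shared by the winner and loser of one
    real-opponent dyad (absent for mirror/control fish), and the residual
    vector eps across genes drawn per (fish, nucleus) from a multivariate
    normal with SD sigma_resid and correlation ``coexpression[(t, k)]``.
    """

    mu: Mapping[tuple[str, str], float]                  # (nucleus, gene) -> baseline
    delta: Mapping[tuple[str, str, str], float]          # (treatment, nucleus, gene)
    sigma_subject: float = 0.3
    sigma_dyad: float = 0.2
    sigma_resid: float = 0.5
    coexpression: Mapping[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def validate(self, design: StudyDesign) -> None:
        for s, name in [
            (self.sigma_subject, "sigma_subject"),
            (self.sigma_dyad, "sigma_dyad"),
            (self.sigma_resid, "sigma_resid"),
        ]:
            if s < 0:
                raise ValueError(f"{name} must be >= 0, got {s}")
        g = len(design.genes)
        for t in design.treatments:
            for k in design.nuclei:
                m = _as_matrix(self.corr(t, k, g), g)
                check_correlation_matrix(m, f"(treatment={t}, nucleus={k})")

    def corr(self, treatment: str, nucleus: str, g: int) -> np.ndarray:
        m = self.coexpression.get((treatment, nucleus))
        if m is None:
            return np.eye(g)
        return _as_matrix(m, g)

    def mean(self, treatment: str, nucleus: str, gene: str) -> float:
        return float(
            self.mu.get((nucleus, gene), 0.0)
            + self.delta.get((treatment, nucleus, gene), 0.0)
        )

    # ------------------------------------------------------------------
    @classmethod
    def null(cls, design: StudyDesign | None = None, **kw) -> "EffectSpec":
        """No treatment effects, independent genes; baseline means only."""
        design = design or StudyDesign()
        mu = {
            (k, g): _DEFAULT_MU.get((k, g), -3.0)
            for k in design.nuclei
            for g in design.genes
        }
        return cls(mu=mu, delta={}, **kw)

    @classmethod
    def default(cls, design: StudyDesign | None = None) -> "EffectSpec":
        """Study-like ground truth.

        Nucleus baselines follow the reported expression gradients (e.g.
        bdnf and neurod highest in the dorsal telencephalon, nlgn2 highest
        ventrally); treatment shifts encode the reported planned-comparison
        findings (bdnf up in Dl of losers/mirror-fighters, neurogenesis
        genes up in Dm of winners, nlgn2 down in Vs of winners/losers, ...);
        co-expression structure differs between treatments so that
        neurogenomic-state partitioning has signal to find.
        """
        design = design or StudyDesign()
        spec = cls.null(design)
        delta = {
            # Dl: bdnf up in mirror-fighters and losers; npas4 down in mirror
            ("mirror", "Dl", "bdnf"): 0.45,
            ("loser", "Dl", "bdnf"): 0.40,
            ("mirror", "Dl", "npas4"): -0.40,
            # Dm: winners up-regulate neurogenesis genes and npas4
            ("winner", "Dm", "neurod"): 0.30,
            ("winner", "Dm", "wnt3"): 0.25,
            ("winner", "Dm", "npas4"): 0.25,
            # Vv: nlgn1 up in winners; wnt3 up in losers and mirror-fighters
            ("winner", "Vv", "nlgn1"): 0.40,
            ("loser", "Vv", "nlgn1"): 0.15,
            ("loser", "Vv", "wnt3"): 0.25,
            ("mirror", "Vv", "wnt3"): 0.25,
            # Vs: nlgn2 down in winners and losers
            ("winner", "Vs", "nlgn2"): -0.30,
            ("loser", "Vs", "nlgn2"): -0.45,
        }
        g = len(design.genes)
        block_a = _block_corr(g, [(0, 1, 2), (3, 4, 5)], 0.8)
        block_b = _block_corr(g, [(0, 3), (1, 4), (2, 5)], 0.8)
        coex: dict[tuple[str, str], np.ndarray] = {}
        for k in design.nuclei:
            # winners carry their own structure; mirror-fighters and losers
            # share one in the dorsal nuclei + Vs, controls another
            coex[("winner", k)] = block_b
            coex[("mirror", k)] = block_a
            coex[("loser", k)] = block_a if k in ("Dm", "Dl", "Vs") else np.eye(g)
            coex[("control", k)] = np.eye(g)
        coex[("control", "Vv")] = block_a  # Vv: control similar to mirror
        return cls(mu=spec.mu, delta=delta, coexpression=coex)


def _block_corr(g: int, blocks, rho: float) -> np.ndarray:
    m = np.eye(g)
    for block in blocks:
        for i in block:
            for j in block:
                if i != j:
                    m[i, j] = rho
    return m


# baseline natural-log relative expression per (nucleus, gene); ordering of
# nuclei per gene follows the reported expression gradients
_DEFAULT_MU: dict[tuple[str, str], float] = {}
_GRADIENTS = {
    "bdnf": {"Dl": -2.0, "Dm": -2.5, "Vv": -3.2, "POA": -3.6, "Vs": -4.0},
    "npas4": {"Dm": -3.0, "Dl": -3.1, "Vv": -3.2, "Vs": -3.6, "POA": -4.0},
    "nlgn1": {"Dm": -3.0, "Dl": -3.0, "Vv": -3.1, "Vs": -3.4, "POA": -3.6},
    "nlgn2": {"Vv": -2.6, "Vs": -2.4, "Dm": -3.0, "Dl": -3.0, "POA": -2.9},
    "wnt3": {"Dm": -3.2, "Vv": -3.3, "Dl": -3.3, "Vs": -3.6, "POA": -3.6},
    "neurod": {"Dm": -1.8, "Dl": -1.6, "Vv": -3.4, "Vs": -3.5, "POA": -3.6},
}
for _gene, _per_nuc in _GRADIENTS.items():
    for _nuc, _v in _per_nuc.items():
        _DEFAULT_MU[(_nuc, _gene)] = _v
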