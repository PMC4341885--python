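"""Interaction odds ratio for a SNP pair.

For two biallelic SNPs the 3x3 table of genotype combinations is collapsed,
under a dominant or recessive transmission assumption, into four classes
(carrier/non-carrier of the minor allele at each SNP).  Splitting each class
by case/control status gives the eight cells

    class                     cases   controls
    non-carrier x non-carrier alpha   beta
    non-carrier x carrier     gamma   delta
    carrier     x non-carrier epsilon zeta
    carrier     x carrier     eta     theta

from which three odds ratios are formed,

    OR1   = beta*epsilon / (alpha*zeta)        single-SNP1 carrier OR
    OR2   = beta*gamma   / (alpha*delta)       single-SNP2 carrier OR
    OR1*2 = beta*eta     / (alpha*theta)       double-carrier OR

and the interaction odds ratio

    I_OR = OR1*2 / (OR1 * OR2) = alpha*delta*zeta*eta / (beta*gamma*epsilon*theta).

I_OR departs from 1 when carrying both risk genotypes changes the odds of
disease beyond the product of the single-genotype effects.  A pseudocount is
added to every cell so the statistic is always finite and positive.  The
"universal" statistic u(I_OR) = max(I_OR, 1/I_OR) folds both interaction
directions onto one upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import MISSING

__all__ = [
    "PairCounts",
    "IorResult",
    "collapse_pair",
    "interaction_odds_ratio",
    "u_transform",
    "u_ior_from_cells",
    "carrier_classes",
]

_MODELS = ("dominant", "recessive")


class DegeneratePairError(ValueError):
    """Raised when a pair has no informative case or no informative control."""


@dataclass(frozen=True)
class PairCounts:
    """The eight cells of the collapsed case/control table for one SNP pair.

    Counts are raw (no pseudocount).  ``model`` records which collapsing
    produced them; ``n_informative`` is the number of samples with both
    genotypes observed.
    """

    alpha: int
    beta: int
    gamma: int
    delta: int
    epsilon: int
    zeta: int
    eta: int
    theta: int
    model: str = "dominant"
    n_informative: int = 0

    def __post_init__(self) -> None:
        cells = self.cells()
        if any(c < 0 for c in cells):
            raise ValueError(f"negative cell count in {cells}")
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.n_informative and sum(cells) != self.n_informative:
            raise ValueError(
                f"cells sum to {sum(cells)} but n_informative={self.n_informative}"
            )

    def cells(self) -> tuple[int, ...]:
        """(alpha, beta, gamma, delta, epsilon, zeta, eta, theta)."""
        return (self.alpha, self.beta, self.gamma, self.delta,
                self.epsilon, self.zeta, self.eta, self.theta)

    def row_totals(self) -> tuple[int, int, int, int]:
        """Per-class totals (cases + controls), in class order."""
        return (self.alpha + self.beta, self.gamma + self.delta,
                self.epsilon + self.zeta, self.eta + self.theta)

    @property
    def n_cases(self) -> int:
        return self.alpha + self.gamma + self.epsilon + self.eta

    @property
    def n_controls(self) -> int:
        return self.beta + self.delta + self.zeta + self.theta

    def swapped_phenotype(self) -> "PairCounts":
        """Counts with case and control columns exchanged."""
        return PairCounts(self.beta, self.alpha, self.delta, self.gamma,
                          self.zeta, self.epsilon, self.theta, self.eta,
                          model=self.model, n_informative=self.n_informative)

    def to_tsv_line(self) -> str:
        return "\t".join(str(v) for v in self.cells()) + f"\t{self.model}\t{self.n_informative}"


@dataclass(frozen=True)
class IorResult:
    """Pseudocount-adjusted odds ratios for one pair."""

    or1: float
    or2: float
    or12: float
    ior: float
    u_ior: float


def carrier_classes(g: np.ndarray, model: str) -> np.ndarray:
    """Boolean carrier indicator for the collapsed class of one SNP.

    Dominant: carrier = at least one minor allele (genotype 1 or 2).
    Recessive: carrier = homozygous minor (genotype 2).
    Missing genotypes return False; mask them with ``g != MISSING``.
    """
    g = np.asarray(g)
    if model == "dominant":
        return g >= 1
    if model == "recessive":
        return g == 2
    raise ValueError(f"model must be one of {_MODELS}, got {model!r}")


def collapse_pair(g1, g2, phenotype, model: str = "dominant") -> PairCounts:
    """Collapse a genotype-vector pair into the eight-cell case/control table.

    Parameters
    ----------
    g1, g2
        Genotype vectors coded as copies of the minor allele (0/1/2) with
        ``MISSING`` (-1) for no-calls.
    phenotype
        Vector with 1 = case, 0 = control.
    model
        "dominant" or "recessive" collapsing.

    Samples missing either genotype are excluded from all eight cells
    (pairwise complete-case).
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    phenotype = np.asarray(phenotype)
    if not (g1.shape == g2.shape == phenotype.shape):
        raise ValueError(
            f"length mismatch: g1 {g1.shape}, g2 {g2.shape}, phenotype {phenotype.shape}"
        )
    present = (g1 != MISSING) & (g2 != MISSING)
    c1 = carrier_classes(g1, model) & present
    c2 = carrier_classes(g2, model) & present
    case = phenotype == 1

    def count(cls1: np.ndarray, cls2: np.ndarray, pheno: np.ndarray) -> int:
        return int(np.count_nonzero(cls1 & cls2 & pheno & present))

    pc = PairCounts(
        alpha=count(~c1, ~c2, case),
        beta=count(~c1, ~c2, ~case),
        gamma=count(~c1, c2, case),
        delta=count(~c1, c2, ~case),
        epsilon=count(c1, ~c2, case),
        zeta=count(c1, ~c2, ~case),
        eta=count(c1, c2, case),
        theta=count(c1, c2, ~case),
        model=model,
        n_informative=int(np.count_nonzero(present)),
    )
    if pc.n_cases == 0 or pc.n_controls == 0:
        raise DegeneratePairError(
            f"pair has {pc.n_cases} informative cases and {pc.n_controls} informative controls"
        )
    return pc


def u_transform(ior):
    """Universal interaction odds ratio u(I_OR) = max(I_OR, 1/I_OR)."""
    ior = np.asarray(ior, dtype=float)
    if np.any(ior <= 0):
        raise ValueError("I_OR must be positive")
    out = np.maximum(ior, 1.0 / ior)
    return float(out) if out.ndim == 0 else out


def u_ior_from_cells(alpha, beta, gamma, delta, epsilon, zeta, eta, theta,
                     pseudocount: float = 1.0):
    """Vectorized (I_OR, u(I_OR)) from raw cell counts (arrays or scalars)."""
    a = np.asarray(alpha, dtype=float) + pseudocount
    b = np.asarray(beta, dtype=float) + pseudocount
    g = np.asarray(gamma, dtype=float) + pseudocount
    d = np.asarray(delta, dtype=float) + pseudocount
    e = np.asarray(epsilon, dtype=float) + pseudocount
    z = np.asarray(zeta, dtype=float) + pseudocount
    h = np.asarray(eta, dtype=float) + pseudocount
    t = np.asarray(theta, dtype=float) + pseudocount
    ior = (a * d * z * h) / (b * g * e * t)
    return ior, np.maximum(ior, 1.0 / ior)


def interaction_odds_ratio(c: PairCounts, pseudocount: float = 1.0) -> IorResult:
    """Compute OR1, OR2, OR1*2, I_OR and u(I_OR) with a pseudocount.

    The pseudocount (default 1) is added unconditionally to all eight cells,
    which keeps every ratio finite and positive.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a, b, g, d, e, z, h, t = (v + pseudocount for v in c.cells())
    or1 = (b * e) / (a * z)
    or2 = (b * g) / (a * d)
    or12 = (b * h) / (a * t)
    ior = (a * d * z * h) / (b * g * e * t)
    return IorResult(or1=or1, or2=or2, or12=or12, ior=ior, u_ior=max(ior, 1.0 / ior))
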