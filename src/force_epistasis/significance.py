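"""Significance of an observed u(I_OR): permutation and exact P-values.

The empirical P-value of a pair is the proportion of case/control label
permutations whose u(I_OR) is at least the observed value.  Because the
permutation null of the collapsed table only depends on the per-class sample
totals, it is also available in closed form: conditional on the margins, the
vector of case counts per class follows a multivariate hypergeometric
distribution, and the exact P-value sums its tail.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .constants import MISSING
from .genotype_io import GenotypeMatrix, recode_to_minor
from .ior_core import (DegeneratePairError, PairCounts, carrier_classes,
                       collapse_pair, interaction_odds_ratio, u_ior_from_cells)
from .scan import PairFilterConfig, pair_passes_filters

__all__ = [
    "ExactPConfig",
    "empirical_pvalue",
    "exact_pvalue",
    "all_pair_pvalues",
    "genome_wide_threshold",
    "pair_rng",
]

#: Relative tolerance when comparing u(I_OR) values for the ">= observed" rule;
#: guards against last-bit float differences between equivalent tables.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class ExactPConfig:
    """Conventions for the exact tail sum.

    ``tail="ior_tail_times_two"`` sums the multivariate-hypergeometric
    probability of tuples whose I_OR (pseudocount-adjusted) is >= x, doubles
    it to account for the reciprocal tail, and caps at 1.  For balanced
    designs (equal case and control counts) this equals Pr(u(I_OR) >= x)
    exactly when x > 1; for unbalanced tables it is conservative.
    """

    cap_at_one: bool = True
    tail: str = "ior_tail_times_two"
    pseudocount: float = 1.0


def pair_rng(seed: int, snp1: str | int, snp2: str | int) -> np.random.Generator:
    """Deterministic per-pair RNG stream, independent of evaluation order."""
    k1 = zlib.crc32(str(snp1).encode())
    k2 = zlib.crc32(str(snp2).encode())
    return np.random.default_rng(np.random.SeedSequence((int(seed), min(k1, k2), max(k1, k2))))


def _class_table(g1, g2, phenotype, model):
    """Class index per sample (0..3, or 4 = missing) and case labels."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    phenotype = np.asarray(phenotype)
    present = (g1 != MISSING) & (g2 != MISSING)
    c1 = carrier_classes(g1, model) & present
    c2 = carrier_classes(g2, model) & present
    cls = np.where(present, (c1.astype(np.int8) << 1) | c2.astype(np.int8), 4)
    return cls, (phenotype == 1)


def _u_from_class_case_counts(case_counts, class_totals, pseudocount):
    """u(I_OR) for case-count vectors over the 4 classes (vectorized).

    ``case_counts`` has shape (..., 4) in class order (alpha, gamma, epsilon,
    eta); ``class_totals`` is length 4.
    """
    cc = np.asarray(case_counts, dtype=float)
    tot = np.asarray(class_totals, dtype=float)
    ctl = tot - cc
    _, u = u_ior_from_cells(cc[..., 0], ctl[..., 0], cc[..., 1], ctl[..., 1],
                            cc[..., 2], ctl[..., 2], cc[..., 3], ctl[..., 3],
                            pseudocount=pseudocount)
    return u


def empirical_pvalue(
    g1,
    g2,
    phenotype,
    model: str = "dominant",
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "permutation",
    pseudocount: float = 1.0,
    add_one: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation P-value for one SNP pair.

    The observed u(I_OR) is computed on the true labels; ``n_perm`` random
    case/control label assignments (shuffled jointly over all samples, so
    case and control totals are preserved) are scored the same way, and the
    P-value is the proportion with u >= observed.

    ``method="permutation"`` shuffles labels explicitly; ``method="table"``
    draws the per-class case counts directly from the induced multivariate
    hypergeometric distribution — the identical null, much faster.  With
    ``add_one`` the (+1)/(n+1) correction is applied; off by default so a
    never-exceeded observation reports 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = collapse_pair(g1, g2, phenotype, model)  # raises on degenerate pairs
    u_obs = interaction_odds_ratio(counts, pseudocount).u_ior
    if rng is None:
        rng = np.random.default_rng(seed)

    cls, case = _class_table(g1, g2, phenotype, model)
    class_totals = np.array([(cls == k).sum() for k in range(4)])
    if method == "permutation":
        onehot = np.stack([cls == k for k in range(4)]).astype(np.int32)  # (4, n)
        perm_labels = rng.permuted(
            np.broadcast_to(case, (n_perm, case.size)), axis=1
        ).astype(np.int32)
        case_counts = perm_labels @ onehot.T                              # (n_perm, 4)
    elif method == "table":
        colors = np.append(class_totals, (cls == 4).sum())
        case_counts = rng.multivariate_hypergeometric(
            colors, int(case.sum()), size=n_perm
        )[:, :4]
    else:
        raise ValueError(f"unknown method {method!r}")

    u_perm = _u_from_class_case_counts(case_counts, class_totals, pseudocount)
    n_ge = int(np.count_nonzero(u_perm >= u_obs * (1 - _TIE_RTOL)))
    if add_one:
        return (n_ge + 1) / (n_perm + 1)
    return n_ge / n_perm


def exact_pvalue(c: PairCounts, x: float, cfg: ExactPConfig | None = None) -> float:
    """Exact tail probability Pr(u(I_OR) >= x) under the permutation null.

    Conditional on the class row totals and the number of informative cases,
    the case counts (alpha', gamma', epsilon', eta') follow a multivariate
    hypergeometric distribution; each admissible tuple's probability is

        C(alpha+beta, alpha') C(gamma+delta, gamma')
        C(epsilon+zeta, epsilon') C(eta+theta, eta') / C(N, n_cases).

    Tuples whose pseudocount-adjusted I_OR is >= x are summed, the sum is
    doubled for the reciprocal tail, and the result capped at 1 (see
    :class:`ExactPConfig`).  The enumeration runs nested loops over alpha'
    and gamma' with the epsilon' axis vectorized.
    """
    if cfg is None:
        cfg = ExactPConfig()
    if x < 1:
        raise ValueError("x must be >= 1 (a u(I_OR) value)")
    rows = np.array(c.row_totals(), dtype=np.int64)
    k_cases = c.n_cases
    n_total = int(rows.sum())
    if k_cases > n_total:
        raise ValueError("inconsistent margins: more cases than samples")

    log_denom = float(gammaln(n_total + 1) - gammaln(k_cases + 1)
                      - gammaln(n_total - k_cases + 1))
    pc = cfg.pseudocount

    total_prob = 0.0
    tail_prob = 0.0
    r1, r2, r3, r4 = (int(v) for v in rows)
    for a in range(max(0, k_cases - r2 - r3 - r4), min(r1, k_cases) + 1):
        rem_a = k_cases - a
        for g in range(max(0, rem_a - r3 - r4), min(r2, rem_a) + 1):
            rem_g = rem_a - g
            e_lo = max(0, rem_g - r4)
            e_hi = min(r3, rem_g)
            if e_lo > e_hi:
                continue
            e = np.arange(e_lo, e_hi + 1)
            h = rem_g - e
            logp = (gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
                    + gammaln(r2 + 1) - gammaln(g + 1) - gammaln(r2 - g + 1)
                    + gammaln(r3 + 1) - gammaln(e + 1) - gammaln(r3 - e + 1)
                    + gammaln(r4 + 1) - gammaln(h + 1) - gammaln(r4 - h + 1)
                    - log_denom)
            prob = np.exp(logp)
            total_prob += float(prob.sum())
            ior = ((a + pc) * (r2 - g + pc) * (r3 - e + pc) * (h + pc)) / \
                  ((r1 - a + pc) * (g + pc) * (e + pc) * (r4 - h + pc))
            tail_prob += float(prob[ior >= x * (1 - _TIE_RTOL)].sum())

    if not np.isclose(total_prob, 1.0, atol=1e-9):
        raise AssertionError(f"enumeration probabilities sum to {total_prob}, not 1")
    p = 2.0 * tail_prob
    if cfg.cap_at_one:
        p = min(p, 1.0)
    return p


def all_pair_pvalues(
    gm: GenotypeMatrix,
    model: str = "dominant",
    n_perm: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
    method: str = "table",
    apply_filters: bool = False,
    filters: PairFilterConfig | None = None,
):
    """Empirical P-values for every SNP pair of a (small) dataset.

    Each pair gets its own RNG stream derived from (seed, snp1 id, snp2 id),
    so results do not depend on evaluation order.  Returns a DataFrame with
    columns ``i, j, snp1, snp2, u_ior, p``.  Pairs rejected by the optional
    scan filters are omitted.
    """
    gm = recode_to_minor(gm)
    gm.require_both_groups()
    ids = gm.snp_meta["id"].astype(str).to_numpy()
    if filters is None:
        filters = PairFilterConfig()
    rows = []
    for i in range(gm.n_snps - 1):
        for j in range(i + 1, gm.n_snps):
            counts = collapse_pair(gm.genotypes[:, i], gm.genotypes[:, j],
                                   gm.phenotype, model)
            if apply_filters:
                ok, _ = pair_passes_filters(counts, gm.snp_meta.iloc[i],
                                            gm.snp_meta.iloc[j], filters)
                if not ok:
                    continue
            rng = pair_rng(seed, ids[i], ids[j])
            p = empirical_pvalue(gm.genotypes[:, i], gm.genotypes[:, j],
                                 gm.phenotype, model=model, n_perm=n_perm,
                                 method=method, pseudocount=pseudocount, rng=rng)
            u = interaction_odds_ratio(counts, pseudocount).u_ior
            rows.append((i, j, ids[i], ids[j], u, p))
    return pd.DataFrame(rows, columns=["i", "j", "snp1", "snp2", "u_ior", "p"])


def genome_wide_threshold(n_independent_snps: float = 1e6, alpha: float = 0.05) -> float:
    """Genome-wide significance threshold for a pairwise interaction scan.

    2 * alpha / n^2 with n independent SNPs; the conventional n = 1e6 and
    alpha = 0.05 give 1e-13.
    """
    return 2.0 * alpha / (n_independent_snps ** 2)
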