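"""Simulation of case-control datasets with a planted epistatic SNP pair.

Disease status is driven by a 3x3 penetrance matrix f(g1, g2) over the
genotypes of two interacting SNPs, one of six classic pure-epistasis models
(no marginal effects).  Both interacting loci share allele frequencies
(p, q = 1 - p); genotypes are drawn under Hardy-Weinberg equilibrium, with
genotype index 0/1/2 counting copies of the q-frequency allele, so
P(index 0) = p^2, P(1) = 2pq, P(2) = q^2.  Individuals are rejection-sampled
until the requested numbers of affected (cases) and unaffected (controls)
are collected; the remaining SNPs are phenotype-independent HWE noise.

Optional noise sources mimic common imperfections of real data:

* GE - genotyping error: each call replaced, with probability ``ge_rate``,
  by one of the other two genotypes uniformly.  By default the error acts
  upstream of the phenotype (``ge_mode="causal"``): disease status is
  assigned from the corrupted genotype, so the observed genotype-phenotype
  association is not attenuated — the convention that matches published
  benchmarks of this design, whose GE results are indistinguishable from
  the no-noise condition.  ``ge_mode="readout"`` instead corrupts the
  genotype matrix after phenotypes are fixed (pure measurement error),
  which attenuates the signal;
* MS - missing data: each call set missing with probability ``ms_rate``
  (applied after GE, always at the readout stage);
* GH - genetic heterogeneity: two independent planted pairs, each causal in
  half of the cases;
* PC - phenocopy: half of the cases carry population (unaffected) genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import MISSING
from .genotype_io import GenotypeMatrix, recode_to_minor, write_plink

__all__ = [
    "PenetranceModel",
    "RITCHIE_MODELS",
    "SimConfig",
    "sample_individual",
    "simulate_dataset",
    "write_dataset",
]

NOISE_KINDS = ("GE", "MS", "GH", "PC")


@dataclass(frozen=True)
class PenetranceModel:
    """A 3x3 penetrance matrix with shared allele frequencies (p, q).

    ``penetrance[i, j]`` is the disease probability for genotype index i at
    SNP1 and j at SNP2 (index = copies of the q-frequency allele).
    """

    model_id: int
    penetrance: np.ndarray
    p: float
    q: float

    def __post_init__(self) -> None:
        f = np.asarray(self.penetrance, dtype=float)
        object.__setattr__(self, "penetrance", f)
        if f.shape != (3, 3) or ((f < 0) | (f > 1)).any():
            raise ValueError("penetrance must be a 3x3 matrix of probabilities")
        if not (0 < self.p < 1 and 0 < self.q < 1):
            raise ValueError("allele frequencies must be in (0, 1)")
        if abs(self.p + self.q - 1) > 1e-9:
            raise ValueError("p + q must equal 1")

    def genotype_probs(self) -> np.ndarray:
        """HWE genotype probabilities [p^2, 2pq, q^2] (both loci)."""
        return np.array([self.p ** 2, 2 * self.p * self.q, self.q ** 2])

    def prevalence(self) -> float:
        """Population disease probability sum_ij P(i) P(j) f(i, j)."""
        w = self.genotype_probs()
        return float(w @ self.penetrance @ w)

    def marginal_penetrance(self, snp: int = 1) -> np.ndarray:
        """Penetrance of each genotype at one SNP, averaged over the other."""
        w = self.genotype_probs()
        return self.penetrance @ w if snp == 1 else self.penetrance.T @ w


#: The six pure-epistasis penetrance models used throughout the benchmark.
#: Models 1-2 have exactly zero marginal effects; models 3-6 were found by a
#: computational search minimizing the marginals, which are therefore equal
#: only to within a few percent.
RITCHIE_MODELS: dict[int, PenetranceModel] = {
    1: PenetranceModel(1, [[0.00, 0.10, 0.00],
                           [0.10, 0.00, 0.10],
                           [0.00, 0.10, 0.00]], p=0.50, q=0.50),
    2: PenetranceModel(2, [[0.00, 0.00, 0.10],
                           [0.00, 0.05, 0.00],
                           [0.10, 0.00, 0.00]], p=0.50, q=0.50),
    3: PenetranceModel(3, [[0.08, 0.07, 0.05],
                           [0.10, 0.00, 0.10],
                           [0.03, 0.10, 0.04]], p=0.25, q=0.75),
    4: PenetranceModel(4, [[0.00, 0.01, 0.09],
                           [0.04, 0.01, 0.08],
                           [0.07, 0.09, 0.03]], p=0.25, q=0.75),
    5: PenetranceModel(5, [[0.07, 0.05, 0.02],
                           [0.05, 0.09, 0.01],
                           [0.02, 0.01, 0.03]], p=0.10, q=0.90),
    6: PenetranceModel(6, [[0.090, 0.001, 0.020],
                           [0.080, 0.070, 0.005],
                           [0.003, 0.007, 0.020]], p=0.10, q=0.90),
}


@dataclass(frozen=True)
class SimConfig:
    """One simulation condition.

    Defaults match the benchmark protocol: 10 biallelic SNPs, 200 cases and
    200 controls, GE and MS rates of 5%.  ``noise`` is any subset of
    {"GE", "MS", "GH", "PC"}.  Null-SNP minor-allele frequencies are drawn
    once per dataset, uniform over ``null_maf_range``.
    """

    model_id: int
    n_cases: int = 200
    n_controls: int = 200
    n_snps: int = 10
    noise: frozenset = frozenset()
    ge_rate: float = 0.05
    ge_mode: str = "causal"
    ms_rate: float = 0.05
    seed: int = 0
    null_maf_range: tuple[float, float] = (0.05, 0.45)
    gh_second_model: int | None = None
    rejection_budget: int = 5_000_000

    def __post_init__(self) -> None:
        object.__setattr__(self, "noise", frozenset(self.noise))
        unknown = self.noise - set(NOISE_KINDS)
        if unknown:
            raise ValueError(f"unknown noise kind(s): {sorted(unknown)}")
        if self.model_id not in RITCHIE_MODELS:
            raise ValueError("model_id must be 1..6")
        if not (0 <= self.ge_rate <= 1 and 0 <= self.ms_rate <= 1):
            raise ValueError("noise rates must be in [0, 1]")
        if self.ge_mode not in ("causal", "readout"):
            raise ValueError("ge_mode must be 'causal' or 'readout'")
        n_planted = 4 if "GH" in self.noise else 2
        if self.n_snps < n_planted:
            raise ValueError(f"need at least {n_planted} SNPs for this noise setting")


def _corrupt(g: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    """Replace each genotype, with probability ``rate``, by one of the other two."""
    if rate <= 0:
        return g
    err = rng.random(g.shape) < rate
    return np.where(err, (g + rng.integers(1, 3, size=g.shape)) % 3, g)


def sample_individual(m: PenetranceModel, rng: np.random.Generator,
                      ge_rate: float = 0.0):
    """Draw one individual: (g1, g2, affected) under HWE + penetrance.

    A non-zero ``ge_rate`` applies causal-stage genotyping error: the drawn
    genotypes are corrupted first and disease probability read off the
    corrupted values (see module docstring).
    """
    g1, g2, affected = _sample_batch(m, rng, 1, ge_rate)
    return int(g1[0]), int(g2[0]), bool(affected[0])


def _sample_batch(m: PenetranceModel, rng: np.random.Generator, size: int,
                  ge_rate: float = 0.0):
    """Vectorized individual sampler; returns (g1, g2, affected) arrays."""
    w = m.genotype_probs()
    g1 = _corrupt(rng.choice(3, p=w, size=size), rng, ge_rate)
    g2 = _corrupt(rng.choice(3, p=w, size=size), rng, ge_rate)
    affected = rng.random(size) < m.penetrance[g1, g2]
    return g1, g2, affected


class RejectionBudgetError(RuntimeError):
    """Rejection sampling exceeded its draw budget (near-zero prevalence)."""


def _collect(m: PenetranceModel, rng, n_needed: int, affected: bool, budget: int,
             ge_rate: float = 0.0):
    """Rejection-sample genotype pairs conditional on affection status."""
    out1, out2 = [], []
    drawn = 0
    got = 0
    while got < n_needed:
        size = max(256, int(1.5 * (n_needed - got) /
                            max(m.prevalence() if affected else 1 - m.prevalence(), 1e-6)))
        size = min(size, 200_000)
        drawn += size
        if drawn > budget:
            raise RejectionBudgetError(
                f"model {m.model_id}: exceeded rejection budget of {budget} draws"
            )
        g1, g2, aff = _sample_batch(m, rng, size, ge_rate)
        keep = aff if affected else ~aff
        out1.append(g1[keep])
        out2.append(g2[keep])
        got += int(keep.sum())
    g1 = np.concatenate(out1)[:n_needed]
    g2 = np.concatenate(out2)[:n_needed]
    return g1, g2


def _collect_unaffected_two_pairs(mA, mB, rng, n_needed, budget, ge_rate=0.0):
    """Genotypes at both planted pairs for individuals unaffected under both."""
    outs = [[], [], [], []]
    got, drawn = 0, 0
    while got < n_needed:
        size = min(max(512, 2 * (n_needed - got)), 200_000)
        drawn += size
        if drawn > budget:
            raise RejectionBudgetError(f"exceeded rejection budget of {budget} draws")
        a1, a2, affA = _sample_batch(mA, rng, size, ge_rate)
        b1, b2, affB = _sample_batch(mB, rng, size, ge_rate)
        keep = ~affA & ~affB
        for out, g in zip(outs, (a1, a2, b1, b2)):
            out.append(g[keep])
        got += int(keep.sum())
    return [np.concatenate(o)[:n_needed] for o in outs]


def _split(n: int, k: int) -> list[int]:
    """Split n into k near-equal integer parts."""
    base = n // k
    parts = [base] * k
    for i in range(n - base * k):
        parts[i] += 1
    return parts


def simulate_dataset(cfg: SimConfig):
    """Generate one case-control dataset per the configuration.

    Returns ``(GenotypeMatrix, truth)`` where truth records the planted pair
    SNP ids (and the second pair under GH), the model id and the seed.  The
    planted pair occupies SNP columns 0-1 (and 2-3 under GH); all SNPs sit
    on one chromosome, 1 Mb apart, so a downstream distance filter never
    removes the planted pair.  The returned matrix is minor-allele coded.
    """
    rng = np.random.default_rng(cfg.seed)
    mA = RITCHIE_MODELS[cfg.model_id]
    gh = "GH" in cfg.noise
    pc = "PC" in cfg.noise
    mB = RITCHIE_MODELS[cfg.gh_second_model or cfg.model_id] if gh else None
    n_planted = 4 if gh else 2
    budget = cfg.rejection_budget
    ge = cfg.ge_rate if ("GE" in cfg.noise and cfg.ge_mode == "causal") else 0.0

    n_pheno = cfg.n_cases // 2 if pc else 0
    n_genetic = cfg.n_cases - n_pheno
    case_blocks = []
    if gh:
        nA, nB = _split(n_genetic, 2)
        # half the cases are caused by pair A; pair B genotypes are population draws
        a1, a2 = _collect(mA, rng, nA, affected=True, budget=budget, ge_rate=ge)
        w = mB.genotype_probs()
        case_blocks.append(np.column_stack(
            [a1, a2, _corrupt(rng.choice(3, p=w, size=nA), rng, ge),
             _corrupt(rng.choice(3, p=w, size=nA), rng, ge)]))
        b1, b2 = _collect(mB, rng, nB, affected=True, budget=budget, ge_rate=ge)
        w = mA.genotype_probs()
        case_blocks.append(np.column_stack(
            [_corrupt(rng.choice(3, p=w, size=nB), rng, ge),
             _corrupt(rng.choice(3, p=w, size=nB), rng, ge), b1, b2]))
    else:
        a1, a2 = _collect(mA, rng, n_genetic, affected=True, budget=budget, ge_rate=ge)
        case_blocks.append(np.column_stack([a1, a2]))
    if n_pheno:
        # phenocopies: population genotypes conditional on being unaffected
        if gh:
            cols = _collect_unaffected_two_pairs(mA, mB, rng, n_pheno, budget, ge_rate=ge)
            case_blocks.append(np.column_stack(cols))
        else:
            p1, p2 = _collect(mA, rng, n_pheno, affected=False, budget=budget, ge_rate=ge)
            case_blocks.append(np.column_stack([p1, p2]))
    case_planted = np.vstack(case_blocks)

    if gh:
        ctl_planted = np.column_stack(
            _collect_unaffected_two_pairs(mA, mB, rng, cfg.n_controls, budget,
                                          ge_rate=ge))
    else:
        c1, c2 = _collect(mA, rng, cfg.n_controls, affected=False, budget=budget, ge_rate=ge)
        ctl_planted = np.column_stack([c1, c2])

    n_samples = cfg.n_cases + cfg.n_controls
    n_null = cfg.n_snps - n_planted
    null_freqs = rng.uniform(*cfg.null_maf_range, size=n_null)
    null_g = _corrupt(rng.binomial(2, null_freqs, size=(n_samples, n_null)), rng, ge)

    genotypes = np.empty((n_samples, cfg.n_snps), dtype=np.int8)
    genotypes[:cfg.n_cases, :n_planted] = case_planted
    genotypes[cfg.n_cases:, :n_planted] = ctl_planted
    genotypes[:, n_planted:] = null_g
    phenotype = np.concatenate([np.ones(cfg.n_cases, dtype=np.int8),
                                np.zeros(cfg.n_controls, dtype=np.int8)])

    if "GE" in cfg.noise and cfg.ge_mode == "readout" and cfg.ge_rate > 0:
        genotypes = _corrupt(genotypes, rng, cfg.ge_rate).astype(np.int8)
    if "MS" in cfg.noise and cfg.ms_rate > 0:
        genotypes[rng.random(genotypes.shape) < cfg.ms_rate] = MISSING

    ids = [f"snp{k + 1}" for k in range(cfg.n_snps)]
    snp_meta = pd.DataFrame({
        "id": ids,
        "chrom": "1",
        "pos": [1_000_000 * (k + 1) for k in range(cfg.n_snps)],
        "allele1": "a",     # counted allele (frequency q at planted SNPs)
        "allele2": "A",
    })
    gm = recode_to_minor(GenotypeMatrix(
        genotypes, phenotype, snp_meta,
        [f"ind{i + 1}" for i in range(n_samples)],
    ))
    truth = {
        "model_id": cfg.model_id,
        "seed": cfg.seed,
        "noise": sorted(cfg.noise),
        "planted_pairs": [[ids[0], ids[1]]] + ([[ids[2], ids[3]]] if gh else []),
    }
    return gm, truth


def write_dataset(gm: GenotypeMatrix, truth: dict, path_prefix,
                  dialect: str = "ped_map") -> None:
    """Write the dataset in PLINK format with a JSON truth sidecar."""
    write_plink(gm, path_prefix, dialect=dialect)
    with open(Path(path_prefix).with_suffix(".truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
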