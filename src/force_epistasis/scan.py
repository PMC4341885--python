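"""Exhaustive SNP-pair scan.

Genotypes are pre-encoded, per SNP and per phenotype group, into packed bit
strings (a carrier mask for the collapsed class and a present mask for
non-missing calls), so every cell of a pair's collapsed contingency table is
an AND/NOT + popcount.  The scan enumerates all unordered SNP pairs passing
distance and sparsity filters, computes u(I_OR) for each, and keeps the
top-K pairs for the (more expensive) significance stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MISSING
from .genotype_io import GenotypeMatrix
from .ior_core import PairCounts, carrier_classes, u_ior_from_cells

__all__ = [
    "BitPlanes",
    "PairFilterConfig",
    "ScanResult",
    "encode",
    "pair_passes_filters",
    "exhaustive_scan",
    "candidate_pair_count",
]

logger = logging.getLogger(__name__)

#: Column order of the scan output table.
SCAN_COLUMNS = ["snp1", "chr1", "pos1", "snp2", "chr2", "pos2",
                "u_ior", "ior", "n_informative"]


@dataclass(frozen=True)
class PairFilterConfig:
    """Pair-level exclusion rules applied to raw (pre-pseudocount) counts.

    Same-chromosome pairs closer than ``min_distance_bp`` are excluded to
    avoid linkage disequilibrium; pairs whose collapsed table has any class
    row total below ``min_row_total`` or any cell below ``min_cell`` are
    excluded because sparse tables yield extreme but unstable u(I_OR).
    """

    min_distance_bp: int = 100_000
    min_row_total: int = 50
    min_cell: int = 5

    def __post_init__(self) -> None:
        if min(self.min_distance_bp, self.min_row_total, self.min_cell) < 0:
            raise ValueError("filter thresholds must be >= 0")


@dataclass
class BitPlanes:
    """Packed per-SNP bit masks, split by phenotype group.

    Arrays have shape (n_snps, n_bytes); bit b of byte w refers to the
    (8*w + b)-th sample of the group.  ``carrier`` is 1 where the sample is
    in the collapsed carrier class, ``present`` where the genotype is
    observed; carriers are always present.
    """

    model: str
    n_cases: int
    n_controls: int
    carrier_cases: np.ndarray
    present_cases: np.ndarray
    carrier_controls: np.ndarray
    present_controls: np.ndarray

    @property
    def n_snps(self) -> int:
        return self.carrier_cases.shape[0]

    def cell_counts_block(self, i: int, j: np.ndarray) -> dict[str, np.ndarray]:
        """All eight cells for pairs (i, j) with j an index array."""
        out = {}
        for grp, (car, pre) in (("case", (self.carrier_cases, self.present_cases)),
                                ("ctl", (self.carrier_controls, self.present_controls))):
            c1, p1 = car[i], pre[i]
            c2, p2 = car[j], pre[j]
            both_present = p1 & p2
            out[f"eta_{grp}"] = _popcount(c1 & c2)
            out[f"gamma_{grp}"] = _popcount(~c1 & c2 & p1)
            out[f"epsilon_{grp}"] = _popcount(c1 & ~c2 & p2)
            out[f"alpha_{grp}"] = _popcount(~c1 & ~c2 & both_present)
        return {
            "alpha": out["alpha_case"], "beta": out["alpha_ctl"],
            "gamma": out["gamma_case"], "delta": out["gamma_ctl"],
            "epsilon": out["epsilon_case"], "zeta": out["epsilon_ctl"],
            "eta": out["eta_case"], "theta": out["eta_ctl"],
        }

    def pair_counts(self, i: int, j: int) -> PairCounts:
        """Collapsed table for one pair, from bit operations."""
        cells = self.cell_counts_block(i, np.array([j]))
        vals = {k: int(v[0]) for k, v in cells.items()}
        return PairCounts(model=self.model, n_informative=sum(vals.values()), **vals)


def _popcount(packed: np.ndarray) -> np.ndarray:
    """Total set bits along the byte axis."""
    return np.bitwise_count(packed).sum(axis=-1, dtype=np.int64)


def _pack_group(genotypes: np.ndarray, model: str) -> tuple[np.ndarray, np.ndarray]:
    present = genotypes != MISSING
    carrier = carrier_classes(genotypes, model) & present
    # packbits over samples; genotypes arrive as (n_group, n_snps)
    carr = np.packbits(carrier.T, axis=1, bitorder="little")
    pres = np.packbits(present.T, axis=1, bitorder="little")
    return carr, pres


def encode(gm: GenotypeMatrix, model: str = "dominant") -> BitPlanes:
    """Bit-encode all genotypes for the chosen collapsing model."""
    case = gm.is_case
    cc, pc = _pack_group(gm.genotypes[case], model)
    cu, pu = _pack_group(gm.genotypes[~case], model)
    return BitPlanes(model=model, n_cases=gm.n_cases, n_controls=gm.n_controls,
                     carrier_cases=cc, present_cases=pc,
                     carrier_controls=cu, present_controls=pu)


def pair_passes_filters(c: PairCounts, meta1, meta2,
                        f: PairFilterConfig) -> tuple[bool, str | None]:
    """Apply the distance and sparsity rules to one pair.

    Returns (passes, reason) where reason is one of "distance", "row_total",
    "min_cell" or None.  The distance rule only applies within a chromosome.
    """
    if str(meta1["chrom"]) == str(meta2["chrom"]) and \
            abs(int(meta1["pos"]) - int(meta2["pos"])) < f.min_distance_bp:
        return False, "distance"
    if min(c.row_totals()) < f.min_row_total:
        return False, "row_total"
    if min(c.cells()) < f.min_cell:
        return False, "min_cell"
    return True, None


def candidate_pair_count(n_snps: int) -> int:
    """Number of unordered SNP pairs, n(n-1)/2."""
    return n_snps * (n_snps - 1) // 2


@dataclass
class ScanResult:
    """Ranked scan output plus bookkeeping counts."""

    pairs: pd.DataFrame
    n_candidate_pairs: int
    n_evaluated: int
    n_rejected: dict[str, int] = field(default_factory=dict)
    model: str = "dominant"


def exhaustive_scan(
    gm: GenotypeMatrix,
    model: str = "dominant",
    filters: PairFilterConfig | None = None,
    top_k: int = 500,
    pseudocount: float = 1.0,
    block_size: int = 2048,
) -> ScanResult:
    """Evaluate u(I_OR) for every SNP pair passing filters; rank the top K.

    The result is deterministic and independent of SNP input order and of
    ``block_size``: pairs are ranked by descending u(I_OR), ties broken by
    the lexicographic (snp1, snp2) id pair, and each output row lists the
    lexicographically smaller id first.
    """
    if gm.n_snps < 2:
        raise ValueError("scan requires at least 2 SNPs")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    gm.require_both_groups()
    if filters is None:
        filters = PairFilterConfig()

    planes = encode(gm, model)
    chrom = gm.snp_meta["chrom"].astype(str).to_numpy()
    pos = gm.snp_meta["pos"].to_numpy(dtype=np.int64)
    ids = gm.snp_meta["id"].astype(str).to_numpy()

    n = gm.n_snps
    rejected = {"distance": 0, "row_total": 0, "min_cell": 0}
    n_evaluated = 0
    acc: list[dict[str, np.ndarray]] = []

    def prune(chunks: list[dict[str, np.ndarray]]) -> list[dict[str, np.ndarray]]:
        cat = {k: np.concatenate([c[k] for c in chunks]) for k in chunks[0]}
        if cat["u"].size > top_k:
            kth = np.partition(cat["u"], cat["u"].size - top_k)[cat["u"].size - top_k]
            keep = cat["u"] >= kth      # keep boundary ties: determinism under blocking
            cat = {k: v[keep] for k, v in cat.items()}
        return [cat]

    for i in range(n - 1):
        j = np.arange(i + 1, n)
        cells = planes.cell_counts_block(i, j)

        same_chr = chrom[j] == chrom[i]
        dist_bad = same_chr & (np.abs(pos[j] - pos[i]) < filters.min_distance_bp)
        rows = np.stack([cells["alpha"] + cells["beta"],
                         cells["gamma"] + cells["delta"],
                         cells["epsilon"] + cells["zeta"],
                         cells["eta"] + cells["theta"]])
        row_bad = ~dist_bad & (rows.min(axis=0) < filters.min_row_total)
        cell_min = np.minimum.reduce([cells[k] for k in
                                      ("alpha", "beta", "gamma", "delta",
                                       "epsilon", "zeta", "eta", "theta")])
        cell_bad = ~dist_bad & ~row_bad & (cell_min < filters.min_cell)
        rejected["distance"] += int(dist_bad.sum())
        rejected["row_total"] += int(row_bad.sum())
        rejected["min_cell"] += int(cell_bad.sum())

        ok = ~(dist_bad | row_bad | cell_bad)
        n_evaluated += int(ok.sum())
        if not ok.any():
            continue
        jo = j[ok]
        ior, u = u_ior_from_cells(*(cells[k][ok] for k in
                                    ("alpha", "beta", "gamma", "delta",
                                     "epsilon", "zeta", "eta", "theta")),
                                  pseudocount=pseudocount)
        acc.append({
            "i": np.full(jo.size, i, dtype=np.int64), "j": jo,
            "u": u, "ior": ior,
            "n_inf": rows[:, ok].sum(axis=0),
        })
        if sum(c["u"].size for c in acc) > max(4 * top_k, block_size):
            acc = prune(acc)

    if not acc:
        logger.warning("no SNP pair passed the filters")
        pairs = pd.DataFrame(columns=SCAN_COLUMNS)
    else:
        cat = prune(acc)[0]
        id1, id2 = ids[cat["i"]], ids[cat["j"]]
        swap = id2 < id1            # canonical orientation: snp1 < snp2
        a = np.where(swap, cat["j"], cat["i"])
        b = np.where(swap, cat["i"], cat["j"])
        pairs = pd.DataFrame({
            "snp1": ids[a], "chr1": chrom[a], "pos1": pos[a],
            "snp2": ids[b], "chr2": chrom[b], "pos2": pos[b],
            "u_ior": cat["u"], "ior": cat["ior"], "n_informative": cat["n_inf"],
        })
        pairs = pairs.sort_values(["u_ior", "snp1", "snp2"],
                                  ascending=[False, True, True],
                                  kind="mergesort").head(top_k).reset_index(drop=True)

    return ScanResult(pairs=pairs,
                      n_candidate_pairs=candidate_pair_count(n),
                      n_evaluated=n_evaluated,
                      n_rejected=rejected,
                      model=model)
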