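"""Case-control genotype data in PLINK text and binary formats.

Reads PED/MAP and BED/BIM/FAM file sets into a :class:`GenotypeMatrix`
whose genotype codes count copies of the dataset-wide minor allele
(0/1/2, ``MISSING`` = -1), applies standard quality-control filters
(sample missingness, SNP missingness, minor-allele frequency) and
computes single-SNP association P-values used to flag main-effect SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .constants import MISSING

__all__ = [
    "GenotypeMatrix",
    "PlinkParseError",
    "read_plink",
    "write_plink",
    "qc_filter",
    "univariate_association",
    "drop_main_effect_snps",
    "recode_to_minor",
]

logger = logging.getLogger(__name__)

#: PLINK phenotype codes mapped to internal labels (1 = case, 0 = control).
_PHENO_MAP = {"2": 1, "1": 0}
_PHENO_UNKNOWN = {"0", "-9", "NA"}

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01


class PlinkParseError(ValueError):
    """Malformed PLINK file; message names the file and offending line."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype calls with phenotype labels and a SNP map.

    Attributes
    ----------
    genotypes
        int8 array of shape (n_samples, n_snps); each entry counts copies of
        ``allele1`` of the corresponding SNP (0, 1, 2) or is ``MISSING`` (-1).
        After :func:`recode_to_minor` (applied by the readers), ``allele1``
        is the dataset-wide minor allele.
    phenotype
        int8 vector, 1 = case, 0 = control.
    snp_meta
        DataFrame with columns ``id, chrom, pos, allele1, allele2``.
    sample_ids
        Per-sample identifiers (PLINK IID).
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        n_samples, n_snps = self.genotypes.shape
        if self.phenotype.shape != (n_samples,):
            raise ValueError("phenotype length does not match genotype rows")
        if len(self.snp_meta) != n_snps:
            raise ValueError("snp_meta length does not match genotype columns")
        if self.sample_ids and len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match genotype rows")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.genotypes[bad])}")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be 0 (control) or 1 (case)")
        if (self.snp_meta["pos"] < 0).any():
            raise ValueError("SNP positions must be non-negative")
        if self.snp_meta["id"].duplicated().any():
            raise ValueError("SNP ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == 1

    @property
    def n_cases(self) -> int:
        return int(np.count_nonzero(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.count_nonzero(self.phenotype == 0))

    def require_both_groups(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("analysis requires at least one case and one control")

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        positions = np.flatnonzero(idx) if idx.dtype == bool else idx
        ids = [self.sample_ids[i] for i in positions] if self.sample_ids else []
        return GenotypeMatrix(
            self.genotypes[positions], self.phenotype[positions], self.snp_meta.copy(), ids
        )

    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx], self.phenotype,
            self.snp_meta.iloc[np.flatnonzero(idx) if idx.dtype == bool else idx],
            list(self.sample_ids),
        )


def _allele1_frequency(genotypes: np.ndarray) -> np.ndarray:
    """Frequency of allele1 (the counted allele) per SNP over non-missing calls."""
    g = genotypes
    present = g != MISSING
    copies = np.where(present, g, 0).sum(axis=0)
    denom = 2 * present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(denom > 0, copies / np.maximum(denom, 1), 0.0)
    return freq


def recode_to_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flip genotype coding so codes count the dataset-wide minor allele.

    The minor allele is defined by pooled frequency over all samples
    (cases + controls); an exact tie at 0.5 is broken toward the
    lexicographically smaller allele name, so the result is deterministic
    and invariant to how alleles were listed in the input files.
    """
    freq = _allele1_frequency(gm.genotypes)
    a1 = gm.snp_meta["allele1"].astype(str).to_numpy()
    a2 = gm.snp_meta["allele2"].astype(str).to_numpy()
    flip = (freq > 0.5) | ((freq == 0.5) & (a2 < a1))
    if not flip.any():
        return gm
    g = gm.genotypes.copy()
    cols = np.flatnonzero(flip)
    block = g[:, cols]
    block[block != MISSING] = 2 - block[block != MISSING]
    g[:, cols] = block
    meta = gm.snp_meta.copy()
    meta.loc[flip, ["allele1", "allele2"]] = meta.loc[flip, ["allele2", "allele1"]].to_numpy()
    return GenotypeMatrix(g, gm.phenotype, meta, list(gm.sample_ids))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _read_map(path: Path, ext: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if ext == "map" and len(fields) != 4:
                raise PlinkParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            if ext == "bim" and len(fields) != 6:
                raise PlinkParseError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
            try:
                pos = int(fields[3])
            except ValueError as exc:
                raise PlinkParseError(f"{path}:{lineno}: bad position {fields[3]!r}") from exc
            row = {"chrom": fields[0], "id": fields[1], "pos": pos}
            if ext == "bim":
                row["allele1"], row["allele2"] = fields[4], fields[5]
            rows.append(row)
    return pd.DataFrame(rows)


def _parse_phenotypes(raw: list[str], path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Map PLINK phenotype strings; returns (keep mask, labels for kept)."""
    keep = np.ones(len(raw), dtype=bool)
    labels = np.zeros(len(raw), dtype=np.int8)
    n_unknown = 0
    for i, code in enumerate(raw):
        if code in _PHENO_MAP:
            labels[i] = _PHENO_MAP[code]
        elif code in _PHENO_UNKNOWN:
            keep[i] = False
            n_unknown += 1
        else:
            raise PlinkParseError(f"{path}: invalid phenotype code {code!r} for sample {i + 1}")
    if n_unknown:
        logger.info("dropped %d sample(s) with unknown phenotype from %s", n_unknown, path)
    return keep, labels


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    snp_meta = _read_map(prefix.with_suffix(".map"), "map")
    n_snps = len(snp_meta)
    ped = prefix.with_suffix(".ped")
    sample_ids: list[str] = []
    phen_raw: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise PlinkParseError(
                    f"{ped}:{lineno}: expected {6 + 2 * n_snps} fields, got {len(fields)}"
                )
            sample_ids.append(fields[1])
            phen_raw.append(fields[5])
            allele_rows.append(fields[6:])
    keep, labels = _parse_phenotypes(phen_raw, ped)
    alleles = np.array(allele_rows, dtype=object).reshape(len(sample_ids), n_snps, 2)

    # Per SNP, name the two observed alleles and count copies of one of them.
    genotypes = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    a1_names, a2_names = [], []
    for j in range(n_snps):
        col = alleles[:, j, :]
        missing = (col == "0").any(axis=1)
        names = sorted(set(col[~missing].ravel()))
        if len(names) > 2:
            raise PlinkParseError(f"{ped}: SNP {snp_meta['id'][j]} has >2 alleles: {names}")
        if not names:
            names = ["0"]
        a1 = names[0]
        a2 = names[1] if len(names) > 1 else names[0]
        a1_names.append(a1)
        a2_names.append(a2)
        genotypes[~missing, j] = (col[~missing] == a1).sum(axis=1)
    snp_meta = snp_meta.assign(allele1=a1_names, allele2=a2_names)

    gm = GenotypeMatrix(
        genotypes[keep], labels[keep], snp_meta,
        [s for s, k in zip(sample_ids, keep) if k],
    )
    return recode_to_minor(gm)


def _read_bed_bim_fam(prefix: Path) -> GenotypeMatrix:
    snp_meta = _read_map(prefix.with_suffix(".bim"), "bim")
    fam = prefix.with_suffix(".fam")
    sample_ids, phen_raw = [], []
    with open(fam) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6:
                raise PlinkParseError(f"{fam}:{lineno}: expected 6 fields, got {len(fields)}")
            sample_ids.append(fields[1])
            phen_raw.append(fields[5])
    keep, labels = _parse_phenotypes(phen_raw, fam)

    bed = prefix.with_suffix(".bed")
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:2].tobytes() != _BED_MAGIC:
        raise PlinkParseError(f"{bed}: bad magic bytes (not a PLINK BED file)")
    if raw[2] != _BED_SNP_MAJOR:
        raise PlinkParseError(f"{bed}: only SNP-major BED files are supported")
    n_samples, n_snps = len(sample_ids), len(snp_meta)
    bytes_per_snp = (n_samples + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * n_snps:
        raise PlinkParseError(
            f"{bed}: size mismatch ({body.size} data bytes, expected {bytes_per_snp * n_snps})"
        )
    codes = body.reshape(n_snps, bytes_per_snp)
    # Unpack 2-bit codes, sample-fastest within each byte (little-endian pairs).
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (codes[:, :, None] >> shifts) & 0b11          # (n_snps, bytes, 4)
    two_bit = two_bit.reshape(n_snps, -1)[:, :n_samples]
    # 00 -> 2 copies of allele1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2, MISSING, 1, 0], dtype=np.int8)
    genotypes = lut[two_bit].T.copy()                       # (n_samples, n_snps)

    gm = GenotypeMatrix(
        genotypes[keep], labels[keep], snp_meta,
        [s for s, k in zip(sample_ids, keep) if k],
    )
    return recode_to_minor(gm)


def read_plink(path_prefix, dialect: str | None = None) -> GenotypeMatrix:
    """Read a PLINK file set into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path_prefix
        Path without extension; ``dialect`` selects ``"ped_map"`` or
        ``"bed_bim_fam"``.  When omitted the dialect is inferred from which
        files exist (BED preferred).

    Genotype codes in the result count copies of the dataset-wide minor
    allele; PLINK phenotype 2 maps to case, 1 to control, and samples with
    unknown phenotype (0/-9) are dropped with a logged count.
    """
    prefix = Path(path_prefix)
    if dialect is None:
        dialect = "bed_bim_fam" if prefix.with_suffix(".bed").exists() else "ped_map"
    if dialect == "ped_map":
        return _read_ped_map(prefix)
    if dialect == "bed_bim_fam":
        return _read_bed_bim_fam(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_plink(gm: GenotypeMatrix, path_prefix, dialect: str = "ped_map") -> None:
    """Write a GenotypeMatrix as PED/MAP or BED/BIM/FAM."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ids = gm.sample_ids or [f"ind{i + 1}" for i in range(gm.n_samples)]
    pheno_codes = np.where(gm.phenotype == 1, "2", "1")
    if dialect == "ped_map":
        _write_map(gm, prefix.with_suffix(".map"))
        a1 = gm.snp_meta["allele1"].astype(str).to_numpy()
        a2 = gm.snp_meta["allele2"].astype(str).to_numpy()
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, sid in enumerate(ids):
                fields = [sid, sid, "0", "0", "0", pheno_codes[i]]
                for j, g in enumerate(gm.genotypes[i]):
                    if g == MISSING:
                        fields += ["0", "0"]
                    else:
                        fields += [a1[j]] * int(g) + [a2[j]] * int(2 - g)
                fh.write(" ".join(fields) + "\n")
    elif dialect == "bed_bim_fam":
        _write_bim(gm, prefix.with_suffix(".bim"))
        with open(prefix.with_suffix(".fam"), "w") as fh:
            for i, sid in enumerate(ids):
                fh.write(f"{sid} {sid} 0 0 0 {pheno_codes[i]}\n")
        # genotype code -> 2-bit BED code (00 hom a1, 10 het, 11 hom a2, 01 missing)
        lut = np.array([0b11, 0b10, 0b00], dtype=np.uint8)
        codes = np.where(gm.genotypes == MISSING, 0b01,
                         lut[np.clip(gm.genotypes, 0, 2)]).astype(np.uint8)
        n_pad = (-gm.n_samples) % 4
        if n_pad:
            codes = np.vstack([codes, np.zeros((n_pad, gm.n_snps), dtype=np.uint8)])
        codes = codes.T.reshape(gm.n_snps, -1, 4)
        packed = (codes[:, :, 0] | (codes[:, :, 1] << 2)
                  | (codes[:, :, 2] << 4) | (codes[:, :, 3] << 6)).astype(np.uint8)
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(_BED_MAGIC + bytes([_BED_SNP_MAJOR]))
            fh.write(packed.tobytes())
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_map(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        for _, r in gm.snp_meta.iterrows():
            fh.write(f"{r['chrom']} {r['id']} 0 {r['pos']}\n")


def _write_bim(gm: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        for _, r in gm.snp_meta.iterrows():
            fh.write(f"{r['chrom']} {r['id']} 0 {r['pos']} {r['allele1']} {r['allele2']}\n")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(
    gm: GenotypeMatrix,
    max_sample_missing: float = 0.05,
    max_snp_missing: float = 0.05,
    min_maf: float = 0.05,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply standard QC in the order samples -> SNP missingness -> MAF.

    A sample is removed when its missing rate exceeds ``max_sample_missing``;
    a SNP when its missing rate (over surviving samples) exceeds
    ``max_snp_missing`` or its minor-allele frequency falls strictly below
    ``min_maf``.  Each step is recomputed on the data surviving the previous
    one.  Returns the filtered matrix and a report with one row per step
    (``step, n_removed, n_remaining``).
    """
    if not (0 <= min_maf <= 0.5):
        raise ValueError("min_maf must be in [0, 0.5]")
    if not (0 <= max_sample_missing <= 1 and 0 <= max_snp_missing <= 1):
        raise ValueError("missing-rate thresholds must be in [0, 1]")

    steps = []

    miss_rate = (gm.genotypes == MISSING).mean(axis=1)
    keep_samples = miss_rate <= max_sample_missing
    steps.append(("sample_missingness", int((~keep_samples).sum()), int(keep_samples.sum())))
    gm = gm.take_samples(keep_samples)
    if gm.n_samples == 0:
        raise ValueError("empty after QC: all samples removed")

    snp_miss = (gm.genotypes == MISSING).mean(axis=0)
    keep_snps = snp_miss <= max_snp_missing
    steps.append(("snp_missingness", int((~keep_snps).sum()), int(keep_snps.sum())))
    gm = gm.take_snps(keep_snps)

    freq = _allele1_frequency(gm.genotypes)
    maf = np.minimum(freq, 1 - freq)
    keep_maf = maf >= min_maf          # strict "below min_maf" exclusion
    steps.append(("maf", int((~keep_maf).sum()), int(keep_maf.sum())))
    gm = gm.take_snps(keep_maf)
    if gm.n_snps == 0:
        raise ValueError("empty after QC: all SNPs removed")

    report = pd.DataFrame(steps, columns=["step", "n_removed", "n_remaining"])
    # Filtering can change which allele is minor; restore the coding invariant.
    return recode_to_minor(gm), report


def univariate_association(gm: GenotypeMatrix) -> np.ndarray:
    """Two-sided single-SNP allelic association P-value per SNP.

    Uses the 1-df allelic chi-square on the 2x2 table of minor/major allele
    counts in cases versus controls (no continuity correction).  Monomorphic
    SNPs get P = 1 by convention (logged).
    """
    gm.require_both_groups()
    g = gm.genotypes
    present = g != MISSING
    copies = np.where(present, g, 0)
    case = gm.is_case
    a = copies[case].sum(axis=0).astype(float)              # minor alleles, cases
    b = (2 * present[case].sum(axis=0) - a).astype(float)   # major alleles, cases
    c = copies[~case].sum(axis=0).astype(float)
    d = (2 * present[~case].sum(axis=0) - c).astype(float)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    mono = (a + c == 0) | (b + d == 0)
    if mono.any():
        logger.info("%d monomorphic SNP(s): P set to 1", int(mono.sum()))
    chi2 = np.where(mono | ~np.isfinite(chi2), 0.0, chi2)
    return stats.chi2.sf(chi2, df=1)


def drop_main_effect_snps(
    gm: GenotypeMatrix, threshold: float = 1e-5
) -> tuple[GenotypeMatrix, list[str]]:
    """Remove SNPs whose univariate association P-value is <= ``threshold``.

    Main-effect SNPs can masquerade as interacting pairs, so they are removed
    before the pair scan when the goal is to demonstrate pure interactions.
    Returns the filtered matrix and the removed SNP ids.
    """
    p = univariate_association(gm)
    drop = p <= threshold
    removed = gm.snp_meta.loc[drop, "id"].tolist()
    if removed:
        logger.info("removed %d main-effect SNP(s) at P<=%g", len(removed), threshold)
    return gm.take_snps(~drop), removed
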