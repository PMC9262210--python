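"""PGS construction: LD-structured genotypes, greedy clumping, scoring.

Variants are selected from GWAS summary statistics by greedy LD clumping —
repeatedly taking the smallest-p variant below the p-value threshold and
removing all variants within a physical window whose dosage r^2 with it
reaches the r^2 threshold (defaults P < 1e-5, r^2 < 0.001, window 10000 kb).
The score is the weighted sum of effect-allele dosages, optionally
standardized to SD units.

There is no real LD reference panel here; :func:`simulate_ld_genotypes`
provides a synthetic one with block-diagonal AR(1) LD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SummaryStats",
    "GenotypeMatrix",
    "ClumpConfig",
    "simulate_ld_genotypes",
    "ld_clump",
    "score_pgs",
    "marginal_gwas",
]

SUMSTAT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "beta", "p"]


def validate_sumstats(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and invariants of a summary-statistics table."""
    missing = [c for c in SUMSTAT_COLUMNS if c not in stats_df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if stats_df["id"].duplicated().any():
        dup = stats_df.loc[stats_df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate variant id: {dup}")
    if ((stats_df["p"] <= 0) | (stats_df["p"] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (stats_df["pos"] < 0).any():
        raise ValueError("positions must be non-negative")
    return stats_df


def read_sumstats(path) -> pd.DataFrame:
    """Read a tab-separated summary-statistics table."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return validate_sumstats(df)


# type alias for clarity; summary stats travel as a validated DataFrame
SummaryStats = pd.DataFrame


@dataclass(frozen=True)
class ClumpConfig:
    p_threshold: float = 1.0e-5
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.r2_threshold <= 0 or self.window_kb <= 0:
            raise ValueError("clumping thresholds must be positive")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Dosage matrix (individuals x variants) with aligned variant metadata.

    ``variants`` carries id / chrom / pos / effect_allele / maf, row-aligned
    to the dosage columns.
    """

    dosages: np.ndarray = field(repr=False)
    variants: pd.DataFrame = field(repr=False)
    block_size: int | None = None
    rho: float | None = None

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.variants)} variant metadata rows"
            )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        ids = self.variants["id"].tolist()
        return self.dosages[:, ids.index(variant_id)]


def simulate_ld_genotypes(
    n: int,
    m_variants: int,
    block_size: int = 10,
    rho: float = 0.8,
    maf_range: tuple[float, float] = (0.05, 0.5),
    spacing_bp: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Simulate biallelic dosages with block-diagonal AR(1) LD.

    Two latent haplotype draws per individual share a within-block AR(1)
    correlation ``rho`` between adjacent variants; each is thresholded at
    the allele-frequency quantile and summed to a 0/1/2 dosage.  Blocks are
    independent; all variants sit on one chromosome at ``spacing_bp``
    intervals.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=m_variants)
    thresholds = stats.norm.ppf(1.0 - mafs)

    def haplotypes() -> np.ndarray:
        z = rng.standard_normal((n, m_variants))
        if rho > 0:
            # AR(1) within blocks: z_j = rho*z_{j-1} + sqrt(1-rho^2)*e_j
            w = np.sqrt(1.0 - rho * rho)
            for j in range(1, m_variants):
                if j % block_size != 0:
                    z[:, j] = rho * z[:, j - 1] + w * z[:, j]
        return (z > thresholds).astype(np.float64)

    dosages = haplotypes() + haplotypes()
    variants = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m_variants)],
            "chrom": 1,
            "pos": (1 + np.arange(m_variants) * spacing_bp).astype(int),
            "effect_allele": "A",
            "maf": mafs,
        }
    )
    return GenotypeMatrix(dosages, variants, block_size=block_size, rho=rho)


def _dosage_r2(dosages: np.ndarray) -> np.ndarray:
    """Pairwise squared sample correlation between dosage columns."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(dosages, rowvar=False)
    r = np.nan_to_num(np.atleast_2d(r))
    return r * r


def ld_clump(
    stats_df: SummaryStats,
    ld_source: GenotypeMatrix,
    config: ClumpConfig = ClumpConfig(),
) -> list[str]:
    """Greedy LD clumping; returns selected variant ids in selection order.

    Repeatedly select the not-yet-removed variant with the smallest p-value
    below ``p_threshold`` (ties broken by chromosome, then position, then
    id), and remove every unselected variant on the same chromosome within
    ``window_kb`` whose dosage r^2 with the selected variant is at least
    ``r2_threshold``.
    """
    validate_sumstats(stats_df)
    stat_ids = list(stats_df["id"])
    ld_ids = list(ld_source.variants["id"])
    if stat_ids != ld_ids:
        for a, b in zip(stat_ids, ld_ids):
            if a != b:
                raise ValueError(
                    f"summary statistics and LD source are not aligned: "
                    f"{a!r} vs {b!r}"
                )
        raise ValueError(
            "summary statistics and LD source differ in length "
            f"({len(stat_ids)} vs {len(ld_ids)})"
        )

    r2 = _dosage_r2(ld_source.dosages)
    chrom = stats_df["chrom"].to_numpy()
    pos = stats_df["pos"].to_numpy(dtype=np.int64)
    p = stats_df["p"].to_numpy(dtype=float)
    window_bp = config.window_kb * 1000.0

    candidate = p < config.p_threshold
    # deterministic greedy order: p, then chrom, then pos, then id
    order = sorted(
        np.nonzero(candidate)[0],
        key=lambda j: (p[j], chrom[j], pos[j], stat_ids[j]),
    )
    removed = np.zeros(len(stat_ids), dtype=bool)
    selected: list[str] = []
    for j in order:
        if removed[j]:
            continue
        selected.append(stat_ids[j])
        removed[j] = True
        same = (
            (chrom == chrom[j])
            & (np.abs(pos - pos[j]) <= window_bp)
            & ~removed
            & (r2[j] >= config.r2_threshold)
        )
        removed |= same
    return selected


def score_pgs(
    genotypes: GenotypeMatrix,
    weights: dict[str, float] | pd.Series,
    standardize: bool = True,
) -> np.ndarray:
    """Per-individual PGS: sum of beta * dosage over the weighted variants.

    With ``standardize`` the score is centred and scaled to sample SD 1
    (SD units); a zero-variance score cannot be standardized and raises.
    """
    if isinstance(weights, pd.Series):
        weights = weights.to_dict()
    ids = list(genotypes.variants["id"])
    index = {vid: j for j, vid in enumerate(ids)}
    missing = [vid for vid in weights if vid not in index]
    if missing:
        raise ValueError(f"weights reference variants absent from genotypes: {missing}")
    w = np.zeros(genotypes.n_variants)
    for vid, beta in weights.items():
        w[index[vid]] = beta
    score = genotypes.dosages @ w
    if standardize:
        sd = score.std(ddof=0)
        if sd == 0:
            raise ValueError("score has zero variance; cannot standardize")
        score = (score - score.mean()) / sd
    return score


def marginal_gwas(genotypes: GenotypeMatrix, phenotype: np.ndarray) -> SummaryStats:
    """Per-variant simple-regression summary statistics.

    Zero-variance variants get beta 0 and p 1 with a warning, so downstream
    clumping never selects them.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != genotypes.n_individuals:
        raise ValueError(
            f"phenotype length {y.shape[0]} != {genotypes.n_individuals} individuals"
        )
    X = genotypes.dosages
    n = y.shape[0]
    xm = X.mean(axis=0)
    xc = X - xm
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    zero_var = sxx == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance variants reported with "
            "beta=0, p=1",
            stacklevel=2,
        )
    sxy = xc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(zero_var, 0.0, sxy / np.where(zero_var, 1.0, sxx))
        resid_ss = (yc * yc).sum() - beta * sxy
        dof = max(n - 2, 1)
        se = np.sqrt(np.maximum(resid_ss, 0.0) / dof / np.where(zero_var, 1.0, sxx))
        t = np.where(
            se > 0,
            beta / np.where(se == 0, 1.0, se),
            np.where(beta == 0, 0.0, np.inf),  # exact fit: p underflows to 0
        )
    p = 2.0 * stats.t.sf(np.abs(t), df=dof)
    p = np.where(zero_var, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    out = genotypes.variants[["id", "chrom", "pos", "effect_allele"]].copy()
    out["beta"] = beta
    out["p"] = p
    return validate_sumstats(out)
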