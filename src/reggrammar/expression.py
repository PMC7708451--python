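"""Expression-matrix processing: TPM, filters, Box-Cox, length de-bias.

The modelling target is built from raw counts in four steps: TPM
normalization, abundance (median TPM < 5) and stability (RSD >= 1)
filters, a Box-Cox power transform of the per-gene median, and removal
of the residual correlation with ORF length by ordinary least squares.
All standard deviations are sample (n-1) estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Genes x experiments matrix with a units tag ('counts' or 'TPM')."""

    gene_ids: list[str]
    experiment_ids: list[str]
    values: np.ndarray
    units: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.shape != (len(self.gene_ids), len(self.experiment_ids)):
            raise ValueError("matrix shape does not match id lists")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.experiment_ids
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, units: str = "counts") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(), units)


@dataclass
class ExpressionSummary:
    gene_id: str
    median_tpm: float
    rsd: float
    boxcox_lambda: float | None = None
    target: float | None = None


def tpm(counts: np.ndarray, orf_lengths: np.ndarray) -> np.ndarray:
    """Transcripts per million for one experiment.

    tpm_i = (counts_i / length_kb_i) / sum_j (counts_j / length_kb_j) * 1e6
    """
    counts = np.asarray(counts, dtype=float)
    orf_lengths = np.asarray(orf_lengths, dtype=float)
    if (orf_lengths <= 0).any():
        raise ValueError("ORF lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rpk = counts / (orf_lengths / 1000.0)
    total = rpk.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    return rpk / total * 1e6


def tpm_matrix(matrix: ExpressionMatrix, orf_lengths: np.ndarray) -> ExpressionMatrix:
    """Column-wise TPM of a raw-count matrix."""
    cols = np.stack(
        [tpm(matrix.values[:, j], orf_lengths) for j in range(matrix.values.shape[1])],
        axis=1,
    )
    return ExpressionMatrix(matrix.gene_ids, matrix.experiment_ids, cols, "TPM")


def summarize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene median TPM, mean, sample SD and RSD."""
    if len(matrix.experiment_ids) < 2:
        raise ValueError("need >= 2 experiments")
    v = matrix.values
    mu = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mu > 0, sd / mu, np.inf)
    return pd.DataFrame(
        {
            "median_tpm": np.median(v, axis=1),
            "mean_tpm": mu,
            "sd_tpm": sd,
            "rsd": rsd,
        },
        index=matrix.gene_ids,
    )


def filter_genes(
    matrix: ExpressionMatrix,
    min_tpm: float = 5.0,
    rsd_max: float = 1.0,
) -> tuple[list[str], list[ExpressionSummary]]:
    """Drop genes with median TPM < ``min_tpm``, then genes with
    RSD >= ``rsd_max``. Returns kept ids and their summaries."""
    if matrix.units != "TPM":
        raise ValueError("filter_genes expects a TPM matrix")
    summ = summarize(matrix)
    low = summ["median_tpm"] < min_tpm
    noisy = (~low) & (summ["rsd"] >= rsd_max)
    kept = summ.index[~(low | noisy)]
    if len(kept) == 0:
        raise ValueError(
            f"no genes left: {int(low.sum())} removed by abundance filter, "
            f"{int(noisy.sum())} by RSD filter"
        )
    summaries = [
        ExpressionSummary(g, float(summ.at[g, "median_tpm"]), float(summ.at[g, "rsd"]))
        for g in kept
    ]
    return list(kept), summaries


def boxcox(values: np.ndarray, lmbda: float | None = None) -> tuple[np.ndarray, float]:
    """Box-Cox transform; lambda by maximum likelihood when not given."""
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("Box-Cox requires strictly positive input")
    if lmbda is None:
        transformed, lmbda = stats.boxcox(values)
        return transformed, float(lmbda)
    return stats.boxcox(values, lmbda=lmbda), float(lmbda)


def inverse_boxcox(values: np.ndarray, lmbda: float) -> np.ndarray:
    from scipy.special import inv_boxcox

    return inv_boxcox(np.asarray(values, dtype=float), lmbda)


def length_correct(
    targets: np.ndarray, orf_lengths: np.ndarray
) -> tuple[np.ndarray, tuple[float, float]]:
    """OLS residuals of ``targets`` on log10 ORF length.

    Returns (residuals, (intercept, slope)). Residuals are exactly
    uncorrelated with the regressor (OLS orthogonality).
    """
    targets = np.asarray(targets, dtype=float)
    orf_lengths = np.asarray(orf_lengths, dtype=float)
    if targets.shape != orf_lengths.shape or targets.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    x = np.log10(orf_lengths)
    if np.ptp(x) == 0:
        warnings.warn("constant ORF lengths; returning mean-centred targets")
        return targets - targets.mean(), (float(targets.mean()), 0.0)
    slope, intercept = np.polyfit(x, targets, 1)
    resid = targets - (intercept + slope * x)
    return resid, (float(intercept), float(slope))


@dataclass
class TargetTransform:
    """Median TPM -> modelling target (Box-Cox then length de-bias).

    Fit on the training split only and frozen, so validation/test values
    never leak into the lambda estimate or the length fit. The inverse
    maps model outputs back to the TPM scale for fold-change analysis.
    """

    lmbda: float | None = None
    intercept: float = 0.0
    slope: float = 0.0
    tpm_floor: float = 1e-3

    def fit(self, median_tpm: np.ndarray, orf_lengths: np.ndarray) -> "TargetTransform":
        transformed, self.lmbda = boxcox(median_tpm)
        _, (self.intercept, self.slope) = length_correct(transformed, orf_lengths)
        return self

    def transform(self, median_tpm: np.ndarray, orf_lengths: np.ndarray) -> np.ndarray:
        if self.lmbda is None:
            raise RuntimeError("TargetTransform not fitted")
        transformed, _ = boxcox(np.asarray(median_tpm, float), lmbda=self.lmbda)
        x = np.log10(np.asarray(orf_lengths, float))
        return transformed - (self.intercept + self.slope * x)

    def inverse(self, target: np.ndarray, orf_lengths: np.ndarray) -> np.ndarray:
        if self.lmbda is None:
            raise RuntimeError("TargetTransform not fitted")
        x = np.log10(np.asarray(orf_lengths, float))
        transformed = np.asarray(target, float) + self.intercept + self.slope * x
        # keep the power-transform inversion inside its domain
        if self.lmbda != 0:
            transformed = np.maximum(transformed, -1.0 / self.lmbda + 1e-9) \
                if self.lmbda > 0 else np.minimum(transformed, -1.0 / self.lmbda - 1e-9)
        out = inverse_boxcox(transformed, self.lmbda)
        return np.maximum(out, self.tpm_floor)


def median_target(
    summaries: list[ExpressionSummary],
    orf_lengths: np.ndarray,
    transform: TargetTransform | None = None,
    fit_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, TargetTransform]:
    """Fill ``summary.target`` with the length-corrected Box-Cox median.

    ``fit_mask`` restricts transform fitting to a subset (the training
    split); transformation is applied to all genes.
    """
    med = np.array([s.median_tpm for s in summaries])
    orf_lengths = np.asarray(orf_lengths, dtype=float)
    if transform is None:
        transform = TargetTransform()
        if fit_mask is None:
            transform.fit(med, orf_lengths)
        else:
            transform.fit(med[fit_mask], orf_lengths[fit_mask])
    target = transform.transform(med, orf_lengths)
    for s, t in zip(summaries, target):
        s.target = float(t)
        s.boxcox_lambda = transform.lmbda
    return target, transform


def variance_ratio(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per gene: var of per-gene median TPM across genes over that gene's
    variance across experiments. Zero per-gene variance -> +inf, flagged."""
    if len(matrix.gene_ids) < 2 or len(matrix.experiment_ids) < 2:
        raise ValueError("need >= 2 genes and >= 2 experiments")
    v = matrix.values
    across = float(np.var(np.median(v, axis=1), ddof=1))
    per_gene = v.var(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        ratio = np.where(per_gene > 0, across / per_gene, np.inf)
    return pd.DataFrame(
        {"ratio": ratio, "flagged_infinite": per_gene == 0}, index=matrix.gene_ids
    )
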