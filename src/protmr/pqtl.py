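"""pQTL mapping: additive-model association and significance thresholds.

Each protein is regressed on genotype dosage (0/1/2) with optional
covariates; the per-variant slope, its standard error, and a two-sided t
p-value on n - k - 2 degrees of freedom (k = number of covariates) are
emitted as association records. The study-wide significance threshold is
5e-8 divided by the number of principal components needed to explain 95%
of the proteome's variance (computed on column-standardized analytes);
the unrounded value is used for filtering, one-significant-figure rounding
only for reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENOME_WIDE_ALPHA = 5e-8

ASSOC_COLUMNS = [
    "protein_id",
    "variant_id",
    "chrom",
    "pos",
    "ea",
    "nea",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "cis_flag",
]


@dataclass
class ThresholdSpec:
    """PC-derived study-wide significance threshold."""

    n_pcs: int
    study_wide_alpha: float
    genome_wide_alpha: float = GENOME_WIDE_ALPHA
    variance_explained: float = 0.95
    standardized: bool = True

    def __post_init__(self):
        if self.study_wide_alpha > self.genome_wide_alpha:
            raise ValueError("study-wide alpha must not exceed genome-wide alpha")

    @property
    def study_wide_alpha_rounded(self) -> float:
        return round_to_sigfigs(self.study_wide_alpha, 1)


def round_to_sigfigs(x: float, sig: int = 1) -> float:
    if x == 0:
        return 0.0
    exp = int(np.floor(np.log10(abs(x))))
    return float(round(x, -exp + sig - 1))


def study_wide_alpha(n_pcs: int) -> float:
    """5e-8 / number of principal components (unrounded)."""
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    return GENOME_WIDE_ALPHA / n_pcs


def derive_study_wide_threshold(
    proteins, variance_explained: float = 0.95, standardize: bool = True
) -> ThresholdSpec:
    """Smallest k whose top-k PCs explain >= the target variance fraction.

    ``proteins`` is a cleaned ProteinMatrix or a samples x analytes
    DataFrame. PCA runs on column-standardized values by default.
    """
    vals = proteins.values if hasattr(proteins, "sample_meta") else proteins
    x = np.asarray(vals, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 analytes")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance analyte; cannot standardize")
        x = x / sd
    if not np.any(x):
        raise ValueError("matrix has zero total variance")
    sv = np.linalg.svd(x, compute_uv=False)
    var = sv**2
    cum = np.cumsum(var) / var.sum()
    n_pcs = int(np.searchsorted(cum, variance_explained - 1e-12) + 1)
    return ThresholdSpec(
        n_pcs=n_pcs,
        study_wide_alpha=study_wide_alpha(n_pcs),
        variance_explained=variance_explained,
        standardized=standardize,
    )


def fit_pqtl(
    proteins,
    panel,
    covariates: pd.DataFrame | None = None,
    maf_min: float = 0.02,
) -> pd.DataFrame:
    """OLS of each protein on each variant's dosage, with covariates.

    Uses Frisch-Waugh-Lovell residualization: protein and dosage are both
    residualized on [intercept, covariates], then the per-variant slope is
    the simple-regression coefficient of the residuals, with the t
    reference on n - k - 2 degrees of freedom. Variants with MAF below
    ``maf_min`` are excluded.
    """
    vals = proteins.values if hasattr(proteins, "sample_meta") else proteins
    y_all = np.asarray(vals, dtype=float)
    n = y_all.shape[0]
    if panel.n_samples != n:
        raise ValueError("sample count mismatch between proteins and panel")

    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        k = c.shape[1]
        design = np.column_stack([np.ones(n), c])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
    else:
        k = 0
        design = np.ones((n, 1))
    df = n - k - 2
    if df <= 0:
        raise ValueError(f"not enough samples: n={n}, covariates={k}")

    q, _ = np.linalg.qr(design)

    def residualize(m: np.ndarray) -> np.ndarray:
        return m - q @ (q.T @ m)

    g = panel.dosages.astype(float)
    eaf = g.mean(axis=0) / 2
    maf = np.minimum(eaf, 1 - eaf)
    keep = maf >= maf_min
    if np.any(g.std(axis=0) == 0):
        const = [panel.variant_ids[j] for j in np.flatnonzero(g.std(axis=0) == 0)]
        raise ValueError(f"constant dosage (zero-variance regressor): {const}")
    g_res = residualize(g[:, keep])
    y_res = residualize(y_all)
    sxx = np.einsum("ij,ij->j", g_res, g_res)
    meta = panel.variant_meta.iloc[keep]

    frames = []
    analyte_ids = list(vals.columns) if hasattr(vals, "columns") else [
        f"P{i}" for i in range(y_all.shape[1])
    ]
    for i, pid in enumerate(analyte_ids):
        yr = y_res[:, i]
        sxy = g_res.T @ yr
        beta = sxy / sxx
        rss = yr @ yr - beta * sxy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / sxx)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pval = np.clip(2 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "protein_id": pid,
                    "variant_id": meta.index,
                    "chrom": meta["chrom"].to_numpy(),
                    "pos": meta["pos"].to_numpy(),
                    "ea": meta["ea"].to_numpy(),
                    "nea": meta["nea"].to_numpy(),
                    "eaf": eaf[keep],
                    "beta": beta,
                    "se": se,
                    "pval": pval,
                    "n": n,
                    "cis_flag": pd.NA,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def classify_cis_trans(
    assoc: pd.DataFrame, genes: pd.DataFrame, window: int = 1_000_000
) -> pd.DataFrame:
    """Set cis_flag: same chromosome and |pos - TSS| <= window (closed).

    ``genes`` is indexed by protein_id with columns chrom and tss.
    """
    out = assoc.copy()
    missing = set(out["protein_id"]) - set(genes.index)
    if missing:
        raise KeyError(f"proteins missing from gene annotation: {sorted(missing)}")
    tss = out["protein_id"].map(genes["tss"]).to_numpy(dtype=float)
    gchrom = out["protein_id"].map(genes["chrom"]).astype(str)
    same_chrom = out["chrom"].astype(str).to_numpy() == gchrom.to_numpy()
    out["cis_flag"] = same_chrom & (
        np.abs(out["pos"].to_numpy(dtype=float) - tss) <= window
    )
    return out
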