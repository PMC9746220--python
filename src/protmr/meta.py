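"""Fixed-effect meta-analysis with heterogeneity flags.

Two combination schemes over allele-aligned per-study records:

* STDERR — inverse-variance weighting: w_i = 1/se_i^2,
  beta = sum(w b)/sum(w), se = sum(w)^(-1/2), two-sided normal p, and
  Cochran's Q = sum w_i (b_i - beta)^2 ~ chi2(m - 1).
* SAMPLESIZE — z-combination with w_i = sqrt(n_i):
  z = sum(w_i z_i)/sqrt(sum w_i^2). Under the fixed-effect model
  z_i = d*sqrt(n_i) + e_i with unit-variance errors the weighted
  least-squares fit of d gives fitted values z*sqrt(n_i/N), and
  Q = sum (z_i - z*sqrt(n_i/N))^2 ~ chi2(m - 1) under homogeneity.

Heterogeneity flags follow the reference naming: flag_heterogeneity
(STDERR HetPVal < 0.05), flag_heterogeneity2 (SAMPLESIZE HetPVal < 0.05),
flag_hetero.all (both).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

HET_ALPHA = 0.05


def _as_arrays(*xs):
    out = [np.asarray(x, dtype=float) for x in xs]
    m = len(out[0])
    if any(len(a) != m for a in out):
        raise ValueError("per-study inputs must have equal length")
    return out


def meta_fixed_stderr(betas, ses) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect combination: (beta, se, p)."""
    b, s = _as_arrays(betas, ses)
    if len(b) < 2:
        raise ValueError("need >= 2 studies (singletons pass through upstream)")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def meta_samplesize(zs, ns) -> tuple[float, float]:
    """Sample-size-weighted z combination: (z_meta, p)."""
    z, n = _as_arrays(zs, ns)
    if len(z) < 2:
        raise ValueError("need >= 2 studies")
    if np.any(~np.isfinite(n)) or np.any(n <= 0):
        raise ValueError("sample sizes must be positive and present")
    w = np.sqrt(n)
    z_meta = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    p = float(2 * stats.norm.sf(abs(z_meta)))
    return z_meta, p


def heterogeneity(
    betas=None, ses=None, zs=None, ns=None, scheme: str = "stderr"
) -> tuple[float, float]:
    """Cochran-style heterogeneity statistic and p under either scheme."""
    if scheme == "stderr":
        b, s = _as_arrays(betas, ses)
        if np.any(s <= 0):
            raise ValueError("all standard errors must be positive")
        w = 1.0 / s**2
        beta = np.sum(w * b) / np.sum(w)
        q = float(np.sum(w * (b - beta) ** 2))
        m = len(b)
    elif scheme == "samplesize":
        z, n = _as_arrays(zs, ns)
        z_meta = np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n))
        fitted = z_meta * np.sqrt(n / np.sum(n))
        q = float(np.sum((z - fitted) ** 2))
        m = len(z)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if m < 2:
        raise ValueError("need >= 2 studies")
    p = float(stats.chi2.sf(q, m - 1))
    return q, p


def meta_analyze(
    studies: list[pd.DataFrame],
    keys: tuple[str, ...] = ("variant_id",),
    allow_singletons: bool = True,
) -> pd.DataFrame:
    """Meta-analyze aligned per-study association tables under both schemes.

    Each study table needs the key columns plus beta, se, n (z derived as
    beta/se); alleles must already be aligned to a common effect allele
    (see :func:`protmr.mr.harmonize` for pairwise alignment). Variants in a
    single study pass through unflagged with n_studies = 1 when
    ``allow_singletons``.
    """
    if len(studies) < 2:
        raise ValueError("need >= 2 study tables")
    stacked = pd.concat(
        [df.assign(_study=i) for i, df in enumerate(studies)], ignore_index=True
    )
    rows = []
    for key, grp in stacked.groupby(list(keys), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        b = grp["beta"].to_numpy(dtype=float)
        s = grp["se"].to_numpy(dtype=float)
        n = grp["n"].to_numpy(dtype=float)
        rec["n_studies"] = len(grp)
        rec["n"] = float(n.sum())
        if len(grp) == 1:
            if not allow_singletons:
                continue
            rec.update(
                beta_meta=float(b[0]),
                se_meta=float(s[0]),
                p_meta=float(2 * stats.norm.sf(abs(b[0] / s[0]))),
                z_meta=float(b[0] / s[0]),
                p_z=float(2 * stats.norm.sf(abs(b[0] / s[0]))),
                q_stderr=np.nan,
                het_pval_stderr=np.nan,
                q_samplesize=np.nan,
                het_pval_samplesize=np.nan,
                flag_heterogeneity=False,
                flag_heterogeneity2=False,
                **{"flag_hetero.all": False},
            )
        else:
            beta, se, p = meta_fixed_stderr(b, s)
            z_meta, p_z = meta_samplesize(b / s, n)
            q1, hp1 = heterogeneity(betas=b, ses=s, scheme="stderr")
            q2, hp2 = heterogeneity(zs=b / s, ns=n, scheme="samplesize")
            f1, f2 = hp1 < HET_ALPHA, hp2 < HET_ALPHA
            rec.update(
                beta_meta=beta,
                se_meta=se,
                p_meta=p,
                z_meta=z_meta,
                p_z=p_z,
                q_stderr=q1,
                het_pval_stderr=hp1,
                q_samplesize=q2,
                het_pval_samplesize=hp2,
                flag_heterogeneity=bool(f1),
                flag_heterogeneity2=bool(f2),
                **{"flag_hetero.all": bool(f1 and f2)},
            )
        rows.append(rec)
    return pd.DataFrame(rows)
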