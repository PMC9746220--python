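"""Cross-tissue comparison of MR results.

Sign concordance of shared protein-phenotype pairs, chi-square
homogeneity tests of phenotype-category proportions between tissues, and
Storey pi1 replication rates between tissue pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TissueComparison:
    shared: pd.DataFrame  # one row per (protein, phenotype) found in >= 2 tissues
    n_shared: int
    n_concordant: int

    @property
    def percent_concordant(self) -> float:
        if self.n_shared == 0:
            return float("nan")
        return round(100.0 * self.n_concordant / self.n_shared)


def concordance(records: pd.DataFrame) -> TissueComparison:
    """Sign concordance of significant MR estimates across tissues.

    ``records`` must already be filtered to significant, colocalized
    results and carry protein_id, phenotype, tissue, beta_mr. A pair
    present in >= 2 tissues is concordant iff all its tissue-level
    estimates share one sign.
    """
    rows = []
    for (pid, pheno), grp in records.groupby(["protein_id", "phenotype"], sort=True):
        if grp["tissue"].nunique() < 2:
            continue
        signs = np.sign(grp["beta_mr"].to_numpy(dtype=float))
        rows.append(
            {
                "protein_id": pid,
                "phenotype": pheno,
                "tissues": ",".join(sorted(grp["tissue"].unique())),
                "concordant": bool(np.all(signs == signs[0])),
            }
        )
    shared = pd.DataFrame(rows, columns=["protein_id", "phenotype", "tissues", "concordant"])
    return TissueComparison(
        shared=shared,
        n_shared=len(shared),
        n_concordant=int(shared["concordant"].sum()) if len(shared) else 0,
    )


def proportion_test(counts_a, counts_b, pool_threshold: float = 1.0) -> float:
    """Two-sided chi-square homogeneity test of category proportions.

    ``counts_a``/``counts_b`` are aligned category count vectors (dicts or
    sequences over the same category universe). Cells whose expected count
    under homogeneity falls below ``pool_threshold`` are pooled into an
    'other' column before testing. 2x2 tables use Yates continuity
    correction.
    """
    if isinstance(counts_a, dict) or isinstance(counts_b, dict):
        cats = sorted(set(counts_a) | set(counts_b))
        a = np.array([counts_a.get(c, 0) for c in cats], dtype=float)
        b = np.array([counts_b.get(c, 0) for c in cats], dtype=float)
    else:
        a = np.asarray(counts_a, dtype=float)
        b = np.asarray(counts_b, dtype=float)
        if len(a) != len(b):
            raise ValueError("count vectors must share the category universe")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("zero-total count vector")
    table = np.vstack([a, b])
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    low = expected.min(axis=0) < pool_threshold
    if low.any() and (~low).sum() >= 1:
        pooled = np.column_stack([table[:, ~low], table[:, low].sum(axis=1)])
        if pooled.shape[1] >= 2:
            table = pooled
    if np.array_equal(table[0] / table[0].sum(), table[1] / table[1].sum()):
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table)
    return float(p)


STOREY_LAMBDAS = np.round(np.arange(0.05, 0.96, 0.05), 2)


def storey_pi0(
    pvalues, lambdas=STOREY_LAMBDAS, method: str = "smoother", fixed_lambda: float = 0.5
) -> float:
    """Estimate the null proportion pi0 from a p-value set.

    'smoother': pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the
    lambda grid, smoothed by a least-squares cubic and evaluated at the
    largest lambda (0.95), clipped to [0, 1]. 'fixed': single-lambda
    estimate at ``fixed_lambda`` — more stable for small m.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if method == "fixed":
        pi0 = np.sum(p > fixed_lambda) / (m * (1 - fixed_lambda))
        return float(np.clip(pi0, 0.0, 1.0))
    lambdas = np.asarray(lambdas, dtype=float)
    pi0_l = np.array([np.sum(p > lam) / (m * (1 - lam)) for lam in lambdas])
    coef = np.polynomial.polynomial.polyfit(lambdas, pi0_l, 3)
    pi0 = np.polynomial.polynomial.polyval(lambdas.max(), coef)
    return float(np.clip(pi0, 0.0, 1.0))


def storey_pi1(pvalues, **kwargs) -> float:
    """Replication rate pi1 = 1 - pi0."""
    return 1.0 - storey_pi0(pvalues, **kwargs)


def znorm_betas(records: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue z-normalized MR estimates for heatmap export.

    Within each tissue's significant set, beta_z = (beta - mean) / sd.
    Presentation-only: sign comparisons always use the raw estimates.
    """
    out = records.copy()
    def z(x):
        sd = x.std(ddof=1)
        return (x - x.mean()) / (sd if sd > 0 else 1.0)
    out["beta_z"] = out.groupby("tissue")["beta_mr"].transform(z)
    return out


@dataclass
class CrossTissueReport:
    comparison: TissueComparison
    proportion_pvalues: dict = field(default_factory=dict)
    pi1: dict = field(default_factory=dict)


def compare_tissues(
    records: pd.DataFrame,
    categories: dict[str, str] | None = None,
    replication_pvalues: dict[tuple[str, str], list] | None = None,
) -> CrossTissueReport:
    """Convenience driver: concordance + proportion tests + pi1 matrix.

    ``categories`` maps phenotype -> category for the proportion tests;
    ``replication_pvalues`` maps a tissue pair to the p-values of one
    tissue's significant pQTLs looked up in the other.
    """
    comp = concordance(records)
    prop: dict = {}
    if categories:
        sig = records[records.get("significant", True)]
        counts = {
            t: sig[sig["tissue"] == t]["phenotype"].map(categories).value_counts().to_dict()
            for t in sig["tissue"].unique()
        }
        tissues = sorted(counts)
        for i, ta in enumerate(tissues):
            for tb in tissues[i + 1 :]:
                if counts[ta] and counts[tb]:
                    prop[(ta, tb)] = proportion_test(counts[ta], counts[tb])
    pi1 = {}
    for pair, ps in (replication_pvalues or {}).items():
        pi1[pair] = storey_pi1(ps)
    return CrossTissueReport(comparison=comp, proportion_pvalues=prop, pi1=pi1)
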