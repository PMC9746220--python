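"""Two-sample MR: harmonization, Wald/IVW estimation, FDR, Steiger filtering.

Harmonization aligns outcome records to the exposure's effect allele in
four steps: (1) swapped effect/other alleles flip the outcome beta and
EAF; (2) strand complements (A<->T, C<->G) are matched; (3) palindromic
variants (A/T, C/G) are aligned by allele frequency when both EAFs are
away from 0.5 (outside [0.42, 0.58]) and dropped otherwise; (4) records
with incompatible alleles are dropped.

Estimation uses the Wald ratio for a single instrument and the
fixed-effect IVW combination of per-variant Wald ratios (equivalently the
zero-intercept weighted regression of outcome on exposure betas) for two
or more. Multiple testing is controlled by Benjamini-Hochberg within each
analysis scope. Steiger filtering retains only pairs whose instruments
explain more variance in the exposure than in the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_ALPHA = 0.05
PPH4_MIN = 0.80
PALINDROME_EAF_BAND = (0.42, 0.58)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = [
    "variant_id",
    "ea",
    "nea",
    "beta_exp",
    "se_exp",
    "eaf_exp",
    "n_exp",
    "beta_out",
    "se_out",
    "eaf_out",
    "n_out",
    "action",
]


def is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    eaf_band: tuple[float, float] = PALINDROME_EAF_BAND,
) -> pd.DataFrame:
    """Align outcome summary statistics to the exposure's effect alleles.

    Inputs are summary-stats tables (variant_id, chrom, pos, ea, nea, eaf,
    beta, se, n); records are matched by chromosome + position. Returns
    one row per exposure variant with an ``action`` column: none, flip,
    strand_flip, strand_flip+flip, or drop(<reason>). Dropped rows keep
    NaN outcome fields and are excluded from estimation downstream.
    """
    out_idx = outcome.set_index(
        [outcome["chrom"].astype(str), outcome["pos"].astype(int)]
    )
    rows = []
    for _, e in exposure.iterrows():
        key = (str(e["chrom"]), int(e["pos"]))
        rec = {
            "variant_id": e["variant_id"],
            "ea": e["ea"].upper(),
            "nea": e["nea"].upper(),
            "beta_exp": float(e["beta"]),
            "se_exp": float(e["se"]),
            "eaf_exp": float(e["eaf"]),
            "n_exp": float(e["n"]),
            "beta_out": np.nan,
            "se_out": np.nan,
            "eaf_out": np.nan,
            "n_out": np.nan,
            "action": "drop(missing_from_outcome)",
        }
        if key in out_idx.index:
            o = out_idx.loc[key]
            if isinstance(o, pd.DataFrame):
                o = o.iloc[0]
            ea, nea = rec["ea"], rec["nea"]
            oea, onea = str(o["ea"]).upper(), str(o["nea"]).upper()
            action = None
            flip = False
            if is_palindromic(ea, nea):
                if {oea, onea} != {ea, nea}:
                    action = "drop(incompatible_alleles)"
                else:
                    lo, hi = eaf_band
                    f_exp, f_out = rec["eaf_exp"], float(o["eaf"])
                    f_out_aligned = f_out if oea == ea else 1 - f_out
                    if lo <= f_exp <= hi or lo <= f_out_aligned <= hi:
                        action = "drop(palindromic_ambiguous)"
                    else:
                        # align by frequency: same side of 0.5 means the
                        # reported effect alleles refer to the same allele
                        flip = (f_exp - 0.5) * (f_out_aligned - 0.5) < 0
                        action = "flip" if flip else "none"
            elif (oea, onea) == (ea, nea):
                action = "none"
            elif (oea, onea) == (nea, ea):
                action, flip = "flip", True
            elif (_COMPLEMENT.get(oea), _COMPLEMENT.get(onea)) == (ea, nea):
                action = "strand_flip"
            elif (_COMPLEMENT.get(oea), _COMPLEMENT.get(onea)) == (nea, ea):
                action, flip = "strand_flip+flip", True
            else:
                action = "drop(incompatible_alleles)"
            if not action.startswith("drop"):
                sign = -1.0 if flip else 1.0
                rec.update(
                    beta_out=sign * float(o["beta"]),
                    se_out=float(o["se"]),
                    eaf_out=(1 - float(o["eaf"])) if flip else float(o["eaf"]),
                    n_out=float(o["n"]),
                )
            rec["action"] = action
        rows.append(rec)
    return pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)


def kept(pairs: pd.DataFrame) -> pd.DataFrame:
    """Harmonized rows usable for estimation (not dropped)."""
    return pairs[~pairs["action"].str.startswith("drop")]


def wald_ratio(beta_exp, se_exp, beta_out, se_out) -> tuple[float, float, float]:
    """Single-instrument MR estimate: (beta, se, p).

    beta = beta_out / beta_exp; se = se_out / |beta_exp| (first-order
    delta, exposure uncertainty ignored); two-sided normal p.
    """
    if beta_exp == 0:
        raise ZeroDivisionError("Wald ratio undefined for beta_exp = 0")
    b = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    p = float(2 * stats.norm.sf(abs(b / se))) if se > 0 else 0.0
    return float(b), float(se), p


def ivw(beta_exp, se_exp, beta_out, se_out) -> tuple[float, float, float]:
    """Fixed-effect IVW of per-variant Wald ratios: (beta, se, p).

    Weights are the inverse variances of the ratios; identical to the
    zero-intercept weighted regression of beta_out on beta_exp with
    weights beta_exp^2/se_out^2.
    """
    be = np.asarray(beta_exp, dtype=float)
    se_e = np.asarray(se_exp, dtype=float)
    bo = np.asarray(beta_out, dtype=float)
    so = np.asarray(se_out, dtype=float)
    if len(be) < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio")
    if np.any(be == 0):
        raise ZeroDivisionError("beta_exp = 0 in IVW input")
    ratios = bo / be
    se_r = so / np.abs(be)
    w = 1.0 / se_r**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return beta, se, p


def mr_estimate(pairs: pd.DataFrame) -> tuple[str, float, float, float]:
    """Route harmonized pairs to Wald ratio (1 IV) or IVW (>= 2 IVs)."""
    use = kept(pairs)
    if use.empty:
        raise ValueError("no usable instruments after harmonization")
    if len(use) == 1:
        r = use.iloc[0]
        b, s, p = wald_ratio(r["beta_exp"], r["se_exp"], r["beta_out"], r["se_out"])
        return "wald", b, s, p
    b, s, p = ivw(use["beta_exp"], use["se_exp"], use["beta_out"], use["se_out"])
    return "ivw", b, s, p


def fdr_adjust(
    records: pd.DataFrame,
    scope: list[str] | None = None,
    p_col: str = "p_mr",
    q_col: str = "fdr_q",
) -> pd.DataFrame:
    """Benjamini-Hochberg q-values within each analysis scope group."""
    out = records.copy()
    if out.empty:
        out[q_col] = pd.Series(dtype=float)
        return out

    def bh(p: pd.Series) -> np.ndarray:
        return multipletests(p.to_numpy(dtype=float), method="fdr_bh")[1]

    if scope:
        out[q_col] = np.nan
        for _, idx in out.groupby(scope, dropna=False).groups.items():
            out.loc[idx, q_col] = bh(out.loc[idx, p_col])
    else:
        out[q_col] = bh(out[p_col])
    return out


def _r2_from_t(t: np.ndarray, n: float) -> float:
    """Summed variance explained by the instruments: r2 = t^2/(t^2 + n - 2)."""
    t2 = np.asarray(t, dtype=float) ** 2
    return float(np.sum(t2 / (t2 + n - 2)))


def steiger_filter(pairs: pd.DataFrame, n_exp=None, n_out=None) -> tuple[bool, float]:
    """Directionality test: do the IVs explain more exposure variance?

    r^2 on each side is the sum over instruments of t^2/(t^2 + n - 2);
    the p-value compares Fisher-z transformed correlations,
    z = (z(r_exp) - z(r_out)) / sqrt(1/(n_exp - 3) + 1/(n_out - 3)),
    two-sided. Returns (steiger_correct, steiger_p);
    correct requires strictly r2_exp > r2_out.
    """
    use = kept(pairs)
    if use.empty:
        raise ValueError("no usable instruments")
    n_exp = float(n_exp if n_exp is not None else use["n_exp"].median())
    n_out = float(n_out if n_out is not None else use["n_out"].median())
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes must exceed 3")
    r2_exp = _r2_from_t(use["beta_exp"] / use["se_exp"], n_exp)
    r2_out = _r2_from_t(use["beta_out"] / use["se_out"], n_out)
    r_exp = np.sqrt(min(r2_exp, 1 - 1e-12))
    r_out = np.sqrt(min(r2_out, 1 - 1e-12))
    z = (np.arctanh(r_exp) - np.arctanh(r_out)) / np.sqrt(
        1 / (n_exp - 3) + 1 / (n_out - 3)
    )
    p = float(2 * stats.norm.sf(abs(z)))
    return bool(r2_exp > r2_out), p


@dataclass
class MRConfig:
    """Inputs and thresholds for one end-to-end MR run."""

    panel: object
    proteins: object  # cleaned log-scale ProteinMatrix
    outcomes: dict  # {phenotype: summary-stats DataFrame}
    genes: pd.DataFrame
    covariates: pd.DataFrame | None = None
    tissue: str = "tissue"
    workflow: str = "both"  # a | b | both
    cis_window: int = 1_000_000
    thresholds: object | None = None  # derived from proteins when None
    fdr_alpha: float = FDR_ALPHA
    pph4_min: float = PPH4_MIN
    coloc_window: int = 500_000
    coloc_priors: tuple = (1e-4, 1e-4, 1e-5)
    run_coloc: bool = True
    assocs: pd.DataFrame | None = None  # precomputed pQTL records, optional
    het_flags: pd.DataFrame | None = None  # per-variant meta flags, optional


def run_workflow(config: MRConfig) -> pd.DataFrame:
    """Full pipeline: pQTL -> IVs -> harmonize -> MR -> FDR -> Steiger -> coloc.

    Returns one MR record per (protein, phenotype, workflow) with the
    significance call: fdr_q < alpha AND pp_h4 > threshold AND
    steiger_correct. With workflow='both' the union is returned with
    provenance: cis_only = found by workflow a (shared), trans_additional
    = unique to workflow b.
    """
    from . import coloc as coloc_mod
    from . import instruments as iv_mod
    from . import pqtl as pqtl_mod

    if config.assocs is not None:
        assocs = config.assocs
    else:
        assocs = pqtl_mod.fit_pqtl(config.proteins, config.panel, config.covariates)
        assocs = pqtl_mod.classify_cis_trans(assocs, config.genes, config.cis_window)
    thresholds = config.thresholds or pqtl_mod.derive_study_wide_threshold(
        config.proteins
    )
    workflows = ["a", "b"] if config.workflow == "both" else [config.workflow]

    rows = []
    for wf in workflows:
        ivsets = iv_mod.select_ivs(
            assocs, config.panel, thresholds, wf, tissue=config.tissue
        )
        for pid, ivset in ivsets.items():
            for pheno, out_stats in config.outcomes.items():
                pairs = harmonize(ivset.variants, out_stats)
                use = kept(pairs)
                if use.empty:
                    continue
                method, b, s, p = mr_estimate(pairs)
                correct, steiger_p = steiger_filter(pairs)
                pp_h4 = np.nan
                if config.run_coloc:
                    results = []
                    for _, iv in use.iterrows():
                        meta = config.panel.variant_meta.loc[iv["variant_id"]]
                        exp_win = coloc_mod.window(
                            assocs[assocs["protein_id"] == pid],
                            meta["chrom"],
                            meta["pos"],
                            config.coloc_window,
                        )
                        out_win = coloc_mod.window(
                            out_stats, meta["chrom"], meta["pos"], config.coloc_window
                        )
                        results.append(
                            coloc_mod.coloc_abf(
                                exp_win, out_win, priors=config.coloc_priors
                            )
                        )
                    pp_h4 = coloc_mod.combine_pph4(results)
                rows.append(
                    {
                        "protein_id": pid,
                        "phenotype": pheno,
                        "tissue": config.tissue,
                        "workflow": wf,
                        "n_ivs": len(use),
                        "method": method,
                        "beta_mr": b,
                        "se_mr": s,
                        "p_mr": p,
                        "steiger_correct": correct,
                        "steiger_p": steiger_p,
                        "pp_h4": pp_h4,
                    }
                )
    records = pd.DataFrame(rows)
    if records.empty:
        return records
    records = fdr_adjust(records, scope=["tissue", "workflow"])
    coloc_ok = (
        (records["pp_h4"] > config.pph4_min)
        if config.run_coloc
        else pd.Series(True, index=records.index)
    )
    records["significant"] = (
        (records["fdr_q"] < config.fdr_alpha)
        & coloc_ok
        & records["steiger_correct"]
    )
    if config.workflow == "both":
        in_a = set(
            map(
                tuple,
                records.loc[records["workflow"] == "a", ["protein_id", "phenotype"]].values,
            )
        )
        keys = records[["protein_id", "phenotype"]].apply(tuple, axis=1)
        records["provenance"] = np.where(keys.isin(in_a), "cis_only", "trans_additional")
    return records
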