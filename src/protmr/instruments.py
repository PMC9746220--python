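"""Instrument selection for MR: significance, pleiotropy, clumping, strength.

Two workflows build instrument sets per protein:

* workflow a ("cis-only"): cis associations passing the PC-derived
  study-wide threshold;
* workflow b ("cis + trans"): any association passing genome-wide 5e-8.

Both then remove pleiotropic variants (significantly associated with >= 5
proteins, plus LD neighbors of those sentinels), LD-clump greedily at
r^2 < 0.001, and require instrument strength F = (beta/se)^2 >= 10.
Provenance records the count surviving each step, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

F_MIN = 10.0
CLUMP_R2 = 0.001
PLEIOTROPY_MAX_PROTEINS = 5
PLEIOTROPY_LD_R2 = 0.1
PLEIOTROPY_LD_WINDOW = 1_000_000


@dataclass
class InstrumentSet:
    protein_id: str
    workflow: str
    variants: pd.DataFrame  # association records of the retained instruments
    f_stats: pd.Series = field(default_factory=pd.Series)
    provenance: dict = field(default_factory=dict)
    tissue: str | None = None

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    @property
    def n_ivs(self) -> int:
        return len(self.variants)


def compute_f_stat(beta, se):
    """Instrument strength F = (beta/se)^2, the squared t-statistic."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def filter_pleiotropic(
    assocs: pd.DataFrame,
    panel,
    max_proteins: int = PLEIOTROPY_MAX_PROTEINS,
    ld_r2: float = PLEIOTROPY_LD_R2,
    ld_window: int = PLEIOTROPY_LD_WINDOW,
) -> tuple[pd.DataFrame, dict]:
    """Drop hub variants hitting >= max_proteins proteins, and LD neighbors.

    ``assocs`` must already be significance-filtered; counting is over the
    distinct proteins each variant appears with. Any variant with
    r^2 >= ld_r2 to a removed sentinel within ld_window bp on the same
    chromosome is removed too.
    """
    counts = assocs.groupby("variant_id")["protein_id"].nunique()
    sentinels = set(counts.index[counts >= max_proteins])
    neighbors: set[str] = set()
    if sentinels:
        meta = panel.variant_meta
        for s in sentinels:
            s_chrom, s_pos = meta.loc[s, "chrom"], meta.loc[s, "pos"]
            near = meta.index[
                (meta["chrom"] == s_chrom)
                & ((meta["pos"] - s_pos).abs() <= ld_window)
                & (meta.index != s)
            ]
            near = [v for v in near if v in set(assocs["variant_id"])]
            if near:
                r2 = panel.ld_r2([s] + list(near)).loc[s, near]
                neighbors |= set(r2.index[(r2 >= ld_r2).to_numpy()])
    removed = sentinels | (neighbors - sentinels)
    kept = assocs[~assocs["variant_id"].isin(removed)].copy()
    info = {
        "sentinels": sorted(sentinels),
        "ld_neighbors_removed": sorted(neighbors - sentinels),
        "n_removed": len(removed),
    }
    return kept, info


def ld_clump(assocs: pd.DataFrame, panel, r2_threshold: float = CLUMP_R2) -> pd.DataFrame:
    """Greedy LD clumping of one protein's associations.

    Sort by ascending (pval, variant_id); accept a variant iff its r^2 with
    every previously accepted variant is below the threshold.
    """
    if assocs.empty:
        return assocs.copy()
    missing = set(assocs["variant_id"]) - set(panel.variant_meta.index)
    if missing:
        raise KeyError(f"variants missing from panel: {sorted(missing)}")
    ordered = assocs.sort_values(["pval", "variant_id"], kind="mergesort")
    ids = list(ordered["variant_id"])
    r2 = panel.ld_r2(ids) if len(ids) > 1 else None
    accepted: list[str] = []
    for v in ids:
        if all(r2.loc[v, a] < r2_threshold for a in accepted) if accepted else True:
            accepted.append(v)
    return ordered[ordered["variant_id"].isin(accepted)].copy()


def select_ivs(
    assocs: pd.DataFrame,
    panel,
    thresholds,
    workflow: str,
    tissue: str | None = None,
    max_proteins: int = PLEIOTROPY_MAX_PROTEINS,
    pleio_ld_r2: float = PLEIOTROPY_LD_R2,
    pleio_ld_window: int = PLEIOTROPY_LD_WINDOW,
    clump_r2: float = CLUMP_R2,
    f_min: float = F_MIN,
) -> dict[str, InstrumentSet]:
    """Build per-protein instrument sets for one workflow.

    Filters apply in order: workflow significance, pleiotropy, LD clump,
    F >= f_min; per-protein provenance carries the count after each step.
    Proteins whose sets come up empty are omitted.
    """
    if workflow not in ("a", "b"):
        raise ValueError("workflow must be 'a' or 'b'")
    if assocs["cis_flag"].isna().any():
        raise ValueError("cis/trans classification required before IV selection")
    if workflow == "a":
        sig = assocs[
            assocs["cis_flag"].astype(bool)
            & (assocs["pval"] < thresholds.study_wide_alpha)
        ]
    else:
        sig = assocs[assocs["pval"] < thresholds.genome_wide_alpha]
    filtered, pleio_info = filter_pleiotropic(
        sig, panel, max_proteins=max_proteins, ld_r2=pleio_ld_r2, ld_window=pleio_ld_window
    )
    out: dict[str, InstrumentSet] = {}
    for pid, grp in filtered.groupby("protein_id", sort=True):
        n_sig = int((sig["protein_id"] == pid).sum())
        clumped = ld_clump(grp, panel, r2_threshold=clump_r2)
        f = pd.Series(
            compute_f_stat(clumped["beta"], clumped["se"]).tolist(),
            index=clumped["variant_id"].tolist(),
        )
        strong = clumped[f.to_numpy() >= f_min]
        if strong.empty:
            continue
        out[pid] = InstrumentSet(
            protein_id=pid,
            workflow=workflow,
            tissue=tissue,
            variants=strong.reset_index(drop=True),
            f_stats=f[f >= f_min],
            provenance={
                "significant": n_sig,
                "after_pleiotropy": len(grp),
                "after_clump": len(clumped),
                "after_f": len(strong),
                "pleiotropy": pleio_info,
            },
        )
    return out
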