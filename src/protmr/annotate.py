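"""Replication accounting, druggable-genome overlap, drug-repurposing calls.

Replication compares current MR results against a prior study's table:
a pair is replicated when the prior shows p < 0.05 with the same effect
direction, not replicated when the prior pair exists but fails either
condition, and novel when absent from the prior; the replication rate is
replicated / (replicated + not replicated).

Druggable-genome overlap assigns each significant protein a tier (1-3
from the tier table, else "tier 4" unclassified) and reports the percent
in tiers 1-3. Drug repurposing keeps phase-4, warning-free drugs targeting
a significant protein and predicts inhibitor for a positive MR estimate,
activator for a negative one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ReplicationTable:
    total: int
    replicated: int
    not_replicated: int
    novel: int
    detail: pd.DataFrame | None = None

    def __post_init__(self):
        if self.total != self.replicated + self.not_replicated + self.novel:
            raise ValueError("counts must satisfy total = replicated + not + novel")

    @property
    def replication_rate(self) -> float:
        denom = self.replicated + self.not_replicated
        if denom == 0:
            return float("nan")  # reported as NA
        return self.replicated / denom

    @property
    def rate_percent(self) -> float:
        r = self.replication_rate
        return float("nan") if np.isnan(r) else round(100 * r)


def replication_rate(current: pd.DataFrame, prior: pd.DataFrame) -> ReplicationTable:
    """Classify current (protein, phenotype) pairs against a prior table.

    ``current`` needs protein_id, phenotype, beta_mr; ``prior`` needs
    protein_id, phenotype, beta, pval.
    """
    prior_idx = prior.set_index(["protein_id", "phenotype"])
    rows = []
    for _, rec in current.iterrows():
        key = (rec["protein_id"], rec["phenotype"])
        if key not in prior_idx.index:
            status = "novel"
        else:
            pr = prior_idx.loc[key]
            if isinstance(pr, pd.DataFrame):
                pr = pr.iloc[0]
            same_sign = np.sign(pr["beta"]) == np.sign(rec["beta_mr"])
            status = "replicated" if (pr["pval"] < 0.05 and same_sign) else "not_replicated"
        rows.append({"protein_id": key[0], "phenotype": key[1], "status": status})
    detail = pd.DataFrame(rows, columns=["protein_id", "phenotype", "status"])
    counts = detail["status"].value_counts()
    return ReplicationTable(
        total=len(detail),
        replicated=int(counts.get("replicated", 0)),
        not_replicated=int(counts.get("not_replicated", 0)),
        novel=int(counts.get("novel", 0)),
        detail=detail,
    )


def druggable_overlap(proteins: pd.DataFrame, tiers: pd.DataFrame) -> dict:
    """Tier assignment and percent of proteins in druggable tiers 1-3.

    ``proteins`` needs protein_id and gene_id (deduplicated by gene);
    ``tiers`` needs gene_id and tier (1, 2, or 3). Unmatched genes are
    'tier 4' (unclassified). Percent is rounded to one decimal.
    """
    if tiers["gene_id"].duplicated().any():
        dups = tiers.loc[tiers["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in tier table: {dups}")
    uniq = proteins.drop_duplicates(subset="gene_id")
    tier_of = tiers.set_index("gene_id")["tier"]
    assigned = uniq["gene_id"].map(tier_of).fillna(4).astype(int)
    counts = {f"tier{t}": int((assigned == t).sum()) for t in (1, 2, 3, 4)}
    total = len(uniq)
    in_tiers = counts["tier1"] + counts["tier2"] + counts["tier3"]
    # half-up to one decimal (86.25 -> 86.3), the field's reporting convention
    percent = float(np.floor(1000.0 * in_tiers / total + 0.5) / 10) if total else 0.0
    return {
        "counts": counts,
        "total": total,
        "n_druggable": in_tiers,
        "percent_tiers_1_3": percent,
        "assignment": pd.DataFrame(
            {"gene_id": uniq["gene_id"].to_numpy(), "tier": assigned.to_numpy()},
            index=uniq["protein_id"].to_numpy(),
        ),
    }


def drug_direction(records: pd.DataFrame, drug_table: pd.DataFrame) -> pd.DataFrame:
    """Phase-4, warning-free drug calls with MR-sign-determined direction.

    ``records`` are significant MR rows (protein_id, phenotype, beta_mr);
    ``drug_table`` needs protein_id, drug, max_phase and an optional
    warning column (non-empty = dropped). A zero MR estimate yields no
    call.
    """
    warn = drug_table.get("warning", pd.Series("", index=drug_table.index)).fillna("")
    eligible = drug_table[(drug_table["max_phase"] == 4) & (warn.astype(str) == "")]
    rows = []
    for _, rec in records.iterrows():
        if rec["beta_mr"] == 0:
            continue
        hits = eligible[eligible["protein_id"] == rec["protein_id"]]
        effect = "inhibitor" if rec["beta_mr"] > 0 else "activator"
        for _, d in hits.iterrows():
            rows.append(
                {
                    "protein_id": rec["protein_id"],
                    "phenotype": rec["phenotype"],
                    "drug": d["drug"],
                    "predicted_effect": effect,
                    "max_phase": int(d["max_phase"]),
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "phenotype", "drug", "predicted_effect", "max_phase"]
    )
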