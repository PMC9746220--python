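"""Synthetic genotypes, proteomes, and outcome GWAS with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: LD-blocked genotypes (Gaussian-copula haplotypes with within-block
AR(1) latent correlation), proteins driven by one strong cis variant plus
optional trans effects and pleiotropic hub variants, quantitative outcome
traits with known protein-mediated causal effects theta, and raw proteomic
plates with injected QC failures recorded in a defect ledger.

Every stage is deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SUMSTATS_COLUMNS

# non-palindromic allele pairs cycled across variants so that strand logic
# downstream never hits the ambiguous A/T, C/G case unless a test builds one
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A")]

_BLOCK_GAP = 3_000_000  # bp between blocks on one chromosome; > 2x the 1 Mb cis window
_VARIANT_SPACING = 5_000


@dataclass
class GenotypePanel:
    """Dosage matrix with per-variant metadata and LD-block assignment.

    dosages: (n_samples, n_variants) array of {0,1,2} effect-allele counts.
    variant_meta: indexed by variant_id with chrom, pos, ea, nea, maf, block.
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(self.dosages.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variant_meta.index)

    @property
    def block_map(self) -> dict[str, int]:
        return self.variant_meta["block"].to_dict()

    def dosage(self, variant_id: str) -> np.ndarray:
        j = self.variant_meta.index.get_loc(variant_id)
        return self.dosages[:, j]

    def ld_r2(self, variant_ids=None) -> pd.DataFrame:
        """Pairwise squared Pearson correlation of dosages."""
        ids = list(variant_ids) if variant_ids is not None else self.variant_ids
        idx = [self.variant_meta.index.get_loc(v) for v in ids]
        g = self.dosages[:, idx].astype(float)
        sd = g.std(axis=0)
        if np.any(sd == 0):
            bad = [ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"monomorphic variants have undefined LD: {bad}")
        r = np.corrcoef(g, rowvar=False)
        r = np.atleast_2d(r)
        return pd.DataFrame(r**2, index=ids, columns=ids)


@dataclass
class TruthManifest:
    """Ground truth of a simulation: cis/trans effects, hubs, causal thetas.

    theta maps protein -> {outcome: causal effect} (0 when non-causal);
    direct_effects maps variant -> {outcome: effect} and models confounding
    (horizontal) pleiotropy acting on the outcome not through any protein.
    """

    cis_assignment: dict[str, tuple[str, float]]
    trans_assignment: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    pleiotropic_hubs: list[str] = field(default_factory=list)
    theta: dict[str, dict[str, float]] = field(default_factory=dict)
    direct_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)
    genes: pd.DataFrame | None = None  # index protein_id: gene_id, chrom, tss

    @property
    def proteins(self) -> list[str]:
        return list(self.cis_assignment)

    @property
    def outcomes(self) -> list[str]:
        names: list[str] = []
        for d in self.theta.values():
            for o in d:
                if o not in names:
                    names.append(o)
        return names

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cis_assignment"] = {p: list(v) for p, v in self.cis_assignment.items()}
        d["trans_assignment"] = {
            p: [list(t) for t in v] for p, v in self.trans_assignment.items()
        }
        d["genes"] = (
            None if self.genes is None else self.genes.reset_index().to_dict("records")
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        genes = d.get("genes")
        if genes is not None:
            genes = pd.DataFrame(genes).set_index("protein_id")
        return cls(
            cis_assignment={p: tuple(v) for p, v in d["cis_assignment"].items()},
            trans_assignment={
                p: [tuple(t) for t in v]
                for p, v in d.get("trans_assignment", {}).items()
            },
            pleiotropic_hubs=list(d.get("pleiotropic_hubs", [])),
            theta=d.get("theta", {}),
            direct_effects=d.get("direct_effects", {}),
            seeds=d.get("seeds", {}),
            genes=genes,
        )


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _bvn_cdf(h: np.ndarray, k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """P(Z1 < h, Z2 < k) under correlation lam, vectorized over pairs.

    Sheppard's integral representation evaluated by 48-node Gauss-Legendre
    quadrature on [0, lam]; accurate to ~1e-10 for |lam| <= 0.9999.
    """
    h = np.atleast_1d(h)[:, None]
    k = np.atleast_1d(k)[:, None]
    lam = np.atleast_1d(lam)[:, None]
    t = lam * (_GL_NODES[None, :] + 1) / 2
    w = lam * _GL_WEIGHTS[None, :] / 2
    integrand = np.exp(
        -(h**2 - 2 * t * h * k + k**2) / (2 * (1 - t**2))
    ) / (2 * np.pi * np.sqrt(1 - t**2))
    base = stats.norm.cdf(h[:, 0]) * stats.norm.cdf(k[:, 0])
    return base + np.sum(w * integrand, axis=1)


def _latent_corr_for_dosage_corr(rho: float, maf_a: np.ndarray, maf_b: np.ndarray) -> np.ndarray:
    """Latent copula correlation giving adjacent-dosage correlation rho.

    Thresholding attenuates correlation, so the latent AR(1) coefficient is
    found per adjacent pair by bisection on the binary (haplotype)
    correlation implied by the bivariate-normal orthant probability;
    dosages, as sums of two iid haplotypes, inherit that correlation.
    Targets beyond what thresholding can reach are clipped to the maximum.
    """
    za, zb = stats.norm.ppf(maf_a), stats.norm.ppf(maf_b)
    denom = np.sqrt(maf_a * (1 - maf_a) * maf_b * (1 - maf_b))

    def binary_corr(lam):
        return (_bvn_cdf(za, zb, lam) - maf_a * maf_b) / denom

    lo = np.zeros_like(za)
    hi = np.full_like(za, 0.9999)
    reachable = binary_corr(hi)
    target = np.minimum(rho, reachable - 1e-9)
    for _ in range(40):
        mid = (lo + hi) / 2
        too_low = binary_corr(mid) < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return (lo + hi) / 2


def _check_maf_range(maf_range) -> tuple[float, float]:
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"MAF range must lie in (0, 0.5], got ({lo}, {hi})")
    return lo, hi


def simulate_genotypes(
    n_samples: int,
    blocks: list[tuple[int, float, tuple[float, float]]],
    seed: int,
    chroms: list[str] | None = None,
) -> GenotypePanel:
    """Simulate LD-blocked {0,1,2} dosages.

    Each block is (n_variants, rho, (maf_lo, maf_hi)). Two haplotypes per
    sample are drawn from a Gaussian copula with AR(1) latent structure
    and thresholded at Phi^-1(maf), so the realized effect allele is the
    minor allele and dosages are in Hardy-Weinberg proportions. ``rho`` is
    the target correlation between adjacent *dosages*: the latent AR(1)
    coefficient is calibrated per adjacent pair to undo the attenuation of
    thresholding, so adjacent r^2 tracks rho^2. Blocks are independent and
    laid on chromosomes (one per block by default) with a 3 Mb gap between
    same-chromosome blocks, so cross-block variants never share a cis
    window.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    dosage_cols: list[np.ndarray] = []
    meta_rows: list[dict] = []
    cursor: dict[str, int] = {}
    vid = 0
    for b, (n_var, rho, maf_range) in enumerate(blocks):
        if n_var <= 0:
            raise ValueError(f"block {b}: non-positive size {n_var}")
        if not (0 <= rho < 1):
            raise ValueError(f"block {b}: rho must be in [0, 1), got {rho}")
        lo, hi = _check_maf_range(maf_range)
        chrom = chroms[b] if chroms is not None else str(b % 22 + 1)
        start = cursor.get(chrom, 1_000_000)
        mafs = rng.uniform(lo, hi, size=n_var)
        # latent haplotype draws built sequentially: z_j = lam_j*z_{j-1} + e
        z = np.empty((2 * n_samples, n_var))
        z[:, 0] = rng.standard_normal(2 * n_samples)
        if n_var > 1:
            if rho > 0:
                lam = _latent_corr_for_dosage_corr(rho, mafs[:-1], mafs[1:])
            else:
                lam = np.zeros(n_var - 1)
            innov = rng.standard_normal((2 * n_samples, n_var - 1))
            s = np.sqrt(1 - lam**2)
            for j in range(1, n_var):
                z[:, j] = lam[j - 1] * z[:, j - 1] + s[j - 1] * innov[:, j - 1]
        thresh = stats.norm.ppf(mafs)
        haps = (z < thresh).astype(np.int8)
        dose = haps[:n_samples] + haps[n_samples:]
        for j in range(n_var):
            ea, nea = _ALLELE_PAIRS[vid % len(_ALLELE_PAIRS)]
            meta_rows.append(
                {
                    "variant_id": f"rs{vid + 1:06d}",
                    "chrom": chrom,
                    "pos": start + j * _VARIANT_SPACING,
                    "ea": ea,
                    "nea": nea,
                    "maf": mafs[j],
                    "block": b,
                }
            )
            vid += 1
        cursor[chrom] = start + n_var * _VARIANT_SPACING + _BLOCK_GAP
        dosage_cols.append(dose)
    meta = pd.DataFrame(meta_rows).set_index("variant_id")
    return GenotypePanel(dosages=np.hstack(dosage_cols), variant_meta=meta)


def design_truth(
    panel: GenotypePanel,
    n_proteins: int,
    outcomes: dict[str, dict[str, float]] | list[str],
    b_cis: float = 0.5,
    trans: dict[str, list[tuple[str, float]]] | None = None,
    hub: tuple[str, int, float] | None = None,
    direct_effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    tss_offset: int = 10_000,
) -> TruthManifest:
    """Build a TruthManifest over a panel.

    Assigns each protein a distinct cis variant (spread across blocks, the
    first variant of successive blocks first), places the encoding gene's
    TSS ``tss_offset`` bp downstream of it, and records causal effects.
    ``outcomes`` is either {outcome: {protein: theta}} or a list of outcome
    names (theta = 0 everywhere). ``hub=(variant_id, n_targets, b)`` wires
    one pleiotropic hub variant into >= n_targets proteins as trans effects.
    """
    rng = np.random.default_rng(seed)
    meta = panel.variant_meta
    block_firsts = meta.reset_index().groupby("block").first()["variant_id"].tolist()
    pool = block_firsts + [v for v in meta.index if v not in block_firsts]
    if n_proteins > len(pool):
        raise ValueError("more proteins than available variants")
    proteins = [f"P{i + 1:03d}" for i in range(n_proteins)]
    cis = {p: (pool[i], float(b_cis)) for i, p in enumerate(proteins)}
    genes = pd.DataFrame(
        {
            "protein_id": proteins,
            "gene_id": [f"ENSG{i + 1:05d}" for i in range(n_proteins)],
            "chrom": [meta.loc[cis[p][0], "chrom"] for p in proteins],
            "tss": [int(meta.loc[cis[p][0], "pos"]) + tss_offset for p in proteins],
        }
    ).set_index("protein_id")
    trans_assignment = {p: list(v) for p, v in (trans or {}).items()}
    hubs: list[str] = []
    if hub is not None:
        hub_var, n_targets, b_hub = hub
        if hub_var not in meta.index:
            raise ValueError(f"hub variant {hub_var} not in panel")
        targets = rng.choice(proteins, size=min(n_targets, n_proteins), replace=False)
        for p in targets:
            trans_assignment.setdefault(p, []).append((hub_var, float(b_hub)))
        hubs.append(hub_var)
    if isinstance(outcomes, dict):
        outcome_names = list(outcomes)
        theta = {
            p: {o: float(outcomes[o].get(p, 0.0)) for o in outcome_names}
            for p in proteins
        }
    else:
        theta = {p: {o: 0.0 for o in outcomes} for p in proteins}
    for p, tlist in trans_assignment.items():
        for v, _ in tlist:
            if v not in meta.index:
                raise ValueError(f"trans variant {v} not in panel")
    return TruthManifest(
        cis_assignment=cis,
        trans_assignment=trans_assignment,
        pleiotropic_hubs=hubs,
        theta=theta,
        direct_effects=dict(direct_effects or {}),
        seeds={"truth": int(seed)},
        genes=genes,
    )


def simulate_proteins(
    panel: GenotypePanel,
    manifest: TruthManifest,
    covariates: pd.DataFrame | None = None,
    covariate_effects: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Simulate log-scale protein abundances.

    protein_j = sum_v b_v * dosage_v + Gamma * covariates + eps,
    eps ~ N(0, noise_sd^2). Returns a log-scale ProteinMatrix whose analyte
    metadata links each analyte to its protein and encoding gene.
    """
    from .qc import ProteinMatrix

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    values = {}
    for p in manifest.proteins:
        y = np.zeros(n)
        effects = [manifest.cis_assignment[p]] + manifest.trans_assignment.get(p, [])
        for v, b in effects:
            if v not in panel.variant_meta.index:
                raise KeyError(f"manifest variant {v} not in panel")
            y = y + float(b) * panel.dosage(v)
        if covariates is not None and covariate_effects:
            for c, g in covariate_effects.items():
                y = y + float(g) * covariates[c].to_numpy(dtype=float)
        y = y + rng.normal(0.0, noise_sd, size=n)
        values[p] = y
    df = pd.DataFrame(values, index=panel.sample_ids)
    sample_meta = pd.DataFrame(
        {"role": "sample", "plate": "plate-1"}, index=panel.sample_ids
    )
    analyte_meta = None
    if manifest.genes is not None:
        analyte_meta = manifest.genes.loc[manifest.proteins].copy()
    return ProteinMatrix(
        values=df, sample_meta=sample_meta, analyte_meta=analyte_meta, log_scale=True
    )


def marginal_gwas(y: np.ndarray, panel: GenotypePanel, n_label: int | None = None) -> pd.DataFrame:
    """Per-variant simple-regression summary statistics of y on dosage."""
    g = panel.dosages.astype(float)
    n = len(y)
    yc = y - y.mean()
    gc = g - g.mean(axis=0)
    sxx = np.einsum("ij,ij->j", gc, gc)
    if np.any(sxx == 0):
        bad = [panel.variant_ids[j] for j in np.flatnonzero(sxx == 0)]
        raise ValueError(f"monomorphic variants: {bad}")
    sxy = gc.T @ yc
    beta = sxy / sxx
    rss = yc @ yc - beta * sxy
    df = n - 2
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pval = 2 * stats.t.sf(np.abs(t), df)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    meta = panel.variant_meta
    out = pd.DataFrame(
        {
            "variant_id": meta.index,
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "ea": meta["ea"].to_numpy(),
            "nea": meta["nea"].to_numpy(),
            "eaf": g.mean(axis=0) / 2,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n_label if n_label is not None else n,
        }
    )
    return out.loc[:, SUMSTATS_COLUMNS].reset_index(drop=True)


def simulate_outcome_gwas(
    panel: GenotypePanel,
    proteins,
    manifest: TruthManifest,
    outcome_noise_sd: float = 1.0,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate outcomes and emit marginal GWAS summary statistics.

    y_o = sum_k theta_{k,o} * protein_k + sum_v direct_{v,o} * dosage_v + eps.
    Returns {outcome: summary-stats DataFrame} over every panel variant.
    """
    if outcome_noise_sd < 0:
        raise ValueError("outcome_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    vals = proteins.values if hasattr(proteins, "values") else proteins
    out: dict[str, pd.DataFrame] = {}
    for o in manifest.outcomes:
        y = np.zeros(panel.n_samples)
        for p in manifest.proteins:
            th = manifest.theta.get(p, {}).get(o, 0.0)
            if th:
                y = y + float(th) * vals[p].to_numpy(dtype=float)
        for v, d in manifest.direct_effects.items():
            eff = d.get(o, 0.0)
            if eff:
                y = y + float(eff) * panel.dosage(v)
        y = y + rng.normal(0.0, outcome_noise_sd, size=panel.n_samples)
        out[o] = marginal_gwas(y, panel)
    return out


# ---------------------------------------------------------------------------
# raw proteomic plates with injected QC defects


@dataclass
class Defect:
    """One injected QC failure.

    kind: 'lod' | 'cv' | 'scale_factor' | 'iqr' (analyte-level) or
    'sample_outlier' (sample-level). Parameters have kind-specific meaning:
    fraction = share of sample wells (lod, iqr) or of analytes
    (sample_outlier) touched; magnitude = calibrator CV (cv), plate-1
    calibrator multiplier (scale_factor), or log10 shift (iqr,
    sample_outlier).
    """

    kind: str
    analyte: str | None = None
    sample: str | None = None
    fraction: float = 0.2
    magnitude: float | None = None


_ANALYTE_KINDS = {"lod", "cv", "scale_factor", "iqr"}


def make_raw_proteomics(
    clean,
    failures: list[Defect] | None = None,
    seed: int = 0,
    n_plates: int = 3,
    base_log10: float = 3.0,
    spread: float = 0.15,
    n_calibrators: int = 8,
    n_buffers: int = 4,
):
    """Back-transform a clean log-scale matrix to raw RFU plates + defects.

    Sample wells get raw value 10**(base_log10 + spread * z). Each plate
    carries 8 calibrator wells (~N(1000, 20) per analyte) and 4 buffer
    wells (~N(100, 10)). Injected defects are recorded in a ledger
    ({'analytes': {id: kind}, 'samples': {id: kind}}) for QC-test
    assertions. Returns (raw ProteinMatrix, ledger).
    """
    from .qc import ProteinMatrix

    failures = list(failures or [])
    rng = np.random.default_rng(seed)
    analytes = list(clean.values.columns)
    samples = list(clean.values.index)

    seen: dict[str, str] = {}
    for d in failures:
        if d.kind in _ANALYTE_KINDS:
            if d.analyte is None or d.analyte not in analytes:
                raise ValueError(f"defect names unknown analyte {d.analyte!r}")
            if d.analyte in seen:
                raise ValueError(
                    f"contradictory defects on analyte {d.analyte}: "
                    f"{seen[d.analyte]} and {d.kind}"
                )
            seen[d.analyte] = d.kind
        elif d.kind == "sample_outlier":
            if d.sample is None or d.sample not in samples:
                raise ValueError(f"defect names unknown sample {d.sample!r}")
        else:
            raise ValueError(f"unknown defect kind {d.kind!r}")

    z = clean.values.to_numpy(dtype=float)
    z = (z - z.mean(axis=0)) / np.where(z.std(axis=0) > 0, z.std(axis=0), 1.0)
    raw = 10.0 ** (base_log10 + spread * z)
    raw_df = pd.DataFrame(raw, index=samples, columns=analytes)

    plates = [f"plate-{i + 1}" for i in range(n_plates)]
    plate_of = {s: plates[i % n_plates] for i, s in enumerate(samples)}

    cal_rows, buf_rows, meta_rows = [], [], []
    cal_sd = {a: 20.0 for a in analytes}
    for d in failures:
        if d.kind == "cv":
            cal_sd[d.analyte] = (d.magnitude if d.magnitude is not None else 0.30) * 1000.0
    for plate in plates:
        for i in range(n_calibrators):
            well = f"{plate}-cal{i + 1}"
            row = {a: rng.normal(1000.0, cal_sd[a]) for a in analytes}
            cal_rows.append(pd.Series(row, name=well))
            meta_rows.append({"well": well, "role": "calibrator", "plate": plate})
        for i in range(n_buffers):
            well = f"{plate}-buf{i + 1}"
            row = {a: rng.normal(100.0, 10.0) for a in analytes}
            buf_rows.append(pd.Series(row, name=well))
            meta_rows.append({"well": well, "role": "buffer", "plate": plate})

    cal_df = pd.DataFrame(cal_rows)
    buf_df = pd.DataFrame(buf_rows)

    ledger = {"analytes": {}, "samples": {}}
    for d in failures:
        if d.kind == "scale_factor":
            factor = d.magnitude if d.magnitude is not None else 0.4
            on_plate = [w for w in cal_df.index if w.startswith(f"{plates[0]}-")]
            cal_df.loc[on_plate, d.analyte] *= factor
            ledger["analytes"][d.analyte] = "scale_factor"
        elif d.kind == "cv":
            ledger["analytes"][d.analyte] = "cv"
        elif d.kind == "lod":
            lod = buf_df[d.analyte].mean() + 2 * buf_df[d.analyte].std(ddof=1)
            k = int(np.ceil(d.fraction * len(samples)))
            hit = rng.choice(samples, size=k, replace=False)
            raw_df.loc[hit, d.analyte] = lod * rng.uniform(0.3, 0.9, size=k)
            ledger["analytes"][d.analyte] = "lod"
        elif d.kind == "iqr":
            shift = d.magnitude if d.magnitude is not None else 3.0
            k = int(np.ceil(d.fraction * len(samples)))
            hit = rng.choice(samples, size=k, replace=False)
            raw_df.loc[hit, d.analyte] *= 10.0**shift
            ledger["analytes"][d.analyte] = "iqr"
        elif d.kind == "sample_outlier":
            shift = d.magnitude if d.magnitude is not None else 3.0
            k = int(np.ceil(d.fraction * len(analytes)))
            hit = rng.choice(analytes, size=k, replace=False)
            raw_df.loc[d.sample, hit] *= 10.0**shift
            ledger["samples"][d.sample] = "sample_outlier"

    values = pd.concat([raw_df, cal_df, buf_df])
    meta = pd.concat(
        [
            pd.DataFrame(
                {"role": "sample", "plate": [plate_of[s] for s in samples]},
                index=samples,
            ),
            pd.DataFrame(meta_rows).set_index("well")[["role", "plate"]],
        ]
    )
    matrix = ProteinMatrix(
        values=values,
        sample_meta=meta,
        analyte_meta=(clean.analyte_meta.copy() if clean.analyte_meta is not None else None),
        log_scale=False,
    )
    return matrix, ledger
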