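"""Aptamer-proteomics quality control.

Four analyte-level filters on raw relative-fluorescence values, then an
iterative sample-outlier step:

1. Minimum detection — the limit of detection (LOD) per analyte is
   mean(buffer wells) + 2*sd(buffer wells); a sample below the LOD is an
   outlier; the analyte is removed when outliers exceed 15% of samples.
2. Scale-factor difference — per analyte, the calibration scale factor of
   each plate is median(cross-plate reference) / median(plate calibrators);
   the analyte fails when max_plate |factor - median(factors)| > 0.5.
3. Calibrator coefficient of variation — sd/mean of each plate's
   calibrator wells (sample sd, ddof=1); fails when any plate's CV > 0.15.
4. IQR strategy — on log10 values, a sample is an outlier when outside
   [Q1 - 1.5*IQR, Q3 + 1.5*IQR] (type-7 quartiles); the analyte is removed
   when outliers exceed 15% of samples.

An analyte is kept only when it passes all four. Sample outliers are then
called (outlier in > 15% of passing analytes), analytes shared by >= 80% of
those outliers are removed, outliers are re-called once, and flagged
samples are dropped. All "15%" thresholds are strict (> 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOD_SD_MULTIPLIER = 2.0
OUTLIER_SAMPLE_FRACTION = 0.15
SCALE_FACTOR_MAX_DIFF = 0.5
CALIBRATOR_CV_MAX = 0.15
IQR_MULTIPLIER = 1.5
SHARED_ANALYTE_FRACTION = 0.8

# filter order fixes the primary removal reason when several would fire
_FILTER_ORDER = ["lod", "scale_factor", "cv", "iqr"]


@dataclass
class ProteinMatrix:
    """Samples x analytes abundance table with well metadata.

    values: DataFrame (rows = wells, columns = analytes), strictly positive
    on the raw scale. sample_meta: per-well role (sample|calibrator|buffer)
    and plate id. log_scale marks matrices already on log10 scale (cleaned
    output; no calibrator/buffer wells).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    analyte_meta: pd.DataFrame | None = None
    log_scale: bool = False

    def wells(self, role: str) -> pd.DataFrame:
        idx = self.sample_meta.index[self.sample_meta["role"] == role]
        return self.values.loc[idx]

    @property
    def plates(self) -> list[str]:
        return sorted(self.sample_meta["plate"].unique())


@dataclass
class QCReport:
    analytes: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)
    iterations: list[dict] = field(default_factory=list)
    quartile_method: str = "linear"  # numpy 'linear' == R type-7

    @property
    def removed_analytes(self) -> list[str]:
        if self.analytes.empty:
            return []
        return list(self.analytes.index[self.analytes["removed"]])

    @property
    def removed_samples(self) -> list[str]:
        if self.samples.empty:
            return []
        return list(self.samples.index[self.samples["outlier"]])

    def summary(self) -> dict:
        return {
            "n_analytes": int(len(self.analytes)),
            "n_analytes_removed": len(self.removed_analytes),
            "n_samples_removed": len(self.removed_samples),
            "removal_reasons": (
                self.analytes.loc[self.analytes["removed"], "reason"]
                .value_counts()
                .to_dict()
                if not self.analytes.empty
                else {}
            ),
            "quartile_method": self.quartile_method,
        }


def _iqr_outlier_mask(log_values: pd.DataFrame, k: float = IQR_MULTIPLIER) -> pd.DataFrame:
    """Boolean mask of per-analyte 1.5*IQR outliers (type-7 quartiles).

    Degenerate IQR = 0 collapses the bounds to the median: any deviating
    value is an outlier.
    """
    q1 = log_values.quantile(0.25, interpolation="linear")
    q3 = log_values.quantile(0.75, interpolation="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (log_values.lt(lo)) | (log_values.gt(hi))


def filter_analytes(matrix: ProteinMatrix) -> QCReport:
    """Apply the four analyte-level filters; verdicts in a QCReport."""
    if matrix.log_scale:
        raise ValueError("analyte filters operate on the raw scale")
    if (matrix.values <= 0).any().any():
        raise ValueError("raw values must be strictly positive")
    buffers = matrix.wells("buffer")
    calibrators = matrix.wells("calibrator")
    if buffers.empty or len(calibrators) < 2:
        raise ValueError("need >= 1 buffer and >= 2 calibrator wells")
    samples = matrix.wells("sample")
    n_samples = len(samples)
    plates = matrix.plates
    cal_plate = matrix.sample_meta.loc[calibrators.index, "plate"]

    lod = buffers.mean() + LOD_SD_MULTIPLIER * buffers.std(ddof=1)
    lod_frac = samples.lt(lod).sum() / n_samples
    lod_fail = lod_frac > OUTLIER_SAMPLE_FRACTION

    plate_medians = calibrators.groupby(cal_plate).median()  # plate x analyte
    reference = plate_medians.median()  # cross-plate median per analyte
    factors = reference / plate_medians
    sf_diff = (factors - factors.median()).abs().max()
    sf_fail = sf_diff > SCALE_FACTOR_MAX_DIFF

    plate_cv = calibrators.groupby(cal_plate).std(ddof=1) / calibrators.groupby(
        cal_plate
    ).mean()
    cv = plate_cv.max()
    cv_fail = cv > CALIBRATOR_CV_MAX

    outliers = _iqr_outlier_mask(np.log10(samples))
    iqr_count = outliers.sum()
    iqr_fail = (iqr_count / n_samples) > OUTLIER_SAMPLE_FRACTION

    fails = {"lod": lod_fail, "scale_factor": sf_fail, "cv": cv_fail, "iqr": iqr_fail}
    removed = lod_fail | sf_fail | cv_fail | iqr_fail
    reason = pd.Series("", index=samples.columns, dtype=object)
    for name in reversed(_FILTER_ORDER):
        reason[fails[name]] = name

    analytes = pd.DataFrame(
        {
            "lod": lod,
            "lod_outlier_frac": lod_frac,
            "lod_fail": lod_fail,
            "scale_factor_diff": sf_diff,
            "scale_factor_fail": sf_fail,
            "cv": cv,
            "cv_fail": cv_fail,
            "iqr_outlier_count": iqr_count,
            "iqr_fail": iqr_fail,
            "removed": removed,
            "reason": reason,
        }
    )
    report = QCReport(analytes=analytes)
    report.iterations.append(
        {"step": "analyte_filters", "n_plates": len(plates), "removed": int(removed.sum())}
    )
    return report


def detect_sample_outliers(matrix: ProteinMatrix, report: QCReport) -> QCReport:
    """Iterative sample-outlier calling over the QC-passing analytes.

    A sample is an outlier when it is an IQR outlier in > 15% of passing
    analytes. Analytes outlying in >= 80% of those samples are removed
    (reason 'shared_by_outliers'); outliers are re-called once on the
    remaining analytes.
    """
    if report.analytes.empty:
        raise ValueError("run filter_analytes first")
    samples = matrix.wells("sample") if not matrix.log_scale else matrix.values
    log_vals = samples if matrix.log_scale else np.log10(samples)
    passing = [a for a in log_vals.columns if not report.analytes.loc[a, "removed"]]

    def call(analytes: list[str]) -> tuple[pd.Series, pd.DataFrame]:
        mask = _iqr_outlier_mask(log_vals[analytes])
        frac = mask.sum(axis=1) / len(analytes)
        return frac, mask

    frac, mask = call(passing)
    flagged = frac.index[frac > OUTLIER_SAMPLE_FRACTION]
    report.iterations.append({"step": "sample_outliers_1", "flagged": int(len(flagged))})
    # the shared-analyte rule speaks of a fraction of outlier samples, which
    # is degenerate for a single outlier; require >= 2 before removing analytes
    if len(flagged) >= 2:
        shared = mask.loc[flagged, passing].mean(axis=0)
        to_remove = shared.index[shared >= SHARED_ANALYTE_FRACTION]
        if len(to_remove) > 0:
            report.analytes.loc[to_remove, ["removed", "reason"]] = [
                True,
                "shared_by_outliers",
            ]
            passing = [a for a in passing if a not in set(to_remove)]
            report.iterations.append(
                {"step": "shared_analyte_removal", "removed": int(len(to_remove))}
            )
        frac, mask = call(passing)
        flagged = frac.index[frac > OUTLIER_SAMPLE_FRACTION]
        report.iterations.append(
            {"step": "sample_outliers_2", "flagged": int(len(flagged))}
        )
    report.samples = pd.DataFrame(
        {"outlier": frac.index.isin(flagged), "outlier_fraction": frac}
    )
    return report


def run_qc(matrix: ProteinMatrix) -> tuple[ProteinMatrix, QCReport]:
    """Full QC: analyte filters, sample outliers, cleaned log10 matrix.

    Accepts either a raw matrix with calibrator/buffer wells or an
    already-cleaned log-scale matrix (the raw-level filters are then
    inapplicable and only the IQR machinery runs), which makes the
    operation idempotent on its own output.
    """
    if matrix.log_scale:
        report = QCReport()
        report.analytes = pd.DataFrame(
            {
                "removed": False,
                "reason": "",
                "iqr_fail": (
                    _iqr_outlier_mask(matrix.values).sum() / len(matrix.values)
                    > OUTLIER_SAMPLE_FRACTION
                ),
            },
            index=matrix.values.columns,
        )
        report.analytes.loc[report.analytes["iqr_fail"], ["removed", "reason"]] = [
            True,
            "iqr",
        ]
    else:
        report = filter_analytes(matrix)
    report = detect_sample_outliers(matrix, report)
    keep_analytes = [
        a for a in matrix.values.columns if not report.analytes.loc[a, "removed"]
    ]
    if not keep_analytes:
        raise ValueError("all analytes removed by QC")
    sample_ids = (
        matrix.values.index
        if matrix.log_scale
        else matrix.sample_meta.index[matrix.sample_meta["role"] == "sample"]
    )
    keep_samples = [s for s in sample_ids if s not in set(report.removed_samples)]
    vals = matrix.values.loc[keep_samples, keep_analytes]
    if not matrix.log_scale:
        vals = np.log10(vals)
    cleaned = ProteinMatrix(
        values=vals,
        sample_meta=matrix.sample_meta.loc[keep_samples],
        analyte_meta=(
            matrix.analyte_meta.loc[
                [a for a in keep_analytes if a in matrix.analyte_meta.index]
            ]
            if matrix.analyte_meta is not None
            else None
        ),
        log_scale=True,
    )
    return cleaned, report
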