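"""Quality control and normalisation for FFPE bead-array expression data.

Degraded FFPE RNA profiled on a WG-DASL-style platform yields many
undetectable probe/sample cells and a pronounced per-slide batch effect
(slides of 8 samples).  The pipeline here reproduces a practical QC chain:

1. :func:`select_best_sample` — drop non-primary-site samples; keep the
   best-detected sample per patient.
2. :func:`detection_filter` — drop samples detectable in fewer than 30% of
   probes, then probes detectable in fewer than 10% of samples.
3. :func:`batch_run_filter` — drop probes whose undetectable cells cluster
   in contiguous runs within a slide far beyond what their overall
   detection rate explains (exact longest-run test, per-slide Bonferroni).
4. :func:`normalize` — log2 transform, per-sample outlier removal, quantile
   normalisation with rank-based imputation of removed cells.

The longest-run null probability is computed exactly by dynamic programming
(:func:`run_pvalue`), so the batch filter has a desk-checkable statistic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix

__all__ = [
    "QcReport",
    "select_best_sample",
    "detection_filter",
    "run_pvalue",
    "batch_run_filter",
    "normalize",
    "log_transform_counts",
    "qc_pipeline",
]

#: detectability call: detection_p below this is "detected"
DETECTION_P_THRESHOLD = 0.01


@dataclass
class QcReport:
    """Bookkeeping for one QC stage (or a whole pipeline run)."""

    stage: str
    n_samples_in: int
    n_samples_out: int
    n_probes_in: int
    n_probes_out: int
    removal_counts: dict = field(default_factory=dict)
    sample_detectable_fraction: pd.Series | None = None
    batch_removed: pd.Series | None = None  # probe id -> run p-value
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        removed_s = self.removal_counts.get("samples", 0)
        removed_p = self.removal_counts.get("probes", 0)
        if self.n_samples_in - removed_s != self.n_samples_out:
            raise ValueError(f"{self.stage}: sample counts do not telescope")
        if self.n_probes_in - removed_p != self.n_probes_out:
            raise ValueError(f"{self.stage}: probe counts do not telescope")


def _detectable_fraction_per_sample(matrix: ExpressionMatrix,
                                    p_threshold: float) -> pd.Series:
    return matrix.detectable(p_threshold).mean(axis=0)


def select_best_sample(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    *,
    p_threshold: float = DETECTION_P_THRESHOLD,
) -> tuple[ExpressionMatrix, QcReport]:
    """Keep one sample per patient: primary-site only, best detection score.

    Non-primary-site samples are discarded first.  Among a patient's
    remaining samples the one with the highest detectable-probe fraction is
    kept; ties break by sample_id order.
    """
    if matrix.detection_p is None:
        raise ValueError("select_best_sample requires detection p-values")
    ann = annotation.loc[[s for s in matrix.sample_ids if s in annotation.index]]
    primary = ann.loc[ann["tissue_site"] == "primary"]
    frac = _detectable_fraction_per_sample(matrix, p_threshold)
    keep: list[str] = []
    for _, grp in primary.groupby("patient_id", sort=False):
        ids = sorted(grp["sample_id"])
        keep.append(max(ids, key=lambda s: (frac[s], )))  # ties -> first by id
    # max() keeps the first maximal element of the sorted id list on ties
    keep = [s for s in matrix.sample_ids if s in set(keep)]
    out = matrix.subset(samples=keep)
    report = QcReport(
        stage="select_best_sample",
        n_samples_in=matrix.shape[1], n_samples_out=out.shape[1],
        n_probes_in=matrix.shape[0], n_probes_out=out.shape[0],
        removal_counts={"samples": matrix.shape[1] - out.shape[1], "probes": 0},
        sample_detectable_fraction=frac,
    )
    return out, report


def detection_filter(
    matrix: ExpressionMatrix,
    sample_min: float = 0.30,
    probe_min: float = 0.10,
    *,
    p_threshold: float = DETECTION_P_THRESHOLD,
) -> tuple[ExpressionMatrix, QcReport]:
    """Discard poorly detected samples, then poorly detected probes.

    A sample is discarded when its detectable-probe fraction is strictly
    below ``sample_min``; a probe when its detectable fraction over the
    *remaining* samples is strictly below ``probe_min``.
    """
    if matrix.detection_p is None:
        raise ValueError("detection_filter requires detection p-values")
    det = matrix.detectable(p_threshold)
    sample_frac = det.mean(axis=0)
    keep_samples = sample_frac.index[sample_frac >= sample_min].tolist()
    if not keep_samples:
        raise ValueError("detection_filter removed every sample")
    probe_frac = det[keep_samples].mean(axis=1)
    keep_probes = probe_frac.index[probe_frac >= probe_min].tolist()
    out = matrix.subset(probes=keep_probes, samples=keep_samples)
    report = QcReport(
        stage="detection_filter",
        n_samples_in=matrix.shape[1], n_samples_out=out.shape[1],
        n_probes_in=matrix.shape[0], n_probes_out=out.shape[0],
        removal_counts={
            "samples": matrix.shape[1] - len(keep_samples),
            "probes": matrix.shape[0] - len(keep_probes),
        },
        sample_detectable_fraction=sample_frac,
    )
    return out, report


def run_pvalue(n: int, k: int, det_rate: float) -> float:
    """P(longest undetectable run >= k) in n independent detection trials.

    Each of the ``n`` positions is detectable with probability ``det_rate``
    independently; the statistic is the length of the longest run of
    consecutive undetectable positions.  Computed exactly by dynamic
    programming over the trailing-run length, so the complement (no run of
    length ``k``) is accumulated to machine precision.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if det_rate <= 0:
        return 1.0  # every position undetectable: a length-n run is certain
    if det_rate >= 1:
        return 0.0
    p, q = det_rate, 1.0 - det_rate
    # f[j]: probability mass of prefixes with no undetectable run >= k and a
    # trailing undetectable run of exactly j (j < k)
    f = np.zeros(k)
    f[0] = 1.0
    for _ in range(n):
        g = np.zeros(k)
        g[0] = f.sum() * p        # a detected position resets the run
        g[1:] = f[:-1] * q        # an undetected position extends it
        f = g                     # mass reaching run length k is dropped
    return float(1.0 - f.sum())


def _longest_false_run(flags: np.ndarray) -> int:
    """Length of the longest run of False in a 1-D boolean array."""
    best = cur = 0
    for v in flags:
        cur = 0 if v else cur + 1
        best = max(best, cur)
    return best


def batch_run_filter(
    matrix: ExpressionMatrix,
    alpha: float = 1e-4,
    *,
    p_threshold: float = DETECTION_P_THRESHOLD,
) -> tuple[ExpressionMatrix, QcReport]:
    """Remove probes whose undetectable cells cluster within one slide.

    For each probe the overall detectable fraction is the null detection
    rate.  Within every slide (samples in load order) the longest run of
    undetectable samples is found and its exact null probability computed
    with :func:`run_pvalue`; the probe's p-value is the minimum over slides,
    Bonferroni-multiplied by the number of slides.  Probes with p < ``alpha``
    are discarded — the signature of a slide-level technical failure rather
    than biology.
    """
    if matrix.detection_p is None:
        raise ValueError("batch_run_filter requires detection p-values")
    if matrix.slide_of is None or matrix.slide_of.isna().any():
        raise ValueError("batch_run_filter requires slide labels for all samples")
    det = matrix.detectable(p_threshold).to_numpy()
    slides = matrix.slide_of
    slide_cols = {
        label: [matrix.sample_ids.index(s) for s in slides.index[slides == label]]
        for label in slides.unique()
    }
    n_slides = len(slide_cols)
    det_rate = det.mean(axis=1)
    pvals = np.ones(matrix.shape[0])
    for i in range(matrix.shape[0]):
        rate = det_rate[i]
        if rate >= 1.0:
            continue
        best = 1.0
        for cols in slide_cols.values():
            flags = det[i, cols]
            k = _longest_false_run(flags)
            if k >= 1:
                best = min(best, run_pvalue(len(cols), k, rate))
        pvals[i] = min(1.0, best * n_slides)
    pser = pd.Series(pvals, index=matrix.values.index)
    keep = pser.index[pser >= alpha].tolist()
    out = matrix.subset(probes=keep)
    report = QcReport(
        stage="batch_run_filter",
        n_samples_in=matrix.shape[1], n_samples_out=out.shape[1],
        n_probes_in=matrix.shape[0], n_probes_out=out.shape[0],
        removal_counts={"samples": 0, "probes": matrix.shape[0] - len(keep)},
        batch_removed=pser[pser < alpha],
    )
    return out, report


def normalize(
    matrix: ExpressionMatrix,
    outlier_sd: float = 3.0,
) -> tuple[ExpressionMatrix, QcReport]:
    """Log2-transform, remove per-sample outliers, quantile-normalise.

    Raw intensities must be strictly positive (an already-log2 matrix is not
    re-transformed).  Per sample, values farther than ``outlier_sd`` sample
    standard deviations from the sample mean are set missing; a constant
    sample (SD = 0) yields no outliers.  The quantile-normalisation target
    is the average of the samples' empirical quantile functions over
    non-missing values; every cell — including missing ones, which are
    imputed and flagged — is mapped to the target value at the quantile of
    its within-sample rank, so each sample's sorted value vector equals the
    common target.
    """
    vals = matrix.values.to_numpy(dtype=float).copy()
    if not matrix.is_log2:
        bad = np.argwhere(vals <= 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                "non-positive raw intensity at probe "
                f"{matrix.values.index[i]!r}, sample {matrix.values.columns[j]!r}"
            )
        vals = np.log2(vals)
    n_probes, n_samples = vals.shape
    # per-sample outlier flags
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1) if n_probes > 1 else np.zeros(n_samples)
    with np.errstate(invalid="ignore"):
        outlier = np.abs(vals - mean) > outlier_sd * sd
    outlier[:, sd == 0] = False
    # target distribution on a common quantile grid
    grid = (np.arange(n_probes) + 0.5) / n_probes
    target = np.zeros(n_probes)
    for j in range(n_samples):
        good = np.sort(vals[~outlier[:, j], j])
        qs = (np.arange(good.size) + 0.5) / good.size
        target += np.interp(grid, qs, good)
    target /= n_samples
    # map every cell (outliers included) to the target at its rank quantile
    out_vals = np.empty_like(vals)
    for j in range(n_samples):
        ranks = rankdata(vals[:, j], method="average")
        q = (ranks - 0.5) / n_probes
        out_vals[:, j] = np.interp(q, grid, target)
    values = pd.DataFrame(out_vals, index=matrix.values.index,
                          columns=matrix.values.columns)
    out_frame = pd.DataFrame(outlier, index=values.index, columns=values.columns)
    out = matrix.with_values(
        values, is_log2=True,
        missing_mask=matrix.missing_mask | out_frame,
        imputed_mask=matrix.imputed_mask | out_frame,
    )
    report = QcReport(
        stage="normalize",
        n_samples_in=n_samples, n_samples_out=n_samples,
        n_probes_in=n_probes, n_probes_out=n_probes,
        removal_counts={"samples": 0, "probes": 0,
                        "outlier_cells": int(outlier.sum())},
        notes=["outlier removal is per-sample (distance from the sample mean)"],
    )
    return out, report


def log_transform_counts(counts: pd.DataFrame, pseudocount: float = 1.0
                         ) -> pd.DataFrame:
    """log2(count + pseudocount) for a non-negative count matrix."""
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}"
        )
    return pd.DataFrame(np.log2(arr + pseudocount), index=counts.index,
                        columns=counts.columns)


def qc_pipeline(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    *,
    sample_min: float = 0.30,
    probe_min: float = 0.10,
    alpha: float = 1e-4,
    outlier_sd: float = 3.0,
    p_threshold: float = DETECTION_P_THRESHOLD,
) -> tuple[ExpressionMatrix, list[QcReport]]:
    """Full QC chain in its fixed order; per-stage reports telescope."""
    m, r1 = select_best_sample(matrix, annotation, p_threshold=p_threshold)
    m, r2 = detection_filter(m, sample_min, probe_min, p_threshold=p_threshold)
    m, r3 = batch_run_filter(m, alpha, p_threshold=p_threshold)
    m, r4 = normalize(m, outlier_sd)
    return m, [r1, r2, r3, r4]
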