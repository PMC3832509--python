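"""Tumor vascularization: VEGF-profile expression ranks and microvessel area.

Expression side: a combined VEGF profile score per sample is the mean of the
sample's within-cohort ranks over the profile genes (ties get average
ranks), and per-gene group differences are Welch t-tests with a Bonferroni
multiplier over the genes tested.

Image side: immunofluorescence histospots carry three channels —
cytokeratin marks tumor epithelium, DAPI marks nuclei, CD31 marks vessel
endothelium.  A binary tumor mask is derived from cytokeratin (Otsu
threshold, morphological closing, small-object removal); spots with less
than 5% tumor content are excluded.  DAPI partitions the tumor area into
nuclear and non-nuclear compartments.  The CD31-positive area inside the
tumor mask, as a percentage of tumor area, is the microvessel area (MVA),
dichotomised at 0.6% into high/low vascularization.  All thresholding uses
Otsu plus a contrast guard: when foreground and background means are not
separated by at least four background standard deviations the channel is
treated as signal-free, because Otsu alone would split the noise mode of an
empty channel and call half the pixels positive.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects

from .datatypes import ExpressionMatrix
from .scoring import stage_adjusted_p

__all__ = [
    "Histospot",
    "MvaResult",
    "read_histospot",
    "write_histospot",
    "vegf_rank_score",
    "per_gene_group_test",
    "tumor_mask",
    "compartment_masks",
    "microvessel_area",
    "mva_association",
]

DEFAULT_MVA_THRESHOLD_PCT = 0.6  # high/low vascularization cut-off, percent
MIN_TUMOR_FRACTION = 0.05
CONTRAST_GUARD_SDS = 4.0
TUMOR_CLOSING_RADIUS = 2
TUMOR_MIN_OBJECT_PX = 50
VESSEL_MIN_OBJECT_PX = 10


@dataclass
class Histospot:
    """One tissue-microarray core: three channels plus derived masks."""

    spot_id: str
    cytokeratin: np.ndarray
    dapi: np.ndarray
    cd31: np.ndarray
    tumor: np.ndarray | None = None
    nuclear: np.ndarray | None = None
    vessel: np.ndarray | None = None
    excluded: bool = False
    exclusion_reason: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.cytokeratin.shape, self.dapi.shape, self.cd31.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name in ("cytokeratin", "dapi", "cd31"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"{name} channel has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cytokeratin.shape


@dataclass
class MvaResult:
    spot_id: str
    tumor_fraction: float | None
    mva_percent: float | None
    high_mva: bool | None
    excluded: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and self.mva_percent is not None:
            raise ValueError("excluded spots carry no MVA value")
        if self.mva_percent is not None and not 0 <= self.mva_percent <= 100:
            raise ValueError("mva_percent outside [0, 100]")


# -- image file I/O ------------------------------------------------------------

_CHANNELS = ("cytokeratin", "dapi", "cd31")
_PNG_SCALE = 65535.0  # 16-bit quantisation for [0, 1]-ranged channels


def write_histospot(spot: Histospot, directory) -> list:
    """Write the three channels as 16-bit grayscale PNG/TIFF files.

    Files are named ``<spot_id>.<channel>.png``; intensities are clipped to
    [0, 1] and quantised to 16 bits.  Returns the paths written.
    """
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in _CHANNELS:
        img = np.clip(getattr(spot, name), 0, 1)
        path = directory / f"{spot.spot_id}.{name}.png"
        iio.imwrite(path, (img * _PNG_SCALE).astype(np.uint16))
        paths.append(path)
    return paths


def read_histospot(spot_id: str, directory) -> Histospot:
    """Read a histospot written by :func:`write_histospot` (PNG or TIFF)."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    channels = {}
    for name in _CHANNELS:
        for ext in ("png", "tif", "tiff"):
            path = directory / f"{spot_id}.{name}.{ext}"
            if path.exists():
                break
        else:
            raise FileNotFoundError(
                f"no {name} channel image for spot {spot_id!r} in {directory}")
        channels[name] = iio.imread(path).astype(float) / _PNG_SCALE
    return Histospot(spot_id=spot_id, **channels)


# -- expression side -----------------------------------------------------------

def vegf_rank_score(matrix: ExpressionMatrix, vegf_genes: list[str]
                    ) -> tuple[pd.Series, list[str]]:
    """Mean within-cohort expression rank over the profile genes per sample.

    For each profile gene present in the matrix, samples are ranked
    ascending (average ranks on ties); a sample's score is the mean of its
    ranks across the available genes.  Returns the score series and the
    list of genes actually used.
    """
    gene_vals = matrix.gene_level()
    genes_used = [g.upper() for g in vegf_genes if g.upper() in gene_vals.index]
    if not genes_used:
        raise ValueError("none of the profile genes are present in the matrix")
    ranks = gene_vals.loc[genes_used].rank(axis=1, method="average")
    return ranks.mean(axis=0), genes_used


def per_gene_group_test(
    matrix: ExpressionMatrix,
    genes: list[str],
    groups: pd.Series,
) -> pd.DataFrame:
    """Welch two-tailed t-test per gene, Bonferroni-adjusted over the genes.

    Genes absent from the matrix are reported with a note and no test; the
    Bonferroni multiplier is the number of genes actually tested.
    """
    gene_vals = matrix.gene_level()
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    common = gene_vals.columns.intersection(groups.index)
    g = groups.loc[common]
    rows = []
    for gene in genes:
        gene = gene.upper()
        if gene not in gene_vals.index:
            rows.append({"gene": gene, "t": np.nan, "p": np.nan,
                         "bonferroni_p": np.nan, "direction": "",
                         "note": "gene absent; skipped"})
            continue
        x = gene_vals.loc[gene, common]
        a = x[g == labels[0]].to_numpy(float)
        b = x[g == labels[1]].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs at least 2 samples")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and np.isclose(
                a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"gene": gene, "t": float(t), "p": float(p),
                     "bonferroni_p": np.nan,
                     "direction": f"{labels[0]} {'>' if t > 0 else '<='} {labels[1]}",
                     "note": ""})
    out = pd.DataFrame(rows).set_index("gene")
    m = out["p"].notna().sum()
    out["bonferroni_p"] = np.minimum(1.0, out["p"] * m)
    return out


# -- image side ----------------------------------------------------------------

def _guarded_otsu_mask(img: np.ndarray) -> np.ndarray:
    """Otsu foreground mask, empty when the channel has no real signal.

    The guard requires the foreground/background mean separation to exceed
    ``CONTRAST_GUARD_SDS`` background standard deviations; both the Otsu
    threshold and the guard are invariant to positive rescaling of the
    channel.
    """
    flat = img.ravel()
    if np.ptp(flat) == 0:
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img)
    mask = img > t
    if not mask.any() or mask.all():
        return np.zeros(img.shape, dtype=bool)
    bg = flat[~mask.ravel()]
    sep = img[mask].mean() - bg.mean()
    if sep < CONTRAST_GUARD_SDS * max(bg.std(), 1e-12):
        return np.zeros(img.shape, dtype=bool)
    return mask


def tumor_mask(spot: Histospot, min_tumor_frac: float = MIN_TUMOR_FRACTION
               ) -> Histospot:
    """Derive the binary tumor mask from cytokeratin; exclude sparse spots.

    Otsu threshold (with the contrast guard), morphological closing with a
    radius-2 disk, then removal of connected components under 50 px.  Spots
    whose tumor fraction falls below ``min_tumor_frac`` are marked excluded
    with a reason; a signal-free channel excludes with reason "no signal".
    """
    if np.ptp(spot.cytokeratin) == 0:
        spot.excluded, spot.exclusion_reason = True, "no signal"
        spot.tumor = np.zeros(spot.shape, dtype=bool)
        return spot
    mask = _guarded_otsu_mask(spot.cytokeratin)
    if not mask.any():
        spot.excluded, spot.exclusion_reason = True, "no signal"
        spot.tumor = mask
        return spot
    mask = closing(mask, disk(TUMOR_CLOSING_RADIUS))
    mask = remove_small_objects(mask, max_size=TUMOR_MIN_OBJECT_PX - 1)
    spot.tumor = mask
    frac = mask.mean()
    if frac < min_tumor_frac:
        spot.excluded = True
        spot.exclusion_reason = (
            f"tumor content {100 * frac:.1f}% below "
            f"{100 * min_tumor_frac:.0f}%")
    return spot


def compartment_masks(spot: Histospot) -> Histospot:
    """Partition the tumor mask into nuclear and non-nuclear compartments.

    Nuclear = Otsu-thresholded DAPI within the tumor mask; non-nuclear is
    its complement within the tumor, so the two are disjoint and their
    union is exactly the tumor mask.
    """
    if spot.tumor is None:
        raise ValueError("tumor mask must be derived first")
    spot.nuclear = _guarded_otsu_mask(spot.dapi) & spot.tumor
    return spot


def microvessel_area(
    spot: Histospot,
    threshold_pct: float = DEFAULT_MVA_THRESHOLD_PCT,
) -> MvaResult:
    """CD31-positive area inside the tumor mask, as percent of tumor area.

    Vessel mask = Otsu-thresholded CD31 (contrast-guarded) intersected with
    the tumor mask, components under 10 px removed.  ``high_mva`` flags
    spots above ``threshold_pct`` percent.
    """
    if spot.tumor is None:
        raise ValueError("tumor mask must be derived first")
    if spot.excluded:
        raise ValueError(
            f"spot {spot.spot_id!r} is excluded ({spot.exclusion_reason})")
    vessel = _guarded_otsu_mask(spot.cd31) & spot.tumor
    vessel = remove_small_objects(vessel, max_size=VESSEL_MIN_OBJECT_PX - 1)
    spot.vessel = vessel
    tumor_px = int(spot.tumor.sum())
    mva = 100.0 * vessel.sum() / tumor_px
    return MvaResult(
        spot_id=spot.spot_id,
        tumor_fraction=float(spot.tumor.mean()),
        mva_percent=float(mva),
        high_mva=bool(mva > threshold_pct),
        excluded=False)


def mva_association(
    mva_results: list[MvaResult],
    annotation: pd.DataFrame,
    covariate: str = "nodal",
    *,
    spot_to_patient: dict[str, str] | None = None,
    threshold_pct: float = DEFAULT_MVA_THRESHOLD_PCT,
    strata_col: str | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
    unknown_values: tuple = ("unknown",),
) -> pd.DataFrame:
    """Association of microvessel area with a two-level clinical covariate.

    Spots are aggregated per patient (mean MVA over the patient's
    non-excluded spots; patients with only excluded spots are dropped with a
    warning).  Two tests are reported side by side: Fisher's exact test on
    the high/low dichotomisation against the covariate, and a Welch t-test
    on the numeric MVA.  With ``strata_col`` given, a stratified-permutation
    adjusted p-value is added for the numeric test using the same machinery
    as signature inference.
    """
    spot_to_patient = spot_to_patient or {}
    per_patient: dict[str, list[float]] = {}
    dropped = []
    for r in mva_results:
        pid = spot_to_patient.get(r.spot_id, r.spot_id)
        if r.excluded:
            per_patient.setdefault(pid, per_patient.get(pid, []))
            continue
        per_patient.setdefault(pid, []).append(r.mva_percent)
    mva = {}
    for pid, vals in per_patient.items():
        if not vals:
            dropped.append(pid)
            continue
        mva[pid] = float(np.mean(vals))
    if dropped:
        warnings.warn(f"patients with only excluded spots dropped: {dropped}",
                      stacklevel=2)
    mva_ser = pd.Series(mva, name="mva_percent")
    ann = annotation.set_index("patient_id") if "patient_id" in annotation.columns \
        and annotation.index.name != "patient_id" else annotation
    ann = ann.loc[[p for p in mva_ser.index if p in ann.index]]
    ann = ann[~ann[covariate].astype(str).isin([str(u) for u in unknown_values])]
    mva_ser = mva_ser.loc[ann.index]
    levels = sorted(ann[covariate].unique())
    if len(levels) != 2:
        raise ValueError(f"covariate {covariate!r} has {len(levels)} levels, need 2")
    high = mva_ser > threshold_pct
    table = [[int(((ann[covariate] == lev) & h).sum()) for h in (high, ~high)]
             for lev in levels]
    _, fisher_p = stats.fisher_exact(table)
    a = mva_ser[ann[covariate] == levels[0]].to_numpy(float)
    b = mva_ser[ann[covariate] == levels[1]].to_numpy(float)
    t, welch_p = stats.ttest_ind(a, b, equal_var=False)
    rows = [
        {"test": "threshold_fisher", "statistic": np.nan, "p": float(fisher_p),
         "detail": f"high/low at {threshold_pct}% vs {covariate}"},
        {"test": "numeric_welch", "statistic": float(t), "p": float(welch_p),
         "detail": f"mean MVA {levels[0]} vs {levels[1]}"},
    ]
    if strata_col is not None:
        adj = stage_adjusted_p(mva_ser, ann[covariate], ann[strata_col],
                               n_resamples=n_resamples, seed=seed)
        rows.append({"test": "numeric_stage_adjusted", "statistic": float(t),
                     "p": float(adj),
                     "detail": f"stratified permutation on {strata_col}"})
    return pd.DataFrame(rows).set_index("test")
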