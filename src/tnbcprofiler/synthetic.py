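"""Synthetic cohorts, count matrices and histospot images with known truth.

Every downstream stage of the pipeline is testable against planted ground
truth generated here, with no external downloads.  The expression generator
emulates the structure of an FFPE WG-DASL cohort: ~90 samples hybridised in
slide batches of 8, ~18k probes with a many-to-one probe->gene mapping,
log-normal background intensities, widespread detection dropout, optional
slide-contiguous dropout runs (the batch artifact the run filter targets),
two ethnicity groups with optional planted differential signature
activation, and an optional group<->stage confounding of tunable strength.
The count generator produces negative-binomial data for the log-count
scoring path, and the histospot generator renders three-channel
immunofluorescence-like images whose recorded truth is the exact pixel
content of the rendered masks.

Effect sizes are expressed in units of the per-feature noise SD and applied
on the log2 scale, aligned with the sign of each signature gene's weight,
so a planted positive effect raises the group's activation scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .datatypes import ExpressionMatrix, GeneSignature, validate_annotation

__all__ = [
    "CohortTruth",
    "SpotTruth",
    "random_signature",
    "simulate_cohort",
    "simulate_counts",
    "simulate_histospot",
]

#: detection p-value model: detected cells draw p ~ U(0, 0.01), undetected
#: cells p ~ U(0.05, 1); the pipeline's detectability call is p < 0.01
DETECTED_P_RANGE = (0.0, 0.01)
UNDETECTED_P_RANGE = (0.05, 1.0)

_STAGE_GE2_BASE_P = 0.70          # baseline share of stage >= 2 tumors
_STAGE_SPLIT_GE2 = (0.55, 0.30, 0.15)  # stages 2/3/4 within the >= 2 share


@dataclass
class CohortTruth:
    """Planted ground truth of a simulated cohort."""

    effect_sizes: dict = field(default_factory=dict)      # signature -> AA-EA shift (SD units)
    stage_effects: dict = field(default_factory=dict)     # signature -> per-stage-step shift
    stage_confounding: float = 1.0                        # odds multiplier AA -> stage>=2
    group_of: dict = field(default_factory=dict)          # sample -> ethnicity
    batch_runs: list = field(default_factory=list)        # (probe, slide, run length)
    lar_high_ids: tuple = ()
    ar_gene: str | None = None


@dataclass(frozen=True)
class SpotTruth:
    """Exact pixel fractions of the rendered ground-truth masks."""

    vessel_fraction_of_tumor: float
    tumor_fraction_of_spot: float

    def __post_init__(self) -> None:
        for f in (self.vessel_fraction_of_tumor, self.tumor_fraction_of_spot):
            if not 0.0 <= f <= 1.0:
                raise ValueError("truth fractions must lie in [0, 1]")


def _gene_pool(n_probes: int) -> tuple[list[str], list[str]]:
    """Probe ids and their gene symbols; ~10% of genes carry two probes."""
    n_genes = max(1, int(round(n_probes * 0.9)))
    probes = [f"P{i:06d}" for i in range(n_probes)]
    genes = [f"G{i % n_genes:06d}" for i in range(n_probes)]
    return probes, genes


def random_signature(name: str, gene_pool: list[str], n_genes: int,
                     seed: int = 0, weighted: bool = False) -> GeneSignature:
    """Draw a signature over an existing gene pool.

    Directional (default): +/-1 weights; ``weighted=True`` draws standard
    normal centroid weights instead.
    """
    rng = np.random.default_rng(seed)
    genes = rng.choice(np.asarray(gene_pool), size=n_genes, replace=False)
    if weighted:
        w = rng.standard_normal(n_genes)
    else:
        w = rng.choice([-1.0, 1.0], size=n_genes)
        if np.ptp(w) == 0:  # all same sign by chance: flip one
            w[0] = -w[0]
    return GeneSignature(name=name, genes=tuple(genes), weights=tuple(w))


def cohort_gene_pool(n_probes: int) -> list[str]:
    """The distinct gene symbols :func:`simulate_cohort` will emit."""
    return sorted(set(_gene_pool(n_probes)[1]))


def _assign_stages(rng: np.random.Generator, is_aa: np.ndarray,
                   confounding: float) -> np.ndarray:
    base_odds = _STAGE_GE2_BASE_P / (1 - _STAGE_GE2_BASE_P)
    odds = np.where(is_aa, base_odds * confounding, base_odds)
    p_ge2 = odds / (1 + odds)
    ge2 = rng.random(len(is_aa)) < p_ge2
    stage = np.ones(len(is_aa), dtype=int)
    stage[ge2] = rng.choice([2, 3, 4], size=int(ge2.sum()), p=_STAGE_SPLIT_GE2)
    return stage


def _apply_signature_shift(values: np.ndarray, probe_sd: np.ndarray,
                           genes: list[str], sig: GeneSignature,
                           sample_cols: np.ndarray, scale: np.ndarray) -> None:
    """Add ``scale[j] * sd_i * sign(w_g)`` to each signature gene's probes."""
    gene_to_rows: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        gene_to_rows.setdefault(g, []).append(i)
    for g, w in zip(sig.genes, sig.weights):
        if g not in gene_to_rows:
            raise ValueError(f"signature {sig.name!r} gene {g!r} not in cohort")
        for i in gene_to_rows[g]:
            values[i, sample_cols] += scale * probe_sd[i] * np.sign(w)


def simulate_cohort(
    n_samples: int = 90,
    n_probes: int = 18345,
    signatures: list[GeneSignature] | None = None,
    effect_sizes: dict[str, float] | None = None,
    stage_effects: dict[str, float] | None = None,
    stage_confounding: float = 1.0,
    detect_rate: float = 0.80,
    slide_size: int = 8,
    n_batch_probes: int = 0,
    batch_run_length: int | None = None,
    lar: dict | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, CohortTruth]:
    """Simulate an FFPE bead-array cohort with planted effects.

    Parameters
    ----------
    effect_sizes
        Signature name -> planted AA-minus-EA activation effect, in units of
        the per-probe noise SD on the log2 scale, sign-aligned with the
        signature weights.  Keys must name provided signatures.
    stage_effects
        Signature name -> per-stage-step shift (same units), applied to all
        samples proportionally to (stage - 1); with ``stage_confounding > 1``
        this creates a stage-driven spurious group difference, the scenario
        the stratified test must neutralise.
    stage_confounding
        Odds multiplier linking AA ethnicity to stage >= 2 (1 = none).
    detect_rate
        Expected fraction of detectable probe/sample cells; detection
        p-values are drawn so that the pipeline's p < 0.01 call reproduces
        it in expectation.
    n_batch_probes / batch_run_length
        Planted slide artifacts: that many probes are made undetectable in
        a contiguous run (default: a full slide) of one slide's samples.
    lar
        Optional ``{"signature": GeneSignature, "frac": 0.12, "effect": 3.0}``
        planting a LAR-high subset: the fraction of samples shifted by the
        effect on the signature genes and on a dedicated AR proxy gene
        (recorded in the truth as ``ar_gene``).
    """
    if slide_size < 2:
        raise ValueError("slide_size must be >= 2")
    if not 0 < detect_rate <= 1:
        raise ValueError("detect_rate must lie in (0, 1]")
    signatures = list(signatures or [])
    sig_names = {s.name for s in signatures}
    effect_sizes = dict(effect_sizes or {})
    stage_effects = dict(stage_effects or {})
    for key in list(effect_sizes) + list(stage_effects):
        if key not in sig_names:
            raise ValueError(f"effect size given for unknown signature {key!r}")
    rng = np.random.default_rng(seed)
    probes, genes = _gene_pool(n_probes)
    samples = [f"S{j:03d}" for j in range(n_samples)]
    # background: per-probe mean and SD, Gaussian noise on the log2 scale
    mu = rng.normal(8.0, 2.0, size=n_probes)
    sd = rng.uniform(0.3, 1.0, size=n_probes)
    values = mu[:, None] + sd[:, None] * rng.standard_normal(
        (n_probes, n_samples))
    # clinical structure
    is_aa = rng.random(n_samples) < 0.5
    stage = _assign_stages(rng, is_aa, stage_confounding)
    aa_cols = np.flatnonzero(is_aa)
    for sig in signatures:
        eff = effect_sizes.get(sig.name, 0.0)
        if eff:
            _apply_signature_shift(values, sd, genes, sig, aa_cols,
                                   np.full(len(aa_cols), eff))
        beta = stage_effects.get(sig.name, 0.0)
        if beta:
            all_cols = np.arange(n_samples)
            _apply_signature_shift(values, sd, genes, sig, all_cols,
                                   beta * (stage - 1).astype(float))
    # LAR-high planting
    lar_ids: tuple[str, ...] = ()
    ar_gene = None
    if lar:
        sig = lar["signature"]
        n_high = max(1, int(round(lar.get("frac", 0.12) * n_samples)))
        high_cols = rng.choice(n_samples, size=n_high, replace=False)
        _apply_signature_shift(values, sd, genes, sig, high_cols,
                               np.full(n_high, float(lar.get("effect", 3.0))))
        # the AR proxy is up-regulated in LAR-high: pick a positive-weight gene
        ar_gene = next(g for g, w in zip(sig.genes, sig.weights) if w > 0)
        lar_ids = tuple(samples[c] for c in sorted(high_cols))
    # detection p-values
    detected = rng.random((n_probes, n_samples)) < detect_rate
    det_p = np.where(
        detected,
        rng.uniform(*DETECTED_P_RANGE, size=(n_probes, n_samples)),
        rng.uniform(*UNDETECTED_P_RANGE, size=(n_probes, n_samples)),
    )
    # slides and planted batch runs
    slide_labels = [f"slide{j // slide_size + 1:02d}" for j in range(n_samples)]
    batch_runs = []
    if n_batch_probes:
        run_len = batch_run_length or slide_size
        if run_len > slide_size:
            raise ValueError("batch_run_length cannot exceed slide_size")
        run_probes = rng.choice(n_probes, size=n_batch_probes, replace=False)
        # batch artifacts strike otherwise well-detected probes; a probe at a
        # mediocre baseline rate going dark for one slide is not separable
        # from chance at the filter's alpha
        for pi in run_probes:
            hi = rng.random(n_samples) < 0.98
            det_p[pi] = np.where(
                hi,
                rng.uniform(*DETECTED_P_RANGE, size=n_samples),
                rng.uniform(*UNDETECTED_P_RANGE, size=n_samples),
            )
        slide_starts = {
            lab: min(j for j, l in enumerate(slide_labels) if l == lab)
            for lab in dict.fromkeys(slide_labels)
        }
        full_slides = [lab for lab in slide_starts
                       if slide_labels.count(lab) >= run_len]
        for pi in run_probes:
            lab = full_slides[int(rng.integers(len(full_slides)))]
            width = slide_labels.count(lab)
            start = slide_starts[lab] + int(rng.integers(width - run_len + 1))
            cols = slice(start, start + run_len)
            det_p[pi, cols] = rng.uniform(*UNDETECTED_P_RANGE, size=run_len)
            batch_runs.append((probes[pi], lab, run_len))
    annotation = validate_annotation(pd.DataFrame({
        "sample_id": samples,
        "patient_id": [f"PT{j:03d}" for j in range(n_samples)],
        "ethnicity": np.where(is_aa, "AA", "EA"),
        "stage": stage.astype(str),
        "nodal": rng.choice(["pos", "neg"], size=n_samples, p=[0.45, 0.55]),
        "age": np.round(rng.normal(55, 10, size=n_samples), 1),
        "tissue_site": "primary",
    }))
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        gene_symbols=pd.Series(genes, index=probes, dtype="string"),
        detection_p=pd.DataFrame(det_p, index=probes, columns=samples),
        slide_of=pd.Series(slide_labels, index=samples),
        is_log2=True,
    )
    truth = CohortTruth(
        effect_sizes=effect_sizes,
        stage_effects=stage_effects,
        stage_confounding=stage_confounding,
        group_of=dict(zip(samples, np.where(is_aa, "AA", "EA"))),
        batch_runs=batch_runs,
        lar_high_ids=lar_ids,
        ar_gene=ar_gene,
    )
    return matrix, annotation, truth


def simulate_counts(
    n_samples: int = 90,
    n_genes: int = 2000,
    signatures: list[GeneSignature] | None = None,
    effect_sizes: dict[str, float] | None = None,
    seed: int = 0,
    dispersion: float = 10.0,
    lar: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Negative-binomial count cohort for the log-count scoring path.

    Effects are planted on the log2 scale in units of each gene's
    approximate log-count SD (delta method: sqrt(1/mu + 1/dispersion)/ln 2),
    so effect sizes are comparable with :func:`simulate_cohort`.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if n_samples < 4:
        raise ValueError("n_samples must be at least 4")
    signatures = list(signatures or [])
    sig_names = {s.name for s in signatures}
    effect_sizes = dict(effect_sizes or {})
    for key in effect_sizes:
        if key not in sig_names:
            raise ValueError(f"effect size given for unknown signature {key!r}")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:06d}" for i in range(n_genes)]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    log2_mu = rng.normal(6.0, 1.5, size=n_genes)
    mu = 2.0 ** log2_mu
    sd_log2 = np.sqrt(1.0 / mu + 1.0 / dispersion) / np.log(2)
    shift = np.zeros((n_genes, n_samples))
    is_aa = rng.random(n_samples) < 0.5
    aa_cols = np.flatnonzero(is_aa)
    gene_row = {g: i for i, g in enumerate(genes)}
    for sig in signatures:
        eff = effect_sizes.get(sig.name, 0.0)
        if not eff:
            continue
        for g, w in zip(sig.genes, sig.weights):
            if g not in gene_row:
                raise ValueError(f"signature {sig.name!r} gene {g!r} not in cohort")
            i = gene_row[g]
            shift[i, aa_cols] += eff * sd_log2[i] * np.sign(w)
    lar_ids: tuple[str, ...] = ()
    ar_gene = None
    if lar:
        sig = lar["signature"]
        n_high = max(1, int(round(lar.get("frac", 0.12) * n_samples)))
        high_cols = rng.choice(n_samples, size=n_high, replace=False)
        for g, w in zip(sig.genes, sig.weights):
            if g not in gene_row:
                raise ValueError(f"LAR signature gene {g!r} not in cohort")
            i = gene_row[g]
            shift[i, high_cols] += float(lar.get("effect", 3.0)) * sd_log2[i] \
                * np.sign(w)
        ar_gene = next(g for g, w in zip(sig.genes, sig.weights) if w > 0)
        lar_ids = tuple(samples[c] for c in sorted(high_cols))
    mean = mu[:, None] * 2.0 ** shift
    p_nb = dispersion / (dispersion + mean)
    counts = rng.negative_binomial(dispersion, p_nb)
    stage = _assign_stages(rng, is_aa, 1.0)
    annotation = validate_annotation(pd.DataFrame({
        "sample_id": samples,
        "patient_id": [f"PT{j:03d}" for j in range(n_samples)],
        "ethnicity": np.where(is_aa, "AA", "EA"),
        "stage": stage.astype(str),
        "nodal": rng.choice(["pos", "neg"], size=n_samples, p=[0.45, 0.55]),
        "age": np.round(rng.normal(55, 10, size=n_samples), 1),
        "tissue_site": "primary",
    }))
    truth = CohortTruth(
        effect_sizes=effect_sizes,
        group_of=dict(zip(samples, np.where(is_aa, "AA", "EA"))),
        lar_high_ids=lar_ids,
        ar_gene=ar_gene,
    )
    return (pd.DataFrame(counts, index=genes, columns=samples),
            annotation, truth)


# -- histospot rendering -------------------------------------------------------

_VESSEL_MIN_PX = 10  # a vessel must survive downstream small-object removal


def _render_tumor(rng: np.random.Generator, size: int, frac: float
                  ) -> np.ndarray:
    """Blob-shaped mask covering exactly round(frac * size^2) pixels."""
    k = int(round(frac * size * size))
    if k == 0:
        return np.zeros((size, size), dtype=bool)
    blur = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8)
    flat = blur.ravel()
    idx = np.argpartition(flat, flat.size - k)[flat.size - k:]
    mask = np.zeros(flat.size, dtype=bool)
    mask[idx] = True
    return mask.reshape(size, size)


def _render_nuclei(rng: np.random.Generator, tumor: np.ndarray,
                   coverage: float = 0.20, radius: int = 3) -> np.ndarray:
    mask = np.zeros_like(tumor)
    tumor_px = int(tumor.sum())
    if tumor_px == 0:
        return mask
    target = coverage * tumor_px
    ys, xs = np.nonzero(tumor)
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    stamp = (yy ** 2 + xx ** 2) <= radius ** 2
    size = tumor.shape[0]
    for _ in range(20 * tumor_px // max(1, stamp.sum())):
        if (mask & tumor).sum() >= target:
            break
        j = int(rng.integers(len(ys)))
        cy, cx = ys[j], xs[j]
        y0, y1 = max(0, cy - radius), min(size, cy + radius + 1)
        x0, x1 = max(0, cx - radius), min(size, cx + radius + 1)
        mask[y0:y1, x0:x1] |= stamp[(y0 - cy + radius):(y1 - cy + radius),
                                    (x0 - cx + radius):(x1 - cx + radius)]
    return mask & tumor


def _render_vessels(rng: np.random.Generator, tumor: np.ndarray,
                    frac: float, n_vessels: int) -> np.ndarray:
    """Curvilinear structures inside the tumor covering ~frac of its pixels."""
    mask = np.zeros_like(tumor)
    tumor_px = int(tumor.sum())
    target = int(round(frac * tumor_px))
    if target == 0 or n_vessels == 0:
        return mask
    if target < n_vessels * _VESSEL_MIN_PX:
        raise ValueError(
            f"image too small for {n_vessels} vessels at fraction {frac}: "
            f"only {target} vessel pixels available")
    ys, xs = np.nonzero(tumor)
    size = tumor.shape[0]
    per_vessel = target / n_vessels
    for v in range(n_vessels):
        vessel_target = round(per_vessel * (v + 1))
        j = int(rng.integers(len(ys)))
        y, x = float(ys[j]), float(xs[j])
        theta = rng.uniform(0, 2 * np.pi)
        steps = 0
        while mask.sum() < vessel_target and steps < 50 * per_vessel:
            steps += 1
            iy, ix = int(round(y)), int(round(x))
            y0, y1 = max(0, iy - 1), min(size, iy + 2)
            x0, x1 = max(0, ix - 1), min(size, ix + 2)
            stamp = np.zeros_like(mask[y0:y1, x0:x1])
            stamp[:] = True
            mask[y0:y1, x0:x1] |= stamp & tumor[y0:y1, x0:x1]
            theta += rng.normal(0, 0.18)
            y += np.sin(theta)
            x += np.cos(theta)
            if not (0 <= y < size and 0 <= x < size) or not tumor[
                    min(size - 1, max(0, int(round(y)))),
                    min(size - 1, max(0, int(round(x))))]:
                # restart inside the tumor, keep the same vessel budget
                j = int(rng.integers(len(ys)))
                y, x = float(ys[j]), float(xs[j])
                theta = rng.uniform(0, 2 * np.pi)
    return mask


def simulate_histospot(
    size_px: int = 256,
    tumor_fraction: float = 0.5,
    vessel_fraction: float = 0.02,
    n_vessels: int = 6,
    noise_sd: float = 0.04,
    seed: int = 0,
    spot_id: str = "spot",
):
    """Render a three-channel histospot image with exact mask truth.

    Cytokeratin is bright on a blob-shaped tumor region covering
    ``tumor_fraction`` of the image; DAPI shows speckled nuclei inside the
    tumor; CD31 is bright on curvilinear vessels inside the tumor covering
    approximately ``vessel_fraction`` of the tumor pixels.  Gaussian noise
    is added to every channel.  The returned :class:`SpotTruth` records the
    exact pixel fractions of the rendered masks, not the requested targets.
    """
    from .angiogenesis import Histospot  # local import avoids a cycle

    if not 0 <= vessel_fraction <= 0.2:
        raise ValueError("vessel_fraction must lie in [0, 0.2]")
    if not 0 <= tumor_fraction <= 1:
        raise ValueError("tumor_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    tumor = _render_tumor(rng, size_px, tumor_fraction)
    nuclei = _render_nuclei(rng, tumor)
    vessels = _render_vessels(rng, tumor, vessel_fraction, n_vessels)
    def channel(fg_mask, lo, hi):
        img = lo + (hi - lo) * fg_mask.astype(float)
        img += rng.normal(0, noise_sd, size=img.shape)
        return np.clip(img, 0, None)
    spot = Histospot(
        spot_id=spot_id,
        cytokeratin=channel(tumor, 0.15, 0.85),
        dapi=channel(nuclei, 0.10, 0.85),
        cd31=channel(vessels, 0.10, 0.90),
        meta={"seed": seed},
    )
    tumor_px = int(tumor.sum())
    truth = SpotTruth(
        vessel_fraction_of_tumor=float(vessels.sum() / tumor_px)
        if tumor_px else 0.0,
        tumor_fraction_of_spot=float(tumor.mean()),
    )
    return spot, truth
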