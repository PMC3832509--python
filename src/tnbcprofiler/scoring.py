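"""Signature activation scoring and group inference.

The activation of a published gene signature in a sample is the Pearson
correlation between the signature's per-gene weight vector and the sample's
expression profile over the signature genes.  Coordinated movement of many
genes is what the score rewards, which makes it robust on noisy, degraded
FFPE material where single probes are unreliable.  Group differences in
activation (e.g. between African American and European American patients)
are tested with a Welch two-tailed t-test; because tumor stage is a
potential confounder, an empirical stage-adjusted p-value is obtained by
permuting group labels *within* stage strata, which preserves each
stratum's group composition and therefore nulls out any stage-driven
difference.  BH-FDR adjusts across signatures.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GeneSignature

__all__ = [
    "ActivationResult",
    "GroupTestResult",
    "activation_score",
    "activation_table",
    "differential_activation",
    "stage_adjusted_p",
    "fdr_adjust",
    "signature_group_tests",
    "lar_cluster",
    "spearman_pc_signature",
]

#: minimum matched genes for a correlation score to be meaningful
MIN_GENES = 3
#: default resampling depth for the stage-adjusted empirical p-value
DEFAULT_RESAMPLES = 1000


@dataclass
class ActivationResult:
    """Per-sample activation scores for one signature."""

    signature: str
    scores: pd.Series          # Pearson r per sample; NaN where undefined
    n_genes_used: int
    genes_used: tuple[str, ...]
    scorable: bool


@dataclass
class GroupTestResult:
    signature: str
    group_labels: tuple[str, str]
    group_means: tuple[float, float]
    n_per_group: tuple[int, int]
    t: float
    p: float
    stage_adjusted_p: float | None = None
    fdr: float | None = None
    n_resamples: int | None = None
    seed: int | None = None


def _gene_profile(matrix: ExpressionMatrix, genes: tuple[str, ...],
                  exclude_imputed: bool) -> pd.DataFrame:
    """Gene-level expression (probes averaged per symbol) for given genes."""
    gene_vals = matrix.gene_level()
    present = [g for g in genes if g in gene_vals.index]
    prof = gene_vals.loc[present]
    if exclude_imputed:
        sym = matrix.gene_symbols.dropna()
        imput = matrix.imputed_mask.loc[sym.index].groupby(sym).any()
        prof = prof.mask(imput.loc[present])
    return prof


def activation_score(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    *,
    exclude_imputed: bool = False,
) -> ActivationResult:
    """Per-sample Pearson correlation with the signature weight vector.

    Gene matching is by uppercase symbol; multiple probes per gene are
    averaged first.  Fewer than three matched genes makes the score
    meaningless: the result is flagged unscorable rather than silently
    zeroed.  A sample whose sub-profile has zero variance has an undefined
    correlation, recorded as NaN.  With ``exclude_imputed=True``, cells
    imputed during quantile normalisation are dropped per sample before
    correlating.
    """
    prof = _gene_profile(matrix, signature.genes, exclude_imputed)
    genes_used = tuple(prof.index)
    if len(genes_used) < MIN_GENES:
        return ActivationResult(
            signature=signature.name,
            scores=pd.Series(np.nan, index=matrix.sample_ids),
            n_genes_used=len(genes_used), genes_used=genes_used,
            scorable=False)
    w_full = signature.as_series().loc[list(genes_used)].to_numpy(float)
    X = prof.to_numpy(float)  # genes x samples, may contain NaN if excluding
    scores = np.full(X.shape[1], np.nan)
    for j in range(X.shape[1]):
        x = X[:, j]
        ok = np.isfinite(x)
        if ok.sum() < MIN_GENES:
            continue
        xv, wv = x[ok], w_full[ok]
        if np.ptp(xv) == 0 or np.ptp(wv) == 0:
            continue  # undefined correlation stays NaN
        scores[j] = np.corrcoef(wv, xv)[0, 1]
    return ActivationResult(
        signature=signature.name,
        scores=pd.Series(scores, index=matrix.sample_ids),
        n_genes_used=len(genes_used), genes_used=genes_used, scorable=True)


def activation_table(
    matrix: ExpressionMatrix,
    signatures: dict[str, GeneSignature],
    *,
    exclude_imputed: bool = False,
) -> pd.DataFrame:
    """Sample x signature matrix of activation scores (NaN if unscorable)."""
    cols = {}
    for name, sig in signatures.items():
        res = activation_score(matrix, sig, exclude_imputed=exclude_imputed)
        cols[name] = res.scores
    return pd.DataFrame(cols)


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return np.inf * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def differential_activation(
    scores: pd.Series,
    groups: pd.Series,
) -> tuple[float, float]:
    """Welch two-tailed t-test between the two groups' activation scores.

    Returns ``(t, p)`` where ``t > 0`` means the first group (by sorted
    label order) has the larger mean.  NaN scores are dropped.
    """
    common = scores.index.intersection(groups.index)
    s, g = scores.loc[common], groups.loc[common]
    ok = s.notna()
    s, g = s[ok], g[ok]
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    a = s[g == labels[0]].to_numpy(float)
    b = s[g == labels[1]].to_numpy(float)
    return _welch_t(a, b)


def _stratified_null_ts(
    values: np.ndarray,
    is_a: np.ndarray,
    strata: np.ndarray,
    n_resamples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """|t| of Welch tests over within-stratum label permutations, vectorised.

    Group counts per stratum are preserved by construction, so the group
    sizes n_a, n_b are constant over permutations.
    """
    n = len(values)
    perm_idx = np.tile(np.arange(n), (n_resamples, 1))
    for s in np.unique(strata):
        cols = np.flatnonzero(strata == s)
        sub = perm_idx[:, cols]
        shuffled = rng.permuted(sub, axis=1)
        perm_idx[:, cols] = shuffled
    a_mask = is_a[perm_idx]  # R x n: which positions carry an A label
    v = values[np.newaxis, :]
    na = int(is_a.sum())
    nb = n - na
    sum_a = (v * a_mask).sum(axis=1)
    sumsq_a = (v ** 2 * a_mask).sum(axis=1)
    sum_b = v.sum() - sum_a
    sumsq_b = (v ** 2).sum() - sumsq_a
    mean_a, mean_b = sum_a / na, sum_b / nb
    var_a = (sumsq_a - na * mean_a ** 2) / (na - 1)
    var_b = (sumsq_b - nb * mean_b ** 2) / (nb - 1)
    se = np.sqrt(np.maximum(var_a / na + var_b / nb, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        ts = np.where(se > 0, (mean_a - mean_b) / se,
                      np.where(mean_a == mean_b, 0.0, np.inf))
    return np.abs(ts)


def stage_adjusted_p(
    scores: pd.Series,
    groups: pd.Series,
    strata: pd.Series,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | np.random.Generator = 0,
    *,
    unknown_stratum: str = "unknown",
) -> float:
    """Empirical group-difference p-value from stratified label resampling.

    The observed statistic is the |Welch t| between the two groups.  Group
    labels are then permuted independently within every stratum
    ``n_resamples`` times (samples with an unknown stratum are excluded),
    and the p-value is ``(1 + #{|t*| >= |t_obs|}) / (n_resamples + 1)`` —
    never exactly zero, and exact in distribution under within-stratum
    exchangeability.  A stratum containing a single group contributes no
    permutation variability (warned).
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    common = scores.index.intersection(groups.index).intersection(strata.index)
    s, g, st = scores.loc[common], groups.loc[common], strata.loc[common]
    ok = s.notna() & (st.astype(str) != unknown_stratum)
    s, g, st = s[ok], g[ok], st[ok]
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    for lev in pd.unique(st):
        if g[st == lev].nunique() < 2:
            warnings.warn(
                f"stratum {lev!r} contains a single group; it contributes no "
                "permutation variability", stacklevel=2)
    t_obs, _ = differential_activation(s, g)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    null_ts = _stratified_null_ts(
        s.to_numpy(float), (g == labels[0]).to_numpy(), st.to_numpy(),
        n_resamples, rng)
    exceed = int(np.sum(null_ts >= abs(t_obs) - 1e-12))
    return (1 + exceed) / (n_resamples + 1)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signature_group_tests(
    activations: pd.DataFrame,
    annotation: pd.DataFrame,
    group_col: str = "ethnicity",
    group_levels: tuple[str, str] = ("AA", "EA"),
    strata_col: str | None = "stage",
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int = 0,
) -> list[GroupTestResult]:
    """Per-signature group tests with stage adjustment and FDR.

    The FDR adjustment is applied across signatures to the stage-adjusted
    empirical p-values when strata are given, otherwise to the raw Welch
    p-values.
    """
    ann = annotation.loc[[s for s in activations.index if s in annotation.index]]
    in_groups = ann[group_col].isin(group_levels)
    ann = ann.loc[in_groups]
    groups = ann[group_col]
    results: list[GroupTestResult] = []
    rng = np.random.default_rng(seed)
    for name in activations.columns:
        scores = activations.loc[ann.index, name]
        t, p = differential_activation(scores, groups)
        mask_a = groups == group_levels[0]
        res = GroupTestResult(
            signature=name,
            group_labels=group_levels,
            group_means=(float(scores[mask_a].mean()),
                         float(scores[~mask_a].mean())),
            n_per_group=(int(mask_a.sum()), int((~mask_a).sum())),
            t=t, p=p, n_resamples=n_resamples, seed=seed)
        if strata_col is not None:
            res.stage_adjusted_p = stage_adjusted_p(
                scores, groups, ann[strata_col], n_resamples, rng)
        results.append(res)
    basis = [r.stage_adjusted_p if r.stage_adjusted_p is not None else r.p
             for r in results]
    for r, q in zip(results, fdr_adjust(basis)):
        r.fdr = float(q)
    return results


def lar_cluster(
    ar_expression: pd.Series,
    lar_scores: pd.Series,
    seed: int = 0,
    restarts: int = 50,
) -> pd.DataFrame:
    """Two-group k-means on (AR expression, LAR activation), z-standardised.

    The cluster with the greater mean LAR activation is labelled
    ``LAR-high``.  The best of ``restarts`` k-means initialisations by
    within-cluster sum of squares is kept, making the partition
    deterministic under the seed.  Returns a frame indexed by sample with
    columns ``cluster`` (0/1) and ``lar_high`` (bool).
    """
    common = ar_expression.index.intersection(lar_scores.index)
    if len(common) < 4:
        raise ValueError("lar_cluster needs at least 4 samples")
    X = np.column_stack([
        ar_expression.loc[common].to_numpy(float),
        lar_scores.loc[common].to_numpy(float),
    ])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    labels = km.fit_predict(Z)
    mean_lar = [lar_scores.loc[common][labels == c].mean() for c in (0, 1)]
    high_cluster = int(np.argmax(mean_lar))
    return pd.DataFrame({
        "cluster": labels,
        "lar_high": labels == high_cluster,
    }, index=common)


def spearman_pc_signature(pc_scores: pd.Series,
                          activation_scores: pd.Series) -> float:
    """Spearman rank correlation (average ranks on ties) over shared samples."""
    common = pc_scores.index.intersection(activation_scores.index)
    a = pc_scores.loc[common].to_numpy(float)
    b = activation_scores.loc[common].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)
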