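"""Unsupervised module discovery by principal component analysis.

Samples are treated as observations and probes as features; each probe is
centred across samples before the decomposition, so a component is a unit
probe-loading vector ("projection scores") plus one score per sample.
Components are reported in descending order of explained variance; tails of
a component's loading ranking (e.g. the 250 most negative probes) define
its gene module for enrichment testing, and component scores are tested
against clinical covariates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .datatypes import ExpressionMatrix

__all__ = ["PCAResult", "run_pca", "top_probes", "associate_component"]

#: components inspected by default in reports (modules beyond the first
#: several rarely add interpretable structure)
DEFAULT_N_COMPONENTS = 8


@dataclass
class PCAResult:
    """Loadings (probe x component), scores (sample x component), variance."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_fraction: pd.Series
    center: pd.Series  # per-probe mean removed before the decomposition

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def run_pca(matrix: ExpressionMatrix, n_components: int | None = None
            ) -> PCAResult:
    """Principal components of a complete (imputed) expression matrix.

    Probes are centred across samples; the decomposition is a full SVD of
    the centred matrix.  Sign convention: each component is oriented so that
    its largest-|loading| probe has a positive loading.  Variance fractions
    are squared singular values over their total, non-increasing, and sum
    to 1 over all components.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if matrix.values.isna().any().any():
        raise ValueError("PCA input must have no missing values (impute upstream)")
    X = matrix.values.to_numpy(dtype=float).T  # samples x probes
    max_rank = min(X.shape)
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # probes x k
    # orient each component: largest-|loading| probe positive
    pivot = np.abs(loadings).argmax(axis=0)
    flip = np.sign(loadings[pivot, np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip
    comp_ids = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=matrix.values.index,
                              columns=comp_ids),
        scores=pd.DataFrame(scores, index=matrix.values.columns,
                            columns=comp_ids),
        variance_fraction=pd.Series(pca.explained_variance_ratio_,
                                    index=comp_ids),
        center=pd.Series(pca.mean_, index=matrix.values.index),
    )


def top_probes(pca: PCAResult, component: str | int, n: int = 250,
               tail: str = "top") -> list[str]:
    """The ``n`` probes with the highest (or lowest) signed loadings.

    ``tail="top"`` returns the probes with the largest signed loadings,
    ``tail="bottom"`` the most negative ones.  Ties break by probe id so the
    selection is deterministic.  The default of 250 probes per tail is the
    conventional module size for downstream enrichment.
    """
    if tail not in {"top", "bottom"}:
        raise ValueError(f"tail must be 'top' or 'bottom', got {tail!r}")
    comp = f"PC{component}" if isinstance(component, int) else component
    if comp not in pca.loadings.columns:
        raise IndexError(f"component {comp!r} out of range")
    if n > pca.loadings.shape[0]:
        raise ValueError(f"n={n} exceeds the {pca.loadings.shape[0]} probes")
    col = pca.loadings[comp]
    ascending = tail == "bottom"
    order = col.to_frame("loading").assign(probe=col.index).sort_values(
        ["loading", "probe"], ascending=[ascending, True]
    )
    return order.index[:n].tolist()


def associate_component(
    pca: PCAResult,
    annotation: pd.DataFrame,
    component: str | int,
    covariates: list[str] | None = None,
    *,
    unknown_values: tuple = ("unknown",),
) -> pd.DataFrame:
    """Test a component's sample scores against clinical covariates.

    Two-level nominal covariates get a Welch two-tailed t-test on the
    scores; numeric covariates get a Pearson correlation with a two-tailed
    p-value.  Samples with an unknown level are excluded per covariate;
    covariates with fewer than two observed levels are skipped with a note.
    Returns one row per covariate: kind, statistic, p, n.
    """
    comp = f"PC{component}" if isinstance(component, int) else component
    if comp not in pca.scores.columns:
        raise IndexError(f"component {comp!r} out of range")
    scores = pca.scores[comp]
    common = [s for s in scores.index if s in annotation.index]
    ann = annotation.loc[common]
    scores = scores.loc[common]
    if covariates is None:
        covariates = [c for c in ann.columns
                      if c not in ("sample_id", "patient_id")]
    rows = []
    for cov in covariates:
        col = ann[cov]
        keep = ~col.astype(str).isin([str(u) for u in unknown_values])
        col, x = col[keep], scores[keep]
        numeric = pd.api.types.is_numeric_dtype(col)
        if not numeric:
            coerced = pd.to_numeric(col, errors="coerce")
            if coerced.notna().all() and col.nunique() > 2:
                col, numeric = coerced, True
        if numeric:
            if col.nunique() < 2 or len(col) < 3:
                rows.append({"covariate": cov, "kind": "numeric", "stat": np.nan,
                             "p": np.nan, "n": len(col),
                             "note": "fewer than 2 observed levels"})
                continue
            r, p = stats.pearsonr(x.to_numpy(float), col.to_numpy(float))
            rows.append({"covariate": cov, "kind": "numeric", "stat": r,
                         "p": p, "n": len(col), "note": ""})
        else:
            levels = sorted(col.dropna().unique())
            if len(levels) != 2:
                rows.append({"covariate": cov, "kind": "nominal", "stat": np.nan,
                             "p": np.nan, "n": len(col),
                             "note": f"{len(levels)} observed level(s), need 2"})
                continue
            a = x[col == levels[0]].to_numpy(float)
            b = x[col == levels[1]].to_numpy(float)
            if np.allclose(a.var(ddof=1) if len(a) > 1 else 0, 0) and \
               np.allclose(b.var(ddof=1) if len(b) > 1 else 0, 0) and \
               np.isclose(a.mean(), b.mean()):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({"covariate": cov, "kind": "nominal", "stat": float(t),
                         "p": float(p), "n": len(col),
                         "note": f"{levels[0]} vs {levels[1]}"})
    return pd.DataFrame(rows).set_index("covariate")
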