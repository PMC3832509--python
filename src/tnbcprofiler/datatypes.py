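"""Core in-memory containers for the expression-phenotyping pipeline.

The central object is :class:`ExpressionMatrix`, a probe-by-sample intensity
matrix as produced by bead-array platforms for degraded FFPE RNA (WG-DASL
style): besides intensities it optionally carries per-cell detection
p-values (probability that the signal is background), a probe-to-gene-symbol
mapping (many probes may map to one symbol), a slide/batch label per sample,
and masks for missing/imputed cells.  Gene signatures, unweighted gene-set
collections and a lightweight GO-style DAG round out the data model.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSignature",
    "GeneSetCollection",
    "GoDag",
    "GoTerm",
    "ANNOTATION_COLUMNS",
    "validate_annotation",
]

#: canonical sample-annotation columns (extra columns are allowed and kept)
ANNOTATION_COLUMNS = (
    "sample_id",
    "patient_id",
    "ethnicity",
    "stage",
    "nodal",
    "age",
    "tissue_site",
)

ETHNICITY_LEVELS = {"AA", "EA", "Hispanic", "unknown"}
NODAL_LEVELS = {"pos", "neg", "unknown"}
TISSUE_LEVELS = {"primary", "other"}


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample-annotation table.

    One row per sample; ``stage`` is coded numerically 1-4 or ``"unknown"``.
    Returns a copy indexed by ``sample_id``.
    """
    ann = annotation.copy()
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation is missing required columns: {missing}")
    if ann["sample_id"].duplicated().any():
        dups = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in annotation: {dups}")
    ann["stage"] = ann["stage"].astype(str)
    bad_stage = set(ann["stage"]) - {"1", "2", "3", "4", "unknown"}
    if bad_stage:
        raise ValueError(f"stage must be 1-4 or 'unknown', got {sorted(bad_stage)}")
    for col, levels in (("ethnicity", ETHNICITY_LEVELS), ("nodal", NODAL_LEVELS),
                        ("tissue_site", TISSUE_LEVELS)):
        bad = set(ann[col].astype(str)) - levels
        if bad:
            raise ValueError(f"unknown {col} level(s): {sorted(bad)}")
    return ann.set_index("sample_id", drop=False)


@dataclass
class ExpressionMatrix:
    """Probe-by-sample intensities with optional detection p-values.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with sample ids as columns.  Raw
        intensities or log2 values, according to ``is_log2``.
    gene_symbols
        Per-probe gene symbol (uppercase-normalised; NaN allowed when the
        probe is unannotated).  Many probes may share a symbol.
    detection_p
        Per-cell detection p-value in [0, 1], same shape as ``values``;
        ``None`` when the platform/file did not provide them.
    slide_of
        Sample -> slide/batch label; ``None`` when batches are unknown.
    missing_mask / imputed_mask
        Boolean frames aligned with ``values`` flagging removed-outlier
        cells and quantile-imputed cells, respectively.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series | None = None
    detection_p: pd.DataFrame | None = None
    slide_of: pd.Series | None = None
    is_log2: bool = False
    missing_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    imputed_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids in expression matrix")
        if self.missing_mask is None:
            self.missing_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if self.imputed_mask is None:
            self.imputed_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        for name in ("detection_p", "missing_mask", "imputed_mask"):
            frame = getattr(self, name)
            if frame is None:
                continue
            if not frame.index.equals(self.values.index) or not frame.columns.equals(
                self.values.columns
            ):
                raise ValueError(f"{name} is not aligned with values")
        if self.detection_p is not None:
            arr = self.detection_p.to_numpy(dtype=float)
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("detection p-values must lie in [0, 1]")
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)
            self.gene_symbols = self.gene_symbols.str.upper()
        if self.slide_of is not None:
            self.slide_of = self.slide_of.reindex(self.values.columns)

    # -- convenience accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def detectable(self, p_threshold: float = 0.01) -> pd.DataFrame:
        """Boolean detectability calls at ``detection_p < p_threshold``."""
        if self.detection_p is None:
            raise ValueError("matrix carries no detection p-values")
        return self.detection_p < p_threshold

    def subset(self, probes: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "ExpressionMatrix":
        """Return a sub-matrix restricted to the given probes/samples."""
        probes = list(probes) if probes is not None else self.probe_ids
        samples = list(samples) if samples is not None else self.sample_ids
        return ExpressionMatrix(
            values=self.values.loc[probes, samples],
            gene_symbols=None if self.gene_symbols is None
            else self.gene_symbols.loc[probes],
            detection_p=None if self.detection_p is None
            else self.detection_p.loc[probes, samples],
            slide_of=None if self.slide_of is None else self.slide_of.loc[samples],
            is_log2=self.is_log2,
            missing_mask=self.missing_mask.loc[probes, samples],
            imputed_mask=self.imputed_mask.loc[probes, samples],
        )

    def with_values(self, values: pd.DataFrame, *, is_log2: bool | None = None,
                    **overrides) -> "ExpressionMatrix":
        new = replace(self, values=values,
                      is_log2=self.is_log2 if is_log2 is None else is_log2)
        for key, val in overrides.items():
            setattr(new, key, val)
        return new

    def gene_level(self, *, agg: str = "mean") -> pd.DataFrame:
        """Collapse probes to gene symbols (mean over probes by default)."""
        if self.gene_symbols is None:
            raise ValueError("matrix carries no gene symbols")
        sym = self.gene_symbols.dropna()
        vals = self.values.loc[sym.index]
        return vals.groupby(sym).agg(agg)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene list with per-gene weights.

    Directional lists use +/-1 weights; subtype centroids use real-valued
    centroid weights.  A constant weight vector carries no direction and is
    rejected.
    """

    name: str
    genes: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.weights):
            raise ValueError(f"signature {self.name!r}: |genes| != |weights|")
        if len(self.genes) == 0:
            raise ValueError(f"signature {self.name!r} is empty")
        object.__setattr__(self, "genes", tuple(g.upper() for g in self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")
        w = np.asarray(self.weights, dtype=float)
        if np.allclose(w, w[0]):
            raise ValueError(
                f"signature {self.name!r} has a constant weight vector; "
                "correlation against it is undefined"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def as_series(self) -> pd.Series:
        return pd.Series(np.asarray(self.weights, float), index=list(self.genes),
                         name=self.name)


class GeneSetCollection(Mapping[str, frozenset]):
    """Named, unweighted gene sets (a parsed GMT file)."""

    def __init__(self, sets: Mapping[str, Iterable[str]],
                 descriptions: Mapping[str, str] | None = None):
        self._sets: dict[str, frozenset] = {}
        for name, genes in sets.items():
            genes = frozenset(g.upper() for g in genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if name in self._sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            self._sets[name] = genes
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


@dataclass(frozen=True)
class GoTerm:
    term_id: str
    name: str
    parents: tuple[str, ...]
    genes: frozenset


class GoDag:
    """GO-style DAG with gene annotations propagated to ancestors.

    The true-path rule is applied at construction: a gene annotated to a term
    is annotated to every ancestor of that term.
    """

    def __init__(self, terms: Iterable[GoTerm]):
        self._terms = {t.term_id: t for t in terms}
        g = nx.DiGraph()
        g.add_nodes_from(self._terms)
        for t in self._terms.values():
            for p in t.parents:
                if p not in self._terms:
                    raise ValueError(f"term {t.term_id} lists unknown parent {p}")
                g.add_edge(t.term_id, p)  # edge child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"GO DAG contains a cycle: {cyc}")
        self.graph = g
        # propagate annotations upward (true-path rule); symbols normalised
        propagated: dict[str, set] = {
            tid: {g.upper() for g in t.genes} for tid, t in self._terms.items()
        }
        for tid in nx.topological_sort(g):  # children before parents
            for parent in g.successors(tid):
                propagated[parent] |= propagated[tid]
        self.annotations: dict[str, frozenset] = {
            tid: frozenset(genes) for tid, genes in propagated.items()
        }

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def term(self, term_id: str) -> GoTerm:
        return self._terms[term_id]

    def ancestors(self, term_id: str) -> set:
        return nx.descendants(self.graph, term_id)  # parent direction

    def topological_order(self) -> list[str]:
        """Term ids with every child before any of its parents."""
        return list(nx.topological_sort(self.graph))
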