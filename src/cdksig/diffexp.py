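"""Quantile normalization and per-contrast differential expression.

A contrast compares treated against vehicle samples of one cell model (or
xenograft) and yields, per gene, a log2 fold change (difference of group
means on the log2 scale), a pooled-variance two-sample t statistic and a
two-sided p-value.  No multiple-testing correction is applied anywhere in
the pipeline: downstream filters work on raw p-values at a fixed alpha,
and consistency across independent conditions is the multiplicity control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, SampleAnnotation

__all__ = [
    "Contrast",
    "ContrastResult",
    "quantile_normalize",
    "log_fold_change",
    "homoscedastic_t_test",
    "run_contrast",
    "filter_by_p",
]


@dataclass(frozen=True)
class Contrast:
    """A treated-vs-control comparison within one model and context."""

    name: str
    treated_sample_ids: tuple[str, ...]
    control_sample_ids: tuple[str, ...]
    model: str = ""
    rb_status: str = ""
    agent: str = ""
    dose_nM: float = 0.0
    context: str = ""

    def __post_init__(self) -> None:
        treated, control = set(self.treated_sample_ids), set(self.control_sample_ids)
        if treated & control:
            raise ValueError(
                f"contrast {self.name!r}: treated and control samples overlap: "
                f"{sorted(treated & control)}"
            )
        if len(treated) < 2 or len(control) < 2:
            raise ValueError(
                f"contrast {self.name!r}: each arm needs >= 2 samples "
                f"(got {len(treated)} treated, {len(control)} control)"
            )

    @classmethod
    def from_annotation(
        cls,
        annotation: SampleAnnotation,
        *,
        model: str,
        agent: str,
        dose_nM: float,
        context: str = "cell_line",
        name: str | None = None,
    ) -> "Contrast":
        """Build the drug-vs-vehicle contrast for one (model, agent, dose) arm."""
        treated = annotation.select(
            model=model, agent=agent, dose_nM=dose_nM, context=context
        )
        control = annotation.select(model=model, agent="vehicle", context=context)
        if not treated or not control:
            raise ValueError(
                f"no samples for model={model!r} agent={agent!r} "
                f"dose={dose_nM} context={context!r}"
            )
        rb_status = str(annotation.row(treated[0])["rb_status"])
        return cls(
            name=name or f"{model}_{agent}{dose_nM:g}_{context}",
            treated_sample_ids=treated,
            control_sample_ids=control,
            model=model,
            rb_status=rb_status,
            agent=agent,
            dose_nM=dose_nM,
            context=context,
        )


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene logFC / t / p for one contrast, one row per matrix gene.

    ``degenerate`` flags genes whose pooled variance was exactly zero with
    unequal group means — reachable only with noiseless synthetic data.
    """

    contrast: Contrast
    gene_ids: tuple[str, ...]
    logfc: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: bool = True

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for attr in ("logfc", "t_stat", "p_value"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{attr} must have one entry per gene")
            object.__setattr__(self, attr, arr)
        if np.any((self.p_value < 0) | (self.p_value > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        if self.degenerate is None:
            object.__setattr__(self, "degenerate", np.zeros(n, dtype=bool))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": list(self.gene_ids),
                "logfc": self.logfc,
                "t": self.t_stat,
                "p": self.p_value,
            }
        ).set_index("gene_id")

    def logfc_of(self, gene_id: str) -> float:
        return float(self.logfc[self.gene_ids.index(gene_id)])


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    Each output column, sorted, equals the across-sample mean of the input
    order statistics at each rank; values within a column that are tied
    share the mean of the reference values over their tied ranks.  The
    operation is idempotent and preserves gene and sample order.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = matrix.values
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(matrix.n_samples):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # ties share the mean of the reference values across their tied ranks
        out[:, j] = (
            pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
        )
    return ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, out)


def _group_values(
    matrix: ExpressionMatrix, contrast: Contrast
) -> tuple[np.ndarray, np.ndarray]:
    treated = matrix.subset_samples(contrast.treated_sample_ids).values
    control = matrix.subset_samples(contrast.control_sample_ids).values
    return treated, control


def log_fold_change(matrix: ExpressionMatrix, contrast: Contrast) -> np.ndarray:
    """Per-gene mean(treated) - mean(control), in log2 units."""
    treated, control = _group_values(matrix, contrast)
    return treated.mean(axis=1) - control.mean(axis=1)


def homoscedastic_t_test(
    matrix: ExpressionMatrix, contrast: Contrast
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-tailed Student's homoscedastic (pooled-variance) t-test per gene.

    Returns ``(t, p, degenerate)`` with df = n1 + n2 - 2.  Zero pooled
    variance yields t = 0, p = 1 when the means agree and p = 0 with the
    degenerate flag set when they differ.
    """
    treated, control = _group_values(matrix, contrast)
    n1, n2 = treated.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples for the t-test")
    m1, m2 = treated.mean(axis=1), control.mean(axis=1)
    ss1 = ((treated - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((control - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled_var = (ss1 + ss2) / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    zero_var = se == 0
    degenerate = zero_var & (diff != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, diff / np.where(zero_var, 1.0, se))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_var & ~degenerate, 1.0, p)
    p = np.where(degenerate, 0.0, p)
    return t, np.clip(p, 0.0, 1.0), degenerate


def run_contrast(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation | None,
    contrast: Contrast,
    *,
    assume_normalized: bool = True,
) -> ContrastResult:
    """Compute the full ContrastResult on an already-normalized matrix.

    ``assume_normalized=False`` applies quantile normalization to the whole
    matrix first.  The annotation, when given, is used to cross-check that
    the contrast's samples exist and share the contrast's model and context.
    """
    if annotation is not None:
        for sid in contrast.treated_sample_ids + contrast.control_sample_ids:
            row = annotation.row(sid)
            if contrast.model and str(row["model"]) != contrast.model:
                raise ValueError(
                    f"sample {sid!r} belongs to model {row['model']!r}, "
                    f"not contrast model {contrast.model!r}"
                )
            if contrast.context and str(row["context"]) != contrast.context:
                raise ValueError(
                    f"sample {sid!r} has context {row['context']!r}, "
                    f"not contrast context {contrast.context!r}"
                )
    if not assume_normalized:
        matrix = quantile_normalize(matrix)
    logfc = log_fold_change(matrix, contrast)
    t, p, degenerate = homoscedastic_t_test(matrix, contrast)
    return ContrastResult(
        contrast=contrast,
        gene_ids=matrix.gene_ids,
        logfc=logfc,
        t_stat=t,
        p_value=p,
        degenerate=degenerate,
        normalized=True,
    )


def filter_by_p(
    results: Sequence[ContrastResult] | Mapping[str, ContrastResult],
    alpha: float,
    scope: Iterable[str],
) -> tuple[str, ...]:
    """Genes with p <= alpha in every in-scope contrast.

    ``scope`` names the contrasts whose p-values gate inclusion — e.g. the
    RB-proficient treatments for the composite signature, or the LY-treated
    comparisons alone.  Genes exceeding alpha in any in-scope contrast are
    excluded.  Gene order follows the first in-scope result.
    """
    if isinstance(results, Mapping):
        by_name = dict(results)
    else:
        by_name = {r.contrast.name: r for r in results}
    scope = list(scope)
    if not scope:
        raise ValueError("p-filter scope must name at least one contrast")
    missing = [s for s in scope if s not in by_name]
    if missing:
        raise KeyError(f"scope names not among results: {missing}")
    first = by_name[scope[0]]
    keep = np.ones(len(first.gene_ids), dtype=bool)
    for name in scope:
        res = by_name[name]
        if res.gene_ids != first.gene_ids:
            order = {g: i for i, g in enumerate(res.gene_ids)}
            idx = np.array([order.get(g, -1) for g in first.gene_ids])
            ok = idx >= 0
            p = np.where(ok, res.p_value[np.maximum(idx, 0)], np.inf)
        else:
            p = res.p_value
        keep &= p <= alpha
    return tuple(g for g, k in zip(first.gene_ids, keep) if k)
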