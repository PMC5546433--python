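"""Derivation of the composite CDK4/6-inhibitor response signature.

A gene enters the composite signature only if, in *every* RB-proficient
treated-vs-vehicle contrast supplied, it (a) moves past the log2
fold-change threshold in the same direction and (b) passes the raw p-value
filter.  The default threshold is |logFC| > 0.5 on the log2 scale; a
1.5-fold preset (log2(1.5) ~ 0.585) is available for the stricter
fold-change reading of the derivation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ContrastResult, filter_by_p

__all__ = [
    "CompositeSignature",
    "FOLD_15_LOG2",
    "direction_sets",
    "derive_composite_signature",
    "concordance_table",
]

FOLD_15_LOG2 = math.log2(1.5)


@dataclass(frozen=True)
class CompositeSignature:
    """Consistently repressed and induced gene sets plus their derivation record."""

    repressed: tuple[str, ...]
    induced: tuple[str, ...]
    logfc_threshold: float
    alpha: float
    contrast_names: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.repressed) & set(self.induced):
            raise ValueError("repressed and induced sets must be disjoint")

    @property
    def genes(self) -> tuple[str, ...]:
        return self.repressed + self.induced

    def to_json(self) -> str:
        return json.dumps(
            {
                "repressed": list(self.repressed),
                "induced": list(self.induced),
                "logfc_threshold": self.logfc_threshold,
                "alpha": self.alpha,
                "contrast_names": list(self.contrast_names),
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "CompositeSignature":
        d = json.loads(text)
        return cls(
            repressed=tuple(d["repressed"]),
            induced=tuple(d["induced"]),
            logfc_threshold=float(d["logfc_threshold"]),
            alpha=float(d["alpha"]),
            contrast_names=tuple(d["contrast_names"]),
            provenance=dict(d.get("provenance", {})),
        )


def direction_sets(
    result: ContrastResult, logfc_threshold: float
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Split one contrast into repressed / induced gene sets.

    Strict inequalities: repressed means logFC < -threshold, induced means
    logFC > +threshold; a gene sitting exactly on the threshold joins
    neither set.
    """
    if not logfc_threshold > 0:
        raise ValueError("logfc_threshold must be positive")
    genes = np.asarray(result.gene_ids, dtype=object)
    repressed = tuple(genes[result.logfc < -logfc_threshold])
    induced = tuple(genes[result.logfc > logfc_threshold])
    return repressed, induced


def derive_composite_signature(
    results: Sequence[ContrastResult],
    logfc_threshold: float = 0.5,
    alpha: float = 0.05,
    *,
    allow_rb_deficient: bool = False,
) -> CompositeSignature:
    """Intersect per-contrast direction sets under the p-filter.

    repressed = genes below -threshold in every contrast AND with
    p <= alpha in every contrast; induced analogously.  All contrasts are
    expected to come from RB-proficient conditions (the biology the
    signature captures); including an RB-deficient contrast requires the
    explicit override.  The result is deterministic and invariant to the
    ordering of ``results``.
    """
    if len(results) < 2:
        raise ValueError("composite signature needs >= 2 contrasts")
    deficient = [
        r.contrast.name for r in results if r.contrast.rb_status == "deficient"
    ]
    if deficient and not allow_rb_deficient:
        raise ValueError(
            f"RB-deficient contrasts in signature derivation: {deficient}; "
            "pass allow_rb_deficient=True to override"
        )
    names = tuple(r.contrast.name for r in results)
    if len(set(names)) != len(names):
        raise ValueError("contrast names must be unique")
    passing = set(filter_by_p(results, alpha, names))
    rep: set[str] | None = None
    ind: set[str] | None = None
    for r in results:
        r_rep, r_ind = direction_sets(r, logfc_threshold)
        rep = set(r_rep) if rep is None else rep & set(r_rep)
        ind = set(r_ind) if ind is None else ind & set(r_ind)
    assert rep is not None and ind is not None
    gene_order = {g: i for i, g in enumerate(results[0].gene_ids)}
    ordered = lambda s: tuple(sorted(s, key=lambda g: gene_order.get(g, len(gene_order))))
    return CompositeSignature(
        repressed=ordered(rep & passing),
        induced=ordered(ind & passing),
        logfc_threshold=float(logfc_threshold),
        alpha=float(alpha),
        contrast_names=tuple(sorted(names)),
        provenance={
            "n_contrasts": len(results),
            "rb_deficient_included": bool(deficient),
            "threshold_semantics": "strict |log2FC| > threshold in all contrasts",
            "p_filter": f"p <= {alpha} in all contrasts",
        },
    )


def concordance_table(
    result_a: ContrastResult,
    result_b: ContrastResult,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pair two contrasts' logFCs, ordered by ``result_a``.

    Returns a frame indexed by gene with columns ``logfc_a``/``logfc_b``
    over the shared gene universe (or the requested subset of it), sorted
    by ``logfc_a`` so the row order matches the x-axis of a concordance
    scatter; Pearson and Spearman correlations are attached as
    ``frame.attrs['pearson_r']`` / ``attrs['spearman_r']``.
    """
    shared = [g for g in result_a.gene_ids if g in set(result_b.gene_ids)]
    if genes is not None:
        wanted = set(genes)
        shared = [g for g in shared if g in wanted]
    if not shared:
        raise ValueError("contrasts share no genes")
    pos_a = {g: i for i, g in enumerate(result_a.gene_ids)}
    pos_b = {g: i for i, g in enumerate(result_b.gene_ids)}
    frame = pd.DataFrame(
        {
            "logfc_a": [result_a.logfc[pos_a[g]] for g in shared],
            "logfc_b": [result_b.logfc[pos_b[g]] for g in shared],
        },
        index=pd.Index(shared, name="gene_id"),
    ).sort_values("logfc_a", kind="mergesort")
    if len(shared) >= 2 and frame["logfc_a"].std() > 0 and frame["logfc_b"].std() > 0:
        pearson = float(stats.pearsonr(frame["logfc_a"], frame["logfc_b"])[0])
        spearman = float(stats.spearmanr(frame["logfc_a"], frame["logfc_b"])[0])
    else:
        pearson = spearman = float("nan")
    frame.attrs["pearson_r"] = pearson
    frame.attrs["spearman_r"] = spearman
    return frame
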