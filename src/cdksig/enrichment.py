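"""Essential-gene labeling and equal-proportions enrichment of the signature.

A gene is called essential when its viability-screen p-values are below
alpha in the tested cell lines (``rule="all"`` by default, i.e. broad
inhibition of viability; ``"any"`` and ``"at_least_k"`` relax this).  The
signature's essential fraction is then compared to the whole universe's
with a two-sided chi-square test of equal proportions — the same test R's
``prop.test`` runs — Yates continuity correction on by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .expression_io import EssentialityTable
from .signature import CompositeSignature

__all__ = [
    "EnrichmentResult",
    "label_essential",
    "equal_proportions_test",
    "enrich_signature",
]


@dataclass(frozen=True)
class EnrichmentResult:
    k_signature: int
    n_signature: int
    k_universe: int
    n_universe: int
    statistic: float
    p_value: float
    continuity_corrected: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k_signature <= self.n_signature):
            raise ValueError("signature margin out of range")
        if not (0 <= self.k_universe <= self.n_universe):
            raise ValueError("universe margin out of range")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")

    @property
    def proportion_signature(self) -> float:
        return self.k_signature / self.n_signature

    @property
    def proportion_universe(self) -> float:
        return self.k_universe / self.n_universe

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def label_essential(
    table: EssentialityTable,
    alpha: float = 0.05,
    rule: str = "all",
    k: int | None = None,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Label genes essential from per-line screen p-values.

    Under ``rule="all"`` a gene is essential iff p < alpha in every cell
    line with a non-missing value (and it has at least one).  ``"any"``
    requires one significant line, ``"at_least_k"`` requires ``k``.

    Returns ``(essential_genes, all_missing_genes)``; genes with no
    observed p-value at all are excluded from both the essential set and
    the evaluable universe and reported in the second tuple.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if rule not in ("all", "any", "at_least_k"):
        raise ValueError(f"unknown essentiality rule {rule!r}")
    if rule == "at_least_k" and (k is None or k < 1):
        raise ValueError("rule='at_least_k' requires k >= 1")
    p = table.pvalues
    observed = ~np.isnan(p)
    n_obs = observed.sum(axis=1)
    sig = (p < alpha) & observed
    n_sig = sig.sum(axis=1)
    if rule == "all":
        essential_mask = (n_obs > 0) & (n_sig == n_obs)
    elif rule == "any":
        essential_mask = n_sig >= 1
    else:
        essential_mask = n_sig >= int(k)  # type: ignore[arg-type]
    genes = np.asarray(table.gene_ids, dtype=object)
    return tuple(genes[essential_mask]), tuple(genes[n_obs == 0])


def equal_proportions_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> EnrichmentResult:
    """Two-sided chi-square test of H0: p1 = p2 on the 2x2 table.

    With ``continuity=True`` the Yates-corrected statistic is used.  A
    degenerate margin — no successes anywhere, or no failures anywhere —
    yields statistic 0 and p = 1.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    col = table.sum(axis=0)
    if col[0] == 0 or col[1] == 0:
        return EnrichmentResult(k1, n1, k2, n2, 0.0, 1.0, continuity)
    row = table.sum(axis=1)
    total = table.sum()
    expected = np.outer(row, col) / total
    diff = np.abs(table - expected)
    if continuity:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return EnrichmentResult(k1, n1, k2, n2, statistic, min(p, 1.0), continuity)


def enrich_signature(
    signature: CompositeSignature | Iterable[str],
    essential: Iterable[str],
    universe: Sequence[str],
    continuity: bool = True,
    background: str = "inclusive",
) -> EnrichmentResult:
    """Test the signature for enrichment of essential genes.

    Compares k1/n1 = essential fraction among signature genes against
    k2/n2 = essential fraction in the universe.  ``background="inclusive"``
    (default) takes the entire gene set as the comparison margin;
    ``"exclusive"`` compares against the universe minus the signature.
    """
    sig_genes = (
        tuple(signature.genes)
        if isinstance(signature, CompositeSignature)
        else tuple(signature)
    )
    universe_set = set(universe)
    outside = sorted(set(sig_genes) - universe_set)
    if outside:
        raise ValueError(f"signature genes absent from universe: {outside}")
    if background not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown background mode {background!r}")
    essential_set = set(essential)
    k1 = sum(g in essential_set for g in sig_genes)
    n1 = len(sig_genes)
    if background == "inclusive":
        n2 = len(universe_set)
        k2 = len(essential_set & universe_set)
    else:
        comp = universe_set - set(sig_genes)
        n2 = len(comp)
        k2 = len(essential_set & comp)
    return equal_proportions_test(k1, n1, k2, n2, continuity=continuity)
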