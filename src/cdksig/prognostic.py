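"""Cohort scoring, dichotomization, and recurrence-free-survival comparison.

Cases are scored by the unweighted mean log2 expression of a gene set and
split into low/high groups either at the median score or at the root
branch of an unsupervised hierarchical clustering of the cases in
signature space.  Group survival is compared with the Kaplan-Meier
product-limit estimator, the two-group log-rank test, and a univariate
Cox proportional-hazards fit (Efron tie handling by default).

The headline p-value of a comparison is the log-rank (score-test) p; the
Cox Wald p is reported alongside it — for a single binary covariate
without ties the score test and the log-rank test coincide exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression_io import ExpressionMatrix, SurvivalTable

__all__ = [
    "CohortStratification",
    "SurvivalComparison",
    "score_cases",
    "median_dichotomize",
    "cluster_dichotomize",
    "km_estimate",
    "logrank_test",
    "cox_ph",
    "compare_survival",
]


@dataclass(frozen=True)
class CohortStratification:
    """Per-case signature scores and the low/high group assignment."""

    case_ids: tuple[str, ...]
    scores: np.ndarray
    groups: tuple[str, ...]  # "low" / "high" per case
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.case_ids)
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (n,) or len(self.groups) != n:
            raise ValueError("scores and groups must align with case_ids")
        if not set(self.groups) <= {"low", "high"}:
            raise ValueError("groups must be 'low' or 'high'")
        object.__setattr__(self, "scores", scores)

    def group_of(self, case_id: str) -> str:
        return self.groups[self.case_ids.index(case_id)]

    @property
    def group_map(self) -> dict[str, str]:
        return dict(zip(self.case_ids, self.groups))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"case_id": self.case_ids, "score": self.scores, "group": self.groups}
        ).set_index("case_id")


@dataclass(frozen=True)
class SurvivalComparison:
    """KM curves per group plus log-rank and Cox summaries."""

    km_curves: dict  # group -> DataFrame(time, n_at_risk, survival)
    logrank_chi2: float
    logrank_p: float
    cox_beta: float
    cox_hr: float
    cox_wald_p: float
    cox_score_p: float
    n_per_group: dict
    events_per_group: dict
    cox_converged: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "logrank_chi2": self.logrank_chi2,
                "logrank_p": self.logrank_p,
                "cox_beta": self.cox_beta,
                "cox_hr": self.cox_hr,
                "cox_wald_p": self.cox_wald_p,
                "cox_score_p": self.cox_score_p,
                "cox_converged": self.cox_converged,
                "n_per_group": self.n_per_group,
                "events_per_group": self.events_per_group,
            },
            indent=2,
            sort_keys=True,
        )


def score_cases(
    cohort_matrix: ExpressionMatrix, gene_set: Iterable[str]
) -> pd.Series:
    """Average log2 expression of the set genes, per case.

    Set genes absent from the matrix are dropped with a warning; if none
    remain the cohort cannot be scored.
    """
    wanted = list(dict.fromkeys(gene_set))
    present = [g for g in wanted if g in set(cohort_matrix.gene_ids)]
    if not present:
        raise ValueError("no signature gene present in the cohort matrix")
    dropped = len(wanted) - len(present)
    if dropped:
        warnings.warn(
            f"{dropped} signature gene(s) absent from cohort matrix; "
            f"scoring on {len(present)} genes",
            stacklevel=2,
        )
    sub = cohort_matrix.subset_genes(present)
    return pd.Series(
        sub.values.mean(axis=0), index=list(cohort_matrix.sample_ids), name="score"
    )


def median_dichotomize(scores: pd.Series | Mapping[str, float]) -> CohortStratification:
    """Median split: high = score > median, low = score <= median.

    Ties at the median go to "low" (documented convention); the median and
    the tie count are recorded in ``parameters``.
    """
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise ValueError("median split needs >= 2 cases")
    med = float(s.median())
    groups = tuple("high" if v > med else "low" for v in s)
    if all(g == "low" for g in groups):
        warnings.warn("all scores <= median (constant scores?); every case is 'low'")
    return CohortStratification(
        case_ids=tuple(str(c) for c in s.index),
        scores=s.to_numpy(),
        groups=groups,
        method="median_split",
        parameters={"median": med, "n_ties_at_median": int((s == med).sum())},
    )


def cluster_dichotomize(
    cohort_matrix: ExpressionMatrix,
    gene_set: Iterable[str] | None = None,
    linkage: str = "complete",
    metric: str = "euclidean",
    standardize: bool = True,
) -> CohortStratification:
    """Two-group stratification from the root split of a case dendrogram.

    Cases are clustered on the (optionally per-gene z-scored) signature
    expression profile with agglomerative hierarchical clustering; the
    tree is cut at its root into exactly two branches and the branch with
    the higher mean signature score is labeled "high" regardless of tree
    orientation.
    """
    matrix = (
        cohort_matrix.subset_genes(
            [g for g in dict.fromkeys(gene_set) if g in set(cohort_matrix.gene_ids)]
        )
        if gene_set is not None
        else cohort_matrix
    )
    if matrix.n_genes < 2 or matrix.n_samples < 2:
        raise ValueError("clustering needs >= 2 genes and >= 2 cases")
    x = matrix.values.T.astype(float)  # cases x genes
    if standardize:
        sd = x.std(axis=0, ddof=0)
        if np.all(sd == 0):
            raise ValueError("constant matrix: no clustering structure")
        keep = sd > 0
        x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    elif np.all(x.std(axis=0) == 0):
        raise ValueError("constant matrix: no clustering structure")
    z = hierarchy.linkage(pdist(x, metric=metric), method=linkage)
    labels = hierarchy.fcluster(z, t=2, criterion="maxclust")
    scores = score_cases(matrix, matrix.gene_ids)
    mean1 = scores.to_numpy()[labels == 1].mean()
    mean2 = scores.to_numpy()[labels == 2].mean()
    high_label = 1 if mean1 > mean2 else 2
    groups = tuple("high" if lab == high_label else "low" for lab in labels)
    return CohortStratification(
        case_ids=tuple(matrix.sample_ids),
        scores=scores.to_numpy(),
        groups=groups,
        method="dendrogram",
        parameters={
            "linkage": linkage,
            "metric": metric,
            "standardize": standardize,
            "n_genes_used": matrix.n_genes,
        },
    )


def _aligned(
    records: SurvivalTable, groups: Mapping[str, str]
) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "case_id": records.case_ids,
            "time": records.times,
            "event": records.events,
        }
    )
    frame["group"] = frame["case_id"].map(dict(groups))
    frame = frame.dropna(subset=["group"])
    if frame.empty:
        raise ValueError("no survival record matches a stratified case")
    return frame


def km_estimate(
    records: SurvivalTable, groups: Mapping[str, str] | CohortStratification
) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves per group with at-risk counts.

    Returns one DataFrame per group with columns ``time``, ``n_at_risk``,
    ``survival``: the right-censored product-limit estimate evaluated at
    the group's observed times.
    """
    if isinstance(groups, CohortStratification):
        groups = groups.group_map
    frame = _aligned(records, groups)
    out: dict[str, pd.DataFrame] = {}
    for name, sub in frame.groupby("group"):
        if sub.empty:
            raise ValueError(f"group {name!r} has no survival records")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        tbl = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        out[str(name)] = pd.DataFrame(
            {
                "time": tbl.index.to_numpy(dtype=float),
                "n_at_risk": tbl["at_risk"].to_numpy(dtype=int),
                "survival": surv.reindex(tbl.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    return out


def logrank_test(
    records: SurvivalTable, groups: Mapping[str, str] | CohortStratification
) -> tuple[float, float]:
    """Two-group log-rank statistic (chi-square, 1 df) and two-sided p."""
    if isinstance(groups, CohortStratification):
        groups = groups.group_map
    frame = _aligned(records, groups)
    names = sorted(frame["group"].unique())
    if len(names) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {names}")
    if frame["event"].sum() == 0:
        warnings.warn("no events in either group; log-rank p = 1")
        return 0.0, 1.0
    a = frame[frame["group"] == names[0]]
    b = frame[frame["group"] == names[1]]
    res = _ll_logrank(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


def cox_ph(
    records: SurvivalTable,
    groups: Mapping[str, str] | CohortStratification,
    ties: str = "efron",
) -> dict:
    """Univariate Cox proportional-hazards fit on the high-vs-low indicator.

    Returns beta (log hazard ratio of "high" relative to "low"), hr =
    exp(beta), the Wald p, and the score-test p.  For a single binary
    covariate the partial-likelihood score test is the log-rank test, and
    the two p-values agree exactly when event times are untied.  Monotone
    likelihood (all events in one group before any in the other) is
    flagged as non-convergence.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie-handling method {ties!r}")
    if isinstance(groups, CohortStratification):
        groups = groups.group_map
    frame = _aligned(records, groups)
    if set(frame["group"]) != {"low", "high"}:
        raise ValueError("Cox fit needs both a 'low' and a 'high' group")
    frame = frame.assign(high=(frame["group"] == "high").astype(float))
    score_chi2, score_p = logrank_test(records, groups)
    events_high = int(frame.loc[frame["high"] == 1, "event"].sum())
    events_low = int(frame.loc[frame["high"] == 0, "event"].sum())
    if events_high == 0 or events_low == 0:
        return {
            "beta": float("nan"),
            "hr": float("nan"),
            "wald_p": float("nan"),
            "score_p": score_p,
            "converged": False,
        }
    if ties == "breslow":
        beta, wald_p, converged = _breslow_fit(
            frame["time"].to_numpy(),
            frame["event"].to_numpy(),
            frame["high"].to_numpy(),
        )
        return {
            "beta": beta,
            "hr": float(np.exp(beta)),
            "wald_p": wald_p,
            "score_p": score_p,
            "converged": converged,
        }
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(
                frame[["time", "event", "high"]],
                duration_col="time",
                event_col="event",
            )
        except Exception:
            return {
                "beta": float("nan"),
                "hr": float("nan"),
                "wald_p": float("nan"),
                "score_p": score_p,
                "converged": False,
            }
    beta = float(cph.params_["high"])
    return {
        "beta": beta,
        "hr": float(np.exp(beta)),
        "wald_p": float(cph.summary.loc["high", "p"]),
        "score_p": score_p,
        "converged": True,
    }


def _breslow_fit(
    time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> tuple[float, float, bool]:
    """Newton maximization of the Breslow partial likelihood, binary covariate.

    With x in {0,1}, each distinct event time t contributes d(t) events and
    a risk set summarized by (n0, n1) = counts at risk per group, so the
    Breslow log-likelihood is sum_t [s1(t)*beta - d(t)*log(n0 + n1*e^beta)].
    """
    order = np.argsort(time, kind="mergesort")
    time, event, x = time[order], event[order], x[order]
    event_times = np.unique(time[event == 1])
    d = np.array([(event & (time == t)).sum() for t in event_times], dtype=float)
    s1 = np.array(
        [(event * x)[time == t].sum() for t in event_times], dtype=float
    )
    n1 = np.array([x[time >= t].sum() for t in event_times], dtype=float)
    n0 = np.array([(1 - x)[time >= t].sum() for t in event_times], dtype=float)
    beta = 0.0
    for _ in range(50):
        e = np.exp(beta)
        pi = n1 * e / (n0 + n1 * e)
        grad = float((s1 - d * pi).sum())
        info = float((d * pi * (1 - pi)).sum())
        if info <= 0:
            return float("nan"), float("nan"), False
        step = grad / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(step) < 1e-10:
            e = np.exp(beta)
            pi = n1 * e / (n0 + n1 * e)
            info = float((d * pi * (1 - pi)).sum())
            se = 1.0 / np.sqrt(info)
            z = beta / se
            wald_p = float(2.0 * stats.norm.sf(abs(z)))
            return float(beta), wald_p, True
    return float(beta), float("nan"), False


def compare_survival(
    records: SurvivalTable, stratification: CohortStratification
) -> SurvivalComparison:
    """Bundle KM curves, log-rank, and Cox results for one stratification."""
    groups = stratification.group_map
    curves = km_estimate(records, groups)
    chi2, logrank_p = logrank_test(records, groups)
    cox = cox_ph(records, groups)
    frame = _aligned(records, groups)
    n_per_group = frame.groupby("group").size().to_dict()
    events_per_group = frame.groupby("group")["event"].sum().astype(int).to_dict()
    return SurvivalComparison(
        km_curves=curves,
        logrank_chi2=chi2,
        logrank_p=logrank_p,
        cox_beta=cox["beta"],
        cox_hr=cox["hr"],
        cox_wald_p=cox["wald_p"],
        cox_score_p=cox["score_p"],
        n_per_group={str(k): int(v) for k, v in n_per_group.items()},
        events_per_group={str(k): int(v) for k, v in events_per_group.items()},
        cox_converged=cox["converged"],
    )
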