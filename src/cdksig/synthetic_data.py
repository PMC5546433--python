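"""Synthetic experiments with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a CDK4/6-inhibitor
perturbation study: an RB-dependent on-target program (repressed and
induced gene sets that respond to drug only in RB-proficient samples), an
abemaciclib-specific off-target program active regardless of RB status
above a dose cutoff, a viability-screen essentiality table in which the
planted signature is enriched for essential genes, and a tumor cohort
whose recurrence hazard depends on the latent signature-expression group.

Everything is driven by an explicit integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_io import (
    EssentialityTable,
    ExpressionMatrix,
    SampleAnnotation,
    SurvivalRecord,
    SurvivalTable,
)

__all__ = [
    "SimulationTruth",
    "DesignArm",
    "default_design",
    "simulate_expression_experiment",
    "simulate_essentiality",
    "simulate_survival_cohort",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Planted structure of one simulated dataset."""

    planted_repressed: tuple[str, ...] = ()
    planted_induced: tuple[str, ...] = ()
    planted_offtarget: tuple[str, ...] = ()
    effect_size: float = 1.0
    offtarget_effect_size: float = 1.0
    noise_sd: float = 0.25
    essential_fraction_signature: float = 0.25
    essential_fraction_background: float = 0.05
    hazard_ratio: float = 2.5
    high_risk_cases: tuple[str, ...] = ()
    planted_essential: tuple[str, ...] = ()
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [
            set(self.planted_repressed),
            set(self.planted_induced),
            set(self.planted_offtarget),
        ]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("planted gene sets must be pairwise disjoint")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.hazard_ratio > 0:
            raise ValueError("hazard_ratio must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DesignArm:
    """One (model, rb_status, agent, dose, context) cell of the condition grid."""

    model: str
    rb_status: str
    agent: str
    dose_nM: float
    context: str = "cell_line"
    n_replicates: int = 3


def default_design(n_replicates: int = 3) -> tuple[DesignArm, ...]:
    """The condition grid the pipeline defaults emulate.

    Two RB-proficient cell lines (MCF7, T47D) treated with palbociclib
    1 uM and abemaciclib 250 nM, the RB-deficient MB468 line with both
    agents plus high-dose abemaciclib, and MB231 xenografts with intact
    or deleted RB under both agents — six RB-proficient drug-vs-vehicle
    contrasts in total, three RB-deficient ones, and vehicle arms
    everywhere.
    """
    arms: list[DesignArm] = []

    def block(model: str, rb: str, context: str, treatments: list[tuple[str, float]]):
        arms.append(DesignArm(model, rb, "vehicle", 0.0, context, n_replicates))
        for agent, dose in treatments:
            arms.append(DesignArm(model, rb, agent, dose, context, n_replicates))

    block("MCF7", "proficient", "cell_line", [("PD", 1000.0), ("LY", 250.0)])
    block("T47D", "proficient", "cell_line", [("PD", 1000.0), ("LY", 250.0)])
    block(
        "MB468",
        "deficient",
        "cell_line",
        [("PD", 1000.0), ("LY", 250.0), ("LY", 1000.0)],
    )
    block("MB231", "proficient", "xenograft", [("PD", 1000.0), ("LY", 1000.0)])
    block("MB231_RBko", "deficient", "xenograft", [("PD", 1000.0), ("LY", 1000.0)])
    return tuple(arms)


def _gene_ids(n_genes: int) -> tuple[str, ...]:
    width = len(str(n_genes))
    return tuple(f"G{i:0{width}d}" for i in range(1, n_genes + 1))


def simulate_expression_experiment(
    design: Sequence[DesignArm] | None = None,
    n_genes: int = 10_000,
    n_repressed: int = 78,
    n_induced: int = 4,
    n_offtarget: int = 30,
    effect_size: float = 1.0,
    offtarget_effect_size: float = 1.0,
    noise_sd: float = 0.25,
    offtarget_dose_cutoff_nM: float = 250.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleAnnotation, SimulationTruth]:
    """Simulate a multi-condition log2 expression experiment.

    value(g, s) = baseline(g) + model_offset(model) + planted effect + noise,
    where the planted on-target programs (``n_repressed`` repressed at
    -effect_size, ``n_induced`` induced at +effect_size) respond only in
    RB-proficient treated samples, and the off-target program (repressed
    at -offtarget_effect_size) responds to abemaciclib (LY) at doses >=
    the cutoff in every model, RB-proficient or not.  Noise is Gaussian
    and homoscedastic on the log2 scale.
    """
    if design is None:
        design = default_design()
    if n_repressed + n_induced + n_offtarget > n_genes:
        raise ValueError("planted sets exceed the gene universe")
    models = {arm.model for arm in design}
    vehicle_models = {arm.model for arm in design if arm.agent == "vehicle"}
    if models - vehicle_models:
        raise ValueError(
            f"models without a vehicle arm: {sorted(models - vehicle_models)}"
        )
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    repressed = genes[:n_repressed]
    induced = genes[n_repressed : n_repressed + n_induced]
    offtarget = genes[n_repressed + n_induced : n_repressed + n_induced + n_offtarget]

    baseline = rng.normal(7.0, 1.0, size=n_genes)
    model_offsets = {m: rng.normal(0.0, 0.25) for m in sorted(models)}

    effect = np.zeros(n_genes)
    effect[:n_repressed] = -effect_size
    effect[n_repressed : n_repressed + n_induced] = effect_size
    off_effect = np.zeros(n_genes)
    off_effect[n_repressed + n_induced : n_repressed + n_induced + n_offtarget] = (
        -offtarget_effect_size
    )

    sample_ids: list[str] = []
    rows: list[dict] = []
    columns: list[np.ndarray] = []
    for arm in design:
        for rep in range(1, arm.n_replicates + 1):
            treated = arm.agent != "vehicle"
            on_target = treated and arm.rb_status == "proficient"
            off_target = arm.agent == "LY" and arm.dose_nM >= offtarget_dose_cutoff_nM
            mu = baseline + model_offsets[arm.model]
            if on_target:
                mu = mu + effect
            if off_target:
                mu = mu + off_effect
            col = mu + rng.normal(0.0, noise_sd, size=n_genes)
            sid = f"{arm.model}_{arm.agent}{arm.dose_nM:g}_{arm.context}_r{rep}"
            sample_ids.append(sid)
            rows.append(
                {
                    "sample_id": sid,
                    "model": arm.model,
                    "rb_status": arm.rb_status,
                    "agent": arm.agent,
                    "dose_nM": arm.dose_nM,
                    "context": arm.context,
                    "replicate": rep,
                }
            )
            columns.append(col)
    matrix = ExpressionMatrix(
        genes, tuple(sample_ids), np.column_stack(columns)
    )
    annotation = SampleAnnotation(pd.DataFrame(rows))
    truth = SimulationTruth(
        planted_repressed=repressed,
        planted_induced=induced,
        planted_offtarget=offtarget,
        effect_size=effect_size,
        offtarget_effect_size=offtarget_effect_size,
        noise_sd=noise_sd,
        seed=seed,
        extra={"offtarget_dose_cutoff_nM": offtarget_dose_cutoff_nM},
    )
    return matrix, annotation, truth


def simulate_essentiality(
    universe: Sequence[str],
    signature: Sequence[str],
    essential_fraction_signature: float = 0.25,
    essential_fraction_background: float = 0.05,
    n_cell_lines: int = 3,
    seed: int = 0,
) -> tuple[EssentialityTable, tuple[str, ...]]:
    """Simulate a per-cell-line viability-screen p-value table.

    Each gene is essential with probability ``essential_fraction_signature``
    if it belongs to the signature and ``essential_fraction_background``
    otherwise; essential genes draw p ~ U(0, 0.05) in every line,
    non-essential genes p ~ U(0.05, 1).  Returns the table and the planted
    essential gene set.
    """
    for frac in (essential_fraction_signature, essential_fraction_background):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("essential fractions must lie in [0, 1]")
    universe = tuple(universe)
    sig_set = set(signature)
    if not sig_set <= set(universe):
        raise ValueError("signature must be a subset of the universe")
    rng = np.random.default_rng(seed)
    in_sig = np.array([g in sig_set for g in universe])
    frac = np.where(
        in_sig, essential_fraction_signature, essential_fraction_background
    )
    essential = rng.random(len(universe)) < frac
    n = len(universe)
    p = np.where(
        essential[:, None],
        rng.uniform(0.0, 0.05, size=(n, n_cell_lines)),
        rng.uniform(0.05, 1.0, size=(n, n_cell_lines)),
    )
    lines = tuple(f"line{i + 1}" for i in range(n_cell_lines))
    table = EssentialityTable(universe, lines, p)
    planted = tuple(np.asarray(universe, dtype=object)[essential])
    return table, planted


def simulate_survival_cohort(
    n_cases: int = 900,
    signature: Sequence[str] | None = None,
    n_genes: int = 500,
    group_shift: float = 2.0,
    cohort_noise_sd: float = 1.0,
    hazard_ratio: float = 2.5,
    baseline_hazard: float = 0.01,
    censoring_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SurvivalTable, SimulationTruth]:
    """Simulate a tumor cohort with signature-dependent recurrence hazard.

    Cases split evenly into two latent groups; the high-expression group
    carries a +``group_shift`` mean shift in the signature genes (in units
    of ``cohort_noise_sd``-scale log2 expression) and an exponential
    recurrence hazard ``baseline_hazard * hazard_ratio`` (per month)
    against ``baseline_hazard`` in the low group — high signature
    expression marks the proliferative, worse-prognosis subtype.
    Censoring times are independent Uniform(0, c) with c calibrated so the
    realized censored fraction approximates ``censoring_fraction``.
    """
    if n_cases < 4:
        raise ValueError("cohort needs >= 4 cases")
    if not 0.0 <= censoring_fraction < 1.0:
        raise ValueError("censoring_fraction must lie in [0, 1)")
    if signature is None:
        signature = _gene_ids(n_genes)[:82]
    signature = tuple(signature)
    genes = tuple(dict.fromkeys(signature + _gene_ids(n_genes)))[:max(n_genes, len(signature))]
    rng = np.random.default_rng(seed)
    case_ids = tuple(f"case{i:04d}" for i in range(1, n_cases + 1))
    high = np.zeros(n_cases, dtype=bool)
    high[rng.permutation(n_cases)[: n_cases // 2]] = True

    baseline = rng.normal(7.0, 1.0, size=len(genes))
    in_sig = np.array([g in set(signature) for g in genes])
    shift = np.outer(in_sig * group_shift, high.astype(float))
    values = (
        baseline[:, None]
        + shift
        + rng.normal(0.0, cohort_noise_sd, size=(len(genes), n_cases))
    )
    matrix = ExpressionMatrix(genes, case_ids, values)

    rates = np.where(high, baseline_hazard * hazard_ratio, baseline_hazard)
    event_times = rng.exponential(1.0 / rates)
    if censoring_fraction > 0:
        c_max = _calibrate_censoring(
            censoring_fraction, baseline_hazard, hazard_ratio
        )
        censor_times = rng.uniform(0.0, c_max, size=n_cases)
        observed = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        observed = event_times
        events = np.ones(n_cases, dtype=int)
    observed = np.maximum(observed, 1e-6)  # time must be strictly positive
    records = tuple(
        SurvivalRecord(cid, float(t), int(e))
        for cid, t, e in zip(case_ids, observed, events)
    )
    truth = SimulationTruth(
        planted_repressed=signature,
        effect_size=group_shift,
        noise_sd=cohort_noise_sd,
        hazard_ratio=hazard_ratio,
        high_risk_cases=tuple(np.asarray(case_ids, dtype=object)[high]),
        seed=seed,
        extra={
            "baseline_hazard": baseline_hazard,
            "censoring_fraction": censoring_fraction,
        },
    )
    return matrix, SurvivalTable(records), truth


def _calibrate_censoring(
    target: float, baseline_hazard: float, hazard_ratio: float
) -> float:
    """Upper censoring bound c with P(C < T) ~ target under the group mixture.

    For T ~ Exp(lam) and C ~ U(0, c), P(C < T) = (1 - exp(-lam*c)) / (lam*c);
    the mixture averages the two group rates.  Solved by bisection.
    """

    def censored_prob(c: float) -> float:
        out = 0.0
        for lam in (baseline_hazard, baseline_hazard * hazard_ratio):
            out += 0.5 * (1.0 - np.exp(-lam * c)) / (lam * c)
        return out

    lo, hi = 1e-6, 1.0
    while censored_prob(hi) > target:
        hi *= 2.0
        if hi > 1e9:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_prob(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
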