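"""Simulation-study harness: how well does each statistic detect gene flow?

Replicate datasets are simulated under the multispecies coalescent
(MSCM, the model the checks assume) and under MSCM+m (secondary-contact
gene flow between a random species pair — a genuine model violation).
Each replicate is pushed through the posterior predictive checks, the
per-statistic violation calls are tabulated into confusion matrices
(positive class: violation called on an MSCM+m dataset), and classifier
quality is summarized by the Matthews correlation coefficient plus the
fraction of correct calls. MSCM+m replicates also record their drawn
migration rate so the gene-flow-versus-p-value trend can be inspected.

Reference design: 6 species on a symmetric topology with splits at
5N/10N/20N generations, Ne = 100,000, 2 haploid samples per species,
contact window opening 2.5N generations ago, migration rate uniform on
[0.5, 5] migrants/generation. Desk-scale defaults (200 SNPs, 20
posterior trees, 20 predictive datasets per replicate) keep a full
harness run in minutes; the statistic definitions are scale-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .ppc import (
    DATA_STATISTICS,
    INFERENCE_STATISTICS,
    PPCConfig,
    run_data_based_check,
    run_inference_based_check,
)
from .simulate import (
    DemographicModel,
    SimulationConfig,
    build_demography,
    draw_mscm_m_scenario,
    simulate_snp_matrix,
)
from .synthetic import SyntheticPosteriorConfig, generate_synthetic_posterior
from .treeio import PosteriorTreeSet, SpeciesTree, TraceLog, parse_newick, sample_posterior_trees

__all__ = [
    "ConfusionMatrix",
    "EvaluationResult",
    "StudyDesign",
    "reference_species_tree",
    "mcc",
    "tabulate_confusion",
    "run_simulation_study",
    "gene_flow_trend",
]

MSCM = "MSCM"
MSCM_M = "MSCM+m"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary classification counts.

    Positive class: a model violation called on an MSCM+m dataset.
    False positives are MSCM datasets flagged as violations; false
    negatives are MSCM+m datasets the statistic failed to flag.
    """

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def fraction_correct(self) -> float:
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return (self.tp + self.tn) / self.total


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)), with the
    usual convention that a zero factor in the denominator — a
    degenerate classifier that only ever answers one way — scores 0.
    """
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def tabulate_confusion(
    truth: Sequence[str], calls: Sequence[bool]
) -> ConfusionMatrix:
    """Cross-tabulate true models against violation calls."""
    if len(truth) != len(calls):
        raise ValueError(
            f"{len(truth)} truth labels vs {len(calls)} calls"
        )
    tp = tn = fp = fn = 0
    for model, called in zip(truth, calls):
        if model == MSCM_M:
            if called:
                tp += 1
            else:
                fn += 1
        elif model == MSCM:
            if called:
                fp += 1
            else:
                tn += 1
        else:
            raise ValueError(f"unknown model label {model!r}")
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# study design


def reference_species_tree(ne: float = 100_000.0) -> SpeciesTree:
    """The 6-species symmetric reference topology, lengths in generations.

    Two mirrored clades of three species; cherries split at 5N, the
    third species joins at 10N, and the root sits at 20N generations.
    """
    n5, n10 = 5 * ne, 10 * ne
    newick = (
        f"(((sp1:{n5:g},sp2:{n5:g}):{n5:g},sp3:{n10:g}):{n10:g},"
        f"((sp4:{n5:g},sp5:{n5:g}):{n5:g},sp6:{n10:g}):{n10:g});"
    )
    return parse_newick(newick, unit="generations")


@dataclass
class StudyDesign:
    """Concrete parameters of one harness run."""

    tree: SpeciesTree = field(default_factory=reference_species_tree)
    ne: float = 100_000.0
    n_snps: int = 200
    haploids_per_species: int = 2
    n_posterior_trees: int = 20
    n_pp_datasets: int = 20
    rate_range: tuple[float, float] = (0.5, 5.0)
    contact_fraction: float = 1.25  # contact window = 2.5 * Ne generations
    topology_jitter: float = 0.0
    length_jitter_cv: float = 0.05
    likelihood_mean: float = -5000.0
    likelihood_sd: float = 50.0
    pp_likelihood_sd: float | None = None  # None: same as likelihood_sd

    def samples_per_species(self) -> dict[str, int]:
        return {sp: self.haploids_per_species for sp in sorted(self.tree.tip_labels)}


@dataclass
class EvaluationResult:
    per_statistic: dict[str, dict]
    trend: pd.DataFrame  # columns: replicate, model, m, statistic, p_value, violation

    def confusion(self, statistic: str) -> ConfusionMatrix:
        return self.per_statistic[statistic]["confusion"]

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for stat, entry in sorted(self.per_statistic.items()):
            cm: ConfusionMatrix = entry["confusion"]
            rows.append(
                {
                    "statistic": stat,
                    "tp": cm.tp,
                    "tn": cm.tn,
                    "fp": cm.fp,
                    "fn": cm.fn,
                    "mcc": entry["mcc"],
                    "fraction_correct": entry["fraction_correct"],
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    def trend_to_csv(self, path: str | Path) -> None:
        self.trend.to_csv(path, index=False)


def _rep_seed(seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=tuple(key)).generate_state(1)[0]
        % (2**31 - 1)
    )


def run_simulation_study(
    n_reps_per_model: int,
    design: StudyDesign | None = None,
    ppc_config: PPCConfig | None = None,
    statistics: Sequence[str] = DATA_STATISTICS + INFERENCE_STATISTICS,
    seed: int = 0,
    models: Sequence[str] = (MSCM, MSCM_M),
    posterior_provider: Callable[..., tuple[PosteriorTreeSet, TraceLog]] | None = None,
) -> EvaluationResult:
    """Run the MSCM vs MSCM+m classification study.

    For every replicate: simulate an "empirical" dataset under the true
    model, emulate the inference step with a synthetic posterior
    centered on the true species tree, run the requested checks, and
    record each statistic's violation call. ``posterior_provider`` may
    replace the synthetic posterior with externally produced
    (tree set, trace log) pairs; it is called as
    ``provider(replicate_index, model_label, true_model)``.

    Fully deterministic under ``seed``.
    """
    design = design or StudyDesign()
    ppc_config = ppc_config or PPCConfig()
    statistics = list(statistics)
    data_stats = [s for s in statistics if s in DATA_STATISTICS]
    inf_stats = [s for s in statistics if s in INFERENCE_STATISTICS]
    unknown = set(statistics) - set(DATA_STATISTICS) - set(INFERENCE_STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    if n_reps_per_model < 1:
        raise ValueError("n_reps_per_model must be >= 1")

    spm = design.samples_per_species()
    truth: list[str] = []
    calls: dict[str, list[bool]] = {s: [] for s in statistics}
    trend_rows: list[dict] = []
    rep_counter = 0
    for model_label in models:
        for rep in range(n_reps_per_model):
            rs = _rep_seed(seed, 0 if model_label == MSCM else 1, rep)
            rng = np.random.default_rng(rs)
            if model_label == MSCM_M:
                true_model = draw_mscm_m_scenario(
                    design.tree,
                    design.ne,
                    rng,
                    rate_range=design.rate_range,
                    contact_fraction=design.contact_fraction,
                )
                m_rate = true_model.migrations[0].rate_m
            else:
                true_model = build_demography(design.tree, design.ne)
                m_rate = 0.0
            sim_cfg = SimulationConfig(
                n_snps=design.n_snps,
                samples_per_species=spm,
                seed=_rep_seed(rs, 1),
            )
            empirical = simulate_snp_matrix(true_model, sim_cfg)
            if posterior_provider is not None:
                posterior, post_log = posterior_provider(
                    rep_counter, model_label, true_model
                )
            else:
                posterior, post_log = generate_synthetic_posterior(
                    SyntheticPosteriorConfig(
                        center_tree=design.tree,
                        n_samples=design.n_posterior_trees,
                        topology_jitter=design.topology_jitter,
                        length_jitter_cv=design.length_jitter_cv,
                        likelihood_mean=design.likelihood_mean,
                        likelihood_sd=design.likelihood_sd,
                        seed=_rep_seed(rs, 2),
                    )
                )
            rep_config = PPCConfig(
                alpha=ppc_config.alpha,
                n_null_comparisons=ppc_config.n_null_comparisons,
                n_pp_tree_comparisons=ppc_config.n_pp_tree_comparisons,
                null_quantile=ppc_config.null_quantile,
                seed=_rep_seed(rs, 3),
            )
            reports = {}
            if data_stats:
                report = run_data_based_check(
                    empirical,
                    posterior,
                    model_builder=lambda t: build_demography(t, design.ne),
                    config=rep_config,
                    sim_config=sim_cfg,
                    n_pp_datasets=design.n_pp_datasets,
                    statistics=data_stats,
                )
                reports.update(report.results)
            if inf_stats:
                pp_results = _synthetic_pp_results(posterior, design, rs)
                report = run_inference_based_check(
                    posterior, post_log, pp_results, rep_config,
                    statistics=inf_stats,
                )
                reports.update(report.results)
            truth.append(model_label)
            for stat in statistics:
                res = reports[stat]
                calls[stat].append(res.violation)
                trend_rows.append(
                    {
                        "replicate": rep_counter,
                        "model": model_label,
                        "m": m_rate,
                        "statistic": stat,
                        "p_value": res.p_value,
                        "violation": res.violation,
                    }
                )
            rep_counter += 1

    per_statistic = {}
    for stat in statistics:
        cm = tabulate_confusion(truth, calls[stat])
        per_statistic[stat] = {
            "confusion": cm,
            "mcc": mcc(cm),
            "fraction_correct": cm.fraction_correct,
        }
    return EvaluationResult(
        per_statistic=per_statistic, trend=pd.DataFrame(trend_rows)
    )


def _synthetic_pp_results(
    posterior: PosteriorTreeSet, design: StudyDesign, rep_seed: int
) -> list[tuple[SpeciesTree, PosteriorTreeSet, TraceLog]]:
    """Emulated re-analyses of the predictive datasets.

    Each predictive dataset's 'inference' is a synthetic posterior
    centered on the posterior tree the dataset came from, with the same
    jitter as the main posterior. ``pp_likelihood_sd`` lets a harness
    inject a likelihood-spread mismatch between the posterior log and
    the predictive logs.
    """
    n_pp = min(design.n_pp_datasets, len(posterior))
    sampled = sample_posterior_trees(
        posterior, n_pp, mode="random", seed=_rep_seed(rep_seed, 4)
    )
    pp_sd = (
        design.pp_likelihood_sd
        if design.pp_likelihood_sd is not None
        else design.likelihood_sd
    )
    out = []
    for k, src in enumerate(sampled):
        trees, log = generate_synthetic_posterior(
            SyntheticPosteriorConfig(
                center_tree=src,
                n_samples=design.n_posterior_trees,
                topology_jitter=design.topology_jitter,
                length_jitter_cv=design.length_jitter_cv,
                likelihood_mean=design.likelihood_mean,
                likelihood_sd=pp_sd,
                seed=_rep_seed(rep_seed, 5, k),
            )
        )
        out.append((src, trees, log))
    return out


def gene_flow_trend(
    result: EvaluationResult, statistic: str
) -> tuple[list[tuple[float, float]], float]:
    """(m, p) pairs for MSCM+m replicates plus their Spearman correlation.

    A negative correlation means stronger gene flow yields smaller
    p-values, i.e. easier detection. Returns correlation 0 when either
    variable is constant.
    """
    if statistic not in result.per_statistic:
        raise KeyError(
            f"statistic {statistic!r} absent; have "
            f"{sorted(result.per_statistic)}"
        )
    sub = result.trend[
        (result.trend["statistic"] == statistic)
        & (result.trend["model"] == MSCM_M)
        & result.trend["p_value"].notna()
    ]
    if sub.empty:
        raise ValueError("no MSCM+m replicates with p-values for this statistic")
    pairs = list(zip(sub["m"].tolist(), sub["p_value"].tolist()))
    m_vals = sub["m"].to_numpy()
    p_vals = sub["p_value"].to_numpy()
    if np.ptp(m_vals) == 0 or np.ptp(p_vals) == 0:
        rho = 0.0
    else:
        rho = float(scipy_stats.spearmanr(m_vals, p_vals).statistic)
    return pairs, rho
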