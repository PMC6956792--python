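"""Posterior predictive comparison engine.

Two families of checks:

* data-based — simulate one predictive SNP dataset per sampled
  posterior tree, then compare F_ST summaries of the empirical dataset
  against the predictive distribution (two-tailed posterior predictive
  p-value for the mean and range; a boxplot outlier test on per-pair
  differences for localization);

* inference-based — compare the posterior tree sample and likelihood
  trace against re-analyses of the predictive datasets: tree distances
  to a null distribution built from within-posterior comparisons, and
  the mean/SD of likelihoods via the same two-tailed p-value.

Violation conventions follow the underlying tail logic: two-tailed
p-values flag when p < alpha, while tree-distance checks flag when the
fraction of predictive-vs-source distances exceeding the null
threshold is itself greater than alpha.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from . import sumstats
from .simulate import DemographicModel, SimulationConfig, SNPMatrix, simulate_snp_matrix
from .sumstats import PairwiseFstMatrix
from .treeio import PosteriorTreeSet, SpeciesTree, TraceLog, sample_posterior_trees

__all__ = [
    "PPCConfig",
    "StatisticResult",
    "PPCReport",
    "two_tailed_ppp",
    "tukey_fivenum",
    "fst_outlier_test",
    "tree_distance_null",
    "tree_distance_ppp",
    "run_data_based_check",
    "run_inference_based_check",
    "DATA_STATISTICS",
    "INFERENCE_STATISTICS",
]

DATA_STATISTICS = ("FSTA", "FSTR", "PFST")
INFERENCE_STATISTICS = ("RF", "KF", "MLM", "MLSD")


@dataclass
class PPCConfig:
    """Tuning knobs of the predictive comparison.

    alpha: significance level for violation calls.
    n_null_comparisons: within-posterior tree pairs drawn to build the
        tree-distance null distribution.
    n_pp_tree_comparisons: predictive trees compared to their source
        posterior tree, per predictive dataset.
    null_quantile: quantile of the null distribution used as the
        tree-distance threshold.
    """

    alpha: float = 0.05
    n_null_comparisons: int = 1000
    n_pp_tree_comparisons: int = 100
    null_quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.null_quantile < 1:
            raise ValueError("null_quantile must be in (0, 1)")
        if self.n_null_comparisons < 1 or self.n_pp_tree_comparisons < 1:
            raise ValueError("comparison counts must be >= 1")


@dataclass
class StatisticResult:
    statistic: str
    violation: bool
    p_value: float | None = None
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class PPCReport:
    results: dict[str, StatisticResult]
    config: PPCConfig
    provenance: dict = field(default_factory=dict)

    def violations(self) -> list[str]:
        return [s for s, r in self.results.items() if r.violation]

    def to_json(self, indent: int | None = 2) -> str:
        payload = {
            "provenance": self.provenance,
            "config": {
                "alpha": self.config.alpha,
                "n_null_comparisons": self.config.n_null_comparisons,
                "n_pp_tree_comparisons": self.config.n_pp_tree_comparisons,
                "null_quantile": self.config.null_quantile,
                "seed": self.config.seed,
            },
            "results": {
                s: {
                    "p_value": r.p_value,
                    "violation": r.violation,
                    "detail": _jsonable(r.detail),
                }
                for s, r in sorted(self.results.items())
            },
        }
        return json.dumps(payload, indent=indent, sort_keys=True)

    def to_table(self) -> str:
        lines = [f"{'statistic':<10}{'p_value':>10}  violation"]
        for s, r in sorted(self.results.items()):
            p = "-" if r.p_value is None else f"{r.p_value:.4f}"
            lines.append(f"{s:<10}{p:>10}  {'YES' if r.violation else 'no'}")
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# kernels


def two_tailed_ppp(empirical: float, predictive: Sequence[float]) -> float:
    """Two-tailed posterior predictive p-value.

    Twice the smaller of the two tail fractions (predictive values above
    vs below the empirical value), capped at 1. Exact ties count in
    neither tail; if every predictive value ties the empirical one there
    is no evidence of discrepancy and p = 1.
    """
    pred = np.asarray(predictive, dtype=float)
    if pred.size == 0:
        raise ValueError("predictive distribution is empty")
    above = int((pred > empirical).sum())
    below = int((pred < empirical).sum())
    if above == 0 and below == 0:
        return 1.0
    return min(1.0, 2.0 * min(above, below) / pred.size)


def tukey_fivenum(x: Sequence[float]) -> tuple[float, float, float, float, float]:
    """Tukey's five-number summary (min, lower hinge, median, upper hinge, max).

    Hinges are medians of the lower/upper halves, the overall median
    included in both when n is odd — the convention behind R's
    ``boxplot.stats``/``fivenum``.
    """
    v = np.sort(np.asarray(x, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    n4 = math.floor((n + 3) / 2) / 2
    idx = [1.0, n4, (n + 1) / 2, n + 1 - n4, float(n)]
    out = []
    for d in idx:
        lo = v[int(math.floor(d)) - 1]
        hi = v[int(math.ceil(d)) - 1]
        out.append(0.5 * (lo + hi))
    return tuple(out)  # type: ignore[return-value]


def fst_outlier_test(
    empirical: PairwiseFstMatrix,
    predictive: Sequence[PairwiseFstMatrix],
    coef: float = 1.5,
) -> tuple[bool, list[tuple[str, str]]]:
    """Boxplot outlier test on per-pair empirical-minus-predictive F_ST.

    For each species pair, average (empirical - predictive) over the
    predictive datasets; a pair whose average difference falls outside
    the Tukey fences (hinge +/- 1.5*IQR across pairs) is an outlier.
    Any outlier is a violation call, and the flagged pairs point at the
    lineages suspected of exchanging genes.
    """
    if len(predictive) < 2:
        raise ValueError("need >= 2 predictive F_ST matrices")
    species = empirical.species
    for m in predictive:
        if m.species != species:
            raise ValueError("species sets differ between matrices")
    pairs: list[tuple[str, str]] = []
    diffs: list[float] = []
    k = len(species)
    for i in range(k):
        for j in range(i + 1, k):
            emp = empirical.values[i, j]
            preds = np.array([m.values[i, j] for m in predictive])
            ok = ~np.isnan(preds)
            if np.isnan(emp) or not ok.any():
                continue
            pairs.append((species[i], species[j]))
            diffs.append(float((emp - preds[ok]).mean()))
    if not pairs:
        raise ValueError("every species pair is undefined")
    _, q1, _, q3, _ = tukey_fivenum(diffs)
    iqr = q3 - q1
    lo, hi = q1 - coef * iqr, q3 + coef * iqr
    outliers = [p for p, d in zip(pairs, diffs) if d < lo or d > hi]
    return bool(outliers), outliers


def tree_distance_null(
    posterior: PosteriorTreeSet,
    kind: str = "RF",
    n: int = 1000,
    seed: int | None = None,
    null_quantile: float = 0.95,
) -> float:
    """Null tree-distance threshold from within-posterior comparisons.

    Draws ``n`` pairs of distinct posterior trees (pairs with
    replacement, members forced distinct), computes their distances, and
    returns the ``null_quantile`` empirical quantile. Distances among
    posterior trees reflect only posterior uncertainty, so predictive
    trees farther from their source than this threshold indicate misfit.
    """
    if len(posterior) < 2:
        raise ValueError("need >= 2 posterior trees for a null distribution")
    dist = _distance_fn(kind)
    rng = np.random.default_rng(seed)
    m = len(posterior)
    vals = np.empty(n)
    for r in range(n):
        i = int(rng.integers(m))
        j = int(rng.integers(m - 1))
        if j >= i:
            j += 1
        vals[r] = dist(posterior[i], posterior[j])
    return float(np.quantile(vals, null_quantile))


def _distance_fn(kind: str) -> Callable[[SpeciesTree, SpeciesTree], float]:
    if kind == "RF":
        return lambda a, b: sumstats.rf_distance(a, b, normalized=True)
    if kind == "KF":
        return sumstats.kf_distance
    raise ValueError(f"unknown tree distance kind {kind!r}")


def tree_distance_ppp(
    posterior: PosteriorTreeSet,
    pp_tree_sets: Sequence[tuple[SpeciesTree, PosteriorTreeSet]],
    kind: str,
    config: PPCConfig,
) -> StatisticResult:
    """Tree-distance posterior predictive check (statistics RF and KF).

    Builds the null threshold from the posterior, then for every
    predictive re-analysis draws ``n_pp_tree_comparisons`` of its trees
    (with replacement) and measures their distance to the posterior
    tree the dataset was simulated from. Pooled over all predictive
    datasets, p is the fraction of comparisons exceeding the threshold;
    p > alpha is a violation (large predictive-to-source distances mean
    the posterior does not resemble data generated under its own model).
    """
    if not pp_tree_sets:
        raise ValueError("no posterior predictive tree sets supplied")
    dist = _distance_fn(kind)
    threshold = tree_distance_null(
        posterior,
        kind=kind,
        n=config.n_null_comparisons,
        seed=config.seed,
        null_quantile=config.null_quantile,
    )
    rng = np.random.default_rng(config.seed + 1)
    exceed = 0
    total = 0
    for ds_index, (source_tree, trees) in enumerate(pp_tree_sets):
        if len(trees) == 0:
            raise ValueError(f"predictive dataset {ds_index} has no trees")
        idx = rng.integers(len(trees), size=config.n_pp_tree_comparisons)
        for i in idx:
            if dist(trees[int(i)], source_tree) > threshold:
                exceed += 1
            total += 1
    p = exceed / total
    return StatisticResult(
        statistic=kind,
        p_value=p,
        violation=p > config.alpha,
        detail={"threshold": threshold, "n_comparisons": total},
    )


# ---------------------------------------------------------------------------
# orchestration


def run_data_based_check(
    empirical: SNPMatrix,
    posterior: PosteriorTreeSet,
    model_builder: Callable[[SpeciesTree], DemographicModel],
    config: PPCConfig,
    sim_config: SimulationConfig,
    n_pp_datasets: int = 100,
    sampling_mode: str = "random",
    statistics: Sequence[str] = DATA_STATISTICS,
) -> PPCReport:
    """Data-based posterior predictive check (FSTA, FSTR, PFST).

    Samples ``n_pp_datasets`` trees from the posterior, simulates one
    predictive SNP dataset per tree under the model returned by
    ``model_builder`` (which turns a posterior tree into a
    DemographicModel, e.g. fixing Ne and the time unit), and compares
    F_ST summaries of the empirical matrix against the predictive
    distribution.
    """
    emp_species = set(empirical.species)
    post_tips = set(posterior.tip_labels)
    if not emp_species <= post_tips:
        raise ValueError(
            f"empirical species {sorted(emp_species - post_tips)} missing "
            "from the posterior trees"
        )
    unknown = set(statistics) - set(DATA_STATISTICS)
    if unknown:
        raise ValueError(f"unknown data-based statistics: {sorted(unknown)}")
    n_pp = min(n_pp_datasets, len(posterior))
    sampled = sample_posterior_trees(
        posterior, n_pp, mode=sampling_mode, seed=config.seed
    )
    emp_fst = sumstats.pairwise_fst(empirical)
    pred_fst: list[PairwiseFstMatrix] = []
    for k, tree in enumerate(sampled):
        model = model_builder(tree)
        cfg = SimulationConfig(
            n_snps=sim_config.n_snps,
            samples_per_species=sim_config.samples_per_species,
            mutation_rate=sim_config.mutation_rate,
            seed=_derive_seed(config.seed, k),
        )
        pred_fst.append(sumstats.pairwise_fst(simulate_snp_matrix(model, cfg)))
    results: dict[str, StatisticResult] = {}
    if "FSTA" in statistics:
        emp = sumstats.fst_mean(emp_fst)
        preds = [sumstats.fst_mean(m) for m in pred_fst]
        p = two_tailed_ppp(emp, preds)
        results["FSTA"] = StatisticResult(
            "FSTA", p_value=p, violation=p < config.alpha,
            detail={"empirical": emp, "predictive_mean": float(np.mean(preds))},
        )
    if "FSTR" in statistics:
        emp = sumstats.fst_range(emp_fst)
        preds = [sumstats.fst_range(m) for m in pred_fst]
        p = two_tailed_ppp(emp, preds)
        results["FSTR"] = StatisticResult(
            "FSTR", p_value=p, violation=p < config.alpha,
            detail={"empirical": emp, "predictive_mean": float(np.mean(preds))},
        )
    if "PFST" in statistics:
        violation, outliers = fst_outlier_test(emp_fst, pred_fst)
        results["PFST"] = StatisticResult(
            "PFST", violation=violation,
            detail={"outlier_pairs": [list(p) for p in outliers]},
        )
    return PPCReport(
        results=results,
        config=config,
        provenance={
            "check": "data-based",
            "n_pp_datasets": n_pp,
            "n_snps": sim_config.n_snps,
        },
    )


def run_inference_based_check(
    posterior: PosteriorTreeSet,
    posterior_log: TraceLog,
    pp_results: Sequence[tuple[SpeciesTree, PosteriorTreeSet, TraceLog]],
    config: PPCConfig,
    statistics: Sequence[str] = INFERENCE_STATISTICS,
) -> PPCReport:
    """Inference-based check (RF, KF, MLM, MLSD).

    ``pp_results`` holds, per predictive dataset, the posterior tree it
    was simulated from together with the tree sample and trace log of
    its re-analysis. Tree distances go through the null-threshold
    procedure; likelihood mean and SD go through the two-tailed
    p-value against the per-dataset predictive summaries.
    """
    if not pp_results:
        raise ValueError("no posterior predictive results supplied")
    unknown = set(statistics) - set(INFERENCE_STATISTICS)
    if unknown:
        raise ValueError(f"unknown inference-based statistics: {sorted(unknown)}")
    results: dict[str, StatisticResult] = {}
    tree_sets = [(src, trees) for src, trees, _ in pp_results]
    for kind in ("RF", "KF"):
        if kind in statistics:
            results[kind] = tree_distance_ppp(posterior, tree_sets, kind, config)
    if "MLM" in statistics or "MLSD" in statistics:
        emp = sumstats.likelihood_mean_sd(posterior_log)
        pred = [sumstats.likelihood_mean_sd(log) for _, _, log in pp_results]
        if "MLM" in statistics:
            p = two_tailed_ppp(emp.mean, [s.mean for s in pred])
            results["MLM"] = StatisticResult(
                "MLM", p_value=p, violation=p < config.alpha,
                detail={"empirical": emp.mean},
            )
        if "MLSD" in statistics:
            p = two_tailed_ppp(emp.sd, [s.sd for s in pred])
            results["MLSD"] = StatisticResult(
                "MLSD", p_value=p, violation=p < config.alpha,
                detail={"empirical": emp.sd},
            )
    return PPCReport(
        results=results,
        config=config,
        provenance={"check": "inference-based", "n_pp_datasets": len(pp_results)},
    )


def _derive_seed(seed: int, k: int) -> int:
    # stable per-dataset seeds below 2**31
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=(k,)).generate_state(1)[0]
        % (2**31 - 1)
    )
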