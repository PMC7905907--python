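"""The full evaluation protocol around the cost-sensitive ensemble.

Each repeat draws a stratified 80/10/10 train/validation/test split, ranks
features with Relief on the training part, grows the feature subset one
ranked feature at a time, and keeps the prefix whose validation-set ensemble
efficiency E is highest (ties toward the smaller subset).  The ensemble is
then re-trained at the chosen size, its vote weights taken from the
configured split, and ensemble plus members are evaluated on the test part.
Repeats are aggregated as mean +/- SD (sample SD, n-1) per metric per method,
compared pairwise with the Wilcoxon signed-rank test, and feature pick counts
are tallied.

Preprocessing order follows the configured mode: ``group`` imputes and
normalizes on the whole table (label-aware group statistics) before
splitting; ``strict`` splits first and fits all statistics on the training
part only, filling held-out cells with label-free overall statistics.

A generational genetic algorithm (tournament selection, uniform crossover,
elitism) is provided for member hyperparameter search with the validation
ensemble E as fitness.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .dataio import Dataset, SplitIndices, ValidationError, stratified_split
from .ensemble import CostSensitiveVotingEnsemble, member_efficiency
from .learners import MEMBER_NAMES, MemberSpec, make_member, positive_scores
from .metrics import (METRIC_NAMES, CostMatrix, MetricSet, compute_weights,
                      confusion, efficiency_index, metric_set,
                      misclassification_cost, wilcoxon_signed_rank)
from .preprocess import (apply_normalizer, drop_sparse_features, fit_imputer,
                         fit_normalizer, impute)
from .relief import ReliefConfig, ReliefResult, relief_weights, top_k

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "GaConfig",
    "RepeatResult",
    "ExperimentSummary",
    "derive_seed",
    "select_feature_subset",
    "run_repeat",
    "run_experiment",
    "ga_optimize",
    "ga_tune",
    "write_outputs",
]


@dataclass(frozen=True)
class ExperimentConfig:
    repeats: int = 10
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    cost_matrix: CostMatrix = field(default_factory=CostMatrix)
    members: tuple[MemberSpec, ...] = tuple(MemberSpec(n) for n in MEMBER_NAMES)
    relief: ReliefConfig = field(default_factory=ReliefConfig)
    preprocess_mode: str = "group"
    missing_threshold: float = 0.5
    weight_source: str = "validation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if self.preprocess_mode not in ("group", "strict"):
            raise ValidationError("preprocess_mode must be group or strict")
        if self.weight_source not in ("train", "validation"):
            raise ValidationError("weight_source must be train or validation")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "cost_matrix" in d:
            d["cost_matrix"] = CostMatrix(**d["cost_matrix"])
        if "members" in d:
            d["members"] = tuple(MemberSpec.from_dict(m) for m in d["members"])
        if "relief" in d:
            d["relief"] = ReliefConfig(**d["relief"])
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)


@dataclass(frozen=True)
class GaConfig:
    population: int = 50
    crossover_fraction: float = 0.8
    elite_fraction: float = 0.05
    generations: int = 20
    mutation_rate: float = 0.2
    tournament: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValidationError("population must be >= 2")
        for f in (self.crossover_fraction, self.elite_fraction, self.mutation_rate):
            if not (0.0 <= f <= 1.0):
                raise ValidationError("fractions must be in [0, 1]")


@dataclass
class RepeatResult:
    index: int
    seed: int
    ranking: tuple[str, ...]
    chosen_k: int
    chosen_subset: tuple[str, ...]
    e_curve: list[float]                  # validation ensemble E per k (fractions)
    weights: dict[str, float]
    member_val_e: dict[str, float]        # per-member validation E at chosen k
    ensemble_val_e: float
    test_metrics: dict[str, MetricSet]    # "ensemble" + member names

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "seed": self.seed,
            "ranking": list(self.ranking),
            "chosen_k": self.chosen_k,
            "chosen_subset": list(self.chosen_subset),
            "e_curve": [round(v, 12) for v in self.e_curve],
            "weights": {k: round(v, 12) for k, v in self.weights.items()},
            "member_val_e": {k: round(v, 12) for k, v in self.member_val_e.items()},
            "ensemble_val_e": round(self.ensemble_val_e, 12),
            "test_metrics": {m: {k: round(v, 10) for k, v in ms.as_dict().items()}
                             for m, ms in self.test_metrics.items()},
        }


@dataclass
class ExperimentSummary:
    config_seed: int
    methods: dict            # method -> metric -> {"mean":, "sd":}
    wilcoxon: dict           # metric -> member -> {"z":, "p":}
    picks: dict[str, int]
    repeats: list[RepeatResult]

    def to_dict(self) -> dict:
        return {
            "seed": self.config_seed,
            "methods": self.methods,
            "wilcoxon": self.wilcoxon,
            "picks": self.picks,
            "repeats": [r.to_dict() for r in self.repeats],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def derive_seed(master: int, index: int) -> int:
    """Counter-based per-repeat seed below 2**31."""
    ss = np.random.SeedSequence([int(master), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# --------------------------------------------------------------------------
# Pipeline stages
# --------------------------------------------------------------------------

def _fit_members(specs: Sequence[MemberSpec], X: np.ndarray, y: np.ndarray,
                 seed: int) -> list[tuple[str, object]]:
    fitted = []
    for i, spec in enumerate(specs):
        est = make_member(replace(spec, seed=derive_seed(seed, i)))
        est.fit(X, y)
        fitted.append((spec.name, est))
    return fitted


def _ensemble_on(members, weights: np.ndarray, X: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    labels = np.vstack([np.asarray(est.predict(X), dtype=int) for _, est in members])
    score = weights @ labels
    return (score >= 0.5).astype(int), score


def _efficiencies(members, X, y, cm: CostMatrix) -> np.ndarray:
    return np.array([member_efficiency(est, X, y, cm) for _, est in members])


def select_feature_subset(train: Dataset, val: Dataset, ranking: Sequence[str],
                          config: ExperimentConfig, seed: int = 0
                          ) -> tuple[int, tuple[str, ...], list[float]]:
    """Grow ranked prefixes and keep the one with the best validation
    ensemble E (ties toward the smaller prefix).

    A prefix whose training fails is skipped with a warning; every prefix
    failing is an error.
    """
    ranking = tuple(ranking)
    if set(ranking) != set(train.schema.names):
        raise ValidationError("ranking must cover every retained feature")
    cm = config.cost_matrix
    curve: list[float] = []
    for k in range(1, len(ranking) + 1):
        subset = list(ranking[:k])
        tr = train.select_features(subset)
        va = val.select_features(subset)
        try:
            members = _fit_members(config.members, tr.X, tr.y, derive_seed(seed, k))
            ref = (tr.X, tr.y) if config.weight_source == "train" else (va.X, va.y)
            e = _efficiencies(members, *ref, cm)
            w = compute_weights(e, cm).weights
            pred, _ = _ensemble_on(members, w, va.X)
            c = confusion(va.y, pred)
            curve.append(efficiency_index(c.accuracy,
                                          misclassification_cost(c, cm), cm))
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("subset size %d skipped: %s", k, exc)
            curve.append(float("nan"))
    finite = [i for i, v in enumerate(curve) if not math.isnan(v)]
    if not finite:
        raise ValidationError("every candidate subset failed to train")
    best = max(finite, key=lambda i: (curve[i], -i))
    k = best + 1
    return k, ranking[:k], curve


def _preprocess_group(dataset: Dataset, config: ExperimentConfig
                      ) -> tuple[Dataset, list[str]]:
    ds, dropped = drop_sparse_features(dataset, config.missing_threshold)
    stats = fit_imputer(ds, labels_available=True)
    ds = impute(ds, stats, mode="group")
    norm = fit_normalizer(ds)
    return apply_normalizer(ds, norm), dropped


def _preprocess_strict(dataset: Dataset, split: SplitIndices,
                       config: ExperimentConfig
                       ) -> tuple[Dataset, Dataset, Dataset, list[str]]:
    ds, dropped = drop_sparse_features(dataset, config.missing_threshold)
    train, val, test = (ds.take(p) for p in split.parts())
    stats = fit_imputer(train, labels_available=True)
    train = impute(train, stats, mode="group")
    val = impute(val, stats, mode="strict")
    test = impute(test, stats, mode="strict")
    norm = fit_normalizer(train)
    return (apply_normalizer(train, norm), apply_normalizer(val, norm),
            apply_normalizer(test, norm), dropped)


def run_repeat(dataset: Dataset, config: ExperimentConfig, index: int
               ) -> RepeatResult:
    """One split -> preprocess -> Relief -> subset search -> test evaluation,
    fully reproducible from (config.seed, index)."""
    seed = derive_seed(config.seed, index)
    if config.preprocess_mode == "group":
        pre, _ = _preprocess_group(dataset, config)
        split = stratified_split(pre, config.fractions, seed=seed)
        train, val, test = (pre.take(p) for p in split.parts())
    else:
        split = stratified_split(dataset, config.fractions, seed=seed)
        train, val, test, _ = _preprocess_strict(dataset, split, config)

    relief_cfg = replace(config.relief, seed=derive_seed(seed, 10_001))
    ranking = relief_weights(train, relief_cfg).ranking
    k, subset, curve = select_feature_subset(train, val, ranking, config,
                                             seed=derive_seed(seed, 10_002))

    tr = train.select_features(subset)
    va = val.select_features(subset)
    te = test.select_features(subset)
    cm = config.cost_matrix
    members = _fit_members(config.members, tr.X, tr.y,
                           derive_seed(derive_seed(seed, 10_002), k))
    ref = (tr.X, tr.y) if config.weight_source == "train" else (va.X, va.y)
    e_ref = _efficiencies(members, *ref, cm)
    weights = compute_weights(e_ref, cm, source=config.weight_source).weights

    val_e = _efficiencies(members, va.X, va.y, cm)
    val_pred, _ = _ensemble_on(members, weights, va.X)
    vc = confusion(va.y, val_pred)
    ensemble_val_e = efficiency_index(vc.accuracy,
                                      misclassification_cost(vc, cm), cm)

    test_metrics: dict[str, MetricSet] = {}
    for name, est in members:
        pred = np.asarray(est.predict(te.X), dtype=int)
        test_metrics[name] = metric_set(confusion(te.y, pred),
                                        positive_scores(est, te.X), te.y, cm)
    pred, score = _ensemble_on(members, weights, te.X)
    test_metrics["ensemble"] = metric_set(confusion(te.y, pred), score, te.y, cm)

    names = [s.name for s in config.members]
    return RepeatResult(
        index=index, seed=seed, ranking=ranking, chosen_k=k, chosen_subset=subset,
        e_curve=curve,
        weights=dict(zip(names, weights.tolist())),
        member_val_e=dict(zip(names, val_e.tolist())),
        ensemble_val_e=float(ensemble_val_e),
        test_metrics=test_metrics,
    )


def run_experiment(dataset: Dataset, config: ExperimentConfig) -> ExperimentSummary:
    """Run all repeats and aggregate mean +/- SD, Wilcoxon tables and feature
    pick counts."""
    results = [run_repeat(dataset, config, i) for i in range(config.repeats)]
    member_names = [s.name for s in config.members]
    methods = member_names + ["ensemble"]

    per_metric: dict[str, dict[str, np.ndarray]] = {}
    for metric in METRIC_NAMES:
        per_metric[metric] = {
            m: np.array([r.test_metrics[m].as_dict()[metric] for r in results])
            for m in methods
        }

    summary_methods = {
        m: {
            metric: {
                "mean": float(np.mean(per_metric[metric][m])),
                "sd": float(np.std(per_metric[metric][m], ddof=1))
                if len(results) > 1 else 0.0,
            }
            for metric in METRIC_NAMES
        }
        for m in methods
    }

    wilcoxon: dict = {}
    if len(results) >= 2:
        for metric in METRIC_NAMES:
            wilcoxon[metric] = {}
            ens = per_metric[metric]["ensemble"]
            for m in member_names:
                res = wilcoxon_signed_rank(ens, per_metric[metric][m])
                wilcoxon[metric][m] = {"z": round(res.z, 6), "p": round(res.p, 6)}

    picks: dict[str, int] = {name: 0 for name in results[0].ranking}
    for r in results:
        for name in r.chosen_subset:
            picks[name] = picks.get(name, 0) + 1

    return ExperimentSummary(config_seed=config.seed, methods=summary_methods,
                             wilcoxon=wilcoxon, picks=picks, repeats=results)


def write_outputs(summary: ExperimentSummary, outdir: str | Path) -> None:
    """summary.json plus flat TSV tables (metrics, Wilcoxon, pick counts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(summary.to_json())
    with open(outdir / "metrics.tsv", "w") as fh:
        fh.write("method\tmetric\tmean\tsd\n")
        for method in sorted(summary.methods):
            for metric in METRIC_NAMES:
                v = summary.methods[method][metric]
                fh.write(f"{method}\t{metric}\t{v['mean']:.4f}\t{v['sd']:.4f}\n")
    with open(outdir / "wilcoxon.tsv", "w") as fh:
        fh.write("metric\tmember\tz\tp\n")
        for metric in summary.wilcoxon:
            for member, v in summary.wilcoxon[metric].items():
                fh.write(f"{metric}\t{member}\t{v['z']:.3f}\t{v['p']:.4f}\n")
    with open(outdir / "picks.tsv", "w") as fh:
        fh.write("feature\tpicked\n")
        for name, count in summary.picks.items():
            fh.write(f"{name}\t{count}\n")


# --------------------------------------------------------------------------
# Genetic-algorithm hyperparameter search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IntParam:
    low: int
    high: int


@dataclass(frozen=True)
class LogRealParam:
    low: float
    high: float


def _sample_param(p, rng: np.random.Generator):
    if isinstance(p, IntParam):
        return int(rng.integers(p.low, p.high + 1))
    return float(np.exp(rng.uniform(np.log(p.low), np.log(p.high))))


def _mutate_param(p, value, rng: np.random.Generator):
    if isinstance(p, IntParam):
        span = max(1, (p.high - p.low) // 10)
        return int(np.clip(value + rng.integers(-span, span + 1), p.low, p.high))
    return float(np.clip(value * np.exp(rng.normal(0.0, 0.3)), p.low, p.high))


def ga_optimize(space: dict, fitness: Callable[[dict], float],
                config: GaConfig = GaConfig()) -> tuple[dict, float, list[float]]:
    """Generational GA over a named parameter space.

    Tournament selection, uniform crossover applied to a ``crossover_fraction``
    of offspring, per-gene mutation, and elitism.  Returns the best genome,
    its fitness, and the best-fitness trajectory.  Deterministic per seed.
    """
    if not space:
        raise ValidationError("empty search space")
    rng = np.random.default_rng(config.seed)
    keys = sorted(space)
    pop = [{k: _sample_param(space[k], rng) for k in keys}
           for _ in range(config.population)]
    n_elite = max(1, math.ceil(config.elite_fraction * config.population))
    history: list[float] = []
    scores = np.array([fitness(g) for g in pop])
    for _ in range(config.generations):
        order = np.argsort(-scores, kind="stable")
        elites = [dict(pop[i]) for i in order[:n_elite]]
        children: list[dict] = []
        while len(children) < config.population - n_elite:
            def pick() -> dict:
                contenders = rng.integers(0, config.population, size=config.tournament)
                best = max(contenders, key=lambda i: (scores[i], -i))
                return dict(pop[best])
            child = pick()
            if rng.random() < config.crossover_fraction:
                other = pick()
                for k in keys:
                    if rng.random() < 0.5:
                        child[k] = other[k]
            for k in keys:
                if rng.random() < config.mutation_rate:
                    child[k] = _mutate_param(space[k], child[k], rng)
            children.append(child)
        pop = elites + children
        scores = np.array([fitness(g) for g in pop])
        history.append(float(scores.max()))
    best = int(np.argmax(scores))
    return pop[best], float(scores[best]), history


DEFAULT_TUNING_SPACE = {
    "rf.n_estimators": IntParam(10, 200),
    "svm.C": LogRealParam(1e-2, 1e2),
    "svm.gamma": LogRealParam(1e-3, 1e1),
    "knn.k": IntParam(1, 15),
    "elm.n_hidden": IntParam(5, 200),
}


def _genome_to_members(genome: dict, base: Sequence[MemberSpec]
                       ) -> tuple[MemberSpec, ...]:
    out = []
    for spec in base:
        hp = dict(spec.hyperparams)
        for key, value in genome.items():
            member, _, param = key.partition(".")
            if member == spec.name:
                hp[param] = value
        out.append(replace(spec, hyperparams=hp))
    return tuple(out)


def ga_tune(dataset: Dataset, config: ExperimentConfig,
            ga: GaConfig = GaConfig(), space: dict | None = None
            ) -> tuple[dict, float]:
    """Search member hyperparameters on one fixed split; the fitness is the
    validation ensemble E with all retained features."""
    space = space or DEFAULT_TUNING_SPACE
    seed = derive_seed(config.seed, 77_001)
    if config.preprocess_mode == "group":
        pre, _ = _preprocess_group(dataset, config)
        split = stratified_split(pre, config.fractions, seed=seed)
        train, val = pre.take(split.train), pre.take(split.validation)
    else:
        split = stratified_split(dataset, config.fractions, seed=seed)
        train, val, _test, _ = _preprocess_strict(dataset, split, config)
    cm = config.cost_matrix

    def fitness(genome: dict) -> float:
        specs = _genome_to_members(genome, config.members)
        members = _fit_members(specs, train.X, train.y, seed)
        ref = ((train.X, train.y) if config.weight_source == "train"
               else (val.X, val.y))
        w = compute_weights(_efficiencies(members, *ref, cm), cm).weights
        pred, _ = _ensemble_on(members, w, val.X)
        c = confusion(val.y, pred)
        return efficiency_index(c.accuracy, misclassification_cost(c, cm), cm)

    best, score, _ = ga_optimize(space, fitness, ga)
    return best, score
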