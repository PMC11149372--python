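"""The seven multi-ancestral learning experiments over one EUR + DDP dataset.

Experiment grid (training data / testing data):

=======  ===========================  =================
name     training                     testing
=======  ===========================  =================
Mix0     EUR + DDP                    EUR + DDP
Mix1     EUR + DDP (same model)       EUR only
Mix2     EUR + DDP (same model)       DDP only
Ind1     EUR                          EUR
Ind2     DDP                          DDP
NT       EUR (no adaptation)          DDP
TL       EUR pretrain, DDP adapt      DDP
=======  ===========================  =================

Mix0/Mix1/Mix2 share one trained model per run; Ind1, NT and the TL
pretraining stage share the EUR model of the same run, so the EUR-facing
results are bitwise independent of whether transfer learning is executed.
Each run reseeds model initialization and mini-batch order; the dataset
split is frozen across runs, making cross-experiment comparisons paired.

Dosages are standardized per population with mean/sd taken from that
population's training split (labels untouched). Population-wise scaling
removes the allele-frequency location shift between cohorts, which a
linear score is insensitive to (it only moves the intercept) but which
would otherwise scramble a ReLU network's activation pattern when an
EUR-trained net scores DDP individuals. The Youden threshold for the
threshold-dependent metrics is tuned on the validation split of the
evaluated population and applied to its test split.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .predictors import DNNConfig, TrainedPredictor, train_dnn, train_lr
from .synth_data import DatasetConfig, MultiAncestryDataset, derive_seed, generate_dataset
from .transfer import fine_tune_dnn, fit_linear_transfer

SCHEMES = ("Mix0", "Mix1", "Mix2", "Ind1", "Ind2", "NT", "TL")
MODEL_KINDS = ("LR", "DL")


@dataclass(frozen=True)
class SchemeSpec:
    scheme: str
    model_kind: str
    n_runs: int = 20
    seed: int = 0
    dnn_overrides: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class RunResults:
    scheme: str
    model_kind: str
    eval_population: str
    reports: list[_metrics.MetricReport]
    predictions: list[np.ndarray]
    seed: int

    @property
    def aurocs(self) -> np.ndarray:
        return np.array([r.auroc for r in self.reports])


class AuditedData:
    """Access-auditing wrapper: counts every label read by (population, split)."""

    def __init__(self, data: MultiAncestryDataset):
        self.data = data
        self.label_reads: Counter = Counter()
        pops = data.populations
        self.eur = "EUR"
        self.ddp = next(p for p in pops if p != "EUR")

    def features(self, population: str | None, split: str) -> np.ndarray:
        return self.data.X[self.data.mask(population, split)]

    def labels(self, population: str | None, split: str) -> np.ndarray:
        self.label_reads[(population or "ALL", split)] += 1
        return self.data.y[self.data.mask(population, split)]


def _standardize(train_X: np.ndarray):
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0)
    sd[sd == 0] = 1.0
    return lambda X: (np.asarray(X, dtype=float) - mu) / sd


def _per_population_scaler(ad: "AuditedData"):
    """Per-population standardizers fitted on each population's train split."""
    scalers = {
        pop: _standardize(ad.features(pop, "train"))
        for pop in (ad.eur, ad.ddp)
    }

    def scale(X: np.ndarray, ancestry: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape, dtype=float)
        for pop, fn in scalers.items():
            m = ancestry == pop
            if m.any():
                out[m] = fn(X[m])
        return out

    return scale


def _train(
    kind: str,
    X_tr, y_tr, X_val, y_val,
    seed: int,
    dnn_overrides: dict,
) -> TrainedPredictor:
    if kind == "LR":
        return train_lr(X_tr, y_tr, seed=seed)
    cfg = DNNConfig(seed=seed, **dnn_overrides)
    return train_dnn(X_tr, y_tr, X_val, y_val, config=cfg)


def run_experiments(
    data: MultiAncestryDataset,
    schemes: tuple[str, ...],
    model_kind: str,
    n_runs: int = 20,
    seed: int = 0,
    dnn_overrides: dict | None = None,
    audit: AuditedData | None = None,
) -> dict[str, RunResults]:
    """Run the requested experiments with shared per-run models.

    Per run r, the mixture model, the EUR model and the DDP model are each
    trained at most once and reused by every scheme that needs them. Model
    seeds depend only on (seed, model role, model kind, r) — never on which
    schemes were requested.
    """
    dnn_overrides = dnn_overrides or {}
    for s in schemes:
        if s not in SCHEMES:
            raise ValueError(f"unknown scheme {s!r}")
    ad = audit if audit is not None else AuditedData(data)
    eur, ddp = ad.eur, ad.ddp
    if any(not data.mask(p, "test").any() for p in (eur, ddp)):
        raise ValueError("a population has an empty test split")

    scale = _per_population_scaler(ad)

    def _features(pop: str | None, split: str) -> np.ndarray:
        m = data.mask(pop, split)
        return scale(data.X[m], data.ancestry[m])

    # features may be read freely; labels go through the audit
    def arrays(pop: str | None, split: str):
        return _features(pop, split), ad.labels(pop, split)

    eval_pop = {"Mix0": "ALL", "Mix1": eur, "Mix2": ddp, "Ind1": eur,
                "Ind2": ddp, "NT": ddp, "TL": ddp}
    out: dict[str, RunResults] = {
        s: RunResults(s, model_kind, eval_pop[s], [], [], seed) for s in schemes
    }

    need_mix = any(s in schemes for s in ("Mix0", "Mix1", "Mix2"))
    need_eur = any(s in schemes for s in ("Ind1", "NT", "TL"))
    need_ddp = "Ind2" in schemes
    need_tl = "TL" in schemes

    for r in range(n_runs):
        models: dict[str, TrainedPredictor] = {}
        if need_mix:
            X_tr, y_tr = arrays(None, "train")
            X_val, y_val = arrays(None, "validation")
            models["mix"] = _train(model_kind, X_tr, y_tr, X_val, y_val,
                                   derive_seed(seed, "mix", model_kind, r), dnn_overrides)
        if need_eur:
            X_tr, y_tr = arrays(eur, "train")
            X_val, y_val = arrays(eur, "validation")
            models["eur"] = _train(model_kind, X_tr, y_tr, X_val, y_val,
                                   derive_seed(seed, "eur", model_kind, r), dnn_overrides)
        if need_ddp:
            X_tr, y_tr = arrays(ddp, "train")
            X_val, y_val = arrays(ddp, "validation")
            models["ddp"] = _train(model_kind, X_tr, y_tr, X_val, y_val,
                                   derive_seed(seed, "ddp", model_kind, r), dnn_overrides)
        if need_tl:
            X_tr, y_tr = arrays(ddp, "train")
            X_val, y_val = arrays(ddp, "validation")
            if model_kind == "DL":
                cfg = DNNConfig(seed=derive_seed(seed, "tl", model_kind, r),
                                **dnn_overrides)
                models["tl"] = fine_tune_dnn(models["eur"], X_tr, y_tr, X_val, y_val, cfg)
            else:
                pre = models["eur"]
                tl = fit_linear_transfer(
                    beta_pre=pre.parameters["coef"],
                    gamma_pre=None,
                    X_target_train=X_tr,
                    y_target_train=y_tr,
                    intercept_pre=pre.parameters["intercept"],
                    X_target_val=X_val,
                    y_target_val=y_val,
                )
                models["tl"] = tl.as_predictor()

        model_for = {"Mix0": "mix", "Mix1": "mix", "Mix2": "mix",
                     "Ind1": "eur", "Ind2": "ddp", "NT": "eur", "TL": "tl"}
        for s in schemes:
            model = models[model_for[s]]
            pop = None if eval_pop[s] == "ALL" else eval_pop[s]
            X_val, y_val = arrays(pop, "validation")
            thr, _, _ = _metrics.youden_threshold(model.predict(X_val), y_val)
            X_te = _features(pop, "test")
            y_te = ad.labels(pop, "test")
            p = model.predict(X_te)
            out[s].reports.append(_metrics.metric_report(p, y_te, threshold=thr))
            out[s].predictions.append(p)
    return out


def run_scheme(data: MultiAncestryDataset, spec: SchemeSpec) -> RunResults:
    """Run a single experiment (retraining shared models as needed)."""
    res = run_experiments(
        data, (spec.scheme,), spec.model_kind, spec.n_runs, spec.seed,
        spec.dnn_overrides,
    )
    return res[spec.scheme]


def run_compendium(
    configs: list[DatasetConfig],
    schemes: tuple[str, ...] = SCHEMES,
    model_kinds: tuple[str, ...] = MODEL_KINDS,
    n_runs: int = 20,
    seed: int = 0,
    dnn_overrides: dict | None = None,
) -> pd.DataFrame:
    """Run the experiment grid over a list of dataset configs.

    Returns a tidy frame with one row per (dataset, scheme, model, run)
    carrying the full metric report of the evaluated population.
    """
    rows = []
    for cfg in configs:
        data = generate_dataset(cfg, derive_seed(seed, "data", cfg.name))
        for kind in model_kinds:
            results = run_experiments(
                data, schemes, kind, n_runs,
                derive_seed(seed, "runs", cfg.name), dnn_overrides,
            )
            for s, rr in results.items():
                for r, rep in enumerate(rr.reports):
                    rows.append({
                        "dataset": cfg.name, "ddp": cfg.ddp, "h2": cfg.h2,
                        "r": cfg.r, "rho": cfg.rho, "scheme": s, "model": kind,
                        "run": r, "population": rr.eval_population,
                        "auroc": rep.auroc, "aupr": rep.aupr,
                        "tjur_r2": rep.tjur_r2, "ppv": rep.ppv, "npv": rep.npv,
                        "sensitivity": rep.sensitivity,
                        "specificity": rep.specificity,
                    })
    return pd.DataFrame(rows)


def per_dataset_auroc_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset mean-AUROC table with 'LR, DL' cells per experiment."""
    mean = (results.groupby(["dataset", "ddp", "h2", "rho", "scheme", "model"])
            ["auroc"].mean().reset_index())
    piv = mean.pivot_table(index=["dataset", "ddp", "h2", "rho"],
                           columns=["scheme", "model"], values="auroc")
    cells = {}
    for s in SCHEMES:
        if (s, "LR") in piv.columns or (s, "DL") in piv.columns:
            lr = piv.get((s, "LR"))
            dl = piv.get((s, "DL"))
            cells[s] = [
                ", ".join(f"{v:.2f}" for v in vals if v is not None and not np.isnan(v))
                for vals in zip(
                    lr if lr is not None else [np.nan] * len(piv),
                    dl if dl is not None else [np.nan] * len(piv),
                )
            ]
    return pd.DataFrame(cells, index=piv.index).reset_index()


#: the compendium-level comparisons: (label, better, worse)
COMPARISONS = (
    ("Mix1_LR vs Mix2_LR", ("Mix1", "LR"), ("Mix2", "LR")),
    ("Mix1_DL vs Mix2_DL", ("Mix1", "DL"), ("Mix2", "DL")),
    ("Ind1_LR vs Ind2_LR", ("Ind1", "LR"), ("Ind2", "LR")),
    ("Ind1_DL vs Ind2_DL", ("Ind1", "DL"), ("Ind2", "DL")),
    ("TL_DL vs Mix2_DL", ("TL", "DL"), ("Mix2", "DL")),
    ("TL_DL vs Ind2_DL", ("TL", "DL"), ("Ind2", "DL")),
    ("TL_DL vs NT_DL", ("TL", "DL"), ("NT", "DL")),
    ("TL_LR vs Mix2_LR", ("TL", "LR"), ("Mix2", "LR")),
    ("TL_LR vs Ind2_LR", ("TL", "LR"), ("Ind2", "LR")),
    ("TL_LR vs NT_LR", ("TL", "LR"), ("NT", "LR")),
    ("TL_DL vs TL_LR", ("TL", "DL"), ("TL", "LR")),
)


def scheme_comparison_table(results: pd.DataFrame) -> pd.DataFrame:
    """Compendium-level mean-AUROC differences with signed-rank p-values.

    For each comparison the per-(dataset, run) AUROC difference is averaged
    over the whole compendium; significance is a one-sided Wilcoxon
    signed-rank test across the matched dataset/run pairs.
    """
    piv = results.pivot_table(index=["dataset", "run"],
                              columns=["scheme", "model"], values="auroc")
    rows = []
    for label, hi, lo in COMPARISONS:
        if hi not in piv.columns or lo not in piv.columns:
            continue
        diff = (piv[hi] - piv[lo]).dropna().to_numpy()
        rows.append({
            "comparison": label,
            "mean_difference": float(diff.mean()),
            "p_value": _metrics.signed_rank_test(diff),
        })
    return pd.DataFrame(rows)
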