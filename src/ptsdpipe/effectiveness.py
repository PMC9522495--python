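"""Therapy-effectiveness evaluation and end-to-end pipeline orchestration.

Two comparisons are implemented.  First, model-versus-expert agreement:
the trained GA-BP network's severity predictions are compared against a
reference ("psychologist") evaluation with MAE, RMSE, Pearson
correlation, and maximum deviation.  Second, pre/post change in the
T1-T9 indicator panel: per-index means before and after therapy, the
mean change (post minus pre; all nine indices score symptoms or burden,
so negative change is improvement), and a two-sided paired t-test.

:func:`run_pipeline` chains the whole analysis — simulate a cohort,
score the checklist, train the GA-BP evaluator, fit the risk-factor
regression, summarise pre/post panels — and writes every artifact plus
a machine-readable manifest (seeds, parameters, file hashes) from which
a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .ga_bp import (
    GAConfig,
    NetworkConfig,
    Normalizer,
    forward,
    init_params,
    save_model,
    train_bp,
    train_ga_bp,
)
from .pclc import score_frame
from .risk_logistic import design_from_cohort, fit_logistic, summarize
from .synthetic_cohort import (
    INDICATOR_LABELS,
    CohortConfig,
    IndicatorPanel,
    generate_dbt_panels,
    panels_to_frame,
    simulate_cohort_frame,
)

__all__ = [
    "EvaluationPair",
    "AgreementMetrics",
    "agreement_metrics",
    "prepost_summary",
    "PipelineConfig",
    "run_pipeline",
]

#: Default focus indices: the three top-level instruments of the panel
#: (PANSS total, SSSI, SQLS).
DEFAULT_FOCUS_INDICES = ("T1", "T5", "T6")


@dataclass(frozen=True)
class EvaluationPair:
    """One case scored by both the model and the expert, on a common scale."""

    case_id: int
    model_score: float
    expert_score: float


@dataclass(frozen=True)
class AgreementMetrics:
    mae: float
    rmse: float
    pearson_r: float | None  # None when either score vector is constant
    max_deviation: float
    n: int


def agreement_metrics(pairs: Sequence[EvaluationPair]) -> AgreementMetrics:
    """Agreement between model output and expert evaluation.

    MAE <= RMSE <= max deviation always holds.  Pearson correlation is
    undefined (reported as None) when either vector is constant, which
    includes the perfect-agreement-on-a-constant case.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 evaluation pairs")
    model = np.array([p.model_score for p in pairs], dtype=float)
    expert = np.array([p.expert_score for p in pairs], dtype=float)
    if not (np.isfinite(model).all() and np.isfinite(expert).all()):
        raise ValueError("scores must be finite")
    dev = np.abs(model - expert)
    if np.ptp(model) == 0 or np.ptp(expert) == 0:
        r = None
    else:
        r = float(np.corrcoef(model, expert)[0, 1])
    return AgreementMetrics(
        mae=float(dev.mean()),
        rmse=float(np.sqrt((dev**2).mean())),
        pearson_r=r,
        max_deviation=float(dev.max()),
        n=len(pairs),
    )


class PanelPairingError(ValueError):
    """A patient lacks a matched pre/post panel pair."""


def _pair_panels(
    panels: Iterable[IndicatorPanel],
) -> dict[int, tuple[IndicatorPanel, IndicatorPanel]]:
    by_patient: dict[int, dict[str, IndicatorPanel]] = {}
    for p in panels:
        slot = by_patient.setdefault(p.patient_id, {})
        if p.phase in slot:
            raise PanelPairingError(
                f"patient {p.patient_id} has duplicate {p.phase} panels"
            )
        slot[p.phase] = p
    unmatched = sorted(pid for pid, s in by_patient.items() if len(s) != 2)
    if unmatched:
        raise PanelPairingError(f"patients without matched pre/post pairs: {unmatched}")
    return {pid: (s["pre"], s["post"]) for pid, s in by_patient.items()}


def prepost_summary(
    panels: Iterable[IndicatorPanel],
    indices: Sequence[str] = DEFAULT_FOCUS_INDICES,
) -> pd.DataFrame:
    """Per-index pre/post means, mean change, and a paired two-sided t-test.

    ``mean_change`` is post minus pre, so negative values indicate
    symptom improvement on every index.  With zero change in every
    patient the t statistic is 0/0; it and its p-value are reported as
    NaN (no-change sentinel).
    """
    pairs = _pair_panels(panels)
    unknown = set(indices) - set(INDICATOR_LABELS)
    if unknown:
        raise ValueError(f"unknown indices: {sorted(unknown)}")
    rows = []
    for t in indices:
        pre = np.array([p.values[t] for p, _ in pairs.values()])
        post = np.array([q.values[t] for _, q in pairs.values()])
        diff = post - pre
        n = len(diff)
        sd = diff.std(ddof=1) if n > 1 else math.nan
        if n > 1 and sd > 0:
            t_stat, p_val = stats.ttest_rel(post, pre)
            t_stat, p_val = float(t_stat), float(p_val)
        else:
            t_stat, p_val = math.nan, math.nan
        rows.append(
            {
                "index": t,
                "pre_mean": pre.mean(),
                "post_mean": post.mean(),
                "mean_change": diff.mean(),
                "change_sd": sd,
                "paired_t": t_stat,
                "p_value": p_val,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of one end-to-end run.

    The GA-BP evaluator is trained to predict the normalised checklist
    total from the 17 item responses; the held-out fraction of the
    scored cohort provides the model-versus-expert comparison, where the
    observed total plays the expert role.
    """

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    net: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(
            n_input=17, n_hidden=12, n_output=1, learning_rate=0.14, max_epochs=200
        )
    )
    ga: GAConfig = field(default_factory=GAConfig)
    optimizer: str = "ga_bp"  # "ga_bp" or "bp"
    holdout_fraction: float = 0.2
    n_patients: int = 10
    focus_indices: tuple[str, ...] = DEFAULT_FOCUS_INDICES

    def __post_init__(self) -> None:
        if self.optimizer not in ("ga_bp", "bp"):
            raise ValueError("optimizer must be 'ga_bp' or 'bp'")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute simulate -> score -> train -> risk table -> effectiveness.

    Writes cohort.csv, scored.csv, model.json, agreement.json,
    risk_table.csv, panels.csv, prepost.csv and manifest.json under
    ``out_dir`` and returns the manifest.  Identical config and seed give
    identical artifacts (the manifest records their SHA-256 digests).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        cohort = simulate_cohort_frame(cohort_cfg)
        cohort.to_csv(out / "cohort.csv", index=False)

        stage = "score"
        scored = score_frame(cohort)
        scored.to_csv(out / "scored.csv", index=False)

        stage = "train"
        scored = scored.copy()
        scored["age"] = scored["age_band"].map(
            lambda b: np.nan if pd.isna(b) else float(b == "18-25")
        )
        scored = scored.dropna(
            subset=["gender", "age", "event_role", "exposure_time", "parent_died"]
        ).reset_index(drop=True)
        feat_cols = [f"item_{k:02d}" for k in range(1, 18)]
        item_norm = Normalizer(1.0, 5.0)  # item codes onto [-1, 1]
        x = item_norm.transform(scored.loc[:, feat_cols].to_numpy(dtype=float))
        y_norm = Normalizer(17.0, 85.0, (0.0, 1.0))
        y = y_norm.transform(scored["total"].to_numpy(dtype=float))[:, None]

        n_hold = max(2, int(round(config.holdout_fraction * len(x))))
        split_rng = np.random.default_rng(config.seed)
        order = split_rng.permutation(len(x))
        test_idx, train_idx = order[:n_hold], order[n_hold:]
        ga_cfg = dataclasses.replace(config.ga, seed=config.seed)
        if config.optimizer == "ga_bp":
            params, ga_trace, bp_trace = train_ga_bp(
                ga_cfg, config.net, x[train_idx], y[train_idx]
            )
        else:
            params0 = init_params(config.net, np.random.default_rng(config.seed))
            params, bp_trace = train_bp(params0, config.net, x[train_idx], y[train_idx])
            ga_trace = []
        save_model(str(out / "model.json"), params, config.net, ga_trace, bp_trace)

        stage = "agreement"
        pred, _ = forward(params, config.net, x[test_idx])
        pairs = [
            EvaluationPair(
                case_id=int(scored["id"].iloc[i]),
                model_score=float(y_norm.inverse(pred[r, 0])),
                expert_score=float(scored["total"].iloc[i]),
            )
            for r, i in enumerate(test_idx)
        ]
        metrics = agreement_metrics(pairs)
        (out / "agreement.json").write_text(
            json.dumps(dataclasses.asdict(metrics), indent=1)
        )

        stage = "risk"
        design = design_from_cohort(scored, outcome="screen_positive")
        risk_table = summarize(fit_logistic(design))
        risk_table.to_csv(out / "risk_table.csv", index=False)

        stage = "panels"
        panels = generate_dbt_panels(n_patients=config.n_patients, seed=config.seed)
        panels_to_frame(panels).to_csv(out / "panels.csv", index=False)
        prepost = prepost_summary(panels, config.focus_indices)
        prepost.to_csv(out / "prepost.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    artifacts = [
        "cohort.csv",
        "scored.csv",
        "model.json",
        "agreement.json",
        "risk_table.csv",
        "panels.csv",
        "prepost.csv",
    ]
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "optimizer": config.optimizer,
        "n_patients": config.n_patients,
        "focus_indices": list(config.focus_indices),
        "net": {
            "n_input": config.net.n_input,
            "n_hidden": config.net.n_hidden,
            "n_output": config.net.n_output,
            "learning_rate": config.net.learning_rate,
            "max_epochs": config.net.max_epochs,
        },
        "ga": {
            "population_size": config.ga.population_size,
            "crossover_prob": config.ga.crossover_prob,
            "mutation_prob": config.ga.mutation_prob,
            "max_generations": config.ga.max_generations,
        },
        "cohort": {
            "n_total": config.cohort.n_total,
            "n_valid": config.cohort.n_valid,
        },
        "agreement": dataclasses.asdict(metrics),
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
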