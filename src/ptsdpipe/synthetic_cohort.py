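"""Synthetic survey cohorts and therapy indicator panels.

The generator emulates a campus PTSD screening survey: 596 questionnaires
of which 488 are complete ("valid"), with fixed demographic margins
(200 male / 288 female; 475 aged 18-25, 10 aged 25-30, 3 over 30; 485
with traumatic-event exposure).  Each valid respondent carries a latent
PTSD probability given by a logistic model on five covariates, a binary
PTSD status drawn from that probability, and 17 ordinal questionnaire
items (1-5) linked to the latent probability through an ordered-threshold
rule.  Margins are imposed by stratified assignment, so the configured
counts are reproduced exactly, not just in expectation.

Covariate coding (configurable, defaults documented here):

* ``gender``       1 = male, 0 = female.  A negative coefficient then
  means men are at lower risk, consistent with women being the more
  susceptible group.
* ``age``          1 = aged 18-25, 0 = older.
* ``event_role``   ordinal 0/1/2 (bystander / witness / directly involved).
* ``exposure_time`` non-negative continuous, log-normal by default; the
  time unit is abstract.
* ``parent_died``  1 = both parents alive, 0 = one or both parents died.
  The "alive" coding makes a negative coefficient mean bereavement raises
  risk.

A second module (:mod:`ptsdpipe.effectiveness`) consumes the pre/post
indicator panels produced here; the panel index system T1-T9 covers the
PANSS total and subscales, SSSI, and SQLS plus three stigma domains.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "INDICATOR_LABELS",
    "CohortConfig",
    "CohortConfigError",
    "Respondent",
    "IndicatorPanel",
    "RiskCoefficients",
    "generate_cohort",
    "simulate_cohort_frame",
    "generate_item_responses",
    "generate_dbt_panels",
    "apply_validity_filter",
    "cohort_to_frame",
    "frame_to_respondents",
    "panels_to_frame",
    "frame_to_panels",
]

N_ITEMS = 17

#: Labels of the therapy-effectiveness index system.
INDICATOR_LABELS = ("T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9")

#: Ordered thresholds carrying a latent severity in [0, 1] to item codes 1-5.
ITEM_THRESHOLDS = (0.2, 0.4, 0.6, 0.8)

#: Default latent item noise (standard deviation on the [0, 1] severity scale).
DEFAULT_ITEM_NOISE = 0.15

#: Default person-level severity noise, shared across a respondent's items.
#: Item noise alone averages out over 17 items, which would make screen
#: positivity a near-deterministic cut on the latent probability; the
#: person-level term models symptom variation not captured by covariates.
DEFAULT_PERSON_NOISE = 0.25

AGE_BANDS = ("18-25", "25-30", ">30")

COVARIATE_COLUMNS = ("gender", "age", "event_role", "exposure_time", "parent_died")


class CohortConfigError(ValueError):
    """Raised when cohort margins are inconsistent; names the offending field."""


@dataclass(frozen=True)
class RiskCoefficients:
    """Logistic coefficients of the latent PTSD model (log-odds scale).

    Slope defaults follow the risk-factor table of the emulated study;
    the intercept is not reported there and defaults to 1.5, which puts
    the synthetic screen-positive prevalence near one quarter.
    """

    intercept: float = 1.5
    gender: float = -0.831
    age: float = -1.243
    event_role: float = 0.117
    exposure_time: float = 0.519
    parent_died: float = -1.968

    def slopes(self) -> dict[str, float]:
        return {
            "gender": self.gender,
            "age": self.age,
            "event_role": self.event_role,
            "exposure_time": self.exposure_time,
            "parent_died": self.parent_died,
        }

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(covariates), self.intercept, dtype=float)
        for name, beta in self.slopes().items():
            eta += beta * covariates[name].to_numpy(dtype=float)
        return eta


@dataclass(frozen=True)
class CohortConfig:
    """Margins and model parameters of a synthetic survey cohort."""

    n_total: int = 596
    n_valid: int = 488
    n_male: int = 200
    n_female: int = 288
    age_band_counts: tuple[int, int, int] = (475, 10, 3)
    trauma_exposed: int = 485
    risk_coefficients: RiskCoefficients = field(default_factory=RiskCoefficients)
    #: (meanlog, sdlog) of the log-normal exposure-time distribution.
    exposure_lognormal: tuple[float, float] = (0.0, 0.5)
    #: Probability that both parents are alive.
    parents_alive_prob: float = 0.95
    item_noise_sd: float = DEFAULT_ITEM_NOISE
    person_noise_sd: float = DEFAULT_PERSON_NOISE
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_total": self.n_total,
            "n_valid": self.n_valid,
            "n_male": self.n_male,
            "n_female": self.n_female,
            "trauma_exposed": self.trauma_exposed,
        }
        for name, value in counts.items():
            if value < 0:
                raise CohortConfigError(f"{name} must be non-negative, got {value}")
        if any(c < 0 for c in self.age_band_counts):
            raise CohortConfigError("age_band_counts must be non-negative")
        if self.n_valid > self.n_total:
            raise CohortConfigError(
                f"n_valid ({self.n_valid}) exceeds n_total ({self.n_total})"
            )
        if self.n_male + self.n_female != self.n_valid:
            raise CohortConfigError(
                "gender_split: n_male + n_female "
                f"({self.n_male}+{self.n_female}) must equal n_valid ({self.n_valid})"
            )
        if sum(self.age_band_counts) != self.n_valid:
            raise CohortConfigError(
                f"age_band_counts {self.age_band_counts} must sum to n_valid "
                f"({self.n_valid})"
            )
        if self.trauma_exposed > self.n_valid:
            raise CohortConfigError(
                f"trauma_exposed ({self.trauma_exposed}) exceeds n_valid "
                f"({self.n_valid})"
            )
        if not 0.0 <= self.parents_alive_prob <= 1.0:
            raise CohortConfigError("parents_alive_prob must be in [0, 1]")
        if self.item_noise_sd < 0:
            raise CohortConfigError("item_noise_sd must be non-negative")
        if self.person_noise_sd < 0:
            raise CohortConfigError("person_noise_sd must be non-negative")

    def with_size(self, n: int) -> "CohortConfig":
        """Rescale all margins proportionally to a fully valid cohort of ``n``.

        Used by large parameter-recovery simulations; the largest-remainder
        rule keeps the scaled counts summing exactly to ``n``.
        """
        male = round(self.n_male / self.n_valid * n)
        ages_raw = [c / self.n_valid * n for c in self.age_band_counts]
        ages = [int(a) for a in ages_raw]
        # distribute the rounding remainder to the largest fractional parts
        rem = n - sum(ages)
        order = np.argsort([a - int(a) for a in ages_raw])[::-1]
        for idx in order[:rem]:
            ages[idx] += 1
        return dataclasses.replace(
            self,
            n_total=n,
            n_valid=n,
            n_male=male,
            n_female=n - male,
            age_band_counts=tuple(ages),
            trauma_exposed=round(self.trauma_exposed / self.n_valid * n),
        )


@dataclass
class Respondent:
    """One survey record; missing entries are ``None`` (incomplete form)."""

    id: int
    gender: int | None
    age_band: str | None
    parent_died: int | None
    event_role: int | None
    exposure_time: float | None
    trauma_exposed: bool | None
    valid: bool
    latent_ptsd_prob: float
    ptsd_positive: int
    items: list[int | None]

    def is_complete(self) -> bool:
        covs = (
            self.gender,
            self.age_band,
            self.parent_died,
            self.event_role,
            self.exposure_time,
            self.trauma_exposed,
        )
        return all(v is not None for v in covs) and all(
            it is not None for it in self.items
        )


@dataclass
class IndicatorPanel:
    """Per-patient indicator values at one phase of therapy."""

    patient_id: int
    phase: str  # "pre" or "post"
    values: dict[str, float]

    def __post_init__(self) -> None:
        if self.phase not in ("pre", "post"):
            raise ValueError(f"phase must be 'pre' or 'post', got {self.phase!r}")
        if set(self.values) != set(INDICATOR_LABELS):
            raise ValueError(
                f"panel keys must be exactly {INDICATOR_LABELS}, got "
                f"{sorted(self.values)}"
            )


# ---------------------------------------------------------------------------
# item link


def _items_from_severity(
    severity: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Ordered-threshold link: latent severity plus Gaussian noise cut at
    fixed thresholds gives item codes 1-5.  Vectorised over (n, 17)."""
    z = severity[:, None] + noise_sd * rng.standard_normal((severity.size, N_ITEMS))
    cuts = np.asarray(ITEM_THRESHOLDS)
    return 1 + (z[:, :, None] > cuts[None, None, :]).sum(axis=2)


def generate_item_responses(
    p: float,
    rng: np.random.Generator,
    noise_sd: float = DEFAULT_ITEM_NOISE,
    person_sd: float = DEFAULT_PERSON_NOISE,
) -> list[int]:
    """Draw one 17-item response vector for latent PTSD probability ``p``.

    The respondent's latent severity is ``p`` plus one person-level
    Gaussian draw (sd ``person_sd``); each item adds independent noise
    (sd ``noise_sd``) and is cut at thresholds 0.2/0.4/0.6/0.8 into codes
    1-5.  With both noises zero, p=0 gives all-1 items (total 17) and
    p=1 all-5 (total 85); the expected total is non-decreasing in ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if noise_sd < 0 or person_sd < 0:
        raise ValueError("noise standard deviations must be non-negative")
    severity = float(p) + person_sd * rng.standard_normal()
    items = _items_from_severity(np.array([severity]), noise_sd, rng)
    return [int(v) for v in items[0]]


# ---------------------------------------------------------------------------
# cohort generation


def _exact_margin_vector(counts: Sequence[int], codes: Sequence, rng) -> np.ndarray:
    out = np.concatenate([np.full(c, code) for c, code in zip(counts, codes)])
    rng.shuffle(out)
    return out


def simulate_cohort_frame(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    include_items: bool = True,
) -> pd.DataFrame:
    """Vectorised cohort draw as a DataFrame (one row per respondent).

    Valid respondents meet the configured gender/age/trauma margins
    exactly; invalid ones are complete draws with one field knocked out
    to missing.  Column layout matches the cohort CSV schema.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, nv = config.n_total, config.n_valid

    gender = _exact_margin_vector(
        (config.n_male, config.n_female), (1, 0), rng
    ).astype(float)
    age_code = _exact_margin_vector(config.age_band_counts, (0, 1, 2), rng).astype(
        float
    )
    exposed = _exact_margin_vector(
        (config.trauma_exposed, nv - config.trauma_exposed), (1, 0), rng
    ).astype(float)

    # pad the invalid tail with unconstrained draws of the same laws
    n_inv = n - nv
    if n_inv:
        gender = np.concatenate(
            [gender, (rng.random(n_inv) < config.n_male / nv).astype(float)]
        )
        age_code = np.concatenate(
            [
                age_code,
                rng.choice(
                    3, size=n_inv, p=np.asarray(config.age_band_counts) / nv
                ).astype(float),
            ]
        )
        exposed = np.concatenate(
            [exposed, (rng.random(n_inv) < config.trauma_exposed / nv).astype(float)]
        )

    parents_alive = (rng.random(n) < config.parents_alive_prob).astype(float)
    event_role = np.where(exposed > 0, rng.integers(0, 3, size=n), 0).astype(float)
    meanlog, sdlog = config.exposure_lognormal
    exposure_time = np.where(exposed > 0, rng.lognormal(meanlog, sdlog, size=n), 0.0)

    covs = pd.DataFrame(
        {
            "gender": gender,
            "age": (age_code == 0).astype(float),  # indicator: aged 18-25
            "event_role": event_role,
            "exposure_time": exposure_time,
            "parent_died": parents_alive,  # coded 1 = parents alive
        }
    )
    prob = expit(config.risk_coefficients.linear_predictor(covs))
    positive = (rng.random(n) < prob).astype(int)

    frame = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "gender": gender,
            "age_band": [AGE_BANDS[int(c)] for c in age_code],
            "parent_died": parents_alive,
            "event_role": event_role,
            "exposure_time": exposure_time,
            "trauma_exposed": exposed.astype(bool),
            "valid": np.arange(n) < nv,
            "latent_ptsd_prob": prob,
            "ptsd_positive": positive,
        }
    )

    if include_items:
        severity = prob + config.person_noise_sd * rng.standard_normal(n)
        items = _items_from_severity(severity, config.item_noise_sd, rng).astype(float)
    else:
        items = np.full((n, N_ITEMS), np.nan)
    for k in range(N_ITEMS):
        frame[f"item_{k + 1:02d}"] = items[:, k]

    # knock one field out of each invalid record so the validity filter
    # (completeness of all items and covariates) rejects exactly them
    if n_inv:
        knockable = [f"item_{k + 1:02d}" for k in range(N_ITEMS)] if include_items else []
        knockable += ["gender", "age_band", "event_role", "exposure_time"]
        for row in range(nv, n):
            col = knockable[rng.integers(len(knockable))]
            frame.loc[row, col] = None if col == "age_band" else np.nan

    # shuffle row order so validity is not positional, then renumber ids
    perm = rng.permutation(n)
    frame = frame.iloc[perm].reset_index(drop=True)
    frame["id"] = np.arange(1, n + 1)
    return frame


def frame_to_respondents(frame: pd.DataFrame) -> list[Respondent]:
    def _opt(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    out = []
    for row in frame.itertuples(index=False):
        items = [
            None if np.isnan(v) else int(v)
            for v in (getattr(row, f"item_{k + 1:02d}") for k in range(N_ITEMS))
        ]
        gender = _opt(row.gender)
        role = _opt(row.event_role)
        out.append(
            Respondent(
                id=int(row.id),
                gender=None if gender is None else int(gender),
                age_band=_opt(row.age_band),
                parent_died=None if _opt(row.parent_died) is None else int(row.parent_died),
                event_role=None if role is None else int(role),
                exposure_time=_opt(row.exposure_time),
                trauma_exposed=None if _opt(row.trauma_exposed) is None else bool(row.trauma_exposed),
                valid=bool(row.valid),
                latent_ptsd_prob=float(row.latent_ptsd_prob),
                ptsd_positive=int(row.ptsd_positive),
                items=items,
            )
        )
    return out


def cohort_to_frame(respondents: Iterable[Respondent]) -> pd.DataFrame:
    rows = []
    for r in respondents:
        row = {
            "id": r.id,
            "gender": np.nan if r.gender is None else r.gender,
            "age_band": r.age_band,
            "parent_died": np.nan if r.parent_died is None else r.parent_died,
            "event_role": np.nan if r.event_role is None else r.event_role,
            "exposure_time": np.nan if r.exposure_time is None else r.exposure_time,
            "trauma_exposed": r.trauma_exposed,
            "valid": r.valid,
            "latent_ptsd_prob": r.latent_ptsd_prob,
            "ptsd_positive": r.ptsd_positive,
        }
        for k, item in enumerate(r.items):
            row[f"item_{k + 1:02d}"] = np.nan if item is None else item
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig, include_items: bool = True) -> list[Respondent]:
    """Generate the full synthetic cohort as :class:`Respondent` records.

    Exactly ``config.n_total`` records are returned, of which exactly
    ``config.n_valid`` are complete; the valid subset reproduces the
    configured gender, age-band, and trauma-exposure margins exactly.
    Identical seeds give identical cohorts.
    """
    frame = simulate_cohort_frame(config, include_items=include_items)
    return frame_to_respondents(frame)


def apply_validity_filter(
    records: Iterable[Respondent],
) -> tuple[list[Respondent], list[Respondent]]:
    """Partition records into (valid, rejected) by completeness.

    A record is valid iff none of its 17 items and none of its covariates
    is missing.  The partition is exhaustive and disjoint.
    """
    valid: list[Respondent] = []
    rejected: list[Respondent] = []
    for r in records:
        (valid if r.is_complete() else rejected).append(r)
    return valid, rejected


# ---------------------------------------------------------------------------
# pre/post therapy panels

#: Default pre-therapy panel means.  T1 is a PANSS total with T2-T4 its
#: positive / negative / general-psychopathology subscales; T5 is the SSSI,
#: T6 the SQLS, and T7-T9 social / ability / treatment stigma scores.
DEFAULT_PRE_MEANS = {
    "T1": 76.0,
    "T2": 18.0,
    "T3": 20.0,
    "T4": 38.0,
    "T5": 30.0,
    "T6": 60.0,
    "T7": 15.0,
    "T8": 12.0,
    "T9": 10.0,
}

#: Default post-therapy shift (negative = improvement on all nine indices).
DEFAULT_POST_SHIFT = {
    "T1": -12.0,
    "T2": -4.0,
    "T3": -3.0,
    "T4": -5.0,
    "T5": -8.0,
    "T6": -10.0,
    "T7": -4.0,
    "T8": -3.0,
    "T9": -2.0,
}

DEFAULT_PANEL_NOISE = {label: 2.0 for label in INDICATOR_LABELS}


def generate_dbt_panels(
    n_patients: int = 10,
    pre_means: dict[str, float] | None = None,
    post_shift: dict[str, float] | None = None,
    noise_sd: dict[str, float] | None = None,
    seed: int = 0,
) -> list[IndicatorPanel]:
    """Simulate matched pre/post indicator panels for ``n_patients``.

    Each patient's pre panel is the configured mean plus Gaussian noise;
    the post panel is that patient's pre value plus the configured shift
    plus fresh noise.  Returns 2*n_patients panels (one pre and one post
    per patient); identical seeds give identical panels.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    pre_means = dict(DEFAULT_PRE_MEANS if pre_means is None else pre_means)
    post_shift = dict(DEFAULT_POST_SHIFT if post_shift is None else post_shift)
    noise_sd = dict(DEFAULT_PANEL_NOISE if noise_sd is None else noise_sd)
    for d, name in ((pre_means, "pre_means"), (post_shift, "post_shift"), (noise_sd, "noise_sd")):
        if set(d) != set(INDICATOR_LABELS):
            raise ValueError(f"{name} must be indexed by exactly {INDICATOR_LABELS}")
    if any(sd < 0 for sd in noise_sd.values()):
        raise ValueError("noise_sd values must be non-negative")

    rng = np.random.default_rng(seed)
    panels: list[IndicatorPanel] = []
    for pid in range(1, n_patients + 1):
        pre = {
            t: pre_means[t] + noise_sd[t] * rng.standard_normal()
            for t in INDICATOR_LABELS
        }
        post = {
            t: pre[t] + post_shift[t] + noise_sd[t] * rng.standard_normal()
            for t in INDICATOR_LABELS
        }
        panels.append(IndicatorPanel(pid, "pre", pre))
        panels.append(IndicatorPanel(pid, "post", post))
    return panels


def panels_to_frame(panels: Iterable[IndicatorPanel]) -> pd.DataFrame:
    rows = [
        {"patient_id": p.patient_id, "phase": p.phase, **p.values} for p in panels
    ]
    return pd.DataFrame(rows, columns=["patient_id", "phase", *INDICATOR_LABELS])


def frame_to_panels(frame: pd.DataFrame) -> list[IndicatorPanel]:
    return [
        IndicatorPanel(
            int(row.patient_id),
            str(row.phase),
            {t: float(getattr(row, t)) for t in INDICATOR_LABELS},
        )
        for row in frame.itertuples(index=False)
    ]
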