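"""Synthetic observers and panels with the statistical structure the
analysis assumes.

Every stage of the toolkit can be exercised without human data:

* detection: observers carry a latent psychometric function in log10
  concentration — a cumulative-normal rise from the 1-in-3 guessing rate,
  with a small lapse rate — and answer 3-AFC triads through it;
* discrimination: 2-AFC panels are drawn from a true Thurstonian d' by
  inverting pc = Phi(d'/sqrt(2));
* ratings: 0-100 intensity scores increase with fat level (log-compressed),
  carry additive modality offsets and subject effects, and are truncated to
  the scale.

All generators are pure functions of their parameters and an explicit
NumPy random generator (or integer seed): identical inputs give identical
outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .concentrations import DilutionSeries
from .staircase import StaircaseConfig, TrialLog, run_staircase

__all__ = [
    "SyntheticObserver",
    "CohortSpec",
    "RatingEffects",
    "p_correct",
    "make_responder",
    "sample_cohort",
    "simulate_threshold_study",
    "simulate_2afc_panel",
    "simulate_ratings",
    "simulate_covariates",
]

_SQRT2 = math.sqrt(2.0)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class SyntheticObserver:
    """Latent psychometric parameters of one simulated assessor.

    ``mu`` is the location of the psychometric function (log10 mM), i.e. the
    concentration at which detection is halfway between chance and certain;
    ``sigma`` its slope parameter in log10 units; ``lapse`` a small
    probability of an attention lapse on any trial (answered at chance).
    """

    participant_id: str
    mu: float
    sigma: float = 0.25
    guess_rate: float = 1.0 / 3.0
    lapse: float = 0.01

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must lie in [0, 0.1]")


def p_correct(observer: SyntheticObserver, mM: float, link: str = "probit") -> float:
    """Probability of a correct forced-choice answer at a concentration.

    p(c) = (1 - lapse) * [g + (1 - g) * F((log10 c - mu)/sigma)] + lapse * g,
    with F the standard normal CDF (``probit``, default) or the logistic
    CDF (``logit``).  Lapses are answered at the guessing rate.
    """
    if mM <= 0:
        raise ValueError("concentration must be positive")
    x = (math.log10(mM) - observer.mu) / observer.sigma
    if link == "probit":
        base = stats.norm.cdf(x)
    elif link == "logit":
        base = 1.0 / (1.0 + math.exp(-x))
    else:
        raise ValueError(f"unknown link {link!r}")
    g = observer.guess_rate
    p = g + (1.0 - g) * base
    return float((1.0 - observer.lapse) * p + observer.lapse * g)


def make_responder(
    observer: SyntheticObserver,
    series: DilutionSeries,
    rng: np.random.Generator | int | None,
    link: str = "probit",
) -> Callable[[int], bool]:
    """Response oracle mapping a ladder level index to correct/incorrect."""
    rng = _as_rng(rng)
    probs = [p_correct(observer, float(c), link=link) for c in series.mM]

    def respond(level_index: int) -> bool:
        return bool(rng.random() < probs[level_index])

    return respond


def respond_3afc(
    observer: SyntheticObserver, mM: float, rng: np.random.Generator | int | None
) -> bool:
    """Single 3-AFC response at an arbitrary concentration."""
    return bool(_as_rng(rng).random() < p_correct(observer, mM))


@dataclass(frozen=True)
class CohortSpec:
    """Population model for a simulated detection-threshold cohort.

    ``mu_dist`` controls where latent thresholds sit on the ladder:

    * ``uniform_middle`` (default): uniform over the log-concentration span
      of the middle six ladder levels — thresholds comfortably inside the
      measurable range;
    * ``uniform``: uniform over ``mu_range`` (log10 mM);
    * ``normal``: normal with ``mu_range = (mean, sd)`` (log10 mM).
    """

    n_observers: int
    series: DilutionSeries
    mu_dist: str = "uniform_middle"
    mu_range: tuple[float, float] | None = None
    sigma: float = 0.25
    lapse: float = 0.01
    guess_rate: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        if self.mu_dist not in ("uniform_middle", "uniform", "normal"):
            raise ValueError(f"unknown mu_dist {self.mu_dist!r}")
        if self.mu_dist in ("uniform", "normal") and self.mu_range is None:
            raise ValueError(f"mu_dist {self.mu_dist!r} requires mu_range")


def sample_cohort(
    spec: CohortSpec, rng: np.random.Generator | int | None
) -> list[SyntheticObserver]:
    """Draw a cohort of synthetic observers from a population spec."""
    rng = _as_rng(rng)
    logs = spec.series.log10_mM
    if spec.mu_dist == "uniform_middle":
        start = max((spec.series.n_levels - 6) // 2, 0)
        stop = min(start + 5, spec.series.n_levels - 1)
        lo, hi = float(logs[start]), float(logs[stop])
        mus = rng.uniform(lo, hi, size=spec.n_observers)
    elif spec.mu_dist == "uniform":
        mus = rng.uniform(*spec.mu_range, size=spec.n_observers)
    else:
        mus = rng.normal(spec.mu_range[0], spec.mu_range[1], size=spec.n_observers)
    width = max(len(str(spec.n_observers)), 2)
    return [
        SyntheticObserver(
            participant_id=f"P{i + 1:0{width}d}",
            mu=float(m),
            sigma=spec.sigma,
            guess_rate=spec.guess_rate,
            lapse=spec.lapse,
        )
        for i, m in enumerate(mus)
    ]


def simulate_threshold_study(
    spec: CohortSpec,
    config: StaircaseConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[TrialLog], pd.DataFrame]:
    """Run the full staircase procedure on a simulated cohort.

    Returns the per-observer trial logs together with the ground-truth table
    (participant_id, mu, sigma, lapse) for recovery checks.  Per-observer
    random streams are spawned from the supplied generator, so the result is
    reproducible from a single seed.
    """
    config = config or StaircaseConfig()
    rng = _as_rng(rng)
    observers = sample_cohort(spec, rng)
    child_seeds = rng.bit_generator.seed_seq.spawn(len(observers))
    logs = []
    for obs, ss in zip(observers, child_seeds):
        responder = make_responder(obs, spec.series, np.random.default_rng(ss))
        logs.append(run_staircase(responder, config, spec.series, participant_id=obs.participant_id))
    truth = pd.DataFrame(
        {
            "participant_id": [o.participant_id for o in observers],
            "mu": [o.mu for o in observers],
            "sigma": [o.sigma for o in observers],
            "lapse": [o.lapse for o in observers],
        }
    )
    return logs, truth


def simulate_2afc_panel(
    true_dprimes: Mapping[str, float],
    n_assessors: int,
    rng: np.random.Generator | int | None,
):
    """Draw a 2-AFC panel from per-pair true d' values.

    Each pair's correct count is Binomial(n_assessors, Phi(d'/sqrt(2))).
    Returns a list of :class:`~fattaste.discrimination.PairDiscrimination`.
    """
    from .discrimination import PairDiscrimination

    rng = _as_rng(rng)
    out = []
    for label, d in true_dprimes.items():
        if d < 0:
            raise ValueError("true d' must be nonnegative")
        pc = float(stats.norm.cdf(d / _SQRT2))
        k = int(rng.binomial(n_assessors, pc))
        out.append(
            PairDiscrimination(pair_label=label, n_total=n_assessors, n_correct=k, guess_rate=0.5)
        )
    return out


@dataclass(frozen=True)
class RatingEffects:
    """Generative model for 0-100 fat-intensity ratings.

    score = clip(b0 + b_fat*log1p(fat%) + modality offset
                 + subject effect + noise, 0, 100)

    Defaults place the 0%-fat baseline near "weak" on the scale, add about
    15 points between 0% and 20% fat, and make odour and mouthfeel cues
    additive enhancements over the masked "taste" condition.
    """

    b0: float = 8.0
    b_fat: float = 5.0
    modality_offsets: Mapping[str, float] = field(
        default_factory=lambda: {
            "taste": 0.0,
            "taste_odour": 4.0,
            "taste_mouthfeel": 6.0,
            "overall": 10.0,
        }
    )
    subject_sd: float = 6.0
    noise_sd: float = 8.0


def simulate_ratings(
    n_participants: int,
    fat_levels: Sequence[float] = (0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0),
    modalities: Sequence[str] = ("taste", "overall"),
    effects: RatingEffects | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, RatingEffects]:
    """Simulate a balanced modality x fat-level rating table.

    Returns the long-format records (participant_id, modality, fat_level,
    score) and the generator parameters for recovery tests.
    """
    effects = effects or RatingEffects()
    for m in modalities:
        if m not in effects.modality_offsets:
            raise ValueError(f"no modality offset declared for {m!r}")
    rng = _as_rng(rng)
    width = max(len(str(n_participants)), 2)
    subj_eff = rng.normal(0.0, effects.subject_sd, size=n_participants)
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:0{width}d}"
        for m in modalities:
            for f in fat_levels:
                mean = (
                    effects.b0
                    + effects.b_fat * math.log1p(f)
                    + effects.modality_offsets[m]
                    + subj_eff[i]
                )
                score = float(np.clip(mean + rng.normal(0.0, effects.noise_sd), 0.0, 100.0))
                rows.append(
                    {"participant_id": pid, "modality": m, "fat_level": f, "score": score}
                )
    return pd.DataFrame(rows), effects


def simulate_covariates(
    truth: pd.DataFrame,
    rng: np.random.Generator | int | None,
    bmi_slope: float = 0.0,
    bmi_sd: float = 3.5,
) -> pd.DataFrame:
    """Anthropometric/intake covariates, by default unrelated to sensitivity.

    ``bmi_slope`` (kg/m^2 per log10 mM of latent threshold) is zero by
    default — the no-association case — and can be raised for power
    exploration.  Energy (kcal/day) and fat intake (% energy) are drawn
    around typical adult values.
    """
    rng = _as_rng(rng)
    n = len(truth)
    mu_centred = truth["mu"] - truth["mu"].mean()
    return pd.DataFrame(
        {
            "participant_id": truth["participant_id"],
            "bmi": 23.5 + bmi_slope * mu_centred + rng.normal(0.0, bmi_sd, size=n),
            "energy_kcal": rng.normal(1950.0, 400.0, size=n),
            "fat_pct_energy": rng.normal(34.0, 5.0, size=n),
        }
    )
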