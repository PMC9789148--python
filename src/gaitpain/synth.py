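"""Synthetic gait signals and synthetic cohorts with known ground truth.

Two generators live here:

``generate_signal``
    A quasi-periodic vertical trunk-acceleration trace built as a train of
    per-step Gaussian-windowed impulses riding on a 1 g baseline.  Left and
    right steps can differ in impulse amplitude (asymmetry), step intervals
    are drawn with a controllable coefficient of variation, and white noise
    is added on top.  The true heel-strike and toe-off times are returned
    alongside the trace so downstream feature code can be validated against
    ground truth rather than against its own event detector.

``generate_cohort``
    A participant table plus a gait-parameter table for an epidemiological
    analysis of walking pain.  The per-person pain category (none / mild
    unilateral / moderate-severe unilateral) follows a baseline-category
    logit model on standardized gait features and covariates with known
    coefficients, so parameter-recovery and variable-selection behaviour can
    be tested against stored truth.

Both generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SpecValidationError
from .types import GaitEventSeries, RawGaitSignal

__all__ = [
    "SignalSpec",
    "CohortSpec",
    "generate_signal",
    "generate_cohort",
    "GAIT_FEATURES",
    "COVARIATES",
    "FEATURE_DISTRIBUTIONS",
]

#: Canonical names of the gait parameters produced by feature extraction,
#: in the order they are reported.
GAIT_FEATURES: tuple[str, ...] = (
    "gait_speed",
    "cadence",
    "step_length",
    "stride_time",
    "stance_time_left",
    "stance_time_right",
    "swing_time_left",
    "swing_time_right",
    "stance_percent_left",
    "stance_percent_right",
    "swing_percent_left",
    "swing_percent_right",
    "step_symmetry",
    "gait_asymmetry",
    "stride_time_cv",
    "stance_time_cv_left",
    "stance_time_cv_right",
    "step_regularity",
    "stride_regularity",
    "sample_entropy",
    "pci",
    "phase_cv",
    "phase_abs_diff",
    "dominant_frequency",
    "amplitude_dominant_frequency",
    "width_dominant_frequency",
    "lyapunov_short",
)

#: Continuous covariates and the categorical ones used by the models.
COVARIATES: tuple[str, ...] = ("age", "bmi", "cesd", "sex", "race_site", "roa_count")

#: (mean, sd) used when drawing each gait parameter parametrically for a
#: synthetic cohort.  Values are in the units of the parameter itself and sit
#: in the range typical of community-dwelling older adults walking over
#: ground.
FEATURE_DISTRIBUTIONS: Mapping[str, tuple[float, float]] = {
    "gait_speed": (1.30, 0.20),
    "cadence": (110.0, 9.0),
    "step_length": (0.70, 0.08),
    "stride_time": (1.10, 0.08),
    "stance_time_left": (0.72, 0.06),
    "stance_time_right": (0.72, 0.06),
    "swing_time_left": (0.40, 0.03),
    "swing_time_right": (0.40, 0.03),
    "stance_percent_left": (62.0, 2.0),
    "stance_percent_right": (62.0, 2.0),
    "swing_percent_left": (38.0, 2.0),
    "swing_percent_right": (38.0, 2.0),
    "step_symmetry": (0.93, 0.10),
    "gait_asymmetry": (4.0, 3.0),
    "stride_time_cv": (2.5, 1.2),
    "stance_time_cv_left": (3.0, 1.5),
    "stance_time_cv_right": (3.0, 1.5),
    "step_regularity": (0.72, 0.12),
    "stride_regularity": (0.85, 0.08),
    "sample_entropy": (0.35, 0.12),
    "pci": (6.0, 3.0),
    "phase_cv": (3.0, 1.5),
    "phase_abs_diff": (3.0, 1.5),
    "dominant_frequency": (1.85, 0.15),
    "amplitude_dominant_frequency": (0.50, 0.20),
    "width_dominant_frequency": (0.30, 0.10),
    "lyapunov_short": (1.20, 0.40),
}


@dataclass(frozen=True)
class SignalSpec:
    """Parameters of one synthetic walking trial.

    Attributes
    ----------
    sampling_rate : float
        Samples per second of the output trace (Hz).
    duration : float
        Trial length in seconds.
    cadence : float
        Steps per minute; the mean step interval is ``60 / cadence``.
    left_right_amplitude_ratio : float
        Ratio of left-step to right-step impulse amplitude; 1.0 is a
        perfectly symmetric gait.
    step_time_cv : float
        Coefficient of variation (sd / mean, as a fraction) of the step
        intervals.
    swing_time_left, swing_time_right : float
        Swing-phase duration per side in seconds; the toe-off of a leg is
        placed this long before its next heel strike.
    noise_sd : float
        Standard deviation of additive white Gaussian noise, in the same
        acceleration units as the impulse train.
    walk_distance : float
        Nominal distance covered by the trial in metres (used for speed and
        step-length computation downstream).
    seed : int
        Seed for the trial's random number generator.
    """

    sampling_rate: float = 100.0
    duration: float = 20.0
    cadence: float = 110.0
    left_right_amplitude_ratio: float = 1.0
    step_time_cv: float = 0.0
    swing_time_left: float = 0.40
    swing_time_right: float = 0.40
    noise_sd: float = 0.0
    walk_distance: float = 20.0
    seed: int = 0
    trial_id: str = "trial"
    first_side: str = "left"

    def validate(self) -> None:
        for name in ("sampling_rate", "duration", "cadence",
                     "left_right_amplitude_ratio",
                     "swing_time_left", "swing_time_right", "walk_distance"):
            if not getattr(self, name) > 0:
                raise SpecValidationError(f"SignalSpec.{name} must be > 0")
        for name in ("step_time_cv", "noise_sd"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"SignalSpec.{name} must be >= 0")
        if self.first_side not in ("left", "right"):
            raise SpecValidationError("SignalSpec.first_side must be 'left' or 'right'")
        stride = 2.0 * 60.0 / self.cadence
        if max(self.swing_time_left, self.swing_time_right) >= stride:
            raise SpecValidationError(
                "SignalSpec.swing_time_left/right must be shorter than the stride time"
            )


# sd of the Gaussian impulse window, as a fraction of the mean step interval
_IMPULSE_WIDTH_FRACTION = 0.10
_IMPULSE_AMPLITUDE = 0.8
_BASELINE = 1.0  # standing gravity component, in g


def generate_signal(spec: SignalSpec) -> tuple[RawGaitSignal, GaitEventSeries]:
    """Generate one walking trial and its ground-truth gait events.

    The trace is ``1 g + sum_k a_k * exp(-(t - t_k)^2 / (2 sigma^2)) + noise``
    where the heel-strike times ``t_k`` are a renewal process with mean
    interval ``60 / cadence`` and the requested coefficient of variation,
    and the amplitudes ``a_k`` alternate between the two sides by
    ``left_right_amplitude_ratio``.

    Returns the signal and a :class:`GaitEventSeries` holding the exact
    heel-strike and toe-off times used to build it.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    mean_step = 60.0 / spec.cadence
    # Heel strikes: first strike half an interval in, subsequent intervals
    # drawn i.i.d.; the loop stops when the next strike would fall inside the
    # trailing half-interval margin, so a cv=0 trial of duration D carries
    # exactly cadence * D / 60 steps.
    strikes = [mean_step / 2.0]
    while True:
        if spec.step_time_cv > 0:
            interval = rng.normal(mean_step, spec.step_time_cv * mean_step)
            interval = max(interval, 0.3 * mean_step)
        else:
            interval = mean_step
        nxt = strikes[-1] + interval
        if nxt > spec.duration - mean_step / 2.0 + 1e-9:
            break
        strikes.append(nxt)
    strikes = np.asarray(strikes)

    sides = np.empty(len(strikes), dtype=object)
    first = 0 if spec.first_side == "left" else 1
    sides[first::2] = "left"
    sides[1 - first::2] = "right"

    ratio = spec.left_right_amplitude_ratio
    amps = np.where(sides == "left", _IMPULSE_AMPLITUDE * ratio, _IMPULSE_AMPLITUDE)

    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    sigma = _IMPULSE_WIDTH_FRACTION * mean_step
    acc = np.full(n, _BASELINE)
    for tk, ak in zip(strikes, amps):
        lo = np.searchsorted(t, tk - 5 * sigma)
        hi = np.searchsorted(t, tk + 5 * sigma)
        acc[lo:hi] += ak * np.exp(-((t[lo:hi] - tk) ** 2) / (2 * sigma**2))
    if spec.noise_sd > 0:
        acc = acc + rng.normal(0.0, spec.noise_sd, size=n)

    left_hs = strikes[sides == "left"]
    right_hs = strikes[sides == "right"]
    # toe-off of a leg sits `swing time` before its next ipsilateral strike
    left_to = left_hs[1:] - spec.swing_time_left
    right_to = right_hs[1:] - spec.swing_time_right

    signal = RawGaitSignal(
        samples=acc,
        sampling_rate=spec.sampling_rate,
        walk_distance=spec.walk_distance,
        trial_id=spec.trial_id,
        first_side=spec.first_side,
    )
    events = GaitEventSeries(
        left_heel_strikes=left_hs,
        right_heel_strikes=right_hs,
        left_toe_offs=left_to,
        right_toe_offs=right_to,
    )
    return signal, events


# --------------------------------------------------------------------------
# Cohort generator
# --------------------------------------------------------------------------

_PAIN_LEVELS = ("none", "mild", "moderate", "severe", "extreme")
_RACE_SITE_LEVELS = ("site1_white", "site1_nonwhite", "site2_white", "site2_nonwhite")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort with a known pain-outcome model.

    The per-person pain category follows a baseline-category logit on the
    standardized gait features and covariates:

    ``log P(mild)/P(none)        = intercept + x' beta``
    ``log P(mod-sev)/P(none)     = intercept_modsev + x' beta_modsev``

    where ``x`` holds z-scores computed with the generator's own (true)
    means and sds, so every coefficient is exactly a log-odds per sd.
    Setting ``intercept_modsev`` very negative (the default) collapses the
    model to a plain binary logistic outcome.
    """

    n_participants: int = 500
    age_mean: float = 63.6
    age_sd: float = 10.4
    bmi_mean: float = 29.5
    bmi_sd: float = 5.5
    cesd_mean: float = 8.0
    cesd_sd: float = 7.0
    p_female: float = 0.56
    race_site_probs: tuple[float, ...] = (0.40, 0.12, 0.36, 0.12)
    kl_probs: tuple[float, ...] = (0.35, 0.20, 0.25, 0.15, 0.05)
    coefficients: Mapping[str, float] = field(default_factory=dict)
    intercept: float = -1.3
    coefficients_modsev: Mapping[str, float] = field(default_factory=dict)
    intercept_modsev: float = -30.0
    bilateral_rate: float = 0.0
    kl_missing_rate: float = 0.10
    missing_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise SpecValidationError("CohortSpec.n_participants must be >= 1")
        for name in ("age_sd", "bmi_sd", "cesd_sd"):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"CohortSpec.{name} must be > 0")
        for name, probs in (("race_site_probs", self.race_site_probs),
                            ("kl_probs", self.kl_probs)):
            p = np.asarray(probs, dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1.0) > 1e-9:
                raise SpecValidationError(
                    f"CohortSpec.{name} must be probabilities summing to 1"
                )
        if not 0 <= self.p_female <= 1:
            raise SpecValidationError("CohortSpec.p_female must be in [0, 1]")
        if not 0 <= self.bilateral_rate < 1:
            raise SpecValidationError("CohortSpec.bilateral_rate must be in [0, 1)")
        if not 0 <= self.kl_missing_rate < 1:
            raise SpecValidationError("CohortSpec.kl_missing_rate must be in [0, 1)")
        known = set(GAIT_FEATURES) | {"age", "bmi", "cesd", "sex", "roa_count"}
        for cmap_name in ("coefficients", "coefficients_modsev"):
            for key in getattr(self, cmap_name):
                if key not in known:
                    raise SpecValidationError(
                        f"CohortSpec.{cmap_name}: unknown variable '{key}'"
                    )
        for key, rate in self.missing_rates.items():
            if not 0 <= rate < 1:
                raise SpecValidationError(
                    f"CohortSpec.missing_rates['{key}'] must be in [0, 1)"
                )


def _draw_features(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_participants
    cols = {}
    for name in GAIT_FEATURES:
        mu, sd = FEATURE_DISTRIBUTIONS[name]
        x = rng.normal(mu, sd, size=n)
        # physically non-negative quantities
        if name in ("gait_asymmetry", "stride_time_cv", "stance_time_cv_left",
                    "stance_time_cv_right", "sample_entropy", "pci", "phase_cv",
                    "phase_abs_diff", "amplitude_dominant_frequency",
                    "width_dominant_frequency", "lyapunov_short"):
            x = np.abs(x)
        cols[name] = x
    return pd.DataFrame(cols)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a participant table, a gait-feature table, and stored truth.

    Returns
    -------
    participants : DataFrame
        One row per participant: id, age, sex, race_site, bmi, cesd,
        per-knee walking-pain ratings, per-knee KL grades for the current
        exam and two prior exams, and TKR flags.
    features : DataFrame
        One row per participant with every gait parameter (parametric
        draws; missingness injected per ``missing_rates``).
    truth : dict
        The spec, the linear-model coefficients, and the latent pain
        category per participant.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants

    features = _draw_features(spec, rng)

    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    bmi = rng.normal(spec.bmi_mean, spec.bmi_sd, size=n)
    cesd = np.clip(rng.normal(spec.cesd_mean, spec.cesd_sd, size=n), 0.0, 60.0)
    sex = np.where(rng.random(n) < spec.p_female, "female", "male")
    race_site = rng.choice(_RACE_SITE_LEVELS, size=n, p=spec.race_site_probs)

    kl = {}
    for knee in ("left", "right"):
        for exam in ("current", "prior1", "prior2"):
            kl[(knee, exam)] = rng.choice(5, size=n, p=spec.kl_probs).astype(float)
        miss = rng.random(n) < spec.kl_missing_rate
        kl[(knee, "current")][miss] = np.nan
    roa_true = (
        (np.where(np.isnan(kl[("left", "current")]), kl[("left", "prior1")],
                  kl[("left", "current")]) >= 2).astype(int)
        + (np.where(np.isnan(kl[("right", "current")]), kl[("right", "prior1")],
                    kl[("right", "current")]) >= 2).astype(int)
    )

    # linear predictors on true z-scores
    def lin_pred(coefs: Mapping[str, float], intercept: float) -> np.ndarray:
        lp = np.full(n, intercept)
        for name, beta in coefs.items():
            if name in GAIT_FEATURES:
                mu, sd = FEATURE_DISTRIBUTIONS[name]
                z = (features[name].to_numpy() - mu) / sd
            elif name == "age":
                z = (age - spec.age_mean) / spec.age_sd
            elif name == "bmi":
                z = (bmi - spec.bmi_mean) / spec.bmi_sd
            elif name == "cesd":
                z = (cesd - spec.cesd_mean) / spec.cesd_sd
            elif name == "sex":
                z = (sex == "female").astype(float)
            elif name == "roa_count":
                z = roa_true.astype(float)
            lp = lp + beta * z
        return lp

    lp_mild = lin_pred(spec.coefficients, spec.intercept)
    lp_ms = lin_pred(spec.coefficients_modsev, spec.intercept_modsev)
    denom = 1.0 + np.exp(lp_mild) + np.exp(lp_ms)
    p_mild = np.exp(lp_mild) / denom
    p_ms = np.exp(lp_ms) / denom
    u = rng.random(n)
    category = np.where(u < p_mild, "mild",
                        np.where(u < p_mild + p_ms, "modsev", "none"))

    pain_left = np.full(n, "none", dtype=object)
    pain_right = np.full(n, "none", dtype=object)
    painful_knee = rng.choice(["left", "right"], size=n)
    sev_choice = rng.choice(["moderate", "severe"], size=n)
    for i in range(n):
        if category[i] == "mild":
            (pain_left if painful_knee[i] == "left" else pain_right)[i] = "mild"
        elif category[i] == "modsev":
            (pain_left if painful_knee[i] == "left" else pain_right)[i] = sev_choice[i]
    if spec.bilateral_rate > 0:
        bilateral = rng.random(n) < spec.bilateral_rate
        pain_left[bilateral] = "mild"
        pain_right[bilateral] = rng.choice(["mild", "moderate"], size=n)[bilateral]
        category = category.astype(object)
        category[bilateral] = "bilateral"

    participants = pd.DataFrame({
        "id": [f"P{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "race_site": race_site,
        "bmi": bmi,
        "cesd": cesd,
        "pain_walking_left": pain_left,
        "pain_walking_right": pain_right,
        "kl_left_current": kl[("left", "current")],
        "kl_left_prior1": kl[("left", "prior1")],
        "kl_left_prior2": kl[("left", "prior2")],
        "kl_right_current": kl[("right", "current")],
        "kl_right_prior1": kl[("right", "prior1")],
        "kl_right_prior2": kl[("right", "prior2")],
        "tkr_left": np.zeros(n, dtype=bool),
        "tkr_right": np.zeros(n, dtype=bool),
    })
    features = features.copy()
    features.insert(0, "id", participants["id"])

    # MCAR missingness
    for col, rate in spec.missing_rates.items():
        target = features if col in features.columns else participants
        if col not in target.columns:
            raise SpecValidationError(f"missing_rates names unknown column '{col}'")
        mask = rng.random(n) < rate
        target.loc[mask, col] = np.nan

    truth = {
        "spec": asdict(spec),
        "coefficients": dict(spec.coefficients),
        "intercept": spec.intercept,
        "coefficients_modsev": dict(spec.coefficients_modsev),
        "intercept_modsev": spec.intercept_modsev,
        "category": category,
        "roa_count_true": roa_true,
    }
    return participants, features, truth
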