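"""Synthetic data with known ground truth for every analysis stage.

Three generators:

* :class:`ObserverModel` — a simulated 2AFC respondent whose probability
  of a correct response follows a cumulative-Gaussian psychometric
  function of the absolute stimulus difference, calibrated so that the
  70.7%-correct point (the level tracked by a 1-up/2-down staircase) is
  an explicit parameter.
* :func:`generate_tremor` — tremor recordings as a narrowband sinusoid
  plus broadband Gaussian noise, with an optional downward peak-
  frequency shift under inertial load emulating mechanical-reflex
  (non-central) tremor.
* :func:`generate_cohort` — cohort tables drawn from the linear
  structural-equation model of the mediation causal graph, returning
  the generating coefficients alongside the table so recovery can be
  checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import cached_property
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from scipy import optimize

from .signals import TremorRecording
from .staircase import TRACKED_P_CORRECT

#: value the discrimination term G must take at threshold_707 so that
#: 0.5 + 0.5 * G = 0.707 (no lapses).
_G_AT_THRESHOLD = 2.0 * TRACKED_P_CORRECT - 1.0

#: default spread as a fraction of threshold_707: a steep psychometric
#: whose uncertainty zone is narrow relative to threshold, for which the
#: 2:1-step staircase's tracked level coincides with the 70.7% point to
#: within one down-step.  Shallower observers (larger spread) push the
#: procedure's equilibrium above the 70.7% point, because the 2:1 step
#: ratio balances drift at p^2 = 2/3 (~81.6% correct) rather than at
#: p^2 = 1/2.
DEFAULT_SPREAD_FRACTION = 0.125


@dataclass(frozen=True)
class ObserverModel:
    """Simulated 2AFC observer.

    The probability of a correct response rises from chance with the
    absolute stimulus difference d:

        P(correct | d) = guess + (1 - guess - lapse) * G(d)

    where G is a cumulative Gaussian of location mu and scale ``spread``
    truncated at d = 0 (G(0) = 0, G(inf) = 1), and mu is calibrated so
    that P(correct) = 0.707 exactly at ``threshold_707`` when lapse = 0.
    ``spread`` controls how steeply performance rises through threshold;
    it defaults to ``threshold_707 / 8`` (see
    :data:`DEFAULT_SPREAD_FRACTION`).
    """

    threshold_707: float
    spread: float | None = None
    lapse: float = 0.0
    guess: float = 0.5

    def __post_init__(self) -> None:
        if self.threshold_707 <= 0:
            raise ValueError("threshold_707 must be positive")
        if not 0 <= self.lapse <= 0.1:
            raise ValueError("lapse must be in [0, 0.1]")
        if self.guess != 0.5:
            raise ValueError("2AFC guess rate is fixed at 0.5")
        if self.spread is not None and self.spread <= 0:
            raise ValueError("spread must be positive")

    @property
    def _spread(self) -> float:
        if self.spread is not None:
            return self.spread
        return DEFAULT_SPREAD_FRACTION * self.threshold_707

    def _g(self, d: np.ndarray | float, mu: float) -> np.ndarray | float:
        s = self._spread
        q = stats.norm.sf(mu / s)  # mass of the untruncated CDF below d=0
        return (stats.norm.sf((mu - np.abs(d)) / s) - q) / (1.0 - q)

    @cached_property
    def _mu(self) -> float:
        s = self._spread
        return float(optimize.brentq(
            lambda m: self._g(self.threshold_707, m) - _G_AT_THRESHOLD,
            -6.0 * s, self.threshold_707 + 6.0 * s))

    def p_correct(self, difference: float) -> float:
        g = self._g(abs(float(difference)), self._mu)
        return self.guess + (1.0 - self.guess - self.lapse) * float(g)


def respond(observer: ObserverModel, stimulus_difference: float,
            rng: np.random.Generator) -> bool:
    """Draw one 2AFC response: True = correct."""
    if stimulus_difference < 0:
        raise ValueError("stimulus_difference must be non-negative")
    return bool(rng.random() < observer.p_correct(stimulus_difference))


def make_responder(observer: ObserverModel, reference_value: float,
                   rng: np.random.Generator):
    """Adapt an observer into a ``respond(trial) -> bool`` callable for
    :class:`~tremorlab.staircase.DualStaircaseSession`."""
    def _respond(trial) -> bool:
        return respond(observer, abs(trial.test_value - reference_value), rng)
    return _respond


@dataclass(frozen=True)
class TremorGenSpec:
    """Parameters of a synthetic tremor recording.

    Defaults emulate a 1-minute postural acceleration recording at
    200 Hz with a 6 Hz tremor peak — the centre of the 4-8 Hz band
    typical of essential tremor — and broadband sensor/physiological
    noise well below the oscillation amplitude.
    """

    amplitude: float = 0.1          # m s^-2 (or degrees for angle)
    frequency: float = 6.0          # Hz
    freq_shift_weighted: float = 0.0  # Hz decrease under load; 0 = central
    noise_sd: float = 0.02
    fs: float = 200.0
    duration: float = 60.0
    condition: str = "postural"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.frequency < self.fs / 2:
            raise ValueError("frequency must lie in (0, fs/2)")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")


def generate_tremor(spec: TremorGenSpec,
                    rng: np.random.Generator | None = None,
                    ) -> TremorRecording:
    """One synthetic recording: sinusoid at ``spec.frequency`` plus white
    Gaussian noise, random starting phase."""
    rng = rng or np.random.default_rng(spec.seed)
    t = np.arange(int(round(spec.duration * spec.fs))) / spec.fs
    phase = rng.uniform(0, 2 * np.pi)
    x = spec.amplitude * np.sin(2 * np.pi * spec.frequency * t + phase)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=len(t))
    return TremorRecording(samples=x, fs=spec.fs, condition=spec.condition,
                           load="unweighted")


def generate_tremor_pair(spec: TremorGenSpec,
                         ) -> tuple[TremorRecording, TremorRecording]:
    """Unweighted plus weighted recordings; the weighted twin oscillates
    at ``frequency - freq_shift_weighted`` (mechanical-reflex tremor
    slows under added inertia; centrally driven tremor does not)."""
    rng = np.random.default_rng(spec.seed)
    unweighted = generate_tremor(spec, rng)
    shifted = TremorGenSpec(
        amplitude=spec.amplitude,
        frequency=spec.frequency - spec.freq_shift_weighted,
        noise_sd=spec.noise_sd, fs=spec.fs, duration=spec.duration,
        condition=spec.condition)
    weighted = generate_tremor(shifted, rng)
    weighted.load = "weighted"
    return unweighted, weighted


def generate_kinetic_trajectory(spec: TremorGenSpec,
                                n_cycles: int = 2,
                                excursion: float = 50.0,
                                velocity: float = 5.0,
                                rng: np.random.Generator | None = None,
                                ) -> TremorRecording:
    """Slow triangular wrist ramp (±excursion/2 at ``velocity`` deg/s,
    ``n_cycles`` extension-flexion cycles) with tremor superimposed."""
    rng = rng or np.random.default_rng(spec.seed)
    half_period = excursion / velocity          # one extension or flexion
    duration = 2 * n_cycles * half_period
    n = int(round(duration * spec.fs))
    t = np.arange(n) / spec.fs
    # triangular wave from -excursion/2 to +excursion/2
    phase = (t % (2 * half_period)) / half_period
    ramp = np.where(phase < 1, -excursion / 2 + excursion * phase,
                    excursion / 2 - excursion * (phase - 1))
    tremor = spec.amplitude * np.sin(
        2 * np.pi * spec.frequency * t + rng.uniform(0, 2 * np.pi))
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd else 0.0
    return TremorRecording(samples=ramp + tremor + noise, fs=spec.fs,
                           condition="kinetic", units="deg")


@dataclass(frozen=True)
class CohortGenSpec:
    """Linear structural-equation model for a two-arm tremor cohort.

    Structural equations (T = group, 0 control / 1 ET; X1 = grip
    strength, X2 = tactile acuity; W = tremor amplitude; M =
    discrimination threshold; Y = functional outcome):

        W = i_w + t_to_w T + x_to_w . X + N(0, sd_w)
        M = i_m + t_to_m T + w_to_m W + x_to_m . X + N(0, sd_m)
        Y = i_y + t_to_y T + m_to_y M + interaction_tm T M
              + w_to_y W + x_to_y . X + N(0, sd_y)

    Default path coefficients emulate the study's finding: a strong
    group effect on tremor amplitude (t_to_w) and on function (t_to_y)
    with essentially no group effect on proprioceptive thresholds
    (t_to_m = 0) — a pure-direct-effect world.  Covariate scales match
    typical grip strength (kg) and monofilament force (g) values.
    Group sizes default to the analysed cohort (22 control, 20 ET).
    """

    n_control: int = 22
    n_et: int = 20
    # arrows of the causal graph
    t_to_w: float = 0.15
    t_to_m: float = 0.0
    t_to_y: float = 10.0
    w_to_m: float = 1.0
    m_to_y: float = 0.0
    w_to_y: float = 5.0
    interaction_tm: float = 0.0
    x_to_w: tuple[float, float] = (0.0, 0.0)
    x_to_m: tuple[float, float] = (-0.02, 1.0)
    x_to_y: tuple[float, float] = (-0.05, 2.0)
    # intercepts
    i_w: float = 0.05
    i_m: float = 4.0
    i_y: float = 4.0
    # noise SDs
    sd_w: float = 0.05
    sd_m: float = 1.0
    sd_y: float = 3.0
    # confounder distributions: grip strength (kg), tactile acuity (g)
    grip_mean: float = 33.0
    grip_sd: float = 10.0
    tactile_mean: float = 0.25
    tactile_sd: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_et) < 3:
            raise ValueError("need at least 3 participants per group")
        if min(self.sd_w, self.sd_m, self.sd_y) <= 0:
            raise ValueError("noise SDs must be positive")


#: Outcome columns and the affine map (offset, scale) applied to the
#: structural Y when filling each column; signs follow the usual
#: directions (ET worse: higher FTM and peg-test time, lower ABILHAND
#: and block count).
OUTCOME_MAPS: Mapping[str, tuple[float, float]] = {
    "ftm_ab": (0.0, 1.0),
    "abilhand": (5.0, -0.2),
    "bbt": (70.0, -1.0),
    "nhpt": (18.0, 0.5),
}


def generate_cohort(spec: CohortGenSpec,
                    ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw a cohort table from the structural-equation model.

    Variables are drawn in causal order: confounders X, then tremor
    amplitude W, then discrimination threshold M, then outcome Y.  The
    primary causal wiring runs through ``width_threshold`` (M) and
    ``postural_rms_weighted`` (W); ``weight_threshold`` and
    ``kinetic_rms_weighted`` are drawn from the same equations with
    independent noise, so they share the marginal structure but are not
    ancestors of the outcomes.  Each outcome column is an affine map of
    an independent draw of the structural Y.

    Returns the table and a dict of the generating coefficients (the
    ground truth for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_et
    t = np.concatenate([np.zeros(spec.n_control), np.ones(spec.n_et)])

    grip = rng.normal(spec.grip_mean, spec.grip_sd, n)
    tactile = np.abs(rng.normal(spec.tactile_mean, spec.tactile_sd, n))
    X = np.column_stack([grip, tactile])

    def draw_w() -> np.ndarray:
        return (spec.i_w + spec.t_to_w * t + X @ np.asarray(spec.x_to_w)
                + rng.normal(0, spec.sd_w, n))

    def draw_m(w: np.ndarray) -> np.ndarray:
        return (spec.i_m + spec.t_to_m * t + spec.w_to_m * w
                + X @ np.asarray(spec.x_to_m) + rng.normal(0, spec.sd_m, n))

    def draw_y(m: np.ndarray, w: np.ndarray) -> np.ndarray:
        return (spec.i_y + spec.t_to_y * t + spec.m_to_y * m
                + spec.interaction_tm * t * m + spec.w_to_y * w
                + X @ np.asarray(spec.x_to_y) + rng.normal(0, spec.sd_y, n))

    w_primary = draw_w()
    w_secondary = draw_w()
    m_primary = draw_m(w_primary)
    m_secondary = draw_m(w_primary)

    table = pd.DataFrame({
        "group": np.where(t == 1, "ET", "control"),
        "grip_strength": grip,
        "tactile_acuity": tactile,
        "width_threshold": m_primary,
        "weight_threshold": m_secondary,
        "postural_rms_weighted": w_primary,
        "kinetic_rms_weighted": w_secondary,
    })
    for col, (offset, scale) in OUTCOME_MAPS.items():
        table[col] = offset + scale * draw_y(m_primary, w_primary)

    truth = {k: v for k, v in asdict(spec).items()
             if isinstance(v, (int, float)) and k != "seed"}
    truth["acme"] = spec.t_to_m * spec.m_to_y          # t = 0 arm
    truth["acme_treated"] = spec.t_to_m * (spec.m_to_y
                                           + spec.interaction_tm)
    return table, truth
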