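"""Synthetic 2DES rating studies with the structure the analysis assumes.

The generator emulates a continuous-rating listening experiment: a panel of
raters (52 by default) tracks each stimulus's emotional trajectory through
the valence/arousal plane at 1 Hz.  Each stimulus has a smooth latent mean
trajectory built from waypoints that visit its designated quadrants; each
participant applies a multiplicative amplitude (log-normal) and an additive
offset (normal) to that mean and adds stationary AR(1) noise, after which
ratings are clipped to [-1, 1] as a bounded slider would.  Group effects are
injected as localized Gaussian bumps added to the mean function of one level
of one factor, for one stimulus x dimension cell — the alternative the
functional test is designed to detect.

Covariates are generated as dimension scores first and then back-filled to
plausible item responses consistent with the configured reverse keys, so the
scoring round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.signal import lfilter

from . import covariates as cov
from .data_model import (
    DIMENSIONS,
    GroupingFactor,
    ParticipantRecord,
    RatingSeries,
    StimulusInfo,
    StudyDataset,
    ValidationError,
)

_QUADRANT_POINTS = {
    "Q1": (0.6, 0.6),
    "Q2": (-0.6, 0.6),
    "Q3": (-0.6, -0.6),
    "Q4": (0.6, -0.6),
}

#: quadrant journeys and durations (seconds) of a 17-stimulus study design:
#: 8 music pieces and 9 speech samples, durations spanning 45-156 s
_DEFAULT_STIMULI = (
    ("music_1", "music", 120, ("Q2",)),
    ("music_2", "music", 84, ("Q1", "Q2", "Q3", "Q4")),
    ("music_3", "music", 114, ("Q1", "Q3")),
    ("music_4", "music", 110, ("Q2", "Q3")),
    ("music_5", "music", 130, ("Q1", "Q4")),
    ("music_6", "music", 108, ("Q1", "Q4")),
    ("music_7", "music", 108, ("Q2", "Q3")),
    ("music_8", "music", 89, ("Q1", "Q2", "Q4")),
    ("speech_1", "speech", 45, ("Q1",)),
    ("speech_2", "speech", 156, ("Q1", "Q4")),
    ("speech_3", "speech", 99, ("Q2",)),
    ("speech_4", "speech", 58, ("Q2",)),
    ("speech_5", "speech", 76, ("Q2", "Q3")),
    ("speech_6", "speech", 100, ("Q3", "Q4")),
    ("speech_7", "speech", 63, ("Q3",)),
    ("speech_8", "speech", 88, ("Q1", "Q4")),
    ("speech_9", "speech", 106, ("Q3", "Q4")),
)


@dataclass(frozen=True)
class StimulusSpec:
    """One simulated stimulus: identity, duration, and 2DES waypoints.

    ``waypoints`` is a tuple of (time_fraction, valence, arousal) triples
    with strictly increasing fractions in [0, 1].
    """

    stimulus_id: str
    modality: str
    duration: int
    waypoints: tuple

    def __post_init__(self):
        fracs = [w[0] for w in self.waypoints]
        if len(self.waypoints) < 2:
            raise ValidationError("need at least 2 waypoints")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValidationError("waypoint time fractions must be strictly increasing")
        if fracs[0] < 0 or fracs[-1] > 1:
            raise ValidationError("waypoint time fractions must lie in [0, 1]")
        for _, v, a in self.waypoints:
            if not (-1 <= v <= 1 and -1 <= a <= 1):
                raise ValidationError("waypoint coordinates must lie in [-1, 1]")

    def expected_quadrant_set(self):
        from .preprocess import classify_quadrant

        return tuple(
            sorted(
                {
                    q
                    for _, v, a in self.waypoints
                    if (q := classify_quadrant(v, a)) != "neutral"
                }
            )
        )


@dataclass(frozen=True)
class GroupEffectSpec:
    """A localized mean difference injected for one level of one factor."""

    factor: str
    level: str
    stimulus_id: str
    dimension: str
    center_s: float
    width_s: float
    amplitude: float

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValidationError(f"dimension must be one of {DIMENSIONS}")
        if self.width_s <= 0:
            raise ValidationError("width must be positive")


@dataclass
class SimulationConfig:
    """Full description of one synthetic study.

    Noise defaults (AR(1) coefficient 0.5, innovation scale 0.15, amplitude
    sigma 0.1, offset sigma 0.05) reproduce the qualitative reliability
    regime of real rating panels (per-stimulus alphas mostly > 0.9, dropping
    sharply as sigma grows).
    """

    stimuli: tuple = None
    n_participants: int = 52
    amplitude_sigma: float = 0.1  # sd of log a_i, a_i ~ LogNormal(0, sigma^2)
    offset_sigma: float = 0.05  # sd of additive offset b_i
    ar_coef: float = 0.5  # AR(1) coefficient rho of the noise
    noise_sigma: float = 0.15  # innovation scale of the AR(1) noise
    noise_sigma_by_level: dict = field(default_factory=dict)  # {(factor, level): sigma}
    effects: tuple = ()
    seed: object = None

    def __post_init__(self):
        if self.stimuli is None:
            self.stimuli = default_stimuli()
        self.stimuli = tuple(self.stimuli)
        self.effects = tuple(self.effects)
        if not 0 <= self.ar_coef < 1:
            raise ValidationError("AR coefficient must lie in [0, 1)")
        if self.noise_sigma < 0 or self.amplitude_sigma < 0 or self.offset_sigma < 0:
            raise ValidationError("noise scales must be non-negative")
        for s in self.stimuli:
            if not 45 <= s.duration <= 156:
                raise ValidationError(
                    f"stimulus {s.stimulus_id} duration {s.duration} outside [45, 156]"
                )
        ids = [s.stimulus_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate stimulus ids")
        known = {s.stimulus_id for s in self.stimuli}
        for e in self.effects:
            if e.stimulus_id not in known:
                raise ValidationError(f"effect targets unknown stimulus {e.stimulus_id}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stimuli = raw.pop("stimuli", None)
        if stimuli is not None:
            stimuli = tuple(
                StimulusSpec(
                    s["stimulus_id"],
                    s["modality"],
                    int(s["duration"]),
                    tuple(tuple(w) for w in s["waypoints"]),
                )
                for s in stimuli
            )
        effects = tuple(GroupEffectSpec(**e) for e in raw.pop("effects", ()))
        nsl = {
            (d["factor"], d["level"]): float(d["sigma"])
            for d in raw.pop("noise_sigma_by_level", ())
        }
        return cls(stimuli=stimuli, effects=effects, noise_sigma_by_level=nsl, **raw)

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["stimuli"] = [asdict(s) for s in self.stimuli]
        d["effects"] = [asdict(e) for e in self.effects]
        d["noise_sigma_by_level"] = [
            {"factor": f, "level": l, "sigma": s}
            for (f, l), s in self.noise_sigma_by_level.items()
        ]
        return d


def default_stimuli() -> tuple:
    """The default 17-stimulus design (8 music + 9 speech)."""
    out = []
    for sid, modality, duration, quadrants in _DEFAULT_STIMULI:
        out.append(
            StimulusSpec(sid, modality, duration, _quadrant_waypoints(quadrants))
        )
    return tuple(out)


def _quadrant_waypoints(quadrants) -> tuple:
    """Waypoints starting near neutral and visiting each quadrant in turn."""
    pts = [(0.0, 0.05, 0.05)]
    n = len(quadrants)
    for i, q in enumerate(quadrants):
        v, a = _QUADRANT_POINTS[q]
        pts.append(((i + 1) / n, v, a))
    return tuple(pts)


# ---------------------------------------------------------------------------
# Curve-level operations


def make_mean_function(waypoints, duration: int):
    """Smooth (valence, arousal) mean curves through 2DES waypoints.

    Uses a shape-preserving cubic (PCHIP) interpolant on the 1 Hz grid,
    clipped to [-1, 1]; the curves pass through each waypoint exactly.
    """
    waypoints = tuple(waypoints)
    if len(waypoints) < 2:
        raise ValidationError("need at least 2 waypoints")
    fracs = np.array([w[0] for w in waypoints], dtype=float)
    if np.any(np.diff(fracs) <= 0):
        raise ValidationError("waypoint time fractions must be strictly increasing")
    t = np.arange(duration, dtype=float)
    times = fracs * (duration - 1)
    out = []
    for coord in (1, 2):
        vals = np.array([w[coord] for w in waypoints], dtype=float)
        interp = PchipInterpolator(times, vals, extrapolate=True)
        out.append(np.clip(interp(t), -1.0, 1.0))
    return out[0], out[1]


def inject_group_effect(curve, t, center_s: float, width_s: float, amplitude: float) -> np.ndarray:
    """Add a Gaussian bump A * exp(-(t - t0)^2 / (2 w^2)), clipped to [-1, 1]."""
    if width_s <= 0:
        raise ValidationError("width must be positive")
    t = np.asarray(t, dtype=float)
    bump = amplitude * np.exp(-((t - center_s) ** 2) / (2.0 * width_s**2))
    return np.clip(np.asarray(curve, dtype=float) + bump, -1.0, 1.0)


def ar1_noise(n: int, rho: float, sigma: float, rng) -> np.ndarray:
    """Stationary AR(1) noise: e_t = rho e_{t-1} + innovation, sd sigma."""
    if sigma == 0:
        return np.zeros(n)
    z = rng.normal(0.0, sigma, size=n)
    z[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - rho**2))
    return lfilter([1.0], [1.0, -rho], z)


def simulate_participant(mean_valence, mean_arousal, amplitude, offset, ar_coef, noise_sigma, seed):
    """One participant's (valence, arousal) rating curves for one stimulus.

    X(t) = clip(a_i * mu(t) + b_i + e(t)) with stationary AR(1) noise e.
    Deterministic given the seed (an int or a numpy Generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for mu in (mean_valence, mean_arousal):
        mu = np.asarray(mu, dtype=float)
        e = ar1_noise(len(mu), ar_coef, noise_sigma, rng)
        out.append(np.clip(amplitude * mu + offset + e, -1.0, 1.0))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Covariate back-filling


def _backfill_tipi(targets: dict, rng) -> tuple:
    """Item responses whose TIPI scoring reproduces the target half-integers."""
    items = [0] * 10
    for dim, (direct, reversed_) in cov.DEFAULT_TIPI_KEY.items():
        s = float(np.clip(np.round(2.0 * targets[dim]) / 2.0, 1.0, 7.0))
        hi = int(np.ceil(s))
        lo = int(np.floor(s))
        items[direct - 1] = hi
        items[reversed_ - 1] = 8 - lo  # recoded back to lo when reverse-keyed
    return tuple(items)


def _backfill_teique(target: float, rng) -> tuple:
    """30 item responses whose keyed mean approximates the target EI score."""
    keyed = np.clip(np.round(target + rng.normal(0.0, 0.8, size=30)), 1, 7).astype(int)
    items = []
    reverse = set(cov.DEFAULT_TEIQUE_REVERSE)
    for i, v in enumerate(keyed, start=1):
        items.append(8 - v if i in reverse else int(v))
    return tuple(items)


def simulate_participants(config: SimulationConfig, rng) -> dict:
    """Roster of participant covariate records for one simulated study."""
    participants = {}
    n = config.n_participants
    genders = np.array(["female"] * (n // 2) + ["male"] * (n - n // 2))
    rng.shuffle(genders)
    # training bands weighted like a typical mixed panel (~15:20:17)
    training = rng.choice(
        [cov.TRAINING_UNTRAINED, cov.TRAINING_MIDDLE, cov.TRAINING_TRAINED],
        size=n,
        p=np.array([15, 20, 17]) / 52.0,
    )
    for i in range(n):
        pid = f"P{i + 1:03d}"
        age = float(np.clip(np.round(rng.normal(32.0, 13.0)), 18, 62))
        tipi_targets = {
            dim: float(np.clip(rng.normal(4.3, 1.1), 1, 7)) for dim in cov.DEFAULT_TIPI_KEY
        }
        ei_target = float(np.clip(rng.normal(4.7, 0.7), 1, 7))
        mood_pre = tuple(int(v) for v in rng.integers(-2, 3, size=6))
        mood_post = tuple(
            int(np.clip(m + rng.integers(-1, 2), -3, 3)) for m in mood_pre
        )
        participants[pid] = ParticipantRecord(
            participant_id=pid,
            age=age,
            gender=str(genders[i]),
            training_category=str(training[i]),
            tipi_items=_backfill_tipi(tipi_targets, rng),
            teique_items=_backfill_teique(ei_target, rng),
            mood_pre=mood_pre,
            mood_post=mood_post,
        )
    return participants


def simulate_recruitment_roster(
    n_recruited: int = 60,
    n_measurement_error: int = 2,
    n_non_native: int = 6,
    seed=None,
) -> dict:
    """A recruitment roster with exclusion flags on the first participants.

    The first ``n_measurement_error`` participants carry the measurement
    error flag and the following ``n_non_native`` the non-native-speaker
    flag; the rest are clean.
    """
    if n_measurement_error + n_non_native > n_recruited:
        raise ValidationError("more flagged participants than recruited")
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(n_participants=n_recruited, seed=seed)
    roster = simulate_participants(cfg, rng)
    pids = sorted(roster)
    for pid in pids[:n_measurement_error]:
        roster[pid].exclusion_flags = frozenset({"measurement_error"})
    for pid in pids[n_measurement_error : n_measurement_error + n_non_native]:
        roster[pid].exclusion_flags = frozenset({"non_native"})
    return roster


# ---------------------------------------------------------------------------
# Whole-study simulation


def simulate_study(config: SimulationConfig):
    """Generate a complete study and its truth manifest.

    Returns ``(dataset, manifest)``.  The manifest records the seed, every
    injected effect (the "true" cells), and the factor level membership, so
    recovery tests can check the battery against ground truth.
    """
    master = np.random.SeedSequence(config.seed)
    rng_cov, rng_traj = [np.random.default_rng(s) for s in master.spawn(2)]

    participants = simulate_participants(config, rng_cov)
    factors = cov.build_grouping_factors(participants)
    for e in config.effects:
        if e.factor not in factors:
            raise ValidationError(f"effect references unknown factor {e.factor!r}")
        if e.level not in factors[e.factor].levels:
            raise ValidationError(
                f"effect level {e.level!r} not a level of factor {e.factor}"
            )

    pids = sorted(participants)
    amplitudes = np.exp(rng_traj.normal(0.0, config.amplitude_sigma, size=len(pids)))
    offsets = rng_traj.normal(0.0, config.offset_sigma, size=len(pids))

    def _participant_sigma(pid):
        for (fname, level), sigma in config.noise_sigma_by_level.items():
            if factors[fname].assignment.get(pid) == level:
                return sigma
        return config.noise_sigma

    ratings, stimuli = [], {}
    for spec in config.stimuli:
        t = np.arange(spec.duration, dtype=float)
        base_v, base_a = make_mean_function(spec.waypoints, spec.duration)
        stimuli[spec.stimulus_id] = StimulusInfo(
            spec.stimulus_id, spec.modality, spec.duration, spec.expected_quadrant_set()
        )
        for k, pid in enumerate(pids):
            mu_v, mu_a = base_v, base_a
            for e in config.effects:
                if e.stimulus_id != spec.stimulus_id:
                    continue
                if factors[e.factor].assignment.get(pid) != e.level:
                    continue
                if e.dimension == "valence":
                    mu_v = inject_group_effect(mu_v, t, e.center_s, e.width_s, e.amplitude)
                else:
                    mu_a = inject_group_effect(mu_a, t, e.center_s, e.width_s, e.amplitude)
            val, aro = simulate_participant(
                mu_v,
                mu_a,
                amplitudes[k],
                offsets[k],
                config.ar_coef,
                _participant_sigma(pid),
                rng_traj,
            )
            ratings.append(RatingSeries(pid, spec.stimulus_id, "valence", t.copy(), val))
            ratings.append(RatingSeries(pid, spec.stimulus_id, "arousal", t.copy(), aro))

    dataset = StudyDataset(ratings=ratings, stimuli=stimuli, participants=participants)
    manifest = {
        "seed": config.seed,
        "config": config.to_manifest(),
        "true_cells": [
            {"stimulus_id": e.stimulus_id, "dimension": e.dimension, "factor": e.factor}
            for e in config.effects
        ],
        "factor_levels": {
            name: {level: f.members(level) for level in f.levels}
            for name, f in factors.items()
        },
    }
    return dataset, manifest


# ---------------------------------------------------------------------------
# Two-group curve panels for calibration experiments

_NULL_WAYPOINTS_1D = ((0.0, 0.0), (0.25, 0.4), (0.5, -0.3), (0.75, 0.3), (1.0, -0.2))


def null_mean_curve(duration: int, waypoints=_NULL_WAYPOINTS_1D) -> np.ndarray:
    """A single-dimension mean trajectory used by size/power simulations."""
    fracs = np.array([w[0] for w in waypoints], dtype=float)
    vals = np.array([w[1] for w in waypoints], dtype=float)
    t = np.arange(duration, dtype=float)
    interp = PchipInterpolator(fracs * (duration - 1), vals, extrapolate=True)
    return np.clip(interp(t), -1.0, 1.0)


def simulate_two_group_curves(
    n_a: int = 26,
    n_b: int = 26,
    duration: int = 120,
    noise_sigma_a: float = 0.15,
    noise_sigma_b: float | None = None,
    ar_coef: float = 0.5,
    amplitude_sigma: float = 0.1,
    offset_sigma: float = 0.05,
    bump_amplitude: float = 0.0,
    bump_center: float | None = None,
    bump_width: float = 10.0,
    seed=None,
):
    """(t, curves_a, curves_b): two panels from one curve-generating process.

    Under the null (``bump_amplitude = 0``) both groups share the same mean
    trajectory; otherwise group b's mean carries a localized Gaussian bump.
    Group-specific ``noise_sigma_b`` produces the heteroscedastic regime.
    """
    rng = np.random.default_rng(seed)
    if noise_sigma_b is None:
        noise_sigma_b = noise_sigma_a
    t = np.arange(duration, dtype=float)
    mu = null_mean_curve(duration)
    mu_b = mu
    if bump_amplitude != 0.0:
        center = duration / 2.0 if bump_center is None else bump_center
        mu_b = inject_group_effect(mu, t, center, bump_width, bump_amplitude)

    def _panel(n, mean, sigma):
        curves = np.empty((n, duration))
        for i in range(n):
            a = np.exp(rng.normal(0.0, amplitude_sigma))
            b = rng.normal(0.0, offset_sigma)
            e = ar1_noise(duration, ar_coef, sigma, rng)
            curves[i] = np.clip(a * mean + b + e, -1.0, 1.0)
        return curves

    return t, _panel(n_a, mu, noise_sigma_a), _panel(n_b, mu_b, noise_sigma_b)


def size_simulation(
    n_reps: int = 500,
    alpha: float = 0.05,
    n_boot: int = 199,
    seed=None,
    **two_group_kwargs,
) -> float:
    """Empirical rejection rate of the bootstrap test under the null.

    Simulates ``n_reps`` independent two-group panels from the same process
    and runs the full pipeline (LOOCV bandwidth, smoothing, bootstrap) on
    each; returns the fraction of p-values at or below ``alpha``.
    """
    from .fanova import BootstrapSpec, FunctionalANOVA

    ss = np.random.SeedSequence(seed)
    rejections = 0
    for child in ss.spawn(n_reps):
        data_seed, boot_seed = child.spawn(2)
        t, a, b = simulate_two_group_curves(seed=data_seed, **two_group_kwargs)
        res = FunctionalANOVA([a, b], t).fit(
            bootstrap=BootstrapSpec(n_boot=n_boot, seed=boot_seed)
        )
        rejections += res.p_value <= alpha
    return rejections / n_reps


def power_simulation(
    bump_amplitude: float,
    n_reps: int = 20,
    alpha: float = 0.05,
    n_boot: int = 199,
    seed=None,
    **two_group_kwargs,
) -> float:
    """Empirical power against a localized bump alternative."""
    return size_simulation(
        n_reps=n_reps,
        alpha=alpha,
        n_boot=n_boot,
        seed=seed,
        bump_amplitude=bump_amplitude,
        **two_group_kwargs,
    )
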