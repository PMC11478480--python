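"""Synthetic multi-terrain insole-pressure simulator.

Generates bilateral 10-channel FSR recordings with ground-truth gait phase
and walking-condition labels.  Each walking condition (level walk, stair
ascent/descent, ramp ascent/descent) has a stride template: per-site loading
curves on the normalized 0–100 % gait cycle built from smooth
attack/decay bumps.  Heel loading leads the cycle, midfoot and forefoot
follow, and the condition shifts the balance — forefoot-dominant loading on
stair ascent, sharp heel/forefoot impacts with a quiet midfoot on stair
descent, and timing-shifted variants on ramps.  The left foot runs the same
template offset by half a cycle.

Subjects differ in per-channel amplitude, cadence, stance fraction,
per-channel timing shifts, stride-timing jitter, and sensor noise, so that
cross-subject generalisation is genuinely harder than own-subject testing.

The simulator is the ground-truth source: phase is 0 exactly at each right
heel-strike sample and advances linearly within the stride, and the
walking-condition label stream switches at right-stride boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import (
    CHANNEL_NAMES,
    FsrRecording,
    SAMPLING_RATE_HZ,
    SITE_ORDER,
    WALKING_CONDITIONS,
    WC_TO_CODE,
)

#: Nominal stance fraction the templates are parameterised at.
_NOMINAL_STANCE = 0.62


@dataclass(frozen=True)
class SensorLayout:
    """Anatomical sensor sites and their anterior–posterior coordinates.

    Coordinates are unitless along the foot axis with heel = 0.0 and
    toe = 1.0; they are what the centre-of-pressure computation weights.
    """

    coordinates: dict = field(
        default_factory=lambda: {
            "heel": 0.0,
            "cuboid": 0.30,
            "meta5": 0.65,
            "meta1": 0.78,
            "toe": 1.0,
        }
    )

    def __post_init__(self):
        if set(self.coordinates) != set(SITE_ORDER):
            raise ValueError(f"layout must define exactly the sites {SITE_ORDER}")
        ordered = [self.coordinates[s] for s in ("heel", "cuboid", "meta5", "meta1", "toe")]
        if not all(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("site coordinates must increase strictly heel -> toe")

    def site_coords(self) -> np.ndarray:
        """Coordinates in SITE_ORDER (toe first, heel last)."""
        return np.array([self.coordinates[s] for s in SITE_ORDER])

    @property
    def n_channels(self) -> int:
        return 2 * len(SITE_ORDER)


@dataclass
class SubjectProfile:
    """Per-subject generative parameters.

    ``amp_scale`` multiplies each of the 10 channels (roughly lognormal
    across a cohort), ``cadence_spm`` is strides per minute, stance fractions
    are per walking condition, ``onset_shift`` shifts each channel's loading
    onset in phase units (heel channels stay pinned at phase 0 so the phase
    anchor is well defined), ``jitter_sd_ms`` perturbs stride durations and
    ``noise_sd`` is the additive sensor-noise SD in normalized force units.
    """

    subject_id: str
    amp_scale: np.ndarray
    cadence_spm: float
    stance_fraction: dict
    onset_shift: np.ndarray
    jitter_sd_ms: float
    noise_sd: float
    seed: int

    def __post_init__(self):
        self.amp_scale = np.asarray(self.amp_scale, dtype=float)
        self.onset_shift = np.asarray(self.onset_shift, dtype=float)
        if self.amp_scale.shape != (len(CHANNEL_NAMES),):
            raise ValueError("amp_scale must have one entry per channel")
        if np.any(self.amp_scale <= 0):
            raise ValueError("amplitude scales must be positive")
        if self.cadence_spm <= 0:
            raise ValueError("cadence must be positive")
        for wc, sf in self.stance_fraction.items():
            if not 0.4 < sf < 0.8:
                raise ValueError(f"stance fraction for {wc} out of (0.4, 0.8): {sf}")


@dataclass
class ScenarioScript:
    """Ordered walking-condition segments making up one trial.

    ``segments`` is a list of ``(walking_condition, n_strides)``;
    ``reverse`` flags a reverse-direction traversal of the course.
    """

    scenario_id: str
    segments: list
    reverse: bool = False

    def __post_init__(self):
        if len(self.segments) < 1:
            raise ValueError("script needs at least one segment")
        for wc, n in self.segments:
            if wc not in WC_TO_CODE:
                raise ValueError(f"unknown walking condition {wc!r}")
            if n < 2:
                raise ValueError("each segment needs at least 2 strides")

    def reversed(self) -> "ScenarioScript":
        """Reverse-direction variant: segment order flipped, ascent<->descent."""
        swap = {"SA": "SD", "SD": "SA", "RA": "RD", "RD": "RA"}
        segs = [(swap.get(wc, wc), n) for wc, n in reversed(self.segments)]
        return ScenarioScript(self.scenario_id + "r", segs, reverse=not self.reverse)

    @property
    def n_strides(self) -> int:
        return sum(n for _, n in self.segments)


# ---------------------------------------------------------------------------
# Stride templates
# ---------------------------------------------------------------------------

# Per condition, per site: (amplitude, onset %, width %, attack %).
# The heel attack is short so heel contact is a sharp, detectable rising
# edge at phase 0; other sites use a symmetric raised-cosine (attack =
# width/2).  All supports end well before 100 % so every channel unloads
# during swing.
_TEMPLATES: dict[str, dict[str, tuple]] = {
    "LW": {
        "heel":   (1.00, 0.0, 40.0, 5.0),
        "cuboid": (0.70, 5.0, 42.0, None),
        "meta5":  (0.80, 12.0, 45.0, None),
        "meta1":  (0.90, 18.0, 44.0, None),
        "toe":    (1.00, 30.0, 34.0, None),
    },
    "SA": {
        "heel":   (0.35, 0.0, 25.0, 5.0),
        "cuboid": (0.50, 4.0, 35.0, None),
        "meta5":  (0.95, 6.0, 52.0, None),
        "meta1":  (1.10, 8.0, 54.0, None),
        "toe":    (1.15, 18.0, 46.0, None),
    },
    "SD": {
        "heel":   (0.90, 0.0, 22.0, 4.0),
        "cuboid": (0.25, 8.0, 30.0, None),
        "meta5":  (0.90, 3.0, 40.0, None),
        "meta1":  (1.00, 4.0, 42.0, None),
        "toe":    (1.10, 6.0, 40.0, None),
    },
    "RA": {
        "heel":   (0.70, 0.0, 30.0, 5.0),
        "cuboid": (0.60, 6.0, 40.0, None),
        "meta5":  (0.90, 10.0, 50.0, None),
        "meta1":  (1.00, 14.0, 52.0, None),
        "toe":    (1.10, 24.0, 44.0, None),
    },
    "RD": {
        "heel":   (1.15, 0.0, 48.0, 5.0),
        "cuboid": (0.80, 4.0, 46.0, None),
        "meta5":  (0.70, 14.0, 40.0, None),
        "meta1":  (0.65, 18.0, 38.0, None),
        "toe":    (0.60, 32.0, 28.0, None),
    },
}


def _bump(phase: np.ndarray, onset: float, width: float, attack: float) -> np.ndarray:
    """Smooth unit bump on [onset, onset+width) of the cyclic 0-100 axis.

    Rises as sin^2 over ``attack`` units, decays as cos^2 over the rest;
    zero elsewhere.  With attack = width/2 this is a raised cosine.
    """
    p = np.mod(phase - onset, 100.0)
    out = np.zeros_like(p)
    rise = p < attack
    out[rise] = np.sin(0.5 * np.pi * p[rise] / attack) ** 2
    fall = (p >= attack) & (p < width)
    out[fall] = np.cos(0.5 * np.pi * (p[fall] - attack) / (width - attack)) ** 2
    return out


@dataclass(frozen=True)
class StrideTemplate:
    """Per-channel loading curves for one walking condition.

    ``stance_scale`` stretches onsets/widths relative to the nominal stance
    fraction; ``onset_shift`` delays individual sites (heel excluded so the
    rising edge stays at phase 0).
    """

    walking_condition: str
    stance_scale: float = 1.0
    onset_shift: dict = field(default_factory=dict)

    def curve(self, site: str, phase: np.ndarray) -> np.ndarray:
        amp, onset, width, attack = _TEMPLATES[self.walking_condition][site]
        s = self.stance_scale
        onset = onset * s
        width = min(width * s, 90.0)
        attack = width / 2.0 if attack is None else min(attack, width / 2.0)
        if site != "heel":
            onset = max(onset + self.onset_shift.get(site, 0.0), 0.0)
        return amp * _bump(phase, onset, width, attack)

    def foot_forces(self, phase: np.ndarray) -> np.ndarray:
        """(n, 5) loading of one foot in SITE_ORDER at the given phases."""
        return np.stack([self.curve(site, phase) for site in SITE_ORDER], axis=1)


def template_curves(wc: str, grid: np.ndarray | None = None) -> np.ndarray:
    """Reference (noise-free, unit-subject) stride curves for one condition."""
    if grid is None:
        grid = np.linspace(0.0, 100.0, 101)
    return StrideTemplate(wc).foot_forces(grid)


# ---------------------------------------------------------------------------
# Cohort and trial simulation
# ---------------------------------------------------------------------------

def make_cohort(n_subjects: int, base_seed: int) -> list[SubjectProfile]:
    """Draw a deterministic cohort of subject profiles.

    Amplitudes are lognormal around 1, cadence is normal around 52
    strides/min, stance fractions vary mildly per condition and subject, and
    each channel gets a small timing shift.  Distinct subjects get distinct
    sub-seeds derived from ``base_seed``.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    base_stance = {"LW": 0.62, "SA": 0.64, "SD": 0.58, "RA": 0.66, "RD": 0.63}
    profiles = []
    children = np.random.SeedSequence(base_seed).spawn(n_subjects)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        amp = np.exp(rng.normal(0.0, 0.25, size=len(CHANNEL_NAMES)))
        cadence = float(np.clip(rng.normal(52.0, 3.0), 45.0, 58.0))
        stance = {
            wc: float(np.clip(v + rng.normal(0.0, 0.03), 0.45, 0.75))
            for wc, v in base_stance.items()
        }
        shift = rng.uniform(-3.0, 3.0, size=len(CHANNEL_NAMES))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                amp_scale=amp,
                cadence_spm=cadence,
                stance_fraction=stance,
                onset_shift=shift,
                jitter_sd_ms=15.0,
                noise_sd=0.02,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
        )
    return profiles


def _site_shift_map(profile: SubjectProfile, side: str) -> dict:
    offset = 0 if side == "L" else len(SITE_ORDER)
    return {
        site: float(profile.onset_shift[offset + k])
        for k, site in enumerate(SITE_ORDER)
        if site != "heel"
    }


def simulate_trial(
    profile: SubjectProfile,
    script: ScenarioScript,
    layout: SensorLayout | None = None,
    trial_index: int = 1,
    seed: int | None = None,
) -> FsrRecording:
    """Simulate one trial of the given scenario for one subject.

    Returns an :class:`FsrRecording` carrying ground truth: ``phase`` (0 at
    each right heel strike, linear within the stride), per-sample walking
    condition codes, ``events`` at condition transitions and
    ``heel_strikes`` at stride starts.  With ``noise_sd == 0`` and
    ``jitter_sd_ms == 0`` repeated trials are bitwise identical.
    """
    if layout is None:
        layout = SensorLayout()
    if seed is None:
        seed = profile.seed
    rng = np.random.default_rng(np.random.SeedSequence((seed, trial_index)))
    fs = SAMPLING_RATE_HZ
    base_duration = 60.0 / profile.cadence_spm

    phases, forces, wc_codes = [], [], []
    heel_strikes, events = [], []
    cursor = 0
    shift_r = _site_shift_map(profile, "R")
    shift_l = _site_shift_map(profile, "L")
    for seg_idx, (wc, n_strides) in enumerate(script.segments):
        if seg_idx > 0:
            events.append(cursor)
        scale = profile.stance_fraction[wc] / _NOMINAL_STANCE
        tmpl_r = StrideTemplate(wc, stance_scale=scale, onset_shift=shift_r)
        tmpl_l = StrideTemplate(wc, stance_scale=scale, onset_shift=shift_l)
        for _ in range(n_strides):
            jitter = rng.normal(0.0, profile.jitter_sd_ms / 1000.0) if profile.jitter_sd_ms > 0 else 0.0
            n = max(int(round((base_duration + jitter) * fs)), 50)
            phase = np.arange(n) * (100.0 / n)
            right = tmpl_r.foot_forces(phase)
            left = tmpl_l.foot_forces(np.mod(phase + 50.0, 100.0))
            stride_forces = np.concatenate([left, right], axis=1) * profile.amp_scale
            heel_strikes.append(cursor)
            phases.append(phase)
            forces.append(stride_forces)
            wc_codes.append(np.full(n, WC_TO_CODE[wc], dtype=np.int8))
            cursor += n

    force_mat = np.concatenate(forces, axis=0)
    if profile.noise_sd > 0:
        force_mat = force_mat + rng.normal(0.0, profile.noise_sd, size=force_mat.shape)
        np.clip(force_mat, 0.0, None, out=force_mat)
    n_total = force_mat.shape[0]
    rec = FsrRecording(
        subject_id=profile.subject_id,
        scenario_id=script.scenario_id,
        trial_index=trial_index,
        time=np.arange(n_total) / fs,
        forces=force_mat,
        wc=np.concatenate(wc_codes),
        events=events,
        normalized=False,
        phase=np.concatenate(phases),
        heel_strikes=heel_strikes,
    )
    rec.validate()
    return rec


def default_scripts(strides_level: int = 30, strides_seg: int = 8) -> list[ScenarioScript]:
    """The three walking scenarios: level course, stair course, ramp course."""
    s = strides_seg
    return [
        ScenarioScript("sc1", [("LW", strides_level)]),
        ScenarioScript("sc2", [("LW", s), ("SA", s + 2), ("LW", s), ("SD", s + 2), ("LW", s)]),
        ScenarioScript("sc3", [("LW", s), ("RA", s + 2), ("LW", s), ("RD", s + 2), ("LW", s)]),
    ]


def simulate_protocol(
    cohort: list[SubjectProfile],
    scripts: list[ScenarioScript],
    trials_per_script: int = 3,
    layout: SensorLayout | None = None,
) -> list[FsrRecording]:
    """Simulate the full walking protocol: every subject performs every
    scenario ``trials_per_script`` times.  Trial seeds are derived from the
    subject seed and the (scenario, trial) identity, so the dataset is
    reproducible end to end.
    """
    if trials_per_script < 1:
        raise ValueError("trials_per_script must be >= 1")
    dataset = []
    for profile in cohort:
        for si, script in enumerate(scripts):
            for t in range(1, trials_per_script + 1):
                seed = int(
                    np.random.SeedSequence((profile.seed, si, t)).generate_state(1)[0]
                    % (2**31)
                )
                dataset.append(
                    simulate_trial(profile, script, layout, trial_index=t, seed=seed)
                )
    return dataset
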