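"""Seeded synthetic cohorts emulating the data regime the filter targets.

Real inputs to the filter are per-subject ICA mixing matrices (component
time courses), six rigid-body motion traces, and reference labels.  None of
these are bundled; instead this module generates cohorts with known ground
truth at realistic scale: T = 270 or 300 volumes at TR = 1.98 s, roughly
35-50 components per subject of which about two thirds are artifacts.

Three component classes are generated:

* ``RSN`` — band-limited (0.009-0.08 Hz) Gaussian noise plus a small
  broadband noise floor, residualized against the motion design so motion
  coupling is nil by construction;
* ``MOTION_ART`` — a random positive combination of the six motion traces
  mixed at weight ``alpha_motion`` with band-limited noise;
* ``POWER_ART`` — high-frequency (f > 0.1 Hz) noise plus the noise floor.

Motion traces are a Gaussian random walk plus slow sinusoidal drift plus
occasional spike transients, with rotations two orders of magnitude smaller
than translations.  All randomness flows from a master seed; subject ``i``
uses sub-seed ``(seed + i * 10007) mod 2^31`` so extending a cohort never
reshuffles earlier subjects.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .criteria import BandConfig
from .errors import InputError
from .io import (
    ARTIFACT,
    RSN_CANDIDATE,
    ICTimecourseSet,
    LabelSet,
    MotionParams,
    write_label_file,
    write_matrix,
)

CLASS_RSN = "RSN"
CLASS_MOTION_ART = "MOTION_ART"
CLASS_POWER_ART = "POWER_ART"

_SUBSEED_STRIDE = 10007  # documented constant: subject i gets seed + i * stride


@dataclass
class CohortConfig:
    """Generator settings; defaults mirror the regime described above."""

    n_subjects: int = 6
    T: int = 270
    tr_seconds: float = 1.98
    n_rsn: int = 14
    n_motion_art: int = 15
    n_power_art: int = 15
    count_jitter: int = 3  # each class count drawn uniformly in base +/- jitter
    alpha_motion: float = 0.95
    noise_floor: float = 0.1
    band: BandConfig = field(default_factory=BandConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 64:
            raise InputError("T must be at least 64")
        if not (0.0 <= self.alpha_motion <= 1.0):
            raise InputError("alpha_motion must lie in [0, 1]")
        if self.count_jitter < 0:
            raise InputError("count_jitter must be non-negative")


@dataclass
class SyntheticSubject:
    timecourses: ICTimecourseSet
    motion: MotionParams
    truth: LabelSet
    classes: np.ndarray  # per-component class names

    def as_triple(self):
        return (self.timecourses, self.motion, self.truth)


@dataclass
class SpatialMapSet:
    """Per-subject component spatial maps: L components x V voxels."""

    subject_id: str
    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not np.all(np.isfinite(self.maps)):
            raise InputError("spatial maps contain non-finite values")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]


def subject_seed(master_seed: int, i: int) -> int:
    return (master_seed + i * _SUBSEED_STRIDE) % (2**31)


def simulate_motion_params(
    T: int,
    tr: float,
    seed: int,
    step_sd: float = 0.02,
    drift_amplitude: float = 0.25,
    drift_min_period_s: float = 200.0,
    spike_rate_per_100: float = 0.5,
    spike_amp_sd: float = 0.3,
    subject_id: str = "sim",
) -> MotionParams:
    """Simulate six rigid-body motion traces.

    Each channel is a Gaussian random walk (increment sd ``step_sd``) plus a
    slow sinusoidal drift (period at least ``drift_min_period_s`` seconds)
    plus Poisson-placed spike transients (rate ``spike_rate_per_100`` per
    100 volumes, exponentially decaying over ~3 volumes).  Rotation channels
    are scaled by 0.01 relative to translations.
    """
    if T < 64:
        raise InputError("T must be at least 64")
    rng = np.random.default_rng(seed)
    t = np.arange(T) * tr
    channels = []
    for c in range(6):
        walk = np.cumsum(rng.normal(0.0, step_sd, size=T))
        period = rng.uniform(drift_min_period_s, 3.0 * drift_min_period_s)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        drift = drift_amplitude * np.sin(2.0 * np.pi * t / period + phase)
        spikes = np.zeros(T)
        n_spikes = rng.poisson(spike_rate_per_100 * T / 100.0)
        if n_spikes > 0 and spike_amp_sd > 0:
            pos = rng.integers(0, T, size=n_spikes)
            amp = rng.normal(0.0, spike_amp_sd, size=n_spikes)
            for p, a in zip(pos, amp):
                decay = a * np.exp(-np.arange(T - p) / 3.0)
                spikes[p:] += decay
        chan = walk + drift + spikes
        if c < 3:  # rotations (rad) are much smaller than translations (mm)
            chan = chan * 0.01
        channels.append(chan)
    return MotionParams(subject_id=subject_id, values=np.column_stack(channels))


def _spectral_mask_noise(
    rng: np.random.Generator, T: int, tr: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """White noise restricted to the open frequency band (f_lo, f_hi).

    Band membership uses the same open-interval rule as the scoring module,
    so generator and scorer never disagree about edge bins.
    """
    white = rng.standard_normal(T)
    fft = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs > f_lo) & (freqs < f_hi)
    if not keep.any():
        raise InputError(f"band ({f_lo}, {f_hi}) Hz contains no frequency bins")
    fft = np.where(keep, fft, 0.0)
    return np.fft.irfft(fft, n=T)


def _unit(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd <= 0:
        raise InputError("degenerate signal in generator")
    return (x - x.mean()) / sd


def simulate_component(
    kind: str, motion: MotionParams, config: CohortConfig, seed: int
) -> np.ndarray:
    """Generate one component time course of the given class (unit variance)."""
    rng = np.random.default_rng(seed)
    T = motion.n_timepoints
    tr = config.tr_seconds
    band = config.band
    nyquist = 0.5 / tr
    if kind == CLASS_RSN:
        x = _unit(_spectral_mask_noise(rng, T, tr, band.f_lo, band.f_hi))
        x = x + config.noise_floor * rng.standard_normal(T)
        design = np.column_stack([np.ones(T), motion.values])
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta  # no motion coupling, by construction
    elif kind == CLASS_MOTION_ART:
        w = rng.uniform(0.2, 1.0, size=6)
        m = _unit(motion.values @ w)
        b = _unit(_spectral_mask_noise(rng, T, tr, band.f_lo, band.f_hi))
        x = config.alpha_motion * m + (1.0 - config.alpha_motion) * b
    elif kind == CLASS_POWER_ART:
        x = _unit(_spectral_mask_noise(rng, T, tr, 0.1, nyquist * (1 + 1e-9)))
        x = x + config.noise_floor * rng.standard_normal(T)
    else:
        raise InputError(f"unknown component class {kind!r}")
    return _unit(x)


def simulate_subject(config: CohortConfig, i: int) -> SyntheticSubject:
    """Generate subject ``i`` of a cohort (deterministic in the master seed)."""
    seed = subject_seed(config.seed, i)
    rng = np.random.default_rng(seed)
    sid = f"sub-{i + 1:03d}"
    motion = simulate_motion_params(config.T, config.tr_seconds, seed=seed + 1,
                                    subject_id=sid)
    counts = {}
    for name, base in ((CLASS_RSN, config.n_rsn),
                       (CLASS_MOTION_ART, config.n_motion_art),
                       (CLASS_POWER_ART, config.n_power_art)):
        lo = max(0, base - config.count_jitter)
        hi = base + config.count_jitter
        counts[name] = int(rng.integers(lo, hi + 1)) if base > 0 else 0
    classes = np.concatenate([
        np.repeat(name, n) for name, n in counts.items()
    ])
    if classes.size == 0:
        raise InputError("configuration generates no components")
    classes = classes[rng.permutation(classes.size)]
    cols = []
    for j, kind in enumerate(classes):
        cols.append(simulate_component(kind, motion, config, seed=seed + 100 + j))
    tcs = ICTimecourseSet(subject_id=sid, timecourses=np.column_stack(cols),
                          tr_seconds=config.tr_seconds)
    labels = LabelSet(
        subject_id=sid,
        labels=np.where(classes == CLASS_RSN, RSN_CANDIDATE, ARTIFACT),
    )
    return SyntheticSubject(timecourses=tcs, motion=motion, truth=labels,
                            classes=classes)


def simulate_cohort(config: CohortConfig) -> list[SyntheticSubject]:
    """Generate a full cohort; subject i depends only on (seed, i)."""
    return [simulate_subject(config, i) for i in range(config.n_subjects)]


def write_cohort(subjects: list[SyntheticSubject], out_dir) -> str:
    """Write a cohort in the on-disk dialects plus a manifest TSV.

    The manifest columns (subject, mix_path, motion_path, labels_path, tr)
    are what the training CLI consumes; paths are stored relative to the
    manifest so a cohort directory can be moved or compared wholesale.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("subject\tmix_path\tmotion_path\tlabels_path\ttr\n")
        for s in subjects:
            sid = s.timecourses.subject_id
            mix = f"{sid}_mix.txt"
            par = f"{sid}_motion.par"
            lab = f"{sid}_labels.tsv"
            write_matrix(s.timecourses.timecourses, os.path.join(out_dir, mix))
            write_matrix(s.motion.values, os.path.join(out_dir, par))
            write_label_file(s.truth, os.path.join(out_dir, lab))
            fh.write(f"{sid}\t{mix}\t{par}\t{lab}\t{s.timecourses.tr_seconds}\n")
    return manifest_path


def make_blob_templates(n_templates: int, n_voxels: int, width: float | None = None) -> np.ndarray:
    """Smooth Gaussian-blob template maps on a 1-D voxel lattice.

    Centers are fixed and evenly spaced so the same templates are shared
    across subjects and seeds.
    """
    if n_templates < 1 or n_voxels < 2 * n_templates:
        raise InputError("need n_voxels >= 2 * n_templates")
    width = width or n_voxels / (6.0 * n_templates)
    v = np.arange(n_voxels, dtype=float)
    centers = (np.arange(n_templates) + 0.5) * n_voxels / n_templates
    return np.exp(-0.5 * ((v[None, :] - centers[:, None]) / width) ** 2)


def _boundary_pattern(n_voxels: int) -> np.ndarray:
    """Edge-concentrated pattern mimicking brain-boundary motion artifacts."""
    v = np.arange(n_voxels, dtype=float)
    scale = max(2.0, n_voxels / 25.0)
    return np.exp(-v / scale) + np.exp(-(n_voxels - 1 - v) / scale)


def simulate_subject_maps(
    n_components: int,
    n_voxels: int,
    templates: np.ndarray,
    noise_sd: float,
    seed: int,
    subject_id: str = "sim",
    boundary_amplitude: float = 3.0,
) -> SpatialMapSet:
    """Spatial maps for one subject on a 1-D voxel lattice.

    The first K components (K = number of templates) are RSN maps: template
    plus Gaussian noise.  The remaining components are artifacts — the first
    is a high-amplitude boundary pattern, the rest pure noise.
    """
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    K = templates.shape[0]
    if K > n_components:
        raise InputError("more templates than components")
    if templates.shape[1] != n_voxels:
        raise InputError("template voxel count mismatch")
    rng = np.random.default_rng(seed)
    maps = np.empty((n_components, n_voxels))
    for j in range(K):
        maps[j] = templates[j] + noise_sd * rng.standard_normal(n_voxels)
    for j in range(K, n_components):
        if j == K:  # structured artifact shared in shape across subjects
            sign = rng.choice([-1.0, 1.0])
            maps[j] = (sign * boundary_amplitude * _boundary_pattern(n_voxels)
                       + noise_sd * rng.standard_normal(n_voxels))
        else:
            maps[j] = rng.standard_normal(n_voxels)
    return SpatialMapSet(subject_id=subject_id, maps=maps)


def simulate_map_cohort(
    n_subjects: int,
    n_components: int,
    n_voxels: int,
    n_templates: int,
    noise_sd: float,
    seed: int,
) -> tuple[list[SpatialMapSet], list[LabelSet], np.ndarray]:
    """Cohort of spatial-map sets with matching truth labels and templates."""
    templates = make_blob_templates(n_templates, n_voxels)
    sets, labels = [], []
    for i in range(n_subjects):
        sid = f"sub-{i + 1:03d}"
        sets.append(
            simulate_subject_maps(n_components, n_voxels, templates, noise_sd,
                                  seed=subject_seed(seed, i), subject_id=sid)
        )
        lab = np.asarray(
            [RSN_CANDIDATE] * n_templates + [ARTIFACT] * (n_components - n_templates),
            dtype=object,
        )
        labels.append(LabelSet(subject_id=sid, labels=lab))
    return sets, labels, templates
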