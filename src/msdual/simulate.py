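"""Synthetic EEG cohorts with ground-truth microstate structure.

Emulates the study conditions of a disorders-of-consciousness (DOC)
microstate experiment: four groups (healthy controls HC and the MCS+,
MCS-, VS patient grades), 32-channel scalp EEG, trials of
rest (120 s) / task (80 s) / post-task rest (120 s), and a graded
Microstate-D profile across groups (coverage, dwell time, and GFP all
attenuate with the severity of the disorder).  Task stimulation
(visual V, olfactory O, combined V-O) additively raises the Microstate-D
coverage target during the task window.

The forward model is deliberately phenomenological, not biophysical:
each ground-truth segment contributes ``sign * a(t) * template`` with a
random polarity sign, a smooth strictly-positive amplitude envelope a(t)
(alpha-band modulated around the class's target GFP), plus spatially
correlated Gaussian noise band-limited to 0.5-50 Hz.  At noise level 0
every sample is therefore an exact scalar multiple of its ground-truth
template — the identifiability regime used by the oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import montage as _montage
from .clustering import TemplateSet
from .io import EEGRecording

GROUPS = ("HC", "MCS+", "MCS-", "VS")
CLASSES = ("A", "B", "C", "D")
CONDITIONS = ("V", "O", "V-O")


@dataclass
class GroupProfile:
    """Generating parameters of one participant group.

    ``coverage`` are per-class time fractions (sum 1), ``dwell_ms``
    per-class mean dwell times, ``gfp_uv`` per-class mean field strengths
    and ``task_modulation`` the additive change (percentage points) of
    Microstate-D coverage during a task window, per condition.
    """

    label: str
    coverage: dict
    dwell_ms: dict
    gfp_uv: dict
    task_modulation: dict = field(default_factory=lambda: dict.fromkeys(CONDITIONS, 0.0))

    def __post_init__(self):
        total = sum(self.coverage.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"coverage targets sum to {total}, not 1")
        if any(v < 0 for v in self.coverage.values()):
            raise ValueError("coverage targets must be non-negative")
        if any(v <= 0 for v in self.dwell_ms.values()):
            raise ValueError("mean dwell times must be positive")
        if any(v <= 0 for v in self.gfp_uv.values()):
            raise ValueError("GFP amplitudes must be positive")
        for cond, mod in self.task_modulation.items():
            if not 0.0 <= self.coverage.get("D", 0.0) + mod / 100.0 <= 1.0:
                raise ValueError(f"modulated D coverage out of [0,1] for {cond}")

    @property
    def classes(self):
        return list(self.coverage)

    def modulated(self, condition: str) -> "GroupProfile":
        """Profile with the task-window D coverage for ``condition``.

        The modulation is added to D; the remaining classes are rescaled
        proportionally so that coverages still sum to one.
        """
        if condition not in self.task_modulation:
            raise ValueError(f"unknown condition {condition!r}")
        shift = self.task_modulation[condition] / 100.0
        d_old = self.coverage["D"]
        d_new = d_old + shift
        scale = (1.0 - d_new) / (1.0 - d_old) if d_old < 1.0 else 0.0
        cov = {c: (d_new if c == "D" else v * scale) for c, v in self.coverage.items()}
        return GroupProfile(self.label, cov, dict(self.dwell_ms),
                            dict(self.gfp_uv), dict(self.task_modulation))


@dataclass
class SimulationConfig:
    """Acquisition and noise settings shared by a simulated cohort."""

    n_channels: int = 32
    fs: float = 250.0
    rest_s: float = 120.0
    task_s: float = 80.0
    post_rest_s: float = 120.0
    noise_level: float = 0.25  # noise RMS / signal RMS
    noise_corr_length: float = 0.03  # spatial correlation length, m
    seed: int = 0

    def __post_init__(self):
        if min(self.rest_s, self.task_s, self.post_rest_s) <= 0:
            raise ValueError("window durations must be positive")
        if self.noise_level < 0:
            raise ValueError("noise level must be >= 0")


@dataclass
class GroundTruth:
    """Generated label sequence plus its segment table."""

    labels: np.ndarray  # per-sample class index
    segments: pd.DataFrame  # class, start, end (exclusive), sign
    fs: float

    def coverage(self, n_classes: int) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes) / self.labels.size

    def mean_dwell_ms(self, n_classes: int) -> np.ndarray:
        out = np.zeros(n_classes)
        lens = (self.segments["end"] - self.segments["start"]).to_numpy()
        cls = self.segments["class"].to_numpy()
        for k in range(n_classes):
            if (cls == k).any():
                out[k] = lens[cls == k].mean() * 1000.0 / self.fs
        return out


# ---------------------------------------------------------------------------
# group profiles of the study conditions
# ---------------------------------------------------------------------------

# Resting-state targets per group: Microstate D carries the reported
# graded profile; A-C coverages share the remaining probability mass in
# proportion to their reported resting values, and their dwell/GFP use
# the reported resting-template cells.
_D_COVERAGE = {"HC": 23.5, "MCS+": 15.1, "MCS-": 9.4, "VS": 4.7}  # percent
_ABC_COVERAGE = {  # percent, relative weights for the non-D remainder
    "HC": {"A": 11.8, "B": 12.1, "C": 16.1},
    "MCS+": {"A": 12.2, "B": 14.2, "C": 14.2},
    "MCS-": {"A": 12.1, "B": 13.2, "C": 14.5},
    "VS": {"A": 11.1, "B": 13.1, "C": 11.9},
}
_DWELL_MS = {
    "HC": {"A": 80.6, "B": 90.6, "C": 97.6, "D": 50.0},
    "MCS+": {"A": 78.6, "B": 88.5, "C": 87.5, "D": 29.0},
    "MCS-": {"A": 81.4, "B": 87.1, "C": 76.1, "D": 30.0},
    "VS": {"A": 82.6, "B": 88.1, "C": 77.2, "D": 24.0},
}
_GFP_UV = {
    "HC": {"A": 4.1, "B": 5.1, "C": 7.1, "D": 7.1},
    "MCS+": {"A": 2.4, "B": 4.2, "C": 6.9, "D": 6.7},
    "MCS-": {"A": 3.6, "B": 5.6, "C": 5.2, "D": 4.4},
    "VS": {"A": 3.5, "B": 3.6, "C": 6.1, "D": 3.1},
}
_TASK_MOD = {  # percentage points added to D coverage in the task window
    "HC": {"V": 3.1, "O": 2.7, "V-O": 7.2},
    "MCS+": {"V": 0.0, "O": 0.0, "V-O": 2.1},
    "MCS-": {"V": 0.0, "O": 0.0, "V-O": 0.0},
    "VS": {"V": 0.0, "O": 0.0, "V-O": 0.0},
}

#: Default group sizes of the emulated study.
GROUP_SIZES = {"HC": 9, "MCS+": 6, "MCS-": 6, "VS": 6}

#: SAM rating centroids (valence, arousal, dominance) of the three odor
#: groups used for the stimulus-selection clustering.
SAM_CENTROIDS = np.array([
    [7.2, 4.8, 4.5],  # high-valence / low-arousal
    [2.3, 5.2, 4.9],  # low-valence / medium-arousal
    [4.6, 6.8, 5.3],  # medium-valence / high-arousal
])


def doc_group_profiles() -> dict:
    """The four DOC-graded group profiles of the emulated study."""
    out = {}
    for g in GROUPS:
        d = _D_COVERAGE[g] / 100.0
        abc = _ABC_COVERAGE[g]
        w = sum(abc.values())
        cov = {c: (1.0 - d) * abc[c] / w for c in ("A", "B", "C")}
        cov["D"] = d
        out[g] = GroupProfile(g, cov, dict(_DWELL_MS[g]), dict(_GFP_UV[g]),
                              dict(_TASK_MOD[g]))
    return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_canonical_templates(ch_names=_montage.DEFAULT_32, K: int = 4) -> TemplateSet:
    """Idealized average-referenced, unit-GFP archetype maps (A-D first)."""
    positions = _montage.channel_positions(ch_names)
    maps = _montage.canonical_maps(positions, K)
    labels = list(_montage.CANONICAL_LABELS[:K]) if K <= 4 else list(range(K))
    return TemplateSet(maps=maps, labels=labels, ch_names=list(ch_names),
                       provenance="canonical")


def _entry_weights(stationary: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Entry weights w so the no-self-transition chain with
    P(i->j) ∝ w_j (j != i) has embedded stationary distribution
    ``stationary``.  Fixed-point iteration on the 4-class chain."""
    q = stationary / stationary.sum()
    active = q > 0
    if active.sum() == 1:
        return q
    w = q.copy()
    for _ in range(n_iter):
        P = np.where(active[None, :] & active[:, None], w[None, :], 0.0)
        np.fill_diagonal(P, 0.0)
        P = P / np.where(P.sum(1, keepdims=True) == 0, 1, P.sum(1, keepdims=True))
        vals, vecs = np.linalg.eig(P.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
        pi = np.abs(pi) / np.abs(pi).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(active, w * np.where(pi > 0, q / np.maximum(pi, 1e-12), 1.0), 0.0)
        w = w / w.sum()
    return w


def simulate_state_sequence(profile: GroupProfile, duration_s: float, fs: float,
                            seed=None) -> GroundTruth:
    """Semi-Markov microstate sequence with gamma(shape 2) dwell times.

    Class entry probabilities are calibrated so that the empirical
    coverage matches the profile's targets and per-class mean dwell
    matches ``dwell_ms`` (both asymptotically).  Consecutive segments
    always differ in class; a random ±1 polarity sign is attached to
    each segment.
    """
    n_total = int(round(duration_s * fs))
    if n_total < 10:
        raise ValueError("need at least 10 samples")
    rng = np.random.default_rng(seed)
    classes = profile.classes
    cov = np.array([profile.coverage[c] for c in classes])
    dwell = np.array([profile.dwell_ms[c] for c in classes]) / 1000.0  # s

    if np.count_nonzero(cov) == 1:
        k = int(np.argmax(cov))
        labels = np.full(n_total, k, dtype=int)
        segs = pd.DataFrame({"class": [k], "start": [0], "end": [n_total],
                             "sign": [int(rng.choice([-1, 1]))]})
        return GroundTruth(labels, segs, fs)

    stationary = cov / dwell
    w = _entry_weights(stationary)
    shape = 2.0

    labels = np.empty(n_total, dtype=int)
    seg_rows = []
    pos = 0
    current = int(rng.choice(len(classes), p=stationary / stationary.sum()))
    while pos < n_total:
        mean_d = dwell[current]
        length = max(1, int(round(rng.gamma(shape, mean_d / shape) * fs)))
        end = min(pos + length, n_total)
        labels[pos:end] = current
        seg_rows.append((current, pos, end, int(rng.choice([-1, 1]))))
        pos = end
        probs = w.copy()
        probs[current] = 0.0
        if probs.sum() == 0:
            break
        current = int(rng.choice(len(classes), p=probs / probs.sum()))
    segs = pd.DataFrame(seg_rows, columns=["class", "start", "end", "sign"])
    return GroundTruth(labels, segs, fs)


def _spatial_noise(rng, positions: np.ndarray, n_samples: int, fs: float,
                   corr_length: float) -> np.ndarray:
    """Spatially correlated, 0.5-50 Hz band-limited, average-referenced noise."""
    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2.0 * corr_length**2)) + 1e-6 * np.eye(len(positions))
    L = np.linalg.cholesky(cov)
    noise = L @ rng.standard_normal((len(positions), n_samples))
    if n_samples > 30:
        sos = sps.butter(4, [0.5, min(50.0, 0.45 * fs)], btype="bandpass",
                         fs=fs, output="sos")
        noise = sps.sosfiltfilt(sos, noise, axis=1)
    return noise - noise.mean(axis=0, keepdims=True)


def synthesize_eeg(templates: TemplateSet, truth: GroundTruth,
                   profile: GroupProfile, config: SimulationConfig,
                   rng=None) -> EEGRecording:
    """Forward model: per-segment sign x envelope x template (+ noise)."""
    if templates.maps.shape[1] != config.n_channels:
        raise ValueError("template channel count does not match the config")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    fs = truth.fs
    n = truth.labels.size
    classes = profile.classes
    gfp = {i: profile.gfp_uv[c] for i, c in enumerate(classes)}

    amplitude = np.empty(n)
    signs = np.empty(n)
    t = np.arange(n) / fs
    for cls, start, end, sign in truth.segments.itertuples(index=False):
        f = rng.uniform(8.0, 12.0)
        phase = rng.uniform(0, 2 * np.pi)
        amplitude[start:end] = gfp[cls] * (
            1.0 + 0.3 * np.sin(2 * np.pi * f * t[start:end] + phase)
        )
        signs[start:end] = sign
    data = (templates.maps[truth.labels] * (signs * amplitude)[:, None]).T

    if config.noise_level > 0:
        positions = _montage.channel_positions(templates.ch_names)
        noise = _spatial_noise(rng, positions, n, fs, config.noise_corr_length)
        signal_rms = np.sqrt(np.mean(data**2))
        noise_rms = np.sqrt(np.mean(noise**2))
        data = data + noise * (config.noise_level * signal_rms / noise_rms)

    return EEGRecording(data=data, fs=fs, ch_names=list(templates.ch_names),
                        reference="average")


def simulate_recording(profile: GroupProfile, templates: TemplateSet,
                       config: SimulationConfig, duration_s: float,
                       seed=None):
    """One resting recording: (EEGRecording, GroundTruth)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = simulate_state_sequence(profile, duration_s, config.fs,
                                    rng.integers(2**31 - 1))
    rec = synthesize_eeg(templates, truth, profile, config, rng)
    return rec, truth


def simulate_cohort(profiles: dict, sizes: dict, config: SimulationConfig,
                    templates: TemplateSet | None = None,
                    duration_s: float = 300.0):
    """A cohort of resting recordings: list of (rec, truth, group_label).

    Per-subject seeds are spawned deterministically from ``config.seed``.
    """
    templates = templates or make_canonical_templates()
    children = np.random.SeedSequence(config.seed).spawn(sum(sizes.values()))
    out = []
    i = 0
    for group, n in sizes.items():
        for _ in range(n):
            rec, truth = simulate_recording(
                profiles[group], templates, config, duration_s,
                seed=children[i])
            out.append((rec, truth, group))
            i += 1
    return out


def simulate_task_session(profile: GroupProfile, condition: str,
                          config: SimulationConfig,
                          templates: TemplateSet | None = None, seed=None):
    """One rest/task/rest session with annotated windows.

    During the task window the Microstate-D coverage target is shifted by
    the profile's modulation for ``condition``; the rest windows use the
    unmodulated profile.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    templates = templates or make_canonical_templates()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    task_profile = profile.modulated(condition)

    parts, offset = [], 0
    for prof, dur in ((profile, config.rest_s), (task_profile, config.task_s),
                      (profile, config.post_rest_s)):
        gt = simulate_state_sequence(prof, dur, config.fs, rng.integers(2**31 - 1))
        segs = gt.segments.copy()
        segs[["start", "end"]] += offset
        parts.append((gt.labels, segs))
        offset += gt.labels.size
    labels = np.concatenate([p[0] for p in parts])
    segments = pd.concat([p[1] for p in parts], ignore_index=True)
    truth = GroundTruth(labels, segments, config.fs)

    rec = synthesize_eeg(templates, truth, profile, config, rng)
    rec.annotations = [
        (0.0, config.rest_s, "rest"),
        (config.rest_s, config.task_s, "task"),
        (config.rest_s + config.task_s, config.post_rest_s, "post_rest"),
    ]
    return rec, truth


def simulate_sam_ratings(centroids=SAM_CENTROIDS, spread=0.3, n_odors: int = 16,
                         seed=None) -> pd.DataFrame:
    """SAM valence/arousal/dominance ratings for ``n_odors`` odors.

    Each odor is assigned a latent group (round-robin over centroids) and
    rated as centroid + N(0, spread), clipped to the 1-9 SAM range.
    """
    centroids = np.asarray(centroids, float)
    rng = np.random.default_rng(seed)
    groups = np.arange(n_odors) % len(centroids)
    vals = centroids[groups] + rng.normal(0.0, spread, size=(n_odors, 3))
    vals = np.clip(vals, 1.0, 9.0)
    return pd.DataFrame({
        "odor": [f"odor_{i + 1:02d}" for i in range(n_odors)],
        "valence": vals[:, 0], "arousal": vals[:, 1], "dominance": vals[:, 2],
        "latent_group": groups,
    })


def summary_matched_sample(mean: float, sd: float, n: int, seed=None) -> np.ndarray:
    """A seeded draw affinely rescaled to the exact sample mean and SD.

    Bridges summary-statistic inference and raw-data inference: the
    returned vector has sample mean ``mean`` and sample SD ``sd``
    (n-1 denominator) to ~1e-12, so a raw-data test on it must agree
    with the corresponding summary-statistic test.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = x - x.mean()
    s = x.std(ddof=1)
    if s == 0:  # astronomically unlikely; keep the contract anyway
        x = np.linspace(-1, 1, n)
        x = x - x.mean()
        s = x.std(ddof=1)
    return mean + sd * x / s


def write_ground_truth(truth: GroundTruth, profile: GroupProfile,
                       config: SimulationConfig, csv_path, json_path) -> None:
    """Sidecar files: segment table (CSV) and profile + seed (JSON)."""
    truth.segments.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump({"profile": asdict(profile), "config": asdict(config)}, fh,
                  indent=2)
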