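"""Back-fitting: template-guided segmentation and microstate parameters.

Given a template set, every EEG sample is assigned to the class whose
map has the highest *absolute* spatial correlation with the sample
topography (polarity-invariant, matching the oscillatory nature of the
sources).  Segments shorter than a minimum duration are then smoothed
away, and the standard temporal parameters — coverage, mean duration,
occurrence rate — plus per-class mean GFP and global goodness-of-fit
(GEV and residual SD) are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import TemplateSet, global_field_power
from .io import EEGRecording

#: Label used for samples that cannot be assigned (zero GFP).
UNASSIGNED = -1
_TIE_TOL = 1e-12


@dataclass
class Segmentation:
    """Per-sample microstate labels with the winning |r| track."""

    labels: np.ndarray  # int class index per sample, UNASSIGNED for none
    correlation: np.ndarray  # |r| to the winning template (0 if unassigned)
    fs: float
    n_classes: int

    def segment_table(self) -> pd.DataFrame:
        """Run-length encoding: one row per contiguous segment."""
        starts, ends, classes = _run_lengths(self.labels)
        return pd.DataFrame({
            "class": classes,
            "start": starts,
            "end": ends,  # exclusive
            "duration_ms": (ends - starts) * 1000.0 / self.fs,
        })


@dataclass
class FitMetrics:
    """Template goodness of fit: GEV ("R^2") and residual SD (uV)."""

    r2: float
    residual_sd: float


def _run_lengths(labels: np.ndarray):
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.array([], int), np.array([], int), np.array([], int)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    return starts, ends, labels[starts]


def _correlation_tracks(rec: EEGRecording, templates: TemplateSet) -> np.ndarray:
    """Signed spatial correlation of every sample to every template, (T, K)."""
    X = rec.data - rec.data.mean(axis=0, keepdims=True)
    M = templates.maps - templates.maps.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(X, axis=0)
    mn = np.linalg.norm(M, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X.T @ M.T) / (xn[:, None] * mn[None, :])
    r[xn == 0] = 0.0
    return r


def _check_montage(rec: EEGRecording, templates: TemplateSet) -> None:
    if templates.maps.shape[1] != rec.n_channels:
        raise ValueError("template channel count does not match the recording")
    if templates.ch_names is not None and list(templates.ch_names) != list(rec.ch_names):
        raise ValueError("template montage does not match the recording")


def backfit(rec: EEGRecording, templates: TemplateSet) -> Segmentation:
    """Assign each sample to the template with the highest |r|.

    Ties (within 1e-12) go to the lowest class index; zero-GFP samples
    are left unassigned.
    """
    if rec.reference != "average":
        raise ValueError("recording must be average-referenced before backfit")
    _check_montage(rec, templates)
    r = np.abs(_correlation_tracks(rec, templates))
    best = r.max(axis=1)
    # first index within tie tolerance of the maximum
    labels = np.argmax(r >= best[:, None] - _TIE_TOL, axis=1)
    zero = np.linalg.norm(
        rec.data - rec.data.mean(axis=0, keepdims=True), axis=0
    ) == 0
    labels[zero] = UNASSIGNED
    best[zero] = 0.0
    return Segmentation(labels=labels, correlation=best, fs=rec.fs,
                        n_classes=templates.K)


def smooth_segmentation(seg: Segmentation, rec: EEGRecording,
                        templates: TemplateSet, min_duration_ms: float = 30.0,
                        fs: float | None = None) -> Segmentation:
    """Remove interior segments shorter than ``min_duration_ms``.

    Iteratively, each too-short interior segment is split between its two
    flanking classes: walking in from the left edge, samples stay with
    the left class while its |r| is at least the right class's |r|; the
    remainder joins the right class.  The first and last segments have no
    neighbor on one side and are exempt.  Each pass strictly reduces the
    segment count, so termination is guaranteed; on exit no interior
    segment is below threshold.
    """
    if min_duration_ms < 0:
        raise ValueError("min_duration_ms must be >= 0")
    fs = fs or seg.fs
    min_len = int(np.ceil(min_duration_ms * fs / 1000.0))
    labels = seg.labels.copy()
    if min_len <= 1 or labels.size == 0:
        return Segmentation(labels, seg.correlation.copy(), fs, seg.n_classes)
    r = np.abs(_correlation_tracks(rec, templates))

    while True:
        starts, ends, classes = _run_lengths(labels)
        n_seg = len(starts)
        short = [
            i for i in range(1, n_seg - 1)
            if ends[i] - starts[i] < min_len and classes[i] != UNASSIGNED
        ]
        if not short:
            break
        # only segments whose flanking segments are untouched this pass,
        # so neighbor classes are never stale (adjacent short segments
        # would otherwise swap labels forever)
        independent = []
        for i in short:
            if not independent or i - independent[-1] > 1:
                independent.append(i)
        changed = False
        for i in independent:
            s, e = starts[i], ends[i]
            left, right = classes[i - 1], classes[i + 1]
            if left == UNASSIGNED and right == UNASSIGNED:
                continue
            changed = True
            if left == UNASSIGNED:
                labels[s:e] = right
                continue
            if right == UNASSIGNED:
                labels[s:e] = left
                continue
            # split point: first sample where the right class wins
            wins_left = r[s:e, left] >= r[s:e, right]
            losers = np.flatnonzero(~wins_left)
            split = s + (losers[0] if losers.size else e - s)
            labels[s:split] = left
            labels[split:e] = right
        if not changed:
            break

    correlation = np.where(
        labels == UNASSIGNED, 0.0, r[np.arange(labels.size), np.clip(labels, 0, None)]
    )
    return Segmentation(labels=labels, correlation=correlation, fs=fs,
                        n_classes=seg.n_classes)


def microstate_parameters(seg: Segmentation, rec: EEGRecording | None = None,
                          fs: float | None = None) -> pd.DataFrame:
    """Coverage (%), mean duration (ms), occurrence (/s), mean GFP (uV).

    One row per class (0..K-1).  Coverage is relative to *assigned*
    samples; classes that never occur report zeros.  ``rec`` is needed
    only for the GFP column.
    """
    fs = fs or seg.fs
    labels = seg.labels
    assigned = labels != UNASSIGNED
    n_assigned = int(assigned.sum())
    starts, ends, classes = _run_lengths(labels)
    gfp = global_field_power(rec) if rec is not None else None

    rows = []
    for k in range(seg.n_classes):
        mask = labels == k
        n_k = int(mask.sum())
        seg_mask = classes == k
        n_segs = int(seg_mask.sum())
        if n_k == 0:
            rows.append({"class": k, "coverage": 0.0, "duration_ms": 0.0,
                         "occurrence": 0.0, "gfp": 0.0})
            continue
        seg_lens = (ends - starts)[seg_mask]
        rows.append({
            "class": k,
            "coverage": 100.0 * n_k / n_assigned,
            "duration_ms": float(seg_lens.mean()) * 1000.0 / fs,
            "occurrence": n_segs / (n_assigned / fs),
            "gfp": float(gfp[mask].mean()) if gfp is not None else np.nan,
        })
    return pd.DataFrame(rows).set_index("class")


def fit_metrics(seg: Segmentation, rec: EEGRecording,
                templates: TemplateSet) -> FitMetrics:
    """Global explained variance and residual standard deviation.

    GEV = sum_t (GFP_t * r_t)^2 / sum_t GFP_t^2, with r_t the signed
    correlation between sample t and its assigned template.  The residual
    SD is the standard deviation over all channels x samples of
    v(t) - a(t) T_k(t), with a(t) the least-squares scalar projection.
    Unassigned samples are excluded from both.
    """
    _check_montage(rec, templates)
    r_all = _correlation_tracks(rec, templates)
    labels = seg.labels
    assigned = labels != UNASSIGNED
    X = rec.data - rec.data.mean(axis=0, keepdims=True)
    gfp = np.sqrt(np.mean(X**2, axis=0))

    r_win = np.zeros(labels.size)
    r_win[assigned] = r_all[assigned, labels[assigned]]
    denom = float(np.sum(gfp[assigned] ** 2))
    gev = float(np.sum((gfp[assigned] * r_win[assigned]) ** 2) / denom) if denom else 0.0

    T = templates.maps  # (K, C), unit GFP
    tn2 = np.sum(T**2, axis=1)
    resid = X[:, assigned].copy()
    lab = labels[assigned]
    a = np.einsum("ct,tc->t", X[:, assigned], T[lab]) / tn2[lab]
    resid -= T[lab].T * a[None, :]
    residual_sd = float(resid.std()) if resid.size else 0.0
    return FitMetrics(r2=gev, residual_sd=residual_sd)


def tidy_parameters(params: pd.DataFrame, labels=None, **meta) -> pd.DataFrame:
    """Long-format (one row per class x metric) view of a parameter table.

    ``meta`` columns (subject, group, condition, template, ...) are
    broadcast onto every row — the shape consumed by the statistics layer.
    """
    out = params.reset_index().melt(id_vars="class", var_name="metric",
                                    value_name="value")
    if labels is not None:
        out["class"] = out["class"].map(lambda k: labels[k])
    for key, val in meta.items():
        out[key] = val
    return out
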