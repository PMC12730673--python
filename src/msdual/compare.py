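"""Comparing resting-state and task-state global templates.

Three tools: the K x K absolute spatial-correlation matrix between two
template sets, a permutation test on topographies (TANOVA), and the
dual-template back-fitting comparison in which the same task recordings
are segmented against both global templates and the resulting parameters
are compared pairwise within each group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .backfit import backfit, fit_metrics, microstate_parameters, smooth_segmentation, tidy_parameters
from .clustering import TemplateSet, abs_spatial_correlation, gmd
from .stats import cohens_d, GroupSummary


def correlation_matrix(set_a: TemplateSet, set_b: TemplateSet) -> pd.DataFrame:
    """|r| between every map of ``set_a`` (rows) and ``set_b`` (columns)."""
    mat = np.array([
        [abs_spatial_correlation(a, b) for b in set_b.maps] for a in set_a.maps
    ])
    return pd.DataFrame(mat, index=list(set_a.labels), columns=list(set_b.labels))


def matched_pair_correlations(set_a: TemplateSet, set_b: TemplateSet) -> pd.Series:
    """|r| between same-labeled maps of the two sets."""
    common = [l for l in set_a.labels if l in set_b.labels]
    return pd.Series(
        {l: abs_spatial_correlation(set_a.map_for(l), set_b.map_for(l)) for l in common},
        name="abs_r",
    )


def _aligned_mean(maps: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Mean of unit-GFP maps, polarity-aligned to a reference map.

    The default reference is the dominant eigenvector of the maps' own
    cross-product matrix (order- and polarity-invariant); passing a
    common reference makes group means comparable under permutation.
    """
    maps = np.asarray(maps, float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(maps**2, axis=1, keepdims=True))
    if np.any(gfp == 0):
        raise ValueError("zero-GFP map in TANOVA input")
    maps = maps / gfp
    if reference is None:
        _, vecs = np.linalg.eigh(maps.T @ maps)
        reference = vecs[:, -1]
    signs = np.sign(maps @ reference)
    signs[signs == 0] = 1.0
    return (signs[:, None] * maps).mean(axis=0)


def tanova(group_a, group_b, n_perm: int = 5000, seed=None) -> dict:
    """Topographic permutation test between two sets of maps.

    The statistic is the global map dissimilarity between the two
    polarity-aligned group-mean topographies (both groups aligned to the
    pooled data's dominant eigenvector, so the statistic does not depend
    on map ordering); the null distribution is built by permuting group
    membership.  Returns the observed GMD and the Monte-Carlo p-value
    (1 + #{perm >= obs}) / (1 + n_perm), which is never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    A = np.asarray(group_a, float)
    B = np.asarray(group_b, float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("each group needs at least 2 maps")
    rng = np.random.default_rng(seed)

    pooled0 = np.vstack([A, B])
    pooled0 = pooled0 - pooled0.mean(axis=1, keepdims=True)
    gfp0 = np.sqrt(np.mean(pooled0**2, axis=1, keepdims=True))
    if np.any(gfp0 == 0):
        raise ValueError("zero-GFP map in TANOVA input")
    _, vecs = np.linalg.eigh((pooled0 / gfp0).T @ (pooled0 / gfp0))
    ref = vecs[:, -1]

    def statistic(x, y):
        return gmd(_aligned_mean(x, ref), _aligned_mean(y, ref))

    observed = statistic(A, B)
    pooled = np.vstack([A, B])
    n_a = A.shape[0]
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        if statistic(pooled[idx[:n_a]], pooled[idx[n_a:]]) >= observed - 1e-15:
            count += 1
    return {"statistic": float(observed), "p": (1 + count) / (1 + n_perm),
            "n_perm": n_perm}


def subject_class_mean_maps(recordings_with_groups, templates: TemplateSet,
                            min_duration_ms: float = 30.0) -> pd.DataFrame:
    """Per-subject polarity-aligned mean map of each microstate class.

    Back-fits each recording, then averages the assigned samples of each
    class after unit-GFP scaling and polarity alignment to the class
    template.  Rows: subject x class; the map is stored as an object
    column (ndarray).
    """
    rows = []
    for subject, (rec, group) in enumerate(recordings_with_groups):
        seg = backfit(rec, templates)
        seg = smooth_segmentation(seg, rec, templates, min_duration_ms)
        X = rec.data - rec.data.mean(axis=0, keepdims=True)
        for k, label in enumerate(templates.labels):
            mask = seg.labels == k
            if mask.sum() < 2:
                continue
            maps = X[:, mask].T
            gfp = np.sqrt(np.mean(maps**2, axis=1, keepdims=True))
            maps = maps / np.where(gfp == 0, 1, gfp)
            signs = np.sign(maps @ templates.maps[k])
            signs[signs == 0] = 1
            rows.append({"subject": subject, "group": group, "class": label,
                         "map": (signs[:, None] * maps).mean(axis=0)})
    return pd.DataFrame(rows)


def dual_template_comparison(task_recordings_by_group: dict,
                             rest_template: TemplateSet,
                             task_template: TemplateSet,
                             min_duration_ms: float = 30.0,
                             alpha: float = 0.05):
    """Back-fit the same task data against both global templates.

    Returns ``(tidy, tests)``:

    * ``tidy`` — long table (subject, group, template, class, metric,
      value) of coverage/GFP/duration per subject under each template,
      plus the per-subject fit metrics (r2, residual_sd);
    * ``tests`` — per (group, class, metric) paired comparison of the
      two templates: paired t-test when the differences pass a
      Shapiro-Wilk normality gate, Wilcoxon signed-rank otherwise, with
      the equal-weight Cohen's d computed from the group-level
      means/SDs of the two template conditions.
    """
    frames = []
    fit_rows = []
    for group, recs in task_recordings_by_group.items():
        for subject, rec in enumerate(recs):
            for tpl_name, tpl in (("rest", rest_template), ("task", task_template)):
                seg = backfit(rec, tpl)
                seg = smooth_segmentation(seg, rec, tpl, min_duration_ms)
                params = microstate_parameters(seg, rec)
                frames.append(tidy_parameters(
                    params, labels=list(tpl.labels), subject=f"{group}-{subject}",
                    group=group, template=tpl_name))
                fm = fit_metrics(seg, rec, tpl)
                fit_rows.append({"subject": f"{group}-{subject}", "group": group,
                                 "template": tpl_name, "r2": fm.r2,
                                 "residual_sd": fm.residual_sd})
    tidy = pd.concat(frames, ignore_index=True)
    fits = pd.DataFrame(fit_rows)

    tests = []
    metrics = ("coverage", "gfp", "duration_ms")
    for group in task_recordings_by_group:
        sub = tidy[tidy["group"] == group]
        for label in rest_template.labels:
            for metric in metrics:
                cell = sub[(sub["class"] == label) & (sub["metric"] == metric)]
                piv = cell.pivot(index="subject", columns="template", values="value")
                if len(piv) < 2 or piv.isna().any().any():
                    continue
                rest, task = piv["rest"].to_numpy(), piv["task"].to_numpy()
                diff = rest - task
                if np.allclose(diff, 0):
                    test, stat, p = "paired-t", 0.0, 1.0
                elif len(diff) >= 3 and sstats.shapiro(diff).pvalue > alpha \
                        and diff.std() > 0:
                    res = sstats.ttest_rel(rest, task)
                    test, stat, p = "paired-t", float(res.statistic), float(res.pvalue)
                else:
                    res = sstats.wilcoxon(rest, task)
                    test, stat, p = "wilcoxon", float(res.statistic), float(res.pvalue)
                d = 0.0 if np.allclose(diff, 0) else cohens_d(
                    GroupSummary(f"{group}-rest", len(rest), rest.mean(), rest.std(ddof=1)),
                    GroupSummary(f"{group}-task", len(task), task.mean(), task.std(ddof=1)),
                )
                tests.append({"group": group, "class": label, "metric": metric,
                              "test": test, "statistic": stat, "p": p,
                              "cohens_d": d, "mean_rest": rest.mean(),
                              "mean_task": task.mean()})
    return pd.concat([tidy, fits.melt(
        id_vars=["subject", "group", "template"], var_name="metric",
        value_name="value").assign(**{"class": "all"})], ignore_index=True), \
        pd.DataFrame(tests)
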