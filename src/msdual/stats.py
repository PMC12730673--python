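"""Group-level statistics for microstate parameters.

Implements the study's statistical layer: an assumption gate
(Shapiro-Wilk normality per group plus Levene homogeneity), one-way
ANOVA with partial eta squared — computable both from raw samples and
directly from reported (n, mean, SD) summaries — Kruskal-Wallis with
epsilon squared and Dunn-Bonferroni post hocs, Bonferroni-corrected
pairwise comparisons, Cohen's d, rank-biserial correlations, a linear
mixed model for the task design (condition x group fixed effects,
subject random intercepts, REML), and the k-means grouping of SAM odor
ratings.

Effect-size conventions: Cohen's d uses the equal-weight pooled SD
sqrt((s1^2+s2^2)/2) by default (the n-weighted pooled SD is available
via ``weighted=True``); epsilon squared is H (N+1) / (N^2 - 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class GroupSummary:
    """(label, n, mean, sd) of one group; sd uses the n-1 denominator."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_samples(cls, label, x) -> "GroupSummary":
        x = np.asarray(x, float)
        return cls(label, len(x), float(x.mean()), float(x.std(ddof=1)))


@dataclass
class TestResult:
    name: str
    statistic: float
    df: tuple
    p: float
    effect_name: str = ""
    effect: float = np.nan
    posthoc: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def anova_from_summary(groups) -> TestResult:
    """One-way ANOVA from per-group (n, mean, sd) summaries.

    SSB = sum n_g (m_g - m)^2 (m the n-weighted grand mean),
    SSW = sum (n_g - 1) s_g^2, F = MSB/MSW, and partial eta squared
    SSB / (SSB + SSW) — for a one-way design partial and plain eta
    squared coincide.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.n for g in groups], float)
    ms = np.array([g.mean for g in groups], float)
    sds = np.array([g.sd for g in groups], float)
    N, G = ns.sum(), len(groups)
    grand = (ns * ms).sum() / N
    ssb = float((ns * (ms - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = G - 1, int(N - G)
    if ssw == 0:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f = (ssb / df1) / (ssw / df2)
        p = float(sstats.f.sf(f, df1, df2))
    eta = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    return TestResult("one-way ANOVA", float(f), (df1, df2), p,
                      "partial eta squared", float(eta))


def anova_oneway(samples: dict) -> TestResult:
    """One-way ANOVA on raw per-group sample vectors.

    F and p come from :func:`scipy.stats.f_oneway`; the effect size is
    computed from the sums of squares.  Must agree with
    :func:`anova_from_summary` applied to the sample summaries.
    """
    keys = list(samples)
    arrays = [np.asarray(samples[k], float) for k in keys]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least two observations")
    res = sstats.f_oneway(*arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    eta = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    df1 = len(arrays) - 1
    df2 = sum(len(a) for a in arrays) - len(arrays)
    return TestResult("one-way ANOVA", float(res.statistic), (df1, df2),
                      float(res.pvalue), "partial eta squared", float(eta))


def assumption_gate(samples: dict, alpha: float = 0.05) -> str:
    """Choose the inference route: "parametric" or "nonparametric".

    Parametric iff every group passes Shapiro-Wilk normality and Levene's
    test (mean-centered) passes, all at ``alpha``.  Degenerate groups
    (constant values, or fewer than 3 observations) route to
    nonparametric.
    """
    arrays = [np.asarray(v, float) for v in samples.values()]
    for a in arrays:
        if len(a) < 3 or np.ptp(a) == 0:
            return "nonparametric"
        if sstats.shapiro(a).pvalue <= alpha:
            return "nonparametric"
    if sstats.levene(*arrays, center="mean").pvalue <= alpha:
        return "nonparametric"
    return "parametric"


# ---------------------------------------------------------------------------
# nonparametric route
# ---------------------------------------------------------------------------

def _dunn_bonferroni(samples: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Dunn's pairwise rank tests with tie correction and Bonferroni."""
    keys = list(samples)
    arrays = {k: np.asarray(samples[k], float) for k in keys}
    pooled = np.concatenate([arrays[k] for k in keys])
    N = len(pooled)
    ranks = sstats.rankdata(pooled)
    offsets = np.cumsum([0] + [len(arrays[k]) for k in keys])
    mean_ranks = {k: ranks[offsets[i]:offsets[i + 1]].mean()
                  for i, k in enumerate(keys)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    pairs = list(itertools.combinations(keys, 2))
    rows = []
    for a, b in pairs:
        na, nb = len(arrays[a]), len(arrays[b])
        se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sstats.norm.sf(abs(z))
        rows.append({"pair": f"{a} vs {b}", "z": z, "p_raw": p,
                     "p_adj": min(1.0, p * len(pairs)),
                     "rank_biserial": rank_biserial(arrays[a], arrays[b])})
    return pd.DataFrame(rows)


def kruskal_wallis(samples: dict, alpha: float = 0.05) -> TestResult:
    """Kruskal-Wallis H (tie-corrected) with epsilon squared.

    epsilon^2 = H (N + 1) / (N^2 - 1).  If p < alpha a Dunn-Bonferroni
    post-hoc table is attached.  When all observations are identical the
    tie correction is degenerate; H is reported as 0 with p = 1.
    """
    arrays = [np.asarray(v, float) for v in samples.values()]
    pooled = np.concatenate(arrays)
    N = len(pooled)
    if np.ptp(pooled) == 0:
        return TestResult("Kruskal-Wallis", 0.0, (len(arrays) - 1,), 1.0,
                          "epsilon squared", 0.0)
    res = sstats.kruskal(*arrays)
    h = float(res.statistic)
    eps2 = h * (N + 1) / (N**2 - 1)
    posthoc = _dunn_bonferroni(samples, alpha) if res.pvalue < alpha else None
    return TestResult("Kruskal-Wallis", h, (len(arrays) - 1,), float(res.pvalue),
                      "epsilon squared", float(eps2), posthoc)


# ---------------------------------------------------------------------------
# pairwise comparisons and effect sizes
# ---------------------------------------------------------------------------

def bonferroni_pairwise(samples: dict, base: str = "t") -> pd.DataFrame:
    """All pairwise comparisons, Bonferroni-adjusted over the pair count.

    ``base`` selects the per-pair test: "t" (Student), "welch", or
    "mannwhitney".  Adjusted p = min(1, raw p x number of pairs).
    """
    keys = list(samples)
    pairs = list(itertools.combinations(keys, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = np.asarray(samples[a], float), np.asarray(samples[b], float)
        if base == "t":
            res = sstats.ttest_ind(xa, xb)
            effect_name, effect = "cohens_d", cohens_d(
                GroupSummary.from_samples(a, xa), GroupSummary.from_samples(b, xb))
        elif base == "welch":
            res = sstats.ttest_ind(xa, xb, equal_var=False)
            effect_name, effect = "cohens_d", cohens_d(
                GroupSummary.from_samples(a, xa), GroupSummary.from_samples(b, xb))
        elif base == "mannwhitney":
            res = sstats.mannwhitneyu(xa, xb, alternative="two-sided")
            effect_name, effect = "rank_biserial", rank_biserial(xa, xb)
        else:
            raise ValueError(f"unknown base test {base!r}")
        rows.append({"pair": f"{a} vs {b}", "statistic": float(res.statistic),
                     "p_raw": float(res.pvalue),
                     "p_adj": min(1.0, float(res.pvalue) * m),
                     effect_name: effect})
    return pd.DataFrame(rows)


def cohens_d(summary1: GroupSummary, summary2: GroupSummary,
             weighted: bool = False) -> float:
    """Cohen's d between two groups from their summaries.

    Default pooling is the equal-weight sqrt((s1^2 + s2^2)/2);
    ``weighted=True`` uses the n-weighted pooled SD.
    """
    if summary1.sd == 0 and summary2.sd == 0:
        raise ValueError("Cohen's d undefined when both SDs are zero")
    if weighted:
        pooled = np.sqrt(
            ((summary1.n - 1) * summary1.sd**2 + (summary2.n - 1) * summary2.sd**2)
            / (summary1.n + summary2.n - 2)
        )
    else:
        pooled = np.sqrt((summary1.sd**2 + summary2.sd**2) / 2.0)
    return float((summary1.mean - summary2.mean) / pooled)


def rank_biserial(x, y=None, paired: bool = False) -> float:
    """Rank-biserial correlation.

    Independent samples: r = 2U/(n1 n2) - 1 with U the Mann-Whitney
    statistic of x.  Paired (y given and ``paired=True``, or y omitted
    and x holding differences): r = (W+ - W-)/(W+ + W-) on the signed
    ranks of the nonzero differences.
    """
    x = np.asarray(x, float)
    if y is not None and not paired:
        y = np.asarray(y, float)
        u = sstats.mannwhitneyu(x, y, alternative="two-sided").statistic
        return float(2.0 * u / (len(x) * len(y)) - 1.0)
    diff = x - np.asarray(y, float) if y is not None else x
    diff = diff[diff != 0]
    if diff.size == 0:
        return 0.0
    ranks = sstats.rankdata(np.abs(diff))
    w_pos = ranks[diff > 0].sum()
    w_neg = ranks[diff < 0].sum()
    return float((w_pos - w_neg) / (w_pos + w_neg))


# ---------------------------------------------------------------------------
# linear mixed model for the task design
# ---------------------------------------------------------------------------

def _interaction_denominator_df(df: pd.DataFrame, n_params: int) -> float:
    """Denominator df for within-subject fixed effects.

    Uses the between-within (containment) rule
    N - p - (S - G), which equals the Satterthwaite value
    (S - G)(C - 1) for a balanced complete group x condition design with
    one observation per subject-condition cell.
    """
    n_obs = len(df)
    n_subj = df["subject"].nunique()
    n_grp = df["group"].nunique()
    return float(max(1, n_obs - n_params - (n_subj - n_grp)))


def lmm_task_model(table: pd.DataFrame, value: str = "value",
                   alpha: float = 0.05):
    """Condition x group mixed model with subject random intercepts.

    Fits ``value ~ C(condition) * C(group)`` with a random intercept per
    subject by REML (statsmodels ``MixedLM``) and tests the
    condition-by-group interaction with a Wald F whose denominator df
    follow the between-within rule (see above).  Returns a dict with the
    fitted model, the fixed-effect table, the interaction test, and
    per-group pairwise condition contrasts.

    Raises ``ValueError`` for non-estimable designs (fewer than two
    conditions or subjects, or a singular fit).
    """
    import statsmodels.formula.api as smf

    req = {"subject", "group", "condition", value}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    if table["condition"].nunique() < 2 or table["subject"].nunique() < 2:
        raise ValueError("need >= 2 conditions and >= 2 subjects")

    df = table.copy()
    formula = f"{value} ~ C(condition) * C(group)"
    import warnings

    try:
        model = smf.mixedlm(formula, df, groups=df["subject"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = model.fit(reml=True)
            except np.linalg.LinAlgError:
                fit = model.fit(reml=True, method="powell")
    except Exception as exc:
        raise ValueError(f"mixed model not estimable: {exc}") from exc
    if not np.all(np.isfinite(fit.params)):
        raise ValueError("mixed model produced non-finite estimates")

    fe = pd.DataFrame({"estimate": fit.fe_params,
                       "se": fit.bse_fe,
                       "p": fit.pvalues[fit.fe_params.index]})

    inter_idx = [i for i, name in enumerate(fit.fe_params.index) if ":" in name]
    if not inter_idx:
        raise ValueError("model has no interaction terms (single group?)")
    L = np.zeros((len(inter_idx), len(fit.fe_params)))
    for row, i in enumerate(inter_idx):
        L[row, i] = 1.0
    cov = np.asarray(fit.cov_params())[: len(fit.fe_params), : len(fit.fe_params)]
    beta = fit.fe_params.to_numpy()
    lb = L @ beta
    lcov = L @ cov @ L.T
    wald = float(lb @ np.linalg.solve(lcov, lb))
    df_num = len(inter_idx)
    df_den = _interaction_denominator_df(df, len(fit.fe_params))
    f_stat = wald / df_num
    p = float(sstats.f.sf(f_stat, df_num, df_den))
    interaction = TestResult("condition x group interaction", f_stat,
                             (df_num, df_den), p)

    # per-group pairwise condition contrasts on the cell means
    contrasts = []
    conditions = sorted(df["condition"].unique())
    groups = sorted(df["group"].unique())
    names = list(fit.fe_params.index)

    def cell_vector(cond, grp):
        v = np.zeros(len(names))
        for i, name in enumerate(names):
            if name == "Intercept":
                v[i] = 1.0
            elif name == f"C(condition)[T.{cond}]":
                v[i] = 1.0
            elif name == f"C(group)[T.{grp}]":
                v[i] = 1.0
            elif name == f"C(condition)[T.{cond}]:C(group)[T.{grp}]":
                v[i] = 1.0
        return v

    for grp in groups:
        for c1, c2 in itertools.combinations(conditions, 2):
            cvec = cell_vector(c1, grp) - cell_vector(c2, grp)
            est = float(cvec @ beta)
            se = float(np.sqrt(cvec @ cov @ cvec))
            t = est / se if se > 0 else 0.0
            contrasts.append({
                "group": grp, "contrast": f"{c1} - {c2}", "estimate": est,
                "se": se, "t": t,
                "p": float(2 * sstats.t.sf(abs(t), df_den)),
            })
    return {"fit": fit, "fixed_effects": fe, "interaction": interaction,
            "contrasts": pd.DataFrame(contrasts)}


# ---------------------------------------------------------------------------
# SAM odor clustering
# ---------------------------------------------------------------------------

def vad_kmeans(ratings: pd.DataFrame, k: int = 3, n_init: int = 10, seed=None):
    """Euclidean k-means on valence/arousal/dominance odor ratings.

    Returns (labels, centroids DataFrame).  Thin wrapper over
    :class:`sklearn.cluster.KMeans` with seeded restarts.
    """
    from sklearn.cluster import KMeans

    cols = ["valence", "arousal", "dominance"]
    X = ratings[cols].to_numpy(float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    centroids = pd.DataFrame(km.cluster_centers_, columns=cols)
    return km.labels_, centroids
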