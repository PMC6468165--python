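"""Intrinsic and exacerbated pause-site detection.

An *intrinsic pause site* (IPS) is an editing stop site whose normalized
sequence count is a Tukey outlier within one replicate: count >
Q3 + 1.5*(Q3 - Q1) over the full zero-filled stop-site histogram
(pre-edited and fully edited transcripts excluded from the histogram).
Replicate-consensus calls require the site to be flagged in at least
``min_support`` replicates.

An *exacerbated pause site* (EPS) is a stop site whose (re)normalized
count increases significantly upon knockdown of an editing factor:
two-sample Student's t-test P < 0.05, Benjamini-Hochberg q < 0.05 across
the transcript's sites, with the increase consistent in every induced
replicate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import SamplePopulation, class_fractions, renormalize_excluding, stop_site_histogram
from .reads import FULLY_EDITED, PRE_EDITED


def ips_threshold(histogram) -> float:
    """Tukey outlier threshold Q3 + 1.5*IQR of a stop-site histogram.

    Quartiles use linear interpolation of order statistics.  The histogram
    must cover every site 0..m with zero fill: the outlier statistic needs
    the full distribution, and the class exclusions govern which reads are
    counted, not which sites appear.
    """
    h = np.asarray(histogram, dtype=float)
    if h.size == 0:
        raise ValueError("empty histogram")
    q1, q3 = np.percentile(h, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


def _as_hist_matrix(replicates, exclude=None) -> np.ndarray:
    if isinstance(replicates[0], SamplePopulation):
        kw = {} if exclude is None else {"exclude": exclude}
        return np.vstack([stop_site_histogram(p, **kw) for p in replicates])
    return np.vstack([np.asarray(h, dtype=float) for h in replicates])


def detect_ips(
    replicates,
    min_support: int = 4,
    site_labeler=None,
) -> pd.DataFrame:
    """Replicate-consensus IPS calls.

    ``replicates`` is a list of :class:`SamplePopulation` or of stop-site
    histogram vectors over a common site domain.  Returns one row per site
    flagged in at least ``min_support`` replicates, with the per-replicate
    thresholds, the support count (so full-support calls are
    distinguishable from n-1 support) and the mean fold of the site's
    count over the per-replicate threshold.
    """
    if len(replicates) < 2:
        raise ValueError("IPS detection requires at least 2 replicates")
    H = _as_hist_matrix(replicates)
    if len({h.size for h in H}) > 1:
        raise ValueError("replicate histograms cover different site domains")
    if site_labeler is None and isinstance(replicates[0], SamplePopulation):
        site_labeler = replicates[0].table.site_label
    thresholds = np.array([ips_threshold(h) for h in H])
    flags = H > thresholds[:, None]
    support = flags.sum(axis=0)
    rows = []
    for s in np.nonzero(support >= min_support)[0]:
        with np.errstate(divide="ignore"):
            folds = np.where(thresholds > 0, H[:, s] / np.where(thresholds > 0, thresholds, 1.0), np.inf)
        rows.append({
            "site": int(s),
            "site_label": site_labeler(int(s)) if site_labeler else int(s),
            "support": int(support[s]),
            "n_replicates": H.shape[0],
            "fold_over_threshold": float(np.mean(folds)),
            "mean_count": float(H[:, s].mean()),
            "per_replicate_count": H[:, s].tolist(),
            "per_replicate_threshold": thresholds.tolist(),
            "per_replicate_flag": flags[:, s].tolist(),
        })
    return pd.DataFrame(rows, columns=[
        "site", "site_label", "support", "n_replicates", "fold_over_threshold",
        "mean_count", "per_replicate_count", "per_replicate_threshold",
        "per_replicate_flag",
    ])


def _student_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample equal-variance t-test with an explicit zero-variance policy.

    When every observation in both groups is identical the difference is
    exactly zero and p = 1; when the pooled variance is zero but the means
    differ, a machine-epsilon variance floor is used instead of dividing
    by zero (the test is then decisively significant without inventing an
    arbitrary statistic).
    """
    na, nb = len(a), len(b)
    diff = a.mean() - b.mean()
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        if diff == 0:
            return 0.0, 1.0
        sp2 = np.finfo(float).eps
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


def _ttest(a, b, welch: bool = False) -> tuple[float, float]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if welch:
        res = stats.ttest_ind(a, b, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        if np.isnan(t):
            return _student_t(a, b)
        return t, p
    return _student_t(a, b)


def eps_table(
    induced: np.ndarray,
    uninduced: np.ndarray,
    alpha: float = 0.05,
    q_alpha: float = 0.05,
    welch: bool = False,
    rule: str = "group",
    low_count: float = 500.0,
    site_labeler=None,
) -> pd.DataFrame:
    """Per-site EPS statistics from stop-site count matrices.

    ``induced``/``uninduced`` are (n_samples, n_sites) matrices of
    (re)normalized stop-site counts.  ``rule='group'`` tests the induced
    group against the uninduced group; ``rule='per_replicate'`` instead
    tests every induced replicate separately against the uninduced group
    (one-sample t-test) and takes the worst p.  Both rules additionally
    require every induced replicate to exceed the uninduced mean.
    Calls with mean count below ``low_count`` in both groups carry a
    low-abundance annotation.
    """
    induced = np.atleast_2d(np.asarray(induced, dtype=float))
    uninduced = np.atleast_2d(np.asarray(uninduced, dtype=float))
    if induced.shape[0] < 2 or uninduced.shape[0] < 2:
        raise ValueError("EPS detection requires at least 2 samples per group")
    if induced.shape[1] != uninduced.shape[1]:
        raise ValueError("group site domains differ")
    n_sites = induced.shape[1]
    mean_u = uninduced.mean(axis=0)
    mean_i = induced.mean(axis=0)
    ts, ps = np.empty(n_sites), np.empty(n_sites)
    for s in range(n_sites):
        if rule == "per_replicate":
            p_each = []
            for x in induced[:, s]:
                res = stats.ttest_1samp(uninduced[:, s], x)
                p = float(res.pvalue)
                if np.isnan(p):
                    p = 1.0 if x == mean_u[s] else 0.0
                p_each.append(p)
            ps[s] = max(p_each)
            ts[s], _ = _ttest(induced[:, s], uninduced[:, s], welch)
        else:
            ts[s], ps[s] = _ttest(induced[:, s], uninduced[:, s], welch)
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    direction = (induced > mean_u[None, :]).all(axis=0)
    is_eps = (ps < alpha) & (qs < q_alpha) & (mean_i > mean_u) & direction
    low = (mean_i < low_count) & (mean_u < low_count)
    return pd.DataFrame({
        "site": np.arange(n_sites),
        "site_label": [site_labeler(s) if site_labeler else s for s in range(n_sites)],
        "mean_uninduced": mean_u,
        "mean_induced": mean_i,
        "t": ts,
        "p": ps,
        "q": qs,
        "direction_consistent": direction,
        "low_abundance": low,
        "is_eps": is_eps,
    })


def detect_eps(
    induced_pops: list[SamplePopulation],
    uninduced_pops: list[SamplePopulation],
    alpha: float = 0.05,
    q_alpha: float = 0.05,
    drop_pre: bool = True,
    drop_full: bool = False,
    welch: bool = False,
    rule: str = "group",
    low_count: float = 500.0,
) -> pd.DataFrame:
    """EPS statistics between induced and uninduced sample populations.

    With ``drop_pre`` (default) each population is first stripped of its
    pre-edited sequences and renormalized, so the comparison concerns only
    transcripts that have entered the editing pathway; ``drop_full``
    additionally removes fully edited sequences from the renormalized pool
    (they are retained by default).
    """
    drop = set()
    if drop_pre:
        drop.add(PRE_EDITED)
    if drop_full:
        drop.add(FULLY_EDITED)
    if drop:
        induced_pops = [renormalize_excluding(p, drop) for p in induced_pops]
        uninduced_pops = [renormalize_excluding(p, drop) for p in uninduced_pops]
    ind = _as_hist_matrix(induced_pops)
    unind = _as_hist_matrix(uninduced_pops)
    labeler = induced_pops[0].table.site_label if isinstance(induced_pops[0], SamplePopulation) else None
    return eps_table(ind, unind, alpha, q_alpha, welch, rule, low_count, labeler)


def class_change_test(
    induced_pops: list[SamplePopulation],
    uninduced_pops: list[SamplePopulation],
    welch: bool = False,
) -> pd.DataFrame:
    """t-test of pre/partial/full class percentages between sample groups."""
    if len(induced_pops) < 2 or len(uninduced_pops) < 2:
        raise ValueError("class change test requires at least 2 samples per group")
    fi = pd.DataFrame([class_fractions(p) for p in induced_pops])
    fu = pd.DataFrame([class_fractions(p) for p in uninduced_pops])
    rows = []
    for cls in ("pre", "partial", "full"):
        t, p = _ttest(fi[cls], fu[cls], welch)
        rows.append({
            "eclass": cls,
            "mean_induced_pct": fi[cls].mean(),
            "mean_uninduced_pct": fu[cls].mean(),
            "t": t,
            "p": p,
        })
    return pd.DataFrame(rows)
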