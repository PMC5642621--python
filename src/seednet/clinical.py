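"""Correlation, covariate and survival validation of candidate genes.

Candidates are validated three ways: Pearson correlation between each
seed-candidate pair retained in the subnetwork (two-sided p from the t
reference with n-2 df, Benjamini-Hochberg adjusted across the supplied
pairs); Welch t-tests of each candidate's expression against binary
clinical covariates; and survival stratification, where per-sample risk
scores (the sum of signature-gene expressions) are median-split into
low/high groups compared by the log-rank test.  The log-rank chi-square
equals the score test at beta = 0 of a single-covariate proportional-
hazards fit on the group indicator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import PairStat, RiskStratification, SeednetError

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def pairwise_correlation(expr: pd.DataFrame, pairs) -> list[PairStat]:
    """Pearson r and two-sided p for each gene pair, with BH adjustment.

    Uses pairwise-complete samples; pairs with a constant gene are
    flagged with NaN statistics and excluded from the adjustment.
    """
    results = []
    for a, b in pairs:
        for g in (a, b):
            if g not in expr.index:
                raise SeednetError(f"gene {g!r} not in expression matrix")
        xy = expr.loc[[a, b]].T.dropna()
        n = len(xy)
        if n < 3:
            raise SeednetError(f"pair ({a}, {b}): fewer than 3 complete samples")
        x, y = xy[a].to_numpy(float), xy[b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("pair (%s, %s): constant gene, no p-value", a, b)
            results.append(PairStat(a, b, float("nan"), float("nan"), n=n))
            continue
        r, p = stats.pearsonr(x, y)
        results.append(PairStat(a, b, float(r), max(float(p), P_FLOOR), n=n))

    ps = [st.p for st in results if np.isfinite(st.p)]
    if ps:
        adj = multipletests(ps, method="fdr_bh")[1]
        it = iter(adj)
        results = [
            PairStat(st.gene_a, st.gene_b, st.statistic, st.p,
                     float(next(it)) if np.isfinite(st.p) else None, st.n)
            for st in results
        ]
    return results


def covariate_tests(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    genes,
    covariate: str,
) -> list[PairStat]:
    """Welch two-sample t-test of each gene's expression across a binary covariate.

    Samples with a missing covariate value are dropped per test; the
    covariate must have exactly two non-missing levels.  Genes for which
    either group has fewer than 2 samples are skipped with a warning.
    """
    if covariate not in clinical.columns:
        raise SeednetError(f"covariate {covariate!r} not in clinical table")
    cov = clinical[covariate].dropna()
    levels = sorted(cov.unique())
    if len(levels) != 2:
        raise SeednetError(
            f"covariate {covariate!r} has {len(levels)} levels; exactly 2 required"
        )
    shared = [s for s in expr.columns if s in cov.index]
    results = []
    for g in genes:
        if g not in expr.index:
            raise SeednetError(f"gene {g!r} not in expression matrix")
        vals = expr.loc[g, shared]
        grp = [vals[cov.loc[shared] == lev].dropna().to_numpy(float) for lev in levels]
        if min(len(grp[0]), len(grp[1])) < 2:
            logger.warning("gene %s: a %s group has <2 samples, skipped", g, covariate)
            continue
        t, p = stats.ttest_ind(grp[0], grp[1], equal_var=False)
        results.append(
            PairStat(g, f"{covariate}:{levels[0]}|{levels[1]}", float(t),
                     max(float(p), P_FLOOR), n=len(grp[0]) + len(grp[1]))
        )
    return results


def risk_score(expr: pd.DataFrame, signature) -> pd.Series:
    """Per-sample risk score: the sum of signature-gene expression values.

    Missing values are excluded from the sum, with the per-sample count
    of missing signature genes logged.
    """
    signature = list(signature)
    missing = [g for g in signature if g not in expr.index]
    if missing:
        raise SeednetError(f"signature genes absent from expression matrix: {missing}")
    block = expr.loc[signature]
    n_missing = int(block.isna().sum().sum())
    if n_missing:
        per_sample = block.isna().sum()
        logger.warning(
            "%d missing signature values excluded (max %d in one sample)",
            n_missing, int(per_sample.max()),
        )
    return block.sum(axis=0, skipna=True)


def logrank_chisq(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Classical two-group log-rank chi-square (1 df).

    This is algebraically the score test at ``beta = 0`` of a Cox
    proportional-hazards model on the group indicator; with no tied event
    times the two are identical (see :func:`cox_score_chisq`).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    order = np.argsort(time, kind="stable")
    time, event, group = time[order], event[order], group[order]
    event_times = np.unique(time[event == 1])

    observed = 0.0
    expected = 0.0
    variance = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d_mask = (time == t) & (event == 1)
        d = d_mask.sum()
        d1 = (d_mask & (group == 1)).sum()
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance <= 0:
        return 0.0
    return float((observed - expected) ** 2 / variance)


def cox_score_chisq(time: np.ndarray, event: np.ndarray, group: np.ndarray) -> float:
    """Score test at beta = 0 of a one-covariate Cox fit (Breslow ties).

    U = sum over events of (x_i - mean of x over the risk set), with
    information summed the same way; chi-square = U^2 / I.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(group, float)
    U = 0.0
    I = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        xbar = x[at_risk].mean()
        d_mask = (time == t) & (event == 1)
        d = d_mask.sum()
        U += x[d_mask].sum() - d * xbar
        I += d * (np.mean(x[at_risk] ** 2) - xbar**2)
    if I <= 0:
        return 0.0
    return float(U**2 / I)


def stratify_and_test(
    scores: pd.Series,
    clinical: pd.DataFrame,
    compute_km: bool = True,
) -> RiskStratification:
    """Median-split survival stratification with a log-rank comparison.

    Samples lacking ``os_days`` or ``event`` are excluded first and
    counted.  The remainder are split at the median score: strictly below
    goes to the low-risk group, strictly above to high-risk, and ties at
    the median to low-risk (a deterministic convention recorded in the
    output).  Kaplan-Meier curves per group and the log-rank chi-square
    and p-value are returned.
    """
    scores = scores.dropna()
    shared = [s for s in scores.index if s in clinical.index]
    clin = clinical.loc[shared]
    complete = clin["os_days"].notna() & clin["event"].notna()
    n_excluded = int((~complete).sum()) + (len(scores) - len(shared))
    kept = clin.index[complete]
    if len(kept) < 4:
        raise SeednetError("fewer than 4 samples with complete survival data")

    s = scores.loc[kept]
    threshold = float(s.median())
    labels = {sid: ("high" if val > threshold else "low") for sid, val in s.items()}
    groups = pd.Series(labels)
    if (groups == "low").all() or (groups == "high").all():
        ties = int((s == threshold).sum())
        raise SeednetError(
            f"median split degenerate: {ties} scores tied at the median {threshold!r}"
        )
    if min((groups == "low").sum(), (groups == "high").sum()) < 2:
        raise SeednetError("a risk group has fewer than 2 samples after the split")

    time = clin.loc[kept, "os_days"].to_numpy(float)
    event = clin.loc[kept, "event"].to_numpy(int)
    grp = (groups.loc[kept] == "high").to_numpy(int)

    chisq = logrank_chisq(time, event, grp)
    p = float(stats.chi2.sf(chisq, df=1))
    p = min(max(p, P_FLOOR), 1.0)

    km_curves: dict[str, list[tuple[float, float]]] = {}
    if compute_km:
        for name, mask in (("low", grp == 0), ("high", grp == 1)):
            kmf = KaplanMeierFitter()
            kmf.fit(time[mask], event[mask], label=name)
            sf = kmf.survival_function_
            km_curves[name] = list(zip(sf.index.to_numpy(float), sf[name].to_numpy(float)))

    return RiskStratification(
        labels=labels,
        n_retained=len(kept),
        n_excluded=n_excluded,
        threshold=threshold,
        logrank_chisq=chisq,
        logrank_p=p,
        km_curves=km_curves,
    )
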