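"""Survival stratification of tumor clusters.

Kaplan-Meier product-limit curves and the G-group log-rank test are
implemented from first principles (they are the quantitative endpoint of
the pipeline). For each cancer type, tumors are grouped by their cluster
assignment and tested twice: once over all clusters present, and once after
excluding clusters contributing fewer than ``min_cluster_size`` samples of
that cancer type.

The log-rank statistic uses the standard hypergeometric moments at each
distinct event time (ties allowed), a quadratic form over the first G-1
groups, and a chi-square reference with G-1 degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_MIN_CLUSTER_SIZE = 25


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit estimator S(t) under right censoring.

    Returns a frame (time, n_at_risk, n_events, survival) with one row per
    distinct event time; the step function starts at S(0) = 1 and is
    right-continuous (the returned survival applies from each event time
    onward).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("need at least one record")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    surv = 1.0
    n = len(times)
    for t in np.unique(times[events == 1]):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        surv *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """G-group log-rank test; returns (chi2 statistic, df, p).

    At each distinct event time t with d_t total events and n_t at risk,
    the observed events per group are compared with the hypergeometric
    expectation d_t * n_{tj} / n_t; the statistic is the quadratic form of
    the summed O-E vector against the summed covariance (first G-1 groups).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    G = len(labels)
    if G < 2:
        raise ValueError("need at least 2 groups")
    if events.sum() == 0:
        raise ValueError("no events")
    gidx = np.searchsorted(labels, groups)
    event_times = np.unique(times[events == 1])
    oe = np.zeros(G)
    cov = np.zeros((G, G))
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        n_tj = np.bincount(gidx[at_risk], minlength=G).astype(float)
        d_tj = np.bincount(
            gidx[(times == t) & (events == 1)], minlength=G
        ).astype(float)
        e_tj = d_t * n_tj / n_t
        oe += d_tj - e_tj
        if n_t > 1:
            frac = n_tj / n_t
            mult = d_t * (n_t - d_t) / (n_t - 1)
            cov += mult * (np.diag(frac) - np.outer(frac, frac))
    v = cov[: G - 1, : G - 1]
    u = oe[: G - 1]
    stat = float(u @ np.linalg.pinv(v) @ u)
    df = G - 1
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


@dataclass
class StratifiedReport:
    """Per-cancer-type log-rank results plus the KM curves behind them."""

    table: pd.DataFrame  # cancer_type, run, n, clusters_used, statistic, df, p
    curves: dict[tuple[str, str, int], pd.DataFrame]  # (cancer_type, run, cluster)


def stratified_survival(
    records: pd.DataFrame,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
) -> StratifiedReport:
    """Log-rank across clusters, per cancer type, with and without the
    small-cluster exclusion.

    ``records`` needs columns sample_id, cancer_type, time, event,
    cluster_id. Run "all" uses every cluster present for the cancer type;
    run "filtered" drops clusters with fewer than ``min_cluster_size``
    samples *of that cancer type*. Cancer types left with fewer than two
    clusters (or without events) in a run are skipped with a notice.
    """
    required = {"sample_id", "cancer_type", "time", "event", "cluster_id"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rows = []
    curves: dict[tuple[str, str, int], pd.DataFrame] = {}
    for ctype, sub in records.groupby("cancer_type", sort=True):
        sizes = sub["cluster_id"].value_counts()
        for run in ("all", "filtered"):
            if run == "filtered":
                keep = sizes[sizes >= min_cluster_size].index
                data = sub[sub["cluster_id"].isin(keep)]
            else:
                data = sub
            used = sorted(data["cluster_id"].unique())
            if len(used) < 2:
                logger.info(
                    "%s/%s: fewer than 2 clusters remain; skipped", ctype, run
                )
                continue
            if data["event"].sum() == 0:
                logger.info("%s/%s: no events; skipped", ctype, run)
                continue
            stat, df, p = logrank_test(
                data["time"], data["event"], data["cluster_id"]
            )
            rows.append(
                (ctype, run, len(data), "|".join(str(c) for c in used), stat, df, p)
            )
            for c in used:
                grp = data[data["cluster_id"] == c]
                curves[(str(ctype), run, int(c))] = kaplan_meier(
                    grp["time"], grp["event"]
                )
    table = pd.DataFrame(
        rows,
        columns=["cancer_type", "run", "n", "clusters_used", "statistic", "df", "p"],
    )
    return StratifiedReport(table=table, curves=curves)
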