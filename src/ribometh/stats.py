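"""Differential-methylation statistics.

Given per-replicate RMS scores, this layer computes the quantities used to
compare lymphoma samples with reactive-lymph-node (RLN) controls:

* ΔRMS — a sample's replicate-mean score minus the control-group mean;
* per-site two-tailed unpaired Student's t-tests with significance classes
  *, **, *** at p < 0.05 / 0.01 / 0.001 (strict inequalities);
* deviation of each sample from the panel average with a one-vs-rest test;
* summed ΔRMS over a site subset (the proliferation-correlate scalar);
* Spearman rank correlations (exact permutation p at small n);
* comparison of two ΔRMS tables keyed by site (e.g. cancer vs development);
* ΔΔCq fold change for the RT-qPCR cross-check.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "delta_rms",
    "site_test",
    "significance_class",
    "differential_table",
    "deviation_from_average",
    "summed_delta",
    "spearman",
    "compare_delta_sets",
    "ddcq_fold",
]

logger = logging.getLogger(__name__)


def site_test(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-tailed unpaired t-test; pooled-variance Student by default.

    Degenerate inputs: n < 2 in either group → (nan, nan), flagged by the
    caller; both groups constant and equal → (0, 1) by convention; both
    constant but unequal → (±inf, 0).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return math.nan, math.nan
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    with warnings.catch_warnings():
        # near-constant groups (scores clipped at 0 or 1) are legitimate input
        warnings.filterwarnings("ignore", message="Precision loss occurred")
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def significance_class(p: float) -> str:
    """Map a p-value to ns / * / ** / *** (strict thresholds)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _valid_scores(scores: pd.DataFrame) -> pd.DataFrame:
    if "valid" in scores.columns:
        return scores[scores["valid"].astype(bool)]
    return scores


def delta_rms(
    scores: pd.DataFrame,
    control_samples: Sequence[str],
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-(sample, site) ΔRMS against the control-group mean.

    ``scores`` is a long frame (sample, replicate, site_id, score[, valid]).
    A sample's score at a site is its replicate mean; the control mean
    averages all control replicates.  Sites invalid on either side are
    omitted (tally logged).  Returns columns sample, site_id, delta,
    sample_mean, control_mean.
    """
    sc = _valid_scores(scores)
    ctrl = sc[sc["sample"].isin(control_samples)]
    if samples is None:
        test = sc[~sc["sample"].isin(control_samples)]
    else:
        test = sc[sc["sample"].isin(samples)]
    control_mean = ctrl.groupby("site_id")["score"].mean()
    sample_mean = test.groupby(["sample", "site_id"])["score"].mean()
    df = sample_mean.reset_index(name="sample_mean")
    df["control_mean"] = df["site_id"].map(control_mean)
    n_before = len(df)
    df = df.dropna(subset=["control_mean"])
    dropped = n_before - len(df)
    if dropped:
        logger.info("delta_rms: %d (sample, site) pairs without control data dropped", dropped)
    if df.empty:
        raise ValueError("no sites shared between samples and controls")
    df["delta"] = df["sample_mean"] - df["control_mean"]
    return df[["sample", "site_id", "delta", "sample_mean", "control_mean"]]


def differential_table(
    scores: pd.DataFrame,
    control_samples: Sequence[str],
    samples: Optional[Sequence[str]] = None,
    welch: bool = False,
) -> pd.DataFrame:
    """ΔRMS plus per-(sample, site) t-test against pooled control replicates.

    Each sample's replicate scores are tested against the replicates of all
    control samples at the same site.  Output columns: sample, site_id,
    delta, t, p, significance, direction (hyper/hypo).
    """
    deltas = delta_rms(scores, control_samples, samples)
    sc = _valid_scores(scores)
    ctrl_reps = {
        site: grp["score"].to_numpy()
        for site, grp in sc[sc["sample"].isin(control_samples)].groupby("site_id")
    }
    rows = []
    for (sample, site), grp in sc[
        sc["sample"].isin(deltas["sample"].unique())
    ].groupby(["sample", "site_id"]):
        if site not in ctrl_reps:
            continue
        t, p = site_test(grp["score"].to_numpy(), ctrl_reps[site], welch=welch)
        rows.append(dict(sample=sample, site_id=site, t=t, p=p))
    tests = pd.DataFrame(rows)
    out = deltas.merge(tests, on=["sample", "site_id"], how="left")
    out["significance"] = [
        significance_class(p) if np.isfinite(p) else "nd" for p in out["p"]
    ]
    out["direction"] = np.where(out["delta"] < 0, "hypo", "hyper")
    return out


def deviation_from_average(scores: pd.DataFrame) -> pd.DataFrame:
    """Each sample's deviation from the panel-average score per site.

    deviation(s, site) = mean_replicate score(s, site) − mean over all
    panel samples' means at that site (so deviations sum to zero across
    samples).  A one-vs-rest Student t-test (this sample's replicates vs
    all other samples' replicates) flags samples significantly above or
    below the average.  Sites missing in any sample are dropped (tallied).
    """
    sc = _valid_scores(scores)
    n_samples = sc["sample"].nunique()
    if n_samples < 2:
        raise ValueError("deviation_from_average needs at least 2 samples")
    means = sc.groupby(["sample", "site_id"])["score"].mean().reset_index()
    complete = means.groupby("site_id")["sample"].nunique() == n_samples
    keep = set(complete[complete].index)
    dropped = complete.size - len(keep)
    if dropped:
        logger.info("deviation_from_average: %d incomplete sites dropped", dropped)
    means = means[means["site_id"].isin(keep)]
    panel_mean = means.groupby("site_id")["score"].mean()
    rows = []
    by_site = {site: grp for site, grp in sc[sc["site_id"].isin(keep)].groupby("site_id")}
    for _, r in means.iterrows():
        site, sample = r["site_id"], r["sample"]
        grp = by_site[site]
        own = grp.loc[grp["sample"] == sample, "score"].to_numpy()
        rest = grp.loc[grp["sample"] != sample, "score"].to_numpy()
        t, p = site_test(own, rest)
        rows.append(
            dict(
                sample=sample,
                site_id=site,
                deviation=r["score"] - panel_mean[site],
                t=t,
                p=p,
                significance=significance_class(p) if np.isfinite(p) else "nd",
            )
        )
    return pd.DataFrame(rows)


def summed_delta(
    deltas: pd.DataFrame, sites: Union[str, Sequence[str]] = "ALL"
) -> pd.Series:
    """Per-sample sum of ΔRMS over a site subset (or all sites)."""
    df = deltas
    if not isinstance(sites, str):
        sites = list(sites)
        known = set(df["site_id"])
        missing = [s for s in sites if s not in known]
        if missing:
            raise KeyError(f"sites absent from the delta table: {missing}")
        df = df[df["site_id"].isin(sites)]
    elif sites != "ALL":
        raise ValueError("sites must be a list of site ids or 'ALL'")
    return df.groupby("sample")["delta"].sum()


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


_EXACT_N = 10


def _rho_midrank(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    den = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if den == 0.0:
        return math.nan
    return float(sx @ sy) / den


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    Pairs with a missing value are dropped.  The two-sided p-value comes
    from the exact permutation distribution of rho for n <= 10 and from
    the t approximation with n−2 degrees of freedom otherwise.  An
    all-tied vector yields rho = nan (flagged via the result).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("spearman needs at least 3 complete pairs")
    rho = _rho_midrank(x, y)
    if math.isnan(rho):
        logger.warning("spearman: a vector is all-tied; rho undefined")
        return CorrelationResult(math.nan, math.nan, n)
    if n <= _EXACT_N:
        p = _exact_perm_p(x, y, rho)
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho * rho)) if abs(rho) < 1 else math.inf
        p = float(2 * sps.t.sf(abs(t), n - 2)) if math.isfinite(t) else 0.0
    return CorrelationResult(rho, min(p, 1.0), n)


def _exact_perm_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for rho by full enumeration.

    Enumerates all n! pairings of the rank vectors in numpy chunks; for a
    fixed pair of rank vectors rho is affine in S = Σ rx_i · ry_{π(i)}, so
    only S varies over permutations.
    """
    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    den = math.sqrt(float(sx @ sx) * float(sy @ sy))
    n_perm = math.factorial(n)
    thresh = abs(rho_obs) - 1e-12
    count = 0
    chunk_rows = 200_000
    it = itertools.permutations(range(n))
    while True:
        flat = np.fromiter(
            itertools.chain.from_iterable(itertools.islice(it, chunk_rows)),
            dtype=np.int8,
        )
        if flat.size == 0:
            break
        perms = flat.reshape(-1, n)
        rhos = (sy[perms] @ sx) / den
        count += int(np.sum(np.abs(rhos) >= thresh))
    return count / n_perm


def compare_delta_sets(
    deltas_a: pd.DataFrame,
    deltas_b: pd.DataFrame,
    suffixes: tuple[str, str] = ("_a", "_b"),
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Inner-join two per-site ΔRMS tables; also list unmatched sites.

    Inputs are keyed by ``site_id`` with a ``delta`` column (e.g. one table
    per condition, each already aggregated per site).  Returns (joined,
    only_in_a, only_in_b); an empty intersection is an error.
    """
    a = deltas_a[["site_id", "delta"]].rename(columns={"delta": f"delta{suffixes[0]}"})
    b = deltas_b[["site_id", "delta"]].rename(columns={"delta": f"delta{suffixes[1]}"})
    joined = a.merge(b, on="site_id", how="inner")
    if joined.empty:
        raise ValueError("no sites shared between the two delta tables")
    only_a = sorted(set(a["site_id"]) - set(b["site_id"]))
    only_b = sorted(set(b["site_id"]) - set(a["site_id"]))
    return joined, only_a, only_b


def ddcq_fold(
    cq_target_sample: float,
    cq_ref_sample: float,
    cq_target_control: float,
    cq_ref_control: float,
) -> float:
    """Relative fold expression by the ΔΔCq method.

    fold = 2^−[(Cq_target,sample − Cq_ref,sample) −
               (Cq_target,control − Cq_ref,control)],
    i.e. double normalization to a reference gene (e.g. snRNA U6) and a
    control sample (expression in the control = 1).
    """
    vals = (cq_target_sample, cq_ref_sample, cq_target_control, cq_ref_control)
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("ΔΔCq requires finite Cq values")
    ddcq = (cq_target_sample - cq_ref_sample) - (cq_target_control - cq_ref_control)
    return 2.0 ** (-ddcq)
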