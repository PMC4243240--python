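"""Permutation log-rank survival association of copy-number regions.

Implements the downstream statistics of the copy-number landscape analysis:
cohort eligibility filtering, Kaplan-Meier estimation, the two-group log-rank
statistic in chi-square form, permutation p-values (10,000 label permutations
by default, plus-one convention), a genome-wide per-arm scan over region
gain/loss carrier status, permutation-based FDR, pairwise between-arm
comparisons stratified by carrier status, and Ward clustering of ordinal call
profiles.

The log-rank machinery is written to evaluate many label permutations at
once: samples are sorted by time (events before censorings at ties), at-risk
group counts become suffix sums, and per-event-time observed/expected terms
are accumulated with ``np.add.reduceat`` across a whole matrix of permuted
label vectors.  Within an arm the same sample permutations are applied to
every region so that each permutation replicate yields a complete genome-scan
p-value vector — the ingredient the permutation FDR needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2, chi2_contingency, rankdata

from .regions import region_carrier_status

__all__ = [
    "filter_cohort",
    "km_estimate",
    "logrank_statistic",
    "permutation_pvalue",
    "associate_genomewide",
    "flag_significance",
    "permutation_fdr",
    "between_arm_tests",
    "cluster_samples",
    "cluster_enrichment",
]

log = logging.getLogger(__name__)


def filter_cohort(clinical: pd.DataFrame) -> pd.DataFrame:
    """Eligibility filter for the supervised analysis.

    A sample is kept iff it received at least three treatment cycles — or two
    if the patient died of rapidly progressive disease — and is not
    microsatellite instable.  Rows with missing cycle counts are excluded.
    """
    cycles = pd.to_numeric(clinical["cycles"], errors="coerce")
    missing = cycles.isna()
    if missing.any():
        log.warning("%d samples dropped for missing cycle counts", int(missing.sum()))
    death = clinical["death_progression"].fillna(False).astype(bool)
    msi = clinical["msi"].fillna(False).astype(bool)
    keep = ((cycles >= 3) | ((cycles >= 2) & death)) & ~msi & ~missing
    return clinical.loc[keep]


def km_estimate(times, events) -> dict:
    """Kaplan-Meier curve with median PFS and its confidence interval.

    Median = smallest time with S(t) <= 0.5, NA (nan) when the curve never
    reaches 0.5; the CI uses the exponential-Greenwood (log(-log)) variance.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    to_na = lambda v: float("nan") if np.isinf(v) else v
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    return {
        "curve": curve,
        "median": to_na(median),
        "median_ci": (to_na(lo), to_na(hi)),
    }


def _sorted_arrays(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.lexsort((1 - events, times))  # events precede censorings at ties
    return times[order], events[order], order


def logrank_statistics_matrix(times, events, groups: np.ndarray) -> np.ndarray:
    """Chi-square-form log-rank statistics for each row of a label matrix.

    ``groups`` is (B, n) boolean; returns (B,) values U^2/V with U the summed
    observed-minus-expected group-1 events and V the summed hypergeometric
    variances over distinct event times.
    """
    t, e, order = _sorted_arrays(times, events)
    G = np.asarray(groups, dtype=float)[:, order]
    n = t.size
    starts = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
    d = np.add.reduceat(e.astype(float), starts)
    n_risk = (n - starts).astype(float)
    keep = d > 0
    suffix = np.cumsum(G[:, ::-1], axis=1)[:, ::-1]
    n1 = suffix[:, starts]
    d1 = np.add.reduceat(G * e, starts, axis=1)
    frac = n1 / n_risk
    U = (d1 - d * frac)[:, keep].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1.0)
    v[:, n_risk <= 1] = 0.0
    V = v[:, keep].sum(axis=1)
    stat = np.zeros_like(U)
    nz = V > 0
    stat[nz] = U[nz] ** 2 / V[nz]
    return stat


def logrank_statistic(times, events, group) -> float:
    """Two-group log-rank statistic (chi-square form) for one label vector."""
    group = np.asarray(group, dtype=bool)
    return float(logrank_statistics_matrix(times, events, group[None, :])[0])


def logrank_pvalue(times, events, group) -> float:
    """Asymptotic chi-square(1) p-value of the log-rank statistic."""
    return float(chi2.sf(logrank_statistic(times, events, group), 1))


def permutation_pvalue(
    times,
    events,
    carriers,
    n_perm: int = 10_000,
    seed: int | None = None,
    return_stats: bool = False,
):
    """Permutation p-value of the log-rank statistic (plus-one convention).

    Carrier labels are permuted over the samples ``n_perm`` times;
    ``p = (1 + #{perm stat >= observed}) / (n_perm + 1)``, so p >= 1/(B+1).
    Degenerate labels (all carriers or none) give p = 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    carriers = np.asarray(carriers, dtype=bool)
    if carriers.all() or not carriers.any():
        return (1.0, np.zeros(n_perm)) if return_stats else 1.0
    obs = logrank_statistic(times, events, carriers)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(carriers, (n_perm, carriers.size)).copy(), axis=1)
    stats = logrank_statistics_matrix(times, events, perms)
    p = (1 + int((stats >= obs - 1e-12).sum())) / (n_perm + 1)
    return (p, stats) if return_stats else p


@dataclass
class ArmScan:
    """Per-arm genome scan output: observed results plus the permutation archive."""

    arm: str
    results: pd.DataFrame
    permuted_p: pd.DataFrame  # (n_perm x tested region:type) permutation p-values


def associate_genomewide(
    region_calls: pd.DataFrame,
    clinical: pd.DataFrame,
    arm: str,
    kinds: tuple[str, ...] = ("gain", "loss"),
    n_perm: int = 10_000,
    min_group: int = 5,
    seed: int | None = None,
    prefiltered: bool = False,
) -> ArmScan:
    """Scan every region x aberration-kind for PFS association within one arm.

    Regions with fewer than ``min_group`` carriers or non-carriers are skipped
    (recorded with a reason).  A single set of sample permutations is shared
    across regions; each permuted statistic is converted to a p-value by its
    rank within that region's permutation distribution, giving the archive of
    genome-scan p-vectors used by :func:`permutation_fdr`.
    """
    cohort = clinical if prefiltered else filter_cohort(clinical)
    cohort = cohort[cohort["arm"] == arm]
    samples = [s for s in region_calls.columns if s in set(cohort["sample_id"])]
    cohort = cohort.set_index("sample_id").loc[samples]
    times = cohort["pfs_days"].to_numpy(dtype=float)
    events = cohort["event"].to_numpy(dtype=int)
    n = len(samples)

    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)

    rows, perm_cols = [], {}
    for region in region_calls.index:
        calls = region_calls.loc[region, samples]
        for kind in kinds:
            carriers = region_carrier_status(calls, kind)
            n_car, n_non = int(carriers.sum()), int((~carriers).sum())
            key = f"{region}:{kind}"
            if min(n_car, n_non) < min_group:
                rows.append(
                    dict(
                        region=region, arm=arm, kind=kind, n_carrier=n_car,
                        n_noncarrier=n_non, logrank_stat=np.nan, perm_p=np.nan,
                        median_carrier=np.nan, median_noncarrier=np.nan,
                        skipped="group below minimum size",
                    )
                )
                continue
            obs = logrank_statistic(times, events, carriers)
            stats = logrank_statistics_matrix(times, events, carriers[perm_idx])
            p = (1 + int((stats >= obs - 1e-12).sum())) / (n_perm + 1)
            perm_cols[key] = rankdata(-stats, method="max") / (n_perm + 1)
            med_c = km_estimate(times[carriers], events[carriers])["median"]
            med_n = km_estimate(times[~carriers], events[~carriers])["median"]
            rows.append(
                dict(
                    region=region, arm=arm, kind=kind, n_carrier=n_car,
                    n_noncarrier=n_non, logrank_stat=obs, perm_p=p,
                    median_carrier=med_c, median_noncarrier=med_n, skipped="",
                )
            )
    results = pd.DataFrame(rows).sort_values("perm_p", na_position="last").reset_index(drop=True)
    return ArmScan(arm=arm, results=results, permuted_p=pd.DataFrame(perm_cols))


def flag_significance(
    scans: list[ArmScan], tier1_alpha: float = 0.005, tier2_alpha: float = 0.05
) -> pd.DataFrame:
    """Two-tier significance over all arms.

    tier1: permutation p < 0.005 in any arm; tier2: p < 0.05 in at least two
    arms (per region x kind, permutation p-values per arm, no cross-arm
    correction).
    """
    all_res = pd.concat([s.results for s in scans], ignore_index=True)
    tested = all_res[all_res["skipped"] == ""]
    pivot = tested.pivot_table(
        index=["region", "kind"], columns="arm", values="perm_p", aggfunc="first"
    )
    flags = pd.DataFrame(
        {
            "tier1": (pivot < tier1_alpha).any(axis=1),
            "tier2": (pivot < tier2_alpha).sum(axis=1) >= 2,
        }
    )
    out = all_res.merge(flags, left_on=["region", "kind"], right_index=True, how="left")
    for c in ("tier1", "tier2"):
        out[c] = out[c].eq(True)  # missing (never-tested) regions -> False
    return out


def permutation_fdr(observed_p: np.ndarray, permuted_p: np.ndarray, threshold: float) -> float:
    """Permutation-based FDR at a p-value threshold.

    ``FDR(t) = mean_b #{permuted p_b <= t} / max(1, #{observed p <= t})``;
    reported as 1 when there are no observed discoveries, and capped at 1.
    """
    observed_p = np.asarray(observed_p, dtype=float)
    permuted_p = np.atleast_2d(np.asarray(permuted_p, dtype=float))
    n_obs = int((observed_p <= threshold).sum())
    if n_obs == 0:
        return 1.0
    false = (permuted_p <= threshold).sum(axis=1).mean()
    return float(min(1.0, false / n_obs))


def between_arm_tests(
    region_calls: pd.Series,
    clinical: pd.DataFrame,
    kind: str,
    arms: tuple[str, ...] | None = None,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Pairwise between-arm log-rank tests stratified by carrier status.

    Within carriers (and separately non-carriers) of the region, every pair
    of arms is compared with the asymptotic two-group log-rank test; pairs
    with an empty stratum come back NA.  Per-arm KM medians are included.
    """
    cohort = clinical if prefiltered else filter_cohort(clinical)
    arms = arms or tuple(pd.unique(cohort["arm"]))
    if len(arms) < 2:
        raise ValueError("need at least two arms")
    cohort = cohort[cohort["sample_id"].isin(region_calls.index)]
    carriers = pd.Series(
        region_carrier_status(region_calls.loc[cohort["sample_id"]], kind),
        index=cohort["sample_id"].to_numpy(),
    )
    rows = []
    for stratum, flag in (("carrier", True), ("noncarrier", False)):
        sel = cohort[carriers.loc[cohort["sample_id"]].to_numpy() == flag]
        medians = {}
        for arm in arms:
            sub = sel[sel["arm"] == arm]
            medians[arm] = (
                km_estimate(sub["pfs_days"], sub["event"])["median"] if len(sub) else np.nan
            )
        for a, b in [(x, y) for i, x in enumerate(arms) for y in arms[i + 1 :]]:
            pair = sel[sel["arm"].isin([a, b])]
            ga = (pair["arm"] == a).to_numpy()
            if ga.all() or not ga.any():
                p = np.nan
            else:
                p = logrank_pvalue(pair["pfs_days"], pair["event"], ga)
            rows.append(
                dict(
                    stratum=stratum, arm_a=a, arm_b=b, n=len(pair), p=p,
                    median_a=medians[a], median_b=medians[b],
                )
            )
    return pd.DataFrame(rows)


def cluster_samples(region_calls: pd.DataFrame, k: int) -> pd.Series:
    """Ward-linkage clustering of samples on ordinal region calls.

    Distance between two samples is the mean absolute difference of their
    ordinal calls across regions ("all regions weighted equally").
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = region_calls.to_numpy(dtype=float).T  # samples x regions
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of samples")
    dist = pdist(X, metric="cityblock") / X.shape[1]
    labels = fcluster(linkage(dist, method="ward"), t=k, criterion="maxclust")
    return pd.Series(labels, index=region_calls.columns, name="cluster")


def cluster_enrichment(labels: pd.Series, flags: pd.Series) -> tuple[float, float]:
    """Pearson chi-square of the cluster x binary-flag contingency table."""
    table = pd.crosstab(labels, flags.astype(bool))
    stat, p, _, _ = chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), float(p)
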