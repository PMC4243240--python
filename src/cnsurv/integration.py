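"""Gene-level dosage filtering, amplification cataloguing and cell-line validation.

Candidate genes are those lying on survival-associated regions (p < 0.005 in
any arm — tier A — or p < 0.05 in at least two arms — tier B) whose expression
correlates positively with their DNA copy number in an independent paired
dataset (one-sided Spearman, alpha 0.05 by default).

Amplifications are maximal runs of +2 calls (the calling stage already
restricts them to 3 Mb or less); recurrent loci are single-linkage groups of
events overlapping by at least one base pair, reported with the number of
distinct samples carrying them.

Cell-line validation classifies each line as aberrant versus normal for a
region (any-overlap rule on segments in the tested state) and compares the
log-IC50 distributions of the two classes with a Kruskal-Wallis test.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata, spearmanr

from .synthetic import CellLinePanel

__all__ = [
    "map_genes_to_region",
    "dosage_correlation",
    "select_candidate_genes",
    "detect_amplicons",
    "recurrent_amplicons",
    "cellline_region_status",
    "kruskal_wallis",
    "validate_regions_in_celllines",
]

log = logging.getLogger(__name__)


def map_genes_to_region(genes: pd.DataFrame, region) -> pd.DataFrame:
    """Genes overlapping a region by >= 1 bp (half-open coordinates).

    ``region`` needs attributes/keys chromosome, start, end.
    """
    get = (lambda k: region[k]) if isinstance(region, (dict, pd.Series)) else (
        lambda k: getattr(region, k)
    )
    hit = (
        (genes["chromosome"] == get("chromosome"))
        & (genes["start"] < get("end"))
        & (genes["end"] > get("start"))
    )
    return genes.loc[hit]


def dosage_correlation(cn: np.ndarray, expression: np.ndarray, method: str = "spearman"):
    """Correlation of copy number with expression; one-sided p for rho > 0.

    Returns (rho, p); (nan, nan) when the copy-number vector is constant.
    """
    cn = np.asarray(cn, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if cn.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(cn) == 0 or np.ptp(expression) == 0:
        log.warning("zero-variance vector; dosage correlation undefined")
        return float("nan"), float("nan")
    if method == "spearman":
        rho, p = spearmanr(cn, expression, alternative="greater")
    elif method == "pearson":
        from scipy.stats import pearsonr

        rho, p = pearsonr(cn, expression, alternative="greater")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p)


def select_candidate_genes(
    flagged_results: pd.DataFrame,
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    paired,
    alpha: float = 0.05,
    method: str = "spearman",
) -> pd.DataFrame:
    """Dosage-sensitive genes on survival-associated regions, by tier.

    ``flagged_results`` is the output of ``flag_significance`` (needs region,
    tier1, tier2); ``regions`` the subregion table indexed like the results'
    region column; ``paired`` a PairedExpressionDataset-like object with
    matched ``copy_number`` and ``expression`` gene x sample frames.  Genes on
    a flagged region but absent from the paired data are reported "untested".
    """
    tiers = (
        flagged_results.groupby("region")[["tier1", "tier2"]].any().query("tier1 or tier2")
    )
    rows = []
    seen = set()
    for region_id, tier_flags in tiers.iterrows():
        region = regions.loc[region_id]
        tier = "A" if tier_flags["tier1"] else "B"
        for g in map_genes_to_region(genes, region).itertuples():
            if g.gene_id in seen:
                continue
            seen.add(g.gene_id)
            if g.gene_id not in paired.copy_number.index:
                rows.append(dict(gene_id=g.gene_id, region=region_id, tier=tier,
                                 rho=np.nan, p=np.nan, status="untested"))
                continue
            rho, p = dosage_correlation(
                paired.copy_number.loc[g.gene_id].to_numpy(),
                paired.expression.loc[g.gene_id].to_numpy(),
                method=method,
            )
            retained = bool(np.isfinite(p) and p < alpha and rho > 0)
            rows.append(dict(gene_id=g.gene_id, region=region_id, tier=tier,
                             rho=rho, p=p, status="retained" if retained else "rejected"))
    return pd.DataFrame(
        rows, columns=["gene_id", "region", "tier", "rho", "p", "status"]
    )


def detect_amplicons(calls: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-sample maximal runs of amplification (+2) calls.

    Returns events with sample_id, chromosome, start, end, n_probes.
    """
    if len(calls) != len(annotation):
        raise ValueError("call matrix rows must match the annotation")
    chroms = annotation["chromosome"].to_numpy()
    starts = annotation["start"].to_numpy()
    ends = annotation["end"].to_numpy()
    rows = []
    for sample in calls.columns:
        amp = calls[sample].to_numpy(dtype=int) == 2
        # break runs at chromosome boundaries
        same_chrom = np.r_[False, chroms[1:] == chroms[:-1]]
        run_start = amp & ~(np.r_[False, amp[:-1]] & same_chrom)
        run_end = amp & ~(np.r_[amp[1:], False] & np.r_[same_chrom[1:], False])
        for a, b in zip(np.flatnonzero(run_start), np.flatnonzero(run_end)):
            rows.append((sample, chroms[a], int(starts[a]), int(ends[b]), b - a + 1))
    return pd.DataFrame(rows, columns=["sample_id", "chromosome", "start", "end", "n_probes"])


def recurrent_amplicons(
    events: pd.DataFrame, min_freq: int = 4, genes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Group amplification events into loci and report the recurrent ones.

    Loci are connected components of the >=1 bp overlap graph (single
    linkage).  The locus span is the intersection of member events; if the
    intersection is empty (chained overlaps) the union is used and flagged.
    Frequency counts distinct samples.  Output sorted by frequency (desc)
    then coordinate, filtered at ``min_freq``.
    """
    rows = []
    for chrom, grp in events.groupby("chromosome", sort=True):
        grp = grp.sort_values(["start", "end"])
        comp, max_end = [], -1
        comps = []
        for ev in grp.itertuples():
            if comp and ev.start >= max_end:
                comps.append(comp)
                comp, max_end = [], -1
            comp.append(ev)
            max_end = max(max_end, ev.end)
        if comp:
            comps.append(comp)
        for comp in comps:
            i_start = max(ev.start for ev in comp)
            i_end = min(ev.end for ev in comp)
            fallback = i_start >= i_end
            if fallback:
                i_start = min(ev.start for ev in comp)
                i_end = max(ev.end for ev in comp)
            freq = len({ev.sample_id for ev in comp})
            locus_genes = ""
            if genes is not None:
                hit = map_genes_to_region(
                    genes, {"chromosome": chrom, "start": i_start, "end": i_end}
                )
                locus_genes = ",".join(hit["gene_id"])
            rows.append(
                dict(chromosome=chrom, start=int(i_start), end=int(i_end),
                     frequency=freq, span_is_union=fallback, genes=locus_genes)
            )
    table = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "frequency", "span_is_union", "genes"]
    )
    table = table[table["frequency"] >= min_freq]
    return table.sort_values(
        ["frequency", "chromosome", "start"], ascending=[False, True, True]
    ).reset_index(drop=True)


def cellline_region_status(segments: pd.DataFrame, region, kind: str) -> bool:
    """Aberrant iff any segment in the tested state overlaps the region >= 1 bp.

    Segment state comes from integer copy number: >2 gain, =2 normal, <2 loss.
    """
    get = (lambda k: region[k]) if isinstance(region, (dict, pd.Series)) else (
        lambda k: getattr(region, k)
    )
    if kind == "gain":
        state = segments["copy"] > 2
    elif kind == "loss":
        state = segments["copy"] < 2
    else:
        raise ValueError(f"kind must be 'gain' or 'loss', got {kind!r}")
    hit = (
        state
        & (segments["chromosome"] == get("chromosome"))
        & (segments["start"] < get("end"))
        & (segments["end"] > get("start"))
    )
    return bool(hit.any())


def kruskal_wallis(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Kruskal-Wallis H with midranks and tie correction; chi-square p.

    ``H = [12 / (N(N+1))] * sum_j R_j^2 / n_j - 3(N+1)``, divided by the tie
    correction ``1 - sum(t^3 - t) / (N^3 - N)``; p from chi2 with k-1 df.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    sizes = np.array([(groups == g).sum() for g in labels])
    if (sizes == 0).any():
        raise ValueError("empty group")
    N = values.size
    ranks = rankdata(values)  # midranks
    H = 12.0 / (N * (N + 1)) * sum(
        ranks[groups == g].sum() ** 2 / (groups == g).sum() for g in labels
    ) - 3.0 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum())) / (N**3 - N)
    if tie == 0.0:  # all values identical
        return 0.0, 1.0
    H /= tie
    return float(H), float(chi2.sf(H, len(labels) - 1))


def validate_regions_in_celllines(
    panel: CellLinePanel,
    regions: pd.DataFrame,
    drug: str,
    subpanels: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-region Kruskal-Wallis of drug log-IC50 by aberration status.

    ``regions`` needs chromosome/start/end/type/label.  Reports the full
    panel and, when the panel carries labels (or ``subpanels`` gives explicit
    line lists), each labelled sub-panel.  Uncorrected p-values — intended
    for a small pre-declared region set.  Rows with fewer than two lines in
    either class come back NA.
    """
    ic = panel.ic50[panel.ic50["drug"] == drug].set_index("line_id")["log_ic50"]
    if ic.empty:
        raise ValueError(f"no IC50 data for drug {drug!r}")
    groups_of: dict[str, list[str]] = {"all": list(ic.index)}
    if subpanels:
        groups_of.update({k: list(v) for k, v in subpanels.items()})
    elif panel.labels is not None:
        for lab, ids in panel.labels.groupby(panel.labels):
            groups_of[str(lab)] = [i for i in ids.index if i in ic.index]
    seg_by_line = dict(tuple(panel.segments.groupby("line_id")))
    rows = []
    for _, reg in regions.iterrows():
        status = {
            lid: cellline_region_status(seg_by_line.get(lid, panel.segments.iloc[0:0]), reg, reg["type"])
            for lid in ic.index
        }
        for pname, lines in groups_of.items():
            ab = [l for l in lines if status[l]]
            no = [l for l in lines if not status[l]]
            if min(len(ab), len(no)) < 2:
                rows.append(dict(region=reg["label"], panel=pname, n_aberrant=len(ab),
                                 n_normal=len(no), H=np.nan, p=np.nan))
                continue
            vals = np.r_[ic.loc[ab].to_numpy(), ic.loc[no].to_numpy()]
            grp = np.r_[np.ones(len(ab)), np.zeros(len(no))]
            H, p = kruskal_wallis(vals, grp)
            rows.append(dict(region=reg["label"], panel=pname, n_aberrant=len(ab),
                             n_normal=len(no), H=H, p=p))
    return pd.DataFrame(rows)
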