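"""Reduce probe x sample call matrices to chromosomal subregions.

A subregion is a maximal run of probes whose per-sample call signature is
(near-)constant across the cohort; it is the unit of the survival association
scan.  Reduction is a greedy left-to-right pass per chromosome: the current
subregion is extended to the next probe while the fraction of samples whose
call differs from the subregion's consensus signature (the per-sample modal
call over member probes) stays within a tolerance.  At tolerance 0 the
reduction is lossless — every probe's calls equal its subregion consensus.

Flagged subregions can be concatenated into "total" regions within one
chromosome arm, either merging every flagged subregion of the arm or only
adjacent runs of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import CALL_STATES

__all__ = [
    "reduce_to_subregions",
    "region_carrier_status",
    "concatenate_significant",
    "TotalRegion",
]

_STATE_INDEX = {s: i for i, s in enumerate(CALL_STATES)}


@dataclass
class TotalRegion:
    """Concatenation of flagged subregions on one chromosome arm."""

    chromosome: str
    arm: str
    start: int
    end: int
    members: list[int] = field(default_factory=list)  # subregion indices
    label: str = ""


def _assign_arms(
    sub: pd.DataFrame, centromeres: Mapping[str, int] | None, annotation: pd.DataFrame
) -> pd.Series:
    """p/q arm by subregion start relative to the centromere (default: midpoint)."""
    if centromeres is None:
        centromeres = {
            c: int(g["end"].max()) // 2 for c, g in annotation.groupby("chromosome")
        }
    return pd.Series(
        [
            "p" if row.start < centromeres.get(row.chromosome, row.start + 1) else "q"
            for row in sub.itertuples()
        ],
        index=sub.index,
    )


def reduce_to_subregions(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    tolerance: float = 0.01,
    centromeres: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Greedy reduction of a probe x sample call matrix to subregions.

    ``calls`` rows must align with ``annotation`` rows (genome order).
    Returns ``(subregions, region_calls)``: a table with chromosome, arm,
    start, end, n_probes, probe_start, probe_end and a subregion x sample
    matrix holding the consensus calls.
    """
    if calls.shape[0] == 0 or calls.shape[1] == 0:
        raise ValueError("empty call matrix")
    if not 0.0 <= tolerance <= 0.2:
        raise ValueError("tolerance must be in [0, 0.2]")
    if len(calls) != len(annotation):
        raise ValueError("call matrix rows must match the annotation")

    X = calls.to_numpy(dtype=int)
    n_samples = X.shape[1]
    chroms = annotation["chromosome"].to_numpy()
    starts = annotation["start"].to_numpy()
    ends = annotation["end"].to_numpy()
    states = np.array(CALL_STATES)

    sub_rows = []
    consensus_rows = []
    offset = 0
    for chrom in pd.unique(chroms):
        n = int((chroms == chrom).sum())
        block = X[offset : offset + n]
        # running per-sample state counts for the open subregion
        counts = np.zeros((n_samples, len(states)), dtype=float)
        open_at = 0

        def consensus(counts: np.ndarray, current: np.ndarray) -> np.ndarray:
            # modal call per sample; ties resolve toward the current consensus
            biased = counts.copy()
            biased[np.arange(n_samples), current] += 0.5
            return biased.argmax(axis=1)

        def close(p_end: int, cons_idx: np.ndarray) -> None:
            sub_rows.append(
                (
                    chrom,
                    int(starts[offset + open_at]),
                    int(ends[offset + p_end - 1]),
                    p_end - open_at,
                    offset + open_at,
                    offset + p_end,
                )
            )
            consensus_rows.append(states[cons_idx])

        cons_idx = np.array([_STATE_INDEX[s] for s in block[0]])
        counts[np.arange(n_samples), cons_idx] += 1
        for p in range(1, n):
            probe_idx = np.array([_STATE_INDEX[s] for s in block[p]])
            frac_diff = float(np.mean(probe_idx != cons_idx))
            if frac_diff <= tolerance:
                counts[np.arange(n_samples), probe_idx] += 1
                cons_idx = consensus(counts, cons_idx)
            else:
                close(p, cons_idx)
                open_at = p
                counts[:] = 0
                counts[np.arange(n_samples), probe_idx] += 1
                cons_idx = probe_idx
        close(n, cons_idx)
        offset += n

    subregions = pd.DataFrame(
        sub_rows,
        columns=["chromosome", "start", "end", "n_probes", "probe_start", "probe_end"],
    )
    subregions["arm"] = _assign_arms(subregions, centromeres, annotation)
    region_calls = pd.DataFrame(
        np.vstack(consensus_rows), columns=calls.columns, index=subregions.index
    )
    return subregions, region_calls


def region_carrier_status(region_calls: pd.Series | np.ndarray, kind: str) -> np.ndarray:
    """Per-sample carrier flags: loss means call <= -1, gain means call >= +1.

    Amplification (+2) counts as gain.
    """
    calls = np.asarray(region_calls, dtype=int)
    if kind == "loss":
        return calls <= -1
    if kind == "gain":
        return calls >= 1
    raise ValueError(f"kind must be 'gain' or 'loss', got {kind!r}")


def concatenate_significant(
    subregions: pd.DataFrame,
    flags: Sequence[bool],
    mode: str = "adjacent_within_arm",
) -> list[TotalRegion]:
    """Merge flagged subregions into total regions within chromosome arms.

    ``mode='within_arm'`` merges every flagged subregion of an arm into one
    region; ``'adjacent_within_arm'`` only merges maximal runs of flagged
    subregions that are adjacent in subregion order.
    """
    if mode not in ("within_arm", "adjacent_within_arm"):
        raise ValueError(f"unknown mode {mode!r}")
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(subregions):
        raise ValueError("flags must align with subregions")
    out: list[TotalRegion] = []
    for (chrom, arm), grp in subregions.groupby(["chromosome", "arm"], sort=False):
        idx = [i for i in grp.index if flags[subregions.index.get_loc(i)]]
        if not idx:
            continue
        if mode == "within_arm":
            runs = [idx]
        else:
            runs, cur = [], [idx[0]]
            positions = {i: k for k, i in enumerate(grp.index)}
            for prev, nxt in zip(idx[:-1], idx[1:]):
                if positions[nxt] == positions[prev] + 1:
                    cur.append(nxt)
                else:
                    runs.append(cur)
                    cur = [nxt]
            runs.append(cur)
        for run in runs:
            start = int(subregions.loc[run, "start"].min())
            end = int(subregions.loc[run, "end"].max())
            out.append(
                TotalRegion(
                    chromosome=str(chrom),
                    arm=str(arm),
                    start=start,
                    end=end,
                    members=list(run),
                    label=f"{chrom}{arm}:{start / 1e6:.2f}-{end / 1e6:.2f}Mb",
                )
            )
    return out
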