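"""Circular binary segmentation (CBS) of probe-level log2 ratios.

The series on each chromosome is split recursively.  At every step the
candidate change is the arc ``[i, j)`` maximising the two-sample t-like
statistic between the probes inside the arc and those outside it

    T(i, j) = |mean_in - mean_out| / (s * sqrt(1/k + 1/m))

where ``k``/``m`` are the inside/outside sizes and ``s`` the (population)
standard deviation of the segment under test.  The split is accepted when its
permutation p-value — the rank of the observed maximal T among maximal T's of
within-segment value permutations — falls below ``alpha``; accepted arcs
split the segment into up to three children and the recursion continues.
There is no post-hoc "undo" pruning.

The arc search is exhaustive, so the maximiser agrees with a brute-force scan
by construction; permutations reuse the same exhaustive search on shuffled
values.  Because a permutation preserves the multiset of values, ``s`` is
permutation-invariant and is dropped from the comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CbsParams", "segment_series", "segment_profile"]


@dataclass(frozen=True)
class CbsParams:
    """Tuning knobs for CBS; defaults follow common practice for aCGH."""

    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0,1)")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def _arc_index(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All arcs [i, j) with both arc and complement >= min_width probes."""
    i_all, j_all = [], []
    for k in range(min_width, n - min_width + 1):  # arc length
        i = np.arange(0, n - k + 1)
        i_all.append(i)
        j_all.append(i + k)
    if not i_all:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(i_all), np.concatenate(j_all)


def _max_arc(X: np.ndarray, i_idx: np.ndarray, j_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise maximum of the unscaled arc statistic |d_in - d_out| * w.

    ``X`` has shape (B, n); returns (max statistic, argmax arc) per row.
    """
    n = X.shape[1]
    S = np.concatenate([np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1)
    k = (j_idx - i_idx).astype(float)
    m = n - k
    w = 1.0 / np.sqrt(1.0 / k + 1.0 / m)
    tot = S[:, -1:]
    sum_in = S[:, j_idx] - S[:, i_idx]
    T = np.abs(sum_in / k - (tot - sum_in) / m) * w
    return T.max(axis=1), T.argmax(axis=1)


def _test_split(
    x: np.ndarray, params: CbsParams, rng: np.random.Generator
) -> tuple[int, int] | None:
    """Best accepted arc of ``x`` or None if no significant change-point."""
    n = x.size
    if n < 2 * params.min_width:
        return None
    s = float(np.std(x))
    if s < 1e-12:
        return None
    i_idx, j_idx = _arc_index(n, params.min_width)
    obs, arg = _max_arc(x[None, :], i_idx, j_idx)
    obs = float(obs[0])
    best = (int(i_idx[arg[0]]), int(j_idx[arg[0]]))

    # permutation p-value with early stopping once rejection is impossible
    threshold = params.alpha * (params.n_perm + 1) - 1  # max allowed exceedances
    exceed = 0
    done = 0
    chunk = max(1, min(params.n_perm, int(4e6 / max(1, i_idx.size))))
    while done < params.n_perm:
        b = min(chunk, params.n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        pmax, _ = _max_arc(perms, i_idx, j_idx)
        exceed += int((pmax >= obs - 1e-12).sum())
        done += b
        if exceed > threshold:
            return None
    p = (1 + exceed) / (params.n_perm + 1)
    return best if p < params.alpha else None


def segment_series(x: np.ndarray, params: CbsParams, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Segment one chromosome's series; returns half-open probe-index spans."""
    x = np.asarray(x, dtype=float)
    final: list[tuple[int, int]] = []
    stack = [(0, x.size)]
    while stack:
        a, b = stack.pop()
        hit = _test_split(x[a:b], params, rng)
        if hit is None:
            final.append((a, b))
            continue
        i, j = hit
        for lo, hi in ((a, a + i), (a + i, a + j), (a + j, b)):
            if hi > lo:
                stack.append((lo, hi))
    return sorted(final)


def segment_profile(
    ratios: np.ndarray, annotation: pd.DataFrame, params: CbsParams | None = None
) -> pd.DataFrame:
    """CBS per chromosome; returns a segment table aligned to the annotation.

    Columns: chromosome, start/end (bp, half-open), start_probe/end_probe
    (global probe indices, half-open), n_probes, mean (arithmetic mean of the
    member probes' log2 ratios).  Chromosomes shorter than ``2*min_width``
    come back as a single segment.  Deterministic given ``params.seed``.
    """
    params = params or CbsParams()
    ratios = np.asarray(ratios, dtype=float)
    if len(ratios) != len(annotation):
        raise ValueError("ratio vector length must match the annotation")
    rng = np.random.default_rng(params.seed)
    rows = []
    chroms = annotation["chromosome"].to_numpy()
    starts = annotation["start"].to_numpy()
    ends = annotation["end"].to_numpy()
    offset = 0
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        n = int(mask.sum())
        x = ratios[offset : offset + n]
        for a, b in segment_series(x, params, rng):
            rows.append(
                (
                    chrom,
                    int(starts[offset + a]),
                    int(ends[offset + b - 1]),
                    offset + a,
                    offset + b,
                    b - a,
                    float(np.mean(x[a:b])),
                )
            )
        offset += n
    return pd.DataFrame(
        rows,
        columns=["chromosome", "start", "end", "start_probe", "end_probe", "n_probes", "mean"],
    )
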