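"""Probe-level aCGH pre-processing: from intensities to 4-state calls.

The fixed stage order is

    dewave -> median normalize -> segment -> mode normalize
           -> purity correct -> call

Log2 ratios are tumour/reference intensity ratios after local background
subtraction, median-centred per array.  Dewaving removes the genomic-wave
artefact by regressing each chromosome's ratios on a wave reference profile.
After segmentation (see :mod:`cnsurv.segment`) the dominant — assumed diploid
— state is re-centred at zero by subtracting the mode of the probe-weighted
segment-mean density.  Segment means are then corrected for tumour-cell
percentage (purity) by inverting the admixture law

    2^m_observed = p * 2^m_tumour + (1 - p)

and finally each segment is assigned one of four states
{loss = -1, normal = 0, gain = +1, amplification = +2} from the posteriors of
a one-dimensional Gaussian mixture fitted to the probe-weighted segment
means, with the convention that a state is only called when its posterior
reaches 0.5 and that amplifications wider than 3 Mb are downgraded to gains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, norm

from .segment import CbsParams, segment_profile  # noqa: F401  (re-exported stage)

__all__ = [
    "CallingParams",
    "compute_log2_profile",
    "dewave",
    "mode_normalize",
    "purity_correct",
    "compute_mad",
    "qc_filter",
    "fit_call_mixture",
    "call_profile",
    "preprocess_profile",
]

log = logging.getLogger(__name__)

#: Calls downgrade threshold: amplifications span at most this many bp.
AMP_MAX_SPAN_BP = 3_000_000

CALL_STATES = (-1, 0, 1, 2)


def compute_log2_profile(
    tumour: np.ndarray,
    reference: np.ndarray,
    background: np.ndarray | float = 0.0,
    eps: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted, median-centred log2 tumour/reference ratios.

    Returns ``(ratios, floored)`` where ``floored`` flags probes whose
    background-corrected intensity was clipped at ``eps``.  The output median
    is exactly zero.
    """
    t = np.asarray(tumour, dtype=float)
    r = np.asarray(reference, dtype=float)
    b = np.broadcast_to(np.asarray(background, dtype=float), t.shape)
    if t.shape != r.shape:
        raise ValueError("tumour and reference must have equal length")
    tc, rc = t - b, r - b
    floored = (tc <= eps) | (rc <= eps)
    if floored.any():
        log.warning("%d probes floored at eps=%g during log2 computation", floored.sum(), eps)
    ratios = np.log2(np.maximum(tc, eps) / np.maximum(rc, eps))
    return ratios - np.median(ratios), floored


def dewave(
    ratios: np.ndarray, wave_reference: np.ndarray, chromosomes: np.ndarray
) -> np.ndarray:
    """Remove the wave artefact by per-chromosome least-squares regression.

    For each chromosome the fitted slope of the ratios on the centred wave
    reference is subtracted, leaving residuals uncorrelated with the wave.
    Chromosomes whose reference has zero variance are left untouched.
    """
    r = np.asarray(ratios, dtype=float).copy()
    w = np.asarray(wave_reference, dtype=float)
    if r.shape != w.shape:
        raise ValueError("wave reference length must match the profile")
    chromosomes = np.asarray(chromosomes)
    for chrom in pd.unique(chromosomes):
        m = chromosomes == chrom
        wc = w[m] - w[m].mean()
        denom = float(wc @ wc)
        if denom < 1e-12:
            log.warning("zero-variance wave reference on %s; dewave skipped", chrom)
            continue
        beta = float(r[m] @ wc) / denom
        r[m] = r[m] - beta * w[m]
    return r


def mode_normalize(
    segments: pd.DataFrame, ratios: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Shift ratios and segment means so the modal segment mean sits at zero.

    The mode is taken from a Gaussian kernel density over segment means
    weighted by probe counts (Silverman bandwidth).  Near-ties between local
    maxima resolve toward the candidate with the larger probe mass, then the
    smaller absolute shift.  Returns (shifted segments, shifted ratios, shift).
    """
    means = segments["mean"].to_numpy(dtype=float)
    weights = segments["n_probes"].to_numpy(dtype=float)
    if means.size == 0:
        raise ValueError("no segments")
    spread = np.ptp(means)
    if means.size == 1 or spread < 1e-12:
        shift = float(means[0])
    else:
        # Silverman's rule with the probe count (not the segment count) as the
        # effective sample size: segments are probe-weighted mass points.
        factor = (0.75 * float(weights.sum())) ** (-0.2)
        kde = gaussian_kde(means, bw_method=factor, weights=weights)
        lo, hi = means.min() - 0.5 * spread, means.max() + 0.5 * spread
        grid = np.linspace(lo, hi, 2048)
        dens = kde(grid)
        near = np.flatnonzero(dens >= dens.max() * (1 - 1e-9))
        if near.size > 1:
            # weight candidates by local probe mass, then prefer small |shift|
            bw = kde.factor * means.std(ddof=0)
            mass = np.array(
                [weights[np.abs(means - grid[g]) <= bw].sum() for g in near]
            )
            near = near[mass == mass.max()]
            shift = float(grid[near[np.argmin(np.abs(grid[near]))]])
        else:
            shift = float(grid[near[0]])
    out = segments.copy()
    out["mean"] = out["mean"] - shift
    return out, np.asarray(ratios, dtype=float) - shift, shift


def purity_correct(
    segments: pd.DataFrame, purity: float, eps: float = 2.0**-10
) -> pd.DataFrame:
    """Invert tumour-cell-percentage dilution of segment means.

    ``corrected = log2(max((2^m - (1 - p)) / p, eps))``; identity at p=1.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0,1]")
    out = segments.copy()
    m = out["mean"].to_numpy(dtype=float)
    linear = (np.exp2(m) - (1.0 - purity)) / purity
    clipped = linear < eps
    if clipped.any():
        log.warning("%d segment means clipped at the purity-correction floor", clipped.sum())
    out["mean"] = np.log2(np.maximum(linear, eps))
    return out


def compute_mad(ratios: np.ndarray, segments: pd.DataFrame) -> float:
    """Median absolute deviation of probes around their segment means (unscaled)."""
    r = np.asarray(ratios, dtype=float)
    fitted = np.empty_like(r)
    for seg in segments.itertuples():
        fitted[seg.start_probe : seg.end_probe] = seg.mean
    return float(np.median(np.abs(r - fitted)))


def qc_filter(mads: pd.Series, threshold: float = 0.4) -> pd.Series:
    """Profile QC: keep MAD <= threshold (profiles above it are excluded)."""
    return mads <= threshold


@dataclass(frozen=True)
class CallingParams:
    """EM settings for the 4-state mixture over segment means."""

    init_means: tuple[float, ...] = (-0.45, 0.0, 0.3, 0.9)
    max_iter: int = 500
    tol: float = 1e-8
    posterior_threshold: float = 0.5
    amp_max_span_bp: int = AMP_MAX_SPAN_BP
    # winsorization bounds applied to segment means during fitting only:
    # floor-clipped deep losses (and extreme amplifications) would otherwise
    # blow up the shared variance and swallow single-copy changes
    fit_clip: tuple[float, float] = (-2.5, 3.0)


def fit_call_mixture(
    means: np.ndarray, weights: np.ndarray, params: CallingParams | None = None
) -> dict:
    """Weighted EM for a shared-variance Gaussian mixture with ordered means.

    Components are kept sorted by mean after every M-step so they retain the
    loss < normal < gain < amplification interpretation.  Components whose
    mixing weight collapses are flagged dropped and contribute no posterior
    mass.  Returns dict(means, variance, mix, dropped).
    """
    params = params or CallingParams()
    x = np.clip(np.asarray(means, dtype=float), *params.fit_clip)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    K = len(params.init_means)
    mu = np.asarray(params.init_means, dtype=float).copy()
    var = max(float(np.sum(w * (x - np.sum(w * x)) ** 2)) / 4.0, 1e-4)
    mix = np.full(K, 1.0 / K)
    prev_ll = -np.inf
    for _ in range(params.max_iter):
        logp = norm.logpdf(x[:, None], mu[None, :], np.sqrt(var)) + np.log(
            np.maximum(mix, 1e-300)
        )
        mx = logp.max(axis=1, keepdims=True)
        like = np.exp(logp - mx)
        denom = like.sum(axis=1, keepdims=True)
        resp = like / denom
        ll = float(np.sum(w * (np.log(denom[:, 0]) + mx[:, 0])))
        rw = resp * w[:, None]
        nk = rw.sum(axis=0)
        mix = nk
        alive = nk > 1e-12
        mu[alive] = (rw[:, alive] * x[:, None]).sum(axis=0) / nk[alive]
        var = max(float(np.sum(rw * (x[:, None] - mu[None, :]) ** 2)), 1e-8)
        order = np.argsort(mu, kind="stable")
        mu, mix = mu[order], mix[order]
        if abs(ll - prev_ll) < params.tol:
            break
        prev_ll = ll
    dropped = mix < 1e-6
    # EM can park two components on one cluster; treat near-duplicates as a
    # degenerate fit: keep the slot whose initial mean is closer, fold the
    # other's mass in, and flag it dropped.
    init_sorted = np.sort(np.asarray(params.init_means, dtype=float))
    for k in range(1, K):
        j = k - 1
        if dropped[k] or dropped[j]:
            continue
        if abs(mu[k] - mu[j]) < 0.05:
            keep, drop_ = (j, k) if abs(mu[j] - init_sorted[j]) <= abs(mu[k] - init_sorted[k]) else (k, j)
            mix[keep] += mix[drop_]
            dropped[drop_] = True
    if dropped.any():
        log.warning("%d mixture components degenerate after EM; dropped", int(dropped.sum()))
    return {"means": mu, "variance": var, "mix": mix, "dropped": dropped}


def _posteriors(model: dict, values: np.ndarray) -> np.ndarray:
    mu, var, mix = model["means"], model["variance"], np.where(model["dropped"], 0.0, model["mix"])
    with np.errstate(under="ignore"):
        logp = norm.logpdf(values[:, None], mu[None, :], np.sqrt(var))
    like = np.exp(logp - logp.max(axis=1, keepdims=True)) * mix[None, :]
    s = like.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return like / s


def call_profile(
    segments: pd.DataFrame, params: CallingParams | None = None, model: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Assign loss/normal/gain/amplification calls to purity-corrected segments.

    Each segment's posterior over the four states comes from the per-sample
    mixture fit; the argmax state is called when its posterior reaches the
    0.5 threshold, otherwise the segment is called normal.  Amplification
    calls wider than 3 Mb are downgraded to gain.  Returns the segment table
    with ``call`` and ``post_loss``..``post_amp`` columns plus the model.
    """
    params = params or CallingParams()
    means = segments["mean"].to_numpy(dtype=float)
    weights = segments["n_probes"].to_numpy(dtype=float)
    if model is None:
        model = fit_call_mixture(means, weights, params)
    post = _posteriors(model, means)
    best = post.argmax(axis=1)
    call = np.where(
        post[np.arange(len(means)), best] >= params.posterior_threshold,
        np.array(CALL_STATES)[best],
        0,
    )
    span = segments["end"].to_numpy() - segments["start"].to_numpy()
    call = np.where((call == 2) & (span > params.amp_max_span_bp), 1, call)
    out = segments.copy()
    out["call"] = call.astype(int)
    for k, name in enumerate(["post_loss", "post_normal", "post_gain", "post_amp"]):
        out[name] = post[:, k]
    return out, model


def probe_calls(segments: pd.DataFrame, n_probes: int) -> np.ndarray:
    """Expand per-segment calls to the probe level."""
    calls = np.zeros(n_probes, dtype=int)
    for seg in segments.itertuples():
        calls[seg.start_probe : seg.end_probe] = seg.call
    return calls


def preprocess_profile(
    ratios: np.ndarray,
    annotation: pd.DataFrame,
    purity: float = 1.0,
    wave_reference: np.ndarray | None = None,
    cbs: CbsParams | None = None,
    calling: CallingParams | None = None,
) -> dict:
    """Run the full per-sample stage chain on a vector of log2 ratios.

    Returns dict with keys ratios (post normalisation), segments (called),
    mad, qc_pass, mode_shift, model.
    """
    r = np.asarray(ratios, dtype=float)
    if wave_reference is not None:
        r = dewave(r, wave_reference, annotation["chromosome"].to_numpy())
    r = r - np.median(r)
    segs = segment_profile(r, annotation, cbs)
    segs, r, shift = mode_normalize(segs, r)
    mad = compute_mad(r, segs)
    segs = purity_correct(segs, purity)
    called, model = call_profile(segs, calling)
    return {
        "ratios": r,
        "segments": called,
        "mad": mad,
        "qc_pass": bool(mad <= 0.4),
        "mode_shift": shift,
        "model": model,
    }
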