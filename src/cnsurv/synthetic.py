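"""Synthetic aCGH cohorts, paired expression data and cell-line panels.

The generator emulates the statistical structure of a multi-arm metastatic
colorectal cancer trial profiled by array CGH:

* per-sample piecewise-constant integer copy-number genomes diluted by tumour
  purity, overlaid with a per-chromosome sinusoidal "wave" artefact and
  Gaussian probe noise;
* per-arm progression-free survival (PFS) drawn from an exponential whose rate
  is the arm baseline scaled multiplicatively by the hazard ratios of the
  driver aberrations a sample carries, with independent exponential censoring
  tuned to a target censoring fraction;
* microsatellite-instable (MSI) samples with near-silent genomes;
* a paired copy-number/expression dataset in which a chosen fraction of genes
  is dosage sensitive (expression tracks copy number at a target correlation);
* a cell-line panel whose log-IC50 shifts when a line is aberrant for a
  tested region.

Everything is reproducible from the seed carried in the configuration; a
:class:`GroundTruth` record of what was planted accompanies every dataset so
recovery tests can score the analysis modules against it.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DriverSpec",
    "CohortConfig",
    "CopyNumberProfile",
    "GroundTruth",
    "PairedExpressionDataset",
    "CellLinePanel",
    "CRC_PANEL_SIZE",
    "FULL_PANEL_SIZE",
    "simulate_probe_annotation",
    "simulate_cohort",
    "simulate_paired_expression",
    "simulate_cellline_panel",
]

#: Number of colorectal-cancer cell lines in the validation sub-panel.
CRC_PANEL_SIZE = 31
#: Cell lines with both copy-number and IC50 data in the full validation panel.
FULL_PANEL_SIZE = 573

# Integer copy-number alphabet used in ground truth; maps onto the four call
# states loss/normal/gain/amplification.
_COPY_FOR_ABERRATION = {"loss": 1, "deep_loss": 0, "gain": 3, "amplification": 5}


@dataclass(frozen=True)
class DriverSpec:
    """A planted aberration with a survival effect.

    ``hazard_ratio_per_arm`` maps arm label to the multiplicative hazard the
    aberration confers in that arm (1.0 = no effect).
    """

    chromosome: str
    start: int
    end: int
    aberration: str  # one of loss / gain / amplification
    carrier_fraction: float
    hazard_ratio_per_arm: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("driver start must be < end")
        if not 0.0 < self.carrier_fraction < 1.0:
            raise ValueError("carrier_fraction must be in (0,1)")
        if self.aberration not in ("loss", "gain", "amplification"):
            raise ValueError(f"unknown aberration {self.aberration!r}")
        if any(h <= 0 for h in self.hazard_ratio_per_arm.values()):
            raise ValueError("hazard ratios must be positive")


@dataclass
class CohortConfig:
    """Simulation knobs for a multi-arm aCGH trial cohort.

    Defaults mirror the trial the analysis was designed for: three arms of
    105/111/133 samples, ~17 kb probe spacing, tumour-cell percentage at least
    70%, 21/349 MSI tumours, and arm-level median PFS near 200/260/390 days.
    The genome itself is scaled down (4 chromosomes x 250 probes).
    """

    arms: tuple[str, ...] = ("CAP", "CAPIRI", "CAPOX-B")
    n_samples_per_arm: Mapping[str, int] = field(
        default_factory=lambda: {"CAP": 105, "CAPIRI": 111, "CAPOX-B": 133}
    )
    n_chromosomes: int = 4
    probes_per_chromosome: int = 250
    probe_spacing: int = 17_000  # bp
    noise_sd: float = 0.25  # log2 units; residual MAD ~ 0.17
    wave_amplitude: float = 0.10  # log2 units
    wave_period: int = 50  # probes
    purity_range: tuple[float, float] = (0.7, 1.0)
    background_aberration_rate: float = 8.0  # expected aberrant segments/genome
    driver_regions: Sequence[DriverSpec] = ()
    baseline_median_pfs: Mapping[str, float] = field(
        default_factory=lambda: {"CAP": 200.0, "CAPIRI": 260.0, "CAPOX-B": 390.0}
    )
    censoring_rate: float = 0.1
    msi_fraction: float = 21 / 349
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.probes_per_chromosome <= 0:
            raise ValueError("chromosome and probe counts must be positive")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be positive")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must be within (0,1]")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0,1)")
        if set(self.n_samples_per_arm) != set(self.arms):
            raise ValueError("n_samples_per_arm keys must match arms")
        if any(n <= 0 for n in self.n_samples_per_arm.values()):
            raise ValueError("sample counts must be positive")
        if set(self.baseline_median_pfs) != set(self.arms):
            raise ValueError("baseline_median_pfs keys must match arms")

    @property
    def chromosome_length(self) -> int:
        return self.probes_per_chromosome * self.probe_spacing

    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class CopyNumberProfile:
    """Per-sample probe-level log2 ratios with purity and QC metadata."""

    sample_id: str
    log2_ratios: np.ndarray
    purity: float
    mad: float | None = None
    qc_pass: bool | None = None


@dataclass
class GroundTruth:
    """What the generator planted; the scoring key for recovery tests."""

    segments: pd.DataFrame  # sample_id, chromosome, start, end, copy
    purity: dict[str, float]
    carriers: pd.DataFrame  # sample_id x driver index, boolean
    wave_reference: np.ndarray  # per-probe wave (mean of simulated normals)
    seed: int
    dosage_genes: list[str] = field(default_factory=list)
    cellline_status: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "purity": self.purity,
            "segments": self.segments.to_dict(orient="list"),
            "carriers": {
                "sample_id": list(self.carriers.index),
                **{str(c): self.carriers[c].astype(bool).tolist() for c in self.carriers},
            },
            "wave_reference": np.asarray(self.wave_reference).tolist(),
            "dosage_genes": self.dosage_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


@dataclass
class PairedExpressionDataset:
    """Matched gene x sample copy-number and expression matrices."""

    copy_number: pd.DataFrame
    expression: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.copy_number.shape[1]


@dataclass
class CellLinePanel:
    """Cell-line copy-number segments plus per-drug log-IC50 values."""

    segments: pd.DataFrame  # line_id, chromosome, start, end, copy
    ic50: pd.DataFrame  # line_id, drug, log_ic50
    labels: pd.Series | None = None  # line_id -> sub-panel label


def simulate_probe_annotation(config: CohortConfig) -> pd.DataFrame:
    """Evenly spaced probes on every chromosome, BED-style half-open coordinates."""
    rows = []
    for chrom in config.chromosomes():
        for k in range(config.probes_per_chromosome):
            rows.append(
                (
                    chrom,
                    k * config.probe_spacing,
                    (k + 1) * config.probe_spacing,
                    f"{chrom}_p{k:05d}",
                )
            )
    ann = pd.DataFrame(rows, columns=["chromosome", "start", "end", "probe_id"])
    return ann[["probe_id", "chromosome", "start", "end"]]


def _wave(config: CohortConfig) -> np.ndarray:
    """The shared wave artefact: one sinusoid per chromosome, fixed phase."""
    k = np.arange(config.probes_per_chromosome)
    per_chrom = np.sin(2 * np.pi * k / config.wave_period)
    return np.tile(per_chrom, config.n_chromosomes)


def _tune_censoring_rate(lambdas: np.ndarray, target: float, tol: float = 0.005) -> float:
    """Bisect the exponential censoring rate c so mean_i c/(lambda_i+c) = target."""
    if target <= 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (lambdas + c)))

    lo, hi = 1e-12, float(lambdas.max())
    while frac(hi) < target:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
        if abs(frac(mid) - target) < tol:
            return mid
    return 0.5 * (lo + hi)


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[CopyNumberProfile], pd.DataFrame, GroundTruth]:
    """Simulate probe-level profiles, a clinical table and ground truth.

    Observed linear ratio at a probe with true copy ``c`` and purity ``p`` is
    ``p*c/2 + (1-p)`` (diploid admixture), log2-transformed, plus the wave and
    Gaussian noise.  PFS is exponential with the arm baseline rate scaled by
    the product of carried drivers' hazard ratios.
    """
    rng = np.random.default_rng(config.seed)
    ann = simulate_probe_annotation(config)
    for d in config.driver_regions:
        if d.chromosome not in config.chromosomes() or d.end > config.chromosome_length:
            raise ValueError(f"driver region {d} outside the simulated genome")

    n_probes = len(ann)
    ppc = config.probes_per_chromosome
    chrom_index = {c: i for i, c in enumerate(config.chromosomes())}
    wave = _wave(config)

    sample_ids, arm_of = [], []
    for arm in config.arms:
        for i in range(config.n_samples_per_arm[arm]):
            sample_ids.append(f"{arm}_{i:04d}")
            arm_of.append(arm)
    n = len(sample_ids)

    msi = rng.random(n) < config.msi_fraction
    purity = rng.uniform(*config.purity_range, size=n)

    # driver carriers (MSI genomes stay silent)
    carriers = np.zeros((n, len(config.driver_regions)), dtype=bool)
    for j, d in enumerate(config.driver_regions):
        carriers[:, j] = (rng.random(n) < d.carrier_fraction) & ~msi
        if carriers[:, j].sum() == 0:
            warnings.warn(
                f"driver {j} ({d.chromosome}:{d.start}-{d.end}) drew zero carriers",
                stacklevel=2,
            )

    profiles: list[CopyNumberProfile] = []
    seg_rows = []
    amp_cap = max(1, int(3_000_000 // config.probe_spacing))  # keep amps <= 3 Mb
    for i, sid in enumerate(sample_ids):
        copies = np.full(n_probes, 2, dtype=int)
        rate = config.background_aberration_rate * (0.02 if msi[i] else 1.0)
        for _ in range(rng.poisson(rate)):
            chrom = rng.integers(config.n_chromosomes)
            kind = rng.choice(
                ["loss", "deep_loss", "gain", "amplification"], p=[0.40, 0.05, 0.45, 0.10]
            )
            max_len = amp_cap if kind == "amplification" else max(2, ppc // 2)
            length = int(rng.integers(2, max_len + 1))
            start = int(rng.integers(0, ppc - length + 1))
            lo = chrom * ppc + start
            copies[lo : lo + length] = _COPY_FOR_ABERRATION[kind]
        for j, d in enumerate(config.driver_regions):
            if carriers[i, j]:
                base = chrom_index[d.chromosome] * ppc
                p0 = base + d.start // config.probe_spacing
                p1 = base + int(np.ceil(d.end / config.probe_spacing))
                copies[p0:p1] = _COPY_FOR_ABERRATION[d.aberration]

        linear = purity[i] * copies / 2.0 + (1.0 - purity[i])
        r = np.log2(np.maximum(linear, 2.0**-10))  # floor homozygous loss at pure tumour
        if config.wave_amplitude > 0:
            r = r + config.wave_amplitude * rng.lognormal(0.0, 0.1) * wave
        if config.noise_sd > 0:
            r = r + rng.normal(0.0, config.noise_sd, size=n_probes)
        profiles.append(CopyNumberProfile(sid, r, float(purity[i])))

        # run-length encode the truth copies
        change = np.flatnonzero(np.diff(copies)) + 1
        bounds = np.r_[0, change, n_probes]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if copies[a] != 2:
                chrom = config.chromosomes()[a // ppc]
                seg_rows.append(
                    (
                        sid,
                        chrom,
                        int(ann.start.iloc[a]),
                        int(ann.end.iloc[b - 1]),
                        int(copies[a]),
                    )
                )

    # survival
    lam = np.empty(n)
    for i in range(n):
        lam[i] = np.log(2) / config.baseline_median_pfs[arm_of[i]]
        for j, d in enumerate(config.driver_regions):
            if carriers[i, j]:
                lam[i] *= d.hazard_ratio_per_arm.get(arm_of[i], 1.0)
    event_t = rng.exponential(1.0 / lam)
    if config.censoring_rate > 0:
        c = _tune_censoring_rate(lam, config.censoring_rate)
        cens_t = rng.exponential(1.0 / c, size=n)
    else:
        cens_t = np.full(n, np.inf)
    pfs = np.minimum(event_t, cens_t)
    event = (event_t <= cens_t).astype(int)

    cycles = 3 + rng.poisson(4.0, size=n)
    early_stop = rng.random(n) < 0.05
    cycles[early_stop] = rng.integers(1, 3, size=int(early_stop.sum()))
    death_prog = early_stop & (rng.random(n) < 0.5)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "arm": arm_of,
            "pfs_days": np.round(pfs, 1),
            "event": event,
            "cycles": cycles,
            "death_progression": death_prog,
            "msi": msi,
            "tumour_cell_pct": np.round(purity, 3),
        }
    )

    truth = GroundTruth(
        segments=pd.DataFrame(
            seg_rows, columns=["sample_id", "chromosome", "start", "end", "copy"]
        ),
        purity={sid: float(p) for sid, p in zip(sample_ids, purity)},
        carriers=pd.DataFrame(carriers, index=sample_ids),
        wave_reference=config.wave_amplitude * wave,
        seed=config.seed,
    )
    return profiles, clinical, truth


def simulate_paired_expression(
    genes: pd.DataFrame,
    dosage_fraction: float,
    rho: float,
    n_samples: int = 141,
    seed: int = 0,
) -> tuple[PairedExpressionDataset, GroundTruth]:
    """Paired copy-number/expression matrices with a dosage-sensitive subset.

    A fraction ``dosage_fraction`` of genes get expression ``a*CN + noise``
    with the noise variance calibrated so the population (Pearson) correlation
    equals ``rho``; the remainder are independent of copy number.  The default
    cohort size matches the 141-sample external expression dataset the method
    filters against.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3 (correlation undefined below)")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must be in [0,1)")
    rng = np.random.default_rng(seed)
    gene_ids = list(genes["gene_id"])
    n_genes = len(gene_ids)
    # ordinal copy-number calls with realistic state frequencies
    cn = rng.choice([-1, 0, 1], size=(n_genes, n_samples), p=[0.22, 0.53, 0.25]).astype(float)
    expr = rng.normal(size=(n_genes, n_samples))
    n_dosage = int(round(dosage_fraction * n_genes))
    dosage_idx = rng.choice(n_genes, size=n_dosage, replace=False)
    if rho > 0 and n_dosage:
        sd_cn = np.sqrt(0.22 + 0.25 - (0.25 - 0.22) ** 2)  # population sd of the call
        sigma = sd_cn * np.sqrt(1.0 / rho**2 - 1.0)
        expr[dosage_idx] = cn[dosage_idx] + rng.normal(0.0, sigma, size=(n_dosage, n_samples))
    samples = [f"S{i:04d}" for i in range(n_samples)]
    ds = PairedExpressionDataset(
        copy_number=pd.DataFrame(cn, index=gene_ids, columns=samples),
        expression=pd.DataFrame(expr, index=gene_ids, columns=samples),
    )
    truth = GroundTruth(
        segments=pd.DataFrame(columns=["sample_id", "chromosome", "start", "end", "copy"]),
        purity={},
        carriers=pd.DataFrame(),
        wave_reference=np.zeros(0),
        seed=seed,
        dosage_genes=[gene_ids[i] for i in sorted(dosage_idx)],
    )
    return ds, truth


def simulate_cellline_panel(
    n_lines: int,
    regions: pd.DataFrame,
    effect: Mapping[str, float],
    seed: int = 0,
    drug: str = "SN-38",
    crc_lines: int = 0,
) -> tuple[CellLinePanel, GroundTruth]:
    """Cell lines with random copy-number segments and region-shifted log-IC50.

    ``regions`` needs columns chromosome/start/end/type/label; ``effect`` maps
    region label to the log-IC50 shift (in units of the 1.0 baseline SD)
    applied to lines aberrant for that region's state.  ``crc_lines`` labels
    the first that many lines as the "CRC-panel" sub-panel (31 in the study).
    """
    if len(regions) == 0:
        raise ValueError("empty region list")
    if n_lines <= 0:
        raise ValueError("n_lines must be positive")
    rng = np.random.default_rng(seed)
    chroms = sorted(set(regions["chromosome"]))
    extent = {
        c: int(regions.loc[regions.chromosome == c, "end"].max() * 2) for c in chroms
    }
    line_ids = [f"CL{i:04d}" for i in range(n_lines)]
    seg_rows = []
    for lid in line_ids:
        for c in chroms:
            # partition the chromosome into a few segments with copies {1,2,3}
            n_seg = int(rng.integers(1, 5))
            cuts = np.sort(rng.integers(1, extent[c], size=n_seg - 1)) if n_seg > 1 else []
            bounds = np.r_[0, cuts, extent[c]].astype(int)
            for a, b in zip(bounds[:-1], bounds[1:]):
                copy = int(rng.choice([1, 2, 3], p=[0.25, 0.5, 0.25]))
                seg_rows.append((lid, c, int(a), int(b), copy))
    segments = pd.DataFrame(seg_rows, columns=["line_id", "chromosome", "start", "end", "copy"])

    status_rows = {}
    shifts = np.zeros(n_lines)
    want = {"gain": lambda s: s > 2, "loss": lambda s: s < 2}
    for _, reg in regions.iterrows():
        pred = want[reg["type"]]
        aberrant = np.zeros(n_lines, dtype=bool)
        for i, lid in enumerate(line_ids):
            segs = segments[
                (segments.line_id == lid)
                & (segments.chromosome == reg["chromosome"])
                & (segments.start < reg["end"])
                & (segments.end > reg["start"])
            ]
            aberrant[i] = bool(pred(segs["copy"]).any())
        status_rows[reg["label"]] = aberrant
        shifts = shifts + aberrant * effect.get(reg["label"], 0.0)

    ic50 = pd.DataFrame(
        {
            "line_id": line_ids,
            "drug": drug,
            "log_ic50": rng.normal(0.0, 1.0, size=n_lines) + shifts,
        }
    )
    labels = pd.Series(
        ["CRC-panel" if i < crc_lines else "other" for i in range(n_lines)],
        index=line_ids,
        name="panel",
    )
    panel = CellLinePanel(segments=segments, ic50=ic50, labels=labels)
    truth = GroundTruth(
        segments=segments.rename(columns={"line_id": "sample_id"}),
        purity={},
        carriers=pd.DataFrame(),
        wave_reference=np.zeros(0),
        seed=seed,
        cellline_status=pd.DataFrame(status_rows, index=line_ids),
    )
    return panel, truth


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["driver_regions"] = [dataclasses.asdict(x) for x in config.driver_regions]
    return d
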