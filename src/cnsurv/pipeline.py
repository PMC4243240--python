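"""End-to-end pipeline driver: simulate -> preprocess -> regions -> associate
-> genes -> amplicons -> celllines, with a reproducibility manifest.

Every stochastic stage draws its seed from the single pipeline seed through
``numpy.random.SeedSequence``, so a rerun with the same configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import integration, io, preprocess, regions, survival, synthetic
from .segment import CbsParams

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    cbs: CbsParams = field(default_factory=CbsParams)
    calling: preprocess.CallingParams = field(default_factory=preprocess.CallingParams)
    region_tolerance: float = 0.01
    n_perm: int = 10_000
    min_group: int = 5
    tier1_alpha: float = 0.005
    tier2_alpha: float = 0.05
    dosage_alpha: float = 0.05
    min_amplicon_freq: int = 4
    mad_threshold: float = 0.4
    n_expression_samples: int = 141
    dosage_fraction: float = 0.3
    dosage_rho: float = 0.6
    n_cell_lines: int = synthetic.FULL_PANEL_SIZE
    cellline_effect_sd: float = -0.5
    seed: int = 0
    skip_dewave: bool = False


def demo_config(seed: int = 0) -> PipelineConfig:
    """A small configuration that exercises every stage in a couple of minutes."""
    cohort = synthetic.CohortConfig(
        n_samples_per_arm={"CAP": 40, "CAPIRI": 40, "CAPOX-B": 40},
        n_chromosomes=2,
        probes_per_chromosome=200,
        probe_spacing=100_000,
        noise_sd=0.15,
        background_aberration_rate=5.0,
        driver_regions=(
            synthetic.DriverSpec(
                chromosome="chr1",
                start=4_000_000,
                end=10_000_000,
                aberration="loss",
                carrier_fraction=0.25,
                hazard_ratio_per_arm={"CAP": 2.5, "CAPIRI": 1.0, "CAPOX-B": 1.0},
            ),
        ),
        seed=seed,
    )
    return PipelineConfig(
        cohort=cohort,
        cbs=CbsParams(n_perm=200, seed=seed),
        n_perm=500,
        seed=seed,
    )


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage, writing all artefact tables plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(6) % (2**31)
    files: list[str] = []

    # --- simulate ------------------------------------------------------
    cohort_cfg = config.cohort
    ann = synthetic.simulate_probe_annotation(cohort_cfg)
    profiles, clinical, truth = synthetic.simulate_cohort(cohort_cfg)
    io.write_bed(ann, outdir / "probes.bed", columns=("chromosome", "start", "end", "probe_id"))
    ratio_matrix = pd.DataFrame(
        {p.sample_id: p.log2_ratios for p in profiles}, index=ann["probe_id"]
    )
    io.write_matrix(ratio_matrix, outdir / "ratios.tsv")
    clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    files += ["probes.bed", "ratios.tsv", "clinical.tsv", "truth.json"]

    # --- preprocess ----------------------------------------------------
    wave = None if config.skip_dewave else truth.wave_reference
    seg_rows, call_cols, qc_rows = [], {}, []
    cbs = CbsParams(
        alpha=config.cbs.alpha, n_perm=config.cbs.n_perm,
        min_width=config.cbs.min_width, seed=int(seeds[0]),
    )
    for prof in profiles:
        res = preprocess.preprocess_profile(
            prof.log2_ratios, ann, purity=prof.purity,
            wave_reference=wave, cbs=cbs, calling=config.calling,
        )
        segs = res["segments"].assign(sample_id=prof.sample_id)
        seg_rows.append(segs)
        call_cols[prof.sample_id] = preprocess.probe_calls(res["segments"], len(ann))
        qc_rows.append(
            dict(sample_id=prof.sample_id, mad=res["mad"],
                 qc_pass=res["mad"] <= config.mad_threshold,
                 mode_shift=res["mode_shift"])
        )
    qc = pd.DataFrame(qc_rows)
    qc.to_csv(outdir / "qc.tsv", sep="\t", index=False)
    all_segs = pd.concat(seg_rows, ignore_index=True)
    io.write_seg(all_segs, outdir / "segments.seg")
    kept = set(qc.loc[qc.qc_pass, "sample_id"])
    calls = pd.DataFrame(call_cols, index=ann["probe_id"])[
        [s for s in call_cols if s in kept]
    ]
    io.write_matrix(calls, outdir / "calls.tsv")
    files += ["qc.tsv", "segments.seg", "calls.tsv"]
    log.info("QC kept %d/%d profiles", len(kept), len(profiles))

    # --- regions -------------------------------------------------------
    subregions, region_calls = regions.reduce_to_subregions(
        calls.reset_index(drop=True), ann, tolerance=config.region_tolerance
    )
    subregions.to_csv(outdir / "subregions.tsv", sep="\t", index=True, index_label="region")
    io.write_matrix(region_calls, outdir / "region_calls.tsv")
    files += ["subregions.tsv", "region_calls.tsv"]

    # --- associate -----------------------------------------------------
    eligible = survival.filter_cohort(clinical)
    eligible = eligible[eligible["sample_id"].isin(calls.columns)]
    scans = []
    for i, arm in enumerate(cohort_cfg.arms):
        scans.append(
            survival.associate_genomewide(
                region_calls, eligible, arm, n_perm=config.n_perm,
                min_group=config.min_group, seed=int(seeds[1]) + i, prefiltered=True,
            )
        )
    flagged = survival.flag_significance(scans, config.tier1_alpha, config.tier2_alpha)
    fdr_rows = []
    for scan in scans:
        tested = scan.results[scan.results["skipped"] == ""]
        fdr = survival.permutation_fdr(
            tested["perm_p"].to_numpy(), scan.permuted_p.to_numpy(), config.tier1_alpha
        )
        fdr_rows.append(dict(arm=scan.arm, threshold=config.tier1_alpha, fdr=fdr))
    flagged.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    pd.DataFrame(fdr_rows).to_csv(outdir / "fdr.tsv", sep="\t", index=False)
    files += ["associations.tsv", "fdr.tsv"]

    # --- genes ---------------------------------------------------------
    genes = _tile_genes(ann, gene_size=200_000)
    paired, _ = synthetic.simulate_paired_expression(
        genes, dosage_fraction=config.dosage_fraction, rho=config.dosage_rho,
        n_samples=config.n_expression_samples, seed=int(seeds[2]),
    )
    candidates = integration.select_candidate_genes(
        flagged, subregions, genes, paired, alpha=config.dosage_alpha
    )
    candidates.to_csv(outdir / "candidate_genes.tsv", sep="\t", index=False)
    files.append("candidate_genes.tsv")

    # --- amplicons -----------------------------------------------------
    events = integration.detect_amplicons(calls, ann)
    loci = integration.recurrent_amplicons(events, min_freq=config.min_amplicon_freq,
                                           genes=genes)
    loci.to_csv(outdir / "amplicons.tsv", sep="\t", index=False)
    files.append("amplicons.tsv")

    # --- celllines -----------------------------------------------------
    sig = flagged[(flagged["tier1"]) & (flagged["skipped"] == "")]
    total_regions = _total_regions_table(sig, subregions)
    if len(total_regions):
        effect = {lab: config.cellline_effect_sd for lab in total_regions["label"]}
        panel, _ = synthetic.simulate_cellline_panel(
            config.n_cell_lines, total_regions, effect, seed=int(seeds[3]),
            crc_lines=synthetic.CRC_PANEL_SIZE,
        )
        validation = integration.validate_regions_in_celllines(panel, total_regions, "SN-38")
    else:
        validation = pd.DataFrame(
            columns=["region", "panel", "n_aberrant", "n_normal", "H", "p"]
        )
    validation.to_csv(outdir / "cellline_validation.tsv", sep="\t", index=False)
    files.append("cellline_validation.tsv")

    io.write_manifest(
        outdir,
        params={
            "seed": config.seed,
            "cohort": synthetic.config_to_dict(cohort_cfg),
            "cbs": vars(config.cbs),
            "n_perm": config.n_perm,
            "region_tolerance": config.region_tolerance,
        },
        files=files,
    )
    return outdir


def _tile_genes(annotation: pd.DataFrame, gene_size: int) -> pd.DataFrame:
    """Synthetic gene annotation tiling the simulated genome."""
    rows = []
    for chrom, grp in annotation.groupby("chromosome", sort=False):
        length = int(grp["end"].max())
        for i, s in enumerate(range(0, length, gene_size)):
            rows.append((f"{chrom}_g{i:04d}", chrom, s, min(s + gene_size, length)))
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


def _total_regions_table(sig: pd.DataFrame, subregions: pd.DataFrame) -> pd.DataFrame:
    """Concatenate significant subregions per aberration kind into total regions."""
    rows = []
    for kind, grp in sig.groupby("kind"):
        flags = subregions.index.isin(grp["region"])
        for tr in regions.concatenate_significant(subregions, flags, mode="adjacent_within_arm"):
            rows.append(dict(chromosome=tr.chromosome, start=tr.start, end=tr.end,
                             type=kind, label=f"{tr.label}:{kind}"))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "type", "label"])
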