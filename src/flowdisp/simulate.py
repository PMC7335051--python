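"""Synthetic cohorts with the measurement structure of the real experiment.

Generates (i) single-sample cytometry event tables with cell-cycle DAPI
structure, doublets, debris and size-coupled fluorescence; (ii) cohorts of
cell lines with Hardy-Weinberg genotypes in which a designated SNP additively
modulates the dispersion (log-scale SD at fixed mean), the mean, or the
bimodality of expression; and (iii) per-read CDR3 annotation tables for the
clonality caller. Fluorescence is simulated directly on the log scale; the
raw-scale export applies ``exp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import CHANNELS, ConfigurationError, EventTable
from .linkage import GenotypeMatrix, VariantRecord

__all__ = [
    "SimSampleConfig",
    "SimCohortConfig",
    "simulate_sample_events",
    "simulate_cohort",
    "simulate_cdr3_reads",
    "simulate_cd23_gmm_table",
    "write_events_csv",
]

#: J-region translation carrying the conserved CDR3/FR4 [FW]-G-X-G motif.
VALID_J_REGION = "YYYYGMDVWGQGTTVTVSS"
#: J-region translation lacking the conserved motif (noise reads).
MOTIFLESS_J_REGION = "YYYYAMDVAAQATTVTVSS"

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimSampleConfig:
    """Stated world for one acquisition sample.

    DAPI is drawn per cell-cycle phase (G1 mode, G2 mode at ~2x G1, S spread
    between them, unstained debris near zero); doublets are sums of two
    singlets with inflated pulse width (FSC-W); log fluorescence couples to
    log scatter through ``size_coupling`` (coefficients of centred log FSC-A
    and log SSC-A), so configured component means equal population means.
    """

    g1_dapi_mode: float = 100.0
    g2_dapi_mode: float = 200.0
    frac_g1: float = 0.62
    frac_s: float = 0.14
    frac_g2: float = 0.14
    frac_unstained: float = 0.05
    frac_doublets: float = 0.05
    size_coupling: tuple[float, float] = (0.3, 0.1)
    fl_components: tuple[tuple[float, float, float], ...] = ((1.0, 5.0, 0.5),)
    dapi_cv: float = 0.04
    fl_noise_sd: float = 0.05
    fsc_log_mean: float = np.log(5e4)
    fsc_log_sd: float = 0.15
    ssc_log_mean: float = np.log(3e4)
    ssc_log_sd: float = 0.20
    fscw_mean: float = 70.0
    fscw_sd: float = 3.0
    doublet_width_factor: float = 1.8

    def validate(self) -> None:
        fracs = {
            "frac_g1": self.frac_g1,
            "frac_s": self.frac_s,
            "frac_g2": self.frac_g2,
            "frac_unstained": self.frac_unstained,
            "frac_doublets": self.frac_doublets,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name}={value} outside [0, 1]")
        if self.frac_g1 + self.frac_s + self.frac_g2 > 1.0 + 1e-9:
            raise ConfigurationError("cell-cycle fractions sum above 1")
        if not self.fl_components:
            raise ConfigurationError("need at least one FL component")
        weights = [w for w, _, _ in self.fl_components]
        if abs(sum(weights) - 1.0) > 1e-6:
            raise ConfigurationError("FL component weights must sum to 1")
        if any(sd <= 0 for _, _, sd in self.fl_components):
            raise ConfigurationError("FL component sds must be positive")
        if self.g2_dapi_mode <= self.g1_dapi_mode:
            raise ConfigurationError("G2 DAPI mode must exceed the G1 mode")


@dataclass
class SimCohortConfig:
    """Stated world for a mapping cohort.

    ``effect_size`` multiplies the log-scale SD per alternate allele under
    ``effect_mode='dispersion'`` (the population mean is identical across
    genotype groups by construction), shifts the log mean per allele under
    ``'mean'``, and shifts the low-component weight p1 per allele under
    ``'bimodality'``.
    """

    n_lines: int = 48
    n_replicates: int = 6
    n_events: int = 20000
    maf: float = 0.25
    n_null_snps: int = 200
    effect_mode: str = "dispersion"
    effect_size: float = 1.5
    base_mean: float = 5.0
    base_cv: float = 0.1
    seed: int = 0
    sample: SimSampleConfig = field(default_factory=SimSampleConfig)
    replicate_sd_noise: float = 0.02
    replicate_mean_noise: float = 0.01
    bimodal_p1: float = 0.5
    bimodal_delta: float = 1.5
    chrom: str = "1"
    tss: int = 5_000_000

    def validate(self) -> None:
        if self.n_events <= 0:
            raise ConfigurationError("n_events must be positive")
        if not 0.0 < self.maf <= 0.5:
            raise ConfigurationError("maf must lie in (0, 0.5]")
        if self.base_cv <= 0:
            raise ConfigurationError("base_cv must be positive")
        if self.n_lines < 2:
            raise ConfigurationError("need at least two lines")
        if self.effect_mode not in {"dispersion", "mean", "bimodality", "null"}:
            raise ConfigurationError(f"unknown effect_mode {self.effect_mode!r}")
        self.sample.validate()


def _draw_singlets(cfg: SimSampleConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    probs = np.array(
        [cfg.frac_g1, cfg.frac_s, cfg.frac_g2, cfg.frac_unstained], dtype=float
    )
    total = probs.sum()
    if total <= 0:
        raise ConfigurationError("all event fractions are zero")
    phase = rng.choice(4, size=n, p=probs / total)

    dapi = np.empty(n)
    g1_sd = cfg.dapi_cv * cfg.g1_dapi_mode
    g2_sd = cfg.dapi_cv * cfg.g2_dapi_mode
    m = phase == 0
    dapi[m] = rng.normal(cfg.g1_dapi_mode, g1_sd, m.sum())
    m = phase == 1
    dapi[m] = rng.uniform(cfg.g1_dapi_mode + 2 * g1_sd, cfg.g2_dapi_mode - 2 * g2_sd, m.sum())
    m = phase == 2
    dapi[m] = rng.normal(cfg.g2_dapi_mode, g2_sd, m.sum())
    m = phase == 3
    dapi[m] = np.abs(rng.normal(0.0, 0.03 * cfg.g1_dapi_mode, m.sum()))

    log_fsc = rng.normal(cfg.fsc_log_mean, cfg.fsc_log_sd, n)
    log_ssc = rng.normal(cfg.ssc_log_mean, cfg.ssc_log_sd, n)
    fsc_w = rng.normal(cfg.fscw_mean, cfg.fscw_sd, n)

    weights = np.array([w for w, _, _ in cfg.fl_components])
    comp = rng.choice(len(weights), size=n, p=weights)
    means = np.array([mu for _, mu, _ in cfg.fl_components])[comp]
    sds = np.array([sd for _, _, sd in cfg.fl_components])[comp]
    mixture = rng.normal(means, sds)
    a, b = cfg.size_coupling
    fl = (
        a * (log_fsc - cfg.fsc_log_mean)
        + b * (log_ssc - cfg.ssc_log_mean)
        + mixture
        + rng.normal(0.0, cfg.fl_noise_sd, n)
    )
    return pd.DataFrame(
        {
            "FSC-A": np.exp(log_fsc),
            "SSC-A": np.exp(log_ssc),
            "FSC-W": fsc_w,
            "DAPI": dapi,
            "FL": fl,
            "phase": np.array(["G1", "S", "G2", "unstained"])[phase],
            "doublet": False,
        }
    )


def simulate_sample_events(
    cfg: SimSampleConfig,
    n_events: int,
    seed: int,
    keep_truth: bool = False,
    meta: dict | None = None,
) -> EventTable:
    """Draw one acquisition sample.

    Doublets are sums of two singlet events on the raw scatter/DAPI scales
    with FSC-W inflated by ``cfg.doublet_width_factor``; their fluorescence is
    the log of the summed raw intensities. With ``keep_truth`` the table keeps
    the ``phase`` and ``doublet`` label columns (gating ignores extra columns).
    """
    cfg.validate()
    if n_events <= 0:
        raise ConfigurationError("n_events must be positive")
    rng = np.random.default_rng(seed)
    n_doublets = int(round(cfg.frac_doublets * n_events))
    n_singlets = n_events - n_doublets
    singlets = _draw_singlets(cfg, n_singlets, rng)
    parts = [singlets]
    if n_doublets > 0:
        pair = _draw_singlets(cfg, 2 * n_doublets, rng)
        a = pair.iloc[:n_doublets].reset_index(drop=True)
        b = pair.iloc[n_doublets:].reset_index(drop=True)
        doublets = pd.DataFrame(
            {
                "FSC-A": a["FSC-A"] + b["FSC-A"],
                "SSC-A": a["SSC-A"] + b["SSC-A"],
                "FSC-W": a["FSC-W"] * cfg.doublet_width_factor
                + rng.normal(0.0, cfg.fscw_sd, n_doublets),
                "DAPI": a["DAPI"] + b["DAPI"],
                "FL": np.log(np.exp(a["FL"]) + np.exp(b["FL"])),
                "phase": "doublet",
                "doublet": True,
            }
        )
        parts.append(doublets)
    data = pd.concat(parts, ignore_index=True)
    data = data.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)
    if not keep_truth:
        data = data[list(CHANNELS)]
    meta = meta or {}
    meta.setdefault("sample_id", "sim0")
    return EventTable(data=data, **meta)


def _hardy_weinberg_genotypes(
    n: int, maf: float, rng: np.random.Generator
) -> np.ndarray:
    return rng.binomial(2, maf, size=n).astype(np.int8)


def _line_parameters(cfg: SimCohortConfig, genotypes: np.ndarray) -> pd.DataFrame:
    base_sd = cfg.base_cv * cfg.base_mean
    g = genotypes.astype(float)
    mean = np.full(cfg.n_lines, cfg.base_mean)
    sd = np.full(cfg.n_lines, base_sd)
    p1 = np.full(cfg.n_lines, np.nan)
    if cfg.effect_mode == "dispersion":
        sd = base_sd * cfg.effect_size**g
    elif cfg.effect_mode == "mean":
        mean = cfg.base_mean + cfg.effect_size * g
    elif cfg.effect_mode == "bimodality":
        p1 = np.clip(cfg.bimodal_p1 + cfg.effect_size * g, 0.05, 0.95)
    return pd.DataFrame(
        {"line_id": [f"L{i:03d}" for i in range(cfg.n_lines)],
         "genotype": genotypes, "mean": mean, "sd": sd, "p1": p1}
    )


def _cohort_structure(
    cfg: SimCohortConfig, rng: np.random.Generator
) -> tuple[GenotypeMatrix, pd.DataFrame, int]:
    """Genotypes, per-line generating parameters and the causal SNP index."""
    n_snps = cfg.n_null_snps + 1
    causal_index = int(rng.integers(n_snps))
    positions = np.sort(
        rng.choice(
            np.arange(cfg.tss - 2_000_000, cfg.tss + 2_000_000, dtype=np.int64),
            size=n_snps,
            replace=False,
        )
    )
    codes = np.empty((cfg.n_lines, n_snps), dtype=np.int8)
    variants = []
    alleles = ("A", "C", "G", "T")
    for j in range(n_snps):
        if j == causal_index:
            maf = cfg.maf
        else:
            maf = rng.uniform(0.05, 0.5)
        codes[:, j] = _hardy_weinberg_genotypes(cfg.n_lines, maf, rng)
        ref, alt = rng.choice(4, size=2, replace=False)
        variants.append(
            VariantRecord(
                chrom=cfg.chrom,
                pos=int(positions[j]),
                id=f"snp{j:04d}",
                ref=alleles[ref],
                alt=alleles[alt],
            )
        )
    line_params = _line_parameters(cfg, codes[:, causal_index])
    genotypes = GenotypeMatrix(
        individuals=list(line_params["line_id"]), variants=variants, codes=codes
    )
    return genotypes, line_params, causal_index


def simulate_cohort(
    cfg: SimCohortConfig,
) -> tuple[GenotypeMatrix, list[EventTable], dict]:
    """Draw genotypes, per-line event tables and the generating truth.

    Genotypes follow Hardy-Weinberg proportions at the configured MAF; null
    SNPs are drawn independently (no LD) with MAFs uniform on [0.05, 0.5].
    Under ``effect_mode='dispersion'`` the per-line log-SD is scaled by
    ``effect_size**allele_count`` while the log mean is held constant.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genotypes, line_params, causal_index = _cohort_structure(cfg, rng)

    tables: list[EventTable] = []
    sample_rows = []
    for i, row in line_params.iterrows():
        for r in range(cfg.n_replicates):
            sd_rep = row["sd"] * np.exp(rng.normal(0.0, cfg.replicate_sd_noise))
            mean_rep = row["mean"] + rng.normal(0.0, cfg.replicate_mean_noise)
            if cfg.effect_mode == "bimodality":
                p1 = float(row["p1"])
                comps = (
                    (p1, mean_rep - cfg.bimodal_delta / 2, sd_rep),
                    (1 - p1, mean_rep + cfg.bimodal_delta / 2, sd_rep),
                )
            else:
                comps = ((1.0, mean_rep, sd_rep),)
            sample_cfg = replace(cfg.sample, fl_components=comps)
            sample_id = f"{row['line_id']}_r{r}"
            tables.append(
                simulate_sample_events(
                    sample_cfg,
                    cfg.n_events,
                    seed=int(rng.integers(2**31)),
                    meta={
                        "sample_id": sample_id,
                        "line_id": row["line_id"],
                        "protein": "SIM",
                        "replicate_index": r,
                        "batch_id": "batch0",
                    },
                )
            )
            sample_rows.append(
                {"sample_id": sample_id, "line_id": row["line_id"],
                 "replicate": r, "mean": mean_rep, "sd": sd_rep}
            )
    truth = {
        "causal_index": causal_index,
        "causal_id": genotypes.variants[causal_index].id,
        "genotypes": genotypes.codes[:, causal_index].copy(),
        "line_params": line_params,
        "sample_params": pd.DataFrame(sample_rows),
        "effect_mode": cfg.effect_mode,
        "effect_size": cfg.effect_size,
    }
    return genotypes, tables, truth


def simulate_line_traits(
    cfg: SimCohortConfig, n_cells: int | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Fast cohort draw at the trait level (no full event tables).

    Per replicate, ``n_cells`` (default ``cfg.n_events``) fluorescence values
    are drawn directly from the per-line generating distribution and
    summarised (mean, SD, CV); intended for mapping calibration and power
    studies where the gating layer is exercised separately. Returns the
    genotypes, a per-sample summary frame and the truth record.
    """
    cfg.validate()
    n_cells = n_cells or cfg.n_events
    rng = np.random.default_rng(cfg.seed)
    genotypes, line_params, causal_index = _cohort_structure(cfg, rng)
    rows = []
    for _, row in line_params.iterrows():
        for r in range(cfg.n_replicates):
            sd_rep = row["sd"] * np.exp(rng.normal(0.0, cfg.replicate_sd_noise))
            mean_rep = row["mean"] + rng.normal(0.0, cfg.replicate_mean_noise)
            if cfg.effect_mode == "bimodality":
                p1 = float(row["p1"])
                comp = rng.random(n_cells) < p1
                mu = np.where(
                    comp, mean_rep - cfg.bimodal_delta / 2, mean_rep + cfg.bimodal_delta / 2
                )
                fl = rng.normal(mu, sd_rep)
            else:
                fl = rng.normal(mean_rep, sd_rep, n_cells)
            mean = fl.mean()
            sd = fl.std(ddof=1)
            rows.append(
                {
                    "sample_id": f"{row['line_id']}_r{r}",
                    "line_id": row["line_id"],
                    "protein": "SIM",
                    "replicate_index": r,
                    "n_cells": n_cells,
                    "mean": mean,
                    "sd": sd,
                    "cv": sd / mean,
                    "outlier": False,
                }
            )
    truth = {
        "causal_index": causal_index,
        "causal_id": genotypes.variants[causal_index].id,
        "genotypes": genotypes.codes[:, causal_index].copy(),
        "line_params": line_params,
        "effect_mode": cfg.effect_mode,
        "effect_size": cfg.effect_size,
    }
    return genotypes, pd.DataFrame(rows), truth


_NOISE_KINDS = ("short_cdr3", "no_motif", "not_found", "no_frame", "no_top_d", "singleton")


def simulate_cdr3_reads(
    clone_freqs: Sequence[tuple[str, float]],
    n_reads: int,
    noise: float = 0.0,
    seed: int = 0,
    sample_id: str = "S1",
    replicate: str = "r1",
) -> pd.DataFrame:
    """Multinomial per-read CDR3 annotation table with planted clone frequencies.

    The noise mass (``max(noise, 1 - sum(freqs))``) is spread round-robin over
    read classes that each violate at least one downstream filter: CDR3
    shorter than 5 aa, missing [FW]-G-X-G J motif, CDR3 not found, missing
    VDJ frame, missing top D gene, and unique singleton clonotypes.
    """
    freqs = np.array([f for _, f in clone_freqs], dtype=float)
    if (freqs < 0).any():
        raise ConfigurationError("clone frequencies must be non-negative")
    if freqs.sum() > 1.0 + 1e-9:
        raise ConfigurationError("clone frequencies sum above 1")
    if not 0.0 <= noise <= 1.0:
        raise ConfigurationError("noise must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    noise_frac = max(noise, 1.0 - freqs.sum())
    scale = (1.0 - noise_frac) / freqs.sum() if freqs.sum() > 0 else 0.0
    probs = np.append(freqs * scale, noise_frac)
    counts = rng.multinomial(n_reads, probs)

    rows = []
    for (peptide, _), count in zip(clone_freqs, counts[:-1]):
        for _ in range(count):
            rows.append(
                {"cdr3_peptide": peptide, "cdr3_found": True,
                 "vdj_frame": "In-frame", "top_d_gene": "IGHD3-10",
                 "j_region_aa": VALID_J_REGION}
            )
    for k in range(counts[-1]):
        kind = _NOISE_KINDS[k % len(_NOISE_KINDS)]
        peptide = "".join(rng.choice(_AA, size=12))
        row = {"cdr3_peptide": peptide, "cdr3_found": True,
               "vdj_frame": "In-frame", "top_d_gene": "IGHD3-10",
               "j_region_aa": VALID_J_REGION}
        if kind == "short_cdr3":
            row["cdr3_peptide"] = "".join(rng.choice(_AA, size=3))
        elif kind == "no_motif":
            row["j_region_aa"] = MOTIFLESS_J_REGION
        elif kind == "not_found":
            row["cdr3_found"] = False
        elif kind == "no_frame":
            row["vdj_frame"] = "N/A"
        elif kind == "no_top_d":
            row["top_d_gene"] = "N/A"
        # 'singleton': a random 12-mer, vanishingly unlikely to recur
        rows.append(row)
    table = pd.DataFrame(rows)
    table.insert(0, "replicate", replicate)
    table.insert(0, "sample_id", sample_id)
    return table.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)


_GMM_CLASS_TEMPLATES = {
    # majority low-expressing cells with a right tail of high expressers
    "low_with_right_tail": dict(p1=0.85, mu1=3.0, mu2=5.0, sigma1=0.35, sigma2=0.9),
    # bulk of cells at high expression with a left tail of low expressers
    "high_with_left_tail": dict(p1=0.15, mu1=3.5, mu2=6.0, sigma1=0.9, sigma2=0.4),
    # two clearly separated co-existing modes
    "bimodal": dict(p1=0.45, mu1=3.2, mu2=6.2, sigma1=0.4, sigma2=0.4),
}


def simulate_cd23_gmm_table(
    sizes: tuple[int, int, int] = (3, 25, 22),
    n_replicates: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """SYNTHETIC stand-in for a per-replicate CD23 mixture-parameter table.

    The study's deposited per-replicate GMM parameter table is not shipped
    here; this generator emulates its structure: three classes of expression
    distributions (low with right tail / high with left tail / clearly
    bimodal) with planted class sizes, per-line jitter and replicate noise.
    Returns the long table (line_id, replicate, p1, mu1, mu2, sigma1, sigma2)
    and the planted class label per line.
    """
    rng = np.random.default_rng(seed)
    # line-to-line jitter within a class, small relative to the between-class
    # parameter differences (the classes are distinct distribution shapes)
    jitter = {"p1": 0.03, "mu1": 0.08, "mu2": 0.08, "sigma1": 0.04, "sigma2": 0.04}
    rows = []
    labels = []
    line = 0
    for cls, (name, tpl) in zip(sizes, _GMM_CLASS_TEMPLATES.items()):
        for _ in range(cls):
            line_id = f"LCL{line:03d}"
            line += 1
            labels.append(name)
            centre = {k: v + rng.normal(0.0, jitter[k]) for k, v in tpl.items()}
            for r in range(n_replicates):
                rows.append(
                    {
                        "line_id": line_id,
                        "replicate": r,
                        "p1": np.clip(centre["p1"] + rng.normal(0.0, 0.02), 0.01, 0.99),
                        "mu1": centre["mu1"] + rng.normal(0.0, 0.05),
                        "mu2": centre["mu2"] + rng.normal(0.0, 0.05),
                        "sigma1": abs(centre["sigma1"] + rng.normal(0.0, 0.02)),
                        "sigma2": abs(centre["sigma2"] + rng.normal(0.0, 0.02)),
                    }
                )
    return pd.DataFrame(rows), np.array(labels)


def write_events_csv(tables: Sequence[EventTable], outdir) -> pd.DataFrame:
    """Write one CSV per sample plus a ``manifest.tsv`` of sample metadata."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for table in tables:
        path = outdir / f"{table.sample_id}.csv"
        table.data.to_csv(path, index=False)
        manifest.append({**table.meta(), "path": path.name})
    frame = pd.DataFrame(manifest)
    frame.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return frame
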