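"""Generators for paired transcriptome/proteome developmental time courses.

The generator emulates the structure of a holometabolous insect life-cycle
survey: 17 timepoints spanning egg, larva, pupa and adult, five biological
replicates each, with

* four-stage archetypal expression programs (a stage-specific gene is
  elevated during its stage and low elsewhere),
* gene-wise transcript-protein coupling of varying strength ``rho``
  (the protein z-profile is a ``rho``-weighted mixture of the gene's
  transcript z-profile and an independent profile),
* maternal transcripts elevated only at the first egg timepoint,
* proteome missing-not-at-random below a detection limit,
* and a second pseudo-species sharing orthologs on a different timepoint
  grid for cross-species comparisons.

Transcript replicate counts are negative-binomial (3'-end tag counting
yields counts) and scaled to counts-per-million; protein log2 LFQ
intensities get additive Gaussian replicate noise. Every draw is governed
by a single seed, so identical configurations reproduce byte-identical
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from devodyn.omics_io import ExpressionMatrix, SampleSheet, Scale

#: Default 17-timepoint silkworm-style grid: 4 egg, 7 larval, 4 pupal, 2 adult.
DEFAULT_TIMEPOINTS: tuple[tuple[str, str], ...] = (
    ("Ewhite", "egg"), ("Ebrown", "egg"), ("Eblack", "egg"), ("Eblue", "egg"),
    ("L0", "larva"), ("L3", "larva"), ("L10", "larva"), ("L17", "larva"),
    ("L24", "larva"), ("L31", "larva"), ("Lc", "larva"),
    ("P0", "pupa"), ("P3", "pupa"), ("P8", "pupa"), ("P12", "pupa"),
    ("AF", "adult"), ("AM", "adult"),
)

#: Fly-like grid for the second pseudo-species: 2 egg, 4 larval, 5 pupal, 2 adult.
FLYLIKE_TIMEPOINTS: tuple[tuple[str, str], ...] = (
    ("e02", "egg"), ("e20", "egg"),
    ("l1", "larva"), ("l2", "larva"), ("l3", "larva"), ("lw", "larva"),
    ("p1", "pupa"), ("p2", "pupa"), ("p3", "pupa"), ("p4", "pupa"), ("p5", "pupa"),
    ("af", "adult"), ("am", "adult"),
)

DEFAULT_STAGE_FRACTIONS = {"egg": 0.15, "larva": 0.15, "pupa": 0.15, "adult": 0.15}


@dataclass
class SimConfig:
    """Configuration of a paired transcriptome/proteome simulation.

    Parameters
    ----------
    n_genes : number of simulated genes.
    timepoints : ordered (label, stage) pairs; default 17-timepoint grid.
    n_replicates : biological replicates per timepoint (>= 2).
    frac_stage_specific : per-stage fraction of stage-specific genes; the
        remainder are temporally stable. Fractions must sum to <= 1.
    archetype_amplitude : log2-scale elevation of a stage-specific gene
        during its stage (z-profile amplitude before standardization).
    coupling_rho : transcript-protein coupling in [-1, 1]; scalar or one
        value per gene.
    prot_noise_sd : Gaussian replicate noise on protein log2 intensities.
    tx_dispersion : negative-binomial size parameter of tag counts
        (variance = mu + mu^2 / size; larger = less overdispersed).
    detection_limit : log2 intensity below which proteome cells go missing
        with probability ``miss_prob_below`` (above: ``miss_prob_above``).
    maternal_frac : fraction of genes elevated (transcript only) at the
        first egg timepoint by ``maternal_boost`` log2 units.
    seed : base seed for all randomness.
    """

    n_genes: int = 2000
    timepoints: Sequence[tuple[str, str]] = DEFAULT_TIMEPOINTS
    n_replicates: int = 5
    frac_stage_specific: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_FRACTIONS))
    archetype_amplitude: float = 2.0
    coupling_rho: float | np.ndarray = 0.8
    prot_noise_sd: float = 0.5
    tx_dispersion: float = 10.0
    detection_limit: float = 22.5
    miss_prob_below: float = 0.9
    miss_prob_above: float = 0.02
    maternal_frac: float = 0.1
    maternal_boost: float = 2.0
    tx_baseline_mean: float = 3.0
    tx_baseline_sd: float = 1.5
    prot_baseline_mean: float = 26.0
    prot_baseline_sd: float = 2.0
    prot_profile_scale: float = 2.0
    reads_per_gene: float = 100.0
    species: str = "A"
    gene_prefix: str = "g"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.tx_dispersion <= 0 or self.prot_noise_sd <= 0:
            raise ValueError("dispersion and noise must be > 0")
        total = sum(self.frac_stage_specific.values())
        if total > 1 + 1e-12 or any(f < 0 for f in self.frac_stage_specific.values()):
            raise ValueError("stage fractions must be nonnegative and sum to <= 1")
        stages = {s for _, s in self.timepoints}
        bad = set(self.frac_stage_specific) - stages
        if bad:
            raise ValueError(f"stage fractions for stages absent from grid: {bad}")

    @property
    def tp_labels(self) -> list[str]:
        return [t for t, _ in self.timepoints]

    @property
    def tp_stages(self) -> list[str]:
        return [s for _, s in self.timepoints]


def _draw_labels(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    stages = list(cfg.frac_stage_specific)
    probs = [cfg.frac_stage_specific[s] for s in stages]
    probs.append(max(0.0, 1.0 - sum(probs)))
    choices = np.array(stages + ["stable"], dtype=object)
    idx = rng.choice(len(choices), size=cfg.n_genes, p=np.array(probs) / sum(probs))
    return choices[idx]


def _latent_tx(cfg: SimConfig, labels: np.ndarray, maternal: np.ndarray,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Latent log2 transcript profile (genes x timepoints) and its z-profile.

    The z-profile excludes the maternal bump: maternal deposition is a
    transcript-only feature and is not propagated to the protein layer.
    """
    stages = np.array(cfg.tp_stages, dtype=object)
    base = rng.normal(cfg.tx_baseline_mean, cfg.tx_baseline_sd, size=cfg.n_genes)
    prof = np.tile(base[:, None], (1, len(stages)))
    for s in set(labels) - {"stable"}:
        in_stage = stages == s
        prof[labels == s] += cfg.archetype_amplitude * in_stage[None, :]
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (prof - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    prof = prof.copy()
    prof[maternal, 0] += cfg.maternal_boost
    return prof, z


def _coupling(cfg: SimConfig) -> np.ndarray:
    rho = np.asarray(cfg.coupling_rho, dtype=float)
    if rho.ndim == 0:
        rho = np.full(cfg.n_genes, float(rho))
    if rho.shape != (cfg.n_genes,):
        raise ValueError("coupling_rho must be scalar or one value per gene")
    if np.abs(rho).max() > 1:
        raise ValueError("coupling_rho must lie in [-1, 1]")
    return rho


def _build_sheet(cfg: SimConfig) -> SampleSheet:
    rows = []
    for tp, stage in cfg.timepoints:
        for rep in range(1, cfg.n_replicates + 1):
            rows.append({"sample_id": f"{tp}_r{rep}", "timepoint": tp,
                         "stage": stage, "replicate": rep, "species": cfg.species})
    return SampleSheet(pd.DataFrame(rows))


def simulate_paired(cfg: SimConfig):
    """Simulate a paired transcriptome (CPM) / proteome (log2 LFQ) time course.

    Returns
    -------
    tx : ExpressionMatrix
        CPM transcript matrix, fully observed.
    prot : ExpressionMatrix
        log2 LFQ protein matrix with intensity-dependent missingness.
    sheet : SampleSheet
    truth : pandas.DataFrame
        Per-gene ground truth: ``label`` (stage or "stable"), ``maternal``,
        ``coupling_rho``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"{cfg.gene_prefix}{i:05d}" for i in range(cfg.n_genes)]
    labels = _draw_labels(cfg, rng)
    maternal = rng.random(cfg.n_genes) < cfg.maternal_frac
    rho = _coupling(cfg)

    tx_latent, tx_z = _latent_tx(cfg, labels, maternal, rng)

    # protein z-profile: rho-weighted mixture with an independent profile
    indep = rng.standard_normal(tx_z.shape)
    prot_z = rho[:, None] * tx_z + np.sqrt(1.0 - rho[:, None] ** 2) * indep
    prot_base = rng.normal(cfg.prot_baseline_mean, cfg.prot_baseline_sd, cfg.n_genes)
    prot_latent = prot_base[:, None] + cfg.prot_profile_scale * prot_z

    sheet = _build_sheet(cfg)
    n_tp = len(cfg.timepoints)
    sample_ids = list(sheet.sample_ids)

    # transcript counts -> CPM
    rel = np.power(2.0, tx_latent)
    total_reads = cfg.reads_per_gene * cfg.n_genes
    cpm = np.empty((cfg.n_genes, n_tp * cfg.n_replicates))
    col = 0
    for t in range(n_tp):
        mean_ct = rel[:, t] / rel[:, t].sum() * total_reads
        p = cfg.tx_dispersion / (cfg.tx_dispersion + mean_ct)
        for _ in range(cfg.n_replicates):
            counts = rng.negative_binomial(cfg.tx_dispersion, p)
            tot = counts.sum()
            cpm[:, col] = counts / tot * 1e6 if tot > 0 else 0.0
            col += 1
    tx = ExpressionMatrix(pd.DataFrame(cpm, index=genes, columns=sample_ids), Scale.cpm)

    # protein replicate intensities with MNAR missingness
    prot_vals = np.repeat(prot_latent, cfg.n_replicates, axis=1)
    prot_vals = prot_vals + rng.normal(0.0, cfg.prot_noise_sd, prot_vals.shape)
    below = prot_vals < cfg.detection_limit
    u = rng.random(prot_vals.shape)
    miss = np.where(below, u < cfg.miss_prob_below, u < cfg.miss_prob_above)
    vals = pd.DataFrame(np.where(miss, np.nan, prot_vals), index=genes, columns=sample_ids)
    prot = ExpressionMatrix(vals, Scale.lfq_log2,
                            pd.DataFrame(miss, index=genes, columns=sample_ids))

    truth = pd.DataFrame({"gene_id": genes, "label": labels,
                          "maternal": maternal, "coupling_rho": rho}).set_index("gene_id")
    return tx, prot, sheet, truth


def simulate_two_species(cfg_a: SimConfig, cfg_b: SimConfig, n_orthologs: int,
                         frac_conserved: float):
    """Simulate two species sharing one-to-one orthologs on different grids.

    Conserved orthologs share the stage label of their species-A partner
    (hence the same archetypal pattern, resampled on species B's grid);
    divergent orthologs get an independently drawn label.

    Returns ``(data_a, data_b, ortholog_map, truth)`` where each ``data_*``
    is the 4-tuple of :func:`simulate_paired`, the map is a 2-column
    DataFrame, and ``truth`` adds a per-ortholog ``conserved`` flag.
    """
    if not 0.0 <= frac_conserved <= 1.0:
        raise ValueError("frac_conserved must lie in [0, 1]")
    if n_orthologs > min(cfg_a.n_genes, cfg_b.n_genes):
        raise ValueError("n_orthologs exceeds a species' gene count")
    if cfg_a.gene_prefix == cfg_b.gene_prefix:
        cfg_b = replace(cfg_b, gene_prefix=cfg_a.gene_prefix + "b_")
    data_a = simulate_paired(cfg_a)
    truth_a = data_a[3]

    rng = np.random.default_rng(cfg_b.seed + 1)
    conserved = rng.random(n_orthologs) < frac_conserved

    # build species B with labels forced on the ortholog block
    b_labels = _draw_labels(cfg_b, np.random.default_rng(cfg_b.seed + 2))
    stages_b = {s for _, s in cfg_b.timepoints}
    a_labels = truth_a["label"].to_numpy(dtype=object)[:n_orthologs]
    force = conserved & np.isin(a_labels, list(stages_b) + ["stable"])
    b_labels[:n_orthologs][force] = a_labels[force]

    data_b = _simulate_with_labels(cfg_b, b_labels)
    map_df = pd.DataFrame({
        "gene_a": truth_a.index[:n_orthologs],
        "gene_b": data_b[3].index[:n_orthologs],
    })
    truth = map_df.assign(conserved=conserved,
                          label_a=a_labels, label_b=b_labels[:n_orthologs])
    return data_a, data_b, map_df, truth


def _simulate_with_labels(cfg: SimConfig, labels: np.ndarray):
    """simulate_paired with externally fixed per-gene stage labels."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"{cfg.gene_prefix}{i:05d}" for i in range(cfg.n_genes)]
    _ = _draw_labels(cfg, rng)  # keep downstream draws aligned with simulate_paired
    maternal = rng.random(cfg.n_genes) < cfg.maternal_frac
    rho = _coupling(cfg)
    tx_latent, tx_z = _latent_tx(cfg, labels, maternal, rng)
    indep = rng.standard_normal(tx_z.shape)
    prot_z = rho[:, None] * tx_z + np.sqrt(1.0 - rho[:, None] ** 2) * indep
    prot_base = rng.normal(cfg.prot_baseline_mean, cfg.prot_baseline_sd, cfg.n_genes)
    prot_latent = prot_base[:, None] + cfg.prot_profile_scale * prot_z

    sheet = _build_sheet(cfg)
    n_tp = len(cfg.timepoints)
    sample_ids = list(sheet.sample_ids)
    rel = np.power(2.0, tx_latent)
    total_reads = cfg.reads_per_gene * cfg.n_genes
    cpm = np.empty((cfg.n_genes, n_tp * cfg.n_replicates))
    col = 0
    for t in range(n_tp):
        mean_ct = rel[:, t] / rel[:, t].sum() * total_reads
        p = cfg.tx_dispersion / (cfg.tx_dispersion + mean_ct)
        for _ in range(cfg.n_replicates):
            counts = rng.negative_binomial(cfg.tx_dispersion, p)
            tot = counts.sum()
            cpm[:, col] = counts / tot * 1e6 if tot > 0 else 0.0
            col += 1
    tx = ExpressionMatrix(pd.DataFrame(cpm, index=genes, columns=sample_ids), Scale.cpm)
    prot_vals = np.repeat(prot_latent, cfg.n_replicates, axis=1)
    prot_vals = prot_vals + rng.normal(0.0, cfg.prot_noise_sd, prot_vals.shape)
    below = prot_vals < cfg.detection_limit
    u = rng.random(prot_vals.shape)
    miss = np.where(below, u < cfg.miss_prob_below, u < cfg.miss_prob_above)
    vals = pd.DataFrame(np.where(miss, np.nan, prot_vals), index=genes, columns=sample_ids)
    prot = ExpressionMatrix(vals, Scale.lfq_log2,
                            pd.DataFrame(miss, index=genes, columns=sample_ids))
    truth = pd.DataFrame({"gene_id": genes, "label": labels,
                          "maternal": maternal, "coupling_rho": rho}).set_index("gene_id")
    return tx, prot, sheet, truth
def _simulate_core(cfg: SimConfig, labels_override=None):
    rng = np.random.default_rng(cfg.seed)
    genes = [f"{cfg.gene_prefix}{i:05d}" for i in range(cfg.n_genes)]
    labels = _draw_labels(cfg, rng)
    if labels_override is not None:
        labels = np.asarray(labels_override, dtype=object)
    maternal = rng.random(cfg.n_genes) < cfg.maternal_frac
    rho = _coupling(cfg)

    tx_latent, tx_z = _latent_tx(cfg, labels, maternal, rng)

    # protein z-profile: rho-weighted mixture with an independent profile
    indep = rng.standard_normal(tx_z.shape)
    prot_z = rho[:, None] * tx_z + np.sqrt(1.0 - rho[:, None] ** 2) * indep
    prot_base = rng.normal(cfg.prot_baseline_mean, cfg.prot_baseline_sd, cfg.n_genes)
    prot_latent = prot_base[:, None] + cfg.prot_profile_scale * prot_z

    sheet = _build_sheet(cfg)
    n_tp = len(cfg.timepoints)
    sample_ids = list(sheet.sample_ids)

    # transcript tag counts -> CPM (columns renormalized to 1e6)
    rel = np.power(2.0, tx_latent)
    total_reads = cfg.reads_per_gene * cfg.n_genes
    cpm = np.empty((cfg.n_genes, n_tp * cfg.n_replicates))
    col = 0
    for t in range(n_tp):
        mean_ct = rel[:, t] / rel[:, t].sum() * total_reads
        p = cfg.tx_dispersion / (cfg.tx_dispersion + mean_ct)
        for _ in range(cfg.n_replicates):
            counts = rng.negative_binomial(cfg.tx_dispersion, p)
            tot = counts.sum()
            cpm[:, col] = counts / tot * 1e6 if tot > 0 else 0.0
            col += 1
    tx = ExpressionMatrix(pd.DataFrame(cpm, index=genes, columns=sample_ids), Scale.cpm)

    # protein replicate intensities with MNAR missingness below the limit
    prot_vals = np.repeat(prot_latent, cfg.n_replicates, axis=1)
    prot_vals = prot_vals + rng.normal(0.0, cfg.prot_noise_sd, prot_vals.shape)
    below = prot_vals < cfg.detection_limit
    u = rng.random(prot_vals.shape)
    miss = np.where(below, u < cfg.miss_prob_below, u < cfg.miss_prob_above)
    vals = pd.DataFrame(np.where(miss, np.nan, prot_vals), index=genes, columns=sample_ids)
    prot = ExpressionMatrix(vals, Scale.lfq_log2,
                            pd.DataFrame(miss, index=genes, columns=sample_ids))

    truth = pd.DataFrame({"gene_id": genes, "label": labels,
                          "maternal": maternal, "coupling_rho": rho}).set_index("gene_id")
    return tx, prot, sheet, truth


def simulate_paired(cfg: SimConfig):
    """Simulate a paired transcriptome (CPM) / proteome (log2 LFQ) time course.

    Returns
    -------
    tx : ExpressionMatrix
        CPM transcript matrix, fully observed.
    prot : ExpressionMatrix
        log2 LFQ protein matrix with intensity-dependent missingness.
    sheet : SampleSheet
    truth : pandas.DataFrame
        Per-gene ground truth: ``label`` (stage or "stable"), ``maternal``,
        ``coupling_rho``.
    """
    return _simulate_core(cfg)


def simulate_two_species(cfg_a: SimConfig, cfg_b: SimConfig, n_orthologs: int,
                         frac_conserved: float):
    """Simulate two species sharing one-to-one orthologs on different grids.

    Conserved orthologs share the stage label of their species-A partner
    (hence the same archetypal pattern, resampled on species B's grid);
    divergent orthologs get an independently drawn label.

    Returns ``(data_a, data_b, ortholog_map, truth)`` where each ``data_*``
    is the 4-tuple of :func:`simulate_paired`, the map is a 2-column
    DataFrame, and ``truth`` adds a per-ortholog ``conserved`` flag.
    """
    if not 0.0 <= frac_conserved <= 1.0:
        raise ValueError("frac_conserved must lie in [0, 1]")
    if n_orthologs > min(cfg_a.n_genes, cfg_b.n_genes):
        raise ValueError("n_orthologs exceeds a species' gene count")
    if cfg_a.gene_prefix == cfg_b.gene_prefix:
        cfg_b = replace(cfg_b, gene_prefix=cfg_a.gene_prefix + "b_")
    data_a = _simulate_core(cfg_a)
    truth_a = data_a[3]

    rng = np.random.default_rng(cfg_b.seed + 1)
    conserved = rng.random(n_orthologs) < frac_conserved

    # force conserved labels on species B's ortholog block
    b_labels = _draw_labels(cfg_b, np.random.default_rng(cfg_b.seed + 2))
    stages_b = {s for _, s in cfg_b.timepoints}
    a_labels = truth_a["label"].to_numpy(dtype=object)[:n_orthologs]
    force = conserved & np.isin(a_labels, list(stages_b) + ["stable"])
    b_labels[:n_orthologs][force] = a_labels[force]

    data_b = _simulate_core(cfg_b, labels_override=b_labels)
    map_df = pd.DataFrame({
        "gene_a": truth_a.index[:n_orthologs],
        "gene_b": data_b[3].index[:n_orthologs],
    })
    truth = map_df.assign(conserved=conserved,
                          label_a=a_labels, label_b=b_labels[:n_orthologs])
    return data_a, data_b, map_df, truth
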