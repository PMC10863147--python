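"""Synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate the statistical structure the pipeline assumes —
negative-binomial bulk counts with a latent driver activity coupling a
planted gene program to the driver, zero-inflated single-cell counts in
which the driver's zeros follow a latent-linked dropout mask,
proportional-hazards survival times tied to a feature threshold,
multi-set TMT intensities with a pooled GIS channel, and triplicate Cq
tables with three reference genes.  Each generator is a pure function of
its parameters and seed and returns the planted truth alongside the
data, so recovery metrics (panel sensitivity, cutoff error, DE power)
can be computed without inspecting generator internals.

Counts use the mean/dispersion NB parameterization var = mu + alpha mu^2,
sampled as a gamma-Poisson mixture.  The program-gene coupling slope is
calibrated so that the expected log2 contrast between the driver's upper
and lower quartile groups equals the requested ``lfc``: for a standard
normal latent the top-minus-bottom quartile mean gap is
2*phi(z_0.75)/0.25 ≈ 2.5426, so slope = lfc / (2.5426 * rho).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import ExpressionMatrix, validate_metadata
from .proteomics import QC_FLAGS, TMTExperiment, TMTSet

#: E[z | top quartile] - E[z | bottom quartile] for z ~ N(0,1)
_QUARTILE_GAP = 2.0 * scipy.stats.norm.pdf(scipy.stats.norm.ppf(0.75)) / 0.25


@dataclass
class GroundTruth:
    driver_gene: str
    program_genes: list[str] = field(default_factory=list)
    true_lfc: dict = field(default_factory=dict)
    true_rho: dict = field(default_factory=dict)
    latent: np.ndarray | None = None
    true_cutoff: float | None = None
    hazard_ratio: float | None = None
    planted: list[str] = field(default_factory=list)
    seed: int | None = None


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_bulk(
    n_samples: int = 124,
    n_genes: int = 1000,
    program_size: int = 30,
    rho: float = 0.6,
    lfc: float = 1.0,
    dispersion: float = 0.1,
    base_mean: float = 50.0,
    driver_slope: float = 1.0,
    libsize_sigma: float = 0.2,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Bulk NB counts with a driver-coupled gene program.

    A standard-normal latent activity per sample drives the log2 mean of
    the driver gene (slope ``driver_slope``) and, attenuated through a
    per-gene latent with correlation ``rho``, of each program gene.  The
    slope of program genes is set so the expected quartile-contrast log2
    fold change equals ``lfc``.  Background genes are independent NB;
    library sizes are log-normal.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if program_size >= n_genes:
        raise ValueError("program_size must be smaller than n_genes")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_samples)
    genes = ["DRIVER"] + [f"PROG{i:04d}" for i in range(program_size)] + [
        f"BG{i:05d}" for i in range(n_genes - program_size - 1)
    ]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    lib = np.exp(rng.normal(0.0, libsize_sigma, n_samples))

    log2mu = np.tile(np.log2(base_mean), (n_genes, n_samples))
    log2mu[0] += driver_slope * z
    slope = lfc / (_QUARTILE_GAP * rho) if rho > 0 else 0.0
    true_rho, true_lfc = {}, {}
    for i in range(program_size):
        eps = rng.standard_normal(n_samples)
        latent_g = rho * z + np.sqrt(1 - rho**2) * eps
        log2mu[1 + i] += slope * latent_g
        true_rho[genes[1 + i]] = rho
        true_lfc[genes[1 + i]] = lfc
    mu = (2.0**log2mu) * lib[None, :]
    counts = _nb_sample(rng, mu, dispersion)

    matrix = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples), layer="counts")
    meta = validate_metadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "idh_status": "wildtype",
                "subtype": rng.choice(["classical", "mesenchymal", "proneural"], n_samples),
                "sample_type": "primary",
            }
        )
    )
    truth = GroundTruth(
        driver_gene="DRIVER",
        program_genes=genes[1 : 1 + program_size],
        true_lfc=true_lfc,
        true_rho=true_rho,
        latent=z,
        seed=seed,
    )
    return matrix, meta, truth


def simulate_sc(
    n_cells: int = 500,
    n_genes: int = 1000,
    dropout: float = 0.4,
    program_size: int = 30,
    rho: float = 0.6,
    lfc: float = 1.0,
    dispersion: float = 0.5,
    base_mean: float = 2.0,
    driver_mean: float = 20.0,
    bg_dropout: float = 0.3,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Zero-inflated single-cell counts with latent-linked driver dropout.

    The driver's zeros come exclusively from a Bernoulli dropout mask with
    per-cell probability ``2 * dropout * (1 - Phi(z))`` — expectation
    ``dropout``, decreasing in the latent activity — so positive/negative
    binarization splits cells by activity and the program genes (coupled
    to the same latent) differ between the groups.  Away from the driver,
    independent per-entry dropout at rate ``bg_dropout`` is applied.
    """
    if not 0 <= dropout <= 0.5:
        raise ValueError("dropout must lie in [0, 0.5] (mask probability cap)")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_cells)
    genes = ["DRIVER"] + [f"PROG{i:04d}" for i in range(program_size)] + [
        f"BG{i:05d}" for i in range(n_genes - program_size - 1)
    ]
    cells = [f"C{i:05d}" for i in range(n_cells)]

    log2mu = np.tile(np.log2(base_mean), (n_genes, n_cells))
    # the sc stratification primitive is +/- binarization, so `lfc` is the
    # expected log2 contrast between driver-positive and -negative cells;
    # under the dropout model p(z) = 2*dropout*(1 - Phi(z)) the latent gap
    # E[z|pos] - E[z|neg] is 1 / (sqrt(pi) * (1 - dropout))
    latent_gap = 1.0 / (np.sqrt(np.pi) * max(1.0 - dropout, 1e-6))
    slope = lfc / (latent_gap * rho) if rho > 0 else 0.0
    for i in range(program_size):
        eps = rng.standard_normal(n_cells)
        latent_g = rho * z + np.sqrt(1 - rho**2) * eps
        log2mu[1 + i] += slope * latent_g
    mu = 2.0**log2mu
    counts = _nb_sample(rng, mu, dispersion).astype(float)

    # driver: strictly positive shifted-NB counts, zeroed only by the mask
    driver_counts = 1 + _nb_sample(rng, np.full(n_cells, driver_mean - 1.0), dispersion)
    p_drop = np.clip(2.0 * dropout * (1.0 - scipy.stats.norm.cdf(z)), 0.0, 1.0)
    mask = rng.random(n_cells) < p_drop
    driver_counts = np.where(mask, 0, driver_counts)
    counts[0] = driver_counts
    if bg_dropout > 0:
        drop_bg = rng.random((n_genes - 1, n_cells)) < bg_dropout
        counts[1:] = np.where(drop_bg, 0.0, counts[1:])

    matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(int), index=genes, columns=cells), layer="counts"
    )
    meta = validate_metadata(
        pd.DataFrame({"sample_id": cells, "malignant": True, "sample_type": "primary"})
    )
    truth = GroundTruth(
        driver_gene="DRIVER",
        program_genes=genes[1 : 1 + program_size],
        true_lfc={g: lfc for g in genes[1 : 1 + program_size]},
        true_rho={g: rho for g in genes[1 : 1 + program_size]},
        latent=z,
        seed=seed,
    )
    return matrix, meta, truth


def simulate_survival(
    values,
    cutoff_quantile: float = 0.6,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.2,
    baseline_hazard: float = 1.0 / 500.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Exponential survival with a hazard step above a value threshold.

    Event times are exponential with hazard ``baseline_hazard`` below the
    ``cutoff_quantile`` threshold of ``values`` and ``hazard_ratio`` times
    that above it; censoring is an independent exponential at rate
    ``censor_rate * baseline_hazard`` (0 → no censoring, all events).
    """
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    cutoff = float(np.quantile(values, cutoff_quantile))
    hazard = np.where(values > cutoff, baseline_hazard * hazard_ratio, baseline_hazard)
    event_times = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_times = rng.exponential(1.0 / (censor_rate * baseline_hazard), len(values))
        os_time = np.minimum(event_times, censor_times)
        os_event = (event_times <= censor_times).astype(int)
    else:
        os_time, os_event = event_times, np.ones(len(values), dtype=int)
    truth = GroundTruth(
        driver_gene="", true_cutoff=cutoff, hazard_ratio=hazard_ratio, seed=seed
    )
    return os_time, os_event, truth


def simulate_tmt(
    n_sets: int = 12,
    n_proteins: int = 300,
    n_channels: int = 6,
    n_normals: int = 4,
    gis_spread: float = 0.05,
    planted_deps: int = 20,
    effect: float = 1.0,
    noise_sigma: float = 0.25,
    flag_rate: float = 0.05,
    driver_protein: str = "PRP",
    seed: int | None = None,
) -> tuple[TMTExperiment, GroundTruth]:
    """Multi-set TMT intensities with a GIS channel and planted DEPs.

    The default layout mirrors a 12-set, 6-channel experiment: each set
    carries one GIS channel, the first ``n_normals`` sets additionally
    carry one normal-tissue channel, and the rest are tumor samples.
    Per-sample latent levels drive a designated driver protein and, at
    half strength, the planted DEP proteins, so stratifying on the driver
    recovers them.  The GIS channel is the mean of the set's sample
    channels perturbed by log-normal noise of scale ``gis_spread``; QC
    flags are sprinkled independently at ``flag_rate`` per flag type.
    """
    rng = np.random.default_rng(seed)
    proteins = [driver_protein] + [f"P{i:05d}" for i in range(n_proteins - 1)]
    dep_ids = proteins[1 : 1 + planted_deps]
    baseline = rng.normal(20.0, 1.5, n_proteins)  # log2 intensity baselines

    sets = []
    for s in range(n_sets):
        channels = [f"ch{c}" for c in range(n_channels)]
        has_normal = s < n_normals
        n_samples_set = n_channels - 1 - int(has_normal)
        u = rng.standard_normal(n_channels - 1)  # per-channel latent driver level
        log2 = np.tile(baseline[:, None], (1, n_channels - 1))
        log2[0] += u
        for i in range(1, 1 + planted_deps):
            log2[i] += 0.5 * effect * u
        log2 += rng.normal(0.0, noise_sigma, log2.shape)
        intens = 2.0**log2
        gis = intens.mean(axis=1) * np.exp(rng.normal(0.0, gis_spread, n_proteins))
        mat = pd.DataFrame(
            np.column_stack([intens, gis]), index=proteins, columns=channels
        )
        roles: dict[str, str] = {c: "sample" for c in channels[:n_samples_set]}
        if has_normal:
            roles[channels[n_samples_set]] = "normal"
        roles[channels[-1]] = "gis"
        sets.append(TMTSet(f"set{s + 1}", mat, roles))

    flags = pd.DataFrame(
        rng.random((n_proteins, len(QC_FLAGS))) < flag_rate,
        index=proteins,
        columns=list(QC_FLAGS),
    )
    flags.loc[driver_protein] = False  # the driver must survive QC
    exp = TMTExperiment(sets, flags)
    truth = GroundTruth(driver_gene=driver_protein, planted=dep_ids, seed=seed)
    return exp, truth


def simulate_qpcr(
    n_samples: int = 103,
    genes: tuple[str, ...] = ("PRNP",),
    refs: tuple[str, ...] = ("TBP", "HPRT", "GUSB"),
    effect: float = 0.0,
    ref_mean: float = 25.0,
    ref_sd: float = 0.5,
    noise_sd: float = 0.3,
    replicate_jitter: float = 0.1,
    n_replicates: int = 2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Cq tables with multi-reference normalization structure.

    Each sample carries a latent log2 expression level per target gene
    (N(0,1), shifted by ``effect`` for the top half of samples); target Cq
    = per-sample reference baseline − level + noise, so higher expression
    means lower Cq.  Replicates jitter around the measured value.
    Returns a long-format table (sample_id, gene, cq, is_reference) and
    the planted per-sample levels.
    """
    rng = np.random.default_rng(seed)
    samples = [f"Q{i:04d}" for i in range(n_samples)]
    high_half = np.arange(n_samples) >= n_samples // 2
    rows = []
    levels: dict[str, np.ndarray] = {}
    ref_cq = {r: rng.normal(ref_mean, ref_sd, n_samples) for r in refs}
    baseline = np.exp(np.mean([np.log(ref_cq[r]) for r in refs], axis=0))
    for g in genes:
        lvl = rng.standard_normal(n_samples) + effect * high_half
        levels[g] = lvl
        cq_g = baseline - lvl + rng.normal(0.0, noise_sd, n_samples)
        for j, sid in enumerate(samples):
            for _ in range(n_replicates):
                rows.append(
                    {
                        "sample_id": sid,
                        "gene": g,
                        "cq": cq_g[j] + rng.normal(0.0, replicate_jitter),
                        "is_reference": False,
                    }
                )
    for r in refs:
        for j, sid in enumerate(samples):
            for _ in range(n_replicates):
                rows.append(
                    {
                        "sample_id": sid,
                        "gene": r,
                        "cq": ref_cq[r][j] + rng.normal(0.0, replicate_jitter),
                        "is_reference": True,
                    }
                )
    table = pd.DataFrame(rows)
    truth = GroundTruth(driver_gene=genes[0], seed=seed)
    truth.true_lfc = {g: effect for g in genes}
    truth.latent = levels[genes[0]]
    truth.planted = list(np.array(samples)[high_half])
    return table, truth
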