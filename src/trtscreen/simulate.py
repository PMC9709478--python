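"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a bulk RNA-seq read-through study:

* a genome of non-overlapping genes with a mix of same-strand, convergent
  and divergent neighbours, so both cis and trans candidate pairs arise;
* strand-specific fragment coverage over gene bodies, with low Poisson
  background in intergenic gaps;
* planted read-through events in patients only: extra upstream-strand
  fragments over the intergenic gap (calibrated to a target intergenic
  fold change) and extra downstream-gene fragments (calibrated to a target
  downstream fold change), both scaled by a shared per-(pair, patient)
  lognormal jitter so the two fold changes are correlated across patients;
* a co-regulated "NETosis" gene block up-regulated in a patient subset;
* clinical traits statistically coupled to read-through burden and block
  activity via a Gaussian copula.

All multiplicative noises are mean-one lognormals, so configured fold
changes are hit in expectation.  A fixed seed fully determines every
output, including written fixture files.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    GeneModel,
    GenePair,
    enumerate_adjacent_pairs,
    pairs_to_frame,
    write_pairs_tsv,
)
from .quantify import ExpressionMatrix, FragmentSet, quantify_features

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_genome",
    "simulate_fragments",
    "simulate_clinical",
    "simulate_cohort",
    "simulate_burden",
    "write_fixture_bundle",
    "PRESETS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    # genome geometry
    n_chromosomes: int = 5
    genes_per_chromosome: int = 100
    gene_length_log_mean: float = math.log(2000.0)
    gene_length_log_sd: float = 0.35
    intergenic_length_log_mean: float = math.log(2000.0)
    intergenic_length_log_sd: float = 0.5
    lnc_fraction: float = 0.06
    # cohort
    n_patients: int = 40
    n_controls: int = 20
    death_frac: float = 15 / 56
    # expression / sequencing
    library_size: int = 40_000
    baseline_fpkm_log_mean: float = 5.0
    baseline_fpkm_log_sd: float = 1.0
    bio_noise_sd: float = 0.25
    intergenic_bg_fpkm_log_mean: float = math.log(25.0)
    intergenic_bg_fpkm_log_sd: float = 0.4
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 60.0
    # planted read-through
    n_trt_pairs_planted: int = 50
    readthrough_intensity: float = 10.0  # target intergenic fold change
    downstream_coupling: float = 3.0  # target downstream fold change
    coupling_jitter_sd: float = 0.25  # shared per-(pair, patient) lognormal sd
    coupling_noise_sd: float = 0.12  # independent per-channel lognormal sd
    trt_activation_prob: float = 0.45  # per planted pair per patient
    burden_spread_sd: float = 0.3  # patient-level spread of activation prob
    prognosis_effect: float = 2.0  # multiplicative activation shift, death group
    upstream_expression_quantile: float = 0.7  # planted pairs need active upstream
    # NETosis block
    netosis_block_genes: int = 30
    netosis_extra_genes: int = 20
    netosis_active_frac: float = 0.5
    netosis_log2_effect: float = 1.5
    # planted lncRNA co-expression
    n_coexpressed_lnc: int = 3
    coexpression_noise_sd: float = 0.05
    # clinical trait couplings (Spearman-scale targets)
    neut_burden_spearman: float = 0.4
    paco2_activity_spearman: float = 0.35
    pao2fio2_activity_spearman: float = -0.4
    virus_prob_active: float = 0.65
    virus_prob_inactive: float = 0.30
    aki_prob_active: float = 0.45
    aki_prob_inactive: float = 0.20

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "genes_per_chromosome", "n_patients", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("death_frac", "netosis_active_frac", "lnc_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 < self.trt_activation_prob < 1:
            raise ValueError("trt_activation_prob must be in (0, 1)")
        if self.readthrough_intensity < 0 or self.downstream_coupling < 0:
            raise ValueError("fold-change targets must be non-negative")


PRESETS: dict[str, dict] = {
    "tiny": dict(
        n_chromosomes=2,
        genes_per_chromosome=10,
        n_patients=4,
        n_controls=2,
        library_size=6000,
        n_trt_pairs_planted=4,
        netosis_block_genes=4,
        netosis_extra_genes=3,
        n_coexpressed_lnc=1,
        lnc_fraction=0.1,
    ),
    "default": {},
    "large": dict(
        n_chromosomes=8,
        genes_per_chromosome=150,
        n_patients=56,
        n_controls=24,
        n_trt_pairs_planted=80,
    ),
}


def config_from_preset(preset: str = "default", **overrides) -> SimulationConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def _mean_one_lognormal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    if sd == 0:
        return np.ones(size)
    return rng.lognormal(-0.5 * sd * sd, sd, size)


# ---------------------------------------------------------------------------
# Genome


def simulate_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[GeneModel], list[GenePair]]:
    """Non-overlapping genes laid out left to right with lognormal lengths
    and gaps, random strands, and a lncRNA biotype fraction."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes: list[GeneModel] = []
    n_total = config.n_chromosomes * config.genes_per_chromosome
    lengths = np.maximum(
        200,
        rng.lognormal(
            config.gene_length_log_mean, config.gene_length_log_sd, n_total
        ).astype(np.int64),
    )
    gaps = np.maximum(
        100,
        rng.lognormal(
            config.intergenic_length_log_mean, config.intergenic_length_log_sd, n_total
        ).astype(np.int64),
    )
    strands = rng.choice(["+", "-"], n_total)
    is_lnc = rng.random(n_total) < config.lnc_fraction
    idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        pos = 1000
        for _ in range(config.genes_per_chromosome):
            start, end = pos, pos + int(lengths[idx])
            biotype = "lncRNA" if is_lnc[idx] else "protein_coding"
            genes.append(
                GeneModel(f"g{idx + 1:04d}", chrom, start, end, strands[idx], biotype)
            )
            pos = end + int(gaps[idx])
            idx += 1
    pairs = enumerate_adjacent_pairs(genes)
    return genes, pairs


# ---------------------------------------------------------------------------
# Cohort structure


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    planted: pd.DataFrame  # pair_id, pair_class, upstream_gene, downstream_gene
    active: pd.DataFrame  # planted pair_id x patient bool
    true_burden: pd.DataFrame  # patient x {cis, trans, total}
    netosis_active: pd.Series  # patient -> bool
    netosis_block: list[str]
    netosis_geneset: list[str]
    prognosis: pd.Series  # patient -> death/remission
    coexpressed_lnc: pd.DataFrame  # lnc_id, partner_gene
    config: SimulationConfig


def _patient_ids(config: SimulationConfig) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(config.n_patients)]


def _control_ids(config: SimulationConfig) -> list[str]:
    return [f"C{i + 1:03d}" for i in range(config.n_controls)]


def _draw_prognosis(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_patients
    n_death = int(round(config.death_frac * n))
    labels = np.array(["remission"] * n, dtype=object)
    labels[rng.choice(n, size=n_death, replace=False)] = "death"
    return labels


def _draw_activation(
    config: SimulationConfig,
    rng: np.random.Generator,
    prognosis: np.ndarray,
    n_planted: int,
) -> np.ndarray:
    """Planted-pair activation matrix (pairs x patients).

    Each patient has an activation probability with lognormal spread around
    the base rate; the death group's probability is shifted by the
    multiplicative ``prognosis_effect`` (clipped to [0.02, 0.98])."""
    n = config.n_patients
    spread = _mean_one_lognormal(rng, config.burden_spread_sd, n)
    mult = np.where(prognosis == "death", config.prognosis_effect, 1.0)
    pi = np.clip(config.trt_activation_prob * spread * mult, 0.02, 0.98)
    return rng.random((n_planted, n)) < pi[None, :]


def _true_burden(
    planted: pd.DataFrame, active: pd.DataFrame
) -> pd.DataFrame:
    cls = planted.set_index("pair_id")["pair_class"]
    keys = {
        pid: tuple(sorted((u, d)))
        for pid, u, d in zip(
            planted["pair_id"], planted["upstream_gene"], planted["downstream_gene"]
        )
    }
    rows = {}
    for p in active.columns:
        called = active.index[active[p]]
        cis = int((cls.loc[called] == "cis").sum())
        trans = int((cls.loc[called] == "trans").sum())
        total = len({keys[pid] for pid in called})
        rows[p] = (cis, trans, total)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["cis", "trans", "total"])
    out.index.name = "patient_id"
    return out


def simulate_burden(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.Series, pd.Series]:
    """Lightweight burden draw (no fragments): total true burden and
    prognosis labels from the same activation model as the full simulator.

    Useful for power and null-calibration studies of the burden tests."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    prognosis = _draw_prognosis(config, rng)
    active = _draw_activation(config, rng, prognosis, config.n_trt_pairs_planted)
    patients = _patient_ids(config)
    burden = pd.Series(active.sum(axis=0), index=patients, name="total")
    return burden, pd.Series(prognosis, index=patients, name="prognosis")


# ---------------------------------------------------------------------------
# Fragments


def _fragment_block(
    rng: np.random.Generator,
    config: SimulationConfig,
    counts: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    chroms: np.ndarray,
    strands: np.ndarray,
) -> pd.DataFrame:
    """Uniform fragments fully contained in their source features.

    Containment keeps the intergenic and downstream fold-change calibration
    exact: gene-body fragments never spill into the gap and read-through
    fragments never leak into gene bodies."""
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    rep = np.repeat(np.arange(len(counts)), counts)
    feat_start = starts[rep]
    feat_len = (ends - starts)[rep]
    frag_len = np.clip(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, total),
        100,
        None,
    ).astype(np.int64)
    frag_len = np.minimum(frag_len, feat_len)
    offset = (rng.random(total) * (feat_len - frag_len + 1)).astype(np.int64)
    fs = feat_start + offset
    return pd.DataFrame(
        {
            "chrom": chroms[rep],
            "start": fs,
            "end": fs + frag_len,
            "strand": strands[rep],
        }
    )


def simulate_fragments(
    genes: Sequence[GeneModel],
    pairs: Sequence[GenePair],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[FragmentSet], GroundTruth]:
    """Strand-specific fragments for controls and patients, plus ground truth.

    Controls carry gene-body coverage proportional to a lognormal baseline
    and Poisson intergenic background only.  Patients additionally carry,
    for each planted active (pair, patient) cell, extra intergenic
    fragments on the upstream strand and extra downstream-gene fragments,
    jointly scaled so the expected intergenic and downstream fold changes
    equal ``readthrough_intensity`` and ``downstream_coupling``."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    genes = list(genes)
    pairs = list(pairs)
    gene_ids = np.array([g.gene_id for g in genes])
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    g_start = np.array([g.start for g in genes], dtype=np.int64)
    g_end = np.array([g.end for g in genes], dtype=np.int64)
    g_chrom = np.array([g.chrom for g in genes])
    g_strand = np.array([g.strand for g in genes])
    g_len_kb = (g_end - g_start) / 1e3
    is_coding = np.array([g.biotype != "lncRNA" for g in genes])

    lib_factor = config.library_size / 1e6
    baseline_fpkm = rng.lognormal(
        config.baseline_fpkm_log_mean, config.baseline_fpkm_log_sd, len(genes)
    )
    gene_rate = baseline_fpkm * g_len_kb * lib_factor

    # planted lncRNA co-expression: lnc tracks a well-expressed coding partner
    lnc_idx = np.flatnonzero(~is_coding)
    partner_of: dict[int, int] = {}
    if config.n_coexpressed_lnc > 0 and lnc_idx.size:
        eligible = np.flatnonzero(is_coding & (baseline_fpkm > np.median(baseline_fpkm)))
        chosen_lnc = rng.choice(
            lnc_idx, size=min(config.n_coexpressed_lnc, lnc_idx.size), replace=False
        )
        partners = rng.choice(eligible, size=len(chosen_lnc), replace=False)
        for li, pi in zip(chosen_lnc, partners):
            partner_of[int(li)] = int(pi)
            gene_rate[li] = 0.8 * baseline_fpkm[pi] * g_len_kb[li] * lib_factor
    coexpressed = pd.DataFrame(
        {
            "lnc_id": [gene_ids[li] for li in partner_of],
            "partner_gene": [gene_ids[pi] for pi in partner_of.values()],
        }
    )

    # intergenic background: one Poisson rate per unique gap and strand, so a
    # convergent gap's two directed pair features see independent strand-
    # specific baselines rather than double-counted background
    p_frame = pairs_to_frame(pairs)
    p_start = p_frame["intergenic_start"].to_numpy()
    p_end = p_frame["intergenic_end"].to_numpy()
    p_chrom = p_frame["chrom"].to_numpy()
    p_strand = np.array([p.upstream.strand for p in pairs])
    gap_index: dict[tuple, int] = {}
    pair_gap = np.empty(len(pairs), dtype=np.int64)
    for i, key in enumerate(zip(p_chrom, p_start, p_end)):
        pair_gap[i] = gap_index.setdefault(key, len(gap_index))
    n_gaps = len(gap_index)
    gap_keys = list(gap_index)
    gap_chrom = np.array([k[0] for k in gap_keys])
    gap_start = np.array([k[1] for k in gap_keys], dtype=np.int64)
    gap_end = np.array([k[2] for k in gap_keys], dtype=np.int64)
    gap_len_kb = (gap_end - gap_start) / 1e3
    bg_fpkm_gap = rng.lognormal(
        config.intergenic_bg_fpkm_log_mean,
        config.intergenic_bg_fpkm_log_sd,
        (n_gaps, 2),  # columns: + and - strand
    )
    bg_rate_gap = bg_fpkm_gap * gap_len_kb[:, None] * lib_factor

    # rescale all rates so the expected fragment total per sample equals the
    # configured library size (FPKM and every fold change are scale-free)
    scale = config.library_size / (gene_rate.sum() + bg_rate_gap.sum())
    gene_rate *= scale
    bg_rate_gap *= scale

    strand_col = (p_strand == "-").astype(int)
    bg_rate = bg_rate_gap[pair_gap, strand_col]  # expected control count per pair feature

    # choose planted pairs among those with an actively expressed upstream gene
    up_idx = np.array([gene_index[p.upstream.gene_id] for p in pairs])
    down_idx = np.array([gene_index[p.downstream.gene_id] for p in pairs])
    threshold = np.quantile(baseline_fpkm, config.upstream_expression_quantile)
    eligible_pairs = np.flatnonzero(
        (baseline_fpkm[up_idx] >= threshold)
        & is_coding[up_idx]
        & is_coding[down_idx]
    )
    n_planted = min(config.n_trt_pairs_planted, eligible_pairs.size)
    if n_planted < config.n_trt_pairs_planted:
        logger.warning(
            "only %d pairs eligible for planting (%d requested)",
            n_planted,
            config.n_trt_pairs_planted,
        )
    planted_idx = np.sort(rng.choice(eligible_pairs, size=n_planted, replace=False))
    planted_ids = p_frame["pair_id"].to_numpy()[planted_idx]
    planted = p_frame.iloc[planted_idx][
        ["pair_id", "pair_class", "upstream_gene", "downstream_gene"]
    ].reset_index(drop=True)

    # NETosis block among coding genes not used by planted pairs
    used = set(up_idx[planted_idx]) | set(down_idx[planted_idx])
    block_pool = np.array(
        [i for i in np.flatnonzero(is_coding) if i not in used]
    )
    n_block = min(config.netosis_block_genes, block_pool.size)
    block_idx = np.sort(rng.choice(block_pool, size=n_block, replace=False))
    extra_pool = np.array([i for i in block_pool if i not in set(block_idx)])
    n_extra = min(config.netosis_extra_genes, extra_pool.size)
    extra_idx = np.sort(rng.choice(extra_pool, size=n_extra, replace=False))
    block_genes = [str(g) for g in gene_ids[block_idx]]
    geneset = block_genes + [str(g) for g in gene_ids[extra_idx]]

    # cohort structure
    patients = _patient_ids(config)
    controls = _control_ids(config)
    prognosis = _draw_prognosis(config, rng)
    active_arr = _draw_activation(config, rng, prognosis, n_planted)
    active = pd.DataFrame(
        active_arr, index=pd.Index(planted_ids, name="pair_id"), columns=patients
    )
    n_net_active = int(round(config.netosis_active_frac * config.n_patients))
    net_active = np.zeros(config.n_patients, dtype=bool)
    net_active[rng.choice(config.n_patients, size=n_net_active, replace=False)] = True
    block_mult = 2.0**config.netosis_log2_effect

    # planted fragments inflate patient library sizes, which would deflate
    # every patient FPKM relative to controls; compensate the planted rates
    # by the expected library ratio so fold-change targets survive the
    # per-million normalisation
    lib_ctrl_exp = gene_rate.sum() + bg_rate_gap.sum()

    samples: list[FragmentSet] = []
    for sid, is_patient, pat_i in (
        [(c, False, None) for c in controls] + [(p, True, i) for i, p in enumerate(patients)]
    ):
        bio = _mean_one_lognormal(rng, config.bio_noise_sd, len(genes))
        for li, pi in partner_of.items():
            bio[li] = bio[pi] * _mean_one_lognormal(rng, config.coexpression_noise_sd, 1)[0]
        rate = gene_rate * bio
        if is_patient and net_active[pat_i]:
            rate = rate.copy()
            rate[block_idx] *= block_mult
        gene_counts = rng.poisson(rate)
        blocks = [
            _fragment_block(rng, config, gene_counts, g_start, g_end, g_chrom, g_strand)
        ]
        for col, strand in ((0, "+"), (1, "-")):
            bg_counts = rng.poisson(bg_rate_gap[:, col])
            blocks.append(
                _fragment_block(
                    rng,
                    config,
                    bg_counts,
                    gap_start,
                    gap_end,
                    gap_chrom,
                    np.full(n_gaps, strand),
                )
            )
        if is_patient:
            act = active_arr[:, pat_i]
            if act.any():
                j = np.flatnonzero(act)
                pj = planted_idx[j]
                block_e = (
                    (block_mult - 1.0) * gene_rate[block_idx].sum()
                    if net_active[pat_i]
                    else 0.0
                )
                extra_e = (
                    (config.readthrough_intensity - 1.0) * bg_rate[pj]
                    + (config.downstream_coupling - 1.0) * gene_rate[down_idx[pj]]
                ).sum()
                extra_frac = min(extra_e / lib_ctrl_exp, 0.5)
                comp = (1.0 + block_e / lib_ctrl_exp) / (1.0 - extra_frac)
                jitter = _mean_one_lognormal(rng, config.coupling_jitter_sd, len(j))
                noise_i = _mean_one_lognormal(rng, config.coupling_noise_sd, len(j))
                noise_d = _mean_one_lognormal(rng, config.coupling_noise_sd, len(j))
                rt_rate = (
                    (config.readthrough_intensity - 1.0)
                    * bg_rate[pj]
                    * comp
                    * jitter
                    * noise_i
                )
                down_rate = (
                    (config.downstream_coupling - 1.0)
                    * gene_rate[down_idx[pj]]
                    * comp
                    * jitter
                    * noise_d
                )
                blocks.append(
                    _fragment_block(
                        rng,
                        config,
                        rng.poisson(np.maximum(rt_rate, 0.0)),
                        p_start[pj],
                        p_end[pj],
                        p_chrom[pj],
                        p_strand[pj],
                    )
                )
                di = down_idx[pj]
                blocks.append(
                    _fragment_block(
                        rng,
                        config,
                        rng.poisson(np.maximum(down_rate, 0.0)),
                        g_start[di],
                        g_end[di],
                        g_chrom[di],
                        g_strand[di],
                    )
                )
        frags = pd.concat(blocks, ignore_index=True)
        frags = frags.sort_values(
            ["chrom", "start", "end", "strand"], kind="stable"
        ).reset_index(drop=True)
        samples.append(FragmentSet(sid, frags))

    truth = GroundTruth(
        planted=planted,
        active=active,
        true_burden=_true_burden(planted, active),
        netosis_active=pd.Series(net_active, index=patients, name="netosis_active"),
        netosis_block=block_genes,
        netosis_geneset=geneset,
        prognosis=pd.Series(prognosis, index=patients, name="prognosis"),
        coexpressed_lnc=coexpressed,
        config=config,
    )
    return samples, truth


# ---------------------------------------------------------------------------
# Clinical traits


def _spearman_to_pearson(rho_s: float) -> float:
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _normal_scores(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Blom-style normal scores of the value ranks; random jitter breaks ties
    so the copula stays well-defined for discrete inputs."""
    from scipy import stats as sps

    jitter = rng.random(len(values)) * 1e-6
    ranks = sps.rankdata(values + jitter)
    return sps.norm.ppf((ranks - 0.375) / (len(values) + 0.25))


def _couple(
    rng: np.random.Generator, z_driver: np.ndarray, rho_s: float
) -> np.ndarray:
    rho = np.clip(_spearman_to_pearson(rho_s), -0.999, 0.999)
    eps = rng.normal(0.0, 1.0, len(z_driver))
    return rho * z_driver + math.sqrt(1.0 - rho * rho) * eps


def simulate_clinical(
    ground_truth: GroundTruth,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Clinical traits coupled to the true burden and block activity.

    Numeric traits are generated through a Gaussian copula on the normal
    scores of true total burden (NEUT%) and of a noisy block-activity
    latent (PaCO2 positively, PaO2/FiO2 negatively: more active NETosis,
    worse gas exchange).  Binary virus/AKI flags are more frequent in
    block-active patients; prognosis labels come from the burden model.
    Controls receive healthy marginals and missing patient-only fields."""
    config = config or ground_truth.config
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    patients = list(ground_truth.true_burden.index)
    n = len(patients)

    z_burden = _normal_scores(
        ground_truth.true_burden["total"].to_numpy(dtype=float), rng
    )
    activity = ground_truth.netosis_active.to_numpy().astype(float)
    z_activity = _normal_scores(activity + rng.normal(0, 0.5, n), rng)

    neut = 87.0 + 7.0 * _couple(rng, z_burden, config.neut_burden_spearman)
    paco2 = 36.0 + 6.0 * _couple(rng, z_activity, config.paco2_activity_spearman)
    pao2_fio2 = 160.0 + 60.0 * _couple(
        rng, z_activity, config.pao2fio2_activity_spearman
    )
    age = rng.normal(62.0, 12.0, n)

    virus_p = np.where(
        ground_truth.netosis_active, config.virus_prob_active, config.virus_prob_inactive
    )
    aki_p = np.where(
        ground_truth.netosis_active, config.aki_prob_active, config.aki_prob_inactive
    )
    virus = np.where(rng.random(n) < virus_p, "yes", "no")
    aki = np.where(rng.random(n) < aki_p, "yes", "no")

    rows = pd.DataFrame(
        {
            "sample_id": patients,
            "group": "patient",
            "prognosis": ground_truth.prognosis.reindex(patients).to_numpy(),
            "virus": virus,
            "aki": aki,
            "neut_pct": np.clip(neut, 40.0, 100.0),
            "paco2": np.clip(paco2, 15.0, 90.0),
            "pao2_fio2": np.clip(pao2_fio2, 40.0, 450.0),
            "age": np.clip(age, 18.0, 95.0),
        }
    )
    controls = _control_ids(config)
    m = len(controls)
    ctrl = pd.DataFrame(
        {
            "sample_id": controls,
            "group": "control",
            "prognosis": pd.NA,
            "virus": pd.NA,
            "aki": pd.NA,
            "neut_pct": np.clip(rng.normal(55.0, 8.0, m), 30.0, 80.0),
            "paco2": np.clip(rng.normal(39.0, 3.0, m), 25.0, 55.0),
            "pao2_fio2": np.clip(rng.normal(430.0, 25.0, m), 300.0, 500.0),
            "age": np.clip(rng.normal(45.0, 12.0, m), 18.0, 90.0),
        }
    )
    return pd.concat([rows, ctrl], ignore_index=True).set_index("sample_id")


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class SimulatedCohort:
    genes: list[GeneModel]
    pairs: list[GenePair]
    samples: list[FragmentSet]
    expr: ExpressionMatrix
    ground_truth: GroundTruth
    clinical: pd.DataFrame

    @property
    def patient_ids(self) -> list[str]:
        return list(self.ground_truth.true_burden.index)

    @property
    def control_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.sample_id not in set(self.patient_ids)]


def simulate_cohort(config: SimulationConfig, stranded: bool = True) -> SimulatedCohort:
    """Full deterministic simulation: genome, fragments, FPKM, clinical."""
    rng = np.random.default_rng(config.seed)
    genes, pairs = simulate_genome(config, rng)
    samples, truth = simulate_fragments(genes, pairs, config, rng)
    expr = quantify_features(genes, pairs, samples, stranded=stranded)
    clinical = simulate_clinical(truth, config, rng)
    return SimulatedCohort(genes, pairs, samples, expr, truth, clinical)


# ---------------------------------------------------------------------------
# Fixture bundle


def _write_gtf(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype or "protein_coding"}";'
            fh.write(
                f"{g.chrom}\ttrtscreen_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_fixture_bundle(config: SimulationConfig, out_dir: str) -> dict[str, str]:
    """Write a complete, deterministic input set for every pipeline stage.

    Emits annotation GTF, per-sample fragment BEDs, FPKM and library-size
    TSVs, clinical TSV, NETosis gene-set file, a binding-evidence table for
    the planted co-expressed lncRNAs, and ground-truth TSVs."""
    os.makedirs(out_dir, exist_ok=True)
    cohort = simulate_cohort(config)
    paths: dict[str, str] = {}

    paths["annotation"] = os.path.join(out_dir, "annotation.gtf")
    _write_gtf(cohort.genes, paths["annotation"])

    paths["pairs"] = os.path.join(out_dir, "pairs.tsv")
    write_pairs_tsv(cohort.pairs, paths["pairs"])

    frag_dir = os.path.join(out_dir, "fragments")
    os.makedirs(frag_dir, exist_ok=True)
    for s in cohort.samples:
        p = os.path.join(frag_dir, f"{s.sample_id}.bed")
        with open(p, "w") as fh:
            for row in s.fragments.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tfrag\t0\t{row.strand}\n")
    paths["fragments_dir"] = frag_dir

    paths["fpkm"] = os.path.join(out_dir, "fpkm.tsv")
    paths["library_sizes"] = os.path.join(out_dir, "library_sizes.tsv")
    cohort.expr.write_tsv(paths["fpkm"], paths["library_sizes"])

    paths["clinical"] = os.path.join(out_dir, "clinical.tsv")
    cohort.clinical.reset_index().to_csv(paths["clinical"], sep="\t", index=False)

    paths["geneset"] = os.path.join(out_dir, "netosis_genes.txt")
    with open(paths["geneset"], "w") as fh:
        fh.write("\n".join(cohort.ground_truth.netosis_geneset) + "\n")

    paths["binding"] = os.path.join(out_dir, "binding.tsv")
    binding = cohort.ground_truth.coexpressed_lnc.rename(
        columns={"partner_gene": "gene_id"}
    )
    binding.to_csv(paths["binding"], sep="\t", index=False)

    gt_dir = os.path.join(out_dir, "ground_truth")
    os.makedirs(gt_dir, exist_ok=True)
    gt = cohort.ground_truth
    gt.planted.to_csv(os.path.join(gt_dir, "planted_pairs.tsv"), sep="\t", index=False)
    gt.active.to_csv(os.path.join(gt_dir, "active_cells.tsv"), sep="\t")
    gt.true_burden.to_csv(os.path.join(gt_dir, "true_burden.tsv"), sep="\t")
    gt.netosis_active.rename_axis("patient_id").to_csv(
        os.path.join(gt_dir, "netosis_active.tsv"), sep="\t"
    )
    paths["ground_truth_dir"] = gt_dir

    paths["samples"] = os.path.join(out_dir, "samples.tsv")
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in cohort.samples],
            "group": [
                "patient" if s.sample_id in set(cohort.patient_ids) else "control"
                for s in cohort.samples
            ],
        }
    ).to_csv(paths["samples"], sep="\t", index=False)
    return paths
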