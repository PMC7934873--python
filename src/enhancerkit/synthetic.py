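"""Synthetic data with known ground truth for every pipeline stage.

The generator encodes the statistical structure the downstream analyses
assume: a random genome; well-spaced bidirectional-transcription origins;
motif instances planted either co-localized with origins or uniformly;
divergent strand-specific read pileups around each origin; per-nucleus
metadata/count tables with controlled group fold changes under
logistic/negative-binomial models; and tiled qPCR Ct values under a planted
nucleosome-protection profile. Truth tables are returned alongside every
simulated object so downstream estimates can be checked without
re-simulation, and fixed seeds give byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .origins import StrandCoverage
from .pwm import reverse_complement

# substream salts so each operation draws from an independent, reproducible stream
_SALT_GENOME, _SALT_ORIGINS, _SALT_MOTIFS, _SALT_COVERAGE = 11, 12, 13, 14


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


@dataclass
class SimulationConfig:
    """Conditions for the genome/origin/motif/coverage simulation.

    Defaults mirror the conditions the motif-displacement and origin-calling
    analyses are validated under: 150 bp planting radius (the MD inner
    radius), 3000 bp origin spacing (no overlap of +/-1500 bp windows),
    geometric read offsets with 60 bp mean, and 500 reads per origin.
    """

    genome_length: int = 100_000
    gc_fraction: float = 0.5
    n_origins: int = 20
    origin_min_spacing: int = 3000
    n_motif_instances: int = 500
    colocalized_fraction: float = 0.5
    placement_radius: int = 150
    reads_per_origin: int = 500
    read_offset_scale: float = 60.0
    noise_read_rate: float = 0.0
    seed: int = 0
    chrom: str = "chrS"
    motif_consensus: str = "TGACGTCATG"

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if not 0.0 <= self.colocalized_fraction <= 1.0:
            raise ValueError("colocalized_fraction must lie in [0, 1]")
        if self.origin_min_spacing <= 2 * self.placement_radius:
            raise ValueError("origin_min_spacing must exceed 2 * placement_radius")
        for name in ("n_origins", "n_motif_instances", "reads_per_origin", "placement_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_offset_scale < 1:
            raise ValueError("read_offset_scale must be >= 1 (mean of a geometric offset)")
        if self.noise_read_rate < 0:
            raise ValueError("noise_read_rate must be >= 0")
        if len(self.motif_consensus) >= self.origin_min_spacing:
            raise ValueError("motif consensus must be shorter than origin_min_spacing")
        if set(self.motif_consensus) - set("ACGT"):
            raise ValueError("motif consensus must be over ACGT")


@dataclass
class NucleusSimConfig:
    """Conditions for the per-nucleus count-table simulation.

    Defaults are the contrast structure of the disease comparison this
    package is validated against: accessibility rate ratio 1.52 and
    expression ratio 1.91 between two groups of 3000 nuclei, lognormal
    depths, and negative-binomial counts with size (shape) parameter
    ``nb_dispersion`` (variance = mu + mu^2 / r; r -> inf is the Poisson
    limit).
    """

    n_nuclei_per_group: int = 3000
    depth_log_mean: float = 7.5
    depth_log_sd: float = 0.4
    baseline_access_rate: float = 0.25
    access_fold_change: float = 1.52
    access_depth_coef: float = 0.25
    baseline_expr_mean: float = 4.0
    expr_fold_change: float = 1.91
    nb_dispersion: float = 0.5
    seed: int = 0
    group_variable: str = "disease"
    group_labels: tuple[str, str] = ("control", "IPF")
    cell_type: str = "secretory"
    access_feature: str = "MUC5B_enhancer"
    expr_feature: str = "MUC5B"

    def __post_init__(self) -> None:
        if self.n_nuclei_per_group <= 0:
            raise ValueError("n_nuclei_per_group must be positive")
        if not 0.0 < self.baseline_access_rate < 1.0:
            raise ValueError("baseline_access_rate must lie in (0, 1)")
        if not 0.0 < self.baseline_access_rate * self.access_fold_change < 1.0:
            raise ValueError("access rate in group b must stay in (0, 1)")
        if self.access_fold_change <= 0 or self.expr_fold_change <= 0:
            raise ValueError("fold changes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.depth_log_sd < 0 or self.baseline_expr_mean <= 0:
            raise ValueError("depth_log_sd must be >= 0 and baseline_expr_mean > 0")
        if self.group_variable not in ("disease", "genotype"):
            raise ValueError("group_variable must be 'disease' or 'genotype'")


# ---------------------------------------------------------------------------
# Genome / origins / motifs / coverage


def simulate_genome(config: SimulationConfig) -> str:
    """Random i.i.d. genome of the configured length and GC fraction."""
    rng = _rng(config.seed, _SALT_GENOME)
    gc = config.gc_fraction
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=config.genome_length, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode("ascii")


def place_origins(config: SimulationConfig) -> pd.DataFrame:
    """Truth origin positions: pairwise >= origin_min_spacing apart, inside
    [placement_radius, genome_length - placement_radius)."""
    n, spacing, radius = config.n_origins, config.origin_min_spacing, config.placement_radius
    if n * spacing > config.genome_length:
        raise ValueError(
            f"cannot place {n} origins with spacing {spacing} in {config.genome_length} bases"
        )
    available = config.genome_length - 2 * radius - (n - 1) * spacing - 1
    if n > 0 and available < 0:
        raise ValueError("origin packing infeasible within placement bounds")
    rng = _rng(config.seed, _SALT_ORIGINS)
    offsets = np.sort(rng.integers(0, available + 1, size=n))
    positions = radius + offsets + np.arange(n) * spacing
    return pd.DataFrame({"chrom": config.chrom, "origin": positions.astype(np.int64)})


def plant_motifs(
    genome: str,
    origins: pd.DataFrame,
    config: SimulationConfig,
    max_retries: int = 200,
) -> tuple[pd.DataFrame, str]:
    """Write motif instances into the genome; return the truth table and the
    edited genome.

    A fraction ``colocalized_fraction`` of instances have centers uniform
    within +/- placement_radius of a random origin; the rest are uniform over
    the genome. The consensus (or its reverse complement, random strand)
    overwrites the genome bases at each site, keeping coordinates stable.
    Overlapping placements are redrawn up to *max_retries*; exhaustion raises.
    """
    rng = _rng(config.seed, _SALT_MOTIFS)
    consensus = config.motif_consensus
    L = len(consensus)
    G = len(genome)
    if G < L:
        raise ValueError("genome shorter than the motif consensus")
    n = config.n_motif_instances
    n_coloc = int(round(config.colocalized_fraction * n))
    origin_pos = origins["origin"].to_numpy()
    if n_coloc > 0 and origin_pos.size == 0:
        raise ValueError("colocalized placement requested but origin set is empty")

    occupied = np.zeros(G, dtype=bool)
    edited = bytearray(genome, "ascii")
    records = []
    for i in range(n):
        colocalized = i < n_coloc
        for _ in range(max_retries):
            if colocalized:
                o = int(origin_pos[rng.integers(0, origin_pos.size)])
                center = o + int(rng.integers(-config.placement_radius, config.placement_radius + 1))
                start = center - L // 2
            else:
                start = int(rng.integers(0, G - L + 1))
            if start < 0 or start + L > G:
                continue
            if occupied[start : start + L].any():
                continue
            break
        else:
            raise RuntimeError(
                f"could not place motif instance {i} without overlap after {max_retries} retries"
            )
        occupied[start : start + L] = True
        strand = "+" if rng.random() < 0.5 else "-"
        planted = consensus if strand == "+" else reverse_complement(consensus)
        edited[start : start + L] = planted.encode("ascii")
        records.append((config.chrom, start, start + L, strand, colocalized, "planted"))

    truth = pd.DataFrame(
        records, columns=["chrom", "start", "end", "strand", "colocalized", "motif_id"]
    )
    truth = truth.sort_values(["start"], kind="stable").reset_index(drop=True)
    return truth, edited.decode("ascii")


def simulate_nascent_coverage(
    origins: pd.DataFrame,
    config: SimulationConfig,
) -> StrandCoverage:
    """Divergent strand-specific read pileups around each origin.

    Each origin receives reads_per_origin/2 plus-strand counts at
    origin + offset and the same number of minus-strand counts at
    origin - offset, with offsets geometric (support >= 1) of mean
    read_offset_scale. Uniform noise reads are added on both strands at
    noise_read_rate reads per base. Reads falling outside the chromosome are
    dropped.
    """
    G = config.genome_length
    plus = np.zeros(G, dtype=np.int64)
    minus = np.zeros(G, dtype=np.int64)
    rng = _rng(config.seed, _SALT_COVERAGE)
    half = config.reads_per_origin // 2
    p_geom = 1.0 / config.read_offset_scale
    for o in origins["origin"].to_numpy():
        if half > 0:
            up = o + rng.geometric(p_geom, size=half)
            down = o - rng.geometric(p_geom, size=half)
            up = up[(up >= 0) & (up < G)]
            down = down[(down >= 0) & (down < G)]
            np.add.at(plus, up, 1)
            np.add.at(minus, down, 1)
    if config.noise_read_rate > 0:
        for arr in (plus, minus):
            k = rng.poisson(config.noise_read_rate * G)
            if k > 0:
                np.add.at(arr, rng.integers(0, G, size=k), 1)
    return StrandCoverage(
        plus={config.chrom: plus}, minus={config.chrom: minus}, lengths={config.chrom: G}
    )


# ---------------------------------------------------------------------------
# Per-nucleus count tables


def simulate_nucleus_table(config: NucleusSimConfig) -> tuple[pd.DataFrame, dict]:
    """Two-group per-nucleus table with known accessibility/expression effects.

    Depth is lognormal; the accessibility indicator is Bernoulli with logit
    linear in group and centered log depth, calibrated so the rate ratio at
    mean log depth equals access_fold_change; the expression count is
    negative binomial with mean proportional to depth and the group ratio
    equal to expr_fold_change. Returns (table, truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 21]))
    n = config.n_nuclei_per_group
    labels = list(config.group_labels)
    group = np.repeat([0, 1], n)
    depth = np.maximum(
        1, rng.lognormal(config.depth_log_mean, config.depth_log_sd, size=2 * n)
    ).astype(np.int64)
    logd_centered = np.log(depth) - config.depth_log_mean

    def logit(p):
        return math.log(p / (1 - p))

    b0 = logit(config.baseline_access_rate)
    b1 = logit(config.baseline_access_rate * config.access_fold_change) - b0
    eta = b0 + b1 * group + config.access_depth_coef * logd_centered
    p_access = 1.0 / (1.0 + np.exp(-eta))
    accessible = (rng.random(2 * n) < p_access).astype(np.int64)

    mu = (
        config.baseline_expr_mean
        * (depth / math.exp(config.depth_log_mean))
        * np.where(group == 1, config.expr_fold_change, 1.0)
    )
    r = config.nb_dispersion
    if math.isinf(r):
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam)

    disease = np.array(labels)[group] if config.group_variable == "disease" else np.repeat("IPF", 2 * n)
    genotype = np.array(labels)[group] if config.group_variable == "genotype" else np.repeat("GG", 2 * n)
    sample = np.array(
        [f"{labels[g]}_s{(i % 2) + 1}" for i, g in enumerate(group)]
    )
    table = pd.DataFrame(
        {
            "nucleus_id": [f"n{i:06d}" for i in range(2 * n)],
            "sample_id": sample,
            "disease": disease,
            "genotype": genotype,
            "cell_type": config.cell_type,
            "total_counts": depth,
            config.access_feature: np.minimum(accessible, depth),
            config.expr_feature: np.minimum(counts, depth),
        }
    )
    truth = {
        "group_variable": config.group_variable,
        "group_labels": labels,
        "access_fold_change": config.access_fold_change,
        "expr_fold_change": config.expr_fold_change,
        "access_logit_intercept": b0,
        "access_logit_group_coef": b1,
        "access_depth_coef": config.access_depth_coef,
        "baseline_expr_mean": config.baseline_expr_mean,
        "nb_dispersion": config.nb_dispersion,
        "seed": config.seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Tiled MNase-qPCR Ct values


def simulate_mnase_ct(
    protection_profile,
    noise_sd: float = 0.2,
    seed: int = 0,
    n_replicates: int = 4,
    midpoints=None,
    amplicon_ids=None,
    undigested_plateau: float = 22.0,
) -> pd.DataFrame:
    """Tiled Ct table under a planted protection profile.

    Per amplicon and replicate, the undigested Ct is drawn near a fixed
    plateau and Ct_digested = Ct_undigested - log2(protection) +
    Normal(0, noise_sd). All protection values must be positive.
    """
    profile = np.asarray(protection_profile, dtype=float)
    if profile.ndim != 1 or profile.size == 0:
        raise ValueError("protection profile must be a nonempty 1-D sequence")
    if np.any(profile <= 0):
        raise ValueError("protection values must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    k = profile.size
    if midpoints is None:
        midpoints = 100 * np.arange(k)
    midpoints = np.asarray(midpoints)
    if amplicon_ids is None:
        amplicon_ids = [f"amp{i + 1:02d}" for i in range(k)]

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    rows = []
    for rep in range(1, n_replicates + 1):
        undig = undigested_plateau + rng.normal(0.0, 0.1, size=k)
        dig = undig - np.log2(profile) + rng.normal(0.0, noise_sd, size=k)
        for i in range(k):
            rows.append((amplicon_ids[i], int(midpoints[i]), dig[i], undig[i], rep))
    return pd.DataFrame(rows, columns=["amplicon_id", "midpoint", "ct_digested", "ct_undigested", "replicate"])


# ---------------------------------------------------------------------------
# Writers


def write_fasta(sequence: str, path, name: str = "chrS") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], path, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_truth_bed(truth: pd.DataFrame, path) -> None:
    """Motif truth as BED6; the score column carries the colocalized flag."""
    with open(path, "w") as fh:
        for row in truth.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.motif_id}\t"
                f"{int(row.colocalized)}\t{row.strand}\n"
            )


def write_chrom_sizes(lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in lengths.items():
            fh.write(f"{chrom}\t{size}\n")
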