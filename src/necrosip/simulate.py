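"""Synthetic H2(18)O-SIP necromass-decomposition experiments.

Generates a ground-truth soil community of labeled (active) and unlabeled
(necromass) taxa and pushes it through the full measurement chain:

1. community: taxonomy over common soil phyla, GC content, genome size,
   gram status, per-taxon first-order necromass decay rate k and growth
   rate g;
2. kinetics: necromass(t) = N0 * exp(-k t) (optional two-phase variant),
   active(t) = inoculum * exp(g t) capped at a carrying capacity, with
   replicate-level lognormal biological noise at t > 0;
3. measurement: per (timepoint, replicate, fraction-class) sample a qPCR
   total drawn lognormally around the true pool sum and multinomial
   sequencing counts — light samples draw from necromass pools, heavy
   samples from active pools.

Decay rates optionally depend on standardized GC content and log10 genome
size through a softplus link, so trait-decomposition correlations of either
sign can be injected and recovered downstream.  Everything is deterministic
given ``rng_seed``; each stage uses its own derived substream.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import (
    AbundanceTables,
    GRAM_NEGATIVE_PHYLA,
    GRAM_POSITIVE_PHYLA,
    TAXONOMY_RANKS,
)

__all__ = [
    "TaxonProfile",
    "SimulationConfig",
    "TruePools",
    "generate_community",
    "simulate_timecourse",
    "simulate_measurements",
    "true_decomposition",
    "representative_sequences",
    "gram_status_for_phylum",
]

# phylum -> (class, order, family, genus) templates; genera follow those the
# study highlights (Blastococcus, Gp16, Massilia, Nitrosospira, ...).
_LINEAGES: dict[str, list[tuple[str, str, str, str]]] = {
    "Actinobacteria": [
        ("Actinomycetia", "Micrococcales", "Micrococcaceae", "Arthrobacter"),
        ("Actinomycetia", "Streptomycetales", "Streptomycetaceae", "Streptomyces"),
        ("Actinomycetia", "Propionibacteriales", "Nocardioidaceae", "Nocardioides"),
        ("Actinomycetia", "Geodermatophilales", "Geodermatophilaceae", "Blastococcus"),
    ],
    "Proteobacteria": [
        ("Alphaproteobacteria", "Hyphomicrobiales", "Beijerinckiaceae", "Beijerinckia"),
        ("Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "unclassified_Sphingomonadaceae"),
        ("Betaproteobacteria", "Burkholderiales", "Oxalobacteraceae", "Massilia"),
        ("Betaproteobacteria", "Nitrosomonadales", "Nitrosomonadaceae", "Nitrosospira"),
        ("Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Burkholderia"),
    ],
    "Acidobacteria": [
        ("Acidobacteriia", "Acidobacteriales", "Acidobacteriaceae", "Gp1"),
        ("Blastocatellia", "Blastocatellales", "Blastocatellaceae", "Gp4"),
        ("Vicinamibacteria", "Vicinamibacterales", "Vicinamibacteraceae", "Gp16"),
    ],
    "Gemmatimonadetes": [
        ("Gemmatimonadetes", "Gemmatimonadales", "Gemmatimonadaceae", "Gemmatimonas"),
    ],
    "Firmicutes": [
        ("Bacilli", "Bacillales", "Bacillaceae", "Bacillus"),
        ("Bacilli", "Bacillales", "Planococcaceae", "Planococcus"),
        ("Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    ],
    "Planctomycetes": [
        ("Planctomycetia", "Isosphaerales", "Isosphaeraceae", "Singulisphaera"),
    ],
    "Bacteroidetes": [
        ("Chitinophagia", "Chitinophagales", "Chitinophagaceae", "Chitinophaga"),
    ],
    "Thaumarchaeota": [
        ("Nitrososphaeria", "Nitrososphaerales", "Nitrososphaeraceae", "Nitrososphaera"),
    ],
}
_PHYLUM_WEIGHTS = {
    "Actinobacteria": 0.26,
    "Proteobacteria": 0.30,
    "Acidobacteria": 0.15,
    "Gemmatimonadetes": 0.07,
    "Firmicutes": 0.10,
    "Planctomycetes": 0.04,
    "Bacteroidetes": 0.05,
    "Thaumarchaeota": 0.03,
}


def gram_status_for_phylum(phylum: str) -> str:
    if phylum in GRAM_POSITIVE_PHYLA:
        return "positive"
    if phylum in GRAM_NEGATIVE_PHYLA:
        return "negative"
    return "not_applicable"


@dataclass(frozen=True)
class TaxonProfile:
    """Identity, traits and true kinetic parameters of one taxon."""

    taxon_id: str
    lineage: tuple[str, ...]  # 7 ranks, domain..species
    gram_status: str
    gc_content: float
    genome_size: int
    necromass_0: float
    decay_rate: float  # k, per day
    growth_rate: float  # g, per day

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if self.decay_rate < 0 or self.growth_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.necromass_0 < 0:
            raise ValueError("necromass_0 must be non-negative")
        if len(self.lineage) != len(TAXONOMY_RANKS):
            raise ValueError("lineage must have 7 ranks")

    @property
    def phylum(self) -> str:
        return self.lineage[1]

    @property
    def genus(self) -> str:
        return self.lineage[5]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of a synthetic SIP experiment.

    Defaults mirror the study layout (days 0/15/30, four destructive
    replicates, 1% inoculum) at desk scale; see docs/methods.md for the
    rationale behind each numeric default.
    """

    n_taxa: int = 200
    timepoints: tuple[int, ...] = (0, 15, 30)
    n_replicates: int = 4
    seq_depth: int = 50_000
    qpcr_cv: float = 0.05
    atom_fraction: float = 0.9
    trait_effects: tuple[float, float] = (0.0, 0.0)  # (beta_gc, beta_logsize)
    rng_seed: int = 0
    # kinetics
    beta0: float = -3.0
    k_sd: float = 0.9
    k_fixed: float | None = None  # force one decay rate on all taxa (null simulations)
    two_phase: bool = False
    two_phase_fast_fraction: float = 0.6
    two_phase_slow_factor: float = 0.1
    bio_cv: float = 0.15
    inoculum_fraction: float = 0.01
    growth_rate_range: tuple[float, float] = (0.20, 0.35)
    carrying_capacity_factor: float = 1.1  # active-pool cap, x necromass_0
    # community
    total_copies: float = 1e9
    abundance_sigma: float = 1.5
    gc_mean: float = 0.66
    gc_sd: float = 0.04
    gc_bounds: tuple[float, float] = (0.58, 0.75)
    logsize_mean: float = 6.6
    logsize_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        tp = tuple(self.timepoints)
        if len(tp) < 1 or tp[0] != 0 or list(tp) != sorted(tp) or len(set(tp)) != len(tp):
            raise ValueError("timepoints must be strictly ascending and start at 0")
        if any(t < 0 for t in tp):
            raise ValueError("timepoints must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.seq_depth <= 0:
            raise ValueError("seq_depth must be positive")
        if self.qpcr_cv < 0:
            raise ValueError("qpcr_cv must be non-negative")
        if not 0.0 <= self.atom_fraction <= 1.0:
            raise ValueError("atom_fraction must be in [0, 1]")
        if self.k_fixed is not None and self.k_fixed < 0:
            raise ValueError("k_fixed must be non-negative")
        if self.bio_cv < 0:
            raise ValueError("bio_cv must be non-negative")
        if not 0 < self.gc_bounds[0] < self.gc_bounds[1] < 1:
            raise ValueError("gc_bounds must be an increasing pair inside (0, 1)")


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # fixed spawn_key per stage: community=0, timecourse=1, measurements=2, sequences=3
    return np.random.default_rng(np.random.SeedSequence(config.rng_seed, spawn_key=(stage,)))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate_community(config: SimulationConfig) -> list[TaxonProfile]:
    """Draw ``n_taxa`` ground-truth taxon profiles.

    Decay rates follow a softplus link on standardized traits,
    ``k = softplus(beta0 + beta_gc*z(gc) + beta_logsize*z(log10 size) + eps)``
    with eps ~ N(0, k_sd); trait_effects=(0, 0) leaves k independent of the
    traits.  ``k_fixed`` overrides the link entirely (null experiments).
    """
    rng = _rng(config, 0)
    n = config.n_taxa
    phyla = list(_PHYLUM_WEIGHTS)
    w = np.array([_PHYLUM_WEIGHTS[p] for p in phyla])
    chosen = rng.choice(len(phyla), size=n, p=w / w.sum())

    lo, hi = config.gc_bounds
    a = (lo - config.gc_mean) / config.gc_sd
    b = (hi - config.gc_mean) / config.gc_sd
    tn = stats.truncnorm(a, b, loc=config.gc_mean, scale=config.gc_sd)
    gc = tn.rvs(size=n, random_state=rng)
    logsize = rng.normal(config.logsize_mean, config.logsize_sd, size=n)
    size = np.maximum(np.round(10.0 ** logsize), 1).astype(np.int64)

    # standardize with the generator's own population moments (exact for the
    # truncated normal) so the betas are unit-comparable across traits
    z_gc = (gc - tn.mean()) / tn.std()
    z_ls = (logsize - config.logsize_mean) / config.logsize_sd
    beta_gc, beta_ls = config.trait_effects
    if config.k_fixed is not None:
        k = np.full(n, float(config.k_fixed))
    else:
        eps = rng.normal(0.0, config.k_sd, size=n)
        k = _softplus(config.beta0 + beta_gc * z_gc + beta_ls * z_ls + eps)

    g = rng.uniform(*config.growth_rate_range, size=n)
    rel = rng.lognormal(0.0, config.abundance_sigma, size=n)
    necromass0 = config.total_copies * rel / rel.sum()

    profiles = []
    for i in range(n):
        ph = phyla[chosen[i]]
        cls, order, family, genus = _LINEAGES[ph][rng.integers(len(_LINEAGES[ph]))]
        domain = "Archaea" if ph == "Thaumarchaeota" else "Bacteria"
        tid = f"OTU_{i + 1}"
        profiles.append(
            TaxonProfile(
                taxon_id=tid,
                lineage=(domain, ph, cls, order, family, genus, f"{genus}_sp_{i + 1}"),
                gram_status=gram_status_for_phylum(ph),
                gc_content=float(gc[i]),
                genome_size=int(size[i]),
                necromass_0=float(necromass0[i]),
                decay_rate=float(k[i]),
                growth_rate=float(g[i]),
            )
        )
    return profiles


@dataclass
class TruePools:
    """Latent necromass/active 16S pools per taxon x timepoint x replicate."""

    taxon_ids: list[str]
    timepoints: tuple[int, ...]
    n_replicates: int
    necromass: np.ndarray  # (n_taxa, n_timepoints, n_replicates)
    active: np.ndarray

    def sample(self, t_index: int, replicate: int) -> tuple[np.ndarray, np.ndarray]:
        return self.necromass[:, t_index, replicate], self.active[:, t_index, replicate]


def necromass_fraction_remaining(k: np.ndarray, t: float, config: SimulationConfig) -> np.ndarray:
    """Noise-free fraction of the day-0 necromass pool left at day t."""
    k = np.asarray(k, dtype=float)
    if config.two_phase:
        f = config.two_phase_fast_fraction
        return f * np.exp(-k * t) + (1 - f) * np.exp(-k * config.two_phase_slow_factor * t)
    return np.exp(-k * t)


def simulate_timecourse(profiles: list[TaxonProfile], config: SimulationConfig) -> TruePools:
    """Propagate true necromass and active pools over the timepoints.

    Biological replicate noise is mean-preserving lognormal with CV
    ``bio_cv``.  Destructive sampling means every replicate is its own
    soil, so necromass pools carry replicate noise at every timepoint;
    the active pool at day 0 is exactly the inoculum seed amount.
    """
    if any(t < 0 for t in config.timepoints):
        raise ValueError("negative timepoint")
    rng = _rng(config, 1)
    k = np.array([p.decay_rate for p in profiles])
    g = np.array([p.growth_rate for p in profiles])
    n0 = np.array([p.necromass_0 for p in profiles])
    inoc = config.inoculum_fraction * n0
    cap = config.carrying_capacity_factor * n0

    nt, nr = len(config.timepoints), config.n_replicates
    necro = np.empty((len(profiles), nt, nr))
    active = np.empty_like(necro)
    sigma = np.sqrt(np.log1p(config.bio_cv**2))
    for j, t in enumerate(config.timepoints):
        necro_t = n0 * necromass_fraction_remaining(k, t, config)
        active_t = np.minimum(inoc * np.exp(g * t), cap)
        for r in range(nr):
            if config.bio_cv == 0:
                noise_n = noise_a = 1.0
            else:
                noise_n = rng.lognormal(-sigma**2 / 2, sigma, size=len(profiles))
                noise_a = 1.0 if t == 0 else rng.lognormal(-sigma**2 / 2, sigma, size=len(profiles))
            necro[:, j, r] = necro_t * noise_n
            active[:, j, r] = active_t * noise_a
    return TruePools(
        taxon_ids=[p.taxon_id for p in profiles],
        timepoints=tuple(config.timepoints),
        n_replicates=nr,
        necromass=necro,
        active=active,
    )


def simulate_measurements(
    pools: TruePools, profiles: list[TaxonProfile], config: SimulationConfig
) -> AbundanceTables:
    """qPCR totals and multinomial sequencing counts for every sample.

    One sample per (timepoint, replicate, fraction class): light samples
    measure the necromass pools, heavy samples the active pools.  The qPCR
    total F is mean-preserving lognormal around the true pool sum with CV
    ``qpcr_cv``; counts are multinomial with ``seq_depth`` trials.  An
    all-zero pool yields zero counts and F = 0 and is flagged.
    """
    if (pools.necromass < 0).any() or (pools.active < 0).any():
        raise ValueError("pools must be non-negative")
    rng = _rng(config, 2)
    sigma = np.sqrt(np.log1p(config.qpcr_cv**2))
    sample_ids, meta_rows, qpcr_vals, count_cols, flags = [], [], [], [], []
    for j, t in enumerate(pools.timepoints):
        for r in range(pools.n_replicates):
            necro, act = pools.sample(j, r)
            for frac, pool in (("light", necro), ("heavy", act)):
                sid = f"d{t}_r{r + 1}_{frac}"
                total = float(pool.sum())
                if total == 0:
                    f_obs = 0.0
                    counts = np.zeros(len(pool), dtype=np.int64)
                    flags.append(f"all-zero pool: {sid}")
                else:
                    f_obs = total if config.qpcr_cv == 0 else float(
                        total * rng.lognormal(-sigma**2 / 2, sigma)
                    )
                    counts = rng.multinomial(config.seq_depth, pool / total)
                sample_ids.append(sid)
                meta_rows.append(
                    {"timepoint_day": int(t), "replicate": r + 1,
                     "fraction_class": frac, "treatment": "H2_18O"}
                )
                qpcr_vals.append(f_obs)
                count_cols.append(counts)

    counts = pd.DataFrame(
        np.column_stack(count_cols), index=pools.taxon_ids, columns=sample_ids
    )
    counts.index.name = "otu_id"
    meta = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    qpcr = pd.Series(qpcr_vals, index=meta.index, name="copies_per_g")
    taxonomy = pd.DataFrame(
        [dict(zip(TAXONOMY_RANKS, p.lineage)) for p in profiles],
        index=pd.Index([p.taxon_id for p in profiles], name="otu_id"),
    )
    return AbundanceTables(counts=counts, sample_meta=meta, qpcr=qpcr,
                           taxonomy=taxonomy, flags=flags)


def true_decomposition(
    profiles: list[TaxonProfile], t: float, config: SimulationConfig | None = None
) -> dict[str, float]:
    """Ground-truth decomposition percentage 100*(1 - exp(-k t)) per taxon.

    With a two-phase ``config`` the matching two-phase survival curve is
    used so the target stays consistent with the simulated kinetics.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    k = np.array([p.decay_rate for p in profiles])
    if config is not None and config.two_phase:
        frac = necromass_fraction_remaining(k, t, config)
    else:
        frac = np.exp(-k * t)
    d = 100.0 * (1.0 - frac)
    return {p.taxon_id: float(d[i]) for i, p in enumerate(profiles)}


def representative_sequences(
    profiles: list[TaxonProfile], config: SimulationConfig, length: int = 253
) -> dict[str, str]:
    """Synthetic 16S-like representative sequence per taxon.

    Base composition is engineered so the sequence GC fraction matches the
    taxon's genomic GC content to within 1/length (< 1% for the default
    length); base order is random but deterministic given the seed.
    """
    rng = _rng(config, 3)
    out = {}
    for p in profiles:
        n_gc = int(round(p.gc_content * length))
        bases = np.concatenate(
            [rng.choice(["G", "C"], size=n_gc), rng.choice(["A", "T"], size=length - n_gc)]
        )
        rng.shuffle(bases)
        out[p.taxon_id] = "".join(bases)
    return out


def ground_truth_table(profiles: list[TaxonProfile], config: SimulationConfig) -> pd.DataFrame:
    """Per-taxon ground-truth table (traits, k, true D at each timepoint)."""
    rows = []
    d_by_t = {t: true_decomposition(profiles, t, config) for t in config.timepoints if t > 0}
    for p in profiles:
        row = {
            "taxon_id": p.taxon_id,
            "gc": p.gc_content,
            "genome_size": p.genome_size,
            "k": p.decay_rate,
            "growth_rate": p.growth_rate,
            "necromass_0": p.necromass_0,
            "gram_status": p.gram_status,
        }
        for t, d in d_by_t.items():
            row[f"true_D_{t}"] = d[p.taxon_id]
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon_id")


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different RNG seed."""
    return replace(config, rng_seed=int(seed))
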