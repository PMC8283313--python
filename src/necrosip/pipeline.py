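"""End-to-end pipeline: simulate (or load) -> gradient QC -> decompose ->
trait correlations -> machine-readable run report.

A single :class:`PipelineConfig` drives every stage; unknown config keys
are rejected by name, and the fully-resolved config (plus its hash and the
package version) is embedded in the report so a run can be reproduced
bit-identically from the report alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decompose import (
    decomposition_table,
    filter_day0_prevalence,
    gram_group_comparison,
    phylum_range_summary,
)
from .gradient import (
    DEFAULT_DENSITY_RANGE,
    DEFAULT_HEAVY_WINDOW,
    DEFAULT_LIGHT_WINDOW,
    gradient_qc,
    pool_fractions,
    simulate_gradient,
)
from .simulate import (
    SimulationConfig,
    generate_community,
    ground_truth_table,
    representative_sequences,
    simulate_measurements,
    simulate_timecourse,
)
from .traits import correlate_traits
from . import io as nio

log = logging.getLogger("necrosip")

__all__ = ["PipelineConfig", "GradientSection", "DecomposeSection", "TraitsSection",
           "PathsSection", "run_pipeline"]


def _from_mapping(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in '{section}': {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            coerced[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


@dataclass(frozen=True)
class GradientSection:
    n_fractions: int = 24
    band_sd: float = 0.002
    density_range: tuple[float, float] = DEFAULT_DENSITY_RANGE
    heavy_threshold: float = 0.01
    rho_at: float = 1.660
    gc_slope: float = 0.098
    delta_max: float = 0.042


@dataclass(frozen=True)
class DecomposeSection:
    alpha: float = 0.05
    day0_threshold: float = 0.0005
    ttest: str = "welch"


@dataclass(frozen=True)
class TraitsSection:
    source: str = "truth"  # 'truth': use the simulator's per-taxon traits
    log_size: bool = False
    weighting: str = "db"


@dataclass(frozen=True)
class PathsSection:
    """Optional user-supplied inputs; when otu_table is set the simulator is skipped."""

    otu_table: str | None = None
    taxonomy: str | None = None
    qpcr: str | None = None
    sample_meta: str | None = None
    trait_table: str | None = None


@dataclass(frozen=True)
class WindowsSection:
    light: tuple[float, float] = DEFAULT_LIGHT_WINDOW
    heavy: tuple[float, float] = DEFAULT_HEAVY_WINDOW


@dataclass(frozen=True)
class PipelineConfig:
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    gradient: GradientSection = field(default_factory=GradientSection)
    windows: WindowsSection = field(default_factory=WindowsSection)
    decompose: DecomposeSection = field(default_factory=DecomposeSection)
    traits: TraitsSection = field(default_factory=TraitsSection)
    paths: PathsSection = field(default_factory=PathsSection)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sections = {
            "simulate": SimulationConfig, "gradient": GradientSection,
            "windows": WindowsSection, "decompose": DecomposeSection,
            "traits": TraitsSection, "paths": PathsSection,
        }
        unknown = set(data) - set(sections)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        kwargs = {
            name: _from_mapping(sec_cls, data.get(name, {}) or {}, name)
            for name, sec_cls in sections.items()
        }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, simulate=dataclasses.replace(self.simulate, rng_seed=int(seed))
        )


def _require_paths(paths: PathsSection) -> None:
    needed = ["taxonomy", "qpcr", "sample_meta"]
    missing = [f"paths.{k}" for k in needed if getattr(paths, k) is None]
    if missing:
        raise ValueError(f"config missing required key(s): {missing}")


def _gradient_stage(config: PipelineConfig, profiles, pools, outdir: Path) -> dict:
    g = config.gradient
    sim = config.simulate
    gc_by_taxon = {p.taxon_id: p.gc_content for p in profiles}
    kwargs = dict(
        atom_fraction=sim.atom_fraction, n_fractions=g.n_fractions, band_sd=g.band_sd,
        density_range=g.density_range, rho_at=g.rho_at, gc_slope=g.gc_slope,
        delta_max=g.delta_max,
    )
    t_index = {t: j for j, t in enumerate(pools.timepoints)}
    tubes = []
    labeled = {}
    for t in pools.timepoints:
        if t == 0:
            continue
        necro, act = pools.sample(t_index[t], 0)
        labeled[t] = simulate_gradient(
            {tid: (necro[i], act[i]) for i, tid in enumerate(pools.taxon_ids)},
            gc_by_taxon, tube_id=f"labeled_d{t}", treatment="H2_18O", **kwargs,
        )
        tubes.append(labeled[t])
    t_last = pools.timepoints[-1]
    necro, act = pools.sample(t_index[t_last], 0)
    control = simulate_gradient(
        {tid: (necro[i] + act[i], 0.0) for i, tid in enumerate(pools.taxon_ids)},
        gc_by_taxon, tube_id=f"control_16O_d{t_last}", treatment="H2_16O", **kwargs,
    )
    n0 = pools.necromass[:, 0, 0]
    uninoculated = simulate_gradient(
        {tid: (n0[i], 0.0) for i, tid in enumerate(pools.taxon_ids)},
        gc_by_taxon, tube_id=f"uninoculated_d{t_last}", treatment="H2_18O",
        inoculated=False, **kwargs,
    )
    tubes += [control, uninoculated]
    nio.write_fraction_table(tubes, outdir / "fractions.tsv")

    qc_main = gradient_qc(labeled[t_last], control, g.heavy_threshold,
                          light_window=config.windows.light, heavy_window=config.windows.heavy)
    qc_ster = gradient_qc(labeled[t_last], uninoculated, g.heavy_threshold,
                          light_window=config.windows.light, heavy_window=config.windows.heavy)
    light_recovery = {}
    for t, prof in labeled.items():
        pooled = pool_fractions(prof, config.windows.light, config.windows.heavy)
        light_recovery[f"day{t}"] = pooled.light_dna / pooled.total if pooled.total else 0.0
    qc = {
        "peak_shift_g_ml": qc_main.peak_shift,
        "sterility_pass": qc_ster.sterility_pass,
        "sterility_tube": qc_ster.sterility_tube,
        "light_fraction_recovery": light_recovery,
    }
    pd.DataFrame(
        [{"metric": k, "value": json.dumps(v) if isinstance(v, dict) else v} for k, v in qc.items()]
    ).to_csv(outdir / "qc.tsv", sep="\t", index=False)
    log.info("gradient QC: peak shift %.4f g/ml, sterility pass=%s",
             qc_main.peak_shift, qc_ster.sterility_pass)
    return qc


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Run every stage and write all outputs plus ``report.json``.

    Deterministic: re-running with an identical config (and seed) rewrites
    byte-identical outputs.  Returns the report dictionary.
    """
    if seed is not None:
        config = config.with_seed(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "rng_seed": sim.rng_seed,
            "config": config.to_dict(),
        }
    }

    truth = None
    if config.paths.otu_table is None:
        log.info("simulating community: %d taxa, timepoints %s, %d replicates",
                 sim.n_taxa, sim.timepoints, sim.n_replicates)
        profiles = generate_community(sim)
        pools = simulate_timecourse(profiles, sim)
        tables = simulate_measurements(pools, profiles, sim)
        truth = ground_truth_table(profiles, sim)
        nio.write_otu_table(tables.counts, outdir / "otu_table.tsv")
        nio.write_taxonomy(tables.taxonomy, outdir / "taxonomy.tsv")
        nio.write_qpcr(tables.qpcr, tables.sample_meta, outdir / "qpcr.csv")
        nio.write_sample_meta(tables.sample_meta, outdir / "sample_meta.tsv")
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t")
        nio.write_fasta(representative_sequences(profiles, sim), outdir / "repseqs.fasta")
        report["qc"] = _gradient_stage(config, profiles, pools, outdir)
    else:
        _require_paths(config.paths)
        tables = nio.load_abundance_tables(
            config.paths.otu_table, config.paths.taxonomy,
            config.paths.qpcr, config.paths.sample_meta,
        )
        report["qc"] = None

    light = tables.restrict(fraction_class="light", treatment="H2_18O")
    n_total = len(tables.otus)
    n_pass_day0 = len(filter_day0_prevalence(light, config.decompose.day0_threshold))
    log.info("day-0 prevalence filter: %d of %d OTUs retained", n_pass_day0, n_total)

    dec = config.decompose
    dtable = decomposition_table(
        tables, alpha=dec.alpha, day0_threshold=dec.day0_threshold, ttest=dec.ttest,
    )
    nio.write_decomposition_table(dtable, outdir / "decomposition.tsv")
    gram = gram_group_comparison(dtable, tables.taxonomy, alpha=dec.alpha,
                                 equal_var=dec.ttest == "student")
    gram.to_csv(outdir / "gram_comparison.tsv", sep="\t", index=False)
    phyla = phylum_range_summary(dtable, tables.taxonomy)
    phyla.to_csv(outdir / "phylum_summary.tsv", sep="\t", index=False)

    meta = light.sample_meta
    f_by_t = light.qpcr.groupby(meta["timepoint_day"]).mean()
    decline = {
        f"day{int(t)}": float(100.0 * (1.0 - f_by_t[t] / f_by_t[0]))
        for t in f_by_t.index if t != 0
    }

    filters = {"n_otus": n_total, "n_pass_day0_filter": n_pass_day0, "per_timepoint": {}}
    for t, grp in dtable.groupby("timepoint_day"):
        ret = grp[grp["passed_day0_filter"] & grp["passed_positive_filter"]]
        nsig = int(ret["significant"].fillna(False).sum())
        filters["per_timepoint"][f"day{int(t)}"] = {
            "n_positive_d": len(ret),
            "n_significant": nsig,
            "pct_significant_of_retained": 100.0 * nsig / len(ret) if len(ret) else float("nan"),
        }
        log.info("day %s: %d retained OTUs, %d significant", t, len(ret), nsig)
    report["filters"] = filters

    # trait correlations
    if config.paths.trait_table is not None:
        trait_table = pd.read_csv(config.paths.trait_table, sep="\t", index_col=0)
    elif truth is not None and config.traits.source == "truth":
        trait_table = truth[["gc", "genome_size"]].rename(columns={"gc": "gc_content"})
    else:
        trait_table = None
    correlations = []
    if trait_table is not None:
        for t in sorted(dtable["timepoint_day"].unique()):
            for c in correlate_traits(dtable, trait_table, int(t),
                                      log_size=config.traits.log_size):
                correlations.append(dataclasses.asdict(c))
        pd.DataFrame(correlations).to_csv(outdir / "trait_correlations.tsv",
                                          sep="\t", index=False)

    report["headline"] = {
        "total_necromass_decline_pct": decline,
        "gram_comparison": json.loads(gram.to_json(orient="records")),
        "phylum_ranges": json.loads(phyla.to_json(orient="records")),
        "trait_correlations": correlations,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if obj is pd.NA:
        return None
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
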