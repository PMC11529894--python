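"""Configuration-driven orchestration of the analysis stages.

A single YAML/dict config drives: input acquisition (sync file or the
synthetic generator), indel masking, per-population window diversity,
pairwise differentiation, TE insertion calling + spectra, group statistics,
and a manifest with seeds, effective parameters and output checksums.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import formats, divergence, mobilome, popgen, stats, synthio

__all__ = ["ConfigError", "PopulationConfig", "RunConfig", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (names the offending field)."""


@dataclass
class PopulationConfig:
    name: str
    column: int
    pool_size: int
    max_coverage: int
    min_coverage: int = 4
    min_count: int = 2

    def spec(self) -> popgen.PoolSpec:
        return popgen.PoolSpec(
            self.name, self.pool_size, self.min_count,
            self.min_coverage, self.max_coverage,
        )


@dataclass
class RunConfig:
    output_dir: str
    populations: List[PopulationConfig]
    seed: int = 1
    window_size: int = 100_000
    min_covered_fraction: float = 0.6
    indel_flank: int = 5
    indel_min_count: int = 2
    sync_path: Optional[str] = None
    mask_bed: Optional[str] = None
    simulate: Optional[dict] = None
    te: Optional[dict] = None
    dxy_snps_only: bool = False
    alpha: float = 0.05

    def window(self) -> popgen.WindowSpec:
        return popgen.WindowSpec(
            self.window_size, self.window_size, self.min_covered_fraction
        )


_POP_REQUIRED = ("name", "column", "pool_size", "max_coverage")


def load_config(source) -> RunConfig:
    """Build a validated RunConfig from a YAML path, YAML text or dict."""
    if isinstance(source, (str, Path)) and os.path.exists(str(source)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    elif isinstance(source, str):
        raw = yaml.safe_load(source)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    if "output_dir" not in raw:
        raise ConfigError("missing required field 'output_dir'")
    pops_raw = raw.get("populations")
    if not pops_raw:
        raise ConfigError("missing required field 'populations'")
    populations = []
    for i, entry in enumerate(pops_raw):
        for key in _POP_REQUIRED:
            if key not in entry:
                raise ConfigError(f"populations[{i}] missing required field {key!r}")
        populations.append(PopulationConfig(
            name=str(entry["name"]),
            column=int(entry["column"]),
            pool_size=int(entry["pool_size"]),
            max_coverage=int(entry["max_coverage"]),
            min_coverage=int(entry.get("min_coverage", 4)),
            min_count=int(entry.get("min_count", 2)),
        ))
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ConfigError("population names must be unique")
    cfg = RunConfig(
        output_dir=str(raw["output_dir"]),
        populations=populations,
        seed=int(raw.get("seed", 1)),
        window_size=int(raw.get("window", {}).get("size", 100_000)),
        min_covered_fraction=float(raw.get("window", {}).get("min_covered_fraction", 0.6)),
        indel_flank=int(raw.get("indel_flank", 5)),
        indel_min_count=int(raw.get("indel_min_count", 2)),
        sync_path=raw.get("sync"),
        mask_bed=raw.get("mask_bed"),
        simulate=raw.get("simulate"),
        te=raw.get("te"),
        dxy_snps_only=bool(raw.get("dxy_snps_only", False)),
        alpha=float(raw.get("alpha", 0.05)),
    )
    if cfg.sync_path is None and cfg.simulate is None:
        raise ConfigError("one of 'sync' or 'simulate' must be provided")
    return cfg


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.8g")


def _acquire_sync(cfg: RunConfig, outdir: Path) -> Tuple[str, Optional[synthio.TruthRecord]]:
    if cfg.sync_path:
        with open(cfg.sync_path) as fh:
            return fh.read(), None
    sim = dict(cfg.simulate or {})
    mu = float(sim.get("mu", 1e-8))
    theta = float(sim.get("theta", 0.005))
    n0 = theta / (4.0 * mu)
    bottleneck = sim.get("bottleneck")
    if bottleneck:
        model = synthio.DemographyModel(
            n0=n0, mu=mu,
            nb=n0 * float(bottleneck.get("nb_fraction", 0.01)),
            t_bottleneck=float(bottleneck.get("t", 180)),
            nc=n0 * float(bottleneck.get("nc_factor", 1.0)),
        )
    else:
        model = synthio.DemographyModel(n0=n0, mu=mu)
    seq = synthio.SeqParams(
        length=int(sim.get("length", 500_000)),
        mean_coverage=float(sim.get("mean_coverage", 60.0)),
        error_rate=float(sim.get("error_rate", 0.001)),
        pool_sizes=tuple(p.pool_size for p in cfg.populations),
    )
    sync_text, truth = synthio.simulate_pool_seq(model, seq, rng_seed=cfg.seed)
    (outdir / "data.sync").write_text(sync_text)
    (outdir / "truth.json").write_text(truth.to_json())
    return sync_text, truth


def _diversity_stage(cfg: RunConfig, sync_text: str, mask: formats.MaskIntervals,
                     outdir: Path) -> pd.DataFrame:
    window = cfg.window()
    rows = []
    for pop in cfg.populations:
        sites = formats.apply_mask(formats.read_sync(sync_text), mask)
        for ws in popgen.window_stats(sites, window, pop.spec(), pop.column):
            rows.append({
                "population": pop.name, "chrom": ws.chrom, "start": ws.start,
                "end": ws.end, "n_valid_sites": ws.n_valid_sites,
                "covered_fraction": ws.covered_fraction, "pi": ws.pi,
                "theta_w": ws.theta_w, "tajima_d": ws.tajima_d,
                "delta_theta": ws.delta_theta, "pi_syn": ws.pi_syn,
                "pi_nonsyn": ws.pi_nonsyn,
            })
    df = pd.DataFrame(rows)
    _write(df, outdir / "diversity.tsv")
    return df


def _differentiation_stage(cfg: RunConfig, sync_text: str, mask: formats.MaskIntervals,
                           outdir: Path) -> pd.DataFrame:
    window = cfg.window()
    rows = []
    pairs = list(itertools.combinations(sorted(cfg.populations, key=lambda p: p.name), 2))
    for a, b in pairs:
        specs = (a.spec(), b.spec())
        indices = (a.column, b.column)
        sites = formats.apply_mask(formats.read_sync(sync_text), mask)
        fst_rows = {(
            r.chrom, r.start): r for r in divergence.window_fst(sites, window, specs, indices)
        }
        sites = formats.apply_mask(formats.read_sync(sync_text), mask)
        for r in divergence.window_dxy(
            sites, window, specs, rng_seed=cfg.seed, pool_indices=indices,
            snps_only=cfg.dxy_snps_only,
        ):
            fr = fst_rows.get((r.chrom, r.start))
            rows.append({
                "chrom": r.chrom, "start": r.start, "end": r.end,
                "pop_a": a.name, "pop_b": b.name,
                "fst": fr.fst if fr else float("nan"),
                "dxy": r.dxy, "n_joint_sites": r.n_joint_sites,
                "n_snps": fr.n_snps if fr else 0,
            })
    df = pd.DataFrame(rows)
    _write(df, outdir / "differentiation.tsv")
    return df


def _te_stage(cfg: RunConfig, outdir: Path) -> Optional[pd.DataFrame]:
    te = cfg.te
    if not te:
        return None
    params = mobilome.SignatureParams(**te.get("params", {}))
    tolerance = int(te.get("tolerance", 25))
    per_pop: Dict[str, List[mobilome.TEInsertion]] = {}
    for i, pop in enumerate(cfg.populations):
        if "evidence_files" in te:
            text = Path(te["evidence_files"][pop.name]).read_text()
            evidence = mobilome.read_pair_evidence(text)
        else:
            sim = te.get("simulate", {})
            freqs = sim.get("frequencies", [0.1 * k for k in range(1, 11)])
            n_ins = int(sim.get("n_insertions", len(freqs) * 10))
            reps = (n_ins + len(freqs) - 1) // len(freqs)
            evidence, truth = synthio.simulate_te_evidence(
                n_ins, (list(freqs) * reps)[:n_ins],
                physical_coverage=int(sim.get("physical_coverage", 40)),
                rng_seed=cfg.seed + 7000 + i,
            )
            (outdir / f"te_truth_{pop.name}.json").write_text(truth.to_json())
        per_pop[pop.name] = mobilome.detect_te_insertions(
            evidence, params, rng_seed=cfg.seed + 8000 + i
        )
    rows = []
    for pop_name, insertions in per_pop.items():
        for ins in insertions:
            rows.append({
                "population": pop_name, "chrom": ins.chrom, "pos": ins.pos,
                "family": ins.family, "order": ins.order,
                "frequency": ins.frequency, "support": ins.support,
            })
    df = pd.DataFrame(rows)
    _write(df, outdir / "te_insertions.tsv")
    unique = mobilome.unique_insertions(per_pop, tolerance)
    spec_rows = []
    for pop_name in sorted(unique):
        spectrum = mobilome.frequency_spectrum(unique[pop_name])
        spec_rows.append({
            "population": pop_name, "n_unique": spectrum.n,
            "low_fraction": spectrum.low_fraction,
            "high_fraction": spectrum.high_fraction,
            "fixed_fraction": spectrum.fixed_fraction,
        })
    _write(pd.DataFrame(spec_rows), outdir / "te_spectrum.tsv")
    return df


def _group_stage(cfg: RunConfig, diversity: pd.DataFrame,
                 differentiation: pd.DataFrame, outdir: Path) -> None:
    rows = []
    for metric in ("pi", "tajima_d", "delta_theta"):
        values = {
            pop: diversity.loc[diversity.population == pop, metric].tolist()
            for pop in diversity.population.unique()
        }
        try:
            cmp = stats.compare_groups(values, metric, alpha=cfg.alpha)
        except ValueError:
            continue
        for group in cmp.groups:
            rows.append({
                "statistic": metric, "group": group, "H": cmp.h, "df": cmp.df,
                "p": cmp.p, "letters": cmp.letters[group],
            })
    if not differentiation.empty:
        for metric in ("fst", "dxy"):
            values = {}
            for (a, b), sub in differentiation.groupby(["pop_a", "pop_b"]):
                values[f"{a}-{b}"] = sub[metric].tolist()
            try:
                cmp = stats.compare_groups(values, metric, alpha=cfg.alpha)
            except ValueError:
                continue
            for group in cmp.groups:
                rows.append({
                    "statistic": metric, "group": group, "H": cmp.h,
                    "df": cmp.df, "p": cmp.p, "letters": cmp.letters[group],
                })
    _write(pd.DataFrame(rows), outdir / "group_comparisons.tsv")


def run_pipeline(config) -> Path:
    """Execute the configured stages and write the report directory.

    Identical config + inputs + seeds produce byte-identical outputs; the
    manifest records effective parameters, seeds and output checksums.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sync_text, _truth = _acquire_sync(cfg, outdir)
    if cfg.mask_bed:
        mask = formats.MaskIntervals.from_bed(Path(cfg.mask_bed).read_text())
    else:
        mask = formats.MaskIntervals()
    diversity = _diversity_stage(cfg, sync_text, mask, outdir)
    differentiation = _differentiation_stage(cfg, sync_text, mask, outdir)
    _te_stage(cfg, outdir)
    _group_stage(cfg, diversity, differentiation, outdir)
    manifest = {
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k != "populations"},
            "populations": [asdict(p) for p in cfg.populations],
        },
        "seed": cfg.seed,
        "outputs": {},
    }
    for path in sorted(outdir.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["outputs"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
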