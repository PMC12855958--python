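"""End-to-end orchestration: config validation, seed management, and the
consolidated report reproducing the headline comparisons at reduced
scale (two-region tuning/geometry contrast, lambda sweep with balance,
path lengths, and the criticality comparison)."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, ising, landscape, lattice, synth, tuning

__all__ = ["PipelineConfig", "Report", "validate_config", "run_pipeline", "SCALE_PRESETS"]

log = logging.getLogger("specgen")

#: Problem sizes per scale preset. ``test`` is a smoke-test size; ``desk``
#: reproduces every qualitative comparison on one CPU; ``full`` approaches
#: the published protocol sizes.
SCALE_PRESETS = {
    "test": dict(
        n_neurons=60, lattice=24, sweep_lams=(0.0, 0.1), sweep_repeats=1,
        n_steps=4000, resting_steps=5000, ising_L=16, ising_nT=12,
        geometry_neurons=30, geometry_repeats=3, ising_steps=(20_000, 10_000),
    ),
    "desk": dict(
        n_neurons=200, lattice=40, sweep_lams=(0.0, 0.01, 0.023, 0.05, 0.1),
        sweep_repeats=5, n_steps=20_000, resting_steps=16_000, ising_L=32,
        ising_nT=40, geometry_neurons=100, geometry_repeats=10,
        ising_steps=(200_000, 100_000),
    ),
    "full": dict(
        n_neurons=307, lattice=200, sweep_lams=(0.5, 0.1, 0.075, 0.05, 0.023, 0.01, 0.0005, 0.0),
        sweep_repeats=10, n_steps=150_000, resting_steps=300_000, ising_L=200,
        ising_nT=500, geometry_neurons=100, geometry_repeats=20,
        ising_steps=(16_000_000, 1_600_000),
    ),
}


@dataclass
class PipelineConfig:
    scale: str = "desk"
    master_seed: int = 0
    outdir: str = "specgen_out"
    stages: tuple[str, ...] = ("recordings", "tuning", "geometry", "sweep", "criticality")

    def subseed(self, stage: str) -> int:
        """Stable per-stage sub-seed derived from the master seed."""
        idx = hash_stage(stage)
        return int(
            np.random.SeedSequence(self.master_seed, spawn_key=(idx,)).generate_state(1)[0]
            % (2**31 - 1)
        )


def hash_stage(stage: str) -> int:
    return sum(ord(c) * (i + 1) for i, c in enumerate(stage)) % 10007


_KNOWN_KEYS = {"scale", "master_seed", "outdir", "stages"}


def validate_config(cfg: dict | PipelineConfig) -> PipelineConfig:
    """Fill defaults, check ranges, and reject unknown keys."""
    if isinstance(cfg, PipelineConfig):
        cfg = asdict(cfg)
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    out = PipelineConfig(**cfg)
    if out.scale not in SCALE_PRESETS:
        raise ValueError(f"scale must be one of {sorted(SCALE_PRESETS)}")
    if not (0 <= out.master_seed < 2**31):
        raise ValueError("master_seed must be a nonnegative 31-bit integer")
    bad = set(out.stages) - set(PipelineConfig().stages)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    return out


@dataclass
class Report:
    config: PipelineConfig
    tables: dict[str, pd.DataFrame]
    summary: dict

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        provenance = {"master_seed": self.config.master_seed, "scale": self.config.scale, "sources": {}}
        for name, df in self.tables.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False, float_format="%.10g")
            provenance["sources"][name] = path.name
        payload = {"summary": self.summary, "provenance": provenance}
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(payload, indent=2, default=float))
        return report_path


def _two_region_tables(preset: dict, seed: int) -> dict[str, synth.RecordingTable]:
    """A sparsely-interconnected (TEO-like) and a densely-interconnected
    (TEa-like) synthetic population over the same stimulus design."""
    design = synth.make_stimulus_design()
    common = dict(
        n_neurons=preset["n_neurons"], gain_ratio=3.0, exemplar_sd=0.15,
        view_sd=0.1, noise_sd=0.2, preferred_category="animal",
    )
    return {
        "TEO_like": synth.generate_population(
            synth.PopulationSpec(shared_factor_weight=0.1, seed=seed, **common), design
        ),
        "TEa_like": synth.generate_population(
            synth.PopulationSpec(shared_factor_weight=0.8, seed=seed + 1, **common), design
        ),
    }


def run_pipeline(cfg: dict | PipelineConfig) -> Report:
    """Execute the enabled stages in dependency order and write the report."""
    cfg = validate_config(cfg)
    preset = SCALE_PRESETS[cfg.scale]
    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {}

    recordings = None
    if {"recordings", "tuning", "geometry"} & set(cfg.stages):
        log.info("stage recordings: generating two-region synthetic tables")
        recordings = _two_region_tables(preset, cfg.subseed("recordings"))

    if "tuning" in cfg.stages:
        log.info("stage tuning")
        rows = []
        for region, rec in recordings.items():
            sel = tuning.select_category_responsive(rec)
            if "animal" in sel:
                cat, ids = "animal", sel["animal"]
            elif sel:
                cat = max(sel, key=lambda c: len(sel[c]))
                ids = sel[cat]
            else:
                # densely pooled populations can flatten every tuning ratio
                # below the selection threshold; fall back to the whole
                # population scored against the animal category
                cat, ids = "animal", np.arange(rec.n_neurons)
            seed = cfg.subseed("tuning")
            rsa = tuning.rsa_scores(rec, ids, cat, seed=seed)
            rows.append(
                dict(
                    region=region, category=cat, n_selected=len(ids),
                    specificity=tuning.specificity_score(rec, ids, cat, seed=seed),
                    gen_exemplar=tuning.generalization_score(rec, ids, cat, "exemplar", seed=seed),
                    gen_view=tuning.generalization_score(rec, ids, cat, "view", seed=seed),
                    gen_sd=tuning.generalization_sd(rec, ids, cat),
                    rsa_between=rsa.between_category_similarity,
                    rsa_within_exemplar=rsa.within_exemplar_similarity,
                    rsa_within_view=rsa.within_view_similarity,
                )
            )
        tables["tuning"] = pd.DataFrame(rows)

    if "geometry" in cfg.stages:
        log.info("stage geometry")
        gcfg = geometry.ManifoldGeometryConfig(
            n_neurons_per_draw=preset["geometry_neurons"],
            n_repeats=preset["geometry_repeats"],
            n_probes=200,
            seed=cfg.subseed("geometry"),
        )
        rows = []
        for region, rec in recordings.items():
            res = geometry.region_geometry(rec, gcfg)
            rows.append(dict(region=region, dimension=res.mean_dimension, radius=res.mean_radius))
        tables["geometry"] = pd.DataFrame(rows)

    sweep_df = None
    if "sweep" in cfg.stages:
        log.info("stage sweep: lambda grid %s", preset["sweep_lams"])
        sweep_df = lattice.lambda_sweep(
            preset["sweep_lams"],
            height=preset["lattice"],
            width=preset["lattice"],
            n_repeats=preset["sweep_repeats"],
            n_steps=preset["n_steps"],
            seed=cfg.subseed("sweep"),
        )
        tables["sweep"] = sweep_df
        agg = sweep_df.groupby("lam")[["specificity", "generalization", "dimension", "radius"]].mean()
        bal = tuning.balance_score(
            agg["specificity"].to_numpy(), agg["generalization"].to_numpy(), agg.index.to_numpy()
        )
        tables["balance"] = pd.DataFrame(
            dict(lam=agg.index, norm_specificity=bal.normalized_specificity,
                 norm_generalization=bal.normalized_generalization, balance=bal.balance)
        )
        summary["balance_peak_lambda"] = float(agg.index[np.argmax(bal.balance)])

    if "criticality" in cfg.stages:
        log.info("stage criticality")
        side = preset["lattice"]
        patterns = synth.generate_lattice_patterns(side, side)
        seed = cfg.subseed("criticality")
        rows = []
        lams = (0.0, 0.05, 0.1)
        for k, lam in enumerate(lams):
            cfgl = lattice.LatticeConfig(
                height=side, width=side, lam=lattice.scale_lambda(lam, side), seed=seed + k
            )
            coupling = lattice.build_coupling(cfgl, patterns)
            h_rest = float(np.mean([
                ising.resting_hamiltonian(
                    lattice.resting_state_run(
                        coupling, n_steps=preset["resting_steps"],
                        seed=seed + 10 + k + 991 * r, patterns=patterns,
                    ).states,
                    side, side,
                )
                for r in range(3)
            ]))
            rows.append(dict(lam=lam, resting_hamiltonian=h_rest))
        icfg = ising.IsingConfig(
            L=side,
            temperatures=np.linspace(0.5, 6.0, preset["ising_nT"]),
            n_equil=preset["ising_steps"][0],
            n_sample=preset["ising_steps"][1],
            n_replicates=3,
            seed=seed + 100,
        )
        sweep = ising.temperature_sweep(icfg)
        for row in rows:
            rep = ising.criticality_report(row["resting_hamiltonian"], sweep)
            row["regime"] = rep.regime
        tables["criticality"] = pd.DataFrame(rows)
        summary["ising_t_c"] = sweep.t_c
        summary["ising_h_c"] = sweep.h_c

    report = Report(cfg, tables, summary)
    report.write(cfg.outdir)
    return report
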