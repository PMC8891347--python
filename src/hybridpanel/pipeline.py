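"""End-to-end pipeline: design -> simulate -> assign -> evaluate -> cohort.

A :class:`RunConfig` captures every knob; :func:`run_pipeline` executes the
stages on a synthetic reference dataset and writes a TSV/JSON artifact
bundle, with every output stamped with the seed and a hash of the
configuration. All randomness is derived from the single global seed, so a
rerun with the same config is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .assign import assign_gibbs, assign_plugin, estimate_reference_frequencies
from .crosses import CLASSES
from .design import FilterConfig, design_panel, model_primer_dropout
from .evaluate import confusion_matrix, error_rates, power_curves
from .synthetic import PopulationModel, simulate_cohort, simulate_rad_dataset

logger = logging.getLogger("hybridpanel")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 1
    outdir: str = "hybridpanel_run"
    model: PopulationModel = field(default_factory=PopulationModel)
    filters: FilterConfig = field(default_factory=FilterConfig)
    #: deployed panel size after modelled primer dropout
    final_panel_size: int = 342
    #: individuals per class for the design-stage informativeness check
    design_sim_n: int = 1000
    #: individuals per class for the performance evaluation
    eval_sim_n: int = 100
    assignment_mode: str = "plugin"
    n_burnin: int = 10_000
    n_sweeps: int = 50_000
    pseudocount: float = 0.5

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d and isinstance(d["model"], dict):
            m = dict(d["model"])
            if "ancestral_freq_range" in m:
                m["ancestral_freq_range"] = tuple(m["ancestral_freq_range"])
            d["model"] = PopulationModel(**m)
        if "filters" in d and isinstance(d["filters"], dict):
            f = dict(d["filters"])
            if "position_window" in f:
                f["position_window"] = tuple(f["position_window"])
            d["filters"] = FilterConfig(**f)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # hash the scientific configuration, not paths
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stamp(self) -> str:
        return f"seed={self.seed} config={self.config_hash()}"


def _write_df(df, path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        df.to_csv(fh, sep="\t", index=True)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full workflow and return the artifact paths."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = config.stamp()
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31)
    artifacts: dict[str, Path] = {}

    # 1. synthetic reference data
    model = dataclasses.replace(config.model, seed=int(seeds[0]))
    panel, records = simulate_rad_dataset(model)
    logger.info("simulated reference panel: %d loci", panel.n_loci)
    hio.write_reference_panel(
        panel, out / "reference.vcf", out / "loci.tsv", out / "popmap.tsv", stamp=stamp
    )
    artifacts["reference_vcf"] = out / "reference.vcf"

    # 2. panel design
    candidates, report, stats = design_panel(panel, config.filters)
    logger.info(
        "filter chain: %s",
        "; ".join(f"{s['stage']}={s['n_survived']}" for s in report.stages),
    )
    deployed, report = model_primer_dropout(
        candidates,
        "random_subset",
        {"k": min(config.final_panel_size, len(candidates))},
        seed=int(seeds[1]),
        report=report,
    )
    deployed = deployed.sort_values("theta", ascending=False, kind="mergesort")
    _write_df(report.to_frame().set_index("stage"), out / "filter_report.tsv", stamp)
    _write_df(deployed[["theta"]], out / "panel.tsv", stamp)
    artifacts["panel"] = out / "panel.tsv"
    artifacts["filter_report"] = out / "filter_report.tsv"

    # 3. reference frequencies restricted to the deployed panel
    sub = panel.subset_loci(list(deployed.index))
    freqs = estimate_reference_frequencies(sub, config.pseudocount)

    # 4. design-stage simulation + assignment
    counts = {c: config.design_sim_n for c in CLASSES}
    sim, labels = simulate_cohort(
        freqs.p0, freqs.p1, counts, seed=int(seeds[2]), loci=list(deployed.index)
    )
    assigned = _assign(sim, sub, freqs, config, int(seeds[3]))
    conf = confusion_matrix(labels, assigned["assigned_class"])
    _write_df(conf, out / "confusion_design.tsv", stamp)
    artifacts["confusion_design"] = out / "confusion_design.tsv"

    # 5. performance evaluation (accuracy / efficiency / power, error rates)
    counts = {c: config.eval_sim_n for c in CLASSES}
    sim_eval, labels_eval = simulate_cohort(
        freqs.p0, freqs.p1, counts, seed=int(seeds[4]), loci=list(deployed.index)
    )
    assigned_eval = _assign(sim_eval, sub, freqs, config, int(seeds[5]))
    curves = power_curves(assigned_eval, labels_eval)
    t1, t2 = error_rates(assigned_eval["assigned_class"], labels_eval)
    _write_df(curves.set_index(["threshold", "class"]), out / "power_curves.tsv", stamp)
    with open(out / "error_rates.json", "w") as fh:
        json.dump({"type_I": t1, "type_II": t2, "stamp": stamp}, fh, indent=1)
    artifacts["power_curves"] = out / "power_curves.tsv"
    artifacts["error_rates"] = out / "error_rates.json"

    # 6. cohort application demo: posteriors table for the evaluation cohort
    _write_df(assigned_eval.set_index("individual"), out / "posteriors.tsv", stamp)
    artifacts["posteriors"] = out / "posteriors.tsv"

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(
            {
                "stamp": stamp,
                "seed": config.seed,
                "config": json.loads(json.dumps(config.to_dict(), default=str)),
                "stages": report.stages,
                "panel_size": int(len(deployed)),
            },
            fh,
            indent=1,
        )
    artifacts["manifest"] = out / "run_manifest.json"
    return artifacts


def _assign(sim, ref_subpanel, freqs, config: RunConfig, seed: int):
    if config.assignment_mode == "plugin":
        return assign_plugin(sim, freqs)
    if config.assignment_mode == "gibbs":
        return assign_gibbs(
            sim,
            ref_subpanel,
            n_burnin=config.n_burnin,
            n_sweeps=config.n_sweeps,
            seed=seed,
            pseudocount=config.pseudocount,
        )
    raise ValueError(f"unknown assignment mode {config.assignment_mode!r}")
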