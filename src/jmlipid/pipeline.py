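"""End-to-end per-receptor workflow and run manifest.

For every receptor the pipeline builds the TM-JM model, lays out the
protein footprint, runs the configured number of seeded replicates,
computes contact matrices, summary statistics, RDF profiles and density
maps, and finally aggregates family-level outputs (positional profiles,
residue probabilities, clustering propensities and their correlation with
net JM charge). Every stochastic output is traceable to a recorded seed in
the run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .contacts import AnalysisConfig, contact_summary, count_contacts, mean_contacts
from .errors import ConfigError, JMLipidError
from .family import (
    PropensityRecord,
    build_family_profile,
    charge_propensity_correlation,
    clustering_propensity,
)
from .io import (
    sha256_file,
    write_contact_matrix,
    write_density_csv,
    write_pwm,
    write_rdf_csv,
    write_trajectory_npz,
)
from .membrane import SPECIES_REGISTRY, LeafletComposition
from .residues import TMJMModel
from .simulate import SimulationConfig, simulate_replicates
from .spatial import density_map, lateral_rdf
from .trajectory import place_protein
from .io import read_receptor_table

logger = logging.getLogger("jmlipid")


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seeds: dict[str, list[int]]  # receptor_id -> per-replicate seeds
    input_hashes: dict[str, str]
    stages: list[str]
    outputs: list[str]
    package_version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path


_DEFAULT_ANALYSIS = {"cutoff": 6.0, "bin_width": 1.0, "r_max": 30.0,
                     "species": ["PIP2", "PS", "PC"], "density_cell": 1.0}
_SIM_KEYS = {"box_edge", "n_lipids", "timestep", "n_frames", "save_stride",
             "n_equil_steps", "kT", "debye_length", "epsilon_elec", "seed"}


def _validate_config(cfg: Mapping[str, Any]) -> dict:
    cfg = dict(cfg)
    for key in ("receptors", "composition", "output_dir"):
        if key not in cfg:
            raise ConfigError(f"config is missing required section {key!r}")
    comp = cfg["composition"]
    for name in comp:
        if name not in SPECIES_REGISTRY:
            raise ConfigError(
                f"unknown species {name!r} in composition; "
                f"known: {sorted(SPECIES_REGISTRY)}"
            )
    analysis = {**_DEFAULT_ANALYSIS, **cfg.get("analysis", {})}
    for name in analysis["species"]:
        if name not in SPECIES_REGISTRY:
            raise ConfigError(f"unknown species {name!r} in analysis.species")
        if name not in comp:
            raise ConfigError(f"analysis species {name!r} absent from composition")
    cfg["analysis"] = analysis
    sim = dict(cfg.get("simulation", {}))
    cfg["replicates"] = int(sim.pop("replicates", 3))
    unknown = set(sim) - _SIM_KEYS
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    cfg["simulation"] = sim
    return cfg


def run_pipeline(config: str | Path | Mapping[str, Any]) -> RunManifest:
    """Run the full analysis described by a structured config.

    ``config`` is a YAML file path or an equivalent mapping. Any stage
    failure aborts with the stage name and receptor id; outputs written
    before the failure are retained.
    """
    input_hashes: dict[str, str] = {}
    if isinstance(config, (str, Path)):
        cfg_path = Path(config)
        cfg_raw = yaml.safe_load(cfg_path.read_text())
        input_hashes[str(cfg_path)] = sha256_file(cfg_path)
    else:
        cfg_raw = dict(config)
    cfg = _validate_config(cfg_raw)

    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    composition = LeafletComposition(cfg["composition"])
    sim_config = SimulationConfig(**cfg["simulation"])
    analysis = cfg["analysis"]
    acfg = AnalysisConfig(contact_cutoff=analysis["cutoff"])
    n_rep = cfg["replicates"]
    write_traj = bool(cfg.get("write_trajectories", False))

    receptors_cfg = cfg["receptors"]
    models: list[TMJMModel] = []
    if isinstance(receptors_cfg, Mapping) and "fasta" in receptors_cfg:
        fasta = Path(receptors_cfg["fasta"])
        annot = Path(receptors_cfg["annotations"])
        input_hashes[str(fasta)] = sha256_file(fasta)
        input_hashes[str(annot)] = sha256_file(annot)
        models = read_receptor_table(
            fasta, annot, jm_length=int(receptors_cfg.get("jm_length", 20))
        )
    else:
        raise ConfigError("receptors section must supply 'fasta' and 'annotations'")
    if not models:
        raise ConfigError("no usable receptors after JM extraction")

    manifest = RunManifest(
        config=cfg, seeds={}, input_hashes=input_hashes, stages=[], outputs=[],
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    records: list[PropensityRecord] = []
    jm_sequences: list[str] = []
    mean_profiles: dict[str, list[np.ndarray]] = {sp: [] for sp in analysis["species"]}

    for model in models:
        rid = model.receptor_id
        stage = "simulate"
        try:
            anchors = place_protein(model, sim_config.box_edge)
            logger.info("simulating %s (%d replicates, seed %d)",
                        rid, n_rep, sim_config.seed)
            trajs = simulate_replicates(anchors, composition, sim_config, n_rep)
            manifest.seeds[rid] = [t.seed for t in trajs]
            manifest.stages.append(f"simulate:{rid}")
            rec_dir = out_dir / rid
            rec_dir.mkdir(exist_ok=True)
            if write_traj:
                for t in trajs:
                    p = write_trajectory_npz(t, rec_dir / f"replicate{t.replicate_id}.npz")
                    manifest.outputs.append(str(p))

            stage = "contacts"
            summary = contact_summary(trajs, analysis["species"], acfg)
            p = rec_dir / "contact_summary.csv"
            summary.to_csv(p, index=False)
            manifest.outputs.append(str(p))
            for sp in analysis["species"]:
                cm = count_contacts(trajs, sp, acfg)
                manifest.outputs.append(
                    str(write_contact_matrix(cm, rec_dir / f"contacts_{sp}.csv"))
                )
                mc = mean_contacts(cm)
                jm_mask = [lb != "TM" for lb in cm.residues]
                mean_profiles[sp].append(mc.values[jm_mask])

            stage = "rdf"
            for sp in analysis["species"]:
                rdf = lateral_rdf(trajs, sp, analysis["bin_width"], analysis["r_max"])
                manifest.outputs.append(
                    str(write_rdf_csv(rdf, rec_dir / f"rdf_{sp}.csv"))
                )

            stage = "density"
            for sp in analysis["species"]:
                dmap = density_map(trajs, sp, analysis["density_cell"])
                manifest.outputs.append(
                    str(write_density_csv(dmap, rec_dir / f"densmap_{sp}.csv"))
                )

            stage = "propensity"
            for sp in analysis["species"]:
                records.append(
                    PropensityRecord(
                        receptor_id=rid, species=sp,
                        propensity=clustering_propensity(
                            trajs, sp, composition, analysis["cutoff"]
                        ),
                        net_jm_charge=model.net_jm_charge,
                    )
                )
            jm_sequences.append(model.jm_sequence)
            manifest.stages.append(f"analyse:{rid}")
        except JMLipidError as exc:
            manifest.write(out_dir / "manifest.json")
            raise JMLipidError(
                f"stage {stage!r} failed for receptor {rid!r}: {exc}"
            ) from exc

    # Family-level outputs.
    profile = build_family_profile(jm_sequences, mean_profiles)
    p = out_dir / "family_mean_contacts.csv"
    profile.mean_contacts.to_csv(p, index_label="jm_position")
    manifest.outputs.append(str(p))
    p = out_dir / "family_class_probability.csv"
    profile.class_probability.to_csv(p, index_label="jm_position")
    manifest.outputs.append(str(p))
    manifest.outputs.append(str(write_pwm(profile.aa_frequency, out_dir / "family_pwm.txt")))

    import pandas as pd

    prop_df = pd.DataFrame([asdict(r) for r in records])
    p = out_dir / "propensity.csv"
    prop_df.to_csv(p, index=False)
    manifest.outputs.append(str(p))

    corr_out: dict[str, Any] = {}
    for sp in analysis["species"]:
        try:
            res = charge_propensity_correlation(records, sp)
            corr_out[sp] = asdict(res)
        except JMLipidError as exc:
            corr_out[sp] = {"skipped": str(exc)}
    p = out_dir / "correlation.json"
    p.write_text(json.dumps(corr_out, indent=2) + "\n")
    manifest.outputs.append(str(p))
    manifest.stages.append("aggregate")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "manifest.json")
    logger.info("pipeline finished: %d receptors, outputs in %s", len(models), out_dir)
    return manifest
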