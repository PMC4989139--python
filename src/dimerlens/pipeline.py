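"""End-to-end orchestration: generate/load -> kinetics -> orientation ->
contacts -> lipid environment -> interface score, with a reproducibility
manifest.

Each stage is a pure function of (trajectory, topology, configuration);
outputs are TSV matrices and JSON summaries written under one output
directory, and the manifest records the seed, configuration and SHA-256
hash of every input and output so a rerun can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig
from .contacts import (
    helix_interface_probability,
    stable_contact_map,
    transient_contact_map,
)
from .kinetics import (
    RegimeSegmentation,
    count_dissociations,
    distance_heatmap,
    distance_series,
    segment_regimes,
)
from .lipids import average_profiles, residue_occupancy, thickness_map
from .orientation import (
    assign_conformer,
    default_regions,
    orientation_density,
    orientation_series,
)
from .score import helix_occupancy, interface_occupancy_matrix
from .synthetic import PlantedScenario, generate_trajectory, gro_skeleton, reference_scenarios
from .tabular import write_matrix
from .topology import SystemTopology, read_topology, write_topology
from .trajectory import Trajectory, read_gro, write_gro

__all__ = ["RunManifest", "PipelineError", "run_pipeline", "load_inputs"]

log = logging.getLogger("dimerlens")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    seed: int
    config: dict
    config_hash: str
    input_hashes: dict[str, str]
    outputs: dict[str, list[str]]
    output_hashes: dict[str, str]
    version: str = __version__
    started: str = ""
    finished: str = ""

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(
    traj_path: str | Path, top_path: str | Path, composition: float = 0.0
) -> tuple[Trajectory, SystemTopology]:
    topology = read_topology(top_path)
    _, frames = read_gro(traj_path)
    traj = Trajectory.from_frames(
        frames, label=Path(traj_path).stem, composition=composition
    )
    if traj.n_beads != topology.n_beads:
        raise PipelineError(
            f"trajectory has {traj.n_beads} beads but topology {topology.n_beads}"
        )
    return traj, topology


# -- stages ------------------------------------------------------------


def kinetics_stage(
    traj: Trajectory,
    top: SystemTopology,
    cfg: AnalysisConfig,
    out: Path,
) -> tuple[RegimeSegmentation, list[Path]]:
    series = distance_series(traj, top)
    seg = segment_regimes(series, cfg)
    meta = {"config": cfg.to_dict(), "label": traj.label}
    paths = []
    df = pd.DataFrame({"time_ns": series.times, "min_distance_nm": series.min_distance})
    p = out / "min_distance.tsv"
    df.to_csv(p, sep="\t", index=False)
    paths.append(p)
    iv = pd.DataFrame(seg.intervals, columns=["start", "end", "label"])
    classes = {idx: cls for idx, cls in seg.dimer_events}
    iv["class"] = [classes.get(i, "") for i in range(len(iv))]
    p = out / "regime_intervals.tsv"
    iv.to_csv(p, sep="\t", index=False)
    paths.append(p)
    events = {
        "dissociations": count_dissociations([seg]),
        "n_stable": len(seg.dimer_intervals("stable")),
        "n_transient": len(seg.dimer_intervals("transient")),
        "config": cfg.to_dict(),
    }
    p = out / "dimer_events.json"
    p.write_text(json.dumps(events, indent=1, sort_keys=True))
    paths.append(p)
    p = out / "distance_heatmap.tsv"
    write_matrix(distance_heatmap([series]), p, metadata=meta)
    paths.append(p)
    return seg, paths


def orientation_stage(
    traj: Trajectory,
    top: SystemTopology,
    seg: RegimeSegmentation,
    cfg: AnalysisConfig,
    out: Path,
) -> list[Path]:
    series = orientation_series(traj, top, seg, cfg)
    paths = []
    df = pd.DataFrame(
        {"frame": series.frames, "theta1_deg": series.theta1, "theta2_deg": series.theta2}
    )
    p = out / "orientation_angles.tsv"
    df.to_csv(p, sep="\t", index=False)
    paths.append(p)
    density = orientation_density([series], cfg)
    p = out / "orientation_density.tsv"
    write_matrix(density, p, metadata={"config": cfg.to_dict()})
    paths.append(p)
    regions = default_regions()
    counts: dict[str, int] = {}
    for t1, t2 in zip(series.theta1, series.theta2):
        lab = assign_conformer(t1, t2, regions)
        counts[lab] = counts.get(lab, 0) + 1
    p = out / "conformer_counts.json"
    p.write_text(json.dumps(counts, indent=1, sort_keys=True))
    paths.append(p)
    return paths


def contacts_stage(
    traj: Trajectory,
    top: SystemTopology,
    seg: RegimeSegmentation,
    cfg: AnalysisConfig,
    out: Path,
) -> list[Path]:
    paths = []
    meta = {"config": cfg.to_dict(), "composition": traj.composition}
    for kind, fn in (("stable", stable_contact_map), ("transient", transient_contact_map)):
        if not seg.dimer_intervals(kind):
            log.info("contacts: no %s dimer events, map skipped", kind)
            continue
        cmap = fn([(traj, seg)], top, cfg)
        p = out / f"contact_map_{kind}.tsv"
        write_matrix(cmap.matrix, p, metadata={**meta, "kind": kind})
        paths.append(p)
        p = out / f"contact_map_{kind}_symmetrized.tsv"
        write_matrix(cmap.symmetrized(), p)
        paths.append(p)
        p = out / f"contact_map_{kind}_raw.tsv"
        write_matrix(cmap.raw, p)
        paths.append(p)
        if cmap.loop_contacts is not None and len(cmap.loop_contacts):
            p = out / f"loop_contacts_{kind}.tsv"
            cmap.loop_contacts.to_csv(p, sep="\t", index=False)
            paths.append(p)
    return paths


def environment_stage(
    traj: Trajectory,
    top: SystemTopology,
    seg: RegimeSegmentation,
    cfg: AnalysisConfig,
    out: Path,
) -> list[Path]:
    paths = []
    by_label = {"monomer": [], "dimer": []}
    for s, e, lab in seg.intervals:
        by_label[lab].append((s, e))
    kinds = [k for k in ("CHOL", "POPC") if top.lipid_molecules(k)]
    for kind in kinds:
        for regime, intervals in by_label.items():
            if not intervals:
                continue
            profs = [
                residue_occupancy(traj, top, intervals, kind, cfg, rid, regime)
                for rid in top.receptor_ids
            ]
            mean = average_profiles(profs)
            df = pd.DataFrame(
                {
                    "helix": [top.helix_of_residue(int(r)) for r in mean.values.index],
                    **{f"R{p.receptor_id}": p.values for p in profs},
                    "mean": mean.values,
                },
            )
            df.index.name = "residue_index"
            p = out / f"occupancy_{kind}_{regime}.tsv"
            write_matrix(df, p, metadata={"config": cfg.to_dict(), "lipid": kind})
            paths.append(p)
    if by_label["monomer"] and top.phosphate_indices().size:
        tmap = thickness_map(traj, top, by_label["monomer"], cfg, receptor_id=1)
        p = out / "thickness_map.tsv"
        write_matrix(
            tmap.grid,
            p,
            metadata={
                "config": cfg.to_dict(),
                "farfield_thickness_nm": tmap.farfield_thickness,
                "receptor_id": tmap.receptor_id,
            },
        )
        paths.append(p)
    return paths


def score_stage(
    traj: Trajectory,
    top: SystemTopology,
    seg: RegimeSegmentation,
    cfg: AnalysisConfig,
    out: Path,
) -> list[Path]:
    paths = []
    dimer = [(s, e) for s, e, lab in seg.intervals if lab == "dimer"]
    if not dimer or not seg.dimer_intervals("stable"):
        log.info("score: no stable dimer regime, stage skipped")
        return paths
    # per-event conformer summary: each stable event is one dimer
    # conformation; record its orientation, conformer label and its own
    # interface-probability vector so conformer-resolved scores can be
    # assembled post hoc
    regions = default_regions()
    by_event = []
    for s, e, _ in seg.dimer_intervals("stable"):
        mid = traj.frame((s + e) // 2)
        from .orientation import rotation_angle

        t1 = rotation_angle(mid, top, 1, cfg.angle_residues)
        t2 = rotation_angle(mid, top, 2, cfg.angle_residues)
        sub = RegimeSegmentation(
            intervals=[(s, e, "dimer")], dimer_events=[(0, "stable")]
        )
        prob = helix_interface_probability([(traj, sub)], top, cfg, kind="stable")
        by_event.append(
            {
                "start": s,
                "end": e,
                "theta1_deg": t1,
                "theta2_deg": t2,
                "conformer": assign_conformer(t1, t2, regions),
                "interface_probability": prob.round(6).to_dict(),
            }
        )
    p = out / "stable_event_conformers.json"
    p.write_text(json.dumps(by_event, indent=1, sort_keys=True))
    paths.append(p)

    kinds = [k for k in ("CHOL", "POPC") if top.lipid_molecules(k)]
    for kind in kinds:
        per_receptor = []
        for rid in top.receptor_ids:
            prof = residue_occupancy(traj, top, dimer, kind, cfg, rid, "dimer")
            occ = helix_occupancy(prof, top)
            prob = helix_interface_probability(
                [(traj, seg)], top, cfg, kind="stable", receptor=rid
            )
            m = interface_occupancy_matrix(occ, prob, cfg, kind, traj.composition)
            per_receptor.append(m)
            p = out / f"interface_score_{kind}_R{rid}.tsv"
            write_matrix(
                m.matrix,
                p,
                metadata={
                    "config": cfg.to_dict(),
                    "lipid": kind,
                    "receptor": rid,
                    "composition": traj.composition,
                },
            )
            paths.append(p)
        mean = sum(m.matrix for m in per_receptor) / len(per_receptor)
        p = out / f"interface_score_{kind}.tsv"
        write_matrix(mean, p, metadata={"config": cfg.to_dict(), "lipid": kind})
        paths.append(p)
    return paths


# -- orchestration -----------------------------------------------------


def _resolve_scenario(spec) -> PlantedScenario:
    if isinstance(spec, str):
        for sc in reference_scenarios():
            if sc.name == spec:
                return sc
        raise PipelineError(f"unknown reference scenario {spec!r}")
    return PlantedScenario.from_dict(spec)


def run_pipeline(
    config: str | Path | dict, out_dir: str | Path | None = None
) -> RunManifest:
    """Run every applicable stage and write a reproducibility manifest.

    ``config`` is a YAML file (or dict) with either a ``scenario`` key (a
    packaged scenario name or an inline scenario description) or an
    ``inputs`` key (``trajectory``/``topology`` paths and optionally
    ``composition``), plus an optional ``analysis`` block of
    :class:`AnalysisConfig` overrides and an ``out_dir``.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise PipelineError("pipeline config must be a mapping")
    cfg = AnalysisConfig.from_dict(config.get("analysis", {}))
    out = Path(out_dir or config.get("out_dir", "dimerlens_run"))
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    input_hashes: dict[str, str] = {}
    outputs: dict[str, list[str]] = {}
    try:
        if "scenario" in config:
            scenario = _resolve_scenario(config["scenario"])
            log.info("stage generate: scenario %s", scenario.name)
            t0 = time.time()
            traj, top, truth = generate_trajectory(scenario, cfg)
            gen_paths = []
            p = out / "trajectory.gro"
            write_gro(traj, gro_skeleton(top), p, title=scenario.name)
            gen_paths.append(p)
            p = out / "topology.tsv"
            write_topology(top, p)
            gen_paths.append(p)
            p = out / "ground_truth.json"
            p.write_text(json.dumps(truth, indent=1, sort_keys=True))
            gen_paths.append(p)
            p = out / "scenario.yaml"
            scenario.to_yaml(p)
            gen_paths.append(p)
            outputs["generate"] = [str(q) for q in gen_paths]
            seed = scenario.seed
            log.info("stage generate done in %.1fs", time.time() - t0)
        elif "inputs" in config:
            inp = config["inputs"]
            for key in ("trajectory", "topology"):
                if key not in inp or not Path(inp[key]).exists():
                    raise PipelineError(f"missing input file for {key!r}")
                input_hashes[inp[key]] = _sha256(Path(inp[key]))
            traj, top = load_inputs(
                inp["trajectory"], inp["topology"], inp.get("composition", 0.0)
            )
            seed = cfg.seed
        else:
            raise PipelineError("config needs either a 'scenario' or an 'inputs' block")

        stages = [
            ("kinetics", None),
            ("orientation", orientation_stage),
            ("contacts", contacts_stage),
            ("environment", environment_stage),
        ]
        t0 = time.time()
        seg, paths = kinetics_stage(traj, top, cfg, out)
        outputs["kinetics"] = [str(p) for p in paths]
        log.info("stage kinetics done in %.1fs (%d intervals)", time.time() - t0,
                 len(seg.intervals))
        for name, fn in stages[1:]:
            t0 = time.time()
            paths = fn(traj, top, seg, cfg, out)
            outputs[name] = [str(p) for p in paths]
            log.info("stage %s done in %.1fs (%d files)", name, time.time() - t0,
                     len(paths))
        if traj.composition > 0:
            t0 = time.time()
            paths = score_stage(traj, top, seg, cfg, out)
            outputs["score"] = [str(p) for p in paths]
            log.info("stage score done in %.1fs", time.time() - t0)
        else:
            log.info("stage score skipped: no cholesterol in this composition")
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest = RunManifest(
        seed=seed,
        config={"analysis": cfg.to_dict(), **{k: v for k, v in config.items() if k != "analysis"}},
        config_hash=hashlib.sha256(cfg.to_json().encode()).hexdigest(),
        input_hashes=input_hashes,
        outputs=outputs,
        output_hashes={
            path: _sha256(Path(path)) for paths in outputs.values() for path in paths
        },
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    return manifest
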