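"""Config-driven pipeline chaining all analysis stages.

A single YAML config describes the input (a visitation CSV or a simulate
block), the master seed, and per-stage settings.  Stages run in order
(summary -> composition -> null_sharing -> modules -> roles -> mueller),
write plain CSV/TSV outputs, and a JSON manifest records input digests, the
config snapshot, per-stage derived seeds and output paths so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .composition import dissimilarity_matrix, permanova
from .modularity import meta_optimize
from .mueller import influence_summary, mueller_matrix
from .network import (
    InteractionNetwork,
    pool_records,
    read_annotations,
    read_visitation_records,
    write_matrix_tsv,
)
from .roles import classify_roles, cz_values, role_thresholds, roles_to_frame
from .seeds import derive_seed
from .sharing import envelopes_to_frame, null_sharing_envelope
from .synthetic import SyntheticConfig, generate_modular, generate_neutral

log = logging.getLogger("pollinet")

STAGE_ORDER = ("summary", "composition", "null_sharing", "modules", "roles", "mueller")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    package_version: str
    master_seed: int
    config: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seeds: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, list[str]] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_input(cfg: dict, master_seed: int, manifest: RunManifest) -> InteractionNetwork:
    inp = cfg.get("input", {})
    plant_groups = {}
    poll_groups = {}
    for key, target in (("plant_groups", plant_groups),
                        ("pollinator_groups", poll_groups)):
        if inp.get(key):
            p = Path(inp[key])
            manifest.input_digests[str(p)] = _digest(p)
            target.update(read_annotations(p))
    if "records" in inp and inp["records"]:
        p = Path(inp["records"])
        manifest.input_digests[str(p)] = _digest(p)
        records = read_visitation_records(p)
    elif "simulate" in inp:
        sim = dict(inp["simulate"])
        mode = sim.pop("mode", "neutral")
        config = SyntheticConfig(
            n_plants=sim.get("plants", 40),
            n_pollinators=sim.get("pollinators", 60),
            n_modules=sim.get("modules", 4),
            affinity=sim.get("affinity", 0.95),
            abundance_sigma=sim.get("sigma", 1.0),
            total_visits=sim.get("visits", 2000),
            seed=derive_seed(master_seed, "simulate"),
        )
        gen = generate_modular if mode == "modular" else generate_neutral
        records, gt = gen(config)
        if not plant_groups:
            plant_groups.update(
                {p: f"block_{m}" for p, m in gt.plant_modules.items()}
            )
        if not poll_groups:
            poll_groups.update(
                {k: f"block_{m}" for k, m in gt.pollinator_modules.items()}
            )
    else:
        raise PipelineError("input", "config needs input.records or input.simulate")
    return pool_records(records, plant_groups, poll_groups)


def run_pipeline(config, output_dir=None) -> RunManifest:
    """Execute the enabled stages of a config (path, YAML string or dict)."""
    if isinstance(config, (str, Path)) and Path(str(config)).exists():
        cfg = yaml.safe_load(Path(config).read_text())
    elif isinstance(config, str):
        cfg = yaml.safe_load(config)
    else:
        cfg = dict(config)
    master_seed = int(cfg.get("master_seed", 0))
    out = Path(output_dir or cfg.get("output_dir", "results/run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        package_version=__version__, master_seed=master_seed, config=cfg
    )
    stages_cfg = cfg.get("stages", {})

    def enabled(stage: str) -> bool:
        sc = stages_cfg.get(stage, {})
        return bool(sc.get("enabled", True))

    def opts(stage: str) -> dict:
        return {k: v for k, v in stages_cfg.get(stage, {}).items() if k != "enabled"}

    try:
        net = _load_input(cfg, master_seed, manifest)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError("input", str(e)) from e
    write_matrix_tsv(net, out / "network.tsv")
    manifest.outputs["input"] = [str(out / "network.tsv")]

    partition = None
    for stage in STAGE_ORDER:
        if not enabled(stage):
            continue
        seed = derive_seed(master_seed, stage)
        manifest.stage_seeds[stage] = seed
        log.info("stage %s starting (seed %d)", stage, seed)
        try:
            if stage == "summary":
                from .network import network_summary

                rep = network_summary(net)
                paths = []
                for name, df in (
                    ("plant_shares", rep.plant_shares),
                    ("pollinator_shares", rep.pollinator_shares),
                    ("plant_group_shares", rep.plant_group_shares),
                    ("pollinator_group_shares", rep.pollinator_group_shares),
                ):
                    p = out / f"summary_{name}.csv"
                    df.to_csv(p, index=False)
                    paths.append(str(p))
                manifest.outputs[stage] = paths
            elif stage == "composition":
                o = opts(stage)
                dm = dissimilarity_matrix(net, o.get("level", "plants"))
                p = out / "braycurtis_plants.tsv"
                dm.to_data_frame().to_csv(p, sep="\t")
                groups = [net.plant_groups[x] for x in net.plant_labels]
                manifest.outputs[stage] = [str(p)]
                if len(set(groups)) >= 2:
                    res = permanova(dm, groups, n_perm=o.get("n_perm", 999), seed=seed)
                    (out / "permanova.csv").write_text(
                        "pseudo_F,p_value,n_permutations\n"
                        f"{res.pseudo_f},{res.p_value},{res.n_permutations}\n"
                    )
                    manifest.outputs[stage].append(str(out / "permanova.csv"))
            elif stage == "null_sharing":
                o = opts(stage)
                focal = o.get("focal")
                if focal in (None, "top"):
                    focal = net.plant_labels[int(net.row_totals.argmax())]
                env = null_sharing_envelope(
                    net, focal, n_rep=o.get("n_rep", 1000), seed=seed
                )
                p = out / "null_sharing.csv"
                envelopes_to_frame(env).to_csv(p, index=False)
                manifest.outputs[stage] = [str(p)]
            elif stage == "modules":
                o = opts(stage)
                partition = meta_optimize(
                    net, n_restarts=o.get("n_restarts", 10), seed=seed
                )
                p = out / "modules.csv"
                df = partition.to_frame()
                df.to_csv(p, index=False)
                (out / "modularity.csv").write_text(
                    f"Q,n_modules\n{partition.q},{partition.n_modules}\n"
                )
                manifest.outputs[stage] = [str(p), str(out / "modularity.csv")]
            elif stage == "roles":
                o = opts(stage)
                if partition is None:
                    partition = meta_optimize(
                        net, n_restarts=10, seed=derive_seed(master_seed, "modules")
                    )
                thr = role_thresholds(
                    net,
                    n_null=o.get("n_null", 1000),
                    quantile=o.get("quantile", 0.95),
                    seed=seed,
                    null_family=o.get("null_family", "patefield"),
                )
                roles = classify_roles(cz_values(net, partition), thr)
                p = out / "roles.csv"
                with open(p, "w") as fh:
                    fh.write(
                        f"# thresholds plants c={thr.plant_c:.4f} z={thr.plant_z:.4f}; "
                        f"pollinators c={thr.pollinator_c:.4f} z={thr.pollinator_z:.4f}; "
                        f"n_null={thr.n_null} quantile={thr.quantile}\n"
                    )
                    roles_to_frame(roles).to_csv(fh, index=False)
                manifest.outputs[stage] = [str(p)]
            elif stage == "mueller":
                paths = []
                for level in ("plants", "pollinators"):
                    M = mueller_matrix(net, level)
                    p = out / f"mueller_{level}.csv"
                    with open(p, "w") as fh:
                        fh.write("# rows = target species, columns = acting species\n")
                        M.to_frame().to_csv(fh)
                    ps = out / f"mueller_{level}_summary.csv"
                    influence_summary(M).to_csv(ps, index=False)
                    paths += [str(p), str(ps)]
                manifest.outputs[stage] = paths
        except PipelineError:
            raise
        except Exception as e:
            raise PipelineError(stage, str(e)) from e
        log.info("stage %s done", stage)

    manifest.write(out / "manifest.json")
    return manifest
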