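"""End-to-end study workflow from one TOML configuration.

A run is a grid of analysis cells named like ``CU``/``DF``: the first letter
picks the data set (``C`` = matrix with continuous characters as such,
``D`` = all-discrete variant) and the rest picks a named constraint level
(``U`` = unconstrained).  Each cell runs: range weighting, constrained
multi-start SPR/TBR search, strict consensus of the MPTs and of the
near-optimal pool, homoplasy indices, relative Bremer supports with
rogue-taxon pruning.  Across cells, representative MPTs are compared
pairwise with Templeton's test under each data set.

All randomness derives from the configured seed; re-running a config
reproduces every TSV/JSON output byte for byte.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .characters import CharacterMatrix
from .matrix_io import read_matrix, read_trees, write_trees
from .scoring import homoplasy_indices
from .search import (
    ConstraintScaffold,
    SearchError,
    collect_suboptimal,
    strict_consensus,
    tbr_search,
)
from .support import find_unstable_taxa, relative_bremer
from .templeton import pairwise_templeton
from .trees import PhyloTree
from .weighting import assign_range_weights

log = logging.getLogger("morphparsimony")

NEAR_OPTIMAL_EPSILON = 1.0  # "within one step" reporting threshold


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    out_dir: Path
    seed: int
    matrices: dict[str, Path]  # data-set letter -> matrix path
    constraints: dict[str, dict]  # level name -> {scaffold, outgroups}
    analyses: list[str]
    starts: int = 3
    epsilon: float = 1.0
    cap: int = 99999
    max_prune: int = 5
    base_dir: Path = Path(".")

    @staticmethod
    def from_toml(path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        try:
            run = raw["run"]
            matrices = {
                key[0].upper(): Path(val) for key, val in raw["matrices"].items()
            }
            constraints = raw.get("constraints", {})
            grid = raw["grid"]["analyses"]
            search = raw.get("search", {})
        except KeyError as exc:
            raise ConfigError(f"missing config section/key: {exc}") from None
        cfg = RunConfig(
            out_dir=Path(run["out_dir"]),
            seed=int(run.get("seed", 0)),
            matrices=matrices,
            constraints={k.upper(): v for k, v in constraints.items()},
            analyses=[a.upper() for a in grid],
            starts=int(search.get("starts", 3)),
            epsilon=float(search.get("epsilon", 1.0)),
            cap=int(search.get("cap", 99999)),
            max_prune=int(search.get("max_prune", 5)),
            base_dir=path.parent,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in self.analyses:
            if len(name) < 2:
                raise ConfigError(f"analysis name {name!r} too short")
            data, level = name[0], name[1:]
            if data not in self.matrices:
                raise ConfigError(f"analysis {name!r}: no matrix for data set {data!r}")
            if level != "U" and level not in self.constraints:
                raise ConfigError(f"analysis {name!r}: unknown constraint {level!r}")
        if len(set(self.analyses)) != len(self.analyses):
            raise ConfigError("duplicate analysis names")


def _resolve(path: Path, base: Path) -> Path:
    return path if path.is_absolute() else base / path


def _load_scaffold(
    cfg: RunConfig, level: str, matrix: CharacterMatrix
) -> ConstraintScaffold:
    if level == "U":
        return ConstraintScaffold.unconstrained(matrix.taxa)
    spec = cfg.constraints[level]
    scaffold_path = spec.get("scaffold", "none")
    outgroups = tuple(spec.get("outgroups", ()))
    if scaffold_path in ("none", "", None):
        return ConstraintScaffold.unconstrained(matrix.taxa, outgroups=outgroups)
    backbone = read_trees(_resolve(Path(scaffold_path), cfg.base_dir))[0]
    floaters_rule = spec.get("floaters", "auto")
    if floaters_rule == "auto":
        floaters = frozenset(matrix.taxa) - backbone.leaf_labels()
    else:
        floaters = frozenset(floaters_rule)
    return ConstraintScaffold(
        backbone=backbone, floaters=floaters, outgroups=outgroups
    )


def _run_cell(cfg: RunConfig, name: str, cell_seed: int, cell_dir: Path) -> dict:
    data_key, level = name[0], name[1:]
    matrix = read_matrix(_resolve(cfg.matrices[data_key], cfg.base_dir))
    matrix, weighting = assign_range_weights(matrix)
    scaffold = _load_scaffold(cfg, level, matrix)

    ensemble = tbr_search(
        matrix,
        scaffold,
        n_starts=cfg.starts,
        seed=cell_seed,
        epsilon=cfg.epsilon,
        cap=cfg.cap,
    )
    mpts = ensemble.mpts
    near = [
        t
        for t, ln in ensemble.trees
        if ln <= ensemble.best_length + NEAR_OPTIMAL_EPSILON + 1e-9
    ]
    consensus_mpt = strict_consensus(mpts)
    consensus_near = strict_consensus(near)
    score = homoplasy_indices(mpts[0], matrix)
    support = relative_bremer(ensemble, consensus_mpt)
    pruned = (
        find_unstable_taxa(ensemble, max_prune=cfg.max_prune)
        if len(ensemble.trees) >= 2
        else None
    )

    cell_dir.mkdir(parents=True, exist_ok=True)
    (cell_dir / "weighting.tsv").write_text(weighting.to_tsv())
    (cell_dir / "mpts.nwk").write_text(write_trees(mpts))
    (cell_dir / "pool.nwk").write_text(write_trees(ensemble.topologies()))
    (cell_dir / "consensus_mpt.nwk").write_text(write_trees([consensus_mpt]))
    (cell_dir / "consensus_near.nwk").write_text(write_trees([consensus_near]))
    (cell_dir / "consensus_support.nwk").write_text(
        write_trees([support.consensus], annotations=True)
    )
    (cell_dir / "score.json").write_text(score.to_json())
    (cell_dir / "support.tsv").write_text(support.to_tsv())
    if pruned is not None:
        lines = ["taxon\tresolution_gain"] + [
            f"{t}\t{g}" for t, g in pruned.pruned_taxa
        ]
        (cell_dir / "pruned_taxa.tsv").write_text("\n".join(lines) + "\n")

    summary = {
        "analysis": name,
        "n_mpts": len(mpts),
        "best_length": round(ensemble.best_length, 6),
        "n_within_1_step": len(near),
        "CI": round(score.ci, 4),
        "RI": round(score.ri, 4),
        "truncated": ensemble.truncated,
        "seed": cell_seed,
    }
    (cell_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_pipeline(config: str | Path | RunConfig) -> Path:
    """Execute the full analysis grid; returns the run directory."""
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_toml(config)
    out_dir = _resolve(cfg.out_dir, cfg.base_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summaries = []
    failures = {}
    representative: dict[str, PhyloTree] = {}
    for i, name in enumerate(cfg.analyses):
        cell_seed = (cfg.seed * 1000 + i) % (2**31 - 1)
        cell_dir = out_dir / name
        log.info("running analysis cell %s (seed %d)", name, cell_seed)
        try:
            summary = _run_cell(cfg, name, cell_seed, cell_dir)
        except Exception as exc:  # a failed cell must not sink the others
            log.error("cell %s failed: %s", name, exc)
            cell_dir.mkdir(parents=True, exist_ok=True)
            failures[name] = {"error": type(exc).__name__, "message": str(exc)}
            (cell_dir / "error.json").write_text(json.dumps(failures[name], indent=2))
            continue
        summaries.append(summary)
        representative[name] = read_trees(cell_dir / "mpts.nwk")[0]

    if summaries:
        import pandas as pd

        pd.DataFrame(summaries).to_csv(
            out_dir / "summary.tsv", sep="\t", index=False
        )

    # pairwise Templeton comparisons of representative MPTs under each data set
    for data_key, mpath in sorted(cfg.matrices.items()):
        if len(representative) < 2:
            continue
        matrix = read_matrix(_resolve(mpath, cfg.base_dir))
        matrix, _ = assign_range_weights(matrix)
        table = pairwise_templeton(matrix, representative)
        table.to_csv(
            out_dir / f"templeton_{data_key}.tsv", sep="\t", index=False,
            float_format="%.6g",
        )

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "analyses": cfg.analyses,
        "completed": [s["analysis"] for s in summaries],
        "failed": failures,
        "search": {
            "starts": cfg.starts,
            "epsilon": cfg.epsilon,
            "cap": cfg.cap,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
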