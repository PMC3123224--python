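"""End-to-end orchestration: census -> trees -> refinement -> sets -> reports.

``run_all`` wires the library stages together on one configuration and
writes every artifact (trees, traces, sets, indices, enrichment, clock) into
a run directory with a manifest recording the seed and a digest of the
configuration, so reruns with identical inputs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import census_io
from .ancestral_reconstruction import plesiomorphic_set, root_branch_changes
from .census_io import AbundanceMatrix, filter_proteomes
from .character_coding import recode, transpose_for_structure_tree
from .function_enrichment import FunctionMap, enrich, enrichment_table, function_diversity
from .iterative_refinement import run_refinement
from .parsimony_engine import SearchConfig, ci_ri, g1_skewness, lundberg_root, mp_search
from .synthetic_data import SimConfig, simulate
from .timeline_clock import compute_nd, fit_clock
from .urancestor_sets import (
    UrancestralSets,
    basal_set,
    classify_occurrence,
    inject_urancestor,
    occurrence_summary,
    popularity,
)


@dataclass
class PipelineConfig:
    """Inputs and knobs of one pipeline run.

    Either file paths (assignments + meta) or a simulation config must be
    given.  Numeric defaults are desk-scale; the published protocol used
    1,000 addition replicates, 30 chains and 50 iterations.
    """

    assignments: Optional[str] = None
    meta: Optional[str] = None
    fmap: Optional[str] = None
    calibrations: Optional[str] = None
    sim: Optional[SimConfig] = None
    evalue_cutoff: float = 1e-4
    lifestyles: tuple[str, ...] = ("FL",)
    n_states: int = 24
    scale: str = "linear"
    n_addition_replicates: int = 2
    swap: str = "NNI"
    n_chains: int = 3
    n_iter: int = 10
    bootstrap_reps: int = 0
    g1_random_trees: int = 200
    seed: int = 0
    outdir: str = "run"

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _load_inputs(cfg: PipelineConfig) -> AbundanceMatrix:
    if cfg.sim is not None:
        m, _truth = simulate(cfg.sim)
        return m
    if not cfg.assignments:
        raise ValueError("either sim or assignments must be configured")
    meta = census_io.read_meta(cfg.meta) if cfg.meta else None
    return census_io.read_assignments(cfg.assignments, cfg.evalue_cutoff, meta)


def run_all(cfg: PipelineConfig) -> Path:
    """Run the full analysis; returns the run directory."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(8) % (2**31 - 1)
    search_cfg = SearchConfig(
        n_addition_replicates=cfg.n_addition_replicates,
        swap=cfg.swap,
        seed=int(seeds[0]),
    )

    # census
    m = _load_inputs(cfg)
    m, dropped = filter_proteomes(m, cfg.lifestyles)
    (out / "dropped_fsfs.txt").write_text("\n".join(dropped) + "\n" if dropped else "")

    # proteome tree
    cm = recode(m, n_states=cfg.n_states, scale=cfg.scale)
    census_io.write_matrix(cm, out / "proteomes.nex", "nexus")
    trees = mp_search(cm, search_cfg)
    rt = lundberg_root(trees[0], cm)
    census_io.write_tree(rt.tree, out / "proteome_tree.nwk")
    ci, ri = ci_ri(rt, cm)
    g1 = g1_skewness(cm, n_random=cfg.g1_random_trees, seed=int(seeds[1]))
    stats = {
        "n_mp_trees": len(trees),
        "unrooted_length": rt.unrooted_length,
        "rooted_length": rt.length,
        "CI": ci,
        "RI": ri,
        "g1": g1,
    }

    # root branch set and refinement
    pset = plesiomorphic_set(root_branch_changes(rt, cm))
    _write_set(out / "root_set.txt", pset.members)
    refinement = run_refinement(
        cm,
        pset.members,
        n_chains=cfg.n_chains,
        n_iter=cfg.n_iter,
        cfg=search_cfg,
        seed=int(seeds[2]),
    )
    max_set = refinement.max_set
    _write_set(out / "max_set.txt", max_set)
    _write_traces(out / "chain_traces.csv", refinement)

    # structure tree and timeline
    st = transpose_for_structure_tree(cm)
    st_cfg = SearchConfig(n_addition_replicates=1, swap="NNI", seed=int(seeds[3]))
    st_trees = mp_search(st, st_cfg)
    st_rt = lundberg_root(st_trees[0], st)
    census_io.write_tree(st_rt.tree, out / "structure_tree.nwk")
    nd = compute_nd(st_rt)
    occ = classify_occurrence(m)
    pd.DataFrame(
        {"fsf": list(nd), "nd": [nd[f] for f in nd], "occurrence": [occ[f] for f in nd]}
    ).sort_values("nd").to_csv(out / "timeline.tsv", sep="\t", index=False)
    occurrence_summary(occ).to_csv(out / "venn.tsv", sep="\t", header=["count"])

    bas = basal_set(nd, occ)
    sets = UrancestralSets(root_set=set(pset.members), max_set=max_set, basal_set=bas)
    _write_set(out / "basal_set.txt", bas)
    _write_set(out / "min_set.txt", sets.min_set)

    # popularity indices
    pop = popularity(m)
    pop["set"] = [
        "min" if f in sets.min_set else "max" if f in max_set else
        "root" if f in pset.members else "-"
        for f in pop.index
    ]
    pop.to_csv(out / "popularity.tsv", sep="\t", index_label="fsf")

    # enrichment
    if cfg.fmap:
        fmap = FunctionMap.from_tsv(cfg.fmap)
        background = set(m.fsfs)
        rows = []
        for name, s in (("min_set", sets.min_set), ("max_set", max_set)):
            if s:
                table = enrichment_table(enrich(s, background, fmap))
                table.insert(0, "set", name)
                rows.append(table)
        if rows:
            pd.concat(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        function_diversity(m, fmap).to_csv(
            out / "function_diversity.tsv", sep="\t", header=["n_subcategories"]
        )

    # molecular clock
    clock_report = {}
    if cfg.calibrations:
        calib = pd.read_csv(cfg.calibrations, sep="\t")
        model = fit_clock(list(zip(calib["age_Ga"], calib["nd"])))
        youngest = {
            name: (max(nd[f] for f in s) if s else None)
            for name, s in (("min_set", sets.min_set), ("max_set", max_set))
            if all(f in nd for f in s)
        }
        clock_report = {
            "slope": model.slope,
            "intercept": model.intercept,
            "r2": model.r2,
            "youngest_nd": youngest,
            "age_Ga": {
                k: model.age_at(v) for k, v in youngest.items() if v is not None
            },
        }
        (out / "clock.json").write_text(json.dumps(clock_report, indent=2))

    # urancestor injection
    injected = {}
    for name, s in (("min_set", sets.min_set), ("max_set", max_set)):
        if not s:
            continue
        cmx = inject_urancestor(cm, s, f"UR_{name}")
        xtrees = mp_search(cmx, search_cfg)
        xrt = lundberg_root(xtrees[0], cmx)
        census_io.write_tree(xrt.tree, out / f"tree_with_{name}.nwk")
        xnd = compute_nd(xrt)
        injected[name] = {
            "nd_of_urancestor": xnd[f"UR_{name}"],
            "is_most_basal": xnd[f"UR_{name}"] <= min(xnd.values()),
        }

    manifest = {
        "seed": cfg.seed,
        "config_digest": cfg.digest(),
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "stage_seeds": [int(s) for s in seeds],
        "tree_stats": stats,
        "set_sizes": {
            "root_set": len(pset.members),
            "root_set_ambiguous": len(pset.ambiguous),
            "max_set": len(max_set),
            "basal_set": len(bas),
            "min_set": len(sets.min_set),
        },
        "refinement_ties": refinement.n_ties,
        "clock": clock_report,
        "injected": injected,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _write_set(path: Path, items: set[str]) -> None:
    path.write_text("\n".join(sorted(items)) + ("\n" if items else ""))


def _write_traces(path: Path, refinement) -> None:
    rows = []
    for trace in refinement.traces:
        for rec in trace.iterations:
            rows.append(
                {
                    "chain": trace.chain_id,
                    "iteration": rec.iteration,
                    "n_fsfs": rec.n_fsfs,
                    "tree_length": rec.tree_length,
                    "n_ambiguous": rec.n_ambiguous,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration (keys mirror PipelineConfig)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "sim" in data and data["sim"] is not None:
        data["sim"] = SimConfig(**data["sim"])
    if "lifestyles" in data:
        data["lifestyles"] = tuple(data["lifestyles"])
    return PipelineConfig(**data)
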