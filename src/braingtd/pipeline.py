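"""End-to-end orchestration: load, prune, GTD, simplify, gated tests.

A run is fully described by a :class:`RunConfig` (loadable from YAML, with
CLI flags overriding) and is deterministic given it.  Every report file is
a machine-readable table; a manifest records input hashes, the package
version, and the configuration so results are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
import yaml

from . import __version__
from ._stats import mean_sem
from .gated_tests import traverse_and_test
from .gtd import compare_pair_sets, pairwise_gtd
from .ontology import (
    GroupTable,
    GroupTableError,
    OntologyTree,
    load_counts,
    parse_structure_graph,
    prune_region,
)
from .simplification import SelectionCriteria, simplification_report, simplify

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    ontology: str = ""
    counts: str = ""
    groups: str = ""
    outdir: str = "results"
    comparisons: Sequence[tuple[str, str]] = ()
    pruned_regions: Sequence[str] = ()  # acronyms
    min_mean: float = 5.0
    presence_fraction: float = 0.5
    min_presence_count: int = 1
    gate_alpha: float = 0.05
    test_alpha: float = 0.05
    equal_var: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "comparisons" in data:
            data["comparisons"] = [tuple(c) for c in data["comparisons"]]
        return cls(**data)

    @property
    def criteria(self) -> SelectionCriteria:
        return SelectionCriteria(
            min_mean=self.min_mean,
            presence_fraction=self.presence_fraction,
            min_presence_count=self.min_presence_count,
        )


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def summarize_groups(brains, groups: GroupTable) -> pd.DataFrame:
    """Per-group labelled-cell totals: n, range, mean +/- SEM."""
    rows = []
    for label in sorted(groups.groups):
        totals = [brains[b].total for b in groups.members(label)]
        mean, sem = mean_sem(totals)
        rows.append(
            {
                "group": label,
                "n_brains": len(totals),
                "totals": ";".join(str(t) for t in sorted(totals)),
                "min": min(totals),
                "max": max(totals),
                "range": f"{min(totals)}-{max(totals)}",
                "mean": mean,
                "sem": sem,
            }
        )
    return pd.DataFrame(rows)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and write all report files.

    Returns a manifest dict (also written to ``manifest.json``).
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tree = parse_structure_graph(config.ontology)
    for acronym in config.pruned_regions:
        tree = prune_region(tree, tree.id_of(acronym))
        logger.info("pruned region %s and its subtree", acronym)
    brains = load_counts(config.counts, tree)
    groups = GroupTable.from_csv(config.groups)
    missing = set(brains) - set(groups.assignments)
    if missing:
        logger.warning("brains without group assignment ignored: %s", sorted(missing))
    for ga, gb in config.comparisons:
        for g in (ga, gb):
            if g not in groups.groups:
                raise ConfigError(f"comparison names unknown group {g!r}")

    summarize_groups(brains, groups).to_csv(outdir / "group_summary.csv", index=False)

    comparison_summaries = {}
    for ga, gb in config.comparisons:
        tag = f"{ga}_vs_{gb}"
        pairs = pairwise_gtd(brains, groups, tree, (ga, gb))
        pairs.to_frame().to_csv(outdir / f"gtd_pairs_{tag}.csv", index=False)
        comparison_summaries[tag] = compare_pair_sets(
            pairs.within_values, pairs.between_values
        )

        brains_a = [brains[b] for b in groups.members(ga)]
        brains_b = [brains[b] for b in groups.members(gb)]
        simplified = simplify(tree, brains_a, brains_b, config.criteria)
        simplification_report(simplified, tree).to_csv(
            outdir / f"simplification_{tag}.csv", index=False
        )
        report = traverse_and_test(
            tree,
            simplified,
            brains_a,
            brains_b,
            alpha=config.gate_alpha,
            equal_var=config.equal_var,
        )
        report.gate_frame(tree).to_csv(outdir / f"gates_{tag}.csv", index=False)
        report.to_frame(tree).to_csv(outdir / f"child_tests_{tag}.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {**asdict(config), "comparisons": [list(c) for c in config.comparisons]},
        "inputs": {
            "ontology": _sha256(config.ontology),
            "counts": _sha256(config.counts),
            "groups": _sha256(config.groups),
        },
        "comparisons": comparison_summaries,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
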