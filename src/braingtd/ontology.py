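"""Hierarchical segmentation ontologies and per-brain cell-count maps.

The ontology is a rooted tree of named brain regions in the Allen
structure-graph JSON dialect (CCFv3-style records with ``id``, ``acronym``,
``name`` and parent linkage).  Cell counts are carried per brain as *direct*
counts — cells assigned to a region itself, not to any of its subregions —
from which *cumulative* counts (region plus all descendants) and fractions
of the brain total are derived.  Direct counts are the single source of
truth; cumulative counts are always recomputed, never stored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, Union

import pandas as pd

logger = logging.getLogger(__name__)

RegionId = int


class OntologyError(ValueError):
    """Base class for structure-graph validation failures."""


class DuplicateRegionError(OntologyError):
    """Two records share a region id or an acronym."""


class MissingParentError(OntologyError):
    """A record names a parent id that is absent from the document."""


class MultipleRootsError(OntologyError):
    """More than one record has no parent."""


class NoRootError(OntologyError):
    """No record lacks a parent (the parent pointers close on themselves)."""


class CycleError(OntologyError):
    """Parent linkage contains a cycle."""


class UnknownRegionError(KeyError):
    """A region id is not present in the ontology."""


class CountTableError(ValueError):
    """A count table row violates the loader contract."""


class EmptyBrainError(ValueError):
    """A brain has zero cells in total and cannot be analysed."""


@dataclass(frozen=True)
class Region:
    """A single node of the ontology.

    ``children`` is kept sorted by ascending region id so that subregion
    composition vectors are reproducible across runs.
    """

    id: RegionId
    acronym: str
    name: str
    parent_id: RegionId | None
    children: tuple[RegionId, ...] = ()


class OntologyTree:
    """A validated, rooted hierarchy of brain regions.

    Parameters
    ----------
    regions
        Mapping of region id to :class:`Region`.  Children lists are
        rebuilt from parent pointers and sorted by id; the input ``children``
        fields are ignored.
    pruned_ids
        Region ids that used to belong to this ontology but were removed by
        :func:`prune_region`.  Count loaders silently drop (and log) rows
        referring to these, while genuinely unknown ids stay hard errors.
    """

    def __init__(
        self,
        regions: Mapping[RegionId, Region],
        pruned_ids: frozenset[RegionId] = frozenset(),
    ) -> None:
        roots = [r.id for r in regions.values() if r.parent_id is None]
        if not roots:
            raise NoRootError("no root region (every record names a parent)")
        if len(roots) > 1:
            raise MultipleRootsError(f"multiple roots: {sorted(roots)}")

        acronyms: dict[str, RegionId] = {}
        children: dict[RegionId, list[RegionId]] = {rid: [] for rid in regions}
        for region in regions.values():
            if region.acronym in acronyms:
                raise DuplicateRegionError(
                    f"acronym {region.acronym!r} used by regions "
                    f"{acronyms[region.acronym]} and {region.id}"
                )
            acronyms[region.acronym] = region.id
            if region.parent_id is not None:
                if region.parent_id not in regions:
                    raise MissingParentError(
                        f"region {region.id} names missing parent {region.parent_id}"
                    )
                children[region.parent_id].append(region.id)

        self.root_id: RegionId = roots[0]
        self.regions: dict[RegionId, Region] = {
            rid: Region(
                id=r.id,
                acronym=r.acronym,
                name=r.name,
                parent_id=r.parent_id,
                children=tuple(sorted(children[rid])),
            )
            for rid, r in regions.items()
        }
        self.pruned_ids = frozenset(pruned_ids)
        self._acronym_index = acronyms

        # reachability from the root doubles as cycle detection
        reached = set(self.iter_depth_first())
        if len(reached) != len(self.regions):
            orphans = sorted(set(self.regions) - reached)
            raise CycleError(f"regions unreachable from root (cycle): {orphans}")

    # -- basic queries -------------------------------------------------

    def __contains__(self, region_id: RegionId) -> bool:
        return region_id in self.regions

    def __len__(self) -> int:
        return len(self.regions)

    def children(self, region_id: RegionId) -> tuple[RegionId, ...]:
        return self[region_id].children

    def __getitem__(self, region_id: RegionId) -> Region:
        try:
            return self.regions[region_id]
        except KeyError:
            raise UnknownRegionError(region_id) from None

    def id_of(self, acronym: str) -> RegionId:
        try:
            return self._acronym_index[acronym]
        except KeyError:
            raise UnknownRegionError(acronym) from None

    def is_leaf(self, region_id: RegionId) -> bool:
        return not self[region_id].children

    def leaves(self) -> list[RegionId]:
        return [rid for rid in sorted(self.regions) if self.is_leaf(rid)]

    def iter_depth_first(self, start: RegionId | None = None) -> Iterator[RegionId]:
        stack = [self.root_id if start is None else start]
        while stack:
            rid = stack.pop()
            yield rid
            stack.extend(reversed(self.regions[rid].children))

    def iter_postorder(self) -> Iterator[RegionId]:
        """Children before parents; used for cumulative-count aggregation."""
        order = list(self.iter_depth_first())
        return reversed(order)

    def iter_breadth_first(self) -> Iterator[RegionId]:
        """Top-down level order with id-sorted children (deterministic)."""
        queue = [self.root_id]
        while queue:
            rid = queue.pop(0)
            yield rid
            queue.extend(self.regions[rid].children)

    def subtree_ids(self, region_id: RegionId) -> set[RegionId]:
        if region_id not in self.regions:
            raise UnknownRegionError(region_id)
        return set(self.iter_depth_first(region_id))

    def to_records(self) -> list[dict]:
        return [
            {
                "id": r.id,
                "acronym": r.acronym,
                "name": r.name,
                "parent_structure_id": r.parent_id,
            }
            for r in (self.regions[rid] for rid in sorted(self.regions))
        ]


def parse_structure_graph(document: Union[str, Path, Sequence[Mapping], Mapping]) -> OntologyTree:
    """Parse an Allen-dialect structure-graph JSON document into an ontology.

    Accepts a path to a JSON file, a parsed list of region records, or the
    Allen API response envelope ``{"msg": [...]}``.  Parent linkage is taken
    from ``parent_structure_id`` when present, otherwise inferred from the
    penultimate element of ``structure_id_path`` (e.g. ``"/997/8/567/"``).
    """
    if isinstance(document, (str, Path)):
        with open(document) as fh:
            document = json.load(fh)
    if isinstance(document, Mapping):
        document = document.get("msg", document)
    if not isinstance(document, Sequence):
        raise OntologyError("structure graph must be a list of region records")

    regions: dict[RegionId, Region] = {}
    for record in document:
        rid = int(record["id"])
        if rid in regions:
            raise DuplicateRegionError(f"duplicate region id {rid}")
        parent = record.get("parent_structure_id")
        if parent is None and "structure_id_path" in record:
            path = [p for p in str(record["structure_id_path"]).split("/") if p]
            if len(path) >= 2:
                parent = int(path[-2])
        regions[rid] = Region(
            id=rid,
            acronym=str(record.get("acronym", str(rid))),
            name=str(record.get("name", str(rid))),
            parent_id=None if parent is None else int(parent),
        )
    return OntologyTree(regions)


def prune_region(tree: OntologyTree, region_id: RegionId) -> OntologyTree:
    """Remove a region and its entire subtree from the ontology.

    Used for ablation analyses that ask how much of a between-group
    difference is carried by one region (e.g. removing retrosplenial
    cortex).  The returned tree remembers the removed ids so count tables
    produced against the full ontology still load (rows in the removed
    subtree are dropped with a warning).
    """
    if region_id not in tree.regions:
        raise UnknownRegionError(region_id)
    if region_id == tree.root_id:
        raise OntologyError("cannot prune the root region")
    removed = tree.subtree_ids(region_id)
    kept = {rid: r for rid, r in tree.regions.items() if rid not in removed}
    return OntologyTree(kept, pruned_ids=tree.pruned_ids | frozenset(removed))


@dataclass
class BrainCounts:
    """One brain's region-assigned cell counts.

    ``direct`` holds cells assigned to each region itself; ``cumulative``
    adds all descendants, so ``cumulative[root]`` equals the brain total.
    """

    brain_id: str
    direct: dict[RegionId, int]
    cumulative: dict[RegionId, int]
    total: int

    @classmethod
    def from_direct(
        cls, brain_id: str, direct: Mapping[RegionId, int], tree: OntologyTree
    ) -> "BrainCounts":
        full_direct = {rid: int(direct.get(rid, 0)) for rid in tree.regions}
        cumulative: dict[RegionId, int] = {}
        for rid in tree.iter_postorder():
            cumulative[rid] = full_direct[rid] + sum(
                cumulative[c] for c in tree.children(rid)
            )
        total = cumulative[tree.root_id]
        if total <= 0:
            raise EmptyBrainError(f"brain {brain_id!r} has zero cells in total")
        return cls(brain_id=brain_id, direct=full_direct, cumulative=cumulative, total=total)

    def fraction(self, region_id: RegionId) -> float:
        return self.cumulative[region_id] / self.total


def fractional_map(brain: BrainCounts) -> dict[RegionId, float]:
    """Cumulative count of every region as a fraction of the brain total.

    This is the per-region "fraction of total labelled inputs" map; the
    fraction at the root is exactly 1.
    """
    if brain.total <= 0:
        raise EmptyBrainError(f"brain {brain.brain_id!r} has zero cells in total")
    return {rid: c / brain.total for rid, c in brain.cumulative.items()}


def load_counts(
    source: Union[str, Path, pd.DataFrame], tree: OntologyTree
) -> dict[str, BrainCounts]:
    """Load a long-format direct-count table (brain_id, region_id, count).

    Regions absent from a brain's rows get a direct count of zero:
    unlabelled regions are zero-input, not missing data.  Rows referring to
    regions that were explicitly pruned from the ontology are dropped with
    a warning; any other unknown region id is an error, as are negative or
    non-integer counts and brains with zero cells in total.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    required = {"brain_id", "region_id", "count"}
    if not required.issubset(df.columns):
        raise CountTableError(f"count table must have columns {sorted(required)}")

    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any() or (counts % 1 != 0).any():
        bad = df.loc[counts.isna() | (counts % 1 != 0)]
        raise CountTableError(f"non-integer counts in rows: {bad.index.tolist()}")
    if (counts < 0).any():
        raise CountTableError("negative counts are not allowed")
    df = df.assign(count=counts.astype(int), region_id=df["region_id"].astype(int))

    in_pruned = df["region_id"].isin(tree.pruned_ids)
    if in_pruned.any():
        lost = int(df.loc[in_pruned, "count"].sum())
        logger.warning(
            "dropping %d rows (%d cells) assigned to pruned regions",
            int(in_pruned.sum()),
            lost,
        )
        df = df.loc[~in_pruned]
    unknown = set(df["region_id"]) - set(tree.regions)
    if unknown:
        raise UnknownRegionError(sorted(unknown))

    brains: dict[str, BrainCounts] = {}
    for brain_id, sub in df.groupby("brain_id", sort=False):
        direct = sub.groupby("region_id")["count"].sum().to_dict()
        brains[str(brain_id)] = BrainCounts.from_direct(str(brain_id), direct, tree)
    return brains


def write_counts(brains: Iterable[BrainCounts], path: Union[str, Path]) -> None:
    """Write direct counts as a long-format CSV (nonzero rows only)."""
    rows = [
        {"brain_id": b.brain_id, "region_id": rid, "count": n}
        for b in brains
        for rid, n in sorted(b.direct.items())
        if n > 0
    ]
    pd.DataFrame(rows, columns=["brain_id", "region_id", "count"]).to_csv(
        path, index=False
    )


class GroupTableError(ValueError):
    """A group table violates the one-group-per-brain contract."""


@dataclass
class GroupTable:
    """Assignment of brains to experimental groups (e.g. Cre-driver lines)."""

    assignments: dict[str, str]
    groups: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        groups: dict[str, list[str]] = {}
        for brain_id, label in self.assignments.items():
            groups.setdefault(label, []).append(brain_id)
        if any(not members for members in groups.values()):
            raise GroupTableError("empty group")
        self.groups = {g: sorted(m) for g, m in groups.items()}

    @classmethod
    def from_csv(cls, source: Union[str, Path, pd.DataFrame]) -> "GroupTable":
        df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
        if not {"brain_id", "group"}.issubset(df.columns):
            raise GroupTableError("group table must have columns brain_id, group")
        if df["brain_id"].duplicated().any():
            dup = df.loc[df["brain_id"].duplicated(), "brain_id"].tolist()
            raise GroupTableError(f"brains assigned to more than one group: {dup}")
        return cls({str(b): str(g) for b, g in zip(df["brain_id"], df["group"])})

    def members(self, label: str) -> list[str]:
        try:
            return self.groups[label]
        except KeyError:
            raise GroupTableError(f"unknown group {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"brain_id": b, "group": g} for b, g in self.assignments.items()]
        )
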