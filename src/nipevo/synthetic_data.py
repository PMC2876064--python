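"""KEGG-like synthetic annotation datasets with controllable group structure.

The generator produces the same shape of data the pipeline expects from a
real pathway database: a universe of ~100-200 pathways drawing metabolites
from a shared pool (a small fraction of "hub" metabolites is sampled
preferentially, so pathways overlap and the resulting NIPs are dense,
clustered, and have small diameters), and taxa that retain each pathway
independently with a group-specific, category-biased probability. ORF
counts are coupled log-linearly to pathway counts, inverting the
pathways ~ log(ORFs) relation the consistency filter relies on.

``effect_size`` scales every between-group difference; at 0 the groups are
exchangeable, which makes null-calibration runs possible. All randomness
flows through one seeded generator, so a (spec, seed) pair is fully
deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotation_io import AnnotationSet, TaxonRecord, write_annotations, write_categories

__all__ = [
    "CATEGORIES",
    "UniverseSpec",
    "GroupSpec",
    "GroupEffectSpec",
    "Universe",
    "SyntheticDataset",
    "generate_universe",
    "generate_taxa",
    "make_inconsistent",
    "default_scenario",
    "write_dataset",
]

# Eleven functional categories mirroring KEGG top-level metabolism classes.
CATEGORIES = (
    "carbohydrate",
    "energy",
    "lipid",
    "amino_acid",
    "glycan",
    "xenobiotics",
    "secondary_metabolites",
    "nucleotide",
    "cofactor_vitamin",
    "terpenoid_polyketide",
    "other",
)


@dataclass
class UniverseSpec:
    """Shape of the pathway/metabolite universe."""

    n_pathways: int = 150
    n_metabolites: int = 400
    metabolites_per_pathway: float = 10.0
    hub_fraction: float = 0.04
    hub_affinity: float = 9.0  # sampling weight of a hub relative to a non-hub
    seed: int = 17

    def __post_init__(self):
        if self.n_pathways < 2:
            raise ValueError("n_pathways must be >= 2")
        if not 0 <= self.hub_fraction <= 1:
            raise ValueError("hub_fraction must be in [0, 1]")
        if self.metabolites_per_pathway > self.n_metabolites:
            raise ValueError("metabolites_per_pathway cannot exceed n_metabolites")


@dataclass
class GroupSpec:
    """One taxa group: size, pathway retention, and planted category biases."""

    label: str
    n_taxa: int
    pathway_retention: float
    retention_bias_by_category: dict[str, float] = field(default_factory=dict)
    overlap_boost: float = 0.0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2 per group")


@dataclass
class GroupEffectSpec:
    """A contrast: group definitions, ORF model, and a global effect scale.

    ``orf_model = (a, b, sd)`` gives ``orf = round(exp((n_pathways - a)/b + noise))``
    with ``noise ~ N(0, sd)``; ``effect_size`` scales all between-group
    differences (0 = exchangeable groups).
    """

    contrast_name: str
    groups: list[GroupSpec]
    orf_model: tuple[float, float, float] = (-75.0, 25.0, 0.15)
    effect_size: float = 1.0


@dataclass
class Universe:
    pathways: dict[str, frozenset[str]]
    categories: dict[str, str]
    hubs: frozenset[str]
    spec: UniverseSpec


@dataclass
class SyntheticDataset:
    annotations: AnnotationSet
    categories: dict[str, str]
    ground_truth: dict


def generate_universe(spec: UniverseSpec, rng: np.random.Generator | None = None) -> Universe:
    """Draw the pathway -> metabolite-set universe.

    Hub metabolites (a ``hub_fraction`` of the pool) are sampled with
    ``hub_affinity``-fold higher probability, which yields overlapping
    pathways and right-skewed NIP degree distributions.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    metabolites = [f"M{i:04d}" for i in range(spec.n_metabolites)]
    n_hubs = int(round(spec.hub_fraction * spec.n_metabolites))
    hubs = frozenset(metabolites[:n_hubs])
    weights = np.ones(spec.n_metabolites)
    weights[:n_hubs] = spec.hub_affinity
    probs = weights / weights.sum()

    pathways: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    for i in range(spec.n_pathways):
        pid = f"P{i:03d}"
        size = max(2, int(rng.poisson(spec.metabolites_per_pathway)))
        size = min(size, spec.n_metabolites)
        chosen = rng.choice(spec.n_metabolites, size=size, replace=False, p=probs)
        pathways[pid] = frozenset(metabolites[j] for j in chosen)
        categories[pid] = CATEGORIES[i % len(CATEGORIES)]
    return Universe(pathways=pathways, categories=categories, hubs=hubs, spec=spec)


def _effective_retention(effects: GroupEffectSpec) -> dict[str, dict[str, float]]:
    """Per-group, per-category retention probability after effect scaling."""
    base = float(np.mean([g.pathway_retention for g in effects.groups]))
    e = effects.effect_size
    out: dict[str, dict[str, float]] = {}
    for g in effects.groups:
        r = base + e * (g.pathway_retention - base)
        per_cat = {}
        for cat in CATEGORIES:
            mult = g.retention_bias_by_category.get(cat, 1.0)
            mult_eff = 1.0 + e * (mult - 1.0)
            per_cat[cat] = min(1.0, max(0.0, r * mult_eff))
        out[g.label] = per_cat
    return out


def generate_taxa(
    universe: Universe, effects: GroupEffectSpec, seed: int | None = None
) -> SyntheticDataset:
    """Sample taxa as category-biased pathway subsets of the universe.

    Each taxon retains each pathway independently with its group's effective
    retention probability; the ``overlap_boost`` of a group (scaled by
    ``effect_size``) is the per-pathway probability of gaining one extra hub
    metabolite. Ground truth records the planted effects.
    """
    rng = np.random.default_rng(universe.spec.seed if seed is None else seed)
    retention = _effective_retention(effects)
    cats = universe.categories
    pids = sorted(universe.pathways)
    hub_list = sorted(universe.hubs)

    # guard against groups too sparse to form a network
    for g in effects.groups:
        expected = sum(retention[g.label][cats[p]] for p in pids)
        if expected < 2:
            raise ValueError(f"group {g.label!r}: expected pathway count {expected:.2f} < 2")

    a, b, sd = effects.orf_model
    taxa: dict[str, dict[str, set[str]]] = {}
    metadata: dict[str, TaxonRecord] = {}
    for g in effects.groups:
        boost = effects.effect_size * g.overlap_boost
        for i in range(g.n_taxa):
            taxon_id = f"{g.label}_{i:03d}"
            pathways: dict[str, set[str]] = {}
            keep = rng.random(len(pids))
            for pid, u in zip(pids, keep):
                if u < retention[g.label][cats[pid]]:
                    mets = set(universe.pathways[pid])
                    if boost > 0 and hub_list and rng.random() < boost:
                        mets.add(hub_list[rng.integers(len(hub_list))])
                    pathways[pid] = mets
            n_p = len(pathways)
            noise = rng.normal(0.0, sd)
            orf = max(1, int(round(math.exp((n_p - a) / b + noise))))
            taxa[taxon_id] = pathways
            metadata[taxon_id] = TaxonRecord(
                taxon_id, orf, {effects.contrast_name: g.label}
            )

    label_a, label_b = (g.label for g in effects.groups[:2])
    expected_direction = {}
    for cat in CATEGORIES:
        delta = retention[label_b][cat] - retention[label_a][cat]
        expected_direction[cat] = (
            "increase" if delta > 1e-12 else "decrease" if delta < -1e-12 else "none"
        )
    ground_truth = {
        "contrast": effects.contrast_name,
        "effect_size": effects.effect_size,
        "groups": [asdict(g) for g in effects.groups],
        "effective_retention": retention,
        "planted_categories": sorted(
            {c for g in effects.groups for c in g.retention_bias_by_category}
        ),
        "expected_frequency_direction": expected_direction,
        "deflated_taxa": [],
    }
    ann = AnnotationSet(taxa=taxa, metadata=metadata)
    return SyntheticDataset(annotations=ann, categories=dict(cats), ground_truth=ground_truth)


def make_inconsistent(
    dataset: SyntheticDataset, fraction: float, deflation: float, seed: int = 0
) -> SyntheticDataset:
    """Deflate the pathway sets of a random taxon fraction, keeping ORF counts.

    The marked taxa lose a ``deflation`` fraction of their pathways and
    become known targets for the annotation-consistency filter; they are
    recorded in ``ground_truth['deflated_taxa']``.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ann = dataset.annotations
    taxon_ids = sorted(ann.taxa)
    k = max(1, int(round(fraction * len(taxon_ids))))
    marked = sorted(rng.choice(len(taxon_ids), size=k, replace=False))
    marked_ids = [taxon_ids[i] for i in marked]

    new_taxa = {t: {p: set(m) for p, m in ps.items()} for t, ps in ann.taxa.items()}
    for t in marked_ids:
        pids = sorted(new_taxa[t])
        n_drop = int(math.floor(deflation * len(pids)))
        drop = set(
            pids[i] for i in rng.choice(len(pids), size=n_drop, replace=False)
        )
        new_taxa[t] = {p: m for p, m in new_taxa[t].items() if p not in drop}
    gt = dict(dataset.ground_truth)
    gt["deflated_taxa"] = marked_ids
    gt["deflation"] = deflation
    new_meta = {
        t: TaxonRecord(t, rec.orf_count, dict(rec.groups)) for t, rec in ann.metadata.items()
    }
    return SyntheticDataset(
        annotations=AnnotationSet(taxa=new_taxa, metadata=new_meta),
        categories=dict(dataset.categories),
        ground_truth=gt,
    )


def default_scenario(
    effect_size: float = 1.0, seed: int = 17
) -> tuple[UniverseSpec, GroupEffectSpec]:
    """The default study conditions: two groups of 50 taxa over 150 pathways.

    A high-retention "free_living" group (0.9) is contrasted with a
    genome-reduced "host_associated" group (0.5) whose lipid and glycan
    pathways are lost at an extra 0.6 multiplier — the planted categories.
    """
    universe = UniverseSpec(seed=seed)
    effects = GroupEffectSpec(
        contrast_name="habitat",
        groups=[
            GroupSpec("free_living", 50, 0.9),
            GroupSpec(
                "host_associated",
                50,
                0.5,
                retention_bias_by_category={"lipid": 0.6, "glycan": 0.6},
            ),
        ],
        effect_size=effect_size,
    )
    return universe, effects


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write annotations.tsv, taxa.tsv, pathway_categories.tsv and
    ground_truth.json; the TSVs round-trip through annotation_io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "taxa": outdir / "taxa.tsv",
        "categories": outdir / "pathway_categories.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_annotations(dataset.annotations, paths["annotations"], paths["taxa"])
    write_categories(dataset.categories, paths["categories"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(dataset.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
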