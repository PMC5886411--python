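"""Clonal trees and assignment of somatic events to clones.

The root of every tree is the matched-normal control. A somatic variant lives
on exactly one edge and is carried by the edge's child clone and all of its
descendants, so carried-variant sets are nested along any root-to-leaf path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (GermlineVariant, InsufficientLociError,
                   InvalidParameterError, in_regions)

ROOT = "normal"


@dataclass
class CloneTree:
    """Rooted clone tree; edges are identified by their child node."""

    nodes: list[str]
    parent: dict[str, Optional[str]]
    model: str
    edge_variants: dict[str, list[GermlineVariant]] = field(default_factory=dict)

    def __post_init__(self):
        roots = [n for n in self.nodes if self.parent[n] is None]
        if roots != [ROOT]:
            raise InvalidParameterError("tree must have exactly one root clone")

    @property
    def subclones(self) -> list[str]:
        return [n for n in self.nodes if n != ROOT]

    def children(self, node: str) -> list[str]:
        return [n for n in self.nodes if self.parent[n] == node]

    def descendants(self, node: str) -> set[str]:
        out: set[str] = set()
        stack = self.children(node)
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(self.children(n))
        return out

    def edges_root_first(self) -> list[str]:
        """Non-root nodes in breadth-first (root-proximal first) order."""
        order = []
        queue = [ROOT]
        while queue:
            n = queue.pop(0)
            kids = self.children(n)
            order.extend(kids)
            queue.extend(kids)
        return order


def build_architecture(n_subclones: int, model: str, seed: int) -> CloneTree:
    """Build a linear chain or a random branched tree of tumor clones.

    Linear: normal -> c1 -> ... -> ck. Branched: a mandatory trunk edge
    normal -> c1, then each further clone attaches to a uniformly random
    existing tumor clone, giving a shared trunk with random private branches.
    One subclone makes the two models coincide.
    """
    if n_subclones < 1:
        raise InvalidParameterError("n_subclones must be >= 1")
    if model not in ("linear", "branched"):
        raise InvalidParameterError(f"unknown architecture model {model!r}")
    names = [f"c{i}" for i in range(1, n_subclones + 1)]
    parent: dict[str, Optional[str]] = {ROOT: None}
    if model == "linear" or n_subclones == 1:
        prev = ROOT
        for n in names:
            parent[n] = prev
            prev = n
    else:
        rng = np.random.default_rng(seed)
        parent[names[0]] = ROOT  # trunk
        for i, n in enumerate(names[1:], start=1):
            parent[n] = names[int(rng.integers(0, i))]
    return CloneTree(nodes=[ROOT] + names, parent=parent, model=model)


def select_somatic_loci(germline_variants: Sequence[GermlineVariant], n: int,
                        target_regions=None, seed: int = 0,
                        vtype: Optional[str] = None) -> list[GermlineVariant]:
    """Randomly pick ``n`` distinct heterozygous loci to become somatic.

    Only het variants are eligible (the switch to hom-ref is undefined
    otherwise); an optional BED-style target and an optional variant-class
    filter restrict the pool further.
    """
    pool = [v for v in germline_variants if v.genotype == "het"
            and (vtype is None or v.vtype == vtype)
            and in_regions(v.chrom, v.pos - 1, target_regions)]
    if n > len(pool):
        raise InsufficientLociError(
            f"requested {n} somatic loci but only {len(pool)} eligible het "
            f"variants are available")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def partition_variants(selected: Sequence[GermlineVariant], tree: CloneTree,
                       seed: int = 0) -> dict[str, list[GermlineVariant]]:
    """Split the selected somatic variants across tree edges.

    Sizes are as even as integer division allows; the remainder goes to the
    edges nearest the root. Which variant lands on which edge is random but
    seeded.
    """
    edges = tree.edges_root_first()
    rng = np.random.default_rng(seed)
    perm = list(selected)
    rng.shuffle(perm)
    n, k = len(perm), len(edges)
    base, rem = divmod(n, k)
    out: dict[str, list[GermlineVariant]] = {}
    i = 0
    for j, e in enumerate(edges):
        size = base + (1 if j < rem else 0)
        out[e] = sorted(perm[i:i + size], key=lambda v: (v.chrom, v.pos))
        i += size
    return out


def carriers(tree: CloneTree,
             edge_variants: dict[str, list[GermlineVariant]]
             ) -> dict[tuple, frozenset]:
    """Map each somatic variant (by key) to the set of clones that carry it:
    the edge's child and every descendant. The root carries nothing."""
    out: dict[tuple, frozenset] = {}
    for child, variants in edge_variants.items():
        clones = frozenset({child} | tree.descendants(child))
        for v in variants:
            out[v.key] = clones
    return out


def carried_by(tree: CloneTree, edge_variants: dict[str, list[GermlineVariant]],
               node: str) -> list[GermlineVariant]:
    """All somatic variants carried by ``node`` (empty for the root)."""
    carr = carriers(tree, edge_variants)
    return sorted((v for vs in edge_variants.values() for v in vs
                   if node in carr[v.key]), key=lambda v: (v.chrom, v.pos))


@dataclass(frozen=True)
class SomaticTruthRecord:
    """One somatic variant with its carrier clones and expected allele
    fraction under a given mixture (0.5 x summed carrier fractions)."""

    variant: GermlineVariant
    carriers: frozenset
    expected_af: float

    def __post_init__(self):
        if not 0.0 <= self.expected_af <= 0.5 + 1e-12:
            raise InvalidParameterError("expected_af must lie in [0, 0.5]")


def truth_records(tree: CloneTree, edge_variants: dict[str, list[GermlineVariant]],
                  fractions: dict[str, float]) -> list[SomaticTruthRecord]:
    """Somatic truth rows for a mixture given as clone -> fraction (sums to 1,
    control included)."""
    carr = carriers(tree, edge_variants)
    out = []
    for vs in edge_variants.values():
        for v in vs:
            cs = carr[v.key]
            af = 0.5 * sum(fractions.get(c, 0.0) for c in cs)
            out.append(SomaticTruthRecord(variant=v, carriers=cs, expected_af=af))
    return sorted(out, key=lambda r: (r.variant.chrom, r.variant.pos))


def write_truth_table(records: list[SomaticTruthRecord], tree: CloneTree,
                      path: Path | str) -> Path:
    """Serialize the somatic truth as a TSV (one row per variant)."""
    carr_edge = {v.key: e for e, vs in tree.edge_variants.items() for v in vs} \
        if tree.edge_variants else {}
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tvtype\tedge\tcarriers\texpected_af\n")
        for r in records:
            v = r.variant
            edge = carr_edge.get(v.key, "")
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.vtype}\t{edge}\t"
                     f"{','.join(sorted(r.carriers))}\t{r.expected_af:.6f}\n")
    return path
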