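"""Shared primitives: domain types, errors, coordinates, and fragment-fate hashing.

Coordinate conventions (used everywhere, converted nowhere else):
variant positions are 1-based (VCF); intervals are 0-based half-open (BED).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pysam


# ---------------------------------------------------------------------------
# Errors

class TumormixError(Exception):
    """Base class for package errors."""


class InvalidParameterError(TumormixError, ValueError):
    pass


class CapacityError(TumormixError):
    """Requested content does not fit in the available sequence/interval space."""


class InsufficientLociError(TumormixError):
    pass


class IncompatiblePlanError(TumormixError):
    """Mixture percentages / final coverage incompatible with input coverage."""


class HeaderIncompatibilityError(TumormixError):
    pass


class UndefinedCorrelationError(TumormixError):
    pass


class InvalidLocusError(TumormixError):
    pass


# ---------------------------------------------------------------------------
# Domain types

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GermlineVariant:
    """A biallelic germline variant with its genotype.

    ``pos`` is 1-based. ``ref``/``alt`` follow VCF conventions: SNVs have
    single-base ref and alt; insertions/deletions share a leading anchor base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str  # "het" | "hom"

    def __post_init__(self):
        if self.ref == self.alt:
            raise InvalidParameterError("ref and alt alleles must differ")
        if self.genotype not in ("het", "hom"):
            raise InvalidParameterError(f"bad genotype {self.genotype!r}")

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "INS"
        return "DEL"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference interval a read must fully cover to be
        informative for this variant (anchor plus, for DELs, the deleted bases;
        for INS, the base after the insertion junction)."""
        p0 = self.pos - 1
        if self.vtype == "SNV":
            return (p0, p0 + 1)
        if self.vtype == "INS":
            return (p0, p0 + 2)
        return (p0, p0 + len(self.ref))  # DEL


@dataclass(frozen=True)
class CnaEvent:
    """A copy-number alteration interval owned by one clone."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    kind: str   # "duplication" | "deletion"
    clone: str

    def __post_init__(self):
        if self.kind not in ("duplication", "deletion"):
            raise InvalidParameterError(f"bad CNA kind {self.kind!r}")
        if self.size < 100:
            raise InvalidParameterError("CNA events must be at least 100 bp")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentSet:
    """Handle to a coordinate-sorted, indexed BAM file."""

    path: Path

    def __post_init__(self):
        self.path = Path(self.path)

    def open(self) -> pysam.AlignmentFile:
        return pysam.AlignmentFile(str(self.path), "rb")

    @property
    def index_path(self) -> Path:
        return Path(str(self.path) + ".bai")

    def n_records(self) -> int:
        with self.open() as f:
            return f.mapped + f.unmapped

    def contigs(self) -> dict[str, int]:
        with self.open() as f:
            return dict(zip(f.references, f.lengths))


def index_bam(path: Path | str) -> None:
    pysam.index(str(path))


# ---------------------------------------------------------------------------
# Fragment fate hashing
#
# All stochastic per-fragment decisions (subsampling, clone partitioning,
# 50 % allele half-sampling) are driven by a keyed hash of the read name, so
# that the two mates of a fragment always share one fate and the decision can
# be recomputed anywhere from (name, seed) alone.

def _seed_key(seed: int) -> bytes:
    return int(seed).to_bytes(8, "little", signed=False)

_U64 = float(2 ** 64)


def fragment_fate(name: str, seed: int) -> tuple[float, float]:
    """Two independent uniforms in [0, 1) derived from a read name and seed.

    The first is used for partition-style decisions (which clone bucket a
    fragment belongs to), the second for keep/drop decisions, so that nested
    operations do not reuse the same randomness.
    """
    h = hashlib.blake2b(name.encode(), digest_size=16, key=_seed_key(seed)).digest()
    return (int.from_bytes(h[:8], "little") / _U64,
            int.from_bytes(h[8:], "little") / _U64)


def fate_arrays(names: Iterable[str], seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`fragment_fate` over many names."""
    key = _seed_key(seed)
    u1 = []
    u2 = []
    for n in names:
        h = hashlib.blake2b(n.encode(), digest_size=16, key=key).digest()
        u1.append(int.from_bytes(h[:8], "little"))
        u2.append(int.from_bytes(h[8:], "little"))
    return (np.asarray(u1, dtype=np.float64) / _U64,
            np.asarray(u2, dtype=np.float64) / _U64)


# ---------------------------------------------------------------------------
# Seed plumbing

def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` reproducible child seeds (< 2**31) from one parent seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# Target regions (BED)

def read_bed(path: Path | str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def in_regions(chrom: str, pos0: int, regions: Optional[list[tuple[str, int, int]]]) -> bool:
    if regions is None:
        return True
    return any(c == chrom and s <= pos0 < e for c, s, e in regions)
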