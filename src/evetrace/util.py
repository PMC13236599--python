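"""Small sequence helpers shared across modules.

Coordinates are 0-based, half-open everywhere inside the package; conversion
to 1-based happens only at the GFF3 boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class SeqRecord:
    """A named DNA sequence over {A,C,G,T} — the common currency of all modules."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement_base(b: str) -> str:
    return b.translate(_COMP)


def is_palindrome(seq: str) -> bool:
    """True when the sequence equals its own reverse complement (even length)."""
    return len(seq) % 2 == 0 and seq == revcomp(seq)


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence with the requested expected GC content."""
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=n, p=p)])


def at_rich_dna(n: int, at: float, rng: np.random.Generator) -> str:
    """Random sequence with AT fraction `at` (used for attachment-site arms)."""
    return random_dna(n, 1.0 - at, rng)


def common_suffix_len(a: str, b: str, cap: int | None = None) -> int:
    n = min(len(a), len(b))
    if cap is not None:
        n = min(n, cap)
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def common_prefix_len(a: str, b: str, cap: int | None = None) -> int:
    n = min(len(a), len(b))
    if cap is not None:
        n = min(n, cap)
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def encode(seq: str) -> np.ndarray:
    """Map ACGT to 0..3 as a uint8 array."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        out[arr == b] = i
    return out


@dataclass
class TruthFeature:
    """A planted feature with validated coordinates (0-based, half-open)."""

    genome_id: str
    feature: str  # attL, attR, attB, telRL, TSD, EVE_interval, IS4, ...
    start: int
    end: int
    detail: str = ""

    def shifted(self, offset: int, genome_id: str | None = None) -> "TruthFeature":
        return TruthFeature(
            genome_id if genome_id is not None else self.genome_id,
            self.feature,
            self.start + offset,
            self.end + offset,
            self.detail,
        )


@dataclass
class TruthSet:
    """Ground truth for simulated genomes: every planted feature, validatable."""

    features: list[TruthFeature] = field(default_factory=list)

    def add(self, *args, **kwargs) -> None:
        self.features.append(TruthFeature(*args, **kwargs))

    def get(self, feature: str, genome_id: str | None = None) -> list[TruthFeature]:
        return [
            f
            for f in self.features
            if f.feature == feature and (genome_id is None or f.genome_id == genome_id)
        ]

    def one(self, feature: str, genome_id: str | None = None) -> TruthFeature:
        hits = self.get(feature, genome_id)
        if len(hits) != 1:
            raise ValueError(f"expected exactly one {feature!r} record, found {len(hits)}")
        return hits[0]

    def extend(self, other: "TruthSet") -> None:
        self.features.extend(other.features)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)
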