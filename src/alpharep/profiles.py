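"""Position-specific residue statistics of aligned repeat-module collections.

The design target of the randomization scheme is the empirical amino-acid
distribution observed at each variable position of a large aligned
collection of natural HEAT-like 31-residue repeat modules, plus the joint
(dipeptide) distribution at the two adjacent variable-position pairs 18-19
and 22-23.  This module builds those statistics from an aligned collection,
applies the curation rule (drop modules with more than a fixed number of
indels), and provides a seeded synthetic-collection generator so the
pipeline can run without any external sequence database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import AMINO_ACIDS, ResidueDistribution
from .presets import MODULE_LENGTH, VARIABLE_POSITIONS

GAP = "-"

# Synthetic stand-in for a natural repeat-module consensus: 31 residues,
# variable positions (1-based) 18, 19, 22, 23, 26, 30 marked 'x'.
SYNTHETIC_MODULE_CONSENSUS = "QAIEAALTAIAKGDPRVxxLIxxLAxDPSxE"

# Synthetic per-position target distributions for the six variable
# positions, consistent with the qualitative biases of natural repeat
# families: Pro common at 18 and absent from 22-30, small side chains
# common at 23, large polar residues at 30.  These are NOT measured
# natural frequencies; they exist so the full pipeline is runnable.
DEFAULT_VARIABLE_PROFILE: dict[int, ResidueDistribution] = {
    18: ResidueDistribution({
        "P": 0.22, "A": 0.13, "S": 0.11, "T": 0.10, "D": 0.08, "E": 0.07,
        "G": 0.06, "K": 0.06, "R": 0.05, "V": 0.04, "L": 0.03, "Y": 0.03, "W": 0.02,
    }),
    19: ResidueDistribution({
        "E": 0.15, "A": 0.13, "Q": 0.11, "L": 0.10, "N": 0.09, "T": 0.08,
        "S": 0.08, "D": 0.07, "R": 0.06, "G": 0.05, "Y": 0.04, "F": 0.02, "W": 0.02,
    }),
    22: ResidueDistribution({
        "R": 0.14, "K": 0.12, "E": 0.11, "L": 0.10, "Q": 0.09, "A": 0.08,
        "T": 0.08, "V": 0.07, "I": 0.06, "M": 0.05, "S": 0.04, "Y": 0.03,
        "F": 0.02, "W": 0.01,
    }),
    23: ResidueDistribution({
        "A": 0.18, "S": 0.14, "T": 0.13, "G": 0.12, "V": 0.09, "N": 0.08,
        "D": 0.07, "E": 0.06, "R": 0.05, "Q": 0.04, "L": 0.02, "I": 0.02,
    }),
    26: ResidueDistribution({
        "A": 0.14, "L": 0.12, "S": 0.10, "T": 0.10, "V": 0.09, "N": 0.08,
        "D": 0.08, "E": 0.07, "K": 0.06, "R": 0.05, "Q": 0.04, "G": 0.03,
        "Y": 0.02, "I": 0.02,
    }),
    30: ResidueDistribution({"E": 0.40, "K": 0.30, "Q": 0.20, "R": 0.06, "N": 0.04}),
}


@dataclass
class RepeatCollection:
    """An aligned collection of repeat modules (rows of equal length).

    Gap characters ('-') are allowed; a module's indel count is its number
    of gap characters.
    """

    modules: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.modules:
            raise ValueError("empty repeat collection")
        length = len(self.modules[0])
        for i, m in enumerate(self.modules):
            if len(m) != length:
                raise ValueError(
                    f"module {i} has length {len(m)}, expected {length} (unaligned input?)"
                )
        self.modules = [m.upper() for m in self.modules]
        if not self.ids:
            self.ids = [f"module_{i:05d}" for i in range(len(self.modules))]

    def __len__(self) -> int:
        return len(self.modules)

    @property
    def alignment_length(self) -> int:
        return len(self.modules[0])

    def indel_counts(self) -> np.ndarray:
        return np.array([m.count(GAP) for m in self.modules], dtype=int)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "RepeatCollection":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([str(r.seq) for r in records], [r.id for r in records])

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(m), id=i, description="")
            for i, m in zip(self.ids, self.modules)
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class PositionProfile:
    """Residue distribution at one 1-based module position."""

    position: int
    distribution: ResidueDistribution


class DipeptideTable:
    """Joint residue-pair frequencies at an ordered position pair.

    Wraps a DataFrame with columns (res_a, res_b, frequency, rank); ranks
    are by decreasing frequency with lexicographic tie-breaking so top-N
    queries are deterministic.
    """

    def __init__(self, pair: tuple[int, int], freqs: dict[tuple[str, str], float]):
        if not freqs:
            raise ValueError("empty dipeptide table")
        total = float(sum(freqs.values()))
        rows = [
            {"res_a": a, "res_b": b, "frequency": f / total}
            for (a, b), f in freqs.items()
            if f > 0
        ]
        df = pd.DataFrame(rows).sort_values(
            ["frequency", "res_a", "res_b"], ascending=[False, True, True]
        )
        df["rank"] = np.arange(1, len(df) + 1)
        self.pair = (int(pair[0]), int(pair[1]))
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def frequency(self, a: str, b: str) -> float:
        hit = self.table[(self.table.res_a == a) & (self.table.res_b == b)]
        return float(hit.frequency.iloc[0]) if len(hit) else 0.0

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {
            (r.res_a, r.res_b): r.frequency for r in self.table.itertuples(index=False)
        }

    def top_n(self, n: int) -> set[tuple[str, str]]:
        if n > len(self.table):
            raise ValueError(
                f"requested top {n} pairs but only {len(self.table)} observed"
            )
        head = self.table.head(n)
        return {(r.res_a, r.res_b) for r in head.itertuples(index=False)}

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def curate_collection(
    collection: RepeatCollection, max_indels: int = 3
) -> RepeatCollection:
    """Drop modules with more than *max_indels* gap characters.

    Mirrors the curation applied to the natural collection: repeats with
    more than three indels relative to the 31-column alignment are removed.
    """
    if max_indels < 0:
        raise ValueError("max_indels must be >= 0")
    counts = collection.indel_counts()
    keep = [i for i, c in enumerate(counts) if c <= max_indels]
    if not keep:
        raise ValueError("curation removed every module")
    return RepeatCollection(
        [collection.modules[i] for i in keep], [collection.ids[i] for i in keep]
    )


def position_frequencies(
    collection: RepeatCollection, position: int
) -> ResidueDistribution:
    """Empirical residue distribution at a 1-based position; gaps excluded."""
    if not 1 <= position <= collection.alignment_length:
        raise ValueError(
            f"position {position} outside module length {collection.alignment_length}"
        )
    col = [m[position - 1] for m in collection.modules if m[position - 1] != GAP]
    if not col:
        raise ValueError(f"position {position} is all-gap")
    counts: dict[str, float] = {}
    for res in col:
        counts[res] = counts.get(res, 0.0) + 1.0
    return ResidueDistribution(counts)


def dipeptide_frequencies(
    collection: RepeatCollection, pair: tuple[int, int]
) -> DipeptideTable:
    """Joint residue-pair distribution at an ordered position pair."""
    a, b = pair
    for p in (a, b):
        if not 1 <= p <= collection.alignment_length:
            raise ValueError(f"position {p} outside module length")
    counts: dict[tuple[str, str], float] = {}
    for m in collection.modules:
        ra, rb = m[a - 1], m[b - 1]
        if GAP in (ra, rb):
            continue
        counts[(ra, rb)] = counts.get((ra, rb), 0.0) + 1.0
    if not counts:
        raise ValueError(f"no gap-free observations at pair {pair}")
    return DipeptideTable(pair, counts)


def boost_residues(
    dist: ResidueDistribution, multipliers: dict[str, float]
) -> ResidueDistribution:
    """Multiply selected residue frequencies (e.g. aromatic enrichment) and
    renormalize.  Multiplier 1.0 leaves a residue untouched."""
    boosted = {r: f * multipliers.get(r, 1.0) for r, f in dist.items()}
    return ResidueDistribution(boosted)


def _sample_residues(rng: np.random.Generator, dist: ResidueDistribution, n: int):
    residues = list(dist.keys())
    p = np.asarray([dist[r] for r in residues], dtype=float)
    p /= p.sum()
    return rng.choice(residues, size=n, p=p)


def generate_synthetic_collection(
    profile: dict[int, ResidueDistribution] | None = None,
    n: int = 1719,
    coupling: float = 0.0,
    joint_tables: dict[tuple[int, int], DipeptideTable] | None = None,
    consensus: str = SYNTHETIC_MODULE_CONSENSUS,
    substitution_rate: float = 0.05,
    gap_rate: float = 0.0,
    seed: int | None = None,
) -> RepeatCollection:
    """Generate an aligned synthetic module collection.

    Variable positions draw from *profile*; with probability *coupling*
    an adjacent pair (18-19, 22-23) is drawn jointly from the matching
    entry of *joint_tables* instead of independently from the marginals.
    Non-variable positions take the consensus residue, substituted at
    *substitution_rate* and gapped at *gap_rate* (both per position).
    Fully reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    if coupling > 0 and not joint_tables:
        raise ValueError("coupling > 0 requires joint_tables")
    profile = dict(profile) if profile is not None else dict(DEFAULT_VARIABLE_PROFILE)
    for pos, dist in profile.items():
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ValueError(f"profile at position {pos} is not normalized")
    if len(consensus) != MODULE_LENGTH:
        raise ValueError(f"consensus must have {MODULE_LENGTH} residues")
    rng = np.random.default_rng(seed)
    L = len(consensus)
    alphabet = list(AMINO_ACIDS)

    grid = np.empty((n, L), dtype="U1")
    variable = sorted(profile)
    for j in range(L):
        pos = j + 1
        if pos in variable:
            grid[:, j] = _sample_residues(rng, profile[pos], n)
        else:
            base = consensus[j]
            col = np.full(n, base, dtype="U1")
            if substitution_rate > 0:
                mask = rng.random(n) < substitution_rate
                col[mask] = rng.choice(alphabet, size=int(mask.sum()))
            grid[:, j] = col

    # Correlated adjacent pairs: overwrite a coupled fraction of rows.
    if coupling > 0:
        for pair, table in joint_tables.items():
            a, b = pair
            if a not in profile or b not in profile:
                continue
            coupled = rng.random(n) < coupling
            idx = np.nonzero(coupled)[0]
            if len(idx) == 0:
                continue
            pairs = list(table.as_dict().items())
            p = np.asarray([f for _, f in pairs])
            p /= p.sum()
            choice = rng.choice(len(pairs), size=len(idx), p=p)
            for row, c in zip(idx, choice):
                ra, rb = pairs[c][0]
                grid[row, a - 1] = ra
                grid[row, b - 1] = rb

    if gap_rate > 0:
        gaps = rng.random((n, L)) < gap_rate
        grid[gaps] = GAP

    return RepeatCollection(["".join(row) for row in grid])


def profile_to_csv(
    profiles: dict[int, ResidueDistribution], path: str | Path
) -> None:
    rows = [
        {"position": pos, "residue": res, "frequency": f}
        for pos, dist in sorted(profiles.items())
        for res, f in dist.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def collection_profiles(
    collection: RepeatCollection,
    positions: tuple[int, ...] = VARIABLE_POSITIONS,
) -> dict[int, ResidueDistribution]:
    """Per-position distributions at the given positions."""
    return {p: position_frequencies(collection, p) for p in positions}
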