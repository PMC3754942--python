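"""Degenerate (IUPAC) codon expansion and translation.

A degenerate codon such as ``vnk`` stands for an equimolar pool of concrete
codons obtained by expanding each ambiguity symbol (``v`` = A/C/G, ``n`` =
A/C/G/T, ``k`` = G/T).  Translating the pool under the standard genetic code
gives a residue distribution: the fraction of molecules in the pool that
encode each amino acid.  These distributions are the building blocks of a
randomization scheme in which several degenerate "cassettes" are mixed at
chosen proportions to approximate a target amino-acid distribution.

Stop codons in a pool are handled by an explicit :class:`StopPolicy` because
phage-display hosts are typically supE (amber-suppressing) strains: TAG may
be read through as Gln, while ochre/opal codons always truncate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum

from Bio.Seq import Seq

IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
AMBER = "TAG"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class StopPolicy(str, Enum):
    """How stop codons inside a degenerate pool are treated.

    ``ERROR``            -- reject the codon, naming the stop codons present.
    ``DROP_RENORMALIZE`` -- remove all stop codons from the pool and
                            renormalize over the coding codons (models
                            truncation products being lost from the library).
    ``AMBER_AS_GLN``     -- read TAG through as Gln (supE suppression);
                            TAA/TGA are still dropped.
    """

    ERROR = "error"
    DROP_RENORMALIZE = "drop-renormalize"
    AMBER_AS_GLN = "amber-as-Gln"


class StopCodonError(ValueError):
    """Raised when a pool contains stop codons under StopPolicy.ERROR."""


@dataclass(frozen=True)
class DegenerateCodon:
    """A three-symbol IUPAC degenerate codon, e.g. ``vnk`` or ``tgg``."""

    symbols: str

    def __post_init__(self) -> None:
        s = self.symbols.upper()
        if len(s) != 3:
            raise ValueError(
                f"degenerate codon must have exactly 3 symbols, got {self.symbols!r}"
            )
        for ch in s:
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"invalid IUPAC nucleotide symbol {ch!r} in codon {self.symbols!r}"
                )
        object.__setattr__(self, "symbols", s)

    @property
    def size(self) -> int:
        """Number of concrete codons in the equimolar pool."""
        return int(
            len(IUPAC_DNA[self.symbols[0]])
            * len(IUPAC_DNA[self.symbols[1]])
            * len(IUPAC_DNA[self.symbols[2]])
        )

    def expand(self) -> set[str]:
        return expand_degenerate_codon(self)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.symbols


class ResidueDistribution(dict):
    """Mapping one-letter residue -> frequency; frequencies sum to 1.

    Subclasses dict so it behaves like a plain mapping; construction
    normalizes and validates.
    """

    def __init__(self, freqs: dict[str, float]):
        total = float(sum(freqs.values()))
        if total <= 0:
            raise ValueError("residue distribution has no mass")
        cleaned = {}
        for res, f in freqs.items():
            if res not in AMINO_ACIDS:
                raise ValueError(f"unknown residue code {res!r}")
            if f < 0:
                raise ValueError(f"negative frequency for {res!r}")
            if f > 0:
                cleaned[res] = f / total
        super().__init__(sorted(cleaned.items()))

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.keys())

    def tv_distance(self, other: "ResidueDistribution") -> float:
        keys = set(self) | set(other)
        return 0.5 * sum(abs(self.get(k, 0.0) - other.get(k, 0.0)) for k in keys)


def _as_codon(codon: "DegenerateCodon | str") -> DegenerateCodon:
    return codon if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon)


def expand_degenerate_codon(codon: "DegenerateCodon | str") -> set[str]:
    """Expand a degenerate codon into its set of concrete upper-case codons."""
    codon = _as_codon(codon)
    out = {
        "".join(bases)
        for bases in itertools.product(*(IUPAC_DNA[s] for s in codon.symbols))
    }
    assert len(out) == codon.size
    return out


def translate_codon(concrete: str) -> str:
    """Translate one concrete codon under the standard genetic code ('*' = stop)."""
    return str(Seq(concrete).translate())


def translate_degenerate_codon(
    codon: "DegenerateCodon | str",
    policy: StopPolicy = StopPolicy.DROP_RENORMALIZE,
) -> ResidueDistribution:
    """Residue distribution of an equimolar degenerate-codon pool.

    Each concrete codon in the expansion carries equal weight; stop codons
    are handled according to *policy*.
    """
    codon = _as_codon(codon)
    pool = sorted(expand_degenerate_codon(codon))
    stops = [c for c in pool if c in STOP_CODONS]
    if policy == StopPolicy.ERROR and stops:
        raise StopCodonError(
            f"codon {codon.symbols!r} encodes stop codons: {', '.join(stops)}"
        )
    counts: dict[str, float] = {}
    for c in pool:
        if c in STOP_CODONS:
            if policy == StopPolicy.AMBER_AS_GLN and c == AMBER:
                counts["Q"] = counts.get("Q", 0.0) + 1.0
            continue  # TAA/TGA (and TAG under drop) removed from the pool
        aa = translate_codon(c)
        counts[aa] = counts.get(aa, 0.0) + 1.0
    if not counts:
        raise StopCodonError(
            f"codon {codon.symbols!r} encodes only stop codons under policy {policy.value}"
        )
    return ResidueDistribution(counts)


def mixture_distribution(
    cassettes: "list[tuple[DegenerateCodon | str, float]]",
    policy: StopPolicy = StopPolicy.DROP_RENORMALIZE,
) -> ResidueDistribution:
    """Weight-averaged residue distribution of a codon mixture.

    ``cassettes`` is a list of (codon, weight) pairs; weights are
    normalized internally, so the result is invariant to rescaling.
    """
    if not cassettes:
        raise ValueError("empty cassette list")
    total_w = float(sum(w for _, w in cassettes))
    if total_w <= 0:
        raise ValueError("cassette weights must have positive sum")
    if any(w < 0 for _, w in cassettes):
        raise ValueError("cassette weights must be non-negative")
    acc: dict[str, float] = {}
    for cod, w in cassettes:
        if w == 0:
            continue
        dist = translate_degenerate_codon(cod, policy)
        for res, f in dist.items():
            acc[res] = acc.get(res, 0.0) + (w / total_w) * f
    return ResidueDistribution(acc)
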