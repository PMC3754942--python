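"""Exact diversity accounting for combinatorial repeat libraries.

The encoded sequence space factorizes: each internal repeat draws
independently from the per-site alternative counts (87 dipeptides at 18-19,
60 at 22-23, 16 residues at 26, 3 at 30 for the published scheme, giving
250,560 repeat sequences), and a protein with n repeats multiplies the
repeat space n times on top of the N-cap alternatives.  All products use
Python big integers, so no space overflows.  Sampling coverage of a finite
library uses the classical occupancy expectation under uniform sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .presets import REPEAT_SITE_COUNTS


def repeat_space(counts=REPEAT_SITE_COUNTS) -> int:
    """Exact number of distinct repeat sequences: product of per-site counts."""
    out = 1
    for c in counts:
        c = int(c)
        if c < 0:
            raise ValueError("site counts must be >= 0")
        out *= c
    return out


def protein_space(repeat_space_size: int, ncap_space: int, n_repeats: int) -> int:
    """Exact number of distinct proteins with ``n_repeats`` internal repeats."""
    if n_repeats < 0:
        raise ValueError("repeat number must be >= 0")
    return int(ncap_space) * int(repeat_space_size) ** int(n_repeats)


def expected_distinct(library_size: float, space: int) -> float:
    """Expected number of distinct variants in a uniform sample.

    E[distinct] = S * (1 - (1 - 1/S)^L); computed via expm1/log1p so it is
    accurate when S is astronomically larger than L.
    """
    if library_size < 0:
        raise ValueError("library size must be >= 0")
    if space < 1:
        raise ValueError("space must be >= 1")
    s = float(space)
    if space == 1:
        return 1.0 if library_size > 0 else 0.0
    return -s * math.expm1(library_size * math.log1p(-1.0 / s))


@dataclass(frozen=True)
class DiversityReport:
    """Sequence-space sizes and sampling coverage across repeat numbers."""

    site_counts: tuple[int, ...]
    ncap_space: int
    library_size: float
    table: pd.DataFrame

    @classmethod
    def build(
        cls,
        site_counts=REPEAT_SITE_COUNTS,
        ncap_space: int = 1,
        library_size: float = 1.7e9,
        n_repeats: range = range(0, 8),
    ) -> "DiversityReport":
        rs = repeat_space(site_counts)
        rows = []
        for n in n_repeats:
            space = protein_space(rs, ncap_space, n)
            exp = expected_distinct(library_size, space) if space >= 1 else 0.0
            rows.append(
                {
                    "n_repeats": n,
                    "space": space,
                    "expected_distinct": exp,
                    "coverage": exp / space if space else float("nan"),
                }
            )
        return cls(
            site_counts=tuple(int(c) for c in site_counts),
            ncap_space=int(ncap_space),
            library_size=float(library_size),
            table=pd.DataFrame(rows),
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
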