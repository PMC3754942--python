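"""Stochastic model of micro-gene polymerization library construction.

A clone is an N-cap, an ordered run of internal modules, and a C-cap.  Each
module (and optionally each cap) independently carries a frame-shift defect
with some probability; a clone is "in frame" (coding) iff no segment is
defective.  The model captures the dominant failure mode of rolling-circle
assembled repeat libraries — incorrectly synthesized or mis-assembled
oligonucleotide modules — and reproduces the characteristic statistics of
such libraries: the fraction of correct motifs, the fraction of in-frame
clones, and the mean motif number among coding clones (which is depressed
relative to the assembly length distribution because long clones are more
likely to contain a defect).

Two construction steps are modeled on top of raw assembly:

* filtration — phage-display capture of clones displaying the N-terminal
  tag retains exactly the in-frame subpopulation;
* module shuffling — pre-validated (defect-free) modules from the filtered
  pool are re-assembled into new clones with fresh length draws; each
  ligation introduces a new defect with a small probability.

Filtration followed by shuffling raises both the in-frame fraction and the
mean motif number among coding clones, which is the point of the two-step
optimized construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AssemblyConfig:
    """Parameters of the assembly error model.

    ``repeat_dist`` is the clone length (module count) distribution:
    ``("geometric", q)`` for a truncated geometric p(n) ∝ q^n on
    0..n_max, or ``("fixed", n)`` for a deterministic length.
    ``eps_mod``/``eps_cap``/``eps_lig`` are the per-module, per-cap and
    per-ligation (shuffling) defect probabilities.
    """

    repeat_dist: tuple = ("geometric", 0.75)
    n_max: int = 10
    eps_mod: float = 0.2
    eps_cap: float = 0.0
    eps_lig: float = 0.03

    def __post_init__(self) -> None:
        for name in ("eps_mod", "eps_cap", "eps_lig"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.length_pmf()  # validates repeat_dist

    def length_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Support 0..n_max and probabilities of the module-count law."""
        family, param = self.repeat_dist
        support = np.arange(self.n_max + 1)
        if family == "geometric":
            if not 0.0 <= param < 1.0:
                raise ValueError("geometric ratio must be in [0, 1)")
            p = np.power(param, support, dtype=float)
        elif family == "fixed":
            n = int(param)
            if not 0 <= n <= self.n_max:
                raise ValueError(f"fixed length {n} outside 0..{self.n_max}")
            p = np.zeros(self.n_max + 1)
            p[n] = 1.0
        elif family == "custom":
            p = np.asarray(param, dtype=float)
            if len(p) != self.n_max + 1 or (p < 0).any() or p.sum() <= 0:
                raise ValueError("custom pmf must be non-negative on 0..n_max")
        else:
            raise ValueError(f"unknown repeat-number family {family!r}")
        return support, p / p.sum()


class ClonePopulation:
    """A set of simulated clones stored as flat arrays.

    Per clone: N-cap/C-cap defect flags, module count, and per-module
    defect flags (a boolean matrix padded to the maximum module count).
    """

    def __init__(
        self,
        n_modules: np.ndarray,
        module_defect: np.ndarray,
        ncap_defect: np.ndarray,
        ccap_defect: np.ndarray,
    ):
        self.n_modules = np.asarray(n_modules, dtype=int)
        self.module_defect = np.asarray(module_defect, dtype=bool)
        self.ncap_defect = np.asarray(ncap_defect, dtype=bool)
        self.ccap_defect = np.asarray(ccap_defect, dtype=bool)
        N = len(self.n_modules)
        if not (len(self.ncap_defect) == len(self.ccap_defect) == N
                and self.module_defect.shape[0] == N):
            raise ValueError("inconsistent clone array lengths")
        if self.n_modules.min(initial=0) < 0:
            raise ValueError("negative module count")
        # defects beyond each clone's module count are padding; force clear
        pad = np.arange(self.module_defect.shape[1])[None, :] >= self.n_modules[:, None]
        self.module_defect = self.module_defect & ~pad

    def __len__(self) -> int:
        return len(self.n_modules)

    @property
    def defective_module_counts(self) -> np.ndarray:
        return self.module_defect.sum(axis=1)

    @property
    def in_frame(self) -> np.ndarray:
        return (
            ~self.ncap_defect
            & ~self.ccap_defect
            & (self.defective_module_counts == 0)
        )

    def subset(self, index: np.ndarray) -> "ClonePopulation":
        return ClonePopulation(
            self.n_modules[index],
            self.module_defect[index],
            self.ncap_defect[index],
            self.ccap_defect[index],
        )

    @classmethod
    def from_flags(cls, clones: list[tuple[bool, list[bool], bool]]) -> "ClonePopulation":
        """Build from explicit (ncap_defect, module defect flags, ccap_defect)
        triples — convenient for hand-built populations in tests."""
        n = np.array([len(mods) for _, mods, _ in clones])
        width = max(int(n.max(initial=0)), 1)
        mat = np.zeros((len(clones), width), dtype=bool)
        for i, (_, mods, _) in enumerate(clones):
            mat[i, : len(mods)] = mods
        return cls(
            n,
            mat,
            np.array([nc for nc, _, _ in clones]),
            np.array([cc for _, _, cc in clones]),
        )


@dataclass(frozen=True)
class LibraryStats:
    """Sequencing-sample statistics of a clone population (one library row)."""

    sample_size: int
    total_motifs: int
    correct_motif_fraction: float
    in_frame_fraction: float
    in_frame_n1_fraction: float
    mean_motifs_in_frame: float
    mean_motifs_in_frame_n1: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Sample size": self.sample_size,
                    "Total motifs": self.total_motifs,
                    "Proportion of correct motifs": self.correct_motif_fraction,
                    "In-frame clones": self.in_frame_fraction,
                    "In-frame clones (n>=1)": self.in_frame_n1_fraction,
                    "Average motifs number": self.mean_motifs_in_frame,
                    "Average motifs number (n>=1)": self.mean_motifs_in_frame_n1,
                }
            ]
        )


def simulate_assembly(
    config: AssemblyConfig, n_clones: int, seed: int | None = None
) -> ClonePopulation:
    """Draw a raw assembled library of ``n_clones`` clones."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    support, pmf = config.length_pmf()
    n = rng.choice(support, size=n_clones, p=pmf)
    width = max(config.n_max, 1)
    defects = rng.random((n_clones, width)) < config.eps_mod
    return ClonePopulation(
        n,
        defects,
        rng.random(n_clones) < config.eps_cap,
        rng.random(n_clones) < config.eps_cap,
    )


def analytic_inframe(config: AssemblyConfig) -> float:
    """Exact in-frame probability: (1-ε_cap)² Σ_n p(n) (1-ε_mod)^n."""
    support, pmf = config.length_pmf()
    return float(
        (1.0 - config.eps_cap) ** 2
        * np.sum(pmf * (1.0 - config.eps_mod) ** support)
    )


def analytic_mean_motifs_inframe(config: AssemblyConfig) -> float:
    """Mean module count conditional on the clone being in frame."""
    support, pmf = config.length_pmf()
    w = pmf * (1.0 - config.eps_mod) ** support
    return float(np.sum(support * w) / np.sum(w))


def filter_inframe(population: ClonePopulation) -> ClonePopulation:
    """Phage-display filtration: retain exactly the in-frame clones."""
    return population.subset(np.nonzero(population.in_frame)[0])


def shuffle_modules(
    filtered: ClonePopulation,
    config: AssemblyConfig,
    n_clones: int | None = None,
    seed: int | None = None,
) -> ClonePopulation:
    """Re-assemble new clones from the pooled modules of filtered clones.

    All pooled modules are defect-free (the input must be in-frame); each
    placement in a new clone acquires a fresh defect with probability
    ``eps_lig``, and caps with ``eps_cap``.
    """
    if len(filtered) == 0:
        raise ValueError("cannot shuffle an empty filtered population")
    if not bool(np.all(filtered.in_frame)):
        raise ValueError("shuffling input must be filtered to in-frame clones")
    pool_size = int(filtered.n_modules.sum())
    if pool_size == 0:
        raise ValueError("filtered population contributes no modules to the pool")
    if n_clones is None:
        n_clones = len(filtered)
    rng = np.random.default_rng(seed)
    support, pmf = config.length_pmf()
    n = rng.choice(support, size=n_clones, p=pmf)
    width = max(config.n_max, 1)
    defects = rng.random((n_clones, width)) < config.eps_lig
    return ClonePopulation(
        n,
        defects,
        rng.random(n_clones) < config.eps_cap,
        rng.random(n_clones) < config.eps_cap,
    )


def library_stats(
    population: ClonePopulation,
    sample_size: int | None = None,
    seed: int | None = None,
) -> LibraryStats:
    """Statistics of a random clone sample, mirroring a sequencing picksheet.

    ``sample_size`` defaults to the full population (deterministic stats);
    smaller values draw a seeded sample without replacement, as when a
    library is characterized by sequencing randomly picked clones.
    """
    N = len(population)
    m = N if sample_size is None else int(sample_size)
    if m < 1:
        raise ValueError("sample size must be >= 1")
    if m > N:
        raise ValueError(f"sample size {m} exceeds population size {N}")
    if m == N:
        sample = population
    else:
        rng = np.random.default_rng(seed)
        sample = population.subset(rng.choice(N, size=m, replace=False))

    total_motifs = int(sample.n_modules.sum())
    bad_motifs = int(sample.defective_module_counts.sum())
    inframe = sample.in_frame
    n = sample.n_modules
    n1 = inframe & (n >= 1)
    return LibraryStats(
        sample_size=m,
        total_motifs=total_motifs,
        correct_motif_fraction=(
            (total_motifs - bad_motifs) / total_motifs if total_motifs else float("nan")
        ),
        in_frame_fraction=float(inframe.mean()),
        in_frame_n1_fraction=float(n1.mean()),
        mean_motifs_in_frame=float(n[inframe].mean()) if inframe.any() else float("nan"),
        mean_motifs_in_frame_n1=float(n[n1].mean()) if n1.any() else float("nan"),
    )


def independent_module_inframe(
    correct_motif_fraction: float, mean_motifs: float
) -> float:
    """In-frame fraction predicted by the independent-module error model.

    With per-module correctness q and average module count n̄, a clone is
    coding with probability ≈ q^n̄.  Useful for checking the internal
    consistency of reported library characterization rows.
    """
    if not 0.0 < correct_motif_fraction <= 1.0:
        raise ValueError("correct-motif fraction must be in (0, 1]")
    if mean_motifs < 0:
        raise ValueError("mean module count must be >= 0")
    return float(correct_motif_fraction ** mean_motifs)
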