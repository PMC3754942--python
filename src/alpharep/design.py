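"""Degenerate-cassette selection and mixing-weight optimization.

Adjacent variable positions (18-19 and 22-23 of the internal module) sit on
the same synthetic oligonucleotide, so their joint diversity must be encoded
by a limited set of degenerate codon-pair cassettes.  Given the per-position
degenerate codon lists, this module:

* enumerates all candidate cassettes (codon pairs) and the amino-acid
  dipeptides each encodes,
* selects a budget-limited subset maximizing dipeptide coverage (greedy
  weighted max-coverage followed by single-swap local refinement — the
  classic (1 - 1/e) approximation with a deterministic tie-break),
* fits cassette mixing proportions on the probability simplex so the
  realized residue/dipeptide distribution matches a natural target
  (simplex-constrained least squares, or relative entropy), and
* reports design metrics: distinct dipeptides encoded, overlap with the
  top-N natural dipeptides, and divergence from the target distribution.

Design constraints (no Cys anywhere, no Pro at configured positions, no
stop read-through) are enforced by rejecting violating cassettes up front.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .codons import (
    DegenerateCodon,
    ResidueDistribution,
    StopPolicy,
    translate_degenerate_codon,
)
from .profiles import DipeptideTable

Item = "str | tuple[str, str]"


@dataclass(frozen=True)
class DesignConstraints:
    """Residue-level constraints on the coding scheme."""

    forbidden: dict[int, frozenset[str]] = field(default_factory=dict)
    stop_policy: StopPolicy = StopPolicy.DROP_RENORMALIZE
    budget: int | None = None

    @classmethod
    def alpharep_default(cls, budget: int | None = None) -> "DesignConstraints":
        """No Cys at any position; no Pro at positions 22, 23, 26."""
        forbidden = {p: frozenset("C") for p in (18, 19, 22, 23, 26, 30)}
        for p in (22, 23, 26):
            forbidden[p] = forbidden[p] | frozenset("P")
        return cls(forbidden=forbidden, budget=budget)

    def allowed(self, position: int, residue: str) -> bool:
        return residue not in self.forbidden.get(position, frozenset())


@dataclass
class Cassette:
    """One degenerate codon (single site) or an ordered codon pair."""

    codons: tuple[str, ...]
    positions: tuple[int, ...]
    distribution: dict = field(default_factory=dict)  # item -> probability
    feasible: bool = True
    violations: tuple[str, ...] = ()
    weight: float = 0.0

    @property
    def encoded(self) -> frozenset:
        return frozenset(self.distribution)

    @property
    def label(self) -> str:
        return "-".join(self.codons)


@dataclass
class CassetteLibrary:
    """A selected cassette set with (optional) mixing weights."""

    cassettes: list[Cassette]
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.cassettes:
            raise ValueError("empty cassette library")

    @property
    def encoded(self) -> frozenset:
        out: frozenset = frozenset()
        for c in self.cassettes:
            out = out | c.encoded
        return out

    def achieved_distribution(self) -> dict:
        """Weight-averaged item distribution (uniform weights if unset)."""
        weights = np.array([c.weight for c in self.cassettes], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones(len(self.cassettes))
        weights = weights / weights.sum()
        acc: dict = {}
        for w, c in zip(weights, self.cassettes):
            for item, p in c.distribution.items():
                acc[item] = acc.get(item, 0.0) + w * p
        return acc

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cassettes:
            rows.append(
                {
                    "site": "-".join(map(str, self.positions)),
                    "cassette_codons": c.label,
                    "weight": c.weight,
                    "encoded_set": ";".join(
                        "".join(i) if isinstance(i, tuple) else i
                        for i in sorted(c.encoded)
                    ),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DesignMetrics:
    distinct_encoded: int
    top_n: int
    top_n_covered: int
    tv_distance: float
    kl_divergence: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _build_cassette(
    codons: tuple[str, ...],
    positions: tuple[int, ...],
    constraints: DesignConstraints,
) -> Cassette:
    dists = [
        translate_degenerate_codon(DegenerateCodon(c), constraints.stop_policy)
        for c in codons
    ]
    violations = []
    for pos, dist in zip(positions, dists):
        for res in dist:
            if not constraints.allowed(pos, res):
                violations.append(f"{res}@{pos}")
    if len(dists) == 1:
        distribution: dict = dict(dists[0])
    else:
        distribution = {
            (a, b): pa * pb
            for (a, pa), (b, pb) in itertools.product(dists[0].items(), dists[1].items())
        }
    return Cassette(
        codons=tuple(c.upper() for c in codons),
        positions=positions,
        distribution=distribution,
        feasible=not violations,
        violations=tuple(violations),
    )


def enumerate_candidates(
    codons_a: list[str],
    codons_b: list[str] | None,
    positions: tuple[int, ...],
    constraints: DesignConstraints | None = None,
) -> list[Cassette]:
    """All candidate cassettes for one site (or ordered site pair).

    With two codon lists, every ordered pair is produced; cassettes whose
    encoded residues violate a constraint are flagged infeasible, not
    silently dropped.
    """
    if not codons_a or (codons_b is not None and not codons_b):
        raise ValueError("codon lists must be non-empty")
    constraints = constraints or DesignConstraints()
    if codons_b is None:
        combos = [(c,) for c in codons_a]
    else:
        combos = [(a, b) for a in codons_a for b in codons_b]
    return [_build_cassette(c, positions, constraints) for c in combos]


def _item_weights(target, items) -> dict:
    if target is None:
        return {i: 1.0 for i in items}
    if isinstance(target, DipeptideTable):
        freqs = target.as_dict()
    else:
        freqs = dict(target)
    return {i: freqs.get(i, 0.0) for i in items}


def _coverage(selected: list[Cassette], weights: dict) -> float:
    covered: set = set()
    for c in selected:
        covered |= c.encoded
    return sum(weights[i] for i in covered)


def select_cassettes(
    candidates: list[Cassette],
    budget: int,
    target=None,
    mode: str = "max-coverage",
) -> list[Cassette]:
    """Budget-limited cassette selection by greedy max-coverage plus swaps.

    In ``max-coverage`` mode every dipeptide counts equally; in
    ``target-weighted-coverage`` mode a dipeptide counts its natural
    frequency (items absent from the target count zero).  Greedy selection
    is followed by single-swap local search until no swap improves the
    (weighted) coverage.  Ties break lexicographically on the cassette
    codon strings, so the result is deterministic.
    """
    if budget < 1:
        raise ValueError("cassette budget must be >= 1")
    if mode not in ("max-coverage", "target-weighted-coverage"):
        raise ValueError(f"unknown selection mode {mode!r}")
    pool = sorted(
        (c for c in candidates if c.feasible), key=lambda c: c.label
    )
    if not pool:
        raise ValueError("no feasible candidate cassettes")
    all_items: set = set()
    for c in pool:
        all_items |= c.encoded
    weights = _item_weights(target if mode == "target-weighted-coverage" else None,
                            all_items)

    selected: list[Cassette] = []
    covered: set = set()
    remaining = list(pool)
    while remaining and len(selected) < budget:
        best, best_gain = None, -1.0
        for c in remaining:  # pool is label-sorted: first max wins ties
            gain = sum(weights[i] for i in c.encoded - covered)
            if gain > best_gain:
                best, best_gain = c, gain
        if best_gain <= 0 and selected:
            break
        selected.append(best)
        covered |= best.encoded
        remaining.remove(best)

    # Single-swap refinement: replace one selected cassette by one unselected
    # if it strictly improves coverage; repeat to a fixed point.
    improved = True
    while improved:
        improved = False
        current = _coverage(selected, weights)
        for i, out in enumerate(list(selected)):
            for cand in pool:
                if cand in selected:
                    continue
                trial = selected[:i] + [cand] + selected[i + 1:]
                if _coverage(trial, weights) > current + 1e-15:
                    selected = trial
                    improved = True
                    current = _coverage(selected, weights)
                    break
            if improved:
                break
    return selected


def optimize_weights(
    library: CassetteLibrary,
    target,
    objective: str = "squared",
    tol: float = 1e-9,
) -> CassetteLibrary:
    """Fit cassette mixing proportions to a target distribution.

    Minimizes either the squared Euclidean distance (default) or the
    relative entropy KL(target || achieved) between the weight-averaged
    encoded distribution and the target, with weights constrained to the
    probability simplex.  Target mass on items no cassette can encode is
    reported on the returned library as ``irreducible_mass``.
    """
    if isinstance(target, DipeptideTable):
        tdict = target.as_dict()
    else:
        tdict = dict(target)
    total = sum(tdict.values())
    if total <= 0:
        raise ValueError("target distribution has no mass")
    tdict = {k: v / total for k, v in tdict.items()}

    items = sorted(set().union(*(c.encoded for c in library.cassettes)) | set(tdict))
    irreducible = sum(
        f for i, f in tdict.items()
        if all(i not in c.encoded for c in library.cassettes)
    )
    A = np.array(
        [[c.distribution.get(i, 0.0) for c in library.cassettes] for i in items]
    )
    t = np.array([tdict.get(i, 0.0) for i in items])
    K = len(library.cassettes)

    if objective == "squared":
        def fun(w):
            r = A @ w - t
            return float(r @ r)

        def jac(w):
            return 2.0 * A.T @ (A @ w - t)
    elif objective == "relative-entropy":
        eps = 1e-12

        def fun(w):
            q = A @ w
            mask = t > 0
            return float(np.sum(t[mask] * np.log(t[mask] / np.maximum(q[mask], eps))))

        def jac(w):
            q = np.maximum(A @ w, eps)
            mask = t > 0
            return -(A[mask].T @ (t[mask] / q[mask]))
    else:
        raise ValueError(f"unknown objective {objective!r}")

    w0 = np.full(K, 1.0 / K)
    res = minimize(
        fun,
        w0,
        jac=jac,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"maxiter": 2000, "ftol": tol},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    out = CassetteLibrary(
        cassettes=[
            Cassette(c.codons, c.positions, dict(c.distribution), c.feasible,
                     c.violations, float(wi))
            for c, wi in zip(library.cassettes, w)
        ],
        positions=library.positions,
    )
    out.objective_value = float(fun(w))
    out.irreducible_mass = float(irreducible)
    return out


def evaluate_design(
    library: CassetteLibrary,
    natural: DipeptideTable,
    n: int = 100,
) -> DesignMetrics:
    """Design metrics against a natural dipeptide table.

    ``top_n_covered`` is the number of the N most frequent natural
    dipeptides the library encodes (the headline figure of merit for a
    coverage-driven design).
    """
    if isinstance(natural, DipeptideTable) and tuple(natural.pair) != tuple(
        library.positions
    ):
        raise ValueError(
            f"library positions {library.positions} != table pair {natural.pair}"
        )
    encoded = library.encoded
    n_eff = min(n, len(natural))
    top = natural.top_n(n_eff)
    achieved = library.achieved_distribution()
    nat = natural.as_dict()
    keys = set(achieved) | set(nat)
    tv = 0.5 * sum(abs(achieved.get(k, 0.0) - nat.get(k, 0.0)) for k in keys)
    eps = 1e-12
    kl = sum(
        f * np.log(f / max(achieved.get(k, 0.0), eps))
        for k, f in nat.items()
        if f > 0
    )
    return DesignMetrics(
        distinct_encoded=len(encoded),
        top_n=n_eff,
        top_n_covered=len(encoded & top),
        tv_distance=float(tv),
        kl_divergence=float(kl),
    )


def design_site_pair(
    codons_a: list[str],
    codons_b: list[str],
    positions: tuple[int, int],
    budget: int,
    target: DipeptideTable | None = None,
    mode: str = "max-coverage",
    constraints: DesignConstraints | None = None,
) -> CassetteLibrary:
    """End-to-end: enumerate, select, and (if a target is given) weight."""
    constraints = constraints or DesignConstraints.alpharep_default()
    candidates = enumerate_candidates(codons_a, codons_b, positions, constraints)
    chosen = select_cassettes(candidates, budget, target=target, mode=mode)
    library = CassetteLibrary(chosen, positions)
    if target is not None:
        library = optimize_weights(library, target)
    return library
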