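"""Clone parsing against a repeat-protein scaffold.

A clone is N-cap + k x (31-residue internal module) + C-cap.  Because the
module length is fixed, segmentation is exact length arithmetic once the
caps are anchored by a sliding consensus match; no profile alignment is
needed.  The annotator recovers k (the motif count) and the residues at the
six variable positions (18, 19, 22, 23, 26, 30) of the N-cap and of every
internal module, producing the standard binder-characterization table (one
row per motif, one column per variable position).

At the DNA level, modules are joined through a restriction site that
overlaps the codon of variable position 30's neighbourhood; the frame
checker verifies segment lengths modulo 3, internal stop codons, and
restriction-site integrity at every junction.

The scaffold consensus shipped here is SYNTHETIC (the real cap and module
sequences come from the scaffold's prior design work and are supplied via
config); it exists so fixtures and round-trip tests are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .presets import MODULE_LENGTH, VARIABLE_POSITIONS

WILDCARD = "X"

# Fixed codon per residue for back-translation.  Chosen so that the module
# junction (Gly at module position 31 followed by Thr at position 1 of the
# next segment) reads GGTACC, a KpnI-style assembly site.
BACKTRANSLATION: dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAC",
}

# Synthetic scaffold consensus: 'X' marks variable positions.
SYNTHETIC_NCAP = "TSIEEALRAIAKGDPRIXXLIXXLAXDPSXG"
SYNTHETIC_MODULE = "TAIEAALRAIAKGDPRVXXLIXXLAXDPSXG"
SYNTHETIC_CCAP = "TDPEVRAAAEKALGQIQ"


@dataclass(frozen=True)
class ScaffoldSpec:
    """Scaffold consensus sequences and matching parameters."""

    ncap: str = SYNTHETIC_NCAP
    module: str = SYNTHETIC_MODULE
    ccap: str = SYNTHETIC_CCAP
    variable_positions: tuple[int, ...] = VARIABLE_POSITIONS
    ncap_variable_positions: tuple[int, ...] = VARIABLE_POSITIONS
    max_mismatch_fraction: float = 0.2
    restriction_site: str = "GGTACC"
    min_ccap_length: int | None = None  # allow C-terminal truncation if set

    def __post_init__(self) -> None:
        if len(self.module) != MODULE_LENGTH:
            raise ValueError(
                f"module consensus must have {MODULE_LENGTH} residues"
            )
        for p in self.variable_positions:
            if not 1 <= p <= len(self.module):
                raise ValueError(f"variable position {p} outside module")
        for p in self.ncap_variable_positions:
            if not 1 <= p <= len(self.ncap):
                raise ValueError(f"N-cap variable position {p} outside N-cap")

    def module_fixed_positions(self) -> list[int]:
        return [
            p for p in range(1, len(self.module) + 1)
            if p not in self.variable_positions
        ]


@dataclass
class CloneAnnotation:
    """Segmentation of a clone plus its variable-position residue calls."""

    ncap_span: tuple[int, int]
    module_spans: list[tuple[int, int]]
    ccap_span: tuple[int, int]
    ncap_calls: dict[int, str]
    module_calls: list[dict[int, str]]

    @property
    def motif_count(self) -> int:
        return len(self.module_spans)

    def to_frame(self) -> pd.DataFrame:
        """Binder-characterization layout: one row per motif, one column
        per variable position (N-cap variable positions share the module
        column numbering)."""
        cols = sorted(set(self.ncap_calls) | {
            p for c in self.module_calls for p in c
        })
        rows = [{"motif": "N-cap",
                 **{f"pos{p}": self.ncap_calls.get(p, "") for p in cols}}]
        for i, calls in enumerate(self.module_calls, start=1):
            rows.append({"motif": f"M{i}",
                         **{f"pos{p}": calls.get(p, "") for p in cols}})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FrameReport:
    """DNA-level reading-frame diagnostics."""

    length_mod3_ok: bool
    module_region_ok: bool
    stop_codon_positions: tuple[int, ...]
    corrupted_junctions: tuple[int, ...]
    frame_shifted_module: int | None

    @property
    def in_frame(self) -> bool:
        return (
            self.length_mod3_ok
            and self.module_region_ok
            and not self.stop_codon_positions
            and not self.corrupted_junctions
        )


class AnnotationError(ValueError):
    """Raised when a clone cannot be segmented against the scaffold."""


def _mismatch_fraction(segment: str, consensus: str, variable: tuple[int, ...]) -> float:
    fixed = [p for p in range(1, len(consensus) + 1) if p not in variable
             and consensus[p - 1] != WILDCARD]
    if not fixed:
        return 0.0
    bad = sum(1 for p in fixed if segment[p - 1] != consensus[p - 1])
    return bad / len(fixed)


def annotate_protein(sequence: str, spec: ScaffoldSpec | None = None) -> CloneAnnotation:
    """Segment a protein clone and call its variable-position residues.

    The N-cap is anchored at the earliest offset where its fixed positions
    match within the mismatch threshold; the motif count k then follows
    from exact length arithmetic, possibly with a truncated C-cap if the
    spec allows one.
    """
    spec = spec or ScaffoldSpec()
    seq = sequence.upper().strip("*")
    nlen, mlen, clen = len(spec.ncap), len(spec.module), len(spec.ccap)
    min_ccap = clen if spec.min_ccap_length is None else spec.min_ccap_length

    # anchor the N-cap (sliding to tolerate leading tags)
    start = None
    for off in range(0, max(len(seq) - nlen, 0) + 1):
        window = seq[off: off + nlen]
        if len(window) < nlen:
            break
        if _mismatch_fraction(window, spec.ncap, spec.ncap_variable_positions) \
                <= spec.max_mismatch_fraction:
            start = off
            break
    if start is None:
        raise AnnotationError("no N-cap match within the mismatch threshold")

    body = len(seq) - start - nlen
    solution = None
    for ccap_obs in range(clen, min_ccap - 1, -1):  # prefer the full C-cap
        middle = body - ccap_obs
        if middle < 0 or middle % mlen:
            continue
        k = middle // mlen
        tail = seq[len(seq) - ccap_obs:]
        cc_frac = _mismatch_fraction(
            tail, spec.ccap[:ccap_obs], spec.ncap_variable_positions[:0]
        )
        if cc_frac <= spec.max_mismatch_fraction:
            solution = (k, ccap_obs)
            break
    if solution is None:
        raise AnnotationError(
            f"no motif count k solves |seq| = |N-cap| + {mlen}k + |C-cap| "
            f"(body length {body})"
        )
    k, ccap_obs = solution

    spans, calls = [], []
    for i in range(k):
        a = start + nlen + i * mlen
        segment = seq[a: a + mlen]
        frac = _mismatch_fraction(segment, spec.module, spec.variable_positions)
        if frac > spec.max_mismatch_fraction:
            raise AnnotationError(
                f"module {i + 1} mismatches consensus at {frac:.0%} of fixed "
                f"positions (threshold {spec.max_mismatch_fraction:.0%})"
            )
        spans.append((a, a + mlen))
        calls.append({p: segment[p - 1] for p in spec.variable_positions})

    ncap_seg = seq[start: start + nlen]
    return CloneAnnotation(
        ncap_span=(start, start + nlen),
        module_spans=spans,
        ccap_span=(len(seq) - ccap_obs, len(seq)),
        ncap_calls={p: ncap_seg[p - 1] for p in spec.ncap_variable_positions},
        module_calls=calls,
    )


def generate_fixture_clone(
    module_residues: list[dict[int, str] | tuple[str, ...]],
    ncap_residues: dict[int, str] | tuple[str, ...] | None = None,
    spec: ScaffoldSpec | None = None,
    seed: int | None = None,
) -> tuple[str, str]:
    """Build a (protein, DNA) clone consistent with the scaffold.

    ``module_residues`` gives, per internal module, the residues at the
    variable positions (a dict keyed by position, or a tuple in position
    order).  Unspecified variable residues are drawn reproducibly from the
    seed.  DNA uses the fixed back-translation table, so the assembly
    restriction site appears at every segment junction.
    """
    import numpy as np

    spec = spec or ScaffoldSpec()
    rng = np.random.default_rng(seed)
    non_cys = sorted(set(BACKTRANSLATION) - {"C"})

    def fill(consensus: str, variable: tuple[int, ...], wanted) -> str:
        if wanted is None:
            wanted = {}
        elif not isinstance(wanted, dict):
            if len(wanted) != len(variable):
                raise ValueError(
                    f"expected {len(variable)} variable residues, got {len(wanted)}"
                )
            wanted = dict(zip(variable, wanted))
        for p, res in wanted.items():
            if p not in variable:
                raise ValueError(f"position {p} is not variable in this segment")
            if res not in BACKTRANSLATION:
                raise ValueError(f"invalid residue {res!r}")
        out = []
        for p in range(1, len(consensus) + 1):
            if p in variable:
                out.append(wanted.get(p) or str(rng.choice(non_cys)))
            else:
                out.append(consensus[p - 1])
        return "".join(out)

    parts = [fill(spec.ncap, spec.ncap_variable_positions, ncap_residues)]
    for wanted in module_residues:
        parts.append(fill(spec.module, spec.variable_positions, wanted))
    parts.append(spec.ccap)
    protein = "".join(parts)
    dna = "".join(BACKTRANSLATION[res] for res in protein)
    return protein, dna


def check_reading_frame(dna: str, spec: ScaffoldSpec | None = None) -> FrameReport:
    """DNA-level frame diagnostics against the scaffold layout.

    Checks overall length modulo 3, whether the inter-cap region is a whole
    number of module-length segments, internal stop codons in frame 0, and
    the restriction site at every expected segment junction.  A corrupted
    junction localizes a frame shift to the first affected module.
    """
    spec = spec or ScaffoldSpec()
    dna = dna.upper()
    bad = set(dna) - set("ACGT")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")

    n_nt = 3 * len(spec.ncap)
    c_nt = 3 * len(spec.ccap)
    m_nt = 3 * len(spec.module)
    length_mod3_ok = len(dna) % 3 == 0
    body = len(dna) - n_nt - c_nt
    module_region_ok = body >= 0 and body % m_nt == 0
    # check one junction past the last whole module so a shortened
    # (frame-shifted) module still exposes a corrupted downstream site
    k = -(-max(body, 0) // m_nt)

    trimmed = dna[: len(dna) - len(dna) % 3]
    aa = str(Seq(trimmed).translate())
    stops = tuple(i for i, r in enumerate(aa) if r == "*")

    # junction j sits between segment j and j+1 (0 = N-cap/module 1);
    # the site spans the last codon before and the first codon after.
    site = spec.restriction_site
    corrupted = []
    first_shift = None
    for j in range(k + 1):
        pos = n_nt + j * m_nt
        window = dna[pos - 3: pos + 3]
        if len(window) < len(site) or window[: len(site)] != site:
            corrupted.append(j)
            if first_shift is None and j > 0:
                first_shift = j  # module j is the first misbehaving segment
    return FrameReport(
        length_mod3_ok=length_mod3_ok,
        module_region_ok=module_region_ok,
        stop_codon_positions=stops,
        corrupted_junctions=tuple(corrupted),
        frame_shifted_module=first_shift,
    )


def annotate_fasta(path, spec: ScaffoldSpec | None = None) -> pd.DataFrame:
    """Annotate every protein record in a FASTA file; one table per clone,
    concatenated with a ``clone`` column."""
    from Bio import SeqIO

    spec = spec or ScaffoldSpec()
    frames = []
    for record in SeqIO.parse(str(path), "fasta"):
        ann = annotate_protein(str(record.seq), spec)
        df = ann.to_frame()
        df.insert(0, "clone", record.id)
        df.insert(1, "motif_count", ann.motif_count)
        frames.append(df)
    if not frames:
        raise ValueError(f"no sequences in {path}")
    return pd.concat(frames, ignore_index=True)
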