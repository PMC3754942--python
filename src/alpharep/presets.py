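"""Default randomization-scheme inputs for the αRep scaffold.

The degenerate codon lists below are the published randomization scheme for
the four library positions encoded on shared oligonucleotides (the adjacent
pairs 18-19 and 22-23 of the 31-residue internal module).  Position 26 is
randomized by its own oligonucleotide set and position 30 is constrained by
the module-assembly restriction site to Glu/Lys/Gln.  The N-cap uses the
simpler vnk / dht scheme.

These are defaults; every entry point also accepts user-supplied codon
lists (plain strings in a YAML/CSV config or on the command line).
"""

from __future__ import annotations

# Degenerate codon lists per variable position of the internal module.
POSITION_CODON_SETS: dict[int, tuple[str, ...]] = {
    18: ("hcc", "kac", "bcg", "gwa", "sgt", "ama", "ncg", "tgg", "ctg", "tac", "ccg"),
    19: ("gma", "kcg", "cwg", "amc", "twc", "cgc", "gac", "tac", "ggt", "tgg"),
    22: ("cgt", "raa", "kct", "cwg", "tac", "ttc", "tgg", "atc", "ayg", "gtt"),
    23: ("ryt", "skt", "gma", "rmc", "sag", "mgc", "wct", "gcg", "ggt", "tcg",
         "cgt", "kct", "gct", "gaa", "aac"),
}

# N-cap randomization: one codon for positions 18/19, one for 22/23/26.
NCAP_CODON_18_19 = "vnk"
NCAP_CODON_22_23_26 = "dht"
# Literal dht encodes 9 residues (N,T,I,D,A,V,Y,S,F).  The published residue
# list for the N-cap positions (A,D,E,F,I,K,L,M,N,S,T,V,Y) is exactly what
# dhk encodes once the amber codon is dropped; both are exposed so the
# discrepancy stays visible rather than silently resolved.
NCAP_CODON_22_23_26_ALT = "dhk"

# Position 30 is restricted by the assembly site to three residues.
POSITION_30_RESIDUES = ("E", "K", "Q")

# Published per-site alternative counts of the repeat-level sequence space.
REPEAT_SITE_COUNTS = (87, 60, 16, 3)

VARIABLE_POSITIONS = (18, 19, 22, 23, 26, 30)
MODULE_LENGTH = 31
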