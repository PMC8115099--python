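"""Three-bit genotype codes and the function-loss partial order.

A genotype is the ordered triple of public-good functions a cell carries,
encoded as an integer 0..7 whose binary digits (MSB = function 1) say
whether the cell produces public good 1, 2 and 3.  Code ``-1`` marks an
empty lattice box everywhere in the package.

The eight genotypes fall into four ecological classes:

* the autonomous ancestor ``[1,1,1]`` (code 7),
* three one-function-loss genotypes (OFLGs): ``[1,1,0]``, ``[1,0,1]``,
  ``[0,1,1]``,
* three two-function-loss genotypes (TFLGs): ``[1,0,0]``, ``[0,1,0]``,
  ``[0,0,1]``,
* the non-producing cheater ``[0,0,0]`` (code 0).

A TFLG and its bitwise complement OFLG jointly cover all three functions;
such a pair is an asymmetric functional complementation pair (AFCP).
"""

from __future__ import annotations

import itertools

import numpy as np

EMPTY: int = -1
N_GENOTYPES: int = 8
N_FUNCTIONS: int = 3

ANCESTOR: int = 7  # [1,1,1]
CHEATER: int = 0  # [0,0,0]
OFLGS: tuple[int, ...] = (6, 5, 3)  # [1,1,0], [1,0,1], [0,1,1]
TFLGS: tuple[int, ...] = (4, 2, 1)  # [1,0,0], [0,1,0], [0,0,1]

#: The three AFCPs as (TFLG, OFLG) code pairs.
AFC_PAIRS: tuple[tuple[int, int], ...] = tuple((t, 7 ^ t) for t in TFLGS)


def bits_to_code(bits) -> int:
    """Map an ordered bit triple like ``[0, 0, 1]`` to its integer code."""
    b = tuple(int(x) for x in bits)
    if len(b) != N_FUNCTIONS or any(x not in (0, 1) for x in b):
        raise ValueError(f"genotype must be 3 binary flags, got {bits!r}")
    return (b[0] << 2) | (b[1] << 1) | b[2]


def code_to_bits(code: int) -> tuple[int, int, int]:
    """Inverse of :func:`bits_to_code`."""
    if not 0 <= code < N_GENOTYPES:
        raise ValueError(f"genotype code must be in 0..7, got {code}")
    return ((code >> 2) & 1, (code >> 1) & 1, code & 1)


def label(code: int) -> str:
    """Human-readable bracket label, e.g. ``'[1,1,0]'`` for code 6."""
    return "[" + ",".join(str(b) for b in code_to_bits(code)) + "]"


def compact_label(code: int) -> str:
    """Compact bit-string label, e.g. ``'110'`` for code 6."""
    return "".join(str(b) for b in code_to_bits(code))


def parse_label(text: str) -> int:
    """Parse ``'110'``, ``'[1,1,0]'`` or an integer string into a code."""
    t = text.strip()
    if t.lstrip("-").isdigit() and len(t) <= 2:
        return int(t)
    digits = [c for c in t if c in "01"]
    return bits_to_code(digits)


def n_functions(code: int) -> int:
    """Number of carried functions (popcount of the code)."""
    if not 0 <= code < N_GENOTYPES:
        raise ValueError(f"genotype code must be in 0..7, got {code}")
    return bin(code).count("1")


def carries(code: int, j: int) -> bool:
    """Whether genotype ``code`` carries function ``j`` (0-based)."""
    return bool((code >> (N_FUNCTIONS - 1 - j)) & 1)


def complement(code: int) -> int:
    """Bitwise complement genotype; a TFLG's complement is its AFCP partner."""
    if not 0 <= code < N_GENOTYPES:
        raise ValueError(f"genotype code must be in 0..7, got {code}")
    return code ^ 7


def is_subset(child: int, parent: int) -> bool:
    """True when the child's function set is contained in the parent's."""
    return (child & parent) == child


def descendants(code: int) -> tuple[int, ...]:
    """All genotypes reachable from ``code`` by loss-only mutation (incl. self)."""
    return tuple(
        c for c in range(N_GENOTYPES) if is_subset(c, code)
    )


def mutation_parents(code: int) -> tuple[int, ...]:
    """Genotypes that can produce ``code`` by losing exactly one function."""
    out = []
    for j in range(N_FUNCTIONS):
        bit = 1 << (N_FUNCTIONS - 1 - j)
        if not code & bit:
            out.append(code | bit)
    return tuple(out)


def census(genotype_grid: np.ndarray) -> np.ndarray:
    """Counts of the 8 genotypes on a grid of codes (-1 = empty)."""
    occ = genotype_grid[genotype_grid >= 0]
    return np.bincount(occ.astype(np.int64), minlength=N_GENOTYPES)


def all_genotypes() -> tuple[int, ...]:
    return tuple(range(N_GENOTYPES))


def enumerate_afc_signatures() -> list[tuple]:
    """Enumerate the coarse branch-signature alphabet for AFC outcomes.

    Each element is ``(three_ofgs, ofg_set, first_tfg, winning_tfg)``: whether
    all three OFLGs colonized before the ancestor disappeared (the first key
    random event), the set of OFLGs that did, the first TFLG to colonize (the
    second key event) and the TFLG of the winning AFCP.  A winning pair's
    OFLG must be in the colonized set, and a TFLG can only colonize if its
    complement OFLG did.  Brute-force enumeration of those constraints.
    """
    sigs = []
    for tfg, ofg in AFC_PAIRS:
        for r in (2, 3):
            for ofg_set in itertools.combinations(OFLGS, r):
                if ofg not in ofg_set:
                    continue
                for first_tfg in (complement(o) for o in ofg_set):
                    sigs.append((r == 3, frozenset(ofg_set), first_tfg, tfg))
    return sorted(set(sigs), key=repr)
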