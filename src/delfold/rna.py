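"""The 3x3 internal-loop RNA library and secondary-structure motif extraction.

The selection library displays six randomized nucleotides as a potential
3-nt x 3-nt internal loop inside a unimolecular hairpin cassette with
single-stranded tails (4^6 = 4,096 members).  Because any of the six
positions may in fact pair, a library "motif" is a 3x3 *window*: two
aligned 3-mers that may contain closing base pairs.  The field's notation
writes the window as 5'XXX/3'YYY with the bottom strand 3'->5' so the two
strands read aligned — e.g. 5'GAG/3'CCC is a 1x1 A.C loop closed by two
G:C pairs.

This module enumerates the library, builds hairpin constructs, extracts
internal loops from dot-bracket structures, windows sub-3x3 loops up to the
library's 6-nt frame, and provides a base-pair-maximizing (Nussinov) fold
as a convenience for synthetic sequences without a supplied structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

RNA_ALPHABET = "ACGU"

#: pairs accepted as genuine (Watson-Crick plus wobble)
CANONICAL_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def is_canonical_pair(x: str, y: str) -> bool:
    return (x, y) in CANONICAL_PAIRS


class PseudoknotError(ValueError):
    """Structure contains crossing base pairs."""


def parse_dotbracket(structure: str) -> dict[int, int]:
    """Pair map (both directions) of a balanced, nested dot-bracket string."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif c not in ".":
            if c in "[]{}<>":
                raise PseudoknotError("pseudoknot bracket layers are not supported")
            raise ValueError(f"unexpected structure character {c!r}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


@dataclass(frozen=True)
class HairpinStructure:
    """An RNA sequence with its (nested) secondary structure annotation."""

    sequence: str
    dotbracket: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and structure lengths differ")
        parse_dotbracket(self.dotbracket)  # validates balance/nesting


@dataclass(frozen=True)
class LoopMotif:
    """A 3x3 window: two aligned 3-mers, bottom written 3'->5'."""

    top: str
    bottom: str

    def __post_init__(self) -> None:
        if len(self.top) != len(self.bottom):
            raise ValueError("window strands must align")

    @property
    def canonical(self) -> str:
        return f"5'{self.top}/3'{self.bottom}"

    @staticmethod
    def from_canonical(text: str) -> "LoopMotif":
        top_part, bottom_part = text.split("/")
        if not top_part.startswith("5'") or not bottom_part.startswith("3'"):
            raise ValueError(f"not a 5'XXX/3'YYY motif string: {text!r}")
        return LoopMotif(top=top_part[2:], bottom=bottom_part[2:])


@dataclass(frozen=True)
class ILLMember:
    """One library member: the two variable 3-mers and its hairpin cassette."""

    top3: str
    bottom3: str  # 3'->5', aligned under top3

    @property
    def motif(self) -> LoopMotif:
        return LoopMotif(top=self.top3, bottom=self.bottom3)

    @property
    def canonical(self) -> str:
        return self.motif.canonical


def enumerate_ill() -> Iterator[ILLMember]:
    """All 4^6 = 4,096 members, in lexicographic order of (top3, bottom3)."""
    for top in itertools.product(RNA_ALPHABET, repeat=3):
        for bottom in itertools.product(RNA_ALPHABET, repeat=3):
            yield ILLMember(top3="".join(top), bottom3="".join(bottom))


@dataclass(frozen=True)
class HairpinScaffold:
    """Cassette surrounding the variable window.

    A documented synthetic cassette: single-stranded tails carrying primer
    binding sites, GC-rich closing stems on both sides of the window, and a
    UUCG apical tetraloop.  Treated as configuration so any production
    cassette can be dropped in.
    """

    tail5: str = "GGAAUCGAUACC"
    stem_outer: str = "GCGCAG"   # 5' side; 3' side is its reverse complement
    stem_inner: str = "GGCAGC"
    apical_loop: str = "UUCG"
    tail3: str = "AUCCGUAGGAAC"

    def __post_init__(self) -> None:
        for name in ("tail5", "stem_outer", "stem_inner", "apical_loop", "tail3"):
            s = getattr(self, name)
            if not s or any(c not in RNA_ALPHABET for c in s):
                raise ValueError(f"scaffold field {name} must be non-empty RNA")

    @property
    def top_slice(self) -> slice:
        start = len(self.tail5) + len(self.stem_outer)
        return slice(start, start + 3)

    @property
    def bottom_slice(self) -> slice:
        """Positions of the bottom-strand variable region (reverse of bottom3)."""
        start = (
            len(self.tail5)
            + len(self.stem_outer)
            + 3
            + len(self.stem_inner)
            + len(self.apical_loop)
            + len(self.stem_inner)
        )
        return slice(start, start + 3)


def build_hairpin(
    member: ILLMember, scaffold: HairpinScaffold | None = None
) -> HairpinStructure:
    """Embed a library member's 6 variable nucleotides into the hairpin cassette.

    The default annotation pairs the scaffold stems and leaves tails, the
    apical loop, and the 3x3 window unpaired; bottom3 is stored 3'->5', so
    it appears reversed in the 5'->3' sequence.
    """
    sc = scaffold or HairpinScaffold()
    seq = (
        sc.tail5
        + sc.stem_outer
        + member.top3
        + sc.stem_inner
        + sc.apical_loop
        + reverse_complement(sc.stem_inner)
        + member.bottom3[::-1]
        + reverse_complement(sc.stem_outer)
        + sc.tail3
    )
    db = (
        "." * len(sc.tail5)
        + "(" * len(sc.stem_outer)
        + "..."
        + "(" * len(sc.stem_inner)
        + "." * len(sc.apical_loop)
        + ")" * len(sc.stem_inner)
        + "..."
        + ")" * len(sc.stem_outer)
        + "." * len(sc.tail3)
    )
    return HairpinStructure(sequence=seq, dotbracket=db)


@dataclass(frozen=True)
class InternalLoop:
    """An extracted loop with sequence coordinates and pairing context.

    ``top``/``bottom`` hold only the unpaired nucleotides (bottom 3'->5',
    aligned); ``left_pairs``/``right_pairs`` are the stem base pairs
    flanking the loop, nearest first, as (top_nt, bottom_nt) tuples —
    enough context to pad sub-3x3 loops out to the library's window.
    """

    top: str
    bottom: str
    top_start: int      # 0-based position of first top-strand loop nt
    bottom_start: int   # 0-based position of first (5'-most) bottom-strand loop nt
    left_pairs: tuple[tuple[str, str], ...]
    right_pairs: tuple[tuple[str, str], ...]

    @property
    def is_bulge(self) -> bool:
        return len(self.top) == 0 or len(self.bottom) == 0

    @property
    def size(self) -> tuple[int, int]:
        return (len(self.top), len(self.bottom))

    def top_positions(self) -> range:
        return range(self.top_start, self.top_start + len(self.top))

    def bottom_positions(self) -> range:
        return range(self.bottom_start, self.bottom_start + len(self.bottom))


def extract_internal_loops(
    h: HairpinStructure,
    include_bulges: bool = True,
    context_depth: int = 3,
) -> list[InternalLoop]:
    """Find every internal/bulge loop between consecutive base pairs.

    For each helix interruption — a pair (i, j) and the next pair (i', j')
    it encloses with only unpaired positions in between on both strands —
    emit the a x b loop (a = i'-i-1 top, b = j-j'-1 bottom, a+b >= 1).
    Bulges (a = 0 or b = 0) are reported when ``include_bulges`` but are
    excluded from 3x3 windowing downstream by default.
    """
    pairs = parse_dotbracket(h.dotbracket)
    seq = h.sequence
    loops: list[InternalLoop] = []
    opening = sorted(i for i, j in pairs.items() if i < j)
    for i in opening:
        j = pairs[i]
        # walk inward to the next paired position on the top strand
        i2 = i + 1
        while i2 < j and i2 not in pairs:
            i2 += 1
        if i2 >= j:
            continue  # hairpin loop, no enclosed helix
        j2 = pairs[i2]
        if j2 > j:
            raise PseudoknotError("crossing pairs encountered")
        # bottom strand between j2 and j must be unpaired for an internal loop
        if any(p in pairs for p in range(j2 + 1, j)):
            continue  # multiloop branch, not a two-way junction
        a = i2 - i - 1
        b = j - j2 - 1
        if a + b == 0:
            continue  # contiguous helix
        # pairing context, nearest-first, only across genuine stacked pairs
        left: list[tuple[str, str]] = []
        pi, pj = i, j
        for _ in range(context_depth):
            if pairs.get(pi) == pj and is_canonical_pair(seq[pi], seq[pj]):
                left.append((seq[pi], seq[pj]))
                pi, pj = pi - 1, pj + 1
            else:
                break
        right: list[tuple[str, str]] = []
        pi, pj = i2, j2
        for _ in range(context_depth):
            if pairs.get(pi) == pj and is_canonical_pair(seq[pi], seq[pj]):
                right.append((seq[pi], seq[pj]))
                pi, pj = pi + 1, pj - 1
            else:
                break
        loop = InternalLoop(
            top=seq[i + 1 : i2],
            bottom=seq[j - 1 : j2 : -1] if b else "",
            top_start=i + 1,
            bottom_start=j2 + 1,
            left_pairs=tuple(left),
            right_pairs=tuple(right),
        )
        if loop.is_bulge and not include_bulges:
            continue
        loops.append(loop)
    return loops


class WindowError(ValueError):
    """Loop cannot be framed in a 3x3 window."""


def window_3x3(loop: InternalLoop) -> set[LoopMotif]:
    """All 3x3 windows containing the loop, padded with flanking base pairs.

    A 3x3 library member whose window partially pairs presents a smaller
    loop; matching therefore pads extracted loops back out to the 6-nt
    frame using adjacent stem nucleotides (WC/GU pairs only).  Symmetric
    a x a loops pad the same number of pairs on each strand: a 3x3 loop is
    its own window, a 2x2 loop yields the two one-sided pad choices, a 1x1
    loop the unique pad-one-pair-each-side window.  Asymmetric loops pad
    each strand independently and emit every valid split; a match on any
    window counts.  Bulges are not windowed.
    """
    a, b = loop.size
    if a > 3 or b > 3:
        raise WindowError(f"loop {a}x{b} exceeds the 3x3 frame")
    if a == 0 or b == 0:
        raise WindowError("bulge loops are excluded from 3x3 windowing")

    def strand_options(n: int) -> list[tuple[int, int]]:
        # balanced padding: the window stays centered on the loop
        return [
            (l, 3 - n - l)
            for l in range(0, 3 - n + 1)
            if abs(l - (3 - n - l)) <= 1
        ]

    windows: set[LoopMotif] = set()
    for lt, rt in strand_options(a):
        if lt > len(loop.left_pairs) or rt > len(loop.right_pairs):
            continue
        for lb, rb in strand_options(b):
            if a == b and (lb, rb) != (lt, rt):
                continue  # symmetric loops pad symmetrically
            if lb > len(loop.left_pairs) or rb > len(loop.right_pairs):
                continue
            # left pads are nearest-first going outward; window reads 5'->3'
            top = (
                "".join(p[0] for p in loop.left_pairs[:lt][::-1])
                + loop.top
                + "".join(p[0] for p in loop.right_pairs[:rt])
            )
            bottom = (
                "".join(p[1] for p in loop.left_pairs[:lb][::-1])
                + loop.bottom
                + "".join(p[1] for p in loop.right_pairs[:rb])
            )
            windows.add(LoopMotif(top=top, bottom=bottom))
    return windows


def nussinov_fold(sequence: str, min_hairpin: int = 3) -> str:
    """Base-pair-maximizing nested fold (WC + GU), deterministic traceback.

    A synthetic-data convenience only: real hairpin structures are inputs.
    Traceback prefers pairing (i, j) over splitting, then the leftmost
    split point, so the structure is unique for a given sequence.
    """
    n = len(sequence)
    if any(c not in RNA_ALPHABET for c in sequence):
        raise ValueError("sequence must be RNA over ACGU")
    if n == 0:
        return ""
    dp = [[0] * n for _ in range(n)]
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j - 1] + 1 if is_canonical_pair(sequence[i], sequence[j]) else 0
            if dp[i + 1][j] > best:
                best = dp[i + 1][j]
            if dp[i][j - 1] > best:
                best = dp[i][j - 1]
            for k in range(i + 1, j):
                val = dp[i][k] + dp[k + 1][j]
                if val > best:
                    best = val
            dp[i][j] = best

    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if dp[i][j] == 0:
                return
            if (
                is_canonical_pair(sequence[i], sequence[j])
                and j - i > min_hairpin
                and dp[i][j] == dp[i + 1][j - 1] + 1
            ):
                structure[i], structure[j] = "(", ")"
                i, j = i + 1, j - 1
                continue
            if dp[i][j] == dp[i + 1][j]:
                i += 1
                continue
            if dp[i][j] == dp[i][j - 1]:
                j -= 1
                continue
            for k in range(i + 1, j):
                if dp[i][j] == dp[i][k] + dp[k + 1][j]:
                    traceback(i, k)
                    i = k + 1
                    break
        return

    traceback(0, n - 1)
    return "".join(structure)


# --- Vienna-format I/O ----------------------------------------------------

def write_vienna(records: Sequence[tuple[str, HairpinStructure]], path: str | Path) -> None:
    """Vienna dot-bracket file: >id / sequence / structure triplets."""
    with open(path, "w") as fh:
        for name, h in records:
            fh.write(f">{name}\n{h.sequence}\n{h.dotbracket}\n")


def read_vienna(path: str | Path) -> dict[str, HairpinStructure]:
    out: dict[str, HairpinStructure] = {}
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        seq, db = lines[i + 1], lines[i + 2]
        out[name] = HairpinStructure(sequence=seq, dotbracket=db)
        i += 3
    return out
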