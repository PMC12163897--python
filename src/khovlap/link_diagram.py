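"""Oriented link diagrams in planar-diagram (PD) notation.

A link diagram is encoded as a list of crossings ``X[i,j,k,l]`` where the
four entries are edge labels read counterclockwise around the crossing,
starting from the edge *i* that enters on the under-strand.  Edges are
numbered with increasing natural numbers along the orientation of each
component, one contiguous block of labels per component (the last edge of a
component wraps back to its first label).

The module validates diagrams, infers component structure and crossing
signs, and provides the canonical fixtures used throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "Crossing",
    "LinkDiagram",
    "PDSyntaxError",
    "PDValidationError",
    "parse_pd",
    "crossing_sign",
    "mirror",
    "writhe",
    "fixtures",
    "FIXTURE_NAMES",
]


class PDSyntaxError(ValueError):
    """Raised when PD text cannot be tokenized."""


class PDValidationError(ValueError):
    """Raised when a PD code does not describe a consistent oriented diagram."""


@dataclass(frozen=True)
class Crossing:
    """One crossing ``X[i,j,k,l]``: *i* enters under, the rest counterclockwise."""

    edges: tuple[int, int, int, int]
    index: int

    def __post_init__(self) -> None:
        if any(e < 1 for e in self.edges):
            raise PDValidationError(f"crossing {self.index}: labels must be >= 1, got {self.edges}")
        # a label repeats only for one-crossing curls, never more than twice
        for e in set(self.edges):
            if self.edges.count(e) > 2:
                raise PDValidationError(
                    f"crossing {self.index}: label {e} appears more than twice in {self.edges}"
                )

    @property
    def i(self) -> int:
        return self.edges[0]

    @property
    def j(self) -> int:
        return self.edges[1]

    @property
    def k(self) -> int:
        return self.edges[2]

    @property
    def l(self) -> int:
        return self.edges[3]


@dataclass
class LinkDiagram:
    """A validated oriented link diagram.

    Attributes
    ----------
    crossings:
        Ordered crossing set; the order fixes the bit positions of the cube
        of smoothings.
    components:
        One ``(lo, hi)`` inclusive label block per link component.
    signs:
        Crossing signs aligned with ``crossings``.
    successor:
        The next edge label along the orientation (wrap-aware).
    """

    crossings: list[Crossing]
    components: list[tuple[int, int]] = field(default_factory=list)
    signs: list[int] = field(default_factory=list)
    successor: dict[int, int] = field(default_factory=dict)
    over_directions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.crossings and not self.successor:
            self.successor, self.over_directions = _infer_successor(self.crossings)
            self.components = _components_from_successor(self.successor)
            self.signs = [
                _sign(c, od) for c, od in zip(self.crossings, self.over_directions)
            ]
        elif not self.crossings:
            # the zero-crossing unknot: a single closed curve with no crossings
            self.components = [(1, 0)]
            self.signs = []

    # -- basic counts -------------------------------------------------

    @property
    def n(self) -> int:
        """Number of crossings."""
        return len(self.crossings)

    @property
    def n_plus(self) -> int:
        return sum(1 for s in self.signs if s > 0)

    @property
    def n_minus(self) -> int:
        return sum(1 for s in self.signs if s < 0)

    @property
    def writhe(self) -> int:
        return self.n_plus - self.n_minus

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def edge_labels(self) -> list[int]:
        out: set[int] = set()
        for c in self.crossings:
            out.update(c.edges)
        return sorted(out)

    def succ(self, edge: int) -> int:
        return self.successor[edge]

    # -- serialization ------------------------------------------------

    def to_pd(self) -> str:
        return " ".join("X[%d,%d,%d,%d]" % c.edges for c in self.crossings)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.n == 0:
            return "LinkDiagram(unknot)"
        return f"LinkDiagram({self.to_pd()})"


# ----------------------------------------------------------------------
# validation machinery


def _infer_successor(
    crossings: list[Crossing],
) -> tuple[dict[int, int], list[tuple[int, int]]]:
    """Build the wrap-aware successor function of the edge labels.

    Each crossing supplies two strand passes: the under-strand runs i -> k,
    so k succeeds i; the over-strand runs between j and l in the direction
    compatible with a globally consistent traversal.  Over-pass directions
    are resolved by constraint propagation (each label has exactly one
    successor and one predecessor) with a preference for the non-wrapping
    direction when both remain possible.  Returns the successor map and the
    resolved over-strand direction (tail, head) of every crossing; the
    latter is recorded because for a two-edge component the global successor
    map alone cannot orient the over-pass.
    """
    counts: dict[int, int] = {}
    for c in crossings:
        for e in c.edges:
            counts[e] = counts.get(e, 0) + 1
    bad = sorted(e for e, ct in counts.items() if ct != 2)
    if bad:
        raise PDValidationError(f"edge labels must appear exactly twice; offending labels: {bad}")

    succ: dict[int, int] = {}
    pred: dict[int, int] = {}

    def add(a: int, b: int, why: str) -> None:
        if succ.get(a, b) != b or pred.get(b, a) != a:
            raise PDValidationError(
                f"inconsistent edge succession at {why}: {a}->{b} conflicts with "
                f"{a}->{succ.get(a)} / {pred.get(b)}->{b}"
            )
        succ[a] = b
        pred[b] = a

    for c in crossings:
        add(c.i, c.k, f"under-strand of crossing {c.index} {c.edges}")

    # resolve over-strand directions
    over_dir: dict[int, tuple[int, int]] = {}
    pending: list[Crossing] = list(crossings)
    while pending:
        progressed = False
        remaining: list[Crossing] = []
        for c in pending:
            j, l = c.j, c.l
            jl_ok = j not in succ and l not in pred
            lj_ok = l not in succ and j not in pred
            if jl_ok and lj_ok:
                remaining.append(c)
                continue
            if jl_ok:
                add(j, l, f"over-strand of crossing {c.index} {c.edges}")
                over_dir[c.index] = (j, l)
            elif lj_ok:
                add(l, j, f"over-strand of crossing {c.index} {c.edges}")
                over_dir[c.index] = (l, j)
            else:
                raise PDValidationError(
                    f"over-strand labels {j},{l} of crossing {c.index} {c.edges} "
                    "cannot be oriented consistently"
                )
            progressed = True
        if not progressed and remaining:
            # no forced choice: prefer the non-wrapping (ascending) direction
            c = remaining.pop(0)
            j, l = c.j, c.l
            lo, hi = min(j, l), max(j, l)
            if hi == lo + 1:
                add(lo, hi, f"over-strand of crossing {c.index} {c.edges}")
                over_dir[c.index] = (lo, hi)
            else:
                add(hi, lo, f"over-strand (wrap) of crossing {c.index} {c.edges}")
                over_dir[c.index] = (hi, lo)
        pending = remaining

    labels = sorted(counts)
    missing = [e for e in labels if e not in succ]
    if missing:
        raise PDValidationError(f"edges without successor (diagram not closable): {missing}")
    return succ, [over_dir[c.index] for c in crossings]


def _components_from_successor(succ: dict[int, int]) -> list[tuple[int, int]]:
    """Decompose the successor function into contiguous, wrapping label blocks."""
    seen: set[int] = set()
    blocks: list[tuple[int, int]] = []
    for start in sorted(succ):
        if start in seen:
            continue
        cyc = [start]
        cur = succ[start]
        while cur != start:
            if cur in seen or len(cyc) > len(succ):
                raise PDValidationError("edge succession does not close into disjoint cycles")
            cyc.append(cur)
            cur = succ[cur]
        seen.update(cyc)
        lo, hi = min(cyc), max(cyc)
        if sorted(cyc) != list(range(lo, hi + 1)):
            raise PDValidationError(
                f"component labels {sorted(cyc)} are not a contiguous block"
            )
        wraps = [(a, succ[a]) for a in cyc if succ[a] != a + 1]
        if wraps != [(hi, lo)]:
            raise PDValidationError(
                f"component block [{lo},{hi}] must be traversed in increasing order "
                f"with a single wrap {hi}->{lo}; found wraps {wraps}"
            )
        blocks.append((lo, hi))
    blocks.sort()
    for (a, b), (c, d) in zip(blocks, blocks[1:]):
        if c <= b:
            raise PDValidationError("component label blocks overlap")
    return blocks


def _sign(c: Crossing, over_direction: tuple[int, int]) -> int:
    """Sign of a crossing: +1 iff the over-strand direction is 90 degrees
    counterclockwise from the under-strand direction.

    With the counterclockwise port order (i, j, k, l) and the under-strand
    running i -> k, the over-strand running j -> l is the positive
    configuration and l -> j the negative one.
    """
    if over_direction == (c.j, c.l):
        return +1
    if over_direction == (c.l, c.j):
        return -1
    raise PDValidationError(
        f"over-strand labels {c.j},{c.l} of crossing {c.index} are not succession-related"
    )


# ----------------------------------------------------------------------
# operations

_TOKEN = re.compile(r"X[\[\(]\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*[\]\)]")


def parse_pd(text: str) -> LinkDiagram:
    """Parse PD-notation text into a validated :class:`LinkDiagram`.

    Accepts whitespace- or comma-separated ``X[a,b,c,d]`` / ``X(a,b,c,d)``
    tokens; lines starting with ``#`` are comments.
    """
    stripped = "\n".join(
        line.split("#", 1)[0] for line in text.splitlines()
    ) if "#" in text else text
    body = stripped.strip()
    if not body:
        raise PDSyntaxError(
            "empty PD text: the zero-crossing unknot must be requested via fixtures('unknot')"
        )
    tuples: list[tuple[int, int, int, int]] = []
    pos = 0
    sep = re.compile(r"[\s,]*")
    while pos < len(body):
        pos = sep.match(body, pos).end()
        if pos >= len(body):
            break
        m = _TOKEN.match(body, pos)
        if not m:
            bad = body[pos : pos + 20].split()[0] if body[pos:].split() else body[pos:]
            raise PDSyntaxError(f"malformed PD token near {bad!r}")
        tuples.append(tuple(int(g) for g in m.groups()))  # type: ignore[arg-type]
        pos = m.end()
    crossings = [Crossing(edges=t, index=i) for i, t in enumerate(tuples)]
    return LinkDiagram(crossings=crossings)


def crossing_sign(diagram: LinkDiagram, crossing: Crossing) -> int:
    """Return the sign (+1/-1) of ``crossing`` within ``diagram``."""
    for c, od in zip(diagram.crossings, diagram.over_directions):
        if c is crossing or (c.index == crossing.index and c.edges == crossing.edges):
            return _sign(crossing, od)
    raise ValueError("crossing does not belong to this diagram")


def writhe(diagram: LinkDiagram) -> int:
    return diagram.writhe


def n_plus(diagram: LinkDiagram) -> int:
    return diagram.n_plus


def n_minus(diagram: LinkDiagram) -> int:
    return diagram.n_minus


def mirror(diagram: LinkDiagram) -> LinkDiagram:
    """The mirror image: over- and under-strands exchanged at every crossing.

    In PD form each tuple is rotated so that the old over-strand becomes the
    new under-strand, entered at its tail: a positive crossing X(i,j,k,l)
    (over j->l) becomes X(j,k,l,i); a negative one (over l->j) becomes
    X(l,i,j,k).  All crossing signs negate and n+/n- swap.
    """
    if diagram.n == 0:
        return LinkDiagram(crossings=[])
    new: list[Crossing] = []
    for c, s in zip(diagram.crossings, diagram.signs):
        i, j, k, l = c.edges
        t = (j, k, l, i) if s > 0 else (l, i, j, k)
        new.append(Crossing(edges=t, index=c.index))
    return LinkDiagram(crossings=new)


# ----------------------------------------------------------------------
# fixtures

# The right-handed trefoil with three positive crossings; edge labels follow
# the orientation 1..6 around the knot.
_TREFOIL_R = "X[1,4,2,5] X[3,6,4,1] X[5,2,6,3]"

# Positive / negative Hopf links, one contiguous label block per component.
# Each component has two edges, so every over-pass direction is the wrap
# (2->1, 4->3), making both crossings positive here.
_HOPF_POS = "X[1,4,2,3] X[3,2,4,1]"

# Figure-eight knot (writhe 0), standard 4-crossing alternating diagram.
_FIGURE8 = "X[4,2,5,1] X[8,6,1,5] X[6,3,7,4] X[2,7,3,8]"

# 8_12: amphichiral alternating two-bridge knot, fraction 29/12 (Conway
# notation C(2,2,2,2)); writhe 0.  This particular 8-crossing diagram was
# generated from a twist-region (rational-tangle) construction of the
# equivalent continued fraction [1,1,2,2,2] and is flype-equivalent, not
# identical, to the symmetric 4-plat drawing: its Khovanov homology is
# symmetric under (r,q) -> (-r,-q) while its non-harmonic Laplacian
# spectra are not, e.g. S^{3,7} != S^{-3,-7}.
_K8_12 = (
    "X[12,4,13,3] X[4,12,5,11] X[2,5,3,6] X[6,1,7,2] "
    "X[10,8,11,7] X[16,14,1,13] X[14,9,15,10] X[8,15,9,16]"
)

# Trefoil diagrams traced from the parametric curve
# (sin u + 2 sin 2u, sin 3u, 2 cos 2u - cos u): the 7-crossing x-y
# projection (z as depth), and the 5-crossing diagram obtained from it by
# removing one poke (the bigon between its third and fourth crossings) by
# hand.  Both have writhe 3 and the Khovanov homology of the right trefoil.
_TREFOIL_XY7 = (
    "X[14,7,1,8] X[10,1,11,2] X[2,9,3,10] X[3,9,4,8] "
    "X[4,13,5,14] X[12,5,13,6] X[11,7,12,6]"
)
_TREFOIL_XY5 = "X[10,5,1,6] X[6,1,7,2] X[2,9,3,10] X[8,3,9,4] X[7,5,8,4]"

_PD_FIXTURES: dict[str, str] = {}  # populated lazily below


def _fixture_pd() -> dict[str, str]:
    if not _PD_FIXTURES:
        trefoil_r = parse_pd(_TREFOIL_R)
        hopf_pos = parse_pd(_HOPF_POS)
        _PD_FIXTURES.update(
            {
                "trefoil_R": _TREFOIL_R,
                "trefoil_L": mirror(trefoil_r).to_pd(),
                "hopf+": _HOPF_POS,
                "hopf-": mirror(hopf_pos).to_pd(),
                "figure8": _FIGURE8,
                "k8_12": _K8_12,
                "trefoil_xy7": _TREFOIL_XY7,
                "trefoil_xy5": _TREFOIL_XY5,
            }
        )
    return _PD_FIXTURES


FIXTURE_NAMES = (
    "unknot",
    "hopf+",
    "hopf-",
    "trefoil_R",
    "trefoil_L",
    "figure8",
    "k8_12",
    "trefoil_xy7",
    "trefoil_xy5",
)


def fixtures(name: str) -> LinkDiagram:
    """Return a canonical diagram by name (see :data:`FIXTURE_NAMES`)."""
    if name == "unknot":
        return LinkDiagram(crossings=[])
    table = _fixture_pd()
    if name not in table:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return parse_pd(table[name])
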