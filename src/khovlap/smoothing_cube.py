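"""The cube of smoothings of a link diagram.

Every vertex alpha of {0,1}^n replaces each crossing by one of the two
planar smoothings, turning the diagram into a disjoint union of cycles.
Cycles are traced by union-find over the edge labels and named canonically
by their least edge label.  Cube edges flip a single 0 to a 1; each either
merges two cycles into one or splits one cycle in two, and carries the sign
(-1)^(number of ones before the flipped position).

The module also provides the Kauffman state sum, an unnormalized Jones
polynomial computed directly from the cube, independent of the chain
complex assembled downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from .link_diagram import LinkDiagram

__all__ = [
    "SmoothingState",
    "CubeEdge",
    "CubeTooLargeError",
    "resolve",
    "enumerate_cube",
    "kauffman_state_sum",
    "DEFAULT_MAX_CROSSINGS",
]

DEFAULT_MAX_CROSSINGS = 16


class CubeTooLargeError(ValueError):
    """Raised when 2^n states would exceed the configured cap."""


@dataclass(frozen=True)
class SmoothingState:
    """A fully smoothed diagram S_alpha.

    ``alpha`` is a binary word (one bit per crossing, in crossing order),
    ``cycles`` the traced cycles as frozensets of edge labels, sorted by
    their canonical (minimum) label.
    """

    alpha: str
    cycles: tuple[frozenset[int], ...]

    @property
    def height(self) -> int:
        return self.alpha.count("1")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(min(c) for c in self.cycles)


@dataclass(frozen=True)
class CubeEdge:
    """A directed edge of the cube, flipping one 0-smoothing to a 1-smoothing."""

    xi: str  # word in {0,1,*} with exactly one *
    source_alpha: str
    target_alpha: str
    sign: int
    kind: str  # "merge" | "split"
    acting_labels: tuple[tuple[int, ...], tuple[int, ...]]  # (consumed, produced)

    @property
    def star_position(self) -> int:
        return self.xi.index("*")


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # keep the smaller label as representative
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _smoothing_pairs(edges: tuple[int, int, int, int], bit: str):
    """Arc pairings of a smoothed crossing X(i,j,k,l).

    The 0-smoothing joins (i,l) and (j,k); the 1-smoothing joins (i,j) and
    (k,l).  This is the unique pairing compatible with the cycle counts of
    the worked trefoil cube (S_000 two cycles, every height-1 state one
    cycle, S_111 three cycles).
    """
    i, j, k, l = edges
    if bit == "0":
        return (i, l), (j, k)
    return (i, j), (k, l)


def resolve(diagram: LinkDiagram, alpha: str) -> SmoothingState:
    """Compute the smoothing S_alpha of ``diagram``.

    ``alpha`` is a binary word of length n, bit positions in crossing order.
    """
    if len(alpha) != diagram.n or any(ch not in "01" for ch in alpha):
        raise ValueError(f"alpha must be a binary word of length {diagram.n}, got {alpha!r}")
    if diagram.n == 0:
        # the zero-crossing unknot resolves to a single cycle with no edges;
        # it is given the canonical label 1
        return SmoothingState(alpha="", cycles=(frozenset({1}),))
    uf = _UnionFind(diagram.edge_labels)
    for crossing, bit in zip(diagram.crossings, alpha):
        for a, b in _smoothing_pairs(crossing.edges, bit):
            uf.union(a, b)
    groups: dict[int, set[int]] = {}
    for e in diagram.edge_labels:
        groups.setdefault(uf.find(e), set()).add(e)
    cycles = tuple(frozenset(groups[r]) for r in sorted(groups))
    return SmoothingState(alpha=alpha, cycles=cycles)


def _edge_between(source: SmoothingState, target: SmoothingState, xi: str) -> CubeEdge:
    src = set(source.cycles)
    tgt = set(target.cycles)
    consumed = sorted(src - tgt, key=min)
    produced = sorted(tgt - src, key=min)
    if len(consumed) == 2 and len(produced) == 1:
        kind = "merge"
    elif len(consumed) == 1 and len(produced) == 2:
        kind = "split"
    else:  # pragma: no cover - impossible on a valid diagram
        raise RuntimeError(
            f"cube edge {xi} changes cycles by {len(consumed)}->{len(produced)}"
        )
    j = xi.index("*")
    sign = -1 if xi[:j].count("1") % 2 else +1
    return CubeEdge(
        xi=xi,
        source_alpha=source.alpha,
        target_alpha=target.alpha,
        sign=sign,
        kind=kind,
        acting_labels=(
            tuple(min(c) for c in consumed),
            tuple(min(c) for c in produced),
        ),
    )


def enumerate_cube(
    diagram: LinkDiagram, max_crossings: int = DEFAULT_MAX_CROSSINGS
) -> tuple[list[SmoothingState], list[CubeEdge]]:
    """All 2^n smoothings and all n*2^(n-1) signed cube edges.

    States are returned in increasing order of alpha read as a binary
    integer; this fixes the bit order referred to elsewhere.
    """
    n = diagram.n
    if n > max_crossings:
        raise CubeTooLargeError(
            f"cube of {n} crossings has 2^{n} states, above the cap of {max_crossings}; "
            "raise max_crossings to proceed"
        )
    if n == 0:
        return [resolve(diagram, "")], []
    states: dict[str, SmoothingState] = {}
    for v in range(2**n):
        alpha = format(v, f"0{n}b")
        states[alpha] = resolve(diagram, alpha)
    edges: list[CubeEdge] = []
    for alpha, st in states.items():
        for pos in range(n):
            if alpha[pos] == "0":
                beta = alpha[:pos] + "1" + alpha[pos + 1 :]
                xi = alpha[:pos] + "*" + alpha[pos + 1 :]
                edges.append(_edge_between(st, states[beta], xi))
    return list(states.values()), edges


def kauffman_state_sum(diagram: LinkDiagram, max_crossings: int = DEFAULT_MAX_CROSSINGS) -> dict[int, int]:
    """Unnormalized Jones polynomial via the Kauffman state sum.

    Returns the Laurent polynomial
    ``sum_alpha (-1)^(l(alpha) - n_minus) q^(l(alpha) + n_plus - 2 n_minus)
    (q + q^-1)^(c(alpha))`` as a sparse mapping power -> coefficient.  This
    is computed directly on the cube and serves as an oracle independent of
    the chain complex.
    """
    states, _ = enumerate_cube(diagram, max_crossings=max_crossings)
    npl, nmi = diagram.n_plus, diagram.n_minus
    poly: dict[int, int] = {}
    for st in states:
        h = st.height
        sign = -1 if (h - nmi) % 2 else +1
        shift = h + npl - 2 * nmi
        # expand (q + q^-1)^c: binomial coefficients at powers c-2t
        c = st.n_cycles
        coeff = 1
        for t in range(c + 1):
            power = shift + c - 2 * t
            poly[power] = poly.get(power, 0) + sign * coeff
            coeff = coeff * (c - t) // (t + 1)
    return {p: v for p, v in poly.items() if v != 0}
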