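"""Diagram-level spectral reports: summaries, heatmaps, chirality analysis.

A full summary collects, per bigrading (r,q), the Laplacian spectrum, the
kernel dimension (the Khovanov homology rank), and the least nonzero
eigenvalue, together with the Poincare and Jones polynomials.  The heatmap
table arranges least-nonzero eigenvalues on the (r,q) grid.  The chirality
report compares S^{r,q} with S^{-r,-q} as multisets: for an achiral knot one
may expect these to agree, so asymmetric pairs flag (diagram-level) evidence
of chirality even where the harmonic spectra (Khovanov homology) are
symmetric.

All exports are deterministic: fixed orderings and floats at 9 significant
digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .khovanov_complex import KhovanovComplex
from .link_diagram import LinkDiagram
from .spectral import (
    SpectrumTable,
    betti_table,
    jones_polynomial,
    poincare_at_minus_one,
    spectrum_table,
)

__all__ = [
    "ChiralityReport",
    "HeatmapTable",
    "FullSummary",
    "full_summary",
    "chirality_report",
    "heatmap_table",
    "SPECTRAL_SYMMETRY_TOL",
]

# multiset comparison tolerance for symmetry verdicts (paper prints 6
# significant figures; dimensions are compared first)
SPECTRAL_SYMMETRY_TOL = 1e-6

_EMPTY = "empty"
_HARMONIC_ONLY = "harmonic-only"


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


@dataclass
class FullSummary:
    diagram_id: str
    pd: str
    spectra: SpectrumTable
    betti: dict[tuple[int, int], int]
    poincare: dict[tuple[int, int], int]
    jones_unnormalized: dict[int, int]
    jones_normalized: dict[int, int]

    def to_json(self) -> str:
        payload = {
            "diagram": self.diagram_id,
            "pd": self.pd,
            "spectra": {
                f"{r},{q}": {
                    "dim": sp.dim,
                    "betti": sp.zero_multiplicity,
                    "lambda_min_nonzero": (
                        _fmt(sp.least_nonzero) if sp.least_nonzero is not None else None
                    ),
                    "eigenvalues": [_fmt(v) for v in sp.eigenvalues],
                }
                for (r, q), sp in self.spectra.items()
            },
            "poincare": {f"{r},{q}": c for (r, q), c in sorted(self.poincare.items())},
            "jones_unnormalized": {str(p): c for p, c in sorted(self.jones_unnormalized.items())},
            "jones_normalized": {str(p): c for p, c in sorted(self.jones_normalized.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=False)

    def spectra_csv(self) -> str:
        lines = ["r,q,index,eigenvalue"]
        for (r, q), sp in self.spectra.items():
            for i, v in enumerate(sp.eigenvalues):
                lines.append(f"{r},{q},{i},{_fmt(v)}")
        return "\n".join(lines) + "\n"


@dataclass
class ChiralityReport:
    diagram_id: str
    pairs: list[tuple[int, int]]  # one representative (r,q) per +/- orbit
    asymmetric_pairs: list[tuple[int, int]]
    homology_symmetric: bool

    @property
    def spectra_symmetric(self) -> bool:
        return not self.asymmetric_pairs

    def to_json(self) -> str:
        return json.dumps(
            {
                "diagram": self.diagram_id,
                "pairs": [list(p) for p in self.pairs],
                "asymmetric_pairs": [list(p) for p in self.asymmetric_pairs],
                "homology_symmetric": self.homology_symmetric,
                "spectra_symmetric": self.spectra_symmetric,
            },
            indent=1,
        )


@dataclass
class HeatmapTable:
    r_values: list[int]
    q_values: list[int]
    cells: dict[tuple[int, int], object] = field(default_factory=dict)
    # cell: least nonzero eigenvalue (float), "harmonic-only", or "empty"

    def cell(self, r: int, q: int):
        return self.cells.get((r, q), _EMPTY)

    def to_csv(self) -> str:
        lines = ["q\\r," + ",".join(str(r) for r in self.r_values)]
        for q in sorted(self.q_values, reverse=True):
            row = [str(q)]
            for r in self.r_values:
                v = self.cell(r, q)
                row.append(_fmt(v) if isinstance(v, float) else str(v))
            lines.append(",".join(row))
        return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------


def full_summary(
    diagram: LinkDiagram, diagram_id: str = "diagram", cx: KhovanovComplex | None = None
) -> FullSummary:
    cx = cx or KhovanovComplex(diagram)
    spectra = spectrum_table(cx)
    bt = betti_table(cx)
    return FullSummary(
        diagram_id=diagram_id,
        pd=diagram.to_pd(),
        spectra=spectra,
        betti=bt,
        poincare=dict(bt),
        jones_unnormalized=poincare_at_minus_one(bt),
        jones_normalized=jones_polynomial(cx, normalized=True),
    )


def chirality_report(
    diagram: LinkDiagram,
    diagram_id: str = "diagram",
    tol: float = SPECTRAL_SYMMETRY_TOL,
    spectra: SpectrumTable | None = None,
) -> ChiralityReport:
    """Compare S^{r,q} against S^{-r,-q} as multisets for every populated
    bigrading orbit of the diagram."""
    spectra = spectra or spectrum_table(diagram)
    pairs: list[tuple[int, int]] = []
    asym: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for key in sorted(spectra.entries):
        r, q = key
        if key in seen or (-r, -q) in seen:
            continue
        seen.add(key)
        rep = max(key, (-r, -q))  # canonical representative of the orbit
        pairs.append(rep)
        a = spectra.entries.get(key)
        b = spectra.entries.get((-r, -q))
        ea = a.eigenvalues if a else np.zeros(0)
        eb = b.eigenvalues if b else np.zeros(0)
        if len(ea) != len(eb) or (len(ea) and np.max(np.abs(ea - eb)) > tol):
            asym.append(rep)
    bt = spectra.betti()
    homology_symmetric = all(bt.get((-r, -q), 0) == v for (r, q), v in bt.items())
    return ChiralityReport(
        diagram_id=diagram_id,
        pairs=pairs,
        asymmetric_pairs=asym,
        homology_symmetric=homology_symmetric,
    )


def heatmap_table(
    diagram: LinkDiagram,
    window: tuple[tuple[int, int], tuple[int, int]] | None = None,
    spectra: SpectrumTable | None = None,
) -> HeatmapTable:
    """Least-nonzero-eigenvalue grid over an (r,q) window.

    Bins with no chain group are marked "empty"; bins whose spectrum is
    entirely zero are marked "harmonic-only" (the least *nonzero* eigenvalue
    does not exist there).
    """
    spectra = spectra or spectrum_table(diagram)
    keys = sorted(spectra.entries)
    if not keys:
        raise ValueError("diagram has no chain groups")
    if window is None:
        rs = [r for r, _ in keys]
        qs = [q for _, q in keys]
        window = ((min(rs), max(rs)), (min(qs), max(qs)))
    (r_lo, r_hi), (q_lo, q_hi) = window
    table = HeatmapTable(
        r_values=list(range(r_lo, r_hi + 1)),
        q_values=list(range(q_lo, q_hi + 1)),
    )
    for r in table.r_values:
        for q in table.q_values:
            sp = spectra.entries.get((r, q))
            if sp is None or sp.dim == 0:
                table.cells[(r, q)] = _EMPTY
            elif sp.least_nonzero is None:
                table.cells[(r, q)] = _HARMONIC_ONLY
            else:
                table.cells[(r, q)] = float(sp.least_nonzero)
    return table
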