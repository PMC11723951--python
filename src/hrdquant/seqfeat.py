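"""HRD sequence-motif grammar scanning and linker physicochemistry.

The heterochromatin retention domain (HRD) is built from four short linear
motifs: a hydrophobic Phi1 ([VI]-x-L), a His-Cys motif (H-x4-C-x{3,4}-C;
the amphibian variant is H-x{3,4}-C-x{13,14}-C), a hydrophobic Phi2
(L-x{5,6}-V-x-L) and a related Phi3 (L-x5-V-x-L), plus the canonical HP1
chromoshadow-domain ligand PxVxL for reference.  Phi1 + His-Cys + Phi2 form
conserved region 1 (CR1); Phi3 is CR2; an intrinsically disordered linker
tethers them.

This module scans sequences for all motif occurrences (including
overlapping matches and every alternative span of variable-gap grammars),
calls the CR1-linker-CR2 architecture under spacing constraints, and
computes linker sequence parameters: net charge per residue (NCPR),
fraction of charged residues (FCR), disorder-promoting fraction, the
per-residue charge profile (window size 1), and a conformational-class
assignment with the corresponding reference functional length.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "DISORDER_PROMOTING",
    "MOTIF_CLASSES",
    "MotifHit",
    "HRDAnnotation",
    "LinkerFeatures",
    "scan_motifs",
    "matches_class",
    "call_hrd",
    "linker_features",
    "composition_heatmap",
    "percent_identity",
    "alignment_identity",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: X is legal input but never matches a constrained motif position
ALPHABET = AMINO_ACIDS + "X"

#: residues statistically enriched in intrinsically disordered regions
DISORDER_PROMOTING = frozenset("ARGQSPEK")

_POSITIVE = frozenset("KR")
_NEGATIVE = frozenset("DE")

_X = f"[{ALPHABET}]"

# each grammar is a list of span variants: (regex for the fixed-length
# variant, offset of the central "0" residue or None).  Variable gaps are
# enumerated so every alternative span is reported.
_GRAMMARS: dict[str, list[tuple[str, int | None]]] = {
    "phi1": [(f"[VI]{_X}L", 0)],
    "hiscys": [
        (f"H{_X}{{4}}C{_X}{{3}}C", None),
        (f"H{_X}{{4}}C{_X}{{4}}C", None),
    ],
    "hiscys_amphibian": [
        (f"H{_X}{{{g1}}}C{_X}{{{g2}}}C", None) for g1 in (3, 4) for g2 in (13, 14)
    ],
    "phi2": [
        (f"L{_X}{{5}}V{_X}L", 6),
        (f"L{_X}{{6}}V{_X}L", 7),
    ],
    "phi3": [(f"L{_X}{{5}}V{_X}L", 6)],
    "pxvxl": [(f"P{_X}V{_X}L", 2)],
}
MOTIF_CLASSES = tuple(_GRAMMARS)

_COMPILED = {
    cls: [(re.compile(f"(?=({pat}))"), zero) for pat, zero in variants]
    for cls, variants in _GRAMMARS.items()
}


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; ``start``/``end`` are 1-based inclusive."""

    motif_class: str
    start: int
    end: int
    matched: str
    core_zero_pos: int | None = None

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class HRDAnnotation:
    """CR1 / linker / CR2 architecture call for one sequence.

    Spans are 1-based inclusive ``(start, end)`` tuples or ``None`` when the
    element is absent.  Gaps count residues strictly between consecutive
    motifs, so the invariant mammalian spacing is gap ``0`` between Phi1 and
    His-Cys and gap ``1`` between His-Cys and Phi2.
    """

    cr1_span: tuple[int, int] | None
    linker_span: tuple[int, int] | None
    cr2_span: tuple[int, int] | None
    gap_phi1_hiscys: int | None
    gap_hiscys_phi2: int | None
    linker_length: int | None
    complete: bool
    motifs: dict = field(default_factory=dict)
    alternatives: list = field(default_factory=list)


#: (FCR upper bound, conformational class, reference functional length in Angstrom)
CONFORMATIONAL_CLASSES: list[tuple[float, str, float]] = [
    (0.10, "compact_globule", 13.0),
    (0.20, "intermediate", 22.5),
    (0.30, "intermediate", 34.3),
    (0.40, "Flory_random_coil", 53.9),
    (1.0 + 1e-9, "self_avoiding_random_coil", 66.6),
]


@dataclass
class LinkerFeatures:
    """Physicochemical profile of a disordered linker segment."""

    length: int
    ncpr: float
    fcr: float
    dp_fraction: float
    charge_profile: np.ndarray
    composition: dict[str, float]
    conformational_class: str
    functional_length: float


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    return seq


def scan_motifs(sequence: str, classes=MOTIF_CLASSES) -> list[MotifHit]:
    """Enumerate every motif occurrence of the requested classes.

    Overlapping matches and all alternative spans of variable-gap grammars
    are reported.  Hits are sorted by start position, then class name, then
    end.  An empty sequence yields an empty list.
    """
    seq = _validate_sequence(sequence)
    unknown = set(classes) - set(MOTIF_CLASSES)
    if unknown:
        raise ValueError(f"unknown motif classes: {sorted(unknown)}")
    hits: list[MotifHit] = []
    for cls in classes:
        for rx, zero in _COMPILED[cls]:
            for m in rx.finditer(seq):
                s = m.start()
                matched = m.group(1)
                hits.append(
                    MotifHit(
                        motif_class=cls,
                        start=s + 1,
                        end=s + len(matched),
                        matched=matched,
                        core_zero_pos=s + 1 + zero if zero is not None else None,
                    )
                )
    hits.sort(key=lambda h: (h.start, h.motif_class, h.end))
    return hits


def matches_class(fragment: str, motif_class: str) -> bool:
    """True if ``fragment`` exactly realizes one span variant of the grammar."""
    frag = _validate_sequence(fragment)
    for rx, _ in _COMPILED[motif_class]:
        m = rx.match(frag)
        if m and m.group(1) == frag:
            return True
    return False


# ---------------------------------------------------------------------------
# architecture calling
# ---------------------------------------------------------------------------

def call_hrd(
    sequence: str,
    hits: list[MotifHit] | None = None,
    gap1_allowed=frozenset({0}),
    gap2_allowed=frozenset({1}),
    linker_bounds: tuple[int, int] = (5, 400),
    hiscys_classes=("hiscys",),
) -> HRDAnnotation:
    """Call the Phi1 -> His-Cys -> Phi2 -> linker -> Phi3 architecture.

    Chains whose inter-motif gaps match ``gap1_allowed``/``gap2_allowed``
    are enumerated; the nearest downstream Phi3 with a linker length within
    ``linker_bounds`` completes the call.  Ambiguity is resolved by minimal
    total span, then leftmost start; remaining valid chains are recorded in
    ``alternatives``.  Incomplete architectures are legal outputs with
    ``complete=False``.
    """
    seq = _validate_sequence(sequence)
    if hits is None:
        hits = scan_motifs(seq)
    by_class: dict[str, list[MotifHit]] = {}
    for h in sorted(hits, key=lambda h: (h.start, h.end, h.motif_class)):
        by_class.setdefault(h.motif_class, []).append(h)

    hc_hits = [h for cls in hiscys_classes for h in by_class.get(cls, [])]
    cr1_chains = []
    for p1 in by_class.get("phi1", []):
        for hc in hc_hits:
            g1 = hc.start - p1.end - 1
            if g1 not in gap1_allowed:
                continue
            for p2 in by_class.get("phi2", []):
                g2 = p2.start - hc.end - 1
                if g2 not in gap2_allowed:
                    continue
                cr1_chains.append((p1, hc, p2, g1, g2))

    full_chains = []
    lo, hi = linker_bounds
    for p1, hc, p2, g1, g2 in cr1_chains:
        for p3 in by_class.get("phi3", []):
            ll = p3.start - p2.end - 1
            if p3.start <= p2.end or not (lo <= ll <= hi):
                continue
            full_chains.append((p1, hc, p2, p3, g1, g2, ll))

    def chain_key(ch):
        p1, _, _, p3 = ch[0], ch[1], ch[2], ch[3]
        return (p3.end - p1.start, p1.start)

    if full_chains:
        full_chains.sort(key=chain_key)
        p1, hc, p2, p3, g1, g2, ll = full_chains[0]
        return HRDAnnotation(
            cr1_span=(p1.start, p2.end),
            linker_span=(p2.end + 1, p3.start - 1) if ll > 0 else None,
            cr2_span=(p3.start, p3.end),
            gap_phi1_hiscys=g1,
            gap_hiscys_phi2=g2,
            linker_length=ll,
            complete=True,
            motifs={"phi1": p1, "hiscys": hc, "phi2": p2, "phi3": p3},
            alternatives=[
                {"cr1": (c[0].start, c[2].end), "cr2": (c[3].start, c[3].end), "linker_length": c[6]}
                for c in full_chains[1:]
            ],
        )
    if cr1_chains:
        cr1_chains.sort(key=lambda c: (c[2].end - c[0].start, c[0].start))
        p1, hc, p2, g1, g2 = cr1_chains[0]
        return HRDAnnotation(
            cr1_span=(p1.start, p2.end),
            linker_span=None,
            cr2_span=None,
            gap_phi1_hiscys=g1,
            gap_hiscys_phi2=g2,
            linker_length=None,
            complete=False,
            motifs={"phi1": p1, "hiscys": hc, "phi2": p2},
        )
    return HRDAnnotation(
        cr1_span=None,
        linker_span=None,
        cr2_span=None,
        gap_phi1_hiscys=None,
        gap_hiscys_phi2=None,
        linker_length=None,
        complete=False,
        motifs={},
    )


# ---------------------------------------------------------------------------
# linker physicochemistry
# ---------------------------------------------------------------------------

def linker_features(
    segment: str,
    dp_set: frozenset[str] = DISORDER_PROMOTING,
    histidine_charged: bool = False,
) -> LinkerFeatures:
    """Sequence parameters of a linker segment.

    ``NCPR = (#K + #R - #D - #E) / L`` and ``FCR = (#K + #R + #D + #E) / L``
    (histidine uncharged by default).  The charge profile assigns +1 to K/R,
    -1 to D/E, 0 otherwise (window size 1).  The conformational class and
    reference functional length come from the FCR band table
    :data:`CONFORMATIONAL_CLASSES`.
    """
    seq = _validate_sequence(segment)
    if not seq:
        raise ValueError("empty linker segment")
    pos = set(_POSITIVE) | ({"H"} if histidine_charged else set())
    charges = np.array(
        [1 if a in pos else -1 if a in _NEGATIVE else 0 for a in seq], dtype=int
    )
    n = len(seq)
    ncpr = float(charges.sum()) / n
    fcr = float(np.abs(charges).sum()) / n
    dp = sum(1 for a in seq if a in dp_set) / n
    comp = {a: seq.count(a) / n for a in AMINO_ACIDS}
    cls, flen = _conformational_class(fcr)
    return LinkerFeatures(
        length=n,
        ncpr=ncpr,
        fcr=fcr,
        dp_fraction=dp,
        charge_profile=charges,
        composition=comp,
        conformational_class=cls,
        functional_length=flen,
    )


def _conformational_class(fcr: float) -> tuple[str, float]:
    for bound, cls, flen in CONFORMATIONAL_CLASSES:
        if fcr < bound:
            return cls, flen
    return CONFORMATIONAL_CLASSES[-1][1:]


def composition_heatmap(segments: list[tuple[str, str]]) -> pd.DataFrame:
    """Residue-fraction matrix (segments x 20 residues), z-scored per column.

    Columns with zero variance get z-score 0.  Disorder-promoting columns
    are listed in ``DataFrame.attrs["disorder_promoting_columns"]``.
    """
    if len(segments) < 2:
        raise ValueError("z-scores undefined for fewer than 2 segments")
    rows = {}
    for label, seq in segments:
        s = _validate_sequence(seq)
        if not s:
            raise ValueError(f"empty segment {label!r}")
        rows[label] = [s.count(a) / len(s) for a in AMINO_ACIDS]
    frac = pd.DataFrame.from_dict(rows, orient="index", columns=list(AMINO_ACIDS))
    mu = frac.mean(axis=0)
    sd = frac.std(axis=0, ddof=0)
    z = (frac - mu).div(sd.where(sd > 0, 1.0), axis=1)
    z.attrs["disorder_promoting_columns"] = sorted(DISORDER_PROMOTING)
    return z


# ---------------------------------------------------------------------------
# alignment identity
# ---------------------------------------------------------------------------

def percent_identity(n_invariant: int, n_positions: int) -> float:
    """Percent of aligned positions that are invariant (e.g. 17/57 -> 29.8%)."""
    if n_positions <= 0 or n_invariant < 0 or n_invariant > n_positions:
        raise ValueError("need 0 <= n_invariant <= n_positions, n_positions > 0")
    return 100.0 * n_invariant / n_positions


def alignment_identity(aligned: list[str]) -> tuple[int, int, float]:
    """Invariant-column count over an aligned block of equal-length sequences.

    Returns ``(n_invariant, n_positions, percent)``; a column is invariant
    when every sequence carries the same non-gap residue.
    """
    if not aligned:
        raise ValueError("empty alignment")
    lengths = {len(s) for s in aligned}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    n_cols = lengths.pop()
    inv = 0
    for i in range(n_cols):
        col = {s[i].upper() for s in aligned}
        if len(col) == 1 and "-" not in col:
            inv += 1
    return inv, n_cols, percent_identity(inv, n_cols)
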