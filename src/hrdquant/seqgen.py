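"""Synthetic HRD-like protein sequences with known planted architecture.

Builds sequences of the form

    flank - Phi1 - gap1 - HisCys - gap2 - Phi2 - linker - Phi3 - flank

where each motif instance is a concrete string validated against its
grammar, the inter-motif gaps are configurable (mammalian spacing: 0 and 1
residues), and the linker is drawn by constrained residue sampling to hit
target NCPR / FCR / disorder-promoting-fraction values.

Gap, linker and flank positions are filled from residue pools that exclude
V, I, L, H and C so the planted motifs are the only intended grammar
matches; composition targets are still achievable because the excluded
residues are all uncharged and (except H) not disorder-promoting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqfeat import matches_class, linker_features

__all__ = ["SequenceSpec", "PlantedSequence", "make_hrd_sequence"]

# uncharged pools that cannot seed spurious motif matches
_DP_UNCHARGED = "AGQSP"  # disorder-promoting, uncharged
_ORDER_UNCHARGED = "FMNTWY"  # order-promoting, uncharged

_DEFAULT_MOTIFS = {
    "phi1": "VHL",
    "hiscys": "HAGQSCAGQC",
    "phi2": "LAGQSTVAL",
    "phi3": "LTSQGAVML",
}


@dataclass(frozen=True)
class SequenceSpec:
    """Recipe for one synthetic HRD sequence.

    ``linker_ncpr``/``linker_fcr``/``linker_dp`` are composition targets for
    the linker (realized within +/-0.05 by counting; infeasible targets such
    as ``|NCPR| > FCR`` are rejected).
    """

    motifs: dict = field(default_factory=lambda: dict(_DEFAULT_MOTIFS))
    gap_phi1_hiscys: int = 0
    gap_hiscys_phi2: int = 1
    linker_length: int = 21
    linker_ncpr: float = 0.05
    linker_fcr: float = 0.15
    linker_dp: float = 0.8
    n_flank: int = 6
    c_flank: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap_phi1_hiscys < 0 or self.gap_hiscys_phi2 < 0:
            raise ValueError("gaps must be non-negative")
        if self.linker_length < 1:
            raise ValueError("linker_length must be >= 1")
        if not abs(self.linker_ncpr) <= self.linker_fcr <= 1.0:
            raise ValueError("composition targets must satisfy |NCPR| <= FCR <= 1")
        if not 0.0 <= self.linker_dp <= 1.0:
            raise ValueError("linker_dp must lie in [0, 1]")
        for cls, inst in self.motifs.items():
            if not matches_class(inst, cls):
                raise ValueError(f"motif instance {inst!r} does not match the {cls} grammar")


@dataclass
class PlantedSequence:
    """A generated sequence plus the 1-based inclusive spans of its motifs."""

    sequence: str
    spans: dict[str, tuple[int, int]]
    linker_span: tuple[int, int]
    spec: SequenceSpec


def _sample_linker(spec: SequenceSpec, rng: np.random.Generator) -> str:
    n = spec.linker_length
    n_charged = round(spec.linker_fcr * n)
    n_pos = round((spec.linker_fcr + spec.linker_ncpr) / 2.0 * n)
    n_pos = min(max(n_pos, 0), n_charged)
    n_neg = n_charged - n_pos
    n_unch = n - n_charged

    # charged disorder-promoting residues: K, R, E (D is not in the set)
    positives = [str(rng.choice(list("KR"))) for _ in range(n_pos)]
    dp_needed = round(spec.linker_dp * n) - n_pos
    negatives = []
    for _ in range(n_neg):
        if dp_needed > 0:
            negatives.append("E")
            dp_needed -= 1
        else:
            negatives.append(str(rng.choice(list("DE"))))
    n_dp_unch = int(np.clip(dp_needed, 0, n_unch))
    uncharged = [str(rng.choice(list(_DP_UNCHARGED))) for _ in range(n_dp_unch)] + [
        str(rng.choice(list(_ORDER_UNCHARGED))) for _ in range(n_unch - n_dp_unch)
    ]
    residues = positives + negatives + uncharged
    return "".join(rng.permutation(residues))


def _neutral(n: int, rng: np.random.Generator) -> str:
    pool = list(_DP_UNCHARGED + _ORDER_UNCHARGED)
    return "".join(str(rng.choice(pool)) for _ in range(n))


def make_hrd_sequence(spec: SequenceSpec) -> PlantedSequence:
    """Assemble a synthetic HRD sequence from a :class:`SequenceSpec`.

    The realized linker NCPR/FCR/DP fraction is verified to lie within
    +/-0.05 of the targets (counting granularity permitting).
    """
    rng = np.random.default_rng(spec.seed)
    linker = _sample_linker(spec, rng)
    feats = linker_features(linker)
    tol = 0.05 + 1.0 / spec.linker_length  # counting granularity on short linkers
    for name, target, got in (
        ("NCPR", spec.linker_ncpr, feats.ncpr),
        ("FCR", spec.linker_fcr, feats.fcr),
        ("DP fraction", spec.linker_dp, feats.dp_fraction),
    ):
        if abs(got - target) > tol:
            raise RuntimeError(
                f"sampled linker misses {name} target ({got:.3f} vs {target:.3f})"
            )

    parts, spans = [], {}
    pos = 0

    def emit(fragment: str, name: str | None = None) -> None:
        nonlocal pos
        if name is not None:
            spans[name] = (pos + 1, pos + len(fragment))
        parts.append(fragment)
        pos += len(fragment)

    emit(_neutral(spec.n_flank, rng))
    emit(spec.motifs["phi1"], "phi1")
    emit(_neutral(spec.gap_phi1_hiscys, rng))
    emit(spec.motifs["hiscys"], "hiscys")
    emit(_neutral(spec.gap_hiscys_phi2, rng))
    emit(spec.motifs["phi2"], "phi2")
    emit(linker, "linker")
    emit(spec.motifs["phi3"], "phi3")
    emit(_neutral(spec.c_flank, rng))

    seq = "".join(parts)
    linker_span = spans.pop("linker")
    return PlantedSequence(sequence=seq, spans=spans, linker_span=linker_span, spec=spec)
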