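"""Four-gene MLSA: per-marker alignment, concatenated identity, JC distance.

Multilocus sequence analysis here follows the classic housekeeping-gene
scheme for *Pseudomonas*: partial 16S rDNA, *gyrB*, *rpoB* and *rpoD*
sequences are aligned per marker, the alignments are pooled in a fixed
concatenation order, and the percent identity of the concatenation is the
pairwise similarity.  The species cutoff conventionally applied to this
statistic is 97%.

Alignment is pairwise global dynamic programming (Needleman–Wunsch with
affine gaps, via Biopython's PairwiseAligner).  Identity is computed over
columns where both sequences have a residue — terminal and internal gap
columns are excluded from the denominator — and IUPAC ambiguity codes only
count as identical when the letters are equal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from Bio import Align

from .matrix import DistanceMatrix

__all__ = [
    "MARKER_ORDER",
    "MarkerProfile",
    "PairwiseAlignment",
    "AlignParams",
    "MissingMarkerError",
    "SaturationError",
    "align_pair",
    "p_distance",
    "jukes_cantor",
    "concatenate_pair",
    "MlsaPairResult",
    "mlsa_matrix",
]

MARKER_ORDER = ("16S", "gyrB", "rpoB", "rpoD")

_IUPAC = frozenset("ACGTURYSWKMBDHVN")


class MissingMarkerError(ValueError):
    """A strain pair cannot be compared because a marker sequence is absent."""


class SaturationError(ValueError):
    """Observed difference proportion at or beyond the JC limit of 3/4."""


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment scoring; penalties are positive magnitudes.

    The first gapped column of a run costs ``gap_open`` and each further
    column ``gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 5.0
    gap_extend: float = 2.0


@dataclass
class MarkerProfile:
    """One strain's partial marker gene sequences.

    ``sequences`` maps marker name (a subset of :data:`MARKER_ORDER`) to an
    upper-case nucleotide sequence.  A profile may be incomplete; pair-level
    operations decide whether that is an error.
    """

    strain_id: str
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, seq in self.sequences.items():
            if name not in MARKER_ORDER:
                raise ValueError(
                    f"unknown marker {name!r}; expected one of {MARKER_ORDER}"
                )
            seq = _validate_nt(seq, f"{self.strain_id}/{name}")
            clean[name] = seq
        self.sequences = clean

    def is_complete(self) -> bool:
        return all(m in self.sequences for m in MARKER_ORDER)


def _validate_nt(seq: str, what: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence for {what}")
    seq = seq.upper()
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in {what}")
    return seq


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped global alignment of two sequences with identity statistics."""

    aligned_a: str
    aligned_b: str
    identity_fraction: float
    compared_columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped sequences must have equal length")

    @classmethod
    def from_gapped(cls, aligned_a: str, aligned_b: str) -> "PairwiseAlignment":
        matches, compared = _count_identity(aligned_a, aligned_b)
        ident = matches / compared if compared else 0.0
        return cls(aligned_a, aligned_b, ident, compared)


def _count_identity(ga: str, gb: str) -> tuple[int, int]:
    matches = 0
    compared = 0
    for x, y in zip(ga, gb):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x == y:
            matches += 1
    return matches, compared


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(a: str, b: str, params: AlignParams | None = None) -> PairwiseAlignment:
    """Globally align two nucleotide sequences; deterministic best alignment."""
    params = params or AlignParams()
    a = _validate_nt(a, "sequence a")
    b = _validate_nt(b, "sequence b")
    aln = _make_aligner(params).align(a, b)[0]
    return PairwiseAlignment.from_gapped(str(aln[0]), str(aln[1]))


def p_distance(aln: PairwiseAlignment) -> float:
    """Observed difference proportion over the compared columns."""
    if aln.compared_columns <= 0:
        raise ValueError("alignment has no compared columns")
    return 1.0 - aln.identity_fraction


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3), defined for 0 <= p < 3/4."""
    if p < 0:
        raise ValueError("difference proportion cannot be negative")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at or beyond the JC saturation limit 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class MlsaPairResult:
    """Pooled 4-gene result for one strain pair.

    Identity is pooled over summed columns of the per-marker alignments —
    longer markers carry proportionally more weight, mirroring a true
    concatenation rather than an average of averages.
    """

    strain_a: str
    strain_b: str
    per_marker: dict[str, PairwiseAlignment]
    markers_used: tuple[str, ...]
    identity_fraction: float
    compared_columns: int
    aligned_a: str
    aligned_b: str

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.identity_fraction

    def jc_distance(self) -> float:
        return jukes_cantor(1.0 - self.identity_fraction)


def concatenate_pair(
    profile_a: MarkerProfile,
    profile_b: MarkerProfile,
    params: AlignParams | None = None,
    allow_missing: bool = False,
) -> MlsaPairResult:
    """Align each marker independently and pool into the MLSA identity.

    Markers are concatenated in the fixed order 16S, gyrB, rpoB, rpoD.  By
    default every marker must be present in both profiles; with
    ``allow_missing`` the pair is downgraded to a 16S-only comparison (with
    a warning) when any protein-coding marker is absent.
    """
    missing = [
        m
        for m in MARKER_ORDER
        if m not in profile_a.sequences or m not in profile_b.sequences
    ]
    if missing and not allow_missing:
        raise MissingMarkerError(
            f"pair ({profile_a.strain_id}, {profile_b.strain_id}) is missing "
            f"marker(s) {missing}; pass allow_missing=True to fall back to 16S"
        )
    markers = MARKER_ORDER
    if missing:
        if "16S" in missing:
            raise MissingMarkerError(
                f"pair ({profile_a.strain_id}, {profile_b.strain_id}) lacks 16S; "
                "no comparison possible"
            )
        warnings.warn(
            f"pair ({profile_a.strain_id}, {profile_b.strain_id}) downgraded "
            f"to 16S-only (missing {missing})"
        )
        markers = ("16S",)
    per_marker = {}
    matches = 0
    compared = 0
    gapped_a = []
    gapped_b = []
    for m in markers:
        aln = align_pair(profile_a.sequences[m], profile_b.sequences[m], params)
        per_marker[m] = aln
        mm, cc = _count_identity(aln.aligned_a, aln.aligned_b)
        matches += mm
        compared += cc
        gapped_a.append(aln.aligned_a)
        gapped_b.append(aln.aligned_b)
    if compared == 0:
        raise ValueError("no compared columns across markers")
    return MlsaPairResult(
        strain_a=profile_a.strain_id,
        strain_b=profile_b.strain_id,
        per_marker=per_marker,
        markers_used=markers,
        identity_fraction=matches / compared,
        compared_columns=compared,
        aligned_a="".join(gapped_a),
        aligned_b="".join(gapped_b),
    )


def mlsa_matrix(
    profiles: list[MarkerProfile],
    params: AlignParams | None = None,
    allow_missing: bool = False,
    mode: str = "percent",
) -> DistanceMatrix:
    """All-vs-all MLSA matrix.

    ``mode="percent"`` yields percent similarity (diagonal 100);
    ``mode="jc"`` yields Jukes–Cantor distances of the pooled p-distances.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ids = [p.strain_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids")
    if mode not in ("percent", "jc"):
        raise ValueError("mode must be 'percent' or 'jc'")
    import numpy as np

    n = len(profiles)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = concatenate_pair(profiles[i], profiles[j], params, allow_missing)
            if mode == "percent":
                v = res.percent_identity
            else:
                v = res.jc_distance()
            vals[i, j] = vals[j, i] = v
    if mode == "percent":
        np.fill_diagonal(vals, 100.0)
        return DistanceMatrix(ids, vals, "percent")
    return DistanceMatrix(ids, vals, "distance")
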