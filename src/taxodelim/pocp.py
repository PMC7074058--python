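"""Percentage of conserved proteins (POCP) for genus delimitation.

POCP between two proteomes is ``100 * (C1 + C2) / (T1 + T2)`` where T1, T2
are the protein counts of the two genomes and C1, C2 are the numbers of
query proteins (in each direction) with a conserved match in the other
proteome.  A match is conserved when its E-value is at most 1e-5, its
identity at least 50%, and — following the original definition of the
index — its aligned region covers at least 50% of the query; the coverage
term can be switched off to apply the bare E-value/identity wording.
Two species of the same genus are expected to share at least half of their
proteins (POCP >= 50%).

The search is Smith–Waterman with BLOSUM62 and BLAST-style affine gaps
(open 11, extend 1), preceded by an exact 4-mer prefilter so only protein
pairs sharing a word are aligned.  E-values use ungapped Karlin–Altschul
statistics for BLOSUM62 (lambda = 0.3176, K = 0.134) with the subject
proteome's total residue count as the database size — a documented
approximation when applied to gapped scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .align import blosum62_matrix, encode_protein, smith_waterman
from .matrix import DistanceMatrix

__all__ = [
    "PocpParams",
    "Proteome",
    "ProteinHit",
    "PocpResult",
    "protein_best_hit",
    "conserved_count",
    "pocp",
    "pocp_pair",
    "pocp_matrix",
]

_AA = frozenset("ARNDCQEGHILKMFPSTWYVBZX")


@dataclass(frozen=True)
class PocpParams:
    """Search and acceptance parameters for the conserved-protein count."""

    evalue_max: float = 1e-5
    min_identity: float = 0.5
    min_coverage: float = 0.5
    coverage_filter: bool = True  # original POCP alignable-region criterion
    gap_open: float = 11.0  # BLAST convention: gap of length g costs open + g*extend
    gap_extend: float = 1.0
    k: int = 4  # exact word prefilter
    exact: bool = False  # align every query/subject pair (no prefilter)
    ka_lambda: float = 0.3176  # ungapped Karlin-Altschul, BLOSUM62
    ka_k: float = 0.134
    genus_cutoff: float = 50.0


class Proteome:
    """A strain's proteins; ids unique, standard residues plus X."""

    def __init__(self, strain_id: str, proteins: list[tuple[str, str]]) -> None:
        ids = [p for p, _ in proteins]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate protein ids in proteome {strain_id}")
        clean = []
        for pid, seq in proteins:
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty protein {pid} in proteome {strain_id}")
            bad = set(seq) - _AA
            if bad:
                raise ValueError(
                    f"non-amino-acid characters {sorted(bad)} in {strain_id}/{pid}"
                )
            clean.append((pid, seq))
        self.strain_id = strain_id
        self.proteins = clean
        self.total_residues = sum(len(s) for _, s in clean)
        self._kmer_index: dict[bytes, set[int]] | None = None
        self._encoded = [encode_protein(s) for _, s in clean]

    def __len__(self) -> int:
        return len(self.proteins)

    def kmer_index(self, k: int) -> dict[bytes, set[int]]:
        if self._kmer_index is None:
            index: dict[bytes, set[int]] = {}
            for i, (_, seq) in enumerate(self.proteins):
                data = seq.encode("ascii")
                for j in range(len(data) - k + 1):
                    index.setdefault(data[j : j + k], set()).add(i)
            self._kmer_index = index
        return self._kmer_index


@dataclass(frozen=True)
class ProteinHit:
    subject_id: str
    score: float
    evalue: float
    identity: float
    coverage: float
    matches: int
    columns: int


def _candidates(query: str, subject: Proteome, params: PocpParams) -> list[int]:
    if params.exact:
        return list(range(len(subject)))
    index = subject.kmer_index(params.k)
    data = query.encode("ascii")
    found: set[int] = set()
    for j in range(len(data) - params.k + 1):
        hits = index.get(data[j : j + params.k])
        if hits:
            found.update(hits)
    return sorted(found)


def protein_best_hit(
    query: str, subject: Proteome, params: PocpParams | None = None
) -> ProteinHit | None:
    """Best subject protein by Smith–Waterman score (minimal E-value).

    Returns ``None`` when no subject shares a seed word (heuristic mode) or
    no alignment scores above zero.  Ties are broken by subject order.
    """
    params = params or PocpParams()
    query = query.upper()
    if not query or not len(subject):
        raise ValueError("empty query or subject")
    smat = blosum62_matrix()
    q = encode_protein(query)
    gap_first = params.gap_open + params.gap_extend
    best: tuple[float, int, object] | None = None
    for idx in _candidates(query, subject, params):
        local = smith_waterman(
            q, subject._encoded[idx], smat, gap_first, params.gap_extend
        )
        if local.score <= 0 or local.columns == 0:
            continue
        if best is None or local.score > best[0]:
            best = (local.score, idx, local)
    if best is None:
        return None
    score, idx, local = best
    evalue = params.ka_k * len(query) * subject.total_residues * math.exp(
        -params.ka_lambda * score
    )
    return ProteinHit(
        subject_id=subject.proteins[idx][0],
        score=score,
        evalue=evalue,
        identity=local.identity,
        coverage=local.q_span / len(query),
        matches=local.matches,
        columns=local.columns,
    )


def _accepted(hit: ProteinHit | None, params: PocpParams) -> bool:
    if hit is None:
        return False
    if hit.evalue > params.evalue_max or hit.identity < params.min_identity:
        return False
    if params.coverage_filter and hit.coverage < params.min_coverage:
        return False
    return True


def conserved_count(
    query_proteome: Proteome, subject_proteome: Proteome, params: PocpParams | None = None
) -> int:
    """Number of query proteins with at least one conserved match."""
    params = params or PocpParams()
    if len(query_proteome) == 0 or len(subject_proteome) == 0:
        warnings.warn("empty proteome in conserved_count; count is 0")
        return 0
    count = 0
    for _, seq in query_proteome.proteins:
        if _accepted(protein_best_hit(seq, subject_proteome, params), params):
            count += 1
    return count


def pocp(C1: int, C2: int, T1: int, T2: int, genus_cutoff: float = 50.0) -> float:
    """POCP = 100 (C1 + C2) / (T1 + T2)."""
    for c, t in ((C1, T1), (C2, T2)):
        if not 0 <= c <= t:
            raise ValueError("conserved counts must satisfy 0 <= Ci <= Ti")
    if T1 + T2 == 0:
        raise ValueError("both proteomes are empty")
    return 100.0 * (C1 + C2) / (T1 + T2)


@dataclass(frozen=True)
class PocpResult:
    strain_a: str
    strain_b: str
    C1: int
    C2: int
    T1: int
    T2: int
    pocp_percent: float
    genus_cutoff: float
    size_ratio: float  # larger proteome / smaller proteome

    @property
    def same_genus(self) -> bool:
        return self.pocp_percent >= self.genus_cutoff

    @property
    def size_warning(self) -> bool:
        """Strong proteome-size asymmetry distorts POCP downward."""
        return self.size_ratio > 1.5


def pocp_pair(
    a: Proteome, b: Proteome, params: PocpParams | None = None
) -> PocpResult:
    params = params or PocpParams()
    C1 = conserved_count(a, b, params)
    C2 = conserved_count(b, a, params)
    T1, T2 = len(a), len(b)
    value = pocp(C1, C2, T1, T2, params.genus_cutoff)
    big, small = max(T1, T2), max(min(T1, T2), 1)
    return PocpResult(a.strain_id, b.strain_id, C1, C2, T1, T2, value,
                      params.genus_cutoff, big / small)


def pocp_matrix(
    proteomes: dict[str, Proteome] | list[Proteome],
    params: PocpParams | None = None,
) -> tuple[DistanceMatrix, "object"]:
    """All-vs-all POCP percent matrix plus the per-pair table."""
    import numpy as np
    import pandas as pd

    params = params or PocpParams()
    if isinstance(proteomes, dict):
        items = [proteomes[k] for k in sorted(proteomes)]
    else:
        items = sorted(proteomes, key=lambda p: p.strain_id)
    labels = [p.strain_id for p in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate proteome ids")
    n = len(items)
    vals = np.zeros((n, n))
    np.fill_diagonal(vals, 100.0)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            res = pocp_pair(items[i], items[j], params)
            vals[i, j] = vals[j, i] = res.pocp_percent
            rows.append({
                "strain_a": res.strain_a, "strain_b": res.strain_b,
                "C1": res.C1, "C2": res.C2, "T1": res.T1, "T2": res.T2,
                "pocp": res.pocp_percent, "genus_call": res.same_genus,
                "size_warning": res.size_warning,
            })
    return DistanceMatrix(labels, vals, "percent"), pd.DataFrame(rows)
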