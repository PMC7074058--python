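"""The decision engine: thresholds, pair verdicts, rank partitions,
synonymy with nomenclatural priority, and cross-method concordance.

The rules condense standard taxogenomic practice for *Pseudomonas*-like
genera:

* 4-gene MLSA species cutoff 97% — a screening metric;
* ANIb >= 95% or dDDH >= 70% — individually sufficient genomic evidence
  that two type strains belong to one genomic species;
* dDDH >= 80% groups strains into the same subspecies within a species;
* POCP >= 50% places two strains in the same genus (two species of one
  genus should share at least half of their proteins);
* 16S rDNA similarity is exclusionary only: below 98.6% two strains are
  different species, above it nothing follows; 94.5% is the genus-level
  bound.

All cutoffs are inclusive (">=" keeps the pair together).  Precedence in
pair verdicts is genomic metrics > MLSA > 16S exclusion, and conflicts are
recorded rather than silently resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import DistanceMatrix

__all__ = [
    "Thresholds",
    "PairMeasure",
    "StrainMeta",
    "PairVerdict",
    "TaxonomicPartition",
    "pair_species_call",
    "cluster_at_threshold",
    "delineate_subspecies",
    "detect_synonyms",
    "assign_genus",
    "concordance_report",
    "strain_meta_from_frame",
]


@dataclass(frozen=True)
class Thresholds:
    """Percent cutoffs for every rank decision (all inclusive, >=)."""

    mlsa_species: float = 97.0
    anib_species: float = 95.0
    ddh_species: float = 70.0
    ddh_subspecies: float = 80.0
    pocp_genus: float = 50.0
    rrna_genus: float = 94.5
    rrna_species_exclusion: float = 98.6
    pocp_borderline_margin: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "mlsa_species", "anib_species", "ddh_species", "ddh_subspecies",
            "pocp_genus", "rrna_genus", "rrna_species_exclusion",
        ):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValueError(f"{name} must be in (0, 100], got {v}")
        if self.ddh_subspecies < self.ddh_species:
            raise ValueError("ddh_subspecies must be >= ddh_species")


@dataclass(frozen=True)
class PairMeasure:
    """All metrics available for one (unordered) strain pair."""

    strain_a: str
    strain_b: str
    rrna_pct: float | None = None
    mlsa_pct: float | None = None
    anib_pct: float | None = None
    ddh_pct: float | None = None
    ddh_provenance: str | None = None  # "external" or "surrogate"
    pocp_pct: float | None = None

    def __post_init__(self) -> None:
        for name in ("rrna_pct", "mlsa_pct", "anib_pct", "ddh_pct", "pocp_pct"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.ddh_pct is not None and self.ddh_provenance not in (
            "external", "surrogate",
        ):
            raise ValueError("ddh values must declare provenance: external or surrogate")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.strain_a, self.strain_b))


@dataclass(frozen=True)
class StrainMeta:
    strain_id: str
    species_name: str
    type_strain: bool = False
    year: int | None = None
    subspecies: str | None = None


def strain_meta_from_frame(df: pd.DataFrame) -> list[StrainMeta]:
    out = []
    for _, row in df.iterrows():
        year = row.get("year")
        out.append(
            StrainMeta(
                strain_id=str(row["strain_id"]),
                species_name=str(row["species_name"]),
                type_strain=bool(row.get("type_strain", False)),
                year=int(year) if pd.notna(year) else None,
                subspecies=row.get("subspecies"),
            )
        )
    return out


@dataclass(frozen=True)
class PairVerdict:
    verdict: str  # "same" | "different" | "inconclusive"
    evidence: tuple[str, ...]
    conflicts: tuple[str, ...] = ()


def pair_species_call(m: PairMeasure, t: Thresholds | None = None) -> PairVerdict:
    """Same-species verdict for one pair under the metric precedence rules.

    Genomic metrics (ANIb, dDDH) are individually sufficient; MLSA decides
    only in their absence (flagged "MLSA-only"); 16S can only exclude.
    """
    t = t or Thresholds()
    if all(
        getattr(m, f) is None for f in ("rrna_pct", "mlsa_pct", "anib_pct", "ddh_pct")
    ):
        raise ValueError("no metrics present for pair")
    evidence: list[str] = []
    conflicts: list[str] = []

    anib_same = None if m.anib_pct is None else m.anib_pct >= t.anib_species
    ddh_same = None if m.ddh_pct is None else m.ddh_pct >= t.ddh_species
    mlsa_same = None if m.mlsa_pct is None else m.mlsa_pct >= t.mlsa_species
    rrna_excludes = (
        None if m.rrna_pct is None else m.rrna_pct < t.rrna_species_exclusion
    )

    def note_rrna():
        if rrna_excludes:
            conflicts.append(
                f"16S {m.rrna_pct:g} < {t.rrna_species_exclusion:g} would exclude; "
                "overridden by higher-precedence metric"
            )

    if anib_same is not None or ddh_same is not None:
        if anib_same:
            evidence.append(f"ANIb {m.anib_pct:g} >= {t.anib_species:g}")
        if ddh_same:
            tag = f" ({m.ddh_provenance})" if m.ddh_provenance else ""
            evidence.append(f"dDDH {m.ddh_pct:g} >= {t.ddh_species:g}{tag}")
        if anib_same or ddh_same:
            if anib_same is False:
                conflicts.append(f"ANIb {m.anib_pct:g} < {t.anib_species:g} disagrees")
            if ddh_same is False:
                conflicts.append(f"dDDH {m.ddh_pct:g} < {t.ddh_species:g} disagrees")
            if mlsa_same is False:
                conflicts.append(f"MLSA {m.mlsa_pct:g} < {t.mlsa_species:g} disagrees")
            note_rrna()
            return PairVerdict("same", tuple(evidence), tuple(conflicts))
        if anib_same is False:
            evidence.append(f"ANIb {m.anib_pct:g} < {t.anib_species:g}")
        if ddh_same is False:
            tag = f" ({m.ddh_provenance})" if m.ddh_provenance else ""
            evidence.append(f"dDDH {m.ddh_pct:g} < {t.ddh_species:g}{tag}")
        if mlsa_same:
            conflicts.append(
                f"MLSA {m.mlsa_pct:g} >= {t.mlsa_species:g} but genomic metrics "
                "below cutoff; genomic metrics take precedence"
            )
        return PairVerdict("different", tuple(evidence), tuple(conflicts))

    if mlsa_same is not None:
        if mlsa_same:
            evidence.append(
                f"MLSA {m.mlsa_pct:g} >= {t.mlsa_species:g} (MLSA-only, no genomic metric)"
            )
            note_rrna()
            return PairVerdict("same", tuple(evidence), tuple(conflicts))
        evidence.append(f"MLSA {m.mlsa_pct:g} < {t.mlsa_species:g}")
        return PairVerdict("different", tuple(evidence), tuple(conflicts))

    # 16S only: exclusion or nothing
    if rrna_excludes:
        evidence.append(f"16S {m.rrna_pct:g} < {t.rrna_species_exclusion:g}")
        return PairVerdict("different", tuple(evidence))
    evidence.append(
        f"16S {m.rrna_pct:g} >= {t.rrna_species_exclusion:g} is not sufficient "
        "for a species call"
    )
    return PairVerdict("inconclusive", tuple(evidence))


# ---------------------------------------------------------------------------
# partitions


@dataclass
class TaxonomicPartition:
    """Disjoint clustering of strains at one rank, with rule provenance."""

    rank: str  # species | subspecies | genus
    clusters: list[frozenset]
    provenance: str

    def __post_init__(self) -> None:
        if self.rank not in ("species", "subspecies", "genus"):
            raise ValueError(f"unknown rank {self.rank!r}")
        seen: set = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if seen & c:
                raise ValueError("clusters are not disjoint")
            seen |= c
        self.clusters = sorted((frozenset(c) for c in self.clusters), key=min)

    def strains(self) -> frozenset:
        return frozenset().union(*self.clusters) if self.clusters else frozenset()

    def mapping(self) -> dict[str, str]:
        width = max(2, len(str(len(self.clusters))))
        return {
            s: f"{self.rank[0].upper()}{i + 1:0{width}d}"
            for i, c in enumerate(self.clusters)
            for s in sorted(c)
        }

    def cluster_of(self, strain: str) -> frozenset:
        for c in self.clusters:
            if strain in c:
                return c
        raise KeyError(strain)

    def co_clustered(self, a: str, b: str) -> bool:
        return self.cluster_of(a) == self.cluster_of(b)

    def cluster_sets(self) -> set[frozenset]:
        return set(self.clusters)

    def matches_assignment(self, assignment: dict[str, str]) -> bool:
        """Exact agreement with a leaf -> label map, up to label renaming."""
        truth: dict[str, set] = {}
        for leaf, lab in assignment.items():
            truth.setdefault(lab, set()).add(leaf)
        return {frozenset(v) for v in truth.values()} == self.cluster_sets()

    @classmethod
    def from_assignment(
        cls, rank: str, assignment: dict[str, str], provenance: str = "planted"
    ) -> "TaxonomicPartition":
        groups: dict[str, set] = {}
        for leaf, lab in assignment.items():
            groups.setdefault(lab, set()).add(leaf)
        return cls(rank, [frozenset(v) for v in groups.values()], provenance)

    def to_frame(self) -> pd.DataFrame:
        mp = self.mapping()
        return pd.DataFrame(
            [
                {"strain_id": s, "rank": self.rank, "cluster": mp[s],
                 "rule": self.provenance}
                for s in sorted(mp)
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomicPartition":
        df = pd.read_csv(path, sep="\t")
        rank = df["rank"].iloc[0]
        rule = df["rule"].iloc[0] if "rule" in df else ""
        groups: dict[str, set] = {}
        for _, row in df.iterrows():
            groups.setdefault(row["cluster"], set()).add(str(row["strain_id"]))
        return cls(rank, [frozenset(v) for v in groups.values()], rule)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller label becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_at_threshold(
    matrix: DistanceMatrix,
    cutoff: float,
    linkage: str = "single",
    allow_missing: bool = False,
    rank: str = "species",
    metric_name: str = "similarity",
) -> TaxonomicPartition:
    """Cut a percent-similarity matrix into clusters at ``cutoff``.

    Single linkage has dendrogram-cut semantics: any chain of pairs at or
    above the cutoff joins a cluster.  Missing pairs (NaN) are an error
    unless ``allow_missing``, in which case they count as below the cutoff
    (with a warning).
    """
    if matrix.mode != "percent":
        raise ValueError("clustering requires a percent-similarity matrix")
    if linkage not in ("single", "complete"):
        raise ValueError("linkage must be 'single' or 'complete'")
    nan_pairs = [(a, b) for a, b, v in matrix.pairs() if np.isnan(v)]
    if nan_pairs:
        if not allow_missing:
            raise ValueError(
                f"matrix has {len(nan_pairs)} missing pair(s), e.g. {nan_pairs[0]}"
            )
        warnings.warn(
            f"{len(nan_pairs)} missing pair(s) treated as below the cutoff"
        )
    provenance = f"{metric_name} >= {cutoff:g} ({linkage} linkage)"
    if linkage == "single":
        uf = _UnionFind(matrix.labels)
        for a, b, v in matrix.pairs():
            if not np.isnan(v) and v >= cutoff:
                uf.union(a, b)
        groups: dict[str, set] = {}
        for l in matrix.labels:
            groups.setdefault(uf.find(l), set()).add(l)
        clusters = [frozenset(v) for v in groups.values()]
    else:
        from scipy.cluster.hierarchy import fcluster
        from scipy.cluster.hierarchy import linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        if nan_pairs:
            raise ValueError("complete linkage does not support missing pairs")
        dist = 100.0 - matrix.values
        np.fill_diagonal(dist, 0.0)
        Z = scipy_linkage(squareform(dist, checks=False), method="complete")
        flat = fcluster(Z, t=100.0 - cutoff, criterion="distance")
        groups = {}
        for lab, cl in zip(matrix.labels, flat):
            groups.setdefault(cl, set()).add(lab)
        clusters = [frozenset(v) for v in groups.values()]
    return TaxonomicPartition(rank, clusters, provenance)


def delineate_subspecies(
    species_cluster: frozenset | set,
    ddh_matrix: DistanceMatrix,
    t: Thresholds | None = None,
    linkage: str = "single",
) -> TaxonomicPartition:
    """Subspecies partition of one species cluster at the dDDH 80% band."""
    t = t or Thresholds()
    members = sorted(species_cluster)
    outside = [s for s in members if s not in ddh_matrix]
    if outside:
        raise ValueError(f"strains outside the dDDH matrix: {outside}")
    sub = ddh_matrix.submatrix(members)
    part = cluster_at_threshold(
        sub, t.ddh_subspecies, linkage=linkage, rank="subspecies", metric_name="dDDH"
    )
    return part


def detect_synonyms(
    partition: TaxonomicPartition, meta: list[StrainMeta] | pd.DataFrame
) -> pd.DataFrame:
    """Later-heterotypic-synonym table from clusters holding >= 2 type strains.

    Within each such cluster the senior name is the one with the earliest
    publication year (ties broken alphabetically and flagged); every other
    type-strain name is listed as a later heterotypic synonym of it.
    """
    if isinstance(meta, pd.DataFrame):
        meta = strain_meta_from_frame(meta)
    by_strain = {m.strain_id: m for m in meta}
    rows = []
    for ci, cluster in enumerate(partition.clusters):
        types = [by_strain[s] for s in sorted(cluster) if s in by_strain
                 and by_strain[s].type_strain]
        if len(types) < 2:
            continue
        missing = [m.strain_id for m in types if m.year is None]
        if missing:
            raise ValueError(
                f"type strain(s) without publication year in a multi-type "
                f"cluster: {missing}"
            )
        ranked = sorted(types, key=lambda m: (m.year, m.species_name))
        senior = ranked[0]
        tie = sum(1 for m in ranked if m.year == senior.year) > 1
        for junior in ranked[1:]:
            rows.append({
                "cluster": f"C{ci + 1:02d}",
                "senior_name": senior.species_name,
                "senior_strain": senior.strain_id,
                "senior_year": senior.year,
                "junior_name": junior.species_name,
                "junior_strain": junior.strain_id,
                "junior_year": junior.year,
                "status": f"later heterotypic synonym of {senior.species_name}",
                "priority_tie": tie,
            })
    return pd.DataFrame(
        rows,
        columns=["cluster", "senior_name", "senior_strain", "senior_year",
                 "junior_name", "junior_strain", "junior_year", "status",
                 "priority_tie"],
    )


def assign_genus(
    pocp_matrix: DistanceMatrix,
    rrna_matrix: DistanceMatrix | None = None,
    t: Thresholds | None = None,
) -> tuple[TaxonomicPartition, list[tuple[str, str, float]]]:
    """Genus partition by single linkage on POCP (optionally 16S-gated).

    An edge requires POCP >= the genus cutoff and, when a 16S matrix is
    supplied, 16S similarity >= the 94.5% genus bound.  Pairs within the
    borderline margin of the cutoff are reported separately.
    """
    t = t or Thresholds()
    if pocp_matrix.mode != "percent":
        raise ValueError("POCP matrix must be percent mode")
    if np.isnan(pocp_matrix.values).any():
        raise ValueError("POCP matrix is incomplete")
    uf = _UnionFind(pocp_matrix.labels)
    borderline = []
    for a, b, v in pocp_matrix.pairs():
        if abs(v - t.pocp_genus) <= t.pocp_borderline_margin:
            borderline.append((a, b, v))
        if v < t.pocp_genus:
            continue
        if rrna_matrix is not None and rrna_matrix.get(a, b) < t.rrna_genus:
            continue
        uf.union(a, b)
    groups: dict[str, set] = {}
    for l in pocp_matrix.labels:
        groups.setdefault(uf.find(l), set()).add(l)
    gate = "" if rrna_matrix is None else f" and 16S >= {t.rrna_genus:g}"
    part = TaxonomicPartition(
        "genus",
        [frozenset(v) for v in groups.values()],
        f"POCP >= {t.pocp_genus:g}{gate} (single linkage)",
    )
    return part, sorted(borderline)


def concordance_report(
    partitions: dict[str, TaxonomicPartition],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise agreement between methods over all strain pairs.

    Returns (summary, disagreements): the summary holds, per method pair,
    the fraction of strain pairs on which both methods agree about
    co-clustering; the disagreement table lists every conflicting strain
    pair with which method merges and which splits it.
    """
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    names = sorted(partitions)
    strain_sets = {n: partitions[n].strains() for n in names}
    ref = strain_sets[names[0]]
    for n in names[1:]:
        if strain_sets[n] != ref:
            raise ValueError(
                f"partitions cover different strain sets: {names[0]} vs {n}"
            )
    strains = sorted(ref)
    pairs = [(a, b) for i, a in enumerate(strains) for b in strains[i + 1 :]]
    co = {
        n: {p: partitions[n].co_clustered(*p) for p in pairs} for n in names
    }
    summary_rows = []
    disagreement_rows = []
    for i, x in enumerate(names):
        for y in names[i + 1 :]:
            agree = 0
            for p in pairs:
                if co[x][p] == co[y][p]:
                    agree += 1
                else:
                    merger, splitter = (x, y) if co[x][p] else (y, x)
                    disagreement_rows.append({
                        "strain_a": p[0], "strain_b": p[1],
                        "merged_by": merger, "split_by": splitter,
                    })
            summary_rows.append({
                "method_a": x, "method_b": y,
                "agreement": agree / len(pairs) if pairs else 1.0,
                "n_pairs": len(pairs),
            })
    return (
        pd.DataFrame(summary_rows),
        pd.DataFrame(disagreement_rows,
                     columns=["strain_a", "strain_b", "merged_by", "split_by"]),
    )
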