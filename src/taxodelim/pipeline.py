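"""End-to-end delimitation pipeline over a (simulated or real) strain set.

Glues the metric modules together: marker profiles -> MLSA and 16S percent
matrices; genomes -> ANIb and surrogate-dDDH matrices; proteomes -> POCP
matrix; then the decision engine cuts species, subspecies and genus
partitions, detects synonyms, and reports cross-method concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ani import AniParams, ani_matrix
from .delineate import (
    TaxonomicPartition,
    Thresholds,
    assign_genus,
    cluster_at_threshold,
    concordance_report,
    delineate_subspecies,
    detect_synonyms,
)
from .matrix import DistanceMatrix
from .mlsa import AlignParams, MarkerProfile, concatenate_pair
from .pocp import PocpParams, Proteome, pocp_matrix
from .simulate import SimulatedClade

__all__ = [
    "Measures",
    "compute_mlsa_and_rrna",
    "compute_measures",
    "DelineationResult",
    "delineate_all",
    "run_clade_pipeline",
]


@dataclass
class Measures:
    """All pairwise metric matrices for one strain set (percent mode)."""

    mlsa: DistanceMatrix
    rrna: DistanceMatrix
    anib: DistanceMatrix
    ddh: DistanceMatrix
    pocp: DistanceMatrix
    ani_table: pd.DataFrame
    pocp_table: pd.DataFrame
    ddh_provenance: str = "surrogate"

    def pair_table(self) -> pd.DataFrame:
        """Long-format table (strain_a, strain_b, metric, value, provenance)."""
        rows = []
        for metric, dm in (
            ("rrna", self.rrna), ("mlsa", self.mlsa), ("anib", self.anib),
            ("ddh", self.ddh), ("pocp", self.pocp),
        ):
            prov = self.ddh_provenance if metric == "ddh" else "computed"
            for a, b, v in dm.pairs():
                rows.append({"strain_a": a, "strain_b": b, "metric": metric,
                             "value": v, "provenance": prov})
        return pd.DataFrame(rows)


def compute_mlsa_and_rrna(
    profiles: list[MarkerProfile], params: AlignParams | None = None
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """4-gene MLSA and 16S-only percent matrices from one pass of alignments."""
    profiles = sorted(profiles, key=lambda p: p.strain_id)
    labels = [p.strain_id for p in profiles]
    n = len(labels)
    mlsa_vals = np.zeros((n, n))
    rrna_vals = np.zeros((n, n))
    np.fill_diagonal(mlsa_vals, 100.0)
    np.fill_diagonal(rrna_vals, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = concatenate_pair(profiles[i], profiles[j], params)
            mlsa_vals[i, j] = mlsa_vals[j, i] = res.percent_identity
            r = res.per_marker["16S"]
            rrna_vals[i, j] = rrna_vals[j, i] = 100.0 * r.identity_fraction
    return (
        DistanceMatrix(labels, mlsa_vals, "percent"),
        DistanceMatrix(labels, rrna_vals, "percent"),
    )


def compute_measures(
    clade: SimulatedClade,
    ani_params: AniParams | None = None,
    pocp_params: PocpParams | None = None,
    align_params: AlignParams | None = None,
) -> Measures:
    """All metric matrices for a simulated clade."""
    profiles = [clade.markers[l] for l in clade.leaves()]
    mlsa_dm, rrna_dm = compute_mlsa_and_rrna(profiles, align_params)
    ani_dm, ddh_dm, ani_table = ani_matrix(clade.genomes, ani_params)
    proteomes = {l: Proteome(l, clade.proteomes[l]) for l in clade.leaves()}
    pocp_dm, pocp_table = pocp_matrix(proteomes, pocp_params)
    return Measures(
        mlsa=mlsa_dm, rrna=rrna_dm, anib=ani_dm, ddh=ddh_dm, pocp=pocp_dm,
        ani_table=ani_table, pocp_table=pocp_table,
    )


@dataclass
class DelineationResult:
    species_anib: TaxonomicPartition
    species_mlsa: TaxonomicPartition
    species_ddh: TaxonomicPartition
    subspecies: TaxonomicPartition
    genus: TaxonomicPartition
    genus_borderline: list[tuple[str, str, float]]
    concordance_summary: pd.DataFrame
    concordance_disagreements: pd.DataFrame
    synonymy: pd.DataFrame | None = None


def delineate_all(
    measures: Measures,
    thresholds: Thresholds | None = None,
    meta: pd.DataFrame | None = None,
) -> DelineationResult:
    """Cut all rank partitions and assemble the reports.

    Species are delineated independently by ANIb (95), MLSA (97) and dDDH
    (70) for the concordance report; subspecies are cut inside each
    ANIb species cluster at dDDH 80; genera by POCP 50 gated on 16S 94.5.
    Synonymy is detected on the ANIb species partition when metadata with
    type-strain years is supplied.
    """
    t = thresholds or Thresholds()
    sp_anib = cluster_at_threshold(
        measures.anib, t.anib_species, allow_missing=True, metric_name="ANIb"
    )
    sp_mlsa = cluster_at_threshold(measures.mlsa, t.mlsa_species, metric_name="MLSA")
    sp_ddh = cluster_at_threshold(
        measures.ddh, t.ddh_species, allow_missing=True,
        metric_name=f"dDDH ({measures.ddh_provenance})",
    )
    sub_clusters: list[frozenset] = []
    for cluster in sp_anib.clusters:
        part = delineate_subspecies(cluster, measures.ddh, t)
        sub_clusters.extend(part.clusters)
    subspecies = TaxonomicPartition(
        "subspecies", sub_clusters,
        f"dDDH ({measures.ddh_provenance}) >= {t.ddh_subspecies:g} within "
        "ANIb species (single linkage)",
    )
    genus, borderline = assign_genus(measures.pocp, measures.rrna, t)
    summary, disagreements = concordance_report(
        {"mlsa": sp_mlsa, "anib": sp_anib, "ddh": sp_ddh}
    )
    synonymy = None
    if meta is not None:
        synonymy = detect_synonyms(sp_anib, meta)
    return DelineationResult(
        species_anib=sp_anib,
        species_mlsa=sp_mlsa,
        species_ddh=sp_ddh,
        subspecies=subspecies,
        genus=genus,
        genus_borderline=borderline,
        concordance_summary=summary,
        concordance_disagreements=disagreements,
        synonymy=synonymy,
    )


def run_clade_pipeline(
    clade: SimulatedClade,
    thresholds: Thresholds | None = None,
    meta: pd.DataFrame | None = None,
    ani_params: AniParams | None = None,
    pocp_params: PocpParams | None = None,
) -> tuple[Measures, DelineationResult]:
    measures = compute_measures(clade, ani_params, pocp_params)
    return measures, delineate_all(measures, thresholds, meta)
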