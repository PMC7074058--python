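"""Synthetic bacterial clades with controlled divergence structure.

Real taxogenomic studies compare type-strain genome assemblies; this module
generates a desk-scale stand-in with known truth so every downstream metric
(MLSA, ANIb, POCP, surrogate dDDH, threshold clustering) can be verified in
a closed loop:

* sites evolve under the Jukes–Cantor model — the same model the distance
  machinery assumes, so observed identities have the closed form
  ``expected_identity(d) = 1/4 + (3/4) exp(-4d/3)``;
* protein-coding genes are lost per branch with probability
  ``1 - (1 - p_loss)^L`` and novel genes are gained at a Poisson rate per
  unit branch length, so shared-protein fractions (POCP) decay with
  divergence;
* four marker genes (16S rDNA, gyrB, rpoB, rpoD) are carried by every leaf
  regardless of gene turnover, with per-marker rate multipliers (16S is an
  order of magnitude slower);
* genomes are assembled as surviving genes plus markers, each element
  followed by its own fixed-length (50 nt) neutral spacer.

Indels, recombination and GC-content structure are deliberately not
simulated: the JC identity calibration must hold exactly.

Determinism: one master seed; every branch derives its own stream by stable
hashing of (seed, sorted leaf set under the branch), so regenerating a
subtree does not depend on traversal order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .mlsa import MARKER_ORDER, MarkerProfile
from .tree import PhyloTree, parse_newick, patristic_distances

__all__ = [
    "SimulationConfig",
    "Ancestor",
    "SimulatedClade",
    "generate_ancestor",
    "evolve_sequence",
    "evolve_clade",
    "simulate_clade",
    "expected_identity",
    "distance_for_identity",
    "balanced_tree_newick",
    "planted_two_genus_config",
    "planted_metadata",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

DEFAULT_MARKER_LENGTHS = {"16S": 1300, "gyrB": 800, "rpoB": 900, "rpoD": 750}
DEFAULT_MARKER_RATES = {"16S": 0.1, "gyrB": 1.0, "rpoB": 1.0, "rpoD": 1.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic clade.

    ``gene_length_codons`` is (mean, min, max) total codons per gene
    including the start and stop codon; lengths are drawn uniformly on
    [min, max] (the mean is descriptive and must lie inside the range).
    Branch lengths on ``tree`` are expected substitutions/site.
    """

    seed: int = 0
    n_genes: int = 200
    gene_length_codons: tuple[int, int, int] = (100, 50, 150)
    marker_lengths: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_LENGTHS))
    marker_rate_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_MARKER_RATES)
    )
    gene_loss_prob_per_unit_branch: float = 0.0
    gene_gain_rate_per_unit_branch: float = 0.0
    spacer_length: int = 50
    tree: str | None = None  # newick with branch lengths
    truth_partition: dict | None = None  # rank -> {leaf -> cluster label}

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        mean, lo, hi = self.gene_length_codons
        if lo < 2:
            raise ValueError("genes must be at least 2 codons (start + stop)")
        if not (lo <= mean <= hi):
            raise ValueError("gene_length_codons mean must lie within [min, max]")
        if set(self.marker_lengths) != set(MARKER_ORDER):
            raise ValueError(f"marker_lengths must cover exactly {MARKER_ORDER}")
        if set(self.marker_rate_multipliers) != set(MARKER_ORDER):
            raise ValueError(f"marker_rate_multipliers must cover exactly {MARKER_ORDER}")
        if any(v < 1 for v in self.marker_lengths.values()):
            raise ValueError("marker lengths must be positive")
        if any(v < 0 for v in self.marker_rate_multipliers.values()):
            raise ValueError("rate multipliers must be >= 0")
        if not 0.0 <= self.gene_loss_prob_per_unit_branch <= 1.0:
            raise ValueError("gene loss probability must be in [0, 1]")
        if self.gene_gain_rate_per_unit_branch < 0:
            raise ValueError("gene gain rate must be >= 0")
        if self.spacer_length < 0:
            raise ValueError("spacer length must be >= 0")


@dataclass
class Ancestor:
    """Ancestral gene set and marker sequences.

    Every gene and every marker carries its own 50-nt neutral spacer that
    follows it in the assembled genome.  Spacers are independent sequences
    (not one shared repeat) so their substitution noise averages out
    genome-wide like any other neutral site.
    """

    genes: list[tuple[str, str, str]]  # (gene id, coding seq, spacer)
    markers: dict[str, str]
    marker_spacers: dict[str, str]


@dataclass
class SimulatedClade:
    """Leaf genomes, proteomes, markers plus the planted ground truth."""

    genomes: dict[str, str]
    proteomes: dict[str, list[tuple[str, str]]]
    markers: dict[str, MarkerProfile]
    gene_ids: dict[str, list[str]]
    truth_partition: dict[str, dict[str, str]] | None
    truth_distances: dict[tuple[str, str], float]
    tree_newick: str
    config: SimulationConfig

    def leaves(self) -> list[str]:
        return sorted(self.genomes)

    def truth_distance(self, a: str, b: str) -> float:
        return self.truth_distances[tuple(sorted((a, b)))]


# ---------------------------------------------------------------------------
# closed forms


def expected_identity(d: float) -> float:
    """Expected site identity under JC after ``d`` substitutions/site."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)


def distance_for_identity(identity: float) -> float:
    """Inverse of :func:`expected_identity` (identity in (1/4, 1])."""
    if not 0.25 < identity <= 1.0:
        raise ValueError("identity must be in (0.25, 1]")
    return -0.75 * math.log((identity - 0.25) / 0.75)


# ---------------------------------------------------------------------------
# rng plumbing


def _branch_rng(seed: int, branch_key: str) -> np.random.Generator:
    h = hashlib.sha256(f"{seed}:{branch_key}".encode()).digest()
    sub = int.from_bytes(h[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


def _branch_tag(branch_key: str) -> str:
    return hashlib.sha256(branch_key.encode()).hexdigest()[:8]


# ---------------------------------------------------------------------------
# ancestor


def _random_gene(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def generate_ancestor(config: SimulationConfig) -> Ancestor:
    """Draw the ancestral gene set, markers and spacer, deterministically."""
    rng = _branch_rng(config.seed, "ancestor")
    _, lo, hi = config.gene_length_codons
    genes = []
    for i in range(config.n_genes):
        n_codons = int(rng.integers(lo, hi + 1))
        genes.append(
            (
                f"g{i:04d}",
                _random_gene(rng, n_codons),
                _random_nt(rng, config.spacer_length),
            )
        )
    markers = {
        m: _random_nt(rng, config.marker_lengths[m]) for m in MARKER_ORDER
    }
    marker_spacers = {
        m: _random_nt(rng, config.spacer_length) for m in MARKER_ORDER
    }
    return Ancestor(genes=genes, markers=markers, marker_spacers=marker_spacers)


# ---------------------------------------------------------------------------
# site evolution


def evolve_sequence(
    seq: str,
    branch_length: float,
    rate_multiplier: float = 1.0,
    rng: np.random.Generator | int | None = None,
    coding: bool = False,
) -> str:
    """Substitute sites independently under JC along one branch.

    Each site is substituted with probability
    ``p(d) = (3/4)(1 - exp(-4 d / 3))`` with
    ``d = branch_length * rate_multiplier``; a substituted site takes one of
    the three other bases uniformly.  With ``coding=True`` internal stop
    codons created by substitution are resampled (the per-site substitution
    probability is unchanged because the redraw stays within the three
    non-ancestral bases).
    """
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    if rate_multiplier < 0:
        raise ValueError("rate multiplier must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    d = branch_length * rate_multiplier
    if d == 0 or not seq:
        return seq
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("simulator sequences must be pure ACGT")
    p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    mask = rng.random(codes.size) < p
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    out = codes.copy()
    out[mask] = (codes[mask] + shifts) % 4
    if coding:
        _fix_internal_stops(out, codes, mask, rng)
    return _BASES[out].tobytes().decode("ascii")


def _fix_internal_stops(out, original, mask, rng) -> None:
    n_codons = out.size // 3
    if n_codons < 2:
        return
    cod = out[: n_codons * 3].reshape(n_codons, 3)
    # stop codons: TAA (3,0,0), TAG (3,0,2), TGA (3,2,0)
    is_stop = (cod[:, 0] == 3) & (
        ((cod[:, 1] == 0) & ((cod[:, 2] == 0) | (cod[:, 2] == 2)))
        | ((cod[:, 1] == 2) & (cod[:, 2] == 0))
    )
    is_stop[-1] = False  # terminal stop codon is legitimate
    for ci in np.flatnonzero(is_stop):
        pos = slice(ci * 3, ci * 3 + 3)
        sub_sites = np.flatnonzero(mask[pos])
        if sub_sites.size == 0:  # ancestral stop not created here; leave it
            continue
        codon = out[pos]
        orig = original[pos]
        while "".join("ACGT"[c] for c in codon) in _STOPS:
            for s in sub_sites:
                codon[s] = (orig[s] + rng.integers(1, 4)) % 4
        out[pos] = codon


# ---------------------------------------------------------------------------
# clade evolution


def evolve_clade(
    ancestor: Ancestor, tree: PhyloTree | str, config: SimulationConfig
) -> SimulatedClade:
    """Evolve the ancestor along every branch of ``tree``.

    Gene loss/gain applies to protein-coding genes only (a gene is lost or
    gained together with its trailing spacer); markers and their spacers
    always persist.  Branch lengths must be present on every non-root edge.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    newick_in = tree
    loss = config.gene_loss_prob_per_unit_branch
    gain = config.gene_gain_rate_per_unit_branch
    _, lo, hi = config.gene_length_codons

    genomes: dict[str, str] = {}
    proteomes: dict[str, list[tuple[str, str]]] = {}
    marker_profiles: dict[str, MarkerProfile] = {}
    gene_ids: dict[str, list[str]] = {}

    def leaf_set(node) -> str:
        return "|".join(sorted(l.name for l in node.leaves()))

    def recurse(node, genes, markers, marker_spacers):
        if node.is_leaf:
            name = node.name
            parts = [g + sp for _, g, sp in genes]
            parts += [markers[m] + marker_spacers[m] for m in MARKER_ORDER]
            genomes[name] = "".join(parts)
            proteomes[name] = [(gid, _translate(g)) for gid, g, _ in genes]
            gene_ids[name] = [gid for gid, _, _ in genes]
            marker_profiles[name] = MarkerProfile(name, dict(markers))
            return
        for child in node.children:
            if child.length is None:
                raise ValueError("every non-root branch needs a length")
            L = child.length
            key = leaf_set(child)
            rng = _branch_rng(config.seed, key)
            new_genes = [
                (
                    gid,
                    evolve_sequence(g, L, 1.0, rng, coding=True),
                    evolve_sequence(sp, L, 1.0, rng),
                )
                for gid, g, sp in genes
            ]
            new_markers = {
                m: evolve_sequence(
                    markers[m], L, config.marker_rate_multipliers[m], rng
                )
                for m in MARKER_ORDER
            }
            new_marker_spacers = {
                m: evolve_sequence(marker_spacers[m], L, 1.0, rng)
                for m in MARKER_ORDER
            }
            p_branch = 1.0 - (1.0 - loss) ** L
            kept = [g for g in new_genes if rng.random() >= p_branch]
            n_gain = int(rng.poisson(gain * L))
            tag = _branch_tag(key)
            for i in range(n_gain):
                n_codons = int(rng.integers(lo, hi + 1))
                kept.append(
                    (
                        f"gain_{tag}_{i}",
                        _random_gene(rng, n_codons),
                        _random_nt(rng, config.spacer_length),
                    )
                )
            recurse(child, kept, new_markers, new_marker_spacers)

    recurse(
        tree.root,
        list(ancestor.genes),
        dict(ancestor.markers),
        dict(ancestor.marker_spacers),
    )

    pat = patristic_distances(tree)
    truth = {
        tuple(sorted((a, b))): v for a, b, v in pat.pairs()
    }
    if config.truth_partition is not None:
        leaves = set(genomes)
        for rank, assign in config.truth_partition.items():
            if set(assign) != leaves:
                raise ValueError(f"truth partition for rank {rank} does not cover leaves")
    from .tree import to_newick

    return SimulatedClade(
        genomes=genomes,
        proteomes=proteomes,
        markers=marker_profiles,
        gene_ids=gene_ids,
        truth_partition=config.truth_partition,
        truth_distances=truth,
        tree_newick=to_newick(newick_in),
        config=config,
    )


def _translate(gene: str) -> str:
    aa = str(Seq(gene).translate())
    return aa[:-1] if aa.endswith("*") else aa


def simulate_clade(config: SimulationConfig) -> SimulatedClade:
    """Generate the ancestor and evolve it along the configured tree."""
    if config.tree is None:
        raise ValueError("config.tree (newick) is required to simulate a clade")
    return evolve_clade(generate_ancestor(config), config.tree, config)


def balanced_tree_newick(depth: int, branch_length: float, prefix: str = "L") -> str:
    """Fully balanced binary tree with 2**depth leaves, uniform lengths."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    counter = [0]

    def build(d: int) -> str:
        if d == 0:
            name = f"{prefix}{counter[0]:03d}"
            counter[0] += 1
            return f"{name}:{branch_length:g}"
        return f"({build(d - 1)},{build(d - 1)}):{branch_length:g}"

    left = build(depth - 1)
    right = build(depth - 1)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# the documented planted fixture


def planted_two_genus_config(seed: int = 0, n_genes: int = 200) -> SimulationConfig:
    """Two genera x three species x 2-3 strains, 15 genomes in all.

    The branch lengths plant divergences on the scales the delimitation
    thresholds operate on:

    * within subspecies: ~0.012 subst/site  -> ANIb ~98.8, surrogate dDDH >> 80
    * between subspecies of one species: 0.032 -> ANIb ~97, dDDH between 70 and 80
    * between species of one genus: ~0.16-0.17 -> ANIb ~86 (< 95), MLSA ~91 (< 97)
    * between genera: ~0.78 plus heavy gene turnover -> POCP << 50

    Gene loss probability 0.7 per unit branch and gain rate 5 per unit
    branch keep within-genus shared-protein fractions well above one half
    and cross-genus fractions below it.
    """
    a1 = "((A1a:0.006,A1b:0.006):0.012,A1c:0.014):0.075"
    a2 = "(A2a:0.006,A2b:0.006):0.075"
    a3 = "(A3a:0.006,A3b:0.006):0.075"
    b1 = "(B1a:0.006,B1b:0.006,B1c:0.006):0.075"
    b2 = "(B2a:0.006,B2b:0.006):0.075"
    b3 = "((B3a:0.006,B3b:0.006):0.012,B3c:0.014):0.075"
    newick = f"(({a1},{a2},{a3}):0.3,({b1},{b2},{b3}):0.3);"

    leaves = [
        "A1a", "A1b", "A1c", "A2a", "A2b", "A3a", "A3b",
        "B1a", "B1b", "B1c", "B2a", "B2b", "B3a", "B3b", "B3c",
    ]
    genus = {l: ("genusA" if l.startswith("A") else "genusB") for l in leaves}
    species = {l: l[:2] for l in leaves}
    subspecies = {}
    for l in leaves:
        if l in ("A1a", "A1b"):
            subspecies[l] = "A1_ssp1"
        elif l == "A1c":
            subspecies[l] = "A1_ssp2"
        elif l in ("B3a", "B3b"):
            subspecies[l] = "B3_ssp1"
        elif l == "B3c":
            subspecies[l] = "B3_ssp2"
        else:
            subspecies[l] = f"{l[:2]}_ssp1"
    return SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        gene_loss_prob_per_unit_branch=0.7,
        gene_gain_rate_per_unit_branch=5.0,
        tree=newick,
        truth_partition={"genus": genus, "species": species, "subspecies": subspecies},
    )


_META_ROWS = [
    # strain, nominal species name, year of the name
    ("A1a", "Ps. alphus", 1985),
    ("A1b", "Ps. betus", 2002),
    ("A1c", "Ps. gammus", 2010),
    ("A2a", "Ps. deltus", 1990),
    ("A2b", "Ps. epsilus", 1999),
    ("A3a", "Ps. zetus", 1978),
    ("A3b", "Ps. etus", 2005),
    ("B1a", "Bs. thetus", 1981),
    ("B1b", "Bs. iotus", 1994),
    ("B1c", "Bs. kappus", 2012),
    ("B2a", "Bs. lambdus", 1988),
    ("B2b", "Bs. mus", 2001),
    ("B3a", "Bs. nus", 1979),
    ("B3b", "Bs. xius", 1996),
    ("B3c", "Bs. omicrus", 2008),
]


def planted_metadata():
    """Strain metadata for the planted fixture.

    Every strain carries its own nominal species name and publication year
    and is flagged as a type strain, so clusters recovered by the pipeline
    expose later names as heterotypic synonyms of the earliest name — the
    situation synonymy detection is built for.
    """
    import pandas as pd

    cfg = planted_two_genus_config()
    ssp = cfg.truth_partition["subspecies"]
    return pd.DataFrame(
        [
            {
                "strain_id": s,
                "species_name": name,
                "type_strain": True,
                "year": year,
                "subspecies": ssp[s],
            }
            for s, name, year in _META_ROWS
        ]
    )
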