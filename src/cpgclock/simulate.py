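"""Synthetic vertebrate panels with a planted lifespan clock.

The generator emulates the study conditions the clock was developed under:
a species panel spanning the five vertebrate classes, a phylogenetically
correlated ln-lifespan trait (Brownian motion on an ultrametric timetree,
with classes confounded with clades as in real data), promoter CpG
densities linearly coupled to ln lifespan for a causal subset of promoters
(a majority positively and a minority negatively coupled, mirroring the
empirical split), and genome/promoter sequences that realize those
densities exactly so the homology and density stages can be exercised on
real files.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .density import DensityMatrix, count_cpg
from .homology import HitTable, PromoterHit
from .predict import SnpRecord
from .train import SpeciesRecord

logger = logging.getLogger(__name__)

#: fraction of causal promoters coupled positively to ln lifespan
#: (the published clock's individually significant loci split 22:12)
POSITIVE_SLOPE_FRACTION = 22 / 34

#: maximum plantable density: CpGs must be realizable as non-overlapping
#: dinucleotides with room for filler
DENSITY_CAP = 0.4

TREE_DEPTH_MY = 500.0


@dataclass
class SimulationConfig:
    """Study-condition knobs for the generator.

    Defaults emulate the published design: 250 species (the study used 252),
    class proportions dominated by mammals, lifespans spanning 1.1-205
    years, a 600-bp promoter window (the promoter-database window -499..+100),
    and effect/noise sizes that put aggregate test-set accuracy in the
    regime the clock reports (ln-scale R^2 around 0.76).
    """

    n_species: int = 250
    class_proportions: Mapping[str, float] = field(default_factory=lambda: {
        "Mammalia": 0.40, "Aves": 0.22, "Fish": 0.22, "Reptilia": 0.10,
        "Amphibia": 0.06,
    })
    n_causal_promoters: int = 40
    n_null_promoters: int = 460
    effect_slope: float = 0.03  # density units per ln-year
    density_noise_sd: float = 0.04  # density units
    lifespan_range: tuple[float, float] = (1.1, 205.0)
    brownian_sd: float = 0.02  # ln-years per sqrt(MY)
    genome_length: int = 400_000
    promoter_length: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"class proportions sum to {total}, not 1")
        if self.n_species < 2 or self.n_causal_promoters < 1 or self.n_null_promoters < 0:
            raise ValueError("counts must be positive")
        if self.lifespan_range[0] <= 0:
            raise ValueError("minimum lifespan must be > 0 years")

    @property
    def n_promoters(self) -> int:
        return self.n_causal_promoters + self.n_null_promoters


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator for recovery tests."""

    tree: str  # newick with branch lengths
    lifespans: dict[str, float]
    causal_ids: list[str]
    true_densities: DensityMatrix
    planted_weights: dict[str, float]


@dataclass
class SyntheticPanel:
    """A complete generated study: tree, records, features, truth."""

    tree: str
    records: list[SpeciesRecord]
    density_matrix: DensityMatrix
    truth: SyntheticTruth

    @property
    def lifespans(self) -> dict[str, float]:
        return self.truth.lifespans

    @property
    def classes(self) -> dict[str, str]:
        return {r.species_id: r.vertebrate_class for r in self.records}


def simulate_tree(n_species: int, seed: int) -> str:
    """Ultrametric pure-birth (Yule) tree, depth scaled to 500 MY.

    Leaves are labelled sp0001..; the newick string is deterministic given
    the seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    next_id = [0]

    def new_node(birth: float) -> dict:
        next_id[0] += 1
        return {"birth": birth, "children": [], "id": next_id[0]}

    # crown-rooted: the root splits at time 0 so every root-to-tip path
    # spans the full tree depth
    root = new_node(0.0)
    root["split"] = 0.0
    active = []
    for _ in range(2):
        child = new_node(0.0)
        root["children"].append(child)
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        parent["split"] = t
        for _ in range(2):
            child = new_node(t)
            parent["children"].append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    scale = TREE_DEPTH_MY / t_end

    leaf_counter = [0]

    def to_newick(node: dict) -> str:
        if node["children"]:
            inner = ",".join(to_newick(c) for c in node["children"])
            length = (node["split"] - node["birth"]) * scale
            return f"({inner}):{length:.6f}"
        leaf_counter[0] += 1
        length = (t_end - node["birth"]) * scale
        return f"sp{leaf_counter[0]:04d}:{length:.6f}"

    return to_newick(root) + ";"


def _leaf_depths_and_order(tree: dendropy.Tree) -> tuple[list[str], dict[str, float]]:
    depth = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    return labels, {lf.taxon.label: depth[id(lf)] for lf in tree.leaf_node_iter()}


def simulate_lifespans(
    tree: str | dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, float], dict[str, str]]:
    """Brownian ln-lifespan trait on the tree, with classes assigned to clades.

    ln lifespan evolves by Brownian motion (sd = brownian_sd per sqrt MY)
    around a class-specific mean, then is min-max rescaled into
    ln(lifespan_range). Classes are assigned to contiguous blocks of the
    tree's leaf order — i.e. to clades — so class and phylogeny are
    confounded as in real data. Returns (lifespans in years, classes).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")

    # Brownian values at the leaves
    value = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge = node.edge.length or 0.0
        value[id(node)] = value[id(node.parent_node)] + rng.normal(
            0.0, config.brownian_sd * math.sqrt(edge)
        )
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]

    # classes as contiguous leaf-order blocks, sized by the proportions
    classes_sorted = sorted(config.class_proportions)
    sizes = _proportion_counts(
        len(labels), [config.class_proportions[c] for c in classes_sorted]
    )
    class_of: dict[str, str] = {}
    pos = 0
    for cls, size in zip(classes_sorted, sizes):
        for lbl in labels[pos:pos + size]:
            class_of[lbl] = cls
        pos += size

    class_means = {
        cls: mean for cls, mean in zip(classes_sorted, np.linspace(0.0, 2.0, len(classes_sorted)))
    }
    raw = np.array([class_means[class_of[lbl]] + value[id(lf)] for lbl, lf in zip(labels, leaves)])

    lo, hi = math.log(config.lifespan_range[0]), math.log(config.lifespan_range[1])
    if np.ptp(raw) == 0:
        ln = np.full_like(raw, (lo + hi) / 2)
    else:
        ln = lo + (raw - raw.min()) / np.ptp(raw) * (hi - lo)
    return {lbl: float(math.exp(v)) for lbl, v in zip(labels, ln)}, class_of


def _proportion_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer counts summing to n, by largest remainder."""
    raw = [f * n for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def simulate_density_matrix(
    lifespans: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    tree: str = "",
) -> tuple[DensityMatrix, SyntheticTruth]:
    """Promoter densities with a planted linear coupling to ln lifespan.

    Causal promoters follow d = clip(base + slope*ln(years) + noise, 0, 0.4)
    with per-promoter base and signed slope (most positive, some negative);
    null promoters are pure noise around their base. The planted slopes and
    the realized matrix are recorded as truth.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    species = list(lifespans)
    ln_y = np.log(np.array([lifespans[s] for s in species]))
    mean_ln = float(ln_y.mean())

    promoter_ids = [f"p{i + 1:04d}" for i in range(config.n_promoters)]
    causal_idx = rng.choice(config.n_promoters, size=config.n_causal_promoters, replace=False)
    causal_ids = [promoter_ids[i] for i in sorted(causal_idx)]
    causal_set = set(causal_ids)

    values = np.zeros((len(species), config.n_promoters))
    planted: dict[str, float] = {}
    for j, pid in enumerate(promoter_ids):
        if pid in causal_set:
            sign = 1.0 if rng.random() < POSITIVE_SLOPE_FRACTION else -1.0
            slope = sign * config.effect_slope * rng.uniform(0.5, 1.5)
            base = rng.uniform(0.12, 0.25) - slope * mean_ln
            col = base + slope * ln_y
            planted[pid] = slope
        else:
            col = np.full(len(species), rng.uniform(0.05, 0.3))
        col = col + rng.normal(0.0, config.density_noise_sd, size=len(species))
        values[:, j] = np.clip(col, 0.0, DENSITY_CAP)

    frame = pd.DataFrame(values, index=species, columns=promoter_ids)
    frame.index.name = "species_id"
    dm = DensityMatrix(frame)
    truth = SyntheticTruth(
        tree=tree, lifespans=dict(lifespans), causal_ids=causal_ids,
        true_densities=dm, planted_weights=planted,
    )
    return dm, truth


def simulate_panel(config: SimulationConfig) -> SyntheticPanel:
    """Full synthetic study: tree -> lifespans/classes -> density matrix."""
    newick = simulate_tree(config.n_species, config.seed)
    rng = np.random.default_rng(config.seed + 1)
    lifespans, class_of = simulate_lifespans(newick, config, rng=rng)
    dm, truth = simulate_density_matrix(lifespans, config, rng=rng, tree=newick)
    source_choices = np.array(["captivity", "wild", "unknown"])
    # provenance mix patterned on the study panel (151 : 84 : 17 of 252)
    source_p = np.array([151, 84, 17]) / 252
    records = [
        SpeciesRecord(
            species_id=s,
            vertebrate_class=class_of[s],
            max_lifespan=lifespans[s],
            source=str(rng.choice(source_choices, p=source_p)),
        )
        for s in dm.species_ids
    ]
    return SyntheticPanel(tree=newick, records=records, density_matrix=dm, truth=truth)


_FILLER = "ACGT"


def _random_filler(rng: np.random.Generator, prev: str) -> str:
    """A filler base that cannot complete a CpG with the previous base."""
    choices = "ACT" if prev == "C" else _FILLER
    return choices[rng.integers(len(choices))]


def _sequence_with_cpgs(length: int, n_cpg: int, rng: np.random.Generator) -> str:
    """A sequence of `length` bases containing exactly `n_cpg` CpGs.

    CG blocks and single filler bases are shuffled; filler never introduces
    an extra CG (no G after a C outside a block).
    """
    if 2 * n_cpg > length:
        raise ValueError(f"cannot place {n_cpg} CpGs in {length} bases")
    tokens = np.zeros(length - n_cpg, dtype=bool)  # True = CG block
    tokens[:n_cpg] = True
    rng.shuffle(tokens)
    out: list[str] = []
    prev = ""
    for is_block in tokens:
        if is_block:
            out.append("CG")
            prev = "G"
        else:
            ch = _random_filler(rng, prev)
            out.append(ch)
            prev = ch
    return "".join(out)


def realize_sequences(
    density_matrix: DensityMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, dict[str, str]], dict[str, str], HitTable, dict[str, list[tuple[str, str, int, int]]]]:
    """Realize the density matrix as genome sequences plus companion files.

    For every species x promoter a promoter_length sequence carrying
    round(d * promoter_length) CpGs is embedded in that species' genome at a
    random offset, separated by CpG-free spacers. Returns (genomes keyed by
    species, promoter query sequences from the first species, a hit table
    with identity 100 and alignment_length = promoter_length, and per-species
    locus lists). Recomputing densities from these outputs reproduces the
    matrix within 1/(2*promoter_length) per entry.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    L = config.promoter_length
    if L < 20:
        raise ValueError("promoter_length must be >= 20")
    genomes: dict[str, dict[str, str]] = {}
    hit_table = HitTable()
    loci: dict[str, list[tuple[str, str, int, int]]] = {}
    queries: dict[str, str] = {}

    for si, species in enumerate(density_matrix.species_ids):
        contig = f"{species}_chr1"
        parts: list[str] = []
        offset = 0
        species_loci: list[tuple[str, str, int, int]] = []
        for pid in density_matrix.promoter_ids:
            spacer_len = int(rng.integers(50, 151))
            spacer = "".join(
                "ACT"[rng.integers(3)] for _ in range(spacer_len)
            )  # A/C/T only: no G, hence no CG inside or across boundaries
            parts.append(spacer)
            offset += spacer_len
            d = float(density_matrix.frame.loc[species, pid])
            n_cpg = int(round(d * L))
            if 2 * n_cpg > L:
                raise ValueError(f"density {d} needs {n_cpg} CpGs; > {L // 2} possible")
            seq = _sequence_with_cpgs(L, n_cpg, rng)
            parts.append(seq)
            species_loci.append((pid, contig, offset, offset + L))
            hit_table.hits[(species, pid)] = PromoterHit(
                promoter_id=pid, species_id=species, contig=contig,
                start=offset, end=offset + L, strand="+",
                percent_identity=100.0, alignment_length=L,
                bitscore=float(L), evalue=0.0,
            )
            if si == 0:
                queries[pid] = seq
            offset += L
        genome_seq = "".join(parts)
        if len(genome_seq) > config.genome_length:
            raise ValueError(
                f"genome_length {config.genome_length} too small for "
                f"{len(genome_seq)} bases of promoters and spacers"
            )
        pad = config.genome_length - len(genome_seq)
        genome_seq += "".join("ACT"[rng.integers(3)] for _ in range(pad))
        genomes[species] = {contig: genome_seq}
        loci[species] = species_loci
    return genomes, queries, hit_table, loci


def simulate_ancient_variants(
    genome: Mapping[str, str],
    loci: Sequence[tuple[str, str, int, int]],
    n_cpg_breaking: int,
    n_cpg_creating: int,
    seed: int,
) -> list[SnpRecord]:
    """Biallelic SNPs inside the loci that each change the CpG count by one.

    Breaking SNPs mutate the C of an existing CpG to T (-1 CpG each);
    creating SNPs mutate the base after a lone C to G (+1 CpG each). The
    two candidate sets are position-disjoint by construction, so edits
    never interact; each position is edited at most once. Raises if the
    loci cannot supply the requested counts, reporting how many were
    possible.
    """
    rng = np.random.default_rng(seed)
    break_candidates: list[tuple[str, int]] = []  # (contig, 0-based C position)
    create_candidates: list[tuple[str, int, str]] = []  # (contig, 0-based edit pos, ref base)
    for _pid, contig, start, end in loci:
        seq = genome[contig]
        for i in range(start, min(end - 1, len(seq) - 1)):
            pair = seq[i:i + 2].upper()
            if pair == "CG":
                break_candidates.append((contig, i))
            elif pair[0] == "C" and pair[1] in "AT":
                create_candidates.append((contig, i + 1, seq[i + 1].upper()))

    rng.shuffle(break_candidates)
    rng.shuffle(create_candidates)
    used: set[tuple[str, int]] = set()

    def reserve(contig: str, pos: int) -> bool:
        if (contig, pos) in used:
            return False
        used.add((contig, pos))
        return True

    records: list[SnpRecord] = []
    n_b = 0
    for contig, i in break_candidates:
        if n_b == n_cpg_breaking:
            break
        if reserve(contig, i):
            records.append(SnpRecord(contig=contig, pos=i + 1, ref="C", alt="T"))
            n_b += 1
    n_c = 0
    for contig, pos, ref in create_candidates:
        if n_c == n_cpg_creating:
            break
        if reserve(contig, pos):
            records.append(SnpRecord(contig=contig, pos=pos + 1, ref=ref, alt="G"))
            n_c += 1
    if n_b < n_cpg_breaking or n_c < n_cpg_creating:
        raise ValueError(
            f"insufficient editable sites: placed {n_b}/{n_cpg_breaking} CpG-breaking "
            f"and {n_c}/{n_cpg_creating} CpG-creating SNPs"
        )
    return sorted(records, key=lambda r: (r.contig, r.pos))


def write_vcf(
    records: Sequence[SnpRecord],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SNP records as a minimal VCF v4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=cpgclock-simulate\n')
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(f"{r.contig}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")
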