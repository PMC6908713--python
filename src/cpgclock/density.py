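"""CpG density computation: per-hit densities, the species x promoter feature
matrix, genome-wide CpG statistics, and TSS-flank density profiles.

The density of a promoter in a species is the number of CpG dinucleotides in
its homology-hit interval divided by the hit's alignment length; promoters
without a qualifying hit have density 0 by convention. The theoretical
maximum is 0.5 (a CpG every second base).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homology import HitTable, PromoterHit, extract_hit_sequence
from .io import read_gff_features

logger = logging.getLogger(__name__)

_ALLOWED_CHARS = frozenset("ACGTNacgtn")


def count_cpg(seq: str) -> int:
    """Number of CpG dinucleotides (a C immediately followed by a G).

    Case-insensitive; any pair containing an N is not a CpG. Characters
    outside {A, C, G, T, N} raise a ValueError.
    """
    bad = set(seq) - _ALLOWED_CHARS
    if bad:
        raise ValueError(f"sequence contains non-nucleotide characters: {sorted(bad)}")
    return seq.upper().count("CG")


def promoter_density(genome: Mapping[str, str], hit: PromoterHit | None) -> float:
    """CpG density of one promoter hit: CpG count / alignment length.

    Returns 0.0 when no hit exists for the promoter in this species.
    """
    if hit is None:
        return 0.0
    if hit.alignment_length <= 0:
        raise ValueError("alignment length must be positive")
    return count_cpg(extract_hit_sequence(genome, hit)) / hit.alignment_length


@dataclass
class DensityMatrix:
    """Species x promoter CpG-density matrix backed by a DataFrame.

    Rows are species, columns promoters; entries lie in [0, 0.5] and are
    exactly 0 where no qualifying hit exists.
    """

    frame: pd.DataFrame

    @property
    def species_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def promoter_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def row(self, species_id: str) -> pd.Series:
        return self.frame.loc[species_id]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="species_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DensityMatrix":
        return cls(pd.read_csv(path, index_col="species_id"))


def build_density_matrix(
    genomes: Mapping[str, Mapping[str, str]] | Iterable[tuple[str, Mapping[str, str]]],
    hit_table: HitTable,
    promoter_ids: Sequence[str],
) -> DensityMatrix:
    """Assemble the species x promoter density matrix.

    One row per species in ``genomes``, one column per listed promoter, in
    the given column order; (species, promoter) pairs absent from the hit
    table are 0.
    """
    if isinstance(genomes, Mapping):
        pairs = list(genomes.items())
    else:
        pairs = list(genomes)
        ids = [s for s, _ in pairs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate species ids in genomes")
    values = np.zeros((len(pairs), len(promoter_ids)))
    for i, (species_id, genome) in enumerate(pairs):
        for j, promoter_id in enumerate(promoter_ids):
            hit = hit_table.get(species_id, promoter_id)
            if hit is not None:
                values[i, j] = promoter_density(genome, hit)
    frame = pd.DataFrame(values, index=[s for s, _ in pairs], columns=list(promoter_ids))
    frame.index.name = "species_id"
    return DensityMatrix(frame)


@dataclass(frozen=True)
class GenomeStats:
    species_id: str
    total_cpg: int
    genome_length: int
    gc_content: float


def genome_stats(genome: Mapping[str, str], species_id: str = "") -> GenomeStats:
    """Genome-wide CpG count, length, and GC content.

    CpGs are counted per contig (never across contig boundaries); N bases
    are excluded from both the GC numerator and denominator.
    """
    if not genome:
        raise ValueError("empty genome")
    total_cpg = 0
    gc = 0
    acgt = 0
    length = 0
    for seq in genome.values():
        total_cpg += count_cpg(seq)
        s = seq.upper()
        length += len(s)
        gc += s.count("G") + s.count("C")
        acgt += s.count("A") + s.count("T") + s.count("G") + s.count("C")
    return GenomeStats(
        species_id=species_id,
        total_cpg=total_cpg,
        genome_length=length,
        gc_content=gc / acgt if acgt else 0.0,
    )


@dataclass
class TssProfile:
    """Mean CpG density in 500-bp bins flanking transcription start sites.

    Bins are ordered 5' -> 3' relative to the gene; ``bin_edges`` gives each
    bin's gene-relative [left, right) offsets from the TSS (TSS at 0).
    """

    species_id: str
    bin_edges: list[tuple[int, int]]
    bin_densities: np.ndarray


def tss_flank_profile(
    genome: Mapping[str, str],
    annotations: str | Path | pd.DataFrame,
    flank: int = 5000,
    bin: int = 500,
    species_id: str = "",
) -> TssProfile:
    """CpG density profile around TSSs: ``2*flank/bin`` gene-oriented bins.

    The TSS is the annotated gene start ('+' strand) or end ('-' strand).
    For each TSS, the flank is cut into fixed-width bins ordered upstream to
    downstream along the gene (minus-strand genes are mirrored); a bin
    truncated by a contig edge is dropped for that TSS. Per-bin density is
    CpG count / bin width, and the profile is the mean over TSSs.
    """
    if isinstance(annotations, (str, Path)):
        feats = read_gff_features(annotations)
    else:
        feats = annotations
    n_bins = (2 * flank) // bin
    offsets = [(-flank + i * bin, -flank + (i + 1) * bin) for i in range(n_bins)]

    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    n_tss = 0
    for row in feats.itertuples():
        if row.seqid not in genome:
            continue
        seq = genome[row.seqid]
        if row.strand == "+":
            tss = row.start - 1  # GFF is 1-based
        elif row.strand == "-":
            tss = row.end - 1
        else:
            continue
        n_tss += 1
        for i, (lo, hi) in enumerate(offsets):
            if row.strand == "+":
                g_lo, g_hi = tss + lo, tss + hi
            else:
                # gene coordinate g maps to genomic tss - g
                g_lo, g_hi = tss - hi + 1, tss - lo + 1
            if g_lo < 0 or g_hi > len(seq):
                continue
            sums[i] += count_cpg(seq[g_lo:g_hi]) / bin
            counts[i] += 1
    if n_tss == 0:
        raise ValueError("no usable TSS in the annotation")
    with np.errstate(invalid="ignore"):
        densities = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return TssProfile(species_id=species_id, bin_edges=offsets, bin_densities=densities)


def compare_profiles_ks(
    a: TssProfile | Sequence[float],
    b: TssProfile | Sequence[float],
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on two bin-density samples."""
    xa = np.asarray(a.bin_densities if isinstance(a, TssProfile) else a, dtype=float)
    xb = np.asarray(b.bin_densities if isinstance(b, TssProfile) else b, dtype=float)
    xa = xa[~np.isnan(xa)]
    xb = xb[~np.isnan(xb)]
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each sample needs at least 2 values")
    res = stats.ks_2samp(xa, xb)
    return float(res.statistic), float(res.pvalue)
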