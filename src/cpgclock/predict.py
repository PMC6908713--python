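"""Applying a fitted clock: lifespan prediction for extant species from
density vectors, and for extinct species by editing called SNPs into the
reference lifespan loci before recomputing densities.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .density import count_cpg
from .train import ClockModel, raw_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Prediction:
    species_id: str
    vertebrate_class: str
    raw_score: float
    ln_lifespan: float
    lifespan_years: float


class SnpRecord(NamedTuple):
    """A biallelic SNP call; ``pos`` is 1-based as in VCF."""

    contig: str
    pos: int
    ref: str
    alt: str
    filter: str | None = None  # None/"PASS"/"." all count as passing


@dataclass
class LocusSet:
    """Lifespan-locus intervals in reference coordinates (0-based half-open)."""

    loci: list[tuple[str, str, int, int]]  # (promoter_id, contig, start, end)

    def __post_init__(self) -> None:
        ids = [p for p, *_ in self.loci]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate promoter ids in locus set")
        for pid, contig, start, end in self.loci:
            if end <= start:
                raise ValueError(f"degenerate locus {pid} [{start}, {end})")

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)


def read_vcf(path: str | Path) -> list[SnpRecord]:
    """Read biallelic SNPs from a VCF (v4.x); indels and multiallelic
    records are skipped with a logged count."""
    from cyvcf2 import VCF

    records: list[SnpRecord] = []
    skipped = 0
    for v in VCF(str(path)):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            skipped += 1
            continue
        records.append(SnpRecord(
            contig=v.CHROM, pos=v.POS, ref=v.REF, alt=v.ALT[0], filter=v.FILTER,
        ))
    if skipped:
        logger.info("skipped %d non-SNP/multiallelic VCF records", skipped)
    return records


def predict_ln_lifespan(model: ClockModel, x: float, vertebrate_class: str) -> float:
    """ln(max lifespan) = c0 + c1*x + a*x + b, with class-specific (a, b).

    A class absent from the calibration uses a = b = 0 (warned once per call).
    """
    from .train import VERTEBRATE_CLASSES

    if (vertebrate_class not in model.class_coefficients
            and vertebrate_class not in VERTEBRATE_CLASSES):
        warnings.warn(
            f"class {vertebrate_class!r} not in calibration; using a = b = 0"
        )
    a, b = model.class_ab(vertebrate_class)
    return model.global_intercept + model.global_slope * x + a * x + b


def predict_lifespan(
    model: ClockModel,
    densities: Mapping[str, float] | pd.Series,
    vertebrate_class: str,
    species_id: str = "sample",
) -> Prediction:
    """Full prediction from a density vector: raw score, ln years, years."""
    x = raw_score(model, densities)
    ln_l = predict_ln_lifespan(model, x, vertebrate_class)
    return Prediction(
        species_id=species_id,
        vertebrate_class=vertebrate_class,
        raw_score=x,
        ln_lifespan=ln_l,
        lifespan_years=math.exp(ln_l),
    )


def apply_snps(
    reference_locus_seq: str,
    locus: tuple[str, int, int],
    variants: Iterable[SnpRecord],
) -> str:
    """Substitute passing biallelic SNPs into a reference locus sequence.

    ``locus`` is (contig, start, end) in 0-based half-open reference
    coordinates; VCF positions are 1-based. The REF allele must match the
    provided reference base (guards against genome-version mix-ups).
    Returns the edited sequence, same length.
    """
    contig, start, end = locus
    if len(reference_locus_seq) != end - start:
        raise ValueError("locus sequence length does not match interval width")
    seq = list(reference_locus_seq)
    skipped = 0
    for v in variants:
        if v.contig != contig:
            continue
        if v.filter not in (None, "PASS", "."):
            continue
        if len(v.ref) != 1 or len(v.alt) != 1:
            skipped += 1
            continue
        idx = v.pos - 1 - start  # 1-based VCF -> offset in the slice
        if not 0 <= idx < end - start:
            continue
        if seq[idx].upper() != v.ref.upper():
            raise ValueError(
                f"REF mismatch at {contig}:{v.pos}: VCF says {v.ref!r}, "
                f"reference has {seq[idx]!r} (genome version mix-up?)"
            )
        seq[idx] = v.alt.upper()
    if skipped:
        logger.info("skipped %d indel/multiallelic records in locus %s", skipped, contig)
    return "".join(seq)


def predict_ancient(
    model: ClockModel,
    reference_genome: Mapping[str, str],
    loci: LocusSet,
    variants: Iterable[SnpRecord] | str | Path,
    vertebrate_class: str,
    species_id: str = "ancient",
) -> Prediction:
    """Lifespan prediction for an extinct species from variant calls.

    Each lifespan locus is sliced from the reference, SNP-edited, and its
    CpG density recomputed with the locus interval width as denominator;
    prediction then proceeds as for an extant species. Model promoters
    missing from the locus set contribute density 0 (with a warning).
    """
    if isinstance(variants, (str, Path)):
        variants = read_vcf(variants)
    variants = list(variants)
    densities: dict[str, float] = {}
    for pid, contig, start, end in loci:
        if contig not in reference_genome:
            raise KeyError(f"locus contig {contig!r} not in reference genome")
        ref_seq = reference_genome[contig][start:end]
        if len(ref_seq) < end - start:
            raise IndexError(f"locus {pid} [{start}, {end}) exceeds contig {contig!r}")
        edited = apply_snps(ref_seq, (contig, start, end), variants)
        densities[pid] = count_cpg(edited) / (end - start)
    missing = [p for p in model.promoter_weights if p not in densities]
    if missing:
        warnings.warn(
            f"{len(missing)} model promoters absent from the locus set; density 0"
        )
    return predict_lifespan(model, densities, vertebrate_class, species_id=species_id)


def predictions_to_csv(predictions: Sequence[Prediction], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "species_id": p.species_id,
                "class": p.vertebrate_class,
                "raw_score": p.raw_score,
                "ln_pred": p.ln_lifespan,
                "years_pred": p.lifespan_years,
            }
            for p in predictions
        ]
    ).to_csv(path, index=False)
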