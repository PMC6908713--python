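"""Promoter-to-genome homology hits: parsing, top-hit filtering, extraction.

A promoter's presence in a species is established by a single best homology
hit with >70% identity (strict). The hit table is normally produced by an
external search tool in 12-column tabular format; a small built-in
seed-and-extend aligner is provided so synthetic fixtures can be aligned
without any external binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: default identity threshold (percent); retention requires strictly greater
DEFAULT_MIN_IDENTITY = 70.0

HIT_TSV_COLUMNS = [
    "species_id", "promoter_id", "contig", "start", "end",
    "strand", "pident", "aln_len", "bitscore", "evalue",
]


@dataclass(frozen=True)
class PromoterHit:
    """One homology hit of a promoter query in one species' genome.

    Coordinates are 0-based half-open on the forward strand of ``contig``.
    ``alignment_length`` is the aligned-column count reported by the search
    tool and may exceed ``end - start`` when the alignment is gapped.
    """

    promoter_id: str
    species_id: str
    contig: str
    start: int
    end: int
    strand: str
    percent_identity: float
    alignment_length: int
    bitscore: float = 0.0
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"degenerate hit interval [{self.start}, {self.end})")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity {self.percent_identity} outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class HitTable:
    """At most one retained hit per (species_id, promoter_id) key."""

    hits: dict[tuple[str, str], PromoterHit] = field(default_factory=dict)

    def get(self, species_id: str, promoter_id: str) -> PromoterHit | None:
        return self.hits.get((species_id, promoter_id))

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits.values())

    @property
    def species_ids(self) -> list[str]:
        return sorted({s for s, _ in self.hits})

    @property
    def promoter_ids(self) -> list[str]:
        return sorted({p for _, p in self.hits})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(HIT_TSV_COLUMNS) + "\n")
            for h in self.hits.values():
                fh.write(
                    f"{h.species_id}\t{h.promoter_id}\t{h.contig}\t{h.start}\t{h.end}\t"
                    f"{h.strand}\t{h.percent_identity}\t{h.alignment_length}\t"
                    f"{h.bitscore}\t{h.evalue}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HitTable":
        table = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != HIT_TSV_COLUMNS:
                raise ValueError(f"unexpected hit-table header: {header}")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                hit = PromoterHit(
                    promoter_id=f[1], species_id=f[0], contig=f[2],
                    start=int(f[3]), end=int(f[4]), strand=f[5],
                    percent_identity=float(f[6]), alignment_length=int(f[7]),
                    bitscore=float(f[8]), evalue=float(f[9]),
                )
                table.hits[(hit.species_id, hit.promoter_id)] = hit
        return table


def parse_blast_tabular(path: str | Path, species_id: str) -> list[PromoterHit]:
    """Parse 12-column tabular search output (outfmt 6) into hits.

    Subject coordinates are 1-based inclusive in the file and converted to
    0-based half-open; ``sstart > send`` marks a minus-strand hit and the
    coordinates are swapped so that ``start < end`` always holds.
    """
    hits: list[PromoterHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 tab-separated fields, got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}") from None
            if sstart <= send:
                strand, start, end = "+", sstart - 1, send
            else:
                strand, start, end = "-", send - 1, sstart
            hits.append(PromoterHit(
                promoter_id=qseqid, species_id=species_id, contig=sseqid,
                start=start, end=end, strand=strand,
                percent_identity=pident, alignment_length=length,
                bitscore=bitscore, evalue=evalue,
            ))
    return hits


def filter_top_hits(
    hits: Iterable[PromoterHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> HitTable:
    """Keep, per (species, promoter), the single best hit above the identity cut.

    The identity threshold is strict (> min_identity). Best = highest
    bitscore, ties broken by lowest e-value, then input order.
    """
    best: dict[tuple[str, str], tuple[float, float, int, PromoterHit]] = {}
    for idx, hit in enumerate(hits):
        if hit.percent_identity <= min_identity:
            continue
        key = (hit.species_id, hit.promoter_id)
        rank = (-hit.bitscore, hit.evalue, idx)
        if key not in best or rank < best[key][:3]:
            best[key] = (*rank, hit)
    return HitTable({k: v[3] for k, v in best.items()})


def extract_hit_sequence(genome: Mapping[str, str], hit: PromoterHit) -> str:
    """Forward-strand genomic slice [start, end) of the hit.

    Minus-strand hits return the same forward slice: the CpG dinucleotide is
    reverse-complement symmetric, so CpG counts are unaffected by strand.
    """
    if hit.contig not in genome:
        raise KeyError(f"contig {hit.contig!r} not present in genome")
    contig_seq = genome[hit.contig]
    if hit.end > len(contig_seq):
        raise IndexError(
            f"hit [{hit.start}, {hit.end}) exceeds contig {hit.contig!r} "
            f"length {len(contig_seq)}"
        )
    return contig_seq[hit.start:hit.end]


def seed_extend_align(
    query: str,
    genome: Mapping[str, str],
    word_size: int = 11,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    promoter_id: str = "query",
    species_id: str = "subject",
) -> PromoterHit | None:
    """Ungapped seed-and-extend alignment of a query against a genome.

    Exact ``word_size``-mers seed ungapped extensions in both directions;
    each extension grows while its running identity stays at or above
    ``min_identity`` percent, and the state with the most matching bases is
    kept. The best extension over all seeds is returned (bitscore = match
    count, evalue = 0 placeholder); None if no seed matches.
    """
    if len(query) < word_size:
        raise ValueError(f"query length {len(query)} < word size {word_size}")
    query = query.upper()
    min_frac = min_identity / 100.0

    qwords: dict[str, list[int]] = {}
    for qpos in range(len(query) - word_size + 1):
        qwords.setdefault(query[qpos:qpos + word_size], []).append(qpos)

    best_hit: tuple[int, PromoterHit] | None = None
    for contig, raw_seq in genome.items():
        seq = raw_seq.upper()
        seen_diagonals: set[int] = set()
        for gpos in range(len(seq) - word_size + 1):
            word = seq[gpos:gpos + word_size]
            for qpos in qwords.get(word, ()):
                diag = gpos - qpos
                if diag in seen_diagonals:
                    continue
                seen_diagonals.add(diag)
                # extend right from the seed
                matches, length = word_size, word_size
                q_end, g_end = qpos + word_size, gpos + word_size
                best_right = (matches, q_end, g_end)
                while q_end < len(query) and g_end < len(seq):
                    matches += query[q_end] == seq[g_end]
                    length += 1
                    q_end += 1
                    g_end += 1
                    if matches / length < min_frac:
                        break
                    if matches > best_right[0]:
                        best_right = (matches, q_end, g_end)
                # extend left from the seed, keeping the right extension fixed
                matches, length = best_right[0], best_right[1] - qpos
                q_start, g_start = qpos, gpos
                best_left = (matches, q_start, g_start)
                while q_start > 0 and g_start > 0:
                    matches += query[q_start - 1] == seq[g_start - 1]
                    length += 1
                    q_start -= 1
                    g_start -= 1
                    if matches / length < min_frac:
                        break
                    if matches > best_left[0]:
                        best_left = (matches, q_start, g_start)
                n_match, q_start, g_start = best_left
                g_end = best_right[2]
                aln_len = g_end - g_start
                identity = 100.0 * n_match / aln_len
                if identity < min_identity:
                    continue
                if best_hit is None or n_match > best_hit[0]:
                    best_hit = (n_match, PromoterHit(
                        promoter_id=promoter_id, species_id=species_id,
                        contig=contig, start=g_start, end=g_end, strand="+",
                        percent_identity=identity, alignment_length=aln_len,
                        bitscore=float(n_match), evalue=0.0,
                    ))
    return best_hit[1] if best_hit else None
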