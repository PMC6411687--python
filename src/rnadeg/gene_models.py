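"""Gene models: GTF I/O, dominant-transcript selection, 3'-end truncation.

RNA degradation in poly(A)-primed libraries erodes coverage far from the
3' terminus, so samples with different RNA integrity are only comparable
over the window next to the 3' end that degradation leaves intact.  This
module builds the counting models for that strategy: per gene, keep the
single most abundant isoform and cut its exon chain down to the last
``window_bp`` (default 500) spliced bases before the 3' end.

Coordinates are 0-based half-open internally; GTF files on disk are
1-based inclusive and conversion happens only at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "Exon",
    "Transcript",
    "GeneModel",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "select_dominant_transcript",
    "truncate_to_3prime_window",
    "truncate_models",
]

DEFAULT_WINDOW_BP = 500


class GtfParseError(ValueError):
    """Malformed GTF input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class Exon:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid exon interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """An isoform: ordered exons plus an expression estimate.

    Exons are stored sorted by genomic start regardless of strand; the
    5'->3' reading order is derived from ``strand`` where needed.
    """

    id: str
    exons: list[Exon]
    abundance: float | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
            if b.chrom != a.chrom or b.strand != a.strand:
                raise ValueError(f"transcript {self.id}: mixed chrom/strand")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def spliced_length_bp(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """A gene with its isoforms and, once selected, the dominant one."""

    gene_id: str
    transcripts: list[Transcript] = field(default_factory=list)
    dominant: str | None = None

    def __post_init__(self) -> None:
        if self.dominant is not None and self.dominant not in {
            t.id for t in self.transcripts
        }:
            raise ValueError(
                f"gene {self.gene_id}: dominant transcript {self.dominant} "
                "not among its transcripts"
            )

    def transcript(self, transcript_id: str) -> Transcript:
        for t in self.transcripts:
            if t.id == transcript_id:
                return t
        raise KeyError(f"gene {self.gene_id}: no transcript {transcript_id}")

    @property
    def dominant_transcript(self) -> Transcript:
        if self.dominant is None:
            raise ValueError(f"gene {self.gene_id}: dominant transcript not set")
        return self.transcript(self.dominant)


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

def _parse_attributes(attr_field: str, line_number: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"malformed attribute {chunk!r}", line_number)
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read exon features from a GTF file into gene models.

    Coordinates are converted from the on-disk 1-based inclusive
    convention to internal 0-based half-open; exon order is normalized to
    genomic position.  ``gene_id`` and ``transcript_id`` attributes are
    mandatory; an optional ``abundance`` attribute populates the
    transcript's expression estimate.
    """
    genes: dict[str, dict[str, dict]] = {}
    gene_order: list[str] = []
    with open(path) as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}",
                    line_number,
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}", line_number
                ) from None
            if end1 < start1:
                raise GtfParseError(
                    f"end {end1} < start {start1}", line_number
                )
            attrs = _parse_attributes(attr, line_number)
            for key in ("gene_id", "transcript_id"):
                if key not in attrs:
                    raise GtfParseError(f"missing {key} attribute", line_number)
            gid, tid = attrs["gene_id"], attrs["transcript_id"]
            if gid not in genes:
                genes[gid] = {}
                gene_order.append(gid)
            tx = genes[gid].setdefault(tid, {"exons": [], "abundance": None})
            tx["exons"].append(Exon(chrom, start1 - 1, end1, strand))
            if "abundance" in attrs:
                tx["abundance"] = float(attrs["abundance"])

    models = []
    for gid in gene_order:
        transcripts = [
            Transcript(tid, rec["exons"], rec["abundance"])
            for tid, rec in genes[gid].items()
        ]
        models.append(GeneModel(gid, transcripts))
    return models


def write_gtf(
    models: Iterable[GeneModel],
    path: str | Path,
    truncated: bool = False,
    source: str = "rnadeg",
) -> None:
    """Write gene models as GTF exon features (1-based inclusive).

    With ``truncated=True`` only the dominant transcript of each gene is
    emitted — the single-isoform counting model.
    """
    lines = []
    for gene in models:
        transcripts = gene.transcripts
        if truncated:
            transcripts = [gene.dominant_transcript]
        for tx in transcripts:
            # exon_number follows the 5'->3' reading order, as aligners emit
            reading = tx.exons if tx.strand == "+" else list(reversed(tx.exons))
            for i, exon in enumerate(reading, start=1):
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.id}"; exon_number "{i}";'
                if tx.abundance is not None:
                    attrs += f' abundance "{tx.abundance:.6g}";'
                lines.append(
                    "\t".join(
                        (
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            attrs,
                        )
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Dominant transcript and truncation
# ---------------------------------------------------------------------------

def select_dominant_transcript(gene: GeneModel) -> str:
    """Pick the most abundant isoform as the gene's counting model.

    Ties are broken by longer spliced length, then lexicographically
    smallest transcript id, so the choice is deterministic.  The choice is
    recorded on the gene and returned.
    """
    if not gene.transcripts:
        raise ValueError(f"gene {gene.gene_id}: no transcripts")
    for t in gene.transcripts:
        if t.abundance is None:
            raise ValueError(
                f"gene {gene.gene_id}: transcript {t.id} has no abundance"
            )
    best = max(
        gene.transcripts,
        key=lambda t: (t.abundance, t.spliced_length_bp, _neg_lex(t.id)),
    )
    gene.dominant = best.id
    return best.id


class _neg_lex(str):
    """Reverses lexicographic order so max() prefers the smallest id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def truncate_to_3prime_window(
    transcript: Transcript, window_bp: int = DEFAULT_WINDOW_BP
) -> Transcript:
    """Keep exactly the spliced bases within ``window_bp`` of the 3' end.

    For a + strand transcript the 3' end sits at the highest genomic
    coordinate, so the walk runs from the last exon backwards; for -
    strand it starts at the lowest coordinate.  A transcript shorter than
    the window is returned unchanged (idempotent by construction).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if transcript.spliced_length_bp <= window_bp:
        return replace(transcript, exons=list(transcript.exons))

    # Walk exons starting from the 3' end, accumulating spliced bases.
    from_high = transcript.strand == "+"
    order = reversed(transcript.exons) if from_high else transcript.exons
    kept: list[Exon] = []
    remaining = window_bp
    for exon in order:
        take = min(len(exon), remaining)
        if from_high:
            kept.append(replace(exon, start=exon.end - take))
        else:
            kept.append(replace(exon, end=exon.start + take))
        remaining -= take
        if remaining == 0:
            break
    return replace(transcript, exons=kept)


def truncate_models(
    models: Iterable[GeneModel], window_bp: int = DEFAULT_WINDOW_BP
) -> list[GeneModel]:
    """Dominant-isoform selection + 3' truncation over a gene collection.

    Genes whose dominant transcript is already set keep it; others get it
    from :func:`select_dominant_transcript`.
    """
    out = []
    for gene in models:
        if gene.dominant is None:
            select_dominant_transcript(gene)
        tx = truncate_to_3prime_window(gene.dominant_transcript, window_bp)
        out.append(GeneModel(gene.gene_id, [tx], dominant=tx.id))
    return out
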