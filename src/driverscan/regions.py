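"""Genomic interval arithmetic, reference-sequence access and gene models.

All internal coordinates are 0-based half-open.  GTF input (1-based,
inclusive) is converted on read; BED is read natively.  Strand is recorded
on gene models but ignored by all region arithmetic, since somatic variant
calls are strandless.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomeSequence",
    "Interval",
    "RegionSet",
    "GeneModel",
    "Annotation",
    "region_op",
    "load_gene_models",
    "build_background",
    "read_bed",
    "read_coding_potential",
    "write_gene_regions",
    "TRINUCLEOTIDES",
]

#: all 64 trinucleotides in code order (code = 16*left + 4*centre + right)
TRINUCLEOTIDES = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # tolerate soft-masked (lowercase) sequence


def open_text(source):
    """Open ``source`` for text reading; transparent gzip; pass through
    file-like objects.  Returns (handle, needs_close)."""
    if hasattr(source, "read"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb")), True
    return open(path, "rt"), True


class GenomeSequence:
    """In-memory reference genome with cached integer encodings.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to sequence string.  Sequences are
        upper-cased; any character outside A/C/G/T is treated as N.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {c: str(s).upper() for c, s in sequences.items()}
        self._codes: dict[str, np.ndarray] = {}
        self._ctx: dict[str, np.ndarray] = {}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of ``[start, end)``; out-of-range is an error."""
        seq = self._seqs.get(chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"query {chrom}:{start}-{end} outside chromosome bounds [0, {len(seq)})"
            )
        return seq[start:end]

    def base_codes(self, chrom: str) -> np.ndarray:
        """uint8 array: A,C,G,T -> 0..3, anything else -> 4."""
        if chrom not in self._codes:
            raw = np.frombuffer(self._seqs[chrom].encode("ascii"), dtype=np.uint8)
            self._codes[chrom] = _BASE_CODE[raw]
        return self._codes[chrom]

    def context_codes(self, chrom: str) -> np.ndarray:
        """int16 array of trinucleotide codes centred on each position.

        Positions whose 3-mer runs off the chromosome or contains a non-ACGT
        base get code -1.
        """
        if chrom not in self._ctx:
            b = self.base_codes(chrom)
            t = np.full(len(b), -1, dtype=np.int16)
            if len(b) >= 3:
                left, mid, right = b[:-2], b[1:-1], b[2:]
                valid = (left < 4) & (mid < 4) & (right < 4)
                codes = (
                    left.astype(np.int16) * 16 + mid.astype(np.int16) * 4 + right
                )
                t[1:-1] = np.where(valid, codes, -1)
            self._ctx[chrom] = t
        return self._ctx[chrom]


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """A normalized set of genomic base pairs (sorted, disjoint, merged).

    Supports exact base-pair set semantics: union, intersection, subtraction
    and membership queries.  Abutting intervals are merged on construction.
    """

    __slots__ = ("_data",)

    def __init__(self, intervals: Iterable[Interval] = ()):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            starts, ends = [], []
            for s, e in pairs:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._data[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )

    # -- construction helpers -------------------------------------------------

    @classmethod
    def single(cls, chrom: str, start: int, end: int) -> "RegionSet":
        return cls([Interval(chrom, start, end)])

    @classmethod
    def _from_arrays(cls, data: dict[str, tuple[np.ndarray, np.ndarray]]) -> "RegionSet":
        out = cls()
        out._data = {c: v for c, v in data.items() if len(v[0])}
        return out

    # -- basic queries --------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._data.get(
            chrom, (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        )

    def intervals(self) -> Iterator[Interval]:
        for chrom in self.chroms:
            starts, ends = self._data[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield Interval(chrom, s, e)

    @property
    def total_bp(self) -> int:
        return int(
            sum((e - s).sum() for s, e in self._data.values())
        )

    def __bool__(self) -> bool:
        return bool(self._data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(
            np.array_equal(self._data[c][0], other._data[c][0])
            and np.array_equal(self._data[c][1], other._data[c][1])
            for c in self._data
        )

    def __repr__(self) -> str:
        ivs = list(self.intervals())
        body = ", ".join(f"{i.chrom}:{i.start}-{i.end}" for i in ivs[:4])
        if len(ivs) > 4:
            body += f", ... ({len(ivs)} intervals)"
        return f"RegionSet({body}, total_bp={self.total_bp})"

    def contains(self, chrom: str, pos: int) -> bool:
        return bool(self.contains_many(chrom, np.asarray([pos]))[0])

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an array of positions."""
        positions = np.asarray(positions, dtype=np.int64)
        starts, ends = self.arrays(chrom)
        if not len(starts):
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        out = np.zeros(len(positions), dtype=bool)
        out[ok] = positions[ok] < ends[idx[ok]]
        return out

    # -- set operations -------------------------------------------------------

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet(list(self.intervals()) + list(other.intervals()))

    def intersect(self, other: "RegionSet") -> "RegionSet":
        data = {}
        for chrom in set(self._data) & set(other._data):
            a_s, a_e = self._data[chrom]
            b_s, b_e = other._data[chrom]
            out_s, out_e = [], []
            i = j = 0
            while i < len(a_s) and j < len(b_s):
                s = max(a_s[i], b_s[j])
                e = min(a_e[i], b_e[j])
                if s < e:
                    out_s.append(s)
                    out_e.append(e)
                if a_e[i] < b_e[j]:
                    i += 1
                else:
                    j += 1
            data[chrom] = (np.asarray(out_s, np.int64), np.asarray(out_e, np.int64))
        return RegionSet._from_arrays(data)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        data = {}
        for chrom in self._data:
            a_s, a_e = self._data[chrom]
            b_s, b_e = other.arrays(chrom)
            if not len(b_s):
                data[chrom] = (a_s.copy(), a_e.copy())
                continue
            out_s, out_e = [], []
            j = 0
            for s, e in zip(a_s.tolist(), a_e.tolist()):
                cur = s
                # advance to the first b interval that can overlap [cur, e)
                while j < len(b_s) and b_e[j] <= cur:
                    j += 1
                k = j
                while k < len(b_s) and b_s[k] < e:
                    if b_s[k] > cur:
                        out_s.append(cur)
                        out_e.append(int(b_s[k]))
                    cur = max(cur, int(b_e[k]))
                    if cur >= e:
                        break
                    k += 1
                if cur < e:
                    out_s.append(cur)
                    out_e.append(e)
            data[chrom] = (np.asarray(out_s, np.int64), np.asarray(out_e, np.int64))
        return RegionSet._from_arrays(data)


def region_op(a: RegionSet, b: RegionSet, op: str) -> RegionSet:
    """Dispatch ``union``/``intersect``/``subtract`` by name."""
    try:
        return getattr(a, op)(b)
    except AttributeError:
        raise ValueError(f"unknown region operation {op!r}") from None


@dataclass
class GeneModel:
    """One gene's test (exonic) region and, once built, its local background.

    ``exonic`` is the union of exons over all transcripts; ``background`` is
    introns plus ``flank_bp`` up/downstream, minus every annotated gene's
    exons and minus masked bases.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    span: Interval
    exonic: RegionSet
    background: RegionSet | None = None
    flank_bp: int = 10_000
    biotype: str = "unknown"
    flags: set[str] = field(default_factory=set)

    @property
    def joint(self) -> RegionSet:
        """Exonic plus background region (the RE sampling space)."""
        if self.background is None:
            raise ValueError(f"background not built for gene {self.gene_id}")
        return self.exonic.union(self.background)


@dataclass
class Annotation:
    """Outcome of annotation parsing and filtering.

    ``genes`` are the retained test genes; ``all_exons`` is the exon union
    over *every* parsed gene of any biotype (used for background exclusion);
    ``dropped`` maps filter reason to the gene ids it removed.
    """

    genes: list[GeneModel]
    all_exons: RegionSet
    n_parsed: int
    dropped: dict[str, list[str]] = field(default_factory=dict)


_GTF_FEATURES = {"gene", "transcript", "exon"}


def _parse_gtf(source, genome: GenomeSequence | None):
    from gffutils.feature import feature_from_line

    handle, needs_close = open_text(source)
    genes: dict[str, dict] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
                start, end = int(feat.start) - 1, int(feat.end)
            except Exception as exc:
                raise ValueError(f"malformed GTF line {lineno}: {exc}") from exc
            if feat.featuretype not in _GTF_FEATURES:
                continue
            attrs = feat.attributes
            gene_id = (attrs.get("gene_id") or [None])[0]
            if gene_id is None:
                raise ValueError(f"malformed GTF line {lineno}: missing gene_id")
            rec = genes.setdefault(
                gene_id,
                {
                    "gene_id": gene_id,
                    "gene_name": gene_id,
                    "chrom": feat.seqid,
                    "strand": feat.strand or ".",
                    "biotype": "unknown",
                    "exons": [],
                    "transcripts": set(),
                },
            )
            biotype = (attrs.get("gene_type") or attrs.get("gene_biotype") or [None])[0]
            if biotype:
                rec["biotype"] = biotype
            name = (attrs.get("gene_name") or [None])[0]
            if name:
                rec["gene_name"] = name
            if feat.featuretype in ("transcript", "exon"):
                tid = (attrs.get("transcript_id") or [None])[0]
                if tid:
                    rec["transcripts"].add(tid)
            if feat.featuretype == "exon":
                if genome is not None:
                    if feat.seqid not in genome:
                        raise ValueError(
                            f"GTF line {lineno}: unknown chromosome {feat.seqid!r}"
                        )
                    if not (0 <= start < end <= genome.length(feat.seqid)):
                        raise ValueError(
                            f"GTF line {lineno}: exon {feat.seqid}:{start}-{end} "
                            "outside chromosome bounds"
                        )
                rec["exons"].append((start, end))
    finally:
        if needs_close:
            handle.close()
    return genes


def read_coding_potential(source) -> dict[str, float]:
    """Read a 2-column TSV of transcript_id -> coding-potential score."""
    import pandas as pd

    handle, needs_close = open_text(source)
    try:
        df = pd.read_csv(
            handle, sep="\t", header=None, comment="#",
            names=["transcript_id", "score"],
        )
    finally:
        if needs_close:
            handle.close()
    return dict(zip(df["transcript_id"].astype(str), df["score"].astype(float)))


def load_gene_models(
    source,
    allowed_biotypes: set[str] | None = None,
    coding_potential: Mapping[str, float] | None = None,
    coding_potential_threshold: float = 0.364,
    overlap_filter: bool = True,
    overlap_mode: str = "span",
    genome: GenomeSequence | None = None,
    flank_bp: int = 10_000,
) -> Annotation:
    """Parse a GTF and build filtered gene models (exonic regions only).

    Genes are retained if their biotype is in ``allowed_biotypes`` (every
    biotype when ``None``), they do not overlap a protein-coding gene
    (``overlap_filter``; protein-coding genes themselves are exempt), and no
    transcript of theirs scores at or above ``coding_potential_threshold`` in the
    ``coding_potential`` table.  ``all_exons`` in the returned annotation
    always covers every parsed gene regardless of filtering.
    """
    if overlap_mode not in ("span", "exon"):
        raise ValueError("overlap_mode must be 'span' or 'exon'")
    parsed = _parse_gtf(source, genome)

    all_exons = RegionSet(
        Interval(rec["chrom"], s, e) for rec in parsed.values() for s, e in rec["exons"]
    )
    coding = [rec for rec in parsed.values() if rec["biotype"] == "protein_coding"]
    coding_spans = RegionSet(
        Interval(rec["chrom"], min(s for s, _ in rec["exons"]),
                 max(e for _, e in rec["exons"]))
        for rec in coding if rec["exons"]
    )
    coding_exons = RegionSet(
        Interval(rec["chrom"], s, e) for rec in coding for s, e in rec["exons"]
    )

    genes: list[GeneModel] = []
    dropped: dict[str, list[str]] = {}
    for gene_id in sorted(parsed):
        rec = parsed[gene_id]
        if not rec["exons"]:
            dropped.setdefault("no_exons", []).append(gene_id)
            continue
        exonic = RegionSet(Interval(rec["chrom"], s, e) for s, e in rec["exons"])
        span = Interval(
            rec["chrom"],
            min(s for s, _ in rec["exons"]),
            max(e for _, e in rec["exons"]),
        )
        if allowed_biotypes is not None and rec["biotype"] not in allowed_biotypes:
            dropped.setdefault("biotype", []).append(gene_id)
            continue
        if overlap_filter and rec["biotype"] != "protein_coding":
            probe = RegionSet([span]) if overlap_mode == "span" else exonic
            other = coding_spans if overlap_mode == "span" else coding_exons
            if probe.intersect(other).total_bp > 0:
                dropped.setdefault("overlaps_coding", []).append(gene_id)
                continue
        if coding_potential is not None:
            scores = [
                coding_potential[t] for t in rec["transcripts"] if t in coding_potential
            ]
            if any(s >= coding_potential_threshold for s in scores):
                dropped.setdefault("coding_potential", []).append(gene_id)
                continue
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=rec["gene_name"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                span=span,
                exonic=exonic,
                flank_bp=flank_bp,
                biotype=rec["biotype"],
            )
        )
    return Annotation(
        genes=genes, all_exons=all_exons, n_parsed=len(parsed), dropped=dropped
    )


def build_background(
    gene: GeneModel,
    all_gene_exons: RegionSet,
    mask: RegionSet | None = None,
    flank_bp: int | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> GeneModel:
    """Attach the local background region to ``gene``.

    Background = (span plus ``flank_bp`` up/downstream, clipped to the
    chromosome) minus the exons of every annotated gene minus masked bases.
    The gene's own exons are part of ``all_gene_exons``, so introns survive
    while exons never do.  A gene whose background comes out empty is flagged
    ``empty_background`` and is skipped by the tests downstream.
    """
    flank = gene.flank_bp if flank_bp is None else flank_bp
    if flank < 0:
        raise ValueError("flank_bp must be >= 0")
    start = gene.span.start - flank
    end = gene.span.end + flank
    if chrom_lengths is not None:
        if gene.chrom not in chrom_lengths:
            raise KeyError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}")
        end = min(end, chrom_lengths[gene.chrom])
    start = max(start, 0)
    background = RegionSet.single(gene.chrom, start, end).subtract(all_gene_exons)
    if mask is not None:
        background = background.subtract(mask)
    out = replace(gene, background=background, flank_bp=flank, flags=set(gene.flags))
    if background.total_bp == 0:
        out.flags.add("empty_background")
    return out


def read_bed(source) -> RegionSet:
    """Read a BED3+ file into a RegionSet (native 0-based half-open)."""
    handle, needs_close = open_text(source)
    intervals = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: {line!r}")
            try:
                intervals.append(Interval(parts[0], int(parts[1]), int(parts[2])))
            except Exception as exc:
                raise ValueError(f"malformed BED line {lineno}: {exc}") from exc
    finally:
        if needs_close:
            handle.close()
    return RegionSet(intervals)


def write_gene_regions(genes: Iterable[GeneModel], outdir) -> None:
    """Write per-gene exonic and background regions as BED6 for audit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind in ("exonic", "background"):
        with open(outdir / f"{kind}.bed", "w") as fh:
            for gene in genes:
                region = gene.exonic if kind == "exonic" else gene.background
                if region is None:
                    continue
                for iv in region.intervals():
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene.gene_id}\t0\t{gene.strand}\n"
                    )
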