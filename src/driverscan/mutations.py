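"""Somatic variant ingestion, trinucleotide contexts and score tracks.

Only single-base substitutions (SBS) and 1-bp insertions/deletions are
retained; everything else is dropped and counted.  Trinucleotide contexts
are taken from the reference genome centred on the affected base (the
deleted base for DEL1, the base at the insertion point for INS1) and are
not strand-collapsed: ``ATA`` and ``TAT`` are distinct keys.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GenomeSequence, RegionSet, Interval, open_text

log = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "FilterStats",
    "TrinucleotideIndex",
    "ScoreTrack",
    "read_and_filter_mutations",
    "write_maf",
    "trinucleotide_context",
    "build_context_index",
    "read_score_track",
]

SBS = "SBS"
INS1 = "INS1"
DEL1 = "DEL1"

_VALID_BASES = frozenset("ACGT")

MAF_COLUMNS = [
    "Chromosome",
    "Start_position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant anchored at a single reference base.

    ``pos`` is the 0-based coordinate of the affected base (SBS, DEL1) or of
    the base at the insertion point (INS1).  ``context`` is the reference
    3-mer centred on ``pos``, with ``N`` padding at chromosome edges.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    mut_class: str = SBS
    context: str = "NNN"

    def sort_key(self):
        return (self.chrom, self.pos, self.ref, self.alt, self.sample_id)


@dataclass
class FilterStats:
    n_input: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)


def trinucleotide_context(genome: GenomeSequence, chrom: str, pos: int) -> str:
    """Reference 3-mer centred on ``pos``; absent flanks become ``N``."""
    length = genome.length(chrom)
    if not 0 <= pos < length:
        raise ValueError(f"position {chrom}:{pos} outside chromosome bounds")
    left = genome.fetch(chrom, pos - 1, pos) if pos >= 1 else "N"
    right = genome.fetch(chrom, pos + 1, pos + 2) if pos + 2 <= length else "N"
    centre = genome.fetch(chrom, pos, pos + 1)
    out = left + centre + right
    return "".join(b if b in _VALID_BASES else "N" for b in out)


def _classify(pos0: int, ref: str, alt: str):
    """Return (anchor position, ref, alt, class) or a drop reason string.

    Accepts both dash-style indels (MAF: ref='-' or alt='-') and anchored
    VCF-style alleles (ref='AT', alt='A').
    """
    ref = ref.strip().upper()
    alt = alt.strip().upper()
    if len(ref) == 1 and len(alt) == 1 and ref in _VALID_BASES and alt in _VALID_BASES:
        if ref == alt:
            return "ref_equals_alt"
        return pos0, ref, alt, SBS
    if ref == "-" and len(alt) == 1 and alt in _VALID_BASES:
        return pos0, ref, alt, INS1
    if alt == "-" and len(ref) == 1 and ref in _VALID_BASES:
        return pos0, ref, alt, DEL1
    if len(ref) == 2 and len(alt) == 1 and ref[0] == alt and set(ref) <= _VALID_BASES:
        return pos0 + 1, ref[1], "-", DEL1  # anchored 1-bp deletion
    if len(ref) == 1 and len(alt) == 2 and alt[0] == ref and set(alt) <= _VALID_BASES:
        return pos0, "-", alt[1], INS1  # anchored 1-bp insertion
    return "not_1bp"


def _finalize(
    raw: list[tuple[str, int, str, str, str]],
    genome: GenomeSequence | None,
    stats: FilterStats,
) -> list[MutationRecord]:
    records = []
    for chrom, pos0, ref, alt, sample in raw:
        stats.n_input += 1
        verdict = _classify(pos0, str(ref), str(alt))
        if isinstance(verdict, str):
            stats.dropped[verdict] += 1
            continue
        anchor, ref, alt, mut_class = verdict
        context = "NNN"
        if genome is not None:
            if chrom not in genome:
                stats.dropped["unknown_chromosome"] += 1
                continue
            if not 0 <= anchor < genome.length(chrom):
                stats.dropped["out_of_bounds"] += 1
                continue
            context = trinucleotide_context(genome, chrom, anchor)
            if mut_class in (SBS, DEL1) and context[1] != ref:
                stats.dropped["ref_mismatch"] += 1
                continue
        records.append(
            MutationRecord(chrom, anchor, ref, alt, str(sample), mut_class, context)
        )
        stats.n_kept += 1
    for reason, n in stats.dropped.items():
        log.warning("dropped %d record(s): %s", n, reason)
    return records


def _read_maf(source) -> list[tuple[str, int, str, str, str]]:
    handle, needs_close = open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    finally:
        if needs_close:
            handle.close()
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF-lite input missing column(s): {', '.join(missing)}")
    return [
        (row.Chromosome, int(row.Start_position) - 1, row.Reference_Allele,
         row.Tumor_Seq_Allele2, row.Tumor_Sample_Barcode)
        for row in df.itertuples()
    ]


def _read_vcf(path) -> list[tuple[str, int, str, str, str]]:
    import pysam

    raw = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            for alt in rec.alts or ():
                carriers = [
                    s for s in samples
                    if any(a not in (None, 0) for a in (rec.samples[s].get("GT") or ()))
                ] or (samples[:1] if samples else ["sample0"])
                for sample in carriers:
                    raw.append((rec.chrom, rec.pos - 1, rec.ref, alt, sample))
    return raw


def read_and_filter_mutations(
    source, genome: GenomeSequence | None = None, fmt: str | None = None
) -> tuple[list[MutationRecord], FilterStats]:
    """Read somatic variants from MAF-lite TSV or VCF and keep SBS/1-bp indels.

    When ``genome`` is supplied, contexts are assigned and records on unknown
    chromosomes or with a reference mismatch are skipped (counted in the
    returned :class:`FilterStats`).
    """
    if fmt is None:
        name = str(getattr(source, "name", source)).lower()
        fmt = "vcf" if name.rstrip(".gz").endswith(".vcf") or name.endswith(".vcf.gz") else "maf"
    raw = _read_vcf(source) if fmt == "vcf" else _read_maf(source)
    stats = FilterStats()
    return _finalize(raw, genome, stats), stats


def write_maf(muts: list[MutationRecord], path) -> None:
    """Write records as MAF-lite TSV (1-based start, dash-style indels)."""
    import gzip

    path = Path(path)
    fh = gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")
    try:
        fh.write("\t".join(MAF_COLUMNS) + "\n")
        for m in muts:
            fh.write(
                f"{m.chrom}\t{m.pos + 1}\t{m.ref}\t{m.alt}\t{m.sample_id}\n"
            )
    finally:
        fh.close()


@dataclass
class TrinucleotideIndex:
    """Positions of a single-chromosome region grouped by 3-mer context.

    Every base of the region whose context is N-free appears under exactly
    one key; N-context bases (chromosome edges, assembly gaps) are absent.
    """

    region: RegionSet
    chrom: str
    context_to_positions: dict[str, np.ndarray]
    n_positions: int

    def positions(self, context: str) -> np.ndarray:
        return self.context_to_positions.get(context, np.empty(0, dtype=np.int64))


def build_context_index(genome: GenomeSequence, region: RegionSet) -> TrinucleotideIndex:
    """Index every N-free-context base of ``region`` by its trinucleotide."""
    from .regions import TRINUCLEOTIDES

    chroms = region.chroms
    if len(chroms) > 1:
        raise ValueError("context index requires a single-chromosome region")
    if not chroms:
        return TrinucleotideIndex(region, "", {}, 0)
    chrom = chroms[0]
    tcodes = genome.context_codes(chrom)
    starts, ends = region.arrays(chrom)
    pos_parts, code_parts = [], []
    for s, e in zip(starts.tolist(), ends.tolist()):
        codes = tcodes[s:e]
        keep = codes >= 0
        pos_parts.append(np.arange(s, e, dtype=np.int64)[keep])
        code_parts.append(codes[keep])
    positions = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
    codes = np.concatenate(code_parts) if code_parts else np.empty(0, np.int16)
    order = np.argsort(codes, kind="stable")
    positions, codes = positions[order], codes[order]
    mapping: dict[str, np.ndarray] = {}
    if len(codes):
        uniq, first = np.unique(codes, return_index=True)
        bounds = list(first) + [len(codes)]
        for code, lo, hi in zip(uniq.tolist(), bounds[:-1], bounds[1:]):
            mapping[TRINUCLEOTIDES[code]] = positions[lo:hi]
    return TrinucleotideIndex(region, chrom, mapping, int(len(positions)))


class ScoreTrack:
    """Base-level functional scores with explicit missingness.

    Backed by per-chromosome sorted position/value arrays; a position with
    no entry is *missing*, which is distinct from a score of 0.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray]], n_duplicates: int = 0):
        self._data = data
        self.n_duplicates = n_duplicates

    @classmethod
    def from_pairs(cls, entries, n_duplicates: int = 0) -> "ScoreTrack":
        """Build from an iterable of (chrom, pos, score); later entries win."""
        by_chrom: dict[str, dict[int, float]] = {}
        for chrom, pos, score in entries:
            by_chrom.setdefault(chrom, {})[int(pos)] = float(score)
        data = {}
        for chrom, mapping in by_chrom.items():
            positions = np.asarray(sorted(mapping), dtype=np.int64)
            values = np.asarray([mapping[p] for p in positions.tolist()])
            data[chrom] = (positions, values)
        return cls(data, n_duplicates)

    @classmethod
    def from_arrays(cls, chrom: str, positions: np.ndarray, values: np.ndarray) -> "ScoreTrack":
        order = np.argsort(positions)
        return cls({chrom: (np.asarray(positions)[order].astype(np.int64),
                            np.asarray(values, dtype=float)[order])})

    def get(self, chrom: str, pos: int):
        values, found = self.get_many(chrom, np.asarray([pos]))
        return float(values[0]) if found[0] else None

    def get_many(self, chrom: str, positions) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup: (values, found) with values undefined where not found."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._data:
            return np.zeros(len(positions)), np.zeros(len(positions), dtype=bool)
        pos_arr, val_arr = self._data[chrom]
        idx = np.searchsorted(pos_arr, positions)
        idx_c = np.clip(idx, 0, len(pos_arr) - 1)
        found = (idx < len(pos_arr)) & (pos_arr[idx_c] == positions)
        values = np.where(found, val_arr[idx_c], np.nan)
        return values, found

    @property
    def coverage(self) -> RegionSet:
        intervals = []
        for chrom, (positions, _) in self._data.items():
            if not len(positions):
                continue
            breaks = np.flatnonzero(np.diff(positions) > 1)
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(positions) - 1]))
            for s, e in zip(starts.tolist(), ends.tolist()):
                intervals.append(Interval(chrom, int(positions[s]), int(positions[e]) + 1))
        return RegionSet(intervals)


def read_score_track(source) -> ScoreTrack:
    """Read a TSV of (chrom, 1-based pos, score) into a :class:`ScoreTrack`.

    Duplicate positions keep the last value (counted and warned); a
    non-numeric score is a parse error reported with its line number.
    """
    handle, needs_close = open_text(source)
    try:
        df = pd.read_csv(
            handle, sep="\t", header=None, comment="#",
            names=["chrom", "pos", "score"], dtype={"chrom": str},
        )
    finally:
        if needs_close:
            handle.close()
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() & df["score"].notna()
    if bad.any():
        lineno = int(bad.idxmax()) + 1
        raise ValueError(f"non-numeric score at line {lineno}: {df['score'][bad.idxmax()]!r}")
    n_dup = int(df.duplicated(subset=["chrom", "pos"]).sum())
    if n_dup:
        log.warning("score track: %d duplicate position(s), keeping last", n_dup)
    track = ScoreTrack.from_pairs(
        zip(df["chrom"], df["pos"].astype(int) - 1, scores.astype(float)),
        n_duplicates=n_dup,
    )
    return track
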