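"""Self-contained synthetic fixtures: genome, annotation, scores, mutations.

The generator emulates the statistical structure the driver tests assume: a
random-sequence genome carrying regularly spaced multi-exon genes, a
base-level functional score track that is higher on exons (as deleteriousness
scores are on functional elements), and passenger mutations placed with
probability proportional to a trinucleotide signature — so that
context-preserving repositioning is the correct null model by construction.
Driver signal is planted on chosen genes either as extra exonic burden, as
preferential placement at high-score exonic bases, or both.

The default scale (1 Mb genome, 300 two-exon genes, 20 000 mutations from
50 samples) keeps a full cohort analysis at thousands of simulations within
desk-scale runtimes while leaving roughly a dozen exonic mutations per gene,
enough for near-continuous empirical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np

from .mutations import MutationRecord, ScoreTrack, SBS, write_maf
from .regions import (
    GeneModel,
    GenomeSequence,
    Interval,
    RegionSet,
    TRINUCLEOTIDES,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate_reference",
    "simulate_null_mutations",
    "plant_driver",
    "generate_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study.

    ``signature`` maps 3-mers to non-negative mutation propensities (flat
    when ``None``); ``driver_plan`` lists (gene_id, mode, fold_effect) with
    mode one of ``burden``/``impact``/``both``; ``score_model`` is
    (exonic mean, background mean, sd) of the Normal score distributions.
    """

    genome_length: int = 1_000_000
    n_genes: int = 300
    exons_per_gene: int = 2
    exon_len: int = 500
    intron_len: int = 1_000
    intergenic_len: int = 1_200
    gc_fraction: float = 0.41
    signature: dict[str, float] | None = None
    n_mutations: int = 20_000
    n_samples: int = 50
    driver_plan: list[tuple[str, str, float]] = field(default_factory=list)
    score_model: tuple[float, float, float] = (10.0, 3.0, 4.0)
    tau: float = 1.0  # softmax temperature for impact-mode placement
    seed: int = 1
    chrom: str = "chr1"
    include_overlap_pair: bool = False

    @property
    def span_len(self) -> int:
        return self.exons_per_gene * self.exon_len + (self.exons_per_gene - 1) * self.intron_len

    @property
    def cell_len(self) -> int:
        return self.intergenic_len + self.span_len

    def validate(self) -> None:
        need = self.n_genes * self.cell_len + self.intergenic_len
        if need > self.genome_length:
            raise ValueError(
                f"{self.n_genes} genes need {need} bp, genome is {self.genome_length} bp"
            )
        if self.signature is not None:
            if any(w < 0 for w in self.signature.values()):
                raise ValueError("signature weights must be >= 0")
            if not any(w > 0 for w in self.signature.values()):
                raise ValueError("signature needs at least one positive weight")
        for _, mode, fold in self.driver_plan:
            if mode not in ("burden", "impact", "both"):
                raise ValueError(f"unknown driver mode {mode!r}")
            if fold < 1:
                raise ValueError("fold_effect must be >= 1")


@dataclass
class SyntheticDataset:
    """A complete in-memory study: reference, annotation, scores, mutations."""

    spec: SyntheticSpec
    genome: GenomeSequence
    genes: list[GeneModel]
    all_exons: RegionSet
    scores: ScoreTrack
    mask: RegionSet
    mutations: list[MutationRecord]
    truth: list[str]

    def gtf_text(self) -> str:
        lines = []
        for gene in self.genes:
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}"; '
                f'gene_type "{gene.biotype}";'
            )
            lines.append(
                f"{gene.chrom}\tsynthetic\tgene\t{gene.span.start + 1}\t{gene.span.end}"
                f"\t.\t{gene.strand}\t.\t{attrs}"
            )
            tid = f"{gene.gene_id}.t1"
            tattrs = attrs + f' transcript_id "{tid}";'
            lines.append(
                f"{gene.chrom}\tsynthetic\ttranscript\t{gene.span.start + 1}\t{gene.span.end}"
                f"\t.\t{gene.strand}\t.\t{tattrs}"
            )
            for iv in gene.exonic.intervals():
                lines.append(
                    f"{iv.chrom}\tsynthetic\texon\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{gene.strand}\t.\t{tattrs}"
                )
        return "\n".join(lines) + "\n"

    def fasta_text(self, width: int = 60) -> str:
        chunks = []
        for chrom in self.genome.chrom_names:
            seq = self.genome.fetch(chrom, 0, self.genome.length(chrom))
            body = "\n".join(seq[i : i + width] for i in range(0, len(seq), width))
            chunks.append(f">{chrom}\n{body}\n")
        return "".join(chunks)

    def write(self, outdir) -> dict[str, Path]:
        """Emit ref.fa, genes.gtf, scores.tsv.gz, mask.bed, muts.maf.gz, truth.txt."""
        import gzip

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "ref.fa",
            "gtf": outdir / "genes.gtf",
            "scores": outdir / "scores.tsv.gz",
            "mask": outdir / "mask.bed",
            "mutations": outdir / "muts.maf.gz",
            "truth": outdir / "truth.txt",
        }
        paths["fasta"].write_text(self.fasta_text())
        paths["gtf"].write_text(self.gtf_text())
        with gzip.open(paths["scores"], "wt") as fh:
            for chrom in self.genome.chrom_names:
                positions, values = self.scores._data.get(chrom, ((), ()))
                for pos, val in zip(np.asarray(positions).tolist(), np.asarray(values).tolist()):
                    fh.write(f"{chrom}\t{pos + 1}\t{val:.4f}\n")
        with open(paths["mask"], "w") as fh:
            for iv in self.mask.intervals():
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        write_maf(self.mutations, paths["mutations"])
        paths["truth"].write_text("".join(f"{g}\n" for g in self.truth))
        return paths


def _signature_array(spec: SyntheticSpec) -> np.ndarray:
    if spec.signature is None:
        return np.ones(64)
    return np.asarray([float(spec.signature.get(t, 0.0)) for t in TRINUCLEOTIDES])


def _position_weights(genome: GenomeSequence, chrom: str, sig: np.ndarray) -> np.ndarray:
    tcodes = genome.context_codes(chrom)
    w = np.zeros(len(tcodes))
    valid = tcodes >= 0
    w[valid] = sig[tcodes[valid]]
    return w


def generate_reference(
    spec: SyntheticSpec,
) -> tuple[GenomeSequence, list[GeneModel], RegionSet, ScoreTrack, RegionSet]:
    """Deterministically build genome, gene models, score track and mask."""
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    p = np.array(
        [(1 - spec.gc_fraction) / 2, spec.gc_fraction / 2,
         spec.gc_fraction / 2, (1 - spec.gc_fraction) / 2]
    )
    draws = rng.choice(4, size=spec.genome_length, p=p)
    sequence = _BASES[draws].tobytes().decode("ascii")
    genome = GenomeSequence({spec.chrom: sequence})

    genes: list[GeneModel] = []
    for i in range(spec.n_genes):
        start = spec.intergenic_len + i * spec.cell_len
        exons = []
        cursor = start
        for _ in range(spec.exons_per_gene):
            exons.append(Interval(spec.chrom, cursor, cursor + spec.exon_len))
            cursor += spec.exon_len + spec.intron_len
        span = Interval(spec.chrom, start, start + spec.span_len)
        genes.append(
            GeneModel(
                gene_id=f"G{i:04d}",
                gene_name=f"G{i:04d}",
                chrom=spec.chrom,
                strand="+" if i % 2 == 0 else "-",
                span=span,
                exonic=RegionSet(exons),
                biotype="lncRNA",
            )
        )
    if spec.include_overlap_pair:
        # a protein-coding gene overlapping the first gene's span, to
        # exercise the annotation overlap filter on round-trip
        first = genes[0]
        start = first.span.start + spec.exon_len // 2
        end = start + spec.exon_len
        genes.append(
            GeneModel(
                gene_id="PCOVER",
                gene_name="PCOVER",
                chrom=spec.chrom,
                strand="+",
                span=Interval(spec.chrom, start, end),
                exonic=RegionSet.single(spec.chrom, start, end),
                biotype="protein_coding",
            )
        )
    all_exons = RegionSet(iv for g in genes for iv in g.exonic.intervals())

    rng_scores = np.random.default_rng([spec.seed, 1])
    exon_mean, bg_mean, sd = spec.score_model
    values = rng_scores.normal(bg_mean, sd, spec.genome_length)
    exonic_mask = np.zeros(spec.genome_length, dtype=bool)
    for iv in all_exons.intervals():
        exonic_mask[iv.start : iv.end] = True
    values[exonic_mask] = rng_scores.normal(exon_mean, sd, int(exonic_mask.sum()))
    scores = ScoreTrack.from_arrays(
        spec.chrom, np.arange(spec.genome_length, dtype=np.int64), values
    )
    return genome, genes, all_exons, scores, RegionSet()


def simulate_null_mutations(
    genome: GenomeSequence,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> list[MutationRecord]:
    """Draw passenger SBS with position probability ∝ signature(context)."""
    spec.validate()
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 2])
    sig = _signature_array(spec)
    weights = _position_weights(genome, spec.chrom, sig)
    total = weights.sum()
    if total <= 0:
        raise ValueError("signature assigns zero weight to every genome position")
    cum = np.cumsum(weights)
    positions = np.searchsorted(cum, rng.random(spec.n_mutations) * total, side="right")
    return _records_at(genome, spec, positions, rng,
                       samples=[f"S{i % spec.n_samples:03d}" for i in range(spec.n_mutations)])


def _records_at(genome, spec, positions, rng, samples) -> list[MutationRecord]:
    tcodes = genome.context_codes(spec.chrom)
    base_codes = genome.base_codes(spec.chrom)
    alt_offsets = rng.integers(1, 4, len(positions))  # 1..3 cyclic shift off ref
    records = []
    for pos, off, sample in zip(np.asarray(positions).tolist(), alt_offsets.tolist(), samples):
        ref_code = int(base_codes[pos])
        alt_code = (ref_code + off) % 4
        records.append(
            MutationRecord(
                chrom=spec.chrom,
                pos=int(pos),
                ref="ACGT"[ref_code],
                alt="ACGT"[alt_code],
                sample_id=sample,
                mut_class=SBS,
                context=TRINUCLEOTIDES[tcodes[pos]] if tcodes[pos] >= 0 else "NNN",
            )
        )
    return records


def _exonic_arrays(genome, spec, gene, sig, scores):
    tcodes = genome.context_codes(spec.chrom)
    pos_parts = []
    for iv in gene.exonic.intervals():
        part = np.arange(iv.start, iv.end, dtype=np.int64)
        pos_parts.append(part[tcodes[iv.start : iv.end] >= 0])
    positions = np.concatenate(pos_parts)
    weights = sig[tcodes[positions]]
    score_values, found = scores.get_many(spec.chrom, positions)
    score_values = np.where(found, score_values, -np.inf)
    return positions, weights, score_values


def plant_driver(
    muts: list[MutationRecord],
    gene: GeneModel,
    mode: str,
    fold_effect: float,
    scores: ScoreTrack,
    spec: SyntheticSpec,
    genome: GenomeSequence,
    rng: np.random.Generator | None = None,
) -> list[MutationRecord]:
    """Plant positive-selection signal on ``gene`` and return the new dataset.

    ``burden`` multiplies the gene's expected exonic count by ``fold_effect``
    with extra signature-respecting exonic mutations; ``impact`` repositions
    the gene's existing exonic mutations towards high-score exonic bases
    (placement weight ∝ exp(score/tau)) without changing the count; ``both``
    does both, placing the extra mutations score-preferentially as well.
    """
    if fold_effect < 1:
        raise ValueError("fold_effect must be >= 1")
    if mode not in ("burden", "impact", "both"):
        raise ValueError(f"unknown driver mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 3])
    sig = _signature_array(spec)
    ex_pos, ex_w, ex_scores = _exonic_arrays(genome, spec, gene, sig, scores)
    if ex_w.sum() <= 0:
        raise ValueError(f"gene {gene.gene_id} has no mutable exonic positions")

    finite = np.isfinite(ex_scores)
    shifted = np.where(finite, ex_scores - ex_scores[finite].max(), -np.inf)
    impact_w = np.where(finite, np.exp(shifted / spec.tau), 0.0)

    def draw(weights: np.ndarray, n: int) -> np.ndarray:
        cum = np.cumsum(weights)
        return ex_pos[np.searchsorted(cum, rng.random(n) * cum[-1], side="right")]

    out = list(muts)
    if mode in ("burden", "both"):
        total_w = _position_weights(genome, spec.chrom, sig).sum()
        expected = spec.n_mutations * ex_w.sum() / total_w
        n_extra = int(round((fold_effect - 1) * expected))
        placement = impact_w if mode == "both" else ex_w
        new_pos = draw(placement, n_extra)
        samples = [f"S{int(s):03d}" for s in rng.integers(0, spec.n_samples, n_extra)]
        out.extend(_records_at(genome, spec, new_pos, rng, samples))
    if mode in ("impact", "both"):
        members = gene.exonic.contains_many(
            spec.chrom, np.asarray([m.pos for m in out], dtype=np.int64)
        )
        moved = []
        for keep, m in zip(members, out):
            if not keep or m.chrom != spec.chrom:
                moved.append(m)
                continue
            new = int(draw(impact_w, 1)[0])
            moved.extend(_records_at(genome, spec, [new], rng, [m.sample_id]))
        out = moved
    return out


def generate_cohort(spec: SyntheticSpec) -> SyntheticDataset:
    """Reference + null mutations + planted drivers, all from ``spec.seed``."""
    genome, genes, all_exons, scores, mask = generate_reference(spec)
    mutations = simulate_null_mutations(genome, spec)
    by_id = {g.gene_id: g for g in genes}
    rng = np.random.default_rng([spec.seed, 3])
    truth = []
    for gene_id, mode, fold in spec.driver_plan:
        if gene_id not in by_id:
            raise KeyError(f"driver plan names unknown gene {gene_id!r}")
        mutations = plant_driver(
            mutations, by_id[gene_id], mode, fold, scores, spec, genome, rng
        )
        truth.append(gene_id)
    return SyntheticDataset(
        spec=spec,
        genome=genome,
        genes=[g for g in genes if g.biotype != "protein_coding"],
        all_exons=all_exons,
        scores=scores,
        mask=mask,
        mutations=mutations,
        truth=truth,
    )
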