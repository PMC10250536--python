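"""Cohort-level modelling interface: build a model from data, fit, inspect.

:class:`DriverDiscoveryModel` bundles a cohort's mutations, gene models,
reference genome, score track and mask; :meth:`~DriverDiscoveryModel.fit`
runs the recurrence and functional-impact repositioning tests for every
gene and returns a :class:`DriverDiscoveryResults` carrying the per-gene
result table, calibration diagnostics and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import CalibrationReport, calibration_report, qq_table
from .engine import GeneResult, SimulationConfig, run_cohort
from .mutations import (
    MutationRecord,
    ScoreTrack,
    read_and_filter_mutations,
    read_score_track,
)
from .regions import (
    GeneModel,
    GenomeSequence,
    RegionSet,
    load_gene_models,
    read_bed,
    read_coding_potential,
)

__all__ = ["DriverDiscoveryModel", "DriverDiscoveryResults"]

RESULT_COLUMNS = [
    "gene_id",
    "n_exonic_obs",
    "n_background_obs",
    "mean_fi_obs",
    "p_re",
    "p_fi",
    "fisher_T",
    "p_combined",
    "q_value",
    "flags",
]


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class DriverDiscoveryModel:
    """Driver-element discovery over a cohort of tumour genomes.

    Parameters
    ----------
    mutations
        Somatic variants (SBS and 1-bp indels) with trinucleotide contexts.
    genes
        Gene models with exonic regions; backgrounds are built at fit time
        from ``all_exons``, ``mask`` and ``flank_bp`` when absent.
    genome
        Reference sequence the contexts and repositioning draw from.
    scores
        Base-level functional score track (CADD-style); without it only the
        burden test is informative and p_fi is fixed at 1.
    """

    def __init__(
        self,
        mutations: Sequence[MutationRecord],
        genes: Sequence[GeneModel],
        genome: GenomeSequence,
        scores: ScoreTrack | None = None,
        mask: RegionSet | None = None,
        all_exons: RegionSet | None = None,
        flank_bp: int = 10_000,
    ):
        self.mutations = list(mutations)
        self.genes = list(genes)
        self.genome = genome
        self.scores = scores
        self.mask = mask
        self.all_exons = all_exons
        self.flank_bp = flank_bp
        self._file_info: dict[str, dict] = {}

    @classmethod
    def from_files(
        cls,
        mutations,
        annotation,
        fasta,
        scores=None,
        mask=None,
        coding_potential=None,
        allowed_biotypes: set[str] | None = None,
        overlap_filter: bool = True,
        overlap_mode: str = "span",
        flank_bp: int = 10_000,
    ) -> "DriverDiscoveryModel":
        """Assemble a model from MAF/VCF, GTF, FASTA, score TSV and BED mask."""
        genome = GenomeSequence.from_fasta(fasta)
        cp = read_coding_potential(coding_potential) if coding_potential else None
        ann = load_gene_models(
            annotation,
            allowed_biotypes=allowed_biotypes,
            coding_potential=cp,
            overlap_filter=overlap_filter,
            overlap_mode=overlap_mode,
            genome=genome,
            flank_bp=flank_bp,
        )
        muts, stats = read_and_filter_mutations(mutations, genome=genome)
        track = read_score_track(scores) if scores else None
        mask_set = read_bed(mask) if mask else None
        model = cls(
            muts, ann.genes, genome, scores=track, mask=mask_set,
            all_exons=ann.all_exons, flank_bp=flank_bp,
        )
        model._file_info = {
            "inputs": {
                name: {"path": str(p), "sha256": _sha256(p)}
                for name, p in (
                    ("mutations", mutations), ("annotation", annotation),
                    ("fasta", fasta), ("scores", scores), ("mask", mask),
                    ("coding_potential", coding_potential),
                )
                if p
            },
            "mutation_filter": {
                "n_input": stats.n_input,
                "n_kept": stats.n_kept,
                "dropped": dict(stats.dropped),
            },
            "annotation": {
                "n_parsed": ann.n_parsed,
                "n_kept": len(ann.genes),
                "dropped": {k: len(v) for k, v in ann.dropped.items()},
            },
        }
        return model

    def fit(
        self,
        n_simulations: int = 10_000,
        seed: int = 1,
        pseudocount: str = "add_one",
    ) -> "DriverDiscoveryResults":
        """Run the repositioning tests for every gene in the cohort."""
        cfg = SimulationConfig(
            n_simulations=n_simulations, seed=seed, pseudocount_mode=pseudocount
        )
        results, manifest = run_cohort(
            self.genes,
            self.mutations,
            self.genome,
            scores=self.scores,
            mask=self.mask,
            cfg=cfg,
            flank_bp=self.flank_bp,
            all_exons=self.all_exons,
        )
        manifest = {"tool": "driverscan", "version": __version__, **manifest}
        manifest.update(self._file_info)
        return DriverDiscoveryResults(self, results, cfg, manifest)


class DriverDiscoveryResults:
    """Fitted per-gene results with diagnostics and export helpers."""

    def __init__(
        self,
        model: DriverDiscoveryModel,
        results: list[GeneResult],
        cfg: SimulationConfig,
        manifest: dict,
    ):
        self.model = model
        self.gene_results = results
        self.cfg = cfg
        self.manifest = manifest

    @property
    def table(self) -> pd.DataFrame:
        """Per-gene result table sorted by combined p-value."""
        rows = [
            {
                "gene_id": r.gene_id,
                "n_exonic_obs": r.n_exonic_obs,
                "n_background_obs": r.n_background_obs,
                "mean_fi_obs": r.mean_fi_obs,
                "p_re": r.p_re,
                "p_fi": r.p_fi,
                "fisher_T": r.fisher_T,
                "p_combined": r.p_combined,
                "q_value": r.q_value,
                "flags": ",".join(sorted(r.flags)),
            }
            for r in self.gene_results
        ]
        df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        return df.sort_values(
            ["p_combined", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)

    def hits(self, q_cutoff: float = 0.1) -> list[str]:
        """Gene ids called at ``q <= q_cutoff``."""
        return sorted(
            r.gene_id for r in self.gene_results if r.tested and r.q_value <= q_cutoff
        )

    def pvalues(self, which: str = "p_combined") -> np.ndarray:
        """P-values of the tested genes (NA-free input for calibration)."""
        return np.asarray(
            [getattr(r, which) for r in self.gene_results if r.tested], dtype=float
        )

    def calibration(self, which: str = "p_combined", literal: bool = False) -> CalibrationReport:
        """Observed-vs-uniform calibration of the tested genes' p-values."""
        return calibration_report(self.pvalues(which), literal=literal)

    def qq_table(self, which: str = "p_combined") -> pd.DataFrame:
        return qq_table(self.pvalues(which))

    def plot_qq(self, which: str = "p_combined", ax=None):
        """QQ plot of observed vs expected -log10 p-values."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        qq = self.qq_table(which)
        ax.scatter(qq["expected_neglog10"], qq["observed_neglog10"], s=8)
        lim = max(qq["expected_neglog10"].max(), qq["observed_neglog10"].max(), 1.0)
        ax.plot([0, lim], [0, lim], lw=1, color="grey")
        ax.set_xlabel(r"expected $-\log_{10} P$")
        ax.set_ylabel(r"observed $-\log_{10} P$")
        ax.set_title(f"QQ ({which}), MLFC={self.calibration(which).mlfc:.3f}")
        return ax

    def summary(self, q_cutoff: float = 0.1, top: int = 10) -> str:
        """Human-readable overview: cohort counts, calibration, top genes."""
        cal = self.calibration()
        n_hits = len(self.hits(q_cutoff))
        df = self.table.head(top)
        lines = [
            "Driver discovery results",
            "=" * 60,
            f"genes tested:      {self.manifest.get('n_tested')} / {self.manifest.get('n_genes')}",
            f"mutations:         {self.manifest.get('n_mutations')}",
            f"simulations:       {self.cfg.n_simulations} (seed {self.cfg.seed})",
            f"hits (q <= {q_cutoff:g}): {n_hits}",
            f"MLFC (combined p): {cal.mlfc:.4f} over {cal.n} genes",
            "-" * 60,
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
                columns=[c for c in RESULT_COLUMNS if c != "flags"],
            ),
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        """Write the result table as TSV with a commented header."""
        df = self.table
        with open(path, "w") as fh:
            fh.write(f"# driverscan {__version__} results\n")
            fh.write("# columns: " + "\t".join(df.columns) + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    def write_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
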