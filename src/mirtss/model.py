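"""Model-level interface: build a promoter model from tracks + annotations,
fit it, inspect the fit, and scan miRNAs.

``MirnaPromoterModel`` bundles the data (binned RPM tracks, gene annotation,
genome table) and the study design (window half-width ``k``, number of random
negatives, SVM grid).  ``fit()`` assembles the labelled profile matrix
(protein-coding TSSs as positives, uniform random positions as negatives),
splits it in half, tunes and trains the RBF-SVM on one half and evaluates the
held-out ROC on the other, returning a :class:`MirnaPromoterResults` that
carries the trained classifier, its diagnostics, and the downstream scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import GenomeTable, TranscriptAnnotation, tss_of
from .classifier import (
    RocResult,
    SvmConfig,
    TrainedClassifier,
    predict_scores,
    roc_auc,
    split_half,
    train_svm,
)
from .coverage import BinnedTrack, read_bed_reads, track_from_reads
from .profiles import Anchor, MeanProfile, build_matrix, mean_profile, sample_random_anchors
from .tss_scan import ScanOutput, distance_summaries, scan_mirnas

__all__ = ["MirnaPromoterModel", "MirnaPromoterResults"]


class MirnaPromoterModel:
    """Histone-mark promoter model for miRNA TSS identification.

    Parameters
    ----------
    tracks
        Mapping mark name -> :class:`~mirtss.coverage.BinnedTrack` (RPM).
    genes
        Protein-coding annotations; their TSSs are the positive training
        anchors.
    genome
        Chromosome-length table.
    k
        Bins per side of each anchor (features span ``2 k`` bins per mark).
    n_random
        Number of uniform random negative anchors.
    exclude_near_tss
        Optional distance (bp); negatives closer than this to any gene TSS
        are rejected.  Default keeps plain uniform sampling.
    n_positive
        Optional subsample size of gene TSS anchors (all genes by default).
    svm
        :class:`~mirtss.classifier.SvmConfig` grid-search settings.
    seed
        Seed for negative sampling, the train/test split and CV folds.
    """

    def __init__(
        self,
        tracks: dict[str, BinnedTrack],
        genes: Sequence[TranscriptAnnotation],
        genome: GenomeTable,
        *,
        k: int = 10,
        n_random: int = 10_000,
        exclude_near_tss: int | None = None,
        n_positive: int | None = None,
        marks: Sequence[str] | None = None,
        svm: SvmConfig | None = None,
        seed: int = 0,
    ):
        self.tracks = dict(tracks)
        self.genes = list(genes)
        self.genome = genome
        self.k = k
        self.n_random = n_random
        self.exclude_near_tss = exclude_near_tss
        self.n_positive = n_positive
        self.marks = list(self.tracks) if marks is None else list(marks)
        self.svm = svm or SvmConfig(seed=seed)
        self.seed = seed
        self.bin_size = next(iter(self.tracks.values())).bin_size

    @classmethod
    def from_files(
        cls,
        mark_beds: dict[str, str],
        genes_gff3,
        sizes_tsv,
        *,
        bin_size: int = 100,
        **kwargs,
    ) -> "MirnaPromoterModel":
        """Build the model from per-mark BED6 alignments, GFF3 and sizes TSV."""
        from .annotation_io import read_annotations, read_genome_table

        genome = read_genome_table(sizes_tsv)
        tracks = {
            mark: track_from_reads(read_bed_reads(path, mark), genome, bin_size=bin_size)
            for mark, path in mark_beds.items()
        }
        genes = read_annotations(genes_gff3, "protein_coding")
        return cls(tracks, genes, genome, **kwargs)

    # ------------------------------------------------------------------

    def positive_anchors(self) -> list[Anchor]:
        anchors = [
            Anchor(g.id, g.interval.chrom, tss_of(g), g.interval.strand)
            for g in self.genes
            if g.interval.strand in ("+", "-")
        ]
        if self.n_positive is not None and self.n_positive < len(anchors):
            rng = np.random.default_rng(self.seed)
            idx = rng.choice(len(anchors), size=self.n_positive, replace=False)
            anchors = [anchors[i] for i in np.sort(idx)]
        return anchors

    def negative_anchors(self) -> list[Anchor]:
        exclusion = None
        dist = 0
        if self.exclude_near_tss:
            exclusion = [(a.chrom, a.position) for a in self.positive_anchors()]
            dist = self.exclude_near_tss
        return sample_random_anchors(
            self.genome,
            self.n_random,
            np.random.default_rng(self.seed + 1),
            exclusion=exclusion,
            exclusion_dist=dist,
        )

    def build_training_matrix(self):
        pos = self.positive_anchors()
        neg = self.negative_anchors()
        return build_matrix(
            self.tracks,
            pos + neg,
            labels=[1] * len(pos) + [-1] * len(neg),
            k=self.k,
            marks=self.marks,
        )

    def fit(self) -> "MirnaPromoterResults":
        """Train the SVM on a stratified half and evaluate on the other."""
        matrix = self.build_training_matrix()
        train, test = split_half(matrix, seed=self.seed)
        classifier = train_svm(train, self.svm)
        scores, _ = predict_scores(classifier, test)
        roc = roc_auc(scores, test.y)
        return MirnaPromoterResults(
            model=self, classifier=classifier, roc=roc, n_train=train.n, n_test=test.n
        )

    def mean_profile(self, mark: str, W: int = 2000) -> MeanProfile:
        """Metagene RPM profile of one mark around the gene TSS anchors."""
        return mean_profile(self.tracks, self.positive_anchors(), mark, W=W)


@dataclass
class MirnaPromoterResults:
    """A fitted promoter model with held-out diagnostics."""

    model: MirnaPromoterModel
    classifier: TrainedClassifier
    roc: RocResult
    n_train: int
    n_test: int

    @property
    def auc(self) -> float:
        return self.roc.auc

    @property
    def params(self) -> dict[str, float]:
        return {"C": self.classifier.C, "gamma": self.classifier.gamma}

    def predict(self, anchors: Sequence[Anchor]) -> pd.DataFrame:
        """Decision scores and probabilities at arbitrary anchors."""
        matrix = build_matrix(
            self.model.tracks, anchors, k=self.model.k, marks=self.model.marks
        )
        scores, probs = predict_scores(self.classifier, matrix)
        return pd.DataFrame(
            {
                "id": [a.id for a in anchors],
                "chrom": [a.chrom for a in anchors],
                "position": [a.position for a in anchors],
                "strand": [a.strand for a in anchors],
                "score": scores,
                "probability": probs,
            }
        )

    def scan(
        self,
        mirnas: Sequence[TranscriptAnnotation],
        *,
        max_upstream: int = 10_000,
        fdr: float = 0.1,
        shared_tol: int = 100,
        n_decoys: int = 10_000,
        decoy_exclusion: int = 2000,
        refine_window: int = 300,
        seed: int | None = None,
    ) -> ScanOutput:
        """Upstream FDR-controlled TSS scan of a miRNA annotation set."""
        return scan_mirnas(
            self.classifier,
            self.model.tracks,
            mirnas,
            self.model.genes,
            self.model.genome,
            marks=self.model.marks,
            k=self.model.k,
            bin_size=self.model.bin_size,
            max_upstream=max_upstream,
            fdr=fdr,
            shared_tol=shared_tol,
            n_decoys=n_decoys,
            decoy_exclusion=decoy_exclusion,
            refine_window=refine_window,
            seed=self.model.seed + 2 if seed is None else seed,
        )

    def distance_summaries(self, mirnas, calls=None):
        return distance_summaries(mirnas, self.model.genes, calls)

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        lines = [
            "miRNA promoter model (RBF-SVM on binned histone RPM profiles)",
            "=" * 62,
            f"marks:              {len(m.marks)} ({', '.join(m.marks)})",
            f"features:           {len(m.marks)} x {2 * m.k} bins of {m.bin_size} bp",
            f"training rows:      {self.n_train} (held-out {self.n_test})",
            f"selected C:         {self.classifier.C:g}",
            f"selected gamma:     {self.classifier.gamma:g}",
            f"CV accuracy:        {self.classifier.cv_accuracy:.3f}",
            f"held-out AUC:       {self.auc:.3f}",
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the held-out evaluation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc.fpr, self.roc.tpr, label=f"AUC = {self.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right")
        return ax
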