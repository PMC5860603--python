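"""Annotation evaluation: per-label goodness of fit and TSS discrimination.

Two complementary views of annotation quality:

1. *Distribution fit.* For each label, the empirical distribution of the
   signal datapoints assigned to it is compared with the model's
   theoretical mixture distribution using the one-sample
   Kolmogorov-Smirnov statistic D (smaller D = closer fit), plus
   quantile-quantile point export for plotting.

2. *TSS discrimination.* Treating each label's segments as predictions of
   active transcription start sites: positives are TSSs with external
   activity support (e.g. CAGE), negatives are TSSs without. Per label,
   precision = TP/(TP+FP) over the TSSs its segments overlap and recall =
   TP over all positives; the label with the best precision is selected
   and its recall reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import label_signal_sample
from .genome import Annotation, GenomicInterval
from .model import ModelParams, mixture_cdf
from .signal_io import BinnedGenome

__all__ = [
    "KSResult",
    "FitSummary",
    "TSSEval",
    "ks_statistic",
    "label_fit_report",
    "qq_points",
    "tss_precision_recall",
    "most_upstream_tss",
]


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov fit
# ---------------------------------------------------------------------------

@dataclass
class KSResult:
    label: int
    track: int
    D: float
    n: int


@dataclass
class FitSummary:
    """Per-label D statistics plus mean/median/best across labels."""

    results: list[KSResult]
    mean_D: float
    median_D: float
    best_D: float
    best_label: int
    skipped_labels: list[int] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "label": [r.label for r in self.results],
                "track": [r.track for r in self.results],
                "D": [r.D for r in self.results],
                "n": [r.n for r in self.results],
            }
        )


def ks_statistic(sample: np.ndarray, cdf) -> float:
    """One-sample KS statistic: sup distance between the empirical CDF of
    ``sample`` and the theoretical ``cdf``.

    D = max over order statistics x_(i) of
    max(i/n - F(x_(i)), F(x_(i)) - (i-1)/n).
    """
    x = np.sort(np.asarray(sample, dtype=np.float64))
    n = x.size
    if n == 0:
        raise ValueError("KS statistic of an empty sample")
    F = np.asarray(cdf(x), dtype=np.float64)
    i = np.arange(1, n + 1)
    d_plus = (i / n - F).max()
    d_minus = (F - (i - 1) / n).max()
    return float(max(d_plus, d_minus))


def label_fit_report(
    annotation: Annotation,
    binned: BinnedGenome,
    params: ModelParams,
    *,
    track: int = 0,
    max_sample: int | None = None,
    seed: int = 0,
) -> FitSummary:
    """Per-label KS D between the empirical label-conditional signal
    distribution and the model's theoretical mixture, on one track.

    All datapoints of a label are used by default (bins weighted
    equally); ``max_sample`` caps the per-label sample (uniform
    subsample, seeded) for speed. Labels with no datapoints are skipped
    and reported.
    """
    results: list[KSResult] = []
    skipped: list[int] = []
    rng = np.random.default_rng(seed)
    for label in range(params.n_labels):
        sample = label_signal_sample(annotation, binned, track, label)
        if sample.size == 0:
            skipped.append(label)
            continue
        if max_sample is not None and sample.size > max_sample:
            sample = rng.choice(sample, size=max_sample, replace=False)
        D = ks_statistic(sample, lambda x: mixture_cdf(params.emission, label, track, x))
        results.append(KSResult(label=label, track=track, D=D, n=int(sample.size)))
    if not results:
        raise ValueError("no label has any datapoints on this track")
    ds = np.array([r.D for r in results])
    best_idx = int(np.argmin(ds))
    return FitSummary(
        results=results,
        mean_D=float(ds.mean()),
        median_D=float(np.median(ds)),
        best_D=float(ds[best_idx]),
        best_label=results[best_idx].label,
        skipped_labels=skipped,
    )


def qq_points(sample: np.ndarray, quantile_fn, num_points: int = 100) -> np.ndarray:
    """Paired (theoretical, empirical) quantiles at probabilities
    (i - 0.5)/num_points; a perfect fit puts every point on the identity
    line."""
    sample = np.asarray(sample, dtype=np.float64)
    if sample.size == 0:
        raise ValueError("QQ points of an empty sample")
    probs = (np.arange(1, num_points + 1) - 0.5) / num_points
    theo = np.array([quantile_fn(p) for p in probs])
    emp = np.quantile(sample, probs)
    return np.column_stack([theo, emp])


# ---------------------------------------------------------------------------
# TSS precision / recall
# ---------------------------------------------------------------------------

@dataclass
class TSSEval:
    """Per-label TSS discrimination counts and the best-precision label."""

    tp: dict[int, int]
    fp: dict[int, int]
    fn: dict[int, int]
    precision: dict[int, float]
    recall: dict[int, float]
    best_label: int
    best_precision: float
    best_label_recall: float
    uncovered_positives: int = 0
    uncovered_negatives: int = 0

    def to_dataframe(self):
        import pandas as pd

        labels = sorted(self.tp)
        return pd.DataFrame(
            {
                "label": labels,
                "TP": [self.tp[l] for l in labels],
                "FP": [self.fp[l] for l in labels],
                "FN": [self.fn[l] for l in labels],
                "precision": [self.precision[l] for l in labels],
                "recall": [self.recall[l] for l in labels],
            }
        )


def _locate(annotation: Annotation, positions: list[GenomicInterval]) -> list[int | None]:
    """Label of the segment overlapping each single-base position, or None."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {iv.chrom for iv, _ in annotation.segments}:
        segs = [(iv.start, iv.end, lab) for iv, lab in annotation.segments if iv.chrom == chrom]
        starts = np.array([s for s, _, _ in segs])
        ends = np.array([e for _, e, _ in segs])
        labs = np.array([l for _, _, l in segs])
        by_chrom[chrom] = (starts, ends, labs)
    out: list[int | None] = []
    for iv in positions:
        hit: int | None = None
        if iv.chrom in by_chrom:
            starts, ends, labs = by_chrom[iv.chrom]
            j = int(np.searchsorted(starts, iv.start, side="right")) - 1
            if j >= 0 and iv.start < ends[j]:
                hit = int(labs[j])
        out.append(hit)
    return out


def tss_precision_recall(
    annotation: Annotation,
    positives: list[GenomicInterval],
    negatives: list[GenomicInterval],
) -> TSSEval:
    """Score every label as a predictor of active TSSs.

    ``positives``/``negatives`` are single-base TSS positions already
    reduced to one (most upstream) TSS per gene — see
    :func:`most_upstream_tss`. For each label: TP = positives overlapped
    by its segments, FP = negatives overlapped, FN = positives overlapped
    by *other* labels. TSSs outside the annotated genome are counted as
    uncovered and reported, never silently dropped.
    """
    pos_labels = _locate(annotation, positives)
    neg_labels = _locate(annotation, negatives)
    labels = annotation.labels_present()
    covered_pos = [l for l in pos_labels if l is not None]
    tp = {l: sum(1 for p in covered_pos if p == l) for l in labels}
    fp = {l: sum(1 for p in neg_labels if p == l) for l in labels}
    fn = {l: len(covered_pos) - tp[l] for l in labels}
    precision = {
        l: tp[l] / (tp[l] + fp[l]) if tp[l] + fp[l] > 0 else np.nan for l in labels
    }
    recall = {
        l: tp[l] / (tp[l] + fn[l]) if tp[l] + fn[l] > 0 else np.nan for l in labels
    }
    defined = [l for l in labels if not np.isnan(precision[l])]
    if defined:
        best = min(defined, key=lambda l: (-precision[l], l))
        best_p, best_r = precision[best], recall[best]
    else:
        best, best_p, best_r = -1, np.nan, np.nan
    return TSSEval(
        tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
        best_label=best, best_precision=float(best_p), best_label_recall=float(best_r),
        uncovered_positives=sum(1 for l in pos_labels if l is None),
        uncovered_negatives=sum(1 for l in neg_labels if l is None),
    )


def most_upstream_tss(genes) -> list[GenomicInterval]:
    """Reduce gene bodies to one single-base TSS per gene, strand-aware.

    ``genes`` is an iterable of (chrom, start, end, name, strand); the TSS
    is the minimum start on '+' and the maximum end - 1 on '-'. For genes
    with several records the most upstream TSS wins.
    """
    best: dict[str, tuple[str, int, str]] = {}
    for chrom, start, end, name, strand in genes:
        if strand not in ("+", "-"):
            raise ValueError(f"gene {name}: strand must be '+' or '-'")
        tss = start if strand == "+" else end - 1
        if name not in best:
            best[name] = (chrom, tss, strand)
        else:
            _, cur, cur_strand = best[name]
            if (strand == "+" and tss < cur) or (strand == "-" and tss > cur):
                best[name] = (chrom, tss, strand)
    return [GenomicInterval(c, t, t + 1) for c, t, _ in best.values()]
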