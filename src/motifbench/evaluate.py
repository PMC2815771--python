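"""Performance and quality measures for motif predictions.

Given a benchmark dataset with embedded ground-truth sites and one or
more prediction runs, this module computes:

* site-level confusion (a predicted site is a true positive when it
  covers at least half the length of an embedded site on the same
  sequence);
* PPV = TP/(TP+FP) and Sens = TP/(TP+FN), plus the species-dependent
  variants spPPV/spSens restricted to the reference species;
* recovery (does the predicted motif model match the model built from
  the embedded sites, with a quality-based rescue rule);
* per-test summaries: D1/R1 (runs with any output), recovery rate RR,
  and quality-measure means over the runs with a correct output;
* the F-value, the harmonic mean of spPPV and spSens.

All quality measures are percentages.  A measure whose denominator is
zero is *undefined* (``None``) and excluded from means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import REFERENCE_SPECIES, BenchmarkDataset, GroundTruthSite
from .motif import (
    DEFAULT_MATCH_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    WeightMatrix,
    build_wm_from_sites,
    compare_motifs,
)


@dataclass(frozen=True)
class PredictedSite:
    """One predicted site, 0-based half-open coordinates."""

    species: str
    gene: str
    start: int
    end: int
    sequence: str = ""
    strand: str = "+"
    score: float | None = None

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"invalid site interval [{self.start}, {self.end})")


@dataclass
class PredictionRun:
    """One finder invocation on one dataset."""

    dataset_id: str
    finder_id: str
    has_output: bool
    sites: list[PredictedSite] = field(default_factory=list)
    model: WeightMatrix | None = None

    def __post_init__(self):
        if not self.has_output and self.sites:
            raise ValueError("a run without output cannot carry predicted sites")


@dataclass
class QualityMeasures:
    ppv: float | None
    sens: float | None
    sp_ppv: float | None
    sp_sens: float | None


@dataclass
class TestSummary:
    __test__ = False  # "Test" prefix is domain vocabulary, not a pytest class

    n_runs: int
    d1_or_r1: int
    rr: float | None
    ppv: float | None
    sens: float | None
    sp_ppv: float | None
    sp_sens: float | None
    f_value: float | None


def match_sites(
    predicted: list[PredictedSite],
    truth: list[GroundTruthSite],
) -> tuple[set[PredictedSite], set[PredictedSite], set[GroundTruthSite]]:
    """Classify sites into (TP, FP, FN) by the half-length overlap rule.

    A predicted site is a true positive iff, on the same (species,
    gene), its overlap with its best-overlapping truth site is at least
    half that truth site's length (ties on overlap broken by leftmost
    truth start).  A truth site is a false negative iff no predicted
    site half-covers it.  Strand is ignored.
    """
    tp: set[PredictedSite] = set()
    fp: set[PredictedSite] = set()
    covered: set[GroundTruthSite] = set()
    truth_by_key: dict[tuple[str, str], list[GroundTruthSite]] = {}
    for t in truth:
        truth_by_key.setdefault((t.species, t.gene), []).append(t)
    for p in predicted:
        candidates = truth_by_key.get((p.species, p.gene), [])
        best, best_overlap = None, 0
        for t in sorted(candidates, key=lambda t: t.start):
            overlap = min(p.end, t.end) - max(p.start, t.start)
            if overlap > best_overlap:
                best, best_overlap = t, overlap
        if best is not None and best_overlap >= best.length / 2.0:
            tp.add(p)
            covered.add(best)
        else:
            fp.add(p)
    # a truth site is recovered if ANY prediction half-covers it, even a
    # prediction whose own best-overlap partner was a different site
    fn = set()
    for t in truth:
        if t in covered:
            continue
        if any(
            (p.species, p.gene) == (t.species, t.gene)
            and min(p.end, t.end) - max(p.start, t.start) >= t.length / 2.0
            for p in predicted
        ):
            continue
        fn.add(t)
    return tp, fp, fn


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def quality_measures(
    tp: set[PredictedSite],
    fp: set[PredictedSite],
    fn: set[GroundTruthSite],
    reference_species: str = REFERENCE_SPECIES,
) -> QualityMeasures:
    """PPV/Sens and their reference-species-restricted variants, in
    percent; ``None`` where the denominator is zero."""
    n_tp, n_fp, n_fn = len(tp), len(fp), len(fn)
    sp_tp = sum(1 for s in tp if s.species == reference_species)
    sp_fp = sum(1 for s in fp if s.species == reference_species)
    sp_fn = sum(1 for s in fn if s.species == reference_species)
    return QualityMeasures(
        ppv=_pct(n_tp, n_tp + n_fp),
        sens=_pct(n_tp, n_tp + n_fn),
        sp_ppv=_pct(sp_tp, sp_tp + sp_fp),
        sp_sens=_pct(sp_tp, sp_tp + sp_fn),
    )


def correct_model(dataset: BenchmarkDataset, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> WeightMatrix:
    """The 'correct' motif model: the WM built from the embedded sites."""
    if not dataset.sites:
        raise ValueError("dataset has no embedded sites")
    seqs = [
        dataset.record(s.species, s.gene).sequence[s.start : s.end] for s in dataset.sites
    ]
    return build_wm_from_sites(seqs, pseudocount=pseudocount, label="correct")


def recovery(
    run: PredictionRun,
    correct: WeightMatrix,
    dataset: BenchmarkDataset,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    reference_species: str = REFERENCE_SPECIES,
) -> int:
    """1 if the run's predicted motif model matches the correct model.

    The predicted model is the run's own model if present, else the WM
    built from its predicted sites.  A model that fails the comparison
    threshold is rescued when both spPPV and spSens exceed 50%, or
    either exceeds 80% (strict inequalities).
    """
    if not run.has_output:
        raise ValueError("recovery is undefined for a run without output")
    predicted_model = run.model
    if predicted_model is None and run.sites:
        seqs = [s.sequence for s in run.sites]
        if all(seqs) and len({len(s) for s in seqs}) == 1:
            predicted_model = build_wm_from_sites(seqs)
    if predicted_model is not None:
        _, is_match = compare_motifs(predicted_model, correct, threshold)
        if is_match:
            return 1
    tp, fp, fn = match_sites(run.sites, dataset.sites)
    q = quality_measures(tp, fp, fn, reference_species)
    sp_ppv = q.sp_ppv if q.sp_ppv is not None else 0.0
    sp_sens = q.sp_sens if q.sp_sens is not None else 0.0
    if (sp_ppv > 50.0 and sp_sens > 50.0) or sp_ppv > 80.0 or sp_sens > 80.0:
        return 1
    return 0


def f_value(sp_ppv: float, sp_sens: float) -> float:
    """Harmonic mean of spPPV and spSens (percent); 0 when both are 0."""
    if sp_ppv + sp_sens == 0:
        return 0.0
    return 2.0 * sp_ppv * sp_sens / (sp_ppv + sp_sens)


def f_difference(summary_combined: TestSummary, summary_baseline: TestSummary) -> float | None:
    """F-value gain of one search space over a baseline space."""
    if summary_combined.f_value is None or summary_baseline.f_value is None:
        return None
    return summary_combined.f_value - summary_baseline.f_value


def _mean_or_none(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def summarize_test(
    runs: list[PredictionRun],
    datasets: dict[str, BenchmarkDataset] | BenchmarkDataset,
    mode: str = "per-dataset",
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    reference_species: str = REFERENCE_SPECIES,
) -> TestSummary:
    """Aggregate runs of one test configuration.

    ``mode="per-dataset"``: each run is one dataset (D1 counts datasets
    with an output).  ``mode="per-run"``: repeated runs on a single
    dataset (R1 counts runs with an output).  RR is the percentage of
    outputs whose model matches the dataset's correct model; quality
    means are taken over the correct outputs only; F is the harmonic
    mean of the mean spPPV and mean spSens.
    """
    if not runs:
        raise ValueError("no runs to summarize")
    if mode not in ("per-dataset", "per-run"):
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(datasets, BenchmarkDataset):
        datasets = {datasets.dataset_id: datasets}
    d1 = sum(1 for r in runs if r.has_output)
    qualities: list[QualityMeasures] = []
    n_correct = 0
    for run in runs:
        if not run.has_output:
            continue
        ds = datasets[run.dataset_id]
        rec = recovery(run, correct_model(ds), ds, threshold, reference_species)
        if rec == 1:
            n_correct += 1
            tp, fp, fn = match_sites(run.sites, ds.sites)
            qualities.append(quality_measures(tp, fp, fn, reference_species))
    rr = None if d1 == 0 else 100.0 * n_correct / d1
    mean_sp_ppv = _mean_or_none([q.sp_ppv for q in qualities])
    mean_sp_sens = _mean_or_none([q.sp_sens for q in qualities])
    f = (
        f_value(mean_sp_ppv, mean_sp_sens)
        if mean_sp_ppv is not None and mean_sp_sens is not None
        else None
    )
    return TestSummary(
        n_runs=len(runs),
        d1_or_r1=d1,
        rr=rr,
        ppv=_mean_or_none([q.ppv for q in qualities]),
        sens=_mean_or_none([q.sens for q in qualities]),
        sp_ppv=mean_sp_ppv,
        sp_sens=mean_sp_sens,
        f_value=f,
    )


# ---------------------------------------------------------------------------
# predictions TSV

_TSV_COLUMNS = [
    "dataset_id", "finder_id", "species", "gene",
    "start", "end", "strand", "site_sequence", "score",
]


def write_predictions(runs: list[PredictionRun], path: str | Path) -> None:
    """Write runs to the predictions TSV (0-based half-open coords).
    A run without sites still contributes a presence marker row when it
    has output; runs without output are recorded with start=end=-1 so
    D1/R1 bookkeeping survives the round trip."""
    rows = []
    for run in runs:
        if not run.has_output:
            rows.append([run.dataset_id, run.finder_id, "", "", -1, -1, "", "", ""])
            continue
        for s in run.sites:
            rows.append([
                run.dataset_id, run.finder_id, s.species, s.gene,
                s.start, s.end, s.strand, s.sequence,
                "" if s.score is None else s.score,
            ])
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> list[PredictionRun]:
    """Read a predictions TSV back into runs (grouped by dataset and
    finder, in file order)."""
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "gene": str}, keep_default_na=False)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"predictions TSV lacks columns: {sorted(missing)}")
    runs: dict[tuple[str, str], PredictionRun] = {}
    for _, row in df.iterrows():
        key = (str(row.dataset_id), str(row.finder_id))
        start, end = int(row.start), int(row.end)
        if key not in runs:
            runs[key] = PredictionRun(key[0], key[1], has_output=start >= 0)
        if start < 0:
            continue
        runs[key].has_output = True
        runs[key].sites.append(
            PredictedSite(
                species=str(row.species), gene=str(row.gene),
                start=start, end=end,
                sequence=str(row.site_sequence),
                strand=str(row.strand) or "+",
                score=float(row.score) if str(row.score) != "" else None,
            )
        )
    return list(runs.values())


_NA = "NA"


def _fmt(v: float | None) -> str:
    return _NA if v is None else f"{v:.2f}"


def write_report(summaries: dict[str, TestSummary], path: str | Path,
                 baselines: dict[str, str] | None = None) -> None:
    """Write a per-test report TSV mirroring the benchmark table layout
    (D1/R1, RR, PPV, Sens, spPPV, spSens, F), with an F-difference
    column against each test's designated baseline test if given."""
    baselines = baselines or {}
    rows = []
    for name, s in summaries.items():
        f_diff = None
        base = baselines.get(name)
        if base is not None and base in summaries:
            f_diff = f_difference(s, summaries[base])
        rows.append([
            name, s.n_runs, s.d1_or_r1, _fmt(s.rr), _fmt(s.ppv), _fmt(s.sens),
            _fmt(s.sp_ppv), _fmt(s.sp_sens), _fmt(s.f_value), _fmt(f_diff),
        ])
    df = pd.DataFrame(
        rows,
        columns=["test", "n_runs", "D1_R1", "RR", "PPV", "Sens", "spPPV", "spSens", "F", "F_diff"],
    )
    df.to_csv(path, sep="\t", index=False)
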