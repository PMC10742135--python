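"""Ranked-frequency classification of CeD from gluten-specific CDR3 catalogs.

The model works on *ranked clonotype frequencies*: with the clonotypes of a
sample ordered from most to least frequent, the i-th clonotype gets
r_i = i / N, where N is the number of clonotypes.  This normalises for
sequencing depth and clone-size differences across samples; abundant clones
have r close to 0, rare ones close to 1, and the threshold t = 1 reduces to
a plain presence/absence test.

Training selects the *coeliac-predictive* subset of a published
gluten-specific CDR3 catalog: sequences whose ranked frequency is at or
below a threshold t in at least one CeD training sample and in none of the
controls (a control occurrence ranked above t does not disqualify).  A
sample is classified CeD iff it contains at least one predictive sequence
at r <= t on any model chain.  The threshold is tuned to maximise
resubstitution accuracy, breaking plateau ties by the narrowest bootstrap
accuracy CI and then by the plateau median.

Also here: leave-one-out cross-validation, bootstrap confidence intervals,
independent-cohort evaluation, candidate-sequence prioritisation, and
motif (position frequency) matrices for logo plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    Cohort,
    EvaluationResult,
    PredictiveModel,
    Repertoire,
    SequenceCatalog,
)

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(round(0.1 * k, 1) for k in range(1, 11))

_EPS = 1e-12  # guards float comparisons of accuracies / thresholds


# ---------------------------------------------------------------------------
# Ranked frequencies
# ---------------------------------------------------------------------------

@dataclass
class RankedRepertoire:
    """Ranked clonotype frequencies of one repertoire.

    ``clone_r`` maps each (V, J, CDR3) key to r_i = i/N; ``cdr3_r`` gives
    each distinct CDR3 the minimum r over clones sharing it (catalog
    matching is at the CDR3-amino-acid level only).
    """

    sample_id: str
    chain: str
    n_clones: int
    clone_r: dict[tuple[str, str, str], float]
    cdr3_r: dict[str, float]


def rank_frequencies(rep: Repertoire) -> RankedRepertoire:
    """Assign ranked frequencies r_i = i/N by descending clone count.

    Count ties are broken deterministically by ascending
    (cdr3_aa, v_segment, j_segment), so the ranking is invariant to the
    input order of the clone table.  An empty repertoire yields an empty
    ranking with a warning.
    """
    if rep.n_clones == 0:
        logger.warning("repertoire %s is empty; empty ranking", rep.sample_id)
        return RankedRepertoire(rep.sample_id, rep.chain, 0, {}, {})
    ordered = sorted(
        rep.clones, key=lambda c: (-c.count, c.cdr3_aa, c.v_segment, c.j_segment)
    )
    n = len(ordered)
    clone_r = {c.key: (i + 1) / n for i, c in enumerate(ordered)}
    cdr3_r: dict[str, float] = {}
    for c in ordered:
        r = clone_r[c.key]
        if c.cdr3_aa not in cdr3_r or r < cdr3_r[c.cdr3_aa]:
            cdr3_r[c.cdr3_aa] = r
    return RankedRepertoire(rep.sample_id, rep.chain, n, clone_r, cdr3_r)


def catalog_hits(
    ranked: RankedRepertoire, catalog: SequenceCatalog, t: float
) -> set[str]:
    """Catalog CDR3s of the ranking's chain present at r <= t."""
    seqs = catalog.sequences(ranked.chain)
    return {s for s in seqs if ranked.cdr3_r.get(s, 2.0) <= t}


# ---------------------------------------------------------------------------
# Cohort-level rank matrices (shared machinery for training / CV / bootstrap)
# ---------------------------------------------------------------------------

class CohortRanking:
    """Per-chain matrices of catalog-sequence ranked frequencies.

    ``r[chain]`` is a (n_sequences, n_samples) float array; absent sequences
    (or a missing chain for an individual) are NaN.  Columns are indexed by
    individual (sample_id), linking chains of one person.
    """

    def __init__(self, cohort: Cohort, catalog: SequenceCatalog,
                 chains: Sequence[str]):
        self.chains = tuple(chains)
        self.sample_ids = cohort.sample_ids(chains=self.chains)
        if not self.sample_ids:
            raise ValueError(
                f"cohort {cohort.name} has no repertoires for chains {self.chains}"
            )
        self.labels = np.array(
            [cohort.labels()[s] for s in self.sample_ids], dtype=object
        )
        self.seqs: dict[str, list[str]] = {}
        self.r: dict[str, np.ndarray] = {}
        self.ranked: dict[tuple[str, str], RankedRepertoire] = {}
        col = {s: i for i, s in enumerate(self.sample_ids)}
        for ch in self.chains:
            seqs = catalog.sequences(ch)
            self.seqs[ch] = seqs
            mat = np.full((len(seqs), len(self.sample_ids)), np.nan)
            idx = {s: i for i, s in enumerate(seqs)}
            for rep in cohort.repertoires:
                if rep.chain != ch:
                    continue
                rk = rank_frequencies(rep)
                self.ranked[(rep.sample_id, ch)] = rk
                j = col[rep.sample_id]
                for seq, rv in rk.cdr3_r.items():
                    i = idx.get(seq)
                    if i is not None:
                        mat[i, j] = rv
            self.r[ch] = mat

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def class_indices(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.flatnonzero(self.labels == "CeD"),
            np.flatnonzero(self.labels == "control"),
        )

    def hit_matrix(self, chain: str, t: float) -> np.ndarray:
        """Boolean (sequence x sample) presence at r <= t (NaN -> False)."""
        with np.errstate(invalid="ignore"):
            return self.r[chain] <= t + _EPS

    def select_masks(
        self, t: float, ced_cols: np.ndarray, ctrl_cols: np.ndarray
    ) -> dict[str, np.ndarray]:
        """Per-chain boolean masks of coeliac-predictive sequences given the
        training columns: a hit at r <= t in >= 1 CeD column and in no
        control column."""
        masks = {}
        for ch in self.chains:
            h = self.hit_matrix(ch, t)
            masks[ch] = h[:, ced_cols].any(axis=1) & ~h[:, ctrl_cols].any(axis=1)
        return masks

    def classify_cols(
        self, t: float, masks: Mapping[str, np.ndarray], cols: np.ndarray
    ) -> np.ndarray:
        """Boolean CeD predictions for the given sample columns: any selected
        sequence present at r <= t on any chain."""
        pred = np.zeros(len(cols), dtype=bool)
        for ch in self.chains:
            h = self.hit_matrix(ch, t)[:, cols]
            pred |= (h & masks[ch][:, None]).any(axis=0)
        return pred


def _evaluate_bool(pred_ced: np.ndarray, truth_ced: np.ndarray) -> EvaluationResult:
    tp = int(np.sum(pred_ced & truth_ced))
    fn = int(np.sum(~pred_ced & truth_ced))
    tn = int(np.sum(~pred_ced & ~truth_ced))
    fp = int(np.sum(pred_ced & ~truth_ced))
    return EvaluationResult(tp=tp, fn=fn, tn=tn, fp=fp)


# ---------------------------------------------------------------------------
# Selection / classification / evaluation (public operations)
# ---------------------------------------------------------------------------

def select_predictive(
    train: Cohort, catalog: SequenceCatalog, t: float, chain: str
) -> frozenset[str]:
    """Coeliac-predictive catalog sequences for one chain at threshold t.

    Exactly the catalog CDR3s with ranked frequency <= t in at least one CeD
    training sample and <= t in zero controls; a control occurrence with
    r > t does not disqualify a sequence.
    """
    ranking = CohortRanking(train, catalog, chains=(chain,))
    ced, ctrl = ranking.class_indices()
    if len(ced) == 0 or len(ctrl) == 0:
        raise ValueError(
            f"training cohort needs >=1 CeD and >=1 control {chain} sample"
        )
    mask = ranking.select_masks(t, ced, ctrl)[chain]
    return frozenset(np.array(ranking.seqs[chain], dtype=object)[mask])


def classify_sample(
    rankings: Mapping[str, RankedRepertoire] | RankedRepertoire,
    model: PredictiveModel,
) -> str:
    """Apply a trained model to one individual's ranking(s).

    ``rankings`` maps chain to the individual's RankedRepertoire (a single
    RankedRepertoire stands for its own chain).  The call must provide at
    least one model chain; the prediction is CeD iff any predictive sequence
    of any available model chain sits at r <= t.
    """
    if isinstance(rankings, RankedRepertoire):
        rankings = {rankings.chain: rankings}
    usable = [ch for ch in model.chains if ch in rankings]
    if not usable:
        raise ValueError(
            f"no ranking provided for any model chain {model.chains}"
        )
    for ch, rk in rankings.items():
        if rk.chain != ch:
            raise ValueError(f"ranking for chain {rk.chain} filed under {ch}")
    if all(rankings[ch].n_clones == 0 for ch in usable):
        logger.warning("empty repertoire(s); classified as control")
        return "control"
    for ch in usable:
        rk = rankings[ch]
        for seq in model.sequences[ch]:
            if rk.cdr3_r.get(seq, 2.0) <= model.threshold + _EPS:
                return "CeD"
    return "control"


def evaluate(predictions: Sequence[str], truth: Sequence[str]) -> EvaluationResult:
    """Confusion counts and measures for aligned CeD/control label vectors."""
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must be aligned and equal length")
    for lab in list(predictions) + list(truth):
        if lab not in ("CeD", "control"):
            raise ValueError(f"labels must be 'CeD' or 'control', got {lab!r}")
    pred = np.array([p == "CeD" for p in predictions])
    tru = np.array([t == "CeD" for t in truth])
    return _evaluate_bool(pred, tru)


# ---------------------------------------------------------------------------
# Threshold optimisation
# ---------------------------------------------------------------------------

@dataclass
class ThresholdScan:
    """Resubstitution performance across a threshold grid, and the
    max-accuracy plateau (all grid members attaining the maximum)."""

    grid: tuple[float, ...]
    results: dict[float, EvaluationResult]
    plateau: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.grid:
            d = self.results[t].as_dict()
            d["threshold"] = t
            d["on_plateau"] = t in self.plateau
            rows.append(d)
        return pd.DataFrame(rows)


def _scan(ranking: CohortRanking, grid: Sequence[float]) -> ThresholdScan:
    ced, ctrl = ranking.class_indices()
    if len(ced) == 0 or len(ctrl) == 0:
        raise ValueError("threshold scan needs both classes in training data")
    train_cols = np.concatenate([ced, ctrl])
    truth = np.isin(train_cols, ced)
    results = {}
    for t in grid:
        masks = ranking.select_masks(t, ced, ctrl)
        pred = ranking.classify_cols(t, masks, train_cols)
        results[t] = _evaluate_bool(pred, truth)
    best = max(results[t].accuracy for t in grid)
    plateau = tuple(t for t in grid if results[t].accuracy >= best - _EPS)
    return ThresholdScan(tuple(grid), results, plateau)


def scan_thresholds(
    train: Cohort,
    catalog: SequenceCatalog,
    grid: Sequence[float] = DEFAULT_GRID,
    chains: Sequence[str] = ("TRA",),
) -> ThresholdScan:
    """Select-and-resubstitute at every grid threshold on the training cohort."""
    if not grid or any(not (0.0 < t <= 1.0) for t in grid):
        raise ValueError("grid must be non-empty with values in (0, 1]")
    return _scan(CohortRanking(train, catalog, chains), grid)


def _bootstrap_measures(
    ranking: CohortRanking, t: float, B: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """B bootstrap replicates of the four measures with per-replicate refit.

    Individuals are resampled with replacement; selection is refit on the
    replicate and evaluated on it (resubstitution within the replicate).
    Replicates with one class only contribute only their defined measures.
    """
    n = ranking.n_samples
    truth_all = ranking.labels == "CeD"
    out = {k: np.full(B, np.nan) for k in
           ("sensitivity", "specificity", "accuracy", "balanced_accuracy")}
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        labs = ranking.labels[idx]
        ced = idx[labs == "CeD"]
        ctrl = idx[labs == "control"]
        if len(ced) == 0 and len(ctrl) == 0:
            continue
        masks = ranking.select_masks(t, ced, ctrl)
        pred = ranking.classify_cols(t, masks, idx)
        res = _evaluate_bool(pred, truth_all[idx])
        for k in out:
            v = getattr(res, k)
            if v is not None:
                out[k][b] = v
    return out


def bootstrap_ci(
    train: Cohort | CohortRanking,
    catalog: Optional[SequenceCatalog],
    t: float,
    chains: Sequence[str] = ("TRA",),
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, tuple[float, float]]:
    """Percentile 95% bootstrap CIs for the evaluation measures at threshold t.

    Training individuals are resampled with replacement B times and the
    predictive set refit per replicate; bounds are the 2.5/97.5 percentiles.
    Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ranking = (
        CohortRanking(train, catalog, chains)
        if isinstance(train, Cohort)
        else train
    )
    rng = np.random.default_rng(seed)
    draws = _bootstrap_measures(ranking, t, B, rng)
    cis = {}
    for k, arr in draws.items():
        vals = arr[~np.isnan(arr)]
        if len(vals) == 0:
            continue
        cis[k] = (
            float(np.percentile(vals, 2.5)),
            float(np.percentile(vals, 97.5)),
        )
    return cis


def choose_threshold(
    scan: ThresholdScan,
    ci_by_threshold: Mapping[float, Mapping[str, tuple[float, float]]],
) -> float:
    """Pick the working threshold from the max-accuracy plateau.

    Preference order: narrowest bootstrap 95% CI for accuracy; remaining
    ties resolved by the median plateau member (lower of two middles).
    """
    plateau = list(scan.plateau)
    if len(plateau) == 1:
        return plateau[0]

    def width(t: float) -> float:
        ci = ci_by_threshold.get(t, {}).get("accuracy")
        return (ci[1] - ci[0]) if ci else np.inf

    best = min(width(t) for t in plateau)
    tied = [t for t in plateau if width(t) <= best + _EPS]
    return tied[(len(tied) - 1) // 2]


@dataclass
class TrainResult:
    model: PredictiveModel
    scan: ThresholdScan
    ci_by_threshold: dict[float, dict[str, tuple[float, float]]]
    evaluation: EvaluationResult  # resubstitution at the chosen threshold


def train_model(
    train: Cohort,
    catalog: SequenceCatalog,
    grid: Sequence[float] = DEFAULT_GRID,
    chains: Sequence[str] = ("TRA",),
    B: int = 1000,
    seed: int = 0,
) -> TrainResult:
    """Full training protocol: threshold scan, bootstrap CIs over the
    plateau, threshold choice, final selection and resubstitution evaluation
    with CIs."""
    ranking = CohortRanking(train, catalog, chains)
    scan = _scan(ranking, grid)
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(scan.plateau))
    cis = {
        t: bootstrap_ci(ranking, None, t, chains, B=B, seed=stream)
        for t, stream in zip(scan.plateau, streams)
    }
    t_opt = choose_threshold(scan, cis)
    ced, ctrl = ranking.class_indices()
    masks = ranking.select_masks(t_opt, ced, ctrl)
    sequences = {
        ch: tuple(sorted(np.array(ranking.seqs[ch], dtype=object)[masks[ch]]))
        for ch in chains
    }
    # per-sequence count of training CeD samples carrying the sequence at r <= t
    training_counts = {}
    for ch in chains:
        h = ranking.hit_matrix(ch, t_opt)[:, ced]
        counts = h.sum(axis=1)
        training_counts[ch] = {
            seq: int(counts[i])
            for i, seq in enumerate(ranking.seqs[ch])
            if masks[ch][i]
        }
    evaluation = scan.results[t_opt]
    evaluation = EvaluationResult(
        tp=evaluation.tp, fn=evaluation.fn, tn=evaluation.tn, fp=evaluation.fp,
        ci=dict(cis.get(t_opt, {})),
    )
    model = PredictiveModel(
        chains=tuple(chains),
        threshold=t_opt,
        sequences=sequences,
        metadata={
            "training_cohort": train.name,
            "grid": list(grid),
            "bootstrap_replicates": B,
            "bootstrap_seed": seed,
            "plateau": list(scan.plateau),
            "training_counts": training_counts,
            "training_evaluation": evaluation.as_dict(),
        },
    )
    return TrainResult(model, scan, cis, evaluation)


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    held_out: str
    truth: str
    prediction: str
    threshold: float
    plateau: tuple[float, ...]
    selected: dict[str, frozenset[str]]


@dataclass
class CrossValReport:
    folds: list[FoldResult]
    pooled: EvaluationResult
    fold_counts: dict[str, dict[str, int]]  # chain -> sequence -> #folds selected
    threshold_range: tuple[float, float]  # union of per-fold plateaus

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def folds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "held_out": f.held_out,
                    "truth": f.truth,
                    "prediction": f.prediction,
                    "threshold": f.threshold,
                    "plateau": ",".join(f"{t:g}" for t in f.plateau),
                    "n_selected": sum(len(s) for s in f.selected.values()),
                }
                for f in self.folds
            ]
        )


def loocv(
    train: Cohort,
    catalog: SequenceCatalog,
    grid: Sequence[float] = DEFAULT_GRID,
    chains: Sequence[str] = ("TRA",),
    B: int = 1000,
    seed: int = 0,
) -> CrossValReport:
    """Leave-one-out cross-validation of the full training protocol.

    Each fold reruns threshold scan, bootstrap-based threshold choice and
    sequence selection on the n-1 remaining individuals, then classifies the
    held-out individual.  Measures are pooled over held-out predictions.
    Folds whose training part loses a class are skipped with a warning.
    """
    ranking = CohortRanking(train, catalog, chains)
    n = ranking.n_samples
    if n < 3:
        raise ValueError("leave-one-out cross-validation needs >= 3 samples")
    ss = np.random.SeedSequence(seed)
    fold_streams = ss.spawn(n)
    folds: list[FoldResult] = []
    fold_counts: dict[str, dict[str, int]] = {ch: {} for ch in chains}
    all_cols = np.arange(n)
    for i in range(n):
        rest = all_cols[all_cols != i]
        labs = ranking.labels[rest]
        ced = rest[labs == "CeD"]
        ctrl = rest[labs == "control"]
        if len(ced) == 0 or len(ctrl) == 0:
            logger.warning(
                "fold %s skipped: training part lost a class", ranking.sample_ids[i]
            )
            continue
        train_cols = np.concatenate([ced, ctrl])
        truth = np.isin(train_cols, ced)
        results = {}
        for t in grid:
            masks = ranking.select_masks(t, ced, ctrl)
            pred = ranking.classify_cols(t, masks, train_cols)
            results[t] = _evaluate_bool(pred, truth)
        best = max(results[t].accuracy for t in grid)
        plateau = tuple(t for t in grid if results[t].accuracy >= best - _EPS)
        sub = _SubsetRanking(ranking, rest)
        streams = fold_streams[i].spawn(len(plateau))
        cis = {
            t: bootstrap_ci(sub, None, t, chains, B=B, seed=stream)
            for t, stream in zip(plateau, streams)
        }
        t_opt = choose_threshold(
            ThresholdScan(tuple(grid), results, plateau), cis
        )
        masks = ranking.select_masks(t_opt, ced, ctrl)
        selected = {}
        for ch in chains:
            sel = frozenset(
                np.array(ranking.seqs[ch], dtype=object)[masks[ch]]
            )
            selected[ch] = sel
            for seq in sel:
                fold_counts[ch][seq] = fold_counts[ch].get(seq, 0) + 1
        pred_i = bool(
            ranking.classify_cols(t_opt, masks, np.array([i]))[0]
        )
        folds.append(
            FoldResult(
                held_out=ranking.sample_ids[i],
                truth=str(ranking.labels[i]),
                prediction="CeD" if pred_i else "control",
                threshold=t_opt,
                plateau=plateau,
                selected=selected,
            )
        )
    scored = [f for f in folds if f.truth in ("CeD", "control")]
    pooled = evaluate([f.prediction for f in scored], [f.truth for f in scored])
    all_plateau = [t for f in folds for t in f.plateau]
    return CrossValReport(
        folds=folds,
        pooled=pooled,
        fold_counts=fold_counts,
        threshold_range=(min(all_plateau), max(all_plateau)),
    )


class _SubsetRanking:
    """Column-subset view of a CohortRanking (used by per-fold bootstraps)."""

    def __init__(self, parent: CohortRanking, cols: np.ndarray):
        self.chains = parent.chains
        self.sample_ids = [parent.sample_ids[c] for c in cols]
        self.labels = parent.labels[cols]
        self.seqs = parent.seqs
        self.r = {ch: parent.r[ch][:, cols] for ch in parent.chains}

    n_samples = CohortRanking.n_samples
    class_indices = CohortRanking.class_indices
    hit_matrix = CohortRanking.hit_matrix
    select_masks = CohortRanking.select_masks
    classify_cols = CohortRanking.classify_cols


# ---------------------------------------------------------------------------
# Independent-cohort testing and sequence prioritisation
# ---------------------------------------------------------------------------

@dataclass
class TestReport:
    predictions: dict[str, str]  # sample_id -> predicted label
    evaluation: Optional[EvaluationResult]  # None if truth labels unknown
    testing_counts: dict[str, dict[str, int]]  # chain -> seq -> #test CeD samples
    confirmed: dict[str, frozenset[str]]  # predictive seqs hit in >=1 test CeD, 0 ctrl


def apply_model(test: Cohort, model: PredictiveModel) -> TestReport:
    """Apply a trained model to an independent cohort, blinded to labels.

    Labels are consulted only after prediction, for evaluation (skipped when
    any truth label is ``unknown``) and for the per-sequence counts of test
    CeD samples carrying each predictive sequence at r <= t.
    """
    present_chains = {rep.chain for rep in test.repertoires}
    missing = [ch for ch in model.chains if ch not in present_chains]
    if missing:
        raise ValueError(f"test cohort lacks model chain(s): {missing}")
    restricted = SequenceCatalog(
        entries=[
            e for e in _model_catalog_entries(model)
        ]
    )
    ranking = CohortRanking(test, restricted, model.chains)
    t = model.threshold
    masks = {
        ch: np.ones(len(ranking.seqs[ch]), dtype=bool) for ch in model.chains
    }
    cols = np.arange(ranking.n_samples)
    pred = ranking.classify_cols(t, masks, cols)
    predictions = {
        s: ("CeD" if p else "control") for s, p in zip(ranking.sample_ids, pred)
    }
    evaluation = None
    labelled = ranking.labels != "unknown"
    if labelled.all():
        evaluation = _evaluate_bool(pred, ranking.labels == "CeD")
    testing_counts: dict[str, dict[str, int]] = {}
    confirmed: dict[str, frozenset[str]] = {}
    ced_cols = np.flatnonzero(ranking.labels == "CeD")
    ctrl_cols = np.flatnonzero(ranking.labels == "control")
    for ch in model.chains:
        h = ranking.hit_matrix(ch, t)
        counts = h[:, ced_cols].sum(axis=1)
        testing_counts[ch] = {
            seq: int(counts[i]) for i, seq in enumerate(ranking.seqs[ch])
        }
        conf = (counts >= 1) & ~h[:, ctrl_cols].any(axis=1)
        confirmed[ch] = frozenset(
            np.array(ranking.seqs[ch], dtype=object)[conf]
        )
    return TestReport(predictions, evaluation, testing_counts, confirmed)


def _model_catalog_entries(model: PredictiveModel):
    from .types import CatalogEntry

    for ch in model.chains:
        for seq in model.sequences[ch]:
            yield CatalogEntry(chain=ch, cdr3_aa=seq)


@dataclass
class RankedSequenceRow:
    rank_label: str
    sequence: str
    training_count: int
    fold_count: int
    testing_count: int


@dataclass
class SequenceRankingTable:
    rows: list[RankedSequenceRow]

    COLUMNS = (
        "Rank",
        "Sequence",
        "Training: Number of CeD Samples",
        "Validation: Number of Cross-Validation Folds",
        "Testing: Number of CeD Samples",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.rank_label, r.sequence, r.training_count, r.fold_count,
                 r.testing_count)
                for r in self.rows
            ],
            columns=list(self.COLUMNS),
        )


def rank_candidate_sequences(
    training_counts: Mapping[str, int],
    fold_counts: Mapping[str, int],
    testing_counts: Mapping[str, int],
) -> SequenceRankingTable:
    """Prioritise candidate sequences by testing-CeD count, then training-CeD
    count (competition ranking; rows tied on both share a rank label
    suffixed '=', and the next rank skips accordingly)."""
    seqs = sorted(
        set(training_counts) | set(fold_counts) | set(testing_counts)
    )
    order = sorted(
        seqs,
        key=lambda s: (-testing_counts.get(s, 0), -training_counts.get(s, 0), s),
    )
    rows: list[RankedSequenceRow] = []
    pos = 0
    while pos < len(order):
        key = (
            testing_counts.get(order[pos], 0),
            training_counts.get(order[pos], 0),
        )
        group = [order[pos]]
        while pos + len(group) < len(order):
            nxt = order[pos + len(group)]
            if (testing_counts.get(nxt, 0), training_counts.get(nxt, 0)) == key:
                group.append(nxt)
            else:
                break
        label = f"{pos + 1}=" if len(group) > 1 else f"{pos + 1}"
        for seq in group:
            rows.append(
                RankedSequenceRow(
                    rank_label=label,
                    sequence=seq,
                    training_count=training_counts.get(seq, 0),
                    fold_count=fold_counts.get(seq, 0),
                    testing_count=testing_counts.get(seq, 0),
                )
            )
        pos += len(group)
    return SequenceRankingTable(rows)


# ---------------------------------------------------------------------------
# Motif matrices and heatmap exports
# ---------------------------------------------------------------------------

AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")


def motif_matrix(sequences: Iterable[str], length: int) -> pd.DataFrame:
    """Position x amino-acid frequency matrix for the sequences of exactly
    the given length (logo-plot input); columns index positions 1..length
    and each position's frequencies sum to 1.  Empty with a warning when no
    sequence has that length."""
    subset = sorted(s for s in sequences if len(s) == length)
    if not subset:
        logger.warning("no sequences of length %d; empty motif matrix", length)
        return pd.DataFrame(index=list(AA_ORDER))
    mat = pd.DataFrame(
        0.0, index=list(AA_ORDER), columns=list(range(1, length + 1))
    )
    for s in subset:
        for pos, aa in enumerate(s, start=1):
            mat.loc[aa, pos] += 1.0
    return mat / len(subset)


def rank_heatmap(
    cohort: Cohort,
    catalog: SequenceCatalog,
    chain: str,
    sequences: Iterable[str],
) -> pd.DataFrame:
    """Sequences x samples matrix of ranked frequencies (NaN = absent),
    the TSV behind the model heatmap figures."""
    ranking = CohortRanking(cohort, catalog, (chain,))
    wanted = list(sequences)
    idx = {s: i for i, s in enumerate(ranking.seqs[chain])}
    data = np.full((len(wanted), ranking.n_samples), np.nan)
    for k, seq in enumerate(wanted):
        if seq in idx:
            data[k] = ranking.r[chain][idx[seq]]
    return pd.DataFrame(data, index=wanted, columns=ranking.sample_ids)
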